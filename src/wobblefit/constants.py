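"""Physical constants used throughout the package.

Gyromagnetic ratios are frozen here, in one place, as ratios relative to
the proton.  Values from the standard CODATA/IUPAC tables.
"""

# gamma(X) / gamma(1H); sign retained (15N precesses in the opposite sense)
GYROMAGNETIC_RATIO_REL_1H: dict[str, float] = {
    "13C": 0.25143,
    "15N": -0.10137,
    "1H": 1.0,
}


def larmor_frequency_hz(nucleus_kind: str, spectrometer_1h_freq_mhz: float) -> float:
    """Larmor frequency (Hz, positive) of *nucleus_kind* on a spectrometer
    whose proton frequency is *spectrometer_1h_freq_mhz* MHz."""
    try:
        ratio = GYROMAGNETIC_RATIO_REL_1H[nucleus_kind]
    except KeyError:
        raise ValueError(f"unknown nucleus kind: {nucleus_kind!r}") from None
    return abs(ratio) * spectrometer_1h_freq_mhz * 1e6
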