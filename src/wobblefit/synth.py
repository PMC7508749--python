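"""Synthetic relaxation-dispersion data with the structure the fits assume.

The generator emulates the measurement chain: for each spin-lock condition
the true R1rho is forward-simulated from an exchange model (eigenvalue
route), relaxation delays are laid out to reach ~70% signal loss within the
nucleus-specific duration cap (60 ms for 13C, 120 ms for 15N), and peak
intensities decay mono-exponentially with multiplicative Gaussian noise.
Reduction then goes through the decay-fitting route, keeping generation and
reduction methodologically independent.

Preset truths cover the three regimes of interest for G.T mismatches at
700 MHz: two-state wobble <-> Watson-Crick-like exchange (p_B a few tenths
of a percent, k_ex ~ 10^3 /s, dw 1-3 ppm for 13C), a second star-topology
"Hoogsteen blowback" process shared across nuclei, and high-pH three-state
wobble/tautomer/anion exchange with 15N dw of tens of ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .bloch import SpinLockCondition, r1rho_grid
from .decay import DecaySeries, fit_monoexponential, reduce_series
from .fitting import FitResult, FitSpec, RDDataset, fit_dispersion, mc_parameter_errors
from .models import ExchangeModel, NucleusChannel

__all__ = [
    "AcquisitionDesign", "SyntheticTruth",
    "design_delays", "default_grid",
    "generate_dataset", "generate_reduced_dataset", "reduce_dataset",
    "recovery_experiment", "RecoveryReport",
    "truth_two_state_tautomer", "truth_star_blowback", "truth_high_ph_star",
]

DURATION_CAPS_S = {"13C": 0.060, "15N": 0.120}


@dataclass
class AcquisitionDesign:
    """Acquisition-design rules for one nucleus type.

    ``max_duration`` defaults to the nucleus-specific cap (60 ms for 13C,
    120 ms for 15N); delays are spaced to lose ``target_loss`` of the signal
    by the last delay.  ``noise_sd`` is the noise amplitude as a fraction of
    the initial intensity; ``noise_model="additive"`` (default) applies it
    as constant-amplitude noise on every point — the thermal peak-height
    noise of NMR spectra — while ``"multiplicative"`` scales it with the
    instantaneous signal.
    """

    nucleus_kind: str
    grid: list[tuple[float, float]] = field(default_factory=list)  # (power, offset) Hz
    n_delays: int = 8
    max_duration: float | None = None
    equilibration_delay: float = 0.005
    target_loss: float = 0.70
    noise_sd: float = 0.02
    noise_model: str = "additive"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_duration is None:
            self.max_duration = DURATION_CAPS_S[self.nucleus_kind]
        if not 3 <= self.n_delays <= 10:
            raise ValueError("n_delays must lie in [3, 10]")
        if self.noise_model not in ("additive", "multiplicative"):
            raise ValueError("noise_model must be 'additive' or 'multiplicative'")
        if not self.grid:
            self.grid = default_grid(self.nucleus_kind)


@dataclass
class SyntheticTruth:
    """The generating exchange model and channels, stored with every
    synthetic dataset so recovery can be scored against it."""

    model: ExchangeModel
    channels: dict[str, NucleusChannel]
    seed: int = 0


def design_delays(r1rho_estimate: float, design: AcquisitionDesign) -> np.ndarray:
    """Equally spaced delays from 0 to min(-ln(1-loss)/R1rho, cap)."""
    if r1rho_estimate <= 0:
        raise ValueError("r1rho_estimate must be positive")
    t_loss = -np.log(1.0 - design.target_loss) / r1rho_estimate
    t_max = min(t_loss, design.max_duration)
    return np.linspace(0.0, t_max, design.n_delays)


def default_grid(nucleus_kind: str,
                 powers: tuple[float, ...] | None = None) -> list[tuple[float, float]]:
    """A documented default spin-lock grid: powers spanning a decade, with
    offsets out to ~+/-3.5x the power and denser near resonance.

    The published measurements used instrument-specific grids; this default
    is config-overridable so real tables can be dropped in.
    """
    if powers is None:
        powers = ((100.0, 200.0, 400.0, 800.0, 1600.0) if nucleus_kind == "15N"
                  else (150.0, 300.0, 600.0, 1200.0, 2400.0, 3600.0))
    grid: list[tuple[float, float]] = []
    # offsets at +/- {0.25, 0.5, 1, 1.5, 2.5, 3.5} x power, plus on-resonance
    rel = np.array([0.25, 0.5, 1.0, 1.5, 2.5, 3.5])
    for w1 in powers:
        offs = np.concatenate([-rel[::-1] * w1, [0.0], rel * w1])
        for o in offs:
            grid.append((float(w1), float(o)))
    return grid


def generate_dataset(truth: SyntheticTruth, design: AcquisitionDesign,
                     nucleus_id: str) -> list[DecaySeries]:
    """Simulate intensity decays for one nucleus over the design grid.

    For each (power, offset): true R1rho from the eigenvalue route, delays
    from :func:`design_delays`, intensities exp(-R1rho t) plus Gaussian
    noise per the design's noise model.  Bit-reproducible for a given
    design seed.
    """
    ch = truth.channels[nucleus_id]
    conds = np.asarray(design.grid, dtype=float)
    rates = r1rho_grid(truth.model, ch, conds)
    rng = np.random.default_rng(design.seed)
    out = []
    for (power, offset), rate in zip(conds, rates):
        delays = design_delays(max(rate, 1e-3), design)
        ideal = np.exp(-rate * delays)
        if design.noise_sd <= 0:
            noisy = ideal
        elif design.noise_model == "additive":
            noisy = ideal + rng.normal(0.0, design.noise_sd, size=ideal.shape)
        else:
            noisy = ideal * (1.0 + rng.normal(0.0, design.noise_sd, size=ideal.shape))
        out.append(DecaySeries(delays=delays, intensities=noisy,
                               condition=SpinLockCondition(power, offset),
                               nucleus_id=nucleus_id))
    return out


def reduce_dataset(series_list: list[DecaySeries], n_mc: int = 100,
                   seed: int = 0, pool_noise: bool = True) -> RDDataset:
    """Reduce a collection of decay series (one nucleus) to an RDDataset.

    With ``pool_noise`` (default), the intensity-noise amplitude is
    estimated once from the pooled mono-exponential residuals of the whole
    grid — the thermal noise of a peak is a property of the spectrum series,
    not of one spin-lock condition — which gives the per-point sigma enough
    degrees of freedom to be well calibrated.  Per-series residual noise is
    used otherwise.
    """
    noise_scale = None
    if pool_noise:
        ss, dof = 0.0, 0
        for s in series_list:
            i0, rate = fit_monoexponential(s)
            resid = s.intensities - i0 * np.exp(-rate * s.delays)
            ss += float(np.sum(resid ** 2))
            dof += max(len(s.delays) - 2, 1)
        noise_scale = np.sqrt(ss / dof)
    points = [reduce_series(s, n_mc=n_mc, seed=seed + k, noise_scale=noise_scale)
              for k, s in enumerate(series_list)]
    return RDDataset.from_points(series_list[0].nucleus_id, points)


def generate_reduced_dataset(truth: SyntheticTruth, design: AcquisitionDesign,
                             nucleus_id: str) -> RDDataset:
    """Shortcut generator: noisy R1rho +/- sigma drawn directly at the
    reduced level (sigma = noise-equivalent fraction of R1rho), skipping the
    decay stage.  Useful for fast model-selection studies."""
    ch = truth.channels[nucleus_id]
    conds = np.asarray(design.grid, dtype=float)
    rates = r1rho_grid(truth.model, ch, conds)
    rng = np.random.default_rng(design.seed)
    sigma = np.maximum(design.noise_sd * np.abs(rates), 1e-3)
    noisy = rates + rng.normal(0.0, sigma)
    return RDDataset(nucleus_id, conds[:, 0], conds[:, 1], noisy, sigma)


# ---------------------------------------------------------------------------
# preset truths (the study regimes, at a 700 MHz spectrometer)

def truth_two_state_tautomer(seed: int = 0) -> SyntheticTruth:
    """Two-state wobble <-> WC-like exchange on one 13C probe:
    p_B = 0.2%, k_ex = 1000 /s, dw = 2 ppm."""
    ch = NucleusChannel(id="T5-C4p", nucleus_kind="13C", r1=2.0, r2=20.0)
    model = ExchangeModel(topology="two_state", p_b=0.002, kex_ab=1000.0,
                          dw_ab={ch.id: 2.0})
    return SyntheticTruth(model=model, channels={ch.id: ch}, seed=seed)


def truth_star_blowback(seed: int = 0) -> SyntheticTruth:
    """Mixed 15N/13C probes sharing wobble->WC-like exchange (state B:
    p_B = 0.2%, k_ex = 1600 /s) plus a common Hoogsteen-blowback process
    (state C: p_C = 0.4%, k_ex = 3000 /s) in a star topology.

    The imino nitrogens carry the large (tens of ppm) shift differences of
    the wobble-to-WC-like transition that anchor the shared populations and
    rates; the sugar carbon senses both processes at the ~2 ppm scale.
    """
    channels = {
        "G15-N1": NucleusChannel(id="G15-N1", nucleus_kind="15N", r1=1.5, r2=6.0),
        "T5-N3": NucleusChannel(id="T5-N3", nucleus_kind="15N", r1=1.5, r2=6.0),
        "T5-C3p": NucleusChannel(id="T5-C3p", nucleus_kind="13C", r1=2.0, r2=20.0),
    }
    model = ExchangeModel(
        topology="star_three_state",
        p_b=0.002, kex_ab=1600.0,
        p_c=0.004, kex_ac=3000.0,
        dw_ab={"G15-N1": 40.0, "T5-N3": -35.0, "T5-C3p": 2.5},
        dw_ac={"G15-N1": 3.0, "T5-N3": 2.0, "T5-C3p": 2.0},
    )
    return SyntheticTruth(model=model, channels=channels, seed=seed)


def truth_high_ph_star(seed: int = 0) -> SyntheticTruth:
    """High-pH three-state star: wobble ground state exchanging with a
    tautomeric state (B: p = 0.075%, k_ex = 4029 /s) and an anionic state
    (C: p = 8.019%, k_ex = 500 /s); two 15N probes with large anion dw and
    one 13C probe whose tautomer dw is weakly determined."""
    channels = {
        "G15-N1": NucleusChannel(id="G15-N1", nucleus_kind="15N", r1=1.5, r2=6.0),
        "T5-N3": NucleusChannel(id="T5-N3", nucleus_kind="15N", r1=1.5, r2=6.0),
        "T5-C4p": NucleusChannel(id="T5-C4p", nucleus_kind="13C", r1=2.0, r2=20.0),
    }
    model = ExchangeModel(
        topology="star_three_state",
        p_b=0.00075, kex_ab=4029.0,
        p_c=0.08019, kex_ac=500.0,
        dw_ab={"G15-N1": 40.0, "T5-N3": -35.0, "T5-C4p": 1.5},
        dw_ac={"G15-N1": 50.0, "T5-N3": -56.0, "T5-C4p": 2.5},
    )
    return SyntheticTruth(model=model, channels=channels, seed=seed)


# ---------------------------------------------------------------------------
# recovery experiments

@dataclass
class RecoveryReport:
    """Scores of a generate -> reduce -> fit round trip against the truth."""

    fit: FitResult
    truth_values: dict[str, float]
    z_scores: dict[str, float]
    bias: dict[str, float]
    poorly_determined: list[str]

    @property
    def max_abs_z(self) -> float:
        return max(abs(z) for z in self.z_scores.values())


def _truth_param_values(truth: SyntheticTruth) -> dict[str, float]:
    m = truth.model
    vals = {"p_b": m.p_b, "kex_ab": m.kex_ab}
    if m.topology != "two_state":
        vals.update({"p_c": m.p_c, "kex_ac": m.kex_ac})
    if m.topology == "triangular_three_state":
        vals["kex_bc"] = m.kex_bc
    for nid, ch in truth.channels.items():
        vals[f"r1:{nid}"] = ch.r1
        vals[f"r2:{nid}"] = ch.r2
        vals[f"dw_ab:{nid}"] = m.dw_ab.get(nid, 0.0)
        if m.topology != "two_state":
            vals[f"dw_ac:{nid}"] = m.dw_ac.get(nid, 0.0)
    return vals


def recovery_experiment(truth: SyntheticTruth, design: AcquisitionDesign,
                        spec: FitSpec, seed: int = 0, n_mc: int = 50,
                        via_decays: bool = True, reduce_n_mc: int = 60,
                        score_params: list[str] | None = None) -> RecoveryReport:
    """Generate a synthetic dataset from *truth*, reduce it, fit it with
    *spec*, estimate MC uncertainties, and score each free parameter as
    z = (estimate - truth) / MC-SD.

    ``score_params`` restricts scoring (e.g. to the shared global
    parameters); by default every free parameter with a truth value and a
    finite uncertainty is scored.
    """
    datasets: dict[str, RDDataset] = {}
    for k, nid in enumerate(truth.channels):
        d = replace(design, nucleus_kind=truth.channels[nid].nucleus_kind,
                    grid=list(design.grid) if design.grid else [],
                    seed=seed + 1000 * k)
        if not d.grid or d.nucleus_kind != design.nucleus_kind:
            d.grid = default_grid(d.nucleus_kind)
        d.max_duration = DURATION_CAPS_S[d.nucleus_kind]
        if via_decays:
            series = generate_dataset(truth, d, nid)
            datasets[nid] = reduce_dataset(series, n_mc=reduce_n_mc,
                                           seed=seed + 7 * k)
        else:
            datasets[nid] = generate_reduced_dataset(truth, d, nid)

    fit = fit_dispersion(datasets, truth.channels, spec)
    mc_parameter_errors(fit, datasets, truth.channels, spec,
                        n_mc=n_mc, seed=seed + 99)

    truth_vals = _truth_param_values(truth)
    names = score_params or [n for n in fit.uncertainties
                             if n in truth_vals and np.isfinite(fit.uncertainties[n])]
    z, bias = {}, {}
    for n in names:
        sd = fit.uncertainties.get(n, np.nan)
        est = fit.params[n]
        bias[n] = est - truth_vals[n]
        z[n] = bias[n] / sd if sd and np.isfinite(sd) and sd > 0 else np.inf
    return RecoveryReport(fit=fit, truth_values=truth_vals, z_scores=z,
                          bias=bias, poorly_determined=fit.poorly_determined())
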