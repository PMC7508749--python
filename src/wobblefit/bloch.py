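"""Bloch–McConnell simulation of off-resonance spin-lock relaxation.

The magnetization of n exchanging states evolves under

    dM/dt = Gamma M,   Gamma = blockdiag(L_i) + K (x) I_3,

where each 3x3 single-state block L_i contains transverse/longitudinal
relaxation, the state-specific resonance offset Omega_i and the spin-lock
amplitude omega_1, and K is the exchange rate matrix acting identically on
the x, y and z components.  The homogeneous form is used (no thermal-
recovery constant): dispersion experiments measure the relative decay of
magnetization prepared at exchange equilibrium, so recovery toward thermal
equilibrium drops out of the mono-exponential decay constant.

Conventions (fixed here, used everywhere):

* spin-lock field along +x with amplitude omega_1 = 2*pi*power;
* resonance offset Omega = omega_obs - omega_rf rotates x into y for
  positive Omega;
* the excited-state offset is Omega_GS + 2*pi*dw*nu_larmor*1e-6;
* all internal frequencies in rad/s; the public surface takes Hz and ppm;
* the tilt angle theta is measured from +z, tan(theta) = omega_1/Omega.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .models import ExchangeModel, NucleusChannel, dw_to_angular, kinetic_rates

__all__ = [
    "SpinLockCondition",
    "EffectiveFieldGeometry",
    "MagnetizationState",
    "build_evolution_matrix",
    "effective_field",
    "initial_magnetization",
    "propagate",
    "r1rho_forward",
    "r1rho_grid",
    "r2eff_transform",
]


@dataclass(frozen=True)
class SpinLockCondition:
    """Spin-lock power (omega_1/2pi, Hz, > 0) and signed carrier offset
    (Omega/2pi, Hz) in the ground-state convention."""

    power: float
    offset: float

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("spin-lock power must be positive")
        if not np.isfinite(self.offset):
            raise ValueError("offset must be finite")


@dataclass(frozen=True)
class EffectiveFieldGeometry:
    """Tilt angle theta (degrees, [0, 180]), effective field magnitude
    omega_eff (rad/s) and per-state offsets (rad/s)."""

    theta: float
    omega_eff: float
    state_offsets: tuple[float, ...]


@dataclass
class MagnetizationState:
    """Stacked per-state (x, y, z) magnetization components at a time point.

    ``vector`` has shape (3n,), ordered (x_1, y_1, z_1, x_2, ...).
    """

    vector: np.ndarray
    time: float = 0.0

    @property
    def per_state(self) -> np.ndarray:
        return self.vector.reshape(-1, 3)


def _state_offsets_rad(model: ExchangeModel, channel: NucleusChannel,
                       sl: SpinLockCondition) -> np.ndarray:
    omega_gs = 2.0 * np.pi * sl.offset
    dw = model.dw_ppm(channel.id)
    return omega_gs + np.array([dw_to_angular(d, channel) for d in dw])


def build_evolution_matrix(model: ExchangeModel, channel: NucleusChannel,
                           sl: SpinLockCondition) -> np.ndarray:
    """Assemble the 3n x 3n homogeneous evolution matrix Gamma."""
    n = model.n_states
    omega1 = 2.0 * np.pi * sl.power
    offsets = _state_offsets_rad(model, channel, sl)
    gamma = np.zeros((3 * n, 3 * n))
    for i in range(n):
        b = 3 * i
        om = offsets[i]
        gamma[b:b + 3, b:b + 3] = [
            [-channel.r2, -om, 0.0],
            [om, -channel.r2, -omega1],
            [0.0, omega1, -channel.r1],
        ]
    K = kinetic_rates(model).rate_matrix()
    gamma += np.kron(K, np.eye(3))
    if not np.all(np.isfinite(gamma)):
        raise ValueError("non-finite entries in evolution matrix")
    return gamma


def effective_field(channel: NucleusChannel, sl: SpinLockCondition,
                    model: ExchangeModel, mode: str = "auto",
                    auto_threshold: float = 1.0) -> EffectiveFieldGeometry:
    """Geometry of the effective field used to tilt and detect magnetization.

    ``mode`` selects the reference offset: ``"gs"`` uses the ground-state
    offset; ``"avg"`` the population-weighted mean offset; ``"auto"``
    switches to the average-state offset when kex_ab >= auto_threshold *
    |dw_ab| (in rad/s) — alignment along the averaged resonance is only
    meaningful when exchange is fast enough to average the shifts.
    """
    if mode not in ("gs", "avg", "auto"):
        raise ValueError(f"unknown alignment mode: {mode!r}")
    offsets = _state_offsets_rad(model, channel, sl)
    omega1 = 2.0 * np.pi * sl.power
    if mode == "auto":
        dw_ab = abs(dw_to_angular(model.dw_ppm(channel.id)[1], channel))
        mode = "avg" if model.kex_ab >= auto_threshold * dw_ab else "gs"
    if mode == "gs":
        omega_ref = offsets[0]
    else:
        omega_ref = float(np.dot(model.populations, offsets))
    if omega1 == 0.0 and omega_ref == 0.0:
        raise ValueError("effective field direction undefined (omega1 = Omega = 0)")
    theta = np.degrees(np.arctan2(omega1, omega_ref))
    omega_eff = float(np.hypot(omega1, omega_ref))
    return EffectiveFieldGeometry(theta=float(theta), omega_eff=omega_eff,
                                  state_offsets=tuple(offsets))


def initial_magnetization(model: ExchangeModel, channel: NucleusChannel,
                          sl: SpinLockCondition,
                          mode: str = "auto") -> MagnetizationState:
    """Equilibrium-population magnetization tilted along the effective field.

    Each state carries p_i * (sin(theta), 0, cos(theta)); the population-
    weighted total has unit norm.  This models the experimental scheme in
    which longitudinal magnetization equilibrates between ground and excited
    states before being tilted onto the effective-field axis.
    """
    geo = effective_field(channel, sl, model, mode=mode)
    th = np.radians(geo.theta)
    axis = np.array([np.sin(th), 0.0, np.cos(th)])
    vec = np.concatenate([p * axis for p in model.populations])
    return MagnetizationState(vector=vec, time=0.0)


def propagate(matrix: np.ndarray, m0: MagnetizationState, t: float) -> MagnetizationState:
    """Evolve magnetization for time *t*: exp(Gamma t) m0."""
    if t < 0:
        raise ValueError("propagation time must be non-negative")
    if not np.all(np.isfinite(matrix)):
        raise ValueError("non-finite evolution matrix")
    if t == 0.0:
        return MagnetizationState(vector=m0.vector.copy(), time=m0.time)
    vec = expm(matrix * t) @ m0.vector
    return MagnetizationState(vector=vec, time=m0.time + t)


def _detection_axis(model: ExchangeModel, theta_deg: float) -> np.ndarray:
    th = np.radians(theta_deg)
    axis = np.array([np.sin(th), 0.0, np.cos(th)])
    return np.tile(axis, model.n_states)


def r2eff_transform(r1rho: float | np.ndarray, r1: float,
                    theta: float | np.ndarray):
    """(R2 + Rex) = (R1rho - R1 cos^2 theta) / sin^2 theta, theta in degrees."""
    th = np.radians(theta)
    s2 = np.sin(th) ** 2
    if np.any(s2 == 0):
        raise ValueError("r2eff undefined at theta = 0 or 180 degrees")
    return (r1rho - r1 * np.cos(th) ** 2) / s2


def _r1rho_eigen_batch(gammas: np.ndarray, m0s: np.ndarray,
                       axes: np.ndarray) -> np.ndarray:
    """Vectorized eigenvalue-route R1rho for stacked matrices.

    For each condition, expand the tilted initial magnetization in the
    eigenbasis of Gamma and return -Re(lambda) of the mode carrying the
    largest amplitude along the detection axis.  Selecting by overlap (not
    merely by smallest |Re|) avoids latching onto spurious slow modes in
    three-state systems.
    """
    w, v = np.linalg.eig(gammas)                       # (m, 3n), (m, 3n, 3n)
    coeff = np.linalg.solve(v, m0s[..., None])[..., 0]  # (m, 3n)
    proj = np.einsum("mk,mkl->ml", axes, v)             # (m, 3n)
    amp = np.abs(coeff * proj)
    sel = np.argmax(amp, axis=1)
    lam = np.take_along_axis(w, sel[:, None], axis=1)[:, 0]
    return -np.real(lam)


def r1rho_grid(model: ExchangeModel, channel: NucleusChannel,
               conditions: list[SpinLockCondition] | np.ndarray,
               mode: str = "auto") -> np.ndarray:
    """Eigenvalue-route R1rho for many spin-lock conditions at once.

    ``conditions`` may be a list of :class:`SpinLockCondition` or an
    (m, 2) array of (power_hz, offset_hz) rows.  This is the fast path the
    dispersion fitter calls inside chi-square evaluation.
    """
    if isinstance(conditions, (list, tuple)) and conditions \
            and isinstance(conditions[0], SpinLockCondition):
        arr = np.asarray([(c.power, c.offset) for c in conditions], dtype=float)
    else:
        arr = np.asarray(conditions, dtype=float)
    m = arr.shape[0]
    n = model.n_states
    omega1 = 2.0 * np.pi * arr[:, 0]
    omega_gs = 2.0 * np.pi * arr[:, 1]
    dw_rad = np.array([dw_to_angular(d, channel) for d in model.dw_ppm(channel.id)])
    offsets = omega_gs[:, None] + dw_rad[None, :]      # (m, n)

    gammas = np.zeros((m, 3 * n, 3 * n))
    for i in range(n):
        b = 3 * i
        gammas[:, b + 0, b + 0] = -channel.r2
        gammas[:, b + 0, b + 1] = -offsets[:, i]
        gammas[:, b + 1, b + 0] = offsets[:, i]
        gammas[:, b + 1, b + 1] = -channel.r2
        gammas[:, b + 1, b + 2] = -omega1
        gammas[:, b + 2, b + 1] = omega1
        gammas[:, b + 2, b + 2] = -channel.r1
    K3 = np.kron(kinetic_rates(model).rate_matrix(), np.eye(3))
    gammas += K3[None, :, :]

    # reference offset for tilt/detection per condition
    if mode == "auto":
        mode = "avg" if model.kex_ab >= abs(dw_rad[1]) else "gs"
    if mode == "gs":
        omega_ref = offsets[:, 0]
    elif mode == "avg":
        omega_ref = offsets @ model.populations
    else:
        raise ValueError(f"unknown alignment mode: {mode!r}")
    theta = np.arctan2(omega1, omega_ref)
    axis = np.zeros((m, 3 * n))
    m0s = np.zeros((m, 3 * n))
    pops = model.populations
    for i in range(n):
        axis[:, 3 * i + 0] = np.sin(theta)
        axis[:, 3 * i + 2] = np.cos(theta)
        m0s[:, 3 * i + 0] = pops[i] * np.sin(theta)
        m0s[:, 3 * i + 2] = pops[i] * np.cos(theta)
    return _r1rho_eigen_batch(gammas, m0s, axis)


def r1rho_forward(model: ExchangeModel, channel: NucleusChannel,
                  sl: SpinLockCondition, delays: np.ndarray | None = None,
                  method: str = "eigenvalue", mode: str = "auto") -> float:
    """Forward-simulated R1rho (s^-1) for one spin-lock condition.

    ``method="eigenvalue"`` returns the decay rate of the spin-locked
    eigenmode; ``method="decay_fit"`` propagates the tilted magnetization
    over *delays*, projects each time point onto the initial effective-field
    axis and fits a mono-exponential — mirroring how experimental data are
    reduced.  The two routes agree to within 1% over standard grids.
    """
    geo = effective_field(channel, sl, model, mode=mode)
    gamma = build_evolution_matrix(model, channel, sl)
    m0 = initial_magnetization(model, channel, sl, mode=mode)
    axis = _detection_axis(model, geo.theta)

    if method == "eigenvalue":
        return float(_r1rho_eigen_batch(gamma[None], m0.vector[None], axis[None])[0])
    if method != "decay_fit":
        raise ValueError(f"unknown method: {method!r}")

    if delays is None:
        est = float(_r1rho_eigen_batch(gamma[None], m0.vector[None], axis[None])[0])
        est = max(est, 1e-3)
        delays = np.linspace(0.0, 1.2039728 / est, 8)   # ~70% loss
    delays = np.asarray(delays, dtype=float)

    # diagonalize once; propagate all delays together
    w, v = np.linalg.eig(gamma)
    c = np.linalg.solve(v, m0.vector.astype(complex))
    signal = np.real((v @ (c[:, None] * np.exp(w[:, None] * delays[None, :]))).T @ axis)
    if np.any(np.diff(signal) > 1e-9 * max(abs(signal[0]), 1e-30)):
        warnings.warn("projected decay is non-monotonic (oscillatory regime)",
                      RuntimeWarning, stacklevel=2)
    from .decay import fit_monoexponential  # local import avoids a cycle
    _, rate = fit_monoexponential(delays, signal)
    return float(rate)
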