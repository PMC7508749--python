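"""Chemical-exchange model containers and rate/unit conversions.

An exchange model describes a sparsely populated excited state (or two)
interconverting with a dominant ground state.  Topologies:

* ``two_state``            A <-> B
* ``star_three_state``     B <-> A <-> C   (excited states connected only
                           through the ground state)
* ``triangular_three_state``  A, B, C all pairwise connected

Populations and exchange rates (k_ex = k_forward + k_backward per pair) are
the fitted thermodynamic/kinetic observables; microscopic first-order rate
constants follow from detailed balance.  Chemical-shift differences Δω are
carried per nucleus in ppm and converted to angular frequency only inside
the relaxation engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import larmor_frequency_hz

TOPOLOGIES = ("two_state", "star_three_state", "triangular_three_state")

# state indices: 0 = A (ground), 1 = B, 2 = C
STATE_LABELS = ("A", "B", "C")


@dataclass(frozen=True)
class NucleusChannel:
    """One observed spin: identity, field, ground-state shift and intrinsic
    relaxation rates.

    Parameters
    ----------
    id : str
        Label such as ``"T5-C4p"`` or ``"G15-N1"``.
    nucleus_kind : {"13C", "15N"}
    spectrometer_1h_freq : float
        Proton Larmor frequency of the spectrometer in MHz (e.g. 700.0).
    gs_shift : float
        Ground-state chemical shift in ppm (used only for reporting).
    r1, r2 : float
        Intrinsic longitudinal / transverse relaxation rates, s^-1, >= 0.
    """

    id: str
    nucleus_kind: str
    spectrometer_1h_freq: float = 700.0
    gs_shift: float = 0.0
    r1: float = 2.0
    r2: float = 20.0

    def __post_init__(self) -> None:
        if self.nucleus_kind not in ("13C", "15N"):
            raise ValueError(f"unknown nucleus kind: {self.nucleus_kind!r}")
        if self.r1 < 0 or self.r2 < 0:
            raise ValueError("relaxation rates must be non-negative")
        if self.spectrometer_1h_freq <= 0:
            raise ValueError("spectrometer frequency must be positive")

    @property
    def larmor_hz(self) -> float:
        """Larmor frequency of the observed nucleus, Hz (positive)."""
        return larmor_frequency_hz(self.nucleus_kind, self.spectrometer_1h_freq)


@dataclass
class ExchangeModel:
    """Exchange topology, populations, rates and per-nucleus shift differences.

    ``dw_ab`` / ``dw_ac`` map nucleus id -> Δω in ppm (excited minus ground).
    Invariants: 0 < p_b < 0.5, 0 <= p_c < 0.5, p_b + p_c < 1; a two-state
    model has p_c = kex_ac = kex_bc = 0; a star topology has kex_bc = 0.
    """

    topology: str
    p_b: float
    kex_ab: float
    p_c: float = 0.0
    kex_ac: float = 0.0
    kex_bc: float = 0.0
    dw_ab: dict[str, float] = field(default_factory=dict)
    dw_ac: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology: {self.topology!r}")
        if not 0.0 < self.p_b < 0.5:
            raise ValueError("p_b must lie in (0, 0.5)")
        if not 0.0 <= self.p_c < 0.5:
            raise ValueError("p_c must lie in [0, 0.5)")
        if self.p_b + self.p_c >= 1.0:
            raise ValueError("p_b + p_c must be < 1")
        if self.kex_ab <= 0:
            raise ValueError("kex_ab must be positive")
        if self.topology == "two_state":
            if self.p_c != 0 or self.kex_ac != 0 or self.kex_bc != 0:
                raise ValueError("two-state model must have p_c = kex_ac = kex_bc = 0")
        else:
            if self.kex_ac <= 0:
                raise ValueError("three-state model requires kex_ac > 0")
            if self.topology == "star_three_state" and self.kex_bc != 0:
                raise ValueError("star topology must have kex_bc = 0")
            if self.topology == "triangular_three_state" and self.kex_bc <= 0:
                raise ValueError("triangular topology requires kex_bc > 0")

    @property
    def n_states(self) -> int:
        return 2 if self.topology == "two_state" else 3

    @property
    def p_a(self) -> float:
        """Ground-state population, 1 - p_b - p_c."""
        return 1.0 - self.p_b - self.p_c

    @property
    def populations(self) -> np.ndarray:
        p = np.array([self.p_a, self.p_b, self.p_c])
        return p[: self.n_states]

    def dw_ppm(self, nucleus_id: str) -> np.ndarray:
        """Per-state Δω in ppm relative to the ground state, shape (n_states,)."""
        out = np.zeros(self.n_states)
        out[1] = self.dw_ab.get(nucleus_id, 0.0)
        if self.n_states == 3:
            out[2] = self.dw_ac.get(nucleus_id, 0.0)
        return out


@dataclass(frozen=True)
class RateSet:
    """Microscopic first-order rate constants per connected state pair.

    ``rates[(i, j)]`` is the rate constant for the i -> j transition in s^-1.
    Detailed balance, k_ij * p_i = k_ji * p_j, holds by construction, and
    k_ij + k_ji equals k_ex for that pair.
    """

    n_states: int
    rates: dict[tuple[int, int], float]

    def rate_matrix(self) -> np.ndarray:
        """Exchange rate matrix K (n x n) acting on population-scaled
        magnetization: dM/dt = K M, with K[j, i] = k_{i->j} for i != j and
        zero column sums (conservation)."""
        K = np.zeros((self.n_states, self.n_states))
        for (i, j), k in self.rates.items():
            K[j, i] += k
            K[i, i] -= k
        return K

    def kex(self, i: int, j: int) -> float:
        """Pair exchange rate k_ex = k_ij + k_ji."""
        return self.rates.get((i, j), 0.0) + self.rates.get((j, i), 0.0)


def kinetic_rates(model: ExchangeModel) -> RateSet:
    """Split each pair's k_ex into forward/backward microscopic constants.

    For a connected pair (i, j), k_{i->j} = p_j / (p_i + p_j) * k_ex and
    k_{j->i} = p_i / (p_i + p_j) * k_ex, which satisfies detailed balance
    and reduces to k_1 = p_B k_ex, k_-1 = p_A k_ex for two-state exchange
    (p_A + p_B = 1).  The stationary distribution of the resulting rate
    matrix is exactly the model's population vector.
    """
    p = np.array([model.p_a, model.p_b, model.p_c])
    pairs: list[tuple[int, int, float]] = [(0, 1, model.kex_ab)]
    if model.topology in ("star_three_state", "triangular_three_state"):
        pairs.append((0, 2, model.kex_ac))
    if model.topology == "triangular_three_state":
        pairs.append((1, 2, model.kex_bc))

    rates: dict[tuple[int, int], float] = {}
    for i, j, kex in pairs:
        if kex <= 0:
            raise ValueError(f"kex for connected pair ({i},{j}) must be positive")
        tot = p[i] + p[j]
        rates[(i, j)] = p[j] / tot * kex
        rates[(j, i)] = p[i] / tot * kex
    return RateSet(n_states=model.n_states, rates=rates)


def dw_to_angular(dw_ppm: float, channel: NucleusChannel) -> float:
    """Convert a chemical-shift difference in ppm to rad s^-1 for *channel*.

    Returns 2*pi * dw * nu_larmor * 1e-6 with the sign of *dw* preserved.
    """
    return 2.0 * np.pi * dw_ppm * channel.larmor_hz * 1e-6


def model_from_rates(rates: RateSet, topology: str,
                     dw_ab: dict[str, float] | None = None,
                     dw_ac: dict[str, float] | None = None) -> ExchangeModel:
    """Reconstruct populations and pair k_ex values from microscopic rates
    (inverse of :func:`kinetic_rates`); populations come from the stationary
    distribution of the rate matrix."""
    K = rates.rate_matrix()
    w, v = np.linalg.eig(K)
    k0 = int(np.argmin(np.abs(w)))
    pop = np.real(v[:, k0])
    pop = pop / pop.sum()
    return ExchangeModel(
        topology=topology,
        p_b=float(pop[1]),
        p_c=float(pop[2]) if rates.n_states == 3 else 0.0,
        kex_ab=rates.kex(0, 1),
        kex_ac=rates.kex(0, 2) if rates.n_states == 3 else 0.0,
        kex_bc=rates.kex(1, 2) if topology == "triangular_three_state" else 0.0,
        dw_ab=dw_ab or {},
        dw_ac=dw_ac or {},
    )
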