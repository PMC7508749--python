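"""Fitting R1rho dispersion grids to chemical-exchange models.

A fit minimizes the sigma-weighted chi-square

    chi2 = sum_i ((R1rho_meas,i - R1rho_calc,i) / sigma_i)^2

over all (spin-lock power, offset) combinations of one or more nuclei,
where R1rho_calc comes from the numerical Bloch-McConnell engine.
Thermodynamic/kinetic parameters (populations, exchange rates) are shared
across nuclei; R1, R2 and the chemical-shift differences are per-nucleus.
Any parameter may instead be fixed — e.g. a "blowback" exchange process
(a neighboring pair's Watson-Crick to Hoogsteen flipping sensed passively
by the mismatch) pinned from an upstream two-state fit of a reporter
nucleus.

Because these objective surfaces are multimodal (the sign of dw, the
p_b * dw trade-off), fits run from several seeded Latin-hypercube starts
and keep the best optimum.  Parameter uncertainties come from a parametric
Monte-Carlo scheme; competing topologies are ranked by Akaike and Bayesian
information-criterion weights.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
import pandas as pd
from scipy.stats import qmc

from .bloch import r1rho_grid, r2eff_transform
from .models import ExchangeModel, NucleusChannel

__all__ = [
    "RDDataset", "FitSpec", "FitResult",
    "chi_square", "fit_dispersion", "mc_parameter_errors",
    "compare_topologies", "pka_from_population",
]


@dataclass
class RDDataset:
    """Reduced dispersion data for one nucleus: R1rho +/- sigma on a grid
    of (power, offset) conditions, all in Hz / s^-1."""

    nucleus_id: str
    power: np.ndarray
    offset: np.ndarray
    r1rho: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.offset = np.asarray(self.offset, dtype=float)
        self.r1rho = np.asarray(self.r1rho, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = len(self.power)
        if not (len(self.offset) == len(self.r1rho) == len(self.sigma) == n):
            raise ValueError("power/offset/r1rho/sigma must have equal length")
        if np.any(self.sigma <= 0):
            raise ValueError("all sigma must be positive")

    @classmethod
    def from_points(cls, nucleus_id: str, points) -> "RDDataset":
        return cls(
            nucleus_id=nucleus_id,
            power=[p.condition.power for p in points],
            offset=[p.condition.offset for p in points],
            r1rho=[p.r1rho for p in points],
            sigma=[p.sigma for p in points],
        )

    @property
    def conditions(self) -> np.ndarray:
        """(m, 2) array of (power_hz, offset_hz)."""
        return np.column_stack([self.power, self.offset])

    @property
    def n_points(self) -> int:
        return len(self.power)


@dataclass
class FitSpec:
    """What to fit and how.

    Canonical parameter names: global ``p_b``, ``p_c``, ``kex_ab``,
    ``kex_ac``, ``kex_bc`` (shared across nuclei by construction) and
    per-nucleus ``r1:<id>``, ``r2:<id>``, ``dw_ab:<id>``, ``dw_ac:<id>``.
    Every parameter of the chosen topology is free unless listed in
    ``fixed``; ``initial`` and ``bounds`` override the defaults.
    """

    topology: str
    fixed: dict[str, float] = field(default_factory=dict)
    initial: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    alignment_mode: str = "auto"
    n_starts: int = 10
    seed: int = 0
    max_nfev: int = 5000
    explore_nfev: int = 250      # evaluation budget per multi-start probe
    n_polish: int = 2            # best probes refined with the full budget
    chi2_tol: float = 1e-8
    check_dw_sign: bool = True


@dataclass
class FitResult:
    """Best-fit parameters (canonical names), chi-square, diagnostics and
    back-calculated profiles; MC uncertainties and information-criterion
    weights are filled in by the respective routines."""

    topology: str
    params: dict[str, float]
    chi2: float
    n_points: int
    n_free: int
    profiles: pd.DataFrame
    success: bool = True
    message: str = ""
    seed: int = 0
    uncertainties: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    aic: float | None = None
    bic: float | None = None
    aic_weight: float | None = None
    bic_weight: float | None = None
    start_chi2: list[float] = field(default_factory=list)

    @property
    def reduced_chi2(self) -> float:
        return self.chi2 / max(self.n_points - self.n_free, 1)

    def poorly_determined(self) -> list[str]:
        """Parameters whose 95% MC interval includes zero (sign/magnitude
        not established by the data) — typically dw of a state whose small
        population and fast exchange contribute little to the profile."""
        out = []
        for name, sd in self.uncertainties.items():
            est = self.params.get(name, 0.0)
            if name.startswith("dw") and 1.96 * sd >= abs(est):
                out.append(name)
        return out


# ---------------------------------------------------------------------------
# parameter bookkeeping

def _safe(name: str) -> str:
    return re.sub(r"[^0-9a-zA-Z_]", "_", name.replace(":", "__"))


def _param_names(topology: str, nucleus_ids) -> list[str]:
    names = ["p_b", "kex_ab"]
    if topology in ("star_three_state", "triangular_three_state"):
        names += ["p_c", "kex_ac"]
    if topology == "triangular_three_state":
        names += ["kex_bc"]
    for nid in nucleus_ids:
        names += [f"r1:{nid}", f"r2:{nid}", f"dw_ab:{nid}"]
        if topology != "two_state":
            names += [f"dw_ac:{nid}"]
    return names


def _default_bound(name: str, channels: dict[str, NucleusChannel]):
    if name in ("p_b", "p_c"):
        return (1e-7, 0.499)
    if name == "kex_bc":
        return (1e-2, 5e4)
    if name.startswith("kex"):
        return (1.0, 5e4)
    if name.startswith("r1:"):
        return (1e-2, 50.0)
    if name.startswith("r2:"):
        return (1e-1, 500.0)
    if name.startswith("dw"):
        nid = name.split(":", 1)[1]
        span = 30.0 if channels[nid].nucleus_kind == "13C" else 100.0
        return (-span, span)
    raise KeyError(name)


def _default_initial(name: str, channels, datasets):
    if name == "p_b":
        return 2e-3
    if name == "p_c":
        return 5e-3
    if name.startswith("kex"):
        return 2000.0
    if name.startswith("r1:"):
        return 1.5
    if name.startswith("r2:"):
        nid = name.split(":", 1)[1]
        return max(float(np.min(datasets[nid].r1rho)), 1.0)
    if name.startswith("dw"):
        nid = name.split(":", 1)[1]
        return 2.0 if channels[nid].nucleus_kind == "13C" else 20.0
    raise KeyError(name)


def _sampling_box(name: str, channels):
    """Box the Latin-hypercube start sampler draws from (narrower than the
    hard bounds; log scale for positive scale parameters)."""
    if name in ("p_b", "p_c"):
        return ("log", 1e-4, 0.2)
    if name.startswith("kex"):
        return ("log", 100.0, 2e4)
    if name.startswith("r1:"):
        return ("lin", 0.5, 5.0)
    if name.startswith("r2:"):
        return ("lin", 5.0, 60.0)
    if name.startswith("dw"):
        nid = name.split(":", 1)[1]
        span = 5.0 if channels[nid].nucleus_kind == "13C" else 60.0
        return ("lin", -span, span)
    raise KeyError(name)


def _model_from_values(topology: str, vals: dict[str, float],
                       nucleus_ids) -> ExchangeModel:
    three = topology != "two_state"
    return ExchangeModel(
        topology=topology,
        p_b=vals["p_b"],
        kex_ab=vals["kex_ab"],
        p_c=vals.get("p_c", 0.0) if three else 0.0,
        kex_ac=vals.get("kex_ac", 0.0) if three else 0.0,
        kex_bc=vals.get("kex_bc", 0.0) if topology == "triangular_three_state" else 0.0,
        dw_ab={nid: vals[f"dw_ab:{nid}"] for nid in nucleus_ids},
        dw_ac={nid: vals.get(f"dw_ac:{nid}", 0.0) for nid in nucleus_ids},
    )


def _channel_with_rates(base: NucleusChannel, vals: dict[str, float]) -> NucleusChannel:
    return replace(base, r1=vals[f"r1:{base.id}"], r2=vals[f"r2:{base.id}"])


# ---------------------------------------------------------------------------
# chi-square

def chi_square(model: ExchangeModel, channels: dict[str, NucleusChannel],
               datasets: dict[str, RDDataset], mode: str = "auto") -> float:
    """Sigma-weighted chi-square of *model* against reduced data.

    Summation runs over every spin-lock power/offset combination of every
    nucleus; each channel's R1/R2 are taken from the channel objects.
    """
    total = 0.0
    for nid, ds in datasets.items():
        if nid not in channels:
            raise KeyError(f"no channel for nucleus {nid!r}")
        calc = r1rho_grid(model, channels[nid], ds.conditions, mode=mode)
        total += float(np.sum(((ds.r1rho - calc) / ds.sigma) ** 2))
    return total


def _residual_vector(vals: dict[str, float], topology: str,
                     channels, datasets, mode: str) -> np.ndarray:
    try:
        model = _model_from_values(topology, vals, list(datasets))
    except ValueError:
        return np.full(sum(d.n_points for d in datasets.values()), 1e6)
    out = []
    for nid, ds in datasets.items():
        ch = _channel_with_rates(channels[nid], vals)
        try:
            calc = r1rho_grid(model, ch, ds.conditions, mode=mode)
        except np.linalg.LinAlgError:
            calc = np.full(ds.n_points, np.inf)
        res = (calc - ds.r1rho) / ds.sigma
        out.append(np.where(np.isfinite(res), res, 1e6))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# fitting

def _build_lm_params(names, spec: FitSpec, channels, datasets) -> lmfit.Parameters:
    pars = lmfit.Parameters()
    for name in names:
        lo, hi = spec.bounds.get(name, _default_bound(name, channels))
        if name in spec.fixed:
            pars.add(_safe(name), value=spec.fixed[name], vary=False)
        else:
            val = spec.initial.get(name, _default_initial(name, channels, datasets))
            val = min(max(val, lo), hi)
            pars.add(_safe(name), value=val, min=lo, max=hi)
    return pars


def _start_values(names, spec: FitSpec, channels, datasets) -> list[dict[str, float]]:
    """First start = user/default initial values; the rest Latin-hypercube
    samples of the free parameters, seeded."""
    free = [n for n in names if n not in spec.fixed]
    starts = [{}]
    if spec.n_starts > 1 and free:
        sampler = qmc.LatinHypercube(d=len(free), seed=spec.seed)
        u = sampler.random(n=spec.n_starts - 1)
        for row in u:
            s = {}
            for j, name in enumerate(free):
                kind, lo, hi = _sampling_box(name, channels)
                blo, bhi = spec.bounds.get(name, _default_bound(name, channels))
                if kind == "log":
                    v = 10 ** (np.log10(lo) + row[j] * (np.log10(hi) - np.log10(lo)))
                else:
                    v = lo + row[j] * (hi - lo)
                s[name] = min(max(v, blo), bhi)
            starts.append(s)
    return starts


def _minimize_from(pars: lmfit.Parameters, start: dict[str, float], topology,
                   channels, datasets, spec: FitSpec,
                   max_nfev: int | None = None):
    p = pars.copy()
    for name, val in start.items():
        sp = p[_safe(name)]
        sp.value = min(max(val, sp.min), sp.max)

    canonical = _param_names(topology, list(datasets))

    def obj(lp):
        vals = {n: lp[_safe(n)].value for n in canonical}
        return _residual_vector(vals, topology, channels, datasets,
                                spec.alignment_mode)

    # parameters span many decades (populations ~1e-3, rates ~1e3):
    # jacobian-based scaling and a generous finite-difference step keep
    # the trust-region steps well conditioned
    out = lmfit.minimize(obj, p, method="least_squares",
                         max_nfev=spec.max_nfev if max_nfev is None else max_nfev,
                         ftol=spec.chi2_tol, xtol=1e-10, gtol=1e-10,
                         x_scale="jac", diff_step=1e-5)
    return out


def fit_dispersion(datasets: dict[str, RDDataset],
                   channels: dict[str, NucleusChannel],
                   spec: FitSpec) -> FitResult:
    """Fit one or several nuclei to an exchange model.

    With a single dataset this is an individual fit; with several, the
    populations and exchange rates are global (shared) while R1, R2 and dw
    stay per-nucleus.  Runs ``spec.n_starts`` seeded starts and returns the
    best optimum with back-calculated profiles.
    """
    if not datasets:
        raise ValueError("no datasets to fit")
    for nid in datasets:
        if nid not in channels:
            raise KeyError(f"no channel for nucleus {nid!r}")
    n_powers = len({float(p) for ds in datasets.values() for p in ds.power})
    if n_powers < 2:
        warnings.warn("fewer than 2 spin-lock powers: exchange parameters "
                      "may not be identifiable", stacklevel=2)

    names = _param_names(spec.topology, list(datasets))
    pars = _build_lm_params(names, spec, channels, datasets)

    if all(n in spec.fixed for n in names):
        # nothing to optimize: evaluate chi-square as-is
        vals = dict(spec.fixed)
        res = _residual_vector(vals, spec.topology, channels, datasets,
                               spec.alignment_mode)
        n_points = sum(ds.n_points for ds in datasets.values())
        return FitResult(topology=spec.topology, params=vals,
                         chi2=float(np.sum(res ** 2)), n_points=n_points,
                         n_free=0,
                         profiles=back_calculate_profiles(
                             vals, spec.topology, channels, datasets,
                             spec.alignment_mode),
                         seed=spec.seed)

    starts = _start_values(names, spec, channels, datasets)

    # stage 1: cheap probes from every start; stage 2: full-budget polish
    # of the most promising endpoints
    probes = []
    start_chi2 = []
    for start in starts:
        try:
            out = _minimize_from(pars, start, spec.topology, channels, datasets,
                                 spec, max_nfev=spec.explore_nfev)
        except Exception:
            start_chi2.append(np.inf)
            continue
        start_chi2.append(float(out.chisqr))
        probes.append(out)
    if not probes:
        raise RuntimeError("all multi-start fits failed to converge")

    probes.sort(key=lambda o: o.chisqr)
    best = None
    for probe in probes[:max(spec.n_polish, 1)]:
        endpoint = {n: probe.params[_safe(n)].value for n in names}
        try:
            out = _minimize_from(pars, endpoint, spec.topology, channels,
                                 datasets, spec)
        except Exception:
            continue
        if best is None or out.chisqr < best.chisqr:
            best = out
    if best is None:
        best = probes[0]

    vals = {n: best.params[_safe(n)].value for n in names}
    flags = []

    if spec.check_dw_sign and not all(f"dw_ab:{nid}" in spec.fixed for nid in datasets):
        flipped = dict(vals)
        for nid in datasets:
            flipped[f"dw_ab:{nid}"] = -flipped[f"dw_ab:{nid}"]
        try:
            out2 = _minimize_from(pars, flipped, spec.topology, channels,
                                  datasets, spec)
            if abs(out2.chisqr - best.chisqr) < 1.0:
                flags.append("dw_sign_degenerate")
            if out2.chisqr < best.chisqr:
                best = out2
                vals = {n: best.params[_safe(n)].value for n in names}
        except Exception:
            pass

    n_points = sum(ds.n_points for ds in datasets.values())
    n_free = sum(1 for n in names if n not in spec.fixed)
    profiles = back_calculate_profiles(vals, spec.topology, channels, datasets,
                                       spec.alignment_mode)
    return FitResult(
        topology=spec.topology,
        params=vals,
        chi2=float(best.chisqr),
        n_points=n_points,
        n_free=n_free,
        profiles=profiles,
        success=bool(best.success),
        message=str(getattr(best, "message", "")),
        seed=spec.seed,
        flags=flags,
        start_chi2=start_chi2,
    )


def back_calculate_profiles(vals: dict[str, float], topology: str,
                            channels, datasets, mode: str = "auto") -> pd.DataFrame:
    """Back-calculated R1rho and (R2+Rex) per condition, for plotting
    dispersion profiles as (R2+Rex) versus Omega/2pi."""
    model = _model_from_values(topology, vals, list(datasets))
    rows = []
    for nid, ds in datasets.items():
        ch = _channel_with_rates(channels[nid], vals)
        calc = r1rho_grid(model, ch, ds.conditions, mode=mode)
        # tilt angle in the ground-state convention for reporting
        theta = np.degrees(np.arctan2(2 * np.pi * ds.power, 2 * np.pi * ds.offset))
        with np.errstate(divide="ignore", invalid="ignore"):
            r2eff = r2eff_transform(calc, ch.r1, theta)
        for k in range(ds.n_points):
            rows.append((nid, ds.power[k], ds.offset[k], theta[k],
                         calc[k], r2eff[k]))
    return pd.DataFrame(rows, columns=["nucleus", "power_hz", "offset_hz",
                                       "theta_deg", "r1rho_calc", "r2eff_calc"])


# ---------------------------------------------------------------------------
# Monte-Carlo parameter uncertainties

def mc_parameter_errors(fit: FitResult, datasets: dict[str, RDDataset],
                        channels: dict[str, NucleusChannel], spec: FitSpec,
                        n_mc: int = 50, seed: int = 0,
                        center: str = "calc") -> dict[str, float]:
    """Parametric Monte-Carlo uncertainties for a converged fit.

    Draws *n_mc* synthetic datasets with each point ~ Normal(center, sigma)
    — center either the back-calculated value (``"calc"``) or the measured
    one (``"meas"``) — refits each from the best-fit start (single start),
    and reports the standard deviation of the refit parameters.  The result
    is stored on ``fit.uncertainties``; parameters whose 95% interval
    includes zero are flagged via :meth:`FitResult.poorly_determined`.
    """
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")
    if center not in ("calc", "meas"):
        raise ValueError("center must be 'calc' or 'meas'")
    rng = np.random.default_rng(seed)
    names = _param_names(spec.topology, list(datasets))
    free = [n for n in names if n not in spec.fixed]

    centers = {}
    prof = fit.profiles
    for nid, ds in datasets.items():
        if center == "calc":
            sub = prof[prof["nucleus"] == nid]
            centers[nid] = sub["r1rho_calc"].to_numpy()
        else:
            centers[nid] = ds.r1rho

    single = replace(spec, n_starts=1, initial=dict(fit.params),
                     check_dw_sign=False, seed=spec.seed)
    pars = _build_lm_params(names, single, channels, datasets)

    samples = {n: [] for n in free}
    for _ in range(n_mc):
        fake = {}
        for nid, ds in datasets.items():
            noisy = centers[nid] + rng.normal(0.0, ds.sigma)
            fake[nid] = RDDataset(nid, ds.power, ds.offset, noisy, ds.sigma)
        try:
            out = _minimize_from(pars, dict(fit.params), spec.topology,
                                 channels, fake, single)
        except Exception:
            continue
        for n in free:
            samples[n].append(out.params[_safe(n)].value)

    unc = {n: float(np.std(v, ddof=1)) if len(v) > 1 else np.nan
           for n, v in samples.items()}
    fit.uncertainties = unc
    return unc


# ---------------------------------------------------------------------------
# model selection and pKa

def compare_topologies(fits: dict[str, FitResult]) -> pd.DataFrame:
    """Akaike/Bayesian information-criterion weights over candidate fits.

    With per-point sigma known, AIC = chi2 + 2k and BIC = chi2 + k ln N
    (constant terms cancel in the weights).  Weights are
    w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2) per criterion.  All fits
    must be on identical data (same N).
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    ns = {f.n_points for f in fits.values()}
    if len(ns) != 1:
        raise ValueError("fits compare different data (unequal N)")
    n = ns.pop()

    rows = {}
    for name, f in fits.items():
        aic = f.chi2 + 2.0 * f.n_free
        bic = f.chi2 + f.n_free * np.log(n)
        rows[name] = [f.chi2, f.n_free, aic, bic]
    df = pd.DataFrame(rows, index=["chi2", "k", "aic", "bic"]).T
    for crit in ("aic", "bic"):
        delta = df[crit] - df[crit].min()
        w = np.exp(-delta / 2.0)
        df[f"{crit}_weight"] = w / w.sum()
    for name, f in fits.items():
        f.aic = float(df.loc[name, "aic"])
        f.bic = float(df.loc[name, "bic"])
        f.aic_weight = float(df.loc[name, "aic_weight"])
        f.bic_weight = float(df.loc[name, "bic_weight"])
    return df


def pka_from_population(p_anion: float, ph: float) -> float:
    """pKa from the fitted anionic-state population at a known pH
    (Henderson-Hasselbalch): pKa = pH - log10(p / (1 - p))."""
    if not 0.0 < p_anion < 1.0:
        raise ValueError("population must lie strictly between 0 and 1")
    return ph - np.log10(p_anion / (1.0 - p_anion))
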