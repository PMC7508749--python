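"""File formats: RD tables (CSV), fit reports (JSON + CSV profiles), config.

RD tables hold either raw rows (one intensity per relaxation delay) or
reduced rows (R1rho +/- sigma per spin-lock condition); the two row kinds
may not be mixed within one dataset_id.  All frequencies are Hz, delays
seconds, and angles degrees at the file boundary; angular frequencies in
rad/s never leave the library.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import __version__
from .bloch import SpinLockCondition
from .decay import DecaySeries
from .fitting import FitResult, FitSpec, RDDataset
from .models import NucleusChannel

__all__ = ["RDTable", "read_rd_table", "write_decays_csv", "write_reduced_csv",
           "write_fit_report", "read_fit_report", "load_config", "spec_from_config"]

RAW_COLUMNS = ["dataset_id", "nucleus_id", "nucleus_kind", "field_MHz",
               "power_Hz", "offset_Hz", "delay_s", "intensity"]
REDUCED_COLUMNS = ["dataset_id", "nucleus_id", "nucleus_kind", "field_MHz",
                   "power_Hz", "offset_Hz", "r1rho", "sigma"]


@dataclass
class RDTable:
    """Parsed RD table: raw decays and/or reduced datasets per
    (dataset_id, nucleus_id), plus channel metadata per nucleus."""

    raw: dict[tuple[str, str], list[DecaySeries]] = field(default_factory=dict)
    reduced: dict[tuple[str, str], RDDataset] = field(default_factory=dict)
    channels: dict[str, NucleusChannel] = field(default_factory=dict)


def _check_columns(df: pd.DataFrame, path) -> str:
    cols = set(df.columns)
    if cols == set(RAW_COLUMNS):
        return "raw"
    if cols == set(REDUCED_COLUMNS):
        return "reduced"
    if {"r1rho"} & cols and "sigma" not in cols:
        raise ValueError(f"{path}: reduced rows must carry a sigma column")
    raise ValueError(f"{path}: unknown column set {sorted(cols)}")


def read_rd_table(path) -> RDTable:
    """Read an RD table CSV ('#' comment lines ignored); returns typed,
    unit-checked datasets with the row count preserved."""
    df = pd.read_csv(path, comment="#")
    kind = _check_columns(df, path)
    table = RDTable()
    for nid, sub in df.groupby("nucleus_id", sort=False):
        kinds = sub["nucleus_kind"].unique()
        fields = sub["field_MHz"].unique()
        if len(kinds) != 1 or len(fields) != 1:
            raise ValueError(f"{path}: inconsistent nucleus_kind/field for {nid}")
        table.channels[str(nid)] = NucleusChannel(
            id=str(nid), nucleus_kind=str(kinds[0]),
            spectrometer_1h_freq=float(fields[0]))

    if kind == "raw":
        for (did, nid, power, offset), sub in df.groupby(
                ["dataset_id", "nucleus_id", "power_Hz", "offset_Hz"], sort=False):
            sub = sub.sort_values("delay_s")
            if sub["delay_s"].duplicated().any():
                raise ValueError(f"{path}: duplicate delay rows for "
                                 f"{did}/{nid} at ({power}, {offset})")
            series = DecaySeries(
                delays=sub["delay_s"].to_numpy(),
                intensities=sub["intensity"].to_numpy(),
                condition=SpinLockCondition(float(power), float(offset)),
                nucleus_id=str(nid))
            table.raw.setdefault((str(did), str(nid)), []).append(series)
    else:
        for (did, nid), sub in df.groupby(["dataset_id", "nucleus_id"], sort=False):
            table.reduced[(str(did), str(nid))] = RDDataset(
                nucleus_id=str(nid),
                power=sub["power_Hz"].to_numpy(),
                offset=sub["offset_Hz"].to_numpy(),
                r1rho=sub["r1rho"].to_numpy(),
                sigma=sub["sigma"].to_numpy())
    return table


def write_decays_csv(path, decays: dict[tuple[str, str], list[DecaySeries]],
                     channels: dict[str, NucleusChannel]) -> None:
    rows = []
    for (did, nid), series_list in decays.items():
        ch = channels[nid]
        for s in series_list:
            for t, y in zip(s.delays, s.intensities):
                rows.append((did, nid, ch.nucleus_kind, ch.spectrometer_1h_freq,
                             s.condition.power, s.condition.offset, t, y))
    pd.DataFrame(rows, columns=RAW_COLUMNS).to_csv(path, index=False)


def write_reduced_csv(path, datasets: dict[tuple[str, str], RDDataset],
                      channels: dict[str, NucleusChannel]) -> None:
    rows = []
    for (did, nid), ds in datasets.items():
        ch = channels[nid]
        for k in range(ds.n_points):
            rows.append((did, nid, ch.nucleus_kind, ch.spectrometer_1h_freq,
                         ds.power[k], ds.offset[k], ds.r1rho[k], ds.sigma[k]))
    pd.DataFrame(rows, columns=REDUCED_COLUMNS).to_csv(path, index=False)


def write_fit_report(fit: FitResult, path, seed: int | None = None) -> None:
    """JSON report (parameters, uncertainties, chi2, N, k, criterion
    weights, version, seed) plus a CSV companion with the back-calculated
    profiles at ``<path>.profiles.csv``."""
    payload = {
        "software": {"name": "wobblefit", "version": __version__},
        "seed": fit.seed if seed is None else seed,
        "topology": fit.topology,
        "params": fit.params,
        "uncertainties": fit.uncertainties,
        "chi2": fit.chi2,
        "reduced_chi2": fit.reduced_chi2,
        "n_points": fit.n_points,
        "n_free": fit.n_free,
        "success": fit.success,
        "message": fit.message,
        "flags": fit.flags,
        "poorly_determined": fit.poorly_determined(),
        "aic": fit.aic, "bic": fit.bic,
        "aic_weight": fit.aic_weight, "bic_weight": fit.bic_weight,
    }
    path = str(path)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    fit.profiles.to_csv(path + ".profiles.csv", index=False)


def read_fit_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration."""
    text = open(path).read()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def spec_from_config(cfg: dict, seed: int | None = None) -> FitSpec:
    """Build a :class:`FitSpec` from a config mapping.

    Recognized keys: topology (required), fixed, initial, bounds,
    alignment_mode, n_starts, seed, max_nfev.
    """
    known = {"topology", "fixed", "initial", "bounds", "alignment_mode",
             "n_starts", "seed", "max_nfev"}
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    bounds = {k: tuple(v) for k, v in cfg.get("bounds", {}).items()}
    return FitSpec(
        topology=cfg["topology"],
        fixed={k: float(v) for k, v in cfg.get("fixed", {}).items()},
        initial={k: float(v) for k, v in cfg.get("initial", {}).items()},
        bounds=bounds,
        alignment_mode=cfg.get("alignment_mode", "auto"),
        n_starts=int(cfg.get("n_starts", 10)),
        seed=int(cfg.get("seed", 0)) if seed is None else seed,
        max_nfev=int(cfg.get("max_nfev", 5000)),
    )
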