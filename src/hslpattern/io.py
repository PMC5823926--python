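"""Readers/writers, run configuration and reproducible end-to-end pipelines.

Two CSV dialects are supported for plate data:

long (one row per measurement), with the condition columns carried per row::

    time_min,well,replicate,genotype,iptg_mM,arabinose_mM,c6_uM,c12_uM,channel,value

wide (one column per well/channel pair, named ``<well>|<channel>``)::

    time_min,W00R0|OD600,W00R0|CFP,...

Wide files carry the per-well conditions in a JSON sidecar written next to
the CSV (suffix ``.meta.json``), which also records the seed and parameter
hash of the run.  Concentrations are serialized in uM for the HSLs and mM
for IPTG/arabinose.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gatecheck, hierarchy, patternscan, ratiometrics
from .circuitsim import (ARABINOSE_LEVELS, C6_LEVELS, C12_LEVELS, IPTG_LEVELS,
                         PARAMETER_SET_NAMES, Condition, GridSpec,
                         MembraneSeries, PlateTimeSeries, WellInfo,
                         parameter_set, params_hash, sender_grid,
                         simulate_membrane, simulate_plate)

__all__ = ["RunConfig", "read_plate_csv", "write_plate_csv",
           "write_membrane_csv", "read_membrane_csv", "run_pipeline",
           "PIPELINES"]

try:
    _VERSION = version("hslpattern")
except PackageNotFoundError:  # pragma: no cover - not installed
    _VERSION = "unknown"

_CHANNELS = ("OD600", "CFP", "YFP", "RFP")
_COND_COLS = {"iptg_mM": "iptg", "arabinose_mM": "arabinose",
              "c6_uM": "c6", "c12_uM": "c12"}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    pipeline: str
    seed: int = 0
    parameter_set: str = "and_rbs250"
    replicates: int = 3
    out_dir: str = "results"
    formats: tuple[str, ...] = ("csv", "json")
    log_level: str = "INFO"

    @staticmethod
    def from_file(path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yml", ".yaml") \
                else json.load(fh)
        return RunConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "formats" in raw:
            raw = dict(raw, formats=tuple(raw["formats"]))
        return RunConfig(**raw)


# --------------------------------------------------------------------------
# plate CSV dialects
# --------------------------------------------------------------------------

def write_plate_csv(ts: PlateTimeSeries, path: str | Path,
                    dialect: str = "long") -> None:
    path = Path(path)
    meta = {
        "blanks": dict(ts.blanks),
        "meta": {k: v for k, v in ts.meta.items()},
        "wells": [
            {"well": w.well, "genotype": w.genotype, "replicate": w.replicate,
             **{col: getattr(w.condition, attr)
                for col, attr in _COND_COLS.items()}}
            for w in ts.wells
        ],
    }
    if dialect == "long":
        rows = []
        for j, w in enumerate(ts.wells):
            for ch in _CHANNELS:
                for i, t in enumerate(ts.times):
                    rows.append({
                        "time_min": t, "well": w.well,
                        "replicate": w.replicate, "genotype": w.genotype,
                        **{col: getattr(w.condition, attr)
                           for col, attr in _COND_COLS.items()},
                        "channel": ch, "value": ts.values[ch][i, j],
                    })
        pd.DataFrame(rows).to_csv(path, index=False)
    elif dialect == "wide":
        data = {"time_min": ts.times}
        for j, w in enumerate(ts.wells):
            for ch in _CHANNELS:
                data[f"{w.well}|{ch}"] = ts.values[ch][:, j]
        pd.DataFrame(data).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1, default=str)


def _well_from_record(rec: dict) -> WellInfo:
    cond = Condition(**{attr: float(rec.get(col, 0.0))
                        for col, attr in _COND_COLS.items()})
    return WellInfo(well=str(rec["well"]), condition=cond,
                    genotype=str(rec.get("genotype", "unknown")),
                    replicate=int(rec.get("replicate", 0)))


def read_plate_csv(path: str | Path, dialect: str = "long") -> PlateTimeSeries:
    """Parse a plate CSV (long or wide dialect) into a validated series.

    Row order in the long dialect is irrelevant; the time axis must be
    strictly increasing after sorting, and all four channels present.
    """
    path = Path(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    sidecar = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            sidecar = json.load(fh)
    df = pd.read_csv(path)
    if dialect == "long":
        missing = {"time_min", "well", "channel", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"long dialect requires columns {sorted(missing)}")
        times = np.array(sorted(df["time_min"].unique()), dtype=float)
        well_ids = sorted(df["well"].unique())  # canonical well ordering
        wells = []
        for wid in well_ids:
            rec = df[df["well"] == wid].iloc[0].to_dict()
            wells.append(_well_from_record(rec))
        channels = sorted(df["channel"].unique())
        for ch in _CHANNELS:
            if ch not in channels:
                raise ValueError(f"missing channel {ch}")
        values = {}
        piv = df.pivot_table(index="time_min", columns=["well", "channel"],
                             values="value", aggfunc="first")
        piv = piv.sort_index()
        for ch in _CHANNELS:
            arr = np.column_stack([piv[(w.well, ch)].to_numpy() for w in wells])
            values[ch] = arr
    elif dialect == "wide":
        if "time_min" not in df.columns:
            raise ValueError("wide dialect requires a time_min column")
        df = df.sort_values("time_min")
        times = df["time_min"].to_numpy(dtype=float)
        pairs = [c for c in df.columns if "|" in c]
        well_ids = sorted({c.split("|")[0] for c in pairs})
        by_well = {rec["well"]: rec for rec in sidecar.get("wells", [])}
        wells = [_well_from_record(by_well.get(w, {"well": w})) for w in well_ids]
        values = {}
        for ch in _CHANNELS:
            cols = [f"{w}|{ch}" for w in well_ids]
            if any(c not in df.columns for c in cols):
                raise ValueError(f"missing channel {ch}")
            values[ch] = df[cols].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    blanks = {k: float(v) for k, v in sidecar.get("blanks", {}).items()}
    return PlateTimeSeries(times=times, wells=wells, values=values,
                           blanks=blanks, meta=sidecar.get("meta", {}))


def write_membrane_csv(ms: MembraneSeries, path: str | Path) -> None:
    rows = []
    fields = {**{f"hsl_{k}": v for k, v in ms.hsl_fields.items()},
              **ms.channels, "OD600": ms.od}
    for name, arr in fields.items():
        for i, t in enumerate(ms.times):
            for q in range(ms.grid.n_quadrants):
                rows.append({"time_min": t, "quadrant": q + 1,
                             "channel": name, "value": arr[i, q]})
    pd.DataFrame(rows).to_csv(Path(path), index=False)
    meta = {"meta": ms.meta, "diffusion": dict(ms.diffusion),
            "hsl_decay": ms.hsl_decay,
            "genotypes": list(ms.grid.genotypes),
            "boundary_index": ms.grid.boundary_index}
    with open(Path(path).with_suffix(".meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1, default=str)


def read_membrane_csv(path: str | Path) -> MembraneSeries:
    path = Path(path)
    df = pd.read_csv(path)
    with open(path.with_suffix(".meta.json")) as fh:
        meta = json.load(fh)
    times = np.array(sorted(df["time_min"].unique()), dtype=float)
    nq = int(df["quadrant"].max())
    grid = GridSpec(n_quadrants=nq, genotypes=tuple(meta["genotypes"]),
                    boundary_index=int(meta["boundary_index"]))
    piv = df.pivot_table(index="time_min", columns=["channel", "quadrant"],
                         values="value", aggfunc="first").sort_index()

    def block(name):
        return np.column_stack([piv[(name, q + 1)].to_numpy()
                                for q in range(nq)])

    return MembraneSeries(
        grid=grid, times=times,
        hsl_fields={"c6": block("hsl_c6"), "c12": block("hsl_c12")},
        channels={ch: block(ch) for ch in ("CFP", "YFP", "RFP")},
        od=block("OD600"), diffusion=meta["diffusion"],
        hsl_decay=float(meta["hsl_decay"]), meta=meta.get("meta", {}),
    )


# --------------------------------------------------------------------------
# end-to-end pipelines
# --------------------------------------------------------------------------

def _pipeline_reporter_titration(cfg: RunConfig, out: Path) -> dict:
    """IPTG titration of the best ratiometric reporter -> dose-response fit."""
    p = parameter_set("reporter_best")
    layout = [(Condition(iptg=c), "ratiometric_reporter") for c in IPTG_LEVELS]
    ts = simulate_plate(p, layout, replicates=cfg.replicates, seed=cfg.seed)
    fit = ratiometrics.titration_max_fold(ts, inducer="iptg")
    if "csv" in cfg.formats:
        write_plate_csv(ts, out / "plate.csv")
    return {"kind": "DoseResponseFit",
            "max_fold": fit.max_fold, "max_fold_sd": fit.max_fold_sd,
            "half_max_conc_mM": fit.half_max_conc, "hill_coef": fit.hill_coef,
            "nonmonotone": fit.nonmonotone}


def _pipeline_controller_titration(cfg: RunConfig, out: Path) -> dict:
    """Arabinose titration of a T7RNAP controller variant."""
    name = cfg.parameter_set if cfg.parameter_set in (
        "T7RNAP", "T7*RNAP", "splitT7", "splitT7*", "splitT7_SynZIP",
        "splitT7*_SynZIP") else "splitT7"
    p = parameter_set(name)
    layout = [(Condition(arabinose=c), "controller") for c in ARABINOSE_LEVELS]
    ts = simulate_plate(p, layout, replicates=cfg.replicates, seed=cfg.seed)
    fit = ratiometrics.titration_max_fold(ts, inducer="arabinose")
    if "csv" in cfg.formats:
        write_plate_csv(ts, out / "plate.csv")
    return {"kind": "DoseResponseFit", "variant": name,
            "max_fold": fit.max_fold, "max_fold_sd": fit.max_fold_sd,
            "half_max_conc_mM": fit.half_max_conc, "hill_coef": fit.hill_coef,
            "nonmonotone": fit.nonmonotone}


def _pipeline_and_grid(cfg: RunConfig, out: Path) -> dict:
    """2D HSL titration of the AND circuit -> gate report."""
    p = parameter_set(cfg.parameter_set if cfg.parameter_set.startswith("and_")
                      else "and_rbs250")
    layout = [(Condition(c6=a, c12=b), "and_full")
              for a in C6_LEVELS for b in C12_LEVELS]
    ts = simulate_plate(p, layout, replicates=cfg.replicates, seed=cfg.seed)
    grid = gatecheck.grid_from_plate(ts)
    if "csv" in cfg.formats:
        write_plate_csv(ts, out / "plate.csv")
    return {"kind": "GateReport", **gatecheck.gate_report(grid)}


def _pipeline_membrane_senders(cfg: RunConfig, out: Path) -> dict:
    """Adjacent sender populations -> position profile + domain call."""
    p = parameter_set(cfg.parameter_set if cfg.parameter_set.startswith("and_")
                      else "and_rbs250")
    grid = sender_grid()
    induced = simulate_membrane(p, grid, "senders", Condition(arabinose=25.0),
                                seed=cfg.seed)
    control = simulate_membrane(p, grid, "senders", Condition(arabinose=0.0),
                                seed=cfg.seed)
    prof = patternscan.position_profile(induced, control, t=3000.0)
    call = patternscan.detect_interface_domain(prof, "RFP")
    if "csv" in cfg.formats:
        write_membrane_csv(induced, out / "membrane.csv")
    return {"kind": "SpatialProfile+DomainCall",
            "profile_rfp": prof.mean["RFP"].tolist(),
            "domain": dataclasses.asdict(call)}


def _pipeline_hierarchy(cfg: RunConfig, out: Path) -> dict:
    plan = hierarchy.plan_hierarchy(3)
    dm = hierarchy.simulate_hierarchy(plan)
    return {"kind": "DomainMap", "n_domains": hierarchy.count_domains(dm),
            "planned": len(plan.domains), "incomplete": dm.incomplete,
            "labels": [l if l else "" for l in dm.labels.tolist()]}


PIPELINES = {
    "reporter-titration": _pipeline_reporter_titration,
    "controller-titration": _pipeline_controller_titration,
    "and-grid": _pipeline_and_grid,
    "membrane-senders": _pipeline_membrane_senders,
    "hierarchy": _pipeline_hierarchy,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute one configured pipeline end-to-end and write its result
    bundle; the same config always yields an identical bundle."""
    if config.pipeline not in PIPELINES:
        raise KeyError(f"unknown pipeline {config.pipeline!r}; "
                       f"choose from {sorted(PIPELINES)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        result = PIPELINES[config.pipeline](config, out)
    except Exception as exc:  # annotate with the failing stage
        raise RuntimeError(f"pipeline {config.pipeline!r} failed: {exc}") from exc
    pset = config.parameter_set
    sidecar = {
        "pipeline": config.pipeline,
        "seed": config.seed,
        "parameter_set": pset,
        "params_hash": params_hash(parameter_set(pset))
        if pset in PARAMETER_SET_NAMES else None,
        "version": _VERSION,
    }
    bundle = {"result": result, "sidecar": sidecar}
    if "json" in config.formats:
        with open(out / f"{config.pipeline}.json", "w") as fh:
            json.dump(bundle, fh, indent=1, default=float)
    return bundle
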