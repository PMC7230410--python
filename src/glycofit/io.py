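"""CSV/JSON input-output and the end-to-end analysis pipeline.

Curves travel as long-format CSV (UTF-8, '.' decimal) with columns
``subject_id, group, test, time_min, glucose_mmol_per_l``; a wide-format
importer (one column per protocol time) is provided for convenience.
:func:`run_pipeline` binds the whole analysis — fit every curve, extract
features from acceptable fits, compute raw trapezoidal AUCs, run the
group comparisons — and writes ``fits.csv``, ``features.csv``,
``classical_auc.csv``, ``comparisons.json`` and a log.  Outputs carry a
provenance header (package version, config hash, seed) and are
byte-identical across reruns with the same config and seed; wall-clock
timestamps appear only in the log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd

from . import __version__
from .classical import (
    DEFAULT_CONTRASTS,
    compare_groups,
    shapiro_normality,
    trapezoid_auc,
)
from .fitting import FitConfig, TimeSeries, fit_model

__all__ = [
    "REQUIRED_COLUMNS",
    "RunConfig",
    "read_timeseries_csv",
    "read_timeseries_wide",
    "write_timeseries_csv",
    "run_pipeline",
]

REQUIRED_COLUMNS = ("subject_id", "group", "test", "time_min", "glucose_mmol_per_l")


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration."""

    input: str
    outdir: str
    protocol: str = "both"  # GTT | ITT | both
    seed: int = 0
    fit: FitConfig = field(default_factory=FitConfig)
    contrasts: Sequence[tuple] = DEFAULT_CONTRASTS
    alpha: float = 0.05
    verbosity: int = 1

    def config_hash(self) -> str:
        """Short stable digest of the analysis settings (paths excluded,
        so the same analysis written elsewhere hashes identically)."""
        d = dataclasses.asdict(self)
        for key in ("input", "outdir", "verbosity"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        fit_raw = raw.pop("fit", {})
        if "contrasts" in raw:
            raw["contrasts"] = tuple(tuple(c) for c in raw["contrasts"])
        return cls(fit=FitConfig(**fit_raw), **raw)


def _frame_to_cohort(df: pd.DataFrame, path) -> List[TimeSeries]:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("time_min", "glucose_mmol_per_l"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric {col} at rows {list(bad[:5])}")
        df[col] = coerced
    dup = df.duplicated(subset=["subject_id", "test", "time_min"], keep=False)
    if dup.any():
        rows = df.index[dup].tolist()
        raise ValueError(
            f"{path}: duplicate (subject_id, test, time_min) at rows {rows[:10]}"
        )
    cohort = []
    for (sid, test), sub in df.groupby(["subject_id", "test"], sort=True):
        sub = sub.sort_values("time_min")
        cohort.append(
            TimeSeries(
                subject_id=str(sid),
                group=str(sub["group"].iloc[0]),
                test=str(test),
                times=sub["time_min"].to_numpy(dtype=float),
                glucose=sub["glucose_mmol_per_l"].to_numpy(dtype=float),
            )
        )
    return cohort


def read_timeseries_csv(path) -> List[TimeSeries]:
    """Read a long-format cohort CSV into validated TimeSeries objects.

    Rows for one (subject, test) are collected and ordered by time;
    missing columns, non-numeric glucose and duplicated time points are
    rejected with the offending rows named.
    """
    df = pd.read_csv(path, comment="#")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return _frame_to_cohort(df, path)


def read_timeseries_wide(path) -> List[TimeSeries]:
    """Convenience importer for wide format: subject_id, group, test,
    then one numeric-named column per time point (minutes)."""
    df = pd.read_csv(path, comment="#")
    id_cols = ["subject_id", "group", "test"]
    time_cols = [c for c in df.columns if c not in id_cols]
    long = df.melt(
        id_vars=id_cols,
        value_vars=time_cols,
        var_name="time_min",
        value_name="glucose_mmol_per_l",
    )
    long["time_min"] = pd.to_numeric(long["time_min"])
    return _frame_to_cohort(long, path)


def _provenance(config: Optional[RunConfig], seed: int) -> str:
    h = config.config_hash() if config is not None else "none"
    return f"# glycofit {__version__} config={h} seed={seed}"


def write_timeseries_csv(
    cohort: Sequence[TimeSeries], path, seed: int = 0, config: Optional[RunConfig] = None
) -> None:
    """Write a cohort as long-format CSV with a provenance header line."""
    rows = [
        {
            "subject_id": ts.subject_id,
            "group": ts.group,
            "test": ts.test,
            "time_min": t,
            "glucose_mmol_per_l": y,
        }
        for ts in cohort
        for t, y in zip(ts.times, ts.glucose)
    ]
    df = pd.DataFrame(rows)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_provenance(config, seed) + "\n")
        # default float repr: shortest round-trip form, so reread == written
        df.to_csv(fh, index=False, lineterminator="\n")


def _write_csv(df: pd.DataFrame, path, header: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def run_pipeline(config: RunConfig) -> dict:
    """Run fit -> features -> classical comparison end to end.

    Reads the cohort at ``config.input``, fits every curve, extracts
    features for acceptable fits, computes raw trapezoidal AUCs and the
    configured group contrasts per test, and writes the report bundle to
    ``config.outdir``.  Curves failing validation are skipped with a
    logged reason; input count always equals fitted + skipped.  Returns a
    dict with the output paths and in-memory tables.
    """
    from .features import extract_features

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"glycofit {__version__} run at {time.strftime('%Y-%m-%dT%H:%M:%S')}"]
    header = _provenance(config, config.seed)

    cohort = read_timeseries_csv(config.input)
    if config.protocol != "both":
        cohort = [ts for ts in cohort if ts.test == config.protocol]
    if not cohort:
        raise ValueError(f"no curves to analyse in {config.input}")

    fit_cfg = dataclasses.replace(config.fit, seed=config.seed)
    fit_rows, feat_rows, auc_rows, skipped = [], [], [], 0
    for ts in sorted(cohort, key=lambda s: (s.test, s.group, s.subject_id)):
        try:
            res = fit_model(ts, fit_cfg)
        except ValueError as exc:
            skipped += 1
            log_lines.append(f"SKIP {ts.subject_id} {ts.test}: {exc}")
            continue
        p = res.params
        fit_rows.append(
            {
                "subject_id": ts.subject_id,
                "group": ts.group,
                "test": ts.test,
                "alpha": p.alpha,
                "omega0_sq": p.omega0_sq,
                "g_stab": p.g_stab,
                "mu": p.mu,
                "nu": p.nu,
                "rss": res.rss,
                "r2": res.r2,
                "est_var": res.est_var,
                "regime": res.regime,
                "converged": res.converged,
                "acceptable": res.acceptable,
                "runs_p": res.runs_p,
                "n_starts_tried": res.n_starts_tried,
            }
        )
        auc_rows.append(
            {
                "subject_id": ts.subject_id,
                "group": ts.group,
                "test": ts.test,
                "auc_trapezoid": trapezoid_auc(ts),
            }
        )
        if res.acceptable:
            f = extract_features(p, ts.test)
            feat_rows.append(
                {
                    "subject_id": ts.subject_id,
                    "group": ts.group,
                    "test": ts.test,
                    "g_init": f.g_init,
                    "g_rate_init": f.g_rate_init,
                    "g_extremum": f.g_extremum,
                    "t_extremum": f.t_extremum,
                    "g_rate_I": f.g_rate_I,
                    "t_I": f.t_I,
                    "g_stab": f.g_stab,
                    "period_h": f.period_h,
                    "auc_model": f.auc_model,
                    "horizon": f.horizon,
                    "extremum_at_boundary": f.extremum_at_boundary,
                }
            )
        else:
            log_lines.append(
                f"GATE {ts.subject_id} {ts.test}: acceptable=False "
                f"(r2={res.r2:.3f}, runs_p={res.runs_p})"
            )

    fits = pd.DataFrame(fit_rows)
    feats = pd.DataFrame(feat_rows)
    aucs = pd.DataFrame(auc_rows)
    _write_csv(fits, outdir / "fits.csv", header)
    _write_csv(feats, outdir / "features.csv", header)
    _write_csv(aucs, outdir / "classical_auc.csv", header)

    comparisons = {"provenance": header.lstrip("# "), "alpha": config.alpha, "tests": {}}
    for test, sub in aucs.groupby("test"):
        by_group = {
            g: grp["auc_trapezoid"].tolist() for g, grp in sub.groupby("group")
        }
        usable = [
            (a, b)
            for a, b in config.contrasts
            if len(by_group.get(a, [])) >= 3 and len(by_group.get(b, [])) >= 3
        ]
        entry = {
            "shapiro": {g: shapiro_normality(v) for g, v in by_group.items()},
            "comparisons": [
                dataclasses.asdict(c)
                for c in (
                    compare_groups(by_group, usable, config.alpha) if usable else []
                )
            ],
        }
        comparisons["tests"][test] = entry
    comp_path = outdir / "comparisons.json"
    comp_path.write_text(json.dumps(comparisons, indent=2, sort_keys=True) + "\n")

    log_lines.append(
        f"curves={len(cohort)} fitted={len(fit_rows)} skipped={skipped} "
        f"acceptable={int(fits['acceptable'].sum()) if len(fits) else 0}"
    )
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    return {
        "fits": fits,
        "features": feats,
        "classical_auc": aucs,
        "comparisons": comparisons,
        "paths": {
            name: str(outdir / name)
            for name in ("fits.csv", "features.csv", "classical_auc.csv", "comparisons.json", "run.log")
        },
        "n_skipped": skipped,
    }
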