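"""Monte-Carlo harness for the planned-missingness study.

Crosses missing-data conditions (no missingness; 4 or 10 of 20 columns at
per-column rates 0.2/0.4/0.6) with four model families (one-/two-factor x
fixed/free loadings) and aggregates per-replication fit indices into the
four familiar summary tables plus sensitivity/recovery percentages.

Each replication draws one base data set per replication index; the
missing-data conditions modify that same base matrix, which keeps
between-condition comparisons free of extra Monte-Carlo noise.  All
randomness derives from a single master seed via SeedSequence, so every
cell is independently reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cfa import build_missing_data_model, build_one_factor, fit_ml
from .datagen import MissingDesign, PopulationModel, generate_dataset
from .robust import estimate_gamma, robust_summary, CFI_DELTA, RMSEA_DELTA
from .tetrachoric import tetrachoric_matrix

__all__ = [
    "COLUMN_SETS",
    "DesignCell",
    "CellSummary",
    "run_cell",
    "run_design",
    "replication_rows",
]

log = logging.getLogger(__name__)

#: named design-column sets for the 20-item instrument
COLUMN_SETS = {
    "none": (),
    "four": tuple(range(17, 21)),
    "ten": tuple(range(11, 21)),
}

_INDEX_KEYS = ("chisq_scaled", "chisq_raw", "rmsea", "srmr", "nnfi", "cfi", "aic")


@dataclass(frozen=True)
class DesignCell:
    """One cell of the simulation design."""

    columns_with_missing: str = "none"  # key of COLUMN_SETS or explicit tuple
    rate: float = 0.0
    model: str = "one_factor"  # "one_factor" | "two_factor"
    loadings: str = "fixed"  # "fixed" | "free"
    reps: int = 100
    master_seed: int = 0
    n: int = 500
    p: int = 20
    loading: float = 0.35
    split_prob: float = 0.5
    scheme: str = "shared"
    B: int = 100
    convention: str = "scaled-model"

    def __post_init__(self):
        if self.model == "two_factor" and self.rate == 0:
            raise ValueError("two-factor models are fit to incomplete data only")
        if self.rate > 0 and not self.columns(""):
            raise ValueError("a positive rate needs design columns")

    def columns(self, default=None):
        if isinstance(self.columns_with_missing, str):
            return COLUMN_SETS.get(self.columns_with_missing, default)
        return tuple(self.columns_with_missing)

    @property
    def label(self) -> str:
        cols = self.columns(()) or ()
        overall = self.rate * len(cols) / self.p
        return f"{self.rate:.0%}/{overall:.0%}"


@dataclass
class CellSummary:
    """Mean and 95% CI per fit index for one design cell."""

    cell: DesignCell
    stats: dict
    reps_used: int
    nonconverged: int
    ridge_count: int
    flags: list = field(default_factory=list)

    def mean(self, key: str) -> float:
        return self.stats[key]["mean"]

    def ci(self, key: str) -> tuple[float, float]:
        return self.stats[key]["ci_lo"], self.stats[key]["ci_hi"]


def _cond_code(columns: tuple, rate: float) -> int:
    return 1000 * len(columns) + int(round(rate * 100))


def _derived_seed(*parts) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % 2**31)


def _model_spec(model: str, loadings: str, p: int, columns):
    if model == "one_factor":
        return build_one_factor(p, loadings)
    if model == "two_factor":
        return build_missing_data_model(p, columns, loadings)
    raise ValueError(f"unknown model {model!r}")


def replication_rows(
    rep: int,
    master_seed: int,
    models: list[tuple[str, str]],
    columns: tuple = (),
    rate: float = 0.0,
    population: PopulationModel | None = None,
    scheme: str = "shared",
    B: int = 100,
    convention: str = "scaled-model",
) -> list[dict]:
    """Run one replication of one condition and fit the requested models.

    ``models`` is a list of (model, loadings) pairs; the generated data,
    tetrachoric matrix and bootstrap Gamma are shared across them.  The
    base continuous matrix depends only on (master_seed, rep), so all
    conditions of a design reuse the same base data per replication.
    """
    population = population or PopulationModel()
    data_seed = _derived_seed(master_seed, rep)
    design = None
    if rate > 0 and columns:
        design = MissingDesign(
            missing_columns=columns,
            per_column_rate=rate,
            scheme=scheme,
            seed=_derived_seed(master_seed, rep, _cond_code(columns, rate)),
        )
    data = generate_dataset(population, design, seed=data_seed)
    corr = tetrachoric_matrix(data)
    gamma = estimate_gamma(
        data, B=B, seed=_derived_seed(master_seed, rep, _cond_code(columns, rate), 7)
    )
    rows = []
    for model, loadings in models:
        spec = _model_spec(model, loadings, population.p, columns)
        fit = fit_ml(corr, spec, N=population.n, seed=_derived_seed(master_seed, rep, 11))
        summary = robust_summary(fit, gamma, corr, population.n, convention=convention)
        row = {
            "rep": rep,
            "model": model,
            "loadings": loadings,
            "rate": rate,
            "n_missing_columns": len(columns),
            "chisq_raw": summary.chisq_raw,
            "chisq_scaled": summary.chisq_scaled,
            "c_sb": summary.c_sb,
            "df": fit.df,
            "converged": fit.converged,
            "heywood": len(fit.heywood_flags),
            "ridge": corr.ridge_applied,
            **summary.indices,
        }
        rows.append(row)
    return rows


def _aggregate(df: pd.DataFrame, cell: DesignCell) -> CellSummary:
    used = df[df["converged"]]
    nonconv = int((~df["converged"]).sum())
    flags = []
    if len(df) and nonconv / len(df) > 0.10:
        flags.append("unreliable: >10% nonconvergence")
    stats = {}
    for key in _INDEX_KEYS:
        vals = used[key].to_numpy()
        m = float(vals.mean()) if vals.size else np.nan
        if vals.size > 1:
            half = 1.96 * vals.std(ddof=1) / np.sqrt(vals.size)
        else:
            half = 0.0
            if "degenerate CI: single replication" not in flags:
                flags.append("degenerate CI: single replication")
        stats[key] = {"mean": m, "ci_lo": m - half, "ci_hi": m + half}
    return CellSummary(
        cell=cell,
        stats=stats,
        reps_used=int(len(used)),
        nonconverged=nonconv,
        ridge_count=int((used["ridge"] > 0).sum()),
        flags=flags,
    )


def run_cell(cell: DesignCell, progress: bool = False) -> CellSummary:
    """Execute every replication of one design cell and aggregate."""
    population = PopulationModel(
        p=cell.p, loading=cell.loading, split_prob=cell.split_prob, n=cell.n
    )
    rows = []
    for rep in range(cell.reps):
        rows.extend(
            replication_rows(
                rep,
                cell.master_seed,
                models=[(cell.model, cell.loadings)],
                columns=cell.columns(()) or (),
                rate=cell.rate,
                population=population,
                scheme=cell.scheme,
                B=cell.B,
                convention=cell.convention,
            )
        )
        if progress and (rep + 1) % 10 == 0:
            log.info("cell %s %s/%s: rep %d/%d", cell.model, cell.loadings, cell.label, rep + 1, cell.reps)
    return _aggregate(pd.DataFrame(rows), cell)


# ---------------------------------------------------------------- full design
_CONDITIONS = [
    ("none", 0.0),
    ("four", 0.2),
    ("four", 0.4),
    ("four", 0.6),
    ("ten", 0.2),
    ("ten", 0.4),
    ("ten", 0.6),
]


def run_design(
    reps: int = 100,
    master_seed: int = 0,
    B: int = 100,
    n: int = 500,
    p: int = 20,
    loading: float = 0.35,
    split_prob: float = 0.5,
    scheme: str = "shared",
    convention: str = "scaled-model",
    outdir=None,
    progress: bool = False,
) -> dict:
    """Run the complete design and emit the four summary tables.

    Returns {"table1".."table4": DataFrame, "percentages": DataFrame,
    "rows": per-replication DataFrame, "manifest": dict}.  Tables follow
    the fixed row layout: complete-data row first, then the four-column
    conditions, then the ten-column conditions.
    """
    population = PopulationModel(p=p, loading=loading, split_prob=split_prob, n=n)
    all_rows = []
    for cond_name, rate in _CONDITIONS:
        columns = COLUMN_SETS[cond_name]
        models = [("one_factor", "fixed"), ("one_factor", "free")]
        if rate > 0:
            models += [("two_factor", "fixed"), ("two_factor", "free")]
        for rep in range(reps):
            for row in replication_rows(
                rep,
                master_seed,
                models=models,
                columns=columns,
                rate=rate,
                population=population,
                scheme=scheme,
                B=B,
                convention=convention,
            ):
                row["condition"] = cond_name
                all_rows.append(row)
        if progress:
            log.info("condition %s rate %.0f%% done", cond_name, rate * 100)
    rows_df = pd.DataFrame(all_rows)

    def _table(model: str, loadings: str) -> pd.DataFrame:
        recs = []
        for cond_name, rate in _CONDITIONS:
            use_model = "one_factor" if rate == 0 else model
            sub = rows_df[
                (rows_df["condition"] == cond_name)
                & (rows_df["rate"] == rate)
                & (rows_df["model"] == use_model)
                & (rows_df["loadings"] == loadings)
            ]
            if sub.empty:
                continue
            cell = DesignCell(
                columns_with_missing=cond_name,
                rate=rate,
                model=use_model,
                loadings=loadings,
                reps=reps,
                master_seed=master_seed,
                n=n,
                p=p,
                loading=loading,
                split_prob=split_prob,
                scheme=scheme,
                B=B,
                convention=convention,
            )
            summ = _aggregate(sub, cell)
            rec = {
                "model": "One factor" if use_model == "one_factor" else "Two factors",
                "missing": cell.label,
                "df": int(sub["df"].iloc[0]),
                "reps_used": summ.reps_used,
                "nonconverged": summ.nonconverged,
                "ridge_count": summ.ridge_count,
            }
            for key in ("chisq_scaled", "rmsea", "srmr", "nnfi", "cfi", "aic"):
                rec[key] = summ.mean(key)
                rec[f"{key}_lo"], rec[f"{key}_hi"] = summ.ci(key)
            recs.append(rec)
        return pd.DataFrame(recs)

    tables = {
        "table1": _table("one_factor", "fixed"),
        "table2": _table("two_factor", "fixed"),
        "table3": _table("one_factor", "free"),
        "table4": _table("two_factor", "free"),
    }

    # sensitivity (one-factor vs complete) and recovery (two-factor vs complete)
    pct = []
    for loadings in ("fixed", "free"):
        t_one = tables["table1" if loadings == "fixed" else "table3"]
        t_two = tables["table2" if loadings == "fixed" else "table4"]
        base = t_one[t_one["missing"] == "0%/0%"].iloc[0]
        for kind, tab in (("sensitivity", t_one), ("recovery", t_two)):
            sub = tab[tab["missing"] != "0%/0%"]
            d_rmsea = sub["rmsea"] - base["rmsea"]
            d_cfi = sub["cfi"] - base["cfi"]
            if kind == "sensitivity":
                hit_r = (d_rmsea >= RMSEA_DELTA).mean()
                hit_c = (-d_cfi >= CFI_DELTA).mean()
            else:
                hit_r = (d_rmsea.abs() < RMSEA_DELTA).mean()
                hit_c = (d_cfi > -CFI_DELTA).mean()
            pct.append(
                {
                    "loadings": loadings,
                    "comparison": kind,
                    "pct_rmsea": 100.0 * float(hit_r),
                    "pct_cfi": 100.0 * float(hit_c),
                }
            )
    percentages = pd.DataFrame(pct)

    manifest = {
        "reps": reps,
        "master_seed": master_seed,
        "B": B,
        "n": n,
        "p": p,
        "loading": loading,
        "split_prob": split_prob,
        "scheme": scheme,
        "convention": convention,
    }
    out = {"rows": rows_df, "percentages": percentages, "manifest": manifest, **tables}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("table1", "table2", "table3", "table4"):
            tables[name].to_csv(outdir / f"{name}.csv", index=False)
        percentages.to_csv(outdir / "percentages.csv", index=False)
        rows_df.to_csv(outdir / "replications.csv", index=False)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
    return out
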