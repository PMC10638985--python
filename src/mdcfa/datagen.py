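"""Synthetic binary data with planned missingness.

Generates unidimensional multivariate-normal data, dichotomizes it, and
removes entries from designated columns the way a planned missing data
design would: the affected columns are fixed by design, the affected rows
are drawn by a seeded random scheme.

The population model is a single common factor: every item loads `loading`
on the latent attribute, so the population correlation matrix has
`loading**2` everywhere off the diagonal.  The default study conditions
are 500 respondents, 20 items, loading 0.35, median split, and missingness
in either columns 17-20 or 11-20 at per-column rates 0.2/0.4/0.6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

__all__ = [
    "MISSING",
    "PopulationModel",
    "MissingDesign",
    "BinaryDataset",
    "population_correlation",
    "simulate_continuous",
    "dichotomize",
    "inject_missing",
    "generate_dataset",
    "load_config",
]

#: integer sentinel for a missing cell in ``BinaryDataset.values``
MISSING: int = -1

#: row-selection schemes for planned missingness.
#: "shared": one set of respondents skips every design column (block /
#: booklet design) — the default, since a planned design assigns whole
#: instrument parts to respondents.  "independent": rows drawn separately
#: per column, giving unstructured (per-cell) planned missingness.
SCHEMES = ("shared", "independent")


@dataclass(frozen=True)
class PopulationModel:
    """One-factor population for binary item data."""

    p: int = 20
    loading: float = 0.35
    split_prob: float = 0.5
    n: int = 500

    def __post_init__(self):
        if not 0 <= self.loading < 1:
            raise ValueError(f"loading must be in [0, 1), got {self.loading}")
        if not 0 < self.split_prob < 1:
            raise ValueError(f"split_prob must be in (0, 1), got {self.split_prob}")
        if self.p < 1:
            raise ValueError("p must be positive")
        if self.n < 2:
            raise ValueError("n must be at least 2")


@dataclass(frozen=True)
class MissingDesign:
    """Which columns lose how much, and how rows are picked.

    ``missing_columns`` are 1-based (column 17 is the 17th item), matching
    the convention used in configs and reports.
    """

    missing_columns: tuple[int, ...]
    per_column_rate: float
    scheme: str = "shared"
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "missing_columns", tuple(int(c) for c in self.missing_columns))
        if not 0 <= self.per_column_rate < 1:
            raise ValueError("per_column_rate must be in [0, 1)")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if any(c < 1 for c in self.missing_columns):
            raise ValueError("missing_columns are 1-based and must be >= 1")

    def n_removed(self, n: int) -> int:
        """Entries removed per design column for a sample of size n."""
        return int(round(self.per_column_rate * n))


@dataclass
class BinaryDataset:
    """n x p matrix over {0, 1, MISSING} plus design metadata."""

    values: np.ndarray
    design: MissingDesign | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int8)
        bad = ~np.isin(self.values, (0, 1, MISSING))
        if bad.any():
            raise ValueError("values must be 0, 1 or MISSING")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    @property
    def is_complete(self) -> bool:
        return not (self.values == MISSING).any()

    def missing_counts(self) -> np.ndarray:
        return (self.values == MISSING).sum(axis=0)

    # ---------------------------------------------------------------- I/O
    def to_csv(self, path, na_rep: str = "NA") -> None:
        cols = [f"item{i + 1:02d}" for i in range(self.p)]
        df = pd.DataFrame(self.values, columns=cols).astype("float64")
        df[self.values == MISSING] = np.nan
        df.to_csv(path, index=False, na_rep=na_rep)

    @classmethod
    def from_csv(cls, path, na_values=("NA", "")) -> "BinaryDataset":
        df = pd.read_csv(path, na_values=list(na_values), keep_default_na=True)
        arr = df.to_numpy(dtype=float)
        vals = np.full(arr.shape, MISSING, dtype=np.int8)
        obs = ~np.isnan(arr)
        vals[obs] = arr[obs].astype(np.int8)
        return cls(values=vals)


def population_correlation(model: PopulationModel) -> np.ndarray:
    """p x p compound-symmetric matrix: 1 on the diagonal, loading^2 off it."""
    r = model.loading**2
    mat = np.full((model.p, model.p), r)
    np.fill_diagonal(mat, 1.0)
    return mat


def simulate_continuous(model: PopulationModel, seed) -> np.ndarray:
    """n x p draws from N(0, R) with R the population correlation matrix."""
    rng = np.random.default_rng(seed)
    corr = population_correlation(model)
    chol = np.linalg.cholesky(corr)  # raises LinAlgError if not PD
    z = rng.standard_normal((model.n, model.p))
    return z @ chol.T


def dichotomize(data: np.ndarray, split_prob: float = 0.5) -> BinaryDataset:
    """Cut continuous scores at Phi^{-1}(1 - split_prob); above the cut -> 1."""
    if not 0 < split_prob < 1:
        raise ValueError("split_prob must be in (0, 1)")
    cut = norm.isf(split_prob)
    vals = (np.asarray(data, dtype=float) > cut).astype(np.int8)
    return BinaryDataset(values=vals, provenance={"split_prob": split_prob, "cut": cut})


def inject_missing(data: BinaryDataset, design: MissingDesign) -> BinaryDataset:
    """Set exactly round(rate * n) entries per design column to MISSING.

    Under the "shared" scheme one seeded sample of rows is blanked in every
    design column; under "independent" each column gets its own sample.
    """
    if not data.is_complete:
        raise ValueError("inject_missing expects a complete dataset")
    n, p = data.values.shape
    if any(c > p for c in design.missing_columns):
        raise ValueError("missing_columns outside the data")
    m = design.n_removed(n)
    vals = data.values.copy()
    if m == 0:
        if design.per_column_rate > 0:
            warnings.warn("per_column_rate * n < 1: no entries removed")
        return BinaryDataset(vals, design=design, provenance=dict(data.provenance))
    rng = np.random.default_rng(design.seed)
    cols0 = [c - 1 for c in design.missing_columns]
    if design.scheme == "shared":
        rows = rng.choice(n, size=m, replace=False)
        for c in cols0:
            vals[rows, c] = MISSING
    else:
        for c in cols0:
            rows = rng.choice(n, size=m, replace=False)
            vals[rows, c] = MISSING
    return BinaryDataset(vals, design=design, provenance=dict(data.provenance))


def generate_dataset(
    model: PopulationModel,
    design: MissingDesign | None = None,
    seed=0,
) -> BinaryDataset:
    """Full generation pipeline: simulate, dichotomize, optionally blank cells."""
    cont = simulate_continuous(model, seed)
    ds = dichotomize(cont, model.split_prob)
    ds.provenance.update({"seed": seed, "model": model})
    if design is not None and design.per_column_rate > 0:
        ds = inject_missing(ds, design)
        ds.provenance.update({"seed": seed, "model": model})
    return ds


def load_config(path) -> dict:
    """Read a YAML generation config into PopulationModel / MissingDesign.

    Keys: n, p, loading, split_prob, missing_columns, rate, scheme, seed.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    model = PopulationModel(
        p=int(raw.get("p", 20)),
        loading=float(raw.get("loading", 0.35)),
        split_prob=float(raw.get("split_prob", 0.5)),
        n=int(raw.get("n", 500)),
    )
    design = None
    if raw.get("missing_columns"):
        design = MissingDesign(
            missing_columns=tuple(raw["missing_columns"]),
            per_column_rate=float(raw.get("rate", 0.0)),
            scheme=raw.get("scheme", "shared"),
            seed=int(raw.get("seed", 0)),
        )
    return {"model": model, "design": design, "seed": int(raw.get("seed", 0))}
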