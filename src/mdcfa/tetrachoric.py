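"""Tetrachoric correlations and probability-based covariances.

A tetrachoric correlation treats each binary item as a dichotomized
standard-normal variable: the threshold tau_i is fixed from the item's
margin via Pr(X_i = 1) = Pr(V_i > tau_i), and the correlation of the
underlying normals is then estimated by maximizing the multinomial
likelihood of the 2x2 table (two-step estimation, as in PRELIS).

Missing entries are replaced by zeros before estimation — the policy that
lets planned missingness show up as systematic variation in the
correlations instead of being imputed away.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._bvn import bvn_cdf
from .datagen import MISSING, BinaryDataset

__all__ = [
    "CorrelationInput",
    "replace_missing_with_zero",
    "estimate_threshold",
    "tetrachoric_pair",
    "tetrachoric_matrix",
    "ensure_pd",
    "probability_based_covariance",
]

log = logging.getLogger(__name__)

#: |rho| bound keeping downstream matrices invertible
RHO_BOUND = 0.999
#: default smallest-eigenvalue floor for positive definiteness
PD_FLOOR = 1e-6
_BISECT_ITER = 54  # interval 2 * 2^-54 ~ 1e-16


class DegenerateMarginError(ValueError):
    """An item has no 0s or no 1s, so no threshold exists."""


@dataclass
class CorrelationInput:
    """Symmetric correlation matrix plus the metadata CFA needs."""

    matrix: np.ndarray
    thresholds: np.ndarray
    pd: bool
    ridge_applied: float = 0.0
    pair_diagnostics: dict = field(default_factory=dict)

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    # ---------------------------------------------------------------- I/O
    def to_csv(self, path) -> None:
        cols = [f"item{i + 1:02d}" for i in range(self.p)]
        pd_df = pd.DataFrame(self.matrix, columns=cols, index=cols)
        pd_df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "CorrelationInput":
        df = pd.read_csv(path, index_col=0)
        mat = df.to_numpy(dtype=float)
        eig = np.linalg.eigvalsh(mat).min()
        return cls(mat, thresholds=np.full(mat.shape[0], np.nan), pd=eig > 0)

    def to_lower_triangular(self, path, fmt: str = "%.6f") -> None:
        """LISREL-style lower-triangular text: row i holds entries 1..i."""
        with open(path, "w") as fh:
            for i in range(self.p):
                fh.write(" ".join(fmt % v for v in self.matrix[i, : i + 1]) + "\n")

    @classmethod
    def from_lower_triangular(cls, path) -> "CorrelationInput":
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    rows.append([float(tok) for tok in line.split()])
        p = len(rows)
        mat = np.zeros((p, p))
        for i, row in enumerate(rows):
            if len(row) != i + 1:
                raise ValueError(f"row {i + 1} has {len(row)} entries, expected {i + 1}")
            mat[i, : i + 1] = row
        mat = mat + mat.T - np.diag(np.diag(mat))
        eig = np.linalg.eigvalsh(mat).min()
        return cls(mat, thresholds=np.full(p, np.nan), pd=eig > 0)

    def thresholds_to_csv(self, path) -> None:
        cols = [f"item{i + 1:02d}" for i in range(self.p)]
        pd.DataFrame({"item": cols, "threshold": self.thresholds}).to_csv(path, index=False)


def replace_missing_with_zero(data: BinaryDataset) -> BinaryDataset:
    """Recode every MISSING cell as 0 (the incorrect-response code)."""
    vals = data.values.copy()
    vals[vals == MISSING] = 0
    return BinaryDataset(vals, design=data.design, provenance=dict(data.provenance))


def estimate_threshold(p1: float) -> float:
    """tau with Pr(V > tau) = p1 for standard-normal V, i.e. Phi^-1(1 - p1)."""
    if not 0.0 < p1 < 1.0:
        raise DegenerateMarginError(f"marginal proportion {p1} admits no threshold")
    return float(norm.isf(p1))


def _solve_rho(n11, n10, n01, n00):
    """Vectorized two-step ML for tetrachoric rho from 2x2 cell counts.

    Thresholds come from the margins; the profile score in rho is
    phi2(tau_i, tau_j; rho) * (n11/pi11 - n10/pi10 - n01/pi01 + n00/pi00),
    which is strictly decreasing, so the maximizer is the unique root,
    found by bisection on [-RHO_BOUND, RHO_BOUND].

    Tables containing a zero cell get 0.5 added to every cell (continuity
    correction).  Returns (rho, tau_i, tau_j, corrected, at_bound).
    """
    n11, n10, n01, n00 = (np.asarray(a, dtype=float) for a in (n11, n10, n01, n00))
    corrected = (n11 == 0) | (n10 == 0) | (n01 == 0) | (n00 == 0)
    n11, n10, n01, n00 = (np.where(corrected, a + 0.5, a) for a in (n11, n10, n01, n00))
    n = n11 + n10 + n01 + n00
    p1i = (n11 + n10) / n
    p1j = (n11 + n01) / n
    tau_i = norm.isf(p1i)
    tau_j = norm.isf(p1j)

    def score(rho):
        # pi11 = P(Vi > tau_i, Vj > tau_j) = Phi2(-tau_i, -tau_j; rho)
        pi11 = bvn_cdf(-tau_i, -tau_j, rho)
        pi10 = np.clip(p1i - pi11, 1e-12, None)
        pi01 = np.clip(p1j - pi11, 1e-12, None)
        pi00 = np.clip(1.0 - p1i - p1j + pi11, 1e-12, None)
        pi11 = np.clip(pi11, 1e-12, None)
        return n11 / pi11 - n10 / pi10 - n01 / pi01 + n00 / pi00

    lo = np.full_like(tau_i, -RHO_BOUND)
    hi = np.full_like(tau_i, RHO_BOUND)
    s_lo = score(lo)
    s_hi = score(hi)
    # score decreasing: root bracketed iff s_lo >= 0 >= s_hi
    at_lower = s_lo < 0
    at_upper = s_hi > 0
    for _ in range(_BISECT_ITER):
        mid = 0.5 * (lo + hi)
        s_mid = score(mid)
        take_hi = s_mid >= 0  # root to the right
        lo = np.where(take_hi, mid, lo)
        hi = np.where(take_hi, hi, mid)
    rho = 0.5 * (lo + hi)
    rho = np.where(at_lower, -RHO_BOUND, rho)
    rho = np.where(at_upper, RHO_BOUND, rho)
    return rho, tau_i, tau_j, corrected, at_lower | at_upper


def tetrachoric_pair(table) -> tuple[float, dict]:
    """Tetrachoric correlation from a single 2x2 count table.

    ``table[a][b]`` counts rows with X_i = a, X_j = b for a, b in {1, 0}
    (i.e. table[0][0] is the both-correct cell).  Returns the estimate and
    a diagnostics record.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or t.sum() <= 0:
        raise ValueError("table must be 2x2 with positive total")
    n11, n10, n01, n00 = t[0, 0], t[0, 1], t[1, 0], t[1, 1]
    if n11 + n10 <= 0 or n01 + n00 <= 0 or n11 + n01 <= 0 or n10 + n00 <= 0:
        raise DegenerateMarginError("zero margin in 2x2 table")
    rho, ti, tj, corrected, bound = _solve_rho(n11, n10, n01, n00)
    diag = {
        "tau_i": float(ti),
        "tau_j": float(tj),
        "corrected": bool(corrected),
        "at_bound": bool(bound),
        "converged": True,
        "n": float(t.sum()),
    }
    return float(rho), diag


def _pair_counts(x: np.ndarray):
    """All pairwise 2x2 cell counts of a 0/1 matrix via one matmul."""
    xf = x.astype(np.float64)
    n = x.shape[0]
    n11 = xf.T @ xf
    ones = xf.sum(axis=0)
    n10 = ones[:, None] - n11
    n01 = ones[None, :] - n11
    n00 = n - n11 - n10 - n01
    return n11, n10, n01, n00


def tetrachoric_matrix(
    data: BinaryDataset,
    policy: str = "zero_replacement",
    pd_floor: float = PD_FLOOR,
    smooth: bool = True,
) -> CorrelationInput:
    """Full p x p tetrachoric matrix under the zero-replacement policy.

    Raises DegenerateMarginError naming the item if any column is constant
    after the policy is applied.  With ``smooth`` the matrix is ridged to
    the PD floor when needed (the smoothing is recorded, never silent).
    """
    if policy != "zero_replacement":
        raise NotImplementedError(f"unknown missing-data policy: {policy}")
    if data.p < 2:
        raise ValueError("need at least two items")
    full = replace_missing_with_zero(data) if not data.is_complete else data
    x = full.values
    n = x.shape[0]
    means = x.mean(axis=0)
    degenerate = np.where((means <= 0) | (means >= 1))[0]
    if degenerate.size:
        raise DegenerateMarginError(
            f"degenerate margin in item(s) {[f'item{i + 1:02d}' for i in degenerate]}"
        )
    n11, n10, n01, n00 = _pair_counts(x)
    iu, ju = np.triu_indices(data.p, k=1)
    rho, _, _, corrected, at_bound = _solve_rho(
        n11[iu, ju], n10[iu, ju], n01[iu, ju], n00[iu, ju]
    )
    mat = np.eye(data.p)
    mat[iu, ju] = rho
    mat[ju, iu] = rho
    thresholds = norm.isf(means)
    eig_min = float(np.linalg.eigvalsh(mat).min())
    ridge = 0.0
    was_pd = eig_min >= pd_floor
    if smooth and not was_pd:
        mat, ridge = ensure_pd(mat, floor=pd_floor)
    out = CorrelationInput(
        matrix=mat,
        thresholds=thresholds,
        pd=was_pd or smooth,
        ridge_applied=ridge,
        pair_diagnostics={
            "n": n,
            "corrected_pairs": int(corrected.sum()),
            "bounded_pairs": int(at_bound.sum()),
            "eig_min_raw": eig_min,
        },
    )
    return out


def ensure_pd(matrix: np.ndarray, floor: float = PD_FLOOR) -> tuple[np.ndarray, float]:
    """Ridge a symmetric matrix up to the eigenvalue floor, keeping unit diagonal.

    Adds c to the diagonal and rescales by 1/(1 + c), so eigenvalues map to
    (lam + c)/(1 + c); c = (floor - lam_min)/(1 - floor) is the smallest
    ridge reaching the floor.  Idempotent: an already-acceptable matrix is
    returned unchanged with ridge 0.
    """
    mat = np.asarray(matrix, dtype=float)
    lam_min = float(np.linalg.eigvalsh(mat).min())
    if lam_min >= floor:
        return mat, 0.0
    c = (floor - lam_min) / (1.0 - floor)
    out = (mat + c * np.eye(mat.shape[0])) / (1.0 + c)
    log.info("ensure_pd: ridge %.3g applied (min eigenvalue was %.3g)", c, lam_min)
    return out, c


def probability_based_covariance(data: BinaryDataset) -> np.ndarray:
    """cov(X_i, X_j) = Pr(X_i=1 and X_j=1) - Pr(X_i=1) Pr(X_j=1).

    Only the code-1 events enter, so missing entries simply count as
    not-1 — no replacement step is needed.
    """
    ones = (data.values == 1).astype(np.float64)
    n = data.n
    p1 = ones.mean(axis=0)
    p11 = (ones.T @ ones) / n
    return p11 - np.outer(p1, p1)
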