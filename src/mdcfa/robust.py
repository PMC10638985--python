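"""Satorra-Bentler scaling and model fit indices.

The ML chi-square from tetrachoric input is not asymptotically chi-square
distributed, because the sampling covariance of tetrachoric correlations
(Gamma) exceeds its normal-theory counterpart.  The Satorra-Bentler
correction divides the raw statistic by c = tr(U Gamma)/df, where U is the
normal-theory residual-weight matrix evaluated at the solution.  Gamma is
estimated by a respondent-level bootstrap of the entire estimation
pipeline — resampling rows of the (zero-replaced) binary data and
re-estimating the full tetrachoric matrix each time — so the correction
reflects exactly the statistic that was computed, including the
missing-data policy.

Fit indices follow the usual definitions: RMSEA, SRMR (correlation-metric
residuals, unaffected by scaling), NNFI/TLI, CFI, and AIC = chi2 + 2t.
By default the scaled chi-square enters the chi-square-based indices for
the fitted model while the independence baseline enters unscaled; both
conventions are available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache
import json

import numpy as np

from .cfa import FitResult, _Parameterization
from .datagen import BinaryDataset
from .tetrachoric import (
    CorrelationInput,
    PD_FLOOR,
    _pair_counts,
    _solve_rho,
    ensure_pd,
    replace_missing_with_zero,
)

__all__ = [
    "GammaEstimate",
    "ScaledFit",
    "estimate_gamma",
    "nt_gamma",
    "sb_scale",
    "baseline_chisq",
    "fit_indices",
    "robust_summary",
    "compare_models",
    "CFI_DELTA",
    "RMSEA_DELTA",
]

log = logging.getLogger(__name__)

#: model-comparison criteria for a substantial change in fit
CFI_DELTA = 0.01
RMSEA_DELTA = 0.015


@dataclass
class GammaEstimate:
    """(N-1)-scaled covariance estimate of vech(S)."""

    matrix: np.ndarray
    method: str
    B: int = 0
    n_redraws: int = 0

    @property
    def meta(self) -> dict:
        return {"method": self.method, "B": self.B, "n_redraws": self.n_redraws}


@dataclass
class ScaledFit:
    """Scaled chi-square plus the index set reported for one model."""

    chisq_raw: float
    chisq_scaled: float
    c_sb: float
    df: int
    t: int
    gamma_meta: dict = field(default_factory=dict)
    indices: dict = field(default_factory=dict)
    baseline: dict = field(default_factory=dict)
    convention: str = "scaled-model"
    flags: list = field(default_factory=list)
    converged: bool = True

    def to_json(self, path=None):
        doc = {
            "chisq_raw": self.chisq_raw,
            "chisq_scaled": self.chisq_scaled,
            "c_sb": self.c_sb,
            "df": self.df,
            "t": self.t,
            "indices": {k: float(v) for k, v in self.indices.items()},
            "baseline": {k: float(v) for k, v in self.baseline.items()},
            "gamma_meta": self.gamma_meta,
            "convention": self.convention,
            "flags": list(self.flags),
            "converged": self.converged,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------- vech algebra
@lru_cache(maxsize=8)
def _vech_idx(p: int):
    return np.triu_indices(p)


@lru_cache(maxsize=8)
def _duplication(p: int) -> np.ndarray:
    """D with vec(A) = D vech(A) for symmetric A, vech in upper-triangle order."""
    iu, ju = _vech_idx(p)
    nstar = iu.size
    d = np.zeros((p * p, nstar))
    for c, (i, j) in enumerate(zip(iu, ju)):
        d[i * p + j, c] = 1.0
        d[j * p + i, c] = 1.0
    return d


def _nt_weight(sigma: np.ndarray) -> np.ndarray:
    """Normal-theory ML weight W = 0.5 D' (Sigma^-1 kron Sigma^-1) D."""
    p = sigma.shape[0]
    a = np.linalg.inv(sigma)
    d = _duplication(p)
    return 0.5 * d.T @ np.kron(a, a) @ d


def nt_gamma(sigma: np.ndarray) -> np.ndarray:
    """Normal-theory Gamma: (N-1) cov(vech S) = Sigma_ik Sigma_jl + Sigma_il Sigma_jk."""
    p = sigma.shape[0]
    iu, ju = _vech_idx(p)
    return (
        sigma[np.ix_(iu, iu)] * sigma[np.ix_(ju, ju)]
        + sigma[np.ix_(iu, ju)] * sigma[np.ix_(ju, iu)]
    )


def _delta_matrix(fit: FitResult) -> np.ndarray:
    """d vech(Sigma)/d theta at the solution, one column per free parameter."""
    par = _Parameterization(fit.spec)
    lam, phi, _ = par.unpack(fit.theta)
    p = fit.spec.p
    iu, ju = _vech_idx(p)
    cols = []
    for i, r in par.lam_free_idx:
        d = np.zeros((p, p))
        d[i, :] += phi[r] * lam[:, r]
        d[:, i] += phi[r] * lam[:, r]
        cols.append(d[iu, ju])
    for r in par.phi_free:
        d = np.outer(lam[:, r], lam[:, r])
        cols.append(d[iu, ju])
    for i in range(p):
        d = np.zeros(iu.size)
        d[(iu == i) & (ju == i)] = 1.0
        cols.append(d)
    return np.column_stack(cols)


def _residual_weight(w: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """U = W - W Delta (Delta' W Delta)^-1 Delta' W."""
    wd = w @ delta
    inner = delta.T @ wd
    return w - wd @ np.linalg.solve(inner, wd.T)


# ---------------------------------------------------------------- Gamma
def estimate_gamma(
    data: BinaryDataset,
    B: int = 200,
    seed=0,
    pd_floor: float = PD_FLOOR,
    smooth: bool = True,
    max_redraws: int = 1000,
) -> GammaEstimate:
    """Bootstrap Gamma for the tetrachoric matrix of ``data``.

    Rows of the zero-replaced binary matrix are resampled with
    replacement; each resample runs the full estimation pipeline
    (thresholds, pairwise ML, PD smoothing).  Resamples with a degenerate
    margin are redrawn and counted.  Returns (N-1) * cov(vech S).
    """
    if B < 50:
        raise ValueError("B must be at least 50")
    x = replace_missing_with_zero(data).values
    n, p = x.shape
    iu_full, ju_full = _vech_idx(p)
    iu, ju = np.triu_indices(p, k=1)
    rng = np.random.default_rng(seed)
    vechs = np.empty((B, iu_full.size))
    redraws = 0
    for b in range(B):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            xb = x[idx]
            means = xb.mean(axis=0)
            if ((means > 0) & (means < 1)).all():
                break
            redraws += 1
            log.info("estimate_gamma: degenerate bootstrap margin, redrawing")
        else:
            raise RuntimeError("could not draw a non-degenerate bootstrap resample")
        n11, n10, n01, n00 = _pair_counts(xb)
        rho, _, _, _, _ = _solve_rho(n11[iu, ju], n10[iu, ju], n01[iu, ju], n00[iu, ju])
        mat = np.eye(p)
        mat[iu, ju] = rho
        mat[ju, iu] = rho
        if smooth:
            mat, _ = ensure_pd(mat, floor=pd_floor)
        vechs[b] = mat[iu_full, ju_full]
    gamma = (n - 1) * np.cov(vechs, rowvar=False)
    return GammaEstimate(matrix=gamma, method="bootstrap", B=B, n_redraws=redraws)


# ---------------------------------------------------------------- scaling
def sb_scale(fit: FitResult, gamma: GammaEstimate | np.ndarray) -> ScaledFit:
    """Scale the raw chi-square by c = tr(U Gamma)/df at the ML solution."""
    gmat = gamma.matrix if isinstance(gamma, GammaEstimate) else np.asarray(gamma)
    meta = gamma.meta if isinstance(gamma, GammaEstimate) else {"method": "given"}
    if fit.df == 0:
        return ScaledFit(
            chisq_raw=fit.chisq_raw,
            chisq_scaled=fit.chisq_raw,
            c_sb=1.0,
            df=0,
            t=fit.spec.t,
            gamma_meta=meta,
            flags=["saturated: scaling undefined, raw statistic returned"],
            converged=fit.converged,
        )
    w = _nt_weight(fit.sigma_hat)
    u = _residual_weight(w, _delta_matrix(fit))
    c = float(np.trace(u @ gmat)) / fit.df
    if c <= 0:
        raise ValueError(f"nonpositive scaling factor c = {c}: Gamma estimation failed")
    return ScaledFit(
        chisq_raw=fit.chisq_raw,
        chisq_scaled=fit.chisq_raw / c,
        c_sb=c,
        df=fit.df,
        t=fit.spec.t,
        gamma_meta=meta,
        converged=fit.converged,
    )


def baseline_chisq(
    S, N: int, gamma: GammaEstimate | np.ndarray | None = None
) -> dict:
    """Independence-baseline chi-square (free diagonal, all covariances 0).

    F_b = sum log s_ii - log|S|, df_b = p(p-1)/2.  When Gamma is supplied
    the baseline is also SB-scaled (c_b from the baseline's own U matrix).
    """
    s_mat = S.matrix if isinstance(S, CorrelationInput) else np.asarray(S, dtype=float)
    p = s_mat.shape[0]
    sign, logdet = np.linalg.slogdet(s_mat)
    if sign <= 0:
        raise ValueError("S must be positive definite")
    f_b = float(np.log(np.diag(s_mat)).sum() - logdet)
    df_b = p * (p - 1) // 2
    out = {"chisq_raw": (N - 1) * f_b, "df": df_b, "c_sb": 1.0}
    out["chisq_scaled"] = out["chisq_raw"]
    if gamma is not None:
        gmat = gamma.matrix if isinstance(gamma, GammaEstimate) else np.asarray(gamma)
        sigma_b = np.diag(np.diag(s_mat))
        w = _nt_weight(sigma_b)
        iu, ju = _vech_idx(p)
        delta_b = np.zeros((iu.size, p))
        for i in range(p):
            delta_b[(iu == i) & (ju == i), i] = 1.0
        u_b = _residual_weight(w, delta_b)
        c_b = float(np.trace(u_b @ gmat)) / df_b
        if c_b <= 0:
            raise ValueError("nonpositive baseline scaling factor")
        out["c_sb"] = c_b
        out["chisq_scaled"] = out["chisq_raw"] / c_b
    return out


# ---------------------------------------------------------------- indices
def fit_indices(chisq, df, chisq_b, df_b, N, S, sigma_hat, t) -> dict:
    """RMSEA / SRMR / NNFI / CFI / AIC from one model-baseline pair."""
    if df <= 0 or df_b <= 0:
        raise ValueError("df and baseline df must be positive")
    s_mat = S.matrix if isinstance(S, CorrelationInput) else np.asarray(S, dtype=float)
    p = s_mat.shape[0]
    excess = max(chisq - df, 0.0)
    rmsea = float(np.sqrt(excess / (df * (N - 1))))
    iu, ju = _vech_idx(p)
    scale = np.sqrt(np.diag(s_mat))
    resid = (s_mat - sigma_hat) / np.outer(scale, scale)
    srmr = float(np.sqrt(np.mean(resid[iu, ju] ** 2)))
    ratio_b = chisq_b / df_b
    nnfi = float((ratio_b - chisq / df) / (ratio_b - 1.0))
    denom = max(chisq_b - df_b, excess, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - excess / denom
    cfi = float(np.clip(cfi, 0.0, 1.0))
    return {
        "rmsea": rmsea,
        "srmr": srmr,
        "nnfi": nnfi,
        "cfi": cfi,
        "aic": float(chisq + 2 * t),
    }


def robust_summary(
    fit: FitResult,
    gamma: GammaEstimate | np.ndarray,
    S,
    N: int,
    convention: str = "scaled-model",
) -> ScaledFit:
    """Scale a fit and attach the full index set.

    convention:
      * "scaled-model" — scaled chi-square for the fitted model, raw
        baseline (default);
      * "scaled"       — both model and baseline scaled;
      * "raw"          — no scaling enters the indices.
    """
    if convention not in ("scaled-model", "scaled", "raw"):
        raise ValueError(f"unknown convention {convention!r}")
    scaled = sb_scale(fit, gamma)
    base = baseline_chisq(S, N, gamma if convention == "scaled" else None)
    chisq = scaled.chisq_raw if convention == "raw" else scaled.chisq_scaled
    chisq_b = base["chisq_scaled"] if convention == "scaled" else base["chisq_raw"]
    scaled.baseline = base
    scaled.convention = convention
    scaled.indices = fit_indices(
        chisq, fit.df, chisq_b, base["df"], N, S, fit.sigma_hat, fit.spec.t
    )
    return scaled


def compare_models(a: ScaledFit, b: ScaledFit) -> dict:
    """Signed index differences b - a with the substantial-change flags."""
    d_cfi = b.indices["cfi"] - a.indices["cfi"]
    d_rmsea = b.indices["rmsea"] - a.indices["rmsea"]
    return {
        "delta_cfi": float(d_cfi),
        "delta_rmsea": float(d_rmsea),
        "substantial_cfi": bool(abs(d_cfi) >= CFI_DELTA),
        "substantial_rmsea": bool(abs(d_rmsea) >= RMSEA_DELTA),
    }
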