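"""Confirmatory factor models for the missing-data design.

Two measurement models are supported, both with orthogonal factors:

* the congeneric one-factor model  x = lambda_a * xi_a + delta, and
* the missing-data two-factor model x = lambda_a * xi_a + lambda_m * xi_m
  + delta, where xi_m loads only on items affected by planned missingness
  and absorbs the systematic variation those items share.

Loadings are either *fixed* (all attribute loadings 1, missing loadings 1
on design columns; the factor variances are estimated) or *free* (loadings
estimated, factor variances fixed to 1).  Estimation minimizes the normal-
theory ML discrepancy F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p, with the
input correlation matrix analyzed as a covariance matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import minimize

from .tetrachoric import CorrelationInput

__all__ = [
    "FREE",
    "ModelSpec",
    "FitResult",
    "build_one_factor",
    "build_missing_data_model",
    "implied_sigma",
    "fit_ml",
    "count_df",
]

FREE = "free"
_PSI_FLOOR = 1e-6  # uniqueness lower bound (Heywood clamp)


@dataclass(frozen=True)
class ModelSpec:
    """Loading pattern and variance parameterization of a measurement model.

    Loading entries are numbers (fixed) or the string "free"; the factor
    covariance is fixed to 0 and all uniquenesses are free.
    """

    p: int
    attr_loadings: tuple
    missing_loadings: tuple | None = None
    phi_attr: float | str = FREE
    phi_missing: float | str | None = None

    def __post_init__(self):
        if len(self.attr_loadings) != self.p:
            raise ValueError("attr_loadings length must equal p")
        if self.missing_loadings is not None and len(self.missing_loadings) != self.p:
            raise ValueError("missing_loadings length must equal p")
        if (self.missing_loadings is None) != (self.phi_missing is None):
            raise ValueError("missing factor needs both loadings and phi_missing")
        for name, lam, phi in (
            ("attribute", self.attr_loadings, self.phi_attr),
            ("missing", self.missing_loadings, self.phi_missing),
        ):
            if lam is None:
                continue
            anchored = any(v != FREE and v != 0 for v in lam) or phi != FREE
            if not anchored:
                raise ValueError(f"{name} factor is not identified (no fixed anchor)")
        if count_df(self) < 0:
            raise ValueError("negative degrees of freedom")

    # ------------------------------------------------------------ bookkeeping
    @property
    def has_missing_factor(self) -> bool:
        return self.missing_loadings is not None

    def free_parameter_names(self) -> list[str]:
        names = [
            f"lambda_attr_{i + 1:02d}"
            for i, v in enumerate(self.attr_loadings)
            if v == FREE
        ]
        if self.has_missing_factor:
            names += [
                f"lambda_miss_{i + 1:02d}"
                for i, v in enumerate(self.missing_loadings)
                if v == FREE
            ]
        if self.phi_attr == FREE:
            names.append("phi_attr")
        if self.phi_missing == FREE:
            names.append("phi_missing")
        names += [f"psi_{i + 1:02d}" for i in range(self.p)]
        return names

    @property
    def t(self) -> int:
        """Number of free parameters."""
        return len(self.free_parameter_names())

    # ------------------------------------------------------------ serialization
    def to_yaml(self, path=None):
        doc = {
            "p": self.p,
            "attr_loadings": list(self.attr_loadings),
            "missing_loadings": (
                list(self.missing_loadings) if self.missing_loadings else None
            ),
            "phi_attr": self.phi_attr,
            "phi_missing": self.phi_missing,
        }
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ModelSpec":
        try:
            with open(source) as fh:
                doc = yaml.safe_load(fh)
        except (OSError, TypeError):
            doc = yaml.safe_load(source)
        return cls(
            p=doc["p"],
            attr_loadings=tuple(doc["attr_loadings"]),
            missing_loadings=(
                tuple(doc["missing_loadings"]) if doc.get("missing_loadings") else None
            ),
            phi_attr=doc.get("phi_attr", FREE),
            phi_missing=doc.get("phi_missing"),
        )


@dataclass
class FitResult:
    """Outcome of one ML fit."""

    spec: ModelSpec
    theta: np.ndarray
    theta_hat: dict
    F_min: float
    chisq_raw: float
    df: int
    converged: bool
    n_iter: int
    gradient_norm: float
    heywood_flags: list = field(default_factory=list)
    sigma_hat: np.ndarray | None = None
    n_starts: int = 1

    def to_json(self, path=None):
        doc = {
            "F_min": self.F_min,
            "chisq_raw": self.chisq_raw,
            "df": self.df,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "gradient_norm": self.gradient_norm,
            "heywood_flags": list(self.heywood_flags),
            "n_starts": self.n_starts,
            "theta_hat": {k: float(v) for k, v in self.theta_hat.items()},
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


# ---------------------------------------------------------------- builders
def build_one_factor(p: int, loadings_mode: str) -> ModelSpec:
    """Congeneric model; fixed mode sets every loading to 1 and frees phi."""
    if p < 3:
        raise ValueError("one-factor model needs p >= 3 for identification")
    if loadings_mode == "fixed":
        return ModelSpec(p=p, attr_loadings=(1.0,) * p, phi_attr=FREE)
    if loadings_mode == "free":
        return ModelSpec(p=p, attr_loadings=(FREE,) * p, phi_attr=1.0)
    raise ValueError("loadings_mode must be 'fixed' or 'free'")


def build_missing_data_model(p: int, missing_columns, loadings_mode: str) -> ModelSpec:
    """Two-factor model with an orthogonal missing-data latent variable.

    ``missing_columns`` are 1-based.  Fixed mode: attribute loadings 1,
    missing loadings 1 on design columns and 0 elsewhere, both variances
    free (attribute) / free (missing).  Free mode: loadings estimated,
    variances fixed to 1; when every column is a design column the first
    missing loading is fixed to 0 to keep the bifactor identified.
    """
    cols = sorted(int(c) for c in missing_columns)
    if not cols:
        raise ValueError("missing_columns must be nonempty")
    if any(c < 1 or c > p for c in cols):
        raise ValueError("missing_columns out of range")
    if p < 3:
        raise ValueError("needs p >= 3")
    in_design = np.zeros(p, dtype=bool)
    in_design[[c - 1 for c in cols]] = True
    if loadings_mode == "fixed":
        lam_m = tuple(1.0 if d else 0.0 for d in in_design)
        return ModelSpec(
            p=p,
            attr_loadings=(1.0,) * p,
            missing_loadings=lam_m,
            phi_attr=FREE,
            phi_missing=FREE,
        )
    if loadings_mode == "free":
        lam_m = [FREE if d else 0.0 for d in in_design]
        if in_design.all():
            lam_m[cols[0] - 1] = 0.0  # bifactor anchor: first loading fixed to zero
        return ModelSpec(
            p=p,
            attr_loadings=(FREE,) * p,
            missing_loadings=tuple(lam_m),
            phi_attr=1.0,
            phi_missing=1.0,
        )
    raise ValueError("loadings_mode must be 'fixed' or 'free'")


def count_df(spec: ModelSpec, p: int | None = None) -> int:
    """Model degrees of freedom p(p+1)/2 - t."""
    p = spec.p if p is None else p
    t = len(spec.free_parameter_names()) if hasattr(spec, "free_parameter_names") else 0
    return p * (p + 1) // 2 - t


# ---------------------------------------------------------------- internals
class _Parameterization:
    """Maps the free-parameter vector theta onto (Lambda, phi, Psi)."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        p = spec.p
        self.k = 2 if spec.has_missing_factor else 1
        self.lam_base = np.zeros((p, self.k))
        self.lam_free_idx = []  # (item, factor) per free loading, theta order
        for i, v in enumerate(spec.attr_loadings):
            if v == FREE:
                self.lam_free_idx.append((i, 0))
            else:
                self.lam_base[i, 0] = float(v)
        if spec.has_missing_factor:
            for i, v in enumerate(spec.missing_loadings):
                if v == FREE:
                    self.lam_free_idx.append((i, 1))
                else:
                    self.lam_base[i, 1] = float(v)
        self.phi_base = np.ones(self.k)
        self.phi_free = []
        if spec.phi_attr == FREE:
            self.phi_free.append(0)
        else:
            self.phi_base[0] = float(spec.phi_attr)
        if spec.has_missing_factor:
            if spec.phi_missing == FREE:
                self.phi_free.append(1)
            else:
                self.phi_base[1] = float(spec.phi_missing)
        self.n_lam = len(self.lam_free_idx)
        self.n_phi = len(self.phi_free)
        self.t = self.n_lam + self.n_phi + p

    def unpack(self, theta):
        lam = self.lam_base.copy()
        for pos, (i, r) in enumerate(self.lam_free_idx):
            lam[i, r] = theta[pos]
        phi = self.phi_base.copy()
        for pos, r in enumerate(self.phi_free):
            phi[r] = theta[self.n_lam + pos]
        psi = theta[self.n_lam + self.n_phi :]
        return lam, phi, psi

    def sigma(self, theta):
        lam, phi, psi = self.unpack(theta)
        return (lam * phi) @ lam.T + np.diag(psi)

    def gradient_from_weight(self, m, lam, phi):
        """d tr(M dSigma/dtheta) for symmetric weight matrix M."""
        g = np.empty(self.t)
        ml = m @ lam  # p x k
        for pos, (i, r) in enumerate(self.lam_free_idx):
            g[pos] = 2.0 * phi[r] * ml[i, r]
        for pos, r in enumerate(self.phi_free):
            g[self.n_lam + pos] = lam[:, r] @ ml[:, r]
        g[self.n_lam + self.n_phi :] = np.diag(m)
        return g

    def start(self, s_matrix, jitter=None, rng=None):
        """Heuristic starting values from the mean off-diagonal of S."""
        p = self.spec.p
        off = s_matrix[np.triu_indices(p, k=1)]
        rbar = float(np.clip(off.mean(), 0.01, 0.9))
        theta = np.empty(self.t)
        for pos, (i, r) in enumerate(self.lam_free_idx):
            theta[pos] = np.sqrt(rbar) if r == 0 else 0.2
        for pos, r in enumerate(self.phi_free):
            theta[self.n_lam + pos] = rbar if r == 0 else 0.05
        theta[self.n_lam + self.n_phi :] = 1.0 - rbar
        if jitter and rng is not None:
            theta = theta * (1.0 + jitter * rng.standard_normal(self.t))
            theta[self.n_lam + self.n_phi :] = np.clip(
                theta[self.n_lam + self.n_phi :], 0.05, None
            )
        return theta


def implied_sigma(spec: ModelSpec, theta) -> np.ndarray:
    """Sigma(theta) = Lambda Phi Lambda' + Psi with orthogonal factors."""
    par = _Parameterization(spec)
    theta = np.asarray(theta, dtype=float)
    if theta.shape[0] != par.t:
        raise ValueError(f"theta has {theta.shape[0]} entries, expected {par.t}")
    return par.sigma(theta)


def fit_ml(
    S,
    spec: ModelSpec,
    N: int,
    max_starts: int = 5,
    seed: int = 0,
    gtol: float = 1e-7,
) -> FitResult:
    """Minimize the ML discrepancy of Sigma(theta) against S.

    S may be a CorrelationInput or a plain symmetric PD matrix; the raw
    chi-square is (N - 1) * F_min.  Quasi-Newton (L-BFGS-B) with analytic
    gradients and up to ``max_starts`` jittered restarts; uniquenesses are
    bounded below at 1e-6 and flagged as Heywood cases when clamped.
    """
    s_mat = S.matrix if isinstance(S, CorrelationInput) else np.asarray(S, dtype=float)
    p = spec.p
    if s_mat.shape != (p, p):
        raise ValueError("S dimension does not match spec")
    if N <= spec.t:
        raise ValueError("sample size must exceed the free parameter count")
    sign, logdet_s = np.linalg.slogdet(s_mat)
    if sign <= 0:
        raise ValueError("S must be positive definite (run ensure_pd first)")
    par = _Parameterization(spec)

    def objective(theta):
        sigma = par.sigma(theta)
        lam, phi, _ = par.unpack(theta)
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            w, v = np.linalg.eigh(sigma)
            v0 = v[:, 0]
            pen_m = np.outer(v0, v0)
            return 1e6 * (1.0 - w[0]), -1e6 * par.gradient_from_weight(pen_m, lam, phi)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        sigma_inv = np.linalg.inv(sigma)
        f = logdet + float((sigma_inv * s_mat).sum()) - logdet_s - p
        m = sigma_inv - sigma_inv @ s_mat @ sigma_inv
        return f, par.gradient_from_weight(m, lam, phi)

    bounds = [(None, None)] * (par.n_lam + par.n_phi) + [(_PSI_FLOOR, None)] * p
    rng = np.random.default_rng(seed)
    best = None
    n_used = 0
    for attempt in range(max_starts):
        theta0 = par.start(s_mat, jitter=0.2 if attempt else None, rng=rng)
        res = minimize(
            objective,
            theta0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 3000, "ftol": 1e-14, "gtol": 1e-10},
        )
        n_used = attempt + 1
        gnorm = float(np.abs(res.jac).max())
        # gradient tolerance relative to the objective scale: badly fitting
        # models sit at F of several units where 1e-7 absolute is unreachable
        ok = res.fun < 1e5 and gnorm < gtol * max(1.0, res.fun)
        if best is None or res.fun < best[0].fun:
            best = (res, gnorm)
        if ok:
            best = (res, gnorm)
            break
    res, gnorm = best
    theta = res.x
    lam, phi, psi = par.unpack(theta)
    heywood = [i for i in range(p) if psi[i] <= _PSI_FLOOR * (1 + 1e-9)]
    f_min = max(float(res.fun), 0.0)
    names = spec.free_parameter_names()
    return FitResult(
        spec=spec,
        theta=theta,
        theta_hat=dict(zip(names, theta)),
        F_min=f_min,
        chisq_raw=(N - 1) * f_min,
        df=count_df(spec),
        converged=bool(res.fun < 1e5 and gnorm < gtol * max(1.0, res.fun) and not heywood),
        n_iter=int(res.nit),
        gradient_norm=gnorm,
        heywood_flags=heywood,
        sigma_hat=par.sigma(theta),
        n_starts=n_used,
    )
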