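"""Additive mixed model of foliar d15N with penalized-spline smooths.

The model is

    y = intercept + landform effect + sum_j f_j(x_j) + b_plot + b_transect + e

with each f_j a thin-plate regression spline, nested Gaussian random
intercepts and Gaussian residuals.  Smooths are handled through their
mixed-model representation: after reparameterisation every penalised
block and every random-intercept block has covariance sigma^2 * tau_b * I,
so the marginal likelihood is that of a linear mixed model.  beta and
sigma^2 are profiled out and the remaining log variance ratios are
optimised by quasi-Newton, giving exact maximum-likelihood estimates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .basis import SmoothBasis

logger = logging.getLogger(__name__)

DEFAULT_SMOOTHS = ("dist_ac", "elev_ac", "log_area_ac", "log_cover", "twi")
RESPONSE = "d15n_obs"


class FitError(RuntimeError):
    """Raised when a model cannot be fitted (degenerate or singular)."""


@dataclass(frozen=True)
class GAMMSpec:
    """Which terms enter the model.

    ``smooth_terms`` may be empty and ``landform`` absent (used during
    model selection); the nested random-intercept structure is controlled
    by ``random`` and is normally kept in every candidate.
    """

    smooth_terms: tuple = DEFAULT_SMOOTHS
    landform: bool = True
    random: bool = True
    k: int = 10
    response: str = RESPONSE
    reference_level: str = "plain"

    @property
    def fixed_terms(self) -> tuple:
        return self.smooth_terms + (("landform",) if self.landform else ())

    def label(self) -> str:
        return "+".join(self.fixed_terms) if self.fixed_terms else "1"


@dataclass
class PartialEffect:
    """One term's centred contribution on a covariate grid."""

    term: str
    grid: np.ndarray           # covariate grid (or class names for landform)
    effect: np.ndarray         # centred effect estimate (permil)
    se: np.ndarray             # standard errors
    x_train: np.ndarray        # training covariate values
    partial_residuals: np.ndarray

    @property
    def ci_halfwidth(self) -> np.ndarray:
        return 1.96 * self.se


class _Design:
    """Assembled design matrices plus block bookkeeping for one table."""

    def __init__(self, table: pd.DataFrame, spec: GAMMSpec,
                 bases: dict | None = None):
        n = len(table)
        y = table[spec.response].to_numpy(dtype=float)
        if not np.all(np.isfinite(y)):
            raise FitError("non-finite response values")

        X_cols, X_names = [np.ones(n)], ["(Intercept)"]
        self.landform_levels: list[str] = []
        self.reference_level = None
        if spec.landform:
            levels = sorted(table["landform"].astype(str).unique())
            if len(levels) < 2:
                raise FitError("landform has a single observed level "
                               "(singular design)")
            ref = spec.reference_level if spec.reference_level in levels else levels[0]
            self.reference_level = ref
            self.landform_levels = levels
            lf = table["landform"].astype(str).to_numpy()
            for lev in levels:
                if lev == ref:
                    continue
                X_cols.append((lf == lev).astype(float))
                X_names.append(f"landform[{lev}]")

        self.bases: dict[str, SmoothBasis] = {}
        Z_blocks, self.blocks = [], []  # blocks: (name, kind, z_slice)
        zc = 0
        for term in spec.smooth_terms:
            basis = (bases or {}).get(term) or SmoothBasis(
                table[term].to_numpy(dtype=float), spec.k)
            self.bases[term] = basis
            X_cols.append(basis.linear_column(table[term].to_numpy(dtype=float)))
            X_names.append(f"s({term}).lin")
            Zb = basis.mixed_columns(table[term].to_numpy(dtype=float))
            Z_blocks.append(Zb)
            self.blocks.append((term, "smooth", slice(zc, zc + Zb.shape[1])))
            zc += Zb.shape[1]

        self.plot_levels: list = []
        self.transect_levels: list = []
        if spec.random:
            plots = sorted(table["plot_id"].astype(str).unique())
            if len(plots) < 2:
                raise FitError("need >= 2 plots for random intercepts")
            self.plot_levels = plots
            pid = table["plot_id"].astype(str).to_numpy()
            Zp = np.column_stack([(pid == p).astype(float) for p in plots])
            Z_blocks.append(Zp)
            self.blocks.append(("plot", "random", slice(zc, zc + Zp.shape[1])))
            zc += Zp.shape[1]
            tkey = (table["plot_id"].astype(str) + "/"
                    + table["transect_id"].astype(str)).to_numpy()
            transects = sorted(set(tkey))
            self.transect_levels = transects
            Zt = np.column_stack([(tkey == t).astype(float) for t in transects])
            Z_blocks.append(Zt)
            self.blocks.append(("transect", "random", slice(zc, zc + Zt.shape[1])))
            zc += Zt.shape[1]

        self.y = y
        self.X = np.column_stack(X_cols)
        self.X_names = X_names
        self.Z = (np.column_stack(Z_blocks) if Z_blocks
                  else np.empty((n, 0)))
        self.n, self.p, self.q = n, self.X.shape[1], self.Z.shape[1]
        # sufficient statistics for fast likelihood evaluations
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ y
        self.ZtX = self.Z.T @ self.X
        self.Zty = self.Z.T @ y
        self.G = self.Z.T @ self.Z
        self.yty = float(y @ y)

    def expand_tau(self, rho: np.ndarray) -> np.ndarray:
        """Per-column variance ratios from per-block log ratios."""
        tau = np.empty(self.q)
        for (name, kind, sl), r in zip(self.blocks, rho):
            tau[sl] = np.exp(r)
        return tau


def _profiled_ml(design: _Design, rho: np.ndarray):
    """Profiled ML log-likelihood and profiled beta / sigma^2 at rho."""
    n = design.n
    if design.q == 0:
        XtVX, XtVy, ytVy, logdetV = design.XtX, design.Xty, design.yty, 0.0
    else:
        s = np.sqrt(design.expand_tau(rho))
        W = np.eye(design.q) + (s[:, None] * design.G) * s[None, :]
        cW, low = linalg.cho_factor(W, lower=True, check_finite=False)
        logdetV = 2.0 * float(np.sum(np.log(np.diag(cW))))
        sZtX = s[:, None] * design.ZtX
        sZty = s * design.Zty
        XtVX = design.XtX - sZtX.T @ linalg.cho_solve((cW, low), sZtX,
                                                      check_finite=False)
        XtVy = design.Xty - sZtX.T @ linalg.cho_solve((cW, low), sZty,
                                                      check_finite=False)
        ytVy = design.yty - float(sZty @ linalg.cho_solve((cW, low), sZty,
                                                          check_finite=False))
    try:
        cX = linalg.cho_factor(XtVX, check_finite=False)
    except linalg.LinAlgError as exc:
        raise FitError(f"singular fixed-effect design: {exc}") from exc
    beta = linalg.cho_solve(cX, XtVy, check_finite=False)
    rss = ytVy - float(beta @ XtVy)
    sigma2 = max(rss / n, 0.0)
    if sigma2 <= 1e-10:
        raise FitError("degenerate fit: residual variance collapsed to zero")
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + n + logdetV)
    return ll, beta, sigma2


@dataclass
class FittedGAMM:
    """A fitted additive mixed model (maximum likelihood)."""

    spec: GAMMSpec
    design: _Design = field(repr=False)
    beta: np.ndarray = field(repr=False)
    b: np.ndarray = field(repr=False)
    tau_blocks: dict = field(default_factory=dict)
    sigma2: float = 0.0
    loglik: float = 0.0
    fitted: np.ndarray = field(default=None, repr=False)
    residuals: np.ndarray = field(default=None, repr=False)
    cov_coef: np.ndarray = field(default=None, repr=False)  # [beta; b] posterior cov
    edf_blocks: dict = field(default_factory=dict)

    # -- scalar summaries --------------------------------------------------
    @property
    def lambdas(self) -> dict:
        """Smoothing parameters (inverse variance ratios) per smooth."""
        return {t: 1.0 / self.tau_blocks[t] for t in self.spec.smooth_terms}

    @property
    def variance_components(self) -> dict:
        out = {"resid": self.sigma2}
        if self.spec.random:
            out["plot"] = self.sigma2 * self.tau_blocks["plot"]
            out["transect"] = self.sigma2 * self.tau_blocks["transect"]
        return out

    def edf(self, term: str) -> float:
        """Effective degrees of freedom of one smooth term (>= 1)."""
        if term not in self.spec.smooth_terms:
            raise ValueError(f"term {term!r} not in model")
        return self.edf_blocks[term]

    def log_likelihood(self) -> float:
        return self.loglik

    def param_count(self) -> int:
        """Estimated-parameter count used for AICc.

        Fixed coefficients (intercept, landform contrasts, one linear
        coefficient per smooth) + one smoothing parameter per smooth +
        variance components (residual, plus plot and transect when random
        intercepts are present).
        """
        k = self.design.p
        k += len(self.spec.smooth_terms)          # smoothing parameters
        k += 1 + (2 if self.spec.random else 0)    # variance components
        return k

    # -- prediction --------------------------------------------------------
    def _fixed_design(self, newdata: pd.DataFrame):
        """(X_new, Z_smooth_new) for the deterministic part of the model."""
        n = len(newdata)
        X_cols = [np.ones(n)]
        if self.spec.landform:
            lf = newdata["landform"].astype(str).to_numpy()
            unknown = set(lf) - set(self.design.landform_levels)
            if unknown:
                raise ValueError(f"unknown landform class(es): {sorted(unknown)}")
            for lev in self.design.landform_levels:
                if lev == self.design.reference_level:
                    continue
                X_cols.append((lf == lev).astype(float))
        Zs = []
        for term in self.spec.smooth_terms:
            x = newdata[term].to_numpy(dtype=float)
            X_cols.append(self.design.bases[term].linear_column(x))
            Zs.append(self.design.bases[term].mixed_columns(x))
        X = np.column_stack(X_cols)
        Z = np.column_stack(Zs) if Zs else np.empty((n, 0))
        return X, Z

    def predict(self, newdata: pd.DataFrame, include_random: bool = False) -> np.ndarray:
        """Predicted d15N (permil).

        The deterministic part is intercept + landform effect + smooth
        effects.  With ``include_random`` the estimated plot and transect
        intercepts are added for groups seen in training (0 for unseen
        groups).
        """
        X, Zs = self._fixed_design(newdata)
        smooth_idx = [i for (name, kind, sl) in self.design.blocks if kind == "smooth"
                      for i in range(sl.start, sl.stop)]
        pred = X @ self.beta
        if Zs.shape[1]:
            pred = pred + Zs @ self.b[smooth_idx]
        if include_random and self.spec.random:
            pid = newdata["plot_id"].astype(str).to_numpy()
            tkey = (newdata["plot_id"].astype(str) + "/"
                    + newdata["transect_id"].astype(str)).to_numpy()
            for name, kind, sl in self.design.blocks:
                if kind != "random":
                    continue
                levels = (self.design.plot_levels if name == "plot"
                          else self.design.transect_levels)
                keys = pid if name == "plot" else tkey
                lookup = dict(zip(levels, self.b[sl]))
                pred = pred + np.array([lookup.get(kk, 0.0) for kk in keys])
        return pred

    def term_effect(self, term: str, x: np.ndarray):
        """Centred effect of one smooth at covariate values x, with SE."""
        if term not in self.spec.smooth_terms:
            raise ValueError(f"term {term!r} not in model")
        basis = self.design.bases[term]
        lin = basis.linear_column(np.asarray(x, dtype=float))
        Zt = basis.mixed_columns(np.asarray(x, dtype=float))
        xi = self.design.X_names.index(f"s({term}).lin")
        sl = next(sl for (name, kind, sl) in self.design.blocks if name == term)
        eff = lin * self.beta[xi] + Zt @ self.b[sl]
        # columns of the joint [beta; b] covariance for this term
        cols = [xi] + list(range(self.design.p + sl.start, self.design.p + sl.stop))
        C = np.column_stack([lin, Zt])
        V = self.cov_coef[np.ix_(cols, cols)]
        se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", C, V, C), 0.0))
        return eff, se

    def partial_effect(self, term: str, n_grid: int = 100) -> PartialEffect:
        """Fig.-3-style partial effect: centred estimate, 95% CI and
        partial residuals (residuals plus the term's own effect)."""
        if term == "landform":
            return self._landform_effect()
        if term not in self.spec.smooth_terms:
            raise ValueError(f"term {term!r} not in model")
        table_x = self._training_covariate(term)
        grid = np.linspace(float(np.min(table_x)), float(np.max(table_x)), n_grid)
        eff, se = self.term_effect(term, grid)
        own, _ = self.term_effect(term, table_x)
        presid = self.residuals + own
        return PartialEffect(term=term, grid=grid, effect=eff, se=se,
                             x_train=table_x, partial_residuals=presid)

    def _training_covariate(self, term: str) -> np.ndarray:
        basis = self.design.bases[term]
        return basis._xs_train * basis._scale + basis._x0

    def _landform_effect(self) -> PartialEffect:
        if not self.spec.landform:
            raise ValueError("landform not in model")
        levels = self.design.landform_levels
        eff, se = [], []
        for lev in levels:
            if lev == self.design.reference_level:
                eff.append(0.0)
                se.append(0.0)
            else:
                i = self.design.X_names.index(f"landform[{lev}]")
                eff.append(float(self.beta[i]))
                se.append(float(np.sqrt(self.cov_coef[i, i])))
        return PartialEffect(term="landform", grid=np.array(levels, dtype=object),
                             effect=np.array(eff), se=np.array(se),
                             x_train=np.array(levels, dtype=object),
                             partial_residuals=self.residuals.copy())

    def to_json(self, path) -> None:
        """Serialise everything needed for exact re-prediction."""
        doc = {
            "spec": {"smooth_terms": list(self.spec.smooth_terms),
                     "landform": self.spec.landform, "random": self.spec.random,
                     "k": self.spec.k, "response": self.spec.response,
                     "reference_level": self.spec.reference_level},
            "beta": self.beta.tolist(),
            "beta_names": self.design.X_names,
            "b": self.b.tolist(),
            "p": self.design.p,
            "blocks": [(name, kind, sl.start, sl.stop)
                       for name, kind, sl in self.design.blocks],
            "tau_blocks": self.tau_blocks,
            "sigma2": self.sigma2,
            "loglik": self.loglik,
            "edf": self.edf_blocks,
            "cov_coef": self.cov_coef.tolist(),
            "landform_levels": self.design.landform_levels,
            "reference_level": self.design.reference_level,
            "plot_levels": self.design.plot_levels,
            "transect_levels": self.design.transect_levels,
            "bases": {t: b.to_dict() for t, b in self.design.bases.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "FittedGAMM":
        """Load a serialised fit for prediction and effect evaluation.

        The loaded object predicts exactly as the original; quantities
        requiring the training table itself (fitted values, partial
        residuals) are unavailable.
        """
        from types import SimpleNamespace

        with open(path) as fh:
            doc = json.load(fh)
        spec = GAMMSpec(smooth_terms=tuple(doc["spec"]["smooth_terms"]),
                        landform=doc["spec"]["landform"],
                        random=doc["spec"]["random"], k=doc["spec"]["k"],
                        response=doc["spec"]["response"],
                        reference_level=doc["spec"]["reference_level"])
        design = SimpleNamespace(
            X_names=doc["beta_names"], p=int(doc["p"]),
            blocks=[(name, kind, slice(a, b))
                    for name, kind, a, b in doc["blocks"]],
            bases={t: SmoothBasis.from_dict(d) for t, d in doc["bases"].items()},
            landform_levels=doc["landform_levels"],
            reference_level=doc["reference_level"],
            plot_levels=doc["plot_levels"],
            transect_levels=doc["transect_levels"])
        return cls(spec=spec, design=design,
                   beta=np.asarray(doc["beta"], dtype=float),
                   b=np.asarray(doc["b"], dtype=float),
                   tau_blocks=doc["tau_blocks"], sigma2=doc["sigma2"],
                   loglik=doc["loglik"], fitted=None, residuals=None,
                   cov_coef=np.asarray(doc["cov_coef"], dtype=float),
                   edf_blocks=doc["edf"])


def fit(table: pd.DataFrame, spec: GAMMSpec, *, bases: dict | None = None,
        tol: float = 1e-8) -> FittedGAMM:
    """Fit the additive mixed model by maximum likelihood.

    Smoothing parameters and variance components are found by optimising
    the profiled ML criterion over log variance ratios; the fit is
    deterministic for a given table and spec.  Pre-built smooth bases may
    be passed (and are shared during model selection).
    """
    design = _Design(table, spec, bases)
    n_blocks = len(design.blocks)

    if n_blocks:
        def neg_ll(rho):
            try:
                ll, _, _ = _profiled_ml(design, rho)
            except FitError:
                return 1e12
            return -ll

        res = optimize.minimize(neg_ll, np.zeros(n_blocks), method="L-BFGS-B",
                                bounds=[(-18.0, 18.0)] * n_blocks,
                                options={"ftol": tol, "gtol": 1e-7,
                                         "maxiter": 500})
        rho = res.x
    else:
        rho = np.zeros(0)
    ll, beta, sigma2 = _profiled_ml(design, rho)

    # final coefficients / covariance from the augmented (ridge) system
    tau = design.expand_tau(rho) if design.q else np.zeros(0)
    C = np.column_stack([design.X, design.Z]) if design.q else design.X
    CtC = C.T @ C
    P = np.zeros_like(CtC)
    if design.q:
        P[design.p:, design.p:] = np.diag(1.0 / tau)
    A = CtC + P
    Ainv = linalg.inv(A)
    theta = Ainv @ (C.T @ design.y)
    beta_hat = theta[:design.p]
    b_hat = theta[design.p:]
    fitted = C @ theta
    residuals = design.y - fitted
    F_diag = np.einsum("ij,ji->i", Ainv, CtC)

    edf_blocks, tau_blocks = {}, {}
    for (name, kind, sl), r in zip(design.blocks, rho):
        tau_blocks[name] = float(np.exp(r))
        if kind == "smooth":
            lin_i = design.X_names.index(f"s({name}).lin")
            edf_blocks[name] = float(F_diag[lin_i]
                                     + np.sum(F_diag[design.p + sl.start:
                                                     design.p + sl.stop]))

    return FittedGAMM(spec=spec, design=design, beta=beta_hat, b=b_hat,
                      tau_blocks=tau_blocks, sigma2=sigma2, loglik=float(ll),
                      fitted=fitted, residuals=residuals,
                      cov_coef=sigma2 * Ainv, edf_blocks=edf_blocks)
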