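"""REML estimation of half-sib trial variance components and family BLUPs.

The model is the standard multi-environment half-sib (HS) family plot model::

    y = M + location + season + year                      (fixed)
        + family + family:location + family:season + family:year
        + rep + row + col + error                         (random, iid normal)

with replicate nested in (location, season, year), and row and column effects
nested in replicate.  Variance parameters are estimated by maximising the
restricted log-likelihood directly (bounded quasi-Newton on the variance
scale), with standard errors from the average-information matrix at the
optimum.  Negative components are constrained at a small positive boundary.

Two computational routes share one public interface:

* when the random terms are all family-nested (family and its interactions),
  the marginal covariance is block-diagonal by family and everything is
  evaluated from small per-family blocks, grouped by identical design
  patterns — fast enough for thousands of families;
* replicate/row/column terms cross families, so the general route evaluates
  the restricted likelihood through sparse mixed-model equations.

Usage::

    model = HalfSibTrialModel.from_csv("trial.csv")
    res = model.fit()
    print(res.summary())
    vc = res.to_variance_components()
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import minimize

from .components import VarianceComponents

__all__ = ["HalfSibTrialModel", "REMLResults", "fit_reml", "DEFAULT_TERMS", "ALL_TERMS"]

DEFAULT_TERMS = ("family", "family:location", "family:season", "family:year")
ALL_TERMS = DEFAULT_TERMS + ("rep", "row", "col")
_FAMILY_NESTED = set(DEFAULT_TERMS)

_REQUIRED_COLS = ("family", "location", "season", "year", "value")


class HalfSibTrialModel:
    """Linear mixed model for long-format half-sib trial records.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per plot with columns ``family, location, season, year, value``
        and, if the corresponding random terms are requested, ``rep, row, col``.
    terms : sequence of str
        Random terms to fit, a subset of ``ALL_TERMS``.  The residual is always
        included.
    """

    def __init__(self, data: pd.DataFrame, terms: Sequence[str] = DEFAULT_TERMS):
        terms = tuple(terms)
        unknown = set(terms) - set(ALL_TERMS)
        if unknown:
            raise ValueError(f"unknown random terms: {sorted(unknown)}")
        need = set(_REQUIRED_COLS)
        if "rep" in terms or "row" in terms or "col" in terms:
            need.add("rep")
        if "row" in terms:
            need.add("row")
        if "col" in terms:
            need.add("col")
        missing = need - set(data.columns)
        if missing:
            raise ValueError(f"data is missing columns: {sorted(missing)}")
        # keep any layout columns present: they break ties in the canonical
        # record order, making the fit invariant to input permutation
        keep = need | ({"rep", "row", "col"} & set(data.columns))
        df = data.loc[:, sorted(keep, key=list(data.columns).index)].copy()
        y = np.asarray(df["value"], dtype=float)
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        if df["family"].nunique() < 2:
            raise ValueError("at least two families are required")
        if {"rep", "row", "col"} <= set(df.columns):
            key = df[["location", "season", "year", "rep", "row", "col"]]
            if key.duplicated().any():
                raise ValueError("duplicate (location, season, year, rep, row, col) records")
        # canonical record order makes the fit invariant to input permutation
        sort_cols = [c for c in ("family", "location", "season", "year", "rep",
                                 "row", "col", "value") if c in df.columns]
        self.data = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
        self.terms = terms
        self.nobs = len(self.data)
        self._build_fixed()

    @classmethod
    def from_csv(cls, path, terms: Sequence[str] = DEFAULT_TERMS) -> "HalfSibTrialModel":
        """Read ``family,location,season,year[,rep,row,col],value`` records."""
        return cls(pd.read_csv(path), terms=terms)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame,
                       terms: Sequence[str] = DEFAULT_TERMS) -> "HalfSibTrialModel":
        """Constructor alias in the spirit of statsmodels' from_* builders."""
        return cls(data, terms=terms)

    def _build_fixed(self) -> None:
        df = self.data
        cols = [np.ones(self.nobs)]
        names = ["mean"]
        for factor in ("location", "season", "year"):
            levels = np.sort(df[factor].unique())
            for lev in levels[1:]:
                cols.append((df[factor] == lev).to_numpy(float))
                names.append(f"{factor}[{lev}]")
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular fixed-effect design (disconnected levels)")
        self.exog = X
        self.exog_names = names
        self.endog = df["value"].to_numpy(float)

    def fit(self, maxiter: int = 500, tol: float = 1e-10,
            start: Optional[Sequence[float]] = None) -> "REMLResults":
        """Maximise the restricted likelihood and return a results object."""
        if set(self.terms) <= _FAMILY_NESTED:
            return _fit_family_blocks(self, maxiter, tol, start)
        return _fit_sparse_mme(self, maxiter, tol, start)


@dataclass
class REMLResults:
    """REML fit of a :class:`HalfSibTrialModel`.

    ``params`` maps each random term (plus ``"residual"``) to its variance
    estimate; ``bse`` holds the matching standard errors from the
    average-information matrix.  ``fe_params`` are the fixed effects,
    ``llf`` the restricted log-likelihood at the optimum.
    """

    model: HalfSibTrialModel
    params: dict
    bse: dict
    fe_params: pd.Series
    llf: float
    converged: bool
    n_iter: int
    _blup: pd.Series = field(repr=False, default=None)
    _grand_mean: float = field(repr=False, default=0.0)

    @property
    def overall_mean(self) -> float:
        """Average fitted fixed-effect value across all plots."""
        return self._grand_mean

    def family_effects(self) -> pd.Series:
        """BLUPs of the family effects (deviations from the overall mean)."""
        return self._blup.copy()

    def family_blups(self) -> pd.Series:
        """Shrunken family means: overall mean plus the family-effect BLUP."""
        return self._blup + self._grand_mean

    def to_variance_components(self) -> VarianceComponents:
        """Map the fit onto the slots consumed by the deterministic engine."""
        if not self.converged:
            raise ValueError("REML fit did not converge; refusing to export components")
        g = self.params.get
        return VarianceComponents(
            family=g("family", 0.0),
            family_x_year=g("family:year", 0.0),
            family_x_season=g("family:season", 0.0),
            family_x_location=g("family:location", 0.0),
            residual=g("residual", 0.0),
        )

    def summary(self) -> str:
        lines = [
            "Half-sib trial REML fit",
            "=" * 58,
            f"No. observations: {self.model.nobs:>8}    "
            f"No. families: {self.model.data['family'].nunique()}",
            f"Restricted log-likelihood: {self.llf:.3f}    "
            f"Converged: {self.converged}",
            "",
            "Variance components (kg^2 ha^-2)",
            "-" * 58,
            f"{'term':<20}{'estimate':>14}{'std. error':>14}",
        ]
        for k, v in self.params.items():
            se = self.bse.get(k, float("nan"))
            lines.append(f"{k:<20}{v:>14.1f}{se:>14.1f}")
        lines += ["", "Fixed effects (kg ha^-1)", "-" * 58]
        for k, v in self.fe_params.items():
            lines.append(f"{k:<20}{v:>14.2f}")
        return "\n".join(lines)


def fit_reml(data: pd.DataFrame, terms: Sequence[str] = DEFAULT_TERMS,
             **kwargs) -> REMLResults:
    """Convenience wrapper: build a :class:`HalfSibTrialModel` and fit it."""
    return HalfSibTrialModel(data, terms=terms).fit(**kwargs)


# ---------------------------------------------------------------------------
# family-block route: random terms all nested within family
# ---------------------------------------------------------------------------

class _PatternGroup:
    """Families sharing an identical within-family design."""

    def __init__(self, Y: np.ndarray, X: np.ndarray, Zs: list[np.ndarray]):
        self.Y = Y          # (F, n) responses
        self.X = X          # (n, p) fixed design, identical across the group
        self.Zs = Zs        # per random term: (n, r) indicator matrix
        self.F, self.n = Y.shape


def _family_groups(model: HalfSibTrialModel) -> tuple[list[_PatternGroup], list, np.ndarray]:
    df = model.data
    X = model.exog
    y = model.endog
    terms = model.terms
    fam_codes, fam_levels = pd.factorize(df["family"], sort=True)
    # pattern key: the exact sequence of (design row, factor levels) per family
    factor_codes = {}
    for factor in ("location", "season", "year"):
        factor_codes[factor] = pd.factorize(df[factor], sort=True)[0]
    nlev = {f: factor_codes[f].max() + 1 for f in factor_codes}

    order = np.argsort(fam_codes, kind="mergesort")
    groups: dict[bytes, list[int]] = {}
    fam_rows: list[np.ndarray] = []
    n_fam = len(fam_levels)
    bounds = np.searchsorted(fam_codes[order], np.arange(n_fam + 1))
    keys = []
    for i in range(n_fam):
        rows = order[bounds[i]:bounds[i + 1]]
        fam_rows.append(rows)
        sig = np.column_stack([factor_codes[f][rows] for f in ("location", "season", "year")])
        keys.append(sig.tobytes())
        groups.setdefault(keys[i], []).append(i)

    out = []
    blup_index = []
    for key, fams in groups.items():
        rows0 = fam_rows[fams[0]]
        Xg = X[rows0]
        Zs = []
        for t in terms:
            if t == "family":
                Zs.append(np.ones((len(rows0), 1)))
            else:
                factor = t.split(":")[1]
                codes = factor_codes[factor][rows0]
                Z = np.zeros((len(rows0), nlev[factor]))
                Z[np.arange(len(rows0)), codes] = 1.0
                Zs.append(Z)
        Yg = np.stack([y[fam_rows[i]] for i in fams])
        out.append(_PatternGroup(Yg, Xg, Zs))
        blup_index.extend(fams)
    return out, list(fam_levels), np.array(blup_index)


def _block_restricted_loglik(theta: np.ndarray, groups: list[_PatternGroup],
                             p: int, want_grad: bool):
    """-2·restricted log-likelihood (up to 2π constant handled by caller)."""
    K = len(theta) - 1
    logdetV = 0.0
    yViy = 0.0
    XtViX = 0.0
    XtViy = 0.0
    cache = []
    for g in groups:
        V = theta[-1] * np.eye(g.n)
        for k in range(K):
            Z = g.Zs[k]
            V += theta[k] * (Z @ Z.T)
        L = np.linalg.cholesky(V)
        Vi = np.linalg.inv(V)
        logdetV += g.F * 2.0 * np.sum(np.log(np.diag(L)))
        yViy += float(np.einsum("fi,ij,fj->", g.Y, Vi, g.Y))
        XtViX = XtViX + g.F * (g.X.T @ Vi @ g.X)
        XtViy = XtViy + g.X.T @ Vi @ g.Y.sum(axis=0)
        cache.append(Vi)
    sign, logdetXtViX = np.linalg.slogdet(XtViX)
    XtViX_inv = np.linalg.inv(XtViX)
    beta = XtViX_inv @ XtViy
    yPy = yViy - float(beta @ XtViy)
    neg2l = logdetV + logdetXtViX + yPy

    if not want_grad:
        return neg2l, beta, XtViX_inv, cache

    grad = np.zeros(K + 1)
    for g, Vi in zip(groups, cache):
        R = g.Y @ Vi - (g.X @ beta) @ Vi  # rows: (y_i - X beta)' Vi  => Py rows
        ViX = Vi @ g.X
        for k in range(K + 1):
            if k < K:
                Z = g.Zs[k]
                ViZ = Vi @ Z
                tr_block = g.F * float(np.einsum("ij,ij->", Z, ViZ))
                XtViB = ViX.T @ Z @ ViZ.T @ g.X
                tr_corr = g.F * float(np.einsum("ij,ji->", XtViX_inv, XtViB))
                S = R @ Z
                quad = float(np.einsum("fi,fi->", S, S))
            else:
                tr_block = g.F * float(np.trace(Vi))
                XtViB = ViX.T @ ViX
                tr_corr = g.F * float(np.einsum("ij,ji->", XtViX_inv, XtViB))
                quad = float(np.einsum("fi,fi->", R, R))
            grad[k] += tr_block - tr_corr - quad
    return neg2l, grad, beta, XtViX_inv, cache


def _fit_family_blocks(model: HalfSibTrialModel, maxiter: int, tol: float,
                       start) -> REMLResults:
    groups, fam_levels, blup_index = _family_groups(model)
    p = model.exog.shape[1]
    K = len(model.terms)
    vary = float(np.var(model.endog))
    lb = max(vary, 1.0) * 1e-10
    if start is None:
        theta0 = np.full(K + 1, vary / (K + 1))
        theta0[-1] = vary / 2.0
    else:
        theta0 = np.asarray(start, float)

    def obj(theta):
        neg2l, grad, *_ = _block_restricted_loglik(theta, groups, p, True)
        return 0.5 * neg2l, 0.5 * grad

    res = minimize(obj, theta0, jac=True, method="L-BFGS-B",
                   bounds=[(lb, None)] * (K + 1),
                   options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-8})
    theta = np.maximum(res.x, lb)

    # polish with average-information scoring steps: quadratic convergence to
    # the interior optimum, so balanced-data fits match closed-form estimators
    # to near machine precision
    converged = bool(res.success)
    f_cur, grad, beta, XtViX_inv, Vis = _block_restricted_loglik(
        theta, groups, p, True)
    for _ in range(60):
        g = 0.5 * np.asarray(grad)
        free = (theta > lb * 1.5) | (g < 0)
        gnorm = float(np.max(np.abs(g[free]))) if free.any() else 0.0
        if gnorm < 1e-9 * max(1.0, abs(f_cur)) * 1e-3 or gnorm < 1e-10:
            converged = True
            break
        AI = _block_ai_matrix(theta, groups, beta, XtViX_inv, Vis)
        step = np.zeros_like(theta)
        try:
            step[free] = np.linalg.solve(AI[np.ix_(free, free)], g[free])
        except np.linalg.LinAlgError:
            break
        improved = False
        for _ls in range(30):
            cand = np.maximum(theta - step, lb)
            f_new, grad_new, beta_n, Xi_n, Vis_n = _block_restricted_loglik(
                cand, groups, p, True)
            if f_new <= f_cur + 1e-12 * abs(f_cur):
                theta, f_cur, grad = cand, f_new, grad_new
                beta, XtViX_inv, Vis = beta_n, Xi_n, Vis_n
                improved = True
                break
            step *= 0.5
        if not improved:
            break
        if np.max(np.abs(step)) < 1e-12 * np.max(np.abs(theta)):
            converged = True
            break

    neg2l, beta, XtViX_inv, Vis = _block_restricted_loglik(theta, groups, p, False)
    llf = -0.5 * (neg2l + (model.nobs - p) * math.log(2.0 * math.pi))

    # average-information matrix at the optimum -> standard errors
    AI = _block_ai_matrix(theta, groups, beta, XtViX_inv, Vis)
    bse = _bse_from_information(AI, list(model.terms) + ["residual"])

    # family BLUPs: u_i = sigma2_f * 1' Vi (y_i - X beta)
    blups = np.empty(len(fam_levels))
    pos = 0
    if "family" in model.terms:
        k_f = model.terms.index("family")
        for g, Vi in zip(groups, Vis):
            resid = g.Y - g.X @ beta
            u = theta[k_f] * (resid @ Vi).sum(axis=1)
            blups[pos:pos + g.F] = u
            pos += g.F
        order = np.empty_like(blup_index)
        order[blup_index] = np.arange(len(blup_index))
        blups = blups[order]
    else:
        blups[:] = 0.0

    params = {t: float(v) for t, v in zip(model.terms, theta[:-1])}
    params["residual"] = float(theta[-1])
    fe = pd.Series(beta, index=model.exog_names)
    grand = float(np.mean(model.exog @ beta))
    return REMLResults(
        model=model, params=params, bse=bse, fe_params=fe, llf=llf,
        converged=converged, n_iter=int(res.nit),
        _blup=pd.Series(blups, index=pd.Index(fam_levels, name="family")),
        _grand_mean=grand,
    )


def _block_ai_matrix(theta, groups, beta, XtViX_inv, Vis) -> np.ndarray:
    K = len(theta) - 1
    # w_k = B_k P y assembled per family; then AI_jk = 0.5 w_j' P w_k
    Py_rows, W = [], [[] for _ in range(K + 1)]
    for g, Vi in zip(groups, Vis):
        Py = (g.Y - g.X @ beta) @ Vi
        Py_rows.append(Py)
        for k in range(K):
            Z = g.Zs[k]
            W[k].append((Py @ Z) @ Z.T)
        W[K].append(Py)
    AI = np.zeros((K + 1, K + 1))
    # P w = Vi w - Vi X (XtViX)^-1 (X' Vi w); accumulate the global X' Vi w first
    XtViW = np.zeros((len(beta), K + 1))
    for gi, (g, Vi) in enumerate(zip(groups, Vis)):
        ViX = Vi @ g.X
        for k in range(K + 1):
            XtViW[:, k] += np.einsum("ip,fi->p", ViX, W[k][gi])
    corr = XtViX_inv @ XtViW
    for gi, (g, Vi) in enumerate(zip(groups, Vis)):
        ViX = Vi @ g.X
        for k in range(K + 1):
            PWk = W[k][gi] @ Vi - np.tile((g.X @ corr[:, k]) @ Vi, (g.F, 1))
            for j in range(k + 1):
                AI[j, k] += 0.5 * float(np.einsum("fi,fi->", W[j][gi], PWk))
    return AI + np.triu(AI, 1).T


def _bse_from_information(AI: np.ndarray, names: list[str]) -> dict:
    try:
        cov = np.linalg.inv(AI)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        return {n: float(s) for n, s in zip(names, se)}
    except np.linalg.LinAlgError:
        return {n: float("nan") for n in names}


# ---------------------------------------------------------------------------
# general sparse route: mixed-model equations for crossed terms
# ---------------------------------------------------------------------------

def _term_design(model: HalfSibTrialModel, term: str) -> sp.csc_matrix:
    df = model.data
    if term == "family":
        codes = pd.factorize(df["family"], sort=True)[0]
    elif term.startswith("family:"):
        factor = term.split(":")[1]
        key = df["family"].astype(str) + "|" + df[factor].astype(str)
        codes = pd.factorize(key, sort=True)[0]
    elif term == "rep":
        key = df[["location", "season", "year", "rep"]].astype(str).agg("|".join, axis=1)
        codes = pd.factorize(key, sort=True)[0]
    elif term in ("row", "col"):
        key = df[["location", "season", "year", "rep", term]].astype(str).agg("|".join, axis=1)
        codes = pd.factorize(key, sort=True)[0]
    else:  # pragma: no cover
        raise ValueError(term)
    n = len(df)
    q = codes.max() + 1
    return sp.csc_matrix((np.ones(n), (np.arange(n), codes)), shape=(n, q))


def _fit_sparse_mme(model: HalfSibTrialModel, maxiter: int, tol: float,
                    start) -> REMLResults:
    y = model.endog
    X = sp.csc_matrix(model.exog)
    Zs = [_term_design(model, t) for t in model.terms]
    qs = [Z.shape[1] for Z in Zs]
    W = sp.hstack([X] + Zs, format="csc")
    M = (W.T @ W).tocsc()
    Wty = W.T @ y
    yty = float(y @ y)
    n, p = model.nobs, model.exog.shape[1]
    K = len(Zs)
    vary = float(np.var(y))
    lb = max(vary, 1.0) * 1e-10

    Ginv_template = np.concatenate([[0.0] * p] + [[1.0] * q for q in qs])
    blocks = np.concatenate([[-1] * p] + [[k] * q for k, q in enumerate(qs)])

    def factorize(theta):
        s2e = theta[-1]
        d = np.zeros(p + sum(qs))
        for k in range(K):
            d[blocks == k] = 1.0 / theta[k]
        C = M / s2e + sp.diags(d)
        return spla.splu(C.tocsc()), d

    def neg2l_of(theta):
        s2e = theta[-1]
        lu, d = factorize(theta)
        rhs = Wty / s2e
        a = lu.solve(rhs)
        yPy = (yty - float(a @ Wty)) / s2e
        logdetC = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        logdetG = float(np.sum([qs[k] * math.log(theta[k]) for k in range(K)]))
        return n * math.log(s2e) + logdetG + logdetC + yPy, a, lu

    # optimise on the log-variance scale: scale-free finite-difference
    # gradients and positivity for free; the lower bound acts as the
    # zero-boundary constraint
    def obj(x):
        v, _, _ = neg2l_of(np.exp(x))
        return 0.5 * v

    theta0 = (np.asarray(start, float) if start is not None
              else np.full(K + 1, vary / (K + 1)))
    x0 = np.log(np.maximum(theta0, lb))
    bnds = [(math.log(lb), math.log(vary) + 12.0)] * (K + 1)
    res = minimize(obj, x0, method="L-BFGS-B", bounds=bnds,
                   options={"maxiter": maxiter, "ftol": tol, "eps": 1e-6})
    res2 = minimize(obj, res.x, method="Nelder-Mead",
                    options={"maxiter": 4000 if not res.success else 400,
                             "fatol": 1e-9, "xatol": 1e-9})
    best = res2 if res2.fun <= res.fun else res
    theta = np.maximum(np.exp(np.clip(best.x, *zip(*bnds))), lb)
    neg2l, a, lu = neg2l_of(theta)
    llf = -0.5 * (neg2l + (n - p) * math.log(2.0 * math.pi))
    beta = a[:p]
    u = a[p:]

    s2e = theta[-1]
    resid = y - W @ a
    Py = resid / s2e

    def apply_P(v):
        return (v - W @ lu.solve((W.T @ v) / s2e)) / s2e

    ws = [Zs[k] @ (Zs[k].T @ Py) for k in range(K)] + [Py]
    AI = np.zeros((K + 1, K + 1))
    Pws = [apply_P(w) for w in ws]
    for j in range(K + 1):
        for k in range(j, K + 1):
            AI[j, k] = AI[k, j] = 0.5 * float(ws[j] @ Pws[k])
    names = list(model.terms) + ["residual"]
    try:
        se = np.sqrt(np.clip(np.diag(np.linalg.inv(AI)), 0.0, None))
        bse = {nm: float(s) for nm, s in zip(names, se)}
    except np.linalg.LinAlgError:
        bse = {nm: float("nan") for nm in names}

    params = {t: float(v) for t, v in zip(model.terms, theta[:-1])}
    params["residual"] = float(s2e)
    fe = pd.Series(beta, index=model.exog_names)
    grand = float(np.mean(model.exog @ beta))
    if "family" in model.terms:
        k = model.terms.index("family")
        off = int(np.sum(qs[:k]))
        fam_levels = pd.factorize(model.data["family"], sort=True)[1]
        blup = pd.Series(u[off:off + qs[k]], index=pd.Index(fam_levels, name="family"))
    else:
        fam_levels = pd.factorize(model.data["family"], sort=True)[1]
        blup = pd.Series(0.0, index=pd.Index(fam_levels, name="family"))
    return REMLResults(
        model=model, params=params, bse=bse, fe_params=fe, llf=llf,
        converged=bool(res.success or res2.success), n_iter=int(res.nit + res2.nit),
        _blup=blup, _grand_mean=grand,
    )
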