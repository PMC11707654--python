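"""Per-trait MET linear mixed models: EM-REML, BLUP, LRT and joint ANOVA.

The model for one trait is

    y = X beta + Z_g u_g + Z_ge u_ge + eps,

with environments and complete replicates (blocks within environments) as
fixed effects, genotype and genotype-by-environment as independent random
effects, u_g ~ N(0, sigma2_g I), u_ge ~ N(0, sigma2_ge I),
eps ~ N(0, sigma2_e I).  Variance components are estimated by restricted
maximum likelihood with the expectation-maximisation algorithm on
Henderson's mixed-model equations; the genotype-by-environment block is
absorbed analytically (its Z'Z is diagonal), so one EM step costs
O((p + g)^3) regardless of the number of observations.

On balanced data the REML solution coincides with the classical ANOVA
moment estimators; the fit is initialised at those estimators, which makes
the balanced case converge immediately and gives unbalanced fits a warm
start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
from scipy import stats

__all__ = [
    "VarianceComponents",
    "FittedMETModel",
    "fit_met_mixed",
    "lrt_random_effects",
    "extract_blups",
    "blup_two_way",
    "joint_anova",
    "residual_normality",
    "anova_moment_estimates",
]


@dataclass
class VarianceComponents:
    """REML variance components and the bookkeeping needed downstream."""

    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    grand_mean: float
    n_env: int
    n_blocks: int

    @property
    def phenotypic_variance(self) -> float:
        return self.sigma2_g + self.sigma2_ge + self.sigma2_e


@dataclass
class FittedMETModel:
    trait: str
    fixed_estimates: pd.Series
    random_g: pd.Series
    random_ge: pd.Series  # indexed by (genotype, environment) of observed cells
    variance_components: VarianceComponents
    restricted_loglik: float
    n_iterations: int
    converged: bool
    loglik_trace: np.ndarray
    residuals: np.ndarray
    env_means: pd.Series  # fixed-effect mean per environment (averaged over blocks)
    has_ge_term: bool = True
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# data preparation


def _prepare_trait(table: pd.DataFrame, trait: str):
    sub = table.loc[table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} not present in the table")
    y = sub["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite values for trait {trait!r}")
    geno = pd.Categorical(sub["genotype"], categories=sorted(sub["genotype"].unique()))
    env = pd.Categorical(sub["environment"], categories=sorted(sub["environment"].unique()))
    blk = pd.Categorical(sub["block"], categories=sorted(sub["block"].unique()))
    if len(geno.categories) < 2:
        raise ValueError("need at least 2 genotypes")
    return y, geno, env, blk


def _fixed_design(env: pd.Categorical, blk: pd.Categorical):
    """Full-rank fixed design: intercept + env + block-within-env (treatment)."""
    n = len(env)
    e, b = len(env.categories), len(blk.categories)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    for j in range(1, e):
        cols.append((env.codes == j).astype(float))
        names.append(f"env[{env.categories[j]}]")
    for j in range(e):
        for k in range(1, b):
            cols.append(((env.codes == j) & (blk.codes == k)).astype(float))
            names.append(f"rep[{env.categories[j]}:{blk.categories[k]}]")
    return np.column_stack(cols), names


def _fixed_cell_means(beta: np.ndarray, names: list[str], env_cats, blk_cats):
    """Fixed-effect mean of every environment x block cell (balanced grid)."""
    e, b = len(env_cats), len(blk_cats)
    out = np.zeros((e, b))
    lookup = {nm: v for nm, v in zip(names, beta)}
    for j, ec in enumerate(env_cats):
        for k, bc in enumerate(blk_cats):
            v = lookup["(Intercept)"]
            v += lookup.get(f"env[{ec}]", 0.0)
            v += lookup.get(f"rep[{ec}:{bc}]", 0.0)
            out[j, k] = v
    return out


# ---------------------------------------------------------------------------
# EM-REML core


def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    Z = np.zeros((len(codes), n_levels))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def anova_moment_estimates(y, gcodes, ecodes, bcodes, g, e, b) -> dict[str, float]:
    """Balanced-ANOVA moment estimators of (sigma2_g, sigma2_ge, sigma2_e).

    Exact on balanced data (sigma2_e = MSE, sigma2_ge = (MS_GE - MSE)/b,
    sigma2_g = (MS_G - MS_GE)/(b e)); on unbalanced data the same sums with
    observed cell means give an approximation used only as an EM warm start.
    Estimates are truncated at zero.
    """
    n = len(y)
    grand = y.mean()
    gm = np.bincount(gcodes, weights=y, minlength=g) / np.maximum(
        np.bincount(gcodes, minlength=g), 1)
    em = np.bincount(ecodes, weights=y, minlength=e) / np.maximum(
        np.bincount(ecodes, minlength=e), 1)
    cell = gcodes * e + ecodes
    c_cnt = np.maximum(np.bincount(cell, minlength=g * e), 1)
    cm = (np.bincount(cell, weights=y, minlength=g * e) / c_cnt).reshape(g, e)
    eb = ecodes * b + bcodes
    eb_cnt = np.maximum(np.bincount(eb, minlength=e * b), 1)
    ebm = np.bincount(eb, weights=y, minlength=e * b) / eb_cnt

    b_eff = n / (g * e)  # replicates per cell (b on balanced data)
    ms_g = e * b_eff * np.sum((gm - grand) ** 2) / (g - 1)
    if e > 1:
        inter = cm - gm[:, None] - em[None, :] + grand
        ms_ge = b_eff * np.sum(inter**2) / ((g - 1) * (e - 1))
    else:
        ms_ge = 0.0
    resid = y - cm[gcodes, ecodes] - (ebm[eb] - em[ecodes])
    df_res = max(n - g * e - e * (b - 1), 1)
    mse = np.sum(resid**2) / df_res
    s2e = max(mse, 0.0)
    s2ge = max((ms_ge - mse) / b_eff, 0.0) if e > 1 else 0.0
    s2g = max((ms_g - ms_ge) / (e * b_eff), 0.0) if e > 1 else max(
        (ms_g - mse) / b_eff, 0.0)
    return {"sigma2_g": s2g, "sigma2_ge": s2ge, "sigma2_e": s2e}


def _em_reml(
    y: np.ndarray,
    X: np.ndarray,
    dense_terms: list[tuple[str, np.ndarray, int]],
    diag_term: tuple[str, np.ndarray, int] | None,
    start: dict[str, float],
    tol: float = 1e-8,
    max_iter: int = 500,
    floor_frac: float = 1e-10,
):
    """EM-REML for a Gaussian mixed model with independent random factors.

    ``dense_terms`` enter the mixed-model equations explicitly; ``diag_term``
    (a factor for which each observation carries exactly one level, so Z'Z is
    diagonal) is absorbed by its Schur complement.  Returns estimates, BLUPs,
    the restricted log-likelihood and its per-iteration trace (non-decreasing
    by EM theory; asserted in the test suite).
    """
    n, p = X.shape
    blocks = [X] + [_indicator(c, q) for (_, c, q) in dense_terms]
    W1 = np.hstack(blocks)
    m1 = W1.shape[1]
    slices, pos = {}, p
    for name, _, q in dense_terms:
        slices[name] = slice(pos, pos + q)
        pos += q
    A = W1.T @ W1
    c1 = W1.T @ y
    yTy = float(y @ y)
    if diag_term is not None:
        dname, dcodes, q2 = diag_term
        d0 = np.bincount(dcodes, minlength=q2).astype(float)
        b2 = np.bincount(dcodes, weights=y, minlength=q2)
        B = np.zeros((q2, m1))
        np.add.at(B, dcodes, W1)
    q_tot = sum(q for _, _, q in dense_terms) + (q2 if diag_term is not None else 0)

    floor = floor_frac * max(float(np.var(y)), np.finfo(float).tiny)
    sigma = {k: max(v, floor) for k, v in start.items()}

    def _solve(sig):
        se2 = sig["residual"]
        S = A.copy()
        for name, _, _q in dense_terms:
            sl = slices[name]
            S[np.arange(sl.start, sl.stop), np.arange(sl.start, sl.stop)] += se2 / sig[name]
        if diag_term is not None:
            Dv = d0 + se2 / sig[dname]
            Bw = B / Dv[:, None]
            S -= B.T @ Bw
            rhs = c1 - B.T @ (b2 / Dv)
        else:
            Dv = Bw = None
            rhs = c1
        try:
            cf = sla.cho_factor(S, lower=True)
        except sla.LinAlgError:
            S = S + np.eye(m1) * 1e-8 * np.trace(S) / m1
            cf = sla.cho_factor(S, lower=True)
        alpha = sla.cho_solve(cf, rhs)
        logdetS = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        # dpotri: inverse from the Cholesky factor, ~3x cheaper than a solve
        # against the identity
        inv_half, info = sla.lapack.dpotri(cf[0], lower=True)
        if info != 0:
            Sinv = sla.cho_solve(cf, np.eye(m1))
        else:
            lower_tri = np.tril(inv_half)
            Sinv = lower_tri + np.tril(inv_half, -1).T
        if diag_term is not None:
            u2 = (b2 - B @ alpha) / Dv
            quad = yTy - alpha @ c1 - u2 @ b2
            logdetM = logdetS + float(np.log(Dv).sum())
        else:
            u2 = None
            quad = yTy - alpha @ c1
            logdetM = logdetS
        quad = max(float(quad), np.finfo(float).tiny)
        m2ll = (n - p - q_tot) * np.log(se2) + logdetM + quad / se2
        for name, _, q in dense_terms:
            m2ll += q * np.log(sig[name])
        if diag_term is not None:
            m2ll += q2 * np.log(sig[dname])
        m2ll += (n - p) * np.log(2.0 * np.pi)
        return {
            "alpha": alpha, "Sinv": Sinv, "u2": u2, "quad": quad,
            "Dv": Dv, "Bw": Bw, "loglik": -0.5 * float(m2ll),
        }

    trace = []
    converged = False
    it = 0
    stagnant = 0
    state = _solve(sigma)
    for it in range(1, max_iter + 1):
        trace.append(state["loglik"])
        se2 = sigma["residual"]
        new = {}
        for name, _, q in dense_terms:
            sl = slices[name]
            u = state["alpha"][sl]
            new[name] = (float(u @ u) + se2 * float(np.trace(state["Sinv"][sl, sl]))) / q
        if diag_term is not None:
            Bw = state["Bw"]
            tr_d = float((1.0 / state["Dv"]).sum()) + float(
                np.sum(state["Sinv"] * (Bw.T @ Bw)))
            u2 = state["u2"]
            new[dname] = (float(u2 @ u2) + se2 * tr_d) / q2
        new["residual"] = state["quad"] / (n - p)
        new = {k: max(v, floor) for k, v in new.items()}
        # components collapsing to the boundary change by a near-constant
        # ratio forever; judge their change relative to the response scale
        scale = 1e-8 * max(float(np.var(y)), np.finfo(float).tiny)
        rel = max(abs(new[k] - sigma[k]) / max(sigma[k], scale) for k in sigma)
        sigma = new
        prev_ll = state["loglik"]
        state = _solve(sigma)
        rel_ll = abs(state["loglik"] - prev_ll) / max(abs(prev_ll), 1.0)
        if rel_ll < tol and rel < tol:
            converged = True
            break
        # a component drifting toward the boundary moves the likelihood by
        # nothing: a persistently flat likelihood also counts as converged
        stagnant = stagnant + 1 if rel_ll < 10.0 * tol else 0
        if stagnant >= 10:
            converged = True
            break
    trace.append(state["loglik"])

    out = {
        "sigma2": sigma,
        "beta": state["alpha"][:p],
        "u_dense": {name: state["alpha"][slices[name]] for name, _, _q in dense_terms},
        "u_diag": state["u2"],
        "loglik": state["loglik"],
        "n_iter": it,
        "converged": converged,
        "trace": np.asarray(trace),
    }
    return out


def _ols_reml(y: np.ndarray, X: np.ndarray):
    """Closed-form REML of the fixed-effects-only model."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    se2 = max(rss / (n - p), np.finfo(float).tiny)
    sign, logdet_xx = np.linalg.slogdet(X.T @ X)
    m2ll = (n - p) * np.log(se2) + logdet_xx + rss / se2 + (n - p) * np.log(2 * np.pi)
    return {"sigma2": {"residual": se2}, "beta": beta, "loglik": -0.5 * m2ll}


# ---------------------------------------------------------------------------
# public fitting API


def fit_met_mixed(
    table: pd.DataFrame,
    trait: str,
    tol: float = 1e-8,
    max_iter: int = 500,
    start: dict[str, float] | None = None,
    include_ge: bool | None = None,
) -> FittedMETModel:
    """Fit the MET mixed model for one trait by EM-REML.

    ``include_ge`` defaults to True when the table holds more than one
    environment; with a single environment the interaction is inestimable
    and a reduced model (genotype only) is fitted with a flag.

    ``start`` may override the warm-start variance components, keyed by
    ``genotype``, ``gxe`` and ``residual`` — useful for testing convergence
    from arbitrary points.
    """
    y, geno, env, blk = _prepare_trait(table, trait)
    g, e, b = len(geno.categories), len(env.categories), len(blk.categories)
    flags = []
    if include_ge is None:
        include_ge = e > 1
    if include_ge and e < 2:
        include_ge = False
    if not include_ge and e > 1:
        flags.append("ge_term_excluded")
    if e < 2:
        flags.append("single_environment:sigma2_ge_inestimable")

    X, xnames = _fixed_design(env, blk)
    gcodes = geno.codes.astype(np.int64)
    ecodes = env.codes.astype(np.int64)
    bcodes = blk.codes.astype(np.int64)

    if np.var(y) <= 1e-28 * max(1.0, float(np.mean(y)) ** 2):
        # constant response: every variance is zero and the likelihood is
        # unbounded; report the exact fixed-effect solution and flag it
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        cellfix = _fixed_cell_means(beta, xnames, env.categories, blk.categories)
        vc = VarianceComponents(0.0, 0.0, 0.0, float(cellfix.mean()), e, b)
        return FittedMETModel(
            trait=trait, fixed_estimates=pd.Series(beta, index=xnames),
            random_g=pd.Series(0.0, index=list(geno.categories)),
            random_ge=pd.Series(dtype=float, index=pd.MultiIndex.from_arrays(
                [[], []], names=["genotype", "environment"])),
            variance_components=vc, restricted_loglik=np.nan, n_iterations=0,
            converged=True, loglik_trace=np.array([]),
            residuals=y - X @ beta,
            env_means=pd.Series(cellfix.mean(axis=1), index=list(env.categories)),
            has_ge_term=False,
            flags=flags + ["degenerate_constant_response"],
        )

    mom = anova_moment_estimates(y, gcodes, ecodes, bcodes, g, e, b)
    s0 = {
        "genotype": mom["sigma2_g"],
        "gxe": mom["sigma2_ge"],
        "residual": mom["sigma2_e"],
    }
    if start:
        s0.update(start)

    if include_ge:
        cell = gcodes * e + ecodes
        observed = np.unique(cell)
        cmap = {c: i for i, c in enumerate(observed)}
        ccodes = np.array([cmap[c] for c in cell])
        res = _em_reml(
            y, X,
            dense_terms=[("genotype", gcodes, g)],
            diag_term=("gxe", ccodes, len(observed)),
            start={"genotype": s0["genotype"], "gxe": s0["gxe"],
                   "residual": s0["residual"]},
            tol=tol, max_iter=max_iter,
        )
        u_ge = res["u_diag"]
        ge_index = pd.MultiIndex.from_tuples(
            [(geno.categories[c // e], env.categories[c % e]) for c in observed],
            names=["genotype", "environment"],
        )
        sigma2_ge = res["sigma2"]["gxe"]
    else:
        res = _em_reml(
            y, X,
            dense_terms=[],
            diag_term=("genotype", gcodes, g),
            start={"genotype": s0["genotype"], "residual": s0["residual"]},
            tol=tol, max_iter=max_iter,
        )
        res["u_dense"] = {"genotype": res["u_diag"]}
        u_ge = np.zeros(0)
        ge_index = pd.MultiIndex.from_arrays([[], []], names=["genotype", "environment"])
        sigma2_ge = 0.0

    if not res["converged"]:
        warnings.warn(f"EM-REML did not converge for trait {trait!r} "
                      f"within {max_iter} iterations")
        flags.append("non_convergence")

    beta = res["beta"]
    cellfix = _fixed_cell_means(beta, xnames, env.categories, blk.categories)
    grand_mean = float(cellfix.mean())
    env_means = pd.Series(cellfix.mean(axis=1), index=list(env.categories))

    u_g = res["u_dense"]["genotype"]
    fitted = X @ beta + u_g[gcodes]
    if include_ge:
        fitted = fitted + u_ge[ccodes]
    residuals = y - fitted

    vc = VarianceComponents(
        sigma2_g=float(res["sigma2"]["genotype"]),
        sigma2_ge=float(sigma2_ge),
        sigma2_e=float(res["sigma2"]["residual"]),
        grand_mean=grand_mean,
        n_env=e,
        n_blocks=b,
    )
    return FittedMETModel(
        trait=trait,
        fixed_estimates=pd.Series(beta, index=xnames),
        random_g=pd.Series(u_g, index=list(geno.categories)),
        random_ge=pd.Series(u_ge, index=ge_index),
        variance_components=vc,
        restricted_loglik=float(res["loglik"]),
        n_iterations=res["n_iter"],
        converged=res["converged"],
        loglik_trace=res["trace"],
        residuals=residuals,
        env_means=env_means,
        has_ge_term=include_ge,
        flags=flags,
    )


def _reduced_loglik(table, trait, drop: str, tol, max_iter) -> tuple[float, bool]:
    """Restricted log-likelihood of the model without one random term."""
    y, geno, env, blk = _prepare_trait(table, trait)
    g, e, b = len(geno.categories), len(env.categories), len(blk.categories)
    X, _ = _fixed_design(env, blk)
    gcodes = geno.codes.astype(np.int64)
    ecodes = env.codes.astype(np.int64)
    bcodes = blk.codes.astype(np.int64)
    mom = anova_moment_estimates(y, gcodes, ecodes, bcodes, g, e, b)
    if drop == "genotype":
        if e < 2:
            res = _ols_reml(y, X)
            return res["loglik"], True
        cell = gcodes * e + ecodes
        observed = np.unique(cell)
        cmap = {c: i for i, c in enumerate(observed)}
        ccodes = np.array([cmap[c] for c in cell])
        res = _em_reml(
            y, X, dense_terms=[], diag_term=("gxe", ccodes, len(observed)),
            start={"gxe": mom["sigma2_ge"] + mom["sigma2_g"],
                   "residual": mom["sigma2_e"]},
            tol=tol, max_iter=max_iter)
    elif drop == "gxe":
        res = _em_reml(
            y, X, dense_terms=[], diag_term=("genotype", gcodes, g),
            start={"genotype": mom["sigma2_g"] + mom["sigma2_ge"],
                   "residual": mom["sigma2_e"]},
            tol=tol, max_iter=max_iter)
    else:
        raise ValueError(drop)
    return res["loglik"], res["converged"]


def lrt_random_effects(
    table: pd.DataFrame,
    trait: str,
    mixture: bool = False,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Likelihood-ratio tests of the random genotype and GEI terms.

    Each random term is removed in turn and the model refitted; the LR
    statistic 2(l_full - l_reduced) is referred to chi-square with one
    degree of freedom, matching the published procedure.  Because the null
    value lies on the boundary of the parameter space, ``mixture=True``
    instead uses the 0.5*chi2(0) + 0.5*chi2(1) mixture (p-values halved).
    """
    full = fit_met_mixed(table, trait, tol=tol, max_iter=max_iter)
    rows = []
    terms = ["genotype"] + (["gxe"] if full.has_ge_term else [])
    for term in terms:
        ll_red, conv = _reduced_loglik(table, trait, term, tol, max_iter)
        lr = 2.0 * (full.restricted_loglik - ll_red)
        if lr < -1e-6:
            warnings.warn(f"negative LR statistic for term {term!r} ({lr:.3g})")
        lr = max(lr, 0.0)
        p = float(stats.chi2.sf(lr, df=1))
        if mixture:
            p = 0.5 * p if lr > 0 else 1.0
        rows.append({
            "term": term, "loglik_full": full.restricted_loglik,
            "loglik_reduced": ll_red, "lr_statistic": lr, "df": 1,
            "p_value": p, "reduced_converged": conv,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BLUP extraction


def extract_blups(model: FittedMETModel) -> dict[str, pd.DataFrame | pd.Series]:
    """Predicted genotype values, overall and per environment.

    Overall prediction = grand fixed mean + genotype BLUP; per-environment
    prediction = environment fixed mean + genotype BLUP + interaction BLUP
    (zero for unobserved cells).
    """
    mu = model.variance_components.grand_mean
    overall = mu + model.random_g
    overall.name = model.trait
    genos = model.random_g.index
    envs = model.env_means.index
    per_env = pd.DataFrame(
        {env: model.env_means[env] + model.random_g for env in envs},
        index=genos,
    )
    for (gid, env), u in model.random_ge.items():
        per_env.loc[gid, env] += u
    return {"overall": overall, "per_env": per_env}


def blup_two_way(
    table: pd.DataFrame, traits: list[str] | None = None, **fit_kws
) -> tuple[pd.DataFrame, dict[str, FittedMETModel]]:
    """Genotype x trait table of overall BLUP-predicted values.

    Fits every trait and assembles the two-way table consumed by the
    selection index (one row per genotype, one column per trait).
    """
    if traits is None:
        traits = sorted(table["trait"].unique())
    models, cols = {}, {}
    for t in traits:
        m = fit_met_mixed(table, t, **fit_kws)
        models[t] = m
        cols[t] = extract_blups(m)["overall"]
    return pd.DataFrame(cols)[traits], models


# ---------------------------------------------------------------------------
# joint analysis of variance


def _rss(y: np.ndarray, cols: list[sp.csr_matrix]) -> float:
    W = sp.hstack(cols, format="csr")
    gram = np.asarray((W.T @ W).todense())
    wty = W.T @ y
    sol, *_ = sla.lstsq(gram, wty, lapack_driver="gelsy")
    return max(float(y @ y - sol @ wty), 0.0)


def _factor_csr(codes: np.ndarray, n_levels: int) -> sp.csr_matrix:
    n = len(codes)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_levels))


_STAR_LEVELS = [(0.001, "***"), (0.01, "**"), (0.05, "*")]


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return "na"
    for thr, s in _STAR_LEVELS:
        if p <= thr:
            return s
    return "ns"


def joint_anova(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Sequential (Type I) combined analysis of variance for one trait.

    Sources ENV, REP(ENV), GEN, GEN x ENV and Residuals with df, SS, MS, F,
    p-value and significance stars (P <= 0.05 / 0.01 / 0.001, else ``ns``).
    On balanced data GEN is tested against the GEN x ENV mean square and all
    other terms against the residual; unbalanced data fall back to residual
    denominators for every term, with a warning.  Empty genotype x
    environment cells reduce the interaction degrees of freedom.
    """
    y, geno, env, blk = _prepare_trait(table, trait)
    n = len(y)
    g, e, b = len(geno.categories), len(env.categories), len(blk.categories)
    gcodes, ecodes, bcodes = (c.codes.astype(np.int64) for c in (geno, env, blk))

    ones = sp.csr_matrix(np.ones((n, 1)))
    Fe = _factor_csr(ecodes, e)
    eb = ecodes * b + bcodes
    eb_obs = np.unique(eb)
    Feb = _factor_csr(np.searchsorted(eb_obs, eb), len(eb_obs))
    Fg = _factor_csr(gcodes, g)
    cell = gcodes * e + ecodes
    cell_obs = np.unique(cell)
    Fc = _factor_csr(np.searchsorted(cell_obs, cell), len(cell_obs))

    models = [[ones], [ones, Fe], [ones, Fe, Feb], [ones, Fe, Feb, Fg],
              [ones, Fe, Feb, Fg, Fc]]
    rss = [_rss(y, m) for m in models]

    n_eb, n_cells = len(eb_obs), len(cell_obs)
    df = {
        "ENV": e - 1,
        "REP(ENV)": n_eb - e,
        "GEN": g - 1,
        "GEN x ENV": max(n_cells - g - e + 1, 0),
    }
    rank_full = n_cells + (n_eb - e)
    df["Residuals"] = n - rank_full
    ss = {
        "ENV": rss[0] - rss[1],
        "REP(ENV)": rss[1] - rss[2],
        "GEN": rss[2] - rss[3],
        "GEN x ENV": rss[3] - rss[4],
        "Residuals": rss[4],
    }

    balanced = (n == g * e * b) and (np.bincount(cell, minlength=g * e).min() >= 1) \
        and len(np.unique(np.bincount(gcodes * e * b + ecodes * b + bcodes,
                                      minlength=g * e * b))) == 1
    ms = {src: (ss[src] / df[src] if df[src] > 0 else np.nan) for src in ss}

    rows = []
    for src in ["ENV", "REP(ENV)", "GEN", "GEN x ENV", "Residuals"]:
        if src == "Residuals":
            rows.append({"source": src, "df": df[src], "SS": ss[src],
                         "MS": ms[src], "F": np.nan, "p_value": np.nan,
                         "signif": ""})
            continue
        if src == "GEN" and balanced and e > 1 and df["GEN x ENV"] > 0:
            denom, dfd = ms["GEN x ENV"], df["GEN x ENV"]
        else:
            denom, dfd = ms["Residuals"], df["Residuals"]
        with np.errstate(divide="ignore", invalid="ignore"):
            F = ms[src] / denom if (denom and np.isfinite(denom) and denom > 0) else np.nan
        p = float(stats.f.sf(F, df[src], dfd)) if np.isfinite(F) and df[src] > 0 else np.nan
        rows.append({"source": src, "df": df[src], "SS": ss[src], "MS": ms[src],
                     "F": F, "p_value": p, "signif": _stars(p)})
    if not balanced:
        warnings.warn("unbalanced data: all ANOVA F tests use the residual "
                      "mean square as denominator")
    out = pd.DataFrame(rows).set_index("source")
    return out


def residual_normality(model: FittedMETModel) -> tuple[float, float]:
    """Shapiro-Wilk test of the fitted model's residuals."""
    r = np.asarray(model.residuals)
    if r.size < 3:
        raise ValueError("insufficient residuals for the Shapiro-Wilk test (need >= 3)")
    if np.allclose(r, r[0]):
        raise ValueError("residuals are constant; normality test undefined")
    w, p = stats.shapiro(r)
    return float(w), float(p)
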