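"""Multi-trait genotype-ideotype distance index (MGIDI).

The index ranks genotypes by their Euclidean distance, in factor-score
space, from an ideotype holding the best possible value of every trait.
Four steps operate on a genotype x trait table of predicted values
(typically across-environment BLUP means):

1.  **Rescaling.**  Each trait is mapped affinely to [0, 100] so that the
    desirable extreme (maximum for "increase" traits, minimum for
    "decrease") lands on 100.  Affine maps preserve the trait correlation
    structure (up to sign for "decrease" columns).
2.  **Exploratory factor analysis.**  Eigen-decomposition of the
    correlation matrix of rescaled values; factors with eigenvalue > 1 are
    retained (at least one); initial loadings eigvec*sqrt(eigval) are
    varimax-rotated.  Factor scores use the regression estimator
    F = Z R^-1 A with Z the column-standardised rescaled matrix.
3.  **Ideotype planning.**  The ideotype row [100, ..., 100] is
    standardised with the genotype-derived column statistics and projected
    through the same score operator.
4.  **Distance and selection.**  MGIDI_i = sqrt(sum_j (gamma_ij - gamma_j)^2);
    the round(intensity * n) genotypes with the smallest distance are
    selected, and per-trait selection differentials and per-factor
    strength/weakness proportions (omega) are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RescaledMatrix", "FactorModel", "MGIDIResult",
    "rescale_traits", "varimax", "fit_factor_model",
    "compute_ideotype_scores", "compute_mgidi", "select_genotypes",
    "strengths_weaknesses", "selection_differential", "mgidi_index",
]


# ---------------------------------------------------------------------------
# step 1: rescaling


@dataclass
class RescaledMatrix:
    values: pd.DataFrame  # genotype x trait, entries in [0, 100]
    original_min: pd.Series
    original_max: pd.Series
    new_min: pd.Series
    new_max: pd.Series
    directions: pd.Series  # "increase" / "decrease" per trait


def rescale_traits(
    two_way: pd.DataFrame, directions: dict[str, str] | str = "increase"
) -> RescaledMatrix:
    """Affinely rescale every trait column to the 0-100 range.

    rX = (eta_n - phi_n) / (eta_0 - phi_0) * (theta - eta_0) + eta_n, where
    (eta_0, phi_0) are the observed column maximum/minimum and (eta_n, phi_n)
    the new ones: (100, 0) for "increase" traits, (0, 100) for "decrease",
    so the desirable extreme always maps to 100.
    """
    if len(two_way) < 2:
        raise ValueError("rescaling needs at least 2 genotypes")
    if isinstance(directions, str):
        directions = {t: directions for t in two_way.columns}
    missing = set(two_way.columns) - set(directions)
    if missing:
        raise ValueError(f"no direction given for traits: {sorted(missing)}")

    vals = {}
    omin = two_way.min()
    omax = two_way.max()
    nmin, nmax = {}, {}
    for t in two_way.columns:
        lo, hi = omin[t], omax[t]
        if hi == lo:
            raise ValueError(f"trait {t!r} is constant; cannot rescale")
        d = directions[t]
        if d == "increase":
            eta_n, phi_n = 100.0, 0.0
        elif d == "decrease":
            eta_n, phi_n = 0.0, 100.0
        else:
            raise ValueError(f"direction for {t!r} must be 'increase' or 'decrease'")
        vals[t] = (eta_n - phi_n) / (hi - lo) * (two_way[t] - hi) + eta_n
        nmin[t], nmax[t] = phi_n, eta_n
    return RescaledMatrix(
        values=pd.DataFrame(vals, index=two_way.index),
        original_min=omin, original_max=omax,
        new_min=pd.Series(nmin), new_max=pd.Series(nmax),
        directions=pd.Series({t: directions[t] for t in two_way.columns}),
    )


# ---------------------------------------------------------------------------
# step 2: factor analysis


def varimax(loadings: np.ndarray, normalize: bool = True,
            eps: float = 1e-8, max_iter: int = 50000):
    """Varimax rotation of a loading matrix (Kaiser-normalised by default).

    The iterative SVD formulation; returns (rotated loadings, rotation
    matrix).  Row norms (communalities) are preserved exactly because the
    rotation is orthogonal.  The stopping tolerance is tighter than the
    customary 1e-5, which otherwise stalls short of simple structure when
    two factors explain nearly equal variance.
    """
    x = np.asarray(loadings, dtype=float).copy()
    p, nc = x.shape
    if nc < 2:
        return x, np.eye(nc)
    sc = None
    if normalize:
        sc = np.sqrt((x**2).sum(axis=1))
        sc[sc == 0] = 1.0
        x = x / sc[:, None]
    rot = np.eye(nc)
    d = 0.0
    for _ in range(max_iter):
        z = x @ rot
        B = x.T @ (z**3 - z @ np.diag((z**2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(B)
        rot = u @ vt
        d_new = s.sum()
        if d_new < d * (1.0 + eps):
            break
        d = d_new
    z = x @ rot
    if normalize:
        z = z * sc[:, None]
    return z, rot


@dataclass
class FactorModel:
    correlation_matrix: pd.DataFrame
    eigenvalues: np.ndarray
    n_retained: int
    loadings_initial: pd.DataFrame  # p x f
    loadings_rotated: pd.DataFrame  # p x f, sign-fixed
    communality: pd.Series
    uniqueness: pd.Series
    explained_variance_pct: np.ndarray
    cumulative_variance_pct: np.ndarray
    scores: pd.DataFrame  # g x f
    ideotype_scores: np.ndarray  # length f
    column_means: pd.Series
    column_sds: pd.Series
    rescaled: RescaledMatrix
    flags: list = field(default_factory=list)

    @property
    def factor_names(self) -> list[str]:
        return list(self.loadings_rotated.columns)

    def factor_assignment(self) -> pd.Series:
        """Trait -> retained factor with the largest absolute loading."""
        return self.loadings_rotated.abs().idxmax(axis=1)


def explained_variance_pct(eigenvalue: float, n_traits: int) -> float:
    """Percentage of total (correlation-matrix) variance for one factor."""
    return 100.0 * eigenvalue / n_traits


def fit_factor_model(
    rescaled: RescaledMatrix,
    n_factors: int | None = None,
    ridge: float = 1e-8,
) -> FactorModel:
    """Eigen-based EFA with varimax rotation and regression factor scores.

    Factors are retained by the Kaiser rule (eigenvalue > 1); if none
    qualifies a single factor is kept with a warning.  Eigenvalues are
    sorted descending with ties broken by original index; after rotation
    each factor's loading vector is sign-fixed so its largest-magnitude
    loading is positive (scores and ideotype scores flip consistently, the
    distances are invariant).  A singular correlation matrix is inverted
    with a ridge on the diagonal, with a warning.
    """
    X = rescaled.values
    g, p = X.shape
    flags = []
    means = X.mean()
    sds = X.std(ddof=1)
    if (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise ValueError(f"constant rescaled columns: {bad}")
    Z = (X - means) / sds
    R = np.corrcoef(X.to_numpy(), rowvar=False)
    R = pd.DataFrame(R, index=X.columns, columns=X.columns)

    w, v = np.linalg.eigh(R.to_numpy())
    order = np.argsort(np.argsort(-w, kind="stable"), kind="stable")  # descending, stable
    idx = np.argsort(-w, kind="stable")
    w, v = w[idx], v[:, idx]
    del order

    if n_factors is None:
        f = int(np.sum(w > 1.0))
        if f == 0:
            f = 1
            flags.append("kaiser_retained_none:fallback_one_factor")
            warnings.warn("no eigenvalue exceeds 1; retaining a single factor")
    else:
        f = int(n_factors)
    f = max(1, min(f, p))

    L = v[:, :f] * np.sqrt(np.clip(w[:f], 0.0, None))
    A, _rot = varimax(L) if f > 1 else (L.copy(), np.eye(1))
    # deterministic signs: largest-|loading| entry of each factor positive
    for j in range(f):
        if A[np.argmax(np.abs(A[:, j])), j] < 0:
            A[:, j] = -A[:, j]

    fac_names = [f"FA{j + 1}" for j in range(f)]
    communality = pd.Series((A**2).sum(axis=1), index=X.columns)
    uniqueness = 1.0 - communality

    Rm = R.to_numpy()
    try:
        Rinv = np.linalg.inv(Rm)
    except np.linalg.LinAlgError:
        Rinv = np.linalg.inv(Rm + ridge * np.eye(p))
        flags.append("singular_correlation:ridge_inverse")
        warnings.warn("singular trait correlation matrix; ridge-stabilised inverse")
    cond = np.linalg.cond(Rm)
    if cond > 1e12 and "singular_correlation:ridge_inverse" not in flags:
        Rinv = np.linalg.inv(Rm + ridge * np.eye(p))
        flags.append("singular_correlation:ridge_inverse")
        warnings.warn("near-singular trait correlation matrix; ridge-stabilised inverse")

    score_op = Rinv @ A  # p x f
    F = Z.to_numpy() @ score_op
    z_id = ((100.0 - means) / sds).to_numpy()
    id_scores = z_id @ score_op

    expl = 100.0 * w[:f] / p
    model = FactorModel(
        correlation_matrix=R,
        eigenvalues=w,
        n_retained=f,
        loadings_initial=pd.DataFrame(L, index=X.columns, columns=fac_names),
        loadings_rotated=pd.DataFrame(A, index=X.columns, columns=fac_names),
        communality=communality,
        uniqueness=uniqueness,
        explained_variance_pct=expl,
        cumulative_variance_pct=np.cumsum(expl),
        scores=pd.DataFrame(F, index=X.index, columns=fac_names),
        ideotype_scores=id_scores,
        column_means=means,
        column_sds=sds,
        rescaled=rescaled,
        flags=flags,
    )
    return model


# ---------------------------------------------------------------------------
# steps 3-4: ideotype, distance, selection


def compute_ideotype_scores(model: FactorModel) -> np.ndarray:
    """Factor scores of the ideotype row [100, ..., 100].

    Standardised with the genotype-derived column means/SDs and projected by
    the same regression score operator as the genotypes, so a genotype whose
    rescaled row is exactly 100 everywhere scores identically.
    """
    return model.ideotype_scores.copy()


def compute_mgidi(model: FactorModel) -> pd.Series:
    """Euclidean genotype-ideotype distance in factor-score space."""
    diff = model.scores.to_numpy() - model.ideotype_scores[None, :]
    d = np.sqrt((diff**2).sum(axis=1))
    return pd.Series(d, index=model.scores.index, name="MGIDI")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def select_genotypes(
    distances: pd.Series, intensity: float = 0.15
) -> tuple[list, float]:
    """Lowest-distance selection at the given intensity.

    Selects round(intensity * n) genotypes (round half away from zero),
    breaking distance ties by genotype label order.  Returns (selected
    labels in ascending-distance order, cut-point distance).
    """
    if not 0.0 < intensity <= 1.0:
        raise ValueError("selection intensity must be in (0, 1]")
    n = len(distances)
    k = max(_round_half_away(intensity * n), 1)
    k = min(k, n)
    # stable sort on a label-ordered series => distance ties break by label
    ranked = distances.loc[sorted(distances.index, key=str)].sort_values(kind="mergesort")
    selected = list(ranked.index[:k])
    return selected, float(ranked.iloc[k - 1])


def strengths_weaknesses(model: FactorModel) -> pd.DataFrame:
    """Per-genotype factor contributions omega_ij = D_ij^2 / sum_j D_ij^2.

    D_ij is the genotype-ideotype distance within factor j.  Rows sum to 1;
    a genotype exactly at the ideotype has undefined proportions and is
    reported as uniform 1/f (flagged via an attrs entry).
    """
    D2 = (model.scores.to_numpy() - model.ideotype_scores[None, :]) ** 2
    tot = D2.sum(axis=1, keepdims=True)
    degenerate = tot[:, 0] == 0.0
    tot[degenerate] = 1.0
    omega = D2 / tot
    omega[degenerate] = 1.0 / model.n_retained
    out = pd.DataFrame(omega, index=model.scores.index, columns=model.factor_names)
    out.attrs["degenerate_rows"] = list(model.scores.index[degenerate])
    return out


def selection_differential(
    two_way: pd.DataFrame,
    selected: list,
    factor_assignment: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-trait gains table: VAR, Factor, Xo, Xs, SD, SD%.

    Xo is the mean of all genotypes, Xs the mean of the selected set,
    SD = Xs - Xo and SD% = 100 * SD / Xo (the selection differential as a
    percentage of the population mean).
    """
    missing = [s for s in selected if s not in two_way.index]
    if missing:
        raise ValueError(f"selected genotypes not in table: {missing[:5]}")
    xo = two_way.mean()
    if (xo == 0).any():
        bad = list(xo.index[xo == 0])
        raise ValueError(f"population mean is zero for traits {bad}; "
                         "percentage differential undefined")
    xs = two_way.loc[selected].mean()
    sd = xs - xo
    out = pd.DataFrame({
        "VAR": two_way.columns,
        "Factor": (factor_assignment.reindex(two_way.columns).to_numpy()
                   if factor_assignment is not None else ""),
        "Xo": xo.to_numpy(), "Xs": xs.to_numpy(), "SD": sd.to_numpy(),
        "SD%": (100.0 * sd / xo).to_numpy(),
    })
    return out


@dataclass
class MGIDIResult:
    model: FactorModel
    distances: pd.Series
    ranking: list
    selected: list
    cut_point: float
    intensity: float
    omega: pd.DataFrame
    gains: pd.DataFrame


def mgidi_index(
    two_way: pd.DataFrame,
    directions: dict[str, str] | str = "increase",
    intensity: float = 0.15,
    n_factors: int | None = None,
) -> MGIDIResult:
    """Run the full index on a genotype x trait table of predicted values."""
    rescaled = rescale_traits(two_way, directions)
    model = fit_factor_model(rescaled, n_factors=n_factors)
    distances = compute_mgidi(model)
    selected, cut = select_genotypes(distances, intensity)
    omega = strengths_weaknesses(model)
    gains = selection_differential(two_way, selected, model.factor_assignment())
    ranking = list(distances.loc[sorted(distances.index, key=str)]
                   .sort_values(kind="mergesort").index)
    return MGIDIResult(
        model=model, distances=distances, ranking=ranking, selected=selected,
        cut_point=cut, intensity=intensity, omega=omega, gains=gains,
    )
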