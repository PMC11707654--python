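import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metsel.mgidi import (
    FactorModel,
    compute_ideotype_scores,
    compute_mgidi,
    fit_factor_model,
    mgidi_index,
    rescale_traits,
    select_genotypes,
    selection_differential,
    strengths_weaknesses,
    varimax,
)


def random_two_way(g=50, p=8, seed=1, corr=None):
    rng = np.random.default_rng(seed)
    if corr is None:
        x = rng.normal(size=(g, p))
    else:
        x = rng.multivariate_normal(np.zeros(p), corr, size=g, method="eigh")
    return pd.DataFrame(x, index=[f"g{i:03d}" for i in range(g)],
                        columns=[f"t{j}" for j in range(p)])


def minimal_model(scores: np.ndarray, ideotype: np.ndarray) -> FactorModel:
    """Bare FactorModel carrying only what distance/omega computations use."""
    g, f = scores.shape
    names = [f"FA{j+1}" for j in range(f)]
    dummy = pd.DataFrame(np.eye(f), columns=names)
    return FactorModel(
        correlation_matrix=dummy, eigenvalues=np.ones(f), n_retained=f,
        loadings_initial=dummy, loadings_rotated=dummy,
        communality=pd.Series(np.ones(f)), uniqueness=pd.Series(np.zeros(f)),
        explained_variance_pct=np.ones(f), cumulative_variance_pct=np.ones(f),
        scores=pd.DataFrame(scores, index=[f"g{i}" for i in range(g)], columns=names),
        ideotype_scores=np.asarray(ideotype, dtype=float),
        column_means=pd.Series(dtype=float), column_sds=pd.Series(dtype=float),
        rescaled=None)


class TestRescale:
    def test_endpoints_and_midpoint(self):
        tw = pd.DataFrame({"a": [2.0, 6.0, 4.0]}, index=["x", "y", "z"])
        r = rescale_traits(tw).values["a"]
        assert r["y"] == 100.0 and r["x"] == 0.0 and r["z"] == 50.0

    def test_decrease_direction_flips(self):
        tw = pd.DataFrame({"a": [2.0, 6.0, 4.0]}, index=["x", "y", "z"])
        r = rescale_traits(tw, {"a": "decrease"}).values["a"]
        assert r["x"] == 100.0 and r["y"] == 0.0

    def test_correlations_preserved(self):
        tw = random_two_way(g=40, p=5, seed=3)
        res = rescale_traits(tw)
        r0 = np.corrcoef(tw.to_numpy(), rowvar=False)
        r1 = np.corrcoef(res.values.to_numpy(), rowvar=False)
        assert np.abs(r0 - r1).max() < 1e-10

    def test_constant_column_named_in_error(self):
        tw = pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]})
        with pytest.raises(ValueError, match="flat"):
            rescale_traits(tw)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="2 genotypes"):
            rescale_traits(pd.DataFrame({"a": [1.0]}))

    @given(lo=st.floats(-100, 100), width=st.floats(0.1, 100),
           frac=st.floats(0, 1))
    @settings(max_examples=60, deadline=None)
    def test_affine_map_property(self, lo, width, frac):
        theta = lo + frac * width
        tw = pd.DataFrame({"a": [lo, lo + width, theta]})
        r = rescale_traits(tw).values["a"]
        assert r.iloc[2] == pytest.approx(100 * frac, abs=1e-8)


class TestFactorModel:
    def test_block_structure_recovered(self):
        corr = np.eye(8)
        corr[:4, :4] = 0.9
        corr[4:, 4:] = 0.9
        np.fill_diagonal(corr, 1.0)
        tw = random_two_way(g=2000, p=8, seed=5, corr=corr)
        model = fit_factor_model(rescale_traits(tw))
        assert model.n_retained == 2
        A = model.loadings_rotated.abs().to_numpy()
        own = [int(np.argmax(A[i])) for i in range(8)]
        assert len(set(own[:4])) == 1 and len(set(own[4:])) == 1
        assert own[0] != own[4]
        assert (np.max(A, axis=1) > 0.85).all()
        assert (np.min(A, axis=1) < 0.15).all()
        # communalities match an independent eigen-decomposition oracle
        R = np.corrcoef(model.rescaled.values.to_numpy(), rowvar=False)
        w, v = np.linalg.eigh(R)
        idx = np.argsort(w)[::-1][:2]
        L = v[:, idx] * np.sqrt(w[idx])
        assert np.allclose((L**2).sum(axis=1), model.communality, atol=1e-6)

    def test_varimax_preserves_communality_and_matches_R(self, tmp_path):
        rng = np.random.default_rng(7)
        tw = random_two_way(g=60, p=6, seed=7)
        model = fit_factor_model(rescale_traits(tw), n_factors=3)
        L = model.loadings_initial.to_numpy()
        A, _ = varimax(L, eps=1e-5)  # R's default stopping tolerance
        assert np.allclose((L**2).sum(1), (A**2).sum(1), atol=1e-8)
        # cross-check the rotation against R's stats::varimax
        np.savetxt(tmp_path / "load.csv", L, delimiter=",")
        rscript = textwrap.dedent("""
            L <- as.matrix(read.csv(%r, header=FALSE))
            v <- varimax(L)
            write.table(unclass(v$loadings), %r, sep=",",
                        row.names=FALSE, col.names=FALSE)
        """) % (str(tmp_path / "load.csv"), str(tmp_path / "rot.csv"))
        subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
        r_rot = np.loadtxt(tmp_path / "rot.csv", delimiter=",")
        # align arbitrary column order/sign before comparing
        cost = np.abs(A.T @ r_rot)
        order = np.argmax(cost, axis=1)
        assert sorted(order) == [0, 1, 2]
        aligned = r_rot[:, order]
        signs = np.sign(np.sum(A * aligned, axis=0))
        assert np.abs(A - aligned * signs).max() < 1e-4

    def test_explained_variance_is_eigenvalue_share(self):
        tw = random_two_way(g=80, p=8, seed=2)
        model = fit_factor_model(rescale_traits(tw))
        assert np.allclose(model.explained_variance_pct,
                           100 * model.eigenvalues[:model.n_retained] / 8)
        assert model.eigenvalues.sum() == pytest.approx(8.0, abs=1e-9)

    def test_kaiser_fallback_on_uncorrelated_columns(self):
        # Helmert contrasts: zero-mean, exactly orthogonal columns, so the
        # sample correlation is the identity and every eigenvalue is exactly 1
        h = np.array([
            [1.0, 1.0, 1.0],
            [-1.0, 1.0, 1.0],
            [0.0, -2.0, 1.0],
            [0.0, 0.0, -3.0],
        ])
        tw = pd.DataFrame(h, columns=["a", "b", "c"])
        with pytest.warns(UserWarning, match="single factor"):
            model = fit_factor_model(rescale_traits(tw))
        assert model.n_retained == 1
        assert np.allclose(model.eigenvalues, 1.0, atol=1e-10)

    def test_uniqueness_complements_communality(self):
        model = fit_factor_model(rescale_traits(random_two_way(seed=11)))
        assert np.allclose(model.communality + model.uniqueness, 1.0, atol=1e-8)


class TestIdeotypeAndDistance:
    def test_perfect_genotype_matches_ideotype(self):
        tw = random_two_way(g=30, p=4, seed=9)
        tw.loc["g000"] = tw.max() + 1.0  # dominates every trait
        res = mgidi_index(tw)
        scores = res.model.scores.loc["g000"].to_numpy()
        assert np.allclose(scores, res.model.ideotype_scores, atol=1e-10)
        assert res.distances["g000"] == pytest.approx(0.0, abs=1e-10)
        assert res.ranking[0] == "g000"

    def test_single_factor_hand_oracle(self):
        tw = random_two_way(g=20, p=2, seed=4)
        rescaled = rescale_traits(tw)
        model = fit_factor_model(rescaled, n_factors=1)
        X = rescaled.values
        z_id = ((100.0 - X.mean()) / X.std(ddof=1)).to_numpy()
        R = np.corrcoef(X.to_numpy(), rowvar=False)
        A = model.loadings_rotated.to_numpy()
        by_hand = z_id @ np.linalg.inv(R) @ A
        assert np.allclose(compute_ideotype_scores(model), by_hand, atol=1e-10)

    def test_ideotype_invariant_to_row_order(self):
        tw = random_two_way(g=25, p=5, seed=8)
        m1 = fit_factor_model(rescale_traits(tw))
        m2 = fit_factor_model(rescale_traits(tw.iloc[::-1]))
        assert np.allclose(m1.ideotype_scores, m2.ideotype_scores, atol=1e-10)

    def test_three_four_five_triangle(self):
        model = minimal_model(np.array([[1.0, 2.0]]), np.array([4.0, 6.0]))
        assert compute_mgidi(model).iloc[0] == pytest.approx(5.0)

    def test_distances_match_brute_force(self):
        rng = np.random.default_rng(12)
        scores, ideo = rng.normal(size=(5, 3)), rng.normal(size=3)
        model = minimal_model(scores, ideo)
        d = compute_mgidi(model)
        for i in range(5):
            expected = np.sqrt(sum((scores[i, j] - ideo[j]) ** 2 for j in range(3)))
            assert abs(d.iloc[i] - expected) < 1e-12

    def test_distance_invariant_to_factor_sign_flip(self):
        rng = np.random.default_rng(3)
        scores, ideo = rng.normal(size=(10, 3)), rng.normal(size=3)
        d1 = compute_mgidi(minimal_model(scores, ideo))
        flip = np.array([1.0, -1.0, 1.0])
        d2 = compute_mgidi(minimal_model(scores * flip, ideo * flip))
        assert np.allclose(d1, d2, atol=1e-12)


class TestSelection:
    @pytest.mark.parametrize("n,expected", [(172, 26), (169, 25), (232, 35),
                                            (573, 86)])
    def test_published_selection_counts(self, n, expected):
        d = pd.Series(np.linspace(0.1, 3.0, n),
                      index=[f"g{i:04d}" for i in range(n)])
        selected, _ = select_genotypes(d, 0.15)
        assert len(selected) == expected

    def test_intensity_one_selects_all(self):
        d = pd.Series([3.0, 1.0, 2.0], index=list("abc"))
        selected, cut = select_genotypes(d, 1.0)
        assert set(selected) == {"a", "b", "c"}
        assert cut == 3.0

    def test_invalid_intensity(self):
        with pytest.raises(ValueError):
            select_genotypes(pd.Series([1.0, 2.0]), 0.0)

    def test_ties_broken_by_label(self):
        d = pd.Series([1.0, 1.0, 1.0, 2.0], index=["c", "a", "b", "d"])
        selected, _ = select_genotypes(d, 0.5)
        assert selected == ["a", "b"]

    def test_selection_monotone_in_intensity(self):
        d = pd.Series(np.random.default_rng(5).normal(size=40) ** 2,
                      index=[f"g{i:02d}" for i in range(40)])
        prev: set = set()
        for intensity in (0.1, 0.2, 0.35, 0.5, 0.8, 1.0):
            sel, _ = select_genotypes(d, intensity)
            assert prev <= set(sel)
            prev = set(sel)


class TestOmegaAndGains:
    def test_single_factor_omega_is_one(self):
        model = minimal_model(np.random.default_rng(1).normal(size=(6, 1)),
                              np.array([2.0]))
        omega = strengths_weaknesses(model)
        assert np.allclose(omega, 1.0)

    def test_direct_arithmetic(self):
        model = minimal_model(np.array([[1.0, 2.0]]), np.array([0.0, 2.0 + np.sqrt(3)]))
        omega = strengths_weaknesses(model)  # D^2 = (1, 3)
        assert np.allclose(omega.iloc[0], [0.25, 0.75])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(21)
        scores, ideo = rng.normal(size=(10, 3)), rng.normal(size=3)
        omega = strengths_weaknesses(minimal_model(scores, ideo))
        d2 = (scores - ideo) ** 2
        assert np.allclose(omega, d2 / d2.sum(axis=1, keepdims=True), atol=1e-12)
        assert np.allclose(omega.sum(axis=1), 1.0, atol=1e-9)

    def test_genotype_at_ideotype_reported_uniform(self):
        scores = np.array([[1.0, 2.0], [0.0, 0.0]])
        model = minimal_model(scores, np.array([0.0, 0.0]))
        omega = strengths_weaknesses(model)
        assert np.allclose(omega.iloc[1], 0.5)
        assert omega.attrs["degenerate_rows"] == ["g1"]

    def test_published_leaf_area_gain(self):
        # population mean 66.5, selected mean 71.07 -> 6.87% differential
        tw = pd.DataFrame({"LA": [72.07, 70.07, 62.93, 60.93]},
                          index=["a", "b", "c", "d"])
        gains = selection_differential(tw, ["a", "b"])
        row = gains.set_index("VAR").loc["LA"]
        assert row["Xo"] == pytest.approx(66.5)
        assert row["SD"] == pytest.approx(4.57)
        assert row["SD%"] == pytest.approx(6.87, abs=5e-3)

    def test_select_all_gives_zero_gain(self):
        tw = random_two_way(g=12, p=3, seed=2) + 10.0
        gains = selection_differential(tw, list(tw.index))
        assert np.allclose(gains["SD"], 0.0, atol=1e-12)
        assert np.allclose(gains["SD%"], 0.0, atol=1e-12)

    def test_simple_percentage(self):
        tw = pd.DataFrame({"x": [55.0, 45.0]}, index=["s", "t"])
        gains = selection_differential(tw, ["s"])
        assert gains["SD%"].iloc[0] == pytest.approx(10.0)

    def test_zero_population_mean_rejected(self):
        tw = pd.DataFrame({"x": [1.0, -1.0]}, index=["s", "t"])
        with pytest.raises(ValueError, match="zero"):
            selection_differential(tw, ["s"])


def test_rank_parity_with_independent_reference(tmp_path):
    """Full-index parity against a base-R implementation written directly
    from the published formulas (rescale, eigen EFA, varimax, regression
    scores, ideotype projection, Euclidean distance)."""
    tw = random_two_way(g=50, p=8, seed=42)
    tw.to_csv(tmp_path / "tw.csv")
    rscript = textwrap.dedent("""
        x <- as.matrix(read.csv(%r, row.names=1))
        r <- apply(x, 2, function(v) 100/(max(v)-min(v))*(v-max(v))+100)
        R <- cor(r)
        ev <- eigen(R)
        f <- max(sum(ev$values > 1), 1)
        L <- ev$vectors[, 1:f, drop=FALSE] %%*%% diag(sqrt(ev$values[1:f]), f)
        A <- if (f > 1) unclass(varimax(L)$loadings)[, ] else L
        Z <- scale(r)
        op <- solve(R) %%*%% A
        S <- Z %%*%% op
        idz <- (100 - colMeans(r)) / apply(r, 2, sd)
        ids <- as.numeric(idz %%*%% op)
        d <- sqrt(rowSums(sweep(S, 2, ids)^2))
        write.csv(data.frame(genotype = rownames(x), mgidi = d), %r,
                  row.names = FALSE)
    """) % (str(tmp_path / "tw.csv"), str(tmp_path / "ref.csv"))
    subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "ref.csv").set_index("genotype")["mgidi"]

    res = mgidi_index(tw)
    from scipy.stats import spearmanr
    rho = spearmanr(res.distances.loc[ref.index], ref).statistic
    assert rho >= 0.99
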