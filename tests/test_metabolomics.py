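"""Metabolite-panel statistics: preprocessing, PLS-DA/VIP, univariate chain,
volcano and clustering, each against an independent route."""

import itertools
import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from muscleomics import (
    MetabolitePanel,
    MetaboSimConfig,
    PLSDA,
    cluster_heatmap,
    discriminant_features,
    fit_plsda,
    pareto_scale,
    preprocess,
    simulate_metabolite_panel,
    univariate_panel,
    volcano,
)
from muscleomics.metabolomics import _mann_whitney


def make_panel(data: dict[str, list[float]], n_a: int, n_b: int) -> MetabolitePanel:
    samples = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    groups = pd.Series(["A"] * n_a + ["B"] * n_b, index=samples)
    return MetabolitePanel(pd.DataFrame(data, index=samples).T, groups)


# ---------------------------------------------------------------------------
# preprocessing


def test_preprocess_hand_case():
    # {1, 10, 100} -> log10 {0,1,2} -> centered {-1,0,1}; sd=1 so Pareto
    # divisor sqrt(1)=1
    panel = make_panel({"m": [1.0, 10.0, 100.0]}, 2, 1)
    out = preprocess(panel)
    assert np.allclose(out["m"].to_numpy(), [-1.0, 0.0, 1.0])


def test_preprocess_constant_variable_centers_only():
    panel = make_panel({"m": [5.0, 5.0, 5.0, 5.0]}, 2, 2)
    with pytest.warns(UserWarning, match="constant"):
        out = preprocess(panel)
    assert np.allclose(out["m"], 0.0)


def test_pareto_scaled_variance_equals_original_sd(rng):
    """After Pareto scaling the variance of a variable equals its pre-scaling
    standard deviation (direct arithmetic identity)."""
    y = rng.lognormal(size=(30, 6))
    logs = np.log10(y)
    scaled = pareto_scale(logs, axis=0)
    assert np.allclose(scaled.var(axis=0, ddof=1), logs.std(axis=0, ddof=1))


def test_preprocess_rejects_nonpositive():
    samples = ["A0", "A1", "A2", "B0", "B1", "B2"]
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=samples)
    df = pd.DataFrame([[1, 2, 3, 4, 5, 0.0]], index=["bad"], columns=samples)
    with pytest.raises(ValueError, match="bad"):
        MetabolitePanel(df, groups)


# ---------------------------------------------------------------------------
# PLS-DA


def test_plsda_separates_separable_groups():
    x = np.zeros((8, 3))
    x[:4, 0] = [5, 6, 5.5, 6.5]
    x[4:, 0] = [-5, -6, -5.5, -6.5]
    x[:, 1:] = np.random.default_rng(0).normal(scale=0.1, size=(8, 2))
    res = fit_plsda(x, ["A"] * 4 + ["B"] * 4, n_components=1)
    s = res.scores[:, 0]
    assert max(s[4:]) < min(s[:4]) or max(s[:4]) < min(s[4:])


def test_plsda_first_weight_is_xty_direction(rng):
    """NIPALS closed form: component-1 weights proportional to X^T y."""
    x = rng.normal(size=(12, 7))
    groups = ["A"] * 6 + ["B"] * 6
    res = fit_plsda(x, groups, n_components=2)
    y = np.array([1.0] * 6 + [-1.0] * 6)
    expect = x.T @ y
    expect /= np.linalg.norm(expect)
    assert np.allclose(res.weights[:, 0], expect) or np.allclose(res.weights[:, 0], -expect)


def test_plsda_orthonormal_columns_pick_response_column():
    """With orthonormal X columns, one of which is the (scaled) group coding,
    the component-1 weight vector is that basis vector up to sign."""
    r = np.random.default_rng(3)
    y = np.array([1.0] * 5 + [-1.0] * 5)
    base = np.column_stack([y / np.linalg.norm(y), r.normal(size=(10, 3))])
    x, _ = np.linalg.qr(base)  # orthonormal columns; column 0 spans y
    groups = ["A"] * 5 + ["B"] * 5
    w = fit_plsda(x, groups, n_components=1).weights[:, 0]
    e0 = np.zeros(4)
    e0[0] = 1.0
    assert np.allclose(w, e0, atol=1e-10) or np.allclose(w, -e0, atol=1e-10)


def test_plsda_matches_sklearn_cross_check(rng):
    """Scores and weights agree with an independent PLS implementation."""
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    x = rng.normal(size=(14, 6))
    x = x - x.mean(axis=0)  # the fit expects column-centered (preprocessed) data
    groups = ["A"] * 7 + ["B"] * 7
    ours = fit_plsda(x, groups, n_components=2)
    y = np.array([1.0] * 7 + [-1.0] * 7)
    ref = sklearn.PLSRegression(n_components=2, scale=False).fit(x, y)
    for a in range(2):
        ratio = ours.weights[:, a] @ ref.x_weights_[:, a]
        assert abs(abs(ratio) - 1) < 1e-8  # unit vectors, equal up to sign
        np.testing.assert_allclose(
            np.abs(ours.scores[:, a]), np.abs(ref.x_scores_[:, a]), atol=1e-8
        )


def test_plsda_rank_deficiency_warns():
    x = np.zeros((6, 3))
    x[:, 0] = [1, 2, 3, -1, -2, -3]
    groups = ["A"] * 3 + ["B"] * 3
    with pytest.warns(UserWarning, match="rank"):
        res = fit_plsda(x, groups, n_components=3)
    assert res.n_components < 3


# ---------------------------------------------------------------------------
# VIP


def test_vip_single_variable_is_one():
    x = np.array([[1.0], [2.0], [3.0], [-1.0], [-2.0], [-3.0]])
    res = fit_plsda(x, ["A"] * 3 + ["B"] * 3, n_components=1)
    assert res.vip.iloc[0] == pytest.approx(1.0, abs=1e-10)


def test_vip_hand_case_two_variables():
    """One component with weights (0.6, 0.8): VIP = (sqrt(2*0.36), sqrt(2*0.64))."""
    from muscleomics.metabolomics import PLSDAResults

    model = PLSDA(np.ones((4, 2)) + np.random.default_rng(0).normal(size=(4, 2)),
                  ["A", "A", "B", "B"], n_components=1)
    res = PLSDAResults(
        model=model,
        weights=np.array([[0.6], [0.8]]),
        scores=np.zeros((4, 1)),
        x_loadings=np.zeros((2, 1)),
        y_loadings=np.array([1.0]),
        explained_y_variance=np.array([0.5]),
        explained_x_variance=np.array([0.5]),
    )
    assert np.allclose(res.vip, [math.sqrt(2 * 0.36), math.sqrt(2 * 0.64)])
    assert res.vip.iloc[0] == pytest.approx(0.848528137, abs=1e-8)
    assert res.vip.iloc[1] == pytest.approx(1.131370849, abs=1e-8)


def test_vip_normalization_identity(rng, planted_panel):
    panel, _ = planted_panel
    for res in (
        fit_plsda(rng.normal(size=(10, 5)), ["A"] * 5 + ["B"] * 5, n_components=2),
        PLSDA.from_panel(panel).fit(),
    ):
        assert (res.vip**2).sum() == pytest.approx(len(res.vip), abs=1e-10)


def test_discriminant_features_cutoff_exclusive():
    panel_res = fit_plsda(
        np.random.default_rng(1).normal(size=(10, 4)), ["A"] * 5 + ["B"] * 5
    )
    all_feats = discriminant_features(panel_res, cutoff=0.0)
    assert len(all_feats) == 4
    assert list(all_feats.values) == sorted(all_feats.values, reverse=True)
    vip = panel_res.vip
    at_max = discriminant_features(panel_res, cutoff=float(vip.max()))
    assert vip.max() not in at_max.values  # strictly exclusive


# ---------------------------------------------------------------------------
# univariate chain


def exhaustive_mwu_p(a, b):
    """Two-sided Mann-Whitney p by enumerating every group assignment."""
    pooled = list(a) + list(b)
    na = len(a)
    ranks = stats.rankdata(pooled)

    def u_stat(idx):
        ra = sum(ranks[i] for i in idx)
        return ra - na * (na + 1) / 2

    observed = u_stat(range(na))
    mu = na * len(b) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        total += 1
        if abs(u_stat(idx) - mu) >= abs(observed - mu) - 1e-12:
            count += 1
    return count / total


def test_mwu_textbook_case():
    # {1,2,3} vs {4,5,6}: the most extreme of C(6,3)=20 assignments, both tails
    assert _mann_whitney(np.array([1.0, 2, 3]), np.array([4.0, 5, 6])) == pytest.approx(0.1)
    assert exhaustive_mwu_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


@pytest.mark.parametrize("na,nb", [(2, 3), (3, 3), (3, 4), (4, 4), (4, 5), (5, 5)])
def test_mwu_matches_exhaustive_enumeration(na, nb):
    r = np.random.default_rng(100 * na + nb)
    for _ in range(3):
        a = r.normal(size=na)
        b = r.normal(loc=0.5, size=nb)
        assert _mann_whitney(a, b) == pytest.approx(exhaustive_mwu_p(a, b), abs=1e-12)


def test_identical_groups_are_ns():
    vals = [1.0, 2.0, 3.0, 4.0]
    panel = make_panel({"m": vals + vals}, 4, 4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        (res,) = univariate_panel(panel)
    assert res.p_value == pytest.approx(1.0)
    assert res.direction == "ns"
    assert res.test_used == "mann_whitney"


def test_welch_matches_closed_form(rng):
    a = rng.normal(loc=1.0, size=12)
    b = rng.normal(loc=0.2, size=10)
    panel = make_panel({"m": list(np.exp(a)) + list(np.exp(b))}, 12, 10)
    (res,) = univariate_panel(panel)
    if res.test_used == "welch_t":
        x, y = np.exp(a), np.exp(b)
        va, vb = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t = (x.mean() - y.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(x) - 1) + vb**2 / (len(y) - 1))
        p = 2 * stats.t.sf(abs(t), df)
        assert res.p_value == pytest.approx(p, abs=1e-12)
    else:  # normality gate rejected the lognormal sample: Mann-Whitney used
        assert res.test_used == "mann_whitney"


def test_normality_gate_selects_test():
    r = np.random.default_rng(4)
    normal_a = r.normal(10, 1, size=12)
    normal_b = r.normal(11, 1, size=12)
    skewed_b = np.exp(r.normal(0, 1.5, size=12)) + 5
    p1 = make_panel({"m": list(normal_a) + list(normal_b)}, 12, 12)
    (r1,) = univariate_panel(p1)
    assert r1.test_used == "welch_t"
    assert r1.normality_p_a > 0.05 and r1.normality_p_b > 0.05
    p2 = make_panel({"m": list(normal_a) + list(skewed_b)}, 12, 12)
    (r2,) = univariate_panel(p2)
    if r2.normality_p_b <= 0.05:
        assert r2.test_used == "mann_whitney"


def test_small_groups_fall_back_with_warning():
    panel = make_panel({"m": [1.0, 2, 3, 4, 5, 6, 7, 8]}, 4, 4)
    with pytest.warns(UserWarning, match="group size"):
        (res,) = univariate_panel(panel)
    assert res.test_used == "mann_whitney"
    assert math.isnan(res.normality_p_a)


def test_sem_and_means_reported():
    a, b = [1.0, 2.0, 3.0], [4.0, 6.0, 8.0]
    panel = make_panel({"m": a + b}, 3, 3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        (res,) = univariate_panel(panel)
    assert res.mean_a == pytest.approx(2.0)
    assert res.mean_b == pytest.approx(6.0)
    assert res.sem_a == pytest.approx(stats.sem(a))
    assert res.log2_fold_change == pytest.approx(math.log2(2.0 / 6.0))


# ---------------------------------------------------------------------------
# volcano


def test_volcano_all_ns_when_p_one():
    vals = [1.0, 2.0, 3.0, 4.0]
    panel = make_panel({"m1": vals + vals, "m2": vals + vals}, 4, 4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        uni = univariate_panel(panel)
    v = volcano(uni)
    assert set(v["volcano_class"]) == {"ns"}


def test_volcano_label_swap_antisymmetry(planted_panel):
    panel, _ = planted_panel
    uni = univariate_panel(panel)
    v1 = volcano(uni)
    flipped = MetabolitePanel(
        panel.concentrations[list(reversed(panel.concentrations.columns))],
        panel.groups,
    )
    v2 = volcano(univariate_panel(flipped))
    inc1 = set(v1.index[v1["volcano_class"] == "increased"])
    dec2 = set(v2.index[v2["volcano_class"] == "decreased"])
    assert inc1 == dec2


def test_planted_orn_classified_increased(planted_panel):
    panel, _ = planted_panel
    v = volcano(univariate_panel(panel))
    assert v.loc["Orn", "volcano_class"] == "increased"


# ---------------------------------------------------------------------------
# clustering


def _uni_quiet(panel):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return univariate_panel(panel)


def test_identical_metabolites_merge_first_at_zero():
    r = np.random.default_rng(2)
    base = list(r.lognormal(size=8))
    other = list(r.lognormal(size=8))
    panel = make_panel({"m1": base, "m2": base, "m3": other}, 4, 4)
    clust = cluster_heatmap(panel, top_k=3, univariate=_uni_quiet(panel))
    assert clust["metabolite_merge_heights"][0] == pytest.approx(0.0, abs=1e-12)
    mets = clust["metabolites"]
    assert abs(mets.index("m1") - mets.index("m2")) == 1


def test_single_linkage_three_points_hand_case():
    """Three metabolites whose preprocessed rows sit on a line: single
    linkage must first merge the closest pair at their distance, then the
    third point at its gap, exactly as computed by hand from the pairwise
    distances."""
    vals = {
        "a": [1.0] * 6,                          # constant -> scaled to zeros
        "b": [1.0, 1.0, 1.0, 10.0, 10.0, 10.0],  # small spread
        "c": [1.0, 1.0, 1.0, 1e9, 1e9, 1e9],     # large spread
    }
    panel = make_panel(vals, 3, 3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        x = preprocess(panel)
        clust = cluster_heatmap(panel, top_k=3, linkage="single", univariate=_uni_quiet(panel))
    rows = {m: x[m].to_numpy() for m in vals}
    d = {
        pair: float(np.linalg.norm(rows[pair[0]] - rows[pair[1]]))
        for pair in (("a", "b"), ("a", "c"), ("b", "c"))
    }
    first = min(d.values())
    heights = clust["metabolite_merge_heights"]
    assert heights[0] == pytest.approx(first, abs=1e-12)
    # hand single-linkage: second merge height is the smallest distance from
    # the remaining point to either member of the first cluster
    pair = min(d, key=d.get)
    rest = ({"a", "b", "c"} - set(pair)).pop()
    second = min(d[tuple(sorted((rest, m)))] for m in pair)
    assert heights[1] == pytest.approx(second, abs=1e-12)


def test_merge_heights_invariant_to_row_order(planted_panel):
    panel, _ = planted_panel
    uni = univariate_panel(panel)
    c1 = cluster_heatmap(panel, top_k=10, univariate=uni)
    perm = panel.concentrations.sample(frac=1, random_state=3)
    shuffled = MetabolitePanel(perm, panel.groups)
    c2 = cluster_heatmap(shuffled, top_k=10, univariate=_uni_quiet(shuffled))
    assert np.allclose(c1["metabolite_merge_heights"], c2["metabolite_merge_heights"])
    assert set(c1["metabolites"]) == set(c2["metabolites"])


def test_top_k_overflow_warns(planted_panel):
    panel, _ = planted_panel
    with pytest.warns(UserWarning, match="top_k"):
        clust = cluster_heatmap(panel, top_k=500, univariate=univariate_panel(panel))
    assert len(clust["metabolites"]) == 50
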