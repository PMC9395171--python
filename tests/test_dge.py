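"""Differential-expression stage: each step against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import nbinom, poisson

from regcascade.dge import (
    CONTROL,
    TREATED,
    NBExactDGE,
    bh_adjust,
    call_de,
    compute_cpm,
    equalize_libraries,
    estimate_common_dispersion,
    exact_nb_test,
    exact_pvalue,
    filter_low_expression,
    tmm_factors,
)

from conftest import make_count_matrix


# ---------------------------------------------------------------- CPM filter

def test_cpm_arithmetic_and_column_normalization():
    cm = make_count_matrix([[5, 0, 1, 2], [5, 10, 1, 2], [0, 0, 3, 4], [2, 4, 1, 2]])
    cpm = compute_cpm(cm)
    assert cpm.iloc[0, 0] == pytest.approx(5 / 12 * 1e6)
    assert cpm.iloc[2, 1] == 0.0
    assert np.allclose(cpm.sum(axis=0), 1e6)


def test_cpm_zero_library_names_sample():
    cm = make_count_matrix([[1, 0, 1, 1], [1, 0, 1, 1]])
    with pytest.raises(ValueError, match="c1"):
        compute_cpm(cm)


def test_filter_is_strict_at_threshold():
    # one count in one sample of a 1e6 library: summed CPM exactly 1 -> removed
    counts = np.zeros((3, 4), dtype=int)
    counts[0, 0] = 1
    counts[2] = [999_999, 1_000_000, 1_000_000, 1_000_000]
    cm = make_count_matrix(counts)
    kept = filter_low_expression(cm, threshold=1.0)
    assert list(kept.gene_ids) == ["g0002"]  # all-zero gene also removed


def test_filter_matches_direct_definition_on_random_matrices():
    rng = np.random.default_rng(0)
    for _ in range(50):
        arr = rng.integers(0, 40, size=(30, 4))
        arr[:, rng.integers(4)] += 1  # avoid zero libraries
        cm = make_count_matrix(arr)
        kept = filter_low_expression(cm, threshold=1.0)
        lib = arr.sum(axis=0)
        expect = [
            g
            for i, g in enumerate(cm.gene_ids)
            if sum(arr[i, j] / lib[j] * 1e6 for j in range(4)) > 1.0
        ]
        assert list(kept.gene_ids) == expect


# ------------------------------------------------------------------- TMM

def test_tmm_identical_columns_gives_unit_factors():
    col = np.array([10, 50, 3, 200, 7])
    cm = make_count_matrix(np.column_stack([col] * 4))
    assert np.allclose(tmm_factors(cm), 1.0)


def test_tmm_corrects_composition_not_depth():
    # pure depth difference, no composition change: factors ~ 1
    rng = np.random.default_rng(5)
    col = rng.integers(5, 500, size=400)
    cm = make_count_matrix(np.column_stack([col, 2 * col, col, 2 * col]))
    f = tmm_factors(cm)
    assert np.allclose(f, 1.0, atol=1e-9)


def test_tmm_geometric_mean_is_one():
    rng = np.random.default_rng(7)
    cm = make_count_matrix(rng.integers(0, 300, size=(200, 6)) + 1)
    f = tmm_factors(cm)
    assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)
    assert (f > 0).all()


def _oracle_fixture_counts():
    """The frozen 300-gene NB fixture used for the external-package oracle."""
    rng = np.random.default_rng(42)
    n_genes, n_samples = 300, 6
    mu = rng.lognormal(mean=4.0, sigma=1.2, size=n_genes)
    depth = np.array([1.0, 1.4, 0.7, 1.1, 0.9, 1.25])
    phi = 0.1
    counts = np.empty((n_genes, n_samples), dtype=int)
    for j in range(n_samples):
        m = mu * depth[j]
        counts[:, j] = rng.negative_binomial(1 / phi, 1 / (1 + phi * m))
    return counts


# factors computed once with edgeR 4.0.16 calcNormFactors(method="TMM") on the
# fixture above; frozen as the independent oracle
EDGER_TMM = [
    1.004679122973,
    1.026836254761,
    1.047670598344,
    0.984990066322,
    0.970019802506,
    0.968354156782,
]

# exactTestBySmallP(y1, y2, dispersion=...) p-values for the first 20 genes,
# same fixture, groups = samples 1-3 vs 4-6 (dispersion 1e-12 ~ Poisson limit)
EDGER_SMALLP_PHI01 = [
    0.843237643684, 0.952914662736, 0.636602500161, 0.134066694974,
    0.555444265361, 0.850253280878, 0.332939616628, 0.445344831738,
    0.368423080171, 0.288697558059, 0.835589414719, 0.550547522866,
    0.484401376723, 0.444893401286, 0.145424687773, 0.967209366102,
    0.977130576802, 0.357055057807, 0.211070294025, 0.201092426783,
]
EDGER_SMALLP_PHI0 = [
    0.538120662194, 0.921948827627, 0.0805862255592, 5.58173735274e-11,
    0.440799067344, 0.79136642778, 0.00812723549969, 0.101452327655,
    0.0415216650564, 0.0721263862378, 0.395679971772, 0.0268528824156,
    0.0757293761746, 0.000485373219992, 1.63002929748e-07, 0.937020169214,
    0.929372785252, 0.114083165412, 3.35658774245e-07, 0.00432738935388,
]


def test_tmm_matches_external_reference_implementation():
    cm = make_count_matrix(_oracle_fixture_counts())
    f = tmm_factors(cm)
    assert np.allclose(f.to_numpy(), EDGER_TMM, rtol=1e-8)


def test_exact_test_matches_external_reference_implementation():
    counts = _oracle_fixture_counts()
    cm = make_count_matrix(counts)
    groups = cm.groups
    pseudo = cm.counts.astype(float)  # oracle conditions on raw sums
    for phi, expected in [(0.1, EDGER_SMALLP_PHI01), (0.0, EDGER_SMALLP_PHI0)]:
        res = exact_nb_test(pseudo, groups, phi)
        assert np.allclose(res["pvalue"].to_numpy()[:20], expected, rtol=1e-6)


# --------------------------------------------------------------- equalize

def test_equalize_identity_when_equal_libraries_and_unit_factors():
    arr = np.array([[10, 10, 10, 10], [90, 90, 90, 90]])
    cm = make_count_matrix(arr)
    f = pd.Series(1.0, index=cm.sample_ids)
    pseudo, n_star = equalize_libraries(cm, f)
    assert np.allclose(pseudo, arr)
    assert n_star == pytest.approx(100.0)


def test_equalize_halves_multiplier_when_library_doubles():
    arr = np.array([[100, 200, 100, 100], [100, 200, 100, 100]])
    cm = make_count_matrix(arr)
    f = pd.Series(1.0, index=cm.sample_ids)
    pseudo, n_star = equalize_libraries(cm, f)
    mult = pseudo.to_numpy() / arr
    assert mult[0, 1] == pytest.approx(mult[0, 0] / 2)


def test_equalize_pseudo_totals_reach_common_size():
    # with unit factors the rescale is purely by library size, so every
    # pseudo column total equals the common size N* by construction
    rng = np.random.default_rng(3)
    cm = make_count_matrix(rng.integers(1, 500, size=(100, 4)))
    f = pd.Series(1.0, index=cm.sample_ids)
    pseudo, n_star = equalize_libraries(cm, f)
    assert np.allclose(pseudo.sum(axis=0), n_star, atol=0.5)
    # and with general factors each column total is N*/factor by design
    f2 = tmm_factors(cm)
    pseudo2, n_star2 = equalize_libraries(cm, f2)
    assert np.allclose(pseudo2.sum(axis=0) * f2, n_star2, atol=0.5)


# --------------------------------------------------------------- dispersion

def test_dispersion_near_zero_on_poisson_data():
    rng = np.random.default_rng(1)
    mu = rng.lognormal(np.log(50), 1.0, 3000)
    y = rng.poisson(mu[:, None], size=(3000, 6)).astype(float)
    cm = make_count_matrix(y.astype(int))
    phi = estimate_common_dispersion(cm.counts.astype(float), cm.groups)
    assert phi <= 0.01


def test_dispersion_recovers_true_value():
    rng = np.random.default_rng(2)
    phi_true = 0.2
    mu = rng.lognormal(np.log(100), 1.0, 5000)
    y = rng.negative_binomial(1 / phi_true, 1 / (1 + phi_true * mu[:, None]), size=(5000, 6))
    cm = make_count_matrix(y)
    phi = estimate_common_dispersion(cm.counts.astype(float), cm.groups)
    assert 0.1 <= phi <= 0.4


def test_dispersion_zero_for_duplicated_samples():
    col = np.array([3.0, 50.0, 7.0, 100.0])
    pseudo = pd.DataFrame(
        np.column_stack([col] * 4), columns=["c0", "c1", "t0", "t1"]
    )
    groups = pd.Series([CONTROL, CONTROL, TREATED, TREATED], index=pseudo.columns)
    with pytest.warns(UserWarning, match="dispersion"):
        assert estimate_common_dispersion(pseudo, groups) == 0.0


# --------------------------------------------------------------- exact test

def test_exact_p_is_one_at_symmetric_mode():
    assert exact_pvalue(5, 10, 3, 3, 0.0) == 1.0
    assert exact_pvalue(0, 0, 3, 3, 0.5) == 1.0


def test_exact_binomial_closed_form():
    # phi=0, n1=n2 -> Binomial(10, 1/2); minimum-likelihood two-sided rule
    assert exact_pvalue(1, 10, 3, 3, 0.0) == pytest.approx(22 / 1024, abs=1e-12)


def _enumeration_oracle(s1, t, n1, n2, phi):
    """Conditional pmf by direct convolution of the two group-sum laws."""
    s = np.arange(t + 1)
    if phi == 0:
        mu = t / (n1 + n2)
        p1 = poisson.pmf(s, n1 * mu)
        p2 = poisson.pmf(t - s, n2 * mu)
    else:
        mu = t / (n1 + n2)
        r1, r2 = n1 / phi, n2 / phi
        q1 = r1 / (r1 + n1 * mu)
        q2 = r2 / (r2 + n2 * mu)
        p1 = nbinom.pmf(s, r1, q1)
        p2 = nbinom.pmf(t - s, r2, q2)
    joint = p1 * p2
    cond = joint / joint.sum()
    return min(1.0, float(cond[cond <= cond[s1] * (1 + 1e-9)].sum()))


@pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
def test_exact_test_matches_enumeration_on_random_cases(phi):
    rng = np.random.default_rng(9)
    for _ in range(60):
        t = int(rng.integers(1, 31))
        s1 = int(rng.integers(0, t + 1))
        n1, n2 = rng.choice([2, 3, 4], size=2)
        assert exact_pvalue(s1, t, int(n1), int(n2), phi) == pytest.approx(
            _enumeration_oracle(s1, t, int(n1), int(n2), phi), abs=1e-9
        )


def test_exact_test_zero_total_is_null_result():
    pseudo = pd.DataFrame(
        np.zeros((1, 4)), columns=["c0", "c1", "t0", "t1"], index=["g0"]
    )
    groups = pd.Series([CONTROL, CONTROL, TREATED, TREATED], index=pseudo.columns)
    res = exact_nb_test(pseudo, groups, 0.1)
    assert res.loc["g0", "pvalue"] == 1.0
    assert res.loc["g0", "log2fc"] == 0.0


# ----------------------------------------------------------------- BH / call

def _bh_oracle(p):
    """Direct-definition step-up: fdr_(i) = min_{j>=i} m p_(j)/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        out[i] = min(running, 1.0)
    return out


def test_bh_forced_equal_minima():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)


def test_bh_single_p_unchanged():
    assert bh_adjust([0.37])[0] == pytest.approx(0.37)


def test_bh_matches_direct_definition_on_random_vectors():
    rng = np.random.default_rng(4)
    for _ in range(300):
        p = rng.uniform(size=rng.integers(1, 40))
        assert np.allclose(bh_adjust(p), _bh_oracle(p), atol=1e-14)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


def test_call_de_strict_threshold_and_sign():
    table = pd.DataFrame(
        {
            "log2fc": [1.0, -1.0, 2.0, 0.5],
            "pvalue": [0.001, 0.001, 0.01, 0.9],
            "fdr": [0.049, 0.049, 0.05, 0.9],
        },
        index=list("abcd"),
    )
    out = call_de(table, alpha=0.05)
    assert list(out["status"]) == ["up", "down", "ns", "ns"]


# ------------------------------------------------------------- model surface

def test_model_fit_excludes_filtered_genes_from_testing():
    rng = np.random.default_rng(8)
    arr = rng.integers(20, 2000, size=(50, 6))
    arr[0] = 0  # never expressed
    cm = make_count_matrix(arr)
    res = NBExactDGE(cm).fit()
    assert res.table.loc["g0000", "status"] == "filtered"
    assert np.isnan(res.table.loc["g0000", "pvalue"])
    tested = res.table[res.table["status"] != "filtered"]
    assert tested["pvalue"].notna().all()
    assert "up-regulated" in res.summary()


def test_model_counts_match_brute_force_recount():
    rng = np.random.default_rng(12)
    mu = rng.lognormal(np.log(80), 1.0, 300)
    fold = np.ones(300)
    fold[:30] = 0.25
    y1 = rng.negative_binomial(10, 10 / (10 + mu[:, None]), size=(300, 3))
    mu2 = mu * fold
    y2 = rng.negative_binomial(10, 10 / (10 + mu2[:, None]), size=(300, 3))
    cm = make_count_matrix(np.hstack([y1, y2]))
    res = NBExactDGE(cm).fit(alpha=0.05)
    t = res.table
    assert res.n_up == ((t["fdr"] < 0.05) & (t["log2fc"] > 0)).sum()
    assert res.n_down == ((t["fdr"] < 0.05) & (t["log2fc"] < 0)).sum()
    assert res.n_down >= 20  # planted 4-fold knockdowns are found
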