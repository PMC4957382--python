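"""Comparative-Ct analysis, t-test conventions and stability measures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mirnaome.qpcr import (call_differential, ddct_fold_change,
                           genorm_stability, normfinder_stability,
                           quantities_from_ct, t_test, FoldChangeResult)


def make_ct(rows):
    return pd.DataFrame(rows, columns=["assay", "tissue", "group",
                                       "biological_rep", "technical_rep",
                                       "Ct"])


def flat_ct(values):
    """values: {(assay, group): [ct per biological rep]} in one tissue."""
    rows = []
    for (assay, group), cts in values.items():
        for bio, ct in enumerate(cts, start=1):
            for tech in (1, 2):
                rows.append((assay, "leaf", group, bio, tech, ct))
    return make_ct(rows)


# --- t test ----------------------------------------------------------------

def test_t_identical_samples_give_p_one():
    assert t_test([1, 2, 3], [1, 2, 3]) == 1.0


def test_t_zero_variance_unequal_means_gives_p_zero():
    assert t_test([0, 0, 0], [5, 5, 5]) == 0.0


def test_t_matches_reference_implementation():
    a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
    expected = sps.ttest_ind(a, b, equal_var=True).pvalue
    assert t_test(a, b) == pytest.approx(expected, rel=1e-12)


def test_t_requires_two_observations_per_sample():
    with pytest.raises(ValueError):
        t_test([1.0], [1.0, 2.0])


# --- ddCt ------------------------------------------------------------------

def test_equal_cts_give_fold_change_one():
    ct = flat_ct({("tgt", "early"): [20, 20, 20],
                  ("tgt", "mature"): [20, 20, 20],
                  ("ref", "early"): [18, 18, 18],
                  ("ref", "mature"): [18, 18, 18]})
    r = ddct_fold_change(ct, "tgt", "ref", "leaf")
    assert r.fold_change == pytest.approx(1.0)
    calls = call_differential([r])
    assert calls[0].direction == "none"


def test_one_cycle_drop_doubles_expression():
    ct = flat_ct({("tgt", "early"): [20, 20, 20],
                  ("tgt", "mature"): [19, 19, 19],
                  ("ref", "early"): [18, 18, 18],
                  ("ref", "mature"): [18, 18, 18]})
    assert ddct_fold_change(ct, "tgt", "ref", "leaf").fold_change \
        == pytest.approx(2.0)


def test_swapping_groups_inverts_fold_change():
    rng = np.random.default_rng(0)
    vals = {("tgt", "early"): list(20 + rng.normal(0, 1, 3)),
            ("tgt", "mature"): list(18 + rng.normal(0, 1, 3)),
            ("ref", "early"): [15.0, 15.1, 14.9],
            ("ref", "mature"): [15.2, 14.8, 15.0]}
    ct = flat_ct(vals)
    f = ddct_fold_change(ct, "tgt", "ref", "leaf").fold_change
    swapped = ct.assign(group=ct["group"].map({"early": "mature",
                                               "mature": "early"}))
    g = ddct_fold_change(swapped, "tgt", "ref", "leaf").fold_change
    assert f * g == pytest.approx(1.0, rel=1e-12)


def test_reference_against_itself_is_exactly_one():
    ct = flat_ct({("ref", "early"): [18.2, 17.9, 18.1],
                  ("ref", "mature"): [19.0, 18.6, 18.8]})
    r = ddct_fold_change(ct, "ref", "ref", "leaf")
    assert r.fold_change == 1.0
    assert r.p_value == 1.0


def test_missing_group_is_an_error():
    ct = flat_ct({("tgt", "early"): [20, 20, 20],
                  ("ref", "early"): [18, 18, 18]})
    with pytest.raises(ValueError):
        ddct_fold_change(ct, "tgt", "ref", "leaf")


def test_technical_replicates_are_averaged_before_statistics():
    rows = []
    for bio, (t1, t2) in enumerate([(20.0, 22.0), (21.0, 21.0),
                                    (20.5, 21.5)], start=1):
        rows += [("tgt", "leaf", "early", bio, 1, t1),
                 ("tgt", "leaf", "early", bio, 2, t2)]
        rows += [("tgt", "leaf", "mature", bio, 1, t1 - 1.0),
                 ("tgt", "leaf", "mature", bio, 2, t2 - 1.0)]
        rows += [("ref", "leaf", "early", bio, 1, 15.0),
                 ("ref", "leaf", "early", bio, 2, 15.0),
                 ("ref", "leaf", "mature", bio, 1, 15.0),
                 ("ref", "leaf", "mature", bio, 2, 15.0)]
    r = ddct_fold_change(make_ct(rows), "tgt", "ref", "leaf")
    assert r.fold_change == pytest.approx(2.0)
    # averaging collapses the within-group dCt variance to zero (the raw
    # technical values differ); unequal means then give p = 0 by convention
    assert r.p_value == 0.0


# --- differential calls ----------------------------------------------------

@pytest.mark.parametrize("fold,p,significant,direction", [
    (0.038, 0.01, True, "down"),
    (3.325, 0.01, True, "up"),
    (1.8, 0.001, False, "none"),
    (2.5, 0.2, False, "none"),
    (0.4, 0.04, True, "down"),
])
def test_two_fold_and_alpha_rule(fold, p, significant, direction):
    r = FoldChangeResult(assay="a", tissue="leaf", fold_change=fold,
                         p_value=p, n_early=3, n_mature=3)
    out = call_differential([r])[0]
    assert out.significant is significant
    assert out.direction == direction


def test_bh_adjustment_is_more_conservative():
    results = [FoldChangeResult(assay=f"a{i}", tissue="leaf", fold_change=3.0,
                                p_value=p, n_early=3, n_mature=3)
               for i, p in enumerate([0.001, 0.04, 0.045, 0.049])]
    plain = sum(r.significant for r in call_differential(results))
    adjusted = sum(r.significant for r in call_differential(results,
                                                            adjust="bh"))
    assert adjusted <= plain


# --- stability -------------------------------------------------------------

def test_genorm_flags_the_noisy_assay():
    samples = 8
    rng = np.random.default_rng(1)
    base = rng.uniform(0.5, 2.0, samples)
    q = pd.DataFrame({
        "s" + str(i): [base[i], 2 * base[i], float(rng.uniform(0.2, 5.0))]
        for i in range(samples)}, index=["a", "b", "noisy"])
    M, trace = genorm_stability(q)
    assert M.index[-1] == "noisy"
    assert trace[0][0] == "noisy"
    assert M["a"] == pytest.approx(M["b"])


def test_genorm_identical_assays_have_zero_m():
    q = pd.DataFrame(np.ones((3, 5)), index=list("abc"))
    M, _ = genorm_stability(q)
    assert np.allclose(M.to_numpy(), 0.0)


def test_genorm_rejects_zero_quantities():
    q = pd.DataFrame(np.ones((3, 4)), index=list("abc"))
    q.iloc[0, 0] = 0.0
    with pytest.raises(ValueError):
        genorm_stability(q)


def test_normfinder_constant_assay_scores_zero():
    q = pd.DataFrame([[1.0] * 6, [1, 2, 1, 2, 1, 2]], index=["flat", "vary"])
    s = normfinder_stability(q, ["g1"] * 3 + ["g2"] * 3)
    assert s["flat"] == pytest.approx(0.0)
    assert s["vary"] > 0


def test_normfinder_detects_pure_group_shift():
    q = pd.DataFrame([[1, 1, 1, 4, 4, 4], [1.0, 1.1, 0.9, 1.0, 1.1, 0.9]],
                     index=["shifted", "stable"])
    s = normfinder_stability(q, ["g1"] * 3 + ["g2"] * 3)
    assert s["shifted"] > s["stable"]


def test_normfinder_and_genorm_orderings_correlate_without_group_effects():
    rng = np.random.default_rng(3)
    agreements = []
    for _ in range(20):
        sds = rng.uniform(0.05, 0.8, 6)
        data = 2.0 ** rng.normal(0, sds[:, None], (6, 10))
        q = pd.DataFrame(data, index=[f"a{i}" for i in range(6)])
        M, _ = genorm_stability(q)
        nf = normfinder_stability(q, ["g1"] * 5 + ["g2"] * 5)
        rho = sps.spearmanr(M.reindex(nf.index).to_numpy(),
                            nf.to_numpy()).statistic
        agreements.append(rho)
    assert np.mean(agreements) > 0


def test_quantity_matrix_shape_and_positivity():
    ct = flat_ct({("a", "early"): [20, 21, 20], ("a", "mature"): [19, 19, 20],
                  ("b", "early"): [15, 15, 16], ("b", "mature"): [15, 16, 15]})
    q = quantities_from_ct(ct)
    assert q.shape == (2, 6)
    assert (q > 0).all().all()
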