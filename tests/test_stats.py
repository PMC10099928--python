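"""Exact test, trend test, Welch's t, and the conjunction verdict."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from airmn.data_model import MnCounts
from airmn.errors import InvalidTableError
from airmn.stats import (
    TrendSpec,
    cochran_armitage,
    cochran_armitage_permutation,
    fisher_exact,
    genotoxic_call,
    insert_heterogeneity_p,
    welch_t,
)
from conftest import make_experiment, make_group


# --- independent enumeration oracle for 2x2 exact tests -----------------

def fisher_oracle(a, b, c, d, sidedness):
    """Exact-integer enumeration over all tables with the observed margins."""
    n1, n2, big_k = a + b, c + d, a + c
    total = math.comb(n1 + n2, big_k)
    lo, hi = max(0, big_k - n2), min(big_k, n1)
    weights = {k: math.comb(n1, k) * math.comb(n2, big_k - k) for k in range(lo, hi + 1)}
    if sidedness == "greater":
        num = sum(w for k, w in weights.items() if k >= a)
    else:
        num = sum(w for w in weights.values() if w <= weights[a])
    return num / total


def test_fisher_matches_hand_enumeration():
    # 3 events among 20 subjects split 10/10, all in the treated arm:
    # p = C(10,3)/C(20,3) = 120/1140
    p = fisher_exact(MnCounts(10, 3), MnCounts(10, 0), sidedness="greater")
    assert p == pytest.approx(120 / 1140, rel=1e-12)


def test_fisher_no_excess_is_nonsignificant():
    p = fisher_exact(MnCounts(100, 5), MnCounts(100, 5), sidedness="greater")
    assert p > 0.5


def test_fisher_on_published_peak_dose_counts():
    treated, control = MnCounts(1033, 171), MnCounts(1811, 5)
    for side in ("greater", "two_sided"):
        p = fisher_exact(treated, control, sidedness=side)
        a, c = treated.n_bnc_mn, control.n_bnc_mn
        oracle = fisher_oracle(a, treated.n_bnc_scored - a, c,
                               control.n_bnc_scored - c, side)
        assert p == pytest.approx(oracle, rel=1e-8)
        assert p < 0.05


@settings(derandomize=True, max_examples=300)
@given(
    n1=st.integers(1, 30),
    n2=st.integers(1, 30),
    f1=st.floats(0, 1),
    f2=st.floats(0, 1),
    side=st.sampled_from(["greater", "two_sided"]),
)
def test_fisher_equals_enumeration_oracle_sampled(n1, n2, f1, f2, side):
    a, c = int(round(f1 * n1)), int(round(f2 * n2))
    p = fisher_exact(MnCounts(n1, a), MnCounts(n2, c), sidedness=side)
    assert p == pytest.approx(
        fisher_oracle(a, n1 - a, c, n2 - c, side), rel=1e-9, abs=1e-12
    )


@settings(derandomize=True, max_examples=200)
@given(
    n1=st.integers(1, 150),
    n2=st.integers(1, 150),
    f1=st.floats(0, 1),
    f2=st.floats(0, 1),
    side=st.sampled_from(["greater", "two_sided"]),
)
def test_fisher_cross_checked_against_scipy(n1, n2, f1, f2, side):
    """Independent library route: scipy's exact test gives the same p."""
    a, c = int(round(f1 * n1)), int(round(f2 * n2))
    p = fisher_exact(MnCounts(n1, a), MnCounts(n2, c), sidedness=side)
    alt = "greater" if side == "greater" else "two-sided"
    ref = sps.fisher_exact([[a, n1 - a], [c, n2 - c]], alternative=alt).pvalue
    assert p == pytest.approx(ref, rel=1e-9, abs=1e-12)


@settings(derandomize=True, max_examples=200)
@given(n1=st.integers(1, 25), n2=st.integers(1, 25), f1=st.floats(0, 1), f2=st.floats(0, 1))
def test_fisher_one_sided_tails_overlap_on_observed_table(n1, n2, f1, f2):
    """P(X >= a) + P(X <= a) = 1 + P(X = a) >= 1 for the two directions."""
    a, c = int(round(f1 * n1)), int(round(f2 * n2))
    p_greater = fisher_exact(MnCounts(n1, a), MnCounts(n2, c), sidedness="greater")
    p_less = fisher_exact(MnCounts(n2, c), MnCounts(n1, a), sidedness="greater")
    assert p_greater + p_less >= 1.0 - 1e-9


def test_fisher_rejects_empty_margin():
    with pytest.raises(InvalidTableError):
        fisher_exact(MnCounts(0, 0), MnCounts(10, 1))


# --- Cochran-Armitage ----------------------------------------------------

HAND_EXAMPLE = (
    [MnCounts(100, 0), MnCounts(100, 5), MnCounts(100, 10)],
    TrendSpec((0.0, 1.0, 2.0)),
)


def test_trend_statistic_matches_hand_computation():
    # numerator 10, variance 0.05*0.95*200 = 9.5 -> z = 10/sqrt(9.5)
    z, p = cochran_armitage(*HAND_EXAMPLE)
    assert z == pytest.approx(10 / math.sqrt(9.5), rel=1e-12)
    assert abs(z - 3.2445) < 1e-4
    assert p == pytest.approx(5.884e-4, rel=1e-3)


def test_trend_zero_when_proportions_equal():
    groups = [MnCounts(200, 10), MnCounts(100, 5), MnCounts(300, 15)]
    z, p = cochran_armitage(groups, TrendSpec((0, 1, 2)))
    assert z == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(0.5)


def test_trend_antisymmetric_under_score_reversal():
    groups, spec = HAND_EXAMPLE
    z_fwd, _ = cochran_armitage(groups, spec)
    z_rev, _ = cochran_armitage(list(reversed(groups)), spec)
    assert z_rev == pytest.approx(-z_fwd)


def test_trend_degenerate_when_no_events():
    z, p = cochran_armitage(
        [MnCounts(100, 0), MnCounts(100, 0)], TrendSpec((0, 1))
    )
    assert (z, p) == (0.0, 1.0)


@settings(derandomize=True, max_examples=100)
@given(a=st.floats(-50, 50), b=st.floats(0.1, 10))
def test_trend_invariant_under_affine_score_rescaling(a, b):
    groups, _ = HAND_EXAMPLE
    z0, _ = cochran_armitage(groups, TrendSpec((0, 1, 2)))
    z1, _ = cochran_armitage(groups, TrendSpec((a, a + b, a + 2 * b)))
    assert z1 == pytest.approx(z0, rel=1e-9)


def test_trend_with_two_groups_is_proportions_score_test():
    g1, g2 = MnCounts(120, 6), MnCounts(150, 18)
    z, _ = cochran_armitage([g1, g2], TrendSpec((0, 1)))
    p1, p2 = 6 / 120, 18 / 150
    pbar = 24 / 270
    z_score = (p2 - p1) / math.sqrt(pbar * (1 - pbar) * (1 / 120 + 1 / 150))
    assert z == pytest.approx(z_score, rel=1e-9)


def test_trend_permutation_mode_agrees_with_asymptotic():
    groups, spec = HAND_EXAMPLE
    _, p_asym = cochran_armitage(groups, spec)
    p_perm = cochran_armitage_permutation(groups, spec, n_resamples=20_000, seed=1)
    se = math.sqrt(p_perm * (1 - p_perm) / 20_000)
    assert abs(p_perm - p_asym) < 4 * se + 2e-4


# --- Welch's t ------------------------------------------------------------

def test_welch_identical_samples():
    t, _, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_welch_hand_example():
    t, df, p = welch_t([1, 2, 3], [2, 3, 4])
    assert t == pytest.approx(-1.2247, abs=1e-4)
    assert df == pytest.approx(4.0, rel=1e-9)
    assert p == pytest.approx(0.2878, abs=1e-4)


def test_welch_antisymmetric_under_swap():
    t1, df1, p1 = welch_t([1, 5, 9, 2], [4, 4, 6])
    t2, df2, p2 = welch_t([4, 4, 6], [1, 5, 9, 2])
    assert t2 == pytest.approx(-t1)
    assert df2 == pytest.approx(df1)
    assert p2 == pytest.approx(p1)


def test_welch_degenerate_constant_samples():
    assert welch_t([2.0, 2.0], [2.0, 2.0])[2] == 1.0
    t, _, p = welch_t([3.0, 3.0], [2.0, 2.0])
    assert math.isinf(t) and p == 0.0


# --- conjunction rule -----------------------------------------------------

def test_reference_experiments_all_called_genotoxic(reference):
    for chem, exp in reference.items():
        call = genotoxic_call(exp)
        assert call.verdict, chem
        assert call.trend_p < 0.05


def test_all_zero_mn_gives_not_genotoxic():
    exp = make_experiment(
        [(500, 0)] * 3, {1.0: [(500, 0)] * 3, 2.0: [(500, 0)] * 3}
    )
    call = genotoxic_call(exp)
    assert not call.verdict
    assert call.degenerate_trend
    assert call.trend_p == 1.0


def test_trend_without_any_significant_dose_is_not_genotoxic():
    # A perfect but tiny monotone trend: no pairwise test can reach 0.05.
    exp = make_experiment(
        [(500, 0)],
        {1.0: [(500, 1)], 2.0: [(500, 2)], 3.0: [(500, 3)]},
    )
    call = genotoxic_call(exp, fisher_sidedness="greater")
    min_possible = fisher_oracle(3, 497, 0, 500, "greater")
    assert min_possible > 0.05
    assert call.significant_doses == ()
    assert not call.verdict


def test_verdict_monotone_in_top_dose_events():
    base = {1.0: [(600, 1)], 2.0: [(600, 4)], 4.0: [(600, 12)]}
    exp = make_experiment([(600, 1)], base)
    assert genotoxic_call(exp).verdict
    more = {1.0: [(600, 1)], 2.0: [(600, 4)], 4.0: [(600, 30)]}
    assert genotoxic_call(make_experiment([(600, 1)], more)).verdict


def test_heterogeneity_warning_on_discordant_inserts():
    hot = make_group(conc=1.0, mn=[(600, 0), (600, 0), (600, 30)])
    assert insert_heterogeneity_p(hot) < 0.05
    calm = make_group(conc=1.0, mn=[(600, 10), (600, 11), (600, 9)])
    assert insert_heterogeneity_p(calm) > 0.05
    exp = make_experiment(
        [(600, 1), (600, 2), (600, 1)], {1.0: [(600, 0), (600, 0), (600, 30)]}
    )
    assert genotoxic_call(exp).heterogeneity_warning


def test_genotox_call_records_assumptions():
    exp = make_experiment([(500, 1)], {1.0: [(500, 2)]})
    call = genotoxic_call(exp, fisher_sidedness="greater")
    assert call.assumptions["fisher_sidedness"] == "greater"
    assert call.assumptions["any_dose_rule"] is True
    assert call.assumptions["trend_scores"] == (0.0, 1.0)
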