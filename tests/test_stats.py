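"""Statistical layer: mixed ANOVA vs a sums-of-squares oracle, Spearman, ROC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from niaflush import (
    EffectResult,
    apply_bonferroni,
    bonferroni_threshold,
    group_time_effects,
    roc_analysis,
    spearman_r,
)
from niaflush.errors import AnalysisError, ValidationError


def _cohort_table(values_by_group, times=(3, 5, 10, 15)):
    """Long-format table from {group: array (n_subjects, n_times)}."""
    rows = []
    for group, matrix in values_by_group.items():
        for i, subject_values in enumerate(np.atleast_2d(matrix)):
            for t, v in zip(times, subject_values):
                rows.append(
                    {"subject": f"{group}{i}", "group": group, "time": t, "value": v}
                )
    return pd.DataFrame(rows)


def split_plot_ss_oracle(values_by_group):
    """Direct sums-of-squares decomposition of the balanced split-plot design."""
    groups = {g: np.atleast_2d(np.asarray(m, dtype=float)) for g, m in values_by_group.items()}
    all_values = np.concatenate([m.ravel() for m in groups.values()])
    grand = all_values.mean()
    t_count = next(iter(groups.values())).shape[1]
    n_total = sum(m.shape[0] for m in groups.values())

    ss_between_subj = t_count * sum(
        ((m.mean(axis=1) - grand) ** 2).sum() for m in groups.values()
    )
    ss_group = t_count * sum(
        m.shape[0] * (m.mean() - grand) ** 2 for m in groups.values()
    )
    ss_subj_within = ss_between_subj - ss_group
    time_means = np.mean(
        np.concatenate([m for m in groups.values()], axis=0), axis=0
    )
    ss_time = n_total * ((time_means - grand) ** 2).sum()
    ss_inter = sum(
        m.shape[0]
        * ((m.mean(axis=0) - m.mean() - time_means + grand) ** 2).sum()
        for m in groups.values()
    )
    ss_total = ((all_values - grand) ** 2).sum()
    ss_err_within = ss_total - ss_between_subj - ss_time - ss_inter

    g = len(groups)
    df = {
        "group": (g - 1, n_total - g),
        "time": (t_count - 1, (n_total - g) * (t_count - 1)),
        "group x time": ((g - 1) * (t_count - 1), (n_total - g) * (t_count - 1)),
    }
    ss_eff = {"group": ss_group, "time": ss_time, "group x time": ss_inter}
    ss_err = {"group": ss_subj_within, "time": ss_err_within, "group x time": ss_err_within}
    out = {}
    for factor in df:
        d1, d2 = df[factor]
        f_stat = (ss_eff[factor] / d1) / (ss_err[factor] / d2)
        out[factor] = {
            "F": f_stat,
            "p": float(sps.f.sf(f_stat, d1, d2)),
            "np2": ss_eff[factor] / (ss_eff[factor] + ss_err[factor]),
        }
    return out


# --- group_time_effects ---------------------------------------------------


def test_mixed_anova_matches_ss_oracle_on_small_table(rng):
    """6 subjects x 4 times: F, p and partial eta^2 from the SS decomposition."""
    data = {
        "HC": rng.normal(10, 2, size=(3, 4)),
        "SZ": rng.normal(8, 2, size=(3, 4)),
    }
    expected = split_plot_ss_oracle(data)
    results = {r.factor: r for r in group_time_effects(_cohort_table(data))}
    assert set(results) == {"group", "time", "group x time"}
    for factor, exp in expected.items():
        assert results[factor].F == pytest.approx(exp["F"], rel=1e-9), factor
        assert results[factor].p == pytest.approx(exp["p"], rel=1e-9), factor
        assert results[factor].partial_eta_sq == pytest.approx(exp["np2"], rel=1e-9)


def test_identical_groups_have_no_group_effect(rng):
    shared = rng.normal(size=(4, 4))
    data = {"A": shared.copy(), "B": shared.copy()}
    results = {r.factor: r for r in group_time_effects(_cohort_table(data))}
    assert results["group"].partial_eta_sq == pytest.approx(0.0, abs=1e-12)
    assert results["group"].p > 0.999


def test_degenerate_single_time_point_perfect_separation():
    table = _cohort_table({"A": [[0.0], [0.0]], "B": [[1.0], [1.0]]}, times=(3,))
    (result,) = group_time_effects(table)
    assert result.factor == "group"
    assert result.partial_eta_sq == pytest.approx(1.0)
    assert result.p == 0.0


def test_partial_eta_sq_invariant_under_affine_rescaling(rng):
    data = {"A": rng.normal(size=(4, 4)), "B": rng.normal(0.5, 1, size=(4, 4))}
    base = group_time_effects(_cohort_table(data))
    rescaled_data = {g: 3.7 * m + 11.0 for g, m in data.items()}
    rescaled = group_time_effects(_cohort_table(rescaled_data))
    for r_base, r_new in zip(base, rescaled):
        assert r_new.partial_eta_sq == pytest.approx(r_base.partial_eta_sq, rel=1e-9)
        assert r_new.F == pytest.approx(r_base.F, rel=1e-9)


@pytest.mark.parametrize(
    "bad_table, message",
    [
        (_cohort_table({"A": np.zeros((1, 4)), "B": np.zeros((3, 4))}), "at least 2"),
        (_cohort_table({"A": np.zeros((3, 4))}), "exactly 2 groups"),
        (
            _cohort_table({"A": np.zeros((2, 4)), "B": np.zeros((2, 4))}).iloc[:-1],
            "all time points",
        ),
    ],
)
def test_malformed_cohorts_rejected(bad_table, message):
    with pytest.raises(ValidationError, match=message):
        group_time_effects(bad_table)


def test_group_p_values_uniform_under_null(rng):
    """Group-effect p-values are U(0, 1) when both groups share a distribution."""
    pvals = []
    for _ in range(200):
        data = {"A": rng.normal(size=(5, 4)), "B": rng.normal(size=(5, 4))}
        results = {r.factor: r for r in group_time_effects(_cohort_table(data))}
        pvals.append(results["group"].p)
    assert sps.kstest(pvals, "uniform").pvalue > 0.01


# --- bonferroni -----------------------------------------------------------


@pytest.mark.parametrize(
    "alpha, m, expected",
    [(0.05, 1, 0.05), (0.05, 27, 0.05 / 27), (0.05, 5, 0.01), (0.01, 10, 0.001)],
)
def test_bonferroni_threshold(alpha, m, expected):
    assert bonferroni_threshold(alpha, m) == pytest.approx(expected)


def test_bonferroni_threshold_rejects_bad_input():
    with pytest.raises(ValidationError):
        bonferroni_threshold(0.05, 0)
    with pytest.raises(ValidationError):
        bonferroni_threshold(1.5, 3)


def test_bonferroni_flag_monotone_in_p():
    results = [
        EffectResult("v", "group", F=1.0, p=p, partial_eta_sq=0.1)
        for p in (0.0001, 0.001, 0.01, 0.049, 0.2)
    ]
    apply_bonferroni(results, alpha=0.05)
    flags = [r.significant for r in results]
    assert flags == sorted(flags, reverse=True)  # once False, never True again


# --- spearman -------------------------------------------------------------


def test_spearman_hand_examples():
    assert spearman_r([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
    assert spearman_r([1, 2, 3, 4], [8, 6, 4, 2]) == pytest.approx(-1.0)
    assert spearman_r([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)


def test_spearman_tied_ranks_match_pearson_of_midranks(rng):
    x = rng.integers(0, 5, size=20).astype(float)
    y = rng.integers(0, 5, size=20).astype(float)
    expected = sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic
    assert spearman_r(x, y) == pytest.approx(expected)


def test_spearman_rejects_degenerate_input():
    with pytest.raises(ValidationError):
        spearman_r([1, 2], [3, 4])
    with pytest.raises(AnalysisError):
        spearman_r([1, 1, 1], [1, 2, 3])


# --- ROC ------------------------------------------------------------------


def pairwise_auc_oracle(scores, labels):
    """AUC as the Mann-Whitney pair statistic with 1/2 for ties."""
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_perfect_separation():
    result = roc_analysis([0.9, 0.8, 0.7, 0.2, 0.1], [1, 1, 1, 0, 0])
    assert result.auc == pytest.approx(1.0)
    assert result.operating_sensitivity == pytest.approx(1.0)
    assert result.operating_specificity == pytest.approx(1.0)


def test_three_vs_three_pair_counting_example():
    # positives {0.9, 0.8, 0.7}, negatives {0.75, 0.6, 0.4}: 8 of 9 pairs correct
    result = roc_analysis([0.9, 0.8, 0.7, 0.75, 0.6, 0.4], [1, 1, 1, 0, 0, 0])
    assert result.auc == pytest.approx(8 / 9)


def test_identical_distributions_near_chance(rng):
    scores = np.concatenate([rng.normal(size=300), rng.normal(size=300)])
    labels = np.array([1] * 300 + [0] * 300)
    assert roc_analysis(scores, labels).auc == pytest.approx(0.5, abs=0.08)


def test_auc_matches_pairwise_oracle_on_random_instances(rng):
    for _ in range(100):
        n = int(rng.integers(4, 21))
        labels = np.zeros(n, dtype=bool)
        labels[: int(rng.integers(1, n))] = True
        rng.shuffle(labels)
        # integer scores force ties
        scores = rng.integers(0, 6, size=n).astype(float)
        if labels.all() or not labels.any():
            continue
        result = roc_analysis(scores, labels)
        assert result.auc == pytest.approx(pairwise_auc_oracle(scores, labels))


def test_roc_curve_is_monotone(rng):
    scores = rng.normal(size=60)
    labels = rng.random(60) < 0.5
    labels[0], labels[1] = True, False
    result = roc_analysis(scores, labels)
    fpr = 1.0 - result.specificity
    assert np.all(np.diff(result.sensitivity) >= 0)
    assert np.all(np.diff(fpr) >= 0)


def test_youden_operating_point_with_tie_toward_sensitivity():
    # two thresholds reach J = 0.5; the rule picks the more sensitive one
    scores = np.array([4.0, 3.0, 2.0, 1.0])
    labels = np.array([1, 1, 0, 0])
    result = roc_analysis(scores, labels)
    assert result.operating_sensitivity == pytest.approx(1.0)
    j = result.sensitivity - (1.0 - result.specificity)
    assert result.operating_sensitivity + result.operating_specificity - 1 == pytest.approx(j.max())


def test_single_class_rejected():
    with pytest.raises(AnalysisError):
        roc_analysis([0.1, 0.2, 0.3], [1, 1, 1])
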