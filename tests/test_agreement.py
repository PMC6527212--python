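import itertools

import numpy as np
import pandas as pd
import pytest

from liverseg.agreement import (ObserverTable, TABLE_FIXTURE, cohort_agreement,
                                icc_2_1, per_case_variability, wilcoxon_paired)

ROUTINE = ["Rad", "Res1", "Res2"]
CORRECTED = ["Res3", "RA"]


def anova_icc_2_1(y):
    """Independent two-way ANOVA oracle for ICC(2,1)."""
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    grand = y.mean()
    ms_r = k * ((y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_c = n * ((y.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    ms_e = ((y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True)
             + grand) ** 2).sum() / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)


def brute_force_wilcoxon(d):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = pd.Series(np.abs(d)).rank().to_numpy()
    w_plus = ranks[d > 0].sum()
    n = len(d)
    stats_all = [np.array(signs) @ ranks for signs in
                 itertools.product([0, 1], repeat=n)]
    stats_all = np.array(stats_all)
    mean_w = ranks.sum() / 2
    observed = abs(w_plus - mean_w)
    p = np.mean(np.abs(stats_all - mean_w) >= observed - 1e-12)
    return p


def test_per_case_variability_worked_examples():
    assert round(per_case_variability([6.79, 1.17, 10.58]), 2) == 6.27
    assert round(per_case_variability([4.20, 0.70]), 2) == 3.50
    assert per_case_variability([2.2, 2.2, 2.2]) == 0.0
    with pytest.raises(ValueError):
        per_case_variability([1.0])


def test_per_case_variability_properties():
    rng = np.random.default_rng(0)
    vals = rng.random(5) * 10
    base = per_case_variability(vals)
    for _ in range(5):
        assert abs(per_case_variability(rng.permutation(vals)) - base) < 1e-12
    a, b = rng.random(2)
    assert abs(per_case_variability([a, b]) - abs(a - b)) < 1e-12


def test_cohort_agreement_on_packaged_table():
    routine = ObserverTable.from_csv(TABLE_FIXTURE, observers=ROUTINE)
    rep = cohort_agreement(routine)
    assert round(rep.mean_variability, 2) == 2.75
    assert round(rep.sd_variability, 2) == 1.41
    corrected = ObserverTable.from_csv(TABLE_FIXTURE, observers=CORRECTED)
    rep2 = cohort_agreement(corrected)
    assert round(rep2.mean_variability, 2) == 0.69
    assert round(rep2.sd_variability, 2) == 0.88
    assert len(rep.per_case_variability) == 21


def test_cohort_agreement_all_zero():
    table = ObserverTable(case_ids=["a", "b"], observer_ids=["x", "y"],
                          values=np.zeros((2, 2)))
    rep = cohort_agreement(table)
    assert rep.mean_variability == 0.0 and rep.sd_variability == 0.0


def test_observer_table_validation():
    with pytest.raises(ValueError):
        ObserverTable(case_ids=["a"], observer_ids=["x"], values=np.zeros((1, 1)))
    with pytest.raises(ValueError):
        ObserverTable(case_ids=["a"], observer_ids=["x", "y"],
                      values=np.array([[1.0, np.nan]]))
    with pytest.raises(ValueError):
        ObserverTable(case_ids=["a"], observer_ids=["x", "y"],
                      values=np.zeros((1, 2)), value_kind="volumes")


def test_icc_perfect_agreement_is_one():
    vols = np.repeat(np.array([[1400.0], [1600.0], [1800.0], [1250.0]]), 3, axis=1)
    table = ObserverTable(case_ids=list("abcd"), observer_ids=list("xyz"),
                          values=vols, value_kind="volume")
    icc, lo, hi = icc_2_1(table)
    assert icc > 0.999999


def test_icc_matches_anova_oracle_to_10_digits():
    rng = np.random.default_rng(1)
    for _ in range(10):
        case_effect = rng.normal(1500, 300, (8, 1))
        rater_effect = rng.normal(0, 30, (1, 3))
        y = case_effect + rater_effect + rng.normal(0, 20, (8, 3))
        table = ObserverTable(case_ids=[f"c{i}" for i in range(8)],
                              observer_ids=list("xyz"), values=y,
                              value_kind="volume")
        icc, lo, hi = icc_2_1(table)
        oracle = anova_icc_2_1(y)
        assert abs(icc - oracle) <= 1e-10 * max(1.0, abs(oracle))
        assert -1.0 <= lo <= icc <= hi <= 1.0


def test_icc_matches_pingouin_cross_check():
    import pingouin as pg
    rng = np.random.default_rng(2)
    y = rng.normal(1500, 250, (6, 1)) + rng.normal(0, 40, (6, 3))
    table = ObserverTable(case_ids=[f"c{i}" for i in range(6)],
                          observer_ids=list("xyz"), values=y, value_kind="volume")
    icc, _, _ = icc_2_1(table)
    long = pd.DataFrame({"case": np.repeat(table.case_ids, 3),
                         "rater": np.tile(table.observer_ids, 6),
                         "value": y.ravel()})
    res = pg.intraclass_corr(long, targets="case", raters="rater", ratings="value")
    ref = float(res.set_index("Type").loc["ICC(A,1)", "ICC"])
    assert abs(icc - ref) < 1e-9


def test_icc_null_distribution_centers_at_zero():
    """Independently shuffled observer columns destroy case structure."""
    rng = np.random.default_rng(3)
    base = rng.normal(1500, 300, 21)
    iccs = []
    for _ in range(100):
        y = np.column_stack([rng.permutation(base) for _ in range(3)])
        table = ObserverTable(case_ids=[f"c{i}" for i in range(21)],
                              observer_ids=list("xyz"), values=y,
                              value_kind="volume")
        iccs.append(icc_2_1(table)[0])
    iccs = np.array(iccs)
    se = iccs.std(ddof=1) / np.sqrt(len(iccs))
    # the finite-sample null expectation of an intraclass correlation is
    # -1/(n-1), not exactly 0
    null_mean = -1.0 / (21 - 1)
    assert null_mean - 3 * se <= iccs.mean() <= 3 * se


def test_icc_requires_volumes_and_enough_cases():
    table = ObserverTable(case_ids=["a", "b"], observer_ids=["x", "y"],
                          values=np.array([[1.0, 2.0], [3.0, 4.0]]))
    with pytest.raises(ValueError):
        icc_2_1(table)
    degenerate = ObserverTable(case_ids=["a", "b"], observer_ids=["x", "y"],
                               values=np.full((2, 2), 1500.0), value_kind="volume")
    with pytest.warns(UserWarning):
        assert icc_2_1(degenerate)[0] == 1.0


def test_wilcoxon_identical_samples():
    a = np.arange(1.0, 9.0)
    p, sig = wilcoxon_paired(a, a)
    assert p == 1.0 and not sig


def test_wilcoxon_matches_brute_force_enumeration():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, -6.0]) + 10.0
    b = np.full(6, 10.0)
    p, _ = wilcoxon_paired(a, b)
    assert abs(p - brute_force_wilcoxon(a - b)) < 1e-12


def test_wilcoxon_extreme_shift_minimal_p():
    rng = np.random.default_rng(4)
    b = rng.random(21)
    a = b + 100.0
    p, sig = wilcoxon_paired(a, b, alpha=0.01)
    assert abs(p - 2 / 2 ** 21) < 1e-12  # the minimal attainable two-sided p
    assert sig


def test_wilcoxon_input_validation():
    with pytest.raises(ValueError):
        wilcoxon_paired([1, 2, 3], [1, 2])
    with pytest.raises(ValueError):
        wilcoxon_paired([1, 2], [1, 2])
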