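"""Effect measures and the univariate per-cell logistic scan."""

import numpy as np
import pandas as pd
import pytest

from braingrid import (
    SimulationConfig,
    TwoByTwo,
    build_matrix,
    fit_logistic,
    generate_cohort,
    odds_ratio,
    relative_risk,
    univariate_scan,
)
from braingrid.involvement import InvolvementMatrix
from braingrid.stats import scan_frame


def oracle_log_or(t):
    """Independent log-space computation of the 2x2 OR and Wald CI."""
    import math

    lo = math.log(t.a * t.d / (t.b * t.c))
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    from scipy.stats import norm

    z = norm.ppf(0.975)
    return math.exp(lo), math.exp(lo - z * se), math.exp(lo + z * se)


# --- odds ratio -----------------------------------------------------------


def test_sex_by_seizure_table_reproduces_published_or():
    """49/9 male vs 21/14 female seizure counts give OR 3.63 (1.36-9.68)."""
    est = odds_ratio(TwoByTwo(49, 9, 21, 14))
    assert est.point == pytest.approx(3.63, abs=0.005)
    assert est.ci_low == pytest.approx(1.36, abs=0.005)
    assert est.ci_high == pytest.approx(9.68, abs=0.005)
    assert est.p < 0.05


def test_balanced_table_or_is_one():
    est = odds_ratio(TwoByTwo(10, 10, 10, 10))
    assert est.point == pytest.approx(1.0)
    assert est.ci_low < 1.0 < est.ci_high


def test_or_matches_independent_log_space_oracle():
    t = TwoByTwo(5, 5, 2, 8)
    est = odds_ratio(t)
    point, lo, hi = oracle_log_or(t)
    assert est.point == pytest.approx(point, rel=1e-12)
    assert est.ci_low == pytest.approx(lo, rel=1e-12)
    assert est.ci_high == pytest.approx(hi, rel=1e-12)


def test_zero_cell_is_flagged_not_raised():
    est = odds_ratio(TwoByTwo(5, 0, 2, 8))
    assert not est.estimable
    assert np.isnan(est.point)


def test_or_reciprocal_under_exposure_flip():
    t = TwoByTwo(30, 12, 18, 25)
    flipped = TwoByTwo(t.c, t.d, t.a, t.b)
    assert odds_ratio(flipped).point == pytest.approx(1 / odds_ratio(t).point)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        TwoByTwo(-1, 2, 3, 4)


# --- relative risk ---------------------------------------------------------


def test_border_risk_table_reproduces_published_rr():
    """11/28 diffuse vs 12/54 sharp seizure risks give RR 1.77 (the printed
    1.78 comes from the pre-rounded 39%/22%)."""
    est = relative_risk(TwoByTwo(11, 17, 12, 42))
    assert est.point == pytest.approx((11 / 28) / (12 / 54), rel=1e-12)
    assert est.point == pytest.approx(1.78, rel=0.01)


def test_identical_risks_give_rr_one():
    assert relative_risk(TwoByTwo(5, 5, 10, 10)).point == pytest.approx(1.0)


def test_forced_arithmetic_rr():
    assert relative_risk(TwoByTwo(2, 2, 1, 3)).point == pytest.approx(2.0)


def test_rr_zero_outcome_flagged():
    assert not relative_risk(TwoByTwo(0, 5, 3, 7)).estimable


def test_rr_empty_group_raises():
    with pytest.raises(ValueError):
        relative_risk(TwoByTwo(0, 0, 3, 7))


# --- logistic fit -----------------------------------------------------------


def test_logistic_on_binary_predictor_equals_2x2_or():
    t = TwoByTwo(49, 9, 21, 14)
    x = np.r_[np.ones(58), np.zeros(35)]
    y = np.r_[np.ones(49), np.zeros(9), np.ones(21), np.zeros(14)]
    fit = fit_logistic(np.column_stack([np.ones(93), x]), y, names=["const", "male"])
    assert fit.converged and not fit.separated
    assert np.exp(fit.params[1]) == pytest.approx(odds_ratio(t).point, rel=1e-6)
    tab = fit.wald_table().loc["male"]
    assert tab["ci_low"] == pytest.approx(odds_ratio(t).ci_low, rel=1e-4)


def test_null_predictor_ci_covers_zero():
    rng = np.random.default_rng(42)
    n = 500
    x = rng.normal(size=n)
    y = (rng.random(n) < 0.5).astype(float)
    fit = fit_logistic(np.column_stack([np.ones(n), x]), y)
    lo = fit.params[1] - 1.96 * fit.se[1]
    hi = fit.params[1] + 1.96 * fit.se[1]
    assert lo < 0 < hi


def test_perfect_separation_flagged():
    x = np.r_[np.zeros(10), np.ones(10)]
    y = x.copy()
    fit = fit_logistic(np.column_stack([np.ones(20), x]), y)
    assert fit.separated


def test_constant_predictor_rejected():
    n = 20
    X = np.column_stack([np.ones(n), np.full(n, 3.0)])
    with pytest.raises(ValueError, match="constant"):
        fit_logistic(X, np.r_[np.ones(10), np.zeros(10)])


# --- univariate scan --------------------------------------------------------


def _matrix_from_array(arr, labels):
    frame = pd.DataFrame(arr, columns=labels)
    frame.index = [f"p{i}" for i in range(len(frame))]
    frame.index.name = "id"
    full = pd.DataFrame(0, index=frame.index, columns=_all_labels())
    full[labels] = frame
    return InvolvementMatrix(full, 0.0, {})


def _all_labels():
    from braingrid.grid import cell_label

    return [
        cell_label(a, c, s) for a in range(1, 5) for c in range(1, 4) for s in range(1, 5)
    ]


def test_never_involved_cell_excluded_as_degenerate():
    rng = np.random.default_rng(1)
    arr = rng.integers(0, 2, size=(40, 1))
    m = _matrix_from_array(arr, ["A1C1S1"])
    outcome = pd.Series(rng.random(40) < 0.5, index=m.frame.index)
    results = {r.cell: r for r in univariate_scan(m, outcome)}
    assert results["A2C1S1"].flag == "degenerate"
    assert "involved=0" in results["A2C1S1"].reason


def test_scan_or_equals_closed_form_2x2():
    rng = np.random.default_rng(2)
    x = rng.integers(0, 2, size=60)
    y = (rng.random(60) < np.where(x == 1, 0.7, 0.4))
    m = _matrix_from_array(x[:, None], ["A1C1S1"])
    outcome = pd.Series(y, index=m.frame.index)
    res = {r.cell: r for r in univariate_scan(m, outcome)}["A1C1S1"]
    closed = odds_ratio(TwoByTwo.from_vectors(x.astype(bool), y))
    assert res.estimate.point == pytest.approx(closed.point, rel=1e-6)


def test_scan_flags_separated_cells():
    y = np.r_[np.ones(10), np.zeros(10)].astype(bool)
    m = _matrix_from_array(y[:, None].astype(int), ["A1C1S1"])
    outcome = pd.Series(y, index=m.frame.index)
    res = {r.cell: r for r in univariate_scan(m, outcome)}["A1C1S1"]
    assert res.flag == "separated"
    assert res.estimate is None


def test_planted_or4_cell_recovered_with_nominal_ci_coverage():
    """Generate-involve-scan loop: the 95% CI for a planted cell effect of
    OR 4 covers the truth in at least 90 of 100 replicates at n=200."""
    target = "A3C2S3"
    covered = 0
    for rep in range(100):
        cfg = SimulationConfig(
            n_patients=200,
            seed=1000 + rep,
            cell_effects={target: float(np.log(4.0))},
            sex_effect=0.0,
            target_prevalence=0.5,
            seeding_weights={target: 0.5, "A1C3S2": 0.25, "A2C1S1": 0.25},
            reference_shape=(24, 24, 24),
        )
        syn = generate_cohort(cfg)
        m = build_matrix(syn.grid, syn.cohort, masks=syn.masks)
        outcome = syn.cohort.to_frame()["seizure"]
        res = {r.cell: r for r in univariate_scan(m, outcome)}[target]
        assert res.flag == "ok"
        if res.estimate.ci_low <= 4.0 <= res.estimate.ci_high:
            covered += 1
    assert covered >= 90


def test_permutation_null_calibration():
    """Permuting outcome labels breaks all associations: across 200
    permutations the fraction of estimable cells with p < 0.05 stays close
    to the nominal 5%.  Run at n=120 with well-populated cells only, where
    the Wald approximation is trustworthy (at very small n it is known to
    be conservative)."""
    syn = generate_cohort(
        SimulationConfig(n_patients=120, seed=77, target_prevalence=0.5,
                         reference_shape=(24, 24, 24))
    )
    m = build_matrix(syn.grid, syn.cohort, masks=syn.masks)
    outcome = syn.cohort.to_frame()["seizure"].to_numpy()
    rng = np.random.default_rng(99)
    hits = trials = 0
    for _ in range(200):
        perm = pd.Series(rng.permutation(outcome), index=m.frame.index)
        for r in univariate_scan(m, perm, min_involved=15):
            if r.flag == "ok":
                trials += 1
                hits += r.estimate.p < 0.05
    rate = hits / trials
    se = np.sqrt(0.05 * 0.95 / trials)
    # permutation replicates are positively correlated (shared involvement
    # matrix), so allow a generous multiple of the iid binomial error
    assert abs(rate - 0.05) < 8 * se, f"rate={rate:.4f}, trials={trials}"


def test_scan_frame_optional_bh_adjustment(synthetic_20):
    syn = synthetic_20
    m = build_matrix(syn.grid, syn.cohort, masks=syn.masks)
    outcome = syn.cohort.to_frame()["seizure"]
    frame = scan_frame(univariate_scan(m, outcome), adjust="bh")
    ok = frame[frame.flag == "ok"]
    assert (ok["p_bh"] >= ok["p"] - 1e-12).all()
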