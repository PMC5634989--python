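"""Agreement statistics against independent brute-force oracles."""
import math

import numpy as np
import pytest
from scipy import stats as sps

from vqfv import (BinaryMask, CaseEvaluation, best_cutoff_per_case,
                  bland_altman, dice, estimate_max, evaluate_case, pearson,
                  summarize_cohort, sweep, volume_difference)


# --- independent oracles -----------------------------------------------------

def dice_bruteforce(a: np.ndarray, b: np.ndarray) -> float:
    """Set-formula Dice on enumerated voxel index sets."""
    sa = {tuple(v) for v in np.argwhere(a)}
    sb = {tuple(v) for v in np.argwhere(b)}
    if not sa and not sb:
        return 1.0
    return 2.0 * len(sa & sb) / (len(sa) + len(sb))


def pearson_bruteforce(x, y):
    """Direct covariance / (sd_x sd_y) evaluation plus the t-based p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    cov = ((x - x.mean()) * (y - y.mean())).sum()
    r = cov / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
    t = r * math.sqrt((n - 2) / (1 - r**2)) if abs(r) < 1 else math.inf
    p = 2 * sps.t.sf(abs(t), n - 2)
    return r, p


# --- dice --------------------------------------------------------------------

def _mask(data):
    return BinaryMask(np.asarray(data, dtype=bool), (1, 1, 1))


def test_dice_identity_disjoint_and_partial():
    a = np.zeros((4, 4, 4), dtype=bool)
    a[:2] = True
    assert dice(_mask(a), _mask(a)) == 1.0
    b = np.zeros((4, 4, 4), dtype=bool)
    b[2:] = True
    assert dice(_mask(a), _mask(b)) == 0.0
    # |a|=8, |b|=8, |a∩b|=6 -> 0.75
    a = np.zeros((4, 4, 4), dtype=bool)
    b = np.zeros((4, 4, 4), dtype=bool)
    a.flat[0:8] = True
    b.flat[2:10] = True
    assert dice(_mask(a), _mask(b)) == pytest.approx(0.75)
    assert dice_bruteforce(a, b) == pytest.approx(0.75)


def test_dice_both_empty_is_one():
    e = _mask(np.zeros((3, 3, 3)))
    assert dice(e, e) == 1.0


def test_dice_matches_bruteforce_on_random_masks():
    rng = np.random.default_rng(0)
    for _ in range(200):
        shape = tuple(rng.integers(2, 6, size=3))
        a = rng.random(shape) > rng.uniform(0.2, 0.9)
        b = rng.random(shape) > rng.uniform(0.2, 0.9)
        got = dice(_mask_with_shape(a), _mask_with_shape(b))
        assert got == dice_bruteforce(a, b)
        # symmetry, bounds
        assert got == dice(_mask_with_shape(b), _mask_with_shape(a))
        assert 0.0 <= got <= 1.0


def _mask_with_shape(data):
    return BinaryMask(data, (1, 1, 1))


# --- bland-altman ------------------------------------------------------------

def test_bland_altman_closed_forms():
    st = bland_altman([1.0, -1.0, 0.0])
    assert st.bias == pytest.approx(0.0)
    assert st.sd == pytest.approx(1.0)
    assert (st.loa_low, st.loa_high) == (pytest.approx(-1.96), pytest.approx(1.96))
    const = bland_altman([5.0, 5.0, 5.0, 5.0])
    assert const.bias == 5.0 and const.sd == 0.0
    assert const.loa_low == const.loa_high == 5.0
    with pytest.raises(ValueError):
        bland_altman([1.0])


def test_bland_altman_matches_bruteforce_on_random_instances():
    rng = np.random.default_rng(1)
    for _ in range(200):
        d = rng.normal(rng.uniform(-10, 10), rng.uniform(0.1, 20), size=rng.integers(2, 40))
        st = bland_altman(d)
        n = len(d)
        mean = sum(d) / n
        sd = math.sqrt(sum((x - mean) ** 2 for x in d) / (n - 1))
        assert st.bias == pytest.approx(mean, abs=1e-12)
        assert st.sd == pytest.approx(sd, abs=1e-12)
        assert st.loa_high - st.loa_low == pytest.approx(2 * 1.96 * st.sd, abs=1e-9)
        assert st.diff_min <= st.bias <= st.diff_max


def test_bland_altman_monte_carlo_limits():
    """1.96-SD construction: LoA of a large normal sample sit near the
    population mean +/- 1.96 sigma (sigma 15.6)."""
    rng = np.random.default_rng(2)
    st = bland_altman(rng.normal(0.0, 15.6, size=10_000))
    assert st.loa_low == pytest.approx(-30.6, abs=0.5)
    assert st.loa_high == pytest.approx(30.6, abs=0.5)


# --- pearson -----------------------------------------------------------------

def test_pearson_perfect_linearity():
    x = np.arange(10.0)
    r, p = pearson(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    r, _ = pearson(x, -x)
    assert r == pytest.approx(-1.0)


def test_pearson_matches_bruteforce():
    x = [1, 2, 3, 4, 5]
    y = [2, 1, 4, 3, 6]
    r, p = pearson(x, y)
    r0, p0 = pearson_bruteforce(x, y)
    assert r == pytest.approx(r0, abs=1e-14)
    assert p == pytest.approx(p0, rel=1e-10)


def test_pearson_matches_bruteforce_on_random_instances():
    rng = np.random.default_rng(3)
    for _ in range(200):
        n = int(rng.integers(3, 30))
        x = rng.normal(size=n)
        y = rng.uniform(-1, 1) * x + rng.normal(size=n)
        r, p = pearson(x, y)
        r0, p0 = pearson_bruteforce(x, y)
        assert r == pytest.approx(r0, abs=1e-12)
        assert p == pytest.approx(p0, rel=1e-8, abs=1e-12)


def test_pearson_input_validation():
    with pytest.raises(ValueError):
        pearson([1, 2], [1, 2])
    with pytest.raises(ValueError):
        pearson([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        pearson([1, 2, 3], [1, 2])


# --- volume difference and per-case evaluation -------------------------------

def test_volume_difference_signed():
    assert volume_difference(30.0, 30.0) == 0.0
    assert volume_difference(45.0, 30.0) == 15.0
    assert volume_difference(10.0, 50.4) == pytest.approx(-40.4)


def test_evaluate_case_self_reference(default_case, default_wl):
    pet = default_case.case.pet_vent
    sw = sweep(pet, default_wl, estimate_max(pet, default_wl))
    evals = evaluate_case(sw, sw.mask_at(15), default_wl, case_id="x")
    at15 = next(e for e in evals if e.cutoff_pct == 15)
    assert at15.dsc == 1.0
    assert at15.volume_diff == 0.0


def test_evaluate_case_empty_reference(default_case, default_wl):
    pet = default_case.case.pet_vent
    sw = sweep(pet, default_wl, estimate_max(pet, default_wl))
    empty = BinaryMask.like(default_wl, np.zeros(default_wl.shape, dtype=bool))
    evals = evaluate_case(sw, empty, default_wl)
    assert all(e.dsc == 0.0 for e in evals if e.volume_pct_wl_auto > 0)


# --- best cutoff -------------------------------------------------------------

def _evals(diffs: dict) -> list:
    return [CaseEvaluation("c", c, 0.0, 0.0, d, 1.0) for c, d in diffs.items()]


@pytest.mark.parametrize("diffs,expected", [
    ({5: 10.0, 15: -2.0, 25: -8.0}, 15),     # unique minimum
    ({10: 3.0, 20: -3.0}, 10),               # |tie|, equidistant from 15 -> lower
    ({15: 7.0}, 15),                         # single entry
    ({10: 3.0, 15: 3.0, 20: -3.0}, 15),      # tie includes 15 -> 15
])
def test_best_cutoff_tie_breaks(diffs, expected):
    assert best_cutoff_per_case(_evals(diffs)) == expected


def test_best_cutoff_empty_rejected():
    with pytest.raises(ValueError):
        best_cutoff_per_case([])


# --- cohort summary ----------------------------------------------------------

def _cohort(n_cases=6, cutoffs=(5, 15, 25), rng=None):
    rng = rng or np.random.default_rng(5)
    out = {}
    for i in range(n_cases):
        ref = rng.uniform(30, 70)
        out[f"c{i}"] = [
            CaseEvaluation(f"c{i}", c, ref + rng.normal(0, 5), ref,
                           0.0, float(rng.uniform(0.5, 1.0)))
            for c in cutoffs]
        for e in out[f"c{i}"]:
            e.volume_diff = e.volume_pct_wl_auto - e.volume_pct_wl_ref
    return out


def test_summary_reaggregation_identity():
    evals = _cohort()
    summ = summarize_cohort(evals, report_cutoff=15)
    diffs15 = [e.volume_diff for evs in evals.values() for e in evs if e.cutoff_pct == 15]
    assert summ.per_cutoff.loc[15, "mean_diff"] == pytest.approx(np.mean(diffs15))
    assert summ.agreement.bias == pytest.approx(np.mean(diffs15))
    assert sum(summ.best_cutoff_histogram.values()) == summ.n


def test_summary_identical_auto_and_ref():
    evals = {}
    rng = np.random.default_rng(6)
    for i in range(5):
        ref = rng.uniform(30, 70)
        evals[f"c{i}"] = [CaseEvaluation(f"c{i}", c, ref, ref, 0.0, 1.0)
                          for c in (5, 15, 25)]
    summ = summarize_cohort(evals, report_cutoff=15)
    assert (summ.per_cutoff.mean_diff == 0).all()
    assert (summ.per_cutoff.dsc_median == 1).all()
    np.testing.assert_allclose(summ.per_cutoff.pearson_r, 1.0)


def test_summary_pft_correlations():
    import pandas as pd

    rng = np.random.default_rng(7)
    evals = {}
    pft_rows = {}
    for i in range(20):
        ref = rng.uniform(30, 80)
        auto = ref + rng.normal(0, 3)
        evals[f"c{i}"] = [CaseEvaluation(f"c{i}", 15, auto, ref, auto - ref, 0.9)]
        pft_rows[f"c{i}"] = {"FEV1_FVC": 0.3 + 0.005 * ref + rng.normal(0, 0.02)}
    pft = pd.DataFrame(pft_rows).T
    summ = summarize_cohort(evals, pft_table=pft, report_cutoff=15)
    corr = summ.pft_correlations
    assert set(corr.index) == {"FEV1_FVC"}
    assert corr.loc["FEV1_FVC", "ref_r"] > 0.5
    assert corr.loc["FEV1_FVC", "auto_significant"] in (True, False)


def test_summary_needs_two_cases():
    evals = _cohort(n_cases=1)
    with pytest.raises(ValueError):
        summarize_cohort(evals, report_cutoff=15)
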