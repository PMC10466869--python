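import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsascan.io import PooledSiteCounts
from bsascan.scan import (
    AssociatedRegion,
    EDRecord,
    ScanConfig,
    association_threshold,
    call_regions,
    compute_ed,
    compute_ed_records,
    fit_scan,
    select_candidates,
)


def _record(chrom, pos, fitted=None, ed=0.0, freq_mut=(1.0, 0, 0, 0), ref="A"):
    return EDRecord(
        chrom=chrom, pos=pos, ref_base=ref, freq_mut=freq_mut,
        freq_wt=(1.0, 0, 0, 0), ed=ed, ed4=ed**4, fitted=fitted,
    )


# ---------------------------------------------------------------------------
# ED statistic
# ---------------------------------------------------------------------------

def test_identical_pools_have_zero_ed():
    site = PooledSiteCounts("chr1", 1, "A", (7, 3, 2, 1), (7, 3, 2, 1))
    rec = compute_ed(site)
    assert rec.ed == 0.0 and rec.ed4 == 0.0


def test_oppositely_fixed_pools_reach_sqrt2():
    site = PooledSiteCounts("chr1", 1, "A", (10, 0, 0, 0), (0, 0, 0, 10))
    assert compute_ed(site).ed == pytest.approx(math.sqrt(2), abs=1e-12)


def test_hand_computed_ed():
    site = PooledSiteCounts("chr1", 1, "A", (15, 5, 0, 0), (5, 15, 0, 0))
    rec = compute_ed(site)
    assert rec.freq_mut == pytest.approx((0.75, 0.25, 0.0, 0.0))
    assert rec.ed == pytest.approx(math.sqrt(0.5), abs=1e-12)
    assert rec.ed4 == pytest.approx(0.25, abs=1e-12)


def test_zero_depth_pool_is_an_error():
    site = PooledSiteCounts("chr1", 1, "A", (0, 0, 0, 0), (5, 5, 0, 0))
    with pytest.raises(ValueError, match="zero-depth"):
        compute_ed(site)


@settings(max_examples=100, deadline=None)
@given(
    mut=st.tuples(*[st.integers(0, 50)] * 4),
    wt=st.tuples(*[st.integers(0, 50)] * 4),
)
def test_ed_pool_swap_symmetry_and_bound(mut, wt):
    if sum(mut) == 0 or sum(wt) == 0:
        return
    a = compute_ed(PooledSiteCounts("c", 1, "A", mut, wt))
    b = compute_ed(PooledSiteCounts("c", 1, "A", wt, mut))
    assert a.ed == pytest.approx(b.ed, abs=1e-12)
    assert a.ed4 == pytest.approx(a.ed**4, abs=1e-12)
    nonzero = [i for i in range(4) if mut[i] + wt[i] > 0]
    if len(nonzero) <= 2:
        assert a.ed <= math.sqrt(2) + 1e-12


def test_mutation_frequency_is_nonref_fraction_of_mut_pool():
    site = PooledSiteCounts("chr1", 1, "G", (0, 5, 15, 0), (0, 0, 20, 0))
    assert compute_ed(site).mut_nonref_freq == pytest.approx(0.25)


# ---------------------------------------------------------------------------
# LOESS
# ---------------------------------------------------------------------------

def loess_oracle(pos, y, span):
    """Brute-force tricube weighted-least-squares evaluation at each site."""
    n = len(pos)
    k = min(n, max(3, math.ceil(span * n)))
    out = []
    for i in range(n):
        nbrs = sorted(range(n), key=lambda j: (abs(pos[j] - pos[i]), j))[:k]
        h = max(abs(pos[j] - pos[i]) for j in nbrs)
        if h == 0:
            out.append(float(np.mean([y[j] for j in nbrs])))
            continue
        w = np.array([(1 - (abs(pos[j] - pos[i]) / h) ** 3) ** 3 for j in nbrs])
        x = np.array([pos[j] - pos[i] for j in nbrs], dtype=float)
        yy = np.array([y[j] for j in nbrs], dtype=float)
        X = np.column_stack([np.ones_like(x), x])
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], yy * sw, rcond=None)
        out.append(float(beta[0]))
    return np.clip(np.array(out), 0.0, None)


def _ed_records_from_arrays(pos, y, chrom="chr1"):
    return [
        EDRecord(chrom, int(p), "A", (1, 0, 0, 0), (1, 0, 0, 0), ed=v ** 0.25, ed4=v)
        for p, v in zip(pos, y)
    ]


def test_loess_matches_bruteforce_wls_oracle():
    rng = np.random.default_rng(0)
    pos = np.sort(rng.choice(10**6, size=200, replace=False)) + 1
    y = rng.gamma(0.3, 0.02, size=200)
    records = fit_scan(_ed_records_from_arrays(pos, y), ScanConfig(span=0.1))
    expected = loess_oracle(list(pos), list(y), 0.1)
    got = np.array([r.fitted for r in records])
    np.testing.assert_allclose(got, expected, atol=1e-9)


def test_loess_constant_invariance():
    pos = np.arange(1, 51) * 100
    records = fit_scan(_ed_records_from_arrays(pos, np.full(50, 0.37)))
    assert all(r.fitted == pytest.approx(0.37, abs=1e-12) for r in records)


def test_loess_reproduces_linear_ramp():
    pos = np.arange(1, 101) * 1000
    y = 1.0 + 2e-5 * pos  # degree-1 fit is exact on a line
    records = fit_scan(_ed_records_from_arrays(pos, y))
    np.testing.assert_allclose([r.fitted for r in records], y, rtol=1e-9)


def test_loess_spreads_single_spike():
    pos = np.arange(1, 22) * 100
    y = np.zeros(21)
    y[10] = 5.0
    records = fit_scan(_ed_records_from_arrays(pos, y), ScanConfig(span=0.3))
    fitted = np.array([r.fitted for r in records])
    assert fitted[10] < 5.0  # peak shrunk
    assert (fitted[[8, 9, 11, 12]] > 0).all()  # mass spread over the window


def test_loess_agrees_with_statsmodels_on_smooth_signal():
    from statsmodels.nonparametric.smoothers_lowess import lowess

    pos = np.arange(1, 301, dtype=float)
    y = 0.2 + 0.1 * np.sin(pos / 30)
    records = fit_scan(_ed_records_from_arrays(pos.astype(int), y), ScanConfig(span=0.2))
    ref = lowess(y, pos, frac=0.2, it=0, return_sorted=False)
    np.testing.assert_allclose([r.fitted for r in records], ref, atol=5e-3)


def test_small_chromosome_falls_back_to_raw(caplog):
    pos = np.arange(1, 6) * 10
    y = np.array([0.1, 0.5, 0.2, 0.9, 0.3])
    with caplog.at_level("WARNING"):
        records = fit_scan(_ed_records_from_arrays(pos, y))
    np.testing.assert_allclose([r.fitted for r in records], y)
    assert any("fall back" in m or "falls back" in m.lower() for m in caplog.messages)


def test_fit_scan_requires_increasing_positions():
    records = _ed_records_from_arrays([10, 10, 20], [0.1, 0.2, 0.3])
    with pytest.raises(ValueError, match="strictly increasing"):
        fit_scan(records)


# ---------------------------------------------------------------------------
# threshold
# ---------------------------------------------------------------------------

def test_threshold_of_identical_values_is_that_value():
    assert association_threshold([1.0, 1.0, 1.0, 1.0]) == pytest.approx(1.0)


def test_threshold_hand_value():
    # median 0, sample SD sqrt(20)
    assert association_threshold([0, 0, 0, 0, 10]) == pytest.approx(
        3 * math.sqrt(20), abs=1e-9
    )


@settings(max_examples=50, deadline=None)
@given(
    values=st.lists(st.floats(-100, 100), min_size=2, max_size=30),
    shift=st.floats(-50, 50),
)
def test_threshold_translation_equivariance(values, shift):
    base = association_threshold(values)
    shifted = association_threshold([v + shift for v in values])
    assert shifted == pytest.approx(base + shift, abs=1e-9)


def test_threshold_requires_two_values():
    with pytest.raises(ValueError):
        association_threshold([1.0])


# ---------------------------------------------------------------------------
# regions and candidates
# ---------------------------------------------------------------------------

def test_regions_from_fitted_patterns():
    recs = [
        _record("chr1", 100, fitted=0.0),
        _record("chr1", 200, fitted=5.0),
        _record("chr1", 300, fitted=5.0),
        _record("chr1", 400, fitted=0.0),
    ]
    (region,) = call_regions(recs, threshold=1.0)
    assert (region.start, region.end, region.n_sites) == (200, 300, 2)
    assert region.peak_fitted == 5.0


def test_single_gap_splits_regions():
    recs = [
        _record("chr1", 100, fitted=5.0),
        _record("chr1", 200, fitted=0.0),
        _record("chr1", 300, fitted=5.0),
    ]
    regions = call_regions(recs, threshold=1.0)
    assert [(r.start, r.end) for r in regions] == [(100, 100), (300, 300)]


def test_chromosome_boundary_splits_regions():
    recs = [_record("chr1", 100, fitted=5.0), _record("chr2", 100, fitted=5.0)]
    assert len(call_regions(recs, threshold=1.0)) == 2


def test_no_site_above_threshold_gives_no_regions():
    recs = [_record("chr1", 100, fitted=0.1)]
    assert call_regions(recs, threshold=1.0) == []


def test_candidate_rules_are_strict_and_region_bound():
    inside_good = _record("chr1", 200, fitted=5.0, ed=0.71, freq_mut=(0.2, 0.8, 0, 0))
    inside_edge = _record("chr1", 300, fitted=5.0, ed=0.71, freq_mut=(0.25, 0.75, 0, 0))
    inside_lowed = _record("chr1", 400, fitted=5.0, ed=0.5, freq_mut=(0.1, 0.9, 0, 0))
    outside = _record("chr1", 900, fitted=0.0, ed=1.0, freq_mut=(0.1, 0.9, 0, 0))
    regions = call_regions([inside_good, inside_edge, inside_lowed, outside], threshold=1.0)
    regions = select_candidates(regions)
    (region,) = regions
    assert [c.pos for c in region.candidates] == [200]  # 0.75 exactly and ed 0.5 exactly excluded
    assert all(c in region.sites for c in region.candidates)
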