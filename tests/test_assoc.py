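import numpy as np
import pytest
from scipy.stats import f as f_dist

from bsascan.assoc import associate_all_sites, fit_association, summarize_bins
from bsascan.io import PhenotypeRecord
from bsascan.simulate import simulate_phenotypes

SITE = "chr1:25000000"


def _records(melatonin, genotypes, ages):
    return [
        PhenotypeRecord(f"s{i}", m, a, {SITE: g})
        for i, (m, g, a) in enumerate(zip(melatonin, genotypes, ages))
    ]


def one_way_anova_oracle(groups):
    """Closed-form one-way ANOVA F and p."""
    k = len(groups)
    N = sum(len(g) for g in groups)
    grand = sum(sum(g) for g in groups) / N
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    F = (ssb / (k - 1)) / (ssw / (N - k))
    return F, float(f_dist.sf(F, k - 1, N - k))


def test_noiseless_recovery_of_genotype_contrast():
    recs = simulate_phenotypes(
        n_animals=60, genotype_effects={"AA": 0.0, "AB": 2.0}, noise_sd=0.0, seed=1
    )
    assoc = fit_association(recs, SITE)
    effects = assoc.model.genotype_effects
    assert effects["AB"] - effects["AA"] == pytest.approx(2.0, abs=1e-9)
    assert assoc.model.genotype_p == pytest.approx(0.0, abs=1e-12)
    assert assoc.significant


def test_single_age_level_equals_one_way_anova():
    rng = np.random.default_rng(4)
    genos = ["AA"] * 10 + ["AB"] * 12 + ["BB"] * 8
    y = list(rng.normal(1.5, 0.5, 30) + [0 if g == "AA" else 0.8 for g in genos])
    recs = _records(y, genos, ["adult"] * 30)
    assoc = fit_association(recs, SITE)
    groups = [
        [m for m, g in zip(y, genos) if g == lvl] for lvl in ("AA", "AB", "BB")
    ]
    F, p = one_way_anova_oracle(groups)
    assert assoc.model.genotype_F == pytest.approx(F, rel=1e-9)
    assert assoc.model.genotype_p == pytest.approx(p, rel=1e-9)


def test_residuals_sum_to_zero():
    recs = simulate_phenotypes(n_animals=80, noise_sd=0.5, seed=6)
    assoc = fit_association(recs, SITE)
    assert assoc.model.residuals.sum() == pytest.approx(0.0, abs=1e-9)


def test_sum_to_zero_constraints_hold():
    recs = simulate_phenotypes(n_animals=120, noise_sd=0.5, seed=8)
    m = fit_association(recs, SITE).model
    assert sum(m.genotype_effects.values()) == pytest.approx(0.0, abs=1e-9)
    assert sum(m.age_effects.values()) == pytest.approx(0.0, abs=1e-9)


def test_p_invariant_under_genotype_relabeling():
    recs = simulate_phenotypes(n_animals=100, noise_sd=0.5, seed=3)
    p1 = fit_association(recs, SITE).model.genotype_p
    relabeled = [
        PhenotypeRecord(
            r.sample_id, r.melatonin, r.age,
            {SITE: {"GG": "XX", "CG": "YY"}[r.genotypes[SITE]]},
        )
        for r in recs
    ]
    p2 = fit_association(relabeled, SITE).model.genotype_p
    assert p1 == pytest.approx(p2, rel=1e-9)


def test_small_class_dropped_then_untestable():
    recs = _records([1.0, 1.2, 1.1, 3.0], ["AA", "AA", "AA", "AB"], ["a"] * 4)
    assoc = fit_association(recs, SITE)
    assert assoc.untestable
    assert assoc.dropped_classes == ["AB"]
    assert assoc.model is None and not assoc.significant


def test_genotype_means_are_raw_class_means():
    recs = _records([1.0, 2.0, 4.0, 6.0], ["AA", "AA", "AB", "AB"], ["a", "b", "a", "b"])
    m = fit_association(recs, SITE).model
    assert m.genotype_means == {"AA": pytest.approx(1.5), "AB": pytest.approx(5.0)}


def test_parameter_recovery_within_three_se():
    hits = 0
    n_trials = 60
    for seed in range(n_trials):
        recs = simulate_phenotypes(
            n_animals=189, genotype_effects={"GG": 0.0, "CG": 2.0},
            noise_sd=0.5, seed=seed, genotype_freqs={"GG": 0.7, "CG": 0.3},
        )
        m = fit_association(recs, SITE).model
        est = m.genotype_effects["CG"] - m.genotype_effects["GG"]
        resid_sd = m.residuals.std(ddof=1)
        counts = {g: sum(1 for r in recs if r.genotypes[SITE] == g) for g in ("GG", "CG")}
        se = resid_sd * np.sqrt(1 / counts["GG"] + 1 / counts["CG"])
        if abs(est - 2.0) <= 3 * se:
            hits += 1
    assert hits / n_trials >= 0.95


def test_associate_all_sites_covers_every_typed_site():
    recs = simulate_phenotypes(n_animals=60, noise_sd=0.3, seed=10)
    out = associate_all_sites(recs)
    assert [a.site for a in out] == [SITE]


# ---------------------------------------------------------------------------
# phenotype binning
# ---------------------------------------------------------------------------

def test_bin_percentages_match_reported_distribution():
    values = [0.2] * 100 + [0.7] * 42 + [1.5] * 53
    df = summarize_bins(values, (0.0, 0.5, 1.0))
    assert list(df["count"]) == [100, 42, 53]
    assert list(df["percent"]) == [51.3, 21.5, 27.2]


def test_all_values_in_one_bin():
    df = summarize_bins([0.1, 0.2, 0.3], (0.0, 0.5, 1.0))
    assert list(df["percent"]) == [100.0, 0.0, 0.0]


def test_interior_edge_goes_to_right_bin():
    df = summarize_bins([0.5], (0.0, 0.5, 1.0))
    assert list(df["count"]) == [0, 1, 0]


def test_bin_input_validation():
    with pytest.raises(ValueError):
        summarize_bins([], (0.0, 1.0))
    with pytest.raises(ValueError):
        summarize_bins([1.0], (0.5, 0.5))
    with pytest.raises(ValueError):
        summarize_bins([-1.0], (0.0, 1.0))
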