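import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exrna_perf import (
    PRESET_PROFILES,
    ValidationError,
    detected_genes,
    log2_to_fold,
    make_replicates,
    replicate_ratios,
    single_positive_analysis,
    subsample_counts,
)

from conftest import build_count_matrix


def alc_step_integration_oracle(ratios: np.ndarray) -> float:
    """Independent oracle: area left of the empirical CDF of a non-negative
    sample, integrated exactly over the CDF's step structure.

    The area between the CDF curve and the vertical axis equals
    integral_0^max (1 - F(x)) dx for a non-negative variable; F is a step
    function so the integral is a finite sum over the sorted sample.
    """
    x = np.sort(np.asarray(ratios, dtype=float))
    n = len(x)
    area = x[0]  # F = 0 on [0, x_min)
    for i in range(n - 1):
        area += (1 - (i + 1) / n) * (x[i + 1] - x[i])
    return float(area)


# ---------------------------------------------------------------------------
# subsampling
# ---------------------------------------------------------------------------


def test_subsample_identity_at_full_depth(toy_cm):
    depth = int(toy_cm.library_sizes().min())
    sub = subsample_counts(toy_cm, depth, seed=0)
    assert (sub.counts["s2"] == toy_cm.counts["s2"]).all()


def test_subsample_single_feature_forced():
    cm = build_count_matrix({"s": [100]}, ["g1"])
    sub = subsample_counts(cm, 10, seed=0)
    assert int(sub.counts.at["g1", "s"]) == 10


def test_subsample_column_sums_exact_and_seeded():
    rng = np.random.default_rng(0)
    cm = build_count_matrix(
        {f"s{i}": rng.integers(0, 500, size=50).tolist() for i in range(4)},
        [f"g{i}" for i in range(50)],
    )
    sub1 = subsample_counts(cm, 1000, seed=7)
    sub2 = subsample_counts(cm, 1000, seed=7)
    assert (sub1.counts.sum(axis=0) == 1000).all()
    assert sub1.counts.equals(sub2.counts)
    assert not sub1.counts.equals(subsample_counts(cm, 1000, seed=8).counts)


def test_subsample_hypergeometric_expectation():
    """Two features (60, 40), depth 50: mean first-feature count is 30."""
    cm = build_count_matrix({"s": [60, 40]}, ["g1", "g2"])
    draws = [
        int(subsample_counts(cm, 50, seed=k).counts.at["g1", "s"])
        for k in range(10_000)
    ]
    assert np.mean(draws) == pytest.approx(30.0, abs=0.5)


def test_subsample_depth_exceeding_library_lists_offenders(toy_cm):
    with pytest.raises(ValidationError, match="s2"):
        subsample_counts(toy_cm, 10_000, seed=0)


# ---------------------------------------------------------------------------
# replicate ratios / ALC
# ---------------------------------------------------------------------------


def test_identical_replicates_have_zero_alc():
    cm = build_count_matrix({"a": [10, 20, 30], "b": [10, 20, 30]}, ["g1", "g2", "g3"])
    res = replicate_ratios(cm, "a", "b", cutoff=4)
    assert res.alc == 0.0
    assert res.median_ratio == 0.0
    assert res.pearson_r == pytest.approx(1.0)


def test_alc_equals_mean_on_constructed_ratios():
    """Counts built to give |log2 ratios| {0,1,2,3} -> ALC (mean) 1.5."""
    cm = build_count_matrix(
        {"a": [16, 16, 16, 16], "b": [16, 8, 4, 2]}, ["g1", "g2", "g3", "g4"]
    )
    res = replicate_ratios(cm, "a", "b", cutoff=1)
    assert sorted(res.ratios.tolist()) == [0.0, 1.0, 2.0, 3.0]
    assert res.alc == pytest.approx(1.5)
    assert res.alc == pytest.approx(alc_step_integration_oracle(res.ratios), abs=1e-12)


def test_no_retained_genes_is_an_error():
    cm = build_count_matrix({"a": [1, 2], "b": [0, 1]}, ["g1", "g2"])
    with pytest.raises(ValidationError, match="no genes"):
        replicate_ratios(cm, "a", "b", cutoff=4)


@given(
    st.lists(st.floats(0, 8, allow_nan=False), min_size=1, max_size=200),
)
@settings(deadline=None, max_examples=200)
def test_alc_mean_equivalence_property(ratios):
    """Area left of the step CDF equals the arithmetic mean to 1e-12."""
    arr = np.array(ratios)
    assert alc_step_integration_oracle(arr) == pytest.approx(
        float(arr.mean()), abs=1e-12
    )


@pytest.mark.parametrize(
    "x,expected,places",
    [(0.403, 1.32, 2), (0.0, 1.0, 6), (0.5, 1.41, 2)],
)
def test_log2_to_fold(x, expected, places):
    assert round(log2_to_fold(x), places) == expected


def test_log2_to_fold_rejects_non_finite():
    with pytest.raises(ValidationError):
        log2_to_fold(float("inf"))


# ---------------------------------------------------------------------------
# single/double positive cutoff analysis
# ---------------------------------------------------------------------------


ENUM_PAIRS = {"a": [0, 3, 1, 10, 0], "b": [5, 0, 0, 12, 2]}


def test_single_positive_enumeration():
    """Pairs {(0,5),(3,0),(1,0),(10,12),(0,2)}: 4 single positives; cutoff 4
    removes the values {3,1,2} -> 3/4; target 0.95 needs cutoff 6."""
    cm = build_count_matrix(ENUM_PAIRS, [f"g{i}" for i in range(5)])
    report = single_positive_analysis(cm, "a", "b", cutoffs=range(1, 11))
    assert report.n_single_positive == 4
    at4 = report.per_cutoff.set_index("cutoff")
    assert at4.loc[4, "removed_single_positive_fraction"] == pytest.approx(0.75)
    assert report.chosen_cutoff == 6


def test_no_single_positives_is_flagged_not_fatal():
    cm = build_count_matrix({"a": [5, 6], "b": [7, 8]}, ["g1", "g2"])
    report = single_positive_analysis(cm, "a", "b")
    assert report.flagged
    assert report.chosen_cutoff == 1
    assert report.n_single_positive == 0


def test_removed_fraction_monotone_and_saturating():
    rng = np.random.default_rng(3)
    a = rng.integers(0, 20, size=300).tolist()
    b = rng.integers(0, 20, size=300).tolist()
    cm = build_count_matrix({"a": a, "b": b}, [f"g{i}" for i in range(300)])
    report = single_positive_analysis(cm, "a", "b", cutoffs=range(1, 40))
    fracs = report.per_cutoff["removed_single_positive_fraction"].to_list()
    assert fracs == sorted(fracs)
    assert fracs[-1] == 1.0  # cutoff above max count removes everything


def test_detected_genes_boundary(toy_cm):
    cm = build_count_matrix({"s": [4, 3, 0]}, ["g1", "g2", "g3"])
    assert detected_genes(cm, "s", cutoff=4) == {"g1"}
    assert detected_genes(cm, "s", cutoff=1) == {"g1", "g2"}
    assert detected_genes(cm, "s", cutoff=100) == set()
    # spikes never count as detected genes
    assert detected_genes(toy_cm, "s1", cutoff=1) == {"g1", "g2"}


def test_library_prep_replicates_more_precise_than_isolation():
    """Lower planted prep-level dispersion must show as a lower ALC."""
    profile = PRESET_PROFILES["ePFP"]
    iso, _ = make_replicates(profile, seed=21, replicate_level="rna_isolation")
    prep, _ = make_replicates(profile, seed=21, replicate_level="library_prep")
    alc_iso = replicate_ratios(iso, *iso.samples[:2]).alc
    alc_prep = replicate_ratios(prep, *prep.samples[:2]).alc
    assert alc_prep < alc_iso
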