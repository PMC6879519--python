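import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exrna_perf import (
    SpikeDesign,
    TruenessModel,
    ValidationError,
    expected_log2fc,
    fit_trueness,
    fraction_within,
    make_spike_panels,
    make_titration,
    observed_log2fc,
)
from exrna_perf.simulate import SEQUIN_DILUTIONS, default_titration_design
from exrna_perf.titration import titration_pairs

from conftest import build_count_matrix

DESIGN = default_titration_design()


@pytest.mark.parametrize(
    "mix,a,b,expected",
    [
        ("Sequin", "T1", "T5", 2.0),  # 1/15000 vs 1/60000: the designed 4-fold range
        ("Sequin", "T3", "T3", 0.0),
        ("ERCC", "T2", "T2", 0.0),
        ("Sequin", "T2", "T3", math.log2(30000 / 21277)),  # ~0.4958
    ],
)
def test_expected_log2fc(mix, a, b, expected):
    assert expected_log2fc(DESIGN, mix, a, b) == pytest.approx(expected, abs=1e-12)


def test_expected_log2fc_unknown_sample():
    with pytest.raises(KeyError):
        expected_log2fc(DESIGN, "Sequin", "T1", "nope")
    with pytest.raises(KeyError):
        expected_log2fc(DESIGN, "weird-mix", "T1", "T2")


@given(
    a=st.sampled_from(DESIGN.samples),
    b=st.sampled_from(DESIGN.samples),
    mix=st.sampled_from(["ERCC", "Sequin"]),
)
@settings(deadline=None, max_examples=50)
def test_expected_log2fc_antisymmetric(a, b, mix):
    e_ab = expected_log2fc(DESIGN, mix, a, b)
    e_ba = expected_log2fc(DESIGN, mix, b, a)
    assert e_ab == pytest.approx(-e_ba, abs=1e-12)


def test_expected_log2fc_telescopes_along_titration():
    """Adjacent-step expected fold changes sum to the extreme-pair value."""
    for mix in DESIGN.mixes:
        chain = sum(
            expected_log2fc(DESIGN, mix, a, b)
            for a, b in zip(DESIGN.samples[:-1], DESIGN.samples[1:])
        )
        extreme = expected_log2fc(DESIGN, mix, DESIGN.samples[0], DESIGN.samples[-1])
        assert chain == pytest.approx(extreme, abs=1e-12)


def test_adjacent_sequin_steps_average_factor_1_41():
    """Geometric mean of adjacent dilution steps is 4**(1/4) ~ 1.414."""
    ratios = [
        SEQUIN_DILUTIONS[i] / SEQUIN_DILUTIONS[i + 1] for i in range(4)
    ]
    geo = float(np.prod(ratios)) ** (1 / 4)
    assert geo == pytest.approx(math.sqrt(2), rel=1e-12)
    assert round(geo, 2) == 1.41


def test_observed_log2fc_basic(toy_cm):
    obs = observed_log2fc(toy_cm, "ERCC", "s1", "s2")
    table = obs.set_index("spike_id")
    assert table.loc["ERCC_1", "observed_log2fc"] == pytest.approx(1.0)  # 900 vs 450
    assert table.loc["ERCC_2", "observed_log2fc"] == pytest.approx(1.0)
    assert not table["excluded_zero"].any()


def test_observed_log2fc_simple_ratio():
    cm = build_count_matrix(
        {"a": [100, 0], "b": [25, 25]},
        ["ERCC_1", "ERCC_2"],
        feature_class=["spike_ercc"] * 2,
    )
    obs = observed_log2fc(cm, "ERCC", "a", "b").set_index("spike_id")
    assert obs.loc["ERCC_1", "observed_log2fc"] == pytest.approx(2.0)
    # zero in one sample: excluded and reported, not silently dropped
    assert bool(obs.loc["ERCC_2", "excluded_zero"])
    assert math.isnan(obs.loc["ERCC_2", "observed_log2fc"])


def test_observed_log2fc_requires_spikes_of_mix(toy_cm):
    with pytest.raises(ValidationError, match="Sequin"):
        observed_log2fc(toy_cm, "Sequin", "s1", "s2")


def test_observed_low_count_flag(toy_cm):
    obs = observed_log2fc(toy_cm, "ERCC", "s1", "s2", min_count=100).set_index("spike_id")
    assert not obs.loc["ERCC_1", "low_count_flag"]  # mean 675
    assert bool(obs.loc["ERCC_2", "low_count_flag"])  # mean 75


@pytest.mark.parametrize(
    "points,slope,r2",
    [
        ([(0, 0), (1, 1), (2, 2)], 1.0, 1.0),
        ([(0, 0), (1, 2), (2, 4)], 2.0, 1.0),
    ],
)
def test_fit_trueness_exact_lines(points, slope, r2):
    df = pd.DataFrame(points, columns=["expected_log2fc", "observed_log2fc"])
    s, a = fit_trueness(df)
    assert s == pytest.approx(slope, abs=1e-12)
    assert a == pytest.approx(r2, abs=1e-12)


def test_fit_trueness_recovers_unit_slope_under_noise():
    rng = np.random.default_rng(42)
    e = rng.uniform(-2, 2, size=200)
    o = e + rng.normal(0, 0.3, size=200)
    df = pd.DataFrame({"expected_log2fc": e, "observed_log2fc": o})
    slope, adj_r2 = fit_trueness(df)
    assert 0.9 <= slope <= 1.1
    assert 0 < adj_r2 < 1


def test_fit_trueness_contract_errors():
    two = pd.DataFrame({"expected_log2fc": [0, 1], "observed_log2fc": [0, 1]})
    with pytest.raises(ValidationError, match="at least 3"):
        fit_trueness(two)
    const = pd.DataFrame({"expected_log2fc": [1, 1, 1], "observed_log2fc": [0, 1, 2]})
    with pytest.raises(ValidationError, match="constant"):
        fit_trueness(const)


def _dev_table(expected, observed):
    return pd.DataFrame({"expected_log2fc": expected, "observed_log2fc": observed})


@pytest.mark.parametrize(
    "deviations,tau,expected",
    [
        ([0.1, 0.4, 0.6], 0.5, 2 / 3),
        ([0.0, 0.0, 0.0], 0.1, 1.0),
        ([1.0], 0.5, 0.0),
    ],
)
def test_fraction_within_enumeration(deviations, tau, expected):
    table = _dev_table([0.0] * len(deviations), deviations)
    out = fraction_within(table, [tau])
    assert out["fraction_within"].iloc[0] == pytest.approx(expected)


def test_fraction_within_empty_raises():
    with pytest.raises(ValidationError):
        fraction_within(_dev_table([], []), [0.5])


@given(st.lists(st.floats(0, 3), min_size=1, max_size=30))
@settings(deadline=None, max_examples=50)
def test_fraction_within_monotone_in_threshold(devs):
    table = _dev_table([0.0] * len(devs), devs)
    out = fraction_within(table, [0.25, 0.5, 1.0, 2.0])
    fracs = out["fraction_within"].to_list()
    assert fracs == sorted(fracs)


def test_noise_free_titration_matches_design_exactly():
    """Without count noise every observed fold change equals the designed one
    (up to integer rounding of very large expected counts)."""
    panels = make_spike_panels(dynamic_range_log2=3.0)
    cm, truth = make_titration(
        DESIGN, panels, library_size=20_000_000_000, noise="none", seed=1
    )
    res = TruenessModel(cm, DESIGN).fit()
    assert res.per_spike["deviation"].abs().max() < 1e-6
    assert res.fits["slope"].to_numpy() == pytest.approx([1.0, 1.0], abs=1e-6)
    assert res.fits["adjusted_r2"].to_numpy() == pytest.approx([1.0, 1.0], abs=1e-6)


def test_titration_pairs_modes():
    assert titration_pairs(DESIGN, "extreme") == [("T1", "T5")]
    assert len(titration_pairs(DESIGN, "adjacent")) == 4
    ref_pairs = titration_pairs(DESIGN, "reference")
    assert all(b == "T3" for _, b in ref_pairs) and len(ref_pairs) == 4
    with pytest.raises(ValueError):
        titration_pairs(DESIGN, "bogus")


def test_trueness_model_with_subsampling_is_seeded(tmp_path):
    cm, _ = make_titration(library_size=200_000, noise="poisson", seed=5)
    model = TruenessModel(cm, DESIGN)
    r1 = model.fit(depth=150_000, seed=9)
    r2 = model.fit(depth=150_000, seed=9)
    pd.testing.assert_frame_equal(r1.per_spike, r2.per_spike)


def test_design_validation():
    with pytest.raises(ValidationError, match="missing dilution"):
        SpikeDesign(samples=("a", "b"), dilution={("ERCC", "a"): 0.1})
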