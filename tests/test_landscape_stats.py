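"""Gini, relative-rate bins, periphery bias, telomere profiles and
pattern classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mareyscape.landscape_stats import (
    chromosome_summary,
    classify_pattern,
    gini_index,
    periphery_bias_ratio,
    periphery_bias_sensitivity,
    relative_rate_bins,
    telomere_distance_correlation,
    telomere_profile,
    BinProfile,
)
from mareyscape.marey_fit import fit_marey, recombination_rates
from mareyscape.synthetic_data import ChromosomeSpec, generate_chromosome, marey_truth, true_landscape

from conftest import make_landscape, make_map


# ---------------------------------------------------------------------------
# Gini


def test_gini_uniform_is_zero():
    assert gini_index(make_landscape(np.full(100, 2.0))) == pytest.approx(0.0, abs=1e-12)


@pytest.mark.parametrize("n", [5, 50, 500])
def test_gini_point_mass_closed_form(n):
    rates = np.zeros(n)
    rates[n // 2] = 7.0
    assert gini_index(make_landscape(rates)) == pytest.approx((n - 1) / n)


def test_gini_two_windows_lorenz():
    assert gini_index(make_landscape([1.0, 3.0])) == pytest.approx(0.25)


def test_gini_all_zero_rejected():
    with pytest.raises(ValueError):
        gini_index(make_landscape(np.zeros(10)))


@given(st.floats(0.1, 100.0))
@settings(max_examples=20, deadline=None)
def test_gini_scale_invariant(scale):
    rng = np.random.default_rng(0)
    rates = rng.gamma(2.0, 1.0, 50)
    g1 = gini_index(make_landscape(rates))
    g2 = gini_index(make_landscape(rates * scale))
    assert g1 == pytest.approx(g2, rel=1e-9)


def test_gini_increases_under_mean_preserving_spread():
    base = np.full(10, 2.0)
    spread = base.copy()
    spread[0] += 1.0
    spread[-1] -= 1.0
    assert gini_index(make_landscape(spread)) > gini_index(make_landscape(base + 1e-9))


# ---------------------------------------------------------------------------
# relative-rate bins


def test_relative_rate_bins_uniform_zero(linear_fit):
    prof = relative_rate_bins(linear_fit, k=10)
    assert np.allclose(prof.values, 0.0, atol=1e-9)


def test_relative_rate_bins_point_segment():
    # nearly all genetic length in one segment: that bin -> log10(k)
    bp = np.linspace(0, 1e7, 400)
    cm = np.clip((bp - 4e6) / 1e6, 0, 1) * 100  # all recombination in [4,5] Mb
    m = make_map(bp, cm, 1e7)
    fit = fit_marey(m, span=0.03)
    prof = relative_rate_bins(fit, k=10)
    assert prof.values[4] == pytest.approx(1.0, abs=0.02)  # log10(10)


def test_relative_rate_bins_double_share():
    vals = np.log10(2.0)
    # 2 segments; first holds 2/3, second 1/3 of a 60 cM map over 10 Mb
    bp = np.linspace(0, 1e7, 600)
    cm = np.where(bp <= 5e6, bp / 5e6 * 40, 40 + (bp - 5e6) / 5e6 * 20)
    m = make_map(bp, cm, 1e7)
    fit = fit_marey(m, span=0.05)
    prof = relative_rate_bins(fit, k=2)
    assert prof.values[0] == pytest.approx(np.log10(40 / 30), abs=0.01)
    assert prof.values[1] == pytest.approx(np.log10(20 / 30), abs=0.01)
    assert vals == pytest.approx(np.log10(2.0))


# ---------------------------------------------------------------------------
# periphery bias


def test_periphery_bias_uniform_is_one():
    assert periphery_bias_ratio(make_landscape(np.ones(100))) == pytest.approx(1.0)


def test_periphery_bias_all_in_tips():
    rates = np.zeros(100)
    rates[:10] = 5.0
    rates[-10:] = 5.0
    assert periphery_bias_ratio(make_landscape(rates)) == pytest.approx(5.0)


def test_periphery_bias_central_only():
    rates = np.zeros(100)
    rates[10:90] = 3.0
    assert periphery_bias_ratio(make_landscape(rates)) == pytest.approx(0.0)


def test_periphery_bias_sensitivity_limits():
    rates = np.exp(-np.minimum(np.arange(100), 99 - np.arange(100)) / 10.0)
    land = make_landscape(rates)
    table = periphery_bias_sensitivity(land, [0.1, 0.2, 0.5, 1.0])
    vals = table["periphery_bias"].to_numpy()
    assert np.all(np.diff(vals) <= 1e-12)  # non-increasing with tip size
    assert vals[-1] == pytest.approx(1.0)
    uniform = periphery_bias_sensitivity(make_landscape(np.ones(50)), [0.1, 0.3, 1.0])
    assert np.allclose(uniform["periphery_bias"], 1.0)


def test_periphery_bias_random_tip_seeded():
    rates = np.concatenate([np.full(50, 4.0), np.full(50, 1.0)])
    land = make_landscape(rates)
    r1 = periphery_bias_ratio(land, mode="random_tip", rng=np.random.default_rng(3))
    r2 = periphery_bias_ratio(land, mode="random_tip", rng=np.random.default_rng(3))
    assert r1 == r2


# ---------------------------------------------------------------------------
# telomere profiles and classification


def test_telomere_profile_uniform_standardized_near_zero():
    rng = np.random.default_rng(0)
    lands = [make_landscape(1.0 + 0.01 * rng.standard_normal(500)) for _ in range(3)]
    prof = telomere_profile(lands, rng=np.random.default_rng(0))
    # no positional structure: standardized bin means hover around zero
    assert np.nanmax(np.abs(prof.values)) < 0.4
    assert abs(np.nanmean(prof.values)) < 0.1


def test_telomere_profile_distal_decreasing():
    spec = ChromosomeSpec(pattern="distal", centromere_dip=(0.0, 0.03))
    truth = marey_truth(spec)
    land = true_landscape(truth, 1e5)
    prof = telomere_profile([land], rng=np.random.default_rng(1))
    v = prof.values[~np.isnan(prof.values)]
    assert v[0] == np.nanmax(prof.values)
    assert v[0] > v[-1]


def test_telomere_profile_seeded_side_choice():
    rates = np.concatenate([np.full(100, 5.0), np.full(100, 1.0)])
    land = make_landscape(rates)
    p1 = telomere_profile([land], rng=np.random.default_rng(7))
    p2 = telomere_profile([land], rng=np.random.default_rng(7))
    assert np.allclose(p1.values, p2.values, equal_nan=True)


def test_classify_distal_peak_bin_one():
    v = np.linspace(2.0, -1.0, 20)
    call = classify_pattern(BinProfile(k=20, values=v))
    assert call.label == "distal" and call.peak_bin == 1


def test_classify_subdistal_peak():
    v = np.full(20, -0.5)
    v[5] = 2.0  # peak at relative distance ~0.1375
    v[0] = -1.0
    call = classify_pattern(BinProfile(k=20, values=v))
    assert call.label == "sub-distal"


def test_classify_central_peak_exception():
    v = np.full(20, -0.5)
    v[17] = 2.0  # near the chromosome centre
    call = classify_pattern(BinProfile(k=20, values=v))
    assert call.label == "exception"


def test_classification_recovers_generator_patterns():
    expected = {"distal": "distal", "sub-distal": "sub-distal", "central-peak": "exception"}
    for pattern, want in expected.items():
        ok = 0
        for i in range(10):
            spec = ChromosomeSpec(
                species=f"s{i}", pattern=pattern, centromere_c=0.45,
                centromere_dip=(0.6, 0.03), n_markers=500, marker_noise_sd=1.0,
            )
            m, _, _ = generate_chromosome(spec, seed=200 + i)
            land = recombination_rates(fit_marey(m, span=0.2, max_grid=1024), 1e5)
            prof = telomere_profile([land], rng=np.random.default_rng(i))
            ok += classify_pattern(prof).label == want
        assert ok >= 9


# ---------------------------------------------------------------------------
# distance correlation and summaries


def test_telomere_distance_correlation_signs():
    spec_d = ChromosomeSpec(pattern="distal", centromere_dip=(0.0, 0.03))
    land_d = true_landscape(marey_truth(spec_d), 1e5)
    rho_d, _ = telomere_distance_correlation(land_d)
    assert rho_d < -0.5
    spec_c = ChromosomeSpec(pattern="central-peak", centromere_dip=(0.0, 0.03))
    land_c = true_landscape(marey_truth(spec_c), 1e5)
    rho_c, _ = telomere_distance_correlation(land_c)
    assert rho_c > 0.5
    rho_u, _ = telomere_distance_correlation(make_landscape(np.ones(50)))
    assert np.isnan(rho_u)


def test_chromosome_summary_arithmetic():
    m = make_map(np.linspace(0, 5e7, 100), np.linspace(0, 120, 100), 5e7)
    land = make_landscape(np.full(500, 2.4))
    rec = chromosome_summary(m, land, species_mean_length=4e7)
    assert rec["excess_co_cm"] == pytest.approx(70.0)
    assert rec["co_number_proxy"] == pytest.approx(2.4)
    assert rec["relative_size"] == pytest.approx(1.25)
    m50 = make_map(np.linspace(0, 5e7, 100), np.linspace(0, 50, 100), 5e7)
    rec50 = chromosome_summary(m50, land)
    assert rec50["excess_co_cm"] == pytest.approx(0.0)
    assert rec50["co_number_proxy"] == pytest.approx(1.0)
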