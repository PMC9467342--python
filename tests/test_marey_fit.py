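"""Loess Marey fitting, span calibration, window rates and bootstrap CIs."""

import numpy as np
import pytest

from mareyscape.loess import loess_predict
from mareyscape.marey_fit import (
    bootstrap_landscape,
    calibrate_span,
    derive_seed,
    fit_marey,
    pseudo_markers,
    recombination_rates,
)
from mareyscape.synthetic_data import ChromosomeSpec, generate_chromosome, true_landscape

from conftest import make_map


# ---------------------------------------------------------------------------
# loess core


def test_loess_reproduces_quadratic_exactly():
    rng = np.random.default_rng(1)
    x = np.sort(rng.uniform(0, 10, 200))
    y = 1.0 + 2.0 * x + 0.3 * x**2
    xe = np.linspace(0.5, 9.5, 50)
    pred = loess_predict(x, y, xe, span=0.4, degree=2)
    assert np.allclose(pred, 1.0 + 2.0 * xe + 0.3 * xe**2, rtol=1e-8)


def test_loess_agrees_with_statsmodels_on_linear_data():
    """Independent cross-check: on noisy linear data the local-quadratic
    smooth and statsmodels' local-linear lowess agree closely away from
    the boundaries."""
    statsmodels = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(2)
    x = np.sort(rng.uniform(0, 100, 400))
    y = 2.0 * x + rng.normal(0, 3, 400)
    ours = loess_predict(x, y, x, span=0.5, degree=1)
    theirs = statsmodels.nonparametric.lowess(y, x, frac=0.5, return_sorted=False)
    inner = slice(50, -50)
    assert np.max(np.abs(ours[inner] - theirs[inner])) < 1.0


# ---------------------------------------------------------------------------
# span calibration


def test_calibrate_noiseless_linear_ties_to_largest_span(linear_map):
    span, table = calibrate_span(linear_map, n_iter=5, seed=0)
    assert span == 0.5
    assert np.all(table["cv_mse"] < 1e-10)


def test_calibrate_deterministic_under_seed():
    spec = ChromosomeSpec(n_markers=120, marker_noise_sd=1.0)
    m, _, _ = generate_chromosome(spec, seed=3)
    s1, t1 = calibrate_span(m, n_iter=5, seed=42)
    s2, t2 = calibrate_span(m, n_iter=5, seed=42)
    assert s1 == s2
    assert np.allclose(t1["cv_mse"], t2["cv_mse"])


def test_calibrate_prefers_small_span_for_sharp_feature():
    """A sharp sub-distal peak with noise needs a small neighbourhood: the
    chosen span should sit at or below the grid median across seeds."""
    spec = ChromosomeSpec(
        pattern="sub-distal", n_markers=400, marker_noise_sd=0.5, centromere_dip=(0.8, 0.02)
    )
    m, _, _ = generate_chromosome(spec, seed=9)
    grid = (0.2, 0.3, 0.4, 0.5)
    chosen = [calibrate_span(m, span_grid=grid, n_iter=20, seed=s)[0] for s in range(3)]
    assert all(s <= 0.3 for s in chosen)


# ---------------------------------------------------------------------------
# fitting


def test_fit_linear_map_exact(linear_map, linear_fit):
    pred = linear_fit.predict(linear_map.genomic_pos)
    assert np.allclose(pred, linear_map.genetic_pos, atol=1e-6)


def test_fit_quadratic_monotone_map_exact():
    bp = np.linspace(0, 50e6, 150)
    cm = 100 * (bp / 50e6) ** 2  # monotone quadratic
    m = make_map(bp, cm, 50e6)
    fit = fit_marey(m, span=0.4)
    assert np.allclose(fit.predict(bp), cm, atol=1e-5)


def test_fit_requires_three_markers():
    m = make_map([0, 1e6], [0, 10], 1e6)
    with pytest.raises(ValueError):
        fit_marey(m)


def test_fitted_function_monotone_despite_interior_dip():
    rng = np.random.default_rng(4)
    bp = np.sort(rng.uniform(0, 2e7, 200))
    cm = bp / 2e5
    dip = (bp > 8e6) & (bp < 1.2e7)
    cm = cm - 20 * dip  # non-monotone cloud
    cm -= cm.min()
    m = make_map(bp, cm, 2e7)
    fit = fit_marey(m, span=0.2, grid_step=1000.0)
    assert np.all(np.diff(fit.grid_cm) >= 0)
    dense = np.linspace(0, 2e7, 5000)
    assert np.all(np.diff(fit.predict(dense)) >= -1e-12)


# ---------------------------------------------------------------------------
# window rates


def test_linear_map_rate_is_two_everywhere(linear_fit):
    land = recombination_rates(linear_fit, 1e5)
    assert np.allclose(land.rate, 2.0, atol=1e-6)
    assert land.n_windows == 500


def test_plateau_has_zero_rate():
    bp = np.concatenate([np.linspace(0, 2e7, 80), np.linspace(3e7, 5e7, 80)])
    cm = np.concatenate([np.linspace(0, 50, 80), np.linspace(50, 50, 80)])
    m = make_map(bp, cm, 5e7)
    fit = fit_marey(m, span=0.2)
    land = recombination_rates(fit, 1e6)
    assert np.all(land.rate[40:] < 0.05)


def test_rate_conservation_and_genome_wide_consistency(linear_fit):
    land = recombination_rates(linear_fit, 1e5)
    total_cm = np.sum(land.rate * land.lengths / 1e6)
    assert total_cm == pytest.approx(linear_fit.map_length_fitted, rel=1e-9)
    genome_wide = linear_fit.map_length_fitted / (linear_fit.map.chromosome_length / 1e6)
    assert land.mean_rate() == pytest.approx(genome_wide, rel=1e-9)


def test_partial_terminal_window():
    m = make_map(np.linspace(0, 5.25e6, 60), np.linspace(0, 21, 60), 5.25e6)
    fit = fit_marey(m, span=0.5)
    land = recombination_rates(fit, 1e6)
    assert land.n_windows == 6
    assert land.ends[-1] == pytest.approx(5.25e6)
    assert land.lengths[-1] == pytest.approx(0.25e6)


def test_rejects_nonpositive_window(linear_fit):
    with pytest.raises(ValueError):
        recombination_rates(linear_fit, 0)


def test_scale_consistency_100kb_vs_1mb():
    """Rates estimated at 100 kb, averaged into 1 Mb blocks, match direct
    1 Mb estimates (the cross-scale quality check)."""
    from scipy.stats import spearmanr

    spec = ChromosomeSpec(length_bp=50e6, n_markers=600, marker_noise_sd=0.5)
    m, _, _ = generate_chromosome(spec, seed=21)
    fit = fit_marey(m, span=0.25)
    fine = recombination_rates(fit, 1e5)
    coarse = recombination_rates(fit, 1e6)
    agg = fine.rate.reshape(-1, 10).mean(axis=1)
    rho = spearmanr(agg, coarse.rate).statistic
    assert rho >= 0.99


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_deterministic_under_seed():
    spec = ChromosomeSpec(n_markers=150, marker_noise_sd=1.0)
    m, _, _ = generate_chromosome(spec, seed=6)
    l1 = bootstrap_landscape(m, span=0.3, window_size=1e6, n_boot=25, seed=5)
    l2 = bootstrap_landscape(m, span=0.3, window_size=1e6, n_boot=25, seed=5)
    assert np.allclose(l1.ci_low, l2.ci_low)
    assert np.allclose(l1.ci_high, l2.ci_high)


def test_bootstrap_narrow_ci_on_noiseless_dense_map(linear_map):
    land = bootstrap_landscape(linear_map, span=0.3, window_size=1e6, n_boot=50, seed=1)
    width = land.ci_high - land.ci_low
    assert np.median(width[5:-5]) < 0.2  # cM/Mb, rates are 2.0


def test_bootstrap_ci_covers_generator_truth():
    spec = ChromosomeSpec(
        pattern="distal", centromere_dip=(0.0, 0.03), n_markers=500, marker_noise_sd=1.0
    )
    m, _, truth = generate_chromosome(spec, seed=2)
    land = bootstrap_landscape(m, span=0.2, window_size=1e6, n_boot=200, seed=3)
    tl = true_landscape(truth, 1e6)
    inside = (tl.rate >= land.ci_low) & (tl.rate <= land.ci_high)
    assert inside.mean() >= 0.9


# ---------------------------------------------------------------------------
# pseudo-markers


def test_pseudo_markers_linear(linear_fit):
    bp, cm = pseudo_markers(linear_fit, 3)
    assert np.allclose(cm, [0, 50, 100], atol=1e-6)
    assert bp[0] == 0 and bp[-1] == linear_fit.map.chromosome_length


def test_pseudo_markers_match_generator_truth():
    spec = ChromosomeSpec(n_markers=500, marker_noise_sd=0.5)
    m, _, truth = generate_chromosome(spec, seed=8)
    fit = fit_marey(m, span=0.2)
    bp, cm = pseudo_markers(fit, 1000)
    err = np.abs(cm - truth.cm_at(bp))
    assert err.max() <= 0.02 * truth.d1
    assert np.all(np.diff(cm) >= 0)


def test_pseudo_markers_rejects_small_n(linear_fit):
    with pytest.raises(ValueError):
        pseudo_markers(linear_fit, 1)


def test_derived_seeds_stable_and_distinct():
    s1 = derive_seed(7, "A", "1")
    assert s1 == derive_seed(7, "A", "1")
    assert s1 != derive_seed(7, "A", "2")
    assert 0 <= s1 < 2**31
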