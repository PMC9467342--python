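"""The synthetic Marey-map generator and its truth bookkeeping."""

import json

import numpy as np
import pytest
from scipy import stats

from mareyscape.marey_fit import fit_marey, recombination_rates
from mareyscape.synthetic_data import (
    ChromosomeSpec,
    co_density,
    generate_chromosome,
    generate_dataset,
    marey_truth,
    sample_genes,
    sample_markers,
    true_landscape,
)


# ---------------------------------------------------------------------------
# densities


def test_uniform_density_flat():
    x, f = co_density(ChromosomeSpec(pattern="uniform", centromere_dip=(0.0, 0.03)))
    assert np.allclose(f, 1.0)


def test_distal_density_peaks_at_tips():
    spec = ChromosomeSpec(pattern="distal", centromere_dip=(0.0, 0.03))
    x, f = co_density(spec)
    assert np.interp(0.02, x, f) > 2 * np.interp(0.5, x, f)


def test_subdistal_density_peak_location_and_tip_depression():
    spec = ChromosomeSpec(pattern="sub-distal", centromere_dip=(0.0, 0.03))
    x, f = co_density(spec)
    half = x <= 0.5
    peak_x = x[half][np.argmax(f[half])]
    assert 0.1 < peak_x < 0.2
    assert f[0] < f.max() / 2


def test_centromere_dip_suppresses_density():
    spec = ChromosomeSpec(pattern="uniform", centromere_c=0.4, centromere_dip=(0.9, 0.03))
    x, f = co_density(spec)
    at_c = np.interp(0.4, x, f)
    away = np.interp(0.1, x, f)
    assert at_c < 0.2 * away


def test_density_integrates_to_one():
    for pattern in ("uniform", "distal", "sub-distal", "central-peak"):
        x, f = co_density(ChromosomeSpec(pattern=pattern))
        assert np.trapezoid(f, x) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# truth construction


def test_truth_monotone_and_total_length():
    for mode in ("per_chromosome", "per_arm"):
        spec = ChromosomeSpec(obligate_mode=mode, excess_coefficient=80.0)
        truth = marey_truth(spec)
        assert np.all(np.diff(truth.cm_grid) >= 0)
        assert truth.cm_grid[-1] == pytest.approx(truth.d1)
        assert truth.cm_grid[0] == 0.0


def test_m3_identity_exact():
    spec = ChromosomeSpec(obligate_mode="per_chromosome", centromere_c=0.3,
                          excess_coefficient=0.0)
    truth = marey_truth(spec)
    assert truth.d_c / truth.d1 == pytest.approx(0.3)
    spec2 = ChromosomeSpec(obligate_mode="per_chromosome", centromere_c=0.3,
                           excess_coefficient=120.0)
    truth2 = marey_truth(spec2)
    assert truth2.d_c / truth2.d1 == pytest.approx(0.3)


def test_m2_identity_exact():
    spec = ChromosomeSpec(obligate_mode="per_arm", centromere_c=0.3,
                          excess_coefficient=100.0)
    truth = marey_truth(spec)
    assert (truth.d_c - 50.0) / (truth.d1 - 100.0) == pytest.approx(0.3)


def test_uniform_m3_linear_map():
    spec = ChromosomeSpec(pattern="uniform", obligate_mode="per_chromosome",
                          centromere_c=0.5, centromere_dip=(0.0, 0.03),
                          excess_coefficient=50.0)
    truth = marey_truth(spec)
    assert truth.d1 == pytest.approx(100.0)
    assert np.allclose(truth.cm_grid, truth.x_grid * 100.0, atol=1e-9)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        ChromosomeSpec(pattern="banana")
    with pytest.raises(ValueError):
        ChromosomeSpec(excess_coefficient=-1.0)
    with pytest.raises(ValueError):
        ChromosomeSpec(centromere_c=1.5)
    with pytest.raises(ValueError):
        ChromosomeSpec(n_markers=1)


# ---------------------------------------------------------------------------
# marker sampling


def test_zero_noise_markers_on_truth():
    spec = ChromosomeSpec(marker_noise_sd=0.0, outlier_frac=0.0, n_markers=100)
    truth = marey_truth(spec)
    m = sample_markers(spec, truth, np.random.default_rng(0))
    assert np.allclose(m.genetic_pos, truth.cm_at(m.genomic_pos))


def test_outlier_bookkeeping():
    spec = ChromosomeSpec(outlier_frac=0.03, n_markers=100)
    truth = marey_truth(spec)
    m = sample_markers(spec, truth, np.random.default_rng(1))
    assert len(truth.outlier_ids) == 3
    displaced = np.isin(m.marker_ids, truth.outlier_ids)
    resid = np.abs(m.genetic_pos - truth.cm_at(m.genomic_pos))
    assert resid[displaced].min() > 0.15 * truth.d1


def test_marker_sampling_deterministic():
    spec = ChromosomeSpec(n_markers=50)
    t1, t2 = marey_truth(spec), marey_truth(spec)
    m1 = sample_markers(spec, t1, np.random.default_rng(9))
    m2 = sample_markers(spec, t2, np.random.default_rng(9))
    assert np.array_equal(m1.genomic_pos, m2.genomic_pos)
    assert np.array_equal(m1.genetic_pos, m2.genetic_pos)


# ---------------------------------------------------------------------------
# gene sampling


def test_uniform_genes_pass_ks():
    spec = ChromosomeSpec(gene_coupling=0.0, gene_total=5000)
    truth = marey_truth(spec)
    nonsig = 0
    for s in range(10):
        genes = sample_genes(spec, truth, np.random.default_rng(s))
        p = stats.kstest(genes.gene_starts / spec.length_bp, "uniform").pvalue
        nonsig += p > 0.01
    assert nonsig >= 9


def test_coupled_genes_concentrate_at_tips():
    spec = ChromosomeSpec(pattern="distal", gene_coupling=1.0, gene_total=5000,
                          centromere_dip=(0.0, 0.03))
    truth = marey_truth(spec)
    genes = sample_genes(spec, truth, np.random.default_rng(2))
    rel = genes.gene_starts / spec.length_bp
    tips = np.mean((rel < 0.1) | (rel > 0.9))
    center = np.mean((rel > 0.4) & (rel < 0.6))
    assert tips > 2 * center


def test_anticoupled_genes_negative_window_correlation():
    spec = ChromosomeSpec(pattern="distal", gene_coupling=-1.0, gene_total=5000,
                          centromere_dip=(0.0, 0.03))
    truth = marey_truth(spec)
    genes = sample_genes(spec, truth, np.random.default_rng(3))
    land = true_landscape(truth, 1e6)
    counts, _ = np.histogram(genes.gene_starts, bins=np.append(land.starts, land.ends[-1]))
    rho = stats.spearmanr(counts, land.rate).statistic
    assert rho < -0.5


# ---------------------------------------------------------------------------
# dataset generation


def test_generate_dataset_files_and_determinism(tmp_path):
    specs = [
        ChromosomeSpec(species=f"sp{s}", chromosome=f"chr{c}", n_markers=50,
                       gene_total=100, length_bp=5e6)
        for s in range(3)
        for c in range(5)
    ]
    out1, out2 = tmp_path / "a", tmp_path / "b"
    objs = generate_dataset(specs, out1, seed=5)
    generate_dataset(specs, out2, seed=5)
    assert len(objs) == 15
    for name in ("markers.tsv", "centromeres.tsv", "truth.json"):
        assert (out1 / name).read_bytes() == (out2 / name).read_bytes()
    truth = json.loads((out1 / "truth.json").read_text())
    assert len(truth) == 15
    assert all(v["model_id"] == "M3" for v in truth.values())
    assert (out1 / "genes_sp0.gff3").exists()


def test_generate_dataset_roundtrip_through_readers(tmp_path):
    from mareyscape.io_maps import read_gff_genes, read_marey_table

    specs = [ChromosomeSpec(species="sp", chromosome="chr1", n_markers=80,
                            gene_total=200, length_bp=5e6)]
    objs = generate_dataset(specs, tmp_path, seed=3)
    maps = read_marey_table(
        tmp_path / "markers.tsv",
        chromosome_lengths={("sp", "chr1"): 5e6},
    )
    assert len(maps) == 1
    assert maps[0].n_markers == 80
    orig = objs[("sp", "chr1")]["map"]
    assert np.allclose(
        np.sort(maps[0].genetic_pos), np.sort(orig.genetic_pos), atol=1e-6
    )
    tracks = read_gff_genes(tmp_path / "genes_sp.gff3", species="sp")
    # non-overlapping synthetic genes survive the overlap-collapsing reader
    assert tracks[0].total_genes == 200


def test_duplicate_keys_rejected(tmp_path):
    specs = [ChromosomeSpec(), ChromosomeSpec()]
    with pytest.raises(ValueError):
        generate_dataset(specs, tmp_path, seed=0)


# ---------------------------------------------------------------------------
# end-to-end recovery


def test_pipeline_recovers_true_window_rates():
    """Zero-noise fixture: fitted 100 kb rates match the generator's true
    rates within 2% (relative) away from the chromosome ends."""
    spec = ChromosomeSpec(pattern="distal", marker_noise_sd=0.0, n_markers=1000,
                          centromere_dip=(0.5, 0.05))
    m, _, truth = generate_chromosome(spec, seed=42)
    fit = fit_marey(m, span=0.05)
    land = recombination_rates(fit, 1e5)
    tl = true_landscape(truth, 1e5)
    interior = slice(25, -25)
    rel = np.abs(land.rate[interior] - tl.rate[interior]) / tl.rate[interior].mean()
    assert np.quantile(rel, 0.95) < 0.02
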