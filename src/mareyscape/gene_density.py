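"""Gene density along chromosomes and its association with recombination.

Genes are counted by start position in the same fixed windows as the
recombination landscape (100 kb by default).  Association is summarised
by per-chromosome Spearman correlations (bootstrap CI of the mean over
chromosomes), a standardized rate-versus-gene-count curve with a
quadratic fit (counts pruned above 20, where window counts get sparse
and noisy), and telomere-distance gene-density profiles classified with
the same distal / sub-distal / exception heuristic as crossovers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_maps import GeneTrack
from .landscape_stats import (
    BinProfile,
    PatternCall,
    classify_pattern,
    telomere_binned_values,
)
from .marey_fit import Landscape

__all__ = [
    "GeneWindowTrack",
    "gene_counts",
    "rate_count_correlation",
    "standardized_rate_by_count",
    "gene_profile_and_classify",
    "pattern_concordance",
]


@dataclass
class GeneWindowTrack:
    """Gene counts in fixed windows tiling one chromosome."""

    species: str
    chromosome: str
    chromosome_length: float
    starts: np.ndarray
    ends: np.ndarray
    counts: np.ndarray

    @property
    def n_windows(self) -> int:
        return int(self.starts.shape[0])


def gene_counts(
    track: GeneTrack,
    window_size: float = 1e5,
    chromosome_length: float | None = None,
) -> GeneWindowTrack:
    """Count gene starts in fixed half-open windows.

    Totals are conserved: the window counts sum to the track's gene count.
    """
    L = chromosome_length if chromosome_length is not None else track.chromosome_length
    if L is None:
        raise ValueError("chromosome length required")
    if track.total_genes and track.gene_starts.max() > L:
        raise ValueError("gene start beyond chromosome length")
    edges = np.arange(0.0, L, window_size)
    edges = np.append(edges, L)
    counts, _ = np.histogram(track.gene_starts, bins=edges)
    # np.histogram closes the last bin; genes exactly at L would be kept,
    # which matches the half-open tiling ending at the chromosome end
    return GeneWindowTrack(
        species=track.species,
        chromosome=track.chromosome,
        chromosome_length=float(L),
        starts=edges[:-1],
        ends=edges[1:],
        counts=counts,
    )


def rate_count_correlation(
    pairs: Sequence[tuple[Landscape, GeneWindowTrack]],
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Per-chromosome Spearman rho between window rates and gene counts,
    with a bootstrap CI (over chromosomes) of the mean rho and the share
    of chromosomes with a significant positive correlation."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    rows = []
    for land, gwt in pairs:
        if land.n_windows != gwt.n_windows:
            raise ValueError(
                f"window tilings differ for {(land.species, land.chromosome)}"
            )
        if np.ptp(land.rate) == 0 or np.ptp(gwt.counts) == 0:
            rows.append(
                {
                    "species": land.species,
                    "chromosome": land.chromosome,
                    "rho": np.nan,
                    "p": np.nan,
                    "excluded": True,
                }
            )
            continue
        res = stats.spearmanr(land.rate, gwt.counts)
        rows.append(
            {
                "species": land.species,
                "chromosome": land.chromosome,
                "rho": float(res.statistic),
                "p": float(res.pvalue),
                "excluded": False,
            }
        )
    per_chrom = pd.DataFrame(rows)
    rhos = per_chrom.loc[~per_chrom["excluded"], "rho"].to_numpy()
    out = {"per_chromosome": per_chrom, "mean_rho": np.nan, "ci": (np.nan, np.nan),
           "share_significant_positive": np.nan}
    if rhos.size:
        out["mean_rho"] = float(np.mean(rhos))
        if rhos.size > 1:
            boots = np.array(
                [np.mean(rng.choice(rhos, size=rhos.size)) for _ in range(n_boot)]
            )
            out["ci"] = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
        sig = (per_chrom["p"] < alpha) & (per_chrom["rho"] > 0)
        out["share_significant_positive"] = float(sig.mean())
    return out


def standardized_rate_by_count(
    species_pairs: dict[str, Sequence[tuple[Landscape, GeneWindowTrack]]],
    max_count: int = 20,
    n_boot: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Standardized recombination rate as a function of window gene count.

    Rates are z-scored within species (chromosomes pooled); windows with
    more than ``max_count`` genes are pruned.  Returns the per-count mean
    with a bootstrap CI and a quadratic least-squares fit of standardized
    rate on count (coefficients highest power first, plus adjusted R2).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    counts_all, z_all = [], []
    for sp, pairs in species_pairs.items():
        rates = np.concatenate([land.rate for land, _ in pairs])
        cnts = np.concatenate([gwt.counts for _, gwt in pairs])
        sd = rates.std()
        if sd == 0:
            continue
        z = (rates - rates.mean()) / sd
        keep = cnts <= max_count
        counts_all.append(cnts[keep])
        z_all.append(z[keep])
    counts = np.concatenate(counts_all)
    z = np.concatenate(z_all)
    rows = []
    for c in range(int(counts.max()) + 1):
        sel = counts == c
        n = int(sel.sum())
        if n == 0:
            continue
        vals = z[sel]
        row = {"gene_count": c, "mean_z_rate": float(vals.mean()), "n_windows": n,
               "ci_low": np.nan, "ci_high": np.nan}
        if n >= 2:
            boots = np.array(
                [np.mean(rng.choice(vals, size=n)) for _ in range(n_boot)]
            )
            row["ci_low"] = float(np.percentile(boots, 2.5))
            row["ci_high"] = float(np.percentile(boots, 97.5))
        rows.append(row)
    curve = pd.DataFrame(rows)
    coefs = np.polyfit(counts, z, 2)
    fitted = np.polyval(coefs, counts)
    rss = float(np.sum((z - fitted) ** 2))
    tss = float(np.sum((z - z.mean()) ** 2))
    n = z.shape[0]
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 3) if n > 3 else np.nan
    return {"curve": curve, "quadratic_coefs": coefs, "adj_r2": float(adj_r2)}


def gene_profile_and_classify(
    pairs: Sequence[GeneWindowTrack],
    n_bins: int = 20,
    rng: np.random.Generator | None = None,
) -> tuple[BinProfile, PatternCall]:
    """Species-level telomere-distance profile of standardized gene counts
    (one random side per chromosome) and its pattern call, using the same
    heuristic as crossover profiles."""
    windows = [
        (gwt.starts, gwt.ends, gwt.counts.astype(float), gwt.chromosome_length)
        for gwt in pairs
    ]
    profile = telomere_binned_values(windows, n_bins=n_bins, standardize=True, rng=rng)
    return profile, classify_pattern(profile)


def pattern_concordance(
    co_labels: dict[str, str], gene_labels: dict[str, str]
) -> pd.DataFrame:
    """Concordance table of crossover vs gene-density pattern labels over
    the species present in both."""
    rows = [
        {"species": sp, "co_pattern": co_labels[sp], "gene_pattern": gene_labels[sp],
         "concordant": co_labels[sp] == gene_labels[sp]}
        for sp in sorted(set(co_labels) & set(gene_labels))
    ]
    return pd.DataFrame(rows)
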