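"""Intra-chromosomal genetic shuffling (r-bar intra).

For a chromosome with Lambda loci, r_intra is the mean recombination
fraction over all Lambda(Lambda-1)/2 locus pairs — the probability that
a random pair of loci is recombined by a crossover at meiosis; it is
bounded above by 0.5 (free recombination).  Recombination fractions are
obtained from pairwise genetic distances through the reverse mapping
function of the source map:

    Haldane (no interference):      r = (1 - exp(-2 d / 100)) / 2
    Kosambi (partial interference): r = tanh(2 d / 100) / 2

Loci are 1,000 pseudo-markers evenly spaced along the chromosome — in
base pairs for the genomic-distance estimate, or in cumulative gene
count for the gene-distance estimate.  Homogeneity of a Marey map on
either scale is measured by the RMSE of the rescaled map to the diagonal
(a perfectly uniform landscape lies on y = x); the scale with the lower
RMSE is the more homogeneous one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_maps import GeneTrack
from .marey_fit import MareyFit, pseudo_markers

__all__ = [
    "ShufflingResult",
    "reverse_haldane",
    "reverse_kosambi",
    "r_intra",
    "shuffling_from_fit",
    "gene_distance_map",
    "gene_pseudo_markers",
    "rmse_homogeneity",
    "compare_scales",
]


@dataclass
class ShufflingResult:
    species: str
    chromosome: str
    r_intra_genomic: float
    r_intra_gene: float | None
    mapping_function: str
    n_loci: int
    rmse_genomic: float
    rmse_gene: float | None
    more_homogeneous_scale: str | None


def _check_nonneg(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distances must be >= 0")
    return d


def reverse_haldane(d) -> np.ndarray | float:
    """Recombination fraction from Haldane cM distance: r = (1 - e^(-2d/100))/2."""
    d = _check_nonneg(d)
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if np.isscalar(d) or r.ndim == 0 else r


def reverse_kosambi(d) -> np.ndarray | float:
    """Recombination fraction from Kosambi cM distance: r = tanh(2d/100)/2."""
    d = _check_nonneg(d)
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if np.isscalar(d) or r.ndim == 0 else r


_REVERSE = {"haldane": reverse_haldane, "kosambi": reverse_kosambi}


def _resolve_mapping_function(name: str) -> str:
    if name in _REVERSE:
        return name
    if name == "none":
        warnings.warn("map has no recorded mapping function; defaulting to Haldane")
        return "haldane"
    raise ValueError(f"unknown mapping function {name!r}")


def r_intra(cm: np.ndarray, mapping_function: str = "haldane") -> float:
    """Mean pairwise recombination fraction over all locus pairs.

    Exact O(Lambda^2) summation over the upper triangle of pairwise cM
    distances (about 5e5 pairs for the default 1,000 pseudo-markers).
    """
    cm = np.asarray(cm, dtype=float)
    lam = cm.shape[0]
    if lam < 2:
        raise ValueError("need at least 2 loci")
    fn = _REVERSE[_resolve_mapping_function(mapping_function)]
    iu = np.triu_indices(lam, k=1)
    d = np.abs(cm[iu[0]] - cm[iu[1]])
    return float(np.mean(fn(d)))


def shuffling_from_fit(
    fit: MareyFit, n_pseudo: int = 1000, mapping_function: str | None = None
) -> float:
    """r_intra over n_pseudo evenly spaced pseudo-markers of a fitted map."""
    mf = mapping_function if mapping_function is not None else fit.map.mapping_function
    _, cm = pseudo_markers(fit, n_pseudo)
    return r_intra(cm, mf)


def gene_distance_map(
    fit: MareyFit, track: GeneTrack, positions: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Re-express map positions in relative gene distance.

    Gene distance of a bp position is the number of gene starts at or
    before it, divided by the total gene count.  Returns (relative gene
    distance, cM) for the given positions (the map's markers by default).
    """
    if track.total_genes == 0:
        raise ValueError("empty gene track")
    if positions is None:
        positions = fit.map.genomic_pos
    g = np.searchsorted(track.gene_starts, positions, side="right") / track.total_genes
    return g, fit.predict(positions)


def gene_pseudo_markers(
    fit: MareyFit, track: GeneTrack, n: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """n pseudo-markers evenly spaced in cumulative gene count, with cM.

    The inverse of the gene-distance transform is taken by interpolating
    bp against the (step) cumulative gene count.
    """
    if n < 2:
        raise ValueError("need at least 2 pseudo-markers")
    if track.total_genes == 0:
        raise ValueError("empty gene track")
    G = track.total_genes
    L = fit.map.chromosome_length
    # cumulative share reached at each gene start, anchored at both ends
    shares = np.concatenate([[0.0], np.arange(1, G + 1) / G])
    bps = np.concatenate([[0.0], track.gene_starts])
    if bps[-1] < L:
        shares = np.append(shares, 1.0)
        bps = np.append(bps, L)
    u = np.linspace(0.0, 1.0, n)
    bp = np.interp(u, shares, bps)
    return u, fit.predict(bp)


def rmse_homogeneity(x: np.ndarray, cm: np.ndarray) -> float:
    """RMSE of a Marey map to the diagonal after rescaling both axes to
    [0, 1]; 0 means a perfectly uniform crossover distribution."""
    x = np.asarray(x, dtype=float)
    cm = np.asarray(cm, dtype=float)
    xr = (x - x.min()) / np.ptp(x) if np.ptp(x) > 0 else x * 0.0
    yr = (cm - cm.min()) / np.ptp(cm) if np.ptp(cm) > 0 else cm * 0.0
    return float(np.sqrt(np.mean((yr - xr) ** 2)))


def compare_scales(
    fit: MareyFit,
    track: GeneTrack | None = None,
    n_pseudo: int = 1000,
    mapping_function: str | None = None,
) -> ShufflingResult:
    """Genetic shuffling and map homogeneity on genomic and gene scales.

    Computes r_intra and the diagonal RMSE from pseudo-markers evenly
    spaced in bp and (when a gene track is given) in cumulative gene
    count, and labels the scale with the lower RMSE as the more
    homogeneous landscape.
    """
    mf = _resolve_mapping_function(
        mapping_function if mapping_function is not None else fit.map.mapping_function
    )
    bp, cm_genomic = pseudo_markers(fit, n_pseudo)
    r_genomic = r_intra(cm_genomic, mf)
    rmse_genomic = rmse_homogeneity(bp, cm_genomic)
    r_gene = rmse_gene = None
    label = None
    if track is not None and track.total_genes > 0:
        u, cm_gene = gene_pseudo_markers(fit, track, n_pseudo)
        r_gene = r_intra(cm_gene, mf)
        rmse_gene = rmse_homogeneity(u, cm_gene)
        label = "gene" if rmse_gene < rmse_genomic else "genomic"
    return ShufflingResult(
        species=fit.map.species,
        chromosome=fit.map.chromosome,
        r_intra_genomic=r_genomic,
        r_intra_gene=r_gene,
        mapping_function=mf,
        n_loci=n_pseudo,
        rmse_genomic=rmse_genomic,
        rmse_gene=rmse_gene,
        more_homogeneous_scale=label,
    )
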