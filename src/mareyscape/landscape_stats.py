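"""Heterogeneity and positional statistics of crossover landscapes.

Covers the Gini index of windowed rates (Lorenz-curve heterogeneity,
0 = perfectly even, -> 1 maximally concentrated), the k-segment log10
relative-rate profile, the periphery-bias ratio (mean rate in the
terminal 10% of the chromosome over the chromosome mean), species-level
telomere-distance profiles in 20 bins with one randomly sampled side per
chromosome, a heuristic distal / sub-distal / exception pattern
classifier, and per-chromosome summary records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_maps import MareyMap
from .marey_fit import Landscape, MareyFit

__all__ = [
    "BinProfile",
    "PatternCall",
    "gini_index",
    "relative_rate_bins",
    "periphery_bias_ratio",
    "periphery_bias_sensitivity",
    "telomere_profile",
    "telomere_binned_values",
    "classify_pattern",
    "telomere_distance_correlation",
    "chromosome_summary",
]


@dataclass
class BinProfile:
    """Per-bin statistic along the chromosome or along telomere distance."""

    k: int
    values: np.ndarray  # NaN where a bin is empty/undefined
    counts: np.ndarray | None = None
    scheme: str = "telomere"  # "telomere" (relative distance) or "genomic"
    standardized: bool = False


@dataclass
class PatternCall:
    """Qualitative crossover (or gene-density) pattern of a species."""

    label: str  # distal | sub-distal | exception
    peak_bin: int  # 1-based index into the 20-bin profile
    peak_distance: float  # relative telomere distance at the peak bin midpoint
    evidence: dict


# ---------------------------------------------------------------------------


def gini_index(landscape: Landscape) -> float:
    """Gini index of the Lorenz curve of per-window rates, weighting each
    window by its length (the terminal partial window counts less)."""
    if landscape.n_windows < 2:
        raise ValueError("need at least 2 windows")
    w = landscape.lengths.astype(float)
    r = landscape.rate.astype(float)
    total = float(np.sum(r * w))
    if total <= 0:
        raise ValueError("all-zero landscape: Gini undefined")
    order = np.argsort(r, kind="stable")
    w, r = w[order], r[order]
    pop = np.concatenate([[0.0], np.cumsum(w) / np.sum(w)])
    val = np.concatenate([[0.0], np.cumsum(r * w) / total])
    return float(1.0 - np.sum(np.diff(pop) * (val[1:] + val[:-1])))


def relative_rate_bins(fit: MareyFit, k: int = 10) -> BinProfile:
    """log10 of each of k equal genomic segments' genetic length over the
    expected share (total / k).  0 everywhere for a uniform map; segments
    with zero genetic length come back as NaN (missing), not -inf."""
    if k < 2:
        raise ValueError("k must be >= 2")
    edges = np.linspace(0.0, fit.map.chromosome_length, k + 1)
    genetic = np.diff(fit.predict(edges))
    total = genetic.sum()
    if total <= 0:
        raise ValueError("zero total genetic length")
    expected = total / k
    with np.errstate(divide="ignore"):
        vals = np.where(genetic > 0, np.log10(genetic / expected), np.nan)
    return BinProfile(k=k, values=vals, scheme="genomic")


def _region_mean_rate(landscape: Landscape, a: float, b: float) -> float:
    """Length-weighted mean rate over [a, b), splitting windows that
    straddle the region boundary."""
    overlap = np.clip(
        np.minimum(landscape.ends, b) - np.maximum(landscape.starts, a), 0.0, None
    )
    w = overlap.sum()
    if w <= 0:
        return np.nan
    return float(np.sum(landscape.rate * overlap) / w)


def periphery_bias_ratio(
    landscape: Landscape,
    tip_frac: float = 0.10,
    mode: str = "both_tips",
    rng: np.random.Generator | None = None,
) -> float:
    """Mean rate in the chromosome tip(s) divided by the chromosome mean.

    ``both_tips`` pools the two terminal ``tip_frac`` regions;
    ``random_tip`` samples one side (seeded via ``rng``).  > 1 means
    recombination concentrates at the periphery.
    """
    if not 0 < tip_frac <= 1:
        raise ValueError("tip_frac must be in (0, 1]")
    L = landscape.chromosome_length
    mean = landscape.mean_rate()
    if mean <= 0:
        raise ValueError("whole-chromosome mean rate is zero")
    if mode == "both_tips":
        left = _region_mean_rate(landscape, 0.0, tip_frac * L)
        right = _region_mean_rate(landscape, (1.0 - tip_frac) * L, L)
        tip = np.nanmean([left, right])
    elif mode == "random_tip":
        rng = rng if rng is not None else np.random.default_rng()
        if rng.random() < 0.5:
            tip = _region_mean_rate(landscape, 0.0, tip_frac * L)
        else:
            tip = _region_mean_rate(landscape, (1.0 - tip_frac) * L, L)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(tip / mean)


def periphery_bias_sensitivity(
    landscape: Landscape, tip_fracs: Sequence[float]
) -> pd.DataFrame:
    """Periphery-bias ratio at several tip sizes; the ratio tends to 1 as
    the tip grows to the whole chromosome."""
    rows = [
        {"tip_frac": f, "periphery_bias": periphery_bias_ratio(landscape, tip_frac=f)}
        for f in tip_fracs
    ]
    return pd.DataFrame(rows)


def telomere_binned_values(
    windows: Sequence[tuple[np.ndarray, np.ndarray, np.ndarray, float]],
    n_bins: int = 20,
    standardize: bool = True,
    rng: np.random.Generator | None = None,
) -> BinProfile:
    """Bin per-window values by relative distance to the nearest telomere.

    ``windows`` is a sequence of (starts, ends, values, chromosome_length)
    tuples, one per chromosome of a species.  Each chromosome is split at
    its midpoint and one side is sampled at random (window midpoints
    decide membership); relative distance to the telomere, in [0, 0.5],
    is divided into ``n_bins`` equal bins.  Values are standardized
    within the species (z-score over all sampled windows) when requested.
    """
    rng = rng if rng is not None else np.random.default_rng()
    dists, vals = [], []
    for starts, ends, values, length in windows:
        mid = 0.5 * (np.asarray(starts) + np.asarray(ends))
        left = rng.random() < 0.5
        sel = mid < length / 2.0 if left else mid >= length / 2.0
        d = mid[sel] / length if left else (length - mid[sel]) / length
        dists.append(d)
        vals.append(np.asarray(values)[sel])
    d = np.concatenate(dists)
    v = np.concatenate(vals).astype(float)
    was_standardized = False
    if standardize:
        sd = v.std()
        if sd > 0:
            v = (v - v.mean()) / sd
            was_standardized = True
        else:
            import warnings

            warnings.warn("zero variance: standardization skipped")
    bins = np.minimum((d / 0.5 * n_bins).astype(int), n_bins - 1)
    out = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = bins == b
        counts[b] = sel.sum()
        if counts[b]:
            out[b] = v[sel].mean()
    return BinProfile(
        k=n_bins, values=out, counts=counts, scheme="telomere",
        standardized=was_standardized,
    )


def telomere_profile(
    landscapes: Sequence[Landscape],
    n_bins: int = 20,
    standardize: bool = True,
    rng: np.random.Generator | None = None,
) -> BinProfile:
    """Species-level telomere-distance profile of recombination rates
    (chromosomes pooled, one random side each)."""
    windows = [(l.starts, l.ends, l.rate, l.chromosome_length) for l in landscapes]
    return telomere_binned_values(windows, n_bins=n_bins, standardize=standardize, rng=rng)


def classify_pattern(profile: BinProfile) -> PatternCall:
    """Call the qualitative crossover pattern from a 20-bin telomere profile.

    distal: profile peaks within relative distance < 0.1 of the telomere
    (recombination decays from the tip).  sub-distal: peak at 0.1-0.2
    with a depressed most-distal bin.  Anything else (e.g. a central
    peak) is an exception.
    """
    v = profile.values
    if np.all(np.isnan(v)):
        return PatternCall("exception", 0, np.nan, {"reason": "empty profile"})
    peak = int(np.nanargmax(v))
    width = 0.5 / profile.k
    peak_dist = (peak + 0.5) * width
    if peak_dist < 0.1:
        label = "distal"
    elif 0.1 <= peak_dist < 0.2 and (np.isnan(v[0]) or v[0] < v[peak]):
        label = "sub-distal"
    else:
        label = "exception"
    return PatternCall(
        label=label,
        peak_bin=peak + 1,
        peak_distance=peak_dist,
        evidence={"peak_value": float(v[peak]), "bin1_value": float(v[0])},
    )


def telomere_distance_correlation(landscape: Landscape) -> tuple[float, float]:
    """Spearman rho (and p) between window rates and relative distance to
    the nearest telomere.  Negative rho = distally biased recombination."""
    if landscape.n_windows < 10:
        raise ValueError("need at least 10 windows")
    mid = landscape.midpoints
    L = landscape.chromosome_length
    dist = np.minimum(mid, L - mid) / L
    if np.ptp(landscape.rate) == 0:
        return np.nan, np.nan
    res = stats.spearmanr(landscape.rate, dist)
    return float(res.statistic), float(res.pvalue)


def chromosome_summary(
    m: MareyMap,
    landscape: Landscape,
    species_mean_length: float | None = None,
) -> dict:
    """Per-chromosome record: mean rate, map lengths, crossover-number
    proxy (map length / 50 cM), excess of COs (map length - 50 cM),
    relative chromosome size, Gini and periphery-bias."""
    length_cm = (
        m.map_length_corrected if m.map_length_corrected is not None else m.map_length_raw
    )
    rec = {
        "species": m.species,
        "chromosome": m.chromosome,
        "chromosome_length_bp": m.chromosome_length,
        "n_markers": m.n_markers,
        "map_length_raw_cm": m.map_length_raw,
        "map_length_corrected_cm": m.map_length_corrected,
        "mean_rate_cm_per_mb": landscape.mean_rate(),
        "co_number_proxy": length_cm / 50.0,
        "excess_co_cm": length_cm - 50.0,
        "relative_size": (
            m.chromosome_length / species_mean_length
            if species_mean_length
            else np.nan
        ),
    }
    try:
        rec["gini"] = gini_index(landscape)
    except ValueError:
        rec["gini"] = np.nan
    try:
        rec["periphery_bias"] = periphery_bias_ratio(landscape)
    except ValueError:
        rec["periphery_bias"] = np.nan
    return rec
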