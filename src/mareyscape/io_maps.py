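"""Reading, validating, orienting, filtering and correcting Marey maps.

A Marey map plots cumulative genetic distance (cM) against physical
position (bp) for the markers of one chromosome.  This module turns
delimited marker tables into :class:`MareyMap` objects, reorients maps so
the Marey function increases, applies the marker-count and end-gap
filters, removes outlier markers by iterated loess residuals, applies the
Hall & Willis map-length correction (+2s per linkage group, s = average
marker spacing), and reads centromere tables and GFF3 gene annotations.

Coordinates: input bp are treated as 1-based inclusive and converted to
0-based half-open internally; all window output follows the BED
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MareyMap",
    "CentromereRecord",
    "GeneTrack",
    "QCReport",
    "ExcessOutliersError",
    "read_marey_table",
    "orient_map",
    "filter_map",
    "remove_outliers",
    "hall_willis_correct",
    "read_gff_genes",
    "read_centromeres",
]

DEFAULT_COLUMNS = {"species": "species", "chromosome": "chr", "cm": "cM", "bp": "bp"}


class ExcessOutliersError(RuntimeError):
    """More than the allowed fraction of markers flagged as outliers —
    the map is likely mis-assembled rather than noisy."""


@dataclass
class MareyMap:
    """Ordered marker table for one chromosome (cM vs bp) plus metadata."""

    species: str
    chromosome: str
    genomic_pos: np.ndarray  # bp, 0-based, sorted strictly increasing
    genetic_pos: np.ndarray  # cM
    marker_ids: np.ndarray
    chromosome_length: float
    mapping_function: str = "none"  # haldane | kosambi | none
    progeny_size: int | None = None
    map_length_corrected: float | None = None
    orientation_applied: bool = False

    def __post_init__(self) -> None:
        self.genomic_pos = np.asarray(self.genomic_pos, dtype=float)
        self.genetic_pos = np.asarray(self.genetic_pos, dtype=float)
        self.marker_ids = np.asarray(self.marker_ids)
        if self.genomic_pos.shape != self.genetic_pos.shape:
            raise ValueError("genomic and genetic position arrays differ in length")
        if np.any(self.genomic_pos < 0) or np.any(
            self.genomic_pos > self.chromosome_length
        ):
            raise ValueError("marker positions outside [0, chromosome_length]")
        if np.any(np.diff(self.genomic_pos) < 0):
            raise ValueError("markers must be sorted by genomic position")
        if np.any(self.genetic_pos < 0):
            raise ValueError("genetic positions must be >= 0")

    @property
    def n_markers(self) -> int:
        return int(self.genomic_pos.shape[0])

    @property
    def map_length_raw(self) -> float:
        if self.n_markers == 0:
            return 0.0
        return float(self.genetic_pos.max() - self.genetic_pos.min())

    @property
    def key(self) -> tuple[str, str]:
        return (self.species, self.chromosome)

    def deduplicated(self) -> "MareyMap":
        """Collapse markers sharing a genomic position to their mean cM
        (loess needs distinct abscissae)."""
        pos, inv = np.unique(self.genomic_pos, return_inverse=True)
        if pos.shape[0] == self.n_markers:
            return self
        cm = np.zeros(pos.shape[0])
        counts = np.zeros(pos.shape[0])
        np.add.at(cm, inv, self.genetic_pos)
        np.add.at(counts, inv, 1.0)
        first = np.full(pos.shape[0], -1, dtype=int)
        for i, j in enumerate(inv):
            if first[j] < 0:
                first[j] = i
        return replace(
            self,
            genomic_pos=pos,
            genetic_pos=cm / counts,
            marker_ids=self.marker_ids[first],
        )


@dataclass
class CentromereRecord:
    """Centromeric index c = short arm / total chromosome length, with the
    bp position it maps to once the chromosome side is decided."""

    species: str
    chromosome: str
    centromeric_index: float
    orientation_confident: bool
    oriented_position: float | None  # bp after orientation, None if undecidable

    def __post_init__(self) -> None:
        if not 0.0 < self.centromeric_index <= 0.5:
            raise ValueError(
                f"centromeric index must be in (0, 0.5], got {self.centromeric_index}"
            )


@dataclass
class GeneTrack:
    """Sorted gene start positions for one chromosome; overlapping genes
    and splice variants collapsed to a single record."""

    species: str
    chromosome: str
    gene_starts: np.ndarray
    chromosome_length: float | None = None

    def __post_init__(self) -> None:
        self.gene_starts = np.sort(np.asarray(self.gene_starts, dtype=float))

    @property
    def total_genes(self) -> int:
        return int(self.gene_starts.shape[0])


@dataclass
class QCReport:
    """Per-chromosome bookkeeping of the cleaning pipeline."""

    entries: dict = field(default_factory=dict)

    def entry(self, key: tuple[str, str]) -> dict:
        return self.entries.setdefault(
            key,
            {
                "kept": True,
                "reasons": [],
                "dropped_rows": 0,
                "removed_outliers": [],
                "orientation_applied": False,
                "correction_delta_cm": np.nan,
            },
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sp, ch), e in self.entries.items():
            rows.append(
                {
                    "species": sp,
                    "chromosome": ch,
                    "kept": e["kept"],
                    "reasons": ";".join(e["reasons"]),
                    "dropped_rows": e["dropped_rows"],
                    "n_removed_outliers": len(e["removed_outliers"]),
                    "orientation_applied": e["orientation_applied"],
                    "correction_delta_cm": e["correction_delta_cm"],
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# marker tables


def read_marey_table(
    path,
    columns: Mapping[str, str] | None = None,
    chromosome_lengths: Mapping[tuple[str, str], float] | None = None,
    sep: str | None = None,
    one_based: bool = True,
    qc: QCReport | None = None,
) -> list[MareyMap]:
    """Read a delimited marker table into one MareyMap per (species, chromosome).

    Rows with unparseable or missing cM/bp are dropped and counted in the
    QC report.  When no chromosome length is supplied the last marker
    position is used.
    """
    col = dict(DEFAULT_COLUMNS)
    if columns:
        col.update(columns)
    df = pd.read_csv(path, sep=sep, engine="python")
    for role in ("species", "chromosome", "cm", "bp"):
        if col[role] not in df.columns:
            raise ValueError(
                f"missing mandatory column '{col[role]}' (role: {role}) in {path}"
            )
    qc = qc if qc is not None else QCReport()
    df = df.copy()
    df[col["cm"]] = pd.to_numeric(df[col["cm"]], errors="coerce")
    df[col["bp"]] = pd.to_numeric(df[col["bp"]], errors="coerce")
    has_ids = "marker" in df.columns

    maps: list[MareyMap] = []
    for (sp, ch), grp in df.groupby([col["species"], col["chromosome"]], sort=True):
        key = (str(sp), str(ch))
        e = qc.entry(key)
        ok = grp[col["cm"]].notna() & grp[col["bp"]].notna()
        e["dropped_rows"] += int((~ok).sum())
        grp = grp[ok]
        if grp.empty:
            e["kept"] = False
            e["reasons"].append("empty")
            warnings.warn(f"chromosome {key} empty after dropping bad rows")
            continue
        bp = grp[col["bp"]].to_numpy(dtype=float)
        if one_based:
            bp = bp - 1.0
        cm = grp[col["cm"]].to_numpy(dtype=float)
        ids = (
            grp["marker"].astype(str).to_numpy()
            if has_ids
            else np.array([f"{sp}_{ch}_m{i}" for i in range(len(grp))])
        )
        order = np.argsort(bp, kind="stable")
        bp, cm, ids = bp[order], cm[order], ids[order]
        length = None
        if chromosome_lengths is not None:
            length = chromosome_lengths.get(key)
        if length is None:
            length = float(bp[-1])
        maps.append(
            MareyMap(
                species=key[0],
                chromosome=key[1],
                genomic_pos=bp,
                genetic_pos=cm - cm.min() if cm.min() < 0 else cm,
                marker_ids=ids,
                chromosome_length=float(length),
            ).deduplicated()
        )
    return maps


def orient_map(m: MareyMap) -> MareyMap:
    """Reorient so the Marey function increases: if Spearman rho(cM, bp) < 0
    genetic positions are reflected (map length minus cM).

    A map with zero genetic variance cannot be oriented and is returned
    unchanged with a warning.
    """
    if m.n_markers < 2:
        raise ValueError("need at least 2 markers to orient a map")
    if np.ptp(m.genetic_pos) == 0:
        warnings.warn(f"map {m.key}: zero genetic variance, cannot orient")
        return m
    rho = stats.spearmanr(m.genetic_pos, m.genomic_pos).statistic
    if rho < 0:
        reflected = m.genetic_pos.max() - m.genetic_pos
        return replace(m, genetic_pos=reflected, orientation_applied=True)
    return m


def filter_map(
    m: MareyMap,
    min_markers: int = 50,
    max_end_gap_frac: float = 0.10,
) -> tuple[bool, list[str]]:
    """Marker-count and terminal-coverage filters.

    A map is dropped if it has fewer than ``min_markers`` markers (default
    50; lower the threshold to reproduce hand-validated ~30-marker
    exceptions) or if more than ``max_end_gap_frac`` of the chromosome is
    uncovered at either end.
    """
    reasons = []
    if m.n_markers < min_markers:
        reasons.append("few_markers")
    # removal triggers when EITHER end is missing more than the threshold
    end_gap = max(m.genomic_pos[0], m.chromosome_length - m.genomic_pos[-1])
    if end_gap > max_end_gap_frac * m.chromosome_length:
        reasons.append("end_gap")
    return (len(reasons) == 0, reasons)


def remove_outliers(
    m: MareyMap,
    resid_frac: float = 0.05,
    max_iter: int = 5,
    span: float | None = None,
    max_removed_frac: float = 0.20,
) -> tuple[MareyMap, list]:
    """Iteratively drop markers far from the loess trend.

    When no span is given it is chosen by a short hold-out calibration,
    so sharply distal maps are not over-smoothed into spurious boundary
    residuals.

    At each pass a robustified loess Marey fit (bisquare-reweighted, so a
    gross outlier cannot drag its own neighbourhood) is computed and
    markers whose absolute residual exceeds ``resid_frac`` x raw map
    length are removed; stops at a fixed point or after ``max_iter``
    passes.  Removing more than ``max_removed_frac`` of the markers
    raises :class:`ExcessOutliersError`.
    """
    from .marey_fit import calibrate_span, fit_marey  # deferred: avoids a cycle

    if span is None:
        span, _ = calibrate_span(m, n_iter=20, seed=0)
    current = m
    removed: list = []
    n0 = m.n_markers
    for _ in range(max_iter):
        thresh = resid_frac * current.map_length_raw
        fit = fit_marey(current, span=span, robust=2, robust_floor=thresh)
        pred = fit.predict(current.genomic_pos)
        resid = np.abs(current.genetic_pos - current.genetic_pos.min() - pred)
        bad = resid > thresh
        if not bad.any():
            break
        removed.extend(current.marker_ids[bad].tolist())
        if len(removed) > max_removed_frac * n0:
            raise ExcessOutliersError(
                f"map {m.key}: {len(removed)}/{n0} markers flagged as outliers"
            )
        current = replace(
            current,
            genomic_pos=current.genomic_pos[~bad],
            genetic_pos=current.genetic_pos[~bad],
            marker_ids=current.marker_ids[~bad],
        )
    return current, removed


def hall_willis_correct(m: MareyMap) -> MareyMap:
    """Add twice the average marker spacing to the linkage-group length to
    account for undetected terminal recombination: s = raw length / (n - 1),
    corrected = raw + 2s.  Marker coordinates are unchanged."""
    if m.n_markers < 2:
        warnings.warn(f"map {m.key}: single marker, correction skipped")
        return m
    s = m.map_length_raw / (m.n_markers - 1)
    return replace(m, map_length_corrected=m.map_length_raw + 2.0 * s)


# ---------------------------------------------------------------------------
# annotations and centromeres


def read_gff_genes(
    path,
    feature_type: str = "gene",
    species: str = "",
    chromosome_lengths: Mapping[str, float] | None = None,
    one_based: bool = True,
) -> list[GeneTrack]:
    """Read gene start positions per chromosome from a GFF3 file.

    Splice variants are implicit (only ``gene`` features are read) and
    genes with overlapping spans are collapsed to a single record whose
    start is the earliest start.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    by_chrom: dict[str, list[tuple[float, float]]] = {}
    for feat in db.features_of_type(feature_type):
        start = float(feat.start) - (1.0 if one_based else 0.0)
        end = float(feat.end)  # GFF3 end is inclusive; half-open end == end
        by_chrom.setdefault(feat.seqid, []).append((start, end))
    if not by_chrom:
        warnings.warn(f"no '{feature_type}' features in {path}")
        return []
    tracks = []
    for chrom, spans in sorted(by_chrom.items()):
        spans.sort()
        merged_starts = []
        cur_start, cur_end = spans[0]
        for s, e in spans[1:]:
            if s < cur_end:  # overlap: one gene
                cur_end = max(cur_end, e)
            else:
                merged_starts.append(cur_start)
                cur_start, cur_end = s, e
        merged_starts.append(cur_start)
        length = None
        if chromosome_lengths is not None:
            length = chromosome_lengths.get(chrom)
        tracks.append(
            GeneTrack(
                species=species,
                chromosome=chrom,
                gene_starts=np.asarray(merged_starts),
                chromosome_length=length,
            )
        )
    return tracks


def read_centromeres(
    path,
    landscapes: Mapping[tuple[str, str], "object"] | None = None,
    sep: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> list[CentromereRecord]:
    """Read a centromeric-index table and orient each index.

    The index (short arm / total length) leaves two candidate positions,
    c*L and (1-c)*L.  When the orientation is unknown the index is placed
    on the side where the fitted landscape has the lowest local
    recombination rate (the putative centromere); such records carry
    ``orientation_confident=False``.
    """
    col = {"species": "species", "chromosome": "chr", "index": "centromeric_index"}
    if columns:
        col.update(columns)
    df = pd.read_csv(path, sep=sep, engine="python")
    for role, name in col.items():
        if name not in df.columns:
            raise ValueError(f"missing mandatory column '{name}' (role: {role})")
    records = []
    for _, row in df.iterrows():
        key = (str(row[col["species"]]), str(row[col["chromosome"]]))
        c = float(row[col["index"]])
        if not 0.0 < c <= 0.5:
            raise ValueError(f"centromeric index {c} outside (0, 0.5] for {key}")
        oriented_position = None
        landscape = landscapes.get(key) if landscapes is not None else None
        if landscape is not None:
            L = landscape.chromosome_length
            pos_a, pos_b = c * L, (1.0 - c) * L
            rate_a = landscape.rate_at(pos_a)
            rate_b = landscape.rate_at(pos_b)
            oriented_position = pos_a if rate_a <= rate_b else pos_b
        records.append(
            CentromereRecord(
                species=key[0],
                chromosome=key[1],
                centromeric_index=c,
                orientation_confident=False,
                oriented_position=oriented_position,
            )
        )
    return records


def write_landscape(landscape, path) -> None:
    """Write a landscape as BED-like TSV: chr, start, end, rate, ci_low, ci_high."""
    landscape.to_frame().to_csv(path, sep="\t", index=False)


def read_landscape(path, species: str = ""):
    """Read a BED-like landscape TSV written by :func:`write_landscape`."""
    from .marey_fit import Landscape

    df = pd.read_csv(path, sep="\t")
    return Landscape(
        species=species,
        chromosome=str(df["chr"].iloc[0]),
        chromosome_length=float(df["end"].iloc[-1]),
        starts=df["start"].to_numpy(dtype=float),
        ends=df["end"].to_numpy(dtype=float),
        rate=df["rate_cM_per_Mb"].to_numpy(dtype=float),
        ci_low=df["ci_low"].to_numpy(dtype=float) if "ci_low" in df else None,
        ci_high=df["ci_high"].to_numpy(dtype=float) if "ci_high" in df else None,
        window_size=float(df["end"].iloc[0] - df["start"].iloc[0]),
    )
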