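"""Synthetic Marey maps, centromeres and gene annotations.

The generator emulates the statistical structure of curated plant
linkage-map data so every pipeline stage is testable without downloads:
monotone Marey functions built from a crossover density with distal,
sub-distal, uniform or central-peak shape, a Gaussian centromeric dip,
obligate-crossover allocation per chromosome (model M3) or per arm
(model M2) plus an excess term, additive marker noise (deliberately not
re-monotonised, producing the disorder the QC stages must absorb),
injected outlier markers with recorded identities, and gene positions
whose density is tunably coupled (gamma in [-1, 1]) to the crossover
density.

Every generated chromosome carries a :class:`TruthRecord` exposing the
noise-free Marey function, true window rates, the generating pattern and
model labels, and injected outlier ids — the oracle for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_maps import GeneTrack, MareyMap
from .marey_fit import Landscape, derive_seed

__all__ = [
    "ChromosomeSpec",
    "TruthRecord",
    "co_density",
    "marey_truth",
    "sample_markers",
    "sample_genes",
    "true_landscape",
    "generate_chromosome",
    "generate_dataset",
]

PATTERNS = ("uniform", "distal", "sub-distal", "central-peak")

_GRID_N = 4097


@dataclass
class ChromosomeSpec:
    """Generative parameters for one synthetic chromosome.

    Defaults describe a typical mid-sized plant chromosome: 50 Mb, a
    distal crossover pattern with an obligate crossover per chromosome
    (the best-supported allocation model), 100 cM of excess crossovers,
    a deep centromeric dip, 500 markers with 1 cM mapping noise and
    2,000 genes moderately coupled to the crossover density.
    """

    species: str = "synthSpecies"
    chromosome: str = "chr1"
    length_bp: float = 50e6
    centromere_c: float = 0.4  # oriented relative position in (0, 1)
    pattern: str = "distal"
    obligate_mode: str = "per_chromosome"  # per_chromosome (M3) | per_arm (M2)
    excess_coefficient: float = 100.0  # a, cM of excess crossovers
    centromere_dip: tuple[float, float] = (0.8, 0.03)  # depth h in [0,1], width w
    n_markers: int = 500
    marker_noise_sd: float = 1.0  # cM
    outlier_frac: float = 0.0
    anchor_ends: bool = True  # terminal markers at 0 and L, as in maps that
    # pass the end-gap coverage filter
    gene_total: int = 2000
    gene_coupling: float = 0.5  # gamma in [-1, 1]
    mapping_function: str = "haldane"
    # shape constants: distal decay scale (plateau by ~20% of length) and
    # sub-distal bump peak position
    distal_scale: float = 0.1
    distal_plateau: float = 0.2
    subdistal_peak: float = 0.15

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.obligate_mode not in ("per_chromosome", "per_arm"):
            raise ValueError(f"unknown obligate mode {self.obligate_mode!r}")
        if not 0.0 < self.centromere_c < 1.0:
            raise ValueError("centromere_c must be in (0, 1)")
        if self.excess_coefficient < 0:
            raise ValueError("excess coefficient a must be >= 0")
        if self.n_markers < 2:
            raise ValueError("need at least 2 markers")
        if self.gene_total < 0:
            raise ValueError("gene_total must be >= 0")

    @property
    def model_id(self) -> str:
        return "M3" if self.obligate_mode == "per_chromosome" else "M2"


@dataclass
class TruthRecord:
    """Noise-free generating state of one synthetic chromosome."""

    spec: ChromosomeSpec
    x_grid: np.ndarray  # relative position in [0, 1]
    density: np.ndarray  # crossover density, integrates to 1
    cm_grid: np.ndarray  # true Marey function on the grid
    d1: float
    d_c: float
    outlier_ids: list = field(default_factory=list)

    @property
    def pattern(self) -> str:
        return self.spec.pattern

    @property
    def model_id(self) -> str:
        return self.spec.model_id

    def cm_at(self, bp) -> np.ndarray:
        rel = np.asarray(bp, dtype=float) / self.spec.length_bp
        return np.interp(rel, self.x_grid, self.cm_grid)


def co_density(spec: ChromosomeSpec, n_grid: int = _GRID_N) -> tuple[np.ndarray, np.ndarray]:
    """Crossover density on the relative coordinate [0, 1].

    Pattern shapes: uniform (flat); distal (mirrored exponential decay
    from each telomere over a plateau, levelling off by ~2x the decay
    scale); sub-distal (mirrored bump peaking at ~0.15 relative distance
    with a depressed tip); central-peak (single interior bump, the
    Capsella/Nelumbo-like exception).  All are multiplied by a Gaussian
    centromeric dip 1 - h exp(-(x-c)^2 / 2w^2) and normalized.
    """
    x = np.linspace(0.0, 1.0, n_grid)
    t = np.minimum(x, 1.0 - x)  # distance to nearest telomere
    if spec.pattern == "uniform":
        f = np.ones_like(x)
    elif spec.pattern == "distal":
        f = spec.distal_plateau + np.exp(-t / spec.distal_scale)
    elif spec.pattern == "sub-distal":
        theta = spec.subdistal_peak / 2.0  # gamma-shape mode k*theta with k=2
        f = 0.1 + (t / theta) ** 2 * np.exp(-t / theta)
    else:  # central-peak
        f = 0.1 + np.exp(-((x - 0.5) ** 2) / (2 * 0.15**2))
    h, w = spec.centromere_dip
    if h > 0:
        f = f * (1.0 - h * np.exp(-((x - spec.centromere_c) ** 2) / (2 * w**2)))
    if np.any(f < 0):
        raise ValueError("negative crossover density after composition")
    f = f / np.trapezoid(f, x)
    return x, f


def marey_truth(spec: ChromosomeSpec) -> TruthRecord:
    """Noise-free monotone Marey function honouring the obligate-crossover
    allocation.

    Arm genetic lengths follow the generating model exactly: under M3
    (one obligate CO per chromosome) d(c) = c*50 + a*c so d(c)/d(1) = c;
    under M2 (one per arm) d(c) = 50 + a*c so (d(c)-50)/(d(1)-100) = c.
    Within each arm, cM accumulate along the normalized cumulative
    crossover density.
    """
    x, f = co_density(spec)
    a, c = spec.excess_coefficient, spec.centromere_c
    if spec.obligate_mode == "per_chromosome":
        d_c = c * 50.0 + a * c
        d1 = 50.0 + a
    else:
        d_c = 50.0 + a * c
        d1 = 100.0 + a
    # cumulative density (trapezoid), normalized to 1 at the chromosome end
    dF = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * np.diff(x))])
    F = dF / dF[-1]
    Fc = np.interp(c, x, F)
    cm = np.where(
        x <= c,
        d_c * F / Fc,
        d_c + (d1 - d_c) * (F - Fc) / (1.0 - Fc),
    )
    cm = np.maximum.accumulate(cm)  # guard against round-off wiggles
    return TruthRecord(spec=spec, x_grid=x, density=f, cm_grid=cm, d1=d1, d_c=d_c)


def sample_markers(
    spec: ChromosomeSpec,
    truth: TruthRecord,
    rng: np.random.Generator,
) -> MareyMap:
    """Draw markers from the truth with additive cM noise and injected
    outliers.

    Marker positions are uniform on the chromosome; cM are the true Marey
    function plus Gaussian noise (not re-monotonised).  A fraction
    ``outlier_frac`` of markers is displaced towards the opposite half of
    the genetic map by 0.2-0.4 of the map length; their ids are recorded
    in ``truth.outlier_ids``.
    """
    n = spec.n_markers
    if spec.anchor_ends and n >= 2:
        bp = np.sort(rng.uniform(0.0, spec.length_bp, size=n - 2))
        bp = np.concatenate([[0.0], bp, [spec.length_bp]])
    else:
        bp = np.sort(rng.uniform(0.0, spec.length_bp, size=n))
    cm = truth.cm_at(bp) + rng.normal(0.0, spec.marker_noise_sd, size=n)
    cm = np.clip(cm, 0.0, None)
    ids = np.array([f"{spec.species}_{spec.chromosome}_m{i}" for i in range(n)])
    k = int(round(spec.outlier_frac * n))
    truth.outlier_ids = []
    if k > 0:
        picks = rng.choice(n, size=k, replace=False)
        mag = rng.uniform(0.2, 0.4, size=k) * truth.d1
        # displace towards the opposite half so outliers never clip back
        # onto the trend near map boundaries
        sign = np.where(cm[picks] < truth.d1 / 2.0, 1.0, -1.0)
        cm[picks] = np.clip(cm[picks] + sign * mag, 0.0, None)
        truth.outlier_ids = sorted(ids[picks].tolist())
    return MareyMap(
        species=spec.species,
        chromosome=spec.chromosome,
        genomic_pos=bp,
        genetic_pos=cm,
        marker_ids=ids,
        chromosome_length=spec.length_bp,
        mapping_function=spec.mapping_function,
    )


def sample_genes(
    spec: ChromosomeSpec,
    truth: TruthRecord,
    rng: np.random.Generator,
) -> GeneTrack:
    """Draw gene start positions with density coupled to the crossover
    density.

    Intensity is a mixture (1 - |gamma|) * uniform + |gamma| * shaped,
    where the shaped part follows the crossover density (gamma > 0) or
    its floored reciprocal (gamma < 0); gamma = 0 gives uniform genes.
    """
    gamma = spec.gene_coupling
    if not -1.0 <= gamma <= 1.0:
        raise ValueError("gene_coupling must be in [-1, 1]")
    x, f = truth.x_grid, truth.density
    fm = f / np.trapezoid(f, x)
    if gamma >= 0:
        shaped = fm
    else:
        inv = 1.0 / np.maximum(fm, 0.1 * fm.mean())
        shaped = inv / np.trapezoid(inv, x)
    intensity = (1.0 - abs(gamma)) + abs(gamma) * shaped
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (intensity[1:] + intensity[:-1]) * np.diff(x))]
    )
    cum /= cum[-1]
    u = rng.random(spec.gene_total)
    starts = np.interp(u, cum, x) * spec.length_bp
    return GeneTrack(
        species=spec.species,
        chromosome=spec.chromosome,
        gene_starts=np.sort(starts),
        chromosome_length=spec.length_bp,
    )


def true_landscape(truth: TruthRecord, window_size: float = 1e5) -> Landscape:
    """Window rates of the noise-free Marey function (the oracle the
    fitted landscape should recover)."""
    L = truth.spec.length_bp
    edges = np.arange(0.0, L, window_size)
    edges = np.append(edges, L)
    cm = truth.cm_at(edges)
    rate = np.diff(cm) / (np.diff(edges) / 1e6)
    return Landscape(
        species=truth.spec.species,
        chromosome=truth.spec.chromosome,
        chromosome_length=L,
        starts=edges[:-1],
        ends=edges[1:],
        rate=rate,
        window_size=window_size,
    )


def generate_chromosome(
    spec: ChromosomeSpec, seed: int = 0
) -> tuple[MareyMap, GeneTrack, TruthRecord]:
    """Generate one chromosome's markers, genes and truth from a master
    seed (per-chromosome stream derived from species/chromosome names)."""
    rng = np.random.default_rng(derive_seed(seed, spec.species, spec.chromosome))
    truth = marey_truth(spec)
    m = sample_markers(spec, truth, rng)
    genes = sample_genes(spec, truth, rng)
    return m, genes, truth


def generate_dataset(
    specs: list[ChromosomeSpec], outdir, seed: int = 0
) -> dict:
    """Generate a multi-species dataset on disk.

    Writes ``markers.tsv`` (species, chr, marker, cM, bp — bp written
    1-based as in published map tables), ``centromeres.tsv`` (centromeric
    index = short arm / total), one GFF3 per species and ``truth.json``.
    Deterministic under the master seed.  Returns the in-memory objects
    keyed by (species, chromosome).
    """
    keys = [(s.species, s.chromosome) for s in specs]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (species, chromosome) keys")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker_rows, cent_rows = [], []
    gff_lines: dict[str, list[str]] = {}
    truth_json: dict[str, dict] = {}
    objects: dict[tuple[str, str], dict] = {}
    for spec in specs:
        m, genes, truth = generate_chromosome(spec, seed)
        objects[(spec.species, spec.chromosome)] = {
            "map": m,
            "genes": genes,
            "truth": truth,
        }
        for i in range(m.n_markers):
            marker_rows.append(
                {
                    "species": spec.species,
                    "chr": spec.chromosome,
                    "marker": m.marker_ids[i],
                    "cM": m.genetic_pos[i],
                    "bp": int(round(m.genomic_pos[i])) + 1,
                }
            )
        cent_rows.append(
            {
                "species": spec.species,
                "chr": spec.chromosome,
                "centromeric_index": min(spec.centromere_c, 1 - spec.centromere_c),
            }
        )
        lines = gff_lines.setdefault(spec.species, [])
        starts = np.round(genes.gene_starts).astype(np.int64) + 1
        for j, s in enumerate(starts):
            end = s + 999
            if j + 1 < starts.shape[0]:
                end = min(end, int(starts[j + 1]) - 1)  # keep genes disjoint
            end = max(end, int(s))
            lines.append(
                f"{spec.chromosome}\tsynth\tgene\t{s}\t{end}\t.\t+\t.\tID=g{spec.chromosome}_{j}"
            )
        truth_json[f"{spec.species}/{spec.chromosome}"] = {
            "d1": truth.d1,
            "d_c": truth.d_c,
            "c": spec.centromere_c,
            "model_id": truth.model_id,
            "pattern": truth.pattern,
            "length_bp": spec.length_bp,
            "outlier_ids": truth.outlier_ids,
        }
    pd.DataFrame(marker_rows).to_csv(outdir / "markers.tsv", sep="\t", index=False)
    pd.DataFrame(cent_rows).to_csv(outdir / "centromeres.tsv", sep="\t", index=False)
    for sp, lines in gff_lines.items():
        with open(outdir / f"genes_{sp}.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write("\n".join(lines) + "\n")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=1)
    return objects
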