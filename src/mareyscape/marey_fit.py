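"""Marey-function fitting and windowed recombination-rate estimation.

The Marey function (genetic position as a function of physical position)
is interpolated by a two-degree polynomial loess whose span is calibrated
by repeated hold-out partitioning (2/3 train, 1/3 test, mean squared
error), with candidate spans in [0.2, 0.5].  Predictions are made
monotone non-decreasing by a cumulative maximum on a dense evaluation
grid and clipped to [0, raw map length], so window rates — the discrete
derivative over fixed non-overlapping windows, in cM/Mb — are never
negative.  95% confidence intervals come from bootstrap resampling of
the markers with the span held fixed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_maps import MareyMap
from .loess import loess_predict

__all__ = [
    "MareyFit",
    "Landscape",
    "calibrate_span",
    "fit_marey",
    "recombination_rates",
    "bootstrap_landscape",
    "pseudo_markers",
    "derive_seed",
]

DEFAULT_SPAN_GRID = (0.2, 0.25, 0.3, 0.35, 0.4, 0.45, 0.5)


def derive_seed(master_seed: int, species: str, chromosome: str) -> int:
    """Stable per-chromosome RNG seed below 2**31, so parallel per-map
    pipelines are reproducible from one master seed."""
    h = zlib.crc32(f"{species}\x00{chromosome}".encode())
    return int((master_seed * 1_000_003 + h) % (2**31 - 1))


@dataclass
class MareyFit:
    """A fitted, monotone-adjusted Marey function for one chromosome."""

    map: MareyMap
    span: float
    grid: np.ndarray  # bp evaluation grid covering [0, chromosome_length]
    grid_cm: np.ndarray  # monotone non-decreasing, clipped to [0, raw length]
    degree: int = 2
    cv_mse_by_span: pd.DataFrame | None = field(default=None, repr=False)

    def predict(self, bp) -> np.ndarray:
        """Fitted cM at genomic position(s) bp (linear interpolation on the
        monotone grid)."""
        return np.interp(np.asarray(bp, dtype=float), self.grid, self.grid_cm)

    @property
    def map_length_fitted(self) -> float:
        return float(self.grid_cm[-1] - self.grid_cm[0])


@dataclass
class Landscape:
    """Windowed recombination rates (cM/Mb) tiling one chromosome."""

    species: str
    chromosome: str
    chromosome_length: float
    starts: np.ndarray  # bp, 0-based half-open windows
    ends: np.ndarray
    rate: np.ndarray  # cM/Mb
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    n_bootstrap: int = 0
    window_size: float | None = None

    @property
    def n_windows(self) -> int:
        return int(self.starts.shape[0])

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.starts + self.ends)

    def mean_rate(self) -> float:
        """Length-weighted chromosome mean rate (cM/Mb)."""
        w = self.lengths
        return float(np.sum(self.rate * w) / np.sum(w))

    def rate_at(self, bp: float) -> float:
        """Rate of the window containing position bp."""
        i = int(np.searchsorted(self.ends, bp, side="right"))
        i = min(i, self.n_windows - 1)
        return float(self.rate[i])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chr": self.chromosome,
                "start": self.starts.astype(np.int64),
                "end": self.ends.astype(np.int64),
                "rate_cM_per_Mb": self.rate,
            }
        )
        if self.ci_low is not None:
            df["ci_low"] = self.ci_low
            df["ci_high"] = self.ci_high
        return df


def _window_edges(length: float, window_size: float) -> np.ndarray:
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    edges = np.arange(0.0, length, window_size)
    return np.append(edges, length)  # terminal partial window retained


def calibrate_span(
    m: MareyMap,
    span_grid=DEFAULT_SPAN_GRID,
    n_iter: int = 1000,
    train_frac: float = 2.0 / 3.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, pd.DataFrame]:
    """Choose the loess span by hold-out cross-validation.

    ``n_iter`` random 2/3-1/3 marker partitions are drawn; for each span
    the model is fitted on the training set and scored by MSE on the test
    set.  The span with the smallest mean MSE wins, ties going to the
    larger (smoother) span.  Returns (span, MSE table).
    """
    if m.n_markers < 9:
        raise ValueError("too few markers to cross-validate a span")
    rng = rng if rng is not None else np.random.default_rng(seed)
    spans = sorted(span_grid)
    x = m.genomic_pos
    y = m.genetic_pos
    n = m.n_markers
    n_train = max(4, int(round(train_frac * n)))
    sse = np.zeros(len(spans))
    cnt = np.zeros(len(spans))
    failed = np.zeros(len(spans), dtype=bool)
    for _ in range(n_iter):
        perm = rng.permutation(n)
        tr = np.sort(perm[:n_train])
        te = perm[n_train:]
        for k, s in enumerate(spans):
            if failed[k]:
                continue
            try:
                pred = loess_predict(x[tr], y[tr], x[te], span=s)
            except (np.linalg.LinAlgError, ValueError):
                failed[k] = True
                continue
            sse[k] += float(np.sum((pred - y[te]) ** 2))
            cnt[k] += te.shape[0]
    if failed.all():
        raise RuntimeError("loess failed at every candidate span")
    mse = np.where(~failed & (cnt > 0), sse / np.maximum(cnt, 1), np.inf)
    # spans tied with the minimum (within round-off) resolve to the largest
    tol = 1e-12 * max(m.map_length_raw, 1.0) ** 2
    best = max(s for s, v in zip(spans, mse) if v <= mse.min() + tol)
    table = pd.DataFrame({"span": spans, "cv_mse": mse, "failed": failed})
    return float(best), table


def fit_marey(
    m: MareyMap,
    span: float = 0.3,
    grid_step: float = 1000.0,
    max_grid: int = 4096,
    cv_table: pd.DataFrame | None = None,
    robust: int = 0,
    robust_floor: float = 0.0,
) -> MareyFit:
    """Fit the two-degree loess Marey function and monotone-adjust it.

    The smooth is evaluated on a grid of ~``grid_step`` bp spacing (capped
    at ``max_grid`` points for very long chromosomes), clipped to
    [0, raw map length] and made non-decreasing by cumulative maximum.
    """
    if m.n_markers < 3:
        raise ValueError("need at least 3 markers to fit a Marey function")
    mm = m.deduplicated()
    n_grid = int(min(max_grid, max(64, np.ceil(mm.chromosome_length / grid_step) + 1)))
    grid = np.linspace(0.0, mm.chromosome_length, n_grid)
    y = mm.genetic_pos - mm.genetic_pos.min()
    pred = loess_predict(
        mm.genomic_pos, y, grid, span=span, degree=2,
        robust=robust, robust_floor=robust_floor,
    )
    pred = np.clip(pred, 0.0, mm.map_length_raw)
    pred = np.maximum.accumulate(pred)
    return MareyFit(map=m, span=span, grid=grid, grid_cm=pred, cv_mse_by_span=cv_table)


def recombination_rates(fit: MareyFit, window_size: float = 1e5) -> Landscape:
    """Discrete derivative of the fitted Marey function in fixed windows.

    rate[a, b) = (fit(b) - fit(a)) / ((b - a) / 1e6) in cM/Mb.  The
    length-weighted mean rate equals fitted map length / chromosome length
    by telescoping, which is the genome-wide consistency check.
    """
    edges = _window_edges(fit.map.chromosome_length, window_size)
    cm = fit.predict(edges)
    widths_mb = np.diff(edges) / 1e6
    rate = np.maximum(np.diff(cm), 0.0) / widths_mb
    return Landscape(
        species=fit.map.species,
        chromosome=fit.map.chromosome,
        chromosome_length=fit.map.chromosome_length,
        starts=edges[:-1],
        ends=edges[1:],
        rate=rate,
        window_size=window_size,
    )


def bootstrap_landscape(
    m: MareyMap,
    span: float = 0.3,
    window_size: float = 1e5,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    grid_step: float = 1000.0,
    max_grid: int = 4096,
) -> Landscape:
    """Landscape with percentile bootstrap CIs from marker resampling.

    The span is calibrated once and reused across replicates.  Replicates
    with fewer than 3 distinct genomic positions are redrawn (and
    counted).  The point estimate is the original (non-resampled) fit.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    base_fit = fit_marey(m, span=span, grid_step=grid_step, max_grid=max_grid)
    land = recombination_rates(base_fit, window_size)
    edges = np.append(land.starts, land.ends[-1])
    mm = m.deduplicated()
    x, y = mm.genomic_pos, mm.genetic_pos - mm.genetic_pos.min()
    n = x.shape[0]
    rates = np.empty((n_boot, land.n_windows))
    n_redrawn = 0
    b = 0
    while b < n_boot:
        idx = np.sort(rng.integers(0, n, size=n))
        if np.unique(x[idx]).shape[0] < 3:
            n_redrawn += 1
            continue
        # replicates are evaluated on the window edges directly: the edge
        # sequence is itself a dense monotone grid at window resolution
        pred = loess_predict(x[idx], y[idx], edges, span=span, degree=2)
        cm_edges = np.maximum.accumulate(np.clip(pred, 0.0, mm.map_length_raw))
        rates[b] = np.maximum(np.diff(cm_edges), 0.0) / (np.diff(edges) / 1e6)
        b += 1
    alpha = (1.0 - ci) / 2.0
    lo = np.percentile(rates, 100 * alpha, axis=0)
    hi = np.percentile(rates, 100 * (1 - alpha), axis=0)
    return Landscape(
        species=m.species,
        chromosome=m.chromosome,
        chromosome_length=m.chromosome_length,
        starts=land.starts,
        ends=land.ends,
        rate=land.rate,
        ci_low=lo,
        ci_high=hi,
        n_bootstrap=n_boot,
        window_size=window_size,
    )


def pseudo_markers(fit: MareyFit, n: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """n pseudo-markers evenly spaced along the chromosome with their
    fitted cM positions (non-decreasing).  Used for genetic shuffling."""
    if n < 2:
        raise ValueError("need at least 2 pseudo-markers")
    bp = np.linspace(0.0, fit.map.chromosome_length, n)
    return bp, fit.predict(bp)
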