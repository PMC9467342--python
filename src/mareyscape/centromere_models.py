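"""Crossover-allocation models and centromere suppression tests.

Three competing models for how genetic length is split around the
centromere (centromeric index c = short arm / total length, oriented):

* M1 "telomere": crossovers split evenly about the physical midpoint
  regardless of the centromere — d(1/2)/d(1) = 0.5.
* M2 "telomere + centromere + one obligate CO per arm": each arm carries
  its 50 cM obligate crossover plus an excess proportional to its
  relative size — (d(c) - 50)/(d(1) - 100) = c.
* M3 "telomere + centromere + one obligate CO per chromosome": the
  obligate 50 cM and the excess are both allocated proportionally to arm
  size — d(c)/d(1) = c.

Observed statistics are read from the monotone fitted Marey function and
each model is scored by OLS of observed on predicted (adjusted R2, AIC,
BIC).  Local centromere suppression is tested by marker bootstrap of the
rate at the centromere against the chromosome mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_maps import CentromereRecord, MareyMap
from .marey_fit import Landscape, MareyFit, fit_marey, recombination_rates
from .loess import loess_predict

__all__ = [
    "ModelFitResult",
    "SuppressionTest",
    "MODEL_IDS",
    "predict_model",
    "observed_statistics",
    "fit_and_select",
    "centromere_suppression_test",
    "orientation_check",
]

MODEL_IDS = ("M1", "M2", "M3")


@dataclass
class ModelFitResult:
    model_id: str
    observed: np.ndarray
    predicted: np.ndarray
    adj_r2: float
    aic: float
    bic: float
    p_value: float
    slope: float
    intercept: float
    n_chromosomes: int


@dataclass
class SuppressionTest:
    species: str
    chromosome: str
    rate_at_centromere: float
    chromosome_mean_rate: float
    ci_low: float
    ci_high: float
    significant: bool
    zero_rate: bool
    n_bootstrap: int


def predict_model(model_id: str, c: float | None = None) -> float:
    """Expected value of each model's statistic for a chromosome with
    oriented centromeric position ratio c."""
    if model_id == "M1":
        return 0.5
    if model_id in ("M2", "M3"):
        if c is None or not 0.0 < c < 1.0:
            raise ValueError(f"{model_id} needs an oriented c in (0, 1), got {c}")
        return float(c)
    raise ValueError(f"unknown model {model_id!r}")


def observed_statistics(
    fit: MareyFit, centromere: CentromereRecord | None = None
) -> dict:
    """Per-chromosome observed statistics for the three models.

    d(1/2) and d(c) are read from the monotone fitted Marey function.
    The M2 statistic is undefined (NaN, flagged) when either arm carries
    less than its obligate 50 cM, i.e. d(1) <= 100 or an arm below 50.
    """
    L = fit.map.chromosome_length
    d1 = fit.map_length_fitted
    if d1 <= 0:
        raise ValueError("zero fitted map length")
    base = fit.predict(0.0)
    d_half = float(fit.predict(L / 2.0) - base)
    out = {
        "species": fit.map.species,
        "chromosome": fit.map.chromosome,
        "d1": d1,
        "d_half_ratio": d_half / d1,
        "c": np.nan,
        "m2_ratio": np.nan,
        "m2_valid": False,
        "m3_ratio": np.nan,
    }
    if centromere is not None and centromere.oriented_position is not None:
        pos = centromere.oriented_position
        if not 0.0 < pos < L:
            raise ValueError("centromere position outside chromosome")
        d_c = float(fit.predict(pos) - base)
        out["c"] = pos / L
        out["m3_ratio"] = d_c / d1
        short_arm = min(d_c, d1 - d_c)
        if d1 > 100.0 and short_arm >= 50.0:
            out["m2_ratio"] = (d_c - 50.0) / (d1 - 100.0)
            out["m2_valid"] = True
    return out


def _ols_fit(observed: np.ndarray, predicted: np.ndarray, model_id: str) -> ModelFitResult:
    n = observed.shape[0]
    if model_id == "M1":
        # constant prediction: score the fixed 0.5 line directly
        resid = observed - 0.5
        rss = float(np.sum(resid**2))
        tss = float(np.sum((observed - observed.mean()) ** 2))
        adj_r2 = 1.0 - rss / tss if tss > 0 else np.nan
        k = 1  # residual variance only
        slope, intercept = 0.0, 0.5
        # one-sample t-test of the mean against 0.5 as the reported p
        p = float(stats.ttest_1samp(observed, 0.5).pvalue) if n > 1 else np.nan
    else:
        res = stats.linregress(predicted, observed)
        slope, intercept = float(res.slope), float(res.intercept)
        fitted = intercept + slope * predicted
        resid = observed - fitted
        rss = float(np.sum(resid**2))
        tss = float(np.sum((observed - observed.mean()) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else np.nan
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else np.nan
        k = 3  # slope, intercept, residual variance
        p = float(res.pvalue)
    sigma2 = max(rss / n, 1e-300)
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    return ModelFitResult(
        model_id=model_id,
        observed=observed,
        predicted=predicted,
        adj_r2=float(adj_r2),
        aic=float(2 * k - 2 * loglik),
        bic=float(k * np.log(n) - 2 * loglik),
        p_value=p,
        slope=slope,
        intercept=intercept,
        n_chromosomes=n,
    )


def fit_and_select(
    records: pd.DataFrame,
    min_species_chromosomes: int = 5,
    require_50cm_arms: bool = False,
) -> dict:
    """Fit all three models across chromosomes and select the best.

    ``records`` is the frame of :func:`observed_statistics` outputs (one
    row per chromosome, columns d_half_ratio / m2_ratio / m3_ratio / c /
    m2_valid / species).  Chromosomes without a valid M2 statistic are
    excluded from M2's regression but retained for M1/M3.  Species-level
    support counts the best adjusted R2 within species having at least
    ``min_species_chromosomes`` chromosomes.  Returns a dict with
    per-model :class:`ModelFitResult`, a Table-1-like frame, the selected
    model id and species support counts.
    """
    df = records.copy()
    if require_50cm_arms:
        df = df[df["m2_valid"]]
    fits: dict[str, ModelFitResult] = {}
    spec = {
        "M1": ("d_half_ratio", None),
        "M2": ("m2_ratio", "c"),
        "M3": ("m3_ratio", "c"),
    }
    for mid, (obs_col, pred_col) in spec.items():
        sub = df.dropna(subset=[obs_col] + ([pred_col] if pred_col else []))
        if mid == "M2":
            sub = sub[sub["m2_valid"]]
        if len(sub) < 3:
            continue
        observed = sub[obs_col].to_numpy(dtype=float)
        predicted = (
            sub[pred_col].to_numpy(dtype=float)
            if pred_col
            else np.full(len(sub), 0.5)
        )
        fits[mid] = _ols_fit(observed, predicted, mid)
    if not fits:
        raise ValueError("no model could be fitted (need >= 3 chromosomes)")

    support = {mid: 0 for mid in fits}
    if "species" in df.columns:
        for _, grp in df.groupby("species"):
            if len(grp) < min_species_chromosomes:
                continue
            best_mid, best_r2 = None, -np.inf
            for mid, (obs_col, pred_col) in spec.items():
                if mid not in fits:
                    continue
                sub = grp.dropna(subset=[obs_col] + ([pred_col] if pred_col else []))
                if mid == "M2":
                    sub = sub[sub["m2_valid"]]
                if len(sub) < 3:
                    continue
                observed = sub[obs_col].to_numpy(dtype=float)
                predicted = (
                    sub[pred_col].to_numpy(dtype=float)
                    if pred_col
                    else np.full(len(sub), 0.5)
                )
                r2 = _ols_fit(observed, predicted, mid).adj_r2
                if np.isfinite(r2) and r2 > best_r2:
                    best_mid, best_r2 = mid, r2
            if best_mid is not None:
                support[best_mid] += 1

    selected = max(fits, key=lambda mid: (np.nan_to_num(fits[mid].adj_r2, nan=-np.inf)))
    table = pd.DataFrame(
        [
            {
                "model": mid,
                "adj_R2": f.adj_r2,
                "p": f.p_value,
                "AIC": f.aic,
                "BIC": f.bic,
                "n": f.n_chromosomes,
                "species_support": support.get(mid, 0),
            }
            for mid, f in fits.items()
        ]
    )
    return {"fits": fits, "table": table, "selected": selected, "support": support}


def centromere_suppression_test(
    m: MareyMap,
    centromere: CentromereRecord,
    span: float = 0.3,
    window_size: float = 1e5,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    grid_step: float = 1000.0,
    max_grid: int = 4096,
) -> SuppressionTest:
    """Bootstrap test of local recombination suppression at the centromere.

    Markers are resampled with replacement; each replicate refits the
    Marey function and yields (rate in the centromere window - chromosome
    mean rate).  Suppression is significant when the upper bound of the
    percentile interval is below zero.
    """
    if centromere.oriented_position is None:
        raise ValueError("centromere must be oriented")
    pos = centromere.oriented_position
    if not 0.0 <= pos <= m.chromosome_length:
        raise ValueError("centromere window outside chromosome coverage")
    rng = rng if rng is not None else np.random.default_rng(seed)
    fit = fit_marey(m, span=span, grid_step=grid_step, max_grid=max_grid)
    land = recombination_rates(fit, window_size)
    point_rate = land.rate_at(pos)
    point_mean = land.mean_rate()
    edges = np.append(land.starts, land.ends[-1])
    widx = min(int(np.searchsorted(land.ends, pos, side="right")), land.n_windows - 1)
    mm = m.deduplicated()
    x, y = mm.genomic_pos, mm.genetic_pos - mm.genetic_pos.min()
    n = x.shape[0]
    diffs = np.empty(n_boot)
    b = 0
    while b < n_boot:
        idx = np.sort(rng.integers(0, n, size=n))
        if np.unique(x[idx]).shape[0] < 3:
            continue
        pred = loess_predict(x[idx], y[idx], edges, span=span, degree=2)
        cm_edges = np.maximum.accumulate(np.clip(pred, 0.0, mm.map_length_raw))
        rates = np.maximum(np.diff(cm_edges), 0.0) / (np.diff(edges) / 1e6)
        w = np.diff(edges)
        diffs[b] = rates[widx] - float(np.sum(rates * w) / np.sum(w))
        b += 1
    alpha = (1.0 - level) / 2.0
    lo = float(np.percentile(diffs, 100 * alpha))
    hi = float(np.percentile(diffs, 100 * (1 - alpha)))
    return SuppressionTest(
        species=m.species,
        chromosome=m.chromosome,
        rate_at_centromere=point_rate,
        chromosome_mean_rate=point_mean,
        ci_low=lo,
        ci_high=hi,
        significant=hi < 0.0,
        zero_rate=point_rate == 0.0,
        n_bootstrap=n_boot,
    )


def orientation_check(landscape: Landscape, centromere: CentromereRecord) -> bool:
    """True when the rate at the oriented centromere position exceeds the
    rate at the mirrored position — the centromere was likely mapped on
    the wrong side.  Metacentric chromosomes (c = 0.5) are never flagged."""
    if centromere.oriented_position is None:
        raise ValueError("centromere must be oriented")
    if centromere.centromeric_index == 0.5:
        return False
    L = landscape.chromosome_length
    pos = centromere.oriented_position
    mirror = L - pos
    return landscape.rate_at(pos) > landscape.rate_at(mirror)
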