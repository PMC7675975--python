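"""Validation against manual annotations.

Automatically detected objects are matched one-to-one to manually annotated
objects by centroid distance d = sqrt(dCx^2 + dCy^2); matched pairs are true
positives, unmatched manual objects false negatives and unmatched automatic
objects false positives.  From the counts: sensitivity = TP/(TP+FN),
precision = TP/(TP+FP), FNR = FN/(FN+TP), F1 = 2TP/(2TP+FP+FN).  Agreement
of paired size measurements is summarized Bland-Altman style as the mean
relative difference with its t-based 95% confidence interval.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist


@dataclass
class DetectionMatch:
    """One-to-one centroid matching between manual and automatic objects."""

    pairs: list[tuple[int, int, float]]  # (manual_idx, auto_idx, distance_px)
    tp: int
    fp: int
    fn: int


@dataclass
class PerformanceMetrics:
    """Detection quality; fields are None when their denominator is empty."""

    sensitivity: float | None
    precision: float | None
    fnr: float | None
    f1: float | None


@dataclass
class BlandAltman:
    """Mean relative difference (%) of paired measurements, with 95% CI."""

    mean_relative_difference: float
    ci95: tuple[float, float]
    n: int


def match_objects(
    manual: np.ndarray, auto: np.ndarray, max_dist_px: float
) -> DetectionMatch:
    """Greedy globally-minimal-distance one-to-one matching.

    Repeatedly pairs the closest unmatched (manual, auto) centroids with
    distance <= ``max_dist_px``; leftovers become false negatives (manual)
    and false positives (auto).  Deterministic and near-optimal at histology
    densities, where objects are far apart relative to localization error.
    """
    if max_dist_px < 0:
        raise ValueError("max_dist_px must be non-negative")
    manual = np.asarray(manual, dtype=float).reshape(-1, 2)
    auto = np.asarray(auto, dtype=float).reshape(-1, 2)
    pairs: list[tuple[int, int, float]] = []
    if len(manual) and len(auto):
        d = cdist(manual, auto)
        order = np.argsort(d, axis=None, kind="stable")
        used_m = np.zeros(len(manual), dtype=bool)
        used_a = np.zeros(len(auto), dtype=bool)
        for flat in order:
            i, j = divmod(int(flat), len(auto))
            if d[i, j] > max_dist_px:
                break
            if used_m[i] or used_a[j]:
                continue
            used_m[i] = used_a[j] = True
            pairs.append((i, j, float(d[i, j])))
    tp = len(pairs)
    return DetectionMatch(pairs=pairs, tp=tp, fp=len(auto) - tp, fn=len(manual) - tp)


def performance(match: DetectionMatch) -> PerformanceMetrics:
    """Sensitivity, precision, false-negative rate and F1 from a matching."""
    tp, fp, fn = match.tp, match.fp, match.fn
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    prec = tp / (tp + fp) if (tp + fp) > 0 else None
    fnr = fn / (fn + tp) if (fn + tp) > 0 else None
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else None
    return PerformanceMetrics(sensitivity=sens, precision=prec, fnr=fnr, f1=f1)


def bland_altman(manual_vals, auto_vals) -> BlandAltman:
    """Mean percentage deviation of automatic from manual measurements.

    Per pair: 100 * (auto - manual) / manual.  Pairs with manual value 0 are
    excluded with a warning.  The 95% CI of the mean uses the t distribution
    with n-1 degrees of freedom (zero width when the spread is zero).
    """
    manual = np.asarray(manual_vals, dtype=float)
    auto = np.asarray(auto_vals, dtype=float)
    if manual.shape != auto.shape:
        raise ValueError("manual and auto value lists must be paired")
    nonzero = manual != 0
    if not nonzero.all():
        warnings.warn(f"excluding {np.count_nonzero(~nonzero)} pair(s) with manual value 0")
    manual, auto = manual[nonzero], auto[nonzero]
    if len(manual) < 3:
        raise ValueError("need at least 3 valid pairs")
    rel = 100.0 * (auto - manual) / manual
    mean = float(rel.mean())
    sd = float(rel.std(ddof=1))
    half = stats.t.ppf(0.975, len(rel) - 1) * sd / np.sqrt(len(rel))
    return BlandAltman(
        mean_relative_difference=mean, ci95=(mean - half, mean + half), n=len(rel)
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation (convenience wrapper; routine statistics)."""
    r, p = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


def icc_two_way_mixed(ratings: np.ndarray) -> float:
    """Two-way mixed, absolute-agreement, single-measure ICC (ICC(A,1)).

    ``ratings`` is (subjects x raters).  Thin convenience over the standard
    mean-squares formulation.
    """
    x = np.asarray(ratings, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ms_r = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_c = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand) ** 2).sum()
    ms_e = sse / ((n - 1) * (k - 1))
    return float((ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n))
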