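"""Mapping-quality metrics between real and estimated intracranial segments.

Three per-sensor metrics quantify how well an estimated segment tracks the
real one: mean squared error, cosine similarity and the Pearson correlation
coefficient.  Reports aggregate them per sensor, then per segment, then per
subject, and finally across subjects, matching the layout of the published
per-subject tables.

A per-sensor trace is a length-L time series; metrics operate on a (real,
estimated) pair of such traces.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MappingReport",
    "mse",
    "cossim",
    "pcorr",
    "evaluate_mapping",
    "mean_of_column",
    "lsq_baseline",
    "report_to_frame",
]

logger = logging.getLogger(__name__)


def _as_trace(y, name: str) -> np.ndarray:
    arr = np.asarray(y, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError(f"{name} must be a 1-D series, got shape {arr.shape}")
    return arr


def mse(y, y_est) -> float:
    """Mean squared error (1/L) sum (y_l - y~_l)^2 for one sensor trace."""
    a, b = _as_trace(y, "y"), _as_trace(y_est, "y_est")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def cossim(y, y_est) -> float:
    """Cosine similarity: inner product over the product of Euclidean norms."""
    a, b = _as_trace(y, "y"), _as_trace(y_est, "y_est")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero-norm trace")
    return float(np.dot(a, b) / (na * nb))


def pcorr(y, y_est) -> float:
    """Pearson correlation: cov(y, y~) / (sigma_y * sigma_y~).

    Population (1/L) convention for covariance and standard deviations; the
    convention cancels in the ratio.
    """
    a, b = _as_trace(y, "y"), _as_trace(y_est, "y_est")
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    ac, bc = a - a.mean(), b - b.mean()
    sa, sb = np.sqrt(np.mean(ac**2)), np.sqrt(np.mean(bc**2))
    if sa == 0.0 or sb == 0.0:
        raise ValueError("Pearson correlation undefined for a zero-variance trace")
    return float(np.mean(ac * bc) / (sa * sb))


@dataclass
class MappingReport:
    """Per-sensor metrics and their aggregates.

    ``per_segment_per_sensor`` maps each metric name to an (n_segments,
    n_sensors) array per subject; ``per_subject_means`` averages over sensors
    then segments; ``cohort_mean`` averages the subject means.
    """

    per_segment_per_sensor: dict[str, dict[str, np.ndarray]]
    per_subject_means: dict[str, dict[str, float]]
    cohort_mean: dict[str, float]
    subject_ids: list[str] = field(default_factory=list)


_METRICS = {"MSE": mse, "PCORR": pcorr, "COSSIM": cossim}


def evaluate_mapping(pairs) -> MappingReport:
    """Evaluate (Y, Y_est) pairs of (L, n_sensors) arrays.

    ``pairs`` is either a list of pairs (treated as one unnamed subject) or a
    mapping ``subject_id -> list of pairs``.  Aggregation order: sensors ->
    segments -> subjects.
    """
    if not isinstance(pairs, dict):
        pairs = {"subject": pairs}
    if not pairs or any(len(v) == 0 for v in pairs.values()):
        raise ValueError("evaluate_mapping requires at least one (Y, Y_est) pair")

    per_subject_raw: dict[str, dict[str, np.ndarray]] = {}
    per_subject_means: dict[str, dict[str, float]] = {}
    for sid, subject_pairs in pairs.items():
        values = {name: [] for name in _METRICS}
        for y, y_est in subject_pairs:
            y, y_est = np.asarray(y, float), np.asarray(y_est, float)
            if y.shape != y_est.shape or y.ndim != 2:
                raise ValueError(
                    f"subject {sid}: pair shapes {y.shape} vs {y_est.shape} "
                    "(expected equal (L, n_sensors))"
                )
            for name, fn in _METRICS.items():
                values[name].append([fn(y[:, m], y_est[:, m]) for m in range(y.shape[1])])
        per_subject_raw[sid] = {name: np.asarray(v) for name, v in values.items()}
        per_subject_means[sid] = {
            name: float(arr.mean(axis=1).mean()) for name, arr in per_subject_raw[sid].items()
        }
    cohort_mean = {
        name: float(np.mean([m[name] for m in per_subject_means.values()]))
        for name in _METRICS
    }
    return MappingReport(per_subject_raw, per_subject_means, cohort_mean, list(pairs))


def mean_of_column(values, rounding: int | None = None) -> float:
    """Arithmetic mean, optionally rounded half-away-from-zero.

    This is the aggregation used for the "Mean" row of per-subject tables;
    half-away-from-zero matches how such tables are conventionally printed.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("mean_of_column: empty input")
    m = float(values.mean())
    if rounding is None:
        return m
    factor = 10.0**rounding
    return math.copysign(math.floor(abs(m) * factor + 0.5), m) / factor


def report_to_frame(report: MappingReport, rounding: int = 3) -> pd.DataFrame:
    """Render a MappingReport as a subject-rows / metric-columns table with a
    Mean row, mirroring the published layout."""
    rows = {sid: report.per_subject_means[sid] for sid in report.subject_ids}
    frame = pd.DataFrame.from_dict(rows, orient="index")[list(_METRICS)]
    frame.loc["Mean"] = {
        name: mean_of_column(frame[name].to_numpy(), rounding) for name in _METRICS
    }
    return frame


def lsq_baseline(train_pairs, test_inputs) -> np.ndarray:
    """Per-sensor ordinary-least-squares mapping from scalp to intracranial
    samples, as a sanity reference for the learned translation.

    Each time sample's scalp vector (length M, plus intercept) predicts each
    intracranial sensor value via an independent linear map.  ``train_pairs``
    is a list of (X, Y) with X (L, M) and Y (L, Mbar); ``test_inputs`` is an
    array (n, L, M).  Returns estimated segments (n, L, Mbar).  Rank-deficient
    designs fall back to the minimum-norm solution.
    """
    xs = np.concatenate([np.asarray(x, float) for x, _ in train_pairs], axis=0)
    ys = np.concatenate([np.asarray(y, float) for _, y in train_pairs], axis=0)
    design = np.column_stack([xs, np.ones(len(xs))])
    coef, _, rank, _ = np.linalg.lstsq(design, ys)
    if rank < design.shape[1]:
        logger.info("lsq_baseline: rank-deficient design (rank %d < %d); "
                    "minimum-norm solution used", rank, design.shape[1])
    test = np.asarray(test_inputs, float)
    single = test.ndim == 2
    if single:
        test = test[None]
    n, L, M = test.shape
    flat = np.column_stack([test.reshape(n * L, M), np.ones(n * L)])
    out = (flat @ coef).reshape(n, L, -1)
    return out[0] if single else out
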