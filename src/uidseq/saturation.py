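"""Library-complexity saturation curves and yield extrapolation.

A saturation curve plots unique reads (consensus reads after UID-family
collapse) against total raw reads, built by nested subsampling: each
subsample extends the previous one, so the curve is monotone by
construction.  Yields extrapolate with a square-root model

    unique = a * sqrt(total) + b,

fitted by ordinary least squares, and unique coverage follows unique reads
linearly (coverage = s * unique + c).  Together the two models answer the
planning question "what detection limit does allocating T raw reads buy?"
since the detection limit at a position is the reciprocal of its unique
coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .consensus import TaggedRead, collapse_reads


@dataclass(frozen=True)
class SaturationCurve:
    """(total reads, unique reads) points from nested subsampling."""

    totals: tuple[int, ...]
    uniques: tuple[int, ...]
    sample_id: str = ""
    step: int = 0

    def __post_init__(self):
        t, u = np.asarray(self.totals), np.asarray(self.uniques)
        if len(t) != len(u):
            raise ValueError("totals and uniques differ in length")
        if len(t) and (np.diff(t) <= 0).any():
            raise ValueError("totals must be strictly increasing")
        if (u > t).any():
            raise ValueError("unique reads cannot exceed total reads")


@dataclass(frozen=True)
class YieldModel:
    """unique = a * sqrt(total) + b, with a residual summary."""

    a: float
    b: float
    rmse: float
    n_points: int


@dataclass(frozen=True)
class CoverageModel:
    """unique coverage = slope * unique reads + intercept."""

    slope: float
    intercept: float
    rmse: float
    n_points: int


def subsample_curve(
    reads: Sequence[TaggedRead],
    step: int,
    seed: int,
    mode: str = "directional",
    min_family_size: int = 3,
    sample_id: str = "",
) -> SaturationCurve:
    """Nested subsampling curve: collapse the first m reads of a seeded
    shuffle for every multiple m of ``step``.

    Because each subsample extends the previous one the unique-read count
    is non-decreasing for any seed.  If ``step`` exceeds the read count a
    single endpoint (all reads) is returned.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    n = len(reads)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    totals = list(range(step, n + 1, step))
    if not totals:
        totals = [n]
    uniques = []
    for m in totals:
        subset = [reads[i] for i in order[:m]]
        _, consensus = collapse_reads(subset, mode=mode, min_family_size=min_family_size)
        uniques.append(len(consensus))
    return SaturationCurve(
        totals=tuple(totals), uniques=tuple(uniques), sample_id=sample_id, step=step
    )


def fit_sqrt_model(
    curves: SaturationCurve | Sequence[SaturationCurve],
    average_per_total: bool = False,
) -> YieldModel:
    """Least-squares fit of unique reads on sqrt(total reads), with intercept.

    ``curves`` may be a single curve or several; points are pooled by
    default.  With ``average_per_total=True`` the unique counts are first
    averaged across curves at each distinct total (useful when fitting a
    cohort-level model).
    """
    if isinstance(curves, SaturationCurve):
        curves = [curves]
    totals = np.concatenate([np.asarray(c.totals, dtype=float) for c in curves])
    uniques = np.concatenate([np.asarray(c.uniques, dtype=float) for c in curves])
    if average_per_total:
        uniq_totals = np.unique(totals)
        uniques = np.array([uniques[totals == t].mean() for t in uniq_totals])
        totals = uniq_totals
    if len(np.unique(totals)) < 2:
        raise ValueError("need at least two distinct totals to fit the model")
    X = np.column_stack([np.sqrt(totals), np.ones_like(totals)])
    coef, *_ = np.linalg.lstsq(X, uniques, rcond=None)
    resid = uniques - X @ coef
    return YieldModel(
        a=float(coef[0]),
        b=float(coef[1]),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n_points=len(totals),
    )


def predict_unique(model: YieldModel, total_reads: float) -> float:
    """Predicted unique reads at a raw-read allocation, floored at 0."""
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    return max(0.0, model.a * np.sqrt(total_reads) + model.b)


def fit_coverage_model(
    unique_reads: Sequence[float], unique_coverage: Sequence[float]
) -> CoverageModel:
    """OLS fit of unique coverage on unique reads across samples."""
    u = np.asarray(unique_reads, dtype=float)
    c = np.asarray(unique_coverage, dtype=float)
    if len(u) != len(c):
        raise ValueError("inputs differ in length")
    if len(np.unique(u)) < 2:
        raise ValueError("need at least two distinct unique-read values")
    X = np.column_stack([u, np.ones_like(u)])
    coef, *_ = np.linalg.lstsq(X, c, rcond=None)
    resid = c - X @ coef
    return CoverageModel(
        slope=float(coef[0]),
        intercept=float(coef[1]),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n_points=len(u),
    )


def predict_coverage(model: CoverageModel, unique_reads: float) -> float:
    """Predicted mean unique coverage at a unique-read yield."""
    return model.slope * unique_reads + model.intercept
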