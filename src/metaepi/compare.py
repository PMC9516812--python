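"""Dissimilarities between methylome profiles, ordination, and SNMV.

Single nucleotide methylation variation (SNMV) is the between-sample
difference in per-site methylation fractions, restricted to positions covered
deeply enough (20x per strand by default) in *every* sample so that missing
coverage never masquerades as epigenetic signal. Profile dissimilarities are
pairwise-complete for the same reason: entries missing in either member of a
pair are dropped, not zero-filled.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DistanceMatrix, ValidationError
from .modcall import ModCall

__all__ = [
    "Ordination",
    "SNMVMatrix",
    "kulczynski",
    "bray_curtis",
    "profile_distance_matrix",
    "pcoa",
    "build_snmv",
    "site_set_intersections",
]


def _pairwise_complete(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    return x[keep], y[keep]


def kulczynski(x: Sequence[float], y: Sequence[float]) -> float:
    """Quantitative Kulczynski dissimilarity, pairwise-complete.

    d = 1 - (sum(min(x,y))/sum(x) + sum(min(x,y))/sum(y)) / 2.
    NaN when either vector sums to zero (undefined, reported missing).
    """
    x, y = _pairwise_complete(x, y)
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("vectors must be non-negative")
    sx, sy = x.sum(), y.sum()
    if sx == 0 or sy == 0:
        return float("nan")
    smin = np.minimum(x, y).sum()
    return float(1.0 - 0.5 * (smin / sx + smin / sy))


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), pairwise-complete."""
    x, y = _pairwise_complete(x, y)
    if (x < 0).any() or (y < 0).any():
        raise ValidationError("vectors must be non-negative")
    denom = (x + y).sum()
    if denom == 0:
        return float("nan")
    return float(np.abs(x - y).sum() / denom)


_METRICS = {"kulczynski": kulczynski, "braycurtis": bray_curtis}


def profile_distance_matrix(
    profiles: Mapping[str, Mapping[str, float]] | pd.DataFrame,
    metric: str = "kulczynski",
) -> DistanceMatrix:
    """All-pairs dissimilarity over labelled feature dicts (NaN = missing)."""
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    fn = _METRICS[metric]
    if isinstance(profiles, pd.DataFrame):
        table = profiles.astype(float)
    else:
        table = pd.DataFrame.from_dict(dict(profiles), orient="index").astype(float)
    labels = list(table.index.astype(str))
    vals = table.to_numpy()
    n = len(labels)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        out[i, j] = out[j, i] = fn(vals[i], vals[j])
    if np.isnan(out).any():
        raise ValidationError("undefined dissimilarity for some pair (zero-sum vector)")
    return DistanceMatrix(labels, out)


@dataclass
class Ordination:
    """Classical-scaling (PCoA) result."""

    labels: list[str]
    coordinates: np.ndarray  # n_objects x n_positive_axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives retained)
    proportion_explained: np.ndarray  # over positive eigenvalues


def pcoa(dm: DistanceMatrix) -> Ordination:
    """Principal coordinate analysis by classical scaling.

    Double-centers -D^2/2, eigendecomposes, and keeps coordinates for positive
    eigenvalues scaled by sqrt(lambda). Negative eigenvalues (non-Euclidean
    input) are retained in the report, uncorrected. Axis signs are fixed by
    forcing each axis's largest-magnitude loading positive.
    """
    d = np.asarray(dm.values, dtype=float)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(abs(eigvals[0]), 1.0) * 1e-12
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    for a in range(coords.shape[1]):
        i_max = np.argmax(np.abs(coords[:, a]))
        if coords[i_max, a] < 0:
            coords[:, a] = -coords[:, a]
    pos_sum = eigvals[pos].sum()
    prop = eigvals[pos] / pos_sum if pos_sum > 0 else eigvals[pos]
    return Ordination(list(dm.labels), coords, eigvals, prop)


@dataclass
class SNMVMatrix:
    """Per-site methylation fractions across samples, complete rows only."""

    positions: list[tuple[str, int, str]]  # (contig, position, strand)
    samples: list[str]
    fractions: np.ndarray  # len(positions) x len(samples)
    min_depth: int = 20
    binary_threshold: float = 0.5

    @property
    def binary(self) -> np.ndarray:
        """Methylated = fraction strictly greater than the threshold."""
        return self.fractions > self.binary_threshold

    def distance_matrix(self, metric: str = "braycurtis") -> DistanceMatrix:
        table = pd.DataFrame(self.fractions.T, index=self.samples)
        return profile_distance_matrix(table, metric=metric)


def build_snmv(
    calls_by_sample: Mapping[str, Iterable[ModCall]],
    min_depth: int = 20,
) -> SNMVMatrix:
    """Site x sample methylation-fraction matrix over commonly covered sites.

    A site enters only when every sample covers it with >= ``min_depth`` reads
    on that strand and reports a fraction; rows are sorted by coordinate.
    """
    samples = sorted(calls_by_sample)
    if len(samples) < 2:
        raise ValidationError("SNMV needs at least two samples")
    per_sample: dict[str, dict[tuple[str, int, str], float]] = {}
    for s in samples:
        d: dict[tuple[str, int, str], float] = {}
        for c in calls_by_sample[s]:
            r = c.record
            if r.coverage >= min_depth and r.frac is not None:
                d[(r.contig_id, r.position, r.strand)] = r.frac
        per_sample[s] = d
    common = set(per_sample[samples[0]])
    for s in samples[1:]:
        common &= set(per_sample[s])
    positions = sorted(common)
    if not positions:
        warnings.warn("no positions covered at required depth in all samples")
    fractions = np.array(
        [[per_sample[s][p] for s in samples] for p in positions], dtype=float
    ).reshape(len(positions), len(samples))
    return SNMVMatrix(positions, samples, fractions, min_depth=min_depth)


def site_set_intersections(snmv: SNMVMatrix) -> dict[tuple[str, ...], int]:
    """Exclusive intersection cardinalities of methylated-site sets (UpSet).

    Keys are the exact sample combinations in which a site is methylated;
    sites methylated in no sample are not reported.
    """
    out: dict[tuple[str, ...], int] = {}
    binary = snmv.binary
    for row in binary:
        combo = tuple(s for s, m in zip(snmv.samples, row) if m)
        if combo:
            out[combo] = out.get(combo, 0) + 1
    return out
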