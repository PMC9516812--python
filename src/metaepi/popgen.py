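"""Within- and between-sample population genetics from pileup allele counts.

The SNP rule: a locus is polymorphic in a sample when some non-reference
allele is supported by frequency > 1% *and* at least four reads; the SNP set
of a genome is the union over samples.

Nucleotide diversity follows the pooled-read estimator with the small-sample
correction: pi_j = (n/(n-1)) * (1 - sum_a f_a^2) at depth n. Population
differentiation is a Hudson-style ratio-of-averages:

    F_ST = 1 - mean(pi_X + pi_Y) / (2 * mean(pi_between)),
    pi_between(j) = 1 - sum_a f_a^X f_a^Y

over the region covered in both samples (no small-sample correction between
samples: cross-sample draws are independent). Ratio-of-averages is used
rather than averaging per-locus ratios because it stays stable when most
sites carry little diversity.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

__all__ = [
    "SNP_MIN_FREQ",
    "SNP_MIN_READS",
    "call_snps",
    "pi",
    "fst",
    "fst_from_frequencies",
    "shannon",
    "mappability",
    "correlate_methylome_fst",
    "mantel",
]

SNP_MIN_FREQ = 0.01
SNP_MIN_READS = 4

_BASES = ["nA", "nC", "nG", "nT"]
_BASE_OF = {"A": "nA", "C": "nC", "G": "nG", "T": "nT"}


def call_snps(
    ac: pd.DataFrame,
    min_freq: float = SNP_MIN_FREQ,
    min_reads: int = SNP_MIN_READS,
) -> pd.DataFrame:
    """SNP loci: any sample with a non-reference allele at freq > 1% and >= 4 reads.

    Returns one row per (contig, position) in the union, with the set of
    samples in which the locus is polymorphic.
    """
    counts = ac[_BASES].to_numpy(dtype=float)
    depth = counts.sum(axis=1)
    ref_col = ac["ref_base"].map(_BASE_OF)
    ref_counts = np.array([row[_BASES.index(c)] for row, c in zip(counts, ref_col)])
    alt = counts.copy()
    for i, c in enumerate(ref_col):
        alt[i, _BASES.index(c)] = 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = alt / depth[:, None]
    is_poly = ((alt_freq > min_freq) & (alt >= min_reads)).any(axis=1) & (depth > 0)
    poly = ac.loc[is_poly, ["contig_id", "position", "sample_id"]]
    grouped = (
        poly.groupby(["contig_id", "position"])["sample_id"]
        .apply(lambda s: tuple(sorted(set(s))))
        .reset_index()
        .rename(columns={"sample_id": "samples"})
    )
    return grouped


def _per_position_frequencies(sub: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    counts = sub[_BASES].to_numpy(dtype=float)
    depth = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(depth[:, None] > 0, counts / depth[:, None], 0.0)
    return freqs, depth


def pi(ac: pd.DataFrame, sample_id: str, min_depth: int = 10) -> float:
    """Genome nucleotide diversity for one sample (mean over covered positions).

    Positions with depth below ``min_depth`` are not covered; positions with
    depth < 2 are skipped (the correction is undefined). Monomorphic covered
    positions contribute 0.
    """
    sub = ac[ac["sample_id"] == sample_id]
    freqs, depth = _per_position_frequencies(sub)
    keep = (depth >= max(min_depth, 2))
    if not keep.any():
        return float("nan")
    f, n = freqs[keep], depth[keep]
    per_pos = (n / (n - 1.0)) * (1.0 - (f ** 2).sum(axis=1))
    return float(per_pos.mean())


def fst(
    ac: pd.DataFrame,
    sample_x: str,
    sample_y: str,
    min_depth: int = 10,
) -> float:
    """Hudson-style ratio-of-averages F_ST between two samples.

    Uses positions covered at >= ``min_depth`` in both samples. Returns NaN
    when mean between-sample diversity is zero (no divergence information).
    """
    if sample_x == sample_y:
        return 0.0
    sx = ac[ac["sample_id"] == sample_x].set_index(["contig_id", "position"])
    sy = ac[ac["sample_id"] == sample_y].set_index(["contig_id", "position"])
    shared = sx.index.intersection(sy.index)
    if len(shared) == 0:
        return float("nan")
    fx, nx = _per_position_frequencies(sx.loc[shared].reset_index())
    fy, ny = _per_position_frequencies(sy.loc[shared].reset_index())
    keep = (nx >= max(min_depth, 2)) & (ny >= max(min_depth, 2))
    if not keep.any():
        return float("nan")
    fx, nx = fx[keep], nx[keep]
    fy, ny = fy[keep], ny[keep]
    pi_x = (nx / (nx - 1.0)) * (1.0 - (fx ** 2).sum(axis=1))
    pi_y = (ny / (ny - 1.0)) * (1.0 - (fy ** 2).sum(axis=1))
    pi_between = 1.0 - (fx * fy).sum(axis=1)
    mean_between = pi_between.mean()
    if mean_between == 0:
        return float("nan")
    return float(1.0 - (pi_x.mean() + pi_y.mean()) / (2.0 * mean_between))


def fst_from_frequencies(px: Sequence[float], py: Sequence[float]) -> float:
    """Analytic F_ST from true biallelic frequencies (infinite-depth limit).

    The truth-set oracle for the estimator above: within-sample diversity
    2p(1-p) per locus, between-sample 1 - (px*py + (1-px)*(1-py)), combined
    as the same ratio of averages.
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    pi_x = 2.0 * px * (1.0 - px)
    pi_y = 2.0 * py * (1.0 - py)
    pi_b = 1.0 - (px * py + (1.0 - px) * (1.0 - py))
    if pi_b.mean() == 0:
        return float("nan")
    return float(1.0 - (pi_x.mean() + pi_y.mean()) / (2.0 * pi_b.mean()))


def shannon(abundances: Sequence[float]) -> float:
    """Shannon diversity H = -sum p ln p over relative abundances."""
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValidationError("abundances must be non-negative")
    total = x.sum()
    if total == 0:
        return float("nan")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def mappability(mapped_reads: float, subsampled_total: float) -> float:
    """Percentage of subsampled reads that aligned."""
    if subsampled_total <= 0:
        raise ValidationError("total must be positive")
    if mapped_reads > subsampled_total:
        raise ValidationError("mapped reads exceed total")
    return 100.0 * mapped_reads / subsampled_total


def mantel(
    dx: np.ndarray,
    dy: np.ndarray,
    permutations: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel test: Pearson r between two square distance matrices with a
    label-permutation p-value (two-sided on |r|)."""
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    n = dx.shape[0]
    if dx.shape != (n, n) or dy.shape != (n, n):
        raise ValidationError("mantel needs two square matrices of equal size")
    iu = np.triu_indices(n, k=1)
    x, y = dx[iu], dy[iu]
    if x.std() == 0 or y.std() == 0:
        return (float("nan"), float("nan"))
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(permutations):
        perm = rng.permutation(n)
        yp = dy[np.ix_(perm, perm)][iu]
        if yp.std() == 0:
            continue
        if abs(np.corrcoef(x, yp)[0, 1]) >= abs(r_obs) - 1e-12:
            count += 1
    p = (count + 1) / (permutations + 1)
    return (r_obs, p)


def correlate_methylome_fst(
    methylome_d: Sequence[float],
    fst_values: Sequence[float],
    dx: np.ndarray | None = None,
    dy: np.ndarray | None = None,
    permutations: int = 9999,
    seed: int | None = None,
) -> tuple[float, float, float | None]:
    """Pearson correlation of methylome dissimilarity vs F_ST over sample pairs.

    Returns (r, p, mantel_p). The parametric p treats pairs as independent,
    which they are not (they share samples); when the two square matrices are
    supplied a Mantel permutation p is reported alongside.
    """
    x = np.asarray(methylome_d, dtype=float)
    y = np.asarray(fst_values, dtype=float)
    if x.size != y.size:
        raise ValidationError("pair vectors must align")
    if x.size < 3:
        raise ValidationError("need at least 3 sample pairs")
    if x.std() == 0 or y.std() == 0:
        return (float("nan"), float("nan"), None)
    r, p = stats.pearsonr(x, y)
    mantel_p = None
    if dx is not None and dy is not None:
        _, mantel_p = mantel(dx, dy, permutations=permutations, seed=seed)
    return (float(r), float(p), mantel_p)
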