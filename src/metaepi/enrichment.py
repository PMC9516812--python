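"""Motif density by genomic region and the gene-shuffle null.

The genome is partitioned into genic, regulatory (a strand-aware window
immediately upstream of each gene start, 100 bp by default), and intergenic
positions, with precedence genic > regulatory > intergenic. The null for
region enrichment keeps motif sites fixed and re-places, per strand, the
observed number of genes with the observed mean length uniformly without
overlap; densities are recomputed per replicate (500 by default). When the
null passes a Shapiro-Wilk normality check (p > 0.05) the observed density is
converted to a z-score and a two-sided normal p; otherwise an empirical
two-sided p is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .io import GeneTable, Genome, ValidationError
from .motifs import MotifSite

__all__ = [
    "REGIONS",
    "RegionPartition",
    "NullDistribution",
    "classify_regions",
    "region_density",
    "shuffle_null",
    "enrichment_test",
]

REGIONS = ("genic", "regulatory", "intergenic")
_CODE = {"intergenic": 0, "regulatory": 1, "genic": 2}


@dataclass
class RegionPartition:
    """Per-position region class for every contig (codes 0/1/2)."""

    classes: dict[str, np.ndarray]
    regulatory_length: int

    def region_lengths(self) -> dict[str, int]:
        out = {r: 0 for r in REGIONS}
        for arr in self.classes.values():
            for name, code in _CODE.items():
                out[name] += int((arr == code).sum())
        return out

    def class_at(self, contig_id: str, position: int) -> str:
        code = int(self.classes[contig_id][position])
        return {v: k for k, v in _CODE.items()}[code]


def classify_regions(genome: Genome, genes: GeneTable, regulatory_length: int = 100) -> RegionPartition:
    """Partition each contig into genic / regulatory / intergenic positions.

    The regulatory window sits on the 5' genomic side of each gene (upstream
    of start for + genes, downstream of end for - genes), truncated at contig
    edges; gene bodies take precedence, so a window overlapping a neighboring
    gene is truncated to the non-genic part. Overlapping genes are allowed and
    resolve to genic.
    """
    if regulatory_length < 0:
        raise ValidationError("regulatory length must be >= 0")
    classes: dict[str, np.ndarray] = {
        cid: np.zeros(len(seq), dtype=np.int8) for cid, seq in genome.contigs
    }
    for r in genes.df.itertuples(index=False):
        arr = classes[r.contig_id]
        if r.end > len(arr):
            raise ValidationError(f"gene {r.gene_id!r} exceeds contig length")
        arr[r.start : r.end] = _CODE["genic"]
    if regulatory_length > 0:
        for r in genes.df.itertuples(index=False):
            arr = classes[r.contig_id]
            if r.strand == "+":
                lo, hi = max(r.start - regulatory_length, 0), r.start
            else:
                lo, hi = r.end, min(r.end + regulatory_length, len(arr))
            window = arr[lo:hi]
            window[window == _CODE["intergenic"]] = _CODE["regulatory"]
    return RegionPartition(classes, regulatory_length)


def region_density(sites: Sequence[MotifSite], partition: RegionPartition) -> dict[str, float]:
    """Sites per kb of each region; the methylated-base coordinate decides the
    region of a site. Empty regions have NaN density."""
    counts = {r: 0 for r in REGIONS}
    code_to_name = {v: k for k, v in _CODE.items()}
    for s in sites:
        arr = partition.classes.get(s.contig_id)
        if arr is None:
            raise ValidationError(f"site on unknown contig {s.contig_id!r}")
        counts[code_to_name[int(arr[s.meth_position])]] += 1
    lengths = partition.region_lengths()
    return {
        r: (counts[r] * 1000.0 / lengths[r]) if lengths[r] > 0 else float("nan")
        for r in REGIONS
    }


def _place_genes(
    rng: np.random.Generator, L: int, n_genes: int, gene_len: int, max_tries: int = 1000
) -> np.ndarray | None:
    """Uniform non-overlapping placement of n genes of fixed length; None on failure."""
    if n_genes * gene_len > L:
        return None
    for _ in range(max_tries):
        starts = np.sort(rng.integers(0, L - gene_len + 1, size=n_genes))
        if n_genes < 2 or (np.diff(starts) >= gene_len).all():
            return starts
    return None


@dataclass
class NullDistribution:
    """Shuffle-null densities per region plus the observed value and the test."""

    observed: dict[str, float]
    null: dict[str, np.ndarray]
    shapiro_p: dict[str, float]
    z: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    method: dict[str, str] = field(default_factory=dict)
    skipped_replicates: int = 0


def shuffle_null(
    genome: Genome,
    genes: GeneTable,
    sites: Sequence[MotifSite],
    n_replicates: int = 500,
    regulatory_length: int = 100,
    seed: int | None = None,
) -> NullDistribution:
    """Region densities under random gene placement, motif sites held fixed.

    Each replicate places, per strand and per contig, the observed number of
    genes at the observed mean length (rounded), uniformly without overlap
    within the strand; region classes and densities are recomputed. Replicates
    whose placement is infeasible after retries are skipped and counted.
    """
    rng = np.random.default_rng(seed)
    observed_partition = classify_regions(genome, genes, regulatory_length)
    observed = region_density(sites, observed_partition)

    # per (contig, strand): gene count and mean length
    stats_by = {}
    for (cid, strand), grp in genes.df.groupby(["contig_id", "strand"]):
        lengths = (grp["end"] - grp["start"]).to_numpy()
        stats_by[(cid, strand)] = (len(grp), max(int(round(lengths.mean())), 1))

    contig_len = {cid: len(seq) for cid, seq in genome.contigs}
    site_pos: dict[str, np.ndarray] = {}
    for s in sites:
        site_pos.setdefault(s.contig_id, []).append(s.meth_position)
    site_pos = {cid: np.asarray(v, dtype=int) for cid, v in site_pos.items()}

    null: dict[str, list[float]] = {r: [] for r in REGIONS}
    skipped = 0
    for _ in range(n_replicates):
        placements: dict[str, list[tuple[np.ndarray, int, str]]] = {}
        ok = True
        for (cid, strand), (n_genes, mean_len) in sorted(stats_by.items()):
            starts = _place_genes(rng, contig_len[cid], n_genes, mean_len)
            if starts is None:
                ok = False
                break
            placements.setdefault(cid, []).append((starts, mean_len, strand))
        if not ok:
            skipped += 1
            continue
        # recompute classes and densities without the table plumbing
        counts = np.zeros(3, dtype=np.int64)
        lengths = np.zeros(3, dtype=np.int64)
        for cid, L in contig_len.items():
            arr = np.zeros(L, dtype=np.int8)
            for starts, glen, strand in placements.get(cid, []):
                for st in starts:
                    arr[st : st + glen] = _CODE["genic"]
            if regulatory_length > 0:
                for starts, glen, strand in placements.get(cid, []):
                    for st in starts:
                        if strand == "+":
                            lo, hi = max(st - regulatory_length, 0), st
                        else:
                            lo, hi = st + glen, min(st + glen + regulatory_length, L)
                        w = arr[lo:hi]
                        w[w == _CODE["intergenic"]] = _CODE["regulatory"]
            lengths += np.bincount(arr, minlength=3)[:3]
            if cid in site_pos:
                counts += np.bincount(arr[site_pos[cid]], minlength=3)[:3]
        for r in REGIONS:
            code = _CODE[r]
            null[r].append(
                counts[code] * 1000.0 / lengths[code] if lengths[code] > 0 else float("nan")
            )
    if skipped:
        warnings.warn(f"{skipped} shuffle replicates skipped (infeasible placement)")

    null_arr = {r: np.asarray(v, dtype=float) for r, v in null.items()}
    shapiro_p: dict[str, float] = {}
    for r in REGIONS:
        v = null_arr[r][~np.isnan(null_arr[r])]
        if v.size >= 3 and np.ptp(v) > 0:
            shapiro_p[r] = float(stats.shapiro(v).pvalue)
        else:
            shapiro_p[r] = float("nan")
    dist = NullDistribution(observed, null_arr, shapiro_p, skipped_replicates=skipped)
    enrichment_test(dist)
    return dist


def enrichment_test(dist: NullDistribution, min_replicates: int = 100) -> NullDistribution:
    """z -> p when the null is normal (Shapiro p > 0.05), empirical otherwise.

    Empirical two-sided p = (1 + #{|null - mean| >= |obs - mean|}) / (n + 1).
    A zero-variance null forces the empirical path with no z.
    """
    for r in REGIONS:
        v = dist.null[r][~np.isnan(dist.null[r])]
        obs = dist.observed[r]
        if v.size < min_replicates or np.isnan(obs):
            dist.z[r] = float("nan")
            dist.p[r] = float("nan")
            dist.method[r] = "insufficient"
            continue
        mu, sd = v.mean(), v.std(ddof=1)
        normal = (not np.isnan(dist.shapiro_p[r])) and dist.shapiro_p[r] > 0.05 and sd > 0
        if normal:
            z = (obs - mu) / sd
            dist.z[r] = float(z)
            dist.p[r] = float(2.0 * stats.norm.sf(abs(z)))
            dist.method[r] = "normal"
        else:
            dist.z[r] = float("nan") if sd == 0 else float((obs - mu) / sd)
            count = int((np.abs(v - mu) >= abs(obs - mu) - 1e-12).sum())
            dist.p[r] = float((1 + count) / (v.size + 1))
            dist.method[r] = "empirical"
    return dist
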