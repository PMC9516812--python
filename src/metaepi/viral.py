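"""Whole-genome bit-score clustering of viral genomes.

Genomes are compared by all-vs-all alignment hit tables (e.g. tBLASTx). With
AB the bit-score sum of all hits between genomes A and B, and AA, BB the
self-comparison sums, the Dice distance is

    D(A, B) = 1 - 2*AB / (AA + BB)

clamped to [0, 1]. Because alignment is not symmetric, AB and BA sums are
averaged when both directions are present. Trees are built from the distance
matrix by neighbor joining, and motif-density differences between clades are
assessed with a two-sided rank-sum test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .io import DistanceMatrix, ValidationError

__all__ = [
    "BitscoreSums",
    "aggregate_bitscores",
    "dice_distance",
    "neighbor_joining",
    "clade_density_association",
    "is_monophyletic",
]


@dataclass
class BitscoreSums:
    """Symmetrized pairwise and self bit-score sums."""

    genomes: list[str]
    self_sums: dict[str, float]
    pair_sums: dict[tuple[str, str], float]  # key sorted pair

    def ab(self, a: str, b: str) -> float:
        if a == b:
            return self.self_sums[a]
        return self.pair_sums.get(tuple(sorted((a, b))), 0.0)


def aggregate_bitscores(hits: pd.DataFrame) -> BitscoreSums:
    """Sum hit bit scores per genome pair; directions averaged when both present.

    Genomes lacking a self sum (AA) cannot be normalized and are excluded with
    a warning.
    """
    if (hits["bit_score"] < 0).any():
        raise ValidationError("negative bit score")
    directed = (
        hits.groupby(["query_genome_id", "subject_genome_id"])["bit_score"]
        .sum()
        .to_dict()
    )
    genomes = sorted(
        set(hits["query_genome_id"]) | set(hits["subject_genome_id"])
    )
    self_sums = {}
    for g in genomes:
        if (g, g) in directed:
            self_sums[g] = float(directed[(g, g)])
    dropped = [g for g in genomes if g not in self_sums]
    if dropped:
        warnings.warn(f"genomes without self-hits excluded: {dropped}")
    kept = [g for g in genomes if g in self_sums]
    pair_sums: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(kept, 2):
        vals = [directed[k] for k in ((a, b), (b, a)) if k in directed]
        if vals:
            pair_sums[(a, b)] = float(np.mean(vals))
    return BitscoreSums(kept, self_sums, pair_sums)


def dice_distance(sums: BitscoreSums) -> DistanceMatrix:
    """D(A,B) = 1 - 2*AB/(AA+BB), clamped to [0, 1]; D(A,A) = 0 exactly."""
    genomes = sums.genomes
    n = len(genomes)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a, b = genomes[i], genomes[j]
        aa, bb = sums.self_sums[a], sums.self_sums[b]
        if aa <= 0 or bb <= 0:
            raise ValidationError(f"non-positive self sum for {a!r} or {b!r}")
        d = 1.0 - 2.0 * sums.ab(a, b) / (aa + bb)
        out[i, j] = out[j, i] = min(max(d, 0.0), 1.0)
    return DistanceMatrix(genomes, out)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Q-matrix ties break toward the lowest label-index pair; negative branch
    lengths are clamped to zero with the deficit reported via a warning. The
    result is an unrooted tree written with a trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 labels")
    if not np.all(np.isfinite(dm.values)):
        raise ValidationError("non-finite distances")
    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in dm.labels]
    deficit = 0.0

    def _clamp(v: float) -> float:
        nonlocal deficit
        if v < 0:
            deficit += -v
            return 0.0
        return v

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        best = None
        best_q = np.inf
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        vi = _clamp(0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2)))
        vj = _clamp(d[i, j] - (0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))))
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = vi
        child_j.length = vj
        new = TreeNode(children=[child_i, child_j])
        keep = [k for k in range(m) if k not in (i, j)]
        dnew = np.zeros(len(keep))
        for a, k in enumerate(keep):
            dnew[a] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.vstack(
            [np.hstack([d[np.ix_(keep, keep)], dnew[:, None]]), np.hstack([dnew, [0.0]])]
        )
        nodes = [nodes[k] for k in keep] + [new]

    # final three nodes joined at an (unrooted) trifurcation
    (a, b, c) = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    a.length = _clamp(0.5 * (dab + dac - dbc))
    b.length = _clamp(0.5 * (dab + dbc - dac))
    c.length = _clamp(0.5 * (dac + dbc - dab))
    root = TreeNode(children=[a, b, c])
    if deficit > 0:
        warnings.warn(f"negative branch lengths clamped; total deficit {deficit:.6g}")
    return root


def is_monophyletic(tree: TreeNode, leaves: set[str]) -> bool:
    """True when some edge of the unrooted tree splits `leaves` from the rest."""
    all_leaves = {t.name for t in tree.tips()}
    if not leaves <= all_leaves:
        raise ValidationError("leaves not in tree")
    if leaves == all_leaves or len(leaves) == 1:
        return True
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if side == leaves or (all_leaves - side) == leaves:
            return True
    return False


def clade_density_association(
    densities: dict[str, float],
    clades: dict[str, str],
) -> dict | None:
    """Two-sided rank-sum test of per-genome motif density between two clades.

    Returns dict with statistic, p, and per-clade medians, or None when any
    clade has fewer than 2 members or fewer than 2 clades exist.
    """
    groups: dict[str, list[float]] = {}
    for g, clade in clades.items():
        if g in densities:
            groups.setdefault(clade, []).append(densities[g])
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        return None
    names = sorted(groups)
    if len(names) != 2:
        raise ValidationError("expected exactly two clades")
    xa, xb = groups[names[0]], groups[names[1]]
    res = stats.ranksums(xa, xb)
    return {
        "clades": names,
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "medians": {names[0]: float(np.median(xa)), names[1]: float(np.median(xb))},
    }
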