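"""IUPAC motif scanning and motif-level methylome profiling.

A methylome here is the per-genome, per-sample picture of which occurrences of
a methyltransferase target motif (e.g. GANTC, GATC) carry a modification
signal. Sites are scanned on both strands; a self-complementary motif such as
GANTC therefore yields two strand-sites per locus, and full vs hemimethylation
of a locus is decided by pairing the two strands.

Site status is three-valued (methylated / unmethylated / unevaluable); ratios
are computed over evaluable sites only, and a motif whose methylated ratio in
a genome-sample falls below 20% is treated as noise rather than a candidate
methylation motif.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import Genome, Kingdom, ValidationError
from .modcall import ModCall

__all__ = [
    "IUPAC",
    "MotifSpec",
    "MotifSite",
    "MethylomeProfile",
    "DiscoveredMotif",
    "revcomp",
    "revcomp_iupac",
    "is_palindromic",
    "scan_motif",
    "status_index",
    "motif_methylation_ratio",
    "is_candidate_motif",
    "breadth_filter",
    "BREADTH_THRESHOLDS",
    "build_5mer_profile",
    "pair_palindromic_sites",
    "motif_density",
    "depletion_score",
    "discover_context_motifs",
]

#: IUPAC nucleotide codes -> the set of concrete bases they match.
#: N in a *sequence* never matches any motif symbol (conservative policy).
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_SET_TO_IUPAC = {v: k for k, v in IUPAC.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of a concrete DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def revcomp_iupac(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern."""
    return pattern.translate(_COMPLEMENT)[::-1]


def is_palindromic(pattern: str) -> bool:
    """True when a motif's reverse complement is the same pattern."""
    return pattern.upper() == revcomp_iupac(pattern.upper())


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for sym in pattern:
        if sym not in IUPAC:
            raise ValidationError(f"invalid IUPAC symbol {sym!r}")
        bases = "".join(sorted(IUPAC[sym]))
        parts.append(f"[{bases}]")
    # lookahead so overlapping matches are all reported
    return re.compile(f"(?=({''.join(parts)}))")


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC motif with the 0-based offset of its methylated base."""

    iupac: str
    meth_offset: int
    mod_type: str = "m6A"

    def __post_init__(self) -> None:
        pattern = self.iupac.upper()
        object.__setattr__(self, "iupac", pattern)
        for sym in pattern:
            if sym not in IUPAC:
                raise ValidationError(f"invalid IUPAC symbol {sym!r} in motif {pattern!r}")
        if not (0 <= self.meth_offset < len(pattern)):
            raise ValidationError("meth_offset outside motif")

    def __len__(self) -> int:
        return len(self.iupac)


@dataclass(frozen=True)
class MotifSite:
    """One strand-occurrence of a motif, in plus-strand coordinates."""

    contig_id: str
    start: int  # plus-strand coordinate of the leftmost matched base
    strand: str
    motif: MotifSpec

    @property
    def meth_position(self) -> int:
        """Plus-strand coordinate of the methylated base of this occurrence."""
        if self.strand == "+":
            return self.start + self.motif.meth_offset
        return self.start + len(self.motif) - 1 - self.motif.meth_offset


@dataclass
class MethylomeProfile:
    """Per-genome-per-sample methylation ratios (motif-level and 5-mer)."""

    genome_id: str
    sample_id: str
    motif_ratios: dict[str, float | None] = field(default_factory=dict)
    fivemer_ratios: dict[str, float] = field(default_factory=dict)
    breadth_10x: float = 1.0


def scan_motif(genome: Genome, motif: MotifSpec) -> list[MotifSite]:
    """All occurrences of a motif on both strands, in plus-strand coordinates.

    Overlapping matches are all reported, and a degenerate palindrome yields
    two sites per locus (one per strand). Sequence N never matches.
    """
    fwd = _iupac_regex(motif.iupac)
    rev = _iupac_regex(revcomp_iupac(motif.iupac))
    sites: list[MotifSite] = []
    for cid, seq in genome.contigs:
        for m in fwd.finditer(seq):
            sites.append(MotifSite(cid, m.start(), "+", motif))
        for m in rev.finditer(seq):
            sites.append(MotifSite(cid, m.start(), "-", motif))
    sites.sort(key=lambda s: (s.contig_id, s.start, s.strand))
    return sites


def status_index(calls: Iterable[ModCall]) -> dict[tuple[str, int, str], ModCall]:
    """Index calls by (contig, plus-strand position, strand)."""
    return {(c.record.contig_id, c.record.position, c.record.strand): c for c in calls}


def site_status(site: MotifSite,
                index: Mapping[tuple[str, int, str], ModCall]) -> str:
    """Status of a motif site: a position with no call at all is unevaluable."""
    call = index.get((site.contig_id, site.meth_position, site.strand))
    if call is None:
        return "unevaluable"
    return call.status


def motif_methylation_ratio(
    sites: Sequence[MotifSite],
    index: Mapping[tuple[str, int, str], ModCall],
) -> float | None:
    """Fraction of evaluable sites that are methylated; None with no evaluable site."""
    n_meth = n_unmeth = 0
    for s in sites:
        st = site_status(s, index)
        if st == "methylated":
            n_meth += 1
        elif st == "unmethylated":
            n_unmeth += 1
    total = n_meth + n_unmeth
    if total == 0:
        return None
    return n_meth / total


#: motifs methylated in < 20% of evaluable sites are treated as noise
CANDIDATE_RATIO = 0.20


def is_candidate_motif(ratio: float | None) -> bool:
    return ratio is not None and ratio >= CANDIDATE_RATIO


#: minimum fraction of the genome covered at 10x for a genome-sample pair to
#: enter the methylome comparison, by kingdom
BREADTH_THRESHOLDS: dict[Kingdom, float] = {
    Kingdom.prokaryote: 0.20,
    Kingdom.eukaryote: 0.10,
    Kingdom.virus: 0.60,
    Kingdom.giant_virus: 0.20,
}


def breadth_filter(profile: MethylomeProfile, kingdom: Kingdom) -> bool:
    """Keep a genome-sample pair unless its 10x breadth is below threshold."""
    try:
        threshold = BREADTH_THRESHOLDS[Kingdom(kingdom)]
    except (KeyError, ValueError) as exc:
        raise ValidationError(f"unknown kingdom {kingdom!r}") from exc
    return profile.breadth_10x >= threshold


def build_5mer_profile(
    genome: Genome,
    index: Mapping[tuple[str, int, str], ModCall],
) -> dict[str, float]:
    """Per-5-mer methylation ratios over both strands.

    An occurrence of 5-mer w is the plus-strand window for a (+) center and
    the reverse-complemented window for a (-) center; it is evaluable when the
    center base's position-strand is evaluable. 5-mers with no evaluable
    occurrence are *missing*, never zero.
    """
    meth: dict[str, int] = {}
    total: dict[str, int] = {}
    seqs = dict(genome.contigs)
    for (cid, pos, strand), call in index.items():
        if call.status == "unevaluable":
            continue
        seq = seqs.get(cid)
        if seq is None or pos < 2 or pos + 3 > len(seq):
            continue
        window = seq[pos - 2 : pos + 3]
        if "N" in window:
            continue
        if strand == "-":
            window = revcomp(window)
        total[window] = total.get(window, 0) + 1
        if call.status == "methylated":
            meth[window] = meth.get(window, 0) + 1
    return {w: meth.get(w, 0) / n for w, n in total.items()}


def pair_palindromic_sites(
    sites: Sequence[MotifSite],
    index: Mapping[tuple[str, int, str], ModCall],
) -> dict[tuple[str, int], str]:
    """Full/hemi status per locus of a self-complementary motif.

    Returns (contig, locus start) -> status in {full, hemi, unmethylated,
    unevaluable}. A locus is *full* when both strand-sites are methylated,
    *hemi* when exactly one is; loci with any unevaluable strand and no
    methylated strand are unevaluable.
    """
    if not sites:
        return {}
    motif = sites[0].motif
    if not is_palindromic(motif.iupac):
        raise ValidationError(f"motif {motif.iupac!r} is not self-complementary")
    by_locus: dict[tuple[str, int], list[str]] = {}
    for s in sites:
        by_locus.setdefault((s.contig_id, s.start), []).append(site_status(s, index))
    out: dict[tuple[str, int], str] = {}
    for locus, statuses in by_locus.items():
        n_meth = statuses.count("methylated")
        n_uneval = statuses.count("unevaluable")
        if n_meth >= 2:
            out[locus] = "full"
        elif n_meth == 1:
            out[locus] = "hemi"
        elif n_uneval > 0:
            out[locus] = "unevaluable"
        else:
            out[locus] = "unmethylated"
    return out


def motif_density(genome: Genome, motif: MotifSpec) -> float:
    """Both-strand site count per kilobase of genome."""
    n = len(scan_motif(genome, motif))
    return n * 1000.0 / genome.length


def _markov_pattern_probability(pattern: str, initial: np.ndarray,
                                transition: np.ndarray) -> float:
    """Probability that an order-1 Markov chain emits a word matching pattern."""
    order = "ACGT"
    idx = {b: i for i, b in enumerate(order)}
    # forward algorithm over the IUPAC sets
    alpha = np.zeros(4)
    for b in IUPAC[pattern[0]]:
        alpha[idx[b]] = initial[idx[b]]
    for sym in pattern[1:]:
        nxt = np.zeros(4)
        for b in IUPAC[sym]:
            j = idx[b]
            nxt[j] = float(alpha @ transition[:, j])
        alpha = nxt
    return float(alpha.sum())


def depletion_score(genome: Genome, motif: MotifSpec) -> float:
    """Observed over expected motif count; < 1 indicates motif depletion.

    The expectation comes from an order-1 Markov model fitted to the genome
    itself, so the score is corrected for mono- and dinucleotide composition.
    """
    k = len(motif)
    if genome.length < k:
        raise ValidationError("genome shorter than motif")
    order = "ACGT"
    idx = {b: i for i, b in enumerate(order)}
    mono = np.zeros(4)
    dint = np.zeros((4, 4))
    for _, seq in genome.contigs:
        for b, c in zip(seq, seq[1:]):
            if b in idx and c in idx:
                dint[idx[b], idx[c]] += 1
        for b in seq:
            if b in idx:
                mono[idx[b]] += 1
    if mono.sum() == 0:
        raise ValidationError("genome has no unambiguous bases")
    initial = mono / mono.sum()
    rowsum = dint.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        transition = np.where(rowsum > 0, dint / rowsum, 0.25)
    p_fwd = _markov_pattern_probability(motif.iupac, initial, transition)
    p_rev = _markov_pattern_probability(revcomp_iupac(motif.iupac), initial, transition)
    expected = sum(max(len(seq) - k + 1, 0) for _, seq in genome.contigs) * (p_fwd + p_rev)
    observed = len(scan_motif(genome, motif))
    if expected == 0:
        return float("nan")
    return observed / expected


# ---------------------------------------------------------------------------
# context-motif discovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscoveredMotif:
    iupac: str
    meth_offset: int
    p: float  # Bonferroni-corrected binomial p for the consensus
    n_sites: int  # methylated windows matching the consensus
    n_windows: int  # total methylated windows examined


def _genome_base_freqs(genome: Genome) -> np.ndarray:
    order = "ACGT"
    counts = np.zeros(4)
    for _, seq in genome.contigs:
        for i, b in enumerate(order):
            counts[i] += seq.count(b)
    if counts.sum() == 0:
        raise ValidationError("genome has no unambiguous bases")
    return counts / counts.sum()


def discover_context_motifs(
    genome: Genome,
    calls: Iterable[ModCall],
    ks: Sequence[int] = (5, 6, 7, 8),
    min_sites: int = 50,
    position_alpha: float = 0.001,
    consensus_mass: float = 0.9,
) -> list[DiscoveredMotif]:
    """Consensus motifs from the sequence context of methylated positions.

    For each window size k, windows centred on methylated bases (reverse
    complemented for minus-strand calls) are stacked; window positions whose
    base composition departs from the genome background (chi-square, Bonferroni
    across positions at ``position_alpha``) become constrained IUPAC symbols —
    the smallest base set holding >= ``consensus_mass`` of the observed mass —
    and all other positions collapse to N. The consensus is reported with a
    Bonferroni-corrected one-sided binomial p for the number of windows it
    matches against its background probability.
    """
    index = status_index(list(calls))
    meth_positions = [key for key, c in index.items() if c.status == "methylated"]
    if len(meth_positions) < min_sites:
        warnings.warn(
            f"only {len(meth_positions)} methylated positions (< {min_sites}); "
            "no motif discovery attempted"
        )
        return []
    seqs = dict(genome.contigs)
    bg = _genome_base_freqs(genome)
    order = "ACGT"
    idx = {b: i for i, b in enumerate(order)}
    results: dict[tuple[str, int], DiscoveredMotif] = {}
    for k in ks:
        center = k // 2
        windows: list[str] = []
        for cid, pos, strand in sorted(meth_positions):
            seq = seqs.get(cid)
            if seq is None:
                continue
            lo, hi = pos - center, pos - center + k
            if lo < 0 or hi > len(seq):
                continue
            w = seq[lo:hi]
            if "N" in w:
                continue
            windows.append(revcomp(w) if strand == "-" else w)
        n = len(windows)
        if n < min_sites:
            continue
        counts = np.zeros((k, 4))
        for w in windows:
            for i, b in enumerate(w):
                counts[i, idx[b]] += 1
        consensus: list[str] = []
        for i in range(k):
            expected = n * bg
            chi_p = stats.chisquare(counts[i], expected).pvalue
            if chi_p < position_alpha / k:
                freqs = counts[i] / n
                ordered = sorted(range(4), key=lambda j: (-freqs[j], j))
                chosen: set[str] = set()
                mass = 0.0
                for j in ordered:
                    chosen.add(order[j])
                    mass += freqs[j]
                    if mass >= consensus_mass:
                        break
                consensus.append(_SET_TO_IUPAC[frozenset(chosen)])
            else:
                consensus.append("N")
        lead = 0
        while lead < k and consensus[lead] == "N":
            lead += 1
        trail = k
        while trail > lead and consensus[trail - 1] == "N":
            trail -= 1
        if lead >= trail:
            continue  # nothing constrained at this k
        pattern = "".join(consensus[lead:trail])
        offset = center - lead
        if not (0 <= offset < len(pattern)):
            continue
        rx = _iupac_regex(pattern)
        n_match = sum(1 for w in windows if rx.match(w[lead:trail]))
        p_bg = 1.0
        for sym in pattern:
            p_bg *= sum(bg[idx[b]] for b in IUPAC[sym])
        raw = stats.binomtest(n_match, n, p_bg, alternative="greater").pvalue
        corrected = min(raw * k, 1.0)
        key = (pattern, offset)
        cand = DiscoveredMotif(pattern, offset, corrected, n_match, n)
        if key not in results or cand.p < results[key].p:
            results[key] = cand
    ranked = sorted(
        results.values(),
        key=lambda m: (m.p, -sum(1 for s in m.iupac if s != "N"), m.iupac),
    )
    return ranked
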