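"""Synthetic communities with known ground truth for every pipeline stage.

The generator emulates the study design this pipeline targets: ~10 ocean
stations sampled over one genome population, long-read kinetic evidence of
methylation at motif sites, strain mixtures with known allele frequencies
(hence known pi and F_ST), a replication-linked hemimethylation gradient, and
phage genome sets with and without motif depletion plus a consistent
bit-score table.

Defaults mirror the study conditions: 10 samples, ~100x per-strand depth,
GANTC planted at ~1 locus/kb (~2 strand-sites/kb on a palindromic motif),
a per-locus methylation probability of 0.85, and a 2.4% fraction of loci that
remain unmethylated in every sample.

A single integer seed fans out to per-component substreams via
``numpy.random.SeedSequence`` spawn keys, so adding components never shuffles
existing draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .io import (
    GeneTable,
    Genome,
    Kingdom,
    ModificationRecord,
    ValidationError,
    write_allele_counts,
    write_fasta,
    write_gene_table,
    write_hits_table,
    write_modifications,
)
from .modcall import ControlKineticModel, call_genome
from .motifs import IUPAC, MotifSpec, is_palindromic, revcomp_iupac, scan_motif

__all__ = [
    "SynthConfig",
    "TruthSet",
    "simulate_genome",
    "simulate_ipd_observations",
    "simulate_population",
    "simulate_phage_set",
    "simulate_decoupled_corpus",
    "emit_corpus",
]

# spawn-key component ids (stable; append-only)
_GENOME, _IPD, _POPULATION, _PHAGE, _SCENARIO = 0, 1, 2, 3, 4


@dataclass
class SynthConfig:
    seed: int = 0
    # genome
    genome_length: int = 100_000
    n_contigs: int = 1
    gc_content: float = 0.5
    skew_delta: float = 0.08  # leading-strand G excess (half-difference of G/C prob)
    ori_position: int | None = None  # default L // 4; ter is ori + L//2
    genes_per_strand: int = 40
    mean_gene_length: int = 900
    # motif planting
    motif: str = "GANTC"
    meth_offset: int = 1
    mod_type: str = "m6A"
    motif_rate_per_kb: float = 1.0  # planted loci per kb
    meth_prob: float = 0.85  # per-sample probability a locus is methylated
    always_unmethylated_frac: float = 0.024
    gradient_h0: float = 0.0  # hemimethylated cell fraction at ori
    # samples / kinetics
    n_samples: int = 10
    depth_per_strand: float = 100.0
    mu_m: float = 4.0  # expected IPD ratio of a fully methylated m6A site
    sigma0: float = 0.35
    cv_m: float = 0.35  # sd of the modified law = cv_m * mu_m
    # population
    n_loci: int = 1000
    pop_depth: float = 100.0
    divergence: float = 0.3  # allele-frequency separation between sample groups
    # phage set
    phage_per_clade: int = 8
    phage_length: int = 20_000
    phage_rate_per_kb: float = 2.0  # planted loci per kb in the normal clade
    depletion_factor: float = 0.2
    within_similarity: float = 0.6  # AB as a fraction of (AA+BB)/2 within clades
    between_similarity: float = 0.1

    def __post_init__(self) -> None:
        for name in ("gc_content", "meth_prob", "always_unmethylated_frac", "gradient_h0"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.genome_length <= 0:
            raise ValidationError("genome_length must be positive")
        if self.n_samples < 2:
            raise ValidationError("need at least 2 samples")
        if not (0.0 < self.depletion_factor <= 1.0):
            raise ValidationError("depletion_factor must be in (0, 1]")
        if self.mu_m <= 1.0:
            raise ValidationError("mu_m must exceed the control mean (1.0)")
        if 2 * self.genes_per_strand * self.mean_gene_length > 2 * self.genome_length:
            raise ValidationError("total gene length exceeds genome length")

    def rng(self, component: int, index: int = 0) -> np.random.Generator:
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(component, index))
        return np.random.default_rng(ss)

    @property
    def sample_ids(self) -> list[str]:
        # stations are numbered from 2 in the emulated survey
        return [f"St{i + 2}" for i in range(self.n_samples)]

    def control(self) -> ControlKineticModel:
        return ControlKineticModel(mu0=1.0, sigma0=self.sigma0)


@dataclass
class TruthSet:
    """Ground truth consistent with the emitted files."""

    ori: int | None = None
    ter: int | None = None
    motif_loci: list[tuple[str, int]] = field(default_factory=list)
    #: per sample: (contig, plus-strand position of methylated base, strand) -> true cell fraction
    site_frac: dict[str, dict[tuple[str, int, str], float]] = field(default_factory=dict)
    universal_unmethylated: list[tuple[str, int]] = field(default_factory=list)
    expected_density: float | None = None  # strand-sites per kb
    # population truth
    group_of: dict[str, str] = field(default_factory=dict)
    freqs: dict[str, np.ndarray] = field(default_factory=dict)  # sample -> per-locus alt freq
    true_fst: float | None = None
    # phage truth
    phage_clades: dict[str, str] = field(default_factory=dict)
    phage_densities: dict[str, float] = field(default_factory=dict)


def _random_sequence(rng: np.random.Generator, L: int, p: np.ndarray) -> np.ndarray:
    """Sequence as a uint8 array over indices into ACGT."""
    return rng.choice(4, size=L, p=p)


_ORDER = np.frombuffer(b"ACGT", dtype=np.uint8)


def _to_str(arr: np.ndarray) -> str:
    return _ORDER[arr].tobytes().decode()


def _scrub_motif(seq: list[str], motif: MotifSpec, rng: np.random.Generator) -> None:
    """Destroy all occurrences of a motif (both strands) in place."""
    from .motifs import _iupac_regex

    patterns = sorted({motif.iupac, revcomp_iupac(motif.iupac)})
    plans = []
    for pat in patterns:
        # mutate the most constrained position to a base outside its set
        off = min(range(len(pat)), key=lambda i: (len(IUPAC[pat[i]]), i))
        outside = sorted(set("ACGT") - IUPAC[pat[off]])
        if outside:
            plans.append((_iupac_regex(pat), off, outside))
    for _ in range(10):
        s = "".join(seq)
        hits = sorted(
            (m.start() + off, tuple(outside))
            for rx, off, outside in plans
            for m in rx.finditer(s)
        )
        if not hits:
            return
        for j, outside in hits:
            seq[j] = outside[int(rng.integers(0, len(outside)))]


def simulate_genome(config: SynthConfig) -> tuple[Genome, GeneTable, TruthSet]:
    """A genome with GC-skew replication structure, genes, and planted motifs.

    The plus strand carries a G-over-C excess on the ori->ter replichore and
    the mirror-image deficit on the other, so the cumulative skew has a unique
    minimum at ori and maximum at ter. Genes are placed per strand without
    overlap; motif loci are planted at known positions after scrubbing
    background occurrences, with per-sample methylation states drawn from the
    configured probabilities and the hemimethylation gradient.
    """
    rng = config.rng(_GENOME)
    L = config.genome_length
    ori = config.ori_position if config.ori_position is not None else L // 4
    ter = (ori + L // 2) % L
    gc = config.gc_content
    delta = min(config.skew_delta, gc / 2)
    at = (1.0 - gc) / 2.0
    p_lead = np.array([at, gc / 2 - delta, gc / 2 + delta, at])  # A C G T; G-rich
    p_lag = np.array([at, gc / 2 + delta, gc / 2 - delta, at])

    arr = np.empty(L, dtype=np.int64)
    idx = np.arange(L)
    on_fwd = ((idx - ori) % L) < ((ter - ori) % L)
    n_fwd = int(on_fwd.sum())
    arr[on_fwd] = _random_sequence(rng, n_fwd, p_lead)
    arr[~on_fwd] = _random_sequence(rng, L - n_fwd, p_lag)
    seq = list(_to_str(arr))

    motif = MotifSpec(config.motif, config.meth_offset, config.mod_type)
    _scrub_motif(seq, motif, rng)

    # plant motif loci at uniform non-overlapping positions
    k = len(motif)
    n_loci = int(round(config.motif_rate_per_kb * L / 1000.0))
    positions: list[int] = []
    occupied = np.zeros(L, dtype=bool)
    tries = 0
    while len(positions) < n_loci and tries < 100 * max(n_loci, 1):
        tries += 1
        p = int(rng.integers(0, L - k + 1))
        if occupied[max(p - k, 0) : p + 2 * k].any():
            continue
        positions.append(p)
        occupied[p : p + k] = True
    positions.sort()
    for p in positions:
        for j, sym in enumerate(motif.iupac):
            bases = sorted(IUPAC[sym])
            seq[p + j] = bases[int(rng.integers(0, len(bases)))]

    # contigs: split the circular order into n_contigs consecutive pieces
    full = "".join(seq)
    bounds = np.linspace(0, L, config.n_contigs + 1, dtype=int)
    contigs = [
        (f"c{i + 1}", full[bounds[i] : bounds[i + 1]]) for i in range(config.n_contigs)
    ]
    genome = Genome("synth", contigs, Kingdom.prokaryote)

    def to_contig(p: int) -> tuple[str, int]:
        i = int(np.searchsorted(bounds, p, side="right") - 1)
        return (f"c{i + 1}", p - int(bounds[i]))

    # genes per strand, non-overlapping within a strand
    rows = []
    gid = 0
    for strand in ("+", "-"):
        placed: list[int] = []
        glen = config.mean_gene_length
        attempts = 0
        while len(placed) < config.genes_per_strand:
            attempts += 1
            if attempts > 100_000:
                raise ValidationError("gene placement infeasible")
            s = int(rng.integers(0, L - glen))
            cid_s, off_s = to_contig(s)
            cid_e, _ = to_contig(s + glen - 1)
            if cid_s != cid_e:
                continue  # keep genes within one contig
            if any(abs(s - q) < glen for q in placed):
                continue
            placed.append(s)
            rows.append((cid_s, off_s, off_s + glen, strand, f"g{gid}"))
            gid += 1
    genes = GeneTable(rows)

    # per-sample methylation truth
    from .structure import OriTer, relative_position

    oriter = OriTer(ori=ori, ter=ter)
    truth = TruthSet(ori=ori, ter=ter)
    truth.motif_loci = [to_contig(p) for p in positions]
    palindromic = is_palindromic(motif.iupac)
    strand_sites_per_locus = 2 if palindromic else 1
    truth.expected_density = strand_sites_per_locus * len(positions) * 1000.0 / L

    u = rng.random(len(positions)) < config.always_unmethylated_frac
    truth.universal_unmethylated = [to_contig(p) for p, flag in zip(positions, u) if flag]
    for sample in config.sample_ids:
        site_frac: dict[tuple[str, int, str], float] = {}
        meth_state = rng.random(len(positions)) < config.meth_prob
        for locus_i, p in enumerate(positions):
            d = relative_position(p, oriter, L)
            if u[locus_i]:
                f = 0.0
            elif meth_state[locus_i]:
                f = 1.0 - config.gradient_h0 * (1.0 - d) / 2.0
            else:
                f = 0.0
            # methylated-base coordinate per strand
            cid, off = to_contig(p)
            site_frac[(cid, off + motif.meth_offset, "+")] = f
            if palindromic:
                site_frac[(cid, off + k - 1 - motif.meth_offset, "-")] = f
        truth.site_frac[sample] = site_frac
    return genome, genes, truth


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log(1.0 + (sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def simulate_ipd_observations(
    truth: TruthSet,
    config: SynthConfig,
    sample_id: str,
) -> tuple[pd.DataFrame, list[ModificationRecord]]:
    """Per-molecule IPD ratios at every truth site for one sample.

    Coverage per strand is Poisson(depth); each molecule is methylated with
    the site's true cell fraction; IPD ratios are lognormal around the control
    mean (1.0, sd sigma0) or the modified mean (mu_m, sd cv_m*mu_m). The
    paired modification records come from running the caller on the table.
    """
    if sample_id not in truth.site_frac:
        raise ValidationError(f"unknown sample {sample_id!r}")
    index = config.sample_ids.index(sample_id)
    rng = config.rng(_IPD, index)
    mu0_log, s0_log = _lognormal_params(1.0, config.sigma0)
    mum_log, sm_log = _lognormal_params(config.mu_m, config.cv_m * config.mu_m)
    rows_contig: list[str] = []
    rows_pos: list[int] = []
    rows_strand: list[str] = []
    rows_ipd: list[float] = []
    for (cid, pos, strand), f in sorted(truth.site_frac[sample_id].items()):
        n = int(rng.poisson(config.depth_per_strand))
        if n == 0:
            continue
        methylated = rng.random(n) < f
        ipd = np.where(
            methylated,
            rng.lognormal(mum_log, sm_log, size=n),
            rng.lognormal(mu0_log, s0_log, size=n),
        )
        rows_contig.extend([cid] * n)
        rows_pos.extend([pos] * n)
        rows_strand.extend([strand] * n)
        rows_ipd.extend(ipd.tolist())
    table = pd.DataFrame(
        {
            "contig_id": rows_contig,
            "position": rows_pos,
            "strand": rows_strand,
            "ipd_ratio": rows_ipd,
        }
    )
    calls = call_genome(table, config.control(), mu_m=config.mu_m)
    records = [c.record for c in calls]
    return table, records


def simulate_population(config: SynthConfig) -> tuple[pd.DataFrame, TruthSet]:
    """Biallelic allele counts for two designed sample groups.

    Loci have a shared baseline frequency; the two groups sit divergence/2
    below and above it (clipped). Read counts are binomial at Poisson depth.
    The analytic Hudson-style F_ST between the group frequency vectors is
    recorded in the truth set.
    """
    rng = config.rng(_POPULATION)
    samples = config.sample_ids
    half = len(samples) // 2
    groups = {s: ("g1" if i < half else "g2") for i, s in enumerate(samples)}
    p0 = rng.uniform(0.2, 0.8, size=config.n_loci)
    p_g1 = np.clip(p0 - config.divergence / 2.0, 0.01, 0.99)
    p_g2 = np.clip(p0 + config.divergence / 2.0, 0.01, 0.99)

    truth = TruthSet()
    truth.group_of = groups
    truth.freqs = {s: (p_g1 if groups[s] == "g1" else p_g2) for s in samples}
    truth.true_fst = _true_fst(p_g1, p_g2)

    rows = []
    positions = np.arange(config.n_loci) * 10  # spaced loci on one contig
    for s in samples:
        p = truth.freqs[s]
        depth = rng.poisson(config.pop_depth, size=config.n_loci)
        alt = rng.binomial(depth, p)
        ref = depth - alt
        for j in range(config.n_loci):
            rows.append(("c1", int(positions[j]), "A", s, int(ref[j]), int(alt[j]), 0, 0))
    ac = pd.DataFrame(
        rows,
        columns=["contig_id", "position", "ref_base", "sample_id", "nA", "nC", "nG", "nT"],
    )
    return ac, truth


def _true_fst(px: np.ndarray, py: np.ndarray) -> float:
    pi_x = 2.0 * px * (1.0 - px)
    pi_y = 2.0 * py * (1.0 - py)
    pi_b = 1.0 - (px * py + (1.0 - px) * (1.0 - py))
    return float(1.0 - (pi_x.mean() + pi_y.mean()) / (2.0 * pi_b.mean()))


def simulate_phage_set(config: SynthConfig) -> tuple[list[Genome], pd.DataFrame, TruthSet]:
    """Two phage clades, one with motif depletion, plus a bit-score table.

    The depleted clade plants the motif at ``depletion_factor`` times the
    normal rate. Within-clade bit-score sums exceed between-clade sums by the
    configured margin, and the table carries both hit directions so pair sums
    aggregate symmetrically.
    """
    rng = config.rng(_PHAGE)
    motif = MotifSpec(config.motif, config.meth_offset, config.mod_type)
    k = len(motif)
    palindromic = is_palindromic(motif.iupac)
    genomes: list[Genome] = []
    truth = TruthSet()
    L = config.phage_length
    for clade, rate_scale in (("normal", 1.0), ("depleted", config.depletion_factor)):
        rate = config.phage_rate_per_kb * rate_scale
        for i in range(config.phage_per_clade):
            name = f"{clade}_{i + 1}"
            arr = _random_sequence(rng, L, np.array([0.25, 0.25, 0.25, 0.25]))
            seq = list(_to_str(arr))
            _scrub_motif(seq, motif, rng)
            n_loci = int(round(rate * L / 1000.0))
            chosen: list[int] = []
            occupied = np.zeros(L, dtype=bool)
            tries = 0
            while len(chosen) < n_loci and tries < 100 * max(n_loci, 1):
                tries += 1
                p = int(rng.integers(0, L - k + 1))
                if occupied[max(p - k, 0) : p + 2 * k].any():
                    continue
                chosen.append(p)
                occupied[p : p + k] = True
            for p in chosen:
                for j, sym in enumerate(motif.iupac):
                    bases = sorted(IUPAC[sym])
                    seq[p + j] = bases[int(rng.integers(0, len(bases)))]
            genomes.append(Genome(name, [(name, "".join(seq))], Kingdom.virus))
            truth.phage_clades[name] = clade
            sites_per_locus = 2 if palindromic else 1
            truth.phage_densities[name] = sites_per_locus * len(chosen) * 1000.0 / L

    names = [g.genome_id for g in genomes]
    self_score = 2.0 * L
    rows = []
    for a in names:
        rows.append((a, a, self_score))
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            same = truth.phage_clades[a] == truth.phage_clades[b]
            frac = config.within_similarity if same else config.between_similarity
            ab = frac * self_score * float(rng.uniform(0.95, 1.05))
            rows.append((a, b, ab))
            rows.append((b, a, ab))
    hits = pd.DataFrame(rows, columns=["query_genome_id", "subject_genome_id", "bit_score"])
    return genomes, hits, truth


def simulate_decoupled_corpus(config: SynthConfig) -> dict:
    """Samples whose strain composition and methylation state vary independently.

    Strain groups split the samples in half (driving SNV differences), while
    methylation groups split them even/odd (driving SNMV differences): at a
    third of the motif loci the "on" methylation group has cell fraction 1 and
    the "off" group 0. Used to reproduce the qualitative pattern that SNMV
    clusters by methylation truth while SNV clusters by strain composition.
    """
    rng = config.rng(_SCENARIO)
    samples = config.sample_ids
    ac, pop_truth = simulate_population(config)
    meth_group = {s: ("mx" if i % 2 == 0 else "my") for i, s in enumerate(samples)}

    genome, genes, truth = simulate_genome(config)
    loci = truth.motif_loci
    variable = rng.random(len(loci)) < 1.0 / 3.0
    motif = MotifSpec(config.motif, config.meth_offset, config.mod_type)
    k = len(motif)
    for s in samples:
        site_frac: dict[tuple[str, int, str], float] = {}
        for (cid, off), var in zip(loci, variable):
            if var:
                f = 1.0 if meth_group[s] == "mx" else 0.0
            else:
                f = 1.0
            site_frac[(cid, off + motif.meth_offset, "+")] = f
            if is_palindromic(motif.iupac):
                site_frac[(cid, off + k - 1 - motif.meth_offset, "-")] = f
        truth.site_frac[s] = site_frac

    calls_by_sample = {}
    for s in samples:
        _, records = simulate_ipd_observations(truth, config, s)
        from .modcall import calls_from_records

        calls_by_sample[s] = calls_from_records(records)
    return {
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "allele_counts": ac,
        "strain_group": pop_truth.group_of,
        "meth_group": meth_group,
        "calls_by_sample": calls_by_sample,
    }


def emit_corpus(config: SynthConfig, out_dir: str | Path) -> dict:
    """Write a full synthetic corpus to disk; returns a manifest of paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, genes, truth = simulate_genome(config)
    write_fasta(genome, out / "genome.fasta")
    write_gene_table(genes, out / "genes.gff3", dialect="gff3")
    paths = {
        "genome": str(out / "genome.fasta"),
        "genes": str(out / "genes.gff3"),
        "modifications": {},
    }
    for s in config.sample_ids:
        table, records = simulate_ipd_observations(truth, config, s)
        mod_path = out / f"modifications_{s}.tsv"
        write_modifications(records, mod_path, dialect="tsv")
        table.to_csv(out / f"ipd_{s}.tsv", sep="\t", index=False)
        paths["modifications"][s] = str(mod_path)
    ac, pop_truth = simulate_population(config)
    write_allele_counts(ac, out / "allele_counts.tsv")
    paths["allele_counts"] = str(out / "allele_counts.tsv")
    phages, hits, phage_truth = simulate_phage_set(config)
    for g in phages:
        write_fasta(g, out / f"phage_{g.genome_id}.fasta")
    write_hits_table(hits, out / "hits.tsv")
    paths["hits"] = str(out / "hits.tsv")

    truth_json = {
        "ori": truth.ori,
        "ter": truth.ter,
        "expected_density": truth.expected_density,
        "n_motif_loci": len(truth.motif_loci),
        "universal_unmethylated": len(truth.universal_unmethylated),
        "true_fst": pop_truth.true_fst,
        "phage_densities": phage_truth.phage_densities,
        "phage_clades": phage_truth.phage_clades,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth_json, fh, indent=2, sort_keys=True)
    paths["truth"] = str(out / "truth.json")
    return paths
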