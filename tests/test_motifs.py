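"""Motif scanning against a brute-force oracle, ratios, profiles, discovery."""

import numpy as np
import pytest

from metaepi.io import Genome, Kingdom, ModificationRecord, ValidationError
from metaepi.modcall import calls_from_records
from metaepi.motifs import (
    IUPAC,
    BREADTH_THRESHOLDS,
    MethylomeProfile,
    MotifSpec,
    breadth_filter,
    build_5mer_profile,
    depletion_score,
    discover_context_motifs,
    is_candidate_motif,
    is_palindromic,
    motif_density,
    motif_methylation_ratio,
    pair_palindromic_sites,
    revcomp,
    scan_motif,
    status_index,
    site_status,
)

from conftest import make_genome


def brute_force_scan(seq: str, pattern: str) -> list[tuple[int, str]]:
    """Independent oracle: positional set membership on both strands."""
    def matches(s, pat):
        return all(c in IUPAC[p] for c, p in zip(s, pat))

    k = len(pattern)
    rc = revcomp(pattern) if set(pattern) <= set("ACGT") else None
    # IUPAC-aware reverse complement via complement of each symbol's set
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc_sets = [
        frozenset(comp[b] for b in IUPAC[p]) for p in reversed(pattern)
    ]

    hits = []
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if matches(w, pattern):
            hits.append((i, "+"))
        if all(c in s for c, s in zip(w, rc_sets)):
            hits.append((i, "-"))
    return sorted(hits)


class TestScan:
    def test_gantc_on_gaatc_yields_both_strands(self):
        g = make_genome("GAATC")
        sites = scan_motif(g, MotifSpec("GANTC", 1))
        assert [(s.start, s.strand) for s in sites] == [(0, "+"), (0, "-")]
        # methylated-base coordinates: + strand offset 1, - strand mirrored
        assert sorted(s.meth_position for s in sites) == [1, 3]

    def test_gatc_palindrome_in_agatct(self):
        g = make_genome("AGATCT")
        sites = scan_motif(g, MotifSpec("GATC", 1))
        assert [(s.start, s.strand) for s in sites] == [(1, "+"), (1, "-")]

    def test_sequence_n_never_matches(self):
        g = make_genome("GANTC")
        assert scan_motif(g, MotifSpec("GANTC", 1)) == []

    def test_overlapping_matches_all_reported(self):
        g = make_genome("AAAA")
        sites = scan_motif(g, MotifSpec("AA", 0))
        assert sum(s.strand == "+" for s in sites) == 3

    def test_invalid_iupac_symbol_rejected(self):
        with pytest.raises(ValidationError):
            MotifSpec("GAXTC", 1)

    def test_equals_brute_force_oracle_on_random_cases(self, rng):
        symbols = list(IUPAC)
        for _ in range(1000):
            L = int(rng.integers(10, 60))
            seq = "".join(rng.choice(list("ACGTN"), size=L, p=[0.24] * 4 + [0.04]))
            k = int(rng.integers(2, 7))
            pattern = "".join(rng.choice(symbols, size=k))
            g = Genome("g", [("c1", seq)])
            got = sorted((s.start, s.strand) for s in scan_motif(g, MotifSpec(pattern, 0)))
            assert got == brute_force_scan(seq, pattern), (seq, pattern)


def _calls(status_map):
    """status_map: (pos, strand) -> status; builds calls on contig c1."""
    records, out = [], []
    for (pos, strand), status in status_map.items():
        if status == "methylated":
            rec = ModificationRecord("c1", pos, strand, "m6A", 50, 80.0, 0.9)
        elif status == "unmethylated":
            rec = ModificationRecord("c1", pos, strand, "m6A", 50, 5.0, 0.05)
        else:
            rec = ModificationRecord("c1", pos, strand, "m6A", 3, 80.0, 0.9)
        records.append(rec)
    return calls_from_records(records)


class TestRatio:
    def test_unevaluable_excluded_from_denominator(self):
        g = make_genome("GAATC" + "T" * 5 + "GACTC" + "T" * 5 + "GAGTC" + "T" * 5 + "GATTC")
        motif = MotifSpec("GANTC", 1)
        sites = [s for s in scan_motif(g, motif) if s.strand == "+"]
        assert len(sites) == 4
        # 3 methylated, 1 unmethylated on + strand; 6 unevaluable (absent calls)
        status = {
            (1, "+"): "methylated",
            (11, "+"): "methylated",
            (21, "+"): "methylated",
            (31, "+"): "unmethylated",
        }
        idx = status_index(_calls(status))
        assert motif_methylation_ratio(sites, idx) == pytest.approx(0.75)

    @pytest.mark.parametrize("ratio,flag", [(0.19, False), (0.20, True)])
    def test_candidate_boundary(self, ratio, flag):
        assert is_candidate_motif(ratio) is flag

    def test_all_unevaluable_is_missing_not_zero(self):
        g = make_genome("GAATC")
        sites = scan_motif(g, MotifSpec("GANTC", 1))
        assert motif_methylation_ratio(sites, {}) is None


class TestBreadth:
    @pytest.mark.parametrize(
        "kingdom,breadth,keep",
        [
            (Kingdom.prokaryote, 0.19, False),
            (Kingdom.prokaryote, 0.20, True),
            (Kingdom.virus, 0.60, True),
            (Kingdom.virus, 0.59, False),
            (Kingdom.eukaryote, 0.50, True),
            (Kingdom.eukaryote, 0.09, False),
            (Kingdom.giant_virus, 0.20, True),
        ],
    )
    def test_kingdom_thresholds_at_boundary(self, kingdom, breadth, keep):
        profile = MethylomeProfile("g", "s", breadth_10x=breadth)
        assert breadth_filter(profile, kingdom) is keep

    def test_unknown_kingdom_rejected(self):
        with pytest.raises(ValidationError):
            breadth_filter(MethylomeProfile("g", "s"), "archaeon")


class TestFivemerProfile:
    def test_all_a_genome_single_fivemer(self):
        g = make_genome("A" * 20)
        status = {(p, "+"): "methylated" for p in range(2, 18)}
        prof = build_5mer_profile(g, status_index(_calls(status)))
        assert prof == {"AAAAA": 1.0}

    def test_no_evaluable_positions_all_missing(self):
        g = make_genome("ACGTACGTAC")
        assert build_5mer_profile(g, {}) == {}

    def test_minus_strand_window_is_revcomp(self):
        g = make_genome("AAGATCC")
        # center at 3 on minus strand: plus window AGATC -> revcomp GATCT
        status = {(3, "-"): "methylated"}
        prof = build_5mer_profile(g, status_index(_calls(status)))
        assert prof == {"GATCT": 1.0}

    def test_planted_gantc_fivemers_fully_methylated(self, small_corpus):
        genome, truth, cfg = (
            small_corpus["genome"],
            small_corpus["truth"],
            small_corpus["config"],
        )
        sample = cfg.sample_ids[0]
        records = [
            ModificationRecord("c1", pos, strand, "m6A", 50,
                               80.0 if f > 0.5 else 5.0, f)
            for (c, pos, strand), f in truth.site_frac[sample].items()
        ]
        prof = build_5mer_profile(genome, status_index(calls_from_records(records)))
        # evaluable contexts are exactly the planted-site windows: the strand-
        # oriented 5-mer centred on the methylated A of GA N TC is xGANT
        assert prof
        for w in prof:
            assert w[1:3] == "GA" and w[4] == "T", w
        assert np.mean(list(prof.values())) > 0.6


class TestPalindromicPairing:
    def test_full_hemi_unmethylated(self):
        g = make_genome("GAATC" + "T" * 5 + "GACTC" + "T" * 5 + "GAGTC")
        motif = MotifSpec("GANTC", 1)
        sites = scan_motif(g, motif)
        status = {
            (1, "+"): "methylated", (3, "-"): "methylated",     # locus 0: full
            (11, "+"): "methylated", (13, "-"): "unmethylated", # locus 10: hemi
            (21, "+"): "unmethylated", (23, "-"): "unmethylated",
        }
        result = pair_palindromic_sites(sites, status_index(_calls(status)))
        assert result == {
            ("c1", 0): "full",
            ("c1", 10): "hemi",
            ("c1", 20): "unmethylated",
        }

    def test_non_palindromic_motif_rejected(self):
        assert is_palindromic("GANTC")
        assert not is_palindromic("GGTAG")
        g = make_genome("GGTAGAAA")
        sites = scan_motif(g, MotifSpec("GGTAG", 2))
        with pytest.raises(ValidationError, match="self-complementary"):
            pair_palindromic_sites(sites, {})


class TestDensity:
    def test_sites_per_kb(self):
        # 5 plus-strand TTAA loci in 1 kb; palindrome so 10 strand-sites
        seq = list("C" * 1000)
        for p in (10, 110, 300, 600, 900):
            seq[p : p + 4] = "TTAA"
        g = make_genome("".join(seq))
        assert motif_density(g, MotifSpec("TTAA", 2)) == pytest.approx(10.0)

    def test_zero_sites(self):
        g = make_genome("C" * 500)
        assert motif_density(g, MotifSpec("GATC", 1)) == 0.0

    def test_invariant_under_contig_splitting(self):
        seq = list("C" * 2000)
        for p in (100, 700, 1500):
            seq[p : p + 5] = "GAATC"
        whole = Genome("g", [("c1", "".join(seq))])
        split = Genome("g", [("c1", "".join(seq[:1000])), ("c2", "".join(seq[1000:]))])
        m = MotifSpec("GANTC", 1)
        assert motif_density(whole, m) == pytest.approx(motif_density(split, m))


class TestDepletion:
    def test_markov_generated_sequence_scores_near_one(self, rng):
        scores = []
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=20_000))
            scores.append(depletion_score(make_genome(seq), MotifSpec("GATC", 1)))
        assert abs(np.mean(scores) - 1.0) < 0.1

    def test_scrubbed_genome_scores_below_one(self, rng):
        from metaepi.synth import _scrub_motif

        seq = list("".join(rng.choice(list("ACGT"), size=20_000)))
        motif = MotifSpec("GATC", 1)
        _scrub_motif(seq, motif, rng)
        assert depletion_score(make_genome("".join(seq)), motif) < 1.0

    def test_uniform_genome_closed_form(self, rng):
        # expected count ~ (L-4) * 2 * prod(p); simulation vs formula
        L, n_rep = 30_000, 8
        counts = []
        for _ in range(n_rep):
            seq = "".join(rng.choice(list("ACGT"), size=L))
            g = make_genome(seq)
            counts.append(len(scan_motif(g, MotifSpec("GANTC", 1))))
        expected = (L - 4) * 2 * (0.25 ** 4)
        sd = np.sqrt(expected)
        assert abs(np.mean(counts) - expected) < 3 * sd / np.sqrt(n_rep)


class TestDiscovery:
    def test_planted_gantc_recovered(self, small_corpus):
        genome, truth, cfg = (
            small_corpus["genome"],
            small_corpus["truth"],
            small_corpus["config"],
        )
        sample = cfg.sample_ids[0]
        records = [
            ModificationRecord(c, pos, strand, "m6A", 50, 80.0, f)
            for (c, pos, strand), f in truth.site_frac[sample].items()
            if f > 0.5
        ]
        found = discover_context_motifs(genome, calls_from_records(records))
        assert found, "no motif discovered from planted methylome"
        top = found[0]
        assert top.p < 0.01
        core = top.iupac
        assert "GA" in core and "TC" in core
        # non-N positions spell out G, A, ., T, C
        assert core.replace("N", ".")[:5] in ("GA.TC", "GANTC".replace("N", "."))

    def test_random_calls_yield_no_motif(self, rng):
        fp = 0
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            seq = "".join(r.choice(list("ACGT"), size=15_000))
            g = make_genome(seq)
            positions = r.choice(np.arange(10, 14_990), size=60, replace=False)
            records = [
                ModificationRecord("c1", int(p), "+", "m6A", 50, 80.0, 0.9)
                for p in positions
            ]
            found = discover_context_motifs(g, calls_from_records(records))
            if any(m.p < 0.01 for m in found):
                fp += 1
        assert fp / n_seeds <= 0.05

    def test_too_few_calls_warns_and_returns_empty(self):
        g = make_genome("ACGT" * 100)
        with pytest.warns(UserWarning, match="methylated positions"):
            assert discover_context_motifs(g, []) == []
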