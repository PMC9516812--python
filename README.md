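# metaepi

Meta-epigenomic analysis of microbial communities: from per-site DNA
modification evidence to motif methylomes, methylome ordination, single
nucleotide methylation variation, population differentiation versus methylome
divergence, replication-linked methylation gradients, motif enrichment by
genomic region, and bit-score Dice-distance viral clustering.

## Who this is for

Microbial ecologists and bioinformaticians working with metagenome-assembled
genomes (MAGs) and SMRT long-read kinetic data who want to move beyond
per-genome methylation calls to *community-scale* epigenomic questions: does a
population's methylome track its strain composition or vary independently of
it; is a methyltransferase target motif (such as the CcrM target GANTC in
Alphaproteobacteria) coupled to the cell cycle; and do phage genomes avoid a
host's methylated motif. The package ships a synthetic-data generator that
emulates all of these signals with known ground truth, so every estimator can
be validated end to end without raw sequencing data.

## The models and statistics at the core

**Kinetic modification calling.** SMRT sequencing reports an interpulse
duration (IPD) per incorporated base; methylation slows the polymerase. Each
position-strand is tested with a one-sample, upper-tailed *t* test of its
per-molecule IPD ratios against the unmodified control mean μ₀, giving a
modification quality value QV = −10·log₁₀(p). A site is evaluable only with
≥ 10× coverage per strand, and methylated when additionally QV ≥ 30. Because
pooled molecules come from many cells, the aggregate signal estimates the
*methylation fraction* — the fraction of cells methylated at that site —
by the method of moments: f = clip((x̄ − μ₀)/(μ_m − μ₀), 0, 1).

**Motif methylomes.** IUPAC motifs are scanned on both strands (a
self-complementary motif like GANTC yields two strand-sites per locus). A
motif's methylation ratio is methylated / (methylated + unmethylated)
evaluable sites; ratios below 20% are treated as noise, not candidate motifs.
Genome–sample pairs enter comparisons only above a kingdom-specific 10×
breadth (prokaryote/giant virus 20%, eukaryote 10%, virus 60%). 5-mer
methylation profiles are compared with the Kulczynski dissimilarity

    d(x, y) = 1 − ½ (Σ min(xᵢ,yᵢ)/Σxᵢ + Σ min(xᵢ,yᵢ)/Σyᵢ)

and Bray–Curtis Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ), ordinated by classical-scaling PCoA.

**Population genetics.** From pileup allele counts, a locus is a SNP when any
non-reference allele has frequency > 1% and ≥ 4 reads in some sample.
Nucleotide diversity per site is π_j = (n/(n−1))(1 − Σ_a f_a²); population
differentiation is a Hudson-style ratio of averages,

    F_ST = 1 − mean(π_X + π_Y) / (2 · mean(π_between)),
    π_between(j) = 1 − Σ_a f_a^X f_a^Y .

Methylome dissimilarity is correlated with F_ST over sample pairs (Pearson,
with an optional Mantel permutation p because pairs share samples).

**Replication structure.** Windowed GC skew (G−C)/(G+C) locates the
replication origin and terminus at the cumulative-skew global minimum and
maximum. With d ∈ [0,1] the relative replichore position (0 at *ori*, 1 at
*ter*), the pooled methylation fraction of a cell-cycle motif follows
m(d) = 1 − h₀(1−d)/2, where h₀ is the hemimethylated cell fraction at the
origin; h₀ is fitted by least squares.

**Motif enrichment by region.** The genome is partitioned into genic,
regulatory (100 bp upstream of gene starts, strand-aware), and intergenic
positions. A 500-replicate null re-places each strand's genes (observed count,
observed mean length) uniformly without overlap; observed densities are
converted to z-scores and two-sided normal p-values when the null passes a
Shapiro–Wilk normality check, else an empirical p is used.

**Viral clustering.** With AB the bit-score sum of all alignment hits between
genomes A and B (directions averaged) and AA, BB the self sums, the Dice
distance is D = 1 − 2·AB/(AA+BB); trees are built by neighbor joining, and
motif densities are compared between clades with a rank-sum test — the
signature of motif-depleted phage lineages.

## Worked example

Generate a synthetic corpus (50 kb genome, 4 samples, GANTC planted at
1 locus/kb with a cell-cycle gradient h₀ = 0.4), then profile it:

```bash
$ cat demo.yaml
genome_length: 50000
n_samples: 4
gradient_h0: 0.4
genes_per_strand: 20
mean_gene_length: 600
n_loci: 200
phage_per_clade: 4
phage_length: 8000

$ metaepi simulate --config demo.yaml --seed 11 --out demo
$ metaepi scan --fasta demo/genome.fasta --motif GANTC --offset 1 \
    --mods demo/modifications_St2.tsv
sites   100
density_per_kb  2.0000
depletion_score 0.2637
methylation_ratio       0.7800
$ metaepi skew --fasta demo/genome.fasta
ori     12300
ter     37400
```

Reading the numbers: 50 planted GANTC loci appear as 100 strand-sites
(2.0/kb, the palindrome counts once per strand); the depletion score 0.26
reflects that background GANTC occurrences were scrubbed before planting, so
the genome carries far fewer sites than its dinucleotide composition predicts;
78% of evaluable sites are methylated in sample St2 (the generator's per-locus
methylation probability is 0.85, minus coverage and gradient effects); and the
inferred *ori* at 12,300 sits within two 1 kb skew windows of the planted
origin at 12,500. The enrichment and viral subcommands behave the same way:

```bash
$ metaepi viral --hits demo/hits.tsv --tree-out demo/tree.nwk
$ metaepi enrich --fasta demo/genome.fasta --genes demo/genes.gff3 \
    --motif GANTC --offset 1 --replicates 200 --seed 11
region  observed  null_mean  null_sd  shapiro_p  z        p       method
genic      2.2308  2.0079    0.3655   0.7888     0.6098   0.542   normal
regulatory 1.6308  2.1475    1.3332   1.689e-05  -0.3876  0.7     empirical
intergenic 1.8492  1.9791    0.3123   0.7962     -0.4161  0.6773  normal
```

Here the motif was planted uniformly, so no region is significantly enriched —
exactly what the calibrated null should say.

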