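"""End-to-end orchestration of the synthetic corpus through every stage.

The pipeline config is the single source of thresholds (coverage 10x/20x,
QV 30, 20% motif-noise cutoff, breadth map, SNP rule, shuffle replicates,
seeds); it is serialized into the output directory next to a manifest that
lists every artifact with a checksum, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from . import compare, enrichment, modcall, motifs, popgen, structure, synth, viral
from .io import DistanceMatrix, write_matrix, write_newick

__all__ = ["PipelineConfig", "run"]


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "metaepi_out"
    # stage toggles
    run_modcall: bool = True
    run_motifs: bool = True
    run_compare: bool = True
    run_popgen: bool = True
    run_structure: bool = True
    run_enrich: bool = True
    run_viral: bool = True
    # thresholds (defaults as used throughout the pipeline)
    min_coverage: int = 10
    snmv_min_depth: int = 20
    min_qv: float = 30.0
    noise_ratio: float = 0.20
    shuffle_replicates: int = 500
    gradient_h0: float = 0.4
    synth: synth.SynthConfig | None = None

    def resolved_synth(self) -> synth.SynthConfig:
        if self.synth is not None:
            return self.synth
        return synth.SynthConfig(seed=self.seed, gradient_h0=self.gradient_h0)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: PipelineConfig) -> dict:
    """Run the staged pipeline on a synthetic corpus; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.resolved_synth()
    results: dict = {"seed": config.seed, "thresholds": {
        "min_coverage": config.min_coverage,
        "snmv_min_depth": config.snmv_min_depth,
        "min_qv": config.min_qv,
        "noise_ratio": config.noise_ratio,
        "shuffle_replicates": config.shuffle_replicates,
    }}

    genome, genes, truth = synth.simulate_genome(cfg)
    spec = motifs.MotifSpec(cfg.motif, cfg.meth_offset, cfg.mod_type)
    sites = motifs.scan_motif(genome, spec)
    results["n_motif_sites"] = len(sites)
    results["motif_density_per_kb"] = motifs.motif_density(genome, spec)

    calls_by_sample = {}
    if config.run_modcall:
        for s in cfg.sample_ids:
            _, records = synth.simulate_ipd_observations(truth, cfg, s)
            calls_by_sample[s] = modcall.calls_from_records(
                records, min_coverage=config.min_coverage, min_qv=config.min_qv
            )
        first = cfg.sample_ids[0]
        index = motifs.status_index(calls_by_sample[first])
        ratio = motifs.motif_methylation_ratio(sites, index)
        results["motif_methylation_ratio"] = ratio
        results["candidate_motif"] = motifs.is_candidate_motif(ratio)

    if config.run_compare and calls_by_sample:
        snmv = compare.build_snmv(calls_by_sample, min_depth=config.snmv_min_depth)
        results["snmv_sites"] = len(snmv.positions)
        if len(snmv.positions) > 0:
            dm = snmv.distance_matrix("braycurtis")
            write_matrix(dm, out / "snmv_braycurtis.csv")
            ord_ = compare.pcoa(dm)
            results["snmv_pcoa_prop1"] = float(ord_.proportion_explained[0]) if len(
                ord_.proportion_explained
            ) else None

    if config.run_popgen:
        ac, pop_truth = synth.simulate_population(cfg)
        s1 = cfg.sample_ids[0]
        s2 = cfg.sample_ids[-1]
        results["pi_sample1"] = popgen.pi(ac, s1)
        results["fst_between_groups"] = popgen.fst(ac, s1, s2)
        results["true_fst"] = pop_truth.true_fst
        results["n_snps"] = int(len(popgen.call_snps(ac)))

    if config.run_structure:
        seq = "".join(s for _, s in genome.contigs)
        profile = structure.gc_skew(seq)
        oriter = structure.locate_ori_ter(profile)
        if oriter is not None:
            results["ori"] = oriter.ori
            results["ter"] = oriter.ter
            sample = cfg.sample_ids[0]
            pos, frac = [], []
            offset = 0
            offsets = {}
            for cid, s in genome.contigs:
                offsets[cid] = offset
                offset += len(s)
            # gradient over methylated sites only (frac > 0.5); unmethylated
            # loci carry no cell-cycle signal
            for (cid, p, strand), f in truth.site_frac[sample].items():
                if f > 0.5:
                    pos.append(offsets[cid] + p)
                    frac.append(f)
            if len(pos) >= 50:
                report = structure.methylation_gradient(pos, frac, oriter, len(seq))
                results["fitted_h0"] = report.h0
                results["true_h0"] = cfg.gradient_h0

    if config.run_enrich:
        null = enrichment.shuffle_null(
            genome, genes, sites,
            n_replicates=config.shuffle_replicates, seed=config.seed,
        )
        results["enrichment"] = {
            r: {"observed": null.observed[r], "p": null.p[r], "method": null.method[r]}
            for r in enrichment.REGIONS
        }

    if config.run_viral:
        phages, hits, phage_truth = synth.simulate_phage_set(cfg)
        sums = viral.aggregate_bitscores(hits)
        dm = viral.dice_distance(sums)
        tree = viral.neighbor_joining(dm)
        write_newick(tree, out / "phage_nj.nwk")
        densities = {g.genome_id: motifs.motif_density(g, spec) for g in phages}
        assoc = viral.clade_density_association(densities, phage_truth.phage_clades)
        results["phage_clade_p"] = assoc["p"] if assoc else None
        results["phage_clades_monophyletic"] = all(
            viral.is_monophyletic(
                tree, {g for g, c in phage_truth.phage_clades.items() if c == clade}
            )
            for clade in ("normal", "depleted")
        )

    manifest_path = out / "manifest.json"
    artifacts = sorted(p for p in out.iterdir() if p.is_file() and p != manifest_path)
    manifest = {
        "config": {
            k: v for k, v in dataclasses.asdict(config).items() if k != "synth"
        },
        "results": _jsonable(results),
        "artifacts": {p.name: _sha256(p) for p in artifacts},
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (obj != obj):
        return None
    return obj
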