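"""End-to-end orchestration of the strain-collection analysis.

Stages (in run order): simulate -> assembly stats -> pangenome
(classification, rarefaction, Canberra clustering) -> SNP calling -> effect
classification -> entropy group reports -> tetranucleotide tree -> ANI
matrix -> SNP NJ tree with bootstrap -> tree comparisons. Every stage writes
plain-text outputs (TSV / FASTA / Newick) into the output directory and can
be re-run individually from the saved intermediates. Randomness in each
stochastic stage comes from a generator derived from the global seed and the
stage name, so toggling stages does not perturb the others.
"""

from __future__ import annotations

import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genome_io, group_analysis, pangenome, phylo, signatures, variants
from .synthetic_evolution import EvolutionConfig, simulate_dataset

log = logging.getLogger("strainphy")


@dataclass
class PipelineConfig:
    outdir: str = "strainphy_out"
    seed: int = 0
    genomes_dir: str | None = None  # None => simulate
    reference: str | None = None
    annotation: str | None = None
    groups_file: str | None = None
    stages: list[str] = field(
        default_factory=lambda: [
            "simulate", "stats", "pangenome", "snps", "effects",
            "entropy", "tetra", "ani", "tree", "compare",
        ]
    )
    # module parameters
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    rarefaction_iterations: int = 49
    anchor_k: int = 21
    ani_fragment_len: int = 1020
    bootstrap_reps: int = 200

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        evo_raw = dict(raw.pop("evolution", {}))
        if "strains_per_group" in evo_raw:
            evo_raw["strains_per_group"] = tuple(evo_raw["strains_per_group"])
        return cls(**raw, evolution=EvolutionConfig(**evo_raw))

    def stage_seed(self, stage: str) -> int:
        return (zlib.crc32(stage.encode()) ^ int(self.seed)) % (2**31)


def _outpath(cfg: PipelineConfig, *parts: str) -> Path:
    p = Path(cfg.outdir).joinpath(*parts)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p


def run_simulate(cfg: PipelineConfig):
    """Generate the synthetic dataset and write it plus its truth tables."""
    evo = cfg.evolution
    evo.seed = cfg.stage_seed("simulate")
    reference, annotations, assemblies, truth = simulate_dataset(evo)
    d = _outpath(cfg, "simulate", "x").parent
    genome_io.write_fasta(reference, d / "reference.fasta")
    genome_io.write_cds_gff(annotations, d / "reference.gff")
    gdir = d / "genomes"
    gdir.mkdir(exist_ok=True)
    for sid, asm in assemblies.items():
        genome_io.write_fasta(asm, gdir / f"{sid}.fasta")
    genome_io.write_newick(truth.true_tree, d / "true_tree.nwk")
    genome_io.write_matrix_tsv(truth.true_ortholog_matrix, d / "true_orthologs.tsv")
    truth.diagnostic_snps.to_csv(d / "true_diagnostic_snps.tsv", sep="\t", index=False)
    genome_io.write_group_table(truth.groups, d / "groups.tsv")
    return reference, annotations, assemblies, truth


def load_inputs(cfg: PipelineConfig):
    """Load reference, annotation, assemblies and groups from configured paths."""
    base = Path(cfg.outdir) / "simulate"
    ref_path = cfg.reference or base / "reference.fasta"
    ann_path = cfg.annotation or base / "reference.gff"
    gdir = Path(cfg.genomes_dir or base / "genomes")
    grp_path = cfg.groups_file or base / "groups.tsv"
    reference = genome_io.read_fasta(ref_path, strain_id="reference")
    annotations = genome_io.read_cds_gff(ann_path)
    assemblies = {
        p.stem: genome_io.read_fasta(p) for p in sorted(gdir.glob("*.fasta"))
    }
    groups = genome_io.read_group_table(grp_path)
    return reference, annotations, assemblies, groups


def run_all(cfg: PipelineConfig) -> dict:
    """Run the configured stages; returns the in-memory result bundle."""
    t0 = time.time()
    results: dict = {}
    stages = cfg.stages

    def timed(stage):
        log.info("stage %s starting", stage)
        return time.time()

    if "simulate" in stages:
        t = timed("simulate")
        reference, annotations, assemblies, truth = run_simulate(cfg)
        results["truth"] = truth
        groups = truth.groups
        log.info("stage simulate done in %.1fs", time.time() - t)
    else:
        reference, annotations, assemblies, groups = load_inputs(cfg)
    results.update(
        reference=reference, annotations=annotations, assemblies=assemblies, groups=groups
    )

    if "stats" in stages:
        t = timed("stats")
        rows = {
            sid: vars(genome_io.assembly_stats(asm)) for sid, asm in assemblies.items()
        }
        stats = pd.DataFrame(rows).T.drop(columns=["cds_count"])
        genome_io.write_matrix_tsv(stats, _outpath(cfg, "stats.tsv"))
        results["stats"] = stats
        log.info("stage stats done in %.1fs", time.time() - t)

    ortho = results.get("truth").true_ortholog_matrix if "truth" in results else None
    if ortho is None:
        tpath = Path(cfg.outdir) / "simulate" / "true_orthologs.tsv"
        if tpath.exists():
            ortho = genome_io.read_matrix_tsv(tpath)
    if "pangenome" in stages and ortho is not None:
        t = timed("pangenome")
        report = pangenome.classify_pangenome(ortho)
        genome_io.write_matrix_tsv(report.to_frame(), _outpath(cfg, "pangenome", "report.tsv"))
        curve = pangenome.rarefaction(
            ortho, iterations=cfg.rarefaction_iterations,
            seed=np.random.default_rng(cfg.stage_seed("pangenome")),
        )
        curve.to_csv(_outpath(cfg, "pangenome", "rarefaction.tsv"), sep="\t", index=False)
        cdm = pangenome.canberra_matrix(ortho)
        genome_io.write_matrix_tsv(cdm.to_dataframe(), _outpath(cfg, "pangenome", "canberra.tsv"))
        order, _, top_split = pangenome.cluster_order(cdm)
        with open(_outpath(cfg, "pangenome", "canberra_order.txt"), "w") as fh:
            fh.write("\n".join(order) + "\n")
        results.update(pangenome_report=report, rarefaction=curve, canberra=cdm,
                       canberra_order=order, canberra_top_split=top_split)
        log.info("stage pangenome done in %.1fs", time.time() - t)

    if "snps" in stages:
        t = timed("snps")
        snp = variants.call_snps(reference, assemblies, k=cfg.anchor_k)
        variants.write_snp_tsv(snp, _outpath(cfg, "snps", "snp_matrix.tsv"))
        variants.write_snp_vcf(snp, _outpath(cfg, "snps", "snps.vcf"))
        pseudo = variants.concat_pseudosequence(snp)
        with open(_outpath(cfg, "snps", "pseudo.fasta"), "w") as fh:
            for sid, seq in pseudo.items():
                fh.write(f">{sid}\n{seq}\n")
        results.update(snp_matrix=snp, pseudo=pseudo)
        log.info("stage snps done in %.1fs (%d positions)", time.time() - t, len(snp))

    if "effects" in stages and "snp_matrix" in results:
        t = timed("effects")
        effects = variants.classify_effects(results["snp_matrix"], annotations, reference)
        pd.DataFrame([vars(e) for e in effects]).to_csv(
            _outpath(cfg, "effects", "effects.tsv"), sep="\t", index=False
        )
        results["effects"] = effects
        log.info("stage effects done in %.1fs", time.time() - t)

    if "entropy" in stages and "snp_matrix" in results:
        t = timed("entropy")
        _, spec = group_analysis.specific_snps(results["snp_matrix"], groups)
        table = group_analysis.snp_effect_table(
            spec, results["snp_matrix"], results.get("effects", []), groups
        )
        genome_io.write_matrix_tsv(table, _outpath(cfg, "entropy", "snp_group_table.tsv"))
        results.update(specific_snps=spec, snp_group_table=table)
        if ortho is not None:
            _, otable = group_analysis.specific_orthologs(ortho, groups)
            genome_io.write_matrix_tsv(
                otable, _outpath(cfg, "entropy", "ortholog_group_table.tsv")
            )
            results["ortholog_group_table"] = otable
        log.info("stage entropy done in %.1fs", time.time() - t)

    if "tetra" in stages:
        t = timed("tetra")
        sigs = [signatures.tetra_signature(a) for _, a in sorted(assemblies.items())]
        sig_df = pd.DataFrame(
            [s.z for s in sigs], index=[s.strain_id for s in sigs],
            columns=signatures.TETRA_WORDS,
        )
        genome_io.write_matrix_tsv(sig_df, _outpath(cfg, "tetra", "signatures.tsv"))
        tdm = signatures.tetra_distance_matrix(sigs)
        genome_io.write_matrix_tsv(tdm.to_dataframe(), _outpath(cfg, "tetra", "tetra_dist.tsv"))
        ttree = phylo.nj_tree(tdm)
        genome_io.write_newick(ttree, _outpath(cfg, "tetra", "tetra_tree.nwk"))
        results.update(tetra=tdm, tetra_tree=ttree)
        log.info("stage tetra done in %.1fs", time.time() - t)

    if "ani" in stages:
        t = timed("ani")
        ani_df, ani_dm = signatures.ani_matrix(assemblies, fragment_len=cfg.ani_fragment_len)
        genome_io.write_matrix_tsv(ani_df, _outpath(cfg, "ani", "ani_matrix.tsv"))
        calls = []
        for i, a in enumerate(ani_df.index):
            for b in ani_df.columns[i + 1:]:
                calls.append((a, b, ani_df.loc[a, b], ani_df.loc[a, b] > 95.0))
        pd.DataFrame(calls, columns=["strain_a", "strain_b", "ani_percent", "same_species"]).to_csv(
            _outpath(cfg, "ani", "species_calls.tsv"), sep="\t", index=False
        )
        atree = phylo.nj_tree(ani_dm)
        genome_io.write_newick(atree, _outpath(cfg, "ani", "ani_tree.nwk"))
        results.update(ani=ani_df, ani_tree=atree)
        log.info("stage ani done in %.1fs", time.time() - t)

    if "tree" in stages and "pseudo" in results:
        t = timed("tree")
        tree, failed = phylo.bootstrap_support(
            results["pseudo"], n_reps=cfg.bootstrap_reps,
            seed=np.random.default_rng(cfg.stage_seed("tree")),
        )
        genome_io.write_newick(tree, _outpath(cfg, "tree", "snp_tree.nwk"))
        results.update(snp_tree=tree, bootstrap_failed=failed)
        log.info("stage tree done in %.1fs", time.time() - t)

    if "compare" in stages:
        t = timed("compare")
        named = {
            k: results[k]
            for k in ("snp_tree", "tetra_tree", "ani_tree")
            if k in results
        }
        rows = []
        names = sorted(named)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                rf, shared = phylo.compare_trees(named[a], named[b])
                rows.append((a, b, rf, len(shared)))
        cmp_df = pd.DataFrame(rows, columns=["tree_a", "tree_b", "rf", "shared_bipartitions"])
        cmp_df.to_csv(_outpath(cfg, "compare", "tree_comparisons.tsv"), sep="\t", index=False)
        results["tree_comparisons"] = cmp_df
        log.info("stage compare done in %.1fs", time.time() - t)

    with open(_outpath(cfg, "run_log.txt"), "a") as fh:
        fh.write(f"seed={cfg.seed} stages={','.join(stages)} wall={time.time() - t0:.1f}s\n")
        fh.write(f"config: {cfg}\n")
    log.info("pipeline done in %.1fs", time.time() - t0)
    return results
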