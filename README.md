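# strainphy

Comparative phylogenomics of closely related bacterial strain collections —
the situation typified by *Oenococcus oeni*, the lactic acid bacterium that
performs malolactic fermentation in wine and cider, whose strains fall into
a few genetic groups shaped by adaptation to specific products. `strainphy`
re-implements that style of analysis as a tested, reusable pipeline over
plain-text formats (FASTA, GFF3, TSV, VCF, Newick), and ships a synthetic
genome-evolution generator so every stage can be validated against known
ground truth.

## What it computes

Given one multi-FASTA assembly per strain, a reference genome with CDS
annotation, and a strain-group table:

- **Assembly statistics** — contigs, total bp, N50, L50, and the
  fragmentation index `N50 ratio = ((contigs − L50) / L50) × contigs`.
- **Pangenome** — ortholog groups classified into coregenome (present in
  all strains), cloudgenome (exactly one strain) and shellgenome (the
  rest); rarefaction of core/pan sizes over random distinct strain subsets;
  Canberra distance on ortholog CDS counts with complete-linkage clustering.
- **SNPs** — reference-anchored SNP matrix from unique k-mer anchor
  chaining (substitutions only; indel-containing segments are excluded),
  per-strain pseudo-sequences concatenating all alleles, and codon-level
  effect classification (synonymous / nonsynonymous / start lost / stop
  lost / stop gained, translation table 11, strand-aware).
- **Group-specific markers** — Shannon entropy `H = −Σ p(xᵢ) log₂ p(xᵢ)`
  of each SNP's alleles (and each ortholog's CDS count) within a named
  strain group; a marker is group-specific when `H = 0` inside the group
  and the group's uniform state occurs in no strain outside it.
- **Trees** — Kimura 2-parameter distances
  `d = −½ ln((1 − 2P − Q)·√(1 − 2Q))` on SNP pseudo-sequences, Saitou–Nei
  neighbor joining with nonparametric bootstrap supports; tetranucleotide
  z-score signatures (1 − Pearson distance); fragment ANI (1,020 bp pieces,
  best reciprocal matches, >95 % = same species); Robinson–Foulds
  comparison between all resulting trees.
- **Simulation** — a rooted strain phylogeny with groups as clades, K2P
  substitutions along branches, whole-gene gain/loss creating
  core/shell/cloud structure, and synonymous group-diagnostic SNPs injected
  at fourfold-degenerate sites, with complete truth tables.

## Worked example

```python
from strainphy.synthetic_evolution import EvolutionConfig, simulate_dataset
from strainphy import pangenome, variants, group_analysis, phylo

cfg = EvolutionConfig(strains_per_group=(4, 3, 1), gene_count_root=60, seed=11)
reference, annotations, assemblies, truth = simulate_dataset(cfg)

rep = pangenome.classify_pangenome(truth.true_ortholog_matrix)
print(rep.to_frame())

snp = variants.call_snps(reference, assemblies)
print("SNP positions:", len(snp))

_, spec = group_analysis.specific_snps(snp, truth.groups)
print({g: len(v) for g, v in spec.items()}, "group-specific SNPs")

pseudo = variants.concat_pseudosequence(snp)
tree, _ = phylo.bootstrap_support(pseudo, n_reps=200, seed=9)
for g, members in truth.groups.items():
    print(g, phylo.is_group_monophyletic(tree, members),
          phylo.group_support(tree, members))
```

prints

```
             ortholog_groups  total_genes
coregenome                52           52
shellgenome               10           10
cloudgenome                7            7
pangenome                 69           69
SNP positions: 4410
{'A': 291, 'B': 292, 'C': 1627} group-specific SNPs
A True 100
B True 100
C True None
```

Of the 60 ancestral genes plus later gains, 52 ortholog groups remain in
every strain (core), 7 are private to one strain (cloud), and
core + shell + cloud = pan by construction. 4,410 variant positions were
called against the ancestor; each group carries a few hundred SNPs fixed
inside it and absent outside (the singleton group C, one strain on a long
branch, has the most). Both multi-strain groups come out monophyletic in
the SNP neighbor-joining tree with 100 % bootstrap support (a singleton is
trivially monophyletic; no internal edge, hence no support value).

The same stages are available from the shell:

```sh
strainphy all --seed 1 --outdir out/          # simulate + every stage
strainphy snps --outdir out/                  # re-run one stage from disk
```

## Layout

| Module | Contents |
| --- | --- |
| `strainphy.genome_io` | FASTA/GFF3/TSV/Newick I/O, assembly statistics, strain groups |
| `strainphy.synthetic_evolution` | genome evolution simulator + truth tables |
| `strainphy.pangenome` | core/shell/cloud, rarefaction, Canberra clustering |
| `strainphy.variants` | anchor-chained SNP calling, pseudo-sequences, effect classification |
| `strainphy.group_analysis` | entropy-based group-specific SNPs/orthologs |
| `strainphy.signatures` | tetranucleotide signatures, fragment ANI |
| `strainphy.phylo` | K2P, neighbor joining, bootstrap, Robinson–Foulds |
| `strainphy.pipeline` / `strainphy.cli` | stage orchestration and the `strainphy` command |

See `docs/methods.md` for the models, parameter choices and limitations.
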