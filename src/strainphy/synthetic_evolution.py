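"""Synthetic bacterial strain-genome evolution with full ground truth.

Generates a strain collection the way the downstream analyses assume real
collections arose: a rooted strain phylogeny whose leaves fall into named
groups (each group a clade, within-group divergence below between-group
divergence), an ancestral genome of protein-coding genes separated by
intergenic spacers, Kimura 2-parameter substitutions applied site-wise along
every branch, whole-gene gain and loss events shaping core/shell/cloud
structure, and group-diagnostic SNPs injected at synonymous third-codon
sites so that each is fixed inside its group and absent outside.

Everything the generator does is recorded in :class:`TruthTables`, which is
the acceptance surface for the rest of the pipeline: the true tree, the true
ortholog count matrix, the injected diagnostic SNPs, every variant position,
and the true allele of every strain at every ancestral-genome position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .genome_io import CdsAnnotation, GenomeAssembly, StrainGroups

BASES = np.array(["A", "C", "G", "T"])
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G
# transversion targets per base code (A,C,G,T)
_TV1 = np.array([1, 0, 1, 0], dtype=np.uint8)
_TV2 = np.array([3, 2, 3, 2], dtype=np.uint8)
_STOP_CODONS = ("TAA", "TAG", "TGA")
# codon prefixes whose third position is fourfold degenerate (table 11)
_FOURFOLD_PREFIXES = {"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"}
_MISSING = np.uint8(255)
_GENE_SEPARATOR = "N" * 25


@dataclass
class EvolutionConfig:
    """Parameters of the simulated strain collection.

    ``tree_depth`` is the expected number of substitutions per site on every
    root-to-leaf path; ``kappa`` the transition/transversion rate ratio;
    ``gain_rate``/``loss_rate``/``duplication_rate`` are events per gene per
    unit branch length.
    """

    strains_per_group: tuple[int, ...] = (10, 6, 1)
    tree_depth: float = 0.02
    kappa: float = 2.0
    gene_count_root: int = 200
    gene_len_mean: int = 999
    gc_content: float = 0.38
    intergenic_mean: int = 80
    gain_rate: float = 2.0
    loss_rate: float = 2.0
    duplication_rate: float = 0.0
    n_diagnostic_snps_per_group: int = 25
    seed: int = 0

    @property
    def n_groups(self) -> int:
        return len(self.strains_per_group)

    @property
    def group_names(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_groups)]

    def validate(self) -> None:
        if any(s < 1 for s in self.strains_per_group):
            raise ValueError("every group needs at least one strain")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        for r in (self.gain_rate, self.loss_rate, self.duplication_rate, self.tree_depth):
            if r < 0:
                raise ValueError("rates and depths must be non-negative")
        if self.gene_len_mean % 3 or self.gene_len_mean < 99:
            raise ValueError("gene_len_mean must be a multiple of 3, at least 99")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")


@dataclass
class TruthTables:
    """Everything the generator knows, for auditing the analysis pipeline."""

    true_tree: TreeNode
    groups: StrainGroups
    true_ortholog_matrix: pd.DataFrame
    diagnostic_snps: pd.DataFrame  # columns: position (1-based), group, allele
    all_variant_positions: np.ndarray
    reference_alleles: pd.DataFrame  # strain rows x position columns? no: see below
    annotations: list[CdsAnnotation] = field(default_factory=list)

    def group_fixed_positions(self, group: str) -> dict[int, str]:
        """Variant positions (1-based) whose fixation in ``group`` the truth
        does not contradict: every group member carrying the site has the
        same allele, and no strain outside the group carries that allele.

        Strains in which the site's gene was lost have no allele there and
        constrain nothing. Computed from the true aligned alleles, so the
        result covers both the injected diagnostics and substitutions that
        happened to occur on the group's stem branch.
        """
        arr = self.reference_alleles.to_numpy()  # strains x positions, uint8
        strains = list(self.reference_alleles.index)
        in_rows = np.array([s in self.groups[group] for s in strains])
        gin = np.ma.masked_equal(arr[in_rows], _MISSING)
        out_arr = arr[~in_rows]
        any_observed = ~gin.mask.all(axis=0) if gin.mask is not np.ma.nomask else np.ones(arr.shape[1], bool)
        allele = gin.min(axis=0)
        uniform = np.asarray(gin.max(axis=0) == allele) & any_observed
        candidate = uniform.copy()
        if out_arr.size:
            contradicted = ((out_arr == allele.filled(200)) & (out_arr != _MISSING)).any(axis=0)
            candidate &= ~contradicted
        pos = np.flatnonzero(candidate)
        variable = np.isin(pos + 1, self.all_variant_positions)
        pos = pos[variable]
        allele = allele.filled(0)
        return {int(p) + 1: str(BASES[allele[p]]) for p in pos}


# ---------------------------------------------------------------------------
# Tree simulation

def _build_clade(names: list[str], height: float, rng: np.random.Generator) -> TreeNode:
    if len(names) == 1:
        node = TreeNode(name=names[0])
        node.length = height
        return node
    k = int(rng.integers(1, len(names)))
    left, right = names[:k], names[k:]
    child_h = height * float(rng.uniform(0.4, 0.8))
    node = TreeNode(children=[_build_clade(left, child_h, rng), _build_clade(right, child_h, rng)])
    node.length = 0.0
    for c in node.children:
        c.length += height - child_h
    return node


def simulate_tree(config: EvolutionConfig, rng: np.random.Generator | None = None) -> TreeNode:
    """Rooted ultrametric strain tree in which every group is a clade.

    Group clades are shallow (30% of ``tree_depth``) and hang off a backbone
    whose joins sit near the root, so within-group distances stay below
    between-group distances.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    depth = config.tree_depth
    clades = []
    for gname, n in zip(config.group_names, config.strains_per_group):
        names = [f"{gname}{i + 1:02d}" for i in range(n)]
        order = list(rng.permutation(len(names)))
        shuffled = [names[i] for i in order]
        h = 0.3 * depth if n > 1 else 0.0
        clade = _build_clade(shuffled, h, rng)
        clade.length = 0.0  # stem set when attached to the backbone
        clades.append((clade, h))
    if len(clades) == 1:
        tree, h = clades[0]
        tree.length = depth - h
        root = TreeNode(children=[tree])
        return root
    # left-laddered backbone; join depths spread between 0.55*depth and depth
    n_join = len(clades) - 1
    join_depths = np.linspace(0.55 * depth, depth, n_join)
    node, h_node = clades[0]
    node_depth = h_node
    for k in range(1, len(clades)):
        other, h_other = clades[k]
        d = float(join_depths[k - 1])
        node.length = d - node_depth
        other.length = d - h_other
        node = TreeNode(children=[node, other])
        node_depth = d
    node.length = 0.0
    return node


def true_groups(config: EvolutionConfig) -> StrainGroups:
    groups = {
        g: {f"{g}{i + 1:02d}" for i in range(n)}
        for g, n in zip(config.group_names, config.strains_per_group)
    }
    return StrainGroups(groups)


# ---------------------------------------------------------------------------
# Root genome

def _random_cds(length: int, rng: np.random.Generator) -> np.ndarray:
    """Random intact CDS (codes): ATG start, no internal stop, one stop."""
    n_codons = length // 3
    codons = ["ATG"]
    sense = [b1 + b2 + b3 for b1 in "ACGT" for b2 in "ACGT" for b3 in "ACGT"]
    non_stop = [c for c in sense if c not in _STOP_CODONS]
    idx = rng.integers(0, len(non_stop), size=n_codons - 2)
    codons.extend(non_stop[i] for i in idx)
    codons.append(_STOP_CODONS[int(rng.integers(0, 3))])
    seq = "".join(codons)
    return np.array([_BASE_CODE[b] for b in seq], dtype=np.uint8)


def _random_spacer(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _gene_length(config: EvolutionConfig, rng: np.random.Generator) -> int:
    return 3 * max(33, int(rng.poisson(config.gene_len_mean / 3)))


def generate_root_genome(
    config: EvolutionConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeAssembly, list[CdsAnnotation]]:
    """Single-contig ancestral genome of interleaved CDS and spacers."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    parts: list[np.ndarray] = []
    annotations: list[CdsAnnotation] = []
    pos = 0
    for g in range(config.gene_count_root):
        spacer = _random_spacer(max(30, int(rng.poisson(config.intergenic_mean))), config.gc_content, rng)
        parts.append(spacer)
        pos += len(spacer)
        length = _gene_length(config, rng)
        cds = _random_cds(length, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        genomic = cds if strand == "+" else _COMPLEMENT[cds[::-1]]
        parts.append(genomic)
        annotations.append(
            CdsAnnotation(
                gene_id=f"g{g + 1:04d}",
                contig_id="ancestor",
                start=pos + 1,
                end=pos + length,
                strand=strand,
            )
        )
        pos += length
    parts.append(_random_spacer(max(30, int(rng.poisson(config.intergenic_mean))), config.gc_content, rng))
    seq = np.concatenate(parts)
    assembly = GenomeAssembly(
        strain_id="ancestor", contigs=[("ancestor", "".join(BASES[seq]))]
    )
    return assembly, annotations


# ---------------------------------------------------------------------------
# K2P site evolution

def k2p_probabilities(d: float, kappa: float) -> tuple[float, float]:
    """(transition probability, per-transversion probability) after expected
    ``d`` substitutions per site at transition/transversion ratio ``kappa``."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e4 = np.exp(-4.0 * beta * d)
    e2 = np.exp(-2.0 * (alpha + beta) * d)
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e4
    return float(p_ts), float(p_tv)


def mutate_sites(seq: np.ndarray, d: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Apply K2P substitutions site-wise for branch length ``d``."""
    if d == 0 or len(seq) == 0:
        return seq.copy()
    p_ts, p_tv = k2p_probabilities(d, kappa)
    u = rng.random(len(seq))
    out = seq.copy()
    c1 = 1.0 - p_ts - 2.0 * p_tv
    ts = (u >= c1) & (u < c1 + p_ts)
    tv1 = (u >= c1 + p_ts) & (u < c1 + p_ts + p_tv)
    tv2 = u >= c1 + p_ts + p_tv
    out[ts] ^= 2  # A<->G, C<->T under the A,C,G,T = 0,1,2,3 coding
    out[tv1] = _TV1[seq[tv1]]
    out[tv2] = _TV2[seq[tv2]]
    return out


# ---------------------------------------------------------------------------
# Whole-genome evolution along the tree

@dataclass
class _NodeState:
    seq: np.ndarray
    present: set[str]
    gained: dict[str, np.ndarray]
    counts: dict[str, int]


def evolve_genomes(
    root: GenomeAssembly,
    annotations: list[CdsAnnotation],
    tree: TreeNode,
    config: EvolutionConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, GenomeAssembly], TruthTables]:
    """Evolve the root genome down the tree; returns leaf assemblies + truth.

    Substitutions follow the K2P closed-form site probabilities; gene loss
    removes a CDS (and its sequence) from all descendants, gene gain inserts
    a novel CDS present in all descendants; diagnostic SNPs are injected
    afterwards at fourfold-degenerate third-codon sites of core genes.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    ref_seq = np.array([_BASE_CODE[b] for b in root.contigs[0][1]], dtype=np.uint8)
    gene_ids = [a.gene_id for a in annotations]
    ann_by_id = {a.gene_id: a for a in annotations}
    gain_counter = [0]

    leaf_states: dict[str, _NodeState] = {}

    def descend(node: TreeNode, state: _NodeState) -> None:
        for child in node.children:
            d = float(child.length or 0.0)
            seq = mutate_sites(state.seq, d, config.kappa, rng)
            gained = {
                gid: mutate_sites(s, d, config.kappa, rng)
                for gid, s in state.gained.items()
            }
            present = set(state.present)
            counts = dict(state.counts)
            if d > 0:
                p_loss = 1.0 - np.exp(-config.loss_rate * d)
                for gid in sorted(present):
                    if rng.random() < p_loss:
                        present.discard(gid)
                        gained.pop(gid, None)
                        counts.pop(gid, None)
                n_gain = int(rng.poisson(config.gain_rate * d * len(present)))
                for _ in range(n_gain):
                    gain_counter[0] += 1
                    gid = f"gain{gain_counter[0]:04d}"
                    gained[gid] = _random_cds(_gene_length(config, rng), rng)
                    present.add(gid)
                    counts[gid] = 1
                n_dup = int(rng.poisson(config.duplication_rate * d * len(present)))
                for _ in range(n_dup):
                    gid = sorted(present)[int(rng.integers(0, len(present)))]
                    counts[gid] = counts.get(gid, 1) + 1
            child_state = _NodeState(seq=seq, present=present, gained=gained, counts=counts)
            if child.is_tip():
                leaf_states[child.name] = child_state
            else:
                descend(child, child_state)

    root_state = _NodeState(
        seq=ref_seq,
        present=set(gene_ids),
        gained={},
        counts={gid: 1 for gid in gene_ids},
    )
    descend(tree, root_state)

    strains = sorted(leaf_states)
    groups = true_groups(config)

    # true aligned alleles over the ancestral coordinate system
    allele_mat = np.stack([leaf_states[s].seq for s in strains]).astype(np.uint8)
    for r, s in enumerate(strains):
        lost = set(gene_ids) - leaf_states[s].present
        for gid in lost:
            a = ann_by_id[gid]
            allele_mat[r, a.start - 1 : a.end] = _MISSING

    diagnostics = _inject_diagnostics(
        allele_mat, strains, groups, annotations, leaf_states, config, rng
    )

    variant = _variant_positions(allele_mat, ref_seq)

    # ortholog truth matrix
    all_gids = gene_ids + [f"gain{i + 1:04d}" for i in range(gain_counter[0])]
    counts = np.zeros((len(all_gids), len(strains)), dtype=int)
    for c, s in enumerate(strains):
        st = leaf_states[s]
        for r, gid in enumerate(all_gids):
            if gid in st.present:
                counts[r, c] = st.counts.get(gid, 1)
    matrix = pd.DataFrame(counts, index=all_gids, columns=strains)
    matrix = matrix[matrix.sum(axis=1) > 0]

    assemblies = {
        s: _emit_assembly(s, leaf_states[s], annotations, config, rng)
        for s in strains
    }

    truth = TruthTables(
        true_tree=tree,
        groups=groups,
        true_ortholog_matrix=matrix,
        diagnostic_snps=diagnostics,
        all_variant_positions=variant,
        reference_alleles=pd.DataFrame(allele_mat, index=strains),
        annotations=annotations,
    )
    return assemblies, truth


def _variant_positions(allele_mat: np.ndarray, ref_seq: np.ndarray) -> np.ndarray:
    observed = allele_mat != _MISSING
    diff = (allele_mat != ref_seq[None, :]) & observed
    return np.flatnonzero(diff.any(axis=0)) + 1


def _inject_diagnostics(
    allele_mat: np.ndarray,
    strains: list[str],
    groups: StrainGroups,
    annotations: list[CdsAnnotation],
    leaf_states: dict[str, _NodeState],
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Inject group-fixed synonymous SNPs at fourfold third-codon sites.

    Eligible sites lie in genes present in every strain, at codons (not the
    start or stop) where all strains currently agree at all three positions
    and the first two sense bases form a fourfold-degenerate box; the group
    allele is set to the transition of the shared base, so it is synonymous
    for every group member and absent outside by construction.
    """
    n_per_group = config.n_diagnostic_snps_per_group
    records: list[tuple[int, str, str]] = []
    if n_per_group == 0:
        return pd.DataFrame(records, columns=["position", "group", "allele"])
    core_genes = [
        a for a in annotations
        if all(a.gene_id in leaf_states[s].present for s in strains)
    ]
    candidates: list[tuple[int, bool]] = []  # (0-based genome pos of third base, is_minus)
    for a in core_genes:
        n_codons = a.length // 3
        for ci in range(1, n_codons - 1):
            if a.strand == "+":
                p0 = a.start - 1 + 3 * ci
                idx = (p0, p0 + 1, p0 + 2)
            else:
                p0 = a.end - 1 - 3 * ci
                idx = (p0, p0 - 1, p0 - 2)
            col = allele_mat[:, list(idx)]
            if (col == _MISSING).any() or not (col == col[0]).all():
                continue
            codes = col[0]
            if a.strand == "-":
                codes = _COMPLEMENT[codes]
            prefix = BASES[codes[0]] + BASES[codes[1]]
            if prefix in _FOURFOLD_PREFIXES:
                candidates.append((idx[2], a.strand == "-"))
    needed = n_per_group * len(groups.groups)
    if needed > len(candidates):
        raise ValueError(
            f"requested {needed} diagnostic SNPs but only {len(candidates)} eligible sites"
        )
    order = rng.permutation(len(candidates))
    taken = 0
    for gname in groups.groups:
        members = np.array([s in groups[gname] for s in strains])
        for _ in range(n_per_group):
            pos, minus = candidates[order[taken]]
            taken += 1
            shared = allele_mat[0, pos]
            new = np.uint8(shared ^ 2)  # transition keeps the fourfold box
            allele_mat[members, pos] = new
            for s, m in zip(strains, members):
                if m:
                    leaf_states[s].seq[pos] = new
            records.append((pos + 1, gname, str(BASES[new])))
    return pd.DataFrame(records, columns=["position", "group", "allele"]).sort_values(
        "position", ignore_index=True
    )


def _emit_assembly(
    strain: str,
    state: _NodeState,
    annotations: list[CdsAnnotation],
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> GenomeAssembly:
    """Leaf genome: ancestral coordinates minus lost genes, gains appended."""
    lost_spans = [
        (a.start - 1, a.end)
        for a in annotations
        if a.gene_id not in state.present
    ]
    lost_spans.sort()
    pieces: list[str] = []
    cursor = 0
    seq_str = "".join(BASES[state.seq])
    for s, e in lost_spans:
        pieces.append(seq_str[cursor:s])
        cursor = e
    pieces.append(seq_str[cursor:])
    ann_by_id = {a.gene_id: a for a in annotations}
    for gid in sorted(state.present):
        copies = state.counts.get(gid, 1)
        if gid in state.gained:
            gene_seq = "".join(BASES[state.gained[gid]])
            extra = copies
        else:
            a = ann_by_id[gid]
            gene_seq = seq_str[a.start - 1 : a.end]
            extra = copies - 1  # first copy already in place
        for _ in range(extra):
            pieces.append(_GENE_SEPARATOR)
            pieces.append(gene_seq)
    return GenomeAssembly(strain_id=strain, contigs=[(strain, "".join(pieces))])


def fragment_assembly(
    assembly: GenomeAssembly, n_contigs: int, rng: np.random.Generator
) -> GenomeAssembly:
    """Split a single-contig assembly at uniform random breakpoints, to
    exercise contig statistics on draft-like inputs."""
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    cid, seq = assembly.contigs[0]
    if n_contigs == 1:
        return assembly
    cuts = np.sort(rng.choice(np.arange(1, len(seq)), size=n_contigs - 1, replace=False))
    bounds = [0, *cuts.tolist(), len(seq)]
    contigs = [
        (f"{cid}_c{i + 1}", seq[bounds[i] : bounds[i + 1]])
        for i in range(n_contigs)
    ]
    return GenomeAssembly(strain_id=assembly.strain_id, contigs=contigs, metadata=dict(assembly.metadata))


def simulate_dataset(
    config: EvolutionConfig,
) -> tuple[GenomeAssembly, list[CdsAnnotation], dict[str, GenomeAssembly], TruthTables]:
    """One-call generator: (reference, annotation, leaf assemblies, truth)."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    root, annotations = generate_root_genome(config, rng)
    assemblies, truth = evolve_genomes(root, annotations, tree, config, rng)
    return root, annotations, assemblies, truth
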