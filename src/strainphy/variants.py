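"""Reference-anchored SNP calling and codon-level effect classification.

Queries are compared to the reference through unique k-mer anchors (k-mers
occurring exactly once in each genome) chained into the longest collinear
sequence; runs of anchors on one diagonal form gap-free matched blocks whose
inter-anchor segments are compared position by position. Segments whose
lengths disagree between the genomes contain indels and are excluded, so
only substitutions are called. Effects are classified per non-reference
allele against the annotated CDS set under bacterial translation table 11.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genome_io import CdsAnnotation, GenomeAssembly

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = np.array(["A", "C", "G", "T"])
_MISSING = np.uint8(255)

EFFECT_CATEGORIES = (
    "noncoding",
    "synonymous",
    "nonsynonymous",
    "start_lost",
    "stop_lost",
    "stop_gained",
)


@dataclass(frozen=True)
class MatchedBlock:
    """Gap-free aligned stretch; 0-based starts, equal length in both."""

    ref_contig: str
    ref_start: int
    qry_contig: str
    qry_start: int
    length: int


@dataclass
class SnpMatrix:
    """Reference-anchored variant positions by strain allele table.

    ``positions`` holds (contig, 1-based position, reference allele);
    ``alleles`` is a DataFrame indexed by (contig, position) with one
    single-character column per strain, '.' marking missing data.
    """

    positions: list[tuple[str, int, str]]
    alleles: pd.DataFrame

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def strain_ids(self) -> list[str]:
        return list(self.alleles.columns)


@dataclass(frozen=True)
class SnpEffectRecord:
    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    effect: str
    gene_id: str | None = None
    codon_change: str | None = None
    aa_change: str | None = None
    truncation_fraction: float | None = None


def _encode(seq: str) -> np.ndarray:
    arr = np.full(len(seq), _MISSING, dtype=np.uint8)
    b = np.frombuffer(seq.encode(), dtype="S1")
    for base, code in _CODE.items():
        arr[b == base.encode()] = code
    return arr


def _unique_kmer_index(assembly: GenomeAssembly, k: int) -> dict[bytes, tuple[str, int]]:
    """k-mer -> (contig, 0-based pos) for k-mers unique genome-wide; k-mers
    containing N are skipped."""
    index: dict[bytes, tuple[str, int] | None] = {}
    for cid, seq in assembly.contigs:
        raw = seq.encode()
        has_n = np.frombuffer(raw, dtype="S1") == b"N"
        bad = np.convolve(has_n.astype(int), np.ones(k, dtype=int), mode="valid") > 0 if len(seq) >= k else []
        for i in range(len(seq) - k + 1):
            if len(bad) and bad[i]:
                continue
            kmer = raw[i : i + k]
            index[kmer] = None if kmer in index else (cid, i)
    return {k_: v for k_, v in index.items() if v is not None}


def _longest_collinear_chain(anchors: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest chain increasing in both coordinates (anchors sorted by ref)."""
    if not anchors:
        return []
    # patience-sorting LIS on query coordinate
    tails: list[int] = []  # query coords of chain tails
    tails_idx: list[int] = []
    parent = [-1] * len(anchors)
    for i, (_, q) in enumerate(anchors):
        j = bisect_left(tails, q)
        if j == len(tails):
            tails.append(q)
            tails_idx.append(i)
        else:
            tails[j] = q
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1]
    while i != -1:
        chain.append(anchors[i])
        i = parent[i]
    return chain[::-1]


def anchor_align(
    reference: GenomeAssembly,
    query: GenomeAssembly,
    k: int = 21,
    _ref_index: dict[bytes, tuple[str, int]] | None = None,
) -> list[MatchedBlock]:
    """Collinear gap-free matched blocks between two genomes.

    Anchors are k-mers unique in both genomes; the longest collinear chain
    per contig pair is kept, and consecutive anchors on one diagonal merge
    into a block spanning from the first anchor to the end of the last.
    Returns an empty list when no anchors exist (strain unmapped).
    """
    if k % 2 == 0 or k < 5:
        raise ValueError("k must be odd and >= 5")
    ref_idx = _ref_index if _ref_index is not None else _unique_kmer_index(reference, k)
    qry_idx = _unique_kmer_index(query, k)
    shared = set(ref_idx) & set(qry_idx)
    by_pair: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for kmer in shared:
        rc, rp = ref_idx[kmer]
        qc, qp = qry_idx[kmer]
        by_pair.setdefault((rc, qc), []).append((rp, qp))
    blocks: list[MatchedBlock] = []
    for (rc, qc), anchors in sorted(by_pair.items()):
        anchors.sort()
        chain = _longest_collinear_chain(anchors)
        if not chain:
            continue
        start_r, start_q = chain[0]
        prev_r, prev_q = chain[0]
        for r, q in chain[1:]:
            if r - prev_r == q - prev_q and r > prev_r:
                prev_r, prev_q = r, q
                continue
            blocks.append(MatchedBlock(rc, start_r, qc, start_q, prev_r + k - start_r))
            start_r, start_q = r, q
            prev_r, prev_q = r, q
        blocks.append(MatchedBlock(rc, start_r, qc, start_q, prev_r + k - start_r))
    return blocks


def _ref_layout(reference: GenomeAssembly) -> tuple[dict[str, int], int, np.ndarray]:
    offsets, total = {}, 0
    for cid, seq in reference.contigs:
        offsets[cid] = total
        total += len(seq)
    codes = np.concatenate([_encode(seq) for _, seq in reference.contigs])
    return offsets, total, codes


def call_snps(
    reference: GenomeAssembly,
    queries: dict[str, GenomeAssembly],
    k: int = 21,
    edge_trim: int = 5,
) -> SnpMatrix:
    """SNP matrix over the union of substitution positions across strains.

    Each strain's allele comes from its aligned block at the position, or is
    missing where no block covers it; positions where the reference base is
    N are skipped. The outermost ``edge_trim`` bases of every block are not
    used for calling: a block edge abuts an indel (or a sequence end), and
    the bases right at a deletion junction can coincide with the removed
    sequence and masquerade as alleles of a locus the strain does not carry.
    """
    offsets, total, ref_codes = _ref_layout(reference)
    ref_index = _unique_kmer_index(reference, k)
    strains = sorted(queries)
    allele = np.full((len(strains), total), _MISSING, dtype=np.uint8)
    for r, sid in enumerate(strains):
        qry = queries[sid]
        qseqs = {cid: _encode(seq) for cid, seq in qry.contigs}
        for blk in anchor_align(reference, qry, k=k, _ref_index=ref_index):
            if blk.length <= 2 * edge_trim:
                continue
            off = offsets[blk.ref_contig] + blk.ref_start + edge_trim
            n_use = blk.length - 2 * edge_trim
            allele[r, off : off + n_use] = qseqs[blk.qry_contig][
                blk.qry_start + edge_trim : blk.qry_start + edge_trim + n_use
            ]
    observed = allele != _MISSING
    variant = ((allele != ref_codes[None, :]) & observed).any(axis=0)
    variant &= ref_codes != _MISSING
    cols = np.flatnonzero(variant)
    # map concatenated coordinates back to (contig, 1-based position)
    contig_bounds = sorted((off, cid) for cid, off in offsets.items())
    bound_offs = [b[0] for b in contig_bounds]
    positions: list[tuple[str, int, str]] = []
    for c in cols:
        i = bisect_left(bound_offs, c + 1) - 1
        off, cid = contig_bounds[i]
        positions.append((cid, int(c - off + 1), str(_BASES[ref_codes[c]])))
    data = {}
    for r, sid in enumerate(strains):
        chars = np.where(
            allele[r, cols] == _MISSING, ".", _BASES[np.minimum(allele[r, cols], 3)]
        )
        data[sid] = chars
    idx = pd.MultiIndex.from_tuples(
        [(c, p) for c, p, _ in positions], names=["contig", "position"]
    )
    return SnpMatrix(positions=positions, alleles=pd.DataFrame(data, index=idx))


def concat_pseudosequence(matrix: SnpMatrix) -> dict[str, str]:
    """Per-strain pseudo-sequence concatenating alleles in position order;
    missing alleles become N. All sequences have length = #positions."""
    out = {}
    for sid in matrix.strain_ids:
        col = matrix.alleles[sid].to_numpy()
        out[sid] = "".join(np.where(col == ".", "N", col))
    return out


# ---------------------------------------------------------------------------
# Effect classification

def _translate(codon: str) -> str:
    return str(Seq(codon).translate(table=11))


def classify_effects(
    matrix: SnpMatrix,
    annotations: list[CdsAnnotation],
    reference: GenomeAssembly,
) -> list[SnpEffectRecord]:
    """Classify every (position, non-reference allele) pair in the matrix.

    A position outside every CDS is noncoding. Inside a CDS the reference
    and mutated codons (strand-aware, table 11) are compared: equal amino
    acids are synonymous; a non-synonymous change in the annotated start
    codon is start_lost; losing the stop codon is stop_lost; creating a
    premature stop is stop_gained with truncation fraction = codon index /
    total codons; anything else is nonsynonymous.
    """
    by_contig: dict[str, list[CdsAnnotation]] = {}
    for a in annotations:
        if a.length % 3 != 0:
            warnings.warn(f"CDS {a.gene_id} length not divisible by 3; gene skipped")
            continue
        by_contig.setdefault(a.contig_id, []).append(a)
    for lst in by_contig.values():
        lst.sort(key=lambda a: a.start)
    seqs = dict(reference.contigs)
    records: list[SnpEffectRecord] = []
    for contig, pos, ref_allele in matrix.positions:
        row = matrix.alleles.loc[(contig, pos)]
        alts = sorted(set(row) - {".", ref_allele})
        cds = _containing_cds(by_contig.get(contig, []), pos)
        for alt in alts:
            if cds is None:
                records.append(
                    SnpEffectRecord(contig, pos, ref_allele, alt, "noncoding")
                )
                continue
            records.append(
                _classify_one(contig, pos, ref_allele, alt, cds, seqs[contig])
            )
    return records


def _containing_cds(sorted_cds: list[CdsAnnotation], pos: int) -> CdsAnnotation | None:
    # assumes non-overlapping CDS (bacterial annotation, as emitted here)
    starts = [a.start for a in sorted_cds]
    i = bisect_right(starts, pos) - 1
    if i >= 0 and sorted_cds[i].end >= pos:
        return sorted_cds[i]
    return None


def _classify_one(
    contig: str, pos: int, ref_allele: str, alt: str, cds: CdsAnnotation, seq: str
) -> SnpEffectRecord:
    if cds.strand == "+":
        cds_offset = pos - cds.start
    else:
        cds_offset = cds.end - pos
    codon_idx, in_codon = divmod(cds_offset, 3)
    n_codons = cds.length // 3
    if cds.strand == "+":
        c0 = cds.start + 3 * codon_idx
        codon = seq[c0 - 1 : c0 + 2]
        ref_codon = codon
        alt_codon = codon[:in_codon] + alt + codon[in_codon + 1 :]
    else:
        c_end = cds.end - 3 * codon_idx  # genome coord of codon's first sense base
        genomic = seq[c_end - 3 : c_end]
        ref_codon = str(Seq(genomic).reverse_complement())
        alt_c = str(Seq(alt).complement())
        alt_codon = ref_codon[:in_codon] + alt_c + ref_codon[in_codon + 1 :]
    ref_aa = _translate(ref_codon)
    alt_aa = _translate(alt_codon)
    if ref_aa == alt_aa:
        effect = "synonymous"
    elif codon_idx == 0:
        effect = "start_lost"
    elif ref_aa == "*":
        effect = "stop_lost"
    elif alt_aa == "*":
        effect = "stop_gained"
    else:
        effect = "nonsynonymous"
    trunc = codon_idx / n_codons if effect == "stop_gained" else None
    return SnpEffectRecord(
        contig=contig,
        position=pos,
        ref_allele=ref_allele,
        alt_allele=alt,
        effect=effect,
        gene_id=cds.gene_id,
        codon_change=f"{ref_codon}>{alt_codon}",
        aa_change=f"{ref_aa}>{alt_aa}",
        truncation_fraction=trunc,
    )


# ---------------------------------------------------------------------------
# Serialization

def write_snp_tsv(matrix: SnpMatrix, path) -> None:
    df = matrix.alleles.copy()
    df.insert(0, "ref", [r for _, _, r in matrix.positions])
    df.to_csv(path, sep="\t")


def write_snp_vcf(matrix: SnpMatrix, path) -> None:
    """Minimal VCF 4.2: CHROM POS ID REF ALT QUAL FILTER INFO FORMAT + GTs."""
    strains = matrix.strain_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(strains) + "\n")
        for (contig, pos, ref), (_, row) in zip(
            matrix.positions, matrix.alleles.iterrows()
        ):
            alts = sorted(set(row) - {".", ref})
            allele_index = {ref: "0", ".": "."}
            allele_index.update({a: str(i + 1) for i, a in enumerate(alts)})
            gts = [allele_index[row[s]] for s in strains]
            fh.write(
                f"{contig}\t{pos}\t.\t{ref}\t{','.join(alts) or '.'}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
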