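import numpy as np
import pytest
from Bio.Seq import Seq

from strainphy import variants
from strainphy.genome_io import CdsAnnotation, GenomeAssembly
from strainphy.variants import (
    anchor_align,
    call_snps,
    classify_effects,
    concat_pseudosequence,
)


def random_genome(rng, n=4000, strain="ref") -> GenomeAssembly:
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
    return GenomeAssembly(strain, [("c1", seq)])


def with_substitution(asm: GenomeAssembly, pos0: int, base: str, strain="q") -> GenomeAssembly:
    cid, seq = asm.contigs[0]
    assert seq[pos0] != base
    return GenomeAssembly(strain, [(cid, seq[:pos0] + base + seq[pos0 + 1:])])


class TestAnchorAlign:
    def test_identity_single_full_block(self, rng):
        ref = random_genome(rng)
        blocks = anchor_align(ref, GenomeAssembly("q", ref.contigs))
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.ref_start, b.qry_start, b.length) == (0, 0, ref.total_bp)

    def test_single_substitution_reported(self, rng):
        ref = random_genome(rng)
        alt = "G" if ref.contigs[0][1][2000] != "G" else "T"
        qry = with_substitution(ref, 2000, alt)
        snp = call_snps(ref, {"q": qry})
        assert snp.positions == [("c1", 2001, ref.contigs[0][1][2000])]
        assert snp.alleles["q"].iloc[0] == alt

    def test_no_anchors_means_unmapped(self, rng):
        ref = random_genome(rng, n=2000)
        other = random_genome(np.random.default_rng(999), n=2000, strain="far")
        snp = call_snps(ref, {"far": other})
        # unrelated genome: no collinear anchors -> all missing, no variants
        assert (snp.alleles["far"] == ".").all() if len(snp) else True

    def test_simulator_coverage_of_core_positions(self, small_dataset, small_snp):
        """Anchor blocks cover nearly all variant positions of retained genes."""
        _, _, _, _, truth = small_dataset
        covered = 0
        arr = truth.reference_alleles
        called = {(p, s): a for (c, p, _), (_, row) in zip(small_snp.positions, small_snp.alleles.iterrows()) for s, a in row.items()}
        observed = sum(1 for v in called.values() if v != ".")
        assert observed / len(called) >= 0.95


class TestCallSnps:
    def test_identical_queries_empty_matrix(self, rng):
        ref = random_genome(rng)
        snp = call_snps(ref, {"a": ref, "b": ref})
        assert len(snp) == 0

    def test_query_order_invariance(self, rng):
        ref = random_genome(rng)
        q1 = with_substitution(ref, 500, "A" if ref.contigs[0][1][500] != "A" else "C", "q1")
        q2 = with_substitution(ref, 3000, "A" if ref.contigs[0][1][3000] != "A" else "C", "q2")
        m1 = call_snps(ref, {"q1": q1, "q2": q2})
        m2 = call_snps(ref, {"q2": q2, "q1": q1})
        assert m1.positions == m2.positions
        assert m1.alleles.equals(m2.alleles)

    def test_private_variant_enters_matrix(self, rng):
        ref = random_genome(rng)
        alt = "T" if ref.contigs[0][1][100] != "T" else "A"
        snp = call_snps(ref, {"q1": with_substitution(ref, 100, alt, "q1"), "q2": ref})
        assert [p for _, p, _ in snp.positions] == [101]
        assert snp.alleles.loc[("c1", 101), "q2"] == ref.contigs[0][1][100]

    def test_indel_segment_excluded(self, rng):
        ref = random_genome(rng, n=6000)
        cid, seq = ref.contigs[0]
        # delete 300 bp and substitute a base inside the adjacent segment
        qseq = seq[:2000] + seq[2300:]
        qry = GenomeAssembly("q", [(cid, qseq)])
        snp = call_snps(ref, {"q": qry})
        assert all(not (1980 <= p <= 2320) for _, p, _ in snp.positions)

    def test_truth_recall_and_precision(self, small_dataset, small_snp):
        _, _, _, _, truth = small_dataset
        tv = set(truth.all_variant_positions.tolist())
        called = {p for _, p, _ in small_snp.positions}
        recall = len(called & tv) / len(tv)
        precision = len(called & tv) / len(called)
        assert recall >= 0.95
        assert precision >= 0.99

    def test_every_diagnostic_snp_called_with_its_allele(self, small_dataset, small_snp):
        _, _, _, _, truth = small_dataset
        idx = {p: i for i, (_, p, _) in enumerate(small_snp.positions)}
        for rec in truth.diagnostic_snps.itertuples():
            assert rec.position in idx
            row = small_snp.alleles.iloc[idx[rec.position]]
            members = truth.groups[rec.group]
            assert all(row[s] == rec.allele for s in members)


class TestPseudosequence:
    def test_three_position_concatenation(self, rng):
        ref = random_genome(rng)
        seq = ref.contigs[0][1]
        qry = ref.contigs[0][1]
        for pos, base in ((10, "A"), (20, "C"), (30, "G")):
            if qry[pos] == base:
                base = "T" if base != "T" else "G"
            qry = qry[:pos] + base + qry[pos + 1:]
        snp = call_snps(ref, {"q": GenomeAssembly("q", [("c1", qry)])})
        pseudo = concat_pseudosequence(snp)
        assert pseudo["q"] == "".join(
            qry[p - 1] for _, p, _ in snp.positions
        )

    def test_lengths_equal_position_count(self, small_snp):
        pseudo = concat_pseudosequence(small_snp)
        assert {len(s) for s in pseudo.values()} == {len(small_snp)}


def oracle_effect(reference, annotations, contig, pos, alt):
    """Full-translation oracle: translate the whole gene before and after
    the substitution and diff the proteins."""
    seq = dict(reference.contigs)[contig]
    for a in annotations:
        if a.contig_id == contig and a.start <= pos <= a.end:
            mutated = seq[: pos - 1] + alt + seq[pos:]
            before = seq[a.start - 1 : a.end]
            after = mutated[a.start - 1 : a.end]
            if a.strand == "-":
                before = str(Seq(before).reverse_complement())
                after = str(Seq(after).reverse_complement())
            p0 = str(Seq(before).translate(table=11))
            p1 = str(Seq(after).translate(table=11))
            if p0 == p1:
                return "synonymous"
            idx = next(i for i, (x, y) in enumerate(zip(p0, p1)) if x != y)
            if idx == 0:
                return "start_lost"
            if p0[idx] == "*":
                return "stop_lost"
            if p1[idx] == "*":
                return "stop_gained"
            return "nonsynonymous"
    return "noncoding"


class TestClassifyEffects:
    def build(self, cds_sense, strand="+", flank=60):
        rng = np.random.default_rng(3)
        left = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=flank)])
        right = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=flank)])
        genomic = cds_sense if strand == "+" else str(Seq(cds_sense).reverse_complement())
        seq = left + genomic + right
        ref = GenomeAssembly("ref", [("c", seq)])
        ann = [CdsAnnotation("g1", "c", flank + 1, flank + len(cds_sense), strand)]
        return ref, ann

    def snp_at(self, ref, genome_pos, alt):
        cid, seq = ref.contigs[0]
        qry = GenomeAssembly("q", [(cid, seq[: genome_pos - 1] + alt + seq[genome_pos:])])
        return call_snps(ref, {"q": qry})

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_synonymous_third_position(self, strand):
        cds = "ATG" + "GGA" + "AAACCTTTG" * 8 + "TAA"
        ref, ann = self.build(cds, strand)
        a = ann[0]
        gpos = a.start + 5 if strand == "+" else a.end - 5
        alt = "G" if strand == "+" else "C"  # GGA -> GGG in sense terms
        snp = self.snp_at(ref, gpos, alt)
        recs = classify_effects(snp, ann, ref)
        assert [r.effect for r in recs] == ["synonymous"]

    def test_stop_gained_truncation_fraction(self):
        codons = ["ATG"] + ["TGG"] * 10 + ["TAA"]
        cds = "".join(codons)
        ref, ann = self.build(cds)
        a = ann[0]
        gpos = a.start + 3 * 4 + 2  # third base of codon index 4 (a TGG)
        snp = self.snp_at(ref, gpos, "A")  # TGG -> TGA
        recs = classify_effects(snp, ann, ref)
        assert recs[0].effect == "stop_gained"
        assert recs[0].truncation_fraction == pytest.approx(4 / 12)

    def test_start_lost_and_stop_lost(self):
        cds = "ATG" + "CCTGGT" * 6 + "TAA"
        ref, ann = self.build(cds)
        a = ann[0]
        recs = classify_effects(self.snp_at(ref, a.start + 2, "A"), ann, ref)
        assert recs[0].effect == "start_lost"  # ATG -> ATA
        recs = classify_effects(self.snp_at(ref, a.end - 2, "C"), ann, ref)
        assert recs[0].effect == "stop_lost"  # TAA -> CAA

    def test_noncoding_outside_cds(self):
        cds = "ATG" + "CCTGGT" * 6 + "TAA"
        ref, ann = self.build(cds)
        pos = ann[0].end + 20  # interior of the right intergenic flank
        cur = ref.contigs[0][1][pos - 1]
        snp = self.snp_at(ref, pos, "A" if cur != "A" else "C")
        recs = classify_effects(snp, ann, ref)
        assert recs[0].effect == "noncoding"

    def test_against_full_translation_oracle(self, small_dataset):
        """1,000+ random substitutions classified identically to the oracle
        that re-translates the whole protein and diffs it."""
        _, reference, annotations, _, _ = small_dataset
        rng = np.random.default_rng(17)
        cid, seq = reference.contigs[0]
        n_checked = 0
        qseq = list(seq)
        picks = []
        while len(picks) < 1100:
            pos = int(rng.integers(1, len(seq)))
            cur = seq[pos - 1]
            alt = "ACGT"[int(rng.integers(0, 4))]
            if alt != cur and qseq[pos - 1] == cur:
                qseq[pos - 1] = alt
                picks.append((pos, alt))
        qry = GenomeAssembly("q", [(cid, "".join(qseq))])
        snp = call_snps(reference, {"q": qry})
        recs = classify_effects(snp, annotations, reference)
        by_key = {(r.position, r.alt_allele): r.effect for r in recs}
        for pos, alt in picks:
            if (pos, alt) not in by_key:
                continue  # position fell in an anchor-poor margin
            assert by_key[(pos, alt)] == oracle_effect(reference, annotations, cid, pos, alt), (pos, alt)
            n_checked += 1
        assert n_checked >= 1000

    def test_strand_symmetry(self):
        """The same biological mutation yields the same call whether the gene
        is annotated on the forward or the reverse strand."""
        cds = "ATG" + "CATGAAGTT" * 5 + "TGG" + "TAA"
        for codon_offset, sense_alt in ((4, "A"), (10, "C")):
            effects = []
            for strand in "+-":
                ref, ann = self.build(cds, strand)
                a = ann[0]
                sense_pos = 3 * codon_offset + 2  # third base of the codon
                if strand == "+":
                    gpos, alt = a.start + sense_pos, sense_alt
                else:
                    gpos = a.end - sense_pos
                    alt = str(Seq(sense_alt).complement())
                recs = classify_effects(self.snp_at(ref, gpos, alt), ann, ref)
                effects.append(recs[0].effect)
            assert effects[0] == effects[1]

    def test_vcf_and_tsv_writers(self, tmp_path, small_snp):
        variants.write_snp_vcf(small_snp, tmp_path / "s.vcf")
        lines = (tmp_path / "s.vcf").read_text().splitlines()
        header = next(l for l in lines if l.startswith("#CHROM"))
        assert header.split("\t")[9:] == small_snp.strain_ids
        assert len([l for l in lines if not l.startswith("#")]) == len(small_snp)
        variants.write_snp_tsv(small_snp, tmp_path / "s.tsv")
        assert (tmp_path / "s.tsv").exists()
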