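"""Reading/writing of genome assemblies, annotations, matrices and trees.

Assemblies are plain multi-FASTA, one file per strain; CDS annotations use
GFF3-style columns; strain groups are one tab-separated row per group;
matrices are TSV with strains as columns. Contig statistics include the
N50-ratio quality metric ``((contigs - L50) / L50) * contigs`` used to rank
draft assemblies (larger = more fragmented relative to contiguity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

_VALID_BASES = frozenset("ACGTN")


@dataclass
class GenomeAssembly:
    """Named, ordered set of contig sequences for one strain."""

    strain_id: str
    contigs: list[tuple[str, str]]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate contig ids in strain {self.strain_id!r}")
        norm = []
        for cid, seq in self.contigs:
            if not seq:
                raise ValueError(f"empty sequence for contig {cid!r} of {self.strain_id!r}")
            seq = seq.upper()
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {cid!r} of {self.strain_id!r} has invalid characters {sorted(bad)}"
                )
            norm.append((cid, seq))
        self.contigs = norm

    @property
    def contig_ids(self) -> list[str]:
        return [cid for cid, _ in self.contigs]

    @property
    def total_bp(self) -> int:
        return sum(len(s) for _, s in self.contigs)

    def sequence(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_bp: int
    n50: int
    l50: int
    n50_ratio: int
    cds_count: int | None = None


@dataclass(frozen=True)
class CdsAnnotation:
    """One CDS on the reference, 1-based inclusive forward-strand coordinates."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"CDS {self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"CDS {self.gene_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_fasta(path: str | Path, strain_id: str | None = None) -> GenomeAssembly:
    """Load a multi-FASTA assembly; sequences are uppercased, order kept."""
    path = Path(path)
    contigs: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        contigs.append((rec.id, seq))
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeAssembly(strain_id=strain_id or path.stem, contigs=contigs)


def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq), id=cid, description="") for cid, seq in assembly.contigs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def assembly_stats(
    assembly: GenomeAssembly, cds_count: int | None = None
) -> AssemblyStats:
    """Contig statistics: N50/L50 and the N50-ratio assembly quality index.

    L50 is the number of longest contigs whose summed length first reaches
    half the assembly; N50 is the length of the last contig in that prefix.
    The ratio ``((n_contigs - L50) / L50) * n_contigs`` is rounded to the
    nearest integer, halves away from zero.
    """
    if not assembly.contigs:
        raise ValueError("empty assembly")
    lengths = sorted((len(s) for _, s in assembly.contigs), reverse=True)
    total = sum(lengths)
    half = total / 2
    cum = 0
    for i, length in enumerate(lengths):
        cum += length
        if cum >= half:
            l50 = i + 1
            n50 = length
            break
    n = len(lengths)
    ratio = _round_half_away(((n - l50) / l50) * n)
    return AssemblyStats(
        n_contigs=n, total_bp=total, n50=n50, l50=l50, n50_ratio=ratio, cds_count=cds_count
    )


# ---------------------------------------------------------------------------
# Strain groups

@dataclass
class StrainGroups:
    """Mapping of group name -> set of strain ids; groups may overlap."""

    groups: dict[str, set[str]]

    def __getitem__(self, name: str) -> set[str]:
        return self.groups[name]

    def __iter__(self):
        return iter(self.groups)

    def items(self):
        return self.groups.items()

    def all_strains(self) -> set[str]:
        out: set[str] = set()
        for s in self.groups.values():
            out |= s
        return out

    def validate_against(self, strain_ids: Iterable[str]) -> None:
        known = set(strain_ids)
        missing = self.all_strains() - known
        if missing:
            raise ValueError(f"groups reference unknown strains: {sorted(missing)}")


def read_group_table(path: str | Path) -> StrainGroups:
    """Read groups from TSV rows ``group_name<TAB>strain1<TAB>strain2...``."""
    groups: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            name, strains = fields[0], [f for f in fields[1:] if f]
            if len(strains) != len(set(strains)):
                raise ValueError(f"duplicate strain in group {name!r} (line {ln})")
            if name in groups:
                raise ValueError(f"group {name!r} defined twice (line {ln})")
            groups[name] = set(strains)
    return StrainGroups(groups)


def write_group_table(groups: StrainGroups, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, strains in groups.items():
            fh.write("\t".join([name, *sorted(strains)]) + "\n")


# ---------------------------------------------------------------------------
# GFF3-like CDS annotation

def read_cds_gff(path: str | Path) -> list[CdsAnnotation]:
    out: list[CdsAnnotation] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
            )
            out.append(
                CdsAnnotation(
                    gene_id=attrs.get("ID", f"cds_{len(out)}"),
                    contig_id=f[0],
                    start=int(f[3]),
                    end=int(f[4]),
                    strand=f[6],
                    product=attrs.get("product", ""),
                )
            )
    return out


def write_cds_gff(annotations: Iterable[CdsAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = f"ID={a.gene_id}"
            if a.product:
                attrs += f";product={a.product}"
            fh.write(
                "\t".join(
                    [a.contig_id, "strainphy", "CDS", str(a.start), str(a.end), ".",
                     a.strand, "0", attrs]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Matrices and trees

def write_matrix_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=True, na_rep=".")


def read_matrix_tsv(path: str | Path, numeric: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["."], keep_default_na=False)
    if numeric:
        df = df.apply(pd.to_numeric)
    return df


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path))


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path))
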