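"""Shannon-entropy detection of group-specific SNPs and ortholog groups.

For a named group of strains and one SNP position, the Shannon entropy of
the alleles carried by the group's members,

    H = -sum_i p(x_i) * log2 p(x_i),

is zero exactly when the group is monomorphic there. A marker is called
*specific* to the group when H = 0 AND the group's uniform state occurs in
no strain outside the group (entropy alone cannot distinguish a diagnostic
site from one that is monomorphic species-wide). Ortholog groups are
treated the same way with the per-strain CDS count playing the role of the
allele, thresholded to presence/absence for the specificity call.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_io import StrainGroups
from .pangenome import validate_ortholog_matrix
from .variants import EFFECT_CATEGORIES, SnpEffectRecord, SnpMatrix


@dataclass(frozen=True)
class GroupEntropyResult:
    item_id: str
    group_name: str
    H: float
    specific: bool
    direction: str | None = None  # orthologs: "present" | "absent"


def shannon_entropy(values) -> float:
    """Shannon entropy (bits) of a multiset of categorical values."""
    values = list(values)
    if not values:
        raise ValueError("entropy of an empty multiset is undefined")
    n = len(values)
    counts = np.array(list(Counter(values).values()), dtype=float)
    p = counts / n
    return float(-(p * np.log2(p)).sum())


def specific_snps(
    matrix: SnpMatrix, groups: StrainGroups
) -> tuple[list[GroupEntropyResult], dict[str, dict[str, str]]]:
    """Entropy over each group's alleles at every SNP position.

    A SNP is specific to a group iff the group has no missing allele there,
    its entropy is zero, and the shared allele is carried by no strain
    outside the group (strains with missing data outside the group
    disqualify the call, conservatively). Returns the per-(position, group)
    entropy results plus, per group, a mapping of position label
    ("contig:pos") to the group's specific allele.
    """
    strains = matrix.strain_ids
    groups.validate_against(strains)
    for gname, members in groups.items():
        if not members:
            raise ValueError(f"group {gname!r} has no strains")
    arr = matrix.alleles.to_numpy(dtype="U1")
    labels = [f"{c}:{p}" for c, p, _ in matrix.positions]
    results: list[GroupEntropyResult] = []
    specific: dict[str, dict[str, str]] = {}
    col_of = {s: i for i, s in enumerate(strains)}
    for gname, members in groups.items():
        in_idx = [col_of[s] for s in sorted(members)]
        out_idx = [col_of[s] for s in strains if s not in members]
        ga = arr[:, in_idx]
        oa = arr[:, out_idx] if out_idx else np.empty((len(labels), 0), dtype="U1")
        g_missing = (ga == ".").any(axis=1)
        uniform = (ga == ga[:, :1]).all(axis=1) & ~g_missing
        o_missing = (oa == ".").any(axis=1)
        if out_idx:
            outside_clear = (oa != ga[:, :1]).all(axis=1) & ~o_missing
        else:
            outside_clear = np.ones(len(labels), dtype=bool)
        spec = uniform & outside_clear
        found = {}
        for i, lab in enumerate(labels):
            vals = [v for v in ga[i] if v != "."]
            h = shannon_entropy(vals) if vals else float("nan")
            is_spec = bool(spec[i])
            results.append(GroupEntropyResult(lab, gname, h, is_spec))
            if is_spec:
                found[lab] = str(ga[i, 0])
        specific[gname] = found
    return results, specific


def snp_effect_table(
    specific: dict[str, dict[str, str]],
    matrix: SnpMatrix,
    effects: list[SnpEffectRecord],
    groups: StrainGroups,
) -> pd.DataFrame:
    """Cross-tabulate group-specific SNPs by effect category, one column per
    group, with a total row — the per-group discriminating-SNP report.

    When a group's specific allele IS the reference allele (every strain
    outside the group mutated away from it), the SNP is reported as
    synonymous for that group by convention: relative to a reference drawn
    from that group the site carries no change.
    """
    eff_of: dict[tuple[str, str], str] = {}
    for rec in effects:
        eff_of[(f"{rec.contig}:{rec.position}", rec.alt_allele)] = rec.effect
    ref_of = {f"{c}:{p}": r for c, p, r in matrix.positions}
    table = pd.DataFrame(
        0, index=list(EFFECT_CATEGORIES), columns=list(groups.groups)
    )
    for gname, found in specific.items():
        for label, allele in found.items():
            if allele == ref_of[label]:
                # group carries the reference allele; coding-zone status only
                any_eff = next(
                    (e for (lab, _), e in eff_of.items() if lab == label), None
                )
                cat = "noncoding" if any_eff == "noncoding" else "synonymous"
            else:
                cat = eff_of.get((label, allele), "noncoding")
            table.loc[cat, gname] += 1
    table.loc["total"] = table.sum(axis=0)
    return table


def specific_orthologs(
    matrix: pd.DataFrame, groups: StrainGroups
) -> tuple[list[GroupEntropyResult], pd.DataFrame]:
    """Entropy of ortholog CDS counts per group, plus present/absent calls.

    An ortholog is specific-present to a group when every member has it and
    no non-member does; specific-absent when no member has it and every
    non-member does. The summary table counts both per group, with a
    total-discriminating row.
    """
    m = validate_ortholog_matrix(matrix)
    strains = list(m.columns)
    groups.validate_against(strains)
    for gname, members in groups.items():
        if not members:
            raise ValueError(f"group {gname!r} has no strains")
    counts = m.to_numpy()
    presence = counts >= 1
    results: list[GroupEntropyResult] = []
    table = pd.DataFrame(
        0, index=["present", "absent", "total"], columns=list(groups.groups)
    )
    col_of = {s: i for i, s in enumerate(strains)}
    for gname, members in groups.items():
        in_idx = [col_of[s] for s in sorted(members)]
        out_idx = [col_of[s] for s in strains if s not in members]
        gin, gout = presence[:, in_idx], presence[:, out_idx]
        present_spec = gin.all(axis=1) & (~gout.any(axis=1) if out_idx else True)
        absent_spec = (~gin.any(axis=1)) & (gout.all(axis=1) if out_idx else False)
        for i, oid in enumerate(m.index):
            h = shannon_entropy(counts[i, in_idx])
            direction = (
                "present" if present_spec[i] else "absent" if absent_spec[i] else None
            )
            results.append(
                GroupEntropyResult(str(oid), gname, h, direction is not None, direction)
            )
        table.loc["present", gname] = int(present_spec.sum())
        table.loc["absent", gname] = int(absent_spec.sum())
    table.loc["total"] = table.loc["present"] + table.loc["absent"]
    return results, table
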