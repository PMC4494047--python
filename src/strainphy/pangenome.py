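"""Pangenome composition, rarefaction, and ortholog-count clustering.

An ortholog matrix holds the number of CDS each strain contributes to each
ortholog group. Groups present in every strain form the coregenome, groups
in exactly one strain the cloudgenome, the rest the shellgenome; pangenome =
core + shell + cloud. Rarefaction resamples distinct strain subsets of every
size to trace how core and pan sizes progress as strains accumulate. Strains
are clustered on Canberra distance between their ortholog-count columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .phylo import DistanceMatrix

CATEGORIES = ("core", "shell", "cloud", "pan")


def validate_ortholog_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    if matrix.empty:
        raise ValueError("empty ortholog matrix")
    m = matrix.fillna(0).astype(int)
    if (m.values < 0).any():
        raise ValueError("ortholog counts must be non-negative")
    if (m.values.sum(axis=1) == 0).any():
        raise ValueError("ortholog matrix contains an all-zero row")
    return m


@dataclass(frozen=True)
class PangenomeReport:
    """Ortholog-group and total-gene counts per pangenome category.

    ``total_genes`` of a group is its maximum per-strain CDS count, so a
    family duplicated in some genome contributes its largest copy number
    once rather than a sum across strains.
    """

    groups: dict[str, int]
    genes: dict[str, int]
    category_of: pd.Series  # ortholog_id -> {core, shell, cloud}

    def __post_init__(self) -> None:
        for d in (self.groups, self.genes):
            if d["core"] + d["shell"] + d["cloud"] != d["pan"]:
                raise ValueError("pangenome categories do not sum to the pangenome")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ortholog_groups": [self.groups[c] for c in CATEGORIES],
                "total_genes": [self.genes[c] for c in CATEGORIES],
            },
            index=[f"{c}genome" for c in CATEGORIES],
        )


def classify_pangenome(matrix: pd.DataFrame) -> PangenomeReport:
    """Classify ortholog groups as core / shell / cloud by presence pattern."""
    m = validate_ortholog_matrix(matrix)
    presence = m.values >= 1
    n_strains = m.shape[1]
    n_present = presence.sum(axis=1)
    cat = np.where(n_present == n_strains, "core", np.where(n_present == 1, "cloud", "shell"))
    max_count = m.values.max(axis=1)
    groups = {c: int((cat == c).sum()) for c in ("core", "shell", "cloud")}
    genes = {c: int(max_count[cat == c].sum()) for c in ("core", "shell", "cloud")}
    groups["pan"] = sum(groups.values())
    genes["pan"] = sum(genes.values())
    return PangenomeReport(
        groups=groups, genes=genes, category_of=pd.Series(cat, index=m.index)
    )


def _core_pan_sizes(presence: np.ndarray, cols: tuple[int, ...]) -> tuple[int, int]:
    sub = presence[:, cols]
    return int(sub.all(axis=1).sum()), int(sub.any(axis=1).sum())


def rarefaction(
    matrix: pd.DataFrame,
    iterations: int = 49,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Core/pan progression by resampling distinct strain subsets.

    For each subset size i from 1 to N, draws ``iterations`` distinct strain
    combinations (no combination repeated; all of them enumerated when fewer
    than ``iterations`` exist) and records core and pan ortholog-group counts
    of the column-restricted matrix. At i = N there is a single combination,
    computed once. Returns a long-format frame (i, iteration, core, pan).
    """
    m = validate_ortholog_matrix(matrix)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    presence = m.values >= 1
    n = m.shape[1]
    rows = []
    for i in range(1, n + 1):
        n_comb = comb(n, i)
        if n_comb <= iterations:
            subsets = [tuple(c) for c in combinations(range(n), i)]
        else:
            seen: set[tuple[int, ...]] = set()
            while len(seen) < iterations:
                pick = tuple(sorted(rng.choice(n, size=i, replace=False).tolist()))
                seen.add(pick)
            subsets = sorted(seen)
        for it, cols in enumerate(subsets):
            core, pan = _core_pan_sizes(presence, cols)
            rows.append((i, it, core, pan))
    return pd.DataFrame(rows, columns=["i", "iteration", "core", "pan"])


def rarefaction_summary(curve: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of core and pan sizes per subset size."""
    g = curve.groupby("i")
    out = pd.DataFrame(
        {
            "core_mean": g["core"].mean(),
            "core_sd": g["core"].std(ddof=1).fillna(0.0),
            "pan_mean": g["pan"].mean(),
            "pan_sd": g["pan"].std(ddof=1).fillna(0.0),
        }
    )
    return out


def canberra_matrix(matrix: pd.DataFrame) -> DistanceMatrix:
    """Canberra distance between strain columns: sum |x-y| / (|x|+|y|),
    terms with x = y = 0 contributing nothing."""
    m = validate_ortholog_matrix(matrix)
    d = squareform(pdist(m.values.T.astype(float), metric="canberra"))
    return DistanceMatrix(ids=list(m.columns), data=d, source="canberra")


def cluster_order(dm: DistanceMatrix) -> tuple[list[str], np.ndarray, dict[str, int]]:
    """Complete-linkage agglomeration of a distance matrix.

    Returns (leaf order, scipy linkage matrix, top-split assignment mapping
    each strain to cluster 1 or 2).
    """
    n = len(dm.ids)
    if n == 1:
        return list(dm.ids), np.empty((0, 4)), {dm.ids[0]: 1}
    z = linkage(squareform(dm.data, checks=False), method="complete")
    order = [dm.ids[i] for i in leaves_list(z)]
    top = fcluster(z, t=2, criterion="maxclust")
    return order, z, {s: int(c) for s, c in zip(dm.ids, top)}
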