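"""Alignment-free and fragment-based genome distances.

Tetranucleotide signatures: observed overlapping 4-mer counts over a genome
plus its reverse complement are compared with the maximal-order Markov
expectation E[w1w2w3w4] = n(w1w2w3) * n(w2w3w4) / n(w2w3) and standardized
with the usual variance approximation, giving a 256-vector of z-scores; the
distance between strains is 1 minus the Pearson correlation of their
z-vectors.

Fragment ANI: one genome is cut into consecutive 1,020 bp pieces, each piece
is aligned to the best-matching region of the other genome (both strands),
and the average nucleotide identity is the mean identity of pieces passing
the 30% identity / 70% coverage retention filter, averaged over the two
directions. Genomes of one species conventionally share > 95% ANI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .genome_io import GenomeAssembly
from .phylo import DistanceMatrix

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

TETRA_WORDS = [
    a + b + c + d
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    for d in "ACGT"
]


@dataclass(frozen=True)
class TetraSignature:
    strain_id: str
    z: np.ndarray  # 256 z-scores, lexicographic word order

    def correlation(self, other: "TetraSignature") -> float:
        return float(np.corrcoef(self.z, other.z)[0, 1])


@dataclass(frozen=True)
class AniResult:
    strain_a: str
    strain_b: str
    ani_percent: float
    fragments_used: int
    same_species: bool


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def _word_counts(seqs: list[str], k: int) -> np.ndarray:
    """Overlapping k-mer counts in lexicographic order; words with N skipped."""
    counts = np.zeros(4**k, dtype=np.int64)
    for seq in seqs:
        codes = np.full(len(seq), -1, dtype=np.int64)
        b = np.frombuffer(seq.encode(), dtype="S1")
        for base, code in _CODE.items():
            codes[b == base.encode()] = code
        if len(codes) < k:
            continue
        idx = np.zeros(len(codes) - k + 1, dtype=np.int64)
        ok = np.ones(len(idx), dtype=bool)
        for j in range(k):
            win = codes[j : j + len(idx)]
            idx = idx * 4 + np.maximum(win, 0)
            ok &= win >= 0
        counts += np.bincount(idx[ok], minlength=4**k)
    return counts


def tetra_signature(genome: GenomeAssembly) -> TetraSignature:
    """256-vector of tetranucleotide z-scores (strand-symmetric)."""
    total = genome.total_bp
    if total < 4:
        raise ValueError(f"genome {genome.strain_id!r} too short for tetranucleotides")
    if total < 50_000:
        warnings.warn(
            f"genome {genome.strain_id!r} has {total} bp; tetranucleotide "
            "signatures are unstable below ~50 kb"
        )
    seqs = [s for _, s in genome.contigs]
    seqs = seqs + [_revcomp(s) for s in seqs]
    n4 = _word_counts(seqs, 4).astype(float)
    n3 = _word_counts(seqs, 3).astype(float)
    n2 = _word_counts(seqs, 2).astype(float)
    z = np.zeros(256)
    for i in range(256):
        w1, rest = i >> 6, i & 0x3F  # rest = w2w3w4
        left3 = i >> 2  # w1w2w3
        mid2 = (i >> 2) & 0xF  # w2w3
        exp = n3[left3] * n3[rest] / n2[mid2] if n2[mid2] > 0 else 0.0
        if exp > 0:
            var = exp * (n2[mid2] - n3[left3]) * (n2[mid2] - n3[rest]) / n2[mid2] ** 2
            if var > 0:
                z[i] = (n4[i] - exp) / np.sqrt(var)
    return TetraSignature(strain_id=genome.strain_id, z=z)


def tetra_distance_matrix(signatures: list[TetraSignature]) -> DistanceMatrix:
    """1 - Pearson correlation between signature z-vectors."""
    ids = [s.strain_id for s in signatures]
    for s in signatures:
        if np.std(s.z) == 0:
            raise ValueError(
                f"signature of strain {s.strain_id!r} is constant; correlation undefined"
            )
    zs = np.stack([s.z for s in signatures])
    corr = np.corrcoef(zs)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry against float round-off
    return DistanceMatrix(ids=ids, data=d, source="tetra")


# ---------------------------------------------------------------------------
# Fragment ANI

_SEED_K = 15
_SEED_STEP = 8
_WINDOW_MARGIN = 48
# extra target sequence kept on both sides of the seeded window, so that a
# whole-gene insertion in the target shows up as a gap in the alignment path
# (and the straddling fragment fails the coverage filter) instead of forcing
# half the fragment to align against unrelated sequence
_WINDOW_SLOP = 3000


def _seed_index(seq: str, k: int = _SEED_K) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = {}
    for i in range(0, len(seq) - k + 1):
        w = seq[i : i + k]
        if "N" in w:
            continue
        idx.setdefault(w, []).append(i)
    return idx


import re

_CIGAR_RE = re.compile(r"(\d+)([=XID])")
_MATCH_SCORE, _MISMATCH_SCORE, _GAP_SCORE = 1, -1, -2


def _cigar_ops(cigar: str):
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def _best_local_piece(cigar: str, frag_len: int) -> tuple[float, float]:
    """(identity, query coverage) of the maximal-scoring local alignment piece.

    The end-free alignment of the whole fragment is rescored with +1 match,
    -1 mismatch, -2 per gap base, and the maximum-scoring contiguous run of
    alignment columns is kept (Kadane over the path). A fragment whose true
    region is absent from the other genome only reaches a short high-scoring
    run and fails the coverage filter, the way a local aligner would simply
    report no usable hit; a fragment straddling a gained/lost gene keeps its
    good side only.
    """
    ops = _cigar_ops(cigar)
    per_base = {"=": _MATCH_SCORE, "X": _MISMATCH_SCORE, "I": _GAP_SCORE, "D": _GAP_SCORE}
    best_score = run_score = 0.0
    best = (0, 0)  # op index range of the best run
    run_start = 0
    for i, (n, op) in enumerate(ops):
        s = per_base[op] * n
        if run_score <= 0 and s > run_score + s:
            run_score, run_start = s, i
        else:
            run_score += s
        if run_score > best_score:
            best_score = run_score
            best = (run_start, i + 1)
    if best_score <= 0:
        return 0.0, 0.0
    seg = ops[best[0] : best[1]]
    matches = sum(n for n, op in seg if op == "=")
    columns = sum(n for n, _ in seg)
    span = sum(n for n, op in seg if op in "=XI")
    return matches / columns, span / frag_len


def _best_fragment_identity(
    frag: str, target: str, index: dict[str, list[int]]
) -> tuple[float, float] | None:
    """Best seeded alignment of a fragment against one target strand.

    Seeds vote for a diagonal; the densest diagonal defines a window of the
    target around the implied placement, and the fragment is aligned to that
    window end-free (infix). Returns (identity, query coverage) of the best
    local piece of that alignment, or None when the fragment has no seed.
    """
    votes: dict[int, int] = {}
    for off in range(0, len(frag) - _SEED_K + 1, _SEED_STEP):
        w = frag[off : off + _SEED_K]
        for tpos in index.get(w, ()):
            diag = (tpos - off) // _WINDOW_MARGIN  # bucket nearby diagonals
            votes[diag] = votes.get(diag, 0) + 1
    if not votes:
        return None
    diag = max(votes, key=lambda d: (votes[d], -d)) * _WINDOW_MARGIN
    lo = max(0, diag - _WINDOW_MARGIN - _WINDOW_SLOP)
    hi = min(len(target), diag + len(frag) + _WINDOW_MARGIN + _WINDOW_SLOP)
    window = target[lo:hi]
    if not window:
        return None
    res = edlib.align(frag, window, mode="HW", task="path")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    return _best_local_piece(res["cigar"], len(frag))


def _prepare_target(genome: GenomeAssembly):
    fwd = "".join(s for _, s in genome.contigs)
    rev = _revcomp(fwd)
    return fwd, rev, _seed_index(fwd), _seed_index(rev)


def _directional_ani(
    genome_a: GenomeAssembly,
    genome_b: GenomeAssembly,
    fragment_len: int,
    min_identity: float,
    min_coverage: float,
    prepared_target=None,
) -> tuple[float | None, int]:
    fwd, rev, idx_f, idx_r = prepared_target or _prepare_target(genome_b)
    identities = []
    for _, seq in genome_a.contigs:
        for start in range(0, len(seq), fragment_len):
            frag = seq[start : start + fragment_len]
            if len(frag) < 100:
                continue  # terminal scraps are uninformative
            if frag.count("N") > (1 - min_coverage) * len(frag):
                continue
            cands = [
                _best_fragment_identity(frag, fwd, idx_f),
                _best_fragment_identity(frag, rev, idx_r),
            ]
            cands = [c for c in cands if c is not None]
            if not cands:
                continue
            identity, coverage = max(cands)
            if identity >= min_identity and coverage >= min_coverage:
                identities.append(identity)
    if not identities:
        return None, 0
    return float(np.mean(identities)), len(identities)


def fragment_ani(
    genome_a: GenomeAssembly,
    genome_b: GenomeAssembly,
    fragment_len: int = 1020,
    min_identity: float = 0.3,
    min_coverage: float = 0.7,
    _targets=None,
) -> AniResult:
    """Reciprocal fragment-based average nucleotide identity.

    Both directions are computed (a's fragments against b, then b's against
    a) and averaged; ``same_species`` flags ANI above the 95% species line.
    Raises if no fragment passes the retention filter in either direction.
    """
    ta = tb = None
    if _targets is not None:
        ta, tb = _targets.get(genome_a.strain_id), _targets.get(genome_b.strain_id)
    ab, n_ab = _directional_ani(
        genome_a, genome_b, fragment_len, min_identity, min_coverage, prepared_target=tb
    )
    ba, n_ba = _directional_ani(
        genome_b, genome_a, fragment_len, min_identity, min_coverage, prepared_target=ta
    )
    vals = [v for v in (ab, ba) if v is not None]
    if not vals:
        raise ValueError(
            f"ANI undefined between {genome_a.strain_id!r} and {genome_b.strain_id!r}: "
            "no fragment passed the retention filter"
        )
    ani = 100.0 * float(np.mean(vals))
    return AniResult(
        strain_a=genome_a.strain_id,
        strain_b=genome_b.strain_id,
        ani_percent=ani,
        fragments_used=n_ab + n_ba,
        same_species=ani > 95.0,
    )


def ani_matrix(
    genomes: dict[str, GenomeAssembly], fragment_len: int = 1020
) -> tuple[pd.DataFrame, DistanceMatrix]:
    """All-pairs ANI (percent) and the derived distance 1 - ANI/100."""
    ids = sorted(genomes)
    n = len(ids)
    targets = {sid: _prepare_target(genomes[sid]) for sid in ids}
    ani = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            r = fragment_ani(genomes[ids[i]], genomes[ids[j]], fragment_len, _targets=targets)
            ani[i, j] = ani[j, i] = r.ani_percent
    df = pd.DataFrame(ani, index=ids, columns=ids)
    dist = 1.0 - ani / 100.0
    np.fill_diagonal(dist, 0.0)
    return df, DistanceMatrix(ids=ids, data=dist, source="ani")
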