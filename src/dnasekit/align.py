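"""Pairwise and progressive protein alignment, identity matrices, and
neighbor-joining trees.

Pairwise global alignment is affine-gap Needleman-Wunsch with BLOSUM62
(gap open 11, gap extension 1 in the BLAST convention: a gap of length k
costs ``11 + k``; ``X`` scores 0 against every residue). These scores feed
three consumers:

* percent-identity matrices with average-linkage clustered ordering, the
  computation behind clustered identity heatmaps of orthogroup members;
* an in-house progressive multiple aligner (UPGMA guide tree,
  profile-profile merging) used to prepare curated orthogroup alignments;
* neighbor-joining trees used as quick monophyly sanity checks on
  orthogroup assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix as _SkbioDM
from skbio import TreeNode
from skbio.tree import nj as _skbio_nj

from .records import GAP, InputError, ProteinRecord, check_unique_ids

GAP_OPEN = 11.0
GAP_EXTEND = 1.0

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "global_align",
    "percent_identity",
    "identity_matrix",
    "progressive_msa",
    "nj_tree",
    "blosum62",
]


@dataclass
class Alignment:
    """A gapped alignment: ordered (record id, gapped sequence) rows."""

    rows: list[tuple[str, str]]
    score: float = 0.0

    @property
    def columns(self) -> int:
        return len(self.rows[0][1]) if self.rows else 0

    def __post_init__(self) -> None:
        ncol = self.columns
        for rid, gapped in self.rows:
            if len(gapped) != ncol:
                raise InputError(f"alignment rows have unequal length (row {rid!r})")

    def degapped(self, i: int) -> str:
        return self.rows[i][1].replace(GAP, "")


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with ordered labels and zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise InputError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise InputError("distance matrix must be symmetric")
        if np.any(self.values < -1e-12):
            raise InputError("distances must be non-negative")
        np.fill_diagonal(self.values, 0.0)


_BLOSUM62_X0 = None


def blosum62():
    """BLOSUM62 with X (and B/Z/*) scoring 0 against everything."""
    global _BLOSUM62_X0
    if _BLOSUM62_X0 is None:
        m = substitution_matrices.load("BLOSUM62").copy()
        for ch in "BZX*":
            i = m.alphabet.index(ch)
            m[i, :] = 0.0
            m[:, i] = 0.0
        _BLOSUM62_X0 = m
    return _BLOSUM62_X0


def _aligner() -> PairwiseAligner:
    a = PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = blosum62()
    # BLAST convention: gap of length k costs open + k*extend
    a.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    a.extend_gap_score = -GAP_EXTEND
    return a


def global_align(a: ProteinRecord, b: ProteinRecord) -> Alignment:
    """Optimal global affine-gap alignment of two records.

    Deterministic: among co-optimal alignments the first one in
    Biopython's enumeration order is returned.
    """
    aligner = _aligner()
    best = aligner.align(a.sequence, b.sequence)[0]
    ga, gb = str(best[0]), str(best[1])
    return Alignment(rows=[(a.id, ga), (b.id, gb)], score=float(best.score))


def percent_identity(aln: Alignment) -> float:
    """Percent identity of a 2-row alignment.

    Identical residue pairs over columns where both rows hold residues
    (gap-containing columns are excluded from the denominator).
    """
    if len(aln.rows) != 2:
        raise InputError("percent_identity requires exactly 2 rows")
    sa, sb = aln.rows[0][1], aln.rows[1][1]
    both = ident = 0
    for x, y in zip(sa, sb):
        if x != GAP and y != GAP:
            both += 1
            if x == y:
                ident += 1
    if both == 0:
        return 0.0
    return 100.0 * ident / both


def identity_matrix(
    records: Sequence[ProteinRecord],
) -> tuple[DistanceMatrix, list[str]]:
    """All-pairs percent identity as distances (100 - identity), with a
    clustered row/column ordering from average-linkage hierarchical
    clustering.

    Returns (distance matrix in input label order, clustered label order).
    """
    if len(records) < 2:
        raise InputError("identity_matrix requires at least 2 records")
    check_unique_ids(records)
    n = len(records)
    ident = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident[i, j] = ident[j, i] = percent_identity(
                global_align(records[i], records[j])
            )
    dist = 100.0 - ident
    np.fill_diagonal(dist, 0.0)
    labels = [r.id for r in records]
    dm = DistanceMatrix(labels=labels, values=dist)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [labels[i] for i in hierarchy.leaves_list(link)]
    return dm, order


def write_identity_tsv(dm: DistanceMatrix, path: str | Path, *, order: list[str] | None = None) -> None:
    """Export percent identities (100 - distance) as TSV with header row/column."""
    labels = order or dm.labels
    idx = {l: i for i, l in enumerate(dm.labels)}
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(labels) + "\n")
        for a in labels:
            vals = [f"{round(100.0 - dm.values[idx[a], idx[b]])}" for b in labels]
            fh.write(a + "\t" + "\t".join(vals) + "\n")


# ---------------------------------------------------------------------------
# Progressive multiple alignment (UPGMA guide tree, profile-profile merge)
# ---------------------------------------------------------------------------


def _column_residues(rows: list[tuple[str, str]], j: int) -> list[str]:
    return [gapped[j] for _, gapped in rows]


def _profile_pair_score(cols_a: list[str], cols_b: list[str], matrix, alpha_index) -> float:
    s = 0.0
    n = 0
    for x in cols_a:
        for y in cols_b:
            n += 1
            if x != GAP and y != GAP:
                s += matrix[alpha_index[x], alpha_index[y]]
    return s / n if n else 0.0


def _profile_align(rows_a: list[tuple[str, str]], rows_b: list[tuple[str, str]]) -> list[tuple[str, str]]:
    """Global affine profile-profile alignment of two gapped row groups.

    Column score is the mean of all cross-group residue-pair BLOSUM62
    scores (gap or X members contribute 0). Traceback tie-break prefers
    diagonal, then a gap in B, then a gap in A — deterministic.
    """
    m = blosum62()
    alpha_index = {ch: i for i, ch in enumerate(m.alphabet)}
    alpha_index[GAP] = -1  # never used for lookup (guarded)
    la = len(rows_a[0][1])
    lb = len(rows_b[0][1])
    cols_a = [_column_residues(rows_a, j) for j in range(la)]
    cols_b = [_column_residues(rows_b, j) for j in range(lb)]
    score = np.empty((la, lb))
    for i in range(la):
        for j in range(lb):
            score[i, j] = _profile_pair_score(cols_a[i], cols_b[j], m, alpha_index)

    neg = -np.inf
    open_cost, ext_cost = GAP_OPEN + GAP_EXTEND, GAP_EXTEND
    M = np.full((la + 1, lb + 1), neg)  # i, j consumed; last step diagonal
    X = np.full((la + 1, lb + 1), neg)  # gap in B (consume A column)
    Y = np.full((la + 1, lb + 1), neg)  # gap in A (consume B column)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -(open_cost + ext_cost * (i - 1))
    for j in range(1, lb + 1):
        Y[0, j] = -(open_cost + ext_cost * (j - 1))
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + score[i - 1, j - 1]
            X[i, j] = max(M[i - 1, j] - open_cost, X[i - 1, j] - ext_cost)
            Y[i, j] = max(M[i, j - 1] - open_cost, Y[i, j - 1] - ext_cost)
    # traceback
    i, j = la, lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))  # 0=M,1=X,2=Y
    steps: list[str] = []
    while i > 0 or j > 0:
        if i == 0:
            steps.append("Y"); j -= 1; continue
        if j == 0:
            steps.append("X"); i -= 1; continue
        if state == 0:
            steps.append("M")
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            state = int(np.argmax(prev))
            i -= 1; j -= 1
        elif state == 1:
            steps.append("X")
            state = 0 if M[i - 1, j] - open_cost >= X[i - 1, j] - ext_cost else 1
            i -= 1
        else:
            steps.append("Y")
            state = 0 if M[i, j - 1] - open_cost >= Y[i, j - 1] - ext_cost else 2
            j -= 1
    steps.reverse()

    out_a = {rid: [] for rid, _ in rows_a}
    out_b = {rid: [] for rid, _ in rows_b}
    ia = ib = 0
    for st in steps:
        if st in ("M", "X"):
            for rid, gapped in rows_a:
                out_a[rid].append(gapped[ia])
            ia += 1
        else:
            for rid, _ in rows_a:
                out_a[rid].append(GAP)
        if st in ("M", "Y"):
            for rid, gapped in rows_b:
                out_b[rid].append(gapped[ib])
            ib += 1
        else:
            for rid, _ in rows_b:
                out_b[rid].append(GAP)
    merged = [(rid, "".join(out_a[rid])) for rid, _ in rows_a]
    merged += [(rid, "".join(out_b[rid])) for rid, _ in rows_b]
    return merged


def progressive_msa(records: Sequence[ProteinRecord]) -> Alignment:
    """Progressive multiple alignment.

    Guide tree: UPGMA (average linkage) on 100 - percent identity.
    Groups are merged bottom-up by profile-profile global alignment.
    Output row order equals input order.
    """
    if len(records) == 0:
        raise InputError("progressive_msa requires at least 1 record")
    if len(records) == 1:
        return Alignment(rows=[(records[0].id, records[0].sequence)])
    check_unique_ids(records)
    dm, _ = identity_matrix(records)
    link = hierarchy.linkage(squareform(dm.values, checks=False), method="average")
    groups: dict[int, list[tuple[str, str]]] = {
        i: [(rec.id, rec.sequence)] for i, rec in enumerate(records)
    }
    n = len(records)
    for k, (a, b, _d, _cnt) in enumerate(link):
        groups[n + k] = _profile_align(groups.pop(int(a)), groups.pop(int(b)))
    final = groups[n + len(link) - 1]
    by_id = dict(final)
    rows = [(rec.id, by_id[rec.id]) for rec in records]
    return Alignment(rows=rows)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree (unrooted) from a distance matrix.

    Exact for additive distances: the generating topology and branch
    lengths are recovered.
    """
    if len(dm.labels) < 3:
        raise InputError("nj_tree requires at least 3 labels")
    sk = _SkbioDM(dm.values, ids=dm.labels)
    return _skbio_nj(sk)
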