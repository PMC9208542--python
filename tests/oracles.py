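"""Independent brute-force oracles used by the test suite.

Each oracle re-derives a quantity by exhaustive enumeration (alignments,
HMM state paths, Dollo labelings) or direct construction (additive
distances from a known tree), without touching the implementation paths
it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from skbio import TreeNode

from dnasekit.align import GAP_EXTEND, GAP_OPEN, blosum62

# ---------------------------------------------------------------------------
# Global affine alignment by exhaustive enumeration
# ---------------------------------------------------------------------------


def brute_force_align_score(a: str, b: str) -> float:
    """Best global alignment score over every monotone alignment,
    scoring each gap run as -(open + extend * length)."""
    m = blosum62()
    idx = {ch: i for i, ch in enumerate(m.alphabet)}
    best = [-math.inf]

    def rec(i: int, j: int, score: float, last: str) -> None:
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + m[idx[a[i]], idx[b[j]]], "M")
        if i < len(a):
            cost = GAP_EXTEND if last == "X" else GAP_OPEN + GAP_EXTEND
            rec(i + 1, j, score - cost, "X")
        if j < len(b):
            cost = GAP_EXTEND if last == "Y" else GAP_OPEN + GAP_EXTEND
            rec(i, j + 1, score - cost, "Y")

    rec(0, 0, 0.0, "M")
    return best[0]


# ---------------------------------------------------------------------------
# Profile HMM forward probability by exhaustive path enumeration
# ---------------------------------------------------------------------------


def brute_force_forward_odds(hmm, seq: str) -> float:
    """Sum over every state path of P(path, seq) / P(seq | background),
    enumerated in probability space. Only tractable for tiny profiles."""
    from dnasekit.hmm import AMINO_ACIDS

    aa = {c: i for i, c in enumerate(AMINO_ACIDS)}
    L = hmm.match_count
    n = len(seq)
    bg = hmm.background
    loop, leave = hmm.flank_loop, 1.0 - hmm.flank_loop

    def em_odds(k: int, pos: int) -> float:
        c = aa[seq[pos]]
        return hmm.match_emissions[k, c] / bg[c]

    total = 0.0

    def core(k: int, state: str, pos: int, end: int, w: float) -> None:
        """Sum path odds; at (state at match index k) having consumed
        seq[..pos); must finish exactly at M_{L-1} consuming seq[..end)."""
        nonlocal total
        if state == "M" and k == L - 1:
            if pos == end:
                total += w
            return
        if state == "M":
            # to M_{k+1}
            if pos < end:
                core(k + 1, "M", pos + 1, end, w * hmm.t_mm[k] * em_odds(k + 1, pos))
            # to I_k
            if pos < end:
                core(k, "I", pos + 1, end, w * hmm.t_mi[k])
            # to D_{k+1} (exists for k+1 <= L-2)
            if k + 1 <= L - 2:
                core(k + 1, "D", pos, end, w * hmm.t_md[k])
        elif state == "I":
            if pos < end:
                core(k + 1, "M", pos + 1, end, w * hmm.t_im[k] * em_odds(k + 1, pos))
                core(k, "I", pos + 1, end, w * hmm.t_ii[k])
        else:  # D at index k (1..L-2)
            if pos < end:
                core(k + 1, "M", pos + 1, end, w * hmm.t_dm[k] * em_odds(k + 1, pos))
            if k + 1 <= L - 2:
                core(k + 1, "D", pos, end, w * hmm.t_dd[k])

    for nflank in range(n + 1):
        for cflank in range(n - nflank + 1):
            start = nflank
            end = n - cflank
            if end - start < 1:
                continue
            w = (loop ** nflank) * leave * (loop ** cflank) * leave
            core(0, "M", start + 1, end, w * em_odds(0, start))
    return total


def brute_force_forward_bits(hmm, seq: str) -> float:
    odds = brute_force_forward_odds(hmm, seq)
    return math.log2(odds) if odds > 0 else -math.inf


# ---------------------------------------------------------------------------
# Random ultrametric trees and additive distances
# ---------------------------------------------------------------------------


def random_ultrametric_tree(rng: np.random.Generator, n_leaves: int) -> TreeNode:
    """Coalescent-style random ultrametric tree with named nodes and ages."""
    nodes = [f"t{i}:0" for i in range(n_leaves)]
    ages = [0.0] * n_leaves
    age = 0.0
    k = 0
    while len(nodes) > 1:
        age += float(rng.uniform(5.0, 50.0))
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        ni, nj = nodes[i], nodes[j]
        ai, aj = ages[i], ages[j]
        merged = f"({_with_len(ni, age - ai)},{_with_len(nj, age - aj)})i{k}"
        k += 1
        nodes = [nodes[x] for x in range(len(nodes)) if x not in (i, j)] + [merged]
        ages = [ages[x] for x in range(len(ages)) if x not in (i, j)] + [age]
    from dnasekit.repertoire import annotate_ages

    tree = TreeNode.read([nodes[0] + ";"])
    return annotate_ages(tree)


def _with_len(newick_frag: str, length: float) -> str:
    # fragments are "name:length" for leaves (strip placeholder) or "(...)name"
    if newick_frag.endswith(":0"):
        return newick_frag[:-2] + f":{length:.10g}"
    return newick_frag + f":{length:.10g}"


def random_additive_tree(rng: np.random.Generator, n_leaves: int) -> TreeNode:
    """Random binary tree with free (non-ultrametric) branch lengths."""
    frags = [f"t{i}" for i in range(n_leaves)]
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        li, lj = rng.uniform(0.5, 5.0, size=2)
        merged = f"({frags[i]}:{li:.10g},{frags[j]}:{lj:.10g})"
        frags = [frags[x] for x in range(len(frags)) if x not in (i, j)] + [merged]
    return TreeNode.read([frags[0] + ";"])


def tree_tip_distances(tree: TreeNode) -> tuple[list[str], np.ndarray]:
    tips = sorted(t.name for t in tree.tips())
    dm = tree.tip_tip_distances(endpoints=tips)
    return tips, dm.data


# ---------------------------------------------------------------------------
# Dollo parsimony by exhaustive labeling search
# ---------------------------------------------------------------------------


def brute_force_dollo_min_losses(tree: TreeNode, present: set[str]) -> int:
    """Minimum loss count over all ancestral 0/1 labelings with exactly
    one gain (a root labeled 1 counts as the gain on the root stem)."""
    internals = [n for n in tree.traverse(include_self=True) if not n.is_tip()]
    best = math.inf
    for bits in itertools.product([0, 1], repeat=len(internals)):
        state = {id(n): b for n, b in zip(internals, bits)}
        for t in tree.tips():
            state[id(t)] = 1 if t.name in present else 0
        gains = state[id(tree)]
        losses = 0
        for node in tree.traverse(include_self=False):
            s_p, s_c = state[id(node.parent)], state[id(node)]
            if s_p == 0 and s_c == 1:
                gains += 1
            elif s_p == 1 and s_c == 0:
                losses += 1
        if gains == 1 and losses < best:
            best = losses
    return int(best)
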