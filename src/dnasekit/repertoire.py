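"""Presence/absence repertoires, Dollo gain/loss dating, and synteny.

The repertoire of a species set is a boolean taxa x orthogroup matrix
built from verified orthogroup calls. Gains and losses are reconstructed
per orthogroup under Dollo parsimony — a gene family arises exactly once,
on the stem branch above the most recent common ancestor (MRCA) of the
taxa that have it, and is lost on the stem of every maximal presence-free
subtree below that ancestor. This minimizes losses given a single gain.
On a dated species tree (a chronogram with node ages in Myr) every event
carries the time interval of its branch, which is how tandem-duplication
windows (e.g. a daughter gene's origin on the amniote stem, ~330 Myr ago)
are read off.

Synteny between two loci distinguishes tandem same-strand arrangements
from divergent head-to-head pairs (minus-strand gene upstream, the two 5'
ends facing a shared bidirectional promoter region) and convergent
tail-to-tail pairs. Coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .features import OrthogroupCall
from .records import InputError

__all__ = [
    "Event",
    "EventSet",
    "GeneLocus",
    "SyntenyRecord",
    "load_tree",
    "annotate_ages",
    "build_matrix",
    "dollo_events",
    "presence_from_events",
    "duplication_interval",
    "detect_synteny",
    "read_loci_tsv",
    "write_loci_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_events_tsv",
]


# ---------------------------------------------------------------------------
# Dated trees
# ---------------------------------------------------------------------------


def ensure_node_names(tree: TreeNode) -> TreeNode:
    i = 0
    for node in tree.preorder():
        if not node.name:
            node.name = f"n{i}"
            i += 1
    return tree


def annotate_ages(tree: TreeNode, root_age: float | None = None) -> TreeNode:
    """Attach an ``age`` (Myr before present) to every node.

    Branch lengths are in Myr; the tree must be ultrametric. With no
    explicit ``root_age`` the root age is the maximum root-to-leaf path.
    """
    depths: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        depths[id(node)] = depths[id(node.parent)] + (node.length or 0.0)
    leaf_depths = [depths[id(t)] for t in tree.tips()]
    span = max(leaf_depths)
    if max(leaf_depths) - min(leaf_depths) > 1e-6 * max(span, 1.0):
        raise InputError("tree is not ultrametric; cannot assign ages")
    if root_age is None:
        root_age = span
    for node in tree.traverse(include_self=True):
        node.age = root_age - depths[id(node)]
    return tree


def load_tree(path: str | Path, root_age: float | None = None) -> TreeNode:
    tree = TreeNode.read(str(path), convert_underscores=False)
    ensure_node_names(tree)
    return annotate_ages(tree, root_age)


# ---------------------------------------------------------------------------
# Presence matrix
# ---------------------------------------------------------------------------


def build_matrix(
    calls: Sequence[OrthogroupCall],
    taxa: Sequence[str],
    orthogroups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Boolean taxa x orthogroup matrix: a cell is true when the taxon
    has at least one call of that orthogroup (flags warn, never reject).
    Taxa without calls keep all-false rows."""
    ogs = sorted({c.label for c in calls}) if orthogroups is None else list(orthogroups)
    mat = pd.DataFrame(False, index=list(taxa), columns=ogs)
    for c in calls:
        if c.taxon not in mat.index:
            raise InputError(f"call taxon {c.taxon!r} not in the taxa list")
        if c.label in mat.columns:
            mat.loc[c.taxon, c.label] = True
    return mat


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.astype(int).to_csv(path, sep="\t", index_label="taxon")


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="taxon")
    return df.astype(bool)


# ---------------------------------------------------------------------------
# Dollo parsimony events
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Event:
    orthogroup: str
    kind: str  # "gain" | "loss"
    parent: str  # name of the branch's parent node ("stem" above the root)
    child: str  # name of the branch's child node
    older: float  # Myr
    younger: float  # Myr

    @property
    def interval(self) -> tuple[float, float]:
        return (self.older, self.younger)


@dataclass
class EventSet:
    gains: dict[str, Event] = field(default_factory=dict)
    losses: dict[str, list[Event]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def all_events(self) -> list[Event]:
        out = list(self.gains.values())
        for ev in self.losses.values():
            out.extend(ev)
        return out


def _presence_counts(tree: TreeNode, present: set[str]) -> dict[int, int]:
    counts: dict[int, int] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            counts[id(node)] = 1 if node.name in present else 0
        else:
            counts[id(node)] = sum(counts[id(c)] for c in node.children)
    return counts


def dollo_events(matrix: pd.DataFrame, tree: TreeNode) -> EventSet:
    """Single-gain / minimal-loss (Dollo) reconstruction per orthogroup.

    The gain sits on the stem branch above the MRCA of all presence taxa;
    one loss sits on the stem of each maximal subtree under the gain with
    no presence taxon. Event intervals are (parent age, child age); a
    gain above the root uses the root's own stem length when the Newick
    supplies one.
    """
    leaf_names = {t.name for t in tree.tips()}
    missing = set(matrix.index) - leaf_names
    if missing:
        raise InputError(f"matrix taxa absent from the tree: {sorted(missing)}")
    events = EventSet()
    for og in matrix.columns:
        present = set(matrix.index[matrix[og]])
        if not present:
            events.warnings.append(f"{og}: absent everywhere, no events inferred")
            events.losses[og] = []
            continue
        if len(present) == 1:
            mrca = tree.find(next(iter(present)))
        else:
            mrca = tree.lca(sorted(present))
        parent = mrca.parent
        if parent is not None:
            gain = Event(og, "gain", parent.name, mrca.name, parent.age, mrca.age)
        else:
            stem = mrca.length or 0.0
            gain = Event(og, "gain", "stem", mrca.name, mrca.age + stem, mrca.age)
        events.gains[og] = gain
        counts = _presence_counts(mrca, present)
        losses: list[Event] = []
        stack = list(mrca.children)
        while stack:
            node = stack.pop()
            if counts[id(node)] == 0:
                losses.append(
                    Event(og, "loss", node.parent.name, node.name, node.parent.age, node.age)
                )
            else:
                stack.extend(node.children)
        events.losses[og] = sorted(losses, key=lambda e: (-e.older, e.child))
    return events


def presence_from_events(
    tree: TreeNode, gain_child: str, loss_children: Iterable[str]
) -> set[str]:
    """Forward-simulate a presence pattern: leaves under the gain node
    minus leaves under any loss node (losses are irreversible)."""
    gain_node = tree.find(gain_child)
    present = {t.name for t in gain_node.tips(include_self=True)}
    for name in loss_children:
        node = tree.find(name)
        present -= {t.name for t in node.tips(include_self=True)}
    return present


def duplication_interval(
    events: EventSet, parent_orthogroup: str, child_orthogroup: str
) -> tuple[float, float]:
    """Time window of the tandem duplication that created
    ``child_orthogroup`` out of ``parent_orthogroup``: the child's
    gain-branch interval, clipped so it cannot predate the parent's own
    origin."""
    if child_orthogroup not in events.gains:
        raise InputError(f"no gain event for orthogroup {child_orthogroup!r}")
    child = events.gains[child_orthogroup]
    older, younger = child.older, child.younger
    parent = events.gains.get(parent_orthogroup)
    if parent is None and parent_orthogroup not in events.losses:
        raise InputError(f"unknown orthogroup {parent_orthogroup!r}")
    if parent is not None:
        older = min(older, parent.older)
    return (older, younger)


def write_events_tsv(events: EventSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("orthogroup\tevent\tparent\tchild\tolder_myr\tyounger_myr\n")
        for ev in sorted(events.all_events(), key=lambda e: (e.orthogroup, e.kind, e.child)):
            fh.write(
                f"{ev.orthogroup}\t{ev.kind}\t{ev.parent}\t{ev.child}\t"
                f"{ev.older:.6g}\t{ev.younger:.6g}\n"
            )


# ---------------------------------------------------------------------------
# Synteny
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneLocus:
    gene: str
    chromosome: str
    start: int  # 0-based, half-open
    end: int
    strand: str  # "+" | "-"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise InputError(f"locus {self.gene!r}: need 0 <= start < end")
        if self.strand not in "+-":
            raise InputError(f"locus {self.gene!r}: strand must be + or -")


@dataclass(frozen=True)
class SyntenyRecord:
    gene_a: str
    gene_b: str
    arrangement: str  # TANDEM_SAME_STRAND | HEAD_TO_HEAD | TAIL_TO_TAIL | UNLINKED
    distance: int  # bp between the spans; -1 when unlinked
    intervening: int
    warning: str | None = None


def detect_synteny(
    loci: Sequence[GeneLocus],
    pair: tuple[str, str],
    all_genes: Sequence[GeneLocus] | None = None,
) -> SyntenyRecord:
    """Classify the genomic arrangement of a gene pair.

    Symmetric in gene order. Head-to-head means divergent strands with
    the minus-strand gene upstream (5' ends facing each other across the
    intergenic gap). Distance is the gap between spans (0 with a warning
    if they overlap); intervening counts genes lying strictly inside the
    gap.
    """
    by_name = {l.gene: l for l in loci}
    try:
        a, b = by_name[pair[0]], by_name[pair[1]]
    except KeyError as exc:
        raise InputError(f"gene {exc.args[0]!r} not found among loci") from None
    if a.chromosome != b.chromosome:
        return SyntenyRecord(pair[0], pair[1], "UNLINKED", -1, 0)
    left, right = (a, b) if a.start <= b.start else (b, a)
    gap_start, gap_end = left.end, right.start
    warning = None
    if gap_end < gap_start:
        distance = 0
        warning = "overlapping gene spans"
        gap_start = gap_end  # empty gap
    else:
        distance = gap_end - gap_start
    if left.strand == right.strand:
        arrangement = "TANDEM_SAME_STRAND"
    elif left.strand == "-" and right.strand == "+":
        arrangement = "HEAD_TO_HEAD"
    else:
        arrangement = "TAIL_TO_TAIL"
    intervening = 0
    if all_genes:
        pair_names = {pair[0], pair[1]}
        for g in all_genes:
            if g.gene in pair_names or g.chromosome != a.chromosome:
                continue
            if g.start >= gap_start and g.end <= gap_end:
                intervening += 1
    return SyntenyRecord(pair[0], pair[1], arrangement, distance, intervening, warning)


def read_loci_tsv(path: str | Path) -> list[GeneLocus]:
    """Read BED-like 6-column loci: chrom, start, end, gene, score, strand."""
    loci = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise InputError(f"{path}:{ln}: expected 6 tab-separated columns")
            chrom, start, end, gene, _score, strand = parts[:6]
            loci.append(GeneLocus(gene, chrom, int(start), int(end), strand))
    return loci


def write_loci_tsv(loci: Iterable[GeneLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            fh.write(f"{l.chromosome}\t{l.start}\t{l.end}\t{l.gene}\t0\t{l.strand}\n")
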