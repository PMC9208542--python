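"""Ground-truthed synthetic data for the whole pipeline.

Real DNase repertoires come from public proteomes; this module emulates
their structure so every stage can be exercised end to end with known
answers and no downloads:

* a bundled 21-leaf chordate chronogram with round TimeTree-style ages
  (editable Newick fixture shipped with the package);
* per-orthogroup *member architectures* — a consensus sequence carrying
  the family's diagnostic implants (signal-peptide or deliberately polar
  N terminus, cysteine pairs and HxK motifs at reference columns, and the
  GPI / basic / SMB / EL C-terminal class) — from which curated seed
  alignments, profile HMMs, and simulated proteome members all derive;
* gene gain/loss histories: presence propagates down the tree from a
  per-orthogroup gain branch, with losses drawn from a Poisson process
  (rate x branch length in Myr); a lost lineage stays lost;
* decoy proteins: residue-shuffled members — composition-matched nulls;
* gene coordinate tables with planted synteny arrangements.

Everything is deterministic for a fixed seed. The reference gain/loss
pattern (`REFERENCE_EVENTS`) encodes the published vertebrate DNase
history: DNase1 and DNase2b ancestral to chordates, a first expansion
(DNase2, DNase1L3, DNase1L1L) before the jawless/jawed split, DNase1L4
and DNase1L5 in early jawed vertebrates, DNase1L1 on the bony-vertebrate
stem, DNase1L4-2 in Neopterygii, DNase1L2 on the amniote stem, and the
documented losses (DNase2 in birds, DNase1L1L in birds and placentals,
DNase2b in agnathans, snakes and monotremes, ...).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .align import Alignment
from .features import EXPECTATION
from .hmm import (
    AMINO_ACIDS,
    ProfileHmm,
    ROBINSON_BACKGROUND,
    build_profile,
    calibrate,
    sample_sequence,
)
from .records import InputError, ProteinRecord
from .repertoire import Event, EventSet, annotate_ages, ensure_node_names, GeneLocus

__all__ = [
    "SimConfig",
    "SimTruth",
    "MemberLayout",
    "ProfileBundle",
    "ORTHOGROUPS",
    "REFERENCE_EVENTS",
    "default_tree",
    "reference_presence_matrix",
    "member_layout",
    "make_seed_alignment",
    "build_synthetic_profiles",
    "simulate_history",
    "identifiable_losses",
    "generate_proteome",
    "generate_gene_table",
]

ORTHOGROUPS = [
    "DNase1", "DNase1L1", "DNase1L1L", "DNase1L2", "DNase1L3",
    "DNase1L4", "DNase1L4-2", "DNase1L5", "DNase2", "DNase2b",
]

# orthogroup -> (gain branch child node, reference loss branch children)
REFERENCE_EVENTS: dict[str, tuple[str, tuple[str, ...]]] = {
    "DNase1":     ("Chordata", ()),
    "DNase2b":    ("Chordata", ("Petromyzon_marinus", "Notechis_scutatus",
                                "Ornithorhynchus_anatinus")),
    "DNase2":     ("Vertebrata", ("Aves",)),
    "DNase1L3":   ("Vertebrata", ("Teleostei",)),
    "DNase1L1L":  ("Vertebrata", ("Aves", "Placentalia")),
    "DNase1L4":   ("Gnathostomata", ("Amniota",)),
    "DNase1L5":   ("Gnathostomata", ("Neopterygii", "Amniota")),
    "DNase1L1":   ("Osteichthyes", ("Aves",)),
    "DNase1L4-2": ("Neopterygii", ("Oryzias_latipes",)),
    "DNase1L2":   ("Amniota", ()),
}


def default_tree() -> TreeNode:
    """The bundled 21-leaf chordate chronogram (ages in Myr)."""
    ref = importlib.resources.files("dnasekit.data") / "chordate21.nwk"
    tree = TreeNode.read([ref.read_text()], convert_underscores=False)
    ensure_node_names(tree)
    return annotate_ages(tree)


def _presence_under(tree: TreeNode, gain_child: str, losses: Iterable[str]) -> set[str]:
    node = tree.find(gain_child)
    present = {t.name for t in node.tips(include_self=True)}
    for name in losses:
        present -= {t.name for t in tree.find(name).tips(include_self=True)}
    return present


def reference_presence_matrix(tree: TreeNode | None = None) -> pd.DataFrame:
    """The published-style presence/absence pattern on the bundled tree."""
    tree = tree if tree is not None else default_tree()
    taxa = [t.name for t in tree.tips()]
    mat = pd.DataFrame(False, index=taxa, columns=ORTHOGROUPS)
    for og, (gain, losses) in REFERENCE_EVENTS.items():
        for taxon in _presence_under(tree, gain, losses):
            mat.loc[taxon, og] = True
    return mat


# ---------------------------------------------------------------------------
# Member architectures and seed alignments
# ---------------------------------------------------------------------------

SP_PREFIX = "MKWKALLLLLAVVAGSSA"  # detectable secretion signal
NOSP_PREFIX = "MDESTNQDESTNQGSTDEQSTNQGSTEDNQSTGQD"  # polar, no signal

CTERM_SUFFIX = {
    "GPI": "SNSTGQALLVVLLAVLL",     # omega + 6-residue spacer + hydrophobic tail
    "BASIC": "KKSKRSKKAGRK",        # net charge +8 in the last 12
    "SMB": "CGDNCQSTCNPACGETCSQC",  # cysteine-rich somatomedin-B-like stretch
    "EL": "GSTNQGSTNQEL",
    "NONE": "GSTAQNSGQTDA",
}

CORE_LEN = 215

# DNase1-family reference cysteines: label -> core offset
_D1_CYS = {"C4": 4, "C32": 32, "C101": 101, "C104": 104, "C173": 173, "C209": 209}
# DNase2-family cysteine pairs and PLD catalytic positions (core offsets)
_D2_CYS = {"2C1a": 30, "2C1b": 90, "2C2a": 110, "2C2b": 140,
           "2C3a": 180, "2C3b": 200, "2C4a": 10, "2C4b": 205}
_D2_PLD = {"PLD1_HxK": 60, "PLD2_HxK": 160}

_NONCYS = [a for a in AMINO_ACIDS if a != "C"]
_NONCYS_P = np.array([ROBINSON_BACKGROUND[AMINO_ACIDS.index(a)] for a in _NONCYS])
_NONCYS_P /= _NONCYS_P.sum()


@dataclass
class MemberLayout:
    """Blueprint of one orthogroup's synthetic members."""

    orthogroup: str
    consensus: str
    prefix: str
    suffix: str
    reference_columns: dict[int, str]      # 0-based consensus column -> label
    forced_residues: dict[int, str]        # columns pinned during sampling
    cterm_class: str
    has_signal: bool


def member_layout(og: str, rng: np.random.Generator) -> MemberLayout:
    """Draw the consensus architecture of one orthogroup.

    The core is background-composition sequence without cysteines;
    diagnostic residues are then implanted at fixed core offsets so the
    expectation table holds by construction.
    """
    exp = EXPECTATION[og]
    if og in ("DNase2", "DNase2b"):
        has_sp, cterm = True, "NONE"
    else:
        _, has_sp, cterm, _ = exp
    prefix = SP_PREFIX if has_sp else NOSP_PREFIX
    core = list(rng.choice(_NONCYS, size=CORE_LEN, p=_NONCYS_P))
    refcols: dict[int, str] = {}
    forced: dict[int, str] = {}
    off = len(prefix)
    if og in ("DNase2", "DNase2b"):
        pairs = ["pair1", "pair2", "pair3"] + (["DNase2b-extra"] if og == "DNase2b" else [])
        from .features import CYS_PAIRS
        for pair in pairs:
            for lab in CYS_PAIRS[pair]:
                col = off + _D2_CYS[lab]
                core[_D2_CYS[lab]] = "C"
                refcols[col] = lab
                forced[col] = "C"
        # register the extra-pair anchors for DNase2 too (not cysteine there)
        if og == "DNase2":
            for lab in ("2C4a", "2C4b"):
                refcols[off + _D2_CYS[lab]] = lab
        for lab, pos in _D2_PLD.items():
            core[pos] = "H"
            core[pos + 2] = "K"
            refcols[off + pos] = lab
            forced[off + pos] = "H"
            forced[off + pos + 1] = core[pos + 1]  # keep the triad contiguous
            forced[off + pos + 2] = "K"
    else:
        expected_pairs = exp[0]
        implanted = {lab for pair in expected_pairs
                     for lab in (pair.split("-")[0], pair.split("-")[1])}
        for lab, pos in _D1_CYS.items():
            refcols[off + pos] = lab
            if lab in implanted:
                core[pos] = "C"
                forced[off + pos] = "C"
    suffix = CTERM_SUFFIX[cterm]
    consensus = prefix + "".join(core) + suffix
    return MemberLayout(
        orthogroup=og, consensus=consensus, prefix=prefix, suffix=suffix,
        reference_columns=refcols, forced_residues=forced,
        cterm_class=cterm, has_signal=has_sp,
    )


def make_seed_alignment(
    layout: MemberLayout,
    rng: np.random.Generator,
    n_rows: int = 16,
    mutation_rate: float = 0.05,
) -> Alignment:
    """A curated-orthologs stand-in: the consensus plus rows mutated at
    non-diagnostic positions (substitutions only, never to cysteine, so
    the alignment is gapless and the implants stay conserved)."""
    protected = set(layout.forced_residues)
    protected.update(range(len(layout.prefix)))
    protected.update(range(len(layout.consensus) - len(layout.suffix), len(layout.consensus)))
    rows = [(f"{layout.orthogroup}|seed0", layout.consensus)]
    for r in range(1, n_rows):
        chars = list(layout.consensus)
        for j in range(len(chars)):
            if j not in protected and rng.random() < mutation_rate:
                chars[j] = rng.choice(_NONCYS, p=_NONCYS_P)
        rows.append((f"{layout.orthogroup}|seed{r}", "".join(chars)))
    return Alignment(rows=rows)


@dataclass
class ProfileBundle:
    profiles: dict[str, ProfileHmm]
    layouts: dict[str, MemberLayout]
    seed: int


def build_synthetic_profiles(
    seed: int = 0,
    *,
    orthogroups: Sequence[str] = tuple(ORTHOGROUPS),
    calibrated: bool = True,
    n_calibration: int = 200,
    n_rows: int = 16,
) -> ProfileBundle:
    """Seed alignments -> profile HMMs (optionally Gumbel-calibrated) for
    every orthogroup, deterministically from one seed."""
    profiles: dict[str, ProfileHmm] = {}
    layouts: dict[str, MemberLayout] = {}
    for i, og in enumerate(orthogroups):
        rng = np.random.default_rng([seed, 1, i])
        layout = member_layout(og, rng)
        msa = make_seed_alignment(layout, rng, n_rows=n_rows)
        hmm = build_profile(msa, og, reference_columns=layout.reference_columns)
        if calibrated:
            hmm = calibrate(hmm, n_samples=n_calibration, seed=int(rng.integers(2**31)))
        profiles[og] = hmm
        layouts[og] = layout
    return ProfileBundle(profiles=profiles, layouts=layouts, seed=seed)


# ---------------------------------------------------------------------------
# Gain/loss history simulation
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    seed: int = 0
    tree: TreeNode | None = None  # default: bundled chordate chronogram
    gain_branches: Mapping[str, str] = field(
        default_factory=lambda: {og: g for og, (g, _) in REFERENCE_EVENTS.items()}
    )
    loss_rate: float = 0.0004  # losses / Myr / lineage
    members_per_cell: int = 1
    decoys_per_taxon: int = 10

    def resolved_tree(self) -> TreeNode:
        return self.tree if self.tree is not None else default_tree()


@dataclass
class SimTruth:
    presence: pd.DataFrame
    events: EventSet
    membership: dict[str, str] = field(default_factory=dict)
    seed: int = 0


def reference_truth(tree: TreeNode | None = None) -> SimTruth:
    """The reference gain/loss history as a ground-truth object (the
    deterministic counterpart of :func:`simulate_history`)."""
    tree = tree if tree is not None else default_tree()
    events = EventSet()
    for og, (gain, losses) in REFERENCE_EVENTS.items():
        events.gains[og] = _gain_event(tree, og, gain)
        evs = []
        for child in losses:
            node = tree.find(child)
            evs.append(Event(og, "loss", node.parent.name, node.name,
                             node.parent.age, node.age))
        events.losses[og] = sorted(evs, key=lambda e: (-e.older, e.child))
    return SimTruth(presence=reference_presence_matrix(tree), events=events)


def _gain_event(tree: TreeNode, og: str, gain_child: str) -> Event:
    node = tree.find(gain_child)
    if node.parent is not None:
        return Event(og, "gain", node.parent.name, node.name, node.parent.age, node.age)
    stem = node.length or 0.0
    return Event(og, "gain", "stem", node.name, node.age + stem, node.age)


def simulate_history(cfg: SimConfig) -> SimTruth:
    """Single gain + Poisson losses per orthogroup on the dated tree.

    Presence propagates from the gain branch; each branch below a still-
    present lineage loses the gene with Poisson(rate x branch Myr) >= 1;
    lost lineages stay lost. Deterministic per seed.
    """
    tree = cfg.resolved_tree()
    rng = np.random.default_rng([cfg.seed, 2])
    taxa = [t.name for t in tree.tips()]
    mat = pd.DataFrame(False, index=taxa, columns=list(cfg.gain_branches))
    events = EventSet()
    for og, gain_child in cfg.gain_branches.items():
        try:
            gain_node = tree.find(gain_child)
        except Exception:
            raise InputError(f"gain branch child {gain_child!r} not in tree")
        events.gains[og] = _gain_event(tree, og, gain_child)
        losses: list[Event] = []
        lost_under: set[int] = set()
        for node in gain_node.preorder(include_self=False):
            if id(node.parent) in lost_under:
                lost_under.add(id(node))
                continue
            branch = node.length or 0.0
            if rng.poisson(cfg.loss_rate * branch) >= 1:
                lost_under.add(id(node))
                losses.append(
                    Event(og, "loss", node.parent.name, node.name,
                          node.parent.age, node.age)
                )
        events.losses[og] = sorted(losses, key=lambda e: (-e.older, e.child))
        present = {t.name for t in gain_node.tips(include_self=True)}
        for ev in losses:
            present -= {t.name for t in tree.find(ev.child).tips(include_self=True)}
        for taxon in present:
            mat.loc[taxon, og] = True
    return SimTruth(presence=mat, events=events, seed=cfg.seed)


def identifiable_losses(truth: SimTruth, tree: TreeNode | None = None) -> dict[str, bool]:
    """Which orthogroup histories a Dollo reconstruction can recover
    exactly: presence must be non-empty, its MRCA must be the gain node,
    and every loss branch's parent must retain a presence leaf (so
    neighbouring losses cannot merge)."""
    tree = tree if tree is not None else default_tree()
    out: dict[str, bool] = {}
    for og in truth.presence.columns:
        present = set(truth.presence.index[truth.presence[og]])
        if not present:
            out[og] = False
            continue
        gain_child = truth.events.gains[og].child
        mrca = (tree.find(next(iter(present))) if len(present) == 1
                else tree.lca(sorted(present)))
        if mrca.name != gain_child:
            out[og] = False
            continue
        ok = True
        for ev in truth.events.losses[og]:
            parent = tree.find(ev.child).parent
            below = {t.name for t in parent.tips(include_self=True)}
            if not below & present:
                ok = False
                break
        out[og] = ok
    return out


# ---------------------------------------------------------------------------
# Proteome generation
# ---------------------------------------------------------------------------


def _sample_member(
    hmm: ProfileHmm, layout: MemberLayout, rng: np.random.Generator
) -> str:
    """One simulated family member: a profile walk with the diagnostic
    states pinned, then the canonical terminal implants written over the
    ends (emulating the strong conservation of targeting signals).

    Indels are suppressed within two states of every diagnostic
    position: like their real counterparts, the implanted residues sit
    inside conserved motif blocks."""
    forced = {}
    col_state = {c: c + 1 for c in range(hmm.match_count)}  # gapless seed MSA
    anchors = set(hmm.reference_map)
    for col, res in layout.forced_residues.items():
        anchors.add(col_state[col])
        forced[col_state[col]] = res
    protected = set()
    for s in anchors:
        protected.update(k for k in range(s - 2, s + 3) if 1 <= k <= hmm.match_count)
    seq = sample_sequence(
        hmm, rng, protected_states=protected, forced_emissions=forced, flanks=False,
    )
    seq = layout.prefix + seq[len(layout.prefix):]
    if len(layout.suffix) > 0:
        seq = seq[: len(seq) - len(layout.suffix)] + layout.suffix
    return seq


def _shuffled(seq: str, rng: np.random.Generator) -> str:
    chars = list(seq)
    rng.shuffle(chars)
    return "".join(chars)


def generate_proteome(
    truth: SimTruth,
    bundle: ProfileBundle,
    cfg: SimConfig,
) -> dict[str, list[ProteinRecord]]:
    """Per-taxon protein sets: sampled members for every present cell
    plus composition-matched shuffled decoys. Membership ground truth is
    recorded onto ``truth`` (decoys map to "decoy")."""
    proteomes: dict[str, list[ProteinRecord]] = {}
    ogs = [og for og in truth.presence.columns if og in bundle.profiles]
    for t_i, taxon in enumerate(truth.presence.index):
        rng = np.random.default_rng([cfg.seed, 3, t_i])
        records: list[ProteinRecord] = []
        for og in ogs:
            if not truth.presence.loc[taxon, og]:
                continue
            for j in range(cfg.members_per_cell):
                seq = _sample_member(bundle.profiles[og], bundle.layouts[og], rng)
                rec = ProteinRecord(id=f"{taxon}|{og}|{j}", sequence=seq, taxon=taxon)
                records.append(rec)
                truth.membership[rec.id] = og
        for j in range(cfg.decoys_per_taxon):
            og = ogs[int(rng.integers(len(ogs)))] if ogs else "DNase1"
            base = _sample_member(bundle.profiles[og], bundle.layouts[og], rng)
            rec = ProteinRecord(
                id=f"{taxon}|decoy|{j}", sequence=_shuffled(base, rng), taxon=taxon
            )
            records.append(rec)
            truth.membership[rec.id] = "decoy"
        proteomes[taxon] = records
    return proteomes


# ---------------------------------------------------------------------------
# Gene tables with planted synteny
# ---------------------------------------------------------------------------


def generate_gene_table(
    planted: Sequence[tuple[str, str, str, int, int]],
    gene_length: int = 1000,
) -> list[GeneLocus]:
    """Construct loci realizing planted arrangements.

    Each plant is (geneA, geneB, arrangement, distance bp, n intervening
    filler genes) and goes on its own synthetic chromosome; UNLINKED
    pairs get two chromosomes. Intervening fillers require
    distance >= 2 * n + 1.
    """
    seen: set[str] = set()
    loci: list[GeneLocus] = []
    for idx, (ga, gb, arrangement, distance, n_inter) in enumerate(planted):
        for g in (ga, gb):
            if g in seen:
                raise InputError(f"gene {g!r} planted twice")
            seen.add(g)
        chrom = f"chr{idx + 1}"
        if arrangement == "UNLINKED":
            loci.append(GeneLocus(ga, chrom, 1000, 1000 + gene_length, "+"))
            loci.append(GeneLocus(gb, f"{chrom}b", 1000, 1000 + gene_length, "+"))
            continue
        if distance < 0:
            raise InputError("planted distance must be >= 0")
        if n_inter > 0 and distance < 2 * n_inter + 1:
            raise InputError(
                f"distance {distance} too small for {n_inter} intervening genes"
            )
        strands = {
            "TANDEM_SAME_STRAND": ("+", "+"),
            "HEAD_TO_HEAD": ("-", "+"),
            "TAIL_TO_TAIL": ("+", "-"),
        }.get(arrangement)
        if strands is None:
            raise InputError(f"unknown arrangement {arrangement!r}")
        a_start = 1000
        a_end = a_start + gene_length
        b_start = a_end + distance
        loci.append(GeneLocus(ga, chrom, a_start, a_end, strands[0]))
        loci.append(GeneLocus(gb, chrom, b_start, b_start + gene_length, strands[1]))
        if n_inter > 0:
            step = max(2, (distance - 2) // n_inter)
            for k in range(n_inter):
                start = a_end + 1 + k * step
                end = min(start + max(1, step - 1), b_start - 1)
                loci.append(GeneLocus(f"filler{idx}_{k}", chrom, start, end, "+"))
    return loci
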