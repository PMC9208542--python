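"""Diagnostic sequence features of DNase family proteins.

HMM bit scores classify, but the families carry independent sequence
fingerprints that verify a classification:

* disulfide-forming cysteine pairs — C4-C32 marks the DNase1L1/1L1L/1L3
  branch, C101-C104 marks DNase1/DNase1L5, C173-C209 is family-wide
  (labels follow human DNase1 numbering, anchored through profile
  reference maps rather than absolute positions, so they survive indels);
* C-terminal classes — GPI-anchor signal (omega site, 6-residue spacer,
  hydrophobic tail) in DNase1L1; lysine/arginine-rich basic peptide in
  DNase1L3/1L4/1L4-2; cysteine-rich somatomedin-B (SMB) domain in
  DNase1L5; a bare conserved "EL" terminus in DNase1L1L;
* an N-terminal secretion signal peptide, absent only from DNase1L4/-2;
* the two HxK catalytic motifs of the phospholipase-D domains of the
  DNase2 family.

Detection thresholds are package heuristics exposed in
:class:`FeatureConfig`; they stand in for external predictors and make no
accuracy claim on real proteins beyond what the synthetic fixtures test.
``consolidate`` compares detected evidence against each orthogroup's
expected signature and emits warning flags on mismatch (never rejection).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .hmm import Hit, ProfileHmm, viterbi_align
from .records import InputError, ProteinRecord

__all__ = [
    "FeatureConfig",
    "FeatureEvidence",
    "OrthogroupCall",
    "CYS_PAIRS",
    "EXPECTATION",
    "map_reference_positions",
    "detect_cys_pairs",
    "classify_cterminus",
    "detect_signal_peptide",
    "detect_pld_hxk",
    "extract_evidence",
    "consolidate",
    "write_calls_tsv",
]

# Kyte-Doolittle hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3, "X": 0.0,
}

CHARGE = {"K": 1, "R": 1, "D": -1, "E": -1}

# reference-label pairs -> their member labels in profile reference maps
CYS_PAIRS: dict[str, tuple[str, str]] = {
    # DNase1 family
    "C4-C32": ("C4", "C32"),
    "C101-C104": ("C101", "C104"),
    "C173-C209": ("C173", "C209"),
    # DNase2 family (three shared pairs + the DNase2b-specific extra)
    "pair1": ("2C1a", "2C1b"),
    "pair2": ("2C2a", "2C2b"),
    "pair3": ("2C3a", "2C3b"),
    "DNase2b-extra": ("2C4a", "2C4b"),
}

PLD_LABELS = ("PLD1_HxK", "PLD2_HxK")

DNASE1_FAMILY = {
    "DNase1", "DNase1L1", "DNase1L1L", "DNase1L2", "DNase1L3",
    "DNase1L4", "DNase1L4-2", "DNase1L5",
}
DNASE2_FAMILY = {"DNase2", "DNase2b"}


@dataclass(frozen=True)
class FeatureConfig:
    """Thresholds of the feature heuristics (all tunable)."""

    # GPI omega-site signal
    omega_residues: str = "SGANDC"
    omega_window: int = 40        # search the last N residues for omega
    gpi_spacer: int = 6           # residues omega+1 .. omega+6
    gpi_tail_min: int = 8         # minimum hydrophobic tail length
    gpi_tail_kd: float = 1.0      # minimum mean tail hydropathy
    # basic C-terminal peptide
    basic_window: int = 12
    basic_min_charge: int = 4
    # somatomedin-B domain
    smb_window: int = 60
    smb_min_cys: int = 6
    # signal peptide heuristic
    sp_region: int = 35
    sp_window: int = 8
    sp_min_kd: float = 1.6
    min_cterm_len: int = 30
    min_sp_len: int = 25


DEFAULT_CONFIG = FeatureConfig()


@dataclass
class FeatureEvidence:
    cys_pairs: frozenset[str] = frozenset()
    cterm_class: str = "NONE"  # GPI | BASIC | SMB | EL | NONE
    omega_site: int | None = None
    basic_charge: int = 0
    signal_peptide: bool = False
    pld_hxk_count: int = 0
    warnings: list[str] = field(default_factory=list)


@dataclass
class OrthogroupCall:
    record_id: str
    taxon: str
    label: str
    bitscore: float
    evalue: float
    evidence: FeatureEvidence
    flags: list[str] = field(default_factory=list)


# Expected feature signature per orthogroup: (cysteine pairs, signal
# peptide, C-terminal class, PLD HxK count or None when not applicable).
EXPECTATION: dict[str, tuple[frozenset[str], bool, str | None, int | None]] = {
    "DNase1":     (frozenset({"C101-C104", "C173-C209"}), True, "NONE", None),
    "DNase1L2":   (frozenset({"C173-C209"}), True, "NONE", None),
    "DNase1L1":   (frozenset({"C4-C32", "C173-C209"}), True, "GPI", None),
    "DNase1L1L":  (frozenset({"C4-C32", "C173-C209"}), True, "EL", None),
    "DNase1L3":   (frozenset({"C4-C32", "C173-C209"}), True, "BASIC", None),
    "DNase1L4":   (frozenset({"C173-C209"}), False, "BASIC", None),
    "DNase1L4-2": (frozenset({"C173-C209"}), False, "BASIC", None),
    "DNase1L5":   (frozenset({"C101-C104", "C173-C209"}), True, "SMB", None),
    "DNase2":     (None, True, None, 2),
    "DNase2b":    (None, True, None, 2),
}


def map_reference_positions(hmm: ProfileHmm, seq: ProteinRecord | str) -> dict[str, int]:
    """Anchor reference residue labels onto a sequence via the Viterbi
    path: labels whose match state is visited by an M step map to the
    emitted 0-based index; deleted states are absent from the mapping.
    """
    if not hmm.reference_map:
        raise InputError(f"profile {hmm.label} carries no reference_map")
    vit = viterbi_align(hmm, seq)
    if not vit.steps:
        raise InputError("empty Viterbi path")
    pos = vit.match_positions()
    return {lab: pos[state] for state, lab in hmm.reference_map.items() if state in pos}


def detect_cys_pairs(mapping: Mapping[str, int], seq: ProteinRecord | str) -> frozenset[str]:
    """Pairs whose two reference positions are both mapped and both
    literally cysteine in the sequence."""
    s = seq.sequence if isinstance(seq, ProteinRecord) else seq
    found = set()
    for pair, (la, lb) in CYS_PAIRS.items():
        if la in mapping and lb in mapping:
            if s[mapping[la]] == "C" and s[mapping[lb]] == "C":
                found.add(pair)
    return frozenset(found)


def _net_charge(segment: str) -> int:
    return sum(CHARGE.get(c, 0) for c in segment)


def _mean_kd(segment: str) -> float:
    if not segment:
        return 0.0
    return sum(KYTE_DOOLITTLE.get(c, 0.0) for c in segment) / len(segment)


def _find_omega(s: str, cfg: FeatureConfig) -> int | None:
    n = len(s)
    # omega needs spacer (6) plus a tail of >= gpi_tail_min to the terminus
    last_valid = n - 1 - cfg.gpi_spacer - cfg.gpi_tail_min
    start = max(0, n - cfg.omega_window)
    for p in range(start, last_valid + 1):
        if s[p] in cfg.omega_residues:
            tail = s[p + cfg.gpi_spacer + 1 :]
            if len(tail) >= cfg.gpi_tail_min and _mean_kd(tail) >= cfg.gpi_tail_kd:
                return p
    return None


def classify_cterminus(
    seq: ProteinRecord | str, cfg: FeatureConfig = DEFAULT_CONFIG
) -> tuple[str, int | None, int]:
    """Classify the C terminus by a deterministic cascade:
    GPI > BASIC > SMB > EL > NONE. Returns (class, omega index or None,
    net charge of the terminal window).
    """
    s = seq.sequence if isinstance(seq, ProteinRecord) else seq
    charge = _net_charge(s[-cfg.basic_window :])
    if len(s) < cfg.min_cterm_len:
        return "NONE", None, charge
    omega = _find_omega(s, cfg)
    if omega is not None:
        return "GPI", omega, charge
    if charge >= cfg.basic_min_charge:
        return "BASIC", None, charge
    if s[-cfg.smb_window :].count("C") >= cfg.smb_min_cys:
        return "SMB", None, charge
    if s.endswith("EL"):
        return "EL", None, charge
    return "NONE", None, charge


def detect_signal_peptide(
    seq: ProteinRecord | str, cfg: FeatureConfig = DEFAULT_CONFIG
) -> bool:
    """Secretion signal heuristic: a hydrophobic window (mean
    Kyte-Doolittle >= 1.6 over 8 residues) within the first 35 residues,
    preceded by a non-negatively charged n-region."""
    s = seq.sequence if isinstance(seq, ProteinRecord) else seq
    if len(s) < cfg.min_sp_len:
        return False
    region_end = min(cfg.sp_region, len(s))
    for i in range(0, region_end - cfg.sp_window + 1):
        window = s[i : i + cfg.sp_window]
        if _mean_kd(window) >= cfg.sp_min_kd and _net_charge(s[:i]) >= 0:
            return True
    return False


def detect_pld_hxk(seq: ProteinRecord | str, mapping: Mapping[str, int]) -> int:
    """Count intact H-x-K catalytic motifs at the two reference-mapped
    phospholipase-D triad positions of a DNase2-family sequence."""
    s = seq.sequence if isinstance(seq, ProteinRecord) else seq
    count = 0
    for lab in PLD_LABELS:
        if lab in mapping:
            h = mapping[lab]
            if h + 2 < len(s) and s[h] == "H" and s[h + 2] == "K":
                count += 1
    return count


def extract_evidence(
    hmm: ProfileHmm, seq: ProteinRecord | str, cfg: FeatureConfig = DEFAULT_CONFIG
) -> FeatureEvidence:
    """Run every detector against one sequence using one profile's
    reference anchoring."""
    s = seq.sequence if isinstance(seq, ProteinRecord) else seq
    warnings: list[str] = []
    mapping: Mapping[str, int] = {}
    if hmm.reference_map:
        mapping = map_reference_positions(hmm, s)
    cys = detect_cys_pairs(mapping, s)
    if len(s) < cfg.min_cterm_len:
        warnings.append("sequence too short for C-terminal classification")
    cterm, omega, charge = classify_cterminus(s, cfg)
    sp = detect_signal_peptide(s, cfg)
    pld = detect_pld_hxk(s, mapping)
    return FeatureEvidence(
        cys_pairs=cys, cterm_class=cterm, omega_site=omega,
        basic_charge=charge, signal_peptide=sp, pld_hxk_count=pld,
        warnings=warnings,
    )


def consolidate(hit: Hit, taxon: str, evidence: FeatureEvidence) -> OrthogroupCall:
    """Merge an HMM best-match hit with feature evidence into a verified
    call; mismatches against the orthogroup's expected signature become
    warning flags, never rejections."""
    flags = list(evidence.warnings)
    exp = EXPECTATION.get(hit.label)
    if exp is not None:
        exp_cys, exp_sp, exp_cterm, exp_pld = exp
        if exp_cys is not None and evidence.cys_pairs != exp_cys:
            missing = sorted(exp_cys - evidence.cys_pairs)
            extra = sorted(evidence.cys_pairs - exp_cys)
            if missing:
                flags.append(f"missing cysteine pair(s): {','.join(missing)}")
            if extra:
                flags.append(f"unexpected cysteine pair(s): {','.join(extra)}")
        if evidence.signal_peptide != exp_sp:
            flags.append(
                "signal peptide detected but not expected" if evidence.signal_peptide
                else "expected signal peptide not detected"
            )
        if exp_cterm is not None and evidence.cterm_class != exp_cterm:
            flags.append(f"C-terminal class {evidence.cterm_class}, expected {exp_cterm}")
        if exp_pld is not None and evidence.pld_hxk_count != exp_pld:
            flags.append(f"HxK motif count {evidence.pld_hxk_count}, expected {exp_pld}")
    return OrthogroupCall(
        record_id=hit.record_id, taxon=taxon, label=hit.label,
        bitscore=hit.bitscore, evalue=hit.evalue, evidence=evidence, flags=flags,
    )


CALLS_HEADER = (
    "record\ttaxon\tlabel\tbitscore\tevalue\tcys_pairs\tcterm_class\t"
    "omega_site\tbasic_charge\tsignal_peptide\tpld_hxk\tflags"
)


def write_calls_tsv(calls: Iterable[OrthogroupCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(CALLS_HEADER + "\n")
        for c in sorted(calls, key=lambda c: (c.taxon, c.record_id)):
            ev = c.evidence
            fh.write(
                f"{c.record_id}\t{c.taxon}\t{c.label}\t{c.bitscore:.6g}\t"
                f"{c.evalue:.6g}\t{','.join(sorted(ev.cys_pairs))}\t"
                f"{ev.cterm_class}\t"
                f"{'NA' if ev.omega_site is None else ev.omega_site}\t"
                f"{ev.basic_charge}\t{int(ev.signal_peptide)}\t"
                f"{ev.pld_hxk_count}\t{';'.join(c.flags)}\n"
            )
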