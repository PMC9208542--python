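"""Profile hidden Markov models for orthogroup classification.

One profile per orthogroup is estimated from a curated multiple alignment
(columns with residue occupancy above a threshold become match states).
The model is a Plan7-style *glocal* architecture: entry into the first
match state and exit from the last are mandatory, while flanking
background-emitting states (N before, C after) absorb sequence overhangs.
Internally: match states M_1..M_L with per-state emissions, insert states
I_k between matches emitting background, and silent delete states D_k for
2 <= k <= L-1 (the terminal matches cannot be deleted).

Scoring is in log space throughout. The forward score sums over all state
paths; Viterbi reports the single best path, which is what anchors
reference residue labels (e.g. ``C101``) onto an arbitrary family member.
Bit scores are log2 odds against an i.i.d. background null. E-values come
from a maximum-likelihood Gumbel fit to the scores of seeded random
background sequences, mirroring the usual extreme-value calibration of
homology search: ``E = dbsize * exp(-lambda * (S - mu))``.

Classification of a proteome is by best match: every record is scored
against every profile and assigned to the highest-scoring profile among
hits passing the E-value threshold (default 1e-20).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import gumbel_r

from .align import Alignment
from .records import AMINO_ACIDS, GAP, InputError, ProteinRecord

__all__ = [
    "ProfileHmm",
    "Hit",
    "ViterbiResult",
    "CalibrationError",
    "build_profile",
    "forward_score",
    "viterbi_align",
    "calibrate",
    "evalue",
    "scan",
    "sample_sequence",
    "write_profile",
    "read_profile",
    "ROBINSON_BACKGROUND",
]

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Robinson & Robinson amino-acid frequencies, ordered as AMINO_ACIDS
ROBINSON_BACKGROUND = np.array([
    0.07805, 0.01925, 0.05364, 0.06295, 0.03856,  # A C D E F
    0.07377, 0.02199, 0.05142, 0.05744, 0.09019,  # G H I K L
    0.02243, 0.04487, 0.05203, 0.04264, 0.05129,  # M N P Q R
    0.07120, 0.05841, 0.06441, 0.01330, 0.03216,  # S T V W Y
])
ROBINSON_BACKGROUND = ROBINSON_BACKGROUND / ROBINSON_BACKGROUND.sum()

FLANK_LOOP = 0.9  # self-loop probability of the N/C flanking states

_LN2 = math.log(2.0)


class CalibrationError(RuntimeError):
    """Raised when background scores are degenerate (zero variance)."""


@dataclass
class ProfileHmm:
    """Per-orthogroup profile HMM (see module docstring for topology).

    Transition arrays are indexed by the 0-based match-state index of the
    source state; entries outside a state's allowed range are zero.
    ``reference_map`` maps 1-based match-state numbers to reference
    residue labels such as ``"C101"`` (human DNase1 numbering).
    """

    label: str
    match_emissions: np.ndarray  # (L, 20)
    background: np.ndarray  # (20,)
    t_mm: np.ndarray  # M_k -> M_{k+1}, k in 0..L-2
    t_mi: np.ndarray  # M_k -> I_k,     k in 0..L-2
    t_md: np.ndarray  # M_k -> D_{k+1}, k in 0..L-3
    t_im: np.ndarray  # I_k -> M_{k+1}, k in 0..L-2
    t_ii: np.ndarray  # I_k -> I_k,     k in 0..L-2
    t_dm: np.ndarray  # D_k -> M_{k+1}, k in 1..L-2
    t_dd: np.ndarray  # D_k -> D_{k+1}, k in 1..L-3
    flank_loop: float = FLANK_LOOP
    calibration: tuple[float, float] | None = None  # (mu, lambda)
    reference_map: dict[int, str] = field(default_factory=dict)

    @property
    def match_count(self) -> int:
        return self.match_emissions.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[int(i)] for i in self.match_emissions.argmax(axis=1))

    def validate(self, tol: float = 1e-9) -> None:
        L = self.match_count
        if L < 1:
            raise InputError("profile needs at least one match state")
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=tol):
            raise InputError("match emissions must sum to 1")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=tol):
            raise InputError("background must sum to 1")
        for k in range(L - 1):
            out = self.t_mm[k] + self.t_mi[k] + (self.t_md[k] if k <= L - 3 else 0.0)
            if not math.isclose(out, 1.0, abs_tol=tol):
                raise InputError(f"M_{k + 1} outgoing transitions must sum to 1")
            if not math.isclose(self.t_im[k] + self.t_ii[k], 1.0, abs_tol=tol):
                raise InputError(f"I_{k + 1} outgoing transitions must sum to 1")
        for k in range(1, L - 1):
            out = self.t_dm[k] + (self.t_dd[k] if k <= L - 3 else 0.0)
            if not math.isclose(out, 1.0, abs_tol=tol):
                raise InputError(f"D_{k + 1} outgoing transitions must sum to 1")
        for state, lab in self.reference_map.items():
            if not 1 <= state <= L:
                raise InputError(f"reference label {lab!r} outside match states")
        labs = list(self.reference_map.values())
        if len(labs) != len(set(labs)):
            raise InputError("reference_map must be injective")

    # cached log parameters used by forward/Viterbi
    def _logs(self):
        if not hasattr(self, "_log_cache"):
            with np.errstate(divide="ignore"):
                lm = np.log(self.match_emissions) - np.log(self.background)[None, :]
                self._log_cache = {
                    "emlo": lm,  # (L, 20) log emission odds
                    "mm": np.log(self.t_mm), "mi": np.log(self.t_mi),
                    "md": np.log(self.t_md), "im": np.log(self.t_im),
                    "ii": np.log(self.t_ii), "dm": np.log(self.t_dm),
                    "dd": np.log(self.t_dd),
                    "loop": math.log(self.flank_loop),
                    "leave": math.log(1.0 - self.flank_loop),
                }
        return self._log_cache


@dataclass(frozen=True)
class Hit:
    """One profile match for one record."""

    record_id: str
    label: str
    bitscore: float
    evalue: float


@dataclass
class ViterbiResult:
    bitscore: float
    # core steps: (state in {"M","I","D"}, 0-based match index, 0-based
    # sequence index or None for silent deletes)
    steps: list[tuple[str, int, int | None]]
    n_flank: int
    c_flank: int

    def match_positions(self) -> dict[int, int]:
        """1-based match state -> 0-based sequence index (M steps only)."""
        return {k + 1: i for (s, k, i) in self.steps if s == "M"}


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------


def build_profile(
    msa: Alignment,
    label: str,
    *,
    occupancy: float = 0.5,
    pseudocount: float = 1.0,
    transition_pseudocount: float = 0.1,
    background: np.ndarray | None = None,
    reference_columns: dict[int, str] | None = None,
) -> ProfileHmm:
    """Estimate a profile HMM from a multiple alignment.

    Columns whose residue occupancy is at least ``occupancy`` become match
    states. Match emissions are residue counts plus
    ``pseudocount * background``, normalized. Transitions are counted from
    each row's implied state path and smoothed additively with
    ``transition_pseudocount``. ``reference_columns`` maps 0-based
    alignment columns (which must be match columns) to reference residue
    labels carried as ``reference_map``.
    """
    if len(msa.rows) < 2:
        raise InputError("build_profile requires an MSA with >= 2 rows")
    bg = ROBINSON_BACKGROUND if background is None else np.asarray(background, float)
    nrow, ncol = len(msa.rows), msa.columns
    col_res = np.array([[row[1][j] for j in range(ncol)] for row in msa.rows])
    occ = (col_res != GAP).mean(axis=0)
    match_cols = [j for j in range(ncol) if occ[j] >= occupancy]
    if not match_cols:
        raise InputError("no alignment column meets the occupancy threshold")
    L = len(match_cols)
    col_to_state = {j: k for k, j in enumerate(match_cols)}  # 0-based

    # emissions
    em = np.tile(bg * pseudocount, (L, 1))
    for k, j in enumerate(match_cols):
        for ch in col_res[:, j]:
            if ch in _AA_INDEX:
                em[k, _AA_INDEX[ch]] += 1.0
    em /= em.sum(axis=1, keepdims=True)

    # transition counts from per-row state paths
    c_mm = np.zeros(L); c_mi = np.zeros(L); c_md = np.zeros(L)
    c_im = np.zeros(L); c_ii = np.zeros(L)
    c_dm = np.zeros(L); c_dd = np.zeros(L)
    match_set = set(match_cols)
    for _, gapped in msa.rows:
        path: list[tuple[str, int]] = []
        k = -1
        for j, ch in enumerate(gapped):
            if j in match_set:
                k = col_to_state[j]
                if ch != GAP:
                    path.append(("M", k))
                elif 1 <= k <= L - 2:
                    path.append(("D", k))
                # deletions of terminal matches are outside the topology
            else:
                if ch != GAP and 0 <= k <= L - 2:
                    path.append(("I", k))
                # residues before the first / after the last match column
                # belong to the flanks and are not core transitions
        for (s1, k1), (s2, k2) in zip(path, path[1:]):
            if s1 == "M" and s2 == "M" and k2 == k1 + 1:
                c_mm[k1] += 1
            elif s1 == "M" and s2 == "I" and k2 == k1:
                c_mi[k1] += 1
            elif s1 == "M" and s2 == "D" and k2 == k1 + 1:
                c_md[k1] += 1
            elif s1 == "I" and s2 == "M" and k2 == k1 + 1:
                c_im[k1] += 1
            elif s1 == "I" and s2 == "I" and k2 == k1:
                c_ii[k1] += 1
            elif s1 == "D" and s2 == "M" and k2 == k1 + 1:
                c_dm[k1] += 1
            elif s1 == "D" and s2 == "D" and k2 == k1 + 1:
                c_dd[k1] += 1

    a = transition_pseudocount
    t_mm = np.zeros(L); t_mi = np.zeros(L); t_md = np.zeros(L)
    t_im = np.zeros(L); t_ii = np.zeros(L)
    t_dm = np.zeros(L); t_dd = np.zeros(L)
    for k in range(L - 1):
        has_d = k <= L - 3
        tot = c_mm[k] + c_mi[k] + (c_md[k] if has_d else 0.0) + a * (3 if has_d else 2)
        t_mm[k] = (c_mm[k] + a) / tot
        t_mi[k] = (c_mi[k] + a) / tot
        if has_d:
            t_md[k] = (c_md[k] + a) / tot
        tot_i = c_im[k] + c_ii[k] + 2 * a
        t_im[k] = (c_im[k] + a) / tot_i
        t_ii[k] = (c_ii[k] + a) / tot_i
    for k in range(1, L - 1):
        has_d = k <= L - 3
        tot = c_dm[k] + (c_dd[k] if has_d else 0.0) + a * (2 if has_d else 1)
        t_dm[k] = (c_dm[k] + a) / tot
        if has_d:
            t_dd[k] = (c_dd[k] + a) / tot

    refmap: dict[int, str] = {}
    if reference_columns:
        for j, lab in reference_columns.items():
            if j not in col_to_state:
                raise InputError(
                    f"reference label {lab!r}: column {j} is not a match column"
                )
            refmap[col_to_state[j] + 1] = lab

    hmm = ProfileHmm(
        label=label, match_emissions=em, background=bg,
        t_mm=t_mm, t_mi=t_mi, t_md=t_md, t_im=t_im, t_ii=t_ii,
        t_dm=t_dm, t_dd=t_dd, reference_map=refmap,
    )
    hmm.validate()
    return hmm


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError:
        # X residues: emit with background everywhere -> log odds 0
        return np.array([_AA_INDEX.get(c, -1) for c in seq], dtype=np.intp)


def _emission_row(logs, code: int, L: int) -> np.ndarray:
    if code < 0:  # X: odds ratio 1 for every state
        return np.zeros(L)
    return logs["emlo"][:, code]


def forward_score(hmm: ProfileHmm, seq: ProteinRecord | str) -> float:
    """Forward bit score: log2 of the summed odds of all state paths
    against the i.i.d. background null. -inf when no path can emit the
    sequence (shorter than the two mandatory terminal matches).
    """
    s = seq.sequence if isinstance(seq, ProteinRecord) else seq
    logs = hmm._logs()
    L, n = hmm.match_count, len(s)
    codes = _encode(s)
    loop, leave = logs["loop"], logs["leave"]
    neg = -np.inf

    fM = np.full(L, neg)
    fI = np.full(L, neg)
    fD = np.full(L, neg)
    ldd = logs["dd"]
    ends = []
    for i in range(1, n + 1):
        e = _emission_row(logs, codes[i - 1], L)
        nM = np.full(L, neg)
        nM[0] = (i - 1) * loop + leave + e[0]
        if L > 1:
            stay = np.logaddexp(fM[:-1] + logs["mm"][:-1], fI[:-1] + logs["im"][:-1])
            stay = np.logaddexp(stay, fD[:-1] + logs["dm"][:-1])
            nM[1:] = np.logaddexp(nM[1:], stay + e[1:])
        nI = np.logaddexp(fM + logs["mi"], fI + logs["ii"])
        nI[L - 1 :] = neg
        nD = np.full(L, neg)
        if L >= 3:
            # D_k (k=1..L-2): entered from M_{k-1} at this position or D_{k-1}
            a = nM[0 : L - 2] + logs["md"][0 : L - 2]  # entry into D_{k} for k=1..L-2
            c = np.concatenate(([0.0], ldd[1 : L - 2]))  # D_{k-1}->D_k, k=2..L-2
            C = np.cumsum(c)
            acc = np.logaddexp.accumulate(a - C)
            nD[1 : L - 1] = acc + C
        fM, fI, fD = nM, nI, nD
        ends.append(fM[L - 1] + (n - i) * loop + leave)
    if not ends:
        return float("-inf")
    total = float(np.logaddexp.reduce(np.array(ends)))
    return total / _LN2


def viterbi_align(hmm: ProfileHmm, seq: ProteinRecord | str) -> ViterbiResult:
    """Best-path (Viterbi) score and state path.

    The score never exceeds the forward score. Each emitted residue maps
    to exactly one M, I, or flank state; ties during traceback prefer
    M over D over I.
    """
    s = seq.sequence if isinstance(seq, ProteinRecord) else seq
    logs = hmm._logs()
    L, n = hmm.match_count, len(s)
    codes = _encode(s)
    loop, leave = logs["loop"], logs["leave"]
    neg = -np.inf

    vM = np.full((n + 1, L), neg)
    vI = np.full((n + 1, L), neg)
    vD = np.full((n + 1, L), neg)
    ldd = logs["dd"]
    for i in range(1, n + 1):
        e = _emission_row(logs, codes[i - 1], L)
        vM[i, 0] = (i - 1) * loop + leave + e[0]
        if L > 1:
            stay = np.maximum(vM[i - 1, :-1] + logs["mm"][:-1], vI[i - 1, :-1] + logs["im"][:-1])
            stay = np.maximum(stay, vD[i - 1, :-1] + logs["dm"][:-1])
            vM[i, 1:] = stay + e[1:]
        vI[i, : L - 1] = np.maximum(
            vM[i - 1, : L - 1] + logs["mi"][: L - 1],
            vI[i - 1, : L - 1] + logs["ii"][: L - 1],
        )
        if L >= 3:
            a = vM[i, 0 : L - 2] + logs["md"][0 : L - 2]
            c = np.concatenate(([0.0], ldd[1 : L - 2]))
            C = np.cumsum(c)
            vD[i, 1 : L - 1] = np.maximum.accumulate(a - C) + C

    if n == 0:
        return ViterbiResult(float("-inf"), [], 0, 0)
    end_scores = np.array([vM[i, L - 1] + (n - i) * loop + leave for i in range(1, n + 1)])
    i = int(np.argmax(end_scores)) + 1
    best = float(end_scores[i - 1])
    if not math.isfinite(best):
        return ViterbiResult(float("-inf"), [], 0, 0)

    steps: list[tuple[str, int, int | None]] = []
    c_flank = n - i
    state, k = "M", L - 1
    while True:
        if state == "M":
            steps.append(("M", k, i - 1))
            if k == 0:
                n_flank = i - 1
                break
            cands = [
                ("M", vM[i - 1, k - 1] + logs["mm"][k - 1]),
                ("D", vD[i - 1, k - 1] + logs["dm"][k - 1]),
                ("I", vI[i - 1, k - 1] + logs["im"][k - 1]),
            ]
            target = vM[i, k] - _emission_row(logs, codes[i - 1], L)[k]
            state = _pick(cands, target)
            i -= 1
            k -= 1
        elif state == "I":
            steps.append(("I", k, i - 1))
            cands = [
                ("M", vM[i - 1, k] + logs["mi"][k]),
                ("I", vI[i - 1, k] + logs["ii"][k]),
            ]
            state = _pick(cands, vI[i, k])
            i -= 1
        else:  # D
            steps.append(("D", k, None))
            cands = [("M", vM[i, k - 1] + logs["md"][k - 1])]
            if k - 1 >= 1:
                cands.append(("D", vD[i, k - 1] + logs["dd"][k - 1]))
            state = _pick(cands, vD[i, k])
            k -= 1
    steps.reverse()
    return ViterbiResult(best / _LN2, steps, n_flank, c_flank)


def _pick(cands: list[tuple[str, float]], target: float) -> str:
    # exact recomputation: the DP maximum equals one candidate bit-for-bit
    for name, val in cands:
        if val == target:
            return name
    # fall back to numeric best under accumulated rounding
    return max(cands, key=lambda t: t[1])[0]


# ---------------------------------------------------------------------------
# Calibration and E-values
# ---------------------------------------------------------------------------


def _background_sequence(rng: np.random.Generator, length: int, bg: np.ndarray) -> str:
    codes = rng.choice(20, size=length, p=bg)
    return "".join(AMINO_ACIDS[c] for c in codes)


def calibrate(hmm: ProfileHmm, n_samples: int = 200, seed: int = 0) -> ProfileHmm:
    """Fit a Gumbel null-score distribution (mu, lambda) by maximum
    likelihood on forward scores of seeded random background sequences of
    length equal to the match count.
    """
    if n_samples < 100:
        raise InputError("calibration requires n_samples >= 100")
    rng = np.random.default_rng(seed)
    scores = np.array([
        forward_score(hmm, _background_sequence(rng, hmm.match_count, hmm.background))
        for _ in range(n_samples)
    ])
    scores = scores[np.isfinite(scores)]
    if len(scores) < 2 or float(np.var(scores)) < 1e-12:
        raise CalibrationError(f"degenerate background score variance for {hmm.label}")
    loc, scale = gumbel_r.fit(scores)
    out = replace(hmm, calibration=(float(loc), float(1.0 / scale)))
    return out


def evalue(hmm: ProfileHmm, bitscore: float, dbsize: int) -> float:
    """Expected number of background hits >= bitscore in dbsize trials."""
    if hmm.calibration is None:
        raise InputError(f"profile {hmm.label} is not calibrated")
    mu, lam = hmm.calibration
    with np.errstate(over="ignore"):
        return float(dbsize * np.exp(-lam * (bitscore - mu)))


def scan(
    profiles: Sequence[ProfileHmm],
    proteome: Sequence[ProteinRecord],
    evalue_threshold: float = 1e-20,
    dbsize: int | None = None,
) -> tuple[list[Hit], dict[str, str | None]]:
    """Score every record against every calibrated profile.

    Returns qualifying hits (E <= threshold) and a best-match assignment
    per record: highest bit score wins, ties break lexicographically by
    label; records with no qualifying hit map to None.
    """
    for p in profiles:
        if p.calibration is None:
            raise InputError(f"profile {p.label} must be calibrated before scan")
    dbsize = len(proteome) if dbsize is None else dbsize
    hits: list[Hit] = []
    assignment: dict[str, str | None] = {}
    for rec in proteome:
        rec_hits = []
        for p in profiles:
            score = forward_score(p, rec)
            ev = evalue(p, score, dbsize) if math.isfinite(score) else float("inf")
            if ev <= evalue_threshold:
                rec_hits.append(Hit(rec.id, p.label, score, ev))
        hits.extend(sorted(rec_hits, key=lambda h: (-h.bitscore, h.label)))
        if rec_hits:
            best = min(rec_hits, key=lambda h: (-h.bitscore, h.label))
            assignment[rec.id] = best.label
        else:
            assignment[rec.id] = None
    return hits, assignment


def write_hits_tsv(hits: Iterable[Hit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("record\tlabel\tbitscore\tevalue\n")
        for h in hits:
            fh.write(f"{h.record_id}\t{h.label}\t{h.bitscore:.6g}\t{h.evalue:.6g}\n")


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def sample_sequence(
    hmm: ProfileHmm,
    seed: int | np.random.Generator = 0,
    *,
    return_path: bool = False,
    protected_states: frozenset[int] | set[int] = frozenset(),
    forced_emissions: dict[int, str] | None = None,
    flanks: bool = True,
):
    """Generate a sequence by walking the state machine begin -> end.

    Deterministic per seed. ``protected_states`` (1-based match indices)
    are never deleted and never preceded by an insertion, and
    ``forced_emissions`` pins emitted residues — together these implant
    diagnostic motifs intact in synthetic members. With
    ``flanks=False`` the background-emitting N/C flank states are
    skipped. Returns the sequence string, optionally with the list of
    (state, match index, position) core steps.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    forced = forced_emissions or {}
    L = hmm.match_count
    out: list[str] = []
    steps: list[tuple[str, int, int | None]] = []

    def emit_bg() -> str:
        return AMINO_ACIDS[rng.choice(20, p=hmm.background)]

    while flanks and rng.random() < hmm.flank_loop:  # N flank
        out.append(emit_bg())

    k = 0
    state = "M"
    while True:
        if state == "M":
            if (k + 1) in forced:
                out.append(forced[k + 1])
            else:
                out.append(AMINO_ACIDS[rng.choice(20, p=hmm.match_emissions[k])])
            steps.append(("M", k, len(out) - 1))
            if k == L - 1:
                break
            if (k + 2) in protected_states:  # keep protected states flush
                state = "M"
                k += 1
                continue
            has_d = k <= L - 3
            probs = [hmm.t_mm[k], hmm.t_mi[k]] + ([hmm.t_md[k]] if has_d else [])
            probs = np.array(probs) / sum(probs)
            choice = rng.choice(len(probs), p=probs)
            state = ["M", "I", "D"][choice]
            if state != "I":
                k += 1
        elif state == "I":
            out.append(emit_bg())
            steps.append(("I", k, len(out) - 1))
            if (k + 2) in protected_states or rng.random() < hmm.t_im[k]:
                state = "M"
                k += 1
        else:  # D
            steps.append(("D", k, None))
            has_d = k <= L - 3 and (k + 2) not in protected_states
            if has_d and rng.random() < (hmm.t_dd[k] / (hmm.t_dd[k] + hmm.t_dm[k])):
                k += 1
            else:
                state = "M"
                k += 1

    while flanks and rng.random() < hmm.flank_loop:  # C flank
        out.append(emit_bg())

    seq = "".join(out)
    return (seq, steps) if return_path else seq


# ---------------------------------------------------------------------------
# Plain-text serialization (round-trips bit-exactly at 6 significant digits)
# ---------------------------------------------------------------------------


def _fmt(values: Iterable[float]) -> str:
    return " ".join(f"{v:.6g}" for v in values)


def write_profile(hmm: ProfileHmm, path: str | Path) -> None:
    L = hmm.match_count
    with open(path, "w") as fh:
        fh.write("# dnasekit profile v1\n")
        fh.write(f"label {hmm.label}\n")
        fh.write(f"match_count {L}\n")
        fh.write(f"alphabet {AMINO_ACIDS}\n")
        fh.write(f"flank_loop {hmm.flank_loop:.6g}\n")
        if hmm.calibration is None:
            fh.write("calibration none\n")
        else:
            fh.write(f"calibration {hmm.calibration[0]:.6g} {hmm.calibration[1]:.6g}\n")
        fh.write(f"background {_fmt(hmm.background)}\n")
        for k in sorted(hmm.reference_map):
            fh.write(f"ref {k} {hmm.reference_map[k]}\n")
        for k in range(L):
            trans = [hmm.t_mm[k], hmm.t_mi[k], hmm.t_md[k],
                     hmm.t_im[k], hmm.t_ii[k], hmm.t_dm[k], hmm.t_dd[k]]
            fh.write(f"state {k + 1} {_fmt(hmm.match_emissions[k])} | {_fmt(trans)}\n")


def read_profile(path: str | Path) -> ProfileHmm:
    label = ""
    L = 0
    flank = FLANK_LOOP
    calib: tuple[float, float] | None = None
    bg = ROBINSON_BACKGROUND
    refmap: dict[int, str] = {}
    em_rows: list[list[float]] = []
    trans_rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, rest = line.partition(" ")
            if key == "label":
                label = rest
            elif key == "match_count":
                L = int(rest)
            elif key == "flank_loop":
                flank = float(rest)
            elif key == "calibration":
                calib = None if rest == "none" else tuple(map(float, rest.split()))  # type: ignore[assignment]
            elif key == "background":
                bg = np.array([float(x) for x in rest.split()])
            elif key == "ref":
                k, lab = rest.split(maxsplit=1)
                refmap[int(k)] = lab
            elif key == "state":
                _, _, payload = rest.partition(" ")
                ems, _, trs = payload.partition(" | ")
                em_rows.append([float(x) for x in ems.split()])
                trans_rows.append([float(x) for x in trs.split()])
    if len(em_rows) != L:
        raise InputError(f"profile file {path}: expected {L} states, got {len(em_rows)}")
    tr = np.array(trans_rows)
    hmm = ProfileHmm(
        label=label,
        match_emissions=np.array(em_rows),
        background=bg,
        t_mm=tr[:, 0], t_mi=tr[:, 1], t_md=tr[:, 2],
        t_im=tr[:, 3], t_ii=tr[:, 4], t_dm=tr[:, 5], t_dd=tr[:, 6],
        flank_loop=flank, calibration=calib, reference_map=refmap,
    )
    hmm.validate(tol=1e-4)  # 6-digit storage loosens normalization slightly
    return hmm
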