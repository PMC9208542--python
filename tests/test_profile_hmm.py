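"""Profile HMM construction, scoring, calibration, scanning, sampling."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from dnasekit.align import Alignment
from dnasekit.hmm import (
    CalibrationError,
    build_profile,
    calibrate,
    evalue,
    forward_score,
    read_profile,
    sample_sequence,
    scan,
    viterbi_align,
    write_profile,
)
from dnasekit.records import InputError, ProteinRecord

from oracles import brute_force_forward_bits


class TestBuildProfile:
    def test_identical_ungapped_rows(self):
        p = build_profile(Alignment(rows=[("a", "ACDE")] * 3), "t")
        assert p.match_count == 4
        for k, res in enumerate("ACDE"):
            assert p.consensus[k] == res
            assert p.match_emissions[k].max() == p.match_emissions[k][list("ACDEFGHIKLMNPQRSTVWY").index(res)]

    def test_low_occupancy_column_becomes_insert(self):
        rows = [("a", "AC-E"), ("b", "AC-E"), ("c", "ACWE")]
        p = build_profile(Alignment(rows=rows), "t")
        assert p.match_count == 3  # the 1/3-occupied column is not a match state

    def test_zero_qualifying_columns_is_error(self):
        rows = [("a", "A---"), ("b", "-C--"), ("c", "--D-"), ("d", "---E")]
        with pytest.raises(InputError):
            build_profile(Alignment(rows=rows), "t", occupancy=0.5)

    def test_normalization_invariants(self, toy_profile):
        toy_profile.validate(tol=1e-9)

    def test_reference_map_requires_match_columns(self):
        rows = [("a", "AC-E"), ("b", "AC-E"), ("c", "ACWE")]
        with pytest.raises(InputError):
            build_profile(Alignment(rows=rows), "t", reference_columns={2: "C4"})
        p = build_profile(Alignment(rows=rows), "t", reference_columns={1: "C4"})
        assert p.reference_map == {2: "C4"}

    def test_synthetic_profiles_carry_cys_reference_columns(self, bundle):
        refmap = bundle.profiles["DNase1L3"].reference_map
        assert {"C4", "C32", "C173", "C209"} <= set(refmap.values())


class TestForwardScore:
    def test_forward_equals_path_enumeration_exhaustively(self, toy_profile):
        """Forward score equals the brute-force sum over all enumerated
        state paths (rel. err <= 1e-9) for every sequence of length <= 4
        over the reduced A/C/G/T residue set, plus sampled length 5-6."""
        seqs = []
        for n in range(1, 5):
            seqs.extend("".join(s) for s in itertools.product("ACGT", repeat=n))
        rng = np.random.default_rng(3)
        for n in (5, 6):
            for _ in range(30):
                seqs.append("".join(rng.choice(list("ACGT"), size=n)))
        for s in seqs:
            got = forward_score(toy_profile, s)
            want = brute_force_forward_bits(toy_profile, s)
            if math.isinf(want):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(want, rel=1e-9), s

    def test_forward_matches_enumeration_on_gappy_profile(self):
        rows = [("a", "AC-GT"), ("b", "A-CGT"), ("c", "ACC-T"), ("d", "ACCGT")]
        p = build_profile(Alignment(rows=rows), "gappy")
        rng = np.random.default_rng(4)
        for _ in range(40):
            s = "".join(rng.choice(list("ACGT"), size=int(rng.integers(2, 7))))
            got = forward_score(p, s)
            want = brute_force_forward_bits(p, s)
            if math.isinf(want):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(want, rel=1e-9), s

    def test_true_members_outscore_unrelated_profile(self, bundle):
        rng = np.random.default_rng(9)
        own = bundle.profiles["DNase1"]
        other = bundle.profiles["DNase2"]
        for _ in range(5):
            seq = sample_sequence(own, rng, flanks=False)
            assert forward_score(own, seq) > forward_score(other, seq) + 50

    def test_degenerate_single_residue_sequence(self):
        p = build_profile(Alignment(rows=[("a", "W"), ("b", "W"), ("c", "W")]), "w1")
        f = forward_score(p, "W")
        v = viterbi_align(p, "W")
        assert math.isfinite(f)
        assert v.bitscore <= f + 1e-9
        assert v.steps == [("M", 0, 0)]

    def test_no_underflow_on_long_sequences(self, bundle):
        rng = np.random.default_rng(10)
        long_seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=5000))
        s = forward_score(bundle.profiles["DNase1"], long_seq)
        assert math.isfinite(s)


class TestViterbi:
    def test_consensus_gives_all_match_path(self, toy_profile):
        v = viterbi_align(toy_profile, toy_profile.consensus)
        assert [s for s, _, _ in v.steps] == ["M"] * toy_profile.match_count

    def test_internal_deletion_yields_one_delete_state(self, toy_profile):
        cons = toy_profile.consensus
        seq = cons[:2] + cons[3:]  # drop the middle match residue
        v = viterbi_align(toy_profile, seq)
        states = [s for s, _, _ in v.steps]
        assert states.count("D") == 1 and states.count("M") == len(cons) - 1

    def test_internal_insertion_yields_one_insert_state(self, toy_profile):
        cons = toy_profile.consensus
        seq = cons[:3] + "W" + cons[3:]
        v = viterbi_align(toy_profile, seq)
        states = [s for s, _, _ in v.steps]
        assert states.count("I") == 1 and states.count("M") == len(cons)

    def test_viterbi_never_exceeds_forward(self, toy_profile, bundle, rng):
        pairs = [(toy_profile, "".join(rng.choice(list("ACGT"), size=n))) for n in range(2, 7) for _ in range(10)]
        own = bundle.profiles["DNase1L1"]
        pairs += [(own, sample_sequence(own, rng, flanks=False)) for _ in range(3)]
        for p, s in pairs:
            assert viterbi_align(p, s).bitscore <= forward_score(p, s) + 1e-9

    def test_every_residue_mapped_once(self, toy_profile, rng):
        for _ in range(20):
            s = "".join(rng.choice(list("ACGT"), size=int(rng.integers(5, 8))))
            v = viterbi_align(toy_profile, s)
            if not v.steps:
                continue
            emitted = [i for st, _, i in v.steps if st in ("M", "I")]
            core = list(range(v.n_flank, len(s) - v.c_flank))
            assert emitted == core


class TestCalibration:
    def test_seeded_calibration_is_deterministic(self, toy_profile):
        a = calibrate(toy_profile, 150, seed=5)
        b = calibrate(toy_profile, 150, seed=5)
        assert a.calibration == b.calibration

    def test_location_family_shift(self, rng):
        """Shifting scores by +c shifts the fitted mu by +c and leaves
        lambda unchanged (Gumbel ML is location-equivariant)."""
        from scipy.stats import gumbel_r

        scores = gumbel_r.rvs(loc=-10.0, scale=1.7, size=400, random_state=17)
        loc0, scale0 = gumbel_r.fit(scores)
        loc1, scale1 = gumbel_r.fit(scores + 6.5)
        assert loc1 == pytest.approx(loc0 + 6.5, abs=1e-6)
        assert scale1 == pytest.approx(scale0, abs=1e-6)

    def test_requires_enough_samples(self, toy_profile):
        with pytest.raises(InputError):
            calibrate(toy_profile, 50, seed=1)

    def test_degenerate_scores_raise(self):
        # a profile whose emissions are swamped by the background prior
        # scores every sequence near-identically -> zero variance
        rows = [("a", "A"), ("b", "A")]
        p = build_profile(Alignment(rows=rows), "flat", pseudocount=1e9)
        with pytest.raises(CalibrationError):
            calibrate(p, 150, seed=2)

    def test_evalue_monotone_decreasing_in_bitscore(self, bundle):
        p = bundle.profiles["DNase1"]
        es = [evalue(p, s, 1000) for s in (0.0, 50.0, 100.0, 200.0)]
        assert es == sorted(es, reverse=True)
        assert all(e >= 0 for e in es)

    def test_member_evalues_pass_threshold(self, bundle):
        """Sequences sampled from a calibrated profile reach the
        E <= 1e-20 significance used for repertoire scans."""
        rng = np.random.default_rng(21)
        p = bundle.profiles["DNase2b"]
        for _ in range(5):
            seq = sample_sequence(p, rng, flanks=False)
            assert evalue(p, forward_score(p, seq), 1000) <= 1e-20


class TestScan:
    def test_empty_proteome_is_empty_result(self, bundle):
        hits, assign = scan(list(bundle.profiles.values()), [])
        assert hits == [] and assign == {}

    def test_uncalibrated_profile_rejected(self, toy_profile):
        with pytest.raises(InputError):
            scan([toy_profile], [ProteinRecord(id="x", sequence="ACGT")])

    def test_members_assigned_to_their_own_profile(self, bundle):
        rng = np.random.default_rng(31)
        profs = list(bundle.profiles.values())
        records, want = [], {}
        for og in ("DNase1", "DNase1L3", "DNase2"):
            for j in range(3):
                seq = sample_sequence(bundle.profiles[og], rng, flanks=False)
                rid = f"{og}|{j}"
                records.append(ProteinRecord(id=rid, sequence=seq))
                want[rid] = og
        _, assign = scan(profs, records)
        assert assign == want

    def test_shuffled_decoys_unassigned(self, bundle):
        rng = np.random.default_rng(32)
        profs = list(bundle.profiles.values())
        records = []
        for j in range(10):
            seq = list(sample_sequence(profs[j % len(profs)], rng, flanks=False))
            rng.shuffle(seq)
            records.append(ProteinRecord(id=f"d{j}", sequence="".join(seq)))
        hits, assign = scan(profs, records)
        assert hits == []
        assert all(v is None for v in assign.values())


class TestSampling:
    def test_deterministic_profile_emits_consensus(self):
        rows = [("a", "ACDEF")] * 4
        p = build_profile(Alignment(rows=rows), "t", pseudocount=1e-12,
                          transition_pseudocount=1e-12)
        assert sample_sequence(p, 1, flanks=False) == "ACDEF"

    def test_seed_determinism_and_variation(self, toy_profile):
        s1 = sample_sequence(toy_profile, 42)
        s2 = sample_sequence(toy_profile, 42)
        s3 = sample_sequence(toy_profile, 43)
        assert s1 == s2
        assert s1 != s3

    def test_samples_outscore_length_matched_shuffles(self, bundle):
        rng = np.random.default_rng(33)
        p = bundle.profiles["DNase1L5"]
        member_scores, shuffle_scores = [], []
        for _ in range(20):
            seq = sample_sequence(p, rng, flanks=False)
            member_scores.append(forward_score(p, seq))
            chars = list(seq)
            rng.shuffle(chars)
            shuffle_scores.append(forward_score(p, "".join(chars)))
        assert np.mean(member_scores) > np.mean(shuffle_scores) + 100


class TestSerialization:
    def test_roundtrip_is_byte_identical(self, bundle, tmp_path):
        p = bundle.profiles["DNase1L1L"]
        f1, f2 = tmp_path / "a.hmm", tmp_path / "b.hmm"
        write_profile(p, f1)
        q = read_profile(f1)
        write_profile(q, f2)
        assert f1.read_bytes() == f2.read_bytes()
        assert q.label == p.label
        assert q.match_count == p.match_count
        assert q.reference_map == p.reference_map
        assert q.calibration == pytest.approx(p.calibration, rel=1e-5)

    def test_loaded_profile_scores_agree(self, toy_profile, tmp_path):
        f = tmp_path / "toy.hmm"
        write_profile(toy_profile, f)
        q = read_profile(f)
        for s in ("ACGTA", "ACG", "TTTT"):
            assert forward_score(q, s) == pytest.approx(forward_score(toy_profile, s), rel=1e-4)
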