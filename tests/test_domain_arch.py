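"""Domain detection (PSSM / heptad coiled-coil), NBS subdomain ordering,
signature typing, 8-way architecture assignment and EM motif discovery."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nlrforge import domain_arch as da
from nlrforge import resources as R
from nlrforge.domain_arch import (
    PSSM,
    DomainHit,
    NbsSignature,
    assign_architecture,
    build_pssm,
    classify_signature,
    coiled_coil_probabilities,
    coiled_coil_scan,
    default_pssms,
    em_discover_motif,
    find_nbs_subdomains,
    scan_pssm,
)
from nlrforge.io_formats import SequenceRecord
from nlrforge.profile_hmm import build_profile


def prot(seq, pid="p"):
    return SequenceRecord(id=pid, description="", residues=seq, alphabet="protein")


def rand_protein(rng, n):
    return "".join(np.array(list(R.AA))[rng.choice(20, size=n, p=R.BACKGROUND)])


@pytest.fixture(scope="module")
def pssms():
    return default_pssms()


@pytest.fixture(scope="module")
def sub_hmms():
    cc = build_profile(list(R.seed_alignment("cc_sub")), name="cc_sub")
    tir = build_profile(list(R.seed_alignment("tir_sub")), name="tir_sub")
    return cc, tir


class TestScanPssm:
    def test_planted_consensus_found_at_offset_and_score_is_window_max(self, pssms, rng):
        tir = pssms["TIR"]
        planted = R.TIR_CONSENSUS
        seq = rand_protein(rng, 5) + planted + rand_protein(rng, 30)
        hits = scan_pssm(seq, tir)
        assert len(hits) == 1 and hits[0].start == 5
        # brute-force window oracle
        enc = R.encode_protein(seq)
        want = max(
            sum(tir.log_odds[k, enc[i + k]] for k in range(tir.width))
            for i in range(len(seq) - tir.width + 1))
        assert hits[0].score == pytest.approx(want)

    def test_homopolymer_has_no_hits(self, pssms):
        assert scan_pssm("A" * 120, pssms["TIR"]) == []

    def test_threshold_at_max_returns_only_argmax_window(self, pssms, rng):
        tir = pssms["TIR"]
        seq = rand_protein(rng, 10) + R.TIR_CONSENSUS + rand_protein(rng, 10)
        enc = R.encode_protein(seq)
        scores = [sum(tir.log_odds[k, enc[i + k]] for k in range(tir.width))
                  for i in range(len(seq) - tir.width + 1)]
        boundary = PSSM(kind="TIR", log_odds=tir.log_odds, threshold=max(scores))
        hits = scan_pssm(seq, boundary)
        assert [h.start for h in hits] == [int(np.argmax(scores))]

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10**6))
    def test_hit_scores_equal_brute_force_for_all_windows(self, seed):
        rng = np.random.default_rng(seed)
        W = int(rng.integers(3, 8))
        lo = np.zeros((W, 21))
        lo[:, :20] = rng.normal(0, 2, size=(W, 20))
        pssm = PSSM(kind="X", log_odds=lo, threshold=-1e9)
        seq = rand_protein(rng, int(rng.integers(W, 40)))
        enc = R.encode_protein(seq)
        brute = {i: sum(lo[k, enc[i + k]] for k in range(W))
                 for i in range(len(seq) - W + 1)}
        for h in scan_pssm(seq, pssm):
            assert h.score == pytest.approx(brute[h.start])


class TestCoiledCoil:
    def test_ideal_heptad_segment_detected_at_planted_offset(self, rng):
        planted = R.HEPTAD * 5  # 35 residues, ideal
        seq = "P" * 10 + planted + "P" * 20
        hits = coiled_coil_scan(seq)
        assert len(hits) == 1
        h = hits[0]
        assert h.start < 45 and h.end > 10  # overlaps [10, 45)
        assert h.validated

    def test_window_score_formula_by_hand(self):
        # one 28-residue ideal window, phase 0: L at a/d, outer elsewhere
        window = R.HEPTAD * 4
        want = 0.0
        for i, aa in enumerate(window):
            table = R.HEPTAD_CORE_SCORES if i % 7 in (0, 3) else R.HEPTAD_OUTER_SCORES
            want += table[R.AA_INDEX[aa]]
        probs = coiled_coil_probabilities(window, window=28)
        expect = 1.0 / (1.0 + np.exp(-(want - da.CC_LOGISTIC_MID) / da.CC_LOGISTIC_SCALE))
        assert probs.max() == pytest.approx(expect)

    def test_polyproline_has_no_segments(self):
        assert coiled_coil_scan("P" * 60) == []

    @pytest.mark.parametrize("shift", range(1, 7))
    def test_detection_is_phase_invariant(self, shift):
        planted = (R.HEPTAD * 6)[shift:shift + 35]
        seq = "G" * 12 + planted + "G" * 12
        assert coiled_coil_scan(seq), f"phase shift {shift} missed"


class TestNbsSubdomains:
    def test_planted_motifs_found_in_order_and_complete(self, pssms, rng):
        seq, truth = R.build_nlr_protein("N_CC", rng)
        hits, complete = find_nbs_subdomains(seq, pssms)
        assert complete
        by_kind = {h.kind: h for h in hits}
        for kind, key in (("PLOOP", "ploop"), ("KINASE2", "kinase2"),
                          ("KINASE3A", "kinase3a"), ("GLPL", "glpl")):
            assert by_kind[kind].start == truth[key][0]

    def test_missing_glpl_gives_partial(self, pssms, rng):
        seq, truth = R.build_nlr_protein("N_CC", rng)
        cut = seq[:truth["glpl"][0] - 2]
        hits, complete = find_nbs_subdomains(cut, pssms)
        assert not complete
        assert {h.kind for h in hits} == {"PLOOP", "KINASE2", "KINASE3A"}

    def test_out_of_order_selection_matches_exhaustive_subset_oracle(self, pssms, rng):
        # plant GLPL before the P-loop: the ordered-subset choice must equal
        # brute force over all candidate combinations
        seq = (rand_protein(rng, 8) + R.GLPL + rand_protein(rng, 12) + R.PLOOP
               + rand_protein(rng, 10) + R.KINASE2_CC + rand_protein(rng, 10))
        hits, complete = find_nbs_subdomains(seq, pssms)
        # oracle: enumerate every subset of per-kind candidates
        cands = {k: [None] + scan_pssm(seq, pssms[k], max_hits=3)
                 for k in da.SUBDOMAIN_ORDER}
        best, best_score = [], -np.inf
        for combo in itertools.product(*(cands[k] for k in da.SUBDOMAIN_ORDER)):
            sel = [h for h in combo if h is not None]
            if any(sel[i].end > sel[i + 1].start for i in range(len(sel) - 1)):
                continue
            s = sum(h.score for h in sel)
            if s > best_score:
                best, best_score = sel, s
        assert not complete
        assert sum(h.score for h in hits) == pytest.approx(best_score)
        assert [(h.kind, h.start) for h in hits] == [(h.kind, h.start) for h in best]


class TestSignature:
    @pytest.mark.parametrize("lineage,expected", [("CC_I", "CC_type"),
                                                  ("TIR", "TIR_type")])
    def test_sampled_nbs_typed_by_kinase2_terminal(self, pssms, sub_hmms,
                                                   lineage, expected):
        rng = np.random.default_rng(hash(lineage) % 2**31)
        hitsum = 0
        for _ in range(10):
            nbs = R.sample_nbs(lineage, rng)
            hits, _ = find_nbs_subdomains(nbs, pssms)
            sig = classify_signature(nbs, hits, *sub_hmms)
            hitsum += sig.type == expected
        assert hitsum == 10

    def test_no_kinase2_and_equal_scores_undetermined(self):
        sig = classify_signature("MKVLE" * 10, [], None, None)
        assert sig.type == "undetermined"
        assert sig.kinase2_terminal is None

    def test_subprofile_fallback_decides_without_kinase2(self, sub_hmms, rng):
        nbs = R.sample_nbs("TIR", rng)
        # strip the kinase-2 hit by passing no subdomain hits
        sig = classify_signature(nbs, [], *sub_hmms)
        assert sig.type == "TIR_type"
        assert sig.tir_subprofile_score > sig.cc_subprofile_score


class TestAssignArchitecture:
    CC = DomainHit("CC", 5, 35, 10.0)
    TIR = DomainHit("TIR", 5, 45, 20.0)
    LRR = DomainHit("LRR", 300, 316, 15.0)
    SIG_CC = NbsSignature(type="CC_type")
    SIG_TIR = NbsSignature(type="TIR_type")

    @pytest.mark.parametrize("hits,sig,code", [
        ([CC, LRR], SIG_CC, "CNL"),
        ([CC], SIG_CC, "CN"),
        ([LRR], SIG_CC, "NL_CC"),
        ([], SIG_CC, "N_CC"),
        ([TIR, LRR], SIG_TIR, "TNL"),
        ([TIR], SIG_TIR, "TN"),
        ([LRR], SIG_TIR, "NL_TIR"),
        ([], SIG_TIR, "N_TIR"),
    ])
    def test_all_eight_codes_reachable(self, hits, sig, code):
        assert assign_architecture(hits, sig, 1.0).code == code

    def test_low_coverage_short_circuits_to_partial(self):
        call = assign_architecture([self.CC, self.LRR], self.SIG_CC, 0.3)
        assert call.code == "PARTIAL"
        assert call.nbs_coverage == 0.3

    def test_cc_and_tir_conflict_resolved_toward_tir(self):
        call = assign_architecture([self.CC, self.TIR, self.LRR], self.SIG_CC, 1.0)
        assert call.code == "TNL"

    def test_pure_function_same_hits_same_code(self):
        a = assign_architecture([self.CC, self.LRR], self.SIG_CC, 1.0)
        b = assign_architecture([self.CC, self.LRR], self.SIG_CC, 1.0)
        assert a.code == b.code == "CNL"


class TestEmMotif:
    def test_planted_width8_motif_recovered(self, rng):
        motif = "WHDYKFCE"
        seqs = []
        for i in range(20):
            s = rand_protein(rng, 50)
            pos = int(rng.integers(0, 43))
            seqs.append(prot(s[:pos] + motif + s[pos + 8:], f"s{i}"))
        pssm, ll = em_discover_motif(seqs, width=8, n_starts=10, seed=3)
        consensus = "".join(R.AA[int(k)] for k in pssm.log_odds[:, :20].argmax(axis=1))
        assert consensus == motif

    def test_identical_sequences_converge_to_a_window(self, rng):
        s = rand_protein(rng, 30)
        seqs = [prot(s, f"s{i}") for i in range(6)]
        pssm, _ = em_discover_motif(seqs, width=6, n_starts=3, seed=1)
        probs = 2 ** pssm.log_odds[:, :20] * R.BACKGROUND
        consensus = "".join(R.AA[int(k)] for k in probs.argmax(axis=1))
        assert consensus in s
        assert probs.max(axis=1).min() > 0.8

    def test_loglik_nondecreasing_within_run(self, rng):
        seqs = [prot(rand_protein(rng, 40), f"s{i}") for i in range(8)]
        trace = []
        em_discover_motif(seqs, width=6, n_starts=1, seed=0, trace=trace)
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_input_validation(self, rng):
        seqs = [prot(rand_protein(rng, 10), f"s{i}") for i in range(6)]
        with pytest.raises(ValueError, match="width"):
            em_discover_motif(seqs, width=20)
        with pytest.raises(ValueError, match="at least 5"):
            em_discover_motif(seqs[:3], width=5)

    def test_deterministic_under_seed(self, rng):
        seqs = [prot(rand_protein(rng, 40), f"s{i}") for i in range(8)]
        a, la = em_discover_motif(seqs, width=6, n_starts=3, seed=9)
        b, lb = em_discover_motif(seqs, width=6, n_starts=3, seed=9)
        assert la == lb
        assert np.allclose(a.log_odds, b.log_odds)
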