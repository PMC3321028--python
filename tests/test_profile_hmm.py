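"""Profile-HMM construction, Viterbi optimality, calibration and the
two-pass refinement with kinase exclusion."""

import inspect

import numpy as np
import pytest

from nlrforge import profile_hmm as hm
from nlrforge import resources as R
from nlrforge.io_formats import SequenceRecord
from nlrforge.profile_hmm import (
    CalibrationParams,
    ProfileHMM,
    build_profile,
    calibrate_evalue,
    kinase_filter,
    refine_species_model,
    search_proteome,
    viterbi,
)


def prot(seq, pid="p"):
    return SequenceRecord(id=pid, description="", residues=seq, alphabet="protein")


def aln(rows):
    return [SequenceRecord(id=f"r{i}", description="", residues=s,
                           alphabet="protein") for i, s in enumerate(rows)]


class TestBuildProfile:
    def test_zero_pseudocount_point_masses(self):
        hmm = build_profile(aln(["MKV", "MKV", "MKV"]), pseudocount=0)
        assert hmm.M == 3
        for k, a in enumerate("MKV", start=1):
            assert hmm.match_emissions[k, R.AA_INDEX[a]] == pytest.approx(1.0)

    def test_laplace_pseudocount_hand_count(self):
        # column {A, A} with pseudocount 1: P(A) = (2+1)/(2+20) = 3/22
        hmm = build_profile(aln(["AK", "AK"]), pseudocount=1)
        assert hmm.match_emissions[1, R.AA_INDEX["A"]] == pytest.approx(3 / 22)

    def test_gappy_column_excluded_from_match_states(self):
        # col 0 gap fraction 0.75 > 0.5 -> dropped, M decremented to 2
        hmm = build_profile(aln(["AKL", "-KL", "-KL", "-KL"]))
        assert hmm.M == 2

    def test_empty_and_all_gapped_rejected(self):
        with pytest.raises(ValueError):
            build_profile([])
        with pytest.raises(ValueError):
            build_profile(aln(["--", "--"]))

    def test_model_invariant_to_row_order(self, rng):
        rows = ["MKVLE", "MRVLE", "MKILE", "MKVQE"]
        a = build_profile(aln(rows))
        b = build_profile(aln(rows[::-1]))
        assert np.allclose(a.match_emissions, b.match_emissions)
        for k in a.transitions:
            assert np.allclose(a.transitions[k], b.transitions[k])

    def test_distributions_normalised(self):
        hmm = build_profile(aln(["MKVL-", "MK-LE", "MKVLE"]))
        assert np.allclose(hmm.match_emissions[1:].sum(axis=1), 1.0)
        for grp in (("MM", "MI", "MD"), ("IM", "II"), ("DM", "DD")):
            total = sum(hmm.transitions[k] for k in grp)
            assert np.allclose(total, 1.0)


# ---------------------------------------------------------------------------
# brute-force path-enumeration oracle for the local Viterbi


def enumerate_best_score(hmm: ProfileHMM, seq: str) -> float:
    """Max log2-odds over every explicit state path, enumerated recursively.

    Mirrors the model definition: free flanks, entry into any match state at
    a -log2(M) charge, exit from any match state for free; insert emissions
    at background (0 bits)."""
    x = [R.AA_INDEX.get(c, 20) for c in seq]
    L, M = len(x), hmm.M
    elo = hmm.match_log_odds()
    t = {k: hmm.transition_log2(k) for k in hmm.transitions}
    best = [-np.inf]

    def walk(state, j, i, score):
        if state == "M":
            best[0] = max(best[0], score)  # may exit here
        if state == "M":
            if j < M and i < L:
                walk("M", j + 1, i + 1, score + t["MM"][j] + elo[j + 1, x[i]])
            if i < L:
                walk("I", j, i + 1, score + t["MI"][j])
            if j < M:
                walk("D", j + 1, i, score + t["MD"][j])
        elif state == "I":
            if j < M and i < L:
                walk("M", j + 1, i + 1, score + t["IM"][j] + elo[j + 1, x[i]])
            if i < L:
                walk("I", j, i + 1, score + t["II"][j])
        else:
            if j < M and i < L:
                walk("M", j + 1, i + 1, score + t["DM"][j] + elo[j + 1, x[i]])
            if j < M:
                walk("D", j + 1, i, score + t["DD"][j])

    entry = -np.log2(M)
    for i0 in range(L):
        for j0 in range(1, M + 1):
            walk("M", j0, i0 + 1, entry + elo[j0, x[i0]])
    return best[0]


def random_profile(rng, M):
    emit = np.vstack([np.zeros(20)] + [rng.dirichlet(np.ones(20) * 0.7)
                                       for _ in range(M)])
    trans = {}
    for grp in (("MM", "MI", "MD"), ("IM", "II"), ("DM", "DD")):
        probs = rng.dirichlet(np.ones(len(grp)), size=M + 1)
        for k, key in enumerate(grp):
            trans[key] = probs[:, k]
    return ProfileHMM(match_emissions=emit,
                      insert_emissions=np.tile(R.BACKGROUND, (M + 1, 1)),
                      transitions=trans)


class TestViterbi:
    @pytest.mark.parametrize("case", range(8))
    def test_matches_exhaustive_path_enumeration(self, case):
        rng = np.random.default_rng(100 + case)
        M = int(rng.integers(2, 4))
        L = int(rng.integers(1, 5))
        hmm = random_profile(rng, M)
        seq = "".join(rng.choice(list(R.AA), size=L))
        got = viterbi(hmm, prot(seq)).bit_score
        want = enumerate_best_score(hmm, seq)
        assert got == pytest.approx(want, abs=1e-9)

    def test_consensus_of_ungapped_zero_pc_profile_scores_all_match(self):
        rows = ["MKVLE", "MKVLE", "MKVLE"]
        hmm = build_profile(aln(rows), pseudocount=0)
        hit = viterbi(hmm, prot(hmm.consensus()))
        assert all(s == "M" for s, _, _ in hit.path)
        elo = hmm.match_log_odds()
        want = sum(elo[k, R.AA_INDEX[a]] for k, a in enumerate("MKVLE", 1))
        want += sum(hmm.transition_log2("MM")[1:5])
        want += -np.log2(hmm.M)
        assert hit.bit_score == pytest.approx(want)

    def test_planted_domain_beats_shuffled_in_every_trial(self, nbarc_hmm):
        rng = np.random.default_rng(77)
        wins = 0
        for _ in range(20):
            seq, _ = R.build_nlr_protein("CNL", rng)
            shuffled = "".join(rng.permutation(list(seq)))
            s_real = viterbi(nbarc_hmm, prot(seq)).bit_score
            s_shuf = viterbi(nbarc_hmm, prot(shuffled)).bit_score
            wins += s_real > s_shuf
        assert wins == 20

    def test_envelope_covers_planted_nbs(self, nbarc_hmm):
        rng = np.random.default_rng(9)
        seq, truth = R.build_nlr_protein("N_CC", rng)
        hit = viterbi(nbarc_hmm, prot(seq))
        s, e = truth["nbs"]
        overlap = max(0, min(e, hit.env_end) - max(s, hit.env_start))
        assert overlap / (e - s) > 0.9

    def test_nonstandard_residue_warns_and_scores(self, nbarc_hmm):
        with pytest.warns(UserWarning, match="treated as X"):
            hit = viterbi(nbarc_hmm, prot("MKVXXBLE"))
        assert np.isfinite(hit.bit_score)


class TestCalibration:
    def test_empirical_tail_matches_fit(self, nbarc_hmm):
        calib = nbarc_hmm.calibration
        rng = np.random.default_rng(555)
        aas = np.array(list(R.AA))
        scores = [
            viterbi(nbarc_hmm,
                    prot("".join(aas[rng.choice(20, 350, p=R.BACKGROUND)]))).bit_score
            for _ in range(1000)
        ]
        frac = np.mean([calib.pvalue(s) <= 0.01 for s in scores])
        assert 0.005 <= frac <= 0.02

    def test_evalue_scales_with_database_size(self, nbarc_hmm):
        c = nbarc_hmm.calibration
        s = 25.0
        assert 200 * c.pvalue(s) == pytest.approx(2 * 100 * c.pvalue(s))

    def test_threshold_scores_ordered(self, nbarc_hmm):
        c = nbarc_hmm.calibration
        assert c.score_at_evalue(1e-60, 300) > c.score_at_evalue(1e-2, 300)

    def test_degenerate_null_distribution_rejected(self):
        # background-equal emissions make every null score identical
        flat = ProfileHMM(
            match_emissions=np.vstack([np.zeros(20)] + [R.BACKGROUND] * 3),
            insert_emissions=np.tile(R.BACKGROUND, (4, 1)),
            transitions={k: np.full(4, v) for k, v in
                         (("MM", 1.0), ("MI", 0.0), ("MD", 0.0), ("IM", 1.0),
                          ("II", 0.0), ("DM", 1.0), ("DD", 0.0))})
        with pytest.raises(ValueError, match="degenerate"):
            calibrate_evalue(flat, n_null=50, null_length=30, seed=0)

    def test_lambda_must_be_positive(self):
        with pytest.raises(ValueError):
            CalibrationParams(mu=0.0, lam=-1.0, n_null_samples=10,
                              null_length=10, seed=0)


@pytest.fixture(scope="module")
def mix():
    """15 planted NLRs + 10 kinase decoys + 50 background proteins."""
    rng = np.random.default_rng(31)
    prots = []
    for i in range(15):
        seq, _ = R.build_nlr_protein(R.CLASS_CODES[i % 8], rng)
        prots.append(prot(seq, f"nbs{i:02d}"))
    for i in range(10):
        prots.append(prot(R.sample_kinase(rng), f"kin{i:02d}"))
    aas = np.array(list(R.AA))
    for i in range(50):
        prots.append(prot("".join(aas[rng.choice(20, 300, p=R.BACKGROUND)]),
                          f"bg{i:02d}"))
    return prots


class TestSearchAndRefine:
    def test_empty_proteome_empty_hits(self, nbarc_hmm):
        assert search_proteome(nbarc_hmm, [], 1e-2) == []

    def test_planted_all_recovered_and_sorted(self, nbarc_hmm, mix):
        hits = search_proteome(nbarc_hmm, mix, 1e-2)
        ids = [h.target_id for h in hits]
        assert {f"nbs{i:02d}" for i in range(15)} <= set(ids)
        assert ids == [h.target_id for h in
                       sorted(hits, key=lambda h: (h.evalue, h.target_id))]

    def test_threshold_nesting(self, nbarc_hmm, mix):
        tight = {h.target_id for h in search_proteome(nbarc_hmm, mix, 1e-60)}
        loose = {h.target_id for h in search_proteome(nbarc_hmm, mix, 1e-2)}
        assert tight <= loose

    def test_refine_defaults_are_strict_1e60_relaxed_1e2(self):
        sig = inspect.signature(refine_species_model)
        assert sig.parameters["strict"].default == 1e-60
        assert sig.parameters["relaxed"].default == 1e-2

    def test_refinement_recovers_all_planted_and_contains_strict_set(
            self, nbarc_hmm, mix):
        species, hits3 = refine_species_model(mix, nbarc_hmm, calib_seed=3)
        ids3 = {h.target_id for h in hits3}
        assert {f"nbs{i:02d}" for i in range(15)} <= ids3
        stage1 = {h.target_id for h in search_proteome(nbarc_hmm, mix, 1e-60)}
        assert stage1 <= ids3

    def test_refine_falls_back_when_too_few_strict_hits(self, nbarc_hmm):
        aas = np.array(list(R.AA))
        rng = np.random.default_rng(8)
        bg = [prot("".join(aas[rng.choice(20, 200, p=R.BACKGROUND)]), f"b{i}")
              for i in range(5)]
        with pytest.warns(UserWarning, match="falling back"):
            species, _ = refine_species_model(bg, nbarc_hmm, calib_seed=5)
        assert species is nbarc_hmm

    def test_kinase_filter_matches_brute_force(self, nbarc_hmm, kinase_hmm, mix):
        hits = search_proteome(nbarc_hmm, mix, 1e-2)
        kept = kinase_filter(hits, mix, kinase_hmm)
        by_id = {p.id: p for p in mix}
        expected = [h for h in hits
                    if viterbi(kinase_hmm, by_id[h.target_id]).bit_score
                    <= h.bit_score]
        assert [h.target_id for h in kept] == [h.target_id for h in expected]
        # decoys all gone, planted NBS all retained
        kept_ids = {h.target_id for h in kept}
        assert not any(i.startswith("kin") for i in kept_ids)
        assert {f"nbs{i:02d}" for i in range(15)} <= kept_ids


class TestSerialization:
    def test_profile_round_trip(self, nbarc_hmm, tmp_path):
        p = tmp_path / "m.profile.tsv"
        hm.save_profile(nbarc_hmm, str(p))
        back = hm.load_profile(str(p))
        assert back.M == nbarc_hmm.M
        assert np.allclose(back.match_emissions, nbarc_hmm.match_emissions)
        assert back.calibration.mu == pytest.approx(nbarc_hmm.calibration.mu)
        s1 = viterbi(nbarc_hmm, prot("MKVLE" * 10)).bit_score
        s2 = viterbi(back, prot("MKVLE" * 10)).bit_score
        assert s1 == pytest.approx(s2)
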