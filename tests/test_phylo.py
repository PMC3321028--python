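"""NBS-domain extraction, progressive alignment vs pairwise DP, distance
models, NJ correctness (closed forms, additivity, brute-force Q choice),
bootstrap behaviour and clade labelling."""

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nlrforge import resources as R
from nlrforge.domain_arch import DomainHit
from nlrforge.io_formats import SequenceRecord
from nlrforge.phylo import (
    MSA,
    DistanceMatrix,
    PhyloTree,
    assign_clades,
    bootstrap_support,
    distance_matrix,
    extract_nbs_domain,
    nj_q_matrix,
    nj_tree,
    progressive_align,
    trim_ragged_ends,
)


def prot(seq, pid="p"):
    return SequenceRecord(id=pid, description="", residues=seq, alphabet="protein")


class TestExtractNbsDomain:
    HITS = [DomainHit("PLOOP", 160, 174, 30.0), DomainHit("GLPL", 410, 420, 20.0)]

    def test_trim_window_arithmetic(self):
        p = prot("A" * 900)
        dom = extract_nbs_domain(p, self.HITS, tail=30)
        assert dom.residues == "A" * (450 - 160)

    def test_missing_ploop_excluded(self):
        p = prot("A" * 900)
        assert extract_nbs_domain(p, [self.HITS[1]]) is None

    def test_tail_clipped_at_protein_end(self):
        p = prot("A" * 425)
        dom = extract_nbs_domain(p, self.HITS, tail=30)
        assert len(dom.residues) == 425 - 160


def gotoh_global(a, b, gap_open=10.0, gap_extend=0.5):
    """Independent affine global alignment score (pairwise oracle)."""
    B = R.blosum62()
    ea = [R.AA_INDEX[c] for c in a]
    eb = [R.AA_INDEX[c] for c in b]
    NEG = -1e30
    la, lb = len(a), len(b)
    M = np.full((la + 1, lb + 1), NEG)
    X = np.full((la + 1, lb + 1), NEG)
    Y = np.full((la + 1, lb + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, lb + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) \
                + B[ea[i - 1], eb[j - 1]]
            X[i, j] = max(M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend)
            Y[i, j] = max(M[i, j - 1] - gap_open, Y[i, j - 1] - gap_extend)
    return max(M[la, lb], X[la, lb], Y[la, lb])


def msa_score(msa, gap_open=10.0, gap_extend=0.5):
    """Affine score of a 2-row alignment."""
    B = R.blosum62()
    a, b = msa.rows
    score, in_gap = 0.0, False
    for ca, cb in zip(a, b):
        if ca == "-" or cb == "-":
            score += -gap_extend if in_gap else -gap_open
            in_gap = True
        else:
            score += B[R.AA_INDEX[ca], R.AA_INDEX[cb]]
            in_gap = False
    return score


class TestProgressiveAlign:
    def test_identical_sequences_align_gap_free(self):
        seqs = [prot("MKVLEDQRST", f"s{i}") for i in range(5)]
        m = progressive_align(seqs)
        assert all("-" not in r for r in m.rows)
        assert m.width == 10

    @pytest.mark.parametrize("seed", range(5))
    def test_two_sequences_reach_optimal_pairwise_score(self, seed):
        rng = np.random.default_rng(200 + seed)
        base = "".join(rng.choice(list(R.AA), 40))
        other = R.mutate(base, rng, 0.2)
        if rng.random() < 0.5:
            cut = int(rng.integers(5, 35))
            other = other[:cut] + other[cut + 3:]
        m = progressive_align([prot(base, "a"), prot(other, "b")])
        assert msa_score(m) == pytest.approx(gotoh_global(base, other))

    def test_planted_three_residue_deletion_is_one_gap_run(self, rng):
        base = R.sample_nbs("CC_I", rng)
        fam = [prot(R.mutate(base, rng, 0.03), f"f{i}") for i in range(4)]
        fam.append(prot(base[:60] + base[63:], "del"))
        m = progressive_align(fam)
        row = m.rows[m.ids.index("del")]
        runs = [len(s) for s in row.split("-") if True]
        n_runs = row.count("-")
        assert n_runs == 3
        assert "---" in row  # single contiguous gap

    def test_single_sequence_returned_as_is(self):
        m = progressive_align([prot("MKVL", "only")])
        assert m.rows == ["MKVL"]

    def test_ungapping_recovers_inputs(self, rng):
        seqs = [prot(R.mutate(R.TIR_CONSENSUS, rng, 0.2), f"s{i}") for i in range(6)]
        m = progressive_align(seqs)
        for rec in seqs:
            assert m.ungapped(m.ids.index(rec.id)) == rec.residues

    def test_trim_ragged_ends(self):
        m = MSA(ids=["a", "b", "c", "d", "e"],
                rows=["AKLMN", "-KLM-", "-KLM-", "-KLM-", "-KLM-"])
        t = trim_ragged_ends(m, max_gap_fraction=0.5)
        assert t.rows[0] == "KLM"


class TestDistanceMatrix:
    def test_identical_pair_zero(self):
        m = MSA(ids=["a", "b"], rows=["MKVL", "MKVL"])
        assert distance_matrix(m).values[0, 1] == 0.0

    def test_hand_counted_p_and_poisson(self):
        a = "A" * 100
        b = "C" * 3 + "A" * 97
        m = MSA(ids=["a", "b"], rows=[a, b])
        assert distance_matrix(m, "p").values[0, 1] == pytest.approx(0.03)
        assert distance_matrix(m, "poisson").values[0, 1] == \
            pytest.approx(-np.log(0.97))

    def test_pairwise_deletion_ignores_gap_columns(self):
        m = MSA(ids=["a", "b"], rows=["AK-L", "AKM-"])
        # comparable columns: 0 and 1 only, both equal
        assert distance_matrix(m).values[0, 1] == 0.0

    def test_no_comparable_columns_names_pair(self):
        m = MSA(ids=["a", "b"], rows=["A-", "-A"])
        with pytest.raises(ValueError, match="a and b"):
            distance_matrix(m)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10**6))
    def test_symmetry_on_random_alignments(self, seed):
        rng = np.random.default_rng(seed)
        rows = ["".join(rng.choice(list(R.AA) + ["-"], 30)) for _ in range(4)]
        rows = [r if r.replace("-", "") else "A" * 30 for r in rows]
        try:
            dm = distance_matrix(MSA(ids=list("abcd"), rows=rows))
        except ValueError:
            return  # incomparable pair: rejection is the contract
        assert np.allclose(dm.values, dm.values.T)


def tree_distances(newick, taxa):
    t = dendropy.Tree.get(data=newick, schema="newick")
    pdm = t.phylogenetic_distance_matrix()
    tx = {x.label: x for x in t.taxon_namespace}
    n = len(taxa)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.distance(tx[taxa[i]], tx[taxa[j]])
    return D


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        t = nj_tree(DistanceMatrix(labels=list("abc"), values=D))
        lengths = {lf.taxon.label: lf.edge.length
                   for lf in t.tree.leaf_node_iter()}
        # three-point formulas: a=(5+9-10)/2=2, b=(5+10-9)/2=3, c=(9+10-5)/2=7
        assert lengths == pytest.approx({"a": 2.0, "b": 3.0, "c": 7.0})

    def test_additive_six_taxon_tree_recovered_exactly(self):
        newick = "((A:1,B:2):1,((C:1.5,D:1):2,(E:3,F:1):1):1);"
        taxa = list("ABCDEF")
        D = tree_distances(newick, taxa)
        t = nj_tree(DistanceMatrix(labels=taxa, values=D))
        got = {frozenset(bp) for bp in t.bipartitions()}
        want = {frozenset("AB"), frozenset("CD"), frozenset("EF"),
                frozenset("CDEF")}
        # bipartitions are canonicalised to the side not containing 'A'
        want = {bp if "A" not in bp else frozenset(set(taxa) - bp) for bp in want}
        assert got == want
        # branch lengths: leaf edges must match the generating tree
        lengths = {lf.taxon.label: lf.edge.length for lf in t.tree.leaf_node_iter()}
        for taxon, expect in zip(taxa, (1, 2, 1.5, 1, 3, 1)):
            assert lengths[taxon] == pytest.approx(expect, abs=1e-9)

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 10**6))
    def test_random_additive_trees_recovered(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        taxa = [f"t{i}" for i in range(n)]
        # random binary tree via sequential joins, positive branch lengths
        import io
        nodes = [f"{t}:{rng.uniform(0.1, 2.0):.4f}" for t in taxa]
        while len(nodes) > 2:
            i, j = sorted(rng.choice(len(nodes), 2, replace=False))
            merged = f"({nodes[i]},{nodes[j]}):{rng.uniform(0.1, 2.0):.4f}"
            nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
            nodes.append(merged)
        newick = f"({nodes[0]},{nodes[1]});"
        D = tree_distances(newick, taxa)
        t = nj_tree(DistanceMatrix(labels=taxa, values=D))
        src = dendropy.Tree.get(data=newick, schema="newick")
        all_taxa = frozenset(taxa)
        want = set()
        for node in src.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if 1 < len(side) < n - 1:
                want.add(side if min(all_taxa) not in side
                         else all_taxa - side)
        assert {frozenset(bp) for bp in t.bipartitions()} == want

    def test_each_join_is_brute_force_q_minimum(self):
        # independent NJ oracle with the same tie-break, compared end-to-end
        rng = np.random.default_rng(4)
        n = 7
        taxa = [f"x{i}" for i in range(n)]
        D = rng.uniform(1, 10, size=(n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        joins = []
        labels = list(taxa)
        work = D.copy()
        while len(labels) > 3:
            m = len(labels)
            Q = nj_q_matrix(work)
            qmin = Q.min()
            cands = [(tuple(sorted((labels[i], labels[j]))), i, j)
                     for i in range(m) for j in range(i + 1, m)
                     if abs(Q[i, j] - qmin) <= 1e-12]
            key, i, j = min(cands)
            joins.append(key)
            newrow = 0.5 * (work[i] + work[j] - work[i, j])
            keep = [k for k in range(m) if k not in (i, j)]
            work = np.vstack([work[np.ix_(keep, keep)],
                              newrow[keep][None, :]])
            work = np.hstack([work, np.append(newrow[keep], 0.0)[:, None]])
            labels = [labels[k] for k in keep] + [min(key)]
        t = nj_tree(DistanceMatrix(labels=taxa, values=D))
        # the oracle's join sequence induces the same clusters as the tree
        got = {frozenset(bp) for bp in t.bipartitions()}
        clusters = {}
        oracle_bps = set()
        for a, b in joins:
            sa = clusters.get(a, {a})
            sb = clusters.get(b, {b})
            merged = sa | sb
            clusters[min(a, b)] = merged
            if 1 < len(merged) < n - 1:
                all_t = frozenset(taxa)
                side = frozenset(merged)
                oracle_bps.add(side if min(taxa) not in side else all_t - side)
        assert got == oracle_bps

    def test_negative_branch_estimates_clamped_and_flagged(self):
        D = np.array([[0, 1, 10, 10], [1, 0, 1, 1],
                      [10, 1, 0, 1], [10, 1, 1, 0]], dtype=float)
        t = nj_tree(DistanceMatrix(labels=list("abcd"), values=D))
        for edge in t.tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0
        assert t.n_negative_clamped > 0

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(labels=["a", "b"],
                                   values=np.array([[0, 1], [1, 0.]])))


def two_clade_msa(rng, n_per=4, within=0.02):
    core1 = "".join(rng.choice(list(R.AA), 120))
    core2 = "".join(rng.choice(list(R.AA), 120))
    ids, rows = [], []
    for i in range(n_per):
        ids.append(f"a{i}")
        rows.append(R.mutate(core1, rng, within))
    for i in range(n_per):
        ids.append(f"b{i}")
        rows.append(R.mutate(core2, rng, within))
    return MSA(ids=ids, rows=rows)


class TestBootstrap:
    def test_default_replicates_500(self):
        import inspect
        assert inspect.signature(bootstrap_support).parameters["replicates"].default \
            == 500

    def test_separated_clades_reach_high_support(self, rng):
        msa = two_clade_msa(rng)
        t = bootstrap_support(msa, replicates=100, seed=5)
        bset = frozenset(f"b{i}" for i in range(4))
        assert t.supports[bset] >= 95

    def test_same_seed_identical_supports(self, rng):
        msa = two_clade_msa(rng)
        a = bootstrap_support(msa, replicates=50, seed=9).supports
        b = bootstrap_support(msa, replicates=50, seed=9).supports
        assert a == b

    def test_invariant_to_taxon_input_order(self, rng):
        msa = two_clade_msa(rng)
        perm = np.random.default_rng(0).permutation(msa.n)
        shuffled = MSA(ids=[msa.ids[i] for i in perm],
                       rows=[msa.rows[i] for i in perm])
        a = bootstrap_support(msa, replicates=50, seed=3).supports
        b = bootstrap_support(shuffled, replicates=50, seed=3).supports
        assert a == b

    def test_supports_within_percent_range(self, rng):
        msa = two_clade_msa(rng, within=0.2)
        t = bootstrap_support(msa, replicates=40, seed=1)
        assert all(0 <= v <= 100 for v in t.supports.values())

    def test_supports_written_as_internal_node_labels(self, rng, tmp_path):
        from nlrforge.io_formats import write_newick

        msa = two_clade_msa(rng)
        t = bootstrap_support(msa, replicates=50, seed=2)
        p = tmp_path / "t.nwk"
        write_newick(t, str(p))
        text = p.read_text()
        assert any(f"){v:.0f}" in text for v in t.supports.values())


class TestAssignClades:
    def make_tree(self):
        rng = np.random.default_rng(10)
        msa = two_clade_msa(rng)
        return nj_tree(distance_matrix(msa))

    def test_unlabeled_leaf_inside_pure_reference_clade(self):
        t = self.make_tree()
        labels = assign_clades(t, {"a0": "CC_I", "b0": "TIR"})
        for i in range(4):
            assert labels[f"a{i}"] == "CC_I"
            assert labels[f"b{i}"] == "TIR"

    def test_reference_leaf_keeps_its_label(self):
        t = self.make_tree()
        labels = assign_clades(t, {"a0": "CC_I", "b0": "TIR", "b1": "CC_II"})
        assert labels["b1"] == "CC_II"

    def test_mixed_enclosing_clades_unassigned(self):
        t = self.make_tree()
        # conflicting references inside the b clade poison every enclosing
        # clade of b2/b3
        labels = assign_clades(t, {"b0": "TIR", "b1": "CC_II"})
        assert labels["b2"] == "unassigned" or labels["b3"] == "unassigned"

    def test_absent_reference_rejected(self):
        t = self.make_tree()
        with pytest.raises(ValueError, match="absent"):
            assign_clades(t, {"zz": "TIR"})
        with pytest.raises(ValueError, match="no reference"):
            assign_clades(t, {})
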