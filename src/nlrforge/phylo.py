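"""NBS-domain phylogeny: P-loop-anchored trimming, progressive multiple
alignment, distance matrices, neighbor-joining with bootstrap, and clade
labelling (CC(I) / CC(II) / TIR).

The alignment is guide-tree progressive: pairwise 3-mer distances feed a
UPGMA guide tree (scipy hierarchical clustering) and profiles are merged by
global profile-profile Needleman-Wunsch with affine gaps (BLOSUM62 expected
column scores).  Trees are Saitou-Nei neighbor joining with deterministic
lexicographic tie-breaking; negative branch-length estimates are clamped to
zero and flagged.  Bootstrap supports come from column resampling: the
support of an internal edge is the percentage of replicate trees containing
the same leaf bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from numba import njit
from scipy.cluster.hierarchy import linkage

from .domain_arch import DomainHit
from .io_formats import SequenceRecord
from .resources import blosum62, encode_protein

__all__ = [
    "MSA",
    "DistanceMatrix",
    "PhyloTree",
    "extract_nbs_domain",
    "progressive_align",
    "trim_ragged_ends",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "assign_clades",
]


@dataclass
class MSA:
    """Aligned sequences, uniform length; '-' is the gap character."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if self.rows and any(len(r) != len(self.rows[0]) for r in self.rows):
            raise ValueError("alignment rows differ in length")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def records(self) -> list[SequenceRecord]:
        return [SequenceRecord(id=i, description="", residues=r, alphabet="protein")
                for i, r in zip(self.ids, self.rows)]

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")

    def gap_fraction(self) -> np.ndarray:
        arr = np.array([list(r) for r in self.rows])
        return (arr == "-").mean(axis=0)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or np.any(np.diag(v) != 0) or np.any(v < 0):
            raise ValueError("distance matrix must be symmetric, zero-diagonal, >= 0")


@dataclass
class PhyloTree:
    """Unrooted NJ tree (dendropy representation) with bootstrap supports
    keyed by leaf bipartition (frozenset of the smaller/canonical side)."""

    tree: dendropy.Tree
    supports: dict[frozenset, float] = field(default_factory=dict)
    n_negative_clamped: int = 0
    clade_labels: dict[str, str] = field(default_factory=dict)

    def leaf_names(self) -> list[str]:
        return sorted(t.label for t in self.tree.taxon_namespace)

    def bipartitions(self) -> dict[frozenset, dendropy.Node]:
        """Internal-edge bipartitions as canonical leaf-name frozensets."""
        all_leaves = frozenset(self.leaf_names())
        anchor = min(all_leaves)
        out = {}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            side = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if len(side) <= 1 or len(side) >= len(all_leaves) - 1:
                continue  # trivial bipartition
            if anchor in side:
                side = all_leaves - side
            out[side] = node
        return out


# ---------------------------------------------------------------------------
# NBS-domain extraction


def extract_nbs_domain(protein: SequenceRecord, subdomain_hits: list[DomainHit],
                       tail: int = 30) -> SequenceRecord | None:
    """Trim to [P-loop start, GLPL end + tail), clipped to the protein.

    Proteins lacking a P-loop or GLPL hit are excluded (returns None), the
    rule used to keep only complete NBS domains in the phylogeny.
    """
    ploop = next((h for h in subdomain_hits if h.kind == "PLOOP"), None)
    glpl = next((h for h in subdomain_hits if h.kind == "GLPL"), None)
    if ploop is None or glpl is None:
        return None
    end = min(len(protein.residues), glpl.end + tail)
    return SequenceRecord(id=protein.id, description="nbs_domain",
                          residues=protein.residues[ploop.start:end],
                          alphabet="protein")


# ---------------------------------------------------------------------------
# progressive alignment


@njit
def _nw_profile_kernel(S, gap_open, gap_extend):
    """Global affine-gap DP on a precomputed column-score matrix.

    Returns pointer matrices for (M, X, Y) where X consumes a row-profile
    column (gap in the other) and Y consumes a column-profile column.
    """
    la, lb = S.shape
    NEGI = -1.0e30
    M = np.full((la + 1, lb + 1), NEGI)
    X = np.full((la + 1, lb + 1), NEGI)
    Y = np.full((la + 1, lb + 1), NEGI)
    PM = np.zeros((la + 1, lb + 1), dtype=np.int8)
    PX = np.zeros((la + 1, lb + 1), dtype=np.int8)
    PY = np.zeros((la + 1, lb + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        X[i, 0] = -gap_open - gap_extend * (i - 1)
        PX[i, 0] = 1 if i > 1 else 0
    for j in range(1, lb + 1):
        Y[0, j] = -gap_open - gap_extend * (j - 1)
        PY[0, j] = 2 if j > 1 else 0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            # match
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            M[i, j] = best + S[i - 1, j - 1]
            PM[i, j] = p
            # gap in B (consume A column i)
            best = M[i - 1, j] - gap_open
            p = 0
            if X[i - 1, j] - gap_extend > best:
                best = X[i - 1, j] - gap_extend
                p = 1
            X[i, j] = best
            PX[i, j] = p
            # gap in A (consume B column j)
            best = M[i, j - 1] - gap_open
            p = 0
            if Y[i, j - 1] - gap_extend > best:
                best = Y[i, j - 1] - gap_extend
                p = 2
            Y[i, j] = best
            PY[i, j] = p
    return M, X, Y, PM, PX, PY


def _profile(rows: list[str]) -> np.ndarray:
    """(L, 20) residue frequencies per column (gaps carry no weight)."""
    L = len(rows[0])
    enc = np.array([encode_protein(r.replace("-", chr(88))) for r in rows])
    gap = np.array([[c == "-" for c in r] for r in rows])
    prof = np.zeros((L, 20))
    for k in range(20):
        prof[:, k] = ((enc == k) & ~gap).sum(axis=0)
    tot = prof.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    return prof / tot


def _merge(a: MSA, b: MSA, B: np.ndarray, gap_open: float, gap_extend: float) -> MSA:
    S = _profile(a.rows) @ B @ _profile(b.rows).T
    M, X, Y, PM, PX, PY = _nw_profile_kernel(S, gap_open, gap_extend)
    la, lb = S.shape
    i, j = la, lb
    finals = {0: M[la, lb], 1: X[la, lb], 2: Y[la, lb]}
    state = max(finals, key=lambda s: (finals[s], -s))
    cols = []  # (consume_a, consume_b)
    while i > 0 or j > 0:
        if state == 0:
            cols.append((True, True))
            state = PM[i, j]
            i, j = i - 1, j - 1
        elif state == 1:
            cols.append((True, False))
            state = PX[i, j]
            i -= 1
        else:
            cols.append((False, True))
            state = PY[i, j]
            j -= 1
    cols.reverse()
    new_rows_a = ["".join(r[ia] if ca else "-" for ca, _, ia in _enum(cols, True))
                  for r in a.rows]
    new_rows_b = ["".join(r[ib] if cb else "-" for _, cb, ib in _enum(cols, False))
                  for r in b.rows]
    return MSA(ids=a.ids + b.ids, rows=new_rows_a + new_rows_b)


def _enum(cols, for_a: bool):
    ia = ib = 0
    out = []
    for ca, cb in cols:
        out.append((ca, cb, ia if for_a else ib))
        if ca:
            ia += 1
        if cb:
            ib += 1
    return out


def _kmer_distance(seqs: list[str], k: int = 3) -> np.ndarray:
    sets = [{s[i:i + k] for i in range(len(s) - k + 1)} for s in seqs]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(sets[i]), len(sets[j])) or 1
            D[i, j] = D[j, i] = 1.0 - len(sets[i] & sets[j]) / denom
    return D


def progressive_align(sequences: list[SequenceRecord],
                      gap_open: float = 10.0, gap_extend: float = 0.5) -> MSA:
    """Guide-tree progressive alignment (UPGMA on shared-3-mer distances,
    profile-profile merges).  Deterministic; a single sequence is returned
    as-is."""
    if not sequences:
        raise ValueError("no sequences to align")
    if len(sequences) == 1:
        return MSA(ids=[sequences[0].id], rows=[sequences[0].residues])
    B = blosum62()
    seqs = [s.residues for s in sequences]
    D = _kmer_distance(seqs)
    n = len(seqs)
    iu = np.triu_indices(n, 1)
    Z = linkage(D[iu], method="average")
    nodes: dict[int, MSA] = {
        i: MSA(ids=[sequences[i].id], rows=[seqs[i]]) for i in range(n)
    }
    for step, (ia, ib, _, _) in enumerate(Z):
        a, b = nodes.pop(int(ia)), nodes.pop(int(ib))
        nodes[n + step] = _merge(a, b, B, gap_open, gap_extend)
    (msa,) = nodes.values()
    # restore the input order of rows
    order = {sid: k for k, sid in enumerate(msa.ids)}
    idx = sorted(range(len(msa.ids)), key=lambda k: [s.id for s in sequences].index(msa.ids[k]))
    return MSA(ids=[msa.ids[k] for k in idx], rows=[msa.rows[k] for k in idx])


def trim_ragged_ends(msa: MSA, max_gap_fraction: float = 0.8) -> MSA:
    """Drop leading/trailing columns whose gap fraction exceeds the cutoff
    (automatic stand-in for manual end curation of the alignment)."""
    if msa.width == 0:
        return msa
    gf = msa.gap_fraction()
    keep = np.flatnonzero(gf <= max_gap_fraction)
    if keep.size == 0:
        return MSA(ids=list(msa.ids), rows=["" for _ in msa.rows])
    lo, hi = keep[0], keep[-1] + 1
    return MSA(ids=list(msa.ids), rows=[r[lo:hi] for r in msa.rows])


# ---------------------------------------------------------------------------
# distances


def distance_matrix(msa: MSA, model: str = "p") -> DistanceMatrix:
    """Pairwise-deletion p-distance, optionally Poisson-corrected
    (-ln(1-p))."""
    if msa.n < 2:
        raise ValueError("need at least 2 rows")
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    arr = np.array([list(r) for r in msa.rows])
    valid = arr != "-"
    n = msa.n
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            m = both.sum()
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {msa.ids[i]} and {msa.ids[j]}")
            p = (arr[i][both] != arr[j][both]).sum() / m
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(f"saturated pair {msa.ids[i]}/{msa.ids[j]}")
                d = -np.log(1.0 - p)
            else:
                d = p
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels=list(msa.ids), values=D)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_q_matrix(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    r = D.sum(axis=1)
    Q = (n - 2) * D - r[:, None] - r[None, :]
    np.fill_diagonal(Q, np.inf)
    return Q


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei agglomeration.

    Each step joins the Q-minimum pair; ties are broken by the
    lexicographically smallest (taxon-key, taxon-key) pair, where a
    cluster's key is the smallest leaf label it contains, keeping runs
    deterministic and input-order invariant.  Negative branch-length
    estimates are clamped to zero and counted.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("non-finite distances")
    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    keys = []
    for lab in dm.labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(nd)
        keys.append(lab)
    D = dm.values.astype(float).copy()
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped += 1
            return 0.0
        return x

    active = list(range(n0))
    while len(active) > 3:
        n = len(active)
        sub = D[np.ix_(active, active)]
        Q = nj_q_matrix(sub)
        qmin = Q.min()
        cands = [(tuple(sorted((keys[active[i]], keys[active[j]]))), i, j)
                 for i, j in zip(*np.where(np.isclose(Q, qmin, rtol=0, atol=1e-12)))
                 if i < j]
        _, ai, aj = min(cands)
        i, j = active[ai], active[aj]
        r = sub.sum(axis=1)
        dij = D[i, j]
        li = clamp(0.5 * dij + (r[ai] - r[aj]) / (2.0 * (n - 2)))
        lj = clamp(dij - (0.5 * dij + (r[ai] - r[aj]) / (2.0 * (n - 2))))
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        # distances to the new node
        newd = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, newd])
        D = np.hstack([D, np.append(newd, 0.0)[:, None]])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    # resolve the final three nodes on a central (unrooted) vertex
    a, b, c = active
    la = clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]))
    lb = clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]))
    lc = clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]))
    center = dendropy.Node()
    for node, ln in ((nodes[a], la), (nodes[b], lb), (nodes[c], lc)):
        center.add_child(node)
        node.edge.length = ln
    tree.seed_node = center
    tree.is_rooted = False
    return PhyloTree(tree=tree, n_negative_clamped=clamped)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(msa: MSA, replicates: int = 500, seed: int = 0,
                      model: str = "p", tree: PhyloTree | None = None) -> PhyloTree:
    """Column-resampling bootstrap on the NJ tree.

    Support of each internal edge = percentage of replicate trees containing
    the same bipartition; supports are written onto internal node labels.
    Deterministic under a fixed seed and invariant to taxon input order
    (replicates resample columns only).
    """
    if msa.width < 2:
        raise ValueError("need at least 2 columns to resample")
    full = tree if tree is not None else nj_tree(distance_matrix(msa, model))
    target = full.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(replicates):
        cols = rng.integers(0, msa.width, size=msa.width)
        rep = MSA(ids=list(msa.ids),
                  rows=["".join(r[c] for c in cols) for r in msa.rows])
        try:
            rep_tree = nj_tree(distance_matrix(rep, model))
        except ValueError:
            continue  # e.g. a resample with no comparable columns for a pair
        rep_bps = set(rep_tree.bipartitions())
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    supports = {bp: 100.0 * c / replicates for bp, c in counts.items()}
    for bp, node in target.items():
        node.label = f"{supports[bp]:.0f}"
    full.supports = supports
    return full


# ---------------------------------------------------------------------------
# clade labels


def assign_clades(ptree: PhyloTree, reference_labels: dict[str, str]) -> dict[str, str]:
    """Label every leaf by its smallest enclosing clade that contains
    reference leaves of exactly one label.

    Reference leaves keep their own label; a leaf whose smallest
    reference-containing clade mixes labels is 'unassigned'.
    """
    tree = ptree.tree
    leaf_names = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = set(reference_labels) - leaf_names
    if missing:
        raise ValueError(f"reference leaves absent from tree: {sorted(missing)}")
    if not reference_labels:
        raise ValueError("no reference labels given")
    # clades of an unrooted tree = both sides of every edge
    sides: list[frozenset] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        under = frozenset(lf.taxon.label for lf in node.leaf_iter())
        sides.append(under)
        sides.append(frozenset(leaf_names - under))
    sides.sort(key=lambda s: (len(s), sorted(s)))
    out = {}
    for name in leaf_names:
        if name in reference_labels:
            out[name] = reference_labels[name]
            continue
        label = "unassigned"
        for side in sides:
            if name not in side:
                continue
            refs = {reference_labels[x] for x in side if x in reference_labels}
            if refs:
                label = next(iter(refs)) if len(refs) == 1 else "unassigned"
                break
        out[name] = label
    ptree.clade_labels = out
    return out
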