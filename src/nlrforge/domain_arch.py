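"""Domain detection and architecture classification for NLR candidates.

Detects the N-terminal TIR and coiled-coil (CC) domains, the C-terminal
leucine-rich repeats (LRR) and the four ordered NBS subdomain motifs
(P-loop < kinase-2 < kinase-3a < GLPL), types the NBS signature (CC-lineage
kinase-2 ends in W, TIR-lineage in D), and assigns each protein one of the
eight architecture codes

    CNL  CN  NL_CC  N_CC   (CC branch)
    TNL  TN  NL_TIR N_TIR  (TIR branch)

or PARTIAL when too little of the NBS model is covered.  Subscripted codes
(NL_CC etc.) mean the N-terminal domain is absent but the NBS carries the
signature of that lineage.

TIR/LRR detection uses position-specific scoring matrices (log2-odds window
scans); the coiled-coil scan is a Lupas-style heptad sliding window with a
logistic probability mapping, standing in for full coiled-coil HMMs with
the same decision-boundary semantics (probability threshold 0.9, second
"validation" margin at 1 - 0.025).  An expectation-maximisation motif
finder (one occurrence per sequence) supports subdomain comparison between
lineages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .io_formats import SequenceRecord
from .resources import (
    AA,
    BACKGROUND,
    HEPTAD_CORE_SCORES,
    HEPTAD_OUTER_SCORES,
    encode_protein,
    nbs_consensus,
    seed_alignment,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PSSM",
    "DomainHit",
    "NbsSignature",
    "ArchitectureCall",
    "build_pssm",
    "default_pssms",
    "scan_pssm",
    "coiled_coil_scan",
    "find_nbs_subdomains",
    "classify_signature",
    "assign_architecture",
    "em_discover_motif",
]

SUBDOMAIN_ORDER = ("PLOOP", "KINASE2", "KINASE3A", "GLPL")


@dataclass
class PSSM:
    """Log2-odds window matrix vs the packaged background, with a bit-score
    acceptance threshold."""

    kind: str
    log_odds: np.ndarray  # (W, 21); column 20 = X, scores 0
    threshold: float

    @property
    def width(self) -> int:
        return self.log_odds.shape[0]

    def __post_init__(self) -> None:
        if self.width < 3:
            raise ValueError("PSSM width must be >= 3")
        if not np.all(np.isfinite(self.log_odds)):
            raise ValueError("PSSM entries must be finite")

    def consensus_score(self) -> float:
        return float(self.log_odds[:, :20].max(axis=1).sum())


@dataclass
class DomainHit:
    kind: str
    start: int
    end: int
    score: float
    validated: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("bad hit interval")


@dataclass
class NbsSignature:
    type: str  # CC_type | TIR_type | undetermined
    kinase2_terminal: str | None = None
    cc_subprofile_score: float | None = None
    tir_subprofile_score: float | None = None


@dataclass
class ArchitectureCall:
    code: str
    supporting: list[DomainHit] = field(default_factory=list)
    nbs_coverage: float = 1.0


# ---------------------------------------------------------------------------
# PSSM construction


def build_pssm(msa: list[SequenceRecord], kind: str, pseudocount: float = 1.0,
               threshold_fraction: float = 0.5) -> PSSM:
    """Estimate a PSSM from ungapped aligned instances.

    The acceptance threshold defaults to ``threshold_fraction`` of the
    consensus (maximum attainable) score.
    """
    rows = [r.residues.upper() for r in msa]
    W = len(rows[0])
    counts = np.full((W, 20), pseudocount)
    for r in rows:
        for k, aa in enumerate(r):
            i = AA.find(aa)
            if i >= 0:
                counts[k, i] += 1.0
    probs = counts / counts.sum(axis=1, keepdims=True)
    lo = np.zeros((W, 21))
    lo[:, :20] = np.log2(probs / BACKGROUND)
    pssm = PSSM(kind=kind, log_odds=lo, threshold=0.0)
    pssm.threshold = threshold_fraction * pssm.consensus_score()
    return pssm


@lru_cache(maxsize=1)
def default_pssms() -> dict[str, PSSM]:
    """Packaged PSSMs: TIR, LRR and the four NBS subdomain motifs.

    Subdomain matrices are cut from the packaged NB-ARC seed family at the
    consensus motif offsets (the kinase-2 matrix therefore mixes W- and
    D-terminal lineage members).
    """
    out = {
        "TIR": build_pssm(list(seed_alignment("tir")), "TIR"),
        "LRR": build_pssm(list(seed_alignment("lrr")), "LRR"),
    }
    _, spans = nbs_consensus("CC_I")
    name_map = {"ploop": "PLOOP", "kinase2": "KINASE2",
                "kinase3a": "KINASE3A", "glpl": "GLPL"}
    rows = list(seed_alignment("nbarc"))
    for motif, (s, e) in spans.items():
        sliced = [SequenceRecord(id=r.id, description="", residues=r.residues[s:e],
                                 alphabet="protein") for r in rows]
        out[name_map[motif]] = build_pssm(sliced, name_map[motif])
    return out


# ---------------------------------------------------------------------------
# window scans


def _window_scores(seq: np.ndarray, pssm: PSSM) -> np.ndarray:
    """Score of every window start; brute-force-equivalent vectorised sum."""
    W = pssm.width
    n = len(seq) - W + 1
    if n <= 0:
        return np.empty(0)
    S = np.zeros(n)
    for k in range(W):
        S += pssm.log_odds[k][seq[k:k + n]]
    return S


def scan_pssm(protein: SequenceRecord | str, pssm: PSSM,
              max_hits: int | None = None) -> list[DomainHit]:
    """All windows scoring >= threshold, made non-overlapping greedily by
    score (ties to the leftmost window)."""
    seq_str = protein.residues if isinstance(protein, SequenceRecord) else protein
    if len(seq_str) < pssm.width:
        return []
    S = _window_scores(encode_protein(seq_str), pssm)
    candidates = np.flatnonzero(S >= pssm.threshold)
    order = sorted(candidates, key=lambda i: (-S[i], i))
    hits: list[DomainHit] = []
    taken: list[tuple[int, int]] = []
    for i in order:
        iv = (int(i), int(i) + pssm.width)
        if any(iv[0] < e and s < iv[1] for s, e in taken):
            continue
        taken.append(iv)
        hits.append(DomainHit(kind=pssm.kind, start=iv[0], end=iv[1],
                              score=float(S[i])))
        if max_hits is not None and len(hits) >= max_hits:
            break
    hits.sort(key=lambda h: h.start)
    return hits


# logistic mapping for heptad window scores; midpoint/scale chosen so an
# ideal 4-heptad window maps to ~1 and background windows to ~0
CC_LOGISTIC_MID = 18.0
CC_LOGISTIC_SCALE = 3.0


def coiled_coil_probabilities(protein: SequenceRecord | str,
                              window: int = 28) -> np.ndarray:
    """Per-residue coiled-coil probability.

    Each window is scored in all seven heptad phases (hydrophobic-core
    propensities at registers a/d, outer propensities elsewhere); a residue's
    probability is the logistic of the best score among covering windows.
    """
    seq_str = protein.residues if isinstance(protein, SequenceRecord) else protein
    L = len(seq_str)
    seq = encode_protein(seq_str)
    core = np.append(HEPTAD_CORE_SCORES, 0.0)[seq]
    outer = np.append(HEPTAD_OUTER_SCORES, 0.0)[seq]
    if L < window:
        return np.zeros(L)
    n = L - window + 1
    best = np.full(n, -np.inf)
    for phase in range(7):
        # register of absolute position i is (i + phase) mod 7; a/d = 0/3
        is_core = ((np.arange(L) + phase) % 7 == 0) | ((np.arange(L) + phase) % 7 == 3)
        per_res = np.where(is_core, core, outer)
        csum = np.concatenate([[0.0], np.cumsum(per_res)])
        best = np.maximum(best, csum[window:] - csum[:-window])
    win_prob = 1.0 / (1.0 + np.exp(-(best - CC_LOGISTIC_MID) / CC_LOGISTIC_SCALE))
    res_prob = np.zeros(L)
    for i in range(n):
        seg = res_prob[i:i + window]
        np.maximum(seg, win_prob[i], out=seg)
    return res_prob


def coiled_coil_scan(protein: SequenceRecord | str, window: int = 28,
                     prob_threshold: float = 0.9,
                     validation_cutoff: float = 0.025) -> list[DomainHit]:
    """Coiled-coil segments: maximal runs of residues at probability >=
    ``prob_threshold``; a segment is flagged validated when its peak
    probability also clears the stricter 1 - ``validation_cutoff`` margin."""
    probs = coiled_coil_probabilities(protein, window=window)
    hits = []
    i = 0
    L = len(probs)
    while i < L:
        if probs[i] >= prob_threshold:
            j = i
            while j < L and probs[j] >= prob_threshold:
                j += 1
            peak = float(probs[i:j].max())
            hits.append(DomainHit(kind="CC", start=i, end=j, score=peak,
                                  validated=peak >= 1.0 - validation_cutoff))
            i = j
        else:
            i += 1
    return hits


# ---------------------------------------------------------------------------
# ordered NBS subdomains


def find_nbs_subdomains(protein: SequenceRecord | str,
                        subdomain_pssms: dict[str, PSSM] | None = None,
                        ) -> tuple[list[DomainHit], bool]:
    """Highest-total-score subset of subdomain hits in canonical order.

    Candidate hits per motif come from :func:`scan_pssm`; the selected
    subset must satisfy P-loop < kinase-2 < kinase-3a < GLPL by start
    coordinate (absent motifs are skipped).  Exhaustive over at most three
    candidates per motif.  Returns (ordered hits, complete?) where complete
    means all four motifs are present.
    """
    pssms = subdomain_pssms or default_pssms()
    cands: list[list[DomainHit | None]] = []
    for kind in SUBDOMAIN_ORDER:
        hits = scan_pssm(protein, pssms[kind], max_hits=3)
        hits.sort(key=lambda h: -h.score)
        cands.append([None] + hits[:3])

    best_sel: list[DomainHit] = []
    best_score = -np.inf
    def ordered(sel: list[DomainHit]) -> bool:
        starts = [h.start for h in sel]
        ends = [h.end for h in sel]
        return all(ends[k] <= starts[k + 1] for k in range(len(sel) - 1))

    for a in cands[0]:
        for b in cands[1]:
            for c in cands[2]:
                for d in cands[3]:
                    sel = [h for h in (a, b, c, d) if h is not None]
                    if not ordered(sel):
                        continue
                    total = sum(h.score for h in sel)
                    if total > best_score:
                        best_score = total
                        best_sel = sel
    complete = len(best_sel) == 4
    return best_sel, complete


# ---------------------------------------------------------------------------
# signature typing and the 8-way architecture call


def classify_signature(protein: SequenceRecord | str,
                       subdomain_hits: list[DomainHit],
                       cc_sub_hmm=None, tir_sub_hmm=None) -> NbsSignature:
    """Type the NBS as CC- or TIR-lineage.

    Primary rule: terminal residue of the kinase-2 motif (W -> CC-lineage,
    D -> TIR-lineage).  Fallback and consistency check: the higher of the
    two lineage sub-profile Viterbi scores.  Undetermined when neither rule
    decides.
    """
    seq = protein.residues if isinstance(protein, SequenceRecord) else protein
    terminal = None
    for h in subdomain_hits:
        if h.kind == "KINASE2":
            terminal = seq[h.end - 1]
    cc_score = tir_score = None
    if cc_sub_hmm is not None and tir_sub_hmm is not None:
        from .profile_hmm import viterbi

        cc_score = viterbi(cc_sub_hmm, seq).bit_score
        tir_score = viterbi(tir_sub_hmm, seq).bit_score
    if terminal == "W":
        sig = "CC_type"
    elif terminal == "D":
        sig = "TIR_type"
    elif cc_score is not None and tir_score is not None and cc_score != tir_score:
        sig = "CC_type" if cc_score > tir_score else "TIR_type"
    else:
        sig = "undetermined"
    return NbsSignature(type=sig, kinase2_terminal=terminal,
                        cc_subprofile_score=cc_score,
                        tir_subprofile_score=tir_score)


def assign_architecture(domain_hits: list[DomainHit], signature: NbsSignature,
                        nbs_coverage: float,
                        partial_threshold: float = 0.5) -> ArchitectureCall:
    """Map one protein's domain evidence to an architecture code.

    Branching: TIR present -> TNL/TN; else CC present -> CNL/CN; neither
    N-terminal domain -> the NBS signature decides the subscript branch
    (undetermined signatures fall into the CC branch, the predominant
    lineage, and are logged).  NBS model coverage below
    ``partial_threshold`` short-circuits to PARTIAL.  Proteins showing both
    CC and TIR are resolved toward TIR (rarer, higher specificity) and
    logged.
    """
    if nbs_coverage < partial_threshold:
        return ArchitectureCall(code="PARTIAL", supporting=list(domain_hits),
                                nbs_coverage=nbs_coverage)
    kinds = {h.kind for h in domain_hits}
    has_tir = "TIR" in kinds
    has_cc = "CC" in kinds
    has_lrr = "LRR" in kinds
    if has_tir and has_cc:
        logger.info("both CC and TIR present; resolving toward TIR")
    if has_tir:
        code = "TNL" if has_lrr else "TN"
    elif has_cc:
        code = "CNL" if has_lrr else "CN"
    else:
        if signature.type == "TIR_type":
            code = "NL_TIR" if has_lrr else "N_TIR"
        else:
            if signature.type == "undetermined":
                logger.info("undetermined NBS signature; defaulting to CC branch")
            code = "NL_CC" if has_lrr else "N_CC"
    return ArchitectureCall(code=code, supporting=list(domain_hits),
                            nbs_coverage=nbs_coverage)


# ---------------------------------------------------------------------------
# EM motif discovery (one occurrence per sequence)


def em_discover_motif(proteins: list[SequenceRecord], width: int,
                      n_starts: int = 10, seed: int = 0,
                      max_iter: int = 200, tol: float = 1e-8,
                      trace: list | None = None,
                      ) -> tuple[PSSM, float]:
    """One-occurrence-per-sequence EM motif discovery.

    Runs ``n_starts`` random restarts and keeps the model with the highest
    log-likelihood.  Deterministic under a fixed seed; the per-iteration
    log-likelihood is non-decreasing (standard EM guarantee).  Returns the
    motif as a :class:`PSSM` plus the final log-likelihood.
    """
    if len(proteins) < 5:
        raise ValueError("need at least 5 sequences")
    seqs = [encode_protein(p.residues) for p in proteins]
    if any(len(s) < width for s in seqs):
        raise ValueError("width exceeds shortest sequence length")
    rng = np.random.default_rng(seed)
    log_bg = np.log(np.append(BACKGROUND, 1.0))

    def loglik_terms(theta_log: np.ndarray, seq: np.ndarray) -> np.ndarray:
        # log P(window | motif) - log P(window | background) per start
        n = len(seq) - width + 1
        t = np.zeros(n)
        for k in range(width):
            t += theta_log[k][seq[k:k + n]] - log_bg[seq[k:k + n]]
        return t

    best_ll = -np.inf
    best_theta = None
    for _ in range(n_starts):
        # initialise from a random window of a random sequence
        s = seqs[rng.integers(len(seqs))]
        i = rng.integers(len(s) - width + 1)
        theta = np.full((width, 20), 1.0 / 20)
        for k in range(width):
            if s[i + k] < 20:
                theta[k] = (theta[k] + 4.0 * np.eye(20)[s[i + k]]) / 5.0
        pseudo = 0.5 * BACKGROUND  # background-proportional Dirichlet prior
        prev_obj = -np.inf
        for _ in range(max_iter):
            theta_log = np.log(np.hstack([theta, np.ones((width, 1))]))
            counts = np.tile(pseudo, (width, 1))
            ll = 0.0
            for seq in seqs:
                t = loglik_terms(theta_log, seq)
                m = t.max()
                w = np.exp(t - m)
                z = w.sum()
                ll += m + np.log(z / len(t))
                w /= z
                for k in range(width):
                    sub = seq[k:k + len(w)]
                    valid = sub < 20
                    np.add.at(counts[k], sub[valid], w[valid])
            # MAP-EM is monotone in the penalized objective (ll + log prior)
            obj = ll + float((pseudo * np.log(theta)).sum())
            theta = counts / counts.sum(axis=1, keepdims=True)
            if trace is not None:
                trace.append(obj)
            if obj - prev_obj < tol and np.isfinite(prev_obj):
                break
            prev_obj = obj
        if prev_obj > best_ll:
            best_ll = prev_obj
            best_theta = theta
    lo = np.zeros((width, 21))
    lo[:, :20] = np.log2(best_theta / BACKGROUND)
    pssm = PSSM(kind="MOTIF", log_odds=lo, threshold=0.0)
    pssm.threshold = 0.5 * pssm.consensus_score()
    return pssm, float(best_ll)
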