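"""Profile hidden Markov models for protein-domain search.

Implements the identification stage of the annotation pipeline: build a
profile HMM from a seed alignment, score proteins with a local Viterbi
algorithm, convert bit scores to E-values through an empirical Gumbel
calibration, run the two-pass species-specific refinement (strict search ->
rebuild from own hits -> relaxed re-search), and exclude protein-kinase
look-alikes that share the P-loop with NB-ARC.

Model structure is the standard match/insert/delete plan-7-like profile:
M match states with position-specific emissions, insert states emitting the
background distribution, and {M,I,D} transitions per position.  Search is
local on both axes ("Smith-Waterman-style flanked"): flanking residues are
absorbed at zero log-odds cost, the alignment may enter the model at any
match state (uniform entry probability 1/M, i.e. a -log2(M) bit charge) and
leave from any match state for free.  Scores are log2-odds against the
packaged Robinson-Robinson background, in bits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.stats import gumbel_r

from .io_formats import SequenceRecord
from .resources import AA, BACKGROUND, encode_protein

__all__ = [
    "ProfileHMM",
    "HmmHit",
    "CalibrationParams",
    "build_profile",
    "viterbi",
    "calibrate_evalue",
    "search_proteome",
    "refine_species_model",
    "kinase_filter",
    "save_profile",
    "load_profile",
]

NEG = -1.0e30  # stand-in for log(0); safe under addition unlike -inf


@dataclass
class CalibrationParams:
    """Gumbel null model for Viterbi bit scores: P(S >= s) = gumbel_sf(s)."""

    mu: float
    lam: float  # 1/scale of the fitted Gumbel
    n_null_samples: int
    null_length: int
    seed: int

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")

    def pvalue(self, score: float) -> float:
        return float(gumbel_r.sf(score, loc=self.mu, scale=1.0 / self.lam))

    def score_at_evalue(self, evalue: float, n_targets: int) -> float:
        return float(gumbel_r.isf(evalue / n_targets, loc=self.mu, scale=1.0 / self.lam))


@dataclass
class ProfileHMM:
    """Profile HMM over the 20-letter amino-acid alphabet.

    ``match_emissions``/``insert_emissions`` are probability rows (sum 1);
    ``transitions[k]`` holds P(next state | state at node k) for the seven
    core moves MM, MI, MD, IM, II, DM, DD.  Node k in 1..M-1; row 0 unused.
    """

    match_emissions: np.ndarray       # (M+1, 20), row 0 unused
    insert_emissions: np.ndarray      # (M+1, 20)
    transitions: dict[str, np.ndarray]  # each (M+1,)
    background: np.ndarray = field(default_factory=lambda: BACKGROUND.copy())
    calibration: CalibrationParams | None = None
    name: str = "profile"

    @property
    def M(self) -> int:
        return self.match_emissions.shape[0] - 1

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("profile must have at least 2 match states")
        for row in self.match_emissions[1:]:
            if abs(row.sum() - 1.0) > 1e-9:
                raise ValueError("match emission row does not sum to 1")

    def match_log_odds(self) -> np.ndarray:
        """(M+1, 21) log2-odds; column 20 (X residues) scores 0."""
        lo = np.full((self.M + 1, 21), 0.0)
        with np.errstate(divide="ignore"):
            lo[1:, :20] = np.log2(self.match_emissions[1:] / self.background)
        lo[np.isneginf(lo)] = NEG
        return lo

    def transition_log2(self, key: str) -> np.ndarray:
        with np.errstate(divide="ignore"):
            out = np.log2(self.transitions[key])
        out[np.isneginf(out)] = NEG
        return out

    def consensus(self) -> str:
        return "".join(AA[int(j)] for j in self.match_emissions[1:].argmax(axis=1))


@dataclass
class HmmHit:
    target_id: str
    bit_score: float
    evalue: float | None
    env_start: int
    env_end: int
    path: list[tuple[str, int, int]]  # (state, model node, 1-based seq pos)

    def __post_init__(self) -> None:
        if self.evalue is not None and self.evalue < 0:
            raise ValueError("E-value must be >= 0")
        if not np.isfinite(self.bit_score):
            raise ValueError("bit score must be finite")

    @property
    def model_nodes_covered(self) -> int:
        return len({j for s, j, _ in self.path if s == "M"})


# ---------------------------------------------------------------------------
# model construction


def build_profile(msa: list[SequenceRecord], match_gap_threshold: float = 0.5,
                  pseudocount: float = 1.0, name: str = "profile") -> ProfileHMM:
    """Estimate a profile HMM from an aligned family.

    Columns whose gap fraction is <= ``match_gap_threshold`` become match
    states.  Laplace-style ``pseudocount`` is added to emission and
    transition counts.  Insert emissions are fixed to the background
    distribution (zero log-odds), the usual lightweight choice.
    """
    if not msa:
        raise ValueError("empty alignment")
    rows = [r.residues.upper() for r in msa]
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("alignment rows differ in length")
    n = len(rows)
    gap_frac = [sum(r[c] in "-." for r in rows) / n for c in range(width)]
    match_cols = [c for c in range(width) if gap_frac[c] <= match_gap_threshold]
    M = len(match_cols)
    if M == 0:
        raise ValueError("all columns gapped; no match states")
    if M < 2:
        raise ValueError("profile needs at least 2 match columns")

    emit = np.full((M + 1, 20), pseudocount, dtype=float)
    emit[0] = 0.0  # node 0 is the begin state; it never emits
    for k, c in enumerate(match_cols, start=1):
        for r in rows:
            aa = r[c]
            if aa in "-.":
                continue
            i = AA.find(aa)
            if i >= 0:
                emit[k, i] += 1.0
    emit[1:] /= emit[1:].sum(axis=1, keepdims=True)

    # transition counts from each row's path through match/insert columns
    tcounts = {k: np.full(M + 1, pseudocount, dtype=float)
               for k in ("MM", "MI", "MD", "IM", "II", "DM", "DD")}
    match_set = set(match_cols)
    for r in rows:
        state, node = "M", 0  # begin treated as match node 0
        for c in range(width):
            if c in match_set:
                nxt = "D" if r[c] in "-." else "M"
                if state + nxt in tcounts:  # I->D has no plan-7 edge: skip
                    tcounts[state + nxt][node] += 1.0
                state, node = nxt, node + 1
            elif r[c] not in "-.":
                if state + "I" in tcounts:  # D->I likewise unmodelled
                    tcounts[state + "I"][node] += 1.0
                state = "I"
        # path end: implicit exit, not counted (local model)

    trans = {}
    groups = (("MM", "MI", "MD"), ("IM", "II"), ("DM", "DD"))
    for group in groups:
        total = sum(tcounts[k] for k in group)
        total[total == 0] = 1.0
        for k in group:
            trans[k] = tcounts[k] / total
    return ProfileHMM(
        match_emissions=emit,
        insert_emissions=np.tile(BACKGROUND, (M + 1, 1)),
        transitions=trans,
        name=name,
    )


# ---------------------------------------------------------------------------
# Viterbi kernel


@njit
def _viterbi_kernel(emit_lo, tMM, tMI, tMD, tIM, tII, tDM, tDD, seq, entry):
    M = emit_lo.shape[0] - 1
    L = seq.shape[0]
    VM = np.full((M + 1, L + 1), NEG)
    VI = np.full((M + 1, L + 1), NEG)
    VD = np.full((M + 1, L + 1), NEG)
    PM = np.zeros((M + 1, L + 1), dtype=np.int8)
    PI = np.zeros((M + 1, L + 1), dtype=np.int8)
    PD = np.zeros((M + 1, L + 1), dtype=np.int8)
    best = NEG
    best_i = 0
    best_j = 0
    for i in range(1, L + 1):
        x = seq[i - 1]
        for j in range(1, M + 1):
            # match
            s = entry
            p = 0
            v = VM[j - 1, i - 1] + tMM[j - 1]
            if v > s:
                s = v
                p = 1
            v = VI[j - 1, i - 1] + tIM[j - 1]
            if v > s:
                s = v
                p = 2
            v = VD[j - 1, i - 1] + tDM[j - 1]
            if v > s:
                s = v
                p = 3
            VM[j, i] = s + emit_lo[j, x]
            PM[j, i] = p
            # insert (emission log-odds 0)
            s = VM[j, i - 1] + tMI[j]
            p = 1
            v = VI[j, i - 1] + tII[j]
            if v > s:
                s = v
                p = 2
            VI[j, i] = s
            PI[j, i] = p
            # delete
            s = VM[j - 1, i] + tMD[j - 1]
            p = 1
            v = VD[j - 1, i] + tDD[j - 1]
            if v > s:
                s = v
                p = 3
            VD[j, i] = s
            PD[j, i] = p
            if VM[j, i] > best:
                best = VM[j, i]
                best_i = i
                best_j = j
    return best, best_i, best_j, PM, PI, PD


def viterbi(hmm: ProfileHMM, protein: SequenceRecord | str) -> HmmHit:
    """Best local alignment of the profile to one protein, in bits.

    Residues outside the 20-letter alphabet are treated as X (scored at the
    background, log-odds 0) with a warning.
    """
    if isinstance(protein, SequenceRecord):
        pid, seq_str = protein.id, protein.residues
    else:
        pid, seq_str = "query", protein
    if not seq_str:
        raise ValueError("protein must be non-empty")
    if any(c not in AA for c in seq_str.upper()):
        warnings.warn(f"{pid}: non-standard residues treated as X")
    seq = encode_protein(seq_str)
    entry = -np.log2(hmm.M)
    score, bi, bj, PM, PI, PD = _viterbi_kernel(
        hmm.match_log_odds(),
        hmm.transition_log2("MM"), hmm.transition_log2("MI"), hmm.transition_log2("MD"),
        hmm.transition_log2("IM"), hmm.transition_log2("II"),
        hmm.transition_log2("DM"), hmm.transition_log2("DD"),
        seq, entry,
    )
    # traceback from the best match cell to the entry cell
    path: list[tuple[str, int, int]] = []
    state, j, i = "M", int(bj), int(bi)
    while True:
        path.append((state, j, i))
        if state == "M":
            p = PM[j, i]
            if p == 0:
                break
            state = "MID"[p - 1]
            j, i = j - 1, i - 1
        elif state == "I":
            state = "MID"[PI[j, i] - 1]
            i -= 1
        else:  # D
            state = "MID"[PD[j, i] - 1]
            j -= 1
    path.reverse()
    emitted = [i for s, _, i in path if s in "MI"]
    return HmmHit(
        target_id=pid,
        bit_score=float(score),
        evalue=None,
        env_start=min(emitted) - 1,
        env_end=max(emitted),
        path=path,
    )


# ---------------------------------------------------------------------------
# E-value calibration


def calibrate_evalue(hmm: ProfileHMM, n_null: int = 1000, null_length: int = 350,
                     seed: int = 0) -> CalibrationParams:
    """Fit a Gumbel law to Viterbi scores of i.i.d. background sequences.

    E-values are then ``n_targets * P(S >= s)`` under the fit.  Deterministic
    for a fixed seed.  The fitted parameters are attached to the model.
    """
    rng = np.random.default_rng(seed)
    aas = np.array(list(AA))
    scores = np.empty(n_null)
    for k in range(n_null):
        seq = "".join(aas[rng.choice(20, size=null_length, p=BACKGROUND)])
        scores[k] = viterbi(hmm, SequenceRecord(
            id=f"null{k}", description="", residues=seq, alphabet="protein")).bit_score
    if np.ptp(scores) < 1e-12:
        raise ValueError("degenerate null score distribution (zero variance)")
    mu, beta = gumbel_r.fit(scores)
    calib = CalibrationParams(mu=float(mu), lam=float(1.0 / beta),
                              n_null_samples=n_null, null_length=null_length,
                              seed=seed)
    hmm.calibration = calib
    return calib


def search_proteome(hmm: ProfileHMM, proteins: list[SequenceRecord],
                    evalue_threshold: float,
                    calib: CalibrationParams | None = None,
                    n_targets: int | None = None) -> list[HmmHit]:
    """Score every protein; keep hits with E-value < threshold.

    Hits are sorted by E-value ascending, ties broken by target id so runs
    are deterministic.
    """
    calib = calib or hmm.calibration
    if calib is None:
        raise ValueError("model is not calibrated")
    N = n_targets if n_targets is not None else len(proteins)
    hits = []
    for prot in proteins:
        h = viterbi(hmm, prot)
        h.evalue = N * calib.pvalue(h.bit_score)
        if h.evalue < evalue_threshold:
            hits.append(h)
    hits.sort(key=lambda h: (h.evalue, h.target_id))
    return hits


# ---------------------------------------------------------------------------
# two-pass species-specific refinement


def refine_species_model(proteome: list[SequenceRecord], seed_hmm: ProfileHMM,
                         strict: float = 1e-60, relaxed: float = 1e-2,
                         calib_seed: int = 0,
                         ) -> tuple[ProfileHMM, list[HmmHit]]:
    """Strict search -> rebuild a species model from own hits -> relaxed
    re-search of the full proteome.

    Stage 1 searches with the seed model at the strict cutoff; stage 2
    aligns the envelope regions of those high-confidence hits and estimates
    a species-specific model from the alignment (recalibrated); stage 3
    re-searches everything at the relaxed cutoff and returns those hits.
    Falls back to the seed model with a warning when stage 1 yields fewer
    than two hits.
    """
    if strict >= relaxed:
        raise ValueError("strict threshold must be below relaxed threshold")
    if seed_hmm.calibration is None:
        calibrate_evalue(seed_hmm, seed=calib_seed)
    strict_hits = search_proteome(seed_hmm, proteome, strict)
    if len(strict_hits) < 2:
        warnings.warn("strict pass yielded < 2 hits; falling back to seed model")
        species = seed_hmm
    else:
        from .phylo import progressive_align

        by_id = {p.id: p for p in proteome}
        envelopes = [
            SequenceRecord(id=h.target_id, description="",
                           residues=by_id[h.target_id].residues[h.env_start:h.env_end],
                           alphabet="protein")
            for h in strict_hits
        ]
        msa = progressive_align(envelopes)
        species = build_profile(msa.records(), name=seed_hmm.name + "_species")
        calibrate_evalue(species, seed=calib_seed + 1)
    return species, search_proteome(species, proteome, relaxed)


def kinase_filter(candidate_hits: list[HmmHit], proteins: list[SequenceRecord],
                  kinase_hmm: ProfileHMM) -> list[HmmHit]:
    """Drop candidates that look more like protein kinases than NBS domains.

    A hit is removed iff its kinase-model bit score exceeds its NBS-model
    bit score.  This mirrors the manual exclusion of kinase-family proteins
    that score on NB-ARC models through the shared P-loop.
    """
    by_id = {p.id: p for p in proteins}
    retained = []
    for h in candidate_hits:
        k = viterbi(kinase_hmm, by_id[h.target_id])
        if k.bit_score <= h.bit_score:
            retained.append(h)
    return retained


# ---------------------------------------------------------------------------
# versioned TSV serialization (sections: EMIT-M, EMIT-I, TRANS, CALIB)

_FORMAT_VERSION = "1"


def save_profile(hmm: ProfileHMM, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"#nlrforge-profile\tv{_FORMAT_VERSION}\t{hmm.name}\tM={hmm.M}\n")
        fh.write("#EMIT-M\n")
        for k in range(1, hmm.M + 1):
            fh.write("\t".join([str(k)] + [f"{p:.10g}" for p in hmm.match_emissions[k]]) + "\n")
        fh.write("#EMIT-I\n")
        fh.write("\t".join(f"{p:.10g}" for p in hmm.insert_emissions[0]) + "\n")
        fh.write("#TRANS\n")
        keys = sorted(hmm.transitions)
        fh.write("\t".join(["node"] + keys) + "\n")
        for k in range(hmm.M + 1):
            fh.write("\t".join([str(k)] + [f"{hmm.transitions[t][k]:.10g}" for t in keys]) + "\n")
        if hmm.calibration is not None:
            c = hmm.calibration
            fh.write("#CALIB\n")
            fh.write(f"{c.mu:.10g}\t{c.lam:.10g}\t{c.n_null_samples}\t{c.null_length}\t{c.seed}\n")


def load_profile(path: str) -> ProfileHMM:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    header = lines[0].split("\t")
    if not header[0].startswith("#nlrforge-profile") or header[1] != f"v{_FORMAT_VERSION}":
        raise ValueError(f"{path}: not a v{_FORMAT_VERSION} nlrforge profile")
    name = header[2]
    M = int(header[3].split("=")[1])
    sec = {ln: i for i, ln in enumerate(lines) if ln.startswith("#")}
    emit = np.zeros((M + 1, 20))
    i = sec["#EMIT-M"] + 1
    for k in range(1, M + 1):
        emit[k] = [float(x) for x in lines[i].split("\t")[1:]]
        i += 1
    ins = np.tile(np.array([float(x) for x in lines[sec["#EMIT-I"] + 1].split("\t")]),
                  (M + 1, 1))
    i = sec["#TRANS"] + 1
    keys = lines[i].split("\t")[1:]
    trans = {k: np.zeros(M + 1) for k in keys}
    i += 1
    for k in range(M + 1):
        vals = lines[i].split("\t")
        for t, v in zip(keys, vals[1:]):
            trans[t][k] = float(v)
        i += 1
    calib = None
    if "#CALIB" in sec:
        mu, lam, n_null, null_len, seed = lines[sec["#CALIB"] + 1].split("\t")
        calib = CalibrationParams(float(mu), float(lam), int(n_null),
                                  int(null_len), int(seed))
    return ProfileHMM(match_emissions=emit, insert_emissions=ins,
                      transitions=trans, calibration=calib, name=name)
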