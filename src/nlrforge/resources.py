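"""Packaged scoring tables, motif consensi and synthetic seed families.

Everything here is either a field-standard constant (amino-acid background
frequencies, BLOSUM62) or a deterministic synthetic stand-in for an external
resource that a real deployment would download (Pfam seed alignments for
NB-ARC/TIR/LRR/protein-kinase, a curated plant R-protein reference set).
The synthetic families are built around the canonical NLR motif vocabulary —
P-loop (GxGKTT), kinase-2 (hhhhDD followed by W in CC-lineage and D in
TIR-lineage NBS domains), kinase-3a, GLPL, the TIR homology region, LxxLxLxx
leucine-rich repeats and heptad coiled-coils — so every downstream stage
(HMM search, PSSM scans, signature typing, phylogeny) sees realistic
structure while remaining fully reproducible offline.

Three NBS sub-lineages are modelled: CC_I and CC_II (both kinase-2 ...W,
divergent elsewhere — mirroring the two CC clades seen in NLR phylogenies)
and TIR (kinase-2 ...D).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from .io_formats import SequenceRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA)}

# Robinson & Robinson amino-acid background frequencies, AA order as above.
_RR = {
    "A": 0.0788, "C": 0.0198, "D": 0.0538, "E": 0.0632, "F": 0.0385,
    "G": 0.0733, "H": 0.0219, "I": 0.0514, "K": 0.0581, "L": 0.0901,
    "M": 0.0224, "N": 0.0448, "P": 0.0468, "Q": 0.0426, "R": 0.0512,
    "S": 0.0711, "T": 0.0568, "V": 0.0644, "W": 0.0132, "Y": 0.0321,
}
BACKGROUND = np.array([_RR[a] for a in AA])
BACKGROUND /= BACKGROUND.sum()


@lru_cache(maxsize=1)
def blosum62() -> np.ndarray:
    """BLOSUM62 as a 20x20 array in AA order."""
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20))
    for i, a in enumerate(AA):
        for j, b in enumerate(AA):
            out[i, j] = m[a][b]
    return out


# ---------------------------------------------------------------------------
# NLR motif vocabulary

PLOOP = "GMGGLGKTTLARQV"
KINASE2_CC = "KYLVLDDVW"          # CC-lineage signature: terminal tryptophan
KINASE2_TIR = "KYLVLDDVD"         # TIR-lineage signature: terminal aspartate
KINASE3A = "GSRIIITTRD"
GLPL = "AEGGLPLALK"
TIR_CONSENSUS = "VFLSFRGEDTRKTFTSHLYAALKRKGIVTFIDDEELRKGD"
LRR_UNIT = "LSELDLSNNSLSGEIP"
HEPTAD = "LEALKEK"                # one abcdefg repeat: L at a and d

# kinase decoy family: shares a Walker-A/P-loop-like motif with NB-ARC (the
# classic confounder) but carries protein-kinase catalytic motifs instead of
# kinase-2/GLPL.
KINASE_PLOOP = "LGSGSFGKVYA"
KINASE_HRD = "VHRDLKPENL"
KINASE_DFG = "GTPEYMDFGL"
KINASE_APE = "DVWSAGVAPE"


def _rand_peptide(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA), size=n, p=BACKGROUND))


def _fixed_peptide(n: int, seed: int) -> str:
    return _rand_peptide(n, np.random.default_rng(seed))


# per-lineage linker consensi between the NBS motifs (fixed, lineage-specific
# so the sub-profiles and the phylogeny can tell lineages apart).  Lengths are
# identical across lineages so lineage consensi align without gaps.
_LINKER_LENGTHS = (30, 25, 40)
_NBS_LINKERS = {
    "CC_I": tuple(_fixed_peptide(n, 1000 + k) for k, n in enumerate(_LINKER_LENGTHS)),
    "CC_II": tuple(_fixed_peptide(n, 2000 + k) for k, n in enumerate(_LINKER_LENGTHS)),
    "TIR": tuple(_fixed_peptide(n, 3000 + k) for k, n in enumerate(_LINKER_LENGTHS)),
}

_KINASE_LINKERS = tuple(_fixed_peptide(n, 4000 + k) for k, n in enumerate((35, 30, 25)))


def nbs_consensus(lineage: str) -> tuple[str, dict[str, tuple[int, int]]]:
    """Consensus NBS domain for a lineage, with motif offsets.

    Returns the sequence and a dict of 0-based half-open motif spans
    (ploop, kinase2, kinase3a, glpl) relative to the domain start.
    """
    l1, l2, l3 = _NBS_LINKERS[lineage]
    k2 = KINASE2_TIR if lineage == "TIR" else KINASE2_CC
    parts = [PLOOP, l1, k2, l2, KINASE3A, l3, GLPL]
    seq = "".join(parts)
    spans: dict[str, tuple[int, int]] = {}
    pos = 0
    names = ["ploop", None, "kinase2", None, "kinase3a", None, "glpl"]
    for name, part in zip(names, parts):
        if name:
            spans[name] = (pos, pos + len(part))
        pos += len(part)
    return seq, spans


def kinase_consensus() -> str:
    l1, l2, l3 = _KINASE_LINKERS
    return KINASE_PLOOP + l1 + KINASE_HRD + l2 + KINASE_DFG + l3 + KINASE_APE


NBS_CONSENSUS_LENGTH = len(nbs_consensus("CC_I")[0])

# motif spans are conserved harder than linkers when sampling family members
MOTIF_NOISE = 0.03
LINKER_NOISE = 0.10


def mutate(seq: str, rng: np.random.Generator, p: float,
           conserved: list[tuple[int, int]] | None = None,
           p_conserved: float = MOTIF_NOISE) -> str:
    """Substitute residues at rate ``p`` (``p_conserved`` inside spans)."""
    out = list(seq)
    for i in range(len(out)):
        rate = p
        if conserved and any(s <= i < e for s, e in conserved):
            rate = p_conserved
        if rng.random() < rate:
            out[i] = AA[rng.integers(20)]
    return "".join(out)


def sample_nbs(lineage: str, rng: np.random.Generator) -> str:
    seq, spans = nbs_consensus(lineage)
    return mutate(seq, rng, LINKER_NOISE, conserved=list(spans.values()))


def sample_tir(rng: np.random.Generator) -> str:
    return mutate(TIR_CONSENSUS, rng, 0.05)


def sample_lrr(n_units: int, rng: np.random.Generator) -> str:
    units = []
    for _ in range(n_units):
        u = list(LRR_UNIT)
        for i in range(len(u)):
            # leucine scaffold positions are what the repeat PSSM keys on
            if u[i] != "L" and rng.random() < 0.15:
                u[i] = AA[rng.integers(20)]
        units.append("".join(u))
    return "".join(units)


def sample_cc(n_heptads: int, rng: np.random.Generator) -> str:
    """Heptad coiled-coil block; noise preserves the a/d hydrophobic core."""
    core_pool = "LIVM"
    outer_pool = "EKQRA"
    out = []
    for h in range(n_heptads):
        for pos, aa in enumerate(HEPTAD):
            if rng.random() < 0.15:
                aa = (core_pool if pos in (0, 3) else outer_pool)[
                    rng.integers(4 if pos in (0, 3) else 5)
                ]
            out.append(aa)
    return "".join(out)


def sample_kinase(rng: np.random.Generator) -> str:
    seq = kinase_consensus()
    motifs = []
    pos = 0
    for part, is_motif in (
        (KINASE_PLOOP, True), (_KINASE_LINKERS[0], False), (KINASE_HRD, True),
        (_KINASE_LINKERS[1], False), (KINASE_DFG, True),
        (_KINASE_LINKERS[2], False), (KINASE_APE, True),
    ):
        if is_motif:
            motifs.append((pos, pos + len(part)))
        pos += len(part)
    return mutate(seq, rng, LINKER_NOISE, conserved=motifs)


# ---------------------------------------------------------------------------
# seed alignments (ungapped synthetic families, Stockholm-compatible rows)


def _family(name: str, sampler, n: int, seed: int) -> list[SequenceRecord]:
    rng = np.random.default_rng(seed)
    return [
        SequenceRecord(id=f"{name}{i + 1:02d}", description="",
                       residues=sampler(rng), alphabet="protein")
        for i in range(n)
    ]


@lru_cache(maxsize=None)
def seed_alignment(family: str) -> tuple[SequenceRecord, ...]:
    """Packaged synthetic seed alignment for a domain family.

    Families: ``nbarc`` (mixed-lineage NBS), ``cc_sub`` / ``tir_sub``
    (lineage-specific NBS sub-profiles), ``tir``, ``lrr``, ``kinase``.
    All rows are ungapped and equal length, so every column is a match
    column at the default gap threshold.
    """
    if family == "nbarc":
        rng = np.random.default_rng(42)
        rows = []
        for i, lineage in enumerate(["CC_I"] * 5 + ["CC_II"] * 3 + ["TIR"] * 4):
            rows.append(SequenceRecord(
                id=f"nbarc{i + 1:02d}", description="",
                residues=sample_nbs(lineage, rng), alphabet="protein"))
        return tuple(rows)
    if family == "cc_sub":
        rng = np.random.default_rng(43)
        rows = [SequenceRecord(id=f"ccsub{i + 1:02d}", description="",
                               residues=sample_nbs("CC_I" if i < 5 else "CC_II", rng),
                               alphabet="protein")
                for i in range(8)]
        return tuple(rows)
    if family == "tir_sub":
        return tuple(_family("tirsub", lambda r: sample_nbs("TIR", r), 8, 44))
    if family == "tir":
        return tuple(_family("tir", sample_tir, 10, 45))
    if family == "lrr":
        return tuple(_family("lrr", lambda r: sample_lrr(1, r), 12, 46))
    if family == "kinase":
        return tuple(_family("kin", sample_kinase, 10, 47))
    raise KeyError(f"unknown seed family {family!r}")


# ---------------------------------------------------------------------------
# whole-protein construction (shared by the synthetic genome generator and
# the packaged reference set)

CLASS_CODES = ("CNL", "CN", "NL_CC", "N_CC", "TNL", "TN", "NL_TIR", "N_TIR")


def class_traits(code: str) -> dict:
    if code not in CLASS_CODES:
        raise KeyError(f"unknown architecture code {code!r}")
    return {
        "has_cc": code in ("CNL", "CN"),
        "has_tir": code in ("TNL", "TN"),
        "has_lrr": code in ("CNL", "NL_CC", "TNL", "NL_TIR"),
        "signature": "CC" if code in ("CNL", "CN", "NL_CC", "N_CC") else "TIR",
    }


def build_nlr_protein(code: str, rng: np.random.Generator,
                      lineage: str | None = None) -> tuple[str, dict]:
    """Assemble one NLR protein of the given architecture class.

    Returns (sequence, truth) where truth maps domain names to 0-based
    half-open offsets on the protein plus ``lineage`` and ``lrr_unit_len``.
    Domain order follows the canonical strictly-ordered NLR layout:
    [CC|TIR] - NBS(P-loop .. GLPL) - [LRR].
    """
    traits = class_traits(code)
    if lineage is None:
        if traits["signature"] == "TIR":
            lineage = "TIR"
        else:
            lineage = "CC_I" if rng.random() < 0.75 else "CC_II"
    parts: list[str] = []
    truth: dict = {"lineage": lineage, "code": code, "lrr_unit_len": len(LRR_UNIT)}
    pos = 0

    def push(seq: str, name: str | None = None):
        nonlocal pos
        if name:
            truth[name] = (pos, pos + len(seq))
        parts.append(seq)
        pos += len(seq)

    push(_rand_peptide(int(rng.integers(10, 31)), rng))
    if traits["has_cc"]:
        push(sample_cc(int(rng.integers(4, 7)), rng), "cc")
    if traits["has_tir"]:
        push(sample_tir(rng), "tir")
    push(_rand_peptide(int(rng.integers(10, 21)), rng))

    nbs_seq, spans = nbs_consensus(lineage)
    raw = nbs_seq
    nbs_seq = mutate(nbs_seq, rng, LINKER_NOISE, conserved=list(spans.values()))
    # the kinase-2 terminal residue is the lineage signature; keep it fixed
    k2e = spans["kinase2"][1]
    nbs_seq = nbs_seq[:k2e - 1] + raw[k2e - 1] + nbs_seq[k2e:]
    nbs_start = pos
    push(nbs_seq, "nbs")
    for motif, (s, e) in spans.items():
        truth[motif] = (nbs_start + s, nbs_start + e)

    if traits["has_lrr"]:
        push(_rand_peptide(int(rng.integers(15, 26)), rng))
        push(sample_lrr(int(rng.integers(4, 13)), rng), "lrr")
        push(_rand_peptide(int(rng.integers(15, 31)), rng))
    else:
        # longer C-tail keeps the NBS away from the extreme 3' end, matching
        # real short-architecture genes and leaving room for terminal lesions
        push(_rand_peptide(int(rng.integers(40, 81)), rng))
    return "".join(parts), truth


@lru_cache(maxsize=1)
def reference_proteins() -> tuple[SequenceRecord, ...]:
    """Packaged synthetic reference R-protein set.

    Stands in for a curated plant-resistance reference database: two intact
    domain-core NLR exemplars per architecture class (description tag
    ``NLR``; no terminal padding, so alignment coverage against them reads
    directly as domain completeness) plus four
    non-NLR stress/defense proteins (tag ``stress``) that exercise the
    "resistance-like" branch of the flanking-window screen.
    """
    rng = np.random.default_rng(314159)
    out = []
    for code in CLASS_CODES:
        for rep in (1, 2):
            traits = class_traits(code)
            if traits["signature"] == "TIR":
                lineage = "TIR"
            else:
                lineage = "CC_I" if rep == 1 else "CC_II"
            parts = []
            if traits["has_cc"]:
                parts.append(sample_cc(5, rng))
            if traits["has_tir"]:
                parts.append(sample_tir(rng))
            if parts:
                parts.append(_rand_peptide(8, rng))
            parts.append(sample_nbs(lineage, rng))
            if traits["has_lrr"]:
                parts.append(_rand_peptide(10, rng))
                parts.append(sample_lrr(6, rng))
            out.append(SequenceRecord(
                id=f"ref_{code}_{rep}", description=f"NLR {code} reference (synthetic)",
                residues="".join(parts), alphabet="protein"))
    for i, name in enumerate(
            ["dehydrin", "nicotianamine_synthase", "erf_tf", "oligouridylate_bp"]):
        out.append(SequenceRecord(
            id=f"ref_stress_{name}", description="stress reference (synthetic)",
            residues=_rand_peptide(320, rng), alphabet="protein"))
    return tuple(out)


# ---------------------------------------------------------------------------
# coiled-coil heptad propensity table (log2-odds, Lupas-style two-class:
# hydrophobic core positions a/d vs outer positions b,c,e,f,g)

_CORE = {
    "L": 2.2, "I": 1.8, "V": 1.5, "M": 1.3, "F": 0.9, "A": 0.6, "Y": 0.2,
    "C": 0.0, "T": -0.4, "S": -0.7, "W": -0.2, "Q": -0.8, "N": -1.0,
    "K": -1.2, "E": -1.2, "R": -1.1, "H": -0.8, "D": -1.5, "G": -1.8, "P": -4.0,
}
_OUTER = {
    "E": 1.1, "K": 1.1, "Q": 0.9, "R": 0.7, "A": 0.6, "D": 0.4, "S": 0.1,
    "N": 0.2, "T": 0.0, "L": -0.2, "M": -0.1, "H": 0.1, "I": -0.5, "V": -0.5,
    "Y": -0.3, "F": -0.5, "C": -0.6, "W": -0.7, "G": -1.2, "P": -3.0,
}
HEPTAD_CORE_SCORES = np.array([_CORE[a] for a in AA])
HEPTAD_OUTER_SCORES = np.array([_OUTER[a] for a in AA])


def encode_protein(seq: str) -> np.ndarray:
    """Protein string -> int array; 20 marks X/unknown residues."""
    return np.array([AA_INDEX.get(c, 20) for c in seq.upper()], dtype=np.int64)


def encode_dna(seq: str) -> np.ndarray:
    table = {"A": 0, "C": 1, "G": 2, "T": 3}
    return np.array([table.get(c, 4) for c in seq.upper()], dtype=np.int64)
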