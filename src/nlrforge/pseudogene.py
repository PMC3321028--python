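"""Pseudogene detection: frameshift-aware alignment of gene DNA against
intact reference proteins, and disablement cause-calling.

The comparison engine is a local dynamic program over (reference residue x
DNA position) in which one reference residue normally consumes three bases
(scored with BLOSUM62 on the translated codon), may consume two or four
bases at a frameshift penalty (switching reading frame), and affine gaps
skip whole codons on either axis.  Stop codons score at the BLOSUM62
mismatch floor and are recorded as premature-stop events; frame switches
are recorded as frameshift events.  A gene's disablement cause is then
called by priority: scaffold-end truncation > premature stop > frameshift >
partial deletion (low reference coverage) > intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, inf

import numpy as np
from numba import njit

from .io_formats import SequenceRecord, translate_cds
from .resources import AA, AA_INDEX, blosum62, encode_dna

__all__ = [
    "FrameshiftAlignment",
    "PseudogeneCall",
    "align_protein_to_dna",
    "call_pseudogene",
]

STOP_SCORE = -4.0   # BLOSUM62 minimum: a stop is as bad as the worst mismatch

# codon (base-4 index) -> amino-acid index; 20 = stop, 21 = ambiguous
_CODON_AA = np.full(64, 21, dtype=np.int64)
_B = {"A": 0, "C": 1, "G": 2, "T": 3}
_T = {"TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
      "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
      "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
      "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
      "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
      "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
      "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
      "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
      "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
      "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
      "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G"}
for _codon, _aa in _T.items():
    _idx = 16 * _B[_codon[0]] + 4 * _B[_codon[1]] + _B[_codon[2]]
    _CODON_AA[_idx] = 20 if _aa == "*" else AA_INDEX[_aa]


def _score_table() -> np.ndarray:
    """(20 ref aa) x (22 codon classes) substitution scores."""
    tab = np.zeros((20, 22))
    tab[:, :20] = blosum62()
    tab[:, 20] = STOP_SCORE
    tab[:, 21] = 0.0
    return tab


@dataclass
class FrameshiftAlignment:
    """Local alignment blocks plus disablement events.

    Blocks are maximal constant-frame runs: ((ref_start, ref_end),
    (dna_start, dna_end), frame).  Events are (kind, dna position, codon
    index) with kind 'frameshift' or 'premature_stop'.
    """

    blocks: list[tuple[tuple[int, int], tuple[int, int], int]]
    events: list[tuple[str, int, int]]
    score: float
    ref_span: tuple[int, int] = (0, 0)
    dna_span: tuple[int, int] = (0, 0)

    @property
    def frameshifts(self):
        return [e for e in self.events if e[0] == "frameshift"]

    @property
    def premature_stops(self):
        return [e for e in self.events if e[0] == "premature_stop"]


@dataclass
class PseudogeneCall:
    gene_id: str
    cause: str                      # intact | premature_stop | frameshift |
                                    # deletion_partial | scaffold_end | unclassifiable
    breakpoint_codon: int | None = None
    reference: str = ""
    score: float = 0.0
    ref_coverage: float = 0.0

    def __post_init__(self) -> None:
        if self.cause == "intact" and self.breakpoint_codon is not None:
            raise ValueError("intact call cannot carry a breakpoint")


# ---------------------------------------------------------------------------
# DP kernel
#
# F[u, v]: best local score with u reference residues and v DNA bases
# consumed.  Pointer codes for F: 0 reset, 1 codon from v-3, 2 codon from
# v-2 (frameshift), 3 codon from v-4 (frameshift), 4 protein-side gap (Ep),
# 5 DNA-side gap (Ed).


@njit
def _fs_kernel(ref, codons, score_tab, gap_open, gap_extend, fs_pen):
    P = ref.shape[0]
    D = codons.shape[0] + 2  # codons[k] encodes bases k, k+1, k+2
    NEGI = -1.0e30
    F = np.zeros((P + 1, D + 1))
    Ep = np.full((P + 1, D + 1), NEGI)
    Ed = np.full((P + 1, D + 1), NEGI)
    PF = np.zeros((P + 1, D + 1), dtype=np.int8)
    PEp = np.zeros((P + 1, D + 1), dtype=np.int8)
    PEd = np.zeros((P + 1, D + 1), dtype=np.int8)
    best = 0.0
    bu = 0
    bv = 0
    for u in range(1, P + 1):
        a = ref[u - 1]
        for v in range(D + 1):
            # protein-side gap (reference residue unmatched, no DNA)
            e1 = F[u - 1, v] - gap_open
            e2 = Ep[u - 1, v] - gap_extend
            if e1 >= e2:
                Ep[u, v] = e1
                PEp[u, v] = 0
            else:
                Ep[u, v] = e2
                PEp[u, v] = 1
            # DNA-side gap (one codon skipped)
            if v >= 3:
                d1 = F[u, v - 3] - gap_open
                d2 = Ed[u, v - 3] - gap_extend
                if d1 >= d2:
                    Ed[u, v] = d1
                    PEd[u, v] = 0
                else:
                    Ed[u, v] = d2
                    PEd[u, v] = 1
            h = 0.0
            p = 0
            if v >= 3:
                s = F[u - 1, v - 3] + score_tab[a, codons[v - 3]]
                if s > h:
                    h = s
                    p = 1
                s = F[u - 1, v - 2] + score_tab[a, codons[v - 3]] - fs_pen
                if s > h:
                    h = s
                    p = 2
            if v >= 4:
                s = F[u - 1, v - 4] + score_tab[a, codons[v - 3]] - fs_pen
                if s > h:
                    h = s
                    p = 3
            if Ep[u, v] > h:
                h = Ep[u, v]
                p = 4
            if Ed[u, v] > h:
                h = Ed[u, v]
                p = 5
            F[u, v] = h
            PF[u, v] = p
            if h > best:
                best = h
                bu = u
                bv = v
    return best, bu, bv, PF, PEp, PEd


def align_protein_to_dna(reference_protein: SequenceRecord | str, dna: str,
                         gap_open: float = 11.0, gap_extend: float = 1.0,
                         frameshift_penalty: float = 12.0,
                         ) -> FrameshiftAlignment:
    """Best local frameshift-aware alignment of a protein to a DNA strand."""
    ref_str = (reference_protein.residues
               if isinstance(reference_protein, SequenceRecord)
               else reference_protein)
    if len(dna) < 3:
        raise ValueError("DNA must be at least one codon long")
    ref = np.array([AA_INDEX.get(c, 0) for c in ref_str.upper()], dtype=np.int64)
    d = encode_dna(dna)
    nc = len(d) - 2
    codons = np.full(max(nc, 1), 21, dtype=np.int64)
    for k in range(nc):
        if d[k] < 4 and d[k + 1] < 4 and d[k + 2] < 4:
            codons[k] = _CODON_AA[16 * d[k] + 4 * d[k + 1] + d[k + 2]]
    best, bu, bv, PF, PEp, PEd = _fs_kernel(
        ref, codons, _score_table(), float(gap_open), float(gap_extend),
        float(frameshift_penalty))

    # traceback
    moves = []  # (pointer, u, v) for F-cells along the path
    state = "F"
    u, v = int(bu), int(bv)
    start_u, start_v = u, v
    while u > 0 or v > 0:
        if state == "F":
            p = PF[u, v]
            if p == 0:
                break
            moves.append((p, u, v))
            if p == 1:
                u, v = u - 1, v - 3
            elif p == 2:
                u, v = u - 1, v - 2
            elif p == 3:
                u, v = u - 1, v - 4
            elif p == 4:
                state = "Ep"
            else:
                state = "Ed"
        elif state == "Ep":
            nxt = PEp[u, v]
            u -= 1
            state = "F" if nxt == 0 else "Ep"
        else:
            nxt = PEd[u, v]
            v -= 3
            state = "F" if nxt == 0 else "Ed"
        start_u, start_v = u, v
    moves.reverse()

    events: list[tuple[str, int, int]] = []
    blocks: list[tuple[tuple[int, int], tuple[int, int], int]] = []
    cur = None  # [ref_s, ref_e, dna_s, dna_e, frame]
    for p, u, v in moves:
        if p in (1, 2, 3):
            frame = v % 3
            consumed = {1: 3, 2: 2, 3: 4}[p]
            if p in (2, 3):
                events.append(("frameshift", v - 3, (v - 3) // 3))
            if codons[v - 3] == 20:
                events.append(("premature_stop", v - 3, (v - 3) // 3))
            if cur is not None and cur[4] == frame and cur[1] == u - 1 and p == 1:
                cur[1] = u
                cur[3] = v
            else:
                if cur is not None:
                    blocks.append(((cur[0], cur[1]), (cur[2], cur[3]), cur[4]))
                cur = [u - 1, u, v - consumed, v, frame]
        else:
            if cur is not None:
                blocks.append(((cur[0], cur[1]), (cur[2], cur[3]), cur[4]))
                cur = None
    if cur is not None:
        blocks.append(((cur[0], cur[1]), (cur[2], cur[3]), cur[4]))
    return FrameshiftAlignment(
        blocks=blocks, events=sorted(events, key=lambda e: e[1]),
        score=float(best),
        ref_span=(start_u, int(bu)), dna_span=(start_v, int(bv)))


# ---------------------------------------------------------------------------
# cause calling


def _kmer_set(s: str, k: int = 4) -> set[str]:
    return {s[i:i + k] for i in range(len(s) - k + 1)}


def call_pseudogene(gene_id: str, gene_dna: str,
                    reference_set: list[SequenceRecord],
                    coverage_threshold: float = 0.8,
                    end_distance: tuple[float, float] = (inf, inf),
                    evalue_cutoff: float = 1e-5,
                    scaffold_end_margin: int = 500,
                    n_candidates: int = 4) -> PseudogeneCall:
    """Call the disablement cause of one gene from its (spliced) CDS DNA.

    The best reference is chosen by alignment score among the
    ``n_candidates`` references sharing most protein 4-mers with the gene's
    frame translations (ties by reference id).  ``end_distance`` gives the
    distance (bp) from the gene's 5' and 3' CDS ends to the scaffold
    termini, in the orientation of ``gene_dna``.
    """
    trans = [translate_cds(gene_dna[f:]) for f in range(3)]
    gene_kmers = set().union(*(_kmer_set(t) for t in trans))
    ranked = sorted(reference_set,
                    key=lambda r: (-len(_kmer_set(r.residues) & gene_kmers), r.id))
    alns = [(align_protein_to_dna(ref, gene_dna), ref)
            for ref in ranked[:n_candidates]]
    top = max(a.score for a, _ in alns)
    # among near-tie scores prefer the reference the gene explains best
    # (highest reference coverage): a shorter same-family reference should
    # win over a longer one whose extra domains simply fail to align
    best_aln, best_ref = min(
        ((a, r) for a, r in alns if a.score >= 0.9 * top),
        key=lambda ar: (-(ar[0].ref_span[1] - ar[0].ref_span[0]) / len(ar[1].residues),
                        -ar[0].score, ar[1].id))
    # Karlin-Altschul style significance on the alignment score
    m = len(best_ref.residues)
    n = max(1, len(gene_dna) // 3)
    evalue = 0.041 * m * n * exp(-0.267 * best_aln.score)
    if evalue > evalue_cutoff:
        return PseudogeneCall(gene_id=gene_id, cause="unclassifiable")

    rs, re_ = best_aln.ref_span
    coverage = (re_ - rs) / m
    # scaffold-end: gene at a scaffold terminus and the alignment truncated
    # on that side
    d5, d3 = end_distance
    truncated_3 = re_ < m - 2
    truncated_5 = rs > 2
    if (d3 <= scaffold_end_margin and truncated_3) or \
       (d5 <= scaffold_end_margin and truncated_5):
        v = best_aln.dna_span[1] if d3 <= scaffold_end_margin else best_aln.dna_span[0]
        return PseudogeneCall(gene_id=gene_id, cause="scaffold_end",
                              breakpoint_codon=v // 3, reference=best_ref.id,
                              score=best_aln.score, ref_coverage=coverage)
    if best_aln.premature_stops:
        kind, pos, codon = best_aln.premature_stops[0]
        return PseudogeneCall(gene_id=gene_id, cause="premature_stop",
                              breakpoint_codon=codon, reference=best_ref.id,
                              score=best_aln.score, ref_coverage=coverage)
    if best_aln.frameshifts:
        kind, pos, codon = best_aln.frameshifts[0]
        return PseudogeneCall(gene_id=gene_id, cause="frameshift",
                              breakpoint_codon=codon, reference=best_ref.id,
                              score=best_aln.score, ref_coverage=coverage)
    if coverage < coverage_threshold:
        return PseudogeneCall(gene_id=gene_id, cause="deletion_partial",
                              breakpoint_codon=best_aln.dna_span[1] // 3,
                              reference=best_ref.id, score=best_aln.score,
                              ref_coverage=coverage)
    return PseudogeneCall(gene_id=gene_id, cause="intact", reference=best_ref.id,
                          score=best_aln.score, ref_coverage=coverage)
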