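"""Physical mapping: anchoring, cluster/singleton analysis, flanking-window
recovery of NBS-derived genes, and distribution tables.

Genes are lifted from scaffold coordinates to pseudomolecule (chromosome)
coordinates through an AGP-like anchor table; clusters are single-linkage
chains of NBS genes whose start-to-start distance is at most 100 kb (the
distance inside which >90% of NBS pseudogenes sit next to another NBS gene);
"alone" genes are further than 3 Mb from any other NBS gene on their
chromosome.  Scaffolds carrying two NBS genes get a 100-kb flanking window,
three or more a 200-kb window; ORFs extracted from the windows are screened
against a packaged reference R-protein set (Smith-Waterman with
Karlin-Altschul E-values) to recover NBS-derived genes that the HMM search
cannot see.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import AnchorTable, GeneModel, SequenceRecord, reverse_complement, translate_cds

__all__ = [
    "AnchoredGene",
    "GeneCluster",
    "FlankWindow",
    "Orf",
    "anchor_genes",
    "detect_clusters",
    "super_clusters",
    "find_singletons",
    "flanking_windows",
    "extract_orfs",
    "screen_nbs_derived",
    "distribution_table",
    "write_clusters_bed",
]

UNANCHORED = "-"
CNL_BRANCH = {"CNL", "CN", "NL_CC", "N_CC"}
TNL_BRANCH = {"TNL", "TN", "NL_TIR", "N_TIR"}


@dataclass
class AnchoredGene:
    gene_id: str
    chromosome: str            # UNANCHORED sentinel when not placed
    start: int                 # 0-based half-open on chromosome
    end: int
    strand: str
    architecture: str = ""
    pseudogene: bool = False
    scaffold: str = ""

    @property
    def anchored(self) -> bool:
        return self.chromosome != UNANCHORED


@dataclass
class GeneCluster:
    cluster_id: str
    chromosome: str
    members: list[str]         # gene ids, chromosome order
    span: tuple[int, int]
    composition: str           # simple_CNL | simple_TNL | mixed

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("cluster needs >= 2 members")


@dataclass
class FlankWindow:
    scaffold_id: str
    start: int
    end: int
    triggering: list[str] = field(default_factory=list)


@dataclass
class Orf:
    orf_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    protein: str


# ---------------------------------------------------------------------------


def anchor_genes(genes: list[GeneModel], anchor_table: AnchorTable,
                 architecture: dict[str, str] | None = None,
                 pseudogene: dict[str, bool] | None = None) -> list[AnchoredGene]:
    """Lift genes to chromosome coordinates.

    Forward placement: chr_start = offset + scaffold_start.  Reverse
    placement mirrors within the scaffold (chr_start = offset +
    scaffold_length - scaffold_end) and flips the strand.  Genes on
    scaffolds absent from the table come back with the unanchored sentinel.
    """
    architecture = architecture or {}
    pseudogene = pseudogene or {}
    out = []
    for g in genes:
        row = anchor_table.lookup(g.seqid)
        if row is None:
            out.append(AnchoredGene(g.gene_id, UNANCHORED, g.start, g.end, g.strand,
                                    architecture.get(g.gene_id, ""),
                                    pseudogene.get(g.gene_id, False), g.seqid))
            continue
        _, chrom, offset, orient, scaf_len = row
        if g.end > scaf_len:
            raise ValueError(f"{g.gene_id} extends past scaffold {g.seqid} length")
        if orient == "+":
            s, e, strand = offset + g.start, offset + g.end, g.strand
        else:
            s = offset + (scaf_len - g.end)
            e = offset + (scaf_len - g.start)
            strand = "-" if g.strand == "+" else "+"
        out.append(AnchoredGene(g.gene_id, chrom, s, e, strand,
                                architecture.get(g.gene_id, ""),
                                pseudogene.get(g.gene_id, False), g.seqid))
    return out


def detect_clusters(anchored: list[AnchoredGene], max_gap: int = 100_000,
                    ) -> tuple[list[GeneCluster], list[AnchoredGene]]:
    """Single-linkage chaining per chromosome.

    Consecutive genes (sorted by start) whose start-to-start gap is at most
    ``max_gap`` join one cluster; chains of length one are singletons.
    Composition is labelled from member architecture codes (simple_CNL /
    simple_TNL / mixed).  Input order does not matter.
    """
    by_chrom: dict[str, list[AnchoredGene]] = {}
    for g in anchored:
        if g.anchored:
            by_chrom.setdefault(g.chromosome, []).append(g)
    clusters: list[GeneCluster] = []
    singletons: list[AnchoredGene] = []
    cid = 0
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        chain = [genes[0]]
        for g in genes[1:]:
            if g.start - chain[-1].start <= max_gap:
                chain.append(g)
            else:
                cid = _emit(chain, chrom, cid, clusters, singletons)
                chain = [g]
        cid = _emit(chain, chrom, cid, clusters, singletons)
    return clusters, singletons


def _emit(chain, chrom, cid, clusters, singletons) -> int:
    if len(chain) == 1:
        singletons.append(chain[0])
        return cid
    codes = {g.architecture for g in chain if g.architecture in CNL_BRANCH | TNL_BRANCH}
    if codes and codes <= CNL_BRANCH:
        comp = "simple_CNL"
    elif codes and codes <= TNL_BRANCH:
        comp = "simple_TNL"
    else:
        comp = "mixed"
    cid += 1
    clusters.append(GeneCluster(
        cluster_id=f"C{cid:03d}", chromosome=chrom,
        members=[g.gene_id for g in chain],
        span=(chain[0].start, max(g.end for g in chain)),
        composition=comp))
    return cid


def super_clusters(clusters: list[GeneCluster], max_span_gap: int = 500_000,
                   ) -> list[list[str]]:
    """Groups of clusters whose spans lie within ``max_span_gap`` of each
    other on the same chromosome (reported separately from clusters)."""
    by_chrom: dict[str, list[GeneCluster]] = {}
    for c in clusters:
        by_chrom.setdefault(c.chromosome, []).append(c)
    out = []
    for chrom in sorted(by_chrom):
        cs = sorted(by_chrom[chrom], key=lambda c: c.span[0])
        group = [cs[0]]
        for c in cs[1:]:
            if c.span[0] - group[-1].span[1] <= max_span_gap:
                group.append(c)
            else:
                if len(group) > 1:
                    out.append([g.cluster_id for g in group])
                group = [c]
        if len(group) > 1:
            out.append([g.cluster_id for g in group])
    return out


def find_singletons(anchored: list[AnchoredGene], min_dist: int = 3_000_000,
                    ) -> list[AnchoredGene]:
    """Genes "alone": strictly further than ``min_dist`` (start-to-start)
    from every other NBS gene on their chromosome, or sole gene there."""
    by_chrom: dict[str, list[AnchoredGene]] = {}
    for g in anchored:
        if g.anchored:
            by_chrom.setdefault(g.chromosome, []).append(g)
    alone = []
    for genes in by_chrom.values():
        genes = sorted(genes, key=lambda g: g.start)
        for i, g in enumerate(genes):
            dists = []
            if i > 0:
                dists.append(g.start - genes[i - 1].start)
            if i + 1 < len(genes):
                dists.append(genes[i + 1].start - g.start)
            if not dists or min(dists) > min_dist:
                alone.append(g)
    return sorted(alone, key=lambda g: (g.chromosome, g.start))


# ---------------------------------------------------------------------------
# flanking windows and the NBS-derived screen


def flanking_windows(scaffold_genes: dict[str, list[GeneModel]],
                     nbs_ids: set[str],
                     scaffold_lengths: dict[str, int],
                     flank_small: int = 100_000,
                     flank_large: int = 200_000) -> list[FlankWindow]:
    """Windows around NBS gene spans, per scaffold.

    Scaffolds with fewer than two NBS genes are skipped; exactly two get a
    ``flank_small`` window around the outermost NBS boundaries, three or
    more get ``flank_large``.  Windows clip at scaffold bounds.
    """
    out = []
    for scaf in sorted(scaffold_genes):
        nbs = [g for g in scaffold_genes[scaf] if g.gene_id in nbs_ids]
        if len(nbs) < 2:
            continue
        flank = flank_small if len(nbs) == 2 else flank_large
        lo = min(g.start for g in nbs)
        hi = max(g.end for g in nbs)
        out.append(FlankWindow(
            scaffold_id=scaf,
            start=max(0, lo - flank),
            end=min(scaffold_lengths[scaf], hi + flank),
            triggering=[g.gene_id for g in nbs]))
    return out


def extract_orfs(scaffold_seq: str, window: FlankWindow,
                 min_codons: int = 80) -> list[Orf]:
    """ATG-to-stop ORFs of >= ``min_codons`` codons, three frames, both
    strands, within the window."""
    region = scaffold_seq[window.start:window.end]
    out = []
    n = 0
    for strand in "+-":
        seq = region if strand == "+" else reverse_complement(region)
        for frame in range(3):
            prot = translate_cds(seq[frame:])
            i = 0
            while True:
                m = prot.find("M", i)
                if m < 0:
                    break
                stop = prot.find("*", m)
                if stop < 0:
                    break
                if stop - m >= min_codons:
                    n += 1
                    s_local = frame + 3 * m
                    e_local = frame + 3 * (stop + 1)
                    if strand == "+":
                        s, e = window.start + s_local, window.start + e_local
                    else:
                        s = window.start + len(region) - e_local
                        e = window.start + len(region) - s_local
                    out.append(Orf(
                        orf_id=f"{window.scaffold_id}_orf{n:03d}",
                        scaffold_id=window.scaffold_id, start=s, end=e,
                        strand=strand, protein=prot[m:stop]))
                i = stop + 1
    return out


# Karlin-Altschul parameters for gapped BLOSUM62 (open 11 / extend 1)
_KA_LAMBDA = 0.267
_KA_K = 0.041


def _sw_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


def _sw_stats(aligner, query: str, ref: str):
    """(evalue, identity fraction, reference coverage) of the best local
    alignment."""
    try:
        aln = aligner.align(query.replace("*", "X"), ref)[0]
    except (IndexError, ValueError):
        return 1e9, 0.0, 0.0
    score = aln.score
    e = _KA_K * len(query) * len(ref) * np.exp(-_KA_LAMBDA * score)
    q_blocks, r_blocks = aln.aligned  # first sequence (query here) is the target
    matched = ref_cov = 0
    ident = 0
    for (qs, qe), (rs, re_) in zip(q_blocks, r_blocks):
        ref_cov += re_ - rs
        for k in range(qe - qs):
            matched += 1
            if aln.target[qs + k] == aln.query[rs + k]:
                ident += 1
    identity = ident / matched if matched else 0.0
    return float(e), identity, ref_cov / len(ref)


def screen_nbs_derived(window_orfs: list[Orf],
                       reference_proteins: list[SequenceRecord],
                       nbs_hmm=None,
                       known_gene_spans: list[tuple[str, int, int]] | None = None,
                       evalue_cutoff: float = 1e-5,
                       min_identity: float = 0.30,
                       min_ref_coverage: float = 0.50,
                       partial_threshold: float = 0.5,
                       nbs_min_bits: float = 25.0) -> pd.DataFrame:
    """Classify window ORFs by homology to the packaged reference set.

    An ORF homologous to an NLR reference (E <= cutoff, identity and
    reference-coverage criteria) is called ``NBS-derived`` when it shows no
    NBS-model signal, ``partial_NBS`` when the model coverage is below
    ``partial_threshold``, and ``NBS`` otherwise; ORFs homologous only to
    non-NLR stress references are ``resistance_like``.  ORFs overlapping
    already-annotated NBS genes (``known_gene_spans``) are skipped.
    """
    from .profile_hmm import viterbi

    known = known_gene_spans or []
    aligner = _sw_aligner()
    rows = []
    for orf in window_orfs:
        if any(sc == orf.scaffold_id and orf.start < e and s < orf.end
               for sc, s, e in known):
            continue
        best = None  # (evalue, ref)
        for ref in reference_proteins:
            e, ident, cov = _sw_stats(aligner, orf.protein, ref.residues)
            if e <= evalue_cutoff and ident >= min_identity and cov >= min_ref_coverage:
                if best is None or e < best[0]:
                    best = (e, ref)
        if best is None:
            continue
        ref = best[1]
        is_nlr = ref.description.startswith("NLR")
        if not is_nlr:
            call = "resistance_like"
            coverage = 0.0
        else:
            coverage = 0.0
            if nbs_hmm is not None:
                h = viterbi(nbs_hmm, SequenceRecord(
                    id=orf.orf_id, description="", residues=orf.protein,
                    alphabet="protein"))
                if h.bit_score >= nbs_min_bits:
                    coverage = h.model_nodes_covered / nbs_hmm.M
            if coverage == 0.0:
                call = "NBS_derived"
            elif coverage < partial_threshold:
                call = "partial_NBS"
            else:
                call = "NBS"
        rows.append({"orf_id": orf.orf_id, "scaffold": orf.scaffold_id,
                     "start": orf.start, "end": orf.end, "strand": orf.strand,
                     "call": call, "best_reference": ref.id,
                     "evalue": best[0], "nbs_coverage": coverage})
    return pd.DataFrame(rows, columns=["orf_id", "scaffold", "start", "end",
                                       "strand", "call", "best_reference",
                                       "evalue", "nbs_coverage"])


# ---------------------------------------------------------------------------
# reporting helpers


def distribution_table(anchored: list[AnchoredGene], bin_size: int = 1_000_000,
                       ) -> pd.DataFrame:
    """Per-chromosome, per-Mb gene counts (chromosome track data)."""
    rows = []
    for g in anchored:
        if g.anchored:
            rows.append({"chromosome": g.chromosome, "bin": g.start // bin_size,
                         "architecture": g.architecture,
                         "pseudogene": g.pseudogene})
    if not rows:
        return pd.DataFrame(columns=["chromosome", "bin", "n_genes", "n_pseudogenes"])
    df = pd.DataFrame(rows)
    out = (df.groupby(["chromosome", "bin"])
             .agg(n_genes=("architecture", "size"), n_pseudogenes=("pseudogene", "sum"))
             .reset_index())
    return out


def write_clusters_bed(clusters: list[GeneCluster], path: str) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            fh.write(f"{c.chromosome}\t{c.span[0]}\t{c.span[1]}\t"
                     f"{c.cluster_id}\t{len(c.members)}\t{c.composition}\n")
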