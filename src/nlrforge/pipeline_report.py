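"""End-to-end pipeline orchestration and summary tables.

Stage order mirrors the annotation workflow: two-pass profile-HMM search of
the proteome -> kinase exclusion -> domain scans and architecture
classification -> anchoring to pseudomolecules -> cluster/singleton
analysis -> flanking-window ORF screen for NBS-derived genes -> pseudogene
cause-calling -> NBS-domain phylogeny with clade labels -> summary tables
(architecture counts with CNL-/TNL-type subtotals, per-chromosome
pseudogene distribution with percentages) and an optional in-silico PCR
primer screen.

All numeric thresholds live in :class:`PipelineConfig` and are echoed to
the run log.  Percentages round half-up at the requested precision.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from . import domain_arch as da
from . import genome_map as gm
from . import phylo as ph
from . import profile_hmm as hm
from .io_formats import SequenceRecord, write_newick
from .resources import reference_proteins, seed_alignment
from .synthetic_genome import SyntheticGenome, load_genome

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "ArchitectureTable",
    "PseudogeneTable",
    "PrimerPair",
    "EXAMPLE_PRIMERS",
    "run_pipeline",
    "architecture_summary",
    "pseudogene_summary",
    "ratio_report",
    "percent",
    "epcr_screen",
]

CODE_ORDER = ("CNL", "CN", "NL_CC", "N_CC", "TNL", "TN", "NL_TIR", "N_TIR")


@dataclass
class PipelineConfig:
    strict_evalue: float = 1e-60
    relaxed_evalue: float = 1e-2
    cc_prob_threshold: float = 0.9
    cc_validation_cutoff: float = 0.025
    cluster_max_gap: int = 100_000
    flank_small: int = 100_000
    flank_large: int = 200_000
    singleton_min_dist: int = 3_000_000
    bootstrap_replicates: int = 500
    partial_nbs_threshold: float = 0.5
    min_nbs_subdomains: int = 2  # automated stand-in for manual curation of
                                 # borderline statistical hits
    epcr_max_mismatch: int = 3
    epcr_max_gaps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        positive = ("strict_evalue", "relaxed_evalue", "cc_prob_threshold",
                    "cluster_max_gap", "flank_small", "flank_large",
                    "singleton_min_dist", "bootstrap_replicates",
                    "partial_nbs_threshold")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.strict_evalue >= self.relaxed_evalue:
            raise ValueError("strict_evalue must be below relaxed_evalue")


@dataclass
class PrimerPair:
    """A PCR primer pair, both sequences 5'->3'."""

    name: str
    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if len(seq) < 15 or set(seq) - set("ACGT"):
                raise ValueError(f"{self.name}: primers must be ACGT, length >= 15")


# example primer pairs from a TMV-resistance-gene splicing assay; the
# default e-PCR fixture
EXAMPLE_PRIMERS = [
    PrimerPair("red", "TAATTGTATTCACGGAAGATTATGGA", "TCAAGAACTACAAGATTTTCATGAGG"),
    PrimerPair("black", "CTGCTGAAATACAGAATCTCATTGAT", "ATTTGTTACTTTGTTCAGTGATCTGC"),
    PrimerPair("orange", "AGAATCTATTGAAGGGCTTGTTCTT", "GTCAATATTCACGGGGTCACTC"),
]


@dataclass
class ArchitectureTable:
    counts: dict[str, int]
    cnl_subtotal: int
    tnl_subtotal: int
    total: int
    partial: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"code": c, "count": self.counts.get(c, 0)} for c in CODE_ORDER[:4]]
        rows.append({"code": "Total CNL type", "count": self.cnl_subtotal})
        rows += [{"code": c, "count": self.counts.get(c, 0)} for c in CODE_ORDER[4:]]
        rows.append({"code": "Total TNL type", "count": self.tnl_subtotal})
        rows.append({"code": "Total", "count": self.total})
        rows.append({"code": "Partial NBS genes", "count": self.partial})
        return pd.DataFrame(rows)


@dataclass
class PseudogeneTable:
    frame: pd.DataFrame  # columns: chromosome, total_genes, pseudogenes, percent


def percent(numerator: int, denominator: int, decimals: int = 2) -> float:
    """100*a/b rounded half-up to ``decimals`` places."""
    if denominator == 0:
        raise ZeroDivisionError("zero denominator")
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(100 * numerator) / Decimal(denominator))
                 .quantize(q, rounding=ROUND_HALF_UP))


def architecture_summary(codes: list[str]) -> ArchitectureTable:
    """Tabulate architecture calls with CNL-/TNL-type subtotals.

    The grand total covers the eight full codes; PARTIAL calls are counted
    separately (the 'partial NBS genes' row of the table).
    """
    counts = {c: 0 for c in CODE_ORDER}
    partial = 0
    for code in codes:
        code = getattr(code, "code", code)
        if code == "PARTIAL":
            partial += 1
        elif code in counts:
            counts[code] += 1
        else:
            raise ValueError(f"unknown architecture code {code!r}")
    cnl = sum(counts[c] for c in CODE_ORDER[:4])
    tnl = sum(counts[c] for c in CODE_ORDER[4:])
    return ArchitectureTable(counts=counts, cnl_subtotal=cnl, tnl_subtotal=tnl,
                             total=cnl + tnl, partial=partial)


def pseudogene_summary(records: pd.DataFrame) -> PseudogeneTable:
    """Per-chromosome pseudogene distribution.

    ``records`` needs columns gene_id, chromosome (unanchored sentinel '-')
    and pseudogene (bool).  Output rows: each chromosome, the '-' row for
    unanchored genes, and a Total row; percentages to 2 dp, half-up.
    """
    df = records.copy()
    rows = []
    chroms = sorted((c for c in df.chromosome.unique() if c != gm.UNANCHORED),
                    key=lambda c: (len(c), c))
    for chrom in chroms + [gm.UNANCHORED]:
        sub = df[df.chromosome == chrom]
        if sub.empty and chrom == gm.UNANCHORED:
            continue
        tot, ps = len(sub), int(sub.pseudogene.sum())
        rows.append({"chromosome": chrom, "total_genes": tot, "pseudogenes": ps,
                     "percent": percent(ps, tot) if tot else 0.0})
    tot, ps = len(df), int(df.pseudogene.sum())
    rows.append({"chromosome": "Total", "total_genes": tot, "pseudogenes": ps,
                 "percent": percent(ps, tot) if tot else 0.0})
    return PseudogeneTable(frame=pd.DataFrame(rows))


def ratio_report(counts: dict[str, tuple[int, int, int]]) -> dict[str, float]:
    """Named percentages: {name: (numerator, denominator, decimals)}."""
    return {name: percent(a, b, dp) for name, (a, b, dp) in counts.items()}


# ---------------------------------------------------------------------------
# in-silico PCR


def _binding_end_positions(template: str, primer: str, max_mismatch: int,
                           max_gaps: int) -> dict[int, tuple[int, int]]:
    """End positions where the primer binds within the edit budget.

    At each template position the primer's minimum-edit alignment (fewest
    substitutions + indels; ties toward fewer indels) is evaluated; the
    position binds iff that alignment carries at most ``max_mismatch``
    substitutions and at most ``max_gaps`` indels, budgeted separately.
    Returns {end_position: (mismatches, gaps)}.  Semi-global DP:
    D[j][g][t] = min substitutions aligning the first j primer bases ending
    at template position t with exactly g indels.
    """
    L = len(template)
    m = len(primer)
    t_arr = np.frombuffer(template.encode(), dtype=np.uint8)
    p_arr = np.frombuffer(primer.encode(), dtype=np.uint8)
    BIG = 10**6
    # indel dimension must reach past max_gaps so the true minimum-edit
    # alignment is found even when it overspends the gap budget
    G = max_gaps + max_mismatch
    prev = np.zeros((G + 1, L + 1), dtype=np.int64)  # j = 0: free start
    for j in range(1, m + 1):
        cur = np.full((G + 1, L + 1), BIG, dtype=np.int64)
        sub = np.where(p_arr[j - 1] == t_arr, 0, 1)
        for g in range(G + 1):
            cur[g, 1:] = prev[g, :-1] + sub                   # (mis)match
            if g > 0:
                np.minimum(cur[g], prev[g - 1], out=cur[g])   # primer base skipped
                np.minimum(cur[g, 1:], cur[g - 1, :-1], out=cur[g, 1:])  # extra base
        prev = cur
    out: dict[int, tuple[int, int]] = {}
    for t in range(1, L + 1):
        best = None  # (total edits, gaps, mismatches)
        for g in range(G + 1):
            s = int(prev[g, t])
            if s < BIG and (best is None or (s + g, g) < best[:2]):
                best = (s + g, g, s)
        if best is not None and best[2] <= max_mismatch and best[1] <= max_gaps:
            out[t] = (best[2], best[1])
    return out


def _collapse_sites(bindings: dict[int, tuple[int, int]], max_gaps: int,
                    ) -> dict[int, tuple[int, int]]:
    """One representative per run of nearby end positions (best quality)."""
    out: dict[int, tuple[int, int]] = {}
    run: list[int] = []
    for t in sorted(bindings):
        if run and t - run[-1] > max_gaps + 1:
            best = min(run, key=lambda x: (bindings[x], x))
            out[best] = bindings[best]
            run = []
        run.append(t)
    if run:
        best = min(run, key=lambda x: (bindings[x], x))
        out[best] = bindings[best]
    return out


def epcr_screen(primer_pairs: list[PrimerPair],
                templates: list[SequenceRecord],
                max_mismatch: int = 3, max_gaps: int = 3,
                max_amplicon: int = 5000) -> pd.DataFrame:
    """Predicted amplicons for each primer pair on each template.

    The forward primer is matched on the + strand and the
    reverse-complemented reverse primer downstream within ``max_amplicon``
    bp; each primer may carry up to ``max_mismatch`` substitutions and
    ``max_gaps`` indels (budgeted separately, as in re-PCR screening).
    """
    from .io_formats import reverse_complement

    rows = []
    for tmpl in templates:
        seq = tmpl.residues.upper()
        for pair in primer_pairs:
            fwd = _collapse_sites(
                _binding_end_positions(seq, pair.forward, max_mismatch, max_gaps),
                max_gaps)
            rev = _collapse_sites(
                _binding_end_positions(seq, reverse_complement(pair.reverse),
                                       max_mismatch, max_gaps),
                max_gaps)
            for fe, (fs_mm, fs_g) in sorted(fwd.items()):
                f_start = max(0, fe - len(pair.forward))
                for re_, (rv_mm, rv_g) in sorted(rev.items()):
                    if re_ <= fe:
                        continue
                    length = re_ - f_start
                    if length > max_amplicon:
                        continue
                    rows.append({
                        "template": tmpl.id, "primer_pair": pair.name,
                        "start": f_start, "end": re_, "length": length,
                        "fwd_mismatches": fs_mm, "fwd_gaps": fs_g,
                        "rev_mismatches": rv_mm, "rev_gaps": rv_g,
                    })
    return pd.DataFrame(rows, columns=["template", "primer_pair", "start", "end",
                                       "length", "fwd_mismatches", "fwd_gaps",
                                       "rev_mismatches", "rev_gaps"])


# ---------------------------------------------------------------------------
# the full pipeline


@dataclass
class PipelineResult:
    config: PipelineConfig
    records: pd.DataFrame            # one row per NBS candidate gene
    hits: list[hm.HmmHit]
    species_hmm: hm.ProfileHMM
    clusters: list[gm.GeneCluster]
    cluster_singletons: list[gm.AnchoredGene]
    alone: list[gm.AnchoredGene]
    windows: list[gm.FlankWindow]
    derived: pd.DataFrame
    tree: ph.PhyloTree | None
    arch_table: ArchitectureTable
    pseudo_table: PseudogeneTable
    epcr: pd.DataFrame

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.records.to_csv(os.path.join(outdir, "calls.tsv"), sep="\t", index=False)
        self.arch_table.to_frame().to_csv(os.path.join(outdir, "arch_table.tsv"),
                                          sep="\t", index=False)
        self.pseudo_table.frame.to_csv(os.path.join(outdir, "pseudo_table.tsv"),
                                       sep="\t", index=False)
        gm.write_clusters_bed(self.clusters, os.path.join(outdir, "clusters.bed"))
        self.derived.to_csv(os.path.join(outdir, "nbs_derived.tsv"), sep="\t",
                            index=False)
        self.epcr.to_csv(os.path.join(outdir, "epcr.tsv"), sep="\t", index=False)
        if self.tree is not None:
            write_newick(self.tree, os.path.join(outdir, "tree.nwk"))
        with open(os.path.join(outdir, "run.log"), "w") as fh:
            for k, v in asdict(self.config).items():
                fh.write(f"{k}\t{v}\n")


def run_pipeline(genome_dir: str | SyntheticGenome,
                 config: PipelineConfig | None = None,
                 outdir: str | None = None,
                 primer_pairs: list[PrimerPair] | None = None) -> PipelineResult:
    """Run every stage on a genome bundle (directory or in-memory).

    Deterministic for a fixed config seed; re-running on the same inputs
    reproduces the result bundle exactly.
    """
    config = config or PipelineConfig()
    if isinstance(genome_dir, SyntheticGenome):
        genome = genome_dir
    else:
        for fname in ("genome.fasta", "genes.gff3", "proteins.fasta", "anchors.tsv"):
            if not os.path.exists(os.path.join(genome_dir, fname)):
                raise FileNotFoundError(f"missing pipeline input {fname} in {genome_dir}")
        genome = load_genome(genome_dir)
    logger.info("pipeline config: %s", asdict(config))
    proteome = [p for p in genome.proteins if p.residues]
    scaf_seq = {s.id: s.residues for s in genome.scaffolds}
    models = {g.gene_id: g for g in genome.genes}

    # stage 1-2: two-pass HMM search, kinase exclusion
    seed_hmm = hm.build_profile(list(seed_alignment("nbarc")), name="nbarc_seed")
    hm.calibrate_evalue(seed_hmm, seed=config.seed)
    species_hmm, candidates = hm.refine_species_model(
        proteome, seed_hmm, strict=config.strict_evalue,
        relaxed=config.relaxed_evalue, calib_seed=config.seed)
    kinase_hmm = hm.build_profile(list(seed_alignment("kinase")), name="kinase")
    hm.calibrate_evalue(kinase_hmm, seed=config.seed + 2)
    hits = hm.kinase_filter(candidates, proteome, kinase_hmm)
    by_id = {p.id: p for p in proteome}

    # stage 3: domain architecture.  Candidates showing fewer than
    # min_nbs_subdomains ordered NBS motifs are dropped here — the automated
    # counterpart of curating marginal E-value hits out of the final set.
    pssms = da.default_pssms()
    cc_sub = hm.build_profile(list(seed_alignment("cc_sub")), name="cc_sub")
    tir_sub = hm.build_profile(list(seed_alignment("tir_sub")), name="tir_sub")
    subdomains: dict[str, list[da.DomainHit]] = {}
    validated = []
    for h in hits:
        sub, _ = da.find_nbs_subdomains(by_id[h.target_id], pssms)
        if len(sub) >= config.min_nbs_subdomains:
            subdomains[h.target_id] = sub
            validated.append(h)
    hits = validated
    calls: dict[str, da.ArchitectureCall] = {}
    for h in hits:
        prot = by_id[h.target_id]
        dhits = da.scan_pssm(prot, pssms["TIR"], max_hits=2)
        dhits += da.scan_pssm(prot, pssms["LRR"])
        dhits += da.coiled_coil_scan(
            prot, prob_threshold=config.cc_prob_threshold,
            validation_cutoff=config.cc_validation_cutoff)
        sub = subdomains[h.target_id]
        sig = da.classify_signature(prot, sub, cc_sub, tir_sub)
        coverage = h.model_nodes_covered / species_hmm.M
        calls[h.target_id] = da.assign_architecture(
            dhits + sub, sig, coverage,
            partial_threshold=config.partial_nbs_threshold)

    # stage 4: anchoring and cluster analysis
    arch = {gid: c.code for gid, c in calls.items()}
    nbs_models = [models[g] for g in arch if g in models]
    anchored = gm.anchor_genes(nbs_models, genome.anchors, architecture=arch)
    clusters, cl_singletons = gm.detect_clusters(anchored,
                                                 max_gap=config.cluster_max_gap)
    alone = gm.find_singletons(anchored, min_dist=config.singleton_min_dist)

    # stage 5: flanking windows and the NBS-derived screen
    scaffold_genes: dict[str, list] = {}
    for g in genome.genes:
        scaffold_genes.setdefault(g.seqid, []).append(g)
    windows = gm.flanking_windows(scaffold_genes, set(arch),
                                  {s.id: len(s.residues) for s in genome.scaffolds},
                                  flank_small=config.flank_small,
                                  flank_large=config.flank_large)
    orfs = []
    for w in windows:
        orfs.extend(gm.extract_orfs(scaf_seq[w.scaffold_id], w))
    known_spans = [(g.seqid, g.start, g.end) for g in genome.genes]
    derived = gm.screen_nbs_derived(
        orfs, list(reference_proteins()), nbs_hmm=species_hmm,
        known_gene_spans=known_spans,
        partial_threshold=config.partial_nbs_threshold)

    # stage 6: pseudogene cause calling
    from .pseudogene import call_pseudogene

    refs = list(reference_proteins())
    pseudo_rows = {}
    for gid in sorted(arch):
        g = models.get(gid)
        if g is None:
            continue
        dna = g.spliced_cds(scaf_seq[g.seqid])
        scaf_len = len(scaf_seq[g.seqid])
        if g.strand == "+":
            end_dist = (g.start, scaf_len - g.end)
        else:
            end_dist = (scaf_len - g.end, g.start)
        pseudo_rows[gid] = call_pseudogene(gid, dna, refs,
                                           end_distance=end_dist)

    # stage 7: phylogeny on complete NBS domains plus labelled references
    tree = None
    phylo_seqs = []
    for h in hits:
        prot = by_id[h.target_id]
        dom = ph.extract_nbs_domain(prot, subdomains[h.target_id])
        if dom is not None:
            phylo_seqs.append(dom)
    ref_leaves = {}
    for rid, lineage in (("ref_CNL_1", "CC_I"), ("ref_NL_CC_1", "CC_I"),
                         ("ref_CNL_2", "CC_II"), ("ref_NL_CC_2", "CC_II"),
                         ("ref_TNL_1", "TIR"), ("ref_TNL_2", "TIR")):
        ref = next(r for r in refs if r.id == rid)
        sub, _ = da.find_nbs_subdomains(ref, pssms)
        dom = ph.extract_nbs_domain(ref, sub)
        if dom is not None:
            phylo_seqs.append(dom)
            ref_leaves[rid] = lineage
    if len(phylo_seqs) >= 4 and ref_leaves:
        msa = ph.trim_ragged_ends(ph.progressive_align(phylo_seqs))
        tree = ph.bootstrap_support(msa, replicates=config.bootstrap_replicates,
                                    seed=config.seed, model="poisson")
        ph.assign_clades(tree, ref_leaves)

    # stage 8: tables
    chrom_of = {a.gene_id: a for a in anchored}
    cluster_of = {}
    for c in clusters:
        for gid in c.members:
            cluster_of[gid] = c.cluster_id
    rec_rows = []
    for gid in sorted(arch):
        a = chrom_of.get(gid)
        pc = pseudo_rows.get(gid)
        rec_rows.append({
            "gene_id": gid,
            "architecture": arch[gid],
            "nbs_coverage": calls[gid].nbs_coverage,
            "chromosome": a.chromosome if a else gm.UNANCHORED,
            "start": a.start if a else -1,
            "end": a.end if a else -1,
            "cluster_id": cluster_of.get(gid, ""),
            "pseudogene": bool(pc and pc.cause not in ("intact", "unclassifiable")),
            "pseudogene_cause": pc.cause if pc else "",
            "breakpoint_codon": pc.breakpoint_codon if pc else None,
            "clade": (tree.clade_labels.get(gid, "") if tree else ""),
        })
    records = pd.DataFrame(rec_rows)
    arch_table = architecture_summary(list(records.architecture))
    pseudo_table = pseudogene_summary(records[["gene_id", "chromosome", "pseudogene"]])
    epcr = epcr_screen(primer_pairs or [], genome.scaffolds) if primer_pairs \
        else pd.DataFrame(columns=["template", "primer_pair", "start", "end",
                                   "length", "fwd_mismatches", "fwd_gaps",
                                   "rev_mismatches", "rev_gaps"])
    result = PipelineResult(
        config=config, records=records, hits=hits, species_hmm=species_hmm,
        clusters=clusters, cluster_singletons=cl_singletons, alone=alone,
        windows=windows, derived=derived, tree=tree, arch_table=arch_table,
        pseudo_table=pseudo_table, epcr=epcr)
    if outdir:
        result.write(outdir)
    return result
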