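"""Synthetic genomes with planted NLR truth.

Emulates the structure a genome-wide NLR annotation pipeline faces on a real
assembly: multi-chromosome pseudomolecules built from anchored scaffolds,
NLR genes of all eight architecture classes planted in clusters and as
singletons, a configurable fraction of pseudogenized copies (premature
stops, frameshifts, partial deletions, scaffold-end truncation), NBS-derived
gene relics near clusters, protein-kinase decoys sharing the P-loop, and
plain background genes.  Every planted feature is recorded in a truth table
so each downstream stage can be scored exactly.

Generation is fully deterministic for a given spec: a single RNG stream is
seeded from the spec and threaded through all sub-operations.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import io_formats as iof
from .io_formats import AnchorTable, GeneModel, SequenceRecord
from .resources import CLASS_CODES, build_nlr_protein, class_traits, sample_kinase

__all__ = [
    "SyntheticSpec",
    "TruthRecord",
    "SyntheticGenome",
    "generate_nlr_protein",
    "plant_pseudogene",
    "generate_genome",
    "load_genome",
]

PSEUDOGENE_CAUSES = ("premature_stop", "frameshift", "deletion_partial", "scaffold_end")

# genetic code plumbing for reverse translation (sense codons only)
_CODON_TABLE = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"], "F": ["TTT", "TTC"],
    "G": ["GGT", "GGC", "GGA", "GGG"], "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}
_STOPS = ("TAA", "TGA", "TAG")
_SENSE_CODONS = [c for lst in _CODON_TABLE.values() for c in lst]


@dataclass
class SyntheticSpec:
    """Generator configuration; defaults are the packaged study conditions."""

    n_chromosomes: int = 5
    chromosome_length: int = 30_000_000
    class_counts: dict[str, int] = field(default_factory=lambda: {
        "CNL": 14, "CN": 8, "NL_CC": 12, "N_CC": 8,
        "TNL": 7, "TN": 4, "NL_TIR": 3, "N_TIR": 4,
    })
    n_clusters: int = 10
    cluster_size_range: tuple[int, int] = (2, 8)
    intra_cluster_gap: tuple[int, int] = (5_000, 60_000)
    pseudogene_fraction: float = 0.4
    cause_mix: dict[str, float] = field(default_factory=lambda: {
        "premature_stop": 0.40, "frameshift": 0.40,
        "deletion_partial": 0.15, "scaffold_end": 0.05,
    })
    n_kinase_decoys: int = 40
    n_background_genes: int = 200
    n_nbs_derived: int = 3          # NLR relics with the NBS fully deleted
    n_partial_nbs: int = 3          # relics retaining ~30% of the NBS
    unanchored_fraction: float = 0.15  # of singleton NLR scaffolds
    intron_range: tuple[int, int] = (0, 2)
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0.0 <= self.pseudogene_fraction <= 1.0:
            raise ValueError("pseudogene_fraction must be in [0, 1]")
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class counts must be >= 0")
        if abs(sum(self.cause_mix.values()) - 1.0) > 1e-9:
            raise ValueError("cause mix must sum to 1")
        unknown = set(self.class_counts) - set(CLASS_CODES)
        if unknown:
            raise ValueError(f"unknown class codes {sorted(unknown)}")

    @property
    def n_nlr(self) -> int:
        return sum(self.class_counts.values())

    @property
    def n_pseudogenes(self) -> int:
        # deterministic rounding: floor(n*f + 0.5)
        return int(np.floor(self.n_nlr * self.pseudogene_fraction + 0.5))


@dataclass
class TruthRecord:
    gene_id: str
    class_code: str            # planted architecture
    expected_code: str         # architecture expected after any lesion
    lineage: str
    domains: dict              # name -> (start, end) on the intact protein
    cause: str = "none"
    breakpoint_codon: int | None = None
    cluster_id: str | None = None
    scaffold: str = ""
    kind: str = "nlr"          # nlr | nbs_derived | partial_nbs | kinase | background

    def __post_init__(self) -> None:
        if (self.breakpoint_codon is not None) != (self.cause != "none"):
            raise ValueError("breakpoint present iff cause != none")


# ---------------------------------------------------------------------------
# protein / DNA construction


def generate_nlr_protein(class_code: str, rng: np.random.Generator,
                         ) -> tuple[SequenceRecord, dict]:
    """One NLR protein of the given class plus its domain-offset truth."""
    seq, truth = build_nlr_protein(class_code, rng)
    rec = SequenceRecord(id="nlr", description=class_code, residues=seq,
                         alphabet="protein")
    return rec, truth


def reverse_translate(protein: str, rng: np.random.Generator,
                      stop: bool = True) -> str:
    codons = [_CODON_TABLE[a][rng.integers(len(_CODON_TABLE[a]))] for a in protein]
    if stop:
        codons.append(_STOPS[rng.integers(3)])
    return "".join(codons)


def plant_pseudogene(cds_dna: str, cause: str, rng: np.random.Generator,
                     codon_window: tuple[int, int] | None = None,
                     deletion_fraction: tuple[float, float] = (0.2, 0.6),
                     ) -> tuple[str, str, int | None]:
    """Disable an intact CDS; returns (mutated dna, cause, breakpoint codon).

    ``codon_window`` restricts where the lesion may fall (0-based codon
    indices, half-open); by default any internal codon.  Causes:
    premature_stop rewrites one sense codon to a random stop; frameshift
    inserts or deletes a single base; deletion_partial removes the terminal
    20-60% of the CDS.  scaffold_end truncation needs assembly context and
    is applied by :func:`generate_genome`, not here.
    """
    if cause in ("none", None):
        return cds_dna, "none", None
    if cause == "scaffold_end":
        raise ValueError("scaffold_end truncation requires genome assembly context")
    if cause not in PSEUDOGENE_CAUSES:
        raise ValueError(f"unknown pseudogene cause {cause!r}")
    n_codons = len(cds_dna) // 3
    if len(cds_dna) % 3 != 0 or n_codons < 3:
        raise ValueError("CDS must be intact (length divisible by 3)")
    lo, hi = codon_window if codon_window else (1, n_codons - 1)
    lo = max(1, lo)
    hi = min(n_codons - 1, hi)
    if cause == "premature_stop":
        k = int(rng.integers(lo, hi))
        stop = _STOPS[rng.integers(3)]
        return cds_dna[:3 * k] + stop + cds_dna[3 * (k + 1):], cause, k
    if cause == "frameshift":
        k = int(rng.integers(lo, hi))
        pos = 3 * k + int(rng.integers(3))
        if rng.random() < 0.5:
            base = "ACGT"[rng.integers(4)]
            return cds_dna[:pos] + base + cds_dna[pos:], cause, k
        return cds_dna[:pos] + cds_dna[pos + 1:], cause, k
    # deletion_partial: cut point uniform in the window when one is given,
    # otherwise drawn as a terminal fraction of the CDS
    if codon_window is not None:
        cut = int(rng.integers(lo, hi + 1))
    else:
        f_lo, f_hi = deletion_fraction
        frac = float(rng.uniform(f_lo, f_hi))
        cut = int(np.clip(n_codons - int(round(frac * n_codons)), lo, hi))
    return cds_dna[:3 * cut], cause, cut


def _lesion_window(truth: dict, n_codons: int, cause: str) -> tuple[int, int]:
    """Codon window for a lesion that keeps a recognisable NBS.

    Stops and frameshifts fall in the NBS tail between kinase-3a and GLPL:
    the lesion stays inside the region every reference covers (so the
    alignment pins the breakpoint) and the pseudogene keeps a clearly
    detectable partial NBS, as the annotated pseudogene population does.
    Terminal truncations (deletion_partial, scaffold_end) cut shortly after
    kinase-2, deep enough that reference coverage reads as loss.
    """
    if cause in ("premature_stop", "frameshift"):
        return int(truth["kinase3a"][1] + 5), int(truth["glpl"][1] - 2)
    lo = truth["kinase2"][1] + 4
    return int(lo), int(lo + 6)


def _expected_code(truth: dict, breakpoint: int | None) -> str:
    """Architecture expected from the protein that survives a lesion.

    The surviving prefix keeps a domain only when the whole domain (or at
    least one complete repeat, for the LRR) lies before the breakpoint; a
    lesion cutting the NBS below half its span downgrades the call to
    PARTIAL.
    """
    code = truth["code"]
    if breakpoint is None:
        return code
    ns, ne = truth["nbs"]
    if (min(breakpoint, ne) - ns) / (ne - ns) < 0.5:
        return "PARTIAL"
    traits = class_traits(code)
    has_lrr = False
    if traits["has_lrr"]:
        lrr_start = truth["lrr"][0]
        has_lrr = breakpoint >= lrr_start + truth["lrr_unit_len"]
    if traits["has_tir"]:
        return "TNL" if has_lrr else "TN"
    if traits["has_cc"]:
        return "CNL" if has_lrr else "CN"
    if traits["signature"] == "TIR":
        return "NL_TIR" if has_lrr else "N_TIR"
    return "NL_CC" if has_lrr else "N_CC"


# ---------------------------------------------------------------------------
# genome assembly


@dataclass
class SyntheticGenome:
    scaffolds: list[SequenceRecord]
    genes: list[GeneModel]
    proteins: list[SequenceRecord]
    anchors: AnchorTable
    truth: pd.DataFrame

    def write(self, outdir: str) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genome": os.path.join(outdir, "genome.fasta"),
            "genes": os.path.join(outdir, "genes.gff3"),
            "proteins": os.path.join(outdir, "proteins.fasta"),
            "anchors": os.path.join(outdir, "anchors.tsv"),
            "truth": os.path.join(outdir, "truth.tsv"),
        }
        iof.write_fasta(self.scaffolds, paths["genome"])
        iof.write_gff3(self.genes, paths["genes"])
        iof.write_fasta(self.proteins, paths["proteins"])
        iof.write_anchor_table(self.anchors, paths["anchors"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        return paths

    def output_sha256(self) -> str:
        h = hashlib.sha256()
        for s in self.scaffolds:
            h.update(s.id.encode())
            h.update(s.residues.encode())
        for p in self.proteins:
            h.update(p.id.encode())
            h.update(p.residues.encode())
        h.update(self.truth.to_csv(sep="\t", index=False).encode())
        for row in self.anchors.rows:
            h.update(repr(row).encode())
        return h.hexdigest()


def load_genome(indir: str) -> SyntheticGenome:
    return SyntheticGenome(
        scaffolds=iof.read_fasta(os.path.join(indir, "genome.fasta"), alphabet="dna"),
        genes=iof.read_gff3(os.path.join(indir, "genes.gff3")),
        proteins=iof.read_fasta(os.path.join(indir, "proteins.fasta"),
                                alphabet="protein"),
        anchors=iof.read_anchor_table(os.path.join(indir, "anchors.tsv")),
        truth=pd.read_csv(os.path.join(indir, "truth.tsv"), sep="\t"),
    )


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def _random_orf_protein(rng: np.random.Generator) -> str:
    n = int(rng.integers(200, 401))
    aas = list(_CODON_TABLE)
    return "M" + "".join(np.array(aas)[rng.integers(0, 20, size=n - 1)])


class _GenePlan:
    """One planted gene before placement."""

    def __init__(self, gene_id, kind, protein, cds, truth: TruthRecord | None,
                 strand, n_introns, annotated=True, at_scaffold_end=False):
        self.gene_id = gene_id
        self.kind = kind
        self.protein = protein
        self.cds = cds
        self.truth = truth
        self.strand = strand
        self.n_introns = n_introns
        self.annotated = annotated
        self.at_scaffold_end = at_scaffold_end


def _build_gene_dna(plan: _GenePlan, rng: np.random.Generator):
    """Insert introns (codon-boundary, GT..AG) -> (genomic seq, exon local spans)."""
    cds = plan.cds
    n_codons = len(cds) // 3
    cuts: list[int] = []
    if plan.n_introns > 0 and n_codons > 20:
        pts = sorted(rng.choice(np.arange(5, n_codons - 5), size=plan.n_introns,
                                replace=False))
        cuts = [3 * int(p) for p in pts]
    pieces = []
    exon_spans = []
    pos_cds = 0
    pos_out = 0
    for cut in cuts + [len(cds)]:
        exon = cds[pos_cds:cut]
        pieces.append(exon)
        exon_spans.append((pos_out, pos_out + len(exon)))
        pos_out += len(exon)
        pos_cds = cut
        if cut < len(cds):
            ilen = int(rng.integers(80, 301))
            intron = "GT" + _random_dna(ilen - 4, rng) + "AG"
            pieces.append(intron)
            pos_out += ilen
    return "".join(pieces), exon_spans


def generate_genome(spec: SyntheticSpec) -> SyntheticGenome:
    """Build the full synthetic assembly + annotation + truth bundle.

    Layout: each planned cluster lives on one scaffold (intra-cluster
    start-to-start gaps bounded by the configured distribution), each
    singleton on its own scaffold, kinase decoys and background genes fill
    cluster gaps and dedicated background scaffolds, NBS-derived relics are
    planted unannotated near cluster spans.  Scaffolds are anchored to
    chromosomes with wide spacing (singletons end up "alone"); a fraction
    of singleton scaffolds stays unanchored.  Byte-identical outputs for
    equal specs.
    """
    rng = np.random.default_rng(spec.seed)

    # ---- gene roster -----------------------------------------------------
    roster = [code for code in CLASS_CODES for _ in range(spec.class_counts.get(code, 0))]
    rng.shuffle(roster)
    n = len(roster)

    # pseudogene causes by largest-remainder apportionment of the mix
    n_pseudo = spec.n_pseudogenes
    causes: list[str] = []
    if n_pseudo:
        raw = {c: spec.cause_mix.get(c, 0.0) * n_pseudo for c in PSEUDOGENE_CAUSES}
        base = {c: int(np.floor(v)) for c, v in raw.items()}
        short = n_pseudo - sum(base.values())
        for c in sorted(PSEUDOGENE_CAUSES, key=lambda c: (-(raw[c] - base[c]), c))[:short]:
            base[c] += 1
        causes = [c for c in PSEUDOGENE_CAUSES for _ in range(base[c])]
    pseudo_idx = sorted(rng.choice(n, size=n_pseudo, replace=False)) if n_pseudo else []
    cause_of = dict(zip(pseudo_idx, causes))

    # ---- build every NLR gene -------------------------------------------
    plans: list[_GenePlan] = []
    for i, code in enumerate(roster):
        gene_id = f"g{i + 1:04d}"
        prot_seq, truth_d = build_nlr_protein(code, rng)
        cds = reverse_translate(prot_seq, rng)
        cause = cause_of.get(i, "none")
        bp = None
        at_end = False
        if cause == "scaffold_end":
            lo, hi = _lesion_window(truth_d, len(prot_seq), "scaffold_end")
            cut = int(rng.integers(lo, hi + 1))
            cds = cds[:3 * cut]
            bp = cut
            at_end = True
        elif cause != "none":
            window = _lesion_window(truth_d, len(prot_seq), cause)
            cds, cause, bp = plant_pseudogene(cds, cause, rng, codon_window=window)
        protein = iof.translate_cds(cds, to_stop=True)
        rec = TruthRecord(gene_id=gene_id, class_code=code,
                          expected_code=_expected_code(truth_d, bp),
                          lineage=truth_d["lineage"],
                          domains={k: v for k, v in truth_d.items()
                                   if isinstance(v, tuple)},
                          cause=cause, breakpoint_codon=bp, kind="nlr")
        strand = "+" if (at_end or rng.random() < 0.5) else "-"
        n_introns = int(rng.integers(spec.intron_range[0], spec.intron_range[1] + 1))
        plans.append(_GenePlan(gene_id, "nlr", protein, cds, rec, strand,
                               n_introns, at_scaffold_end=at_end))

    # NBS-derived relics (unannotated ORFs planted near clusters)
    derived_plans: list[_GenePlan] = []
    for j in range(spec.n_nbs_derived + spec.n_partial_nbs):
        code = ("CNL", "NL_CC", "TNL")[j % 3]
        prot_seq, truth_d = build_nlr_protein(code, rng)
        s, e = truth_d["nbs"]
        if j < spec.n_nbs_derived:
            relic = prot_seq[:s] + prot_seq[e:]
            kind = "nbs_derived"
        else:
            keep = s + int(0.3 * (e - s))
            relic = prot_seq[:keep] + prot_seq[e:]
            kind = "partial_nbs"
        relic = "M" + relic
        gene_id = f"nd{j + 1:03d}"
        rec = TruthRecord(gene_id=gene_id, class_code=code, expected_code=code,
                          lineage=truth_d["lineage"], domains={}, kind=kind)
        derived_plans.append(_GenePlan(gene_id, kind, relic,
                                       reverse_translate(relic, rng), rec,
                                       "+", 0, annotated=False))

    decoy_plans = []
    for j in range(spec.n_kinase_decoys):
        seq = sample_kinase(rng)
        gene_id = f"k{j + 1:04d}"
        rec = TruthRecord(gene_id=gene_id, class_code="kinase",
                          expected_code="kinase", lineage="-", domains={},
                          kind="kinase")
        decoy_plans.append(_GenePlan(gene_id, "kinase", seq,
                                     reverse_translate(seq, rng), rec,
                                     "+" if rng.random() < 0.5 else "-", 0))
    bg_plans = []
    for j in range(spec.n_background_genes):
        seq = _random_orf_protein(rng)
        gene_id = f"b{j + 1:04d}"
        rec = TruthRecord(gene_id=gene_id, class_code="background",
                          expected_code="background", lineage="-", domains={},
                          kind="background")
        bg_plans.append(_GenePlan(gene_id, "background", seq,
                                  reverse_translate(seq, rng), rec,
                                  "+" if rng.random() < 0.5 else "-", 0))

    # ---- cluster plan ----------------------------------------------------
    lo, hi = spec.cluster_size_range
    sizes = []
    budget = n
    for _ in range(spec.n_clusters):
        if budget < lo + 1:
            break
        size = int(rng.integers(lo, hi + 1))
        size = min(size, budget - 1) if budget - size < 0 else size
        # keep at least enough left over for a couple of singletons
        size = min(size, max(lo, budget - 2))
        if size < lo:
            break
        sizes.append(size)
        budget -= size
    # scaffold-end genes must terminate their own scaffold -> singletons
    end_idx = [i for i, p in enumerate(plans) if p.at_scaffold_end]
    normal_idx = [i for i in range(n) if i not in end_idx]
    rng.shuffle(normal_idx)
    clusters: list[list[int]] = []
    pos = 0
    for size in sizes:
        if pos + size > len(normal_idx):
            break
        clusters.append(normal_idx[pos:pos + size])
        pos += size
    singleton_idx = normal_idx[pos:] + end_idx

    # ---- scaffold construction ------------------------------------------
    scaffolds: list[SequenceRecord] = []
    gene_models: list[GeneModel] = []
    scaffold_of_gene: dict[str, str] = {}

    filler_pool = decoy_plans + bg_plans
    rng.shuffle(filler_pool)
    filler_cursor = 0
    derived_cursor = 0
    scaf_no = 0

    def place_genes(scaf_id, plan_list, gaps, margin_left, margin_right,
                    derived_here=0):
        """Lay out genes left-to-right; returns scaffold sequence."""
        nonlocal filler_cursor, derived_cursor
        parts: list[str] = []
        cursor = 0

        def pad(nbp):
            nonlocal cursor
            parts.append(_random_dna(nbp, rng))
            cursor += nbp

        def lay(plan: _GenePlan):
            nonlocal cursor
            gdna, exon_spans = _build_gene_dna(plan, rng)
            glen = len(gdna)
            if plan.strand == "-":
                gdna = iof.reverse_complement(gdna)
                exon_spans = sorted((glen - e, glen - s) for s, e in exon_spans)
            gstart = cursor
            parts.append(gdna)
            cursor += glen
            if plan.annotated:
                spans = [(gstart + s, gstart + e) for s, e in exon_spans]
                gene_models.append(GeneModel(
                    gene_id=plan.gene_id, seqid=scaf_id, strand=plan.strand,
                    exons=spans, cds=list(spans), protein_id=plan.gene_id))
            if plan.truth is not None:
                plan.truth.scaffold = scaf_id
            scaffold_of_gene[plan.gene_id] = scaf_id

        pad(margin_left)
        # optionally drop an unannotated relic into the left margin
        for _ in range(derived_here):
            if derived_cursor < len(derived_plans) and cursor > 3000:
                back = cursor - int(rng.integers(1500, min(40_000, cursor - 1000)))
                dp = derived_plans[derived_cursor]
                derived_cursor += 1
                gdna, _ = _build_gene_dna(dp, rng)
                seq_so_far = "".join(parts)
                insert_at = max(200, back)
                parts[:] = [seq_so_far[:insert_at], gdna, seq_so_far[insert_at:]]
                cursor += len(gdna)
                dp.truth.scaffold = scaf_id
                scaffold_of_gene[dp.gene_id] = scaf_id
        for k, plan in enumerate(plan_list):
            if k > 0:
                gap = gaps() if callable(gaps) else gaps
                # occasionally interleave a decoy/background gene in the gap
                if gap > 6000 and filler_cursor < len(filler_pool) and rng.random() < 0.5:
                    fp = filler_pool[filler_cursor]
                    filler_cursor += 1
                    pre = int(rng.integers(500, gap // 3))
                    pad(pre)
                    lay(fp)
                    pad(max(200, gap - pre - len(fp.cds)))
                else:
                    pad(gap)
            lay(plan)
        if plan_list and plan_list[-1].at_scaffold_end:
            pass  # scaffold truncates the final gene: no right margin
        else:
            pad(margin_right)
        return "".join(parts)

    cluster_scaffolds = []
    for ci, members in enumerate(clusters):
        scaf_no += 1
        scaf_id = f"scaf{scaf_no:03d}"
        cid = f"cluster{ci + 1:02d}"
        mplans = [plans[i] for i in members]
        for p in mplans:
            p.truth.cluster_id = cid
        seq = place_genes(
            scaf_id, mplans,
            gaps=lambda: int(rng.integers(*spec.intra_cluster_gap)),
            margin_left=int(rng.integers(30_000, 60_000)),
            margin_right=int(rng.integers(30_000, 60_000)),
            derived_here=1,
        )
        scaffolds.append(SequenceRecord(id=scaf_id, description="", residues=seq))
        cluster_scaffolds.append(scaf_id)

    singleton_scaffolds = []
    for si in singleton_idx:
        scaf_no += 1
        scaf_id = f"scaf{scaf_no:03d}"
        plan = plans[si]
        seq = place_genes(scaf_id, [plan],
                          gaps=0,
                          margin_left=int(rng.integers(40_000, 80_000)),
                          margin_right=int(rng.integers(40_000, 80_000)))
        scaffolds.append(SequenceRecord(id=scaf_id, description="", residues=seq))
        singleton_scaffolds.append(scaf_id)

    # background-only scaffolds for the remaining fillers
    while filler_cursor < len(filler_pool):
        scaf_no += 1
        scaf_id = f"scaf{scaf_no:03d}"
        batch = filler_pool[filler_cursor:filler_cursor + 30]
        filler_cursor += len(batch)
        seq = place_genes(scaf_id, batch,
                          gaps=lambda: int(rng.integers(1_000, 6_000)),
                          margin_left=5_000, margin_right=5_000)
        scaffolds.append(SequenceRecord(id=scaf_id, description="", residues=seq))

    # ---- anchoring -------------------------------------------------------
    n_unanchored = int(np.floor(spec.unanchored_fraction * len(singleton_scaffolds) + 0.5))
    unanchored = set()
    if n_unanchored and singleton_scaffolds:
        unanchored = set(rng.choice(singleton_scaffolds,
                                    size=min(n_unanchored, len(singleton_scaffolds)),
                                    replace=False))
    anchor_rows = []
    cursors = {f"chr{c + 1}": 2_000_000 for c in range(spec.n_chromosomes)}
    order = [s for s in scaffolds if s.id not in unanchored]
    for k, scaf in enumerate(order):
        chrom = f"chr{(k % spec.n_chromosomes) + 1}"
        offset = cursors[chrom]
        if offset + len(scaf.residues) > spec.chromosome_length:
            raise ValueError("requested genes exceed available genome space")
        orient = "+" if rng.random() < 0.7 else "-"
        anchor_rows.append((scaf.id, chrom, offset, orient, len(scaf.residues)))
        cursors[chrom] = offset + len(scaf.residues) + 3_500_000

    # ---- outputs ---------------------------------------------------------
    all_plans = plans + derived_plans + decoy_plans + bg_plans
    proteins = [SequenceRecord(id=p.gene_id, description=p.kind,
                               residues=p.protein, alphabet="protein")
                for p in all_plans if p.annotated]
    truth_rows = []
    for p in all_plans:
        t = p.truth
        truth_rows.append({
            "gene_id": t.gene_id, "kind": t.kind, "class_code": t.class_code,
            "expected_code": t.expected_code, "lineage": t.lineage,
            "cause": t.cause,
            "breakpoint_codon": "" if t.breakpoint_codon is None else t.breakpoint_codon,
            "cluster_id": t.cluster_id or "",
            "scaffold": t.scaffold,
            "domains": ";".join(f"{k}:{v[0]}-{v[1]}" for k, v in sorted(t.domains.items())),
        })
    truth = pd.DataFrame(truth_rows)
    gene_models.sort(key=lambda g: (g.seqid, g.start))
    return SyntheticGenome(
        scaffolds=scaffolds,
        genes=gene_models,
        proteins=proteins,
        anchors=AnchorTable(rows=anchor_rows),
        truth=truth,
    )
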