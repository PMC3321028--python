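"""Readers/writers for the external formats the pipeline touches, plus the
shared genome data model.

Conventions
-----------
All coordinates handed to or read from files (GFF3, anchor tables, BED) are
1-based inclusive, the convention of those formats.  Everything held in
memory is 0-based half-open.  :func:`to_internal` / :func:`to_file` are the
only places the conversion happens.

Supported formats: FASTA, GFF3, Stockholm, Newick, TSV (anchor/truth/summary
tables) and BED for cluster output.  Parsing of FASTA/Stockholm is delegated
to Biopython, GFF3 to gffutils, Newick to dendropy; this module owns the
validation and the mapping onto the domain types below.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import pandas as pd
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord
from Bio.Align import MultipleSeqAlignment

__all__ = [
    "SequenceRecord",
    "GeneModel",
    "AnchorTable",
    "FastaParseError",
    "GffValidationError",
    "to_internal",
    "to_file",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_stockholm",
    "write_stockholm",
    "read_newick",
    "write_newick",
    "read_anchor_table",
    "write_anchor_table",
    "translate_cds",
    "reverse_complement",
]

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")


class FastaParseError(ValueError):
    pass


class GffValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# coordinate conversion


def to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """1-based inclusive file interval -> 0-based half-open internal interval."""
    return start_1based - 1, end_1based


def to_file(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open internal interval -> 1-based inclusive file interval."""
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# domain types


@dataclass
class SequenceRecord:
    """One FASTA record; residues are upper-case, alphabet 'dna' or 'protein'."""

    id: str
    description: str
    residues: str
    alphabet: str = "dna"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if self.alphabet not in ("dna", "protein"):
            raise ValueError(f"unknown alphabet {self.alphabet!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class GeneModel:
    """A protein-coding gene model: exon and CDS spans on one scaffold.

    Spans are internal 0-based half-open, sorted, non-overlapping.
    """

    gene_id: str
    seqid: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    protein_id: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GffValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        for name, spans in (("exon", self.exons), ("cds", self.cds)):
            for (s, e) in spans:
                if not (0 <= s < e):
                    raise GffValidationError(f"{self.gene_id}: bad {name} span {(s, e)}")
            for (a, b), (c, d) in zip(spans, spans[1:]):
                if c < b:
                    raise GffValidationError(
                        f"{self.gene_id}: {name} spans overlap or unsorted"
                    )
        # every CDS base must lie within some exon
        for (s, e) in self.cds:
            if not any(es <= s and e <= ee for es, ee in self.exons):
                raise GffValidationError(
                    f"{self.gene_id}: CDS span {(s, e)} outside exon bounds"
                )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def spliced_cds(self, scaffold_seq: str) -> str:
        """Spliced CDS in transcription order (reverse-complemented on -)."""
        parts = [scaffold_seq[s:e] for s, e in self.cds]
        cds = "".join(parts)
        if self.strand == "-":
            cds = reverse_complement(cds)
        return cds


@dataclass
class AnchorTable:
    """Scaffold-to-pseudomolecule placements (AGP-like).

    One row per scaffold: (scaffold_id, chromosome, chromosome_offset bp,
    orientation, scaffold_length bp).  Offsets are 0-based internal.
    """

    rows: list[tuple[str, str, int, str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for scaf, chrom, offset, orient, length in self.rows:
            if scaf in seen:
                raise ValueError(f"duplicate scaffold {scaf} in anchor table")
            seen.add(scaf)
            if offset < 0 or length <= 0:
                raise ValueError(f"bad placement for {scaf}")
            if orient not in "+-":
                raise ValueError(f"bad orientation for {scaf}")
            by_chrom.setdefault(chrom, []).append((offset, offset + length))
        for chrom, spans in by_chrom.items():
            spans.sort()
            for (a, b), (c, d) in zip(spans, spans[1:]):
                if c < b:
                    raise ValueError(f"overlapping placements on {chrom}")

    def lookup(self, scaffold_id: str):
        for row in self.rows:
            if row[0] == scaffold_id:
                return row
        return None

    def chromosome_length(self, chrom: str) -> int:
        return max(
            (off + length for _, c, off, _, length in self.rows if c == chrom),
            default=0,
        )


# ---------------------------------------------------------------------------
# FASTA


def _infer_alphabet(residues: str) -> str:
    return "dna" if set(residues) <= DNA_ALPHABET else "protein"


def read_fasta(path: str, alphabet: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects, file order.

    Residues are upper-cased.  An empty file yields an empty list.  A
    malformed header or sequence data before any header raises
    :class:`FastaParseError` naming the offending line number.
    """
    with open(path) as fh:
        lines = fh.readlines()
    seen_header = False
    for lineno, line in enumerate(lines, start=1):
        text = line.strip()
        if not text:
            continue
        if text.startswith(">"):
            if len(text) == 1 or text[1].isspace():
                raise FastaParseError(f"{path}:{lineno}: malformed FASTA header")
            seen_header = True
        elif not seen_header:
            raise FastaParseError(f"{path}:{lineno}: sequence data before header")
    records = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            residues = str(rec.seq).upper()
            records.append(
                SequenceRecord(
                    id=rec.id,
                    description=rec.description[len(rec.id):].strip(),
                    residues=residues,
                    alphabet=alphabet or _infer_alphabet(residues),
                )
            )
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})[0]
        raise FastaParseError(f"{path}: duplicate record id {dup}")
    return records


def write_fasta(records: list[SequenceRecord], path: str, width: int = 60) -> None:
    bio = [
        _BioSeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path: str) -> list[GeneModel]:
    """Read gene/mRNA/exon/CDS features into one :class:`GeneModel` per mRNA.

    Coordinates in the file are 1-based inclusive and converted at this
    boundary.  A CDS span outside its mRNA's exon union raises
    :class:`GffValidationError` naming the gene.
    """
    import gffutils

    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("##gff-version"):
            raise GffValidationError(f"{path}: missing ##gff-version header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise GffValidationError(
                    f"{path}:{lineno}: expected 9 tab-separated columns"
                )
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models = []
    for mrna in db.features_of_type("mRNA", order_by=("seqid", "start")):
        exons = sorted(
            to_internal(f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted(
            to_internal(f.start, f.end) for f in db.children(mrna, featuretype="CDS")
        )
        if not exons:
            exons = list(cds)
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.id
        protein_id = mrna.attributes.get("protein_id", [""])[0]
        models.append(
            GeneModel(
                gene_id=gene_id,
                seqid=mrna.seqid,
                strand=mrna.strand,
                exons=exons,
                cds=cds,
                protein_id=protein_id,
            )
        )
    return models


def write_gff3(models: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gs, ge = to_file(m.start, m.end)
            attrs = f"ID={m.gene_id}"
            fh.write(
                f"{m.seqid}\tnlrforge\tgene\t{gs}\t{ge}\t.\t{m.strand}\t.\t{attrs}\n"
            )
            mrna_id = f"{m.gene_id}.1"
            mattrs = f"ID={mrna_id};Parent={m.gene_id}"
            if m.protein_id:
                mattrs += f";protein_id={m.protein_id}"
            fh.write(
                f"{m.seqid}\tnlrforge\tmRNA\t{gs}\t{ge}\t.\t{m.strand}\t.\t{mattrs}\n"
            )
            for i, (s, e) in enumerate(m.exons, 1):
                fs, fe = to_file(s, e)
                fh.write(
                    f"{m.seqid}\tnlrforge\texon\t{fs}\t{fe}\t.\t{m.strand}\t.\t"
                    f"ID={mrna_id}.exon{i};Parent={mrna_id}\n"
                )
            for i, (s, e) in enumerate(m.cds, 1):
                fs, fe = to_file(s, e)
                fh.write(
                    f"{m.seqid}\tnlrforge\tCDS\t{fs}\t{fe}\t.\t{m.strand}\t0\t"
                    f"ID={mrna_id}.cds;Parent={mrna_id}\n"
                )


# ---------------------------------------------------------------------------
# Stockholm


def read_stockholm(path: str) -> list[SequenceRecord]:
    """Read a Stockholm alignment; rows keep their gaps ('-')."""
    aln = AlignIO.read(path, "stockholm")
    return [
        SequenceRecord(
            id=rec.id,
            description="",
            residues=str(rec.seq).upper().replace(".", "-"),
            alphabet="protein",
        )
        for rec in aln
    ]


def write_stockholm(records: list[SequenceRecord], path: str) -> None:
    aln = MultipleSeqAlignment(
        [_BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    )
    with open(path, "w") as fh:
        AlignIO.write(aln, fh, "stockholm")


# ---------------------------------------------------------------------------
# Newick (trees are dendropy.Tree; phylo wraps them in PhyloTree)


def write_newick(tree, path: str) -> None:
    """Write a tree (PhyloTree or dendropy.Tree) as Newick.

    Branch lengths are printed with 6 significant digits minimum; bootstrap
    supports travel as internal node labels; leaf names containing
    whitespace are quoted (dendropy's writer handles quoting).
    """
    dtree = getattr(tree, "tree", tree)
    text = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        preserve_spaces=True,  # whitespace-bearing labels come out quoted
        real_value_format_specifier=".8g",
    )
    with open(path, "w") as fh:
        fh.write(text)


def read_newick(path: str):
    import dendropy

    return dendropy.Tree.get(
        path=path,
        schema="newick",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )


# ---------------------------------------------------------------------------
# anchor table TSV

_ANCHOR_COLS = ["scaffold_id", "chromosome", "chromosome_offset", "orientation", "scaffold_length"]


def read_anchor_table(path: str) -> AnchorTable:
    df = pd.read_csv(path, sep="\t", dtype={"scaffold_id": str, "chromosome": str})
    missing = [c for c in _ANCHOR_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: anchor table missing columns {missing}")
    rows = [
        (r.scaffold_id, r.chromosome, int(r.chromosome_offset), r.orientation,
         int(r.scaffold_length))
        for r in df.itertuples()
    ]
    return AnchorTable(rows=rows)


def write_anchor_table(table: AnchorTable, path: str) -> None:
    pd.DataFrame(table.rows, columns=_ANCHOR_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sequence utilities

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str, to_stop: bool = False) -> str:
    """Standard-code (table 1) translation; internal stops become '*'.

    Trailing bases that do not fill a codon are dropped (frameshifted
    pseudogene CDSs are not codon-sized).
    """
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate(table=1, to_stop=to_stop))
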