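"""Readers and writers for the file formats shared across the pipeline.

Conventions fixed here and relied on everywhere else:

* genomic coordinates are 0-based, half-open internally; GTF I/O converts
  to/from the format's 1-based inclusive convention at the boundary;
* sequences are upper-case DNA over ``ACGTN`` (``U`` is normalized to ``T``
  on read, so RNA and DNA inputs meet the same scoring code);
* no other module parses files ad hoc — everything flows through here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line


class FormatError(ValueError):
    """Raised for malformed input files, naming the offending location."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval.

    ``start``/``end`` are 0-based half-open; ``strand`` may be ``.`` because
    intergenic transfrags are often unstranded.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def distance_to(self, other: "GenomicInterval") -> int:
        """Signed gap between closest edges; 0 if the intervals overlap.

        Positive when ``other`` starts downstream of ``self``.
        """
        if other.chrom != self.chrom:
            raise ValueError("intervals on different chromosomes")
        if other.start >= self.end:
            return other.start - self.end
        if self.start >= other.end:
            return -(self.start - other.end)
        return 0


@dataclass
class TranscriptModel:
    """A transcript with locus, exon structure and gffcompare class code."""

    transcript_id: str
    gene_id: str
    interval: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    class_code: str = "="

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )

    @property
    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)


@dataclass
class BlastHit:
    """One row of BLAST tabular (outfmt 6) output."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    evalue: float
    query_len: int | None = None
    subject_len: int | None = None
    bitscore: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent identity outside [0, 100]")
        if self.evalue < 0:
            raise ValueError("negative E-value")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read a 9-column GTF into :class:`TranscriptModel` records.

    Exon features are grouped by their ``transcript_id`` attribute; the
    gffcompare ``class_code`` attribute is honoured when present and defaults
    to ``"="`` (a match to reference annotation) otherwise.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict[str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise FormatError(f"{path}: line {lineno}: expected 9 columns")
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            attrs = {k: v[0] for k, v in feat.attributes.items() if v}
            tid = attrs.get("transcript_id")
            if tid is None:
                raise FormatError(
                    f"{path}: line {lineno}: missing transcript_id attribute"
                )
            info = meta.setdefault(tid, {})
            if tid not in order:
                order.append(tid)
            info.setdefault("gene_id", attrs.get("gene_id", tid))
            if "class_code" in attrs:
                info["class_code"] = attrs["class_code"]
            info.setdefault("chrom", feat.seqid)
            info.setdefault("strand", feat.strand if feat.strand in STRANDS else ".")
            if feat.featuretype == "exon":
                try:
                    iv = GenomicInterval(
                        feat.seqid, feat.start - 1, feat.end,
                        feat.strand if feat.strand in STRANDS else ".",
                    )
                except ValueError as exc:
                    raise FormatError(f"{path}: line {lineno}: {exc}") from exc
                exons.setdefault(tid, []).append(iv)

    transcripts = []
    for tid in order:
        if tid not in exons:
            continue  # transcript line without exon rows
        info = meta[tid]
        ivs = exons[tid]
        span = GenomicInterval(
            info["chrom"], min(e.start for e in ivs), max(e.end for e in ivs),
            info["strand"],
        )
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"],
                interval=span,
                exons=ivs,
                class_code=info.get("class_code", "="),
            )
        )
    return transcripts


def write_gtf(transcripts: Iterable[TranscriptModel], path: str | Path) -> None:
    """Write transcripts as GTF (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for tx in transcripts:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'class_code "{tx.class_code}";'
            )
            iv = tx.interval
            fh.write(
                "\t".join(
                    [iv.chrom, "pollen_lncrna", "transcript", str(iv.start + 1),
                     str(iv.end), ".", iv.strand, ".", attrs]
                ) + "\n"
            )
            for exon in tx.exons:
                fh.write(
                    "\t".join(
                        [exon.chrom, "pollen_lncrna", "exon", str(exon.start + 1),
                         str(exon.end), ".", exon.strand, ".", attrs]
                    ) + "\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered id -> sequence mapping.

    Sequences are upper-cased and ``U`` is normalized to ``T``; duplicate ids
    are an error.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        out[rec.id] = _normalize(str(rec.seq))
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BLAST outfmt 6
# ---------------------------------------------------------------------------

def read_blast6(path: str | Path) -> list[BlastHit]:
    """Read 12-column BLAST tabular output.

    Columns follow the standard ``outfmt 6`` order:
    qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore.  Query/subject lengths are not part of the format and
    must be supplied separately (e.g. from FASTA).
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(parts)}"
                )
            try:
                hits.append(
                    BlastHit(
                        query_id=parts[0],
                        subject_id=parts[1],
                        percent_identity=float(parts[2]),
                        alignment_length=int(parts[3]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_blast6(hits: Iterable[BlastHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [h.query_id, h.subject_id, f"{h.percent_identity:.2f}",
                     str(h.alignment_length), "0", "0", "0", "0", "0", "0",
                     f"{h.evalue:.2g}", f"{h.bitscore:.1f}"]
                ) + "\n"
            )


# ---------------------------------------------------------------------------
# OBO (GO ontology subset: id / name / namespace / is_a)
# ---------------------------------------------------------------------------

def read_obo(path: str | Path) -> nx.DiGraph:
    """Read an OBO ontology into a DAG with ``is_a`` edges child -> parent.

    Node attributes carry ``name`` and ``namespace``.  A cyclic ontology is
    rejected.
    """
    multi = obonet.read_obo(str(path))
    dag = nx.DiGraph()
    for node, data in multi.nodes(data=True):
        dag.add_node(node, name=data.get("name", node),
                     namespace=data.get("namespace", ""))
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(dag):
        raise FormatError(f"{path}: ontology contains an is_a cycle")
    return dag


# ---------------------------------------------------------------------------
# Counts + design TSV
# ---------------------------------------------------------------------------

DESIGN_COLUMNS = ["cultivar", "stage", "condition", "replicate"]


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples count matrix (TSV, first column = gene id)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if (counts.values < 0).any():
        raise FormatError(f"{path}: negative counts")
    return counts


def read_design(path: str | Path) -> pd.DataFrame:
    """Read the sidecar design table (sample, cultivar, stage, condition, replicate)."""
    design = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise FormatError(f"{path}: design table missing columns {missing}")
    return design


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# Newick (serializer for the phylo module's trees)
# ---------------------------------------------------------------------------

def write_newick(tree, path: str | Path) -> None:
    """Serialize a :class:`pollen_lncrna.phylo.PhyloTree` (or node) to newick."""
    text = tree.to_newick() if hasattr(tree, "to_newick") else str(tree)
    with open(path, "w") as fh:
        fh.write(text if text.endswith(";") else text + ";")
        fh.write("\n")
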