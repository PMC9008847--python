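"""Genome/annotation I/O, coordinate conventions and sequence utilities.

Internal coordinates are 0-based half-open throughout; GFF3 input and output
use the standard 1-based inclusive convention. Chromosome sequences are held
uppercase over the alphabet {A, C, G, T, N}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import AnnotationError, FormatError, InputError, ReferenceError_, TranslationError

log = logging.getLogger("wrkyfam.io")

NUC_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeAssembly:
    """A set of chromosome sequences keyed by id."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Slice [start, end) of a chromosome; bounds are checked."""
        if chrom not in self.sequences:
            raise ReferenceError_(f"unknown chromosome {chrom!r}")
        seq = self.sequences[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise InputError(f"interval [{start},{end}) outside {chrom} (len {len(seq)})")
        return seq[start:end]


@dataclass
class GeneModel:
    """One gene model: span, exons and CDS in 0-based half-open genome coordinates.

    ``exons`` and ``cds`` are sorted by start regardless of strand; for a minus
    strand gene the first transcribed exon is therefore the last in the list.
    """

    gene_id: str
    chromosome: str
    strand: Literal["+", "-"]
    span: tuple[int, int]
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise InputError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise InputError(f"{self.gene_id}: empty exon [{s},{e})")
            if prev_end is not None and s < prev_end:
                raise InputError(f"{self.gene_id}: overlapping exons")
            prev_end = e
        if self.exons and (self.exons[0][0] < self.span[0] or self.exons[-1][1] > self.span[1]):
            raise InputError(f"{self.gene_id}: exon outside gene span")

    @property
    def cds_len(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def translation_start(self) -> int:
        """Genome position of the first CDS base in transcription order."""
        if not self.cds:
            raise AnnotationError(f"{self.gene_id}: no CDS")
        return self.cds[0][0] if self.strand == "+" else self.cds[-1][1]

    @property
    def transcription_start(self) -> int:
        return self.span[0] if self.strand == "+" else self.span[1]

    def n_introns(self) -> int:
        if not self.exons:
            raise AnnotationError(f"{self.gene_id}: no exons")
        return len(self.exons) - 1


@dataclass
class Promoter:
    """An upstream region in promoter orientation (5'→3' toward the gene)."""

    gene_id: str
    seq: str
    chromosome: str
    strand: str
    start: int  # genomic interval [start, end) the sequence was read from
    end: int
    truncated: bool

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path, alphabet: frozenset[str] | None = NUC_ALPHABET) -> GenomeAssembly:
    """Read a multi-record FASTA into a :class:`GenomeAssembly`.

    Sequences are uppercased and line-joined; duplicate record ids and empty
    sequences are rejected. Pass ``alphabet=None`` to skip alphabet checking
    (e.g. for protein FASTA read through :func:`read_protein_fasta`).
    """
    path = Path(path)
    seqs: dict[str, str] = {}
    with open(path) as fh:
        first = fh.read(1)
        if first != ">":
            raise FormatError(f"{path}: not FASTA (first byte {first!r})")
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has empty sequence")
        if alphabet is not None:
            bad = set(seq) - alphabet
            if bad:
                raise FormatError(f"{path}: record {rec.id!r} has invalid characters {sorted(bad)}")
        seqs[rec.id] = seq
    if not seqs:
        raise FormatError(f"{path}: no FASTA records")
    return GenomeAssembly(seqs)


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Read a protein FASTA into an id → sequence map (uppercased)."""
    return dict(read_fasta(path, alphabet=None).sequences)


def write_fasta(sequences: dict[str, str] | GenomeAssembly, path: str | Path, width: int = 60) -> None:
    if isinstance(sequences, GenomeAssembly):
        sequences = sequences.sequences
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gff(path: str | Path, assembly: GenomeAssembly) -> list[GeneModel]:
    """Read GFF3 gene models, converting to 0-based half-open coordinates.

    One :class:`GeneModel` is returned per gene; when a gene carries several
    mRNAs the one with the longest total CDS is kept (the family tables report
    a single protein per gene). Features on chromosomes absent from
    ``assembly`` or extending beyond the chromosome end are rejected.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in assembly:
            raise ReferenceError_(f"{gene.id}: unknown chromosome {gene.seqid!r}")
        chrom_len = assembly.lengths[gene.seqid]
        if gene.end > chrom_len:
            raise InputError(f"{gene.id}: feature end {gene.end} beyond {gene.seqid} length {chrom_len}")
        best: GeneModel | None = None
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            raise FormatError(f"{gene.id}: gene without mRNA child")
        for mrna in mrnas:
            exons = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="exon")]
            cds = [(f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS")]
            for f in db.children(mrna):
                if f.end > chrom_len:
                    raise InputError(
                        f"{f.id or mrna.id}: feature end {f.end} beyond {gene.seqid} length {chrom_len}"
                    )
            model = GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand,
                span=(gene.start - 1, gene.end),
                exons=exons,
                cds=cds,
            )
            if best is None or model.cds_len > best.cds_len:
                best = model
        models.append(best)
    return models


def write_gff(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models back to GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in models:
            s0, e0 = g.span
            fh.write(f"{g.chromosome}\twrkyfam\tgene\t{s0 + 1}\t{e0}\t.\t{g.strand}\t.\tID={g.gene_id}\n")
            mrna_id = f"{g.gene_id}.t1"
            fh.write(f"{g.chromosome}\twrkyfam\tmRNA\t{s0 + 1}\t{e0}\t.\t{g.strand}\t.\tID={mrna_id};Parent={g.gene_id}\n")
            for s, e in g.exons:
                fh.write(f"{g.chromosome}\twrkyfam\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\tParent={mrna_id}\n")
            for s, e in g.cds:
                fh.write(f"{g.chromosome}\twrkyfam\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\tParent={mrna_id}\n")


def extract_upstream(
    gene: GeneModel,
    assembly: GenomeAssembly,
    length: int,
    anchor: Literal["transcription_start", "translation_start"] = "transcription_start",
) -> Promoter:
    """Extract the ``length`` bases immediately upstream (5') of a gene.

    The anchor is either the transcription start (gene span edge) or the
    translation start (first CDS base). On the minus strand the upstream
    region lies 3' of the anchor in genome order and is reverse-complemented
    so the returned sequence always reads 5'→3' toward the gene. Regions that
    would run off the chromosome end are truncated with a logged warning.
    """
    if anchor == "transcription_start":
        pos = gene.transcription_start
    elif anchor == "translation_start":
        pos = gene.translation_start
    else:
        raise InputError(f"unknown anchor {anchor!r}")
    chrom_len = assembly.lengths[gene.chromosome]
    if gene.strand == "+":
        start, end = max(0, pos - length), pos
    else:
        start, end = pos, min(chrom_len, pos + length)
    seq = assembly.fetch(gene.chromosome, start, end)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    truncated = len(seq) < length
    if truncated:
        log.warning("[promoter] %s: upstream region truncated to %d bp by chromosome end", gene.gene_id, len(seq))
    return Promoter(gene.gene_id, seq, gene.chromosome, gene.strand, start, end, truncated)


def spliced_cds(gene: GeneModel, assembly: GenomeAssembly) -> str:
    """Concatenate CDS segments in transcription order (minus strand revcomp'd)."""
    if not gene.cds:
        raise AnnotationError(f"{gene.gene_id}: no CDS")
    parts = [assembly.fetch(gene.chromosome, s, e) for s, e in gene.cds]
    seq = "".join(parts)
    if gene.strand == "-":
        seq = reverse_complement(seq)
    return seq


def translate_cds(gene: GeneModel, assembly: GenomeAssembly) -> str:
    """Translate a gene's spliced CDS with the standard genetic code.

    A trailing stop codon is stripped; an internal stop raises
    :class:`TranslationError` naming the offending codon index.
    """
    cds = spliced_cds(gene, assembly)
    if len(cds) < 3 or len(cds) % 3:
        raise TranslationError(f"{gene.gene_id}: CDS length {len(cds)} not a positive multiple of 3")
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot:
        raise TranslationError(f"{gene.gene_id}: internal stop at codon {prot.index('*')}")
    return prot
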