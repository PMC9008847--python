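"""Promoter scanning for IUPAC-consensus cis-regulatory elements.

Scans 2-kb upstream regions on both strands for a library of named consensus
elements (W-box, ABRE, LTR, ...). Matching is exact per position under the
IUPAC ambiguity codes; an N in the *promoter* matches nothing (conservative
treatment of assembly gaps). Minus-strand matches are reported at the
plus-strand offset of the reverse-complement occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import InputError
from .io_core import GeneModel, GenomeAssembly, Promoter, extract_upstream, reverse_complement

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def iupac_reverse_complement(consensus: str) -> str:
    return consensus.translate(_IUPAC_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CisMotif:
    """A named cis-element consensus in IUPAC notation."""

    name: str
    iupac: str
    category: str = "other"

    def __post_init__(self) -> None:
        if len(self.iupac) < 4:
            raise InputError(f"motif {self.name}: consensus shorter than 4")
        bad = set(self.iupac) - set(IUPAC)
        if bad:
            raise InputError(f"motif {self.name}: invalid IUPAC codes {sorted(bad)}")


@dataclass(frozen=True)
class CisHit:
    """One motif occurrence within a promoter (0-based promoter offset)."""

    gene_id: str
    motif: str
    strand: str
    offset: int
    matched: str


#: W-box consensus — the WRKY binding site (C/T)TGAC(C/T).
W_BOX = CisMotif("W-box", "YTGACY", "stress")


def _matches_at(promoter: str, consensus: str, i: int) -> bool:
    for j, code in enumerate(consensus):
        base = promoter[i + j]
        # N in the promoter matches no code, including N
        if base == "N" or base not in IUPAC[code]:
            return False
    return True


def scan_motif(promoter: str | Promoter, motif: CisMotif, gene_id: str = "") -> list[CisHit]:
    """All occurrences of a motif on both strands of a promoter.

    A minus-strand occurrence is found by scanning the reverse complement of
    the consensus and is reported at its plus-strand offset.
    """
    if isinstance(promoter, Promoter):
        gene_id = gene_id or promoter.gene_id
        promoter = promoter.seq
    promoter = promoter.upper()
    m = len(motif.iupac)
    rc = iupac_reverse_complement(motif.iupac)
    hits: list[CisHit] = []
    for i in range(len(promoter) - m + 1):
        if _matches_at(promoter, motif.iupac, i):
            hits.append(CisHit(gene_id, motif.name, "+", i, promoter[i : i + m]))
        if _matches_at(promoter, rc, i):
            hits.append(CisHit(gene_id, motif.name, "-", i, promoter[i : i + m]))
    return hits


def load_motif_library(path: str | Path | None = None) -> list[CisMotif]:
    """Load the packaged (or a user) motif table (name, iupac, category)."""
    if path is None:
        path = resources.files("wrkyfam.data") / "cis_motifs.tsv"
    df = pd.read_csv(path, sep="\t")
    return [CisMotif(str(r.name), str(r.iupac).upper(), str(r.category)) for r in df.itertuples(index=False)]


def element_profile(
    genes: Sequence[GeneModel],
    assembly: GenomeAssembly,
    library: Iterable[CisMotif],
    promoter_len: int = 2000,
    anchor: str = "transcription_start",
) -> tuple[pd.DataFrame, list[CisHit]]:
    """Per-gene motif hit-count matrix over a promoter library.

    Returns ``(counts, hits)`` where ``counts`` is a genes × motifs DataFrame
    with an extra boolean ``truncated`` column flagging promoters cut short
    by a chromosome end, and ``hits`` is the flat list of individual
    occurrences (promoter offsets).
    """
    library = list(library)
    names = [m.name for m in library]
    rows = []
    all_hits: list[CisHit] = []
    for gene in genes:
        prom = extract_upstream(gene, assembly, promoter_len, anchor=anchor)
        counts = {}
        for motif in library:
            hits = scan_motif(prom, motif)
            counts[motif.name] = len(hits)
            all_hits.extend(hits)
        counts["truncated"] = prom.truncated
        rows.append(pd.Series(counts, name=gene.gene_id))
    if not rows:
        return pd.DataFrame(columns=names + ["truncated"]), []
    return pd.DataFrame(rows, columns=names + ["truncated"]), all_hits
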