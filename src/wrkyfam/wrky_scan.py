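"""WRKY domain detection, group/subgroup classification and family annotation.

A WRKY domain is recognised here by its two landmarks: the heptapeptide
(WRKYGQK or a known variant) and, downstream of it, a zinc finger of either
the C2H2 form (C-X4/5-C-X22/23-H-X-H, groups I and II) or the C2HC form
(C-X7-C-X23-H-X-C, group III). Proteins with two complete C2H2 domains are
group I, one complete C2H2 domain group II, a C2HC domain group III; group II
subgroups IIa-IIe are assigned by best local-alignment hit against a labelled
reference-domain set.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.SeqUtils import molecular_weight

from .errors import AnnotationError, InputError
from .io_core import GeneModel, GenomeAssembly, translate_cds

log = logging.getLogger("wrkyfam.scan")

AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Heptapeptide variants accepted as WRKY-domain landmarks. WRKYGQK is the
#: canonical form; the others are variants observed in plant WRKY families.
HEPTAPEPTIDE_VARIANTS = (
    "WRKYGQK",
    "WRKYGEK",
    "WRKYGRK",
    "WKKYGQK",
    "WKRYGQK",
    "WRKYGKK",
)

#: Residues searched downstream of a heptapeptide for the zinc finger.
ZF_WINDOW = 80

# C2HC is tested first at each position: its fixed 7-residue first spacer is
# the more specific (group III) pattern.
_ZF_PATTERNS = (
    ("C2HC", re.compile(r"C(.{7})C(.{23})H.C")),
    ("C2H2", re.compile(r"C(.{4,5})C(.{22,23})H.H")),
)


@dataclass
class DomainHit:
    """One WRKY-domain occurrence within a protein (residue coordinates)."""

    hept_start: int
    hept_variant: str
    zf_type: Literal["C2H2", "C2HC", "none"] = "none"
    zf_span: tuple[int, int] | None = None
    spacer1: int | None = None
    spacer2: int | None = None

    @property
    def complete(self) -> bool:
        return self.zf_type != "none"

    @property
    def end(self) -> int:
        """Residue index one past the domain (finger end, or heptapeptide end)."""
        return self.zf_span[1] if self.zf_span else self.hept_start + len(self.hept_variant)


@dataclass
class ReferenceDomain:
    """A labelled reference WRKY domain used for subgroup assignment."""

    ref_id: str
    label: str  # one of I, IIa..IIe, III
    sequence: str


@dataclass
class WRKYAnnotation:
    """Per-gene family annotation (one output-table row)."""

    gene_id: str
    group: str
    subgroup: str
    hits: list[DomainHit] = field(default_factory=list)
    chromosome: str = ""
    cds_len: int = 0
    prot_len: int = 0
    mw: float = 0.0
    pi: float = 0.0
    introns: int = 0
    rescued: bool = False
    ref_margin: float = 0.0


def _check_protein(protein: str) -> None:
    if not protein:
        raise InputError("empty protein sequence")
    bad = set(protein) - AA20
    if bad:
        raise InputError(f"non-amino-acid characters {sorted(bad)}")


def find_heptapeptides(
    protein: str, variants: Sequence[str] = HEPTAPEPTIDE_VARIANTS
) -> list[tuple[int, str]]:
    """All exact heptapeptide-variant occurrences, left to right.

    Overlapping occurrences are all reported.
    """
    _check_protein(protein)
    hits = []
    vset = tuple(variants)
    for i in range(len(protein) - 6):
        window = protein[i : i + 7]
        for v in vset:
            if window == v:
                hits.append((i, v))
                break
    return hits


def find_zinc_finger(protein: str, from_index: int, window: int = ZF_WINDOW) -> DomainHit:
    """Nearest zinc-finger match at or downstream of ``from_index``.

    Returns a :class:`DomainHit` fragment carrying only the finger fields
    (``hept_start`` is set to ``from_index`` for bookkeeping); ``zf_type`` is
    ``"none"`` when no pattern matches within ``window`` residues — absence is
    a value, not an error.
    """
    _check_protein(protein)
    if not 0 <= from_index <= len(protein):
        raise InputError(f"from_index {from_index} out of range")
    region_end = min(len(protein), from_index + window)
    for start in range(from_index, region_end):
        for zf_type, pat in _ZF_PATTERNS:
            m = pat.match(protein, start, region_end)
            if m:
                s, e = m.span()
                spacer1 = len(m.group(1))
                spacer2 = len(m.group(2))
                return DomainHit(
                    hept_start=from_index,
                    hept_variant="",
                    zf_type=zf_type,
                    zf_span=(s, e),
                    spacer1=spacer1,
                    spacer2=spacer2,
                )
    return DomainHit(hept_start=from_index, hept_variant="", zf_type="none")


def scan_protein(protein: str, variants: Sequence[str] = HEPTAPEPTIDE_VARIANTS) -> list[DomainHit]:
    """Full domain scan: heptapeptides plus their downstream zinc fingers."""
    hits = []
    for idx, variant in find_heptapeptides(protein, variants):
        zf = find_zinc_finger(protein, idx + len(variant))
        hits.append(
            DomainHit(
                hept_start=idx,
                hept_variant=variant,
                zf_type=zf.zf_type,
                zf_span=zf.zf_span,
                spacer1=zf.spacer1,
                spacer2=zf.spacer2,
            )
        )
    return hits


def classify_group(hits: Iterable[DomainHit]) -> str:
    """Group call from a protein's domain hits.

    Two or more complete C2H2 domains → I; exactly one → II; any complete
    C2HC (without a second C2H2) → III; heptapeptide(s) without a complete
    finger → ``"unresolved"`` (candidate for reference rescue).
    """
    hits = list(hits)
    if not hits:
        raise AnnotationError("no WRKY domain hits: not a WRKY protein")
    n_c2h2 = sum(1 for h in hits if h.zf_type == "C2H2")
    n_c2hc = sum(1 for h in hits if h.zf_type == "C2HC")
    if n_c2h2 >= 2:
        return "I"
    if n_c2hc >= 1:
        return "III"
    if n_c2h2 == 1:
        return "II"
    return "unresolved"


_DEFAULT_MATRIX = "BLOSUM62"


def _make_aligner(matrix: str = _DEFAULT_MATRIX) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def assign_subgroup(
    query: str,
    refs: Sequence[ReferenceDomain],
    matrix: str = _DEFAULT_MATRIX,
) -> tuple[str, float, float]:
    """Best-hit subgroup label for a query domain.

    Scores the query against every labelled reference domain by local
    alignment and returns ``(label, best_score, margin)`` where margin is the
    gap to the best reference of any *other* label. Ties on score are broken
    toward the lexicographically smallest ref_id (logged); if no reference
    scores positive the label is ``"unassigned"``.
    """
    if not refs:
        raise InputError("empty reference set")
    if not query:
        raise InputError("empty query domain")
    aligner = _make_aligner(matrix)
    scored = sorted(
        ((aligner.score(query, r.sequence), r.ref_id, r.label) for r in refs),
        key=lambda t: (-t[0], t[1]),
    )
    best_score, best_id, best_label = scored[0]
    if best_score <= 0:
        return "unassigned", best_score, 0.0
    if len(scored) > 1 and scored[1][0] == best_score:
        log.warning("[subgroup] tie at score %.1f between %s and %s; keeping %s",
                    best_score, best_id, scored[1][1], best_id)
    others = [s for s, _, lab in scored if lab != best_label]
    margin = best_score - max(others) if others else best_score
    return best_label, float(best_score), float(margin)


# EMBOSS pKa set used for the isoelectric point.
_PKA_NTERM = 8.6
_PKA_CTERM = 3.6
_PKA_SIDE = {"C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1}
_POSITIVE = frozenset("HKR")


def protein_mw(protein: str) -> float:
    """Average-mass molecular weight in kDa (sum of residue masses + water).

    Returned at full precision; output tables round half-up to 2 decimals.
    """
    _check_protein(protein)
    da = molecular_weight(protein, seq_type="protein")
    return da / 1000.0


def net_charge(protein: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge at a given pH (EMBOSS pKa values)."""
    _check_protein(protein)
    pos = 1.0 / (1.0 + 10 ** (ph - _PKA_NTERM))
    neg = 1.0 / (1.0 + 10 ** (_PKA_CTERM - ph))
    for aa in protein:
        pka = _PKA_SIDE.get(aa)
        if pka is None:
            continue
        if aa in _POSITIVE:
            pos += 1.0 / (1.0 + 10 ** (ph - pka))
        else:
            neg += 1.0 / (1.0 + 10 ** (pka - ph))
    return pos - neg


def protein_pi(protein: str, tol: float = 0.01) -> float:
    """Isoelectric point by bisection of the net-charge curve on [0, 14].

    The net charge is strictly decreasing in pH, so bisection to a pH
    interval narrower than ``tol`` brackets the unique root.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(protein, mid) > 0:
            lo = mid
        else:
            hi = mid
    return round((lo + hi) / 2.0, 2)


def count_introns(gene: GeneModel) -> int:
    """Number of introns = exon count − 1."""
    return gene.n_introns()


def _round_half_up(x: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def load_reference_domains(path: str | Path | None = None) -> list[ReferenceDomain]:
    """Load the packaged (or a user) labelled reference-domain table."""
    if path is None:
        path = resources.files("wrkyfam.data") / "reference_domains.synthetic.tsv"
    df = pd.read_csv(path, sep="\t")
    refs = [ReferenceDomain(str(r.ref_id), str(r.label), str(r.sequence)) for r in df.itertuples()]
    labels = {"I", "IIa", "IIb", "IIc", "IId", "IIe", "III"}
    for r in refs:
        if r.label not in labels:
            raise InputError(f"reference {r.ref_id}: unknown label {r.label!r}")
        if not r.sequence:
            raise InputError(f"reference {r.ref_id}: empty sequence")
    return refs


def load_table1() -> pd.DataFrame:
    """The packaged 64-gene family annotation table (fixture data)."""
    path = resources.files("wrkyfam.data") / "table1.tsv"
    return pd.read_csv(path, sep="\t")


def _domain_slice(protein: str, hit: DomainHit) -> str:
    return protein[hit.hept_start : max(hit.end, hit.hept_start + 30)]


def annotate_protein(
    gene_id: str,
    protein: str,
    refs: Sequence[ReferenceDomain],
    variants: Sequence[str] = HEPTAPEPTIDE_VARIANTS,
) -> WRKYAnnotation | None:
    """Scan and classify one protein; ``None`` if it carries no heptapeptide.

    Proteins with a heptapeptide but no complete zinc finger are rescued to
    the group of their best reference hit and flagged ``rescued`` — mirroring
    family members that have lost one domain but still cluster with group I.
    """
    hits = scan_protein(protein, variants)
    if not hits:
        return None
    group = classify_group(hits)
    subgroup = "none"
    rescued = False
    margin = 0.0
    query = _domain_slice(protein, hits[-1])
    label, _, margin = assign_subgroup(query, refs)
    if group == "unresolved":
        rescued = True
        if label == "unassigned":
            group = "unresolved"
        elif label.startswith("II"):
            group, subgroup = "II", label
        else:
            group = label
    elif group == "II":
        subgroup = label if label.startswith("II") else "none"
    ann = WRKYAnnotation(
        gene_id=gene_id,
        group=group,
        subgroup=subgroup,
        hits=hits,
        prot_len=len(protein),
        mw=protein_mw(protein),
        pi=protein_pi(protein),
        rescued=rescued,
        ref_margin=margin,
    )
    return ann


def annotate_family(
    models: Sequence[GeneModel],
    assembly: GenomeAssembly,
    refs: Sequence[ReferenceDomain] | None = None,
    variants: Sequence[str] = HEPTAPEPTIDE_VARIANTS,
) -> list[WRKYAnnotation]:
    """Identify and annotate all WRKY family members among gene models."""
    if refs is None:
        refs = load_reference_domains()
    out = []
    for gene in models:
        try:
            protein = translate_cds(gene, assembly)
        except Exception as exc:  # skip untranslatable models, but say so
            log.warning("[scan] %s: skipped (%s)", gene.gene_id, exc)
            continue
        ann = annotate_protein(gene.gene_id, protein, refs, variants)
        if ann is None:
            continue
        ann.chromosome = gene.chromosome
        ann.cds_len = gene.cds_len
        ann.introns = count_introns(gene)
        out.append(ann)
    return out


def annotations_to_frame(annotations: Sequence[WRKYAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        label = a.subgroup if a.group == "II" and a.subgroup != "none" else a.group
        rows.append(
            dict(
                name=a.gene_id, gene_id=a.gene_id, group=label, chromosome=a.chromosome,
                cds_bp=a.cds_len, protein_aa=a.prot_len,
                mw_kda=_round_half_up(a.mw, 2), pi=a.pi,
                introns=a.introns, n_domains=len(a.hits), rescued=a.rescued,
            )
        )
    return pd.DataFrame(rows)


def summarize_family_table(table: pd.DataFrame) -> dict:
    """Aggregate a family annotation table the way the study reports it.

    Expects the fixture/table columns ``group`` (subgroup label: I, IIa..IIe,
    III), ``chromosome``, ``cds_bp``, ``protein_aa``, ``mw_kda``, ``pi``.
    Means are rounded half-up to the printed precision (integer bp, 2-decimal
    kDa / pI).
    """
    if table is None or len(table) == 0:
        raise InputError("empty annotation table")
    t = table
    major = t["group"].map(lambda g: "II" if str(g).startswith("II") and g != "III" else str(g))
    group_counts = major.value_counts().to_dict()
    subgroup_counts = t.loc[major == "II", "group"].value_counts().to_dict()
    chrom_counts = t["chromosome"].astype(str).value_counts().to_dict()

    def stats(col: str, ndigits: int) -> dict:
        s = t[col]
        return {
            "min": _round_half_up(float(s.min()), ndigits),
            "max": _round_half_up(float(s.max()), ndigits),
            "mean": _round_half_up(float(s.mean()), ndigits),
        }

    return {
        "n_members": int(len(t)),
        "cds_bp": stats("cds_bp", 0),
        "protein_aa": stats("protein_aa", 0),
        "mw_kda": stats("mw_kda", 2),
        "pi": stats("pi", 2),
        "group_counts": group_counts,
        "subgroup_counts": subgroup_counts,
        "chromosome_counts": chrom_counts,
    }
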