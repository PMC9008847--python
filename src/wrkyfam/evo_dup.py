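"""Duplicate-pair detection, NG86 Ka/Ks, duplication dating and synteny.

Paralog pairs are called from protein global alignments (identity > 75% of
aligned columns and the shorter sequence covering > 75% of the longer), then
classified tandem (same chromosome, within 100 kb, no intervening family
member) or segmental. Synonymous and nonsynonymous rates are estimated by
the Nei–Gojobori (1986) counting method with Jukes–Cantor correction, and
each duplication is dated as T = Ks / (2λ) with a synonymous clock λ.
Cross-genome orthology is approximated by reciprocal best hits, with
collinear blocks called as order-preserving chains of ortholog pairs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .config import AnalysisConfig
from .errors import InputError, SaturationError, TranslationError
from .io_core import GeneModel

log = logging.getLogger("wrkyfam.evo")

_CODON_TABLE = standard_dna_table.forward_table
_STOP_CODONS = frozenset(standard_dna_table.stop_codons)
_BASES = "ACGT"


@dataclass
class DuplicatePair:
    """A paralog pair with its divergence, age and selection regime."""

    gene_a: str
    gene_b: str
    identity: float
    coverage: float
    dup_type: str  # tandem | segmental
    ka: float = float("nan")
    ks: float = float("nan")
    kaks: float = float("nan")
    t_mya: float = float("nan")
    regime: str = "undefined"


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    score: float
    reciprocal: bool


@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    orientation: str  # + | -
    pairs: list[OrthologPair]

    def __len__(self) -> int:
        return len(self.pairs)


def _global_aligner(matrix: str = "BLOSUM62") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    # terminal gaps are free so coverage reflects genuine overlap
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def _aligned_strings(a: str, b: str, matrix: str = "BLOSUM62") -> tuple[str, str]:
    aln = _global_aligner(matrix).align(a, b)[0]
    sa, sb = str(aln[0]), str(aln[1])
    return sa, sb


def pairwise_protein_identity(a: str, b: str, matrix: str = "BLOSUM62") -> tuple[float, float]:
    """Identity and coverage of two proteins under global alignment.

    identity: identical columns / aligned columns excluding terminal gaps.
    coverage: columns where both sequences have a residue / longer length.
    Symmetric in (a, b).
    """
    if not a or not b:
        raise InputError("empty protein sequence")
    sa, sb = _aligned_strings(a, b, matrix)
    # trim terminal gap columns (gap in either sequence at the ends)
    start = 0
    end = len(sa)
    while start < end and (sa[start] == "-" or sb[start] == "-"):
        start += 1
    while end > start and (sa[end - 1] == "-" or sb[end - 1] == "-"):
        end -= 1
    core_a, core_b = sa[start:end], sb[start:end]
    ncols = len(core_a)
    if ncols == 0:
        return 0.0, 0.0
    ident = sum(1 for x, y in zip(core_a, core_b) if x == y and x != "-")
    both = sum(1 for x, y in zip(sa, sb) if x != "-" and y != "-")
    coverage = both / max(len(a), len(b))
    return ident / ncols, coverage


def codon_align(cds_a: str, cds_b: str, matrix: str = "BLOSUM62") -> tuple[str, str]:
    """Gap-free in-frame codon alignment of two CDS.

    The protein global alignment is back-threaded onto the coding sequences
    codon by codon; columns with a gap in either protein are dropped.
    Trailing stop codons are stripped before translation.
    """
    pa = _translate_for_alignment(cds_a)
    pb = _translate_for_alignment(cds_b)
    sa, sb = _aligned_strings(pa, pb, matrix)
    out_a, out_b = [], []
    ia = ib = 0
    for x, y in zip(sa, sb):
        if x != "-" and y != "-":
            out_a.append(cds_a[3 * ia : 3 * ia + 3])
            out_b.append(cds_b[3 * ib : 3 * ib + 3])
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
    return "".join(out_a), "".join(out_b)


def _translate_for_alignment(cds: str) -> str:
    if len(cds) < 3 or len(cds) % 3:
        raise TranslationError(f"CDS length {len(cds)} not a positive multiple of 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons[-1] in _STOP_CODONS:
        codons = codons[:-1]
    prot = []
    for i, c in enumerate(codons):
        if c in _STOP_CODONS:
            raise TranslationError(f"internal stop at codon {i}")
        prot.append(_CODON_TABLE[c])
    return "".join(prot)


# ---------------------------------------------------------------------------
# NG86 with Jukes-Cantor correction
# ---------------------------------------------------------------------------

def _codon_aa(codon: str) -> str | None:
    """Amino acid for a codon, or None for a stop."""
    return _CODON_TABLE.get(codon)


def _syn_fraction(codon: str) -> float:
    """Synonymous site count of one codon (NG86 site definition).

    Each of the three positions contributes the fraction of its three
    possible single-base changes that preserve the amino acid; changes to a
    stop codon count as nonsynonymous.
    """
    aa = _codon_aa(codon)
    if aa is None:
        raise InputError(f"stop codon {codon} in alignment")
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if _codon_aa(alt) == aa:
                s += 1.0 / 3.0
    return s


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two codons.

    All minimal substitution pathways (orderings of the differing positions)
    are averaged with equal weight; pathways passing through a stop codon are
    discarded. If every pathway is blocked by stops, all pathways are used
    with steps into or out of a stop counted as nonsynonymous.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0

    def walk(order: tuple[int, ...], allow_stops: bool) -> tuple[float, float] | None:
        cur = codon_a
        sd = nd = 0.0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            aa_cur, aa_nxt = _codon_aa(cur), _codon_aa(nxt)
            if aa_nxt is None and nxt != codon_b and not allow_stops:
                return None
            if aa_cur is not None and aa_nxt is not None and aa_cur == aa_nxt:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd

    paths = [walk(order, allow_stops=False) for order in itertools.permutations(diff)]
    valid = [p for p in paths if p is not None]
    if not valid:
        valid = [walk(order, allow_stops=True) for order in itertools.permutations(diff)]
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


def ng86_site_counts(cds_a: str, cds_b: str) -> tuple[float, float, float, float]:
    """(S, N, Sd, Nd) — NG86 site and difference counts for an aligned pair.

    Sites are averaged over the two sequences; differences are averaged over
    all minimal substitution pathways per codon.
    """
    if len(cds_a) != len(cds_b):
        raise InputError(f"aligned CDS lengths differ ({len(cds_a)} vs {len(cds_b)})")
    if not cds_a or len(cds_a) % 3:
        raise InputError(f"aligned CDS length {len(cds_a)} not a positive multiple of 3")
    S = Sd = Nd = 0.0
    n_codons = len(cds_a) // 3
    for i in range(n_codons):
        ca, cb = cds_a[3 * i : 3 * i + 3], cds_b[3 * i : 3 * i + 3]
        S += (_syn_fraction(ca) + _syn_fraction(cb)) / 2.0
        sd, nd = _pathway_counts(ca, cb)
        Sd += sd
        Nd += nd
    N = 3.0 * n_codons - S
    return S, N, Sd, Nd


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); p >= 3/4 saturates."""
    if p < 0:
        raise InputError(f"negative proportion {p}")
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.4f} at or beyond Jukes-Cantor ceiling 3/4")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86_kaks(cds_a: str, cds_b: str) -> tuple[float, float]:
    """(Ka, Ks) by NG86 counting with Jukes-Cantor correction.

    Expects equal-length, gap-free, in-frame codon alignments (run
    :func:`codon_align` first for unaligned CDS); trailing stop codons are
    stripped when both sequences end in one.
    """
    if len(cds_a) >= 3 and len(cds_a) == len(cds_b):
        if cds_a[-3:] in _STOP_CODONS and cds_b[-3:] in _STOP_CODONS:
            cds_a, cds_b = cds_a[:-3], cds_b[:-3]
    S, N, Sd, Nd = ng86_site_counts(cds_a, cds_b)
    ps = Sd / S if S > 0 else 0.0
    pn = Nd / N if N > 0 else 0.0
    return jukes_cantor(pn), jukes_cantor(ps)


def date_duplication(ks: float, lambda_rate: float = 6.1e-9) -> float:
    """Age of a duplication in Mya: T = Ks / (2λ) / 10⁶."""
    if ks < 0:
        raise InputError(f"negative Ks {ks}")
    if lambda_rate <= 0:
        raise InputError("lambda_rate must be positive")
    return ks / (2.0 * lambda_rate) / 1e6


def classify_regime(ka: float, ks: float, tol: float = 1e-9) -> str:
    """Selection regime from the Ka/Ks ratio (purifying / neutral / positive)."""
    if ka < 0 or ks < 0:
        raise InputError("Ka and Ks must be nonnegative")
    if ks == 0:
        return "undefined"
    ratio = ka / ks
    if abs(ratio - 1.0) <= tol:
        return "neutral"
    return "purifying" if ratio < 1.0 else "positive"


def find_duplicate_pairs(
    models: Sequence[GeneModel],
    proteins: Mapping[str, str],
    cds: Mapping[str, str],
    config: AnalysisConfig | None = None,
) -> list[DuplicatePair]:
    """All duplicate pairs within a gene family, classified and dated.

    A pair qualifies when protein identity and coverage both exceed the
    configured thresholds (strict inequality). Tandem requires the same
    chromosome, start-to-start distance within ``tandem_dist`` and — unless
    ``tandem_requires_adjacency`` is off — no third family member between the
    two; everything else is segmental. Ka/Ks saturation leaves the rate
    fields NaN with a logged warning.
    """
    config = config or AnalysisConfig()
    by_id = {g.gene_id: g for g in models}
    order: dict[str, list[tuple[int, str]]] = {}
    for g in models:
        order.setdefault(g.chromosome, []).append((g.span[0], g.gene_id))
    for lst in order.values():
        lst.sort()
    pairs: list[DuplicatePair] = []
    ids = [g.gene_id for g in models]
    for ga_id, gb_id in itertools.combinations(ids, 2):
        identity, coverage = pairwise_protein_identity(proteins[ga_id], proteins[gb_id])
        if identity <= config.pair_identity_min or coverage <= config.pair_coverage_min:
            continue
        ga, gb = by_id[ga_id], by_id[gb_id]
        dup_type = "segmental"
        if ga.chromosome == gb.chromosome:
            dist = abs(ga.span[0] - gb.span[0])
            if dist <= config.tandem_dist:
                if config.tandem_requires_adjacency:
                    lo, hi = sorted((ga.span[0], gb.span[0]))
                    between = [gid for s, gid in order[ga.chromosome]
                               if lo < s < hi and gid not in (ga_id, gb_id)]
                    dup_type = "tandem" if not between else "segmental"
                else:
                    dup_type = "tandem"
        pair = DuplicatePair(ga_id, gb_id, identity, coverage, dup_type)
        try:
            aln_a, aln_b = codon_align(cds[ga_id], cds[gb_id])
            ka, ks = ng86_kaks(aln_a, aln_b)
            pair.ka, pair.ks = ka, ks
            pair.kaks = ka / ks if ks > 0 else float("nan")
            pair.t_mya = date_duplication(ks, config.lambda_rate)
            pair.regime = classify_regime(ka, ks)
        except SaturationError as exc:
            log.warning("[dup] %s-%s: %s", ga_id, gb_id, exc)
        pairs.append(pair)
    return pairs


def reciprocal_best_hits(
    proteome_a: Mapping[str, str],
    proteome_b: Mapping[str, str],
    matrix: str = "BLOSUM62",
) -> list[OrthologPair]:
    """Reciprocal best hits between two proteomes by local-alignment score.

    A pair is reciprocal iff each member is the other's unique top hit; ties
    for the top score yield no call (logged).
    """
    if not proteome_a or not proteome_b:
        raise InputError("empty proteome")
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    scores: dict[tuple[str, str], float] = {}
    for ida, pa in proteome_a.items():
        for idb, pb in proteome_b.items():
            scores[(ida, idb)] = float(aligner.score(pa, pb))

    def unique_best(ident: str, candidates: list[str], get) -> str | None:
        ranked = sorted(((-get(c), c) for c in candidates))
        if len(ranked) > 1 and ranked[0][0] == ranked[1][0]:
            log.warning("[rbh] tie for %s at score %.1f; no reciprocal call", ident, -ranked[0][0])
            return None
        return ranked[0][1]

    ids_a, ids_b = list(proteome_a), list(proteome_b)
    best_a = {a: unique_best(a, ids_b, lambda b: scores[(a, b)]) for a in ids_a}
    best_b = {b: unique_best(b, ids_a, lambda a: scores[(a, b)]) for b in ids_b}

    out = [
        OrthologPair(a, b, scores[(a, b)], True)
        for a, b in scores
        if best_a[a] == b and b is not None and best_b[b] == a
    ]
    return sorted(out, key=lambda p: (p.gene_a, p.gene_b))


def collinear_blocks(
    pairs: Sequence[OrthologPair],
    order_a: Mapping[str, Sequence[str]],
    order_b: Mapping[str, Sequence[str]],
    min_chain: int = 3,
) -> list[CollinearBlock]:
    """Order-preserving chains of ortholog pairs between chromosome pairs.

    Within each chromosome pair, chains must be strictly increasing in
    genome-A rank and strictly monotone (increasing or decreasing) in
    genome-B rank. Chains of length ≥ ``min_chain`` are extracted greedily,
    longest first, each pair used at most once.
    """
    rank_a = {g: (c, i) for c, genes in order_a.items() for i, g in enumerate(genes)}
    rank_b = {g: (c, i) for c, genes in order_b.items() for i, g in enumerate(genes)}
    grouped: dict[tuple[str, str], list[tuple[int, int, OrthologPair]]] = {}
    for p in pairs:
        if p.gene_a not in rank_a or p.gene_b not in rank_b:
            continue
        ca, ia = rank_a[p.gene_a]
        cb, ib = rank_b[p.gene_b]
        grouped.setdefault((ca, cb), []).append((ia, ib, p))

    blocks: list[CollinearBlock] = []
    for (ca, cb), items in sorted(grouped.items()):
        remaining = sorted(items)
        while True:
            chain_up = _longest_chain(remaining, descending=False)
            chain_dn = _longest_chain(remaining, descending=True)
            chain, orient = (chain_up, "+") if len(chain_up) >= len(chain_dn) else (chain_dn, "-")
            if len(chain) < min_chain:
                break
            blocks.append(CollinearBlock(ca, cb, orient, [p for _, _, p in chain]))
            used = {id(t) for t in chain}
            remaining = [t for t in remaining if id(t) not in used]
    return blocks


def _longest_chain(items: list[tuple[int, int, OrthologPair]], descending: bool) -> list:
    """Longest chain strictly increasing in rank A and strictly monotone in B (DP)."""
    n = len(items)
    if n == 0:
        return []
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if items[j][0] >= items[i][0]:
                continue
            if descending:
                ok = items[j][1] > items[i][1]
            else:
                ok = items[j][1] < items[i][1]
            if ok and best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    end = max(range(n), key=lambda i: best_len[i])
    chain = []
    while end != -1:
        chain.append(items[end])
        end = prev[end]
    return chain[::-1]
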