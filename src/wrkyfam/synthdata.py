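"""Seeded generators for every pipeline input, with recorded ground truth.

Each generator is a pure function of its arguments (seed included) and
returns, beside the dataset, a :class:`SyntheticTruth` record of everything
that was planted: gene groups and intron counts, promoter element positions,
duplicate-pair target divergences, differential-expression effects and
coexpression modules. The generated data emulate the shape of a small plant
genome study — a compact genome with a WRKY family of known composition,
paralog pairs of controlled synonymous divergence, 2-kb promoters with known
element content, and TPM expression matrices with planted effects.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, SaturationError
from .evo_dup import _CODON_TABLE, _STOP_CODONS, ng86_site_counts
from .expression import ExpressionMatrix
from .io_core import GeneModel, GenomeAssembly, reverse_complement
from .promoter_cis import IUPAC, CisMotif, scan_motif
from .wrky_scan import load_reference_domains

#: Background base composition (GC = 0.40).
_BG_BASES = "ACGT"
_BG_WEIGHTS = (0.30, 0.20, 0.20, 0.30)

# flank alphabet for synthetic proteins: no W (cannot seed a spurious
# heptapeptide), no C/H (cannot seed a spurious zinc finger)
_FLANK_AA = "ADEFGIKLMNPQRSTVY"

_CODONS_OF: dict[str, list[str]] = {}
for codon, aa in _CODON_TABLE.items():
    _CODONS_OF.setdefault(aa, []).append(codon)
for v in _CODONS_OF.values():
    v.sort()
_SENSE_CODONS = sorted(_CODON_TABLE)


@dataclass
class SyntheticTruth:
    """Ground truth for a generated dataset."""

    seed: int
    groups: dict[str, str] = field(default_factory=dict)
    subgroups: dict[str, str] = field(default_factory=dict)
    introns: dict[str, int] = field(default_factory=dict)
    promoter_elements: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    ks_target: float | None = None
    ka_target: float | None = None
    de_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    modules: list[list[str]] = field(default_factory=list)
    folds: dict[str, dict[str, float]] = field(default_factory=dict)


def _bg_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choices(_BG_BASES, weights=_BG_WEIGHTS, k=n))


def _reverse_translate(rng: random.Random, protein: str) -> str:
    return "".join(rng.choice(_CODONS_OF[aa]) for aa in protein)


def _mutate_domain(rng: random.Random, domain: str, k: int) -> str:
    """Substitute up to k residues outside the heptapeptide and C/H anchors."""
    seq = list(domain)
    hept = domain.find("WRKYGQK")
    fixed = set(range(hept, hept + 7)) if hept >= 0 else set()
    fixed |= {i for i, aa in enumerate(seq) if aa in "CH"}
    pool = [i for i in range(len(seq)) if i not in fixed]
    for i in rng.sample(pool, min(k, len(pool))):
        seq[i] = rng.choice([a for a in _FLANK_AA if a != seq[i]])
    return "".join(seq)


def _plant_protein(rng: random.Random, group: str, subgroup: str,
                   refs_by_label: Mapping[str, str]) -> str:
    """Build a family-member protein for a planted group/subgroup."""
    if group == "I":
        d1 = _mutate_domain(rng, refs_by_label["I"], 3)
        d2 = _mutate_domain(rng, refs_by_label["I"], 3)
        core = d1 + "".join(rng.choices(_FLANK_AA, k=30)) + d2
    else:
        label = subgroup if group == "II" else "III"
        core = _mutate_domain(rng, refs_by_label[label], 3)
    nflank = "".join(rng.choices(_FLANK_AA, k=rng.randint(15, 40)))
    cflank = "".join(rng.choices(_FLANK_AA, k=rng.randint(10, 30)))
    return "M" + nflank + core + cflank


def _scrub_motif(chrom: list[str], motif: CisMotif, window: tuple[int, int],
                 keep: list[tuple[int, int]], rng: random.Random) -> None:
    """Remove chance occurrences of a motif from a genome window.

    Bases inside the ``keep`` intervals (planted copies) are never touched.
    """
    lo, hi = window
    protected = set()
    for s, e in keep:
        protected.update(range(s, e))
    for _ in range(50):  # converges in a few passes
        seq = "".join(chrom[lo:hi])
        hits = scan_motif(seq, motif)
        dirty = False
        for h in hits:
            s = lo + h.offset
            e = s + len(motif.iupac)
            if all(p in protected for p in range(s, e)):
                continue
            editable = [p for p in range(s, e) if p not in protected]
            if not editable:
                continue
            p = rng.choice(editable)
            chrom[p] = rng.choice([b for b in "ACGT" if b != chrom[p]])
            dirty = True
        if not dirty:
            return


def gen_family_genome(
    n_genes: int,
    group_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    n_chromosomes: int = 4,
    promoter_elements: Mapping[str, tuple[str, int]] | None = None,
    promoter_len: int = 2000,
    utr5: int = 50,
    intergenic: int = 2600,
) -> tuple[GenomeAssembly, list[GeneModel], SyntheticTruth]:
    """A small genome carrying a WRKY family of known composition.

    Each gene's CDS encodes a protein with the planted heptapeptide(s) and
    zinc-finger pattern of its group (I: two C2H2 domains; II: one C2H2,
    subgroup drawn uniformly from IIa–e; III: one C2HC), embedded in random
    flanks and split over multi-exon structures with known intron counts.
    ``promoter_elements`` maps a motif name to ``(consensus, copies)``; the
    stated number of copies is planted into every gene's promoter and chance
    occurrences of that motif are scrubbed from the rest of the window, so
    the truth positions are exhaustive.
    """
    if n_genes < 1:
        raise InputError("n_genes must be >= 1")
    group_mix = dict(group_mix or {"I": 0.3, "II": 0.5, "III": 0.2})
    if abs(sum(group_mix.values()) - 1.0) > 1e-9:
        raise InputError(f"group_mix must sum to 1, got {sum(group_mix.values())}")
    if any(v < 0 for v in group_mix.values()):
        raise InputError("group_mix fractions must be nonnegative")
    rng = random.Random(seed)
    if promoter_elements:
        # promoters must not overlap between neighbouring genes when planting
        intergenic = max(intergenic, 2 * promoter_len + 200)
    refs_by_label = {}
    for ref in load_reference_domains():
        refs_by_label.setdefault(ref.label, ref.sequence)

    truth = SyntheticTruth(seed=seed)
    groups = list(group_mix)
    weights = [group_mix[g] for g in groups]
    chroms: dict[str, list[str]] = {f"chr{i + 1}": [] for i in range(n_chromosomes)}
    models: list[GeneModel] = []

    for gi in range(n_genes):
        gene_id = f"SYNW{gi + 1:03d}"
        group = rng.choices(groups, weights=weights)[0]
        subgroup = rng.choice(["IIa", "IIb", "IIc", "IId", "IIe"]) if group == "II" else "none"
        protein = _plant_protein(rng, group, subgroup, refs_by_label)
        cds = _reverse_translate(rng, protein) + rng.choice(["TAA", "TGA", "TAG"])
        n_introns = rng.randint(1, 6)
        cuts = sorted(rng.sample(range(3, len(cds) - 3), n_introns))
        cds_parts = [cds[a:b] for a, b in zip([0] + cuts, cuts + [len(cds)])]

        # forward-sense gene region: 5' UTR + exon/intron alternation
        region_parts: list[str] = [_bg_seq(rng, utr5)]
        exon_rel: list[tuple[int, int]] = []
        cds_rel: list[tuple[int, int]] = []
        pos = utr5
        exon_rel.append((0, utr5))  # first exon starts with the UTR
        for pi, part in enumerate(cds_parts):
            if pi > 0:
                intron = _bg_seq(rng, rng.randint(80, 300))
                region_parts.append(intron)
                pos += len(intron)
                exon_rel.append((pos, pos))
            region_parts.append(part)
            cds_rel.append((pos, pos + len(part)))
            s, _ = exon_rel[-1]
            exon_rel[-1] = (s, pos + len(part))
            pos += len(part)
        region = "".join(region_parts)

        chrom_name = f"chr{gi % n_chromosomes + 1}"
        chrom = chroms[chrom_name]
        strand = rng.choice("+-")
        gap = _bg_seq(rng, intergenic)
        chrom.extend(gap)
        gene_start = len(chrom)
        L = len(region)
        if strand == "+":
            chrom.extend(region)
            exons = [(gene_start + s, gene_start + e) for s, e in exon_rel]
            cds_iv = [(gene_start + s, gene_start + e) for s, e in cds_rel]
        else:
            chrom.extend(reverse_complement(region))
            exons = [(gene_start + L - e, gene_start + L - s) for s, e in exon_rel]
            cds_iv = [(gene_start + L - e, gene_start + L - s) for s, e in cds_rel]
        models.append(
            GeneModel(gene_id, chrom_name, strand, (gene_start, gene_start + L),
                      exons=exons, cds=cds_iv)
        )
        truth.groups[gene_id] = group
        truth.subgroups[gene_id] = subgroup
        truth.introns[gene_id] = n_introns

    for chrom in chroms.values():
        chrom.extend(_bg_seq(rng, intergenic))

    if promoter_elements:
        for gene in models:
            chrom = chroms[gene.chromosome]
            anchor = gene.transcription_start
            truth.promoter_elements[gene.gene_id] = {}
            for name, (consensus, copies) in promoter_elements.items():
                motif = CisMotif(name, consensus.upper())
                m = len(consensus)
                offsets = [100 + j * (m + 40) for j in range(copies)]
                if offsets and offsets[-1] + m > promoter_len:
                    raise InputError(f"too many copies of {name} for a {promoter_len}-bp promoter")
                keep = []
                for off in offsets:
                    # instantiate ambiguity codes to concrete bases
                    planted = "".join(rng.choice(IUPAC[c]) for c in motif.iupac)
                    # promoter offset off is 0 at the far (5') end of the window
                    if gene.strand == "+":
                        s = anchor - promoter_len + off
                        chrom[s : s + m] = list(planted)
                    else:
                        s = anchor + promoter_len - off - m
                        chrom[s : s + m] = list(reverse_complement(planted))
                    keep.append((s, s + m))
                if gene.strand == "+":
                    window = (anchor - promoter_len, anchor)
                else:
                    window = (anchor, anchor + promoter_len)
                _scrub_motif(chrom, motif, window, keep, rng)
                truth.promoter_elements[gene.gene_id][name] = offsets

    assembly = GenomeAssembly({name: "".join(seq) for name, seq in chroms.items()})
    return assembly, models, truth


def gen_duplicate_pair(
    n_codons: int,
    ks_target: float,
    ka_target: float = 0.05,
    seed: int = 0,
) -> tuple[str, str, SyntheticTruth]:
    """A CDS pair with controlled synonymous and nonsynonymous divergence.

    The second sequence is derived from the first by a Poisson number of
    single-base substitutions placed at distinct synonymous (resp.
    nonsynonymous) sites, so that the NG86 proportions match the
    Jukes-Cantor-implied targets in expectation. Substitutions never create
    stop codons; at most one substitution lands in any codon. Targets whose
    implied proportion approaches the JC ceiling raise
    :class:`SaturationError`.
    """
    if n_codons < 100:
        raise InputError("n_codons must be >= 100")
    if ks_target < 0 or ka_target < 0:
        raise InputError("divergence targets must be nonnegative")
    rng = random.Random(seed)
    codons_a = [rng.choice(_SENSE_CODONS) for _ in range(n_codons)]
    cds_a = "".join(codons_a)
    S, N, _, _ = ng86_site_counts(cds_a, cds_a)

    def implied_p(d: float) -> float:
        p = 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))
        if p > 0.70:
            raise SaturationError(
                f"target divergence {d} implies p={p:.3f}, too close to the JC ceiling")
        return p

    n_syn = int(np.random.default_rng(seed).poisson(implied_p(ks_target) * S)) if ks_target > 0 else 0
    n_non = int(np.random.default_rng(seed + 1).poisson(implied_p(ka_target) * N)) if ka_target > 0 else 0

    codons_b = list(codons_a)
    touched: set[int] = set()

    def candidates(synonymous: bool) -> list[tuple[int, str]]:
        out = []
        for ci in range(n_codons):
            if ci in touched:
                continue
            codon = codons_b[ci]
            aa = _CODON_TABLE[codon]
            for pos in range(3):
                for base in "ACGT":
                    if base == codon[pos]:
                        continue
                    alt = codon[:pos] + base + codon[pos + 1 :]
                    if alt in _STOP_CODONS:
                        continue
                    if (_CODON_TABLE[alt] == aa) == synonymous:
                        out.append((ci, alt))
        return out

    for count, synonymous in ((n_syn, True), (n_non, False)):
        pool = candidates(synonymous)
        by_codon: dict[int, list[str]] = {}
        for ci, alt in pool:
            by_codon.setdefault(ci, []).append(alt)
        if count > len(by_codon):
            raise SaturationError("not enough untouched codons for the target divergence")
        for ci in rng.sample(sorted(by_codon), count):
            codons_b[ci] = rng.choice(by_codon[ci])
            touched.add(ci)

    truth = SyntheticTruth(seed=seed, ks_target=ks_target, ka_target=ka_target)
    return cds_a, "".join(codons_b), truth


def gen_expression(
    n_genes: int,
    conditions: Sequence[str],
    n_reps: int = 3,
    de_effects: Mapping[str, Mapping[str, float]] | None = None,
    modules: Sequence[Sequence[str]] | None = None,
    noise_sd: float = 0.2,
    module_noise_sd: float | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """A TPM matrix with planted log2 effects and coexpression modules.

    Genes are named G0001..; samples ``<condition>_r<rep>``. Log2-scale
    means carry the planted per-condition effects; module members follow a
    shared per-sample latent profile with their own (typically tighter)
    noise ``module_noise_sd`` so their pairwise correlation approaches 1 as
    it shrinks, while the background keeps the realistic ``noise_sd``.
    Values are exponentiated and renormalised to TPM (columns sum to 10⁶);
    the renormalisation couples genes through the library total, as in real
    TPM data, so module recovery is only clean against a background large
    enough to buffer the module's mass.
    """
    if n_reps < 2:
        raise InputError("n_reps must be >= 2")
    if not conditions:
        raise InputError("need at least one condition")
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    de_effects = {g: dict(v) for g, v in (de_effects or {}).items()}
    modules = [list(m) for m in (modules or [])]
    unknown = {g for m in modules for g in m} - set(genes)
    unknown |= set(de_effects) - set(genes)
    if unknown:
        raise InputError(f"unknown gene ids in planted-truth arguments: {sorted(unknown)}")

    samples = [f"{c}_r{r + 1}" for c in conditions for r in range(n_reps)]
    cond_of = {s: s.rsplit("_r", 1)[0] for s in samples}
    base = rng.uniform(3.0, 8.0, size=n_genes)
    log2x = np.tile(base[:, None], (1, len(samples)))
    for gi, g in enumerate(genes):
        for cond, eff in de_effects.get(g, {}).items():
            for si, s in enumerate(samples):
                if cond_of[s] == cond:
                    log2x[gi, si] += eff
    module_ids = set()
    for m in modules:
        latent = rng.normal(0.0, 1.5, size=len(samples))
        for g in m:
            gi = genes.index(g)
            log2x[gi, :] = base[gi] + latent
            module_ids.add(g)
    noise = rng.normal(0.0, 1.0, size=log2x.shape)
    sd_row = np.array([
        (module_noise_sd if module_noise_sd is not None else noise_sd)
        if g in module_ids else noise_sd
        for g in genes
    ])
    log2x += noise * sd_row[:, None]
    raw = np.power(2.0, log2x)
    tpm = raw / raw.sum(axis=0, keepdims=True) * 1e6
    values = pd.DataFrame(tpm, index=genes, columns=samples)
    cond_series = pd.Series([cond_of[s] for s in samples], index=samples)
    truth = SyntheticTruth(seed=seed, de_effects=de_effects, modules=modules)
    return ExpressionMatrix(values, cond_series), truth


def gen_ct_table(
    fold_truth: Mapping[str, Mapping[str, float]],
    ct_ref: float = 15.0,
    noise_sd: float = 0.1,
    seed: int = 0,
    n_reps: int = 3,
    control: str = "0h",
    reference: str = "18S",
    ct_base: float = 24.0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """A tidy qPCR Ct table consistent with planted fold changes.

    ``fold_truth`` maps gene → condition → true fold relative to the control
    condition (control fold is fixed at 1). The reference gene rows carry a
    constant baseline Ct; target Ct drops by log2(fold) under each condition.
    """
    rng = np.random.default_rng(seed)
    conditions = sorted({c for folds in fold_truth.values() for c in folds} | {control})
    rows = []
    for cond in conditions:
        for rep in range(1, n_reps + 1):
            rows.append((reference, cond, rep, ct_ref + rng.normal(0, noise_sd)))
    truth = SyntheticTruth(seed=seed)
    for gene, folds in fold_truth.items():
        truth.folds[gene] = {control: 1.0, **dict(folds)}
        for cond in conditions:
            fold = 1.0 if cond == control else folds.get(cond, 1.0)
            if fold <= 0:
                raise InputError(f"{gene}/{cond}: fold must be positive")
            for rep in range(1, n_reps + 1):
                ct = ct_base - math.log2(fold) + rng.normal(0, noise_sd)
                rows.append((gene, cond, rep, ct))
    table = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])
    return table, truth


def gen_ortholog_proteomes(
    n_genes: int, seed: int = 0, n_mutations: int = 10, length: tuple[int, int] = (120, 250)
) -> tuple[dict[str, str], dict[str, str], dict[str, str]]:
    """Two proteomes related by planted 1:1 orthology (for best-hit tests).

    Returns (proteome_a, proteome_b, a_to_b mapping). Each B protein is its
    A counterpart with ``n_mutations`` random substitutions.
    """
    rng = random.Random(seed)
    aa = "ACDEFGHIKLMNPQRSTVWY"
    proteome_a, proteome_b, mapping = {}, {}, {}
    for i in range(n_genes):
        ida, idb = f"A{i + 1:03d}", f"B{i + 1:03d}"
        prot = "".join(rng.choice(aa) for _ in range(rng.randint(*length)))
        mut = list(prot)
        for p in rng.sample(range(len(mut)), min(n_mutations, len(mut))):
            mut[p] = rng.choice([x for x in aa if x != mut[p]])
        proteome_a[ida] = prot
        proteome_b[idb] = "".join(mut)
        mapping[ida] = idb
    return proteome_a, proteome_b, mapping
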