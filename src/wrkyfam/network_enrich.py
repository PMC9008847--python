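"""Target prediction, pathway enrichment and coexpression networks.

A gene is a predicted WRKY target when its 2-kb region upstream of the ATG
carries at least one W-box ((C/T)TGAC(C/T)) on either strand. Predicted
target sets are tested for pathway over-representation with the
hypergeometric upper tail (equivalent to one-sided Fisher's exact for this
margin structure) and Benjamini–Hochberg FDR control. TF–gene coexpression
edges are retained at |PCC| ≥ 0.95 with p < 0.05 (both configurable, as is
Pearson vs Spearman).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .errors import InputError
from .expression import ExpressionMatrix, log_transform
from .io_core import GeneModel, GenomeAssembly, extract_upstream
from .promoter_cis import W_BOX, scan_motif


@dataclass
class CoexpressionEdge:
    tf: str
    partner: str
    pcc: float
    p_value: float

    @property
    def sign(self) -> str:
        return "positive" if self.pcc >= 0 else "negative"


@dataclass
class EnrichmentResult:
    pathway: str
    k: int  # targets annotated to the pathway
    K: int  # background genes annotated to the pathway
    n: int  # target-set size (within background)
    N: int  # background size
    p_value: float
    q_value: float
    significant: bool


def predict_targets(
    genes: Sequence[GeneModel],
    assembly: GenomeAssembly,
    promoter_len: int = 2000,
    anchor: str = "translation_start",
) -> set[str]:
    """Genes with ≥1 W-box in the upstream region (either strand)."""
    targets = set()
    for gene in genes:
        prom = extract_upstream(gene, assembly, promoter_len, anchor=anchor)
        if scan_motif(prom, W_BOX):
            targets.add(gene.gene_id)
    return targets


def hypergeom_enrich(
    targets: set[str],
    pathway_map: Mapping[str, Sequence[str]],
    background: set[str] | None = None,
    config: AnalysisConfig | None = None,
) -> list[EnrichmentResult]:
    """Pathway over-representation of a target set.

    ``pathway_map`` maps pathway id → annotated genes. The background
    defaults to all genes in the map; targets outside the background are
    ignored. Significance requires p < enrich_p_max and BH q < enrich_fdr_max.
    """
    config = config or AnalysisConfig()
    if background is None:
        background = {g for genes in pathway_map.values() for g in genes}
    if not background:
        raise InputError("empty background")
    N = len(background)
    tset = targets & background
    n = len(tset)
    rows = []
    for pathway in sorted(pathway_map):
        annotated = set(pathway_map[pathway]) & background
        K = len(annotated)
        k = len(annotated & tset)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((pathway, k, K, p))
    if not rows:
        return []
    pvals = [r[3] for r in rows]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    out = []
    for (pathway, k, K, p), q in zip(rows, qvals):
        sig = bool(p < config.enrich_p_max and q < config.enrich_fdr_max)
        out.append(EnrichmentResult(pathway, k, K, n, N, p, float(q), sig))
    return out


def pearson_edge(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with its two-sided t-distribution p-value.

    r = ±1 returns p = 0. Vectors must have equal length ≥ 3 and nonzero
    variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InputError("profiles must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InputError("zero-variance profile: correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    if abs(r) >= 1.0 - 1e-12:  # exactly collinear up to float round-off
        return math.copysign(1.0, r), 0.0
    return r, float(res.pvalue)


def spearman_edge(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise InputError("profiles must have equal length >= 3")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def build_network(
    tf_genes: Sequence[str],
    matrix: ExpressionMatrix,
    config: AnalysisConfig | None = None,
    log_scale: bool = True,
) -> list[CoexpressionEdge]:
    """Score all TF × non-TF pairs and keep significant coexpression edges.

    Profiles are log2(TPM+1) by default. An edge is retained when
    |r| ≥ pcc_min and p < pcc_p_max (Pearson or Spearman per config).
    Self-pairs and TF–TF pairs are excluded.
    """
    config = config or AnalysisConfig()
    missing = set(tf_genes) - set(matrix.genes)
    if missing:
        raise InputError(f"TF genes absent from matrix: {sorted(missing)}")
    values = log_transform(matrix.values) if log_scale else matrix.values
    corr = pearson_edge if config.pcc_method == "pearson" else spearman_edge
    tf_set = set(tf_genes)
    partners = [g for g in matrix.genes if g not in tf_set]
    edges = []
    for tf in tf_genes:
        xtf = values.loc[tf].to_numpy()
        if np.std(xtf) == 0:
            continue
        for partner in partners:
            xp = values.loc[partner].to_numpy()
            if np.std(xp) == 0:
                continue
            r, p = corr(xtf, xp)
            if abs(r) >= config.pcc_min and p < config.pcc_p_max:
                edges.append(CoexpressionEdge(tf, partner, r, p))
    return edges


def network_summary(edges: Sequence[CoexpressionEdge]) -> dict:
    """Edge counts by sign, partner count and per-TF degree."""
    degree: dict[str, int] = {}
    for e in edges:
        degree[e.tf] = degree.get(e.tf, 0) + 1
    return {
        "n_edges": len(edges),
        "n_positive": sum(1 for e in edges if e.sign == "positive"),
        "n_negative": sum(1 for e in edges if e.sign == "negative"),
        "n_partners": len({e.partner for e in edges}),
        "tf_degree": degree,
    }


def edges_to_frame(edges: Sequence[CoexpressionEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.tf, e.partner, e.pcc, e.p_value, e.sign) for e in edges],
        columns=["tf", "gene", "pcc", "p", "sign"],
    )


def write_graphml(edges: Sequence[CoexpressionEdge], path) -> None:
    """Export the coexpression network for external viewers."""
    g = nx.Graph()
    for e in edges:
        g.add_node(e.tf, kind="tf")
        if e.partner not in g:
            g.add_node(e.partner, kind="gene")
        g.add_edge(e.tf, e.partner, pcc=e.pcc, p=e.p_value, sign=e.sign)
    nx.write_graphml(g, path)
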