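"""End-to-end orchestration: run all stages on one input bundle.

The pipeline is deterministic given inputs and config; a manifest written
next to the outputs records the config and a hash of it so a run can be
audited and reproduced.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import evo_dup, expression, network_enrich, promoter_cis, wrky_scan
from .config import AnalysisConfig
from .errors import InputError
from .io_core import read_fasta, read_gff, spliced_cds, translate_cds

log = logging.getLogger("wrkyfam.pipeline")


def report_summary(table: pd.DataFrame, out=None) -> dict:
    """Print the family summary block (counts, ranges, means) and return it.

    The block mirrors how gene-family surveys report their annotation table:
    member count, CDS/protein/MW/pI ranges with means, then per-group,
    per-subgroup and per-chromosome counts in a fixed order.
    """
    s = wrky_scan.summarize_family_table(table)
    lines = [
        f"family members: {s['n_members']}",
        f"CDS length (bp): min {s['cds_bp']['min']:.0f}  max {s['cds_bp']['max']:.0f}  mean {s['cds_bp']['mean']:.0f}",
        f"protein length (aa): min {s['protein_aa']['min']:.0f}  max {s['protein_aa']['max']:.0f}  mean {s['protein_aa']['mean']:.0f}",
        f"MW (kDa): min {s['mw_kda']['min']:.2f}  max {s['mw_kda']['max']:.2f}  mean {s['mw_kda']['mean']:.2f}",
        f"pI: min {s['pi']['min']:.2f}  max {s['pi']['max']:.2f}  mean {s['pi']['mean']:.2f}",
    ]
    for key, title in (("group_counts", "group"), ("subgroup_counts", "subgroup")):
        counts = s[key]
        lines.append(title + ": " + "  ".join(f"{k}={counts[k]}" for k in sorted(counts)))
    chrom = s["chromosome_counts"]
    lines.append("chromosome: " + "  ".join(
        f"{k}={chrom[k]}" for k in sorted(chrom, key=lambda c: (len(c), c))))
    text = "\n".join(lines)
    print(text, file=out)
    return s


def run_pipeline(config: AnalysisConfig, inputs: dict, outdir: str | Path) -> dict:
    """Run every stage the inputs support and write tab-separated outputs.

    ``inputs`` keys: ``genome`` + ``gff`` (required); optional
    ``expression`` (2-line-header TSV), ``control``/``treatments`` condition
    labels, ``pathways`` (gene<TAB>pathway). Returns a dict of output paths.
    Input paths are validated before any stage runs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for key in ("genome", "gff"):
        if key not in inputs:
            raise InputError(f"missing required input {key!r}")
    for key in ("genome", "gff", "expression", "pathways"):
        if key in inputs and not Path(inputs[key]).exists():
            raise InputError(f"input {key!r} not found: {inputs[key]}")

    outputs: dict[str, Path] = {}
    assembly = read_fasta(inputs["genome"])
    models = read_gff(inputs["gff"], assembly)
    log.info("[pipeline] %d gene models on %d sequences", len(models), len(assembly.sequences))

    # stage: family scan
    annotations = wrky_scan.annotate_family(models, assembly)
    family_ids = {a.gene_id for a in annotations}
    ann_table = wrky_scan.annotations_to_frame(annotations)
    outputs["annotation"] = outdir / "family_annotation.tsv"
    ann_table.to_csv(outputs["annotation"], sep="\t", index=False)

    family_models = [m for m in models if m.gene_id in family_ids]

    # stage: promoter cis-elements
    library = promoter_cis.load_motif_library()
    counts, _hits = promoter_cis.element_profile(
        family_models, assembly, library, promoter_len=config.promoter_len,
        anchor="transcription_start")
    outputs["cis_elements"] = outdir / "cis_element_counts.tsv"
    counts.to_csv(outputs["cis_elements"], sep="\t", index_label="gene")

    # stage: duplication / selection / dating
    proteins = {m.gene_id: translate_cds(m, assembly) for m in family_models}
    cds = {m.gene_id: spliced_cds(m, assembly) for m in family_models}
    pairs = evo_dup.find_duplicate_pairs(family_models, proteins, cds, config)
    outputs["duplicates"] = outdir / "duplicate_pairs.tsv"
    pd.DataFrame([asdict(p) for p in pairs]).to_csv(outputs["duplicates"], sep="\t", index=False)

    # stage: W-box target prediction (+ optional enrichment)
    targets = network_enrich.predict_targets(
        models, assembly, promoter_len=config.promoter_len, anchor="translation_start")
    outputs["targets"] = outdir / "predicted_targets.tsv"
    pd.Series(sorted(targets), name="gene").to_csv(outputs["targets"], sep="\t", index=False)
    if "pathways" in inputs:
        pmap_df = pd.read_csv(inputs["pathways"], sep="\t", names=["gene", "pathway"], header=None)
        pathway_map = {p: list(g["gene"]) for p, g in pmap_df.groupby("pathway")}
        enr = network_enrich.hypergeom_enrich(targets, pathway_map, config=config)
        outputs["enrichment"] = outdir / "enrichment.tsv"
        pd.DataFrame([asdict(e) for e in enr]).to_csv(outputs["enrichment"], sep="\t", index=False)

    # stage: expression / DEGs / coexpression
    if "expression" in inputs:
        matrix = expression.ExpressionMatrix.from_tsv(inputs["expression"])
        conds = list(dict.fromkeys(matrix.conditions))
        control = inputs.get("control", conds[0])
        treatments = inputs.get("treatments", [c for c in conds if c != control])
        deg_rows = []
        for t in treatments:
            for rec in expression.call_degs(matrix, control, t, config):
                deg_rows.append(dict(gene=rec.gene_id, control=control, treatment=t,
                                     log2fc=rec.log2fc, p=rec.p_value, status=rec.status))
        outputs["degs"] = outdir / "degs.tsv"
        pd.DataFrame(deg_rows).to_csv(outputs["degs"], sep="\t", index=False)

        tf_in_matrix = sorted(family_ids & set(matrix.genes))
        if tf_in_matrix:
            flags = expression.fold_induction_flags(matrix, control, treatments)
            induced = [g for g in tf_in_matrix if flags.get(g)]
            edges = network_enrich.build_network(induced, matrix, config)
            outputs["network"] = outdir / "coexpression_edges.tsv"
            network_enrich.edges_to_frame(edges).to_csv(outputs["network"], sep="\t", index=False)

    manifest = {
        "config": {k: v for k, v in vars(config).items()},
        "config_sha256": hashlib.sha256(
            json.dumps(vars(config), sort_keys=True, default=str).encode()).hexdigest(),
        "seed": config.rng_seed,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    outputs["manifest"] = outdir / "manifest.json"
    return {k: str(v) for k, v in outputs.items()}
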