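"""Expression transforms, differential-expression calls and qPCR statistics.

RNA-seq abundances are handled as TPM; tests for differential expression
under chilling stress follow the study's dual rule (two-sided Welch t-test
p < 0.05 on log2(TPM+1) replicates and |log2 fold-change| ≥ 1, with a
pseudocount of 1 inside the fold ratio). qPCR relative expression uses the
2^-ΔΔCt method, compared across timepoints by one-way ANOVA with Duncan's
multiple range test for letter groupings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .errors import InputError

TPM_TOTAL = 1e6


@dataclass
class ExpressionMatrix:
    """Genes × samples abundance matrix with a condition label per sample."""

    values: pd.DataFrame  # genes (rows) × samples (columns), TPM scale
    conditions: pd.Series  # sample -> condition label

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.conditions.index):
            raise InputError("sample ids of values and conditions disagree")
        if (self.values.to_numpy() < 0).any():
            raise InputError("negative expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def samples_of(self, condition: str) -> list[str]:
        cols = [s for s, c in self.conditions.items() if c == condition]
        if not cols:
            raise InputError(f"no samples with condition {condition!r}")
        return cols

    def to_tsv(self, path: str | Path) -> None:
        """Write with a 2-line header: sample ids, then condition labels."""
        with open(path, "w") as fh:
            fh.write("gene\t" + "\t".join(self.values.columns) + "\n")
            fh.write("condition\t" + "\t".join(self.conditions.astype(str)) + "\n")
            for gene, row in self.values.iterrows():
                fh.write(gene + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            cond_line = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "gene" or not cond_line or cond_line[0] != "condition":
            raise InputError(f"{path}: expected 2-line header (gene .. / condition ..)")
        samples = header[1:]
        conditions = pd.Series(cond_line[1:], index=samples)
        values = pd.read_csv(path, sep="\t", skiprows=2, header=None, index_col=0)
        values.columns = samples
        values.index.name = "gene"
        return cls(values, conditions)


@dataclass
class DEGRecord:
    gene_id: str
    condition_pair: tuple[str, str]  # (control, treatment)
    log2fc: float
    p_value: float
    status: str  # up | down | ns


@dataclass
class QPCRResult:
    gene_id: str
    folds: dict[str, float]  # timepoint -> mean 2^-ΔΔCt
    anova_f: float
    anova_p: float
    duncan_letters: dict[str, str] = field(default_factory=dict)


def counts_to_tpm(counts: pd.DataFrame, gene_lengths: Mapping[str, float],
                  conditions: pd.Series | None = None) -> ExpressionMatrix:
    """Convert raw counts to TPM: length-normalised rates scaled to 10⁶ per sample."""
    lengths = pd.Series({g: gene_lengths[g] for g in counts.index}, dtype=float)
    if (lengths <= 0).any():
        raise InputError("gene lengths must be positive")
    rates = counts.div(lengths / 1000.0, axis=0)
    totals = rates.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise InputError(f"all-zero samples: {bad}")
    tpm = rates.div(totals, axis=1) * TPM_TOTAL
    if conditions is None:
        conditions = pd.Series("na", index=counts.columns)
    return ExpressionMatrix(tpm, conditions)


def log_transform(values: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x + 1)."""
    if (values.to_numpy() < 0).any():
        raise InputError("negative values in expression matrix")
    return np.log2(values + 1.0)


def call_degs(matrix: ExpressionMatrix, control: str, treatment: str,
              config: AnalysisConfig | None = None) -> list[DEGRecord]:
    """Differential-expression calls between two conditions.

    log2fc = log2((mean TPM_treatment + 1) / (mean TPM_control + 1)); p from a
    two-sided Welch t-test on log2(TPM+1) replicate values. Status follows
    the dual threshold (p < deg_p_max and |log2fc| ≥ deg_abs_log2fc_min).
    """
    config = config or AnalysisConfig()
    cols_c = matrix.samples_of(control)
    cols_t = matrix.samples_of(treatment)
    if len(cols_c) < 2 or len(cols_t) < 2:
        raise InputError("need at least 2 replicates per condition")
    logm = log_transform(matrix.values)
    out = []
    for gene in matrix.genes:
        mc = matrix.values.loc[gene, cols_c].mean()
        mt = matrix.values.loc[gene, cols_t].mean()
        lfc = math.log2((mt + 1.0) / (mc + 1.0))
        res = stats.ttest_ind(logm.loc[gene, cols_t], logm.loc[gene, cols_c], equal_var=False)
        p = float(res.pvalue) if math.isfinite(res.pvalue) else 1.0
        status = "ns"
        if p < config.deg_p_max and abs(lfc) >= config.deg_abs_log2fc_min:
            status = "up" if lfc > 0 else "down"
        out.append(DEGRecord(gene, (control, treatment), lfc, p, status))
    return out


def fold_induction_flags(matrix: ExpressionMatrix, baseline: str,
                         treatments: Sequence[str]) -> dict[str, bool]:
    """Genes whose pseudocounted mean fold over baseline exceeds 2 in any treatment."""
    cols_b = matrix.samples_of(baseline)
    mb = matrix.values[cols_b].mean(axis=1)
    flags = pd.Series(False, index=matrix.values.index)
    for t in treatments:
        mt = matrix.values[matrix.samples_of(t)].mean(axis=1)
        flags |= (mt + 1.0) / (mb + 1.0) > 2.0
    return flags.to_dict()


def ddct(ct_target_t: float, ct_ref_t: float, ct_target_c: float, ct_ref_c: float) -> tuple[float, float]:
    """ΔΔCt and the 2^-ΔΔCt fold for one treated/control Ct quadruple."""
    for v in (ct_target_t, ct_ref_t, ct_target_c, ct_ref_c):
        if not math.isfinite(v):
            raise InputError("Ct values must be finite")
    ddct_val = (ct_target_t - ct_ref_t) - (ct_target_c - ct_ref_c)
    return ddct_val, 2.0 ** (-ddct_val)


def anova_duncan(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> tuple[float, float, dict[str, str]]:
    """One-way ANOVA with Duncan's multiple range test letters.

    Means are sorted descending; a pair spanning p ranked means differs
    significantly when its difference exceeds the least significant range
    R_p = q(1-α_p; p, df_error) · sqrt(MSE/n) with Duncan's protection level
    α_p = 1-(1-α)^(p-1). Groups sharing a letter are not significantly
    different. Balanced designs only.
    """
    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    sizes = {k: len(v) for k, v in groups.items()}
    if min(sizes.values()) < 2:
        raise InputError("need at least 2 replicates per group")
    if len(set(sizes.values())) != 1:
        raise InputError("Duncan letters support balanced designs only")
    n = next(iter(sizes.values()))
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    f_stat, p_val = stats.f_oneway(*arrays)
    k = len(labels)
    df_err = k * (n - 1)
    mse = float(np.mean([np.var(a, ddof=1) for a in arrays]))

    means = {lab: float(np.mean(a)) for lab, a in zip(labels, arrays)}
    ranked = sorted(labels, key=lambda l: -means[l])

    def lsr(span: int) -> float:
        protection = 1.0 - (1.0 - alpha) ** (span - 1)
        q = stats.studentized_range.ppf(1.0 - protection, span, df_err)
        return float(q * math.sqrt(mse / n))

    def differ(i: int, j: int) -> bool:  # i < j in ranked order
        span = j - i + 1
        return means[ranked[i]] - means[ranked[j]] > lsr(span)

    # maximal runs of mutually non-significant means -> one letter per run
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and not differ(i, j + 1):
            j += 1
        intervals.append((i, j))
    maximal = [iv for iv in intervals
               if not any(o != iv and o[0] <= iv[0] and iv[1] <= o[1] for o in intervals)]
    maximal = sorted(set(maximal))
    letters = {lab: "" for lab in labels}
    for letter_idx, (lo, hi) in enumerate(maximal):
        ch = chr(ord("a") + letter_idx)
        for lab in ranked[lo : hi + 1]:
            letters[lab] += ch
    return float(f_stat), float(p_val), letters


def qpcr_analysis(ct_table: pd.DataFrame, gene: str, reference: str = "18S",
                  control: str | None = None, alpha: float = 0.05) -> QPCRResult:
    """Per-gene 2^-ΔΔCt folds plus ANOVA/Duncan across timepoints.

    ``ct_table`` is tidy with columns gene, condition, replicate, ct; the
    reference gene's rows carry ``reference`` in the gene column. Replicates
    are paired with the reference by (condition, replicate); the control
    condition defaults to the lexicographically first.
    """
    need = {"gene", "condition", "replicate", "ct"}
    if not need.issubset(ct_table.columns):
        raise InputError(f"ct table must have columns {sorted(need)}")
    tgt = ct_table[ct_table["gene"] == gene]
    ref = ct_table[ct_table["gene"] == reference]
    if tgt.empty or ref.empty:
        raise InputError(f"missing rows for target {gene!r} or reference {reference!r}")
    ref_ct = ref.set_index(["condition", "replicate"])["ct"]
    conditions = sorted(tgt["condition"].unique())
    control = control if control is not None else conditions[0]
    ctrl_rows = tgt[tgt["condition"] == control]
    ctrl_dct = float((ctrl_rows.set_index("replicate")["ct"]
                      - ref_ct.loc[control]).mean())
    per_cond_folds: dict[str, list[float]] = {}
    for cond in conditions:
        rows = tgt[tgt["condition"] == cond]
        folds = []
        for _, r in rows.iterrows():
            dct = r["ct"] - ref_ct.loc[(cond, r["replicate"])]
            folds.append(2.0 ** (-(dct - ctrl_dct)))
        per_cond_folds[cond] = folds
    f_stat, p_val, letters = anova_duncan(per_cond_folds, alpha=alpha)
    mean_folds = {c: float(np.mean(v)) for c, v in per_cond_folds.items()}
    return QPCRResult(gene, mean_folds, f_stat, p_val, letters)
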