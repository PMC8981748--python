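"""Downstream read-outs: tumor mutational burden, survival cutpoint, and
risk-group comparisons of externally produced score tables.

TMB counts nonsynonymous mutations per megabase of captured exome (38 Mb
default). The survival cutpoint is the maximally selected rank statistic:
the TMB value maximising the standardized two-group log-rank statistic over
a quantile-restricted candidate grid. The reported statistic is NOT
corrected for having searched over cutpoints, and is labelled as such.

Immune deconvolution and checkpoint scores are consumed as inputs (the
algorithms producing them are published tools); comparisons are rank-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, logrank_statistic
from .errors import ConfigError, DataError

logger = logging.getLogger("pairrisk")

__all__ = [
    "NONSYNONYMOUS_CLASSES",
    "compute_tmb",
    "CutpointResult",
    "surv_cutpoint",
    "mutation_frequency_by_group",
    "compare_scores_by_group",
]

#: MAF classes counted toward TMB (Silent/IGR/Intron/UTR etc. excluded)
NONSYNONYMOUS_CLASSES = frozenset(
    {
        "Missense_Mutation",
        "Nonsense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "In_Frame_Del",
        "In_Frame_Ins",
        "Splice_Site",
        "Translation_Start_Site",
        "Nonstop_Mutation",
    }
)


def compute_tmb(maf: pd.DataFrame, samples, capture_mb: float = 38.0) -> pd.DataFrame:
    """Nonsynonymous mutations per megabase, per sample.

    ``samples`` fixes the cohort: samples absent from the MAF get tmb = 0
    and are flagged (``in_maf = False``). tmb = n_mut / capture_mb.
    """
    if capture_mb <= 0:
        raise ConfigError(f"capture_mb must be positive, got {capture_mb}")
    required = {"Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"}
    if not required.issubset(maf.columns):
        raise DataError(f"MAF missing columns: {sorted(required - set(maf.columns))}")
    nonsyn = maf[maf["Variant_Classification"].isin(NONSYNONYMOUS_CLASSES)]
    counts = nonsyn.groupby("Tumor_Sample_Barcode").size()
    samples = list(samples)
    n_mut = pd.Series([int(counts.get(s, 0)) for s in samples], index=samples, name="n_mut")
    out = pd.DataFrame(
        {
            "n_mut": n_mut,
            "tmb": n_mut / capture_mb,
            "in_maf": [s in set(maf["Tumor_Sample_Barcode"]) for s in samples],
        }
    )
    out.index.name = "sample"
    n_absent = int((~out["in_maf"]).sum())
    if n_absent:
        logger.info("TMB: %d samples absent from MAF assigned tmb=0", n_absent)
    return out


@dataclass
class CutpointResult:
    """Maximally selected rank-statistic cutpoint for a continuous marker."""

    cutpoint: float
    max_stat: float  # |standardized log-rank|; selection-biased, uncorrected
    groups: pd.Series  # 'high' (marker > cutpoint) / 'low'


def surv_cutpoint(
    values: pd.Series, clinical: pd.DataFrame, min_prop: float = 0.1
) -> CutpointResult:
    """Optimal survival cutpoint of a continuous marker (e.g. TMB).

    Candidate cutpoints are the observed marker values leaving at least
    ``min_prop`` of samples on each side; for each, the standardized
    two-group log-rank statistic is computed and the argmax returned.
    Exhaustive over the grid, hence deterministic.
    """
    if not 0 < min_prop < 0.5:
        raise ConfigError(f"min_prop must be in (0, 0.5), got {min_prop}")
    common = [s for s in values.index if s in clinical.index]
    v = values.loc[common].to_numpy(dtype=float)
    time = clinical.loc[common, "time"].to_numpy(dtype=float)
    event = clinical.loc[common, "event"].to_numpy(dtype=int)
    if event.sum() < 10:
        warnings.warn(f"only {int(event.sum())} events; cutpoint is unstable", stacklevel=2)
    uniq = np.unique(v)
    if uniq.size < 2:
        raise DataError("all marker values equal; no cutpoint exists")
    n = v.size
    frac_le = np.searchsorted(np.sort(v), uniq, side="right") / n
    candidates = uniq[(frac_le >= min_prop) & (frac_le <= 1.0 - min_prop)]
    if candidates.size == 0:
        raise DataError(f"no candidate cutpoints leave >= {min_prop:.0%} per side")
    best = None
    for c in candidates:
        try:
            z, _ = logrank_statistic(time, event, v > c)
        except DataError:
            continue
        if best is None or abs(z) > best[0]:
            best = (abs(z), float(c))
    if best is None:
        raise DataError("no candidate cutpoint produced an informative split")
    max_stat, cut = best
    groups = pd.Series(np.where(v > cut, "high", "low"), index=common, name="tmb_group")
    return CutpointResult(cutpoint=cut, max_stat=max_stat, groups=groups)


def mutation_frequency_by_group(
    maf: pd.DataFrame, groups: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene percent of mutated samples per risk group, any variant class.

    Every sample in ``groups`` counts in its denominator even with no MAF
    rows. Returns ``(per_gene, overall)``: per_gene has one column per group
    plus a pooled frequency (sorted descending); overall is the per-group
    fraction of samples carrying at least one mutation.
    """
    labels = sorted(groups.unique())
    mutated = maf.groupby("Hugo_Symbol")["Tumor_Sample_Barcode"].agg(set)
    rows = {}
    for gene, carriers in mutated.items():
        rows[gene] = {
            lab: len(carriers & set(groups.index[groups == lab])) / max((groups == lab).sum(), 1)
            for lab in labels
        }
    per_gene = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    if per_gene.empty:
        per_gene = pd.DataFrame(columns=labels)
    n_by_group = groups.value_counts()
    per_gene["pooled"] = (
        sum(per_gene[lab] * n_by_group[lab] for lab in labels) / n_by_group.sum()
        if len(per_gene)
        else pd.Series(dtype=float)
    )
    per_gene = per_gene.sort_values("pooled", ascending=False)
    per_gene.index.name = "gene"

    with_any = set(maf["Tumor_Sample_Barcode"])
    overall = pd.Series(
        {
            lab: np.mean([s in with_any for s in groups.index[groups == lab]])
            for lab in labels
        },
        name="mutated_sample_rate",
    )
    return per_gene, overall


def compare_scores_by_group(
    score_table: pd.DataFrame,
    groups: pd.Series,
    risk_scores: pd.Series,
    min_per_group: int = 3,
) -> pd.DataFrame:
    """High-vs-low comparison of each external score plus its correlation
    with the continuous riskScore.

    Per feature: two-sided Wilcoxon rank-sum across risk groups (BH-adjusted
    across features) and Spearman rho/p against the riskScore. Features with
    fewer than ``min_per_group`` observations in either group are skipped.
    """
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise DataError(f"need exactly two risk groups, got {labels}")
    common = [s for s in groups.index if s in score_table.index]
    rows = []
    for feat in score_table.columns:
        col = score_table.loc[common, feat].dropna()
        g = groups.loc[col.index]
        a = col[g == labels[0]].to_numpy(dtype=float)
        b = col[g == labels[1]].to_numpy(dtype=float)
        if len(a) < min_per_group or len(b) < min_per_group:
            warnings.warn(f"feature {feat!r}: < {min_per_group} per group; skipped", stacklevel=2)
            continue
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rs = risk_scores.loc[col.index].to_numpy(dtype=float)
        if np.ptp(col.to_numpy(dtype=float)) == 0 or np.ptp(rs) == 0:
            rho, rho_p = 0.0, 1.0
        else:
            rho, rho_p = stats.spearmanr(rs, col.to_numpy(dtype=float))
        rows.append((feat, float(stat), float(p), float(rho), float(rho_p)))
    res = pd.DataFrame(rows, columns=["feature", "wilcoxon_stat", "p", "spearman_rho", "spearman_p"])
    res["fdr"] = bh_adjust(res["p"].to_numpy()) if len(res) else []
    return res
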