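"""Relative qPCR quantification (2^−ΔΔCt) and RNA-seq concordance.

ΔCt = mean target Ct − mean reference Ct per (gene, condition); ΔΔCt is the
difference against a designated control condition; fold change = 2^−ΔΔCt.
Replicates are aggregated by arithmetic mean on the cycle scale. Plate-wide
Ct shifts cancel in ΔΔCt, and the control condition's fold change is 1 by
construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ValidationError


def ddct_fold_change(ct: pd.DataFrame, control_condition: str) -> pd.DataFrame:
    """Fold change per (gene, condition) from a Ct table.

    ``ct`` needs columns gene, condition, replicate, ct_target, ct_reference.
    Returns a DataFrame indexed by (gene, condition) with delta_ct,
    delta_delta_ct, fold_change and log2_fold_change columns.
    """
    needed = {"gene", "condition", "ct_target", "ct_reference"}
    if not needed <= set(ct.columns):
        raise ValidationError(f"Ct table missing columns {sorted(needed - set(ct.columns))}")
    grouped = ct.groupby(["gene", "condition"])[["ct_target", "ct_reference"]].mean()
    delta_ct = grouped["ct_target"] - grouped["ct_reference"]
    genes = delta_ct.index.get_level_values("gene").unique()
    rows = []
    for gene in genes:
        per_gene = delta_ct.loc[gene]
        if control_condition not in per_gene.index:
            raise ValidationError(f"gene {gene}: control condition {control_condition!r} missing")
        ref = per_gene.loc[control_condition]
        for cond, dct in per_gene.items():
            ddct = dct - ref
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "delta_ct": float(dct),
                    "delta_delta_ct": float(ddct),
                    "fold_change": float(2.0 ** -ddct),
                    "log2_fold_change": float(-ddct),
                }
            )
    return pd.DataFrame(rows).set_index(["gene", "condition"])


def concordance(
    qpcr_log2fc: pd.Series,
    rnaseq_log2fc: pd.Series,
) -> tuple[float, pd.DataFrame]:
    """Pearson r between qPCR and RNA-seq log2 fold changes over the shared
    (gene, condition) pairs; returns (r, paired table). Requires >= 3 pairs."""
    shared = qpcr_log2fc.index.intersection(rnaseq_log2fc.index)
    if len(shared) < 3:
        raise ValidationError("need at least 3 shared (gene, condition) pairs")
    x = qpcr_log2fc.loc[shared].to_numpy(dtype=float)
    y = rnaseq_log2fc.loc[shared].to_numpy(dtype=float)
    r = float(stats.pearsonr(x, y)[0])
    pairs = pd.DataFrame({"qpcr_log2fc": x, "rnaseq_log2fc": y}, index=shared)
    return r, pairs


def rnaseq_log2fc_table(cpm: pd.DataFrame, condition_of_sample: dict[str, str], control_condition: str) -> pd.Series:
    """Mean log2 CPM fold change vs control per (gene, condition), the
    RNA-seq side of the concordance comparison."""
    conds = sorted(set(condition_of_sample.values()))
    if control_condition not in conds:
        raise ValidationError(f"unknown control condition {control_condition!r}")
    means = {}
    for c in conds:
        cols = [s for s, cc in condition_of_sample.items() if cc == c and s in cpm.columns]
        means[c] = np.log2(cpm[cols]).mean(axis=1)
    rows = {}
    for c in conds:
        for gene in cpm.index:
            rows[(gene, c)] = means[c][gene] - means[control_condition][gene]
    s = pd.Series(rows)
    s.index = pd.MultiIndex.from_tuples(s.index, names=["gene", "condition"])
    return s
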