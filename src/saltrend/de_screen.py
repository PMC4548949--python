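"""Pairwise differential-expression screening and the differential gene union.

The screen mirrors unreplicated pooled-library RNA-seq practice: fold change
computed on library-size-normalised means (CPM with a pseudocount), an exact
or asymptotic count test, BH correction across genes, and selection at
FC > 2 or FC < 0.5 with p < 0.05 and FDR < 0.05 (all strict).

Test choice depends on the design: with one library per condition the
Audic–Claverie exact test (a conditional binomial on the two counts given
their sum, success probability set by the library-size ratio) is used; with
replicates a two-sided t-test on log2 CPM. At typical replicate numbers
(2–3 per condition) a per-gene t-test has so few degrees of freedom that its
p-values cannot clear a BH-FDR gate even for large true effects, so the
default replicated test moderates the per-gene variance with an
empirical-Bayes shrink toward a common prior (scaled-F hierarchical model,
estimated by matching moments of log sample variances), which adds the prior
degrees of freedom to the residual ones. A plain Welch t-test remains
available via ``method="welch"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust
from .io_formats import CountMatrix, ValidationError


def normalize_cpm(counts: CountMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """Counts per million: (count + c) / (library + c·G) × 1e6 per sample."""
    lib = counts.values.sum(axis=0)
    if (lib <= 0).any():
        raise ValidationError("zero library size")
    g = counts.values.shape[0]
    return (counts.values + pseudocount) / (lib + pseudocount * g) * 1e6


def select_longest_transcript(counts: CountMatrix) -> CountMatrix:
    """Collapse transcript rows to one row per gene, keeping the longest
    transcript (ties broken lexicographically by transcript id)."""
    if counts.gene_of is None:
        return counts
    lengths = counts.transcript_lengths or {}
    by_gene: dict[str, list[str]] = {}
    for tx in counts.values.index:
        by_gene.setdefault(counts.gene_of.get(tx, tx), []).append(tx)
    keep: dict[str, str] = {}
    for gene, txs in by_gene.items():
        if len(txs) > 1:
            missing = [t for t in txs if t not in lengths]
            if missing:
                raise ValidationError(f"gene {gene}: transcripts without length: {missing}")
            keep[gene] = max(sorted(txs), key=lambda t: lengths[t])
        else:
            keep[gene] = txs[0]
    genes = sorted(keep)
    values = counts.values.loc[[keep[g] for g in genes]].copy()
    values.index = pd.Index(genes, name=counts.values.index.name)
    return CountMatrix(
        values,
        dict(counts.condition_of_sample),
        list(counts.condition_order),
        gene_of=None,
        transcript_lengths=None,
    )


@dataclass(frozen=True)
class DEResult:
    gene: str
    comparison: str  # "A_vs_B", FC = B over A
    fold_change: float
    log2fc: float
    p_value: float
    fdr: float
    selected: bool


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    from scipy.special import polygamma

    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x  # good starting point: trigamma(y) ~ 1/y for large y
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return float(y)


def _fit_scaled_f(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment estimates (prior df d0, prior variance s0^2) for the hierarchy
    s2_g ~ s0^2 * F(df, d0), fitted on log variances."""
    from scipy.special import digamma, polygamma

    z = np.log(np.maximum(s2, 1e-12))
    e = float(z.mean())
    v = float(z.var(ddof=1)) if z.size > 1 else 0.0
    evar = v - float(polygamma(1, df / 2))
    if evar > 1e-10:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(e - digamma(df / 2) + np.log(df / 2) + digamma(d0 / 2) - np.log(d0 / 2)))
    else:  # no excess spread: variances effectively equal, infinite prior df
        d0 = np.inf
        s02 = float(np.exp(e - digamma(df / 2) + np.log(df / 2)))
    return d0, s02


def _moderated_t_p(log_a: np.ndarray, log_b: np.ndarray) -> np.ndarray:
    """Two-sided p-values for mean log-expression differences with
    empirical-Bayes variance moderation (pooled two-sample t on the
    shrunken variance, df = residual + prior)."""
    na, nb = log_a.shape[1], log_b.shape[1]
    df = na + nb - 2
    ss = log_a.var(axis=1, ddof=1) * (na - 1) + log_b.var(axis=1, ddof=1) * (nb - 1)
    s2 = ss / df
    d0, s02 = _fit_scaled_f(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    t = (log_b.mean(axis=1) - log_a.mean(axis=1)) / se
    if np.isinf(df_total):
        return 2.0 * stats.norm.sf(np.abs(t))
    return 2.0 * stats.t.sf(np.abs(t), df_total)


def _audic_claverie_p(x: int, y: int, lib_x: float, lib_y: float) -> float:
    """Exact two-sided test for one count per condition: conditional on the
    total x + y, y ~ Binomial(x + y, lib_y / (lib_x + lib_y)) under the null."""
    total = x + y
    if total == 0:
        return 1.0
    p0 = lib_y / (lib_x + lib_y)
    return float(stats.binomtest(y, total, p0, alternative="two-sided").pvalue)


def pairwise_de(
    counts: CountMatrix,
    condition_a: str,
    condition_b: str,
    fc_high: float = 2.0,
    fc_low: float = 0.5,
    p_threshold: float = 0.05,
    fdr_threshold: float = 0.05,
    pseudocount: float = 0.5,
    method: str = "auto",
) -> list[DEResult]:
    """Screen every gene for differential expression between two conditions.

    Fold change is mean CPM(B) / mean CPM(A). Selection requires
    (FC > fc_high or FC < fc_low) and p < p_threshold and fdr < fdr_threshold,
    strict inequalities throughout.

    ``method``: "auto" picks the moderated t for replicated designs and the
    exact count test for 1-vs-1; "moderated", "welch" and "exact" force a
    choice (exact pools counts within condition).
    """
    samples_a = counts.samples_of(condition_a)
    samples_b = counts.samples_of(condition_b)
    if not samples_a or not samples_b:
        raise ValidationError(f"no samples for comparison {condition_a} vs {condition_b}")
    if method not in {"auto", "moderated", "welch", "exact"}:
        raise ValueError(f"unknown method {method!r}")
    replicated = len(samples_a) >= 2 and len(samples_b) >= 2
    if method == "auto":
        method = "moderated" if replicated else "exact"
    if method in {"moderated", "welch"} and not replicated:
        raise ValidationError(f"method {method!r} needs >= 2 replicates per condition")
    cpm = normalize_cpm(counts, pseudocount)
    mean_a = cpm[samples_a].mean(axis=1).to_numpy()
    mean_b = cpm[samples_b].mean(axis=1).to_numpy()
    fc = mean_b / mean_a
    if method == "moderated":
        log_a = np.log2(cpm[samples_a].to_numpy())
        log_b = np.log2(cpm[samples_b].to_numpy())
        pvals = np.minimum(_moderated_t_p(log_a, log_b), 1.0)
    elif method == "welch":
        log_a = np.log2(cpm[samples_a].to_numpy())
        log_b = np.log2(cpm[samples_b].to_numpy())
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.ttest_ind(log_b, log_a, axis=1, equal_var=False)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
    else:
        lib = counts.values.sum(axis=0)
        lib_a = float(lib[samples_a].sum())
        lib_b = float(lib[samples_b].sum())
        xa = counts.values[samples_a].sum(axis=1).to_numpy()
        xb = counts.values[samples_b].sum(axis=1).to_numpy()
        pvals = np.array(
            [_audic_claverie_p(int(round(a)), int(round(b)), lib_a, lib_b) for a, b in zip(xa, xb)]
        )
    fdr = np.asarray(bh_adjust(pvals.tolist()))
    label = f"{condition_a}_vs_{condition_b}"
    out = []
    for i, gene in enumerate(counts.values.index):
        sel = (fc[i] > fc_high or fc[i] < fc_low) and pvals[i] < p_threshold and fdr[i] < fdr_threshold
        out.append(
            DEResult(str(gene), label, float(fc[i]), float(np.log2(fc[i])), float(pvals[i]), float(fdr[i]), bool(sel))
        )
    return out


def de_union(comparisons: dict[str, list[DEResult]]) -> pd.DataFrame:
    """Union of genes selected in at least one comparison.

    Returns a gene-indexed DataFrame with one boolean provenance column per
    comparison, sorted by gene id; invariant to comparison order.
    """
    if not comparisons:
        raise ValidationError("no comparisons supplied")
    selected: dict[str, set[str]] = {
        label: {r.gene for r in results if r.selected} for label, results in comparisons.items()
    }
    union = sorted(set().union(*selected.values()))
    data = {label: [g in sel for g in union] for label, sel in sorted(selected.items())}
    return pd.DataFrame(data, index=pd.Index(union, name="gene"))


def regulation_signs(results: list[DEResult]) -> dict[str, str]:
    """up/down sign per selected gene from the fold-change direction."""
    return {r.gene: ("up" if r.fold_change > 1 else "down") for r in results if r.selected}
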