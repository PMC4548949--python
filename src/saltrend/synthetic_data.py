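"""Synthetic three-condition expression study with known ground truth.

Emulates a salinity-series design (three ordered conditions, e.g. 0, 8 and
16 psu): each gene follows one of the 8 step profiles or stays flat, with
per-condition expected counts on a log2 grid (m, m + s1·Δ, m + s1·Δ + s2·Δ)
and negative-binomial sampling noise around library-size-scaled means.
Companion generators plant enriched terms into a gene-set collection, draw
a typed gene-relation table, and emit qPCR Ct tables consistent with the
planted fold changes — so every downstream stage of the pipeline can be
checked against the generator's own truth.

Defaults are the study conditions used throughout the test-suite: 1000
genes, step Δ = 2 log2 units, NB dispersion 0.05, three replicates per
condition, 1% of genes planted in each of the 8 profiles (92% flat) — a
differential fraction of ~8%, in line with what whole-transcriptome salinity
or stress studies report, and small enough that library-composition bias
under total-count normalisation stays negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, GeneSet, GeneSetCollection, RelationTable
from .trend_cluster import FLAT, enumerate_profiles

__all__ = [
    "FLAT",
    "SimulationConfig",
    "simulate_counts",
    "simulate_gene_sets",
    "simulate_relations",
    "simulate_ct",
    "truth_log2fc",
    "simulate_all",
]


class ConfigError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_genes: int = 1000
    profile_fractions: dict[int, float] = field(default_factory=lambda: {i: 0.01 for i in range(8)})
    conditions: tuple[str, ...] = ("0psu", "8psu", "16psu")
    replicates_per_condition: int = 3
    baseline_log_mean: float = 7.0  # log2 scale
    baseline_log_sd: float = 1.5
    step_log2fc: float = 2.0
    nb_dispersion: float = 0.05  # 0 degenerates to Poisson
    library_sizes: list[float] | None = None  # None: unscaled expected means
    # gene sets
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 50)
    n_planted_terms: int = 5
    planting_enrichment: float = 0.8
    # relations
    n_relations: int = 300
    indirect_fraction: float = 0.2
    # qPCR
    n_ct_genes: int = 25
    ct_replicates: int = 3
    ct_reference_level: float = 18.0
    ct_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.profile_fractions.values())
        if total > 1.0 + 1e-9:
            raise ConfigError("profile fractions must sum to at most 1 (remainder is flat)")
        if any(f < 0 for f in self.profile_fractions.values()):
            raise ConfigError("profile fractions must be nonnegative")
        if set(self.profile_fractions) - set(range(8)):
            raise ConfigError("profile indices must be 0..7")
        if self.step_log2fc <= 0:
            raise ConfigError("step_log2fc must be positive")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if len(self.conditions) != 3:
            raise ConfigError("the generator emulates a 3-condition design")
        if self.replicates_per_condition < 1:
            raise ConfigError("need at least one replicate per condition")

    @property
    def flat_fraction(self) -> float:
        return 1.0 - sum(self.profile_fractions.values())


def _rng(config: SimulationConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per stage
    return np.random.default_rng([stage, config.seed])


def _gene_ids(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{i:0{width}d}" for i in range(n)]


def assign_truth(config: SimulationConfig) -> dict[str, int]:
    """Gene → planted profile index (FLAT for no trend), deterministic in n."""
    genes = _gene_ids(config.n_genes)
    truth: dict[str, int] = {}
    pos = 0
    for idx in sorted(config.profile_fractions):
        count = int(round(config.profile_fractions[idx] * config.n_genes))
        for g in genes[pos : pos + count]:
            truth[g] = idx
        pos += count
    for g in genes[pos:]:
        truth[g] = FLAT
    return truth


def expected_log2_means(config: SimulationConfig, truth: dict[str, int], baselines: np.ndarray) -> pd.DataFrame:
    """Per-gene, per-condition expected log2 mean: m, m+s1Δ, m+s1Δ+s2Δ."""
    profiles = {p.index: p for p in enumerate_profiles(3)}
    genes = list(truth)
    rows = np.empty((len(genes), 3))
    for i, g in enumerate(genes):
        m = baselines[i]
        idx = truth[g]
        if idx == FLAT:
            rows[i] = (m, m, m)
        else:
            cum = np.concatenate([[0.0], np.cumsum(profiles[idx].steps)])
            rows[i] = m + cum * config.step_log2fc
    return pd.DataFrame(rows, index=genes, columns=list(config.conditions))


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, dict[str, int]]:
    """Draw the count matrix and return it with the gene → profile truth."""
    rng = _rng(config, 1)
    truth = assign_truth(config)
    genes = list(truth)
    baselines = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=len(genes))
    log2mu = expected_log2_means(config, truth, baselines)
    reps = config.replicates_per_condition
    sample_ids = [f"{c}_r{j+1}" for c in config.conditions for j in range(reps)]
    cond_of = {f"{c}_r{j+1}": c for c in config.conditions for j in range(reps)}
    mu = np.repeat(2.0 ** log2mu.to_numpy(), reps, axis=1)
    if config.library_sizes is not None:
        sizes = np.asarray(config.library_sizes, dtype=float)
        if sizes.shape != (len(sample_ids),):
            raise ConfigError(f"library_sizes must have length {len(sample_ids)}")
        mu = mu / mu.sum(axis=0, keepdims=True) * sizes
    if config.nb_dispersion == 0:
        counts = rng.poisson(mu)
    else:
        n_param = 1.0 / config.nb_dispersion
        p_param = n_param / (n_param + mu)
        counts = rng.negative_binomial(n_param, p_param)
    values = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=sample_ids)
    return CountMatrix(values, cond_of, list(config.conditions)), truth


def simulate_gene_sets(
    config: SimulationConfig, truth: dict[str, int], namespace: str = "GO"
) -> tuple[GeneSetCollection, list[str]]:
    """Gene-set collection with ``n_planted_terms`` terms enriched for the
    non-flat (DE-destined) stratum; remaining terms draw members uniformly.
    Returns the collection and the planted term ids."""
    rng = _rng(config, 2)
    genes = np.array(list(truth))
    stratum = np.array([g for g, p in truth.items() if p != FLAT])
    lo, hi = config.term_size_range
    if hi > len(genes):
        raise ConfigError("term size range exceeds gene count")
    terms: list[GeneSet] = []
    planted: list[str] = []
    for i in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        tid = f"T{i:04d}"
        if i < config.n_planted_terms and len(stratum) > 0:
            n_strat = min(int(round(config.planting_enrichment * size)), len(stratum))
            members = set(rng.choice(stratum, size=n_strat, replace=False))
            pool = np.array([g for g in genes if g not in members])
            members |= set(rng.choice(pool, size=size - n_strat, replace=False))
            planted.append(tid)
        else:
            members = set(rng.choice(genes, size=size, replace=False))
        terms.append(GeneSet(tid, f"synthetic term {i}", namespace, frozenset(members)))
    return GeneSetCollection(terms, frozenset(genes)), planted


_KINDS = ("activation", "inhibition", "binding", "compound", "expression", "phosphorylation", "dissociation")


def simulate_relations(config: SimulationConfig, truth: dict[str, int]) -> RelationTable:
    """Random typed gene–gene relations over the simulated gene universe."""
    rng = _rng(config, 3)
    genes = np.array(list(truth))
    rows = []
    seen = set()
    while len(rows) < config.n_relations:
        u, v = rng.choice(genes, size=2, replace=False)
        if (u, v) in seen:
            continue
        seen.add((u, v))
        rows.append(
            {
                "source": u,
                "target": v,
                "kind": _KINDS[int(rng.integers(len(_KINDS)))],
                "directed": True,
                "indirect": bool(rng.random() < config.indirect_fraction),
            }
        )
    return RelationTable(pd.DataFrame(rows))


def truth_log2fc(config: SimulationConfig, truth: dict[str, int]) -> pd.DataFrame:
    """Planted log2 fold change vs the first (control) condition per gene."""
    profiles = {p.index: p for p in enumerate_profiles(3)}
    rows = {}
    for g, idx in truth.items():
        if idx == FLAT:
            rows[g] = [0.0, 0.0, 0.0]
        else:
            cum = np.concatenate([[0.0], np.cumsum(profiles[idx].steps)])
            rows[g] = (cum * config.step_log2fc).tolist()
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(config.conditions))


def simulate_ct(config: SimulationConfig, truth: dict[str, int]) -> pd.DataFrame:
    """Ct table consistent with the planted fold changes.

    ct_target = reference_level + per-gene offset − planted log2FC vs control
    (+ Gaussian noise, sd ``ct_noise_sd``); the reference gene is constant
    across conditions, mirroring a stable housekeeping normaliser.
    """
    rng = _rng(config, 4)
    non_flat = [g for g, p in truth.items() if p != FLAT]
    pool = non_flat if len(non_flat) >= config.n_ct_genes else list(truth)
    chosen = list(rng.choice(np.array(pool), size=config.n_ct_genes, replace=False))
    lfc = truth_log2fc(config, truth)
    offsets = rng.uniform(2.0, 10.0, size=len(chosen))
    rows = []
    for gi, g in enumerate(chosen):
        for cond in config.conditions:
            for rep in range(1, config.ct_replicates + 1):
                noise = rng.normal(0.0, config.ct_noise_sd) if config.ct_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "gene": g,
                        "condition": cond,
                        "replicate": rep,
                        "ct_target": config.ct_reference_level + offsets[gi] - lfc.loc[g, cond] + noise,
                        "ct_reference": config.ct_reference_level,
                    }
                )
    return pd.DataFrame(rows)


def simulate_all(config: SimulationConfig) -> dict:
    """Run every generator; returns counts, truth, sets, planted ids,
    relations and the Ct table in one mapping."""
    counts, truth = simulate_counts(config)
    sets, planted = simulate_gene_sets(config, truth)
    relations = simulate_relations(config, truth)
    ct = simulate_ct(config, truth)
    return {
        "counts": counts,
        "truth": truth,
        "gene_sets": sets,
        "planted_terms": planted,
        "relations": relations,
        "ct": ct,
    }
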