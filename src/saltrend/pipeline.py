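"""End-to-end pipeline orchestration: simulate → DE → trend → enrichment →
networks → qPCR, with a hash manifest for reproducibility checks."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import de_screen, enrichment, networks, qpcr_validation, synthetic_data, trend_cluster
from .io_formats import write_counts, write_design, write_gene_sets, write_relations, write_ct_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every screening threshold of the pipeline, with the defaults used
    throughout: FC gates 2 / 0.5, p and FDR 0.05, trend correlation floor
    0.85, co-expression |r| > 0.999, GO p 0.01, pathway p 0.05."""

    fc_high: float = 2.0
    fc_low: float = 0.5
    p_threshold: float = 0.05
    fdr_threshold: float = 0.05
    min_r: float = 0.85
    coexpr_r_threshold: float = 0.999
    coexpr_p_threshold: float = 0.05
    go_p: float = 0.01
    go_fdr: float = 0.05
    pathway_p: float = 0.05
    pseudocount: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fc_low < 1 < self.fc_high):
            raise ValueError("need fc_low < 1 < fc_high, both positive")
        for name in ("p_threshold", "fdr_threshold", "min_r", "coexpr_r_threshold", "go_p", "pathway_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        return cls(**{k: v for k, v in mapping.items() if k in known})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    sim_config: synthetic_data.SimulationConfig,
    pipe_config: PipelineConfig,
    out_dir: str | Path,
) -> dict:
    """Run every pipeline stage on a freshly simulated study.

    Writes counts/design/truth/sets/relations/ct inputs plus the per-stage
    result tables into ``out_dir`` and returns a manifest mapping each output
    file to its sha256 (identical seeds give identical manifests). Any stage
    failure aborts with the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    stage = "simulate"
    try:
        sim = synthetic_data.simulate_all(sim_config)
        counts = sim["counts"]
        write_counts(counts, out / "counts.tsv")
        write_design(counts, out / "design.tsv")
        pd.Series(sim["truth"], name="profile").rename_axis("gene").to_csv(out / "truth.tsv", sep="\t")
        write_gene_sets(sim["gene_sets"], out / "sets.gmt")
        write_relations(sim["relations"], out / "relations.tsv")
        write_ct_table(sim["ct"], out / "ct.tsv")

        stage = "de_screen"
        conds = counts.condition_order
        pairs = [(conds[0], conds[1]), (conds[0], conds[2]), (conds[1], conds[2])]
        de_results = {}
        for a, b in pairs:
            de_results[f"{a}_vs_{b}"] = de_screen.pairwise_de(
                counts, a, b,
                fc_high=pipe_config.fc_high, fc_low=pipe_config.fc_low,
                p_threshold=pipe_config.p_threshold, fdr_threshold=pipe_config.fdr_threshold,
                pseudocount=pipe_config.pseudocount,
            )
        de_rows = [
            {
                "gene": r.gene, "comparison": r.comparison, "fold_change": r.fold_change,
                "log2fc": r.log2fc, "p_value": r.p_value, "fdr": r.fdr, "selected": r.selected,
            }
            for results in de_results.values()
            for r in results
        ]
        pd.DataFrame(de_rows).to_csv(out / "de.tsv", sep="\t", index=False)
        union = de_screen.de_union(de_results)
        union.to_csv(out / "de_union.tsv", sep="\t")

        stage = "trend_cluster"
        cpm = de_screen.normalize_cpm(counts, pipe_config.pseudocount)
        cond_means = pd.DataFrame(
            {c: np.log2(cpm[counts.samples_of(c)]).mean(axis=1) for c in conds}
        )
        union_expr = cond_means.loc[union.index]
        assignments = trend_cluster.assign_profiles(union_expr, pipe_config.min_r)
        trend_rows = [
            {"gene": a.gene, "profile": a.profile, "r": a.r, "assigned": a.assigned}
            for a in assignments
        ]
        pd.DataFrame(trend_rows).to_csv(out / "trend.tsv", sep="\t", index=False)
        trend_cluster.profile_table().to_csv(out / "profiles.tsv", sep="\t", index=False)
        significance = trend_cluster.tendency_significance(
            assignments, union_expr, pipe_config.min_r, seed=pipe_config.seed
        )
        pd.DataFrame(
            [
                {
                    "profile": s.profile, "observed": s.observed, "expected": s.expected,
                    "p_value": s.p_value, "adjusted_p": s.adjusted_p,
                }
                for s in significance
            ]
        ).to_csv(out / "tendency_significance.tsv", sep="\t", index=False)
        categories = trend_cluster.categorize(assignments)

        stage = "enrichment"
        thresholds = {
            "GO": {"p": pipe_config.go_p, "fdr": pipe_config.go_fdr},
            "PATHWAY": {"p": pipe_config.pathway_p, "fdr": None},
        }
        enr_rows = []
        for cat, genes in categories.items():
            if cat == trend_cluster.CATEGORY_REVERSAL or not genes:
                continue  # reversal reported but not analyzed
            for r in enrichment.run_enrichment(genes, sim["gene_sets"], thresholds=thresholds):
                enr_rows.append(
                    {
                        "category": cat, "term_id": r.term_id, "name": r.name, "k": r.k,
                        "K": r.K, "n": r.n, "N": r.N, "fisher_p": r.fisher_p, "chisq_p": r.chisq_p,
                        "enrichment_ratio": r.enrichment_ratio, "fdr_custom": r.fdr_custom,
                        "fdr_bh": r.fdr_bh, "significant": r.significant,
                        "members": ",".join(r.members_in_list),
                    }
                )
        pd.DataFrame(enr_rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)

        stage = "networks"
        signs_all: dict[str, str] = {}
        for results in de_results.values():
            signs_all.update(de_screen.regulation_signs(results))
        act = networks.build_gene_act(sim["relations"], union.index.tolist(), signs_all)
        networks.node_table(act).to_csv(out / "gene_act_nodes.tsv", sep="\t", index=False)
        networks.edge_table(act).to_csv(out / "gene_act_edges.tsv", sep="\t", index=False)
        coexpr_input = np.log2(cpm.loc[union.index])
        coex = networks.build_coexpression(
            coexpr_input, pipe_config.coexpr_r_threshold, pipe_config.coexpr_p_threshold
        )
        networks.node_table(coex).to_csv(out / "coexpression_nodes.tsv", sep="\t", index=False)
        networks.edge_table(coex).to_csv(out / "coexpression_edges.tsv", sep="\t", index=False)

        stage = "qpcr"
        control = conds[0]
        fc = qpcr_validation.ddct_fold_change(sim["ct"], control)
        fc.to_csv(out / "qpcr.tsv", sep="\t")
        rnaseq = qpcr_validation.rnaseq_log2fc_table(cpm, counts.condition_of_sample, control)
        non_control = fc.index.get_level_values("condition") != control
        r, pairs_table = qpcr_validation.concordance(
            fc.loc[non_control, "log2_fold_change"], rnaseq
        )
        pairs_table.to_csv(out / "qpcr_concordance_pairs.tsv", sep="\t")
        (out / "qpcr_concordance.json").write_text(
            json.dumps({"pearson_r": r, "n_pairs": int(len(pairs_table))}, indent=2)
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for path in sorted(out.iterdir()):
        if path.is_file() and path.name != "manifest.json":
            manifest[path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
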