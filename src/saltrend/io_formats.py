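"""Tabular readers/writers and sequencing-QC summary arithmetic.

All on-disk formats are plain text: count matrices and relation/Ct tables
are tab-separated with ``#`` comment lines, gene sets are GMT. Gene ids are
opaque UTF-8 strings; no species assumption is made anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RELATION_KINDS = frozenset(
    {
        "activation",
        "inhibition",
        "binding",
        "compound",
        "expression",
        "phosphorylation",
        "dissociation",
    }
)


class FormatError(ValueError):
    """Raised when an input file does not parse as the declared format."""


class ValidationError(ValueError):
    """Raised when parsed data violate a container invariant."""


# ---------------------------------------------------------------------------
# CountMatrix


@dataclass
class CountMatrix:
    """Gene (or transcript) × sample nonnegative expression counts.

    Parameters
    ----------
    values
        DataFrame, rows indexed by gene/transcript id, columns by sample id.
    condition_of_sample
        Mapping sample id → condition label. Every column must be covered.
    condition_order
        Total order over condition labels (e.g. ``["0psu", "8psu", "16psu"]``).
    gene_of
        Optional row id → gene id mapping when rows are transcripts.
    transcript_lengths
        Optional row id → length (bp) mapping, required for collapsing
        multi-transcript genes to their longest transcript.
    """

    values: pd.DataFrame
    condition_of_sample: dict[str, str]
    condition_order: list[str]
    gene_of: dict[str, str] | None = None
    transcript_lengths: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate row ids: {dups}")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("negative counts are not allowed")
        missing = [s for s in self.values.columns if s not in self.condition_of_sample]
        if missing:
            raise ValidationError(f"samples without a condition: {missing}")
        unknown = set(self.condition_of_sample.values()) - set(self.condition_order)
        if unknown:
            raise ValidationError(f"conditions not in condition_order: {sorted(unknown)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def samples_of(self, condition: str) -> list[str]:
        if condition not in self.condition_order:
            raise ValidationError(f"unknown condition {condition!r}")
        return [s for s in self.values.columns if self.condition_of_sample[s] == condition]

    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)


def read_counts(
    path: str | Path,
    condition_of_sample: Mapping[str, str] | None = None,
    condition_order: Sequence[str] | None = None,
    design_path: str | Path | None = None,
) -> CountMatrix:
    """Read a TSV count matrix (genes in rows, samples in columns).

    Condition labels come either from ``condition_of_sample`` /
    ``condition_order`` or from a sidecar design TSV with columns
    ``sample``, ``condition`` (condition order = order of first appearance).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    except Exception as exc:  # malformed header / ragged rows
        raise FormatError(f"cannot parse count matrix {path}: {exc}") from exc
    if df.columns.size == 0:
        raise FormatError(f"{path}: header names no samples")
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicated gene ids in first column")
    if not all(np.issubdtype(t, np.number) for t in df.dtypes):
        raise FormatError(f"{path}: non-numeric values in count matrix")
    if design_path is not None:
        design = pd.read_csv(design_path, sep="\t", comment="#")
        if not {"sample", "condition"} <= set(design.columns):
            raise FormatError(f"{design_path}: design needs 'sample' and 'condition' columns")
        condition_of_sample = dict(zip(design["sample"].astype(str), design["condition"].astype(str)))
        condition_order = list(dict.fromkeys(design["condition"].astype(str)))
    if condition_of_sample is None or condition_order is None:
        raise ValidationError("a condition mapping (inline or design file) is required")
    return CountMatrix(df, dict(condition_of_sample), list(condition_order))


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.values.to_csv(path, sep="\t", index_label="gene")


def write_design(cm: CountMatrix, path: str | Path) -> None:
    rows = [{"sample": s, "condition": cm.condition_of_sample[s]} for s in cm.sample_ids]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene sets (GMT)


@dataclass(frozen=True)
class GeneSet:
    term_id: str
    name: str
    namespace: str  # "GO" or "PATHWAY"
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """Flat gene-set annotation (GO-term or pathway style)."""

    terms: list[GeneSet]
    background: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate term ids")
        if not self.background:
            members: set[str] = set()
            for t in self.terms:
                members |= t.members
            self.background = frozenset(members)
        for t in self.terms:
            if not t.members <= self.background:
                raise ValidationError(f"term {t.term_id} has members outside the background")

    def __len__(self) -> int:
        return len(self.terms)


def read_gene_sets(
    path: str | Path,
    namespace: str = "GO",
    background: Iterable[str] | None = None,
) -> GeneSetCollection:
    """Read a GMT file: term id, description, then member genes, tab-separated."""
    terms: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            terms.append(GeneSet(fields[0], fields[1], namespace, frozenset(fields[2:])))
    bg = frozenset(background) if background is not None else frozenset()
    return GeneSetCollection(terms, bg)


def write_gene_sets(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in coll.terms:
            fh.write("\t".join([t.term_id, t.name, *sorted(t.members)]) + "\n")


# ---------------------------------------------------------------------------
# Gene relation table (KEGG-style edge semantics)


@dataclass
class RelationTable:
    """Typed gene–gene relations: activation, inhibition, binding, compound,
    expression, phosphorylation or dissociation; direct or indirect."""

    edges: pd.DataFrame  # columns: source, target, kind, directed, indirect

    COLUMNS = ("source", "target", "kind", "directed", "indirect")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.edges.columns)
        if missing:
            raise ValidationError(f"relation table missing columns: {sorted(missing)}")
        bad = set(self.edges["kind"]) - RELATION_KINDS
        if bad:
            raise ValidationError(f"unknown relation kinds: {sorted(bad)}")
        self_loops = self.edges["source"] == self.edges["target"]
        if (self_loops & ~self.edges["indirect"].astype(bool)).any():
            raise ValidationError("direct self-loop relations are not allowed")

    def __len__(self) -> int:
        return len(self.edges)


def read_relations(path: str | Path) -> RelationTable:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"source": str, "target": str, "kind": str})
    except Exception as exc:
        raise FormatError(f"cannot parse relation table {path}: {exc}") from exc
    for col in ("directed", "indirect"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].astype(str).str.lower().isin({"true", "1", "yes"})
    return RelationTable(df)


def write_relations(rt: RelationTable, path: str | Path) -> None:
    rt.edges.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# qPCR cycle-threshold table


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct table: gene, condition, replicate, ct_target, ct_reference."""
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"gene", "condition", "replicate", "ct_target", "ct_reference"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: Ct table missing columns {sorted(needed - set(df.columns))}")
    if not np.isfinite(df[["ct_target", "ct_reference"]].to_numpy()).all():
        raise ValidationError("Ct values must be finite")
    if (df[["ct_target", "ct_reference"]].to_numpy() <= 0).any():
        raise ValidationError("Ct values must be positive")
    return df


def write_ct_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Sequencing-QC summary arithmetic


@dataclass
class ReadStats:
    """Per-library read accounting: raw, filtered, mapped, uniquely mapped.

    Counts may be in raw units or millions; every rate is scale-invariant.
    """

    libraries: list[str]
    raw_reads: np.ndarray
    filtered_reads: np.ndarray
    mapped_reads: np.ndarray
    unique_mapped_reads: np.ndarray

    def __post_init__(self) -> None:
        arrs = [self.raw_reads, self.filtered_reads, self.mapped_reads, self.unique_mapped_reads]
        for i, a in enumerate(arrs):
            arrs[i] = np.asarray(a, dtype=float)
        self.raw_reads, self.filtered_reads, self.mapped_reads, self.unique_mapped_reads = arrs
        n = len(self.libraries)
        if any(a.shape != (n,) for a in arrs):
            raise ValidationError("per-library count arrays must match library list length")
        ok = (
            (0 <= self.unique_mapped_reads)
            & (self.unique_mapped_reads <= self.mapped_reads)
            & (self.mapped_reads <= self.filtered_reads)
            & (self.filtered_reads <= self.raw_reads)
        )
        if not ok.all():
            raise ValidationError("require 0 <= unique <= mapped <= filtered <= raw per library")


def read_read_stats(path: str | Path) -> ReadStats:
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"library", "raw_reads", "filtered_reads", "mapped_reads", "unique_mapped_reads"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: read-stats table missing {sorted(needed - set(df.columns))}")
    return ReadStats(
        df["library"].astype(str).tolist(),
        df["raw_reads"].to_numpy(),
        df["filtered_reads"].to_numpy(),
        df["mapped_reads"].to_numpy(),
        df["unique_mapped_reads"].to_numpy(),
    )


class UndefinedRateError(ZeroDivisionError):
    pass


def compute_qc_rates(stats: ReadStats, printed_rates: Mapping[str, float] | None = None) -> dict:
    """Totals, means and aggregate percentage rates from per-library counts.

    filter_rate = Σfiltered/Σraw, mapping_rate = Σmapped/Σfiltered,
    unique_rate = Σunique/Σfiltered; percentages are reported rounded to one
    decimal (unrounded values retained under ``*_exact``). When
    ``printed_rates`` supplies externally reported percentages, the
    discrepancy computed − printed is included rather than silently trusted.
    """
    tot_raw = float(stats.raw_reads.sum())
    tot_filt = float(stats.filtered_reads.sum())
    tot_map = float(stats.mapped_reads.sum())
    tot_uni = float(stats.unique_mapped_reads.sum())
    if tot_raw == 0 or tot_filt == 0:
        raise UndefinedRateError("zero denominator in rate computation")
    n = len(stats.libraries)
    exact = {
        "filter_rate": 100.0 * tot_filt / tot_raw,
        "mapping_rate": 100.0 * tot_map / tot_filt,
        "unique_rate": 100.0 * tot_uni / tot_filt,
    }
    out: dict = {
        "totals": {
            "raw_reads": tot_raw,
            "filtered_reads": tot_filt,
            "mapped_reads": tot_map,
            "unique_mapped_reads": tot_uni,
        },
        "means": {
            "raw_reads": round(tot_raw / n, 1),
            "filtered_reads": round(tot_filt / n, 1),
            "mapped_reads": round(tot_map / n, 1),
            "unique_mapped_reads": round(tot_uni / n, 1),
        },
        "rates": {k: round(v, 1) for k, v in exact.items()},
        "rates_exact": exact,
    }
    if printed_rates:
        out["printed_rate_discrepancy"] = {
            k: round(out["rates"][k] - printed_rates[k], 1) for k in printed_rates if k in out["rates"]
        }
    return out
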