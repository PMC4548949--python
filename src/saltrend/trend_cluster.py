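"""Step-profile (tendency) clustering of genes across ordered conditions.

With three ordered conditions a gene's trajectory is summarised by two
consecutive step signs (s1, s2), each in {-1, 0, +1}; excluding the
all-flat (0, 0) case leaves 8 model profiles. A gene is assigned to the
profile whose model vector (0, s1, s1+s2) has the highest Pearson
correlation with the gene's per-condition expression summary, provided
that correlation reaches ``min_r`` (default 0.85).

Profiles are numbered lexicographically over (s1, s2) with -1 < 0 < +1,
so index 0 = (-1,-1) ... index 7 = (+1,+1). The four categories partition
the profiles 2/2/2/2:

* constant-change: (-1,-1) and (+1,+1) — indices 0, 7
* change-then-stable: (-1,0) and (+1,0) — indices 1, 6
* stable-then-change: (0,-1) and (0,+1) — indices 3, 4
* reversal: (-1,+1) and (+1,-1) — indices 2, 5 (reported, flagged as not
  analyzed: such genes show no net difference between the first and last
  condition)
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import bh_adjust

UNASSIGNED = -1
FLAT = -1  # ground-truth label for genes with no planted trend

CATEGORY_CONSTANT = "constant-change"
CATEGORY_CHANGE_THEN_STABLE = "change-then-stable"
CATEGORY_STABLE_THEN_CHANGE = "stable-then-change"
CATEGORY_REVERSAL = "reversal"


@dataclass(frozen=True)
class TrendProfile:
    index: int
    steps: tuple[int, ...]

    @property
    def model_vector(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(self.steps)])

    @property
    def category(self) -> str:
        s = self.steps
        if len(s) != 2:
            raise ValueError("categories are defined for the 3-condition design")
        if s[0] != 0 and s[1] != 0:
            return CATEGORY_CONSTANT if s[0] == s[1] else CATEGORY_REVERSAL
        return CATEGORY_CHANGE_THEN_STABLE if s[1] == 0 else CATEGORY_STABLE_THEN_CHANGE


def enumerate_profiles(n_conditions: int = 3) -> list[TrendProfile]:
    """All non-flat step-sign profiles over n ordered conditions: 3^(n-1) - 1."""
    if n_conditions < 2:
        raise ValueError("need at least 2 conditions")
    profiles = []
    idx = 0
    for steps in itertools.product((-1, 0, 1), repeat=n_conditions - 1):
        if all(s == 0 for s in steps):
            continue
        profiles.append(TrendProfile(idx, steps))
        idx += 1
    return profiles


@dataclass(frozen=True)
class TrendAssignment:
    gene: str
    profile: int  # profile index, or UNASSIGNED
    r: float

    @property
    def assigned(self) -> bool:
        return self.profile != UNASSIGNED


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float(xc @ yc) / denom


def assign_profiles(
    expr: pd.DataFrame,
    min_r: float = 0.85,
    profiles: list[TrendProfile] | None = None,
) -> list[TrendAssignment]:
    """Assign each gene (row of ``expr``, columns = ordered conditions) to the
    best-correlated model profile; genes whose best r < min_r, or whose
    expression has zero variance, stay unassigned. Ties break to the lowest
    profile index.
    """
    if profiles is None:
        profiles = enumerate_profiles(expr.shape[1])
    model_len = len(profiles[0].steps) + 1
    if expr.shape[1] != model_len:
        raise ValueError(f"expression summary has {expr.shape[1]} conditions, profiles expect {model_len}")
    models = np.stack([p.model_vector for p in profiles])  # (P, C)
    mc = models - models.mean(axis=1, keepdims=True)
    mnorm = np.linalg.norm(mc, axis=1)
    x = expr.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    xnorm = np.linalg.norm(xc, axis=1)
    out: list[TrendAssignment] = []
    for i, gene in enumerate(expr.index):
        if not np.isfinite(x[i]).all():
            raise ValueError(f"non-finite expression for gene {gene}")
        if xnorm[i] == 0.0:
            out.append(TrendAssignment(str(gene), UNASSIGNED, float("nan")))
            continue
        rs = (mc @ xc[i]) / (mnorm * xnorm[i])
        best = int(np.argmax(rs))  # argmax returns the first (lowest-index) maximum
        r = float(rs[best])
        if r >= min_r:
            out.append(TrendAssignment(str(gene), profiles[best].index, r))
        else:
            out.append(TrendAssignment(str(gene), UNASSIGNED, r))
    return out


@dataclass(frozen=True)
class TendencySignificance:
    profile: int
    observed: int
    expected: float
    p_value: float
    adjusted_p: float


def _permutation_expected(
    expr: pd.DataFrame,
    min_r: float,
    profiles: list[TrendProfile],
    n_permutations: int | None,
    seed: int | None,
) -> np.ndarray:
    """Expected per-profile assignment counts when each gene's condition
    order carries no information: average assignment counts over condition
    permutations (all of them, or a Monte-Carlo sample)."""
    n_cond = expr.shape[1]
    perms = list(itertools.permutations(range(n_cond)))
    perms = [p for p in perms if p != tuple(range(n_cond))] + [tuple(range(n_cond))]
    if n_permutations is not None and n_permutations < len(perms):
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(perms), size=n_permutations, replace=False)
        perms = [perms[i] for i in chosen]
    counts = np.zeros(len(profiles))
    for perm in perms:
        permuted = expr.iloc[:, list(perm)]
        permuted.columns = expr.columns
        for a in assign_profiles(permuted, min_r, profiles):
            if a.assigned:
                counts[a.profile] += 1
    return counts / len(perms)


def tendency_significance(
    assignments: list[TrendAssignment],
    expr: pd.DataFrame,
    min_r: float = 0.85,
    mode: str = "permutation",
    n_permutations: int | None = None,
    seed: int | None = None,
) -> list[TendencySignificance]:
    """Per-profile over-representation of observed assignments vs a null.

    The null expectation is either condition-permutation based (default) or a
    uniform 1/P share of assigned genes (``mode="uniform"``). Each profile is
    tested with a one-sided Fisher exact test on the 2×2 table (in-profile vs
    not) × (observed vs expected pool); p-values are BH-adjusted across
    profiles.
    """
    if not assignments:
        raise ValueError("no assignments supplied")
    profiles = enumerate_profiles(expr.shape[1])
    observed = np.zeros(len(profiles), dtype=int)
    for a in assignments:
        if a.assigned:
            observed[a.profile] += 1
    n_assigned = int(observed.sum())
    if mode == "permutation":
        expected = _permutation_expected(expr, min_r, profiles, n_permutations, seed)
    elif mode == "uniform":
        expected = np.full(len(profiles), n_assigned / len(profiles))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    exp_total = expected.sum()
    pvals = []
    for i in range(len(profiles)):
        table = [
            [int(observed[i]), n_assigned - int(observed[i])],
            [int(round(expected[i])), int(round(exp_total - expected[i]))],
        ]
        if n_assigned == 0 or exp_total == 0:
            pvals.append(1.0)
        else:
            pvals.append(float(stats.fisher_exact(table, alternative="greater")[1]))
    adjusted = bh_adjust(pvals)
    return [
        TendencySignificance(profiles[i].index, int(observed[i]), float(expected[i]), pvals[i], adjusted[i])
        for i in range(len(profiles))
    ]


def categorize(assignments: list[TrendAssignment]) -> dict[str, list[str]]:
    """Partition assigned genes into the profile categories.

    The reversal category is included (key present) but is conventionally
    excluded from downstream enrichment since those genes show no net change
    between the outer conditions; callers decide.
    """
    profiles = {p.index: p for p in enumerate_profiles(3)}
    out: dict[str, list[str]] = {
        CATEGORY_CONSTANT: [],
        CATEGORY_CHANGE_THEN_STABLE: [],
        CATEGORY_STABLE_THEN_CHANGE: [],
        CATEGORY_REVERSAL: [],
    }
    for a in assignments:
        if a.assigned:
            out[profiles[a.profile].category].append(a.gene)
    return out


def profile_table() -> pd.DataFrame:
    """Index → steps → category mapping, for transparent output."""
    rows = [
        {"profile": p.index, "s1": p.steps[0], "s2": p.steps[1], "category": p.category}
        for p in enumerate_profiles(3)
    ]
    return pd.DataFrame(rows)
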