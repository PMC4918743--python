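"""Association tests: Fisher exact on 2x2 tables, Mann-Whitney U on burdens.

The Fisher test uses the two-sided probability-mass convention (sum over
tables with the same margins whose hypergeometric probability does not
exceed the observed table's). The Mann-Whitney U test offers an exact mode
(full enumeration of group assignments over the pooled midranks, valid with
or without ties) and a normal approximation with tie and continuity
corrections; automatic selection enumerates when n + m <= 16 and there are
no ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _scipy_stats


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = factor present/absent, columns = signature present/absent."""

    a: int  # factor present, signature present
    b: int  # factor present, signature absent
    c: int  # factor absent, signature present
    d: int  # factor absent, signature absent

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.n == 0:
            raise ValueError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def fisher_exact_two_tailed(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    A zero row or column margin carries no information and returns 1.0 (the
    hypergeometric distribution is degenerate).
    """
    arr = table.as_array()
    if 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
        return 1.0
    return float(_scipy_stats.fisher_exact(arr, alternative="two-sided").pvalue)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x against y, from rank sums with midranks for ties."""
    pooled = np.concatenate([x, y])
    ranks = _scipy_stats.rankdata(pooled)
    r_x = ranks[: len(x)].sum()
    return float(r_x - len(x) * (len(x) + 1) / 2)


def _exact_mwu_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by enumerating all C(n+m, n) group assignments.

    Uses midranks throughout, so the enumeration remains a valid permutation
    test in the presence of ties. The two-sided p is the probability of a U
    at least as far from its null mean nm/2 as observed.
    """
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _scipy_stats.rankdata(pooled)
    mean_u = n * m / 2
    observed = abs(_u_statistic(x, y) - mean_u)
    hits = 0
    offset = n * (n + 1) / 2
    for idx in combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mean_u) >= observed - 1e-12:
            hits += 1
    return hits / comb(n + m, n)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    mode: str = "auto",
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U for x, two-sided p).

    mode 'exact' enumerates all group assignments (feasible for small
    samples); 'normal-approx' uses the normal approximation with tie and
    continuity corrections; 'auto' enumerates when n + m <= 16 and the
    pooled data are tie-free, otherwise approximates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if mode == "auto":
        mode = "exact" if (len(x) + len(y) <= 16 and not has_ties) else "normal-approx"
    u = _u_statistic(x, y)
    if mode == "exact":
        return u, _exact_mwu_p(x, y)
    if mode == "normal-approx":
        result = _scipy_stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        return u, float(result.pvalue)
    raise ValueError(f"unknown mode {mode!r}")


#: Closed vocabulary for the Lauren histological classification.
LAUREN_TYPES = ("intestinal", "diffuse", "mixed", "unknown")


@dataclass(frozen=True)
class SampleAnnotation:
    """Histology annotations for one sample."""

    sample_id: str
    cohort: str = ""
    histology_lauren: str = "unknown"
    discohesive_growth: bool | None = None

    def __post_init__(self) -> None:
        if self.histology_lauren not in LAUREN_TYPES:
            raise ValueError(
                f"histology_lauren must be one of {LAUREN_TYPES}, got {self.histology_lauren!r}"
            )


def build_contingency(
    annotations: Sequence[SampleAnnotation],
    calls: Mapping[str, bool],
    stratifier: str,
    present_levels: Sequence[object],
) -> ContingencyTable2x2:
    """Cross-tabulate an annotation against signature calls.

    ``stratifier`` names the annotation field ('histology_lauren' or
    'discohesive_growth'); samples whose value is unknown (the 'unknown'
    level or None) are excluded before counting. ``present_levels`` lists the
    values collapsed into the factor-present row; every remaining known
    level forms the factor-absent row.
    """
    a = b = c = d = 0
    for annotation in annotations:
        value = getattr(annotation, stratifier)
        if value is None or value == "unknown":
            continue
        if annotation.sample_id not in calls:
            raise KeyError(f"no signature call for annotated sample {annotation.sample_id!r}")
        called = bool(calls[annotation.sample_id])
        if value in present_levels:
            a += called
            b += not called
        else:
            c += called
            d += not called
    return ContingencyTable2x2(a=a, b=b, c=c, d=d)


def format_p(p: float) -> str:
    """Report formatting: 4 decimals at p >= 0.001, else 3-significant scientific."""
    if p >= 0.001:
        return f"{p:.4f}"
    return f"{p:.2e}"
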