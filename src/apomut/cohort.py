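"""Tumor-cohort mutation analysis.

Collapses each exome substitution onto the pyrimidine strand, classifies
the APOBEC-target TpC dinucleotide context, tallies per-tumor mutation
loads by class, compares a copy-number-deficient subset against the whole
cohort (Mann-Whitney), and rank-correlates per-gene expression with
per-tumor loads (Spearman).

The deficiency status of a tumor (e.g. homozygous deletion of a gene of
interest) is an input flag; copy-number inference is out of scope.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulator import BASES, COMPLEMENT

__all__ = [
    "TumorMutation",
    "CollapsedClass",
    "CohortTable",
    "COLLAPSED_CLASSES",
    "collapse_and_classify",
    "reverse_complement_mutation",
    "per_tumor_loads",
    "deficient_fraction",
    "compare_deficient_vs_all",
    "mann_whitney",
    "expression_load_correlation",
]

#: pyrimidine-strand substitution classes
COLLAPSED_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


@dataclass(frozen=True)
class TumorMutation:
    """One substitution record with its immediate flanks on the reported
    strand (flanks may be N, which excludes the record from context
    tallies but not from class counts)."""

    tumor_id: str
    ref_base: str
    alt_base: str
    flank5: str = "N"
    flank3: str = "N"

    def __post_init__(self):
        if self.ref_base not in BASES or self.alt_base not in BASES:
            raise ValueError(
                f"ref/alt must be A/C/G/T, got {self.ref_base!r}>{self.alt_base!r}"
            )
        if self.ref_base == self.alt_base:
            raise ValueError("ref_base equals alt_base")
        for f in (self.flank5, self.flank3):
            if f not in BASES and f != "N":
                raise ValueError(f"flank must be A/C/G/T/N, got {f!r}")


@dataclass(frozen=True)
class CollapsedClass:
    """Pyrimidine-strand classification of a substitution.

    ``tpc`` is True when the collapsed reference is a C immediately
    preceded 5' by T (the APOBEC3A/B target dinucleotide), False when the
    5' flank is known and not T, and None when the needed flank is unknown.
    ``context`` is the collapsed trinucleotide (5' flank + ref + 3' flank)
    or "unknown" when a flank is N.
    """

    substitution: str
    tpc: bool | None
    context: str


def reverse_complement_mutation(mut: TumorMutation) -> TumorMutation:
    """The same mutation reported on the opposite strand."""
    comp = dict(COMPLEMENT, N="N")
    return TumorMutation(
        tumor_id=mut.tumor_id,
        ref_base=comp[mut.ref_base],
        alt_base=comp[mut.alt_base],
        flank5=comp[mut.flank3],
        flank3=comp[mut.flank5],
    )


def collapse_and_classify(mut: TumorMutation) -> CollapsedClass:
    """Collapse onto the pyrimidine strand and classify the TpC context.

    Purine-reference records (G or A) are replaced by their reverse
    complement so the reference is C or T; classification is therefore
    strand-involutive. TpC is true iff the collapsed reference is C with a
    T immediately 5'.
    """
    if mut.ref_base in "GA":
        mut = reverse_complement_mutation(mut)
    substitution = f"{mut.ref_base}>{mut.alt_base}"
    if mut.ref_base == "C":
        tpc = None if mut.flank5 == "N" else (mut.flank5 == "T")
    else:
        tpc = False
    context = (
        "unknown"
        if "N" in (mut.flank5, mut.flank3)
        else mut.flank5 + mut.ref_base + mut.flank3
    )
    return CollapsedClass(substitution=substitution, tpc=tpc, context=context)


@dataclass
class CohortTable:
    """Per-tumor mutation loads plus expression and deficiency annotation.

    ``loads`` is indexed by tumor_id with one column per collapsed class,
    ``TpC_<class>`` columns for C classes, ``tpc_total``, ``total``
    (point mutations), ``insertions`` and ``deletions``. ``expression`` is
    a tumor × gene frame; ``deficient`` a boolean Series.
    """

    loads: pd.DataFrame
    expression: pd.DataFrame
    deficient: pd.Series

    def class_loads(self, substitution_class: str, tpc_only: bool = False) -> pd.Series:
        col = f"TpC_{substitution_class}" if tpc_only else substitution_class
        return self.loads[col]


def per_tumor_loads(
    roster: list[str] | pd.Index,
    mutations: list[TumorMutation],
    insertions: dict[str, int] | None = None,
    deletions: dict[str, int] | None = None,
    expression: pd.DataFrame | None = None,
    deficient_flags: dict[str, bool] | None = None,
) -> CohortTable:
    """Tally per-tumor mutation loads over a cohort roster.

    Tumors with zero mutations are retained with zero counts. Mutations
    whose tumor_id is not on the roster, or duplicate tumor_ids in the
    roster, raise an error. Duplicate mutation records count with
    multiplicity (positions are not part of the schema).
    """
    roster = list(roster)
    dupes = [t for t, n in pd.Series(roster).value_counts().items() if n > 1]
    if dupes:
        raise ValueError(f"duplicate tumor_ids in roster: {sorted(dupes)}")
    roster_set = set(roster)
    unknown = sorted({m.tumor_id for m in mutations} - roster_set)
    if unknown:
        raise ValueError(f"mutations reference tumor_ids not on the roster: {unknown}")

    tpc_cols = [f"TpC_{c}" for c in COLLAPSED_CLASSES if c.startswith("C")]
    cols = list(COLLAPSED_CLASSES) + tpc_cols + [
        "tpc_total",
        "total",
        "insertions",
        "deletions",
    ]
    loads = pd.DataFrame(0, index=pd.Index(roster, name="tumor_id"), columns=cols)
    if mutations:
        classified = pd.DataFrame(
            [
                (m.tumor_id, cc.substitution, bool(cc.tpc))
                for m, cc in ((m, collapse_and_classify(m)) for m in mutations)
            ],
            columns=["tumor_id", "substitution", "tpc"],
        )
        by_class = classified.groupby(["tumor_id", "substitution"]).size().unstack(fill_value=0)
        loads.loc[by_class.index, by_class.columns] += by_class
        tpc = classified[classified.tpc]
        if len(tpc):
            by_tpc = tpc.groupby(["tumor_id", "substitution"]).size().unstack(fill_value=0)
            by_tpc.columns = [f"TpC_{c}" for c in by_tpc.columns]
            loads.loc[by_tpc.index, by_tpc.columns] += by_tpc
            loads["tpc_total"] = loads[tpc_cols].sum(axis=1)
        loads["total"] = loads[list(COLLAPSED_CLASSES)].sum(axis=1)
    for col, source in (("insertions", insertions), ("deletions", deletions)):
        if source:
            unknown = sorted(set(source) - roster_set)
            if unknown:
                raise ValueError(f"{col} reference tumor_ids not on the roster: {unknown}")
            for t, n in source.items():
                loads.at[t, col] = int(n)

    if expression is None:
        expression = pd.DataFrame(index=loads.index)
    else:
        expression = expression.reindex(loads.index)
    flags = pd.Series(False, index=loads.index, name="deficient")
    if deficient_flags:
        for t, v in deficient_flags.items():
            if t not in roster_set:
                raise ValueError(f"deficient flag for unknown tumor_id {t!r}")
            flags[t] = bool(v)
    return CohortTable(loads=loads, expression=expression, deficient=flags)


def deficient_fraction(n_deficient: int, n_total: int) -> float:
    """Percentage of the cohort in the deficient subset, to 1 decimal
    (e.g. 14 of 817 → 1.7)."""
    if n_total <= 0:
        raise ValueError("cohort is empty")
    return round(100.0 * n_deficient / n_total, 1)


def _rank_u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x with average-rank tie handling."""
    n1 = len(x)
    ranks = stats.rankdata(np.concatenate([x, y]))
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def _exact_mann_whitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by full enumeration of group labelings.

    Enumerates all C(n1+n2, n1) assignments of the pooled values to the
    first group (tie-safe: U is computed on average ranks each time) and
    returns 2·min(P(U ≤ u), P(U ≥ u)), capped at 1.
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = _rank_u_statistic(x, y)
    ranks = stats.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    us = np.array(
        [ranks[list(idx)].sum() - offset for idx in itertools.combinations(range(len(pooled)), n1)]
    )
    eps = 1e-9
    p_le = np.mean(us <= u_obs + eps)
    p_ge = np.mean(us >= u_obs - eps)
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def mann_whitney(x, y, exact_max_n: int = 8) -> dict:
    """Two-sided Mann-Whitney test.

    Exact p by full enumeration when both groups have at most
    ``exact_max_n`` observations; otherwise the normal approximation with
    tie correction (no continuity correction). Returns a dict with ``U``
    (for the first group), ``p`` and ``method``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    u = _rank_u_statistic(x, y)
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        p = _exact_mann_whitney_p(x, y)
        method = "exact_enumeration"
    else:
        _, p = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        p = float(p)
        method = "normal_approximation"
    return {"U": u, "p": p, "method": method}


def compare_deficient_vs_all(
    table: CohortTable,
    substitution_class: str | None = None,
    tpc_only: bool = False,
    disjoint: bool = False,
) -> dict:
    """Compare the deficient subset against the cohort for one load.

    ``substitution_class=None`` compares total point-mutation load. By
    default "all" means the full cohort including the deficient subset;
    ``disjoint=True`` compares deficient versus proficient only. Also
    reports the median and mean fold-change (deficient over comparison
    group).
    """
    if substitution_class is None:
        values = table.loads["total"]
        label = "total"
    else:
        values = table.class_loads(substitution_class, tpc_only=tpc_only)
        label = ("TpC_" if tpc_only else "") + substitution_class
    deficient = values[table.deficient]
    comparison = values[~table.deficient] if disjoint else values
    if len(deficient) == 0 or len(comparison) == 0:
        raise ValueError("comparison requires non-empty groups")
    result = mann_whitney(deficient.to_numpy(), comparison.to_numpy())
    med = float(comparison.median())
    mean = float(comparison.mean())
    result.update(
        {
            "class": label,
            "n_deficient": int(len(deficient)),
            "n_comparison": int(len(comparison)),
            "median_fold_change": float(deficient.median()) / med if med else math.inf,
            "mean_fold_change": float(deficient.mean()) / mean if mean else math.inf,
        }
    )
    return result


def adjust_p_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional; per-test p-values
    with a 0.01 star threshold are the default reporting convention)."""
    return np.asarray(stats.false_discovery_control(np.asarray(p_values, dtype=float)))


def expression_load_correlation(expression, loads, star_threshold: float = 0.01) -> dict:
    """Spearman rank correlation of per-tumor expression against load.

    rho is the product-moment correlation of the average-ranked paired
    values (tie-safe); p comes from the t approximation with n−2 degrees
    of freedom. ``star`` marks p below the 0.01 figure convention.
    """
    x = np.asarray(expression, dtype=float)
    y = np.asarray(loads, dtype=float)
    if len(x) != len(y):
        raise ValueError("expression and loads must be paired per tumor")
    if len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman rho is undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return {"rho": float(rho), "p": float(p), "n": len(x), "star": bool(p < star_threshold)}
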