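"""Differential-expression and genotype-expression group comparisons.

Two-group contrasts use the Wilcoxon rank-sum test (exact null for small
untied samples, tie/continuity-corrected normal approximation otherwise);
three or more groups use one-way ANOVA with Tukey HSD pairwise adjustment.
Per-screen families of p-values are Benjamini-Hochberg corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import ContractError, CountMatrix, RipGenotypeMatrix

log = logging.getLogger("svaexo")


@dataclass
class GroupComparison:
    transcript_id: str
    grouping: str
    group_levels: list
    statistic: float
    p: float
    p_adjusted: float | None = None
    pairwise: list | None = None  # [(level_i, level_j, p_tukey), ...] iff >= 3 levels
    estimable: bool = True
    note: str = ""


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def wilcoxon_two_group(values_a, values_b) -> tuple:
    """Rank-sum (Mann-Whitney U) statistic and two-sided p.

    Exact null enumeration when n_a + n_b <= 20 and the pooled sample has
    no ties; otherwise the normal approximation with tie and continuity
    corrections. Degenerate all-equal input returns p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ContractError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return float(a.size * b.size / 2), 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def anova_tukey(values_by_group: Mapping[str, Sequence[float]]) -> tuple:
    """One-way ANOVA (F, p) plus Tukey HSD pairwise p-values.

    Pairwise p-values come from the studentized-range distribution with the
    pooled within-group variance. Returned pairwise list is None for two
    groups.
    """
    levels = list(values_by_group)
    groups = [np.asarray(values_by_group[g], dtype=float) for g in levels]
    if len(groups) < 2:
        raise ContractError("ANOVA requires >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise ContractError("every group needs n >= 2")
    pooled_var = sum(((g - g.mean()) ** 2).sum() for g in groups) / (
        sum(g.size for g in groups) - len(groups)
    )
    if pooled_var <= 0:
        raise ContractError("zero pooled within-group variance")
    F, p = stats.f_oneway(*groups)
    pairwise = None
    if len(groups) >= 3:
        res = stats.tukey_hsd(*groups)
        pairwise = [
            (levels[i], levels[j], float(res.pvalue[i, j]))
            for i in range(len(levels))
            for j in range(i + 1, len(levels))
        ]
    return float(F), float(p), pairwise


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1),
    in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ContractError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------

def _subset_samples(matrix: CountMatrix, subset: Mapping[str, str] | None) -> pd.Index:
    meta = matrix.metadata.loc[matrix.sample_ids]
    keep = pd.Series(True, index=meta.index)
    for key, value in (subset or {}).items():
        if key not in meta.columns:
            raise ContractError(f"unknown metadata column {key!r}")
        keep &= meta[key].astype(str) == str(value)
    return meta.index[keep]


def _compare_groups(values_by_group: Mapping[str, np.ndarray], transcript_id, grouping):
    levels = list(values_by_group)
    if len(levels) == 2:
        stat, p = wilcoxon_two_group(values_by_group[levels[0]], values_by_group[levels[1]])
        return GroupComparison(transcript_id, grouping, levels, stat, p)
    F, p, pairwise = anova_tukey(values_by_group)
    return GroupComparison(transcript_id, grouping, levels, F, p, pairwise=pairwise)


def de_screen(
    matrix: CountMatrix,
    grouping: str,
    subset: Mapping[str, str] | None = None,
    min_group_n: int = 2,
    pool_als: bool = True,
) -> list:
    """Per-transcript group comparison with BH correction across the screen.

    Two metadata levels -> Wilcoxon; >= 3 -> ANOVA + Tukey. ``pool_als``
    merges ALS and ALSND into one case level when grouping by diagnosis.
    The BH family is all transcripts tested in this invocation.
    """
    samples = _subset_samples(matrix, subset)
    meta = matrix.metadata.loc[samples]
    if grouping not in meta.columns:
        raise ContractError(f"unknown grouping column {grouping!r}")
    labels = meta[grouping].astype(str)
    if grouping == "diagnosis" and pool_als:
        labels = labels.replace({"ALS": "ALS/ALSND", "ALSND": "ALS/ALSND"})
    counts = labels.value_counts()
    levels = sorted(counts.index[counts >= min_group_n])
    if len(levels) < 2:
        raise ContractError("fewer than two usable groups after subsetting")
    members = {g: labels.index[labels == g] for g in levels}

    comparisons = []
    for tid in matrix.transcript_ids:
        row = matrix.counts.loc[tid]
        values = {g: row[members[g]].to_numpy(dtype=float) for g in levels}
        try:
            comparisons.append(_compare_groups(values, tid, grouping))
        except ContractError as exc:
            comparisons.append(
                GroupComparison(
                    tid, grouping, levels, np.nan, np.nan,
                    estimable=False, note=str(exc),
                )
            )
    ok = [c for c in comparisons if c.estimable]
    if ok:
        adjusted = bh_adjust([c.p for c in ok])
        for c, padj in zip(ok, adjusted):
            c.p_adjusted = float(padj)
    return comparisons


def genotype_expression(
    matrix: CountMatrix,
    genotypes: RipGenotypeMatrix,
    sva_id: str,
    transcript_id: str,
    subset: Mapping[str, str] | None = None,
    min_group_n: int = 2,
) -> GroupComparison:
    """Expression of one transcript across the AA/PA/PP genotype classes.

    Missing genotypes are excluded; genotype classes below ``min_group_n``
    are dropped, and the comparison degrades to a rank test when only two
    classes remain. Fewer than two usable classes -> not estimable.
    """
    if transcript_id not in matrix.counts.index:
        raise ContractError(f"unknown transcript {transcript_id!r}")
    if sva_id not in genotypes.sva_ids:
        raise ContractError(f"unknown SVA {sva_id!r}")
    samples = [
        s for s in _subset_samples(matrix, subset) if s in genotypes.sample_ids
    ]
    geno = genotypes.genotypes.loc[sva_id, samples]
    geno = geno[geno != "missing"]
    values = {}
    for level in ("AA", "PA", "PP"):
        members = geno.index[geno == level]
        if len(members) >= min_group_n:
            values[level] = matrix.counts.loc[transcript_id, members].to_numpy(float)
    if len(values) < 2:
        return GroupComparison(
            transcript_id, "genotype", list(values), np.nan, np.nan,
            estimable=False, note="fewer than two usable genotype classes",
        )
    return _compare_groups(values, transcript_id, "genotype")


# ---------------------------------------------------------------------------
# convenience normaliser
# ---------------------------------------------------------------------------

def median_of_ratios(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios size-factor normalisation (convenience only; the
    screens consume matrices that are already normalised)."""
    logc = np.log(counts.replace(0, np.nan))
    ref = logc.mean(axis=1)
    ratios = logc.sub(ref, axis=0)
    size = np.exp(ratios.median(axis=0))
    return counts.div(size, axis=1)


def comparisons_to_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "transcript_id": c.transcript_id,
                "grouping": c.grouping,
                "levels": ",".join(map(str, c.group_levels)),
                "statistic": c.statistic,
                "p": c.p,
                "p_adjusted": c.p_adjusted,
                "pairwise": (
                    ";".join(f"{i}-{j}:{p:.4g}" for i, j, p in c.pairwise)
                    if c.pairwise
                    else ""
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "grouping", "levels", "statistic", "p", "p_adjusted", "pairwise"],
    )
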