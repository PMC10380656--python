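"""Presence/absence (RIP) genotyping from SV deletion calls and
genotype-phenotype association.

A reference SVA's "absent" allele shows up as a deletion in short-read SV
calls: a PASS deletion with sufficient reciprocal overlap genotypes the
locus, mapping VCF 0/0, 0/1, 1/1 to PP, PA, AA. Associations use additive
(minor-allele-count) coding: logistic regression for case/control status,
linear regression for age at onset, and a Cox proportional-hazards model
for survival — each Bonferroni-corrected over the loci surviving the MAF
filter for that analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter

from .core_io import (
    AmbiguityError,
    ContractError,
    RipGenotypeMatrix,
    SvaElement,
    SvDeletionCall,
    ValidationError,
)

log = logging.getLogger("svaexo")

_GT_MAP = {"0/0": "PP", "0/1": "PA", "1/1": "AA", "missing": "missing"}

#: number of absent (A) alleles per genotype
A_DOSE = {"PP": 0, "PA": 1, "AA": 2}


@dataclass
class AssociationResult:
    sva_id: str
    minor_allele: str            # 'P' or 'A'
    maf_by_group: dict           # group label -> minor allele frequency
    estimate: float              # OR, slope (years/allele) or HR
    ci95: tuple
    p_unadjusted: float
    p_bonferroni: float
    n: int
    estimable: bool = True
    note: str = ""

    # Table-2 style alias
    @property
    def odds_ratio(self) -> float:
        return self.estimate


# ---------------------------------------------------------------------------
# genotyping
# ---------------------------------------------------------------------------

def genotype_rips_from_sv(
    deletions: Sequence[SvDeletionCall],
    svas: Sequence[SvaElement],
    reciprocal_overlap: float = 0.5,
    min_gq: int = 20,
) -> RipGenotypeMatrix:
    """Assign PASS deletions to SVAs by reciprocal overlap and map genotypes.

    GQ below ``min_gq`` becomes missing (records without a GQ value are
    kept). Samples with no overlapping deletion at a genotyped locus, and
    all samples of SVAs with no assigned deletion, are PP — the reference
    genome carries the element. Two PASS deletions matching one SVA raise
    an ambiguity error.
    """
    samples: list[str] = []
    for d in deletions:
        for s in d.sample_genotypes:
            if s not in samples:
                samples.append(s)
    if not samples:
        raise ContractError("no samples in the deletion call set")

    data = {}
    for sva in svas:
        matches = [
            d
            for d in deletions
            if d.filter_status == "PASS"
            and sva.interval.reciprocal_overlap(d.interval) >= reciprocal_overlap
        ]
        if len(matches) > 1:
            ids = [f"{d.variant_id}@{d.interval.chrom}:{d.interval.start}" for d in matches]
            raise AmbiguityError(
                f"{sva.sva_id}: multiple PASS deletions assigned: {ids}"
            )
        if not matches:
            data[sva.sva_id] = {s: "PP" for s in samples}
            continue
        d = matches[0]
        row = {}
        for s in samples:
            gt = _GT_MAP[d.sample_genotypes.get(s, "0/0")]
            gq = d.genotype_qualities.get(s)
            if gq is not None and gq < min_gq:
                gt = "missing"
            row[s] = gt
        data[sva.sva_id] = row

    frame = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    frame = frame.loc[[s.sva_id for s in svas]]
    return RipGenotypeMatrix(frame)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def compute_maf(
    matrix: RipGenotypeMatrix, group_labels: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Per-SVA minor allele and frequency, overall and per group.

    freq(A) = (2*AA + PA) / (2 * non-missing samples); the minor allele is
    the rarer of P/A overall, ties designating A. All-missing SVAs are
    excluded with a warning.
    """
    rows = []
    for sva_id in matrix.sva_ids:
        geno = matrix.genotypes.loc[sva_id]
        ok = geno[geno != "missing"]
        if ok.empty:
            warnings.warn(f"{sva_id}: all genotypes missing; excluded from MAF table")
            continue
        freq_a = _freq_a(ok)
        minor = "A" if freq_a <= 0.5 else "P"
        row = {
            "sva_id": sva_id,
            "minor_allele": minor,
            "maf": freq_a if minor == "A" else 1.0 - freq_a,
            "n_genotyped": len(ok),
        }
        if group_labels is not None:
            groups = pd.Series(group_labels)
            for g in sorted(groups.unique()):
                members = groups.index[groups == g]
                sub = ok[ok.index.isin(members)]
                if sub.empty:
                    row[f"maf_{g}"] = np.nan
                else:
                    fa = _freq_a(sub)
                    row[f"maf_{g}"] = fa if minor == "A" else 1.0 - fa
        rows.append(row)
    return pd.DataFrame(rows).set_index("sva_id") if rows else pd.DataFrame()


def _freq_a(genotypes: pd.Series) -> float:
    doses = genotypes.map(A_DOSE)
    return float(doses.sum()) / (2 * len(doses))


def filter_maf(maf_table: pd.DataFrame, threshold: float = 0.05) -> list:
    """SVA ids with MAF strictly greater than ``threshold``."""
    return list(maf_table.index[maf_table["maf"] > threshold])


# ---------------------------------------------------------------------------
# unadjusted allelic odds ratio (sanity-check oracle)
# ---------------------------------------------------------------------------

def allelic_or_from_counts(table) -> tuple:
    """OR and Woolf 95% CI from a 2x2 allele-count table
    [[case_minor, case_major], [control_minor, control_major]].
    Zero cells get the Haldane-Anscombe +0.5 correction."""
    (a, b), (c, d) = [[float(x) for x in row] for row in table]
    if min(a, b, c, d) < 0:
        raise ContractError("allele counts must be >= 0")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a / b) / (c / d)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = np.exp(np.log(or_) - 1.96 * se), np.exp(np.log(or_) + 1.96 * se)
    return float(or_), (float(lo), float(hi))


# ---------------------------------------------------------------------------
# model helpers
# ---------------------------------------------------------------------------

def _dosage(matrix: RipGenotypeMatrix, sva_id: str, minor: str) -> pd.Series:
    geno = matrix.genotypes.loc[sva_id]
    dose = geno.map(A_DOSE).astype("float64")
    if minor == "P":
        dose = 2.0 - dose
    dose[geno == "missing"] = np.nan
    return dose


def _design(covariate_frame: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix: dummy-code categoricals, drop constants."""
    num = pd.get_dummies(covariate_frame, drop_first=True, dtype=float)
    keep = [c for c in num.columns if num[c].nunique() > 1]
    return num[keep].astype(float)


def bonferroni(p: float, m: int) -> float:
    return min(1.0, m * p) if np.isfinite(p) else np.nan


def is_case(diagnosis: pd.Series) -> pd.Series:
    """ALS / ALSND count as cases, NNC as controls."""
    return diagnosis.isin(["ALS", "ALSND"]).astype(int)


# ---------------------------------------------------------------------------
# case-control association
# ---------------------------------------------------------------------------

def associate_case_control(
    matrix: RipGenotypeMatrix,
    phenotypes: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "platform"),
    maf_threshold: float = 0.05,
) -> list:
    """Per-SVA logistic regression of case status on minor-allele dosage.

    ``phenotypes`` is indexed by sample with either a binary ``case``
    column or a ``diagnosis`` column (ALS/ALSND vs NNC). Bonferroni m =
    number of SVAs surviving the MAF filter.
    """
    pheno = phenotypes.loc[[s for s in matrix.sample_ids if s in phenotypes.index]]
    case = (
        pheno["case"].astype(int)
        if "case" in pheno.columns
        else is_case(pheno["diagnosis"])
    )
    groups = case.map({1: "case", 0: "ctrl"})
    sub = RipGenotypeMatrix(matrix.genotypes[pheno.index])
    maf = compute_maf(sub, group_labels=groups.to_dict())
    tested = filter_maf(maf, maf_threshold)
    m = len(tested)

    results = []
    for sva_id in tested:
        minor = maf.at[sva_id, "minor_allele"]
        dose = _dosage(sub, sva_id, minor)
        df = pd.concat([case.rename("y"), dose.rename("g"), pheno[list(covariates)]], axis=1)
        df = df.dropna()
        X = pd.concat([df[["g"]], _design(df[list(covariates)])], axis=1)
        est, ci, p, ok, note = _fit_logistic(df["y"], X)
        maf_groups = {
            g: float(maf.at[sva_id, f"maf_{g}"])
            for g in ("ctrl", "case")
            if f"maf_{g}" in maf.columns
        }
        results.append(
            AssociationResult(
                sva_id=sva_id,
                minor_allele=minor,
                maf_by_group=maf_groups,
                estimate=est,
                ci95=ci,
                p_unadjusted=p,
                p_bonferroni=bonferroni(p, m),
                n=len(df),
                estimable=ok,
                note=note,
            )
        )
    return results


def _fit_logistic(y: pd.Series, X: pd.DataFrame) -> tuple:
    """Fit y ~ X via IRLS; return (OR, CI, p, estimable, note) for 'g'."""
    Xc = sm.add_constant(X.astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y.astype(float), Xc, family=sm.families.Binomial()).fit(
                maxiter=100
            )
        beta = fit.params["g"]
        se = fit.bse["g"]
        if not np.isfinite(se) or abs(beta) > 15 or se > 50:
            return np.nan, (np.nan, np.nan), np.nan, False, "separation"
        ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
        return float(np.exp(beta)), ci, float(fit.pvalues["g"]), True, ""
    except Exception as exc:  # singular fits, perfect separation
        return np.nan, (np.nan, np.nan), np.nan, False, f"not estimable: {exc}"


# ---------------------------------------------------------------------------
# age at onset
# ---------------------------------------------------------------------------

def associate_age_at_onset(
    matrix: RipGenotypeMatrix,
    phenotypes: pd.DataFrame,
    covariates: Sequence[str] = ("sex", "platform", "onset_site"),
    maf_threshold: float = 0.05,
) -> list:
    """Linear regression of age at onset on minor-allele dosage (cases only)."""
    pheno = phenotypes.loc[[s for s in matrix.sample_ids if s in phenotypes.index]]
    if "diagnosis" in pheno.columns:
        pheno = pheno[is_case(pheno["diagnosis"]) == 1]
    pheno = pheno.dropna(subset=["onset_age"])
    sub = RipGenotypeMatrix(matrix.genotypes[pheno.index])
    maf = compute_maf(sub)
    tested = filter_maf(maf, maf_threshold)
    m = len(tested)

    results = []
    for sva_id in tested:
        minor = maf.at[sva_id, "minor_allele"]
        dose = _dosage(sub, sva_id, minor)
        df = pd.concat(
            [pheno["onset_age"].rename("y"), dose.rename("g"), pheno[list(covariates)]],
            axis=1,
        ).dropna()
        distinct = df["g"].nunique()
        if distinct < 2 or (distinct < 3 and len(df) < 10):
            results.append(
                AssociationResult(
                    sva_id, minor, {}, np.nan, (np.nan, np.nan), np.nan, np.nan,
                    n=len(df), estimable=False, note="too few genotype classes",
                )
            )
            continue
        X = sm.add_constant(
            pd.concat([df[["g"]], _design(df[list(covariates)])], axis=1).astype(float)
        )
        fit = sm.OLS(df["y"].astype(float), X).fit()
        beta, se = fit.params["g"], fit.bse["g"]
        p = float(fit.pvalues["g"])
        results.append(
            AssociationResult(
                sva_id=sva_id,
                minor_allele=minor,
                maf_by_group={},
                estimate=float(beta),
                ci95=(float(beta - 1.96 * se), float(beta + 1.96 * se)),
                p_unadjusted=p,
                p_bonferroni=bonferroni(p, m),
                n=len(df),
            )
        )
    return results


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------

def associate_survival(
    matrix: RipGenotypeMatrix,
    phenotypes: pd.DataFrame,
    covariates: Sequence[str] = ("sex", "platform", "onset_age", "onset_site"),
    maf_threshold: float = 0.05,
) -> list:
    """Cox proportional-hazards HR per minor-allele copy; right-censoring
    honoured via the event indicator."""
    pheno = phenotypes.loc[[s for s in matrix.sample_ids if s in phenotypes.index]]
    if "diagnosis" in pheno.columns:
        pheno = pheno[is_case(pheno["diagnosis"]) == 1]
    pheno = pheno.dropna(subset=["survival_months", "event"])
    sub = RipGenotypeMatrix(matrix.genotypes[pheno.index])
    maf = compute_maf(sub)
    tested = filter_maf(maf, maf_threshold)
    m = len(tested)

    results = []
    for sva_id in tested:
        minor = maf.at[sva_id, "minor_allele"]
        dose = _dosage(sub, sva_id, minor)
        df = pd.concat(
            [
                pheno[["survival_months", "event"]],
                dose.rename("g"),
                pheno[list(covariates)],
            ],
            axis=1,
        ).dropna()
        if df["event"].astype(int).sum() == 0 or df["g"].nunique() < 2:
            results.append(
                AssociationResult(
                    sva_id, minor, {}, np.nan, (np.nan, np.nan), np.nan, np.nan,
                    n=len(df), estimable=False, note="no events or constant genotype",
                )
            )
            continue
        model_df = pd.concat(
            [
                df[["survival_months", "event", "g"]].astype(float),
                _design(df[list(covariates)]),
            ],
            axis=1,
        )
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(model_df, duration_col="survival_months", event_col="event")
        except Exception as exc:
            results.append(
                AssociationResult(
                    sva_id, minor, {}, np.nan, (np.nan, np.nan), np.nan, np.nan,
                    n=len(df), estimable=False, note=f"not estimable: {exc}",
                )
            )
            continue
        beta = float(cph.params_["g"])
        se = float(cph.standard_errors_["g"])
        p = float(cph.summary.loc["g", "p"])
        results.append(
            AssociationResult(
                sva_id=sva_id,
                minor_allele=minor,
                maf_by_group={},
                estimate=float(np.exp(beta)),
                ci95=(float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
                p_unadjusted=p,
                p_bonferroni=bonferroni(p, m),
                n=len(df),
            )
        )
    return results


# ---------------------------------------------------------------------------
# result table
# ---------------------------------------------------------------------------

ASSOC_COLUMNS = (
    "sva_id",
    "chrom",
    "start",
    "end",
    "minor_allele",
    "maf_ctrl",
    "maf_case",
    "or_or_hr_or_slope",
    "ci_low",
    "ci_high",
    "p_unadj",
    "p_bonferroni",
)


def results_to_frame(
    results: Sequence[AssociationResult], svas: Sequence[SvaElement] | None = None
) -> pd.DataFrame:
    coords = {}
    if svas:
        coords = {s.sva_id: s.interval for s in svas}
    rows = []
    for r in results:
        iv = coords.get(r.sva_id)
        rows.append(
            {
                "sva_id": r.sva_id,
                "chrom": iv.chrom if iv else "",
                "start": iv.start if iv else np.nan,
                "end": iv.end if iv else np.nan,
                "minor_allele": r.minor_allele,
                "maf_ctrl": r.maf_by_group.get("ctrl", np.nan),
                "maf_case": r.maf_by_group.get("case", np.nan),
                "or_or_hr_or_slope": r.estimate,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "p_unadj": r.p_unadjusted,
                "p_bonferroni": r.p_bonferroni,
            }
        )
    return pd.DataFrame(rows, columns=list(ASSOC_COLUMNS))
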