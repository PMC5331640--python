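"""Association screens linking temporal variability to taxa and outcomes.

Four screens are provided, each emitting tidy rows of
:class:`AssociationResult`:

* genus ↔ CV Pearson correlations (heatmap row ordering = r descending),
* genus abundance across stability categories (Kruskal–Wallis),
* CV comparisons between clinical outcome groups (Welch t), with a
  Mann–Whitney variant for genus-vs-infection contrasts,
* multivariable OLS of each CV measure on the clinical covariates.

Multiple-testing correction is Benjamini–Hochberg, applied within one
family per screen per site per measure — never pooled across screens.
Genus screens are restricted to genera whose cohort-wide mean relative
abundance is at least ``min_mean_abundance`` (default 1%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .exceptions import DomainError, InsufficientDataError
from .formats_io import CohortMetadata, FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "relative_abundance",
    "aggregate_genus",
    "pearson",
    "kruskal_wallis",
    "welch_t",
    "mann_whitney",
    "benjamini_hochberg",
    "genus_cv_correlation",
    "genus_category_tests",
    "outcome_comparisons",
    "genus_outcome_tests",
    "multivariable_ols",
    "regression_grid",
    "REGRESSION_COVARIATES",
]

#: Combined-n threshold below which the Mann–Whitney p is exact
#: (tie-free data only); above it a tie-corrected normal approximation.
MW_EXACT_MAX_N = 16

DEFAULT_MIN_MEAN_ABUNDANCE = 0.01

#: Covariates of the multivariable regression, in design-matrix order.
#: Chemotherapy uses fludarabine-containing regimens as the reference
#: level, with "other" collapsed into the reference.
REGRESSION_COVARIATES = [
    "age",
    "pip_tazo_gt72h",
    "cefepime_gt72h",
    "carbapenem_gt72h",
    "days_all_abx",
    "days_treatment_abx",
    "n_antibiotics",
    "chemo_non_fludarabine_high_intensity",
    "chemo_hypomethylator",
]


@dataclass
class AssociationResult:
    feature: str
    statistic_name: str
    statistic: float
    p_raw: float
    p_adj: float
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.p_raw <= 1 and 0 <= self.p_adj <= 1):
            raise DomainError("p values must lie in [0, 1]")


def _results_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [vars(r) for r in results],
        columns=["feature", "statistic_name", "statistic", "p_raw", "p_adj", "n"],
    )


# ---------------------------------------------------------------------------
# Table transforms
# ---------------------------------------------------------------------------


def relative_abundance(table: FeatureTable) -> pd.DataFrame:
    """Column-normalized taxon × sample matrix (each column sums to 1)."""
    totals = table.sample_totals()
    if np.any(totals == 0):
        zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise DomainError(f"zero-total samples must be dropped first: {zero[:5]}")
    return pd.DataFrame(
        table.counts / totals.astype(float),
        index=table.taxon_ids,
        columns=table.sample_ids,
    )


def aggregate_genus(table: FeatureTable) -> FeatureTable:
    """Sum counts of taxa sharing a genus label; 'unclassified' is kept
    as its own bucket."""
    genera: list[str] = []
    index: dict[str, int] = {}
    for taxon in table.taxon_ids:
        genus = table.taxonomy[taxon]
        if genus not in index:
            index[genus] = len(genera)
            genera.append(genus)
    counts = np.zeros((len(genera), len(table.sample_ids)), dtype=np.int64)
    for i, taxon in enumerate(table.taxon_ids):
        counts[index[table.taxonomy[taxon]]] += table.counts[i]
    return FeatureTable(genera, list(table.sample_ids), counts, {g: g for g in genera})


# ---------------------------------------------------------------------------
# Elementary tests (validated wrappers over scipy)
# ---------------------------------------------------------------------------


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment r with a two-sided p from the t transform (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise InsufficientDataError(f"Pearson correlation needs n >= 3, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square (k−1 df) p value.

    Degenerate input where every observation is identical returns
    ``(0.0, 1.0)`` — no evidence of any group difference.
    """
    if len(groups) < 2:
        raise InsufficientDataError("Kruskal–Wallis needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for i, g in enumerate(arrays):
        if g.size == 0:
            raise InsufficientDataError(f"group {i} is empty")
    if sum(g.size for g in arrays) < 3:
        raise InsufficientDataError("Kruskal–Wallis needs total n >= 3")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t test; returns (t, df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("Welch t needs >= 2 observations per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            # identical constant groups: no difference, maximal p
            return 0.0, float(a.size + b.size - 2), 1.0
        raise DomainError("both groups constant with different means; t undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann–Whitney U (reported as min(U_a, U_b)) with two-sided p.

    Exact p when combined n ≤ ``MW_EXACT_MAX_N`` and the data are
    tie-free; otherwise the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InsufficientDataError("Mann–Whitney needs non-empty groups")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    exact = (a.size + b.size) <= MW_EXACT_MAX_N and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    u_a = float(res.statistic)
    u = min(u_a, a.size * b.size - u_a)
    return u, float(res.pvalue)


def benjamini_hochberg(p: Sequence[float]) -> np.ndarray:
    """Standard BH step-up adjustment; preserves input order.

    ``adj_(i) = min_{j >= i} min(1, m * p_(j) / j)`` over the sorted
    p values.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise DomainError("p values must be a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DomainError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def significance_stars(p_adj: float) -> str:
    if p_adj <= 0.001:
        return "***"
    if p_adj <= 0.01:
        return "**"
    if p_adj <= 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Screens
# ---------------------------------------------------------------------------


def _profile_lookup(profiles: pd.DataFrame, site: str, measure: str) -> dict[str, float]:
    sub = profiles[(profiles["site"] == site) & profiles[measure].notna()]
    return dict(zip(sub["patient_id"], sub[measure].astype(float)))


def _filter_genera(genus_rel: pd.DataFrame, min_mean_abundance: float) -> pd.DataFrame:
    keep = genus_rel.mean(axis=1) >= min_mean_abundance
    return genus_rel.loc[keep]


def genus_cv_correlation(
    genus_rel: pd.DataFrame,
    profiles: pd.DataFrame,
    meta: CohortMetadata,
    measure: str,
    site: str,
    level: str = "sample",
    min_mean_abundance: float = DEFAULT_MIN_MEAN_ABUNDANCE,
) -> pd.DataFrame:
    """Per-genus Pearson correlation between relative abundance and the
    patient's CV, BH-adjusted across genera, sorted by r descending.

    ``level="sample"`` pairs every sample with its patient's CV (the
    heatmap convention, one column per sample); ``level="patient_mean"``
    first averages each patient's sample abundances, which avoids the
    pseudo-replication of repeated samples per patient.
    """
    if level not in ("sample", "patient_mean"):
        raise ValueError(f"unknown level {level!r}")
    cv_by_patient = _profile_lookup(profiles, site, measure)
    sample_ids = [
        sid
        for sid in genus_rel.columns
        if sid in meta.samples
        and meta.samples[sid].site == site
        and meta.samples[sid].patient_id in cv_by_patient
    ]
    if not sample_ids:
        logger.warning("no %s samples with %s profiles", site, measure)
        return _results_frame([])
    sub = _filter_genera(genus_rel[sample_ids], min_mean_abundance)
    if sub.empty:
        logger.warning("no genera pass the %.3f mean-abundance filter", min_mean_abundance)
        return _results_frame([])

    if level == "sample":
        cvs = np.array([cv_by_patient[meta.samples[sid].patient_id] for sid in sample_ids])
        abundance = sub
    else:
        patient_of = pd.Series({sid: meta.samples[sid].patient_id for sid in sample_ids})
        abundance = sub.T.groupby(patient_of).mean().T
        cvs = np.array([cv_by_patient[pid] for pid in abundance.columns])

    rows: list[tuple[str, float, float, int]] = []
    for genus in abundance.index:
        values = abundance.loc[genus].to_numpy(dtype=float)
        if np.ptp(values) == 0:
            logger.warning("genus %s constant across samples; excluded", genus)
            continue
        r, p = pearson(values, cvs)
        rows.append((genus, r, p, values.size))
    if not rows:
        return _results_frame([])
    p_adj = benjamini_hochberg([row[2] for row in rows])
    results = [
        AssociationResult(genus, "pearson_r", r, p, float(adj), n)
        for (genus, r, p, n), adj in zip(rows, p_adj)
    ]
    frame = _results_frame(results)
    return frame.sort_values("statistic", ascending=False, kind="stable").reset_index(drop=True)


def genus_category_tests(
    genus_rel: pd.DataFrame,
    assignments: pd.DataFrame,
    meta: CohortMetadata,
    site: str,
    min_mean_abundance: float = DEFAULT_MIN_MEAN_ABUNDANCE,
) -> pd.DataFrame:
    """Kruskal–Wallis of per-patient mean genus abundance across the
    stable/average/variable categories, BH-adjusted across genera.

    Abundance is summarized per patient (mean of that patient's sample
    relative abundances) because the categories are patient-level.
    """
    cat = assignments[assignments["site"] == site]
    category_of = dict(zip(cat["patient_id"], cat["category"]))
    if not category_of:
        raise InsufficientDataError(f"no stability assignments for site {site!r}")
    sample_ids = [
        sid
        for sid in genus_rel.columns
        if sid in meta.samples
        and meta.samples[sid].site == site
        and meta.samples[sid].patient_id in category_of
    ]
    sub = _filter_genera(genus_rel[sample_ids], min_mean_abundance)
    patient_of = pd.Series({sid: meta.samples[sid].patient_id for sid in sample_ids})
    per_patient = sub.T.groupby(patient_of).mean().T  # genus x patient

    groups_index: dict[str, list[str]] = {"stable": [], "average": [], "variable": []}
    for pid in per_patient.columns:
        groups_index[category_of[pid]].append(pid)
    empty = [c for c, pids in groups_index.items() if not pids]
    if empty:
        raise InsufficientDataError(
            f"stability categories {empty} are empty at site {site!r}; "
            "the cohort is too small for category tests"
        )

    rows: list[tuple[str, float, float, int]] = []
    for genus in per_patient.index:
        groups = [
            per_patient.loc[genus, pids].to_numpy(dtype=float)
            for pids in groups_index.values()
        ]
        h, p = kruskal_wallis(groups)
        rows.append((genus, h, p, per_patient.shape[1]))
    if not rows:
        return _results_frame([])
    p_adj = benjamini_hochberg([row[2] for row in rows])
    results = [
        AssociationResult(genus, "kruskal_H", h, p, float(adj), n)
        for (genus, h, p, n), adj in zip(rows, p_adj)
    ]
    frame = _results_frame(results)
    frame["stars"] = [significance_stars(v) for v in frame["p_adj"]]
    return frame.sort_values("p_adj", kind="stable").reset_index(drop=True)


OUTCOMES = ("infection_during_ic_any", "infection_during_ic_mdi", "infection_90d_post", "remission")


def _outcome_indicator(meta: CohortMetadata, patient_id: str, outcome: str) -> bool | None:
    info = meta.patients[patient_id]
    if outcome == "infection_during_ic_any":
        if info.infection_during_ic is None:
            return None
        return info.infection_during_ic != "none"
    if outcome == "infection_during_ic_mdi":
        if info.infection_during_ic is None:
            return None
        return info.infection_during_ic == "MDI"
    if outcome == "infection_90d_post":
        return info.infection_90d_post
    if outcome == "remission":
        return info.remission
    raise ValueError(f"unknown outcome {outcome!r}; choose from {OUTCOMES}")


def outcome_comparisons(
    profiles: pd.DataFrame,
    meta: CohortMetadata,
    outcome: str,
    measure: str,
    site: str,
) -> AssociationResult:
    """Welch t comparison of one CV measure between outcome groups."""
    cv_by_patient = _profile_lookup(profiles, site, measure)
    pos, neg = [], []
    for pid, cv in cv_by_patient.items():
        flag = _outcome_indicator(meta, pid, outcome)
        if flag is None:
            continue
        (pos if flag else neg).append(cv)
    if len(pos) < 2 or len(neg) < 2:
        raise InsufficientDataError(
            f"outcome {outcome!r} at {site!r}: group sizes {len(pos)}/{len(neg)} "
            "(need >= 2 each)"
        )
    t, _df, p = welch_t(pos, neg)
    return AssociationResult(
        feature=f"{outcome}:{site}:{measure}",
        statistic_name="welch_t",
        statistic=t,
        p_raw=p,
        p_adj=p,  # single test; family of one
        n=len(pos) + len(neg),
    )


def genus_outcome_tests(
    genus_rel: pd.DataFrame,
    meta: CohortMetadata,
    outcome: str,
    site: str,
    genera: Sequence[str],
) -> pd.DataFrame:
    """Mann–Whitney genus-abundance contrasts between outcome groups.

    Abundance is summarized per patient (mean over samples) and each
    listed genus is tested individually; the returned family is
    BH-adjusted across the listed genera.
    """
    sample_ids = [
        sid for sid in genus_rel.columns
        if sid in meta.samples and meta.samples[sid].site == site
    ]
    patient_of = pd.Series({sid: meta.samples[sid].patient_id for sid in sample_ids})
    per_patient = genus_rel[sample_ids].T.groupby(patient_of).mean().T
    rows: list[tuple[str, float, float, int]] = []
    for genus in genera:
        if genus not in per_patient.index:
            logger.warning("genus %s not present; skipped", genus)
            continue
        pos, neg = [], []
        for pid in per_patient.columns:
            flag = _outcome_indicator(meta, pid, outcome)
            if flag is None:
                continue
            (pos if flag else neg).append(float(per_patient.loc[genus, pid]))
        if not pos or not neg:
            raise InsufficientDataError(f"outcome {outcome!r}: a group is empty")
        u, p = mann_whitney(pos, neg)
        rows.append((genus, u, p, len(pos) + len(neg)))
    if not rows:
        return _results_frame([])
    p_adj = benjamini_hochberg([row[2] for row in rows])
    results = [
        AssociationResult(genus, "mannwhitney_U", u, p, float(adj), n)
        for (genus, u, p, n), adj in zip(rows, p_adj)
    ]
    return _results_frame(results)


# ---------------------------------------------------------------------------
# Multivariable regression
# ---------------------------------------------------------------------------


def _design_matrix(meta: CohortMetadata, patient_ids: Sequence[str]) -> pd.DataFrame:
    rows = []
    missing: list[str] = []
    for pid in patient_ids:
        info = meta.patients[pid]
        needed = [
            info.age, info.pip_tazo_gt72h, info.cefepime_gt72h, info.carbapenem_gt72h,
            info.days_all_abx, info.days_treatment_abx, info.n_antibiotics,
            info.chemo_category,
        ]
        if any(v is None for v in needed):
            missing.append(pid)
            continue
        rows.append(
            {
                "patient_id": pid,
                "age": float(info.age),
                "pip_tazo_gt72h": float(info.pip_tazo_gt72h),
                "cefepime_gt72h": float(info.cefepime_gt72h),
                "carbapenem_gt72h": float(info.carbapenem_gt72h),
                "days_all_abx": float(info.days_all_abx),
                "days_treatment_abx": float(info.days_treatment_abx),
                "n_antibiotics": float(info.n_antibiotics),
                "chemo_non_fludarabine_high_intensity": float(
                    info.chemo_category == "non_fludarabine_high_intensity"
                ),
                "chemo_hypomethylator": float(info.chemo_category == "hypomethylator"),
            }
        )
    if missing:
        raise DomainError(
            f"patients with missing regression covariates: {missing}; "
            "covariates are never imputed"
        )
    return pd.DataFrame(rows).set_index("patient_id")[REGRESSION_COVARIATES]


def multivariable_ols(
    profiles: pd.DataFrame,
    meta: CohortMetadata,
    site: str,
    measure: str,
) -> pd.DataFrame:
    """OLS of one CV measure on the clinical covariates, with intercept.

    Returns one row per covariate: coefficient, standard error, t, and
    two-sided p. Raises on rank deficiency (naming collinear columns)
    and on missing covariate values (naming patients).
    """
    cv_by_patient = _profile_lookup(profiles, site, measure)
    patient_ids = sorted(cv_by_patient)
    design = _design_matrix(meta, patient_ids)
    y = pd.Series({pid: cv_by_patient[pid] for pid in design.index}, name=measure)
    x = sm.add_constant(design, has_constant="add")
    if len(y) <= x.shape[1]:
        raise InsufficientDataError(
            f"{len(y)} patients for {x.shape[1]} parameters at {site}/{measure}"
        )
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # identify offending columns via pivoted QR
        from scipy.linalg import qr

        _q, rmat, piv = qr(x.to_numpy(), pivoting=True)
        diag = np.abs(np.diag(rmat))
        bad = [x.columns[piv[i]] for i in range(len(diag)) if diag[i] < 1e-10 * diag.max()]
        bad += [x.columns[j] for j in piv[len(diag):]]
        raise DomainError(f"design matrix is rank deficient; collinear columns: {bad}")
    fit = sm.OLS(y.to_numpy(), x.to_numpy()).fit()
    out = pd.DataFrame(
        {
            "covariate": x.columns,
            "coef": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    out = out[out["covariate"] != "const"].reset_index(drop=True)
    out.insert(0, "site", site)
    out.insert(1, "measure", measure)
    return out


def regression_grid(
    profiles: pd.DataFrame,
    meta: CohortMetadata,
    measures: Sequence[str] = ("cv_shannon", "cv_uu", "cv_wu"),
) -> pd.DataFrame:
    """Covariate p-value grid over {oral, stool} × the given measures."""
    frames = []
    for site in ("oral", "stool"):
        for measure in measures:
            frames.append(multivariable_ols(profiles, meta, site, measure))
    return pd.concat(frames, ignore_index=True)
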