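"""Per-patient, per-site temporal-variability statistics.

The central quantity is the coefficient of variation (CV) — sample
standard deviation (n−1 denominator) over mean — computed per patient
and body site over (a) the longitudinal α-diversity values and (b) the
set of within-patient UniFrac distances. Patients are then classified
per site into quartile-based stability categories: first quartile
"stable", middle two "average", fourth "variable".

Documented ambiguity: the within-patient distance set defaults to all
unordered pairs of that patient's samples; a consecutive-by-order mode
is available (``pair_mode="consecutive"``). This is the single most
consequential convention choice in the module.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DomainError, InsufficientCohortError, InsufficientDataError
from .formats_io import SITES, CohortMetadata, DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "coefficient_of_variation",
    "alpha_cv",
    "beta_cv",
    "build_profiles",
    "categorize",
    "cross_site_correlation",
    "CV_MEASURES",
]

#: Profile columns holding CV values, in output order.
CV_MEASURES = ("cv_shannon", "cv_simpson", "cv_chao1", "cv_uu", "cv_wu")

PAIR_MODES = ("all_pairs", "consecutive")
CATEGORIES = ("stable", "average", "variable")

DEFAULT_MIN_SAMPLES = 3


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample standard deviation (ddof=1) divided by the mean.

    Requires at least two values and a strictly positive mean.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise DomainError("values must be one-dimensional")
    if arr.size < 2:
        raise InsufficientDataError(
            f"coefficient of variation needs >= 2 values, got {arr.size}"
        )
    mean = arr.mean()
    if mean <= 0:
        raise DomainError(f"coefficient of variation undefined for mean {mean}")
    return float(arr.std(ddof=1) / mean)


def alpha_cv(
    alpha: pd.DataFrame,
    meta: CohortMetadata,
    patient: str,
    site: str,
    metric: str = "shannon",
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> float:
    """CV of one patient-site's longitudinal α-diversity values."""
    sample_ids = [s for s in meta.samples_for(patient, site) if s in alpha.index]
    if len(sample_ids) < min_samples:
        raise InsufficientDataError(
            f"patient {patient!r} has {len(sample_ids)} {site} samples "
            f"(min_samples={min_samples})"
        )
    return coefficient_of_variation(alpha.loc[sample_ids, metric].to_numpy())


def _within_patient_distances(
    dm: DistanceMatrix,
    meta: CohortMetadata,
    patient: str,
    site: str,
    pair_mode: str,
) -> np.ndarray:
    sample_ids = [s for s in meta.samples_for(patient, site) if s in dm.ids]
    idx = {s: i for i, s in enumerate(dm.ids)}
    pos = [idx[s] for s in sample_ids]
    if pair_mode == "all_pairs":
        pairs = list(itertools.combinations(pos, 2))
    elif pair_mode == "consecutive":
        pairs = list(zip(pos, pos[1:]))
    else:
        raise ValueError(f"unknown pair_mode {pair_mode!r}; choose from {PAIR_MODES}")
    return np.array([dm.values[i, j] for i, j in pairs])


def beta_cv(
    dm: DistanceMatrix,
    meta: CohortMetadata,
    patient: str,
    site: str,
    pair_mode: str = "all_pairs",
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> float:
    """CV of the within-patient UniFrac distance multiset at one site."""
    sample_ids = [s for s in meta.samples_for(patient, site) if s in dm.ids]
    if len(sample_ids) < min_samples:
        raise InsufficientDataError(
            f"patient {patient!r} has {len(sample_ids)} {site} samples "
            f"(min_samples={min_samples})"
        )
    distances = _within_patient_distances(dm, meta, patient, site, pair_mode)
    return coefficient_of_variation(distances)


def build_profiles(
    alpha: pd.DataFrame,
    dms: Mapping[str, DistanceMatrix],
    meta: CohortMetadata,
    pair_mode: str = "all_pairs",
    min_samples: int = DEFAULT_MIN_SAMPLES,
) -> pd.DataFrame:
    """One variability profile per (patient, site) with enough samples.

    ``dms`` maps ``"uu"``/``"wu"`` to the unweighted / weighted UniFrac
    distance matrices. CV columns that cannot be computed (e.g. a zero
    mean distance) are left as NaN — absent, not zero. Patient-sites
    below ``min_samples`` are skipped with a logged reason.
    """
    if pair_mode not in PAIR_MODES:
        raise ValueError(f"unknown pair_mode {pair_mode!r}; choose from {PAIR_MODES}")
    rows = []
    for patient in sorted(meta.patients):
        for site in SITES:
            sample_ids = [s for s in meta.samples_for(patient, site) if s in alpha.index]
            if len(sample_ids) < min_samples:
                if sample_ids:
                    logger.info(
                        "skipping patient %s site %s: %d samples < min_samples=%d",
                        patient, site, len(sample_ids), min_samples,
                    )
                continue
            row: dict[str, object] = {
                "patient_id": patient,
                "site": site,
                "n_samples": len(sample_ids),
            }
            for metric in ("shannon", "simpson", "chao1"):
                try:
                    row[f"cv_{metric}"] = alpha_cv(
                        alpha, meta, patient, site, metric, min_samples
                    )
                except (DomainError, InsufficientDataError) as exc:
                    logger.info("cv_%s undefined for %s/%s: %s", metric, patient, site, exc)
                    row[f"cv_{metric}"] = np.nan
            for key in ("uu", "wu"):
                if key not in dms:
                    row[f"cv_{key}"] = np.nan
                    continue
                try:
                    row[f"cv_{key}"] = beta_cv(
                        dms[key], meta, patient, site, pair_mode, min_samples
                    )
                except (DomainError, InsufficientDataError) as exc:
                    logger.info("cv_%s undefined for %s/%s: %s", key, patient, site, exc)
                    row[f"cv_{key}"] = np.nan
            rows.append(row)
    columns = ["patient_id", "site", "n_samples", *CV_MEASURES]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class StabilityAssignment:
    patient_id: str
    site: str
    measure: str
    category: str


def categorize(profiles: pd.DataFrame, measure: str) -> pd.DataFrame:
    """Quartile stability categories for one CV measure, per body site.

    Quartiles use linear-interpolation quantiles. Boundary ties go to
    the extreme category (CV ≤ Q1 → stable, CV ≥ Q3 → variable); when
    Q1 = Q3 every patient is "average". Sites with fewer than 4 defined
    profiles raise :class:`InsufficientCohortError`.
    """
    if measure not in CV_MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {CV_MEASURES}")
    rows = []
    for site in SITES:
        sub = profiles[(profiles["site"] == site) & profiles[measure].notna()]
        if sub.empty:
            continue
        if len(sub) < 4:
            raise InsufficientCohortError(
                f"site {site!r} has only {len(sub)} profiles with {measure}; "
                "quartile categorization needs >= 4"
            )
        cvs = sub[measure].to_numpy(dtype=float)
        q1, q3 = np.quantile(cvs, [0.25, 0.75])  # linear interpolation
        for patient, cv in zip(sub["patient_id"], cvs):
            if q1 == q3:
                category = "average"
            elif cv <= q1:
                category = "stable"
            elif cv >= q3:
                category = "variable"
            else:
                category = "average"
            rows.append(
                {"patient_id": patient, "site": site, "measure": measure, "category": category}
            )
    return pd.DataFrame(rows, columns=["patient_id", "site", "measure", "category"])


def cross_site_correlation(
    profiles: pd.DataFrame, measure: str
) -> tuple[float, float, int]:
    """Pearson r between oral and stool CVs of the same patients.

    Returns ``(r, two-sided p, n pairs)``; p comes from the t transform
    with n−2 degrees of freedom.
    """
    if measure not in CV_MEASURES:
        raise ValueError(f"unknown measure {measure!r}; choose from {CV_MEASURES}")
    wide = profiles.pivot_table(
        index="patient_id", columns="site", values=measure, aggfunc="first"
    )
    if "oral" not in wide.columns or "stool" not in wide.columns:
        raise InsufficientDataError("need profiles at both body sites")
    paired = wide[["oral", "stool"]].dropna()
    n = len(paired)
    if n < 3:
        raise InsufficientDataError(f"only {n} patients have both sites (need >= 3)")
    oral = paired["oral"].to_numpy()
    stool = paired["stool"].to_numpy()
    if np.ptp(oral) == 0 or np.ptp(stool) == 0:
        raise DomainError("zero variance in one site's CVs")
    r, p = stats.pearsonr(oral, stool)
    return float(r), float(p), n
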