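"""α-diversity metrics and UniFrac β-diversity distances.

Metric conventions (stated here because the tools this package mirrors
do not agree on them):

* Shannon uses the natural logarithm.
* Simpson is the Gini–Simpson form, ``1 − Σ p_i²`` (in [0, 1)).
* Chao1 is the bias-corrected estimator
  ``S_obs + F1·(F1 − 1) / (2·(F2 + 1))``.
* Weighted UniFrac defaults to the normalized form (range [0, 1]).
* No rarefaction is applied by default; all metrics operate on relative
  abundances of the full counts. :func:`rarefy` offers seeded
  without-replacement subsampling for sensitivity analyses.
* Samples with zero total counts are dropped from table-level
  computations with a logged warning rather than failing the run.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, TreeError
from .formats_io import DistanceMatrix, FeatureTable
from .phylo import PhyloTree, postorder_branches

logger = logging.getLogger(__name__)

__all__ = [
    "shannon",
    "simpson",
    "chao1",
    "unweighted_unifrac",
    "weighted_unifrac",
    "alpha_table",
    "beta_matrix",
    "rarefy",
    "branch_structure",
]

ALPHA_METRICS = ("shannon", "simpson", "chao1")
BETA_METRICS = ("unweighted", "weighted_normalized", "weighted_raw")


# ---------------------------------------------------------------------------
# α diversity
# ---------------------------------------------------------------------------


def _as_counts(v: Mapping[str, float] | Sequence[float] | np.ndarray) -> np.ndarray:
    if isinstance(v, Mapping):
        arr = np.asarray(list(v.values()), dtype=float)
    else:
        arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise DomainError("community vector must be one-dimensional")
    if np.any(arr < 0):
        raise DomainError("community vector contains negative counts")
    return arr


def shannon(v: Mapping[str, float] | Sequence[float]) -> float:
    """Shannon diversity, ``−Σ p ln p`` over taxa with positive counts."""
    counts = _as_counts(v)
    total = counts.sum()
    if total <= 0:
        raise DomainError("cannot compute Shannon diversity of an all-zero vector")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def simpson(v: Mapping[str, float] | Sequence[float]) -> float:
    """Gini–Simpson diversity, ``1 − Σ p²``."""
    counts = _as_counts(v)
    total = counts.sum()
    if total <= 0:
        raise DomainError("cannot compute Simpson diversity of an all-zero vector")
    p = counts / total
    return float(1.0 - (p * p).sum())


def chao1(v: Mapping[str, float] | Sequence[float]) -> float:
    """Bias-corrected Chao1 richness, ``S_obs + F1(F1−1)/(2(F2+1))``."""
    counts = _as_counts(v)
    if not np.all(counts == np.floor(counts)):
        raise DomainError("Chao1 requires integer counts")
    total = counts.sum()
    if total <= 0:
        raise DomainError("cannot compute Chao1 of an all-zero vector")
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


# ---------------------------------------------------------------------------
# UniFrac
# ---------------------------------------------------------------------------


def branch_structure(
    tree: PhyloTree, taxon_ids: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Branch lengths and a branch × taxon descendant incidence matrix.

    ``incidence[b, t]`` is True when taxon ``t`` descends through branch
    ``b``. Taxa must all be leaves of ``tree``.
    """
    leaf_set = set(tree.leaf_names())
    missing = [t for t in taxon_ids if t not in leaf_set]
    if missing:
        raise TreeError(f"taxa not present in tree: {missing[:5]}")
    branches = postorder_branches(tree)
    col = {t: i for i, t in enumerate(taxon_ids)}
    lengths = np.empty(len(branches))
    incidence = np.zeros((len(branches), len(taxon_ids)), dtype=bool)
    for b, (length, leafset) in enumerate(branches):
        lengths[b] = length
        for taxon in leafset:
            j = col.get(taxon)
            if j is not None:
                incidence[b, j] = True
    return lengths, incidence


def _pair_vectors(
    tree: PhyloTree,
    a: Mapping[str, float],
    b: Mapping[str, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    taxa = sorted(set(a) | set(b))
    va = np.array([float(a.get(t, 0)) for t in taxa])
    vb = np.array([float(b.get(t, 0)) for t in taxa])
    if np.any(va < 0) or np.any(vb < 0):
        raise DomainError("negative counts in community vector")
    if va.sum() <= 0 or vb.sum() <= 0:
        raise DomainError("both communities must contain at least one positive count")
    support = (va > 0) | (vb > 0)
    present = [t for t, keep in zip(taxa, support) if keep]
    lengths, incidence = branch_structure(tree, present)
    return lengths, incidence.astype(float) @ va[support], incidence.astype(float) @ vb[support]


def unweighted_unifrac(
    tree: PhyloTree, a: Mapping[str, float], b: Mapping[str, float]
) -> float:
    """Fraction of observed branch length unique to one community.

    Presence/absence only: ``Σ l·[exactly one side] / Σ l·[either side]``.
    """
    lengths, flow_a, flow_b = _pair_vectors(tree, a, b)
    in_a = flow_a > 0
    in_b = flow_b > 0
    union = float(lengths[in_a | in_b].sum())
    if union == 0:
        raise DomainError("no observed branch length; tree has zero-length support")
    unique = float(lengths[in_a ^ in_b].sum())
    return unique / union


def weighted_unifrac(
    tree: PhyloTree,
    a: Mapping[str, float],
    b: Mapping[str, float],
    normalized: bool = True,
) -> float:
    """Abundance-weighted UniFrac, ``Σ l·|p_a − p_b|``.

    ``normalized=True`` (the default) divides by ``Σ l·(p_a + p_b)`` so
    the distance lies in [0, 1].
    """
    lengths, flow_a, flow_b = _pair_vectors(tree, a, b)
    total_a = float(sum(a.values()))
    total_b = float(sum(b.values()))
    prop_a = flow_a / total_a
    prop_b = flow_b / total_b
    raw = float((lengths * np.abs(prop_a - prop_b)).sum())
    if not normalized:
        return raw
    denom = float((lengths * (prop_a + prop_b)).sum())
    if denom == 0:
        raise DomainError("zero normalizing branch mass")
    return raw / denom


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Seeded without-replacement subsampling to a common depth.

    Samples with fewer than ``depth`` total counts are dropped with a
    logged warning.
    """
    if depth <= 0:
        raise DomainError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        logger.warning("rarefy: dropping %d samples below depth %d: %s",
                       len(dropped), depth, dropped[:10])
    new_samples = [s for s, k in zip(table.sample_ids, keep) if k]
    if not new_samples:
        raise DomainError("rarefaction removed every sample")
    n_taxa = len(table.taxon_ids)
    out = np.zeros((n_taxa, len(new_samples)), dtype=np.int64)
    for j, sid in enumerate(new_samples):
        col = table.counts[:, table.sample_ids.index(sid)]
        pool = np.repeat(np.arange(n_taxa), col)
        chosen = rng.choice(pool, size=depth, replace=False)
        out[:, j] = np.bincount(chosen, minlength=n_taxa)
    return FeatureTable(list(table.taxon_ids), new_samples, out, dict(table.taxonomy))


# ---------------------------------------------------------------------------
# Table-level computations
# ---------------------------------------------------------------------------


def _drop_empty_samples(table: FeatureTable) -> FeatureTable:
    totals = table.sample_totals()
    if np.all(totals > 0):
        return table
    dropped = [s for s, t in zip(table.sample_ids, totals) if t == 0]
    logger.warning("excluding %d zero-count samples: %s", len(dropped), dropped[:10])
    kept = [s for s, t in zip(table.sample_ids, totals) if t > 0]
    if not kept:
        raise DomainError("every sample has zero total counts")
    return table.select_samples(kept)


def alpha_table(table: FeatureTable) -> pd.DataFrame:
    """Per-sample Shannon/Simpson/Chao1, indexed by sample id."""
    table = _drop_empty_samples(table)
    records = {}
    for j, sid in enumerate(table.sample_ids):
        col = table.counts[:, j]
        records[sid] = {
            "shannon": shannon(col),
            "simpson": simpson(col),
            "chao1": chao1(col),
        }
    out = pd.DataFrame.from_dict(records, orient="index")
    out.index.name = "sample_id"
    return out


def beta_matrix(table: FeatureTable, tree: PhyloTree, metric: str) -> DistanceMatrix:
    """All-pairs UniFrac distance matrix for the table's samples.

    ``metric`` is one of ``unweighted``, ``weighted_normalized``,
    ``weighted_raw``. Implemented through a branch × sample flow matrix
    so the cost is linear in branches per sample pair.
    """
    if metric not in BETA_METRICS:
        raise ValueError(f"unknown beta metric {metric!r}; choose from {BETA_METRICS}")
    table = _drop_empty_samples(table)
    lengths, incidence = branch_structure(tree, table.taxon_ids)
    inc = incidence.astype(float)
    counts = table.counts.astype(float)
    totals = counts.sum(axis=0)
    n = len(table.sample_ids)
    values = np.zeros((n, n))
    if metric == "unweighted":
        present = inc @ (counts > 0) > 0  # (branches, samples)
        for i in range(n - 1):
            pi = present[:, i : i + 1]
            union = np.where(pi | present[:, i + 1 :], lengths[:, None], 0.0).sum(axis=0)
            uniq = np.where(pi ^ present[:, i + 1 :], lengths[:, None], 0.0).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                row = np.where(union > 0, uniq / np.where(union > 0, union, 1.0), 0.0)
            values[i, i + 1 :] = row
    else:
        props = (inc @ counts) / totals  # (branches, samples)
        for i in range(n - 1):
            diff = np.abs(props[:, i : i + 1] - props[:, i + 1 :])
            raw = (lengths[:, None] * diff).sum(axis=0)
            if metric == "weighted_raw":
                values[i, i + 1 :] = raw
            else:
                denom = (lengths[:, None] * (props[:, i : i + 1] + props[:, i + 1 :])).sum(axis=0)
                values[i, i + 1 :] = np.where(denom > 0, raw / np.where(denom > 0, denom, 1.0), 0.0)
    values = values + values.T
    return DistanceMatrix(list(table.sample_ids), values)
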