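"""End-to-end orchestration: simulate/load → diversity → variability → screens.

A run consumes a :class:`RunConfig` (from YAML or constructed in code),
executes every stage, and writes a fixed artifact set into the output
directory::

    alpha.tsv  beta_uu.tsv  beta_wu.tsv  profiles.tsv  categories.tsv
    genus_cv.tsv  genus_category.tsv  outcomes.tsv  regression.tsv
    summary.json

Outputs are deterministic given the config (files carry the config hash
and seed but no timestamps), so re-running a config reproduces the
numeric artifacts byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import association, diversity, synthetic, variability
from .exceptions import DomainError, InsufficientDataError, MicrovarError
from .formats_io import (
    CohortMetadata,
    FeatureTable,
    read_feature_table,
    read_metadata,
    write_distance_matrix,
)
from .phylo import PhyloTree, parse_newick

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "ARTIFACTS"]

ARTIFACTS = (
    "alpha.tsv",
    "beta_uu.tsv",
    "beta_wu.tsv",
    "profiles.tsv",
    "categories.tsv",
    "genus_cv.tsv",
    "genus_category.tsv",
    "outcomes.tsv",
    "regression.tsv",
)

_FLOAT_FORMAT = "%.12g"


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``inputs`` (paths to table/tree/samples/patients) or
    ``simulate`` (cohort-generator overrides) must be present.
    """

    out_dir: str
    seed: int = 0
    inputs: dict[str, str] | None = None
    simulate: dict[str, Any] | None = None
    pair_mode: str = "all_pairs"
    min_samples: int = 3
    genus_threshold: float = 0.01
    measures: tuple[str, ...] = ("cv_shannon", "cv_wu")
    genus_cv_level: str = "sample"

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.simulate is None):
            raise MicrovarError("exactly one of 'inputs' or 'simulate' must be given")
        if not (0 < self.genus_threshold < 1):
            raise MicrovarError("genus_threshold must lie in (0, 1)")
        for m in self.measures:
            if m not in variability.CV_MEASURES:
                raise MicrovarError(f"unknown measure {m!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        if "measures" in data:
            data["measures"] = tuple(data["measures"])
        return cls(**data)

    def canonical(self) -> dict[str, Any]:
        data = dataclasses.asdict(self)
        data.pop("out_dir")  # output location must not affect the hash
        data["measures"] = list(self.measures)
        return data

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(config: RunConfig) -> tuple[FeatureTable, PhyloTree, CohortMetadata]:
    if config.simulate is not None:
        overrides = dict(config.simulate)
        overrides.setdefault("seed", config.seed)
        if "samples_per_patient" in overrides:
            overrides["samples_per_patient"] = tuple(overrides["samples_per_patient"])
        cohort_cfg = synthetic.CohortConfig(**overrides)
        table, tree, meta, _truth = synthetic.generate_cohort(cohort_cfg)
        return table, tree, meta
    paths = config.inputs or {}
    missing = [k for k in ("table", "tree", "samples", "patients") if k not in paths]
    if missing:
        raise MicrovarError(f"input paths missing: {missing}")
    table = read_feature_table(paths["table"])
    tree = parse_newick(Path(paths["tree"]).read_text())
    meta = read_metadata(paths["samples"], paths["patients"])
    return table, tree, meta


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute every stage and write the full artifact set.

    Returns the machine-readable summary that is also written to
    ``summary.json``. Stage failures propagate wrapped with the stage
    name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name: str):
        logger.info("stage: %s", name)
        return name

    current = stage("load")
    try:
        table, tree, meta = _load_inputs(config)

        current = stage("diversity")
        alpha = diversity.alpha_table(table)
        dm_uu = diversity.beta_matrix(table, tree, "unweighted")
        dm_wu = diversity.beta_matrix(table, tree, "weighted_normalized")
        _write_tsv(alpha, out / "alpha.tsv", index=True)
        write_distance_matrix(dm_uu, out / "beta_uu.tsv")
        write_distance_matrix(dm_wu, out / "beta_wu.tsv")

        current = stage("variability")
        profiles = variability.build_profiles(
            alpha, {"uu": dm_uu, "wu": dm_wu}, meta,
            pair_mode=config.pair_mode, min_samples=config.min_samples,
        )
        _write_tsv(profiles, out / "profiles.tsv")
        categories = pd.concat(
            [variability.categorize(profiles, m) for m in config.measures],
            ignore_index=True,
        )
        _write_tsv(categories, out / "categories.tsv")

        current = stage("associate")
        nonzero = [
            s for s, t in zip(table.sample_ids, table.sample_totals()) if t > 0
        ]
        genus_table = association.aggregate_genus(table.select_samples(nonzero))
        genus_rel = association.relative_abundance(genus_table)

        genus_cv_frames = []
        for site in ("oral", "stool"):
            for measure in config.measures:
                frame = association.genus_cv_correlation(
                    genus_rel, profiles, meta, measure, site,
                    level=config.genus_cv_level,
                    min_mean_abundance=config.genus_threshold,
                )
                frame.insert(0, "site", site)
                frame.insert(1, "measure", measure)
                genus_cv_frames.append(frame)
        _write_tsv(pd.concat(genus_cv_frames, ignore_index=True), out / "genus_cv.tsv")

        category_frames = []
        for site in ("oral", "stool"):
            for measure in config.measures:
                sub = categories[categories["measure"] == measure]
                try:
                    frame = association.genus_category_tests(
                        genus_rel, sub, meta, site,
                        min_mean_abundance=config.genus_threshold,
                    )
                except InsufficientDataError as exc:
                    logger.warning("genus_category %s/%s skipped: %s", site, measure, exc)
                    continue
                frame.insert(0, "site", site)
                frame.insert(1, "measure", measure)
                category_frames.append(frame)
        _write_tsv(
            pd.concat(category_frames, ignore_index=True)
            if category_frames else pd.DataFrame(),
            out / "genus_category.tsv",
        )

        outcome_rows = []
        for outcome in ("infection_during_ic_any", "infection_90d_post", "remission"):
            for site in ("oral", "stool"):
                for measure in config.measures:
                    try:
                        res = association.outcome_comparisons(
                            profiles, meta, outcome, measure, site
                        )
                    except (DomainError, InsufficientDataError) as exc:
                        logger.warning("outcome %s %s/%s skipped: %s", outcome, site, measure, exc)
                        continue
                    outcome_rows.append(
                        {"outcome": outcome, "site": site, "measure": measure,
                         "statistic": res.statistic, "p": res.p_raw, "n": res.n}
                    )
        _write_tsv(pd.DataFrame(outcome_rows), out / "outcomes.tsv")

        current = stage("regression")
        try:
            regression = association.regression_grid(profiles, meta)
        except (DomainError, InsufficientDataError) as exc:
            logger.warning("regression skipped: %s", exc)
            regression = pd.DataFrame()
        _write_tsv(regression, out / "regression.tsv")
    except MicrovarError as exc:
        raise MicrovarError(f"stage {current!r} failed: {exc}") from exc

    summary: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_samples": len(table.sample_ids),
        "n_taxa": len(table.taxon_ids),
        "n_patients": len(meta.patients),
        "per_site": {},
        "cross_site": {},
        "screen_hits": {},
    }
    for site in ("oral", "stool"):
        sub = profiles[profiles["site"] == site]
        summary["per_site"][site] = {
            m: {
                "mean": _round(sub[m].mean()),
                "sd": _round(sub[m].std(ddof=1)),
                "n": int(sub[m].notna().sum()),
            }
            for m in variability.CV_MEASURES
        }
    for measure in config.measures:
        try:
            r, p, n = variability.cross_site_correlation(profiles, measure)
            summary["cross_site"][measure] = {"r": _round(r), "p": _round(p), "n": n}
        except (DomainError, InsufficientDataError) as exc:
            logger.warning("cross-site correlation for %s skipped: %s", measure, exc)
    genus_cv_all = pd.concat(genus_cv_frames, ignore_index=True)
    summary["screen_hits"]["genus_cv_p_adj_lt_05"] = int((genus_cv_all["p_adj"] < 0.05).sum())
    if category_frames:
        cat_all = pd.concat(category_frames, ignore_index=True)
        summary["screen_hits"]["genus_category_p_adj_lt_05"] = int((cat_all["p_adj"] < 0.05).sum())
    outcome_df = pd.DataFrame(outcome_rows)
    if not outcome_df.empty:
        summary["screen_hits"]["outcomes_p_lt_05"] = int((outcome_df["p"] < 0.05).sum())
    if not regression.empty:
        summary["screen_hits"]["regression_p_lt_05"] = int((regression["p"] < 0.05).sum())

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary


def _round(value: float) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(np.format_float_positional(float(value), precision=10, unique=True))
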