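"""Synthetic longitudinal two-site cohorts with planted ground truth.

The generator emulates the shape of a hospitalized-cohort study — tens
of patients, oral and stool sampling every few days over about a month,
16S-style genus-structured count tables — while planting the effects
the analysis pipeline is meant to recover:

* each patient carries a volatility level σ_p (a stable/variable
  mixture) shared across body sites, which drives a Gaussian random
  walk on log-composition (softmax-renormalized per timepoint);
* antibiotic exposure (``days_all_abx``) is drawn independently and
  then *causally* inflates the oral — and only the oral — walk scale,
  so regressions should flag it for oral but not stool responses;
* pathogen genera are enriched (and commensal genera depleted) in
  volatile patient-sites, and volatile patients receive transient
  pathogen bloom spikes;
* infection outcomes are Bernoulli with logits increasing in the oral
  (during-treatment infection) or stool (post-treatment infection)
  volatility.

All randomness flows from a single seeded generator, so identical
(config, seed) yields bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError
from .formats_io import (
    CohortMetadata,
    FeatureTable,
    PatientInfo,
    SampleInfo,
    write_feature_table,
    write_metadata,
)
from .phylo import Node, PhyloTree

__all__ = [
    "CohortConfig",
    "SyntheticTruth",
    "GENERA",
    "PATHOGEN_GENERA",
    "COMMENSAL_GENERA",
    "generate_tree",
    "generate_cohort",
    "make_fixture",
    "null_config",
    "FIXTURE_SEED",
]

# genus -> (oral prior weight, stool prior weight); pathogens bloom and
# track volatility upward, commensals track it downward.
GENERA: dict[str, tuple[float, float]] = {
    "Streptococcus": (3.0, 1.0),
    "Staphylococcus": (1.5, 1.0),
    "Stenotrophomonas": (0.5, 0.2),
    "Enterococcus": (0.3, 1.5),
    "Akkermansia": (0.05, 1.5),
    "Pseudobutyrivibrio": (0.05, 1.0),
    "Subdoligranulum": (0.05, 1.2),
    "Faecalibacterium": (0.05, 2.0),
    "Lactobacillus": (0.5, 1.0),
    "Bacteroides": (0.1, 3.0),
    "Prevotella": (1.5, 1.5),
    "Blautia": (0.05, 1.5),
    "Roseburia": (0.05, 1.2),
    "Veillonella": (1.5, 0.8),
    "Haemophilus": (1.5, 0.2),
    "Neisseria": (1.8, 0.1),
    "Fusobacterium": (1.0, 0.3),
    "Actinomyces": (1.2, 0.3),
    "Rothia": (1.5, 0.2),
    "Gemella": (1.0, 0.2),
    "Clostridium": (0.1, 1.2),
    "Escherichia": (0.1, 1.0),
    "Klebsiella": (0.1, 0.8),
    "Bifidobacterium": (0.05, 1.0),
    "unclassified": (0.5, 0.5),
}

PATHOGEN_GENERA = ("Staphylococcus", "Streptococcus", "Stenotrophomonas", "Enterococcus")
COMMENSAL_GENERA = ("Akkermansia", "Pseudobutyrivibrio", "Subdoligranulum", "Faecalibacterium")

FIXTURE_SEED = 20170228
FIXTURE_N_PATIENTS = 12

_CHEMO_LEVELS = ("fludarabine", "non_fludarabine_high_intensity", "hypomethylator", "other")
_CHEMO_PROBS = (0.32, 0.32, 0.24, 0.12)


@dataclass(frozen=True)
class CohortConfig:
    """Tunable knobs of the cohort generator; defaults mirror the study
    design being emulated (59 patients, 6–9 samples per site, mean
    sequencing depth 28,622)."""

    n_patients: int = 59
    samples_per_patient: tuple[int, int] = (6, 9)
    n_taxa: int = 120
    sigma_low: float = 0.15
    sigma_high: float = 0.5
    variable_fraction: float = 0.35
    site_sigma_noise: float = 0.25
    pathogen_coupling: float = 1.2
    commensal_coupling: float = 1.2
    abx_coupling: float = 1.3
    infection_coupling: float = 1.5
    bloom_prob: float = 0.35
    depth: float = 28622.0
    seed: int = 0

    def validate(self) -> None:
        if not (self.sigma_high > self.sigma_low > 0):
            raise DomainError("need sigma_high > sigma_low > 0")
        if self.depth <= 0:
            raise DomainError("depth must be positive")
        if self.n_patients < 8:
            raise DomainError("n_patients must be >= 8")
        if not (0 <= self.variable_fraction <= 1):
            raise DomainError("variable_fraction must lie in [0, 1]")
        lo, hi = self.samples_per_patient
        if not (1 <= lo <= hi):
            raise DomainError("samples_per_patient must be an increasing positive range")
        if self.n_taxa < 2:
            raise DomainError("n_taxa must be >= 2")
        for name in ("pathogen_coupling", "commensal_coupling", "abx_coupling",
                     "infection_coupling", "bloom_prob", "site_sigma_noise"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")


def null_config(**overrides: object) -> CohortConfig:
    """A no-effect configuration: one volatility level, zero couplings.

    Used for type-I-error calibration of the screens.
    """
    cfg = CohortConfig(
        variable_fraction=0.0,
        pathogen_coupling=0.0,
        commensal_coupling=0.0,
        abx_coupling=0.0,
        infection_coupling=0.0,
        bloom_prob=0.0,
    )
    return replace(cfg, **overrides)  # type: ignore[arg-type]


@dataclass
class SyntheticTruth:
    """Planted per-patient ground truth, reproducible from (config, seed)."""

    config: CohortConfig
    patients: pd.DataFrame  # patient_id, variable, sigma_base, sigma_oral, sigma_stool, ...

    def variable_patients(self) -> list[str]:
        return list(self.patients.loc[self.patients["variable"], "patient_id"])


# ---------------------------------------------------------------------------
# Taxa and tree
# ---------------------------------------------------------------------------


def assign_taxa(n_taxa: int, genera: Sequence[str] | None = None) -> tuple[list[str], dict[str, str]]:
    """Deterministic taxon ids and round-robin genus assignment."""
    genera = list(genera) if genera is not None else list(GENERA)
    width = max(3, len(str(n_taxa)))
    taxon_ids = [f"OTU_{i + 1:0{width}d}" for i in range(n_taxa)]
    taxonomy = {t: genera[i % len(genera)] for i, t in enumerate(taxon_ids)}
    return taxon_ids, taxonomy


def _random_join(nodes: list[Node], rng: np.random.Generator) -> Node:
    nodes = list(nodes)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = Node(None, float(rng.exponential(1.0)), [left, right])
        nodes.append(parent)
    return nodes[0]


def generate_tree(
    n_taxa: int,
    seed: int,
    taxonomy: dict[str, str] | None = None,
) -> PhyloTree:
    """Random bifurcating rooted tree with exponential(1) branch lengths.

    Taxa of one genus are attached within a single clade, so genus-mates
    are closer on average than cross-genus pairs.
    """
    if n_taxa < 2:
        raise DomainError("generate_tree needs n_taxa >= 2")
    if taxonomy is None:
        _taxa, taxonomy = assign_taxa(n_taxa)
    rng = np.random.default_rng(seed)
    by_genus: dict[str, list[str]] = {}
    for taxon, genus in taxonomy.items():
        by_genus.setdefault(genus, []).append(taxon)
    clades: list[Node] = []
    for genus in sorted(by_genus):
        leaves = [Node(t, float(rng.exponential(1.0))) for t in sorted(by_genus[genus])]
        clades.append(_random_join(leaves, rng))
    root = _random_join(clades, rng)
    root.length = 0.0
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(
    config: CohortConfig,
) -> tuple[FeatureTable, PhyloTree, CohortMetadata, SyntheticTruth]:
    """Draw a full synthetic cohort; see the module docstring for the
    generative model. Deterministic given ``config`` (incl. its seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    taxon_ids, taxonomy = assign_taxa(config.n_taxa)
    tree = generate_tree(config.n_taxa, config.seed + 1, taxonomy)
    genus_of = np.array([taxonomy[t] for t in taxon_ids])
    is_pathogen = np.isin(genus_of, PATHOGEN_GENERA)
    is_commensal = np.isin(genus_of, COMMENSAL_GENERA)
    pathogen_genera_present = [g for g in PATHOGEN_GENERA if g in set(genus_of)]

    n = config.n_patients
    width = max(2, len(str(n)))
    patient_ids = [f"P{i + 1:0{width}d}" for i in range(n)]

    # --- patient-level truth ------------------------------------------
    variable = rng.random(n) < config.variable_fraction
    sigma_base = np.where(variable, config.sigma_high, config.sigma_low)

    days_all_abx = np.clip(np.round(rng.normal(26.0, 6.0, size=n)), 5, 55)
    abx_z = (days_all_abx - 26.0) / 6.0

    site_noise = {site: rng.normal(0.0, config.site_sigma_noise, size=n) for site in ("oral", "stool")}
    sigma_site = {
        "oral": sigma_base * np.exp(site_noise["oral"] + config.abx_coupling * abx_z),
        "stool": sigma_base * np.exp(site_noise["stool"]),
    }

    # standardized log-volatility per site, used for abundance/outcome couplings
    mid = math.sqrt(config.sigma_low * config.sigma_high)
    half_span = max(math.log(config.sigma_high / config.sigma_low) / 2.0, 1e-6)
    z_site = {s: (np.log(sigma_site[s]) - math.log(mid)) / half_span for s in ("oral", "stool")}

    infection_ic = rng.random(n) < _sigmoid(0.0 + config.infection_coupling * z_site["oral"])
    infection_type = np.where(rng.random(n) < 0.5, "MDI", "clinical")
    infection_90d = rng.random(n) < _sigmoid(-0.85 + config.infection_coupling * z_site["stool"])

    age = np.clip(np.round(rng.normal(55.0, 10.0, size=n)), 20, 85)
    days_treatment_abx = np.minimum(
        np.clip(np.round(rng.normal(16.0, 6.0, size=n)), 0, None), days_all_abx
    )
    n_antibiotics = 1 + rng.poisson(4.0, size=n)
    pip_tazo = rng.random(n) < 0.24
    cefepime = rng.random(n) < 0.44
    carbapenem = rng.random(n) < 0.66
    chemo = rng.choice(_CHEMO_LEVELS, size=n, p=_CHEMO_PROBS)
    remission = rng.random(n) < 0.34

    patients: dict[str, PatientInfo] = {}
    for i, pid in enumerate(patient_ids):
        patients[pid] = PatientInfo(
            age=float(age[i]),
            days_all_abx=float(days_all_abx[i]),
            days_treatment_abx=float(days_treatment_abx[i]),
            n_antibiotics=int(n_antibiotics[i]),
            pip_tazo_gt72h=bool(pip_tazo[i]),
            cefepime_gt72h=bool(cefepime[i]),
            carbapenem_gt72h=bool(carbapenem[i]),
            chemo_category=str(chemo[i]),
            infection_during_ic=str(infection_type[i]) if infection_ic[i] else "none",
            infection_90d_post=bool(infection_90d[i]),
            remission=bool(remission[i]),
        )

    # --- per-sample counts --------------------------------------------
    site_prior = {
        "oral": np.array([GENERA[g][0] for g in genus_of]),
        "stool": np.array([GENERA[g][1] for g in genus_of]),
    }
    lo, hi = config.samples_per_patient
    bloom_magnitude = 2.0 * config.pathogen_coupling

    samples: dict[str, SampleInfo] = {}
    columns: list[np.ndarray] = []
    sample_ids: list[str] = []
    for i, pid in enumerate(patient_ids):
        for site in ("oral", "stool"):
            n_t = int(rng.integers(lo, hi + 1))
            z = float(z_site[site][i])
            sigma = float(sigma_site[site][i])

            log_w = np.log(site_prior[site]) + rng.normal(0.0, 0.7, size=config.n_taxa)
            log_w += config.pathogen_coupling * z * is_pathogen
            log_w -= config.commensal_coupling * z * is_commensal
            # within-genus unevenness so OTUs of one genus differ
            log_w += np.log(rng.dirichlet(np.full(config.n_taxa, 1.5)) * config.n_taxa + 1e-9)

            day = -int(rng.integers(0, 3))
            x = log_w.copy()
            for order in range(1, n_t + 1):
                if order > 1:
                    x = x + rng.normal(0.0, sigma, size=config.n_taxa)
                    day += 4 + int(rng.integers(-1, 2))
                x_obs = x.copy()
                if variable[i] and config.bloom_prob > 0 and rng.random() < config.bloom_prob:
                    bloom_genus = pathogen_genera_present[
                        int(rng.integers(len(pathogen_genera_present)))
                    ]
                    x_obs[genus_of == bloom_genus] += bloom_magnitude
                p = np.exp(x_obs - x_obs.max())
                p /= p.sum()
                total = int(rng.poisson(config.depth))
                counts = rng.multinomial(total, p) if total > 0 else np.zeros(config.n_taxa, dtype=np.int64)
                sid = f"{pid}_{'O' if site == 'oral' else 'S'}{order:02d}"
                sample_ids.append(sid)
                columns.append(counts.astype(np.int64))
                samples[sid] = SampleInfo(patient_id=pid, site=site, day=day, order=order)

    table = FeatureTable(
        taxon_ids, sample_ids, np.column_stack(columns), dict(taxonomy)
    )
    meta = CohortMetadata(samples=samples, patients=patients)
    truth = SyntheticTruth(
        config=config,
        patients=pd.DataFrame(
            {
                "patient_id": patient_ids,
                "variable": variable,
                "sigma_base": sigma_base,
                "sigma_oral": sigma_site["oral"],
                "sigma_stool": sigma_site["stool"],
                "days_all_abx": days_all_abx,
                "infection_during_ic": infection_ic,
                "infection_90d_post": infection_90d,
            }
        ),
    )
    return table, tree, meta, truth


# ---------------------------------------------------------------------------
# Pinned fixture
# ---------------------------------------------------------------------------


def fixture_config() -> CohortConfig:
    """The pinned small-cohort configuration used by tests and docs."""
    return CohortConfig(
        n_patients=FIXTURE_N_PATIENTS,
        depth=2000.0,
        seed=FIXTURE_SEED,
    )


def make_fixture(out_dir: str | Path) -> dict[str, Path]:
    """Write the pinned 12-patient cohort in all on-disk formats.

    Returns the mapping of artifact name → path. Regenerating with the
    pinned seed reproduces the files byte-for-byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, tree, meta, truth = generate_cohort(fixture_config())
    paths = {
        "table": out / "table.tsv",
        "tree": out / "tree.nwk",
        "samples": out / "samples.tsv",
        "patients": out / "patients.tsv",
        "truth": out / "truth.tsv",
    }
    write_feature_table(table, paths["table"])
    paths["tree"].write_text(tree.to_newick() + "\n")
    write_metadata(meta, paths["samples"], paths["patients"])
    truth.patients.to_csv(paths["truth"], sep="\t", index=False)
    return paths
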