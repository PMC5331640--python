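from pathlib import Path

import pandas as pd
import pytest

from microvar import diversity, variability
from microvar.formats_io import read_feature_table, read_metadata
from microvar.phylo import parse_newick

FIXTURE_DIR = Path(__file__).parent / "data" / "fixture"

TOY_NEWICK = "((A:1,B:1):1,(C:1,D:1):1):0;"


@pytest.fixture
def toy_tree():
    return parse_newick(TOY_NEWICK)


@pytest.fixture(scope="session")
def fixture_paths():
    return {
        "table": FIXTURE_DIR / "table.tsv",
        "tree": FIXTURE_DIR / "tree.nwk",
        "samples": FIXTURE_DIR / "samples.tsv",
        "patients": FIXTURE_DIR / "patients.tsv",
        "truth": FIXTURE_DIR / "truth.tsv",
    }


@pytest.fixture(scope="session")
def fixture_cohort(fixture_paths):
    table = read_feature_table(fixture_paths["table"])
    tree = parse_newick(fixture_paths["tree"].read_text())
    meta = read_metadata(fixture_paths["samples"], fixture_paths["patients"])
    return table, tree, meta


@pytest.fixture(scope="session")
def fixture_truth(fixture_paths):
    return pd.read_csv(fixture_paths["truth"], sep="\t")


@pytest.fixture(scope="session")
def fixture_analysis(fixture_cohort):
    """Alpha table, distance matrices and profiles of the pinned cohort."""
    table, tree, meta = fixture_cohort
    alpha = diversity.alpha_table(table)
    dms = {
        "uu": diversity.beta_matrix(table, tree, "unweighted"),
        "wu": diversity.beta_matrix(table, tree, "weighted_normalized"),
    }
    profiles = variability.build_profiles(alpha, dms, meta)
    return alpha, dms, profiles
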