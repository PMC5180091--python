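import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from driverforest import label_assembly as la
from driverforest.curation import reference_rules, synthetic_reference_membership
from driverforest.feature_pipeline import prepare_features
from driverforest.pu_forest import ForestConfig, fit_forest, oob_posteriors
from driverforest.synthetic_data import (
    SimConfig,
    generate_source_membership,
    generate_universe,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


SMALL_CONFIG = SimConfig(n_genes=600, n_tsg=20, n_og=20, seed=11)


@pytest.fixture(scope="session")
def small_universe():
    return generate_universe(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_membership(small_universe):
    return generate_source_membership(small_universe.truth, SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_labels(small_universe, small_membership):
    m = small_membership
    rules = [
        la.Rule(name="consensus", type="consensus",
                sources=tuple(m.membership.columns), min_count=3)
    ]
    high = la.assemble_high_confidence(m, rules, {})
    cols = list(m.membership.columns)
    return la.assign_tiers(
        m, high,
        {"medium_sources": cols[: len(cols) // 2],
         "low_sources": cols[len(cols) // 2:]},
    )


@pytest.fixture(scope="session")
def small_matrix(small_universe):
    X, column_map, report = prepare_features(small_universe.features)
    return X, column_map, report


@pytest.fixture(scope="session")
def small_model(small_matrix, small_labels):
    X, _, _ = small_matrix
    training = la.build_training_labels(small_labels)
    return fit_forest(X, training, ForestConfig(n_trees=150, seed=5))


@pytest.fixture(scope="session")
def small_posteriors(small_model, small_matrix):
    X, _, _ = small_matrix
    return oob_posteriors(small_model, X)


@pytest.fixture(scope="session")
def reference_membership():
    return synthetic_reference_membership()


@pytest.fixture(scope="session")
def reference_label_set(reference_membership):
    rules, overrides, tier_cfg = reference_rules()
    high = la.assemble_high_confidence(reference_membership, rules, overrides)
    return la.assign_tiers(reference_membership, high, tier_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def toy_membership(
    genes: list[str],
    sources: dict[str, list[str]],
    roles: dict[tuple[str, str], str] | None = None,
    alteration: dict[str, str] | None = None,
) -> la.SourceMembership:
    """Small hand-built evidence tables for unit tests."""
    idx = pd.Index(genes, name="gene_id")
    member = pd.DataFrame(
        {s: idx.isin(gs) for s, gs in sources.items()}, index=idx
    )
    role_df = pd.DataFrame(None, index=idx, columns=member.columns, dtype=object)
    for (g, s), r in (roles or {}).items():
        role_df.loc[g, s] = r
    meta = pd.DataFrame(
        {
            "category": {s: "db" for s in sources},
            "alteration": {s: (alteration or {}).get(s) for s in sources},
        }
    )
    return la.SourceMembership(membership=member, roles=role_df, sources=meta)
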