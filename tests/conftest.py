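"""Shared fixtures: the default synthetic cohort and derived results.

Expensive pipeline stages run once per session and are reused by the unit,
property and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import ferronet as fn


@pytest.fixture(scope="session")
def cohort():
    """Default matched-site cohort: 1200 genes, 15 patients x 4 sites."""
    spec = fn.CohortSpec(seed=1, modules=fn.default_modules())
    matrix, ann, truth = fn.simulate_cohort(spec)
    return {"spec": spec, "matrix": matrix, "annotation": ann, "truth": truth}


@pytest.fixture(scope="session")
def signature_sets(cohort):
    return fn.signature_collection(cohort["truth"], cohort["spec"])


@pytest.fixture(scope="session")
def network_result(cohort):
    return fn.build_network(cohort["matrix"])


@pytest.fixture(scope="session")
def cohort_result(cohort, signature_sets):
    return fn.run_cohort(cohort["matrix"], cohort["annotation"],
                         [signature_sets])


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixture")
    paths = fn.default_fixture(out, seed=1)
    return paths
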