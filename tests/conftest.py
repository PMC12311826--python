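import datetime as dt

import numpy as np
import pytest

from vaxhes import (ClaimRecord, SimConfig, ZipGraph,
                    build_aggregated_contact_graph, minmax_normalize_weights,
                    simulate_contact_network, simulate_geography,
                    simulate_panel)


@pytest.fixture(scope="session")
def small_study():
    """A 20-ZIP, 6-quarter synthetic study shared by ETL and stats tests."""
    cfg = SimConfig(N=20, TS=6, seed=7)
    geom = simulate_geography(cfg)
    edges = simulate_contact_network(geom, cfg)
    ga = minmax_normalize_weights(
        build_aggregated_contact_graph(edges, sorted(geom.centroids)))
    panel, truth = simulate_panel(geom, ga, cfg)
    return {"cfg": cfg, "geom": geom, "edges": edges, "ga": ga,
            "panel": panel, "truth": truth}


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_claim(person="p1", date=dt.date(2020, 2, 1), zip_="22001", age=3,
               dx="J06.9", **kw):
    return ClaimRecord(person_key=person, incurred_date=date, zip=zip_,
                       age_years=age, dx_code=dx, **kw)


@pytest.fixture
def claim_factory():
    return make_claim


def random_graph(rng, n, density=0.5):
    """Random symmetric hollow weighted graph for oracle comparisons."""
    W = rng.random((n, n)) * (rng.random((n, n)) < density)
    W = np.triu(W, 1)
    W = W + W.T
    return ZipGraph([f"z{i}" for i in range(n)], W)
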