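"""Shared fixtures: hand-built configurations and a small simulated forest."""

import numpy as np
import pandas as pd
import pytest

import treehoi as th


def make_plot(rows, bounds, grouping=None):
    """Build a grouped CensusPlot from (id, species, x, y, dbh0) tuples."""
    df = pd.DataFrame(rows, columns=["id", "species", "x", "y", "dbh0"])
    df["alive1"] = 1
    df["dbh1"] = np.nan
    plot = th.CensusPlot(trees=df, bounds=bounds)
    return th.assign_groups(plot, grouping or th.GroupingScheme())


def random_plot(rng, n=100, side=50.0, groups=("A", "B")):
    df = pd.DataFrame({
        "id": [f"t{i}" for i in range(n)],
        "species": rng.choice(list(groups), n),
        "x": rng.uniform(0, side, n),
        "y": rng.uniform(0, side, n),
        "dbh0": rng.uniform(1, 30, n),
        "alive1": 1, "dbh1": np.nan})
    plot = th.CensusPlot(trees=df, bounds=(0, side, 0, side))
    return th.assign_groups(plot, th.GroupingScheme())


def terms_frame_equal(batch_row, oracle: th.NeighbourhoodTerms, rtol=1e-10):
    """Max relative deviation between a batch row and an oracle result."""
    worst = 0.0
    for g, val in oracle.di.items():
        b = batch_row[f"di_{g}"]
        denom = abs(val) if val else 1.0
        worst = max(worst, abs(b - val) / denom)
    for (j, k), val in oracle.hoi.items():
        b = batch_row[f"hoi_{j}_{k}"]
        denom = abs(val) if val else 1.0
        worst = max(worst, abs(b - val) / denom)
    return worst


def small_scenario(seed=0):
    """A cheap two-group scenario for structural tests (not for power)."""
    sc = th.default_scenario(seed)
    from dataclasses import replace
    return replace(
        sc,
        bounds=(0.0, 70.0, 0.0, 70.0),
        groups=(th.GroupSpec(name="A", abundance=1700, spatial="poisson"),
                th.GroupSpec(name="B", abundance=80, spatial="thomas",
                             n_parents=8, cluster_sd=5.0)),
        kernel=th.KernelParams(u=1.0, v=0.8, R=8.0))


@pytest.fixture(scope="session")
def sim_plot():
    """One simulated two-census forest shared across model-level tests."""
    return th.simulate_census(small_scenario(seed=42))


@pytest.fixture(scope="session")
def sim_scenario():
    return small_scenario(seed=42)


@pytest.fixture(scope="session")
def sim_terms(sim_plot, sim_scenario):
    return th.terms_batch(sim_plot, sim_scenario.kernel, focal_group="A")
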