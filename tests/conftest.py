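import numpy as np
import pandas as pd
import pytest

import chondroflux as cf


@pytest.fixture(scope="session")
def full_net():
    return cf.build_full_network()


@pytest.fixture(scope="session")
def reduced_net():
    """Packaged network reduced to its measurable panel plus the collagen-II
    synthesis column (the standard 48 x 39 analysis matrix)."""
    return cf.default_reduced_network("collagen2")


@pytest.fixture(scope="session")
def protein_flux(reduced_net):
    return cf.generate_true_flux(reduced_net, "protein_like")


@pytest.fixture(scope="session")
def toy_chain():
    """A external -> B internal -> C external, second step reversible."""
    return cf.StoichiometricNetwork(
        [cf.Metabolite("A", role="external"), cf.Metabolite("B"),
         cf.Metabolite("C", role="external")],
        [cf.Reaction("R1", "G", False, {"A": -1, "B": 1}),
         cf.Reaction("R2", "G", True, {"B": -1, "C": 1})],
    )


def make_table(values: dict, group="compressed") -> cf.IntensityTable:
    """values: {(time, metabolite): [replicates]} -> IntensityTable."""
    records = []
    for (t, met), reps in values.items():
        for i, x in enumerate(reps):
            records.append({"sample_id": f"{group}_t{t}_r{i}", "group": group,
                            "time_min": float(t), "metabolite_id": met,
                            "intensity": float(x)})
    return cf.IntensityTable(pd.DataFrame(records))


@pytest.fixture
def simulated(reduced_net, protein_flux):
    cfg = cf.SimulationConfig(network=reduced_net, true_flux=protein_flux,
                              noise_cv=0.05, seed=11)
    table, truth = cf.generate_table(cfg)
    return table, truth, reduced_net
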