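import networkx as nx
import pytest

import netbiomark as nb
from netbiomark.core_io import InteractionNetwork


def graph_from_edges(edges) -> InteractionNetwork:
    g = nx.Graph()
    g.add_edges_from(edges)
    return InteractionNetwork(g)


def path_network(labels: str) -> InteractionNetwork:
    return graph_from_edges(zip(labels[:-1], labels[1:]))


@pytest.fixture(scope="session")
def scenario() -> nb.Scenario:
    """One default planted-biomarker scenario shared across tests."""
    return nb.simulate_scenario(nb.ScenarioConfig(seed=3))


@pytest.fixture(scope="session")
def scenario_activities(scenario):
    """ssGSEA activity matrices (organoid/patient standardized, isogenic
    raw NES) computed once for the shared scenario."""
    coll = scenario.pathways
    return {
        "organoid": nb.standardize(nb.ssgsea_scores(scenario.organoids.expression, coll)),
        "patient": nb.standardize(nb.ssgsea_scores(scenario.patients.expression, coll)),
        "isogenic": nb.ssgsea_scores(scenario.isogenic.expression, coll),
    }


@pytest.fixture(scope="session")
def scenario_ranking(scenario, scenario_activities):
    """Coefficient ranking trained on the proximal pathways of the
    shared scenario."""
    records = nb.select_proximal_pathways(
        scenario.network, scenario.drug_targets["drugX"], scenario.pathways, seed=11
    )
    proximal = [r.pathway for r in records if r.proximal]
    act = scenario_activities["organoid"]
    sub = nb.PathwayActivityMatrix(act.df.loc[proximal], value_scale="zscore")
    return nb.fit_model(sub, scenario.organoids.response, seed=5)
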