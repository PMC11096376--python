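"""The hypothesized causal DAG over traits, geography, and timing."""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "BODY_MASS",
    "FLIGHT_MODE",
    "SEX",
    "BREED_LAT",
    "NB_LAT_ABS",
    "MIG_DIST",
    "DEP_NB",
    "ARR_B",
    "DEP_B",
    "ARR_NB",
    "TIMING_NODES",
    "DagModel",
    "build_default_dag",
]

BODY_MASS = "BodyMass"
FLIGHT_MODE = "FlightMode"
SEX = "Sex"
BREED_LAT = "BreedLat"
NB_LAT_ABS = "NBLatAbs"
MIG_DIST = "MigDist"
DEP_NB = "DepNB"
ARR_B = "ArrB"
DEP_B = "DepB"
ARR_NB = "ArrNB"

#: The four migration-timing nodes, in annual-cycle order.
TIMING_NODES = (DEP_NB, ARR_B, DEP_B, ARR_NB)

#: Random-intercept structure shared by every structural equation.
DEFAULT_RANDOM_EFFECTS = ("phylo", "species", "paper", "year")


@dataclass
class DagModel:
    """A causal DAG with one regression equation per endogenous node.

    ``equations`` maps each endogenous node to its ordered predictor
    list; edges are exactly the (predictor, node) pairs. Exogenous nodes
    have no equation.
    """

    nodes: list[str]
    equations: dict[str, list[str]]
    random_effects: tuple[str, ...] = DEFAULT_RANDOM_EFFECTS

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def edges(self) -> list[tuple[str, str]]:
        return [(p, node) for node, parents in self.equations.items() for p in parents]

    @property
    def endogenous(self) -> list[str]:
        return list(self.equations)

    @property
    def exogenous(self) -> list[str]:
        return [n for n in self.nodes if n not in self.equations]

    def parents(self, node: str) -> list[str]:
        return list(self.equations.get(node, []))

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def topological_order(self) -> list[str]:
        order = list(nx.lexicographical_topological_sort(self.graph(), key=self.nodes.index))
        return order

    def validate(self) -> None:
        known = set(self.nodes)
        for node, parents in self.equations.items():
            if node not in known:
                raise ValueError(f"equation response {node!r} is not a declared node")
            unknown = [p for p in parents if p not in known]
            if unknown:
                raise ValueError(f"equation for {node!r} uses unknown node(s) {unknown}")
            if node in parents:
                raise ValueError(f"{node!r} cannot predict itself")
            if len(set(parents)) != len(parents):
                raise ValueError(f"duplicate predictors in equation for {node!r}")
        g = self.graph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"graph contains a cycle: {cycle}")

    # -- edits (for config-driven DAG modifications) -----------------------
    def add_edge(self, src: str, dst: str) -> None:
        if dst not in self.equations:
            self.equations[dst] = []
        if src in self.equations[dst]:
            return
        self.equations[dst].append(src)
        self.validate()

    def remove_edge(self, src: str, dst: str) -> None:
        try:
            self.equations[dst].remove(src)
        except (KeyError, ValueError):
            raise ValueError(f"edge {src!r} -> {dst!r} not in graph") from None


def build_default_dag(include_sex: bool = False) -> DagModel:
    """The default nine-node model (ten with sex).

    Body mass drives the latitudes; mass, latitudes, and flight mode
    drive migration distance; every timing equation takes mass, the
    latitudes, distance, and flight mode, plus all earlier timings of the
    same annual cycle (carry-over). There are no edges between annual
    cycles. With ``include_sex`` a binary sex covariate is added to the
    four timing equations.
    """
    nodes = [BODY_MASS, FLIGHT_MODE, BREED_LAT, NB_LAT_ABS, MIG_DIST, *TIMING_NODES]
    base = [BODY_MASS, BREED_LAT, NB_LAT_ABS, MIG_DIST, FLIGHT_MODE]
    equations: dict[str, list[str]] = {
        BREED_LAT: [BODY_MASS],
        NB_LAT_ABS: [BODY_MASS],
        MIG_DIST: [BODY_MASS, BREED_LAT, NB_LAT_ABS, FLIGHT_MODE],
        DEP_NB: list(base),
        ARR_B: base + [DEP_NB],
        DEP_B: base + [DEP_NB, ARR_B],
        ARR_NB: base + [DEP_NB, ARR_B, DEP_B],
    }
    if include_sex:
        nodes.insert(2, SEX)
        for timing in TIMING_NODES:
            equations[timing] = equations[timing] + [SEX]
    return DagModel(nodes=nodes, equations=equations)
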