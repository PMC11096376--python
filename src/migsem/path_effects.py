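"""Path tracing over the fitted DAG and d-separation testing.

Direct effects are the standardized coefficients of single edges;
indirect effects sum the products of edge weights over every directed
path of length two or more; totals add the two. Edges whose 95% interval
covers zero are gated to weight zero before tracing, which is the rule
that reproduces the published indirect/total arithmetic from the printed
direct coefficients.

Causal-structure evaluation uses the standard d-separation basis set:
every non-adjacent ordered pair (excluding pairs of exogenous variables)
is tested conditional on the union of both variables' parents, and the
claim-level p-values are combined with Fisher's C against a chi-square
with 2k degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

from .sem_engine.dag import (
    ARR_B,
    ARR_NB,
    BODY_MASS,
    BREED_LAT,
    DEP_B,
    DEP_NB,
    MIG_DIST,
    NB_LAT_ABS,
    DagModel,
)
from .sem_engine.fit import EquationFit

__all__ = [
    "PathContribution",
    "EffectEntry",
    "EffectTable",
    "IndependenceClaim",
    "DSepResult",
    "decompose_effects",
    "fishers_c",
    "basis_set",
    "dsep_tests",
    "round_half_away",
    "format_effect",
    "render_effect_table",
]


@dataclass(frozen=True)
class PathContribution:
    nodes: tuple[str, ...]
    product: float


@dataclass
class EffectEntry:
    source: str
    target: str
    direct: float | None  # None when the edge is absent or gated out
    indirect: float
    paths: list[PathContribution] = field(default_factory=list)

    @property
    def total(self) -> float:
        return (self.direct or 0.0) + self.indirect

    @property
    def has_indirect_path(self) -> bool:
        return bool(self.paths)


@dataclass
class EffectTable:
    entries: dict[tuple[str, str], EffectEntry]

    def __getitem__(self, key: tuple[str, str]) -> EffectEntry:
        return self.entries[key]

    def get(self, source: str, target: str) -> EffectEntry | None:
        return self.entries.get((source, target))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "source": e.source,
                "target": e.target,
                "direct": e.direct,
                "indirect": e.indirect,
                "total": e.total,
                "n_indirect_paths": len(e.paths),
            }
            for e in self.entries.values()
        ]
        return pd.DataFrame(rows)


def decompose_effects(
    dag: DagModel,
    fits: Mapping[str, EquationFit],
    gate: str = "significant",
    force: bool = False,
) -> EffectTable:
    """Direct/indirect/total standardized effects for every node pair.

    *gate* is ``"significant"`` (edges with intervals covering zero get
    weight 0, the default) or ``"all"`` (use every posterior-mean/REML
    estimate). Non-converged fits are refused unless ``force=True``.
    """
    if gate not in {"significant", "all"}:
        raise ValueError(f"unknown gate {gate!r}")
    dag.validate()
    missing = [n for n in dag.endogenous if n not in fits]
    if missing:
        raise ValueError(f"missing fits for endogenous node(s): {missing}")
    bad = [n for n in dag.endogenous if not fits[n].converged]
    if bad and not force:
        raise ValueError(
            f"fit(s) did not converge: {bad}; pass force=True to decompose anyway"
        )

    weights: dict[tuple[str, str], float] = {}
    for node in dag.endogenous:
        fit = fits[node]
        for parent in dag.parents(node):
            if parent not in fit.coefficients:
                raise ValueError(f"fit for {node!r} lacks coefficient for {parent!r}")
            c = fit.coefficients[parent]
            keep = gate == "all" or c.significant
            weights[(parent, node)] = c.estimate if keep else 0.0

    g = nx.DiGraph()
    g.add_nodes_from(dag.nodes)
    for (src, dst), w in weights.items():
        if w != 0.0:
            g.add_edge(src, dst, weight=w)

    entries: dict[tuple[str, str], EffectEntry] = {}
    for src in dag.nodes:
        for dst in dag.nodes:
            if src == dst:
                continue
            direct = None
            if (src, dst) in weights and weights[(src, dst)] != 0.0:
                direct = weights[(src, dst)]
            paths: list[PathContribution] = []
            if g.has_node(src) and g.has_node(dst):
                for path in nx.all_simple_paths(g, src, dst):
                    if len(path) < 3:
                        continue
                    prod = 1.0
                    for a, b in zip(path, path[1:]):
                        prod *= g[a][b]["weight"]
                    paths.append(PathContribution(nodes=tuple(path), product=prod))
            indirect = float(sum(p.product for p in paths))
            entries[(src, dst)] = EffectEntry(
                source=src, target=dst, direct=direct, indirect=indirect, paths=paths
            )
    return EffectTable(entries=entries)


# ---------------------------------------------------------------------------
# d-separation


@dataclass(frozen=True)
class IndependenceClaim:
    """x independent of y given the conditioning set."""

    x: str
    y: str
    conditioning: tuple[str, ...]


@dataclass
class DSepResult:
    claims: list[IndependenceClaim]
    p_values: list[float]
    c_statistic: float
    df: int
    p_global: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "x": c.x,
                "y": c.y,
                "conditioning": "+".join(c.conditioning),
                "p_value": p,
            }
            for c, p in zip(self.claims, self.p_values)
        ]
        return pd.DataFrame(rows)


def basis_set(dag: DagModel) -> list[IndependenceClaim]:
    """The d-separation basis set of the DAG.

    One claim per non-adjacent ordered pair (earlier, later) in
    topological order, conditioned on the parents of both variables.
    Pairs of exogenous variables are excluded (no causal claim is made
    about their association).
    """
    dag.validate()
    order = dag.topological_order()
    pos = {n: i for i, n in enumerate(order)}
    adjacent = {frozenset(e) for e in dag.edges}
    exogenous = set(dag.exogenous)
    claims: list[IndependenceClaim] = []
    for j, later in enumerate(order):
        for earlier in order[:j]:
            if frozenset((earlier, later)) in adjacent:
                continue
            if earlier in exogenous and later in exogenous:
                continue
            cond = sorted(
                (set(dag.parents(later)) | set(dag.parents(earlier))) - {earlier, later},
                key=pos.__getitem__,
            )
            claims.append(IndependenceClaim(x=earlier, y=later, conditioning=tuple(cond)))
    return claims


def fishers_c(p_values: Sequence[float]) -> tuple[float, int, float]:
    """Fisher's C over claim-level p-values: ``(C, df, global p)``.

    ``C = -2 * sum(log p)`` against chi-square with ``2k`` degrees of
    freedom. A p-value of exactly zero is a decisive violation and is
    rejected rather than propagated as infinity.
    """
    if len(p_values) < 1:
        raise ValueError("at least one claim p-value is required")
    for p in p_values:
        if p == 0:
            raise ValueError("claim p-value of 0: decisive violation, C undefined")
        if not (0.0 < p <= 1.0):
            raise ValueError(f"p-value {p} outside (0, 1]")
    c = -2.0 * float(sum(math.log(p) for p in p_values))
    df = 2 * len(p_values)
    return c, df, float(stats.chi2.sf(c, df))


def dsep_tests(
    dag: DagModel,
    derived: pd.DataFrame,
    phylo,
    settings=None,
) -> DSepResult:
    """Test every basis-set claim by mixed-model regression.

    Each claim (x, y | Z) is tested by regressing y's variable on Z plus
    x with the full random-effect structure; the claim p-value is the
    two-sided Wald p of x's coefficient (REML backend).
    """
    from .sem_engine.design import assemble_matrix
    from .sem_engine.fit import FitSettings, fit_equation

    settings = settings or FitSettings(backend="reml")
    claims = basis_set(dag)
    if not claims:
        raise ValueError("saturated DAG: empty basis set, no test possible")
    p_values: list[float] = []
    for claim in claims:
        predictors = list(claim.conditioning) + [claim.x]
        m = assemble_matrix(derived, claim.y, predictors=predictors)
        fit = fit_equation(m, phylo, settings)
        coef = fit.coefficients[claim.x]
        if coef.p_value is None:
            raise ValueError("d-separation testing requires the REML backend")
        p_values.append(max(coef.p_value, 1e-300))
    c, df, p_global = fishers_c(p_values)
    return DSepResult(claims=claims, p_values=p_values, c_statistic=c, df=df, p_global=p_global)


# ---------------------------------------------------------------------------
# rendering

#: Table layout: four timing rows by seven explanatory-variable columns.
TABLE_ROWS = (DEP_NB, ARR_B, DEP_B, ARR_NB)
TABLE_COLUMNS = (BODY_MASS, BREED_LAT, NB_LAT_ABS, MIG_DIST, DEP_NB, ARR_B, DEP_B)

_ROW_LABELS = {
    DEP_NB: "Departure date from non-breeding site",
    ARR_B: "Arrival date at breeding site",
    DEP_B: "Departure date from breeding site",
    ARR_NB: "Arrival date at non-breeding site",
}
_COL_LABELS = {
    BODY_MASS: "Body mass",
    BREED_LAT: "Breeding latitude",
    NB_LAT_ABS: "Non-breeding latitude",
    MIG_DIST: "Migration distance",
    DEP_NB: "Departure date from non-breeding site",
    ARR_B: "Arrival date at breeding site",
    DEP_B: "Departure date from breeding site",
}


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round with ties going away from zero (not banker's rounding).

    The value is first snapped to 10 decimal digits so that binary float
    artifacts in path products (0.35 * 0.10 = 0.0349999...96) do not flip
    a tie the wrong way.
    """
    snapped = Decimal(repr(float(x))).quantize(Decimal("1e-10"), rounding=ROUND_HALF_UP)
    quant = Decimal(1).scaleb(-decimals)
    return float(snapped.quantize(quant, rounding=ROUND_HALF_UP))


def format_effect(x: float, decimals: int = 2) -> str:
    """Format preserving a signed zero, e.g. -0.003 -> ``-0.00``."""
    r = round_half_away(x, decimals)
    text = f"{abs(r):.{decimals}f}"
    return ("-" if (r < 0 or (r == 0 and x < 0)) else "") + text


def render_effect_table(table: EffectTable, decimals: int = 2) -> pd.DataFrame:
    """Render the decomposition in the published layout.

    Rows are the four timings x {Direct, Indirect, Total}; columns the
    seven explanatory variables. A dash marks an absent effect: a gated
    or missing edge (Direct), no surviving multi-edge path (Indirect), or
    both (Total).
    """
    rows = []
    for target in TABLE_ROWS:
        for kind in ("Direct", "Indirect", "Total"):
            row: dict[str, str] = {
                "Timing": _ROW_LABELS[target],
                "Effect": kind,
            }
            for source in TABLE_COLUMNS:
                if source == target:
                    row[_COL_LABELS[source]] = ""
                    continue
                entry = table.get(source, target)
                if entry is None:
                    row[_COL_LABELS[source]] = "-"
                    continue
                if kind == "Direct":
                    cell = "-" if entry.direct is None else format_effect(entry.direct, decimals)
                elif kind == "Indirect":
                    cell = (
                        format_effect(entry.indirect, decimals)
                        if entry.has_indirect_path
                        else "-"
                    )
                else:
                    cell = (
                        format_effect(entry.total, decimals)
                        if (entry.direct is not None or entry.has_indirect_path)
                        else "-"
                    )
                row[_COL_LABELS[source]] = cell
            rows.append(row)
    return pd.DataFrame(rows)
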