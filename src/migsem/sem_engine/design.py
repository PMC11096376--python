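"""Model-matrix assembly: variable mapping, coding, and z-scoring."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dag import (
    ARR_B,
    ARR_NB,
    BODY_MASS,
    BREED_LAT,
    DEP_B,
    DEP_NB,
    FLIGHT_MODE,
    MIG_DIST,
    NB_LAT_ABS,
    SEX,
    DagModel,
)

__all__ = ["NODE_COLUMNS", "ModelMatrix", "assemble_matrix", "node_values", "zscore"]

logger = logging.getLogger(__name__)

#: Mapping from DAG node to the derived-table column it is read from.
#: Body mass enters on the natural-log scale; standardized coefficients
#: are invariant to any further positive rescaling.
NODE_COLUMNS = {
    BODY_MASS: "body_mass",
    FLIGHT_MODE: "flight_mode",
    SEX: "sex",
    BREED_LAT: "breed_lat",
    NB_LAT_ABS: "nonbreed_lat_abs",
    MIG_DIST: "spring_distance",
    DEP_NB: "dep_nb_doy",
    ARR_B: "arr_b_doy",
    DEP_B: "dep_b_doy",
    ARR_NB: "arr_nb_doy",
}

#: Duration responses available to the single-equation (duration) models.
DURATION_COLUMNS = {
    "SpringDuration": "spring_duration",
    "BreedingDuration": "breeding_duration",
    "AutumnDuration": "autumn_duration",
    "NonbreedingDuration": "nonbreeding_duration",
}


def zscore(x: np.ndarray, name: str = "column") -> np.ndarray:
    """Center to mean 0 and scale to SD 1 (population SD)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"zero-variance predictor: {name}")
    return (x - x.mean()) / sd


def node_values(derived: pd.DataFrame, node: str) -> np.ndarray:
    """Raw (pre-scaling) values of a DAG node from the derived table.

    Flight mode is coded flapping=0 / soaring=1; sex female=0 / male=1
    with unknown mapped to NaN (removed by listwise deletion); body mass
    is log-transformed. The non-breeding latitude column is already the
    absolute value.
    """
    if node in DURATION_COLUMNS:
        return np.asarray(derived[DURATION_COLUMNS[node]], dtype=float)
    col = NODE_COLUMNS[node]
    if node == FLIGHT_MODE:
        return np.asarray(derived[col].map({"flapping": 0.0, "soaring": 1.0}), dtype=float)
    if node == SEX:
        return np.asarray(
            derived[col].map({"female": 0.0, "male": 1.0, "unknown": np.nan}), dtype=float
        )
    if node == BODY_MASS:
        return np.log(np.asarray(derived[col], dtype=float))
    return np.asarray(derived[col], dtype=float)


@dataclass
class ModelMatrix:
    """z-scored response and predictors plus grouping indices."""

    response: str
    predictors: list[str]
    y: np.ndarray
    X: np.ndarray
    species_levels: list[str]
    species_idx: np.ndarray
    paper_levels: list[str]
    paper_idx: np.ndarray
    year_levels: list[int]
    year_idx: np.ndarray
    n_dropped: int = 0
    y_raw_sd: float = 1.0

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_species(self) -> int:
        return len(self.species_levels)


def assemble_matrix(
    derived: pd.DataFrame,
    response: str,
    dag: DagModel | None = None,
    predictors: list[str] | None = None,
    standardize_response: bool = True,
) -> ModelMatrix:
    """Build the fitting matrix for one structural equation.

    Predictors default to the DAG equation of *response*. Rows with any
    missing value in the response or a predictor are removed (listwise
    deletion, logged). All columns are z-scored; binary codings (flight
    mode, sex) are z-scored like any other explanatory variable so every
    coefficient is on the same standardized scale.
    """
    if predictors is None:
        if dag is None:
            raise ValueError("either a DAG or an explicit predictor list is required")
        predictors = dag.parents(response)
        if not predictors:
            raise ValueError(f"{response!r} has no equation in the DAG")

    raw = {response: node_values(derived, response)}
    for p in predictors:
        raw[p] = node_values(derived, p)
    mask = np.ones(len(derived), dtype=bool)
    for v in raw.values():
        mask &= np.isfinite(v)
    n_dropped = int((~mask).sum())
    if n_dropped:
        logger.info("assemble_matrix(%s): listwise deletion dropped %d rows", response, n_dropped)
    if mask.sum() < len(predictors) + 2:
        raise ValueError(f"too few complete rows for equation {response!r}")

    sub = derived.loc[mask]
    y_raw = raw[response][mask]
    y_sd = float(np.std(y_raw))
    if standardize_response:
        y = zscore(y_raw, response)
    else:
        y = y_raw.astype(float)
    X = np.column_stack([zscore(raw[p][mask], p) for p in predictors])

    species = sub["species"].astype(str).to_numpy()
    species_levels = sorted(set(species))
    sp_pos = {s: i for i, s in enumerate(species_levels)}
    species_idx = np.array([sp_pos[s] for s in species], dtype=int)

    # paper nested in species: the grouping factor is the species:paper pair
    paper = (sub["species"].astype(str) + ":" + sub["paper_id"].astype(str)).to_numpy()
    paper_levels = sorted(set(paper))
    pa_pos = {s: i for i, s in enumerate(paper_levels)}
    paper_idx = np.array([pa_pos[s] for s in paper], dtype=int)

    years = sub["year"].astype(int).to_numpy()
    year_levels = sorted(set(years))
    yr_pos = {v: i for i, v in enumerate(year_levels)}
    year_idx = np.array([yr_pos[v] for v in years], dtype=int)

    return ModelMatrix(
        response=response,
        predictors=list(predictors),
        y=y,
        X=X,
        species_levels=species_levels,
        species_idx=species_idx,
        paper_levels=paper_levels,
        paper_idx=paper_idx,
        year_levels=year_levels,
        year_idx=year_idx,
        n_dropped=n_dropped,
        y_raw_sd=y_sd,
    )
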