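"""Synthetic annual-cycle bundles with known ground truth.

The generator draws a Yule tree, species traits with phylogenetic
signal, and record-level variables from the default causal DAG: each
endogenous node is a linear combination of its standardized parents plus
phylogenetic, species, paper-within-species, year, and residual
components. Component sizes are chosen so every node has implied
variance exactly 1, which makes the generating coefficients directly
comparable to fitted standardized coefficients.

Standardized values are then mapped to natural units (dates around
calendar anchors, kilometres, degrees) and coordinates are back-computed
so that the great-circle distance between the written non-breeding and
breeding coordinates reproduces the generated migration distance. The
defaults mirror the structure of the study data this emulates: 186
species, roughly 1708 records with a heavy-tailed per-species count
distribution, ~37% unknown sex, and mean event dates in late March,
early May, late August, and mid October.
"""

from __future__ import annotations

import datetime as dt
import json
import math
import os
from dataclasses import dataclass, field, replace
from typing import Any

import dendropy
import numpy as np
from scipy import linalg

from .cycle_data import (
    SpeciesTraits,
    TrackRecord,
    write_tracking_table,
    write_trait_table,
)
from .phylo_cov import vcv_from_tree
from .sem_engine.dag import (
    ARR_B,
    ARR_NB,
    BODY_MASS,
    BREED_LAT,
    DEP_B,
    DEP_NB,
    FLIGHT_MODE,
    MIG_DIST,
    NB_LAT_ABS,
    TIMING_NODES,
    DagModel,
    build_default_dag,
)

__all__ = [
    "DEFAULT_PATH_COEFFICIENTS",
    "SimulationTruth",
    "SyntheticBundle",
    "simulate_tree",
    "simulate_dataset",
    "simulate_bundle",
    "write_bundle",
]

_KM_PER_DEG = math.pi * 6371.0088 / 180.0

#: Default generating coefficients; magnitudes follow the published
#: effect sizes so synthetic runs exercise realistic signal-to-noise.
#: These are generator defaults, not estimates of the real data.
DEFAULT_PATH_COEFFICIENTS: dict[tuple[str, str], float] = {
    (BODY_MASS, BREED_LAT): 0.10,
    (BODY_MASS, NB_LAT_ABS): 0.45,
    (BODY_MASS, MIG_DIST): -0.30,
    (BREED_LAT, MIG_DIST): 0.40,
    (NB_LAT_ABS, MIG_DIST): -0.45,
    (BODY_MASS, DEP_NB): -0.33,
    (BREED_LAT, DEP_NB): 0.29,
    (BREED_LAT, ARR_B): 0.21,
    (MIG_DIST, ARR_B): 0.24,
    (DEP_NB, ARR_B): 0.35,
    (BODY_MASS, DEP_B): 0.42,
    (ARR_B, DEP_B): 0.10,
    (BODY_MASS, ARR_NB): 0.23,
    (MIG_DIST, ARR_NB): 0.14,
    (ARR_B, ARR_NB): 0.17,
    (DEP_B, ARR_NB): 0.38,
}


@dataclass
class SimulationTruth:
    """Every generating value of a synthetic bundle."""

    n_species: int = 186
    mean_records_per_species: float = 1708 / 186
    records_dispersion: float = 1.0  # NB shape for the extra-records count
    papers_per_species_mean: float = 1.65
    year_range: tuple[int, int] = (2008, 2021)
    path_coefficients: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_PATH_COEFFICIENTS)
    )
    re_proportions: dict[str, float] = field(
        default_factory=lambda: {"phylo": 0.05, "species": 0.15, "paper": 0.08, "year": 0.02}
    )
    unknown_sex_fraction: float = 0.37
    p_soaring: float = 0.30
    mass_phylo_signal: float = 0.60
    log_mass_mean: float = 5.6
    log_mass_sd: float = 1.1
    breed_lat_anchor: float = 48.0
    breed_lat_sd: float = 5.0
    nb_lat_abs_anchor: float = 18.0
    nb_lat_abs_sd: float = 6.0
    southern_fraction: float = 0.18
    dist_anchor_km: float = 8000.0
    dist_sd_km: float = 800.0
    date_anchors: dict[str, float] = field(
        default_factory=lambda: {DEP_NB: 86.0, ARR_B: 122.0, DEP_B: 238.0, ARR_NB: 289.0}
    )
    date_sds: dict[str, float] = field(
        default_factory=lambda: {DEP_NB: 12.0, ARR_B: 13.0, DEP_B: 18.0, ARR_NB: 18.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if any(v < 0 for v in self.re_proportions.values()):
            raise ValueError("random-effect variance proportions must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        d = {
            k: v
            for k, v in vars(self).items()
            if k not in ("path_coefficients", "year_range")
        }
        d["year_range"] = list(self.year_range)
        d["path_coefficients"] = {
            f"{src}->{dst}": w for (src, dst), w in self.path_coefficients.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationTruth":
        d = dict(d)
        coeffs = {}
        for key, w in d.pop("path_coefficients", {}).items():
            src, dst = key.split("->")
            coeffs[(src, dst)] = float(w)
        year_range = tuple(d.pop("year_range", (2008, 2021)))
        base = cls(year_range=year_range, **d)
        if coeffs:
            base = replace(base, path_coefficients=coeffs)
        return base


@dataclass
class SyntheticBundle:
    records: list[TrackRecord]
    traits: dict[str, SpeciesTraits]
    newick: str
    truth: dict[str, Any]
    node_values: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def simulate_tree(
    n_species: int, seed: int | None = None, rng: np.random.Generator | None = None
) -> dendropy.Tree:
    """Yule (pure-birth) tree scaled to unit root-to-tip depth."""
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    if rng is None:
        rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    birth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    # root split at time 0
    tips = []
    for _ in range(2):
        child = dendropy.Node()
        tree.seed_node.add_child(child)
        birth[child] = 0.0
        tips.append(child)
    t = 0.0
    while len(tips) < n_species:
        t += rng.exponential(1.0 / len(tips))
        node = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            birth[child] = t
            tips.append(child)
    t_end = t + rng.exponential(1.0 / len(tips))
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            node.edge.length = 0.0
            continue
        end = birth[node.child_nodes()[0]] if node.child_nodes() else t_end
        node.edge.length = (end - birth[node]) / t_end
    width = len(str(n_species))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = taxa.new_taxon(label=f"Species_{i + 1:0{width}d}")
    return tree


def _phylo_trait(
    L: np.ndarray, signal: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance species trait: Brownian + independent mixture."""
    n = L.shape[0]
    return math.sqrt(signal) * (L @ rng.standard_normal(n)) + math.sqrt(
        1.0 - signal
    ) * rng.standard_normal(n)


def _implied_fixed_variance(
    parents: list[str], coeffs: dict[str, float], S: dict[tuple[str, str], float]
) -> float:
    v = 0.0
    for a in parents:
        for b in parents:
            v += coeffs[a] * coeffs[b] * S[(a, b)]
    return v


def _wrap_lon(lon: np.ndarray) -> np.ndarray:
    return (lon + 180.0) % 360.0 - 180.0


def simulate_dataset(
    truth: SimulationTruth, tree: dendropy.Tree | None = None
) -> SyntheticBundle:
    """Generate a full bundle (records, traits, tree, truth) from *truth*."""
    rng = np.random.default_rng(truth.seed)
    if tree is None:
        tree = simulate_tree(truth.n_species, rng=rng)
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(species) != truth.n_species:
        raise ValueError(
            f"tree has {len(species)} tips but truth.n_species={truth.n_species}"
        )
    S_sp = len(species)
    cov = vcv_from_tree(tree)
    order_idx = cov.index_of(species)
    C_corr = cov.C_corr[np.ix_(order_idx, order_idx)]
    L = linalg.cholesky(C_corr + 1e-10 * np.eye(S_sp), lower=True)

    # ---- species-level traits -------------------------------------------
    z_mass = _phylo_trait(L, truth.mass_phylo_signal, rng)
    mass = np.exp(truth.log_mass_mean + truth.log_mass_sd * z_mass)
    soaring = rng.random(S_sp) < truth.p_soaring
    p = truth.p_soaring
    z_fm = (soaring.astype(float) - p) / math.sqrt(p * (1.0 - p))

    traits: dict[str, SpeciesTraits] = {}
    for i, sp in enumerate(species):
        traits[sp] = SpeciesTraits(
            species=sp,
            order=f"Order{i // 18 + 1:02d}",
            family=f"Family{i // 6 + 1:02d}",
            min_mass_female=round(float(mass[i] * 0.9), 2),
            min_mass_male=round(float(mass[i] * 1.1), 2),
        )

    # ---- design: records, papers, years ---------------------------------
    extra_mean = max(truth.mean_records_per_species - 1.0, 1e-6)
    k = truth.records_dispersion
    n_per_species = 1 + rng.negative_binomial(k, k / (k + extra_mean), size=S_sp)
    n_rec = int(n_per_species.sum())
    sp_idx = np.repeat(np.arange(S_sp), n_per_species)

    papers_per_species = 1 + rng.poisson(max(truth.papers_per_species_mean - 1.0, 0.0), S_sp)
    paper_labels: list[str] = []
    paper_offset = np.zeros(S_sp, dtype=int)
    for i, npap in enumerate(papers_per_species):
        paper_offset[i] = len(paper_labels)
        paper_labels.extend(f"paper_{i + 1:03d}_{j + 1}" for j in range(npap))
    paper_idx = np.array(
        [
            paper_offset[s] + rng.integers(papers_per_species[s])
            for s in sp_idx
        ],
        dtype=int,
    )
    y0, y1 = truth.year_range
    years = rng.integers(y0, y1 + 1, size=n_rec)
    year_levels = np.arange(y0, y1 + 1)
    year_idx = years - y0

    sex = np.where(
        rng.random(n_rec) < truth.unknown_sex_fraction,
        "unknown",
        np.where(rng.random(n_rec) < 0.5, "female", "male"),
    )

    # ---- DAG recursion on the standardized scale ------------------------
    # Exogenous nodes are standardized *empirically at record level*: the
    # analysis pipeline z-scores what it reads, and correlated
    # phylogenetic draws can have a sample SD far from 1, which would
    # otherwise rescale every downstream generating coefficient.
    dag = build_default_dag()
    bm_rec = z_mass[sp_idx]
    fm_rec = soaring[sp_idx].astype(float)
    if fm_rec.std() == 0:  # tiny simulations can draw a single flight mode
        fm_rec = z_fm[sp_idx]
    else:
        fm_rec = (fm_rec - fm_rec.mean()) / fm_rec.std()
    values: dict[str, np.ndarray] = {
        BODY_MASS: (bm_rec - bm_rec.mean()) / bm_rec.std(),
        FLIGHT_MODE: fm_rec,
    }
    S: dict[tuple[str, str], float] = {
        (BODY_MASS, BODY_MASS): 1.0,
        (FLIGHT_MODE, FLIGHT_MODE): 1.0,
        (BODY_MASS, FLIGHT_MODE): 0.0,
        (FLIGHT_MODE, BODY_MASS): 0.0,
    }
    equations_truth: dict[str, Any] = {}
    natural: dict[str, np.ndarray] = {}
    doy: dict[str, np.ndarray] = {}
    n_clipped_dist = 0

    def _standardize(x: np.ndarray) -> np.ndarray:
        return (x - x.mean()) / x.std()

    for node in [n for n in dag.topological_order() if n in dag.equations]:
        parents = dag.parents(node)
        coeffs = {p_: truth.path_coefficients.get((p_, node), 0.0) for p_ in parents}
        var_fixed = _implied_fixed_variance(parents, coeffs, S)
        re = dict(truth.re_proportions)
        var_resid = 1.0 - var_fixed - sum(re.values())
        if var_resid < 0.02:
            raise ValueError(
                f"equation {node}: implied residual variance {var_resid:.3f} too small; "
                "reduce path coefficients or random-effect proportions"
            )
        u_phylo = math.sqrt(re["phylo"]) * (L @ rng.standard_normal(S_sp))
        u_species = math.sqrt(re["species"]) * rng.standard_normal(S_sp)
        u_paper = math.sqrt(re["paper"]) * rng.standard_normal(len(paper_labels))
        u_year = math.sqrt(re["year"]) * rng.standard_normal(len(year_levels))
        eps = math.sqrt(var_resid) * rng.standard_normal(n_rec)
        fixed = np.zeros(n_rec)
        for p_ in parents:
            fixed += coeffs[p_] * values[p_]
        latent = (
            fixed
            + u_phylo[sp_idx]
            + u_species[sp_idx]
            + u_paper[paper_idx]
            + u_year[year_idx]
            + eps
        )

        # Map to natural units immediately and feed the *realized*
        # standardized value to downstream equations, so the written data
        # carry exactly the coefficients recorded in the truth file
        # (rounding/feasibility clipping would otherwise act as
        # errors-in-variables on every descendant equation).
        if node == BREED_LAT:
            natural[node] = np.clip(
                truth.breed_lat_anchor + truth.breed_lat_sd * latent, 0.5, 84.0
            )
            values[node] = _standardize(natural[node])
            scale = truth.breed_lat_sd / float(natural[node].std())
        elif node == NB_LAT_ABS:
            natural[node] = np.clip(
                truth.nb_lat_abs_anchor + truth.nb_lat_abs_sd * latent, 0.2, 84.0
            )
            values[node] = _standardize(natural[node])
            scale = truth.nb_lat_abs_sd / float(natural[node].std())
        elif node == MIG_DIST:
            breed_lat_nat = natural[BREED_LAT]
            nb_abs_nat = natural[NB_LAT_ABS]
            d_target = truth.dist_anchor_km + truth.dist_sd_km * latent
            southern = rng.random(n_rec) < truth.southern_fraction
            # keep a southern non-breeding site only when the target
            # distance can actually span the equator crossing
            southern &= d_target > _KM_PER_DEG * (breed_lat_nat + nb_abs_nat) + 100.0
            nb_lat = np.where(southern, -nb_abs_nat, nb_abs_nat)
            min_d = _KM_PER_DEG * np.abs(breed_lat_nat - nb_lat) + 1.0
            max_d = _KM_PER_DEG * (180.0 - np.abs(breed_lat_nat + nb_lat)) - 1.0
            dist_km = np.clip(d_target, min_d, max_d)
            n_clipped_dist = int(np.sum(dist_km != d_target))
            natural["nb_lat"] = nb_lat
            natural[node] = dist_km
            values[node] = _standardize(dist_km)
            scale = truth.dist_sd_km / float(dist_km.std())
        elif node in TIMING_NODES:
            day = np.round(
                truth.date_anchors[node] + truth.date_sds[node] * latent
            ).astype(int)
            if node == DEP_NB:
                day = np.maximum(day, 2)
            elif node == ARR_B:
                day = np.maximum(day, doy[DEP_NB] + 2)
            elif node == DEP_B:
                day = np.maximum(day, doy[ARR_B] + 2)
            else:  # ARR_NB: keep the non-breeding duration positive
                day = np.clip(day, doy[DEP_B] + 2, doy[DEP_NB] + 363)
            doy[node] = day
            values[node] = _standardize(day.astype(float))
            scale = truth.date_sds[node] / float(day.std())
        else:
            values[node] = latent
            scale = 1.0

        # The truth file records the *realized* coefficients of the data
        # as written: re-standardizing the mapped response multiplies
        # every coefficient by nominal_sd / realized_sd (and the variance
        # components by its square). Without this, the ~3% sample-SD
        # fluctuation of the correlated group effects would show up as
        # unexplained error on every large coefficient.
        realized = {p_: c_ * scale for p_, c_ in coeffs.items()}

        # propagate implied covariances (all nodes have implied variance 1)
        for other in list(values):
            if other == node:
                continue
            c = sum(realized[p_] * S[(p_, other)] for p_ in parents)
            S[(node, other)] = S[(other, node)] = c
        S[(node, node)] = 1.0
        equations_truth[node] = {
            "coefficients": realized,
            "variance_components": {
                **{k: v * scale**2 for k, v in re.items()},
                "resid": var_resid * scale**2,
            },
        }

    breed_lat = natural[BREED_LAT]
    nb_lat = natural["nb_lat"]
    dist_km = natural[MIG_DIST]

    phi1 = np.radians(breed_lat)
    phi2 = np.radians(nb_lat)
    cos_dlam = (
        np.cos(dist_km / 6371.0088) - np.sin(phi1) * np.sin(phi2)
    ) / (np.cos(phi1) * np.cos(phi2))
    dlam = np.degrees(np.arccos(np.clip(cos_dlam, -1.0, 1.0)))
    breed_lon = rng.uniform(-180.0, 180.0, size=n_rec)
    direction = np.where(rng.random(n_rec) < 0.5, 1.0, -1.0)
    nb_lon = _wrap_lon(breed_lon + direction * dlam)

    # ---- assemble records ------------------------------------------------
    records: list[TrackRecord] = []
    level = np.where(rng.random(n_rec) < 0.10, "population", "individual")
    capture = rng.choice(
        ["breeding", "nonbreeding", "stopover"], size=n_rec, p=[0.5, 0.35, 0.15]
    )
    width = len(str(n_rec))
    for i in range(n_rec):
        year = int(years[i])
        jan1 = dt.date(year, 1, 1)
        rec = TrackRecord(
            record_id=f"R{i + 1:0{width}d}",
            species=species[sp_idx[i]],
            level=str(level[i]),
            paper_id=paper_labels[paper_idx[i]],
            year=year,
            sex=str(sex[i]),
            capture_site_class=str(capture[i]),
            breed_lat=round(float(breed_lat[i]), 6),
            breed_lon=round(float(breed_lon[i]), 6),
            nb_first_lat=round(float(nb_lat[i]), 6),
            nb_first_lon=round(float(nb_lon[i]), 6),
            nb_last_lat=round(float(nb_lat[i]), 6),
            nb_last_lon=round(float(nb_lon[i]), 6),
            dep_nb=jan1 + dt.timedelta(days=int(doy[DEP_NB][i]) - 1),
            arr_b=jan1 + dt.timedelta(days=int(doy[ARR_B][i]) - 1),
            dep_b=jan1 + dt.timedelta(days=int(doy[DEP_B][i]) - 1),
            arr_nb=jan1 + dt.timedelta(days=int(doy[ARR_NB][i]) - 1),
            flight_mode="soaring" if soaring[sp_idx[i]] else "flapping",
        )
        rec.validate()
        records.append(rec)

    truth_out = {
        "truth": truth.to_dict(),
        "equations": equations_truth,
        "n_records": n_rec,
        "n_species": S_sp,
        "n_papers": len(paper_labels),
        "clipped_distance_fraction": n_clipped_dist / n_rec,
    }
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return SyntheticBundle(
        records=records,
        traits=traits,
        newick=newick,
        truth=truth_out,
        node_values=values,
    )


def simulate_bundle(
    n_species: int = 186,
    mean_records_per_species: float | None = None,
    seed: int = 0,
    **overrides: Any,
) -> SyntheticBundle:
    """Convenience wrapper: build a truth, simulate, return the bundle."""
    kwargs: dict[str, Any] = {"n_species": n_species, "seed": seed}
    if mean_records_per_species is not None:
        kwargs["mean_records_per_species"] = mean_records_per_species
    kwargs.update(overrides)
    return simulate_dataset(SimulationTruth(**kwargs))


def write_bundle(bundle: SyntheticBundle, out_dir: str) -> dict[str, str]:
    """Write tracking CSV, trait CSV, Newick tree, and truth JSON."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "tracking": os.path.join(out_dir, "tracking.csv"),
        "traits": os.path.join(out_dir, "traits.csv"),
        "tree": os.path.join(out_dir, "tree.nwk"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_tracking_table(bundle.records, paths["tracking"])
    write_trait_table(bundle.traits, paths["traits"])
    with open(paths["tree"], "w") as fh:
        fh.write(bundle.newick + "\n")
    with open(paths["truth"], "w") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
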