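"""Knockout simulation: flux sampling and exometabolomic z-score profiles.

A pathway knockout sets the bounds of every reaction in that pathway to
[0, 0].  A knockout that cannot reach 10% of the wild-type maximum biomass
is classified infeasible and produces no profile.  For the remaining
(functional) knockouts, steady-state fluxes are drawn from the constrained
polytope {v : S v = 0, lb <= v <= ub, v_biomass >= floor} for both the
wild-type and the knockout state with an artificially-centred hit-and-run
sampler, and each exchangeable metabolite receives a z-score

    z = (mean_KO - mean_WT) / sqrt((sd_WT^2 + sd_KO^2) / 2)

on its net exchange flux (positive flux = export, so positive z means more
of the metabolite in the medium).  The profile of z-scores is the simulated
exometabolomic read-out handed to the pathway-analysis methods.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from cobra.flux_analysis import flux_variability_analysis
from cobra.sampling import ACHRSampler
from cobra.util.array import create_stoichiometric_matrix

from .model import MetabolicModel

__all__ = [
    "KnockoutScenario",
    "FluxSampleSet",
    "ZScoreProfile",
    "knockout_pathway",
    "classify_feasibility",
    "sample_fluxes",
    "compute_zscores",
    "run_all_scenarios",
    "scenario_seed",
]

STEADY_TOL = 1e-6
Z_MAX = 50.0

STATUS_FUNCTIONAL = "functional"
STATUS_INFEASIBLE = "infeasible"
STATUS_BLOCKED = "blocked"
STATUS_EXCLUDED = "excluded_miscellaneous"


@dataclass(frozen=True)
class KnockoutScenario:
    pathway_id: str
    ko_reaction_ids: frozenset[str]
    status: str


@dataclass(frozen=True)
class FluxSampleSet:
    """Sampled flux matrix (n_samples x n_reactions), columns = reaction_ids."""

    reaction_ids: tuple[str, ...]
    samples: np.ndarray
    seed: int
    n_samples: int

    def column(self, reaction_id: str) -> np.ndarray:
        return self.samples[:, self.reaction_ids.index(reaction_id)]


@dataclass(frozen=True)
class ZScoreProfile:
    """One simulated exometabolomic profile: base metabolite id -> z."""

    scenario: str
    zscores: dict[str, float]
    n_wt: int
    n_ko: int


def knockout_pathway(model: MetabolicModel, pathway_id: str) -> MetabolicModel:
    """Return a copy of ``model`` with the pathway's reaction bounds at [0, 0]."""
    if pathway_id not in model.pathway_reactions:
        raise KeyError(f"unknown pathway: {pathway_id!r}")
    ko = model.copy()
    for rid in model.pathway_reactions[pathway_id]:
        ko.cmodel.reactions.get_by_id(rid).bounds = (0.0, 0.0)
    return ko


def classify_feasibility(
    ko_model: MetabolicModel,
    wt_max_biomass: float,
    floor_fraction: float = 0.1,
) -> str:
    """'infeasible' if the knockout cannot reach the biomass floor, else 'functional'."""
    if wt_max_biomass <= 0:
        raise ValueError("wild-type maximum biomass must be positive")
    value = ko_model.max_biomass()
    if np.isnan(value):  # LP infeasible
        return STATUS_INFEASIBLE
    return (
        STATUS_INFEASIBLE
        if value < floor_fraction * wt_max_biomass
        else STATUS_FUNCTIONAL
    )


def _single_point(cmodel, tol: float = 1e-9):
    """The unique flux vector of a zero-dimensional polytope, or None."""
    fva = flux_variability_analysis(cmodel, fraction_of_optimum=0.0)
    if (fva["maximum"] - fva["minimum"]).abs().max() < tol:
        point = fva["minimum"]
        return point.reindex([r.id for r in cmodel.reactions]).to_numpy()
    return None


def sample_fluxes(
    model: MetabolicModel,
    n_samples: int,
    seed: int,
    biomass_floor: float,
    thinning: int = 100,
) -> FluxSampleSet:
    """Draw steady-state flux samples under the biomass floor.

    Uses artificially-centred hit-and-run with FVA warmup; reproducible for
    a fixed seed.  Fluxes of reactions fixed by zero-width bounds (knocked-out
    reactions) are exact.  Degenerate polytopes that consist of a single
    point yield ``n_samples`` copies of that point.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    cm = model.cmodel.copy()
    cm.reactions.get_by_id(model.biomass_reaction_id).lower_bound = biomass_floor
    rids = tuple(r.id for r in cm.reactions)
    try:
        # reproject onto S v = 0 every `thinning` steps: long chains drift
        # off the steady-state subspace otherwise
        sampler = ACHRSampler(cm, thinning=thinning, seed=seed,
                              nproj=max(thinning, 1))
        frame = sampler.sample(n_samples)
        mat = frame[list(rids)].to_numpy()
    except ValueError as err:
        if "single point" not in str(err):
            raise
        point = _single_point(cm)
        if point is None:
            raise
        mat = np.tile(point, (n_samples, 1))
    # zero-width bounds are hard constraints: pin those columns exactly
    for j, r in enumerate(cm.reactions):
        if r.lower_bound == r.upper_bound:
            mat[:, j] = r.lower_bound
    _validate_samples(cm, mat)
    return FluxSampleSet(reaction_ids=rids, samples=mat, seed=seed,
                         n_samples=n_samples)


def _validate_samples(cmodel, mat: np.ndarray) -> None:
    smat = create_stoichiometric_matrix(cmodel)
    resid = np.abs(smat @ mat.T).max() if mat.size else 0.0
    if resid > STEADY_TOL:
        raise RuntimeError(f"sampling violated steady state (|S v| = {resid:.2e})")
    lb = np.array([r.lower_bound for r in cmodel.reactions])
    ub = np.array([r.upper_bound for r in cmodel.reactions])
    slack = max((lb - mat).max(initial=0.0), (mat - ub).max(initial=0.0))
    if slack > STEADY_TOL:
        raise RuntimeError(f"sampling violated flux bounds (slack = {slack:.2e})")


def exchange_flux_matrix(
    model: MetabolicModel, samples: FluxSampleSet
) -> pd.DataFrame:
    """Net export flux per exchangeable metabolite (columns), per sample (rows).

    Fluxes are sign-normalised (positive = export to the medium); multiple
    exchange reactions for the same base metabolite are summed.
    """
    cols: dict[str, np.ndarray] = {}
    for rid, met in sorted(model.exchange_metabolite.items()):
        v = model.exchange_sign[rid] * samples.column(rid)
        cols[met] = cols[met] + v if met in cols else v
    return pd.DataFrame(cols)


def compute_zscores(
    wt: FluxSampleSet,
    ko: FluxSampleSet,
    model: MetabolicModel,
    z_max: float = Z_MAX,
    scenario: str = "",
) -> ZScoreProfile:
    """z-score per exchangeable metabolite between KO and WT sample sets.

    z = (mean_KO - mean_WT) / sqrt((sd_WT^2 + sd_KO^2)/2), clipped to
    ``±z_max``.  If both states have zero variance the z is 0 for equal
    means and ±z_max otherwise.
    """
    wt_ex = exchange_flux_matrix(model, wt)
    ko_ex = exchange_flux_matrix(model, ko)
    zs: dict[str, float] = {}
    for met in wt_ex.columns:
        w, k = wt_ex[met].to_numpy(), ko_ex[met].to_numpy()
        diff = k.mean() - w.mean()
        pooled = np.sqrt((w.std(ddof=1) ** 2 + k.std(ddof=1) ** 2) / 2.0)
        if pooled == 0.0:
            z = 0.0 if diff == 0.0 else np.sign(diff) * z_max
        else:
            z = float(np.clip(diff / pooled, -z_max, z_max))
        zs[met] = float(z)
    return ZScoreProfile(scenario=scenario, zscores=zs,
                         n_wt=wt.n_samples, n_ko=ko.n_samples)


def scenario_seed(seed: int, pathway_id: str) -> int:
    """Stable per-scenario sampler seed below 2^31 (order-independent)."""
    return (seed * 1_000_003 + zlib.crc32(pathway_id.encode())) % (2**31 - 1)


def run_all_scenarios(
    model: MetabolicModel,
    n_samples: int = 5000,
    seed: int = 42,
    floor_fraction: float = 0.1,
    thinning: int = 100,
    wt_samples: FluxSampleSet | None = None,
) -> tuple[dict[str, ZScoreProfile], pd.DataFrame]:
    """Simulate every pathway knockout against one shared wild-type state.

    Returns (profiles keyed by pathway id, scenario ledger).  The ledger has
    one row per pathway of the model, including the blocked pathways removed
    at pruning, with its status: functional (profile produced), infeasible
    (below the biomass floor), blocked, or excluded_miscellaneous.
    """
    wt_max = model.max_biomass()
    floor = floor_fraction * wt_max
    if wt_samples is None:
        wt_samples = sample_fluxes(model, n_samples, seed, floor, thinning)
    misc = model.miscellaneous_pathways
    profiles: dict[str, ZScoreProfile] = {}
    rows = []
    for pid in sorted(model.pathway_reactions):
        if pid in misc:
            rows.append((pid, STATUS_EXCLUDED, len(model.pathway_reactions[pid])))
            continue
        ko = knockout_pathway(model, pid)
        status = classify_feasibility(ko, wt_max, floor_fraction)
        if status == STATUS_FUNCTIONAL:
            ko_samples = sample_fluxes(
                ko, n_samples, scenario_seed(seed, pid), floor, thinning
            )
            profiles[pid] = compute_zscores(wt_samples, ko_samples, model,
                                            scenario=pid)
        rows.append((pid, status, len(model.pathway_reactions[pid])))
    for pid in sorted(model.blocked_pathways):
        rows.append((pid, STATUS_BLOCKED, 0))
    ledger = pd.DataFrame(rows, columns=["pathway", "status", "n_reactions"])
    return profiles, ledger
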