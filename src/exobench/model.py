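"""Loading, validation and preprocessing of constraint-based metabolic models.

A model is read from SBML (Level 3 + fbc) together with a side-compound list
and an optional pathway-category table.  Pathways ("subsystems") are sets of
reactions; a reaction belongs to at most one pathway.  Preprocessing removes
blocked reactions (flux-variability min = max = 0 under default bounds),
prunes orphaned metabolites, converts reaction pathway sets to metabolite
pathway sets, and derives the exchangeable background — the base ids of all
metabolites that possess an exchange reaction, i.e. the metabolites that
could ever appear in an exometabolomic profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import cobra
import cobra.io
from cobra.flux_analysis import flux_variability_analysis

__all__ = [
    "MetabolicModel",
    "MetabolitePathwaySets",
    "MISCELLANEOUS_CATEGORY",
    "DEFAULT_BIOMASS_ID",
    "base_id",
    "load_sbml",
    "find_blocked_reactions",
    "prune_model",
    "reactions_to_metabolite_sets",
    "exchangeable_background",
    "read_side_compounds",
    "read_categories",
    "read_gmt",
    "write_gmt",
]

MISCELLANEOUS_CATEGORY = "Miscellaneous"

#: Biomass reaction id of Human-GEM; toy models use their own id and pass it
#: explicitly.  There is no SBML convention for marking the biomass reaction,
#: so it always comes from configuration.
DEFAULT_BIOMASS_ID = "MAR13082"

#: Compartment codes treated as extracellular when auto-detecting exchange
#: reactions ("e" is the classic convention, "s" is Human-GEM's).
EXTRACELLULAR_COMPARTMENTS = frozenset({"e", "s", "x"})


def base_id(met_id: str, compartment: str) -> str:
    """Strip the compartment suffix from a metabolite id.

    Two conventions are recognised: an underscore-separated suffix
    (``glc__D_c`` -> ``glc__D``) and a bare trailing compartment code
    (Human-GEM's ``MAM01965s`` -> ``MAM01965``).  Compartmental copies of a
    metabolite thereby collapse onto one base id, so "unique metabolites"
    are counted once across compartments.
    """
    if compartment and met_id.endswith(f"_{compartment}"):
        return met_id[: -(len(compartment) + 1)]
    if compartment and len(met_id) > len(compartment) and met_id.endswith(compartment):
        return met_id[: -len(compartment)]
    return met_id


@dataclass
class MetabolicModel:
    """A constraint-based model plus the pathway bookkeeping the benchmark needs.

    Wraps a :class:`cobra.Model` (stoichiometry, bounds, solver access) and
    carries the derived structure: the reaction->pathway partition, exchange
    reactions normalised so that positive flux means export to the medium,
    side-compound membership and pathway categories.
    """

    cmodel: cobra.Model
    biomass_reaction_id: str
    side_compounds: frozenset[str] = frozenset()
    pathway_reactions: dict[str, frozenset[str]] = field(default_factory=dict)
    pathway_categories: dict[str, str] = field(default_factory=dict)
    #: rxn id -> base id of the single exchanged metabolite
    exchange_metabolite: dict[str, str] = field(default_factory=dict)
    #: rxn id -> +1 if positive flux exports the metabolite, -1 if it imports
    exchange_sign: dict[str, int] = field(default_factory=dict)
    #: pathways emptied by pruning (recorded, no longer in ``pathway_reactions``)
    blocked_pathways: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.biomass_reaction_id not in self.cmodel.reactions:
            raise ValueError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )

    # -- convenience ------------------------------------------------------
    @property
    def reaction_pathway(self) -> dict[str, str]:
        """Inverse of ``pathway_reactions`` (reaction id -> pathway id)."""
        return {
            rid: pid for pid, rids in self.pathway_reactions.items() for rid in rids
        }

    @property
    def miscellaneous_pathways(self) -> frozenset[str]:
        return frozenset(
            p
            for p, cat in self.pathway_categories.items()
            if cat == MISCELLANEOUS_CATEGORY and p in self.pathway_reactions
        )

    def metabolite_base_id(self, met_id: str) -> str:
        met = self.cmodel.metabolites.get_by_id(met_id)
        return base_id(met.id, met.compartment or "")

    def is_side_compound(self, met_id: str) -> bool:
        return self.metabolite_base_id(met_id) in self.side_compounds

    def copy(self) -> "MetabolicModel":
        return replace(self, cmodel=self.cmodel.copy())

    def max_biomass(self) -> float:
        with self.cmodel as m:
            m.objective = self.biomass_reaction_id
            value = m.slim_optimize(error_value=float("nan"))
        return float(value)


@dataclass(frozen=True)
class MetabolitePathwaySets:
    """Pathway -> set of base metabolite ids, derived from reaction sets.

    A metabolite may belong to several pathways; ``include_side`` records
    whether ubiquitous side compounds (water, ATP, ...) are in the sets.
    """

    sets: dict[str, frozenset[str]]
    include_side: bool = True

    def __getitem__(self, pathway_id: str) -> frozenset[str]:
        return self.sets[pathway_id]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()


# ---------------------------------------------------------------------------
# sidecar file readers
# ---------------------------------------------------------------------------

def read_side_compounds(path) -> frozenset[str]:
    """One base metabolite id per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return frozenset(out)


def read_categories(path) -> dict[str, str]:
    """Two-column TSV (pathway id, category); a header line is permitted."""
    cats: dict[str, str] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {i + 1} is not 2-column TSV")
            if i == 0 and parts[0].lower() in {"pathway", "pathway_id"}:
                continue
            cats[parts[0]] = parts[1]
    return cats


def read_gmt(path) -> dict[str, frozenset[str]]:
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = frozenset(p for p in parts[2:] if p)
    return sets


def write_gmt(sets: MetabolitePathwaySets | dict, path, description: str = "na") -> None:
    mapping = sets.sets if isinstance(sets, MetabolitePathwaySets) else sets
    with open(path, "w") as fh:
        for name in sorted(mapping):
            members = "\t".join(sorted(mapping[name]))
            fh.write(f"{name}\t{description}\t{members}\n")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _detect_exchanges(cmodel: cobra.Model) -> tuple[dict[str, str], dict[str, int]]:
    """Single-metabolite reactions on an extracellular metabolite.

    Returns (rxn id -> base metabolite id, rxn id -> sign) with the sign
    chosen so that positive flux means export into the medium: for the
    canonical form ``m_e ->`` (coefficient -1) positive flux already exports,
    for ``-> m_e`` (coefficient +1) it is flipped.
    """
    ex_met: dict[str, str] = {}
    ex_sign: dict[str, int] = {}
    for rxn in cmodel.reactions:
        mets = rxn.metabolites
        if len(mets) != 1:
            continue
        (met, coeff), = mets.items()
        if (met.compartment or "") not in EXTRACELLULAR_COMPARTMENTS:
            continue
        ex_met[rxn.id] = base_id(met.id, met.compartment or "")
        ex_sign[rxn.id] = -1 if coeff > 0 else 1
    return ex_met, ex_sign


def _pathways_from_groups(cmodel: cobra.Model) -> dict[str, frozenset[str]]:
    pathways: dict[str, set[str]] = {}
    seen: dict[str, str] = {}
    for group in cmodel.groups:
        name = group.name or group.id
        rids = {m.id for m in group.members if isinstance(m, cobra.Reaction)}
        if not rids:
            continue
        for rid in rids:
            if rid in seen and seen[rid] != name:
                raise ValueError(
                    f"reaction {rid!r} is annotated to two pathways "
                    f"({seen[rid]!r} and {name!r}); each reaction may belong "
                    "to exactly one pathway"
                )
            seen[rid] = name
        pathways.setdefault(name, set()).update(rids)
    return {p: frozenset(r) for p, r in pathways.items()}


def _pathways_from_subsystems(cmodel: cobra.Model) -> dict[str, frozenset[str]]:
    pathways: dict[str, set[str]] = {}
    for rxn in cmodel.reactions:
        if rxn.subsystem:
            pathways.setdefault(rxn.subsystem, set()).add(rxn.id)
    return {p: frozenset(r) for p, r in pathways.items()}


def load_sbml(
    path,
    side_compound_path=None,
    category_path=None,
    biomass_id: str = DEFAULT_BIOMASS_ID,
) -> MetabolicModel:
    """Load an SBML L3/fbc model with its side-compound and category sidecars.

    Pathway membership is read from SBML groups (falling back to reaction
    subsystem notes); a reaction annotated to more than one pathway is a hard
    error.  Exchange reactions are auto-detected as single-metabolite
    reactions on an extracellular metabolite.  ``biomass_id`` must name a
    reaction in the model.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cmodel = cobra.io.read_sbml_model(str(path))
    for rxn in cmodel.reactions:
        if rxn.lower_bound is None or rxn.upper_bound is None:
            raise ValueError(f"reaction {rxn.id!r} is missing flux bounds")
        if rxn.lower_bound > rxn.upper_bound:
            raise ValueError(f"reaction {rxn.id!r} has lower bound > upper bound")
    pathways = _pathways_from_groups(cmodel)
    if not pathways:
        pathways = _pathways_from_subsystems(cmodel)
    side = read_side_compounds(side_compound_path) if side_compound_path else frozenset()
    cats = read_categories(category_path) if category_path else {}
    ex_met, ex_sign = _detect_exchanges(cmodel)
    # the biomass pseudo-reaction is never part of a knockout pathway
    pathways = {
        p: rids - {biomass_id}
        for p, rids in pathways.items()
        if rids - {biomass_id}
    }
    return MetabolicModel(
        cmodel=cmodel,
        biomass_reaction_id=biomass_id,
        side_compounds=side,
        pathway_reactions=pathways,
        pathway_categories=cats,
        exchange_metabolite=ex_met,
        exchange_sign=ex_sign,
    )


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def find_blocked_reactions(model: MetabolicModel, tol: float = 1e-9) -> frozenset[str]:
    """Reactions whose FVA minimum and maximum are both zero (within ``tol``).

    Computed under default bounds with no biomass requirement
    (``fraction_of_optimum=0``), so a reaction is blocked only if the network
    structure itself prevents it from ever carrying flux.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    cm = model.cmodel
    with cm:
        if cm.slim_optimize(error_value=None) is None:
            raise RuntimeError("model is infeasible under default bounds")
        fva = flux_variability_analysis(cm, fraction_of_optimum=0.0)
    blocked = fva[(fva["minimum"].abs() < tol) & (fva["maximum"].abs() < tol)]
    return frozenset(blocked.index)


def prune_model(model: MetabolicModel, blocked: frozenset[str]) -> MetabolicModel:
    """Remove blocked reactions and then any metabolite left orphaned.

    Pathways whose reaction sets become empty are recorded in
    ``blocked_pathways``; the returned model satisfies all loading
    invariants and the input model is untouched.
    """
    unknown = set(blocked) - {r.id for r in model.cmodel.reactions}
    if unknown:
        raise ValueError(f"unknown reactions in blocked set: {sorted(unknown)}")
    cmodel = model.cmodel.copy()
    if blocked:
        cmodel.remove_reactions(
            [cmodel.reactions.get_by_id(r) for r in sorted(blocked)],
            remove_orphans=True,
        )
    newly_blocked = set()
    pathways = {}
    for pid, rids in model.pathway_reactions.items():
        kept = rids - blocked
        if kept:
            pathways[pid] = kept
        else:
            newly_blocked.add(pid)
    ex_met = {r: m for r, m in model.exchange_metabolite.items() if r not in blocked}
    ex_sign = {r: s for r, s in model.exchange_sign.items() if r not in blocked}
    return replace(
        model,
        cmodel=cmodel,
        pathway_reactions=pathways,
        exchange_metabolite=ex_met,
        exchange_sign=ex_sign,
        blocked_pathways=model.blocked_pathways | frozenset(newly_blocked),
    )


def reactions_to_metabolite_sets(
    model: MetabolicModel, include_side: bool = True
) -> MetabolitePathwaySets:
    """Convert reaction pathway sets to metabolite pathway sets.

    Each pathway collects the base ids of the substrates and products of its
    reactions; a metabolite therefore may appear in several pathways.  With
    ``include_side=False`` the ubiquitous side compounds are dropped, which
    is the variant used for overlap and graph computations.
    """
    cm = model.cmodel
    sets: dict[str, frozenset[str]] = {}
    for pid, rids in model.pathway_reactions.items():
        members: set[str] = set()
        for rid in rids:
            for met in cm.reactions.get_by_id(rid).metabolites:
                members.add(base_id(met.id, met.compartment or ""))
        if not include_side:
            members -= model.side_compounds
        sets[pid] = frozenset(members)
    return MetabolitePathwaySets(sets=sets, include_side=include_side)


def exchangeable_background(model: MetabolicModel) -> frozenset[str]:
    """Base ids of every metabolite that has at least one exchange reaction.

    This is the ORA/GSEA background: only these metabolites can ever show up
    in an exometabolomic profile.
    """
    return frozenset(model.exchange_metabolite.values())
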