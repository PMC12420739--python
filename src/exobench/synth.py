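"""Small ground-truth metabolic models for exercising the benchmark.

The generator stitches structural archetypes onto a common core (nutrient
import -> biomass precursors -> biomass) so that every downstream stage has
an exactly known answer:

* ``essential`` — the sole producer of a biomass precursor; knocking it out
  makes the model infeasible.
* ``unique_exporter`` — a linear chain that consumes three imported
  substrates and exports a product no other pathway touches; its knockout
  leaves a strong, specific signature on the exometabolome (detectable).
* ``internal_only`` — a closed cycle of intracellular metabolites with no
  exchangeable member (exchangeable ratio 0); its knockout is invisible in
  the exometabolome (undetectable).
* ``redundant_pair`` — two pathways that can each supply the same biomass
  precursor; knocking out either one stays feasible.
* ``blocked`` — a dead-end branch that can never carry flux and is removed
  at pruning.

Archetypes are fixed templates, not random graphs: the benchmark needs exact
ground truth, not statistical realism.  The seed only jitters flux capacities,
so structure (and hence ground truth) is seed-independent while simulated
flux magnitudes vary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import cobra
import cobra.io
import numpy as np
from cobra.core import Group

from .model import (
    MISCELLANEOUS_CATEGORY,
    MetabolicModel,
    load_sbml,
    read_side_compounds,
)

__all__ = ["ToyModelSpec", "GroundTruth", "generate_toy_model", "write_sbml",
           "REFERENCE_ARCHETYPES", "sidecar_paths"]

ARCHETYPES = ("essential", "unique_exporter", "internal_only",
              "redundant_pair", "blocked")

#: the 6-pathway reference fixture used throughout the test-bench
REFERENCE_ARCHETYPES = (
    "essential",
    "unique_exporter",
    "internal_only",
    "redundant_pair",
    "redundant_pair",
    "blocked",
)

_CATEGORY = {
    "essential": "Amino acid metabolism",
    "unique_exporter": "Carbohydrate metabolism",
    "internal_only": "Lipid metabolism",
    "redundant_pair": "Energy metabolism",
    "blocked": "Lipid metabolism",
}

TRANSPORT_PATHWAY = "Transport reactions"
BIOMASS_ID = "biomass"
_SIDE_POOL = ("atp", "adp", "h2o")


@dataclass(frozen=True)
class ToyModelSpec:
    """Blueprint for a generated toy model."""

    pathway_archetypes: tuple[str, ...] = REFERENCE_ARCHETYPES
    n_side_compounds: int = 3
    seed: int = 42

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_archetypes)

    def __post_init__(self) -> None:
        if self.n_pathways < 1:
            raise ValueError("need at least one pathway")
        bad = set(self.pathway_archetypes) - set(ARCHETYPES)
        if bad:
            raise ValueError(f"unknown archetypes: {sorted(bad)}")
        if "essential" not in self.pathway_archetypes:
            raise ValueError(
                "biomass requires a precursor: include at least one "
                "'essential' pathway"
            )
        if self.pathway_archetypes.count("redundant_pair") == 1:
            raise ValueError(
                "'redundant_pair' archetypes share a precursor and must come "
                "in groups of at least two (one alone would be essential)"
            )
        if not 0 <= self.n_side_compounds <= len(_SIDE_POOL):
            raise ValueError(f"n_side_compounds must be in [0, {len(_SIDE_POOL)}]")


@dataclass(frozen=True)
class GroundTruth:
    """Known labels for a generated model, keyed by pathway name."""

    essential_pathways: frozenset[str] = frozenset()
    blocked_pathways: frozenset[str] = frozenset()
    expected_tp_pathways: frozenset[str] = frozenset()
    expected_fn_pathways: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        groups = [self.essential_pathways, self.blocked_pathways,
                  self.expected_tp_pathways, self.expected_fn_pathways]
        n = sum(len(g) for g in groups)
        if len(frozenset().union(*groups)) != n:
            raise ValueError("ground-truth pathway classes must be disjoint")


class _Builder:
    """Incremental cobra-model assembly with compartment-suffixed ids."""

    def __init__(self) -> None:
        self.cmodel = cobra.Model("toy")
        self.pathway_reactions: dict[str, set[str]] = {}
        self._mets: dict[str, cobra.Metabolite] = {}

    def met(self, base: str, comp: str) -> cobra.Metabolite:
        mid = f"{base}_{comp}"
        if mid not in self._mets:
            m = cobra.Metabolite(mid, name=base, compartment=comp)
            self._mets[mid] = m
            self.cmodel.add_metabolites([m])
        return self._mets[mid]

    def rxn(self, rid: str, stoich: dict[cobra.Metabolite, float],
            lb: float, ub: float, pathway: str | None) -> None:
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        self.cmodel.add_reactions([r])
        r.add_metabolites(stoich)
        if pathway is not None:
            self.pathway_reactions.setdefault(pathway, set()).add(rid)

    def exchange(self, base: str, lb: float, ub: float) -> None:
        """EX plus transport, both in the miscellaneous transport pathway."""
        e, c = self.met(base, "e"), self.met(base, "c")
        self.rxn(f"EX_{base}_e", {e: -1.0}, lb, ub, TRANSPORT_PATHWAY)
        if lb < 0 <= ub or ub <= 0:  # importable
            self.rxn(f"T_{base}_in", {e: -1.0, c: 1.0}, 0.0, 1000.0,
                     TRANSPORT_PATHWAY)
        if ub > 0:  # exportable
            self.rxn(f"T_{base}_out", {c: -1.0, e: 1.0}, 0.0, 1000.0,
                     TRANSPORT_PATHWAY)


def generate_toy_model(spec: ToyModelSpec = ToyModelSpec()
                       ) -> tuple[MetabolicModel, GroundTruth]:
    """Build the toy model and its ground truth for ``spec``.

    Deterministic given ``spec.seed``; the wild-type model always supports a
    positive biomass flux (and hence the 10%-of-maximum biomass floor used
    during sampling).
    """
    rng = np.random.default_rng(spec.seed)
    side = frozenset(_SIDE_POOL[: spec.n_side_compounds])
    b = _Builder()
    categories: dict[str, str] = {TRANSPORT_PATHWAY: MISCELLANEOUS_CATEGORY}
    essential, blocked_gt, tp_gt, fn_gt = set(), set(), set(), set()

    def jitter(x: float) -> float:
        return round(float(x * rng.uniform(0.9, 1.1)), 3)

    # common core: nutrient and two auxiliary biomass substrates
    b.exchange("nut", -jitter(20.0), 1000.0)
    b.exchange("x1", -jitter(50.0), 0.0)
    b.exchange("x2", -jitter(50.0), 0.0)
    biomass_substrates = [b.met("x1", "c"), b.met("x2", "c")]

    counters: dict[str, int] = {}
    names: list[str] = []
    for arch in spec.pathway_archetypes:
        counters[arch] = counters.get(arch, 0) + 1
        k = counters[arch]
        tag = f"{k}" if spec.pathway_archetypes.count(arch) > 1 else ""

        if arch == "essential":
            name = f"Essential biosynthesis {tag}".strip()
            pre = b.met(f"preE{k}", "c")
            mid = b.met(f"eint{k}", "c")
            b.rxn(f"R_ess{k}a", {b.met("nut", "c"): -1.0, mid: 1.0},
                  0.0, 1000.0, name)
            b.rxn(f"R_ess{k}b", {mid: -1.0, pre: 1.0}, 0.0, 1000.0, name)
            biomass_substrates.append(pre)
            essential.add(name)

        elif arch == "unique_exporter":
            name = f"Unique exporter pathway {tag}".strip()
            cap = jitter(10.0)
            for s in ("a", "b", "c"):
                b.exchange(f"{s}{k}", -cap, 0.0)
            b.exchange(f"uexp{k}", 0.0, 1000.0)
            u1 = b.met(f"u{k}", "c")
            s1 = {b.met(f"a{k}", "c"): -1.0, b.met(f"b{k}", "c"): -1.0, u1: 1.0}
            s2 = {u1: -1.0, b.met(f"c{k}", "c"): -1.0,
                  b.met(f"uexp{k}", "c"): 1.0}
            if "h2o" in side:
                s1[b.met("h2o", "c")] = 1.0
                s2[b.met("h2o", "c")] = -1.0
            b.rxn(f"R_uex{k}a", s1, 0.0, 1000.0, name)
            b.rxn(f"R_uex{k}b", s2, 0.0, 1000.0, name)
            tp_gt.add(name)

        elif arch == "internal_only":
            name = f"Internal cycle {tag}".strip()
            i1, i2, i3 = (b.met(f"icyc{k}{j}", "c") for j in "123")
            s1: dict = {i1: -1.0, i2: 1.0}
            s2: dict = {i2: -1.0, i3: 1.0}
            if {"atp", "adp"} <= side:
                s1.update({b.met("atp", "c"): -1.0, b.met("adp", "c"): 1.0})
                s2.update({b.met("adp", "c"): -1.0, b.met("atp", "c"): 1.0})
            b.rxn(f"R_cyc{k}a", s1, 0.0, 1000.0, name)
            b.rxn(f"R_cyc{k}b", s2, 0.0, 1000.0, name)
            b.rxn(f"R_cyc{k}c", {i3: -1.0, i1: 1.0}, 0.0, 1000.0, name)
            fn_gt.add(name)

        elif arch == "redundant_pair":
            name = f"Redundant synthesis {tag}".strip()
            pre = b.met("preR", "c")
            if "preR" not in {m.id[:-2] for m in biomass_substrates}:
                biomass_substrates.append(pre)
            b.exchange(f"w{k}", 0.0, 1000.0)
            b.rxn(f"R_red{k}", {b.met("nut", "c"): -1.0, pre: 1.0,
                                b.met(f"w{k}", "c"): 1.0}, 0.0, 1000.0, name)

        elif arch == "blocked":
            name = f"Dead-end pathway {tag}".strip()
            d1, d2 = b.met(f"dead{k}a", "c"), b.met(f"dead{k}b", "c")
            b.rxn(f"R_dead{k}a", {b.met("nut", "c"): -1.0, d1: 1.0},
                  0.0, 1000.0, name)
            b.rxn(f"R_dead{k}b", {d1: -1.0, d2: 1.0}, 0.0, 1000.0, name)
            blocked_gt.add(name)

        categories[name] = _CATEGORY[arch]
        names.append(name)

    b.rxn(BIOMASS_ID, {m: -1.0 for m in biomass_substrates}, 0.0, 1000.0, None)
    b.cmodel.objective = BIOMASS_ID

    from .model import _detect_exchanges  # shares the loader's conventions

    ex_met, ex_sign = _detect_exchanges(b.cmodel)
    model = MetabolicModel(
        cmodel=b.cmodel,
        biomass_reaction_id=BIOMASS_ID,
        side_compounds=side,
        pathway_reactions={p: frozenset(r) for p, r in
                           b.pathway_reactions.items()},
        pathway_categories=categories,
        exchange_metabolite=ex_met,
        exchange_sign=ex_sign,
    )
    truth = GroundTruth(
        essential_pathways=frozenset(essential),
        blocked_pathways=frozenset(blocked_gt),
        expected_tp_pathways=frozenset(tp_gt),
        expected_fn_pathways=frozenset(fn_gt),
    )
    if model.max_biomass() <= 0:
        raise RuntimeError("generated wild-type model cannot produce biomass")
    return model, truth


# ---------------------------------------------------------------------------
# SBML round trip
# ---------------------------------------------------------------------------

def sidecar_paths(path) -> tuple[Path, Path]:
    """(side-compound list, category TSV) companions of an SBML path."""
    p = Path(path)
    return p.with_suffix(".side.txt"), p.with_suffix(".categories.tsv")


def write_sbml(model: MetabolicModel, path) -> None:
    """Write the model as SBML L3/fbc plus its two sidecar files.

    Pathway membership goes into SBML groups; side compounds and pathway
    categories go into the plain-text companions so that
    ``load_sbml(path, *sidecar_paths(path))`` round-trips the model.
    """
    cm = model.cmodel.copy()
    cm.groups.clear()
    groups = []
    for i, pid in enumerate(sorted(model.pathway_reactions)):
        g = Group(f"g{i + 1}", name=pid, kind="partonomy")
        g.add_members([cm.reactions.get_by_id(r)
                       for r in sorted(model.pathway_reactions[pid])])
        groups.append(g)
    cm.add_groups(groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cobra.io.write_sbml_model(cm, str(path))
    _sort_group_members(path)
    side_path, cat_path = sidecar_paths(path)
    side_path.write_text("".join(f"{s}\n" for s in sorted(model.side_compounds)))
    with open(cat_path, "w") as fh:
        fh.write("pathway\tcategory\n")
        for pid in sorted(model.pathway_categories):
            fh.write(f"{pid}\t{model.pathway_categories[pid]}\n")


def _sort_group_members(path) -> None:
    """Sort <groups:member> elements by idRef for reproducible output.

    The in-memory group container is unordered, so the writer emits members
    in arbitrary order; sorting makes same-seed outputs byte-identical.
    """
    from lxml import etree

    tree = etree.parse(str(path))
    ns = "http://www.sbml.org/sbml/level3/version1/groups/version1"
    for lom in tree.iter(f"{{{ns}}}listOfMembers"):
        members = sorted(lom, key=lambda e: e.get(f"{{{ns}}}idRef") or "")
        lom.text = "\n            "
        for m in members:
            lom.remove(m)
        for m in members:
            m.tail = "\n            "
            lom.append(m)
        if members:
            members[-1].tail = "\n          "
    tree.write(str(path), xml_declaration=True, encoding="UTF-8")


def load_toy_sbml(path, biomass_id: str = BIOMASS_ID) -> MetabolicModel:
    """Load a model written by :func:`write_sbml` with its sidecars."""
    side_path, cat_path = sidecar_paths(path)
    return load_sbml(path, side_path, cat_path, biomass_id=biomass_id)
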