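"""Construction of the lipid ontology DAG.

The ontology is a directed acyclic graph of terms organized in four branches —
lipid classification, chemical and physical properties, function, and cellular
component — each rooted in a category term whose identifier carries the
``CAT`` prefix.  Lipid species are enumerated combinatorially: every lipid
class rule describes a backbone and a number of acyl positions, and species
are all unordered multisets of chains drawn from a fatty-acid alphabet
(37 entries by default), plus a sum-composition layer that aggregates
molecular species by total carbons and double bonds.

Species are nodes distinct from terms; each species carries a set of *direct*
term associations (its classification leaf, chemical terms inferred from the
name, class-level charge/curvature/function/component terms, and optional
biophysical category terms).  The *annotation closure* rule — a species
annotated to a term is annotated to all of the term's ancestors — is applied
on demand.

An "edge" is either one ``is_a`` link between terms or one direct
species-to-term association; closure edges are not counted.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .nomenclature import (
    ESTER,
    ETHER_O,
    ETHER_P,
    MOLECULAR_SPECIES,
    SPHINGOID_D,
    SUM_COMPOSITION,
    FattyAcyl,
    LipidSpecies,
    canonical_name,
)

__all__ = [
    "LipidOntologyError",
    "OntologyTerm",
    "LipidClassRule",
    "Ontology",
    "DEFAULT_FATTY_ACIDS",
    "DEFAULT_SPHINGOID_BASES",
    "load_class_rules",
    "default_class_rules",
    "enumerate_species",
    "infer_chemical_terms",
    "infer_chemical_term_names",
    "build_ontology",
    "prune_redundant_parents",
    "read_obo",
    "write_obo",
    "term_id_for_name",
]


class LipidOntologyError(Exception):
    """Structural problem in the ontology (cycle, unknown term, bad stanza)."""


BRANCH_CLASSIFICATION = "lipid_classification"
BRANCH_CHEMPHYS = "chemical_physical_properties"
BRANCH_FUNCTION = "function"
BRANCH_COMPONENT = "cellular_component"

#: Branch-root and subcategory ("CAT") terms: name -> (id, branch, parent name).
_CAT_TERMS: dict[str, tuple[str, str, str | None]] = {
    "lipid classification": ("CAT:0000001", BRANCH_CLASSIFICATION, None),
    "chemical and physical properties": ("CAT:0000002", BRANCH_CHEMPHYS, None),
    "function": ("CAT:0000003", BRANCH_FUNCTION, None),
    "cellular component": ("CAT:0000004", BRANCH_COMPONENT, None),
    "contains fatty acid": ("CAT:0000100", BRANCH_CHEMPHYS, "chemical and physical properties"),
    "fatty acid length": ("CAT:0000110", BRANCH_CHEMPHYS, "chemical and physical properties"),
    "fatty acid unsaturation": ("CAT:0000120", BRANCH_CHEMPHYS, "chemical and physical properties"),
    "type by bond": ("CAT:0000130", BRANCH_CHEMPHYS, "chemical and physical properties"),
    "intrinsic curvature": ("CAT:0000140", BRANCH_CHEMPHYS, "chemical and physical properties"),
    "charge headgroup": ("CAT:0000150", BRANCH_CHEMPHYS, "chemical and physical properties"),
    "chain-melting transition temperature": ("CAT:0000160", BRANCH_CHEMPHYS, "chemical and physical properties"),
    "bilayer thickness": ("CAT:0000170", BRANCH_CHEMPHYS, "chemical and physical properties"),
    "lateral diffusion": ("CAT:0000180", BRANCH_CHEMPHYS, "chemical and physical properties"),
}

_CHARGE_TERMS = {
    "negative": "headgroup with negative charge",
    "positive_zwitterion": "headgroup with positive charge / zwitter-ion",
    "neutral": "neutral headgroup",
}
_CURVATURE_TERMS = {
    "negative": "negative intrinsic curvature",
    "neutral": "neutral intrinsic curvature",
    "positive": "positive intrinsic curvature",
}
_BOND_BY_POSITIONS = {1: "monoacyl", 2: "diacyl", 3: "triacyl", 4: "tetraacyl"}

#: Biophysical properties and the human-readable label used in term names.
PROPERTY_LABELS = {
    "transition_temperature": "transition temperature",
    "bilayer_thickness": "bilayer thickness",
    "lateral_diffusion": "lateral diffusion",
}
#: CAT parent term of each property's category terms.
PROPERTY_CAT_PARENT = {
    "transition_temperature": "chain-melting transition temperature",
    "bilayer_thickness": "bilayer thickness",
    "lateral_diffusion": "lateral diffusion",
}
CATEGORY_NAMES = ("very low", "low", "average", "high", "very high")

#: The default fatty-acid alphabet (37 chains): (carbons, double bonds).
DEFAULT_FATTY_ACIDS: tuple[tuple[int, int], ...] = tuple(
    (c, db)
    for c, dbs in (
        (12, (0,)),
        (14, (0, 1)),
        (16, (0, 1)),
        (18, (0, 1, 2, 3)),
        (20, (0, 1, 2, 3, 4, 5)),
        (22, (0, 1, 2, 3, 4, 5, 6)),
        (24, (0, 1, 2, 3, 4, 5, 6)),
        (26, (0, 1, 2, 3, 4, 5, 6, 7)),
    )
    for db in dbs
)

#: Sphingosine (d18:1) and sphinganine (d18:0) backbones.
DEFAULT_SPHINGOID_BASES: tuple[FattyAcyl, ...] = (
    FattyAcyl(18, 0, SPHINGOID_D),
    FattyAcyl(18, 1, SPHINGOID_D),
)


def term_id_for_name(name: str) -> str:
    """Deterministic term id for a generated (non-CAT) term."""
    if name in _CAT_TERMS:
        return _CAT_TERMS[name][0]
    digest = hashlib.blake2b(name.encode("utf-8"), digest_size=4).hexdigest()
    return f"LPO:{digest}"


@dataclass(frozen=True)
class OntologyTerm:
    """A node of the ontology DAG."""

    term_id: str
    name: str
    parents: frozenset[str]
    branch: str | None = None

    @property
    def is_category(self) -> bool:
        return self.term_id.startswith("CAT")


@dataclass(frozen=True)
class LipidClassRule:
    """Construction rule for one lipid class."""

    class_id: str
    name: str
    n_acyl_positions: int
    backbone: str  # glycerol | sphingoid | sterol | none
    linkage: str  # ester | ether_O | ether_P (applies to the first chain)
    classification_parents: tuple[str, ...]
    headgroup_charge: str  # negative | positive_zwitterion | neutral
    curvature: str | None  # negative | neutral | positive | None
    function_terms: tuple[str, ...]
    component_terms: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_acyl_positions < 0:
            raise ValueError("n_acyl_positions must be >= 0")
        if self.backbone == "sphingoid" and self.n_acyl_positions < 1:
            raise ValueError("sphingoid classes need at least the base position")

    @property
    def ether_prefix(self) -> str:
        return {ETHER_O: "O-", ETHER_P: "P-"}.get(self.linkage, "")

    @property
    def bond_type_term(self) -> str:
        if self.backbone == "sphingoid":
            return "sphingoid amide bond"
        if self.linkage == ETHER_O:
            return "ether bond"
        if self.linkage == ETHER_P:
            return "vinyl ether bond"
        return _BOND_BY_POSITIONS.get(self.n_acyl_positions, "polyacyl")


def load_class_rules(path) -> list[LipidClassRule]:
    """Load lipid class rules from the versioned CSV table."""
    import csv

    rules = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            rules.append(
                LipidClassRule(
                    class_id=row["class_id"],
                    name=row["name"],
                    n_acyl_positions=int(row["n_acyl_positions"]),
                    backbone=row["backbone"],
                    linkage=row["linkage"],
                    classification_parents=tuple(
                        p.strip() for p in row["classification_parents"].split(">")
                    ),
                    headgroup_charge=row["headgroup_charge"],
                    curvature=row["curvature"].strip() or None,
                    function_terms=tuple(
                        t.strip() for t in row["function_terms"].split(";") if t.strip()
                    ),
                    component_terms=tuple(
                        t.strip() for t in row["component_terms"].split(";") if t.strip()
                    ),
                )
            )
    return rules


def default_class_rules() -> list[LipidClassRule]:
    """The mammalian class-rule set shipped with the package."""
    ref = resources.files("lipidont").joinpath("data/class_rules.csv")
    with resources.as_file(ref) as path:
        return load_class_rules(path)


class Ontology:
    """Terms, species and annotations of a lipid ontology.

    Parameters
    ----------
    terms
        Mapping term_id -> :class:`OntologyTerm`.
    species
        Mapping canonical name -> :class:`LipidSpecies`.
    annotations
        Mapping canonical name -> tuple of directly associated term ids.
    rules
        Optional class rules the species were enumerated from.
    """

    def __init__(
        self,
        terms: Mapping[str, OntologyTerm],
        species: Mapping[str, LipidSpecies] | None = None,
        annotations: Mapping[str, tuple[str, ...]] | None = None,
        rules: Sequence[LipidClassRule] | None = None,
    ) -> None:
        self.terms: dict[str, OntologyTerm] = dict(terms)
        self.species: dict[str, LipidSpecies] = dict(species or {})
        self.annotations: dict[str, tuple[str, ...]] = dict(annotations or {})
        self.rules = list(rules or [])
        self._name_index = {t.name: t.term_id for t in self.terms.values()}
        self._ancestor_cache: dict[str, frozenset[str]] = {}
        self._children: dict[str, set[str]] | None = None
        self._term_species: dict[str, set[str]] | None = None
        self._check_structure()

    # -- structure ---------------------------------------------------------

    def _check_structure(self) -> None:
        for tid, term in self.terms.items():
            for p in term.parents:
                if p not in self.terms:
                    raise LipidOntologyError(f"term {tid} has unknown parent {p}")
        for name, tids in self.annotations.items():
            for tid in tids:
                if tid not in self.terms:
                    raise LipidOntologyError(
                        f"species {name!r} references unknown term {tid}"
                    )
        graph = self.term_graph()
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise LipidOntologyError(f"ontology contains a cycle: {cycle}")

    def term_graph(self) -> nx.DiGraph:
        """Directed graph with edges child -> parent."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for tid, term in self.terms.items():
            for p in term.parents:
                g.add_edge(tid, p)
        return g

    @property
    def edge_count(self) -> int:
        """is_a links plus direct (pre-closure) species associations."""
        n_isa = sum(len(t.parents) for t in self.terms.values())
        n_assoc = sum(len(a) for a in self.annotations.values())
        return n_isa + n_assoc

    def term_by_name(self, name: str) -> OntologyTerm:
        try:
            return self.terms[self._name_index[name]]
        except KeyError:
            raise LipidOntologyError(f"no term named {name!r}") from None

    def resolve_term(self, key: str) -> str:
        """Resolve a term id or term name to a term id."""
        if key in self.terms:
            return key
        if key in self._name_index:
            return self._name_index[key]
        raise LipidOntologyError(f"unknown term {key!r}")

    # -- closure -----------------------------------------------------------

    def ancestors(self, term_id: str) -> frozenset[str]:
        """Transitive closure over parent links (the term itself excluded)."""
        if term_id not in self.terms:
            raise LipidOntologyError(f"unknown term {term_id!r}")
        cached = self._ancestor_cache.get(term_id)
        if cached is not None:
            return cached
        out: set[str] = set()
        for p in self.terms[term_id].parents:
            out.add(p)
            out |= self.ancestors(p)
        result = frozenset(out)
        self._ancestor_cache[term_id] = result
        return result

    def descendants(self, term_id: str) -> frozenset[str]:
        """All terms whose ancestor set contains ``term_id``."""
        if self._children is None:
            children: dict[str, set[str]] = {tid: set() for tid in self.terms}
            for tid, term in self.terms.items():
                for p in term.parents:
                    children[p].add(tid)
            self._children = children
        if term_id not in self.terms:
            raise LipidOntologyError(f"unknown term {term_id!r}")
        out: set[str] = set()
        stack = [term_id]
        while stack:
            for child in self._children[stack.pop()]:
                if child not in out:
                    out.add(child)
                    stack.append(child)
        return frozenset(out)

    def closed_annotations(self, species_name: str) -> frozenset[str]:
        """Direct annotations of a species plus all their ancestors."""
        tids = self.annotations.get(species_name)
        if tids is None:
            raise LipidOntologyError(f"unknown species {species_name!r}")
        out: set[str] = set(tids)
        for tid in tids:
            out |= self.ancestors(tid)
        return frozenset(out)

    def species_of_term(self, term_id: str) -> frozenset[str]:
        """All species whose closed annotation set contains the term."""
        if term_id not in self.terms:
            raise LipidOntologyError(f"unknown term {term_id!r}")
        if self._term_species is None:
            index: dict[str, set[str]] = {}
            for name in self.annotations:
                for tid in self.closed_annotations(name):
                    index.setdefault(tid, set()).add(name)
            self._term_species = index
        return frozenset(self._term_species.get(term_id, ()))

    # -- mutation used by the biophysics layer ------------------------------

    def add_terms(self, new_terms: Iterable[OntologyTerm]) -> None:
        for term in new_terms:
            if term.term_id in self.terms:
                continue
            for p in term.parents:
                if p not in self.terms:
                    raise LipidOntologyError(
                        f"term {term.term_id} has unknown parent {p}"
                    )
            self.terms[term.term_id] = term
            self._name_index[term.name] = term.term_id
        self._ancestor_cache.clear()
        self._children = None
        self._term_species = None

    def add_annotations(self, extra: Mapping[str, Iterable[str]]) -> None:
        """Append direct species -> term associations (deduplicated)."""
        for name, tids in extra.items():
            if name not in self.species:
                raise LipidOntologyError(f"unknown species {name!r}")
            tids = tuple(tids)
            for tid in tids:
                if tid not in self.terms:
                    raise LipidOntologyError(
                        f"species {name!r} references unknown term {tid}"
                    )
            merged = dict.fromkeys(self.annotations.get(name, ()) + tids)
            self.annotations[name] = tuple(merged)
        self._term_species = None


def enumerate_species(
    rules: Sequence[LipidClassRule],
    fatty_acids: Sequence[tuple[int, int]] | None = None,
    sphingoid_bases: Sequence[FattyAcyl] | None = None,
) -> list[LipidSpecies]:
    """Enumerate all lipid species implied by the class rules.

    For each class the molecular-species layer contains every unordered
    multiset of ``n_acyl_positions`` chains drawn with repetition from the
    fatty-acid alphabet (sphingoid classes take one base plus
    ``n_acyl_positions - 1`` acyls).  A sum-composition layer over distinct
    (total carbons, total double bonds) pairs is added for classes with at
    least two chain positions; one-chain classes render identically at both
    levels, so no sum layer is emitted for them.
    """
    if fatty_acids is None:
        fatty_acids = DEFAULT_FATTY_ACIDS
    if not fatty_acids:
        raise ValueError("fatty-acid alphabet must be non-empty")
    if sphingoid_bases is None:
        sphingoid_bases = DEFAULT_SPHINGOID_BASES
    alphabet = sorted(fatty_acids)

    out: list[LipidSpecies] = []
    for rule in rules:
        n = rule.n_acyl_positions
        sphingo = rule.backbone == "sphingoid"
        n_acyl = n - 1 if sphingo else n
        chain_sets: list[tuple[FattyAcyl, ...]] = []
        for combo in itertools.combinations_with_replacement(alphabet, n_acyl):
            acyls = [FattyAcyl(c, db, ESTER) for c, db in combo]
            if rule.linkage in (ETHER_O, ETHER_P) and acyls:
                acyls[0] = FattyAcyl(combo[0][0], combo[0][1], rule.linkage)
            if sphingo:
                for base in sphingoid_bases:
                    chain_sets.append((base, *acyls))
            else:
                chain_sets.append(tuple(acyls))
        sums: set[tuple[int, int]] = set()
        n_chains = n_acyl + (1 if sphingo else 0)
        for chains in chain_sets:
            tc = sum(a.carbons for a in chains)
            tdb = sum(a.double_bonds for a in chains)
            out.append(
                LipidSpecies(
                    rule.class_id,
                    MOLECULAR_SPECIES,
                    chains,
                    tc,
                    tdb,
                    sphingoid=sphingo,
                    ether_prefix=rule.ether_prefix,
                )
            )
            sums.add((tc, tdb))
        if n_chains >= 2:
            for tc, tdb in sorted(sums):
                out.append(
                    LipidSpecies(
                        rule.class_id,
                        SUM_COMPOSITION,
                        (),
                        tc,
                        tdb,
                        sphingoid=sphingo,
                        ether_prefix=rule.ether_prefix,
                    )
                )
    return out


def infer_chemical_term_names(species: LipidSpecies) -> set[str]:
    """Chemical-description term names read off a species name.

    Molecular species contribute one "contains CX:Y" term per distinct
    (non-sphingoid) chain; both levels contribute a total-length and a
    total-unsaturation term; a bond-type term is included whenever it is
    derivable from the name alone (chain count, ether prefix, sphingoid base).
    """
    names: set[str] = {
        f"total fatty acid length C{species.total_carbons}",
        f"total fatty acid unsaturation {species.total_double_bonds}",
    }
    if species.level == MOLECULAR_SPECIES:
        for acyl in species.acyls:
            if not acyl.is_sphingoid:
                names.add(f"contains C{acyl.carbons}:{acyl.double_bonds}")
    if species.ether_prefix == "O-":
        names.add("ether bond")
    elif species.ether_prefix == "P-":
        names.add("vinyl ether bond")
    elif species.sphingoid:
        names.add("sphingoid amide bond")
    elif species.level == MOLECULAR_SPECIES:
        names.add(_BOND_BY_POSITIONS.get(len(species.acyls), "polyacyl"))
    return names


def infer_chemical_terms(species: LipidSpecies) -> set[str]:
    """Chemical-description term ids for a species (see the names variant)."""
    return {term_id_for_name(n) for n in infer_chemical_term_names(species)}


def _category_term_names(property_name: str) -> list[str]:
    label = PROPERTY_LABELS[property_name]
    return [f"{cat} {label}" for cat in CATEGORY_NAMES]


def build_ontology(
    rules: Sequence[LipidClassRule],
    fatty_acids: Sequence[tuple[int, int]] | None = None,
    property_assignments: Mapping[str, Iterable[str]] | None = None,
    sphingoid_bases: Sequence[FattyAcyl] | None = None,
) -> Ontology:
    """Assemble the four-branch ontology DAG with species annotations.

    Parameters
    ----------
    rules
        Lipid class rules (see :func:`default_class_rules`).
    fatty_acids
        Fatty-acid alphabet as (carbons, double bonds) pairs; the 37-entry
        default covers C12-C26 chains.
    property_assignments
        Optional mapping canonical species name -> iterable of biophysical
        category term *names* (e.g. ``"very low transition temperature"``).
        When given, all five category terms of every referenced property are
        created under the property's CAT term.
    sphingoid_bases
        Sphingoid backbones; defaults to d18:0 and d18:1.
    """
    if not rules:
        raise ValueError("rules must be non-empty")
    terms: dict[str, OntologyTerm] = {}
    name_to_id: dict[str, str] = {}

    def add(name: str, parents: Iterable[str], branch: str, term_id: str | None = None) -> str:
        tid = term_id or term_id_for_name(name)
        if name in name_to_id:
            return name_to_id[name]
        parent_ids = frozenset(name_to_id[p] for p in parents)
        terms[tid] = OntologyTerm(tid, name, parent_ids, branch)
        name_to_id[name] = tid
        return tid

    for cat_name, (cat_id, branch, parent) in _CAT_TERMS.items():
        add(cat_name, [parent] if parent else [], branch, term_id=cat_id)
    for name in _CHARGE_TERMS.values():
        add(name, ["charge headgroup"], BRANCH_CHEMPHYS)
    for name in _CURVATURE_TERMS.values():
        add(name, ["intrinsic curvature"], BRANCH_CHEMPHYS)
    for name in ("monoacyl", "diacyl", "triacyl", "tetraacyl", "polyacyl",
                 "ether bond", "vinyl ether bond", "sphingoid amide bond"):
        add(name, ["type by bond"], BRANCH_CHEMPHYS)

    for rule in rules:
        parent = "lipid classification"
        for lineage_name in rule.classification_parents:
            add(lineage_name, [parent], BRANCH_CLASSIFICATION)
            parent = lineage_name
        for fname in rule.function_terms:
            add(fname, ["function"], BRANCH_FUNCTION)
        for cname in rule.component_terms:
            add(cname, ["cellular component"], BRANCH_COMPONENT)

    species_list = enumerate_species(rules, fatty_acids, sphingoid_bases)
    rule_by_class = {r.class_id: r for r in rules}

    # Static per-class annotation ids (everything that does not depend on the
    # chain composition).
    static_ids: dict[str, tuple[str, ...]] = {}
    for rule in rules:
        ids = [name_to_id[rule.classification_parents[-1]]]
        ids.append(name_to_id[_CHARGE_TERMS[rule.headgroup_charge]])
        if rule.curvature:
            ids.append(name_to_id[_CURVATURE_TERMS[rule.curvature]])
        ids.extend(name_to_id[f] for f in rule.function_terms)
        ids.extend(name_to_id[c] for c in rule.component_terms)
        ids.append(name_to_id[rule.bond_type_term])
        static_ids[rule.class_id] = tuple(dict.fromkeys(ids))

    contains_ids: dict[tuple[int, int], str] = {}
    length_ids: dict[int, str] = {}
    unsat_ids: dict[int, str] = {}

    def contains_id(c: int, db: int) -> str:
        tid = contains_ids.get((c, db))
        if tid is None:
            tid = add(f"contains C{c}:{db}", ["contains fatty acid"], BRANCH_CHEMPHYS)
            contains_ids[(c, db)] = tid
        return tid

    def length_id(tc: int) -> str:
        tid = length_ids.get(tc)
        if tid is None:
            tid = add(f"total fatty acid length C{tc}", ["fatty acid length"], BRANCH_CHEMPHYS)
            length_ids[tc] = tid
        return tid

    def unsat_id(tdb: int) -> str:
        tid = unsat_ids.get(tdb)
        if tid is None:
            tid = add(f"total fatty acid unsaturation {tdb}", ["fatty acid unsaturation"],
                      BRANCH_CHEMPHYS)
            unsat_ids[tdb] = tid
        return tid

    species: dict[str, LipidSpecies] = {}
    annotations: dict[str, tuple[str, ...]] = {}
    for sp in species_list:
        cname = canonical_name(sp)
        if cname in species:
            raise LipidOntologyError(f"duplicate species {cname!r}")
        species[cname] = sp
        ids = [length_id(sp.total_carbons), unsat_id(sp.total_double_bonds)]
        if sp.level == MOLECULAR_SPECIES:
            seen: set[tuple[int, int]] = set()
            for acyl in sp.acyls:
                key = (acyl.carbons, acyl.double_bonds)
                if not acyl.is_sphingoid and key not in seen:
                    seen.add(key)
                    ids.append(contains_id(*key))
        ids.extend(static_ids[sp.lipid_class])
        annotations[cname] = tuple(dict.fromkeys(ids))

    ontology = Ontology(terms, species, annotations, rules=rules)
    if property_assignments:
        attach_property_assignments(ontology, property_assignments)
    return ontology


def attach_property_assignments(
    ontology: Ontology,
    property_assignments: Mapping[str, Iterable[str]],
) -> None:
    """Attach biophysical category term annotations to an ontology in place.

    ``property_assignments`` maps canonical species names to category term
    names of the form ``"<category> <property label>"``.  All five category
    terms of every property that occurs are created.
    """
    valid_names: dict[str, str] = {}
    for prop, label in PROPERTY_LABELS.items():
        for term_name in _category_term_names(prop):
            valid_names[term_name] = prop
    referenced_props: set[str] = set()
    for names in property_assignments.values():
        for term_name in names:
            prop = valid_names.get(term_name)
            if prop is None:
                raise LipidOntologyError(
                    f"unknown biophysical category term {term_name!r}"
                )
            referenced_props.add(prop)
    new_terms = []
    for prop in sorted(referenced_props):
        parent_id = ontology.resolve_term(PROPERTY_CAT_PARENT[prop])
        for term_name in _category_term_names(prop):
            new_terms.append(
                OntologyTerm(term_id_for_name(term_name), term_name,
                         frozenset([parent_id]), BRANCH_CHEMPHYS)
            )
    ontology.add_terms(new_terms)
    ontology.add_annotations(
        {
            name: tuple(term_id_for_name(t) for t in term_names)
            for name, term_names in property_assignments.items()
        }
    )


def prune_redundant_parents(
    ontology: Ontology,
    candidate_terms: set[str],
    universe: set[str] | None = None,
) -> set[str]:
    """Drop the most generic term of ancestor/descendant pairs with equal
    annotated species sets; only the most specific term survives.

    ``universe`` optionally restricts the species sets compared (as during an
    enrichment run, where only matched species matter).
    """
    unknown = [t for t in candidate_terms if t not in ontology.terms]
    if unknown:
        raise LipidOntologyError(f"unknown terms in candidate set: {unknown}")

    def annotated(tid: str) -> frozenset[str]:
        sp = ontology.species_of_term(tid)
        return sp & frozenset(universe) if universe is not None else sp

    sets = {tid: annotated(tid) for tid in candidate_terms}
    dropped: set[str] = set()
    for tid in candidate_terms:
        for anc in ontology.ancestors(tid) & candidate_terms:
            if sets[anc] == sets[tid]:
                dropped.add(anc)
    return set(candidate_terms) - dropped


# -- OBO input/output -------------------------------------------------------


def write_obo(ontology: Ontology, path, include_species: bool = True) -> None:
    """Write the ontology as OBO 1.2 ([Term] stanzas with is_a links).

    Species are written as terms whose ``is_a`` links are their direct
    annotations, mirroring how species live in published lipid-ontology files.
    """
    lines = ["format-version: 1.2", "ontology: lipidont", ""]
    for tid in sorted(ontology.terms):
        term = ontology.terms[tid]
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {term.name}")
        if term.branch:
            lines.append(f"namespace: {term.branch}")
        for p in sorted(term.parents):
            lines.append(f"is_a: {p} ! {ontology.terms[p].name}")
        lines.append("")
    if include_species:
        for name in sorted(ontology.species):
            lines.append("[Term]")
            lines.append(f"id: {name}")
            lines.append(f"name: {name}")
            lines.append("namespace: lipid_species")
            for tid in ontology.annotations.get(name, ()):
                lines.append(f"is_a: {tid} ! {ontology.terms[tid].name}")
            lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))


def _prescan_obo(path) -> None:
    """Light validation pass reporting malformed stanzas with line numbers."""
    with open(path, encoding="utf-8") as fh:
        in_term = False
        has_id = False
        start = 0
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if stripped == "[Term]":
                if in_term and not has_id:
                    raise LipidOntologyError(
                        f"malformed [Term] stanza without id at line {start}"
                    )
                in_term, has_id, start = True, False, lineno
            elif in_term and stripped.startswith("id:"):
                if not stripped[3:].strip():
                    raise LipidOntologyError(f"empty id at line {lineno}")
                has_id = True
        if in_term and not has_id:
            raise LipidOntologyError(f"malformed [Term] stanza without id at line {start}")


def read_obo(path) -> Ontology:
    """Read an OBO file into an ontology skeleton (terms and is_a links only).

    Species stanzas, if present, are read back as plain terms; annotations are
    not reconstructed.  Cycles raise :class:`LipidOntologyError`.
    """
    import obonet

    _prescan_obo(path)
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # pragma: no cover - parser-specific messages
        raise LipidOntologyError(f"failed to parse OBO file {path}: {exc}") from exc
    terms: dict[str, OntologyTerm] = {}
    for tid, data in graph.nodes(data=True):
        parents = frozenset(
            v for _, v, key in graph.out_edges(tid, keys=True) if key == "is_a"
        )
        terms[tid] = OntologyTerm(
            tid, data.get("name", tid), parents, data.get("namespace")
        )
    # Ontology.__init__ re-checks parents and acyclicity.
    return Ontology(terms)
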