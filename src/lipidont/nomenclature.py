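"""Parsing and canonicalization of lipid shorthand nomenclature.

Lipidomics software emits lipid names in a variety of closely related
shorthand dialects: ``PC(34:1)``, ``PC 34:1``, ``PC(16:0/18:1)``,
``PC(16:0_18:1)``, ``SM(d18:1/16:0)``, ``PC(O-34:1)`` and so on.  This module
parses a documented whitelist of those dialects into :class:`LipidSpecies`
objects, renders a single canonical name per species, and matches heterogeneous
input name lists against an ontology.

Conventions
-----------
* *sn*-positions are not distinguished: acyl chains are sorted by carbon count
  (ascending), then by number of double bonds (ascending).  ``PC(18:1/16:0)``
  and ``PC(16:0/18:1)`` are the same species, canonically ``PC(16:0_18:1)``.
* Sphingoid bases (``d18:0``, ``d18:1``) always come first in a name.
* Ether/plasmalogen chains carry an ``O-``/``P-`` prefix on the first chain.
* Two description levels exist: *sum composition* (total carbons and double
  bonds only, e.g. ``PS(34:2)``) and *molecular species* (individual chains,
  e.g. ``PC(16:0_18:1)``).

Names outside the whitelist are never guessed at: parsing returns an explicit
:class:`Unmatched` record carrying the reason.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .ontology import Ontology

__all__ = [
    "ESTER",
    "ETHER_O",
    "ETHER_P",
    "SPHINGOID_D",
    "FattyAcyl",
    "LipidSpecies",
    "Unmatched",
    "MatchReport",
    "parse_lipid_name",
    "canonical_name",
    "match_names",
    "read_name_list",
    "DEFAULT_SYNONYMS",
]

# Linkage kinds for a chain.
ESTER = "ester"
ETHER_O = "ether_O"  # alkyl ether (O-)
ETHER_P = "ether_P"  # vinyl ether / plasmalogen (P-)
SPHINGOID_D = "sphingoid_d"  # sphingoid long-chain base (d prefix)

SUM_COMPOSITION = "sum_composition"
MOLECULAR_SPECIES = "molecular_species"

#: Supported sphingoid long-chain bases: sphinganine d18:0 and sphingosine d18:1.
SPHINGOID_BASES = ((18, 0), (18, 1))


@dataclass(frozen=True, order=True)
class FattyAcyl:
    """A single fatty acyl chain (or sphingoid base) of a lipid."""

    carbons: int
    double_bonds: int
    linkage: str = ESTER
    hydroxyl_count: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError(f"chain needs >= 2 carbons, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError("double_bonds must be >= 0")
        if self.double_bonds >= self.carbons:
            raise ValueError(
                f"{self.double_bonds} double bonds impossible on {self.carbons} carbons"
            )
        if self.linkage not in (ESTER, ETHER_O, ETHER_P, SPHINGOID_D):
            raise ValueError(f"unknown linkage {self.linkage!r}")
        if self.linkage == SPHINGOID_D:
            if (self.carbons, self.double_bonds) not in SPHINGOID_BASES:
                raise ValueError(
                    "supported sphingoid bases are d18:0 and d18:1, "
                    f"got d{self.carbons}:{self.double_bonds}"
                )

    @property
    def is_sphingoid(self) -> bool:
        return self.linkage == SPHINGOID_D

    def shorthand(self) -> str:
        prefix = {ESTER: "", ETHER_O: "O-", ETHER_P: "P-", SPHINGOID_D: "d"}[self.linkage]
        return f"{prefix}{self.carbons}:{self.double_bonds}"


@dataclass(frozen=True)
class LipidSpecies:
    """A parsed lipid at sum-composition or molecular-species level.

    ``acyls`` is empty at sum-composition level.  At molecular-species level
    the chains are stored in canonical order (sphingoid base first, then by
    carbons ascending, double bonds ascending) and the totals are consistent
    with the chains by construction.
    """

    lipid_class: str
    level: str
    acyls: tuple[FattyAcyl, ...]
    total_carbons: int
    total_double_bonds: int
    sphingoid: bool = False
    ether_prefix: str = ""  # "", "O-" or "P-" (class-level bond type)

    def __post_init__(self) -> None:
        if self.level not in (SUM_COMPOSITION, MOLECULAR_SPECIES):
            raise ValueError(f"unknown level {self.level!r}")
        if self.level == MOLECULAR_SPECIES:
            if sum(a.carbons for a in self.acyls) != self.total_carbons:
                raise ValueError("total_carbons inconsistent with chains")
            if sum(a.double_bonds for a in self.acyls) != self.total_double_bonds:
                raise ValueError("total_double_bonds inconsistent with chains")

    @property
    def canonical_name(self) -> str:
        return canonical_name(self)

    def to_sum_composition(self) -> "LipidSpecies":
        """Collapse a molecular species onto its sum-composition parent."""
        if self.level == SUM_COMPOSITION:
            return self
        return LipidSpecies(
            lipid_class=self.lipid_class,
            level=SUM_COMPOSITION,
            acyls=(),
            total_carbons=self.total_carbons,
            total_double_bonds=self.total_double_bonds,
            sphingoid=self.sphingoid,
            ether_prefix=self.ether_prefix,
        )


@dataclass(frozen=True)
class Unmatched:
    """Explicit parse/match failure: the raw name plus a human-readable reason."""

    raw: str
    reason: str

    def __bool__(self) -> bool:  # unmatched is falsy, a species is truthy
        return False


@dataclass
class MatchReport:
    """Summary of matching a list of raw names against an ontology."""

    n_input: int
    n_matched: int
    unmatched_names: list[str]
    rows: list[dict] = field(default_factory=list)

    @property
    def matched_fraction(self) -> float:
        return self.n_matched / self.n_input if self.n_input else 0.0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.rows, columns=["raw_name", "canonical_name", "matched", "reason"]
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _sort_chains(chains: Iterable[FattyAcyl]) -> tuple[FattyAcyl, ...]:
    """Canonical chain order: sphingoid base first, then (carbons, double bonds)."""
    return tuple(
        sorted(chains, key=lambda a: (not a.is_sphingoid, a.carbons, a.double_bonds))
    )


def canonical_name(species: LipidSpecies) -> str:
    """Render the canonical shorthand name of a species.

    Molecular species list chains sorted, joined with ``_`` inside
    parentheses; sum compositions render ``CLASS(tc:tdb)``.  The function is
    idempotent under re-parsing.
    """
    # Ether classes carry an " O-"/" P-" suffix in their class id; the prefix
    # is rendered inside the parentheses instead.
    cls = species.lipid_class.removesuffix(" O-").removesuffix(" P-")
    if species.level == SUM_COMPOSITION:
        d = "d" if species.sphingoid else ""
        body = f"{species.ether_prefix}{d}{species.total_carbons}:{species.total_double_bonds}"
    else:
        chains = _sort_chains(species.acyls)
        body = "_".join(a.shorthand() for a in chains)
    return f"{cls}({body})"


# A chain token: optional d / O- / P- prefix, then carbons:double_bonds.
_CHAIN_RE = re.compile(r"^(?P<prefix>d|O-|P-)?(?P<c>\d+):(?P<db>\d+)$")
# Leading class token: letters, digits and internal spaces/hyphens not part of
# the composition.  The composition starts at '(' or at the last space before
# a chain-like token.
_NAME_RE = re.compile(
    r"^(?P<cls>[A-Za-z][A-Za-z0-9]*)\s*"
    r"(?:\((?P<paren>[^()]*)\)|\s+(?P<bare>\S.*))$"
)

#: Common vendor aliases mapped onto the class abbreviations used here.
DEFAULT_SYNONYMS: dict[str, str] = {
    "LysoPC": "LPC",
    "LysoPE": "LPE",
    "LysoPS": "LPS",
    "LysoPG": "LPG",
    "LysoPA": "LPA",
    "LysoPI": "LPI",
    "TAG": "TG",
    "DAG": "DG",
    "MAG": "MG",
    "ChE": "CE",
    "CholE": "CE",
    "GlcCer": "HexCer",
    "GalCer": "HexCer",
    "LacCer": "Hex2Cer",
}


def _parse_chain_token(token: str) -> tuple[str, int, int] | None:
    """Tokenize one chain into (linkage, carbons, double_bonds), or None."""
    m = _CHAIN_RE.match(token.strip())
    if m is None:
        return None
    c, db = int(m.group("c")), int(m.group("db"))
    if c < 2 or db >= c:
        return None
    prefix = m.group("prefix")
    linkage = {None: ESTER, "d": SPHINGOID_D, "O-": ETHER_O, "P-": ETHER_P}[prefix]
    return linkage, c, db


def parse_lipid_name(
    raw: str,
    synonyms: Mapping[str, str] | None = None,
) -> LipidSpecies | Unmatched:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Parameters
    ----------
    raw
        The raw name, e.g. ``"PC(16:0/18:1)"`` or ``"SM d18:1/16:0"``.
    synonyms
        Class-abbreviation alias table; defaults to :data:`DEFAULT_SYNONYMS`.

    Returns
    -------
    LipidSpecies or Unmatched
        A species when the name matches a supported dialect, otherwise an
        :class:`Unmatched` record with the reason — never a silent guess.

    Raises
    ------
    ValueError
        If ``raw`` is empty.
    """
    if synonyms is None:
        synonyms = DEFAULT_SYNONYMS
    if not isinstance(raw, str) or not raw.strip():
        raise ValueError("lipid name must be non-empty text")
    name = raw.strip()
    m = _NAME_RE.match(name)
    if m is None:
        return Unmatched(raw, "does not match any supported shorthand dialect")
    cls = m.group("cls")
    cls = synonyms.get(cls, cls)
    body = m.group("paren") if m.group("paren") is not None else m.group("bare")
    body = body.strip()
    if not body:
        return Unmatched(raw, "empty lipid composition")

    tokens = re.split(r"[/_]", body)
    toks = [_parse_chain_token(t) for t in tokens]
    if any(t is None for t in toks):
        bad = tokens[toks.index(None)]
        return Unmatched(raw, f"unparseable chain composition {bad.strip()!r}")

    # Class-level ether prefix: O-/P- on the first chain token only.
    ether_prefix = ""
    if toks[0][0] in (ETHER_O, ETHER_P):
        ether_prefix = "O-" if toks[0][0] == ETHER_O else "P-"
    if any(t[0] in (ETHER_O, ETHER_P) for t in toks[1:]):
        return Unmatched(raw, "ether prefix allowed on the first chain only")

    n_sphingoid = sum(t[0] == SPHINGOID_D for t in toks)
    if n_sphingoid > 1:
        return Unmatched(raw, "more than one sphingoid base")

    sphingo_class = cls in ("SM", "Cer", "HexCer", "Hex2Cer")
    # Ether classes are distinct class ids ("PC O-"); the prefix is rendered
    # inside the composition when the name is formatted.
    cls_full = f"{cls} {ether_prefix}" if ether_prefix else cls

    if len(toks) == 1:
        linkage, c, db = toks[0]
        # A lone "tc:tdb" token is a sum composition (one-chain classes render
        # identically, so matching resolves either way).  A "d" prefix marks a
        # sphingoid sum composition, e.g. SM(d34:1).
        sphingo = sphingo_class or linkage == SPHINGOID_D
        return LipidSpecies(
            cls_full, SUM_COMPOSITION, (), c, db,
            sphingoid=sphingo, ether_prefix=ether_prefix,
        )

    if n_sphingoid == 1 and toks[0][0] != SPHINGOID_D:
        return Unmatched(raw, "sphingoid base must be the first chain")
    try:
        chains = [FattyAcyl(c, db, linkage) for linkage, c, db in toks]
    except ValueError as exc:
        return Unmatched(raw, str(exc))

    ordered = _sort_chains(chains)
    # Position-blind convention: after sorting, the ether prefix attaches to
    # the first non-sphingoid chain.
    if ether_prefix:
        relinked = []
        done = False
        for ch in ordered:
            if not done and not ch.is_sphingoid:
                linkage = ETHER_O if ether_prefix == "O-" else ETHER_P
                relinked.append(FattyAcyl(ch.carbons, ch.double_bonds, linkage))
                done = True
            else:
                relinked.append(
                    FattyAcyl(ch.carbons, ch.double_bonds, ESTER)
                    if ch.linkage in (ETHER_O, ETHER_P)
                    else ch
                )
        ordered = tuple(relinked)
    return LipidSpecies(
        cls_full,
        MOLECULAR_SPECIES,
        ordered,
        sum(ch.carbons for ch in ordered),
        sum(ch.double_bonds for ch in ordered),
        sphingoid=n_sphingoid == 1,
        ether_prefix=ether_prefix,
    )


def read_name_list(path) -> list[str]:
    """Read a plain-text lipid name list (one name per line, ``#`` comments)."""
    names: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                names.append(line)
    return names


def match_names(
    raw_names: list[str],
    ontology: "Ontology",
    synonyms: Mapping[str, str] | None = None,
) -> tuple[dict[str, str], MatchReport]:
    """Match raw lipid names against the species of an ontology.

    Each name is parsed and canonicalized, then looked up among the ontology
    species.  Molecular-species names whose exact chains are not enumerated
    fall back to their sum-composition parent.  Duplicate names that collapse
    onto the same species node after canonicalization map to the same node.

    Returns
    -------
    (mapping, report)
        ``mapping`` maps each matched raw name to the canonical name of its
        ontology species node; ``report`` summarizes the match.
    """
    if not raw_names:
        raise ValueError("raw_names must be non-empty")
    mapping: dict[str, str] = {}
    rows: list[dict] = []
    unmatched: list[str] = []
    for raw in raw_names:
        parsed = parse_lipid_name(raw, synonyms=synonyms)
        if isinstance(parsed, Unmatched):
            unmatched.append(raw)
            rows.append({"raw_name": raw, "canonical_name": "", "matched": False,
                         "reason": parsed.reason})
            continue
        cname = canonical_name(parsed)
        node = None
        if cname in ontology.species:
            node = cname
        elif parsed.level == MOLECULAR_SPECIES:
            fallback = canonical_name(parsed.to_sum_composition())
            if fallback in ontology.species:
                node = fallback
        if node is None:
            unmatched.append(raw)
            rows.append({"raw_name": raw, "canonical_name": cname, "matched": False,
                         "reason": "no such species in the ontology"})
        else:
            mapping[raw] = node
            rows.append({"raw_name": raw, "canonical_name": node, "matched": True,
                         "reason": ""})
    report = MatchReport(
        n_input=len(raw_names),
        n_matched=len(raw_names) - len(unmatched),
        unmatched_names=unmatched,
        rows=rows,
    )
    return mapping, report
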