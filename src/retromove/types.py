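"""Shared domain types for the retrogene-movement analysis.

The analysis works on four kinds of objects: a gene x species matrix of
Muller-element locations with retro/parental markup (:class:`LocationMatrix`),
a gene x species matrix of signed sex-bias log-ratios with significance flags
(:class:`ExpressionMatrix`), a per-species Muller-element -> linkage map with
neo-X exceptions (:class:`MullerMap`), and ortholog families of gene models
with intron and flanking-gene structure (:class:`GeneModel`,
:class:`OrthologSet`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

MULLER_ELEMENTS = ("A", "B", "C", "D", "E", "F")

#: the 12 sequenced Drosophila species, in the conventional phylogenetic order
SPECIES_12 = (
    "Dmel", "Dsec", "Dsim", "Dyak", "Dere", "Dana",
    "Dpse", "Dper", "Dwil", "Dmoj", "Dvir", "Dgri",
)

X_LINKED = "X-linked"
AUTOSOMAL = "autosomal"

#: ordered movement classes; "X->A" means source X-linked, target autosomal
MOVEMENT_CLASSES = ("X->A", "A->X", "A->A", "X->X")


class RetromoveError(Exception):
    """Base error for this package."""


class ParseError(RetromoveError):
    """Malformed input file or cell token."""


class InferenceError(RetromoveError):
    """An event could not be inferred (no relocation, ambiguous source, ...)."""


@dataclass(frozen=True)
class LocationCell:
    """One (gene, species) entry of the location matrix.

    ``states`` holds the Muller-element symbols (or the literal ``"X"``
    marker) the copy was placed on, in file order; more than one symbol means
    an ambiguity set, an empty tuple means missing.  ``retro`` marks the cell
    as carrying the intronless (retroposed) copy, ``degraded`` a
    degenerated/partial remnant, ``secondary`` an additional independent
    retrocopy annotated in parentheses, ``footnote`` a dagger-style footnote.
    """

    states: tuple[str, ...] = ()
    retro: bool = False
    degraded: bool = False
    secondary: tuple[str, ...] = ()
    footnote: bool = False

    @property
    def missing(self) -> bool:
        return not self.states

    @property
    def state_set(self) -> frozenset[str]:
        return frozenset(self.states)


@dataclass
class LocationMatrix:
    """Gene x species Muller-element assignments with copy-type markup."""

    species: tuple[str, ...]
    cells: dict[str, dict[str, LocationCell]]  # gene -> species -> cell

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.cells)

    def cell(self, gene: str, species: str) -> LocationCell:
        return self.cells[gene][species]

    def row(self, gene: str) -> dict[str, LocationCell]:
        return self.cells[gene]

    def validate(self) -> None:
        for gene, row in self.cells.items():
            if not any(not c.missing for c in row.values()):
                raise ParseError(f"gene {gene} has no non-missing state")
            retro = {s for s, c in row.items() if c.retro and not c.missing}
            parental = {s for s, c in row.items() if not c.retro and not c.missing}
            if retro & parental:  # pragma: no cover - defensive
                raise ParseError(f"gene {gene}: retro/parental species overlap")


@dataclass
class ExpressionMatrix:
    """Gene x species signed log-ratios (positive = male-biased) + flags.

    ``values[g][s]`` is None when missing; ``significant`` is only defined
    where a value is present.  ``retro_copy`` mirrors the bold markup marking
    species that carry the retroposed copy; it is annotation only and never
    enters a computation.
    """

    species: tuple[str, ...]
    values: dict[str, dict[str, Optional[float]]]
    significant: dict[str, dict[str, bool]]
    retro_copy: dict[str, dict[str, bool]]

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.values)

    def validate(self) -> None:
        for gene in self.values:
            for sp in self.species:
                if self.values[gene][sp] is None and self.significant[gene][sp]:
                    raise ParseError(
                        f"{gene}/{sp}: significance flag without a value"
                    )


@dataclass(frozen=True)
class MullerMap:
    """Per-species mapping from Muller element to linkage class.

    Element A is X-linked in every Drosophila species; Muller D is
    ancestrally autosomal but part of a neo-X in the obscura clade
    (D. pseudoobscura / D. persimilis).
    """

    linkage: Mapping[str, Mapping[str, str]]  # species -> element -> class

    def linkage_of(self, species: str, element: str) -> str:
        try:
            return self.linkage[species][element]
        except KeyError as exc:
            raise KeyError(f"no linkage for ({species}, {element})") from exc

    def x_elements(self, species: str) -> frozenset[str]:
        return frozenset(
            e for e, lk in self.linkage[species].items() if lk == X_LINKED
        )

    def validate(self, species: Iterable[str] | None = None) -> None:
        for sp in species or self.linkage:
            if self.linkage_of(sp, "A") != X_LINKED:
                raise ValueError(f"element A must be X-linked in {sp}")


@dataclass(frozen=True)
class GeneModel:
    """A single annotated gene copy in one species.

    Coordinates are 1-based inclusive.  ``cds_introns`` counts introns inside
    the CDS span of the minimum-intron isoform; ``utr_introns`` counts introns
    falling entirely in untranslated regions of that isoform.  Flanking lists
    hold neighbouring gene IDs by coordinate order (nearest first).
    """

    species: str
    gene_id: str
    scaffold: str
    strand: str
    start: int
    end: int
    cds_introns: int
    utr_introns: int = 0
    flank_left: tuple[str, ...] = ()
    flank_right: tuple[str, ...] = ()
    degraded: bool = False

    def __post_init__(self) -> None:
        if self.cds_introns < 0 or self.utr_introns < 0:
            raise ValueError("intron counts must be non-negative")
        if self.gene_id in self.flank_left or self.gene_id in self.flank_right:
            raise ValueError("flanking lists must exclude the gene itself")

    @property
    def intronless(self) -> bool:
        return self.cds_introns == 0

    @property
    def flanks(self) -> frozenset[str]:
        return frozenset(self.flank_left) | frozenset(self.flank_right)


@dataclass
class OrthologSet:
    """One ortholog family: per-species gene-model copies (0, 1 or more)."""

    family_id: str
    members: dict[str, list[GeneModel]] = field(default_factory=dict)

    def species_with_copies(self) -> tuple[str, ...]:
        return tuple(s for s, ms in self.members.items() if ms)

    def all_models(self) -> list[GeneModel]:
        return [m for ms in self.members.values() for m in ms]


@dataclass
class OrthologCohort:
    """A collection of families plus the gene-id -> family-id lookup used to
    compare flanking genes across species."""

    families: list[OrthologSet]
    gene_to_family: dict[str, str] = field(default_factory=dict)

    def family_of_gene(self, gene_id: str) -> Optional[str]:
        return self.gene_to_family.get(gene_id)


@dataclass(frozen=True)
class MovementEvent:
    """One inferred chromosomal relocation of a retrogene."""

    gene: str
    source: str  # Muller element of the parental copy
    target: str  # Muller element of the retroposed copy
    event_branch: str  # canonical branch label, or "ambiguous"
    single_origin: bool
    basis: str  # "copy-type flags" | "parsimony-root"
    context_species: tuple[str, ...] = ()  # species carrying the derived copy
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise InferenceError(f"{self.gene}: source equals target")


@dataclass(frozen=True)
class FitchResult:
    """Minimum-change ancestral reconstruction on the species tree.

    ``node_states`` maps a node label (leaf taxon, or the sorted tuple of
    descendant taxa for internal nodes) to the set of states that node takes
    in at least one most-parsimonious reconstruction (MPR).  ``mpr_edges``
    are the parent->child branches on which some MPR places a state change,
    each labelled by the child-side node label.
    """

    node_states: Mapping[tuple[str, ...] | str, frozenset[str]]
    min_changes: int
    mpr_edges: frozenset[str]
    root_states: frozenset[str]
    multi_origin_flagged: bool = False


@dataclass(frozen=True)
class ChiSquareResult:
    observed: tuple[float, ...]
    expected: tuple[float, ...]
    categories: tuple[str, ...]
    statistic: float
    df: int
    pvalue: float
    mc_pvalue: Optional[float] = None
    mc_reps: Optional[int] = None
    mc_seed: Optional[int] = None


@dataclass(frozen=True)
class RetroCall:
    """Outcome of the retrogene screen for one ortholog family."""

    family_id: str
    candidate: bool
    intronless_census: Mapping[str, int]
    intron_bearing_census: Mapping[str, int]
    parental_lost: Optional[bool] = None
    relocation_confirmed: Optional[bool] = None
    exclusion_reason: str = "none"  # no-flanking-support | low-quality | not-retro | none
    utr_intron_flag: bool = False

    @property
    def retained(self) -> bool:
        return bool(
            self.candidate
            and self.parental_lost
            and self.relocation_confirmed
            and self.exclusion_reason == "none"
        )
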