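"""Discrete morphological character matrices.

A matrix is a taxa-by-characters grid of cells. Each cell carries a set of
integer state codes together with a *kind* that distinguishes how a
multi-state observation is to be interpreted:

``single``
    one observed state;
``polymorphic``
    the taxon genuinely exhibits every state in the set (NEXUS ``(01)``);
``uncertain``
    exactly one of the states in the set is true but which one is unknown
    (NEXUS ``{01}``);
``missing``
    no information (``?``) — scored as compatible with every state of the
    character, but tallied separately in matrix summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence


def normalize_taxon(name: str) -> str:
    """Normalize a taxon label: strip and replace whitespace with underscores.

    Tree files (newick) conventionally use underscores where data tables use
    spaces; all taxon matching in this package happens after this
    normalization.
    """
    return "_".join(str(name).split())


class CellKind(str, Enum):
    SINGLE = "single"
    POLYMORPHIC = "polymorphic"
    UNCERTAIN = "uncertain"
    MISSING = "missing"


@dataclass(frozen=True)
class Cell:
    """One matrix entry: a state set plus its interpretation.

    ``states`` is ``None`` exactly when the cell is missing.
    """

    states: frozenset | None
    kind: CellKind

    def __post_init__(self):
        if self.kind is CellKind.MISSING:
            if self.states is not None:
                raise ValueError("missing cell must have states=None")
            return
        if not self.states:
            raise ValueError(f"{self.kind.value} cell requires a non-empty state set")
        if self.kind is CellKind.SINGLE and len(self.states) != 1:
            raise ValueError("single cell must hold exactly one state")
        if self.kind in (CellKind.POLYMORPHIC, CellKind.UNCERTAIN) and len(self.states) < 2:
            raise ValueError(f"{self.kind.value} cell must hold at least two states")
        if any((not isinstance(s, int)) or s < 0 for s in self.states):
            raise ValueError("state codes must be non-negative integers")

    # -- constructors ------------------------------------------------------
    @staticmethod
    def single(state: int) -> "Cell":
        return Cell(frozenset({int(state)}), CellKind.SINGLE)

    @staticmethod
    def polymorphic(states: Iterable[int]) -> "Cell":
        return Cell(frozenset(int(s) for s in states), CellKind.POLYMORPHIC)

    @staticmethod
    def uncertain(states: Iterable[int]) -> "Cell":
        return Cell(frozenset(int(s) for s in states), CellKind.UNCERTAIN)

    @staticmethod
    def missing() -> "Cell":
        return Cell(None, CellKind.MISSING)

    # -- predicates --------------------------------------------------------
    @property
    def is_missing(self) -> bool:
        return self.kind is CellKind.MISSING

    @property
    def is_polymorphic(self) -> bool:
        return self.kind is CellKind.POLYMORPHIC

    def max_state(self) -> int:
        return -1 if self.states is None else max(self.states)


@dataclass(frozen=True)
class CharacterDefinition:
    """A single unordered multistate character.

    State codes are the integers ``0 .. n_states - 1``; ``state_labels``
    gives one description per code.
    """

    label: str
    state_labels: tuple

    def __post_init__(self):
        object.__setattr__(self, "state_labels", tuple(self.state_labels))
        if len(self.state_labels) < 2:
            raise ValueError(f"character {self.label!r} needs >= 2 states")

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    @staticmethod
    def generic(label: str, n_states: int) -> "CharacterDefinition":
        return CharacterDefinition(label, tuple(f"state{i}" for i in range(n_states)))


@dataclass(frozen=True)
class Constraint:
    """A positive monophyly constraint: the named ingroup taxa must form a clade."""

    name: str
    ingroup: frozenset

    def __post_init__(self):
        object.__setattr__(
            self, "ingroup", frozenset(normalize_taxon(t) for t in self.ingroup)
        )
        if len(self.ingroup) < 2:
            raise ValueError(f"constraint {self.name!r}: ingroup needs >= 2 taxa")

    def validate_against(self, taxa: Sequence[str]) -> None:
        taxa = set(taxa)
        stray = self.ingroup - taxa
        if stray:
            raise ValueError(
                f"constraint {self.name!r} names taxa absent from the matrix: "
                + ", ".join(sorted(stray))
            )
        if len(self.ingroup) >= len(taxa):
            raise ValueError(
                f"constraint {self.name!r} must leave at least one taxon outside the ingroup"
            )


@dataclass
class MatrixSummary:
    n_taxa: int
    n_characters: int
    missing_fraction: float
    polymorphic_fraction: float
    uncertain_fraction: float
    n_polymorphic_characters: int
    n_variable_characters: int
    n_informative_characters: int

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class CharacterMatrix:
    """Taxa × characters grid of :class:`Cell` values.

    Parameters
    ----------
    taxa : sequence of str
        Unique taxon names (normalized: internal whitespace becomes ``_``).
    characters : sequence of CharacterDefinition
    cells : nested sequence, shape (n_taxa, n_characters)
    """

    def __init__(self, taxa, characters, cells):
        self.taxa = [normalize_taxon(t) for t in taxa]
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError("duplicate taxon name(s): " + ", ".join(dupes))
        self.characters = list(characters)
        self.cells = [list(row) for row in cells]
        if len(self.cells) != len(self.taxa):
            raise ValueError(
                f"cell grid has {len(self.cells)} rows for {len(self.taxa)} taxa"
            )
        for i, row in enumerate(self.cells):
            if len(row) != len(self.characters):
                raise ValueError(
                    f"row {self.taxa[i]!r} has {len(row)} cells for "
                    f"{len(self.characters)} characters"
                )
            for j, cell in enumerate(row):
                k = self.characters[j].n_states
                if cell.max_state() >= k:
                    raise ValueError(
                        f"state code {cell.max_state()} out of range for character "
                        f"{self.characters[j].label!r} (n_states={k}) at taxon "
                        f"{self.taxa[i]!r}"
                    )
        self._index = {t: i for i, t in enumerate(self.taxa)}

    # -- basic shape -------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.characters)

    def row(self, taxon: str):
        return self.cells[self._index[normalize_taxon(taxon)]]

    def column(self, j: int):
        return [row[j] for row in self.cells]

    def __eq__(self, other):
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa == other.taxa
            and self.characters == other.characters
            and self.cells == other.cells
        )

    # -- derived views -----------------------------------------------------
    def take_characters(self, indices: Sequence[int]) -> "CharacterMatrix":
        """New matrix keeping (possibly repeated) character columns, in order.

        Repetition makes this directly usable for bootstrap resampling.
        """
        chars = [self.characters[j] for j in indices]
        cells = [[row[j] for j in indices] for row in self.cells]
        return CharacterMatrix(self.taxa, chars, cells)

    def with_taxon_order(self, taxa: Sequence[str]) -> "CharacterMatrix":
        taxa = [normalize_taxon(t) for t in taxa]
        if sorted(taxa) != sorted(self.taxa):
            raise ValueError("taxon reordering must be a permutation of the taxa")
        cells = [self.cells[self._index[t]] for t in taxa]
        return CharacterMatrix(taxa, self.characters, cells)

    def with_shuffled_rows(self, permutation: Sequence[int]) -> "CharacterMatrix":
        """Reassign data rows to taxa by ``permutation`` (tip randomization).

        Taxon *i* receives the row of taxon ``permutation[i]``; the taxon
        list itself is unchanged.
        """
        if sorted(permutation) != list(range(self.n_taxa)):
            raise ValueError("permutation must cover all row indices")
        cells = [self.cells[p] for p in permutation]
        return CharacterMatrix(self.taxa, self.characters, cells)

    # -- summaries ---------------------------------------------------------
    def summary(self) -> MatrixSummary:
        if self.n_taxa == 0 or self.n_characters == 0:
            raise ValueError("cannot summarize an empty matrix")
        total = self.n_taxa * self.n_characters
        n_missing = n_poly = n_unc = 0
        poly_chars = set()
        n_variable = n_informative = 0
        for j in range(self.n_characters):
            col = self.column(j)
            for i, c in enumerate(col):
                if c.is_missing:
                    n_missing += 1
                elif c.kind is CellKind.POLYMORPHIC:
                    n_poly += 1
                    poly_chars.add(j)
                elif c.kind is CellKind.UNCERTAIN:
                    n_unc += 1
            if self._column_is_variable(col):
                n_variable += 1
            if self._column_is_informative(col):
                n_informative += 1
        return MatrixSummary(
            n_taxa=self.n_taxa,
            n_characters=self.n_characters,
            missing_fraction=n_missing / total,
            polymorphic_fraction=n_poly / total,
            uncertain_fraction=n_unc / total,
            n_polymorphic_characters=len(poly_chars),
            n_variable_characters=n_variable,
            n_informative_characters=n_informative,
        )

    @staticmethod
    def _column_is_variable(col) -> bool:
        # variable: cannot assign one state compatible with every cell
        sets = [c.states for c in col if not c.is_missing]
        if not sets:
            return False
        common = frozenset.intersection(*sets)
        return len(common) == 0

    @staticmethod
    def _column_is_informative(col) -> bool:
        # parsimony-informative: >= 2 states each fixed in >= 2 taxa
        from collections import Counter

        counts = Counter()
        for c in col:
            if c.kind is CellKind.SINGLE:
                counts[next(iter(c.states))] += 1
        return sum(1 for v in counts.values() if v >= 2) >= 2
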