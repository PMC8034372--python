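"""Area systems, range-state spaces, and taxon range codings.

A geographic range is a non-empty subset of discrete areas, encoded as a
bitmask over an ordered :class:`AreaSet`. The default five-area system is
the study design this package emulates: A = Indian Subcontinent, B = Asia
(non-Indian Indomalaya), C = East of the Wallace Line, D = Americas,
E = Africa. The :class:`StateSpace` enumerates the ancestral range states
the models are allowed to visit: all non-empty subsets up to a maximum
cardinality, minus an explicit exclusion list (geographically implausible
combinations such as Asia plus the Americas), plus an optional null range
that acts as the absorbing state under range loss.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from paleorange.chronogram import Chronogram

__all__ = [
    "AreaSet",
    "StateSpace",
    "RangeData",
    "default_areas",
    "build_state_space",
    "load_range_codings",
    "load_exclusions",
    "parse_exclusions",
]

DEFAULT_AREA_NAMES = {
    "A": "Indian Subcontinent",
    "B": "Asia (non-Indian Indomalaya)",
    "C": "East of the Wallace Line",
    "D": "Americas",
    "E": "Africa",
}


@dataclass(frozen=True)
class AreaSet:
    """Ordered set of single-letter area codes with human-readable names."""

    codes: tuple[str, ...]
    names: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (2 <= len(self.codes) <= 16):
            raise ValueError("2-16 areas supported")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("area codes must be unique")
        for c in self.codes:
            if len(c) != 1 or not c.isalpha():
                raise ValueError(f"area code must be a single letter: {c!r}")

    def __len__(self) -> int:
        return len(self.codes)

    def bit(self, code: str) -> int:
        try:
            return 1 << self.codes.index(code)
        except ValueError:
            raise KeyError(f"unknown area code {code!r}") from None

    def mask(self, letters: Iterable[str]) -> int:
        m = 0
        for c in letters:
            m |= self.bit(c)
        return m

    def letters(self, mask: int) -> str:
        return "".join(c for i, c in enumerate(self.codes) if mask >> i & 1)


def default_areas() -> AreaSet:
    """The five-area circumtropical system (A-E)."""
    return AreaSet(tuple("ABCDE"), DEFAULT_AREA_NAMES)


def _popcount(x: int) -> int:
    return bin(x).count("1")


class StateSpace:
    """Ordered, validated set of allowed range states.

    States are bitmasks over ``areas``, ordered by cardinality then by
    ascending bitmask (lexicographic in area order); the null range, when
    included, is index 0. Excluded subsets are removed entirely: they have
    no row or column in any rate matrix built over this space.
    """

    def __init__(
        self,
        areas: AreaSet,
        states: Sequence[int],
        max_range_size: int,
        exclusions: frozenset[int],
        include_null: bool,
    ) -> None:
        self.areas = areas
        self.states = tuple(states)
        self.max_range_size = max_range_size
        self.exclusions = exclusions
        self.include_null = include_null
        self.index = {s: i for i, s in enumerate(self.states)}
        if len(self.index) != len(self.states):
            raise ValueError("duplicate states")

    def __len__(self) -> int:
        return len(self.states)

    def __contains__(self, mask: int) -> bool:
        return mask in self.index

    @property
    def nonnull_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.states) if s != 0]

    def labels(self) -> list[str]:
        return ["0" if s == 0 else self.areas.letters(s) for s in self.states]

    def cardinality(self, state_index: int) -> int:
        return _popcount(self.states[state_index])

    def mask_of(self, letters: str) -> int:
        m = self.areas.mask(letters)
        if m not in self.index:
            raise KeyError(f"range {letters!r} is not an allowed state")
        return m

    def __repr__(self) -> str:
        return (
            f"<StateSpace: {len(self)} states over {len(self.areas)} areas, "
            f"max range {self.max_range_size}>"
        )


def build_state_space(
    areas: AreaSet,
    max_range_size: int,
    exclusions: Iterable[Iterable[str]] | Iterable[str] = (),
    include_null: bool = True,
) -> StateSpace:
    """Enumerate allowed range states.

    ``exclusions`` lists subsets to drop, each as an iterable of area
    letters (or a letter string like ``"BD"``). Only the listed subsets are
    removed — supersets stay unless listed themselves.
    """
    if not (1 <= max_range_size <= len(areas)):
        raise ValueError("max_range_size must be in [1, n_areas]")
    excl = frozenset(areas.mask(e) for e in exclusions)
    if 0 in excl:
        raise ValueError("cannot exclude the empty range")
    states = [
        m
        for m in range(1, 1 << len(areas))
        if _popcount(m) <= max_range_size and m not in excl
    ]
    states.sort(key=lambda m: (_popcount(m), m))
    if include_null:
        states.insert(0, 0)
    return StateSpace(areas, states, max_range_size, excl, include_null)


class RangeData:
    """Observed tip ranges: taxon label -> allowed range state (bitmask)."""

    def __init__(self, space: StateSpace, codings: Mapping[str, int]) -> None:
        self.space = space
        for taxon, mask in codings.items():
            if mask == 0 or mask not in space:
                raise ValueError(
                    f"taxon {taxon!r}: observed range "
                    f"{space.areas.letters(mask) or '(empty)'} is not an allowed state"
                )
        self.codings = dict(codings)

    def __len__(self) -> int:
        return len(self.codings)

    def __getitem__(self, taxon: str) -> int:
        return self.codings[taxon]

    def taxa(self) -> list[str]:
        return list(self.codings)

    def taxa_per_area(self) -> dict[str, int]:
        """Number of taxa whose range includes each area (one-hot column sums)."""
        tally = {c: 0 for c in self.space.areas.codes}
        for mask in self.codings.values():
            for c in self.space.areas.letters(mask):
                tally[c] += 1
        return tally

    def max_observed_range_size(self) -> int:
        return max(_popcount(m) for m in self.codings.values())

    def validate_against(self, tree: "Chronogram", strict: bool = True) -> None:
        tips = set(tree.tip_labels)
        coded = set(self.codings)
        missing = tips - coded
        if missing:
            raise ValueError(f"tips without range codings: {sorted(missing)}")
        extra = coded - tips
        if extra:
            msg = f"codings for taxa absent from the tree: {sorted(extra)}"
            if strict:
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)


def parse_exclusions(lines: Iterable[str]) -> list[str]:
    """Parse an exclusions listing: one subset per line as a letter string."""
    out = []
    for raw in lines:
        s = raw.split("#", 1)[0].strip()
        if s:
            out.append(s)
    return out


def load_exclusions(path: str | Path) -> list[str]:
    return parse_exclusions(Path(path).read_text().splitlines())


def load_range_codings(
    path: str | Path,
    space: StateSpace,
    tree: "Chronogram | None" = None,
    strict: bool = True,
) -> RangeData:
    """Load a two-column TSV of taxon and area-letter string (e.g. ``AB``).

    Every chronogram tip must be coded; codings for absent taxa raise in
    strict mode and warn otherwise. Letters outside the area system and
    observed states on the exclusion list are always errors.
    """
    codings: dict[str, int] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'taxon<TAB>letters'")
        taxon, letters = parts[0].strip(), parts[1].strip()
        if taxon in codings:
            raise ValueError(f"{path}:{lineno}: duplicate coding for {taxon!r}")
        try:
            mask = space.areas.mask(letters)
        except KeyError as exc:
            raise ValueError(f"{path}:{lineno}: taxon {taxon!r}: {exc}") from None
        if mask == 0:
            raise ValueError(f"{path}:{lineno}: empty range for {taxon!r}")
        if mask not in space:
            raise ValueError(
                f"{path}:{lineno}: taxon {taxon!r}: range {letters!r} is excluded "
                "or exceeds the maximum range size"
            )
        codings[taxon] = mask
    data = RangeData(space, codings)
    if tree is not None:
        data.validate_against(tree, strict=strict)
    return data
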