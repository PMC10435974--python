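"""Genus trait reference: trophic group, colonizer-persister value, body weight.

Every downstream computation (trophic aggregation, maturity-type indices,
metabolic footprints) classifies genera through a :class:`TraitTable`.  The
package ships an editable fixture covering the 46-genus universe of a
kiwifruit-orchard cover-crop study (19 bacterivores, 6 fungivores, 9 plant
parasites, 12 omnivores/predators); users supply their own delimited file for
other communities via :func:`load_traits`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "TROPHIC_GROUPS",
    "GenusTraits",
    "TraitTable",
    "TraitTableError",
    "UnknownGenusError",
    "load_traits",
    "write_traits",
    "default_traits",
]

#: The four feeding-habit classes of soil nematodes.
TROPHIC_GROUPS = ("Ba", "Fu", "Pp", "Op")

_REQUIRED_COLUMNS = ("genus", "trophic_group", "cp_value", "fresh_weight_ug")


class TraitTableError(ValueError):
    """A trait table violates its format or value constraints."""


class UnknownGenusError(KeyError):
    """A genus has no record in the trait table."""

    def __init__(self, genera: Iterable[str]):
        self.genera = tuple(genera)
        super().__init__(", ".join(self.genera))

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message plain
        return f"genus not in trait table: {', '.join(self.genera)}"


@dataclass(frozen=True)
class GenusTraits:
    """Traits of one genus.

    Parameters
    ----------
    genus
        Genus name (capitalised by convention; matching is case-insensitive).
    trophic_group
        One of ``Ba`` (bacterivore), ``Fu`` (fungivore), ``Pp`` (plant
        parasite), ``Op`` (omnivore/predator).
    cp_value
        Colonizer-persister score, an integer on the 1-5 life-history scale
        (1 = extreme opportunist, 5 = persister).
    fresh_weight
        Fresh body weight of one individual in micrograms; strictly positive.
    predator
        Marks predatory taxa inside the merged Op group.  Only consulted when
        assigning c-p 2 taxa to the structure component of the faunal profile.
    """

    genus: str
    trophic_group: str
    cp_value: int
    fresh_weight: float
    predator: bool = False

    def __post_init__(self) -> None:
        if not self.genus or not str(self.genus).strip():
            raise TraitTableError("genus name must be non-empty")
        if self.trophic_group not in TROPHIC_GROUPS:
            raise TraitTableError(
                f"{self.genus}: trophic_group {self.trophic_group!r} not in "
                f"{TROPHIC_GROUPS}"
            )
        if self.cp_value not in (1, 2, 3, 4, 5):
            raise TraitTableError(
                f"{self.genus}: cp_value must be an integer in 1-5, got "
                f"{self.cp_value!r}"
            )
        if not self.fresh_weight > 0:
            raise TraitTableError(
                f"{self.genus}: fresh_weight must be > 0, got {self.fresh_weight!r}"
            )


class TraitTable:
    """An immutable collection of :class:`GenusTraits` keyed case-insensitively.

    Duplicate genus names (compared case-insensitively) are rejected.
    """

    def __init__(self, records: Iterable[GenusTraits]):
        self._records: dict[str, GenusTraits] = {}
        for rec in records:
            key = rec.genus.lower()
            if key in self._records:
                raise TraitTableError(f"duplicate genus: {rec.genus}")
            self._records[key] = rec

    def lookup(self, genus: str) -> GenusTraits:
        """Return the record for *genus*; raise :class:`UnknownGenusError` on a miss."""
        try:
            return self._records[genus.lower()]
        except KeyError:
            raise UnknownGenusError([genus]) from None

    def resolve(self, genera: Iterable[str]) -> dict[str, GenusTraits]:
        """Look up many genera at once, reporting *all* misses together."""
        hits, misses = {}, []
        for g in genera:
            rec = self._records.get(g.lower())
            if rec is None:
                misses.append(g)
            else:
                hits[g] = rec
        if misses:
            raise UnknownGenusError(misses)
        return hits

    @property
    def genera(self) -> tuple[str, ...]:
        return tuple(rec.genus for rec in self._records.values())

    def __contains__(self, genus: object) -> bool:
        return isinstance(genus, str) and genus.lower() in self._records

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[GenusTraits]:
        return iter(self._records.values())

    def __repr__(self) -> str:
        return f"TraitTable({len(self)} genera)"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genus": [r.genus for r in self],
                "trophic_group": [r.trophic_group for r in self],
                "cp_value": [r.cp_value for r in self],
                "fresh_weight_ug": [r.fresh_weight for r in self],
                "predator": [int(r.predator) for r in self],
            }
        )


def load_traits(path: str | Path) -> TraitTable:
    """Read a trait table from delimited text (comma or tab auto-detected).

    The file must carry a header with columns ``genus``, ``trophic_group``,
    ``cp_value`` and ``fresh_weight_ug``; an optional ``predator`` column
    (0/1) marks predatory taxa.  Lines starting with ``#`` are ignored.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TraitTableError(f"trait table missing column(s): {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        cp_raw = getattr(row, "cp_value")
        cp = int(cp_raw)
        if cp != cp_raw:
            raise TraitTableError(f"{row.genus}: cp_value must be an integer, got {cp_raw!r}")
        records.append(
            GenusTraits(
                genus=str(row.genus).strip(),
                trophic_group=str(row.trophic_group).strip(),
                cp_value=cp,
                fresh_weight=float(getattr(row, "fresh_weight_ug")),
                predator=bool(int(getattr(row, "predator", 0) or 0)),
            )
        )
    return TraitTable(records)


def write_traits(table: TraitTable, path: str | Path, sep: str = ",") -> None:
    """Write *table* back to delimited text, round-tripping :func:`load_traits`."""
    table.to_frame().to_csv(path, sep=sep, index=False)


def default_traits() -> TraitTable:
    """The packaged 46-genus fixture (editable reference data, not code)."""
    with resources.as_file(
        resources.files("nemafauna").joinpath("data/genus_traits.csv")
    ) as p:
        return load_traits(p)
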