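"""Nematode ecological indices: MI, PPI, WI, NCR and the faunal-profile EI/SI.

MI and PPI are c-p-weighted means, ``sum(v(i) * f(i))``, where ``v(i)`` is the
colonizer-persister value of taxon *i* and ``f(i)`` its proportion of the
free-living (MI) or plant-parasitic (PPI) abundance.  WI = (Ba+Fu)/Pp and
NCR = Ba/(Ba+Fu) describe the decomposition channels.  EI and SI locate a
sample in the faunal profile:

    EI = 100 * e / (e + b),    SI = 100 * s / (s + b)

with e, b, s weighted sums of guild abundances (guild = trophic group x c-p
class).  The guild memberships follow the faunal-profile convention: the
enrichment component is Ba1 and Fu2, the basal component Ba2 and Fu2, and the
structure component Ba3-5, Fu3-5, omnivore c-p 3-5 and predator c-p 2-5.
Note that Fu2 contributes to both e and b; with the merged
omnivore/predator (Op) group used here, Op c-p 3-5 take the structure weights
and a c-p 2 taxon enters the structure component only if its trait record is
flagged predatory.  The canonical weights (Ba1 3.2, Fu2/Ba2 0.8, c-p 3/4/5 =
1.8/3.2/5.0) are defaults; supply a :class:`GuildWeights` to override.

Undefined indices (zero denominators: no free-living taxa for MI, no plant
parasites for PPI/WI, ...) are returned as NaN — an explicit missing value,
never 0 — and should be excluded from downstream ANOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .community import CommunitySample, CommunityTable, aggregate_trophic
from .traits import GenusTraits, TraitTable

__all__ = [
    "FREE_LIVING_GROUPS",
    "GuildWeights",
    "IndexSet",
    "maturity_index",
    "plant_parasite_index",
    "wasilewska_index",
    "nematode_channel_ratio",
    "enrichment_structure_components",
    "enrichment_index",
    "structure_index",
    "compute_indices",
    "indices_table",
]

#: Trophic groups counted as free-living for the maturity index.
FREE_LIVING_GROUPS = ("Ba", "Fu", "Op")


@dataclass(frozen=True)
class GuildWeights:
    """Weights of the guilds entering the e, b and s faunal-profile components.

    Each mapping is ``(trophic_group, cp_value) -> weight``.  ``predator_cp2``
    is the structure weight given to c-p 2 taxa flagged predatory in the trait
    table (the merged Op group otherwise starts at c-p 3).
    """

    enrichment: Mapping[tuple[str, int], float] = field(
        default_factory=lambda: {("Ba", 1): 3.2, ("Fu", 2): 0.8}
    )
    basal: Mapping[tuple[str, int], float] = field(
        default_factory=lambda: {("Ba", 2): 0.8, ("Fu", 2): 0.8}
    )
    structure: Mapping[tuple[str, int], float] = field(
        default_factory=lambda: {
            (g, cp): {3: 1.8, 4: 3.2, 5: 5.0}[cp]
            for g in ("Ba", "Fu", "Op")
            for cp in (3, 4, 5)
        }
    )
    predator_cp2: float = 0.8

    def __post_init__(self) -> None:
        for name in ("enrichment", "basal", "structure"):
            w = getattr(self, name)
            if any(v <= 0 for v in w.values()):
                raise ValueError(f"{name} weights must be > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "GuildWeights":
        """Read overrides from delimited text with columns component, group, cp, weight."""
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        base = cls()
        maps = {
            "enrichment": dict(base.enrichment),
            "basal": dict(base.basal),
            "structure": dict(base.structure),
        }
        for row in df.itertuples(index=False):
            maps[str(row.component)][(str(row.group), int(row.cp))] = float(row.weight)
        return cls(**maps)


@dataclass
class IndexSet:
    """The per-sample index values; NaN marks an undefined index."""

    MI: float
    PPI: float
    WI: float
    NCR: float
    EI: float
    SI: float
    e: float
    b: float
    s: float

    def as_dict(self) -> dict[str, float]:
        return dict(self.__dict__)


def _resolved(sample: CommunitySample, traits: TraitTable) -> dict[str, tuple[float, GenusTraits]]:
    present = {g: a for g, a in sample.abundance.items() if a > 0}
    recs = traits.resolve(present)
    return {g: (a, recs[g]) for g, a in present.items()}


def _cp_weighted_mean(items: list[tuple[float, int]]) -> float:
    total = sum(a for a, _ in items)
    if total <= 0:
        return math.nan
    return sum(a * cp for a, cp in items) / total


def maturity_index(
    sample: CommunitySample, traits: TraitTable, include_cp1: bool = True
) -> float:
    """Maturity index over free-living (Ba, Fu, Op) taxa on the c-p 1-5 scale.

    ``include_cp1=False`` gives the MI2-5 variant (c-p 1 opportunists
    excluded, proportions renormalised).  NaN when no qualifying abundance.
    """
    items = [
        (a, r.cp_value)
        for a, r in _resolved(sample, traits).values()
        if r.trophic_group in FREE_LIVING_GROUPS and (include_cp1 or r.cp_value >= 2)
    ]
    return _cp_weighted_mean(items)


def plant_parasite_index(sample: CommunitySample, traits: TraitTable) -> float:
    """The same c-p-weighted mean restricted to plant-parasitic (Pp) taxa."""
    items = [
        (a, r.cp_value)
        for a, r in _resolved(sample, traits).values()
        if r.trophic_group == "Pp"
    ]
    return _cp_weighted_mean(items)


def wasilewska_index(Ba: float, Fu: float, Pp: float) -> float:
    """(Ba + Fu) / Pp — microbial-feeding vs plant-feeding nematodes."""
    if Pp <= 0:
        return math.nan
    return (Ba + Fu) / Pp


def nematode_channel_ratio(Ba: float, Fu: float) -> float:
    """Ba / (Ba + Fu) — the share of the bacterial decomposition channel."""
    if Ba + Fu <= 0:
        return math.nan
    return Ba / (Ba + Fu)


def _structure_weight(rec: GenusTraits, weights: GuildWeights) -> float | None:
    if rec.cp_value == 2 and rec.predator:
        return weights.predator_cp2
    return weights.structure.get((rec.trophic_group, rec.cp_value))


def enrichment_structure_components(
    sample: CommunitySample, traits: TraitTable, weights: GuildWeights | None = None
) -> tuple[float, float, float]:
    """Weighted guild sums (e, b, s) feeding the enrichment/structure indices."""
    weights = weights or GuildWeights()
    e = b = s = 0.0
    for a, rec in _resolved(sample, traits).values():
        key = (rec.trophic_group, rec.cp_value)
        we = weights.enrichment.get(key)
        if we is not None:
            e += we * a
        wb = weights.basal.get(key)
        if wb is not None:
            b += wb * a
        ws = _structure_weight(rec, weights)
        if ws is not None:
            s += ws * a
    return e, b, s


def enrichment_index(e: float, b: float) -> float:
    """EI = 100 * e / (e + b); NaN when e + b = 0."""
    if e + b <= 0:
        return math.nan
    return 100.0 * e / (e + b)


def structure_index(s: float, b: float) -> float:
    """SI = 100 * s / (s + b); NaN when s + b = 0."""
    if s + b <= 0:
        return math.nan
    return 100.0 * s / (s + b)


def compute_indices(
    sample: CommunitySample,
    traits: TraitTable,
    weights: GuildWeights | None = None,
    include_cp1: bool = True,
) -> IndexSet:
    """All six indices plus the e/b/s components for one sample."""
    groups = aggregate_trophic(sample, traits)
    e, b, s = enrichment_structure_components(sample, traits, weights)
    return IndexSet(
        MI=maturity_index(sample, traits, include_cp1=include_cp1),
        PPI=plant_parasite_index(sample, traits),
        WI=wasilewska_index(groups["Ba"], groups["Fu"], groups["Pp"]),
        NCR=nematode_channel_ratio(groups["Ba"], groups["Fu"]),
        EI=enrichment_index(e, b),
        SI=structure_index(s, b),
        e=e,
        b=b,
        s=s,
    )


def indices_table(
    table: CommunityTable,
    traits: TraitTable,
    weights: GuildWeights | None = None,
    include_cp1: bool = True,
) -> pd.DataFrame:
    """Per-sample index table (rows = samples) for export or ANOVA."""
    rows = {}
    for sample in table:
        rows[sample.sample_id] = compute_indices(
            sample, traits, weights, include_cp1=include_cp1
        ).as_dict()
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    df.insert(0, "treatment", list(table.treatments))
    return df
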