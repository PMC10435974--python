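"""Community data model: per-100 g abundances, subsample expansion, aggregation.

Field convention: nematodes are extracted from a known mass of soil, the total
count is expressed per 100 g dry soil, and a fixed-size subsample (typically
100 individuals) is identified to genus under the microscope.  Genus-level
abundances are therefore the per-100 g total allocated proportionally to the
identified counts, and are real-valued rather than integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .traits import TROPHIC_GROUPS, TraitTable

__all__ = [
    "CommunitySample",
    "CommunityTable",
    "normalize_abundance",
    "expand_identification",
    "aggregate_trophic",
    "shannon_index",
    "read_community",
    "read_metadata",
    "write_community",
]


@dataclass
class CommunitySample:
    """One plot's genus abundances (individuals per 100 g dry soil)."""

    sample_id: str
    treatment: str
    abundance: dict[str, float]
    metadata: dict[str, float | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {g: a for g, a in self.abundance.items() if a < 0 or not math.isfinite(a)}
        if bad:
            raise ValueError(f"negative or non-finite abundances: {bad}")

    @property
    def total(self) -> float:
        return float(sum(self.abundance.values()))

    def check_resolves(self, traits: TraitTable) -> None:
        """Raise if any genus with positive abundance is missing from *traits*."""
        traits.resolve([g for g, a in self.abundance.items() if a > 0])


class CommunityTable:
    """An ordered collection of samples sharing a genus universe.

    Absent genera are zeros, not missing values: after alignment every genus
    observed anywhere has a value in every sample.
    """

    def __init__(self, samples: Iterable[CommunitySample]):
        self.samples: list[CommunitySample] = list(samples)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in community table")
        universe = sorted({g for s in self.samples for g in s.abundance})
        for s in self.samples:
            s.abundance = {g: float(s.abundance.get(g, 0.0)) for g in universe}
        self._genera = tuple(universe)

    @property
    def genera(self) -> tuple[str, ...]:
        return self._genera

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(s.sample_id for s in self.samples)

    @property
    def treatments(self) -> tuple[str, ...]:
        return tuple(s.treatment for s in self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[CommunitySample]:
        return iter(self.samples)

    def __getitem__(self, sample_id: str) -> CommunitySample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def subset(self, treatment: str) -> "CommunityTable":
        return CommunityTable(s for s in self.samples if s.treatment == treatment)

    def to_frame(self) -> pd.DataFrame:
        """Genera x samples abundance matrix."""
        return pd.DataFrame(
            {s.sample_id: [s.abundance[g] for g in self._genera] for s in self.samples},
            index=pd.Index(self._genera, name="genus"),
        )

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample genus proportions (columns sum to 1; all-zero samples stay 0)."""
        df = self.to_frame()
        totals = df.sum(axis=0)
        return df.div(totals.where(totals > 0, 1.0), axis=1)

    def metadata_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            rows.append({"sample_id": s.sample_id, "treatment": s.treatment, **s.metadata})
        return pd.DataFrame(rows).set_index("sample_id")

    @classmethod
    def from_frame(
        cls,
        abundances: pd.DataFrame,
        metadata: pd.DataFrame | None = None,
    ) -> "CommunityTable":
        """Build a table from a genera x samples frame plus optional metadata.

        *metadata* is indexed (or keyed by a ``sample_id`` column) with at
        least a ``treatment`` column; extra columns become sample covariates.
        """
        meta = None
        if metadata is not None:
            meta = metadata.copy()
            if "sample_id" in meta.columns:
                meta = meta.set_index("sample_id")
            meta.index = meta.index.astype(str)
        samples = []
        for sid in abundances.columns:
            treatment, extra = "", {}
            if meta is not None:
                row = meta.loc[str(sid)]
                treatment = str(row.get("treatment", ""))
                extra = {k: v for k, v in row.items() if k != "treatment"}
            samples.append(
                CommunitySample(
                    sample_id=str(sid),
                    treatment=treatment,
                    abundance={str(g): float(v) for g, v in abundances[sid].items()},
                    metadata=extra,
                )
            )
        return cls(samples)


def normalize_abundance(raw_count: float, dry_mass: float) -> float:
    """Convert an extracted count to individuals per 100 g dry soil.

    ``raw_count`` individuals recovered from ``dry_mass`` grams of dry soil
    scale to ``raw_count * 100 / dry_mass``.
    """
    if not dry_mass > 0:
        raise ValueError(f"dry_mass must be > 0 g, got {dry_mass}")
    if raw_count < 0:
        raise ValueError(f"raw_count must be >= 0, got {raw_count}")
    return raw_count * 100.0 / dry_mass


def expand_identification(
    total_per100g: float, identified_counts: Mapping[str, float]
) -> dict[str, float]:
    """Allocate a sample's total abundance across the identified subsample.

    Each genus receives ``total * count / subsample_total``, so genus
    abundances sum exactly to the per-100 g total.  A typical subsample is
    100 individuals.
    """
    if total_per100g < 0:
        raise ValueError("total_per100g must be >= 0")
    subtotal = float(sum(identified_counts.values()))
    if subtotal <= 0:
        if total_per100g > 0:
            raise ValueError("empty identification subsample with positive total abundance")
        return {g: 0.0 for g in identified_counts}
    return {g: total_per100g * c / subtotal for g, c in identified_counts.items()}


def aggregate_trophic(sample: CommunitySample, traits: TraitTable) -> dict[str, float]:
    """Sum genus abundances into the four trophic groups (Ba, Fu, Pp, Op).

    Every genus with positive abundance must resolve in *traits*; misses are
    reported all at once.  The four group sums partition the sample total.
    """
    present = {g: a for g, a in sample.abundance.items() if a > 0}
    resolved = traits.resolve(present)
    out = {g: 0.0 for g in TROPHIC_GROUPS}
    for genus, a in present.items():
        out[resolved[genus].trophic_group] += a
    return out


def shannon_index(abundances: Sequence[float] | Mapping[str, float]) -> float:
    """Shannon-Weiner diversity H = -sum(p_i ln p_i), natural log.

    Computed over positive entries of *abundances* (values or a genus map);
    all-zero input is undefined and raises.
    """
    vals = np.asarray(
        list(abundances.values()) if isinstance(abundances, Mapping) else list(abundances),
        dtype=float,
    )
    if np.any(vals < 0):
        raise ValueError("abundances must be non-negative")
    vals = vals[vals > 0]
    if vals.size == 0:
        raise ValueError("Shannon index undefined for an all-zero community")
    p = vals / vals.sum()
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# Delimited-text I/O (rows = genera, columns = samples; metadata keyed by
# sample_id with treatment, replicate, dry_mass_g and free covariate columns)

def read_community(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "genus"
    return df.astype(float)


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if "sample_id" not in df.columns:
        raise ValueError("metadata file must have a sample_id column")
    return df.set_index("sample_id")


def write_community(table: CommunityTable, path: str | Path, sep: str = ",") -> None:
    table.to_frame().to_csv(path, sep=sep)
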