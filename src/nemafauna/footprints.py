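"""Metabolic footprints and the functional-footprint faunal profile.

The metabolic footprint of taxon *t* estimates its carbon utilization as the
sum of a respiration term and a production term,

    F_t = N_t * (0.1 * W_t / m_t + 0.273 * W_t^0.75)

with N_t the abundance (per 100 g dry soil), W_t the fresh body weight (ug)
and m_t the c-p value.  Footprints sum within trophic groups (BaF, FuF, PpF,
OpF) and over life-history classes: the enrichment footprint Fe (c-p 1-2,
fast responders) and the structure footprint Fs (c-p 3-5, persisters)
partition the total.

The functional metabolic footprint draws a rhombus around the faunal-profile
point (SI, EI) with half-diagonals 0.5*Fs/k horizontally and 0.5*Fe/k
vertically (k a unit-conversion constant); its area summarises enrichment and
structure metabolism jointly, and the quadrant of (SI, EI) classifies the
soil food-web condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .community import CommunitySample, CommunityTable
from .indices import FREE_LIVING_GROUPS, GuildWeights, compute_indices
from .traits import TraitTable

__all__ = [
    "FootprintSet",
    "FaunalProfile",
    "QUADRAT_MEANING",
    "taxon_footprint",
    "group_footprints",
    "enrichment_structure_footprints",
    "functional_footprint",
    "classify_quadrat",
    "shoelace_area",
    "footprint_table",
    "faunal_profiles",
    "plot_faunal_profile",
]

#: Soil food-web condition read off the (SI, EI) quadrant of the faunal profile.
QUADRAT_MEANING = {
    "A": "nutrient-enriched, disturbed soil; food web disrupted (high EI, low SI)",
    "B": "soil nutrient status is better and the soil is less disturbed; "
    "the food web is mature and stable (high EI, high SI)",
    "C": "soil nutrient enrichment is poor and the environment less disturbed; "
    "structured but resource-limited food web (low EI, high SI)",
    "D": "nutrient-depleted, stressed and degraded soil food web (low EI, low SI)",
}


@dataclass
class FootprintSet:
    """Per-taxon and aggregated metabolic footprints for one sample."""

    per_taxon: dict[str, float]
    BaF: float
    FuF: float
    PpF: float
    OpF: float
    total: float
    Fe: float
    Fs: float

    def as_dict(self) -> dict[str, float]:
        return {
            "BaF": self.BaF,
            "FuF": self.FuF,
            "PpF": self.PpF,
            "OpF": self.OpF,
            "NMF": self.total,
            "Fe": self.Fe,
            "Fs": self.Fs,
        }


@dataclass
class FaunalProfile:
    """The rhombus of the functional metabolic footprint around (SI, EI)."""

    EI: float
    SI: float
    Fe: float
    Fs: float
    k: float
    vertices: tuple[tuple[float, float], ...]
    area: float
    quadrat: str

    @property
    def meaning(self) -> str:
        return QUADRAT_MEANING[self.quadrat]


def taxon_footprint(N: float, W: float, m: float) -> float:
    """Metabolic footprint N * (0.1*W/m + 0.273*W**0.75) of one taxon."""
    if N < 0:
        raise ValueError(f"abundance must be >= 0, got {N}")
    if not W > 0:
        raise ValueError(f"fresh weight must be > 0 ug, got {W}")
    if not 1 <= m <= 5:
        raise ValueError(f"c-p value must be in 1..5, got {m}")
    return N * (0.1 * W / m + 0.273 * W**0.75)


def group_footprints(sample: CommunitySample, traits: TraitTable) -> FootprintSet:
    """Per-taxon footprints summed by trophic group and by c-p life-history class.

    BaF + FuF + PpF + OpF and Fe + Fs each recover the total footprint.
    """
    present = {g: a for g, a in sample.abundance.items() if a > 0}
    recs = traits.resolve(present)
    per_taxon: dict[str, float] = {}
    groups = {"Ba": 0.0, "Fu": 0.0, "Pp": 0.0, "Op": 0.0}
    fe = fs = 0.0
    for genus, a in present.items():
        rec = recs[genus]
        f = taxon_footprint(a, rec.fresh_weight, rec.cp_value)
        per_taxon[genus] = f
        groups[rec.trophic_group] += f
        if rec.cp_value <= 2:
            fe += f
        else:
            fs += f
    return FootprintSet(
        per_taxon=per_taxon,
        BaF=groups["Ba"],
        FuF=groups["Fu"],
        PpF=groups["Pp"],
        OpF=groups["Op"],
        total=sum(per_taxon.values()),
        Fe=fe,
        Fs=fs,
    )


def enrichment_structure_footprints(
    sample: CommunitySample, traits: TraitTable, free_living_only: bool = False
) -> tuple[float, float]:
    """(Fe, Fs): footprints of c-p 1-2 and c-p 3-5 taxa.

    All taxa are included by default; ``free_living_only=True`` restricts the
    partition to Ba/Fu/Op taxa.
    """
    present = {g: a for g, a in sample.abundance.items() if a > 0}
    recs = traits.resolve(present)
    fe = fs = 0.0
    for genus, a in present.items():
        rec = recs[genus]
        if free_living_only and rec.trophic_group not in FREE_LIVING_GROUPS:
            continue
        f = taxon_footprint(a, rec.fresh_weight, rec.cp_value)
        if rec.cp_value <= 2:
            fe += f
        else:
            fs += f
    return fe, fs


def shoelace_area(vertices: Sequence[tuple[float, float]]) -> float:
    """Area of a simple polygon from its ordered vertices (shoelace formula)."""
    n = len(vertices)
    acc = 0.0
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        acc += x1 * y2 - x2 * y1
    return abs(acc) / 2.0


def classify_quadrat(EI: float, SI: float) -> str:
    """Quadrant label of the (SI, EI) faunal-profile point.

    A: EI > 50, SI <= 50; B: EI > 50, SI > 50; C: EI <= 50, SI > 50;
    D: EI <= 50, SI <= 50.  A value of exactly 50 falls in the lower
    ("<= 50") quadrant on that axis.
    """
    if not (0 <= EI <= 100 and 0 <= SI <= 100):
        raise ValueError("EI and SI must lie in [0, 100]")
    if EI > 50:
        return "B" if SI > 50 else "A"
    return "C" if SI > 50 else "D"


def functional_footprint(
    EI: float, SI: float, Fe: float, Fs: float, k: float = 1.0
) -> FaunalProfile:
    """Build the faunal-profile rhombus and its functional-footprint area.

    Vertices, connected in sequence around the centre (SI, EI):
    (SI - 0.5*Fs/k, EI), (SI, EI + 0.5*Fe/k), (SI + 0.5*Fs/k, EI),
    (SI, EI - 0.5*Fe/k).  The enclosed area — computed by the shoelace
    formula — equals Fe*Fs/(2*k**2).
    """
    if not k > 0:
        raise ValueError(f"conversion constant k must be > 0, got {k}")
    if Fe < 0 or Fs < 0:
        raise ValueError("Fe and Fs must be >= 0")
    hx = 0.5 * Fs / k
    hy = 0.5 * Fe / k
    vertices = (
        (SI - hx, EI),
        (SI, EI + hy),
        (SI + hx, EI),
        (SI, EI - hy),
    )
    # shoelace on centre-translated vertices: translation-invariant, and
    # immune to cancellation when a half-diagonal is tiny relative to (SI, EI)
    centred = ((-hx, 0.0), (0.0, hy), (hx, 0.0), (0.0, -hy))
    return FaunalProfile(
        EI=EI,
        SI=SI,
        Fe=Fe,
        Fs=Fs,
        k=k,
        vertices=vertices,
        area=shoelace_area(centred),
        quadrat=classify_quadrat(EI, SI),
    )


def footprint_table(table: CommunityTable, traits: TraitTable) -> pd.DataFrame:
    """Per-sample footprint summary (rows = samples) for export or ANOVA."""
    rows = {s.sample_id: group_footprints(s, traits).as_dict() for s in table}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    df.insert(0, "treatment", list(table.treatments))
    return df


def faunal_profiles(
    table: CommunityTable,
    traits: TraitTable,
    k: float = 1.0,
    weights: GuildWeights | None = None,
) -> dict[str, FaunalProfile]:
    """Faunal profile (EI, SI, Fe, Fs, rhombus, quadrat) for every sample."""
    out = {}
    for sample in table:
        idx = compute_indices(sample, traits, weights)
        fe, fs = enrichment_structure_footprints(sample, traits)
        out[sample.sample_id] = functional_footprint(idx.EI, idx.SI, fe, fs, k=k)
    return out


def plot_faunal_profile(profiles: dict[str, FaunalProfile], ax=None):
    """Render faunal-profile rhombi on the SI (x) vs EI (y) plane.

    Quadrant divider lines sit at 50; axes span 0-100.  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for label, prof in profiles.items():
        xs = [v[0] for v in prof.vertices] + [prof.vertices[0][0]]
        ys = [v[1] for v in prof.vertices] + [prof.vertices[0][1]]
        (line,) = ax.plot(xs, ys, alpha=0.8)
        ax.plot([prof.SI], [prof.EI], "o", color=line.get_color(), label=label)
    ax.axhline(50, color="grey", lw=0.8)
    ax.axvline(50, color="grey", lw=0.8)
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 100)
    ax.set_xlabel("Structure index (SI)")
    ax.set_ylabel("Enrichment index (EI)")
    ax.legend(fontsize="small")
    return ax
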