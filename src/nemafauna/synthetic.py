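"""Synthetic community scenarios emulating a cover-crop field experiment.

The default scenario mirrors a 4-treatment (CK, C2, C4, C8 — 0, 2, 4, 8
cover-crop species) x 3-replicate randomized design: 46 genera (19 Ba, 6 Fu,
9 Pp, 12 Op) drawn per plot from negative-binomial distributions around
group-structured baselines, a 100-individual identification subsample per
sample, and soil covariates (moisture, pH, C and N pools, microbial biomass,
plant biomass) with treatment shifts and couplings to trophic-group
abundances.  The planted treatment pattern is the qualitative field
expectation: all cover-crop treatments raise total abundance, fungivores are
elevated under C4/C8 (x1.6), plant parasites under C2/C8 (x1.4).

All randomness flows from one scenario seed through ``numpy``'s
``SeedSequence`` spawning; no global random state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community import CommunitySample, CommunityTable, expand_identification
from .traits import TraitTable, default_traits

__all__ = [
    "CovariateSpec",
    "ScenarioConfig",
    "ScenarioResult",
    "default_baselines",
    "default_effects",
    "default_covariates",
    "generate_community",
    "generate_identification_counts",
    "generate_soil_covariates",
    "generate_scenario",
    "apply_identification",
    "generate_correlated_blocks",
    "generate_hub_table",
]

#: Dominant genera in the emulated community (boosted baselines).
_DOMINANTS = ("Aphelenchoides", "Eucephalobus", "Rhabditis")

#: Baseline total abundance per trophic group, individuals per 100 g dry soil.
_GROUP_TOTALS = {"Ba": 200.0, "Fu": 80.0, "Pp": 70.0, "Op": 50.0}


def default_baselines(traits: TraitTable | None = None,
                      pool: Sequence[str] | None = None) -> dict[str, float]:
    """Per-genus baseline means: group totals spread within groups,
    with the dominant genera weighted 3x."""
    traits = traits or default_traits()
    pool = list(pool) if pool is not None else list(traits.genera)
    by_group: dict[str, list[str]] = {}
    for g in pool:
        by_group.setdefault(traits.lookup(g).trophic_group, []).append(g)
    baselines = {}
    for group, genera in by_group.items():
        w = {g: (3.0 if g in _DOMINANTS else 1.0) for g in genera}
        total_w = sum(w.values())
        for g in genera:
            baselines[g] = _GROUP_TOTALS[group] * w[g] / total_w
    return baselines


def default_effects() -> dict[str, dict[str, float]]:
    """Treatment x trophic-group abundance multipliers (the planted pattern)."""
    return {
        "CK": {"Ba": 1.0, "Fu": 1.0, "Pp": 1.0, "Op": 1.0},
        "C2": {"Ba": 1.3, "Fu": 1.0, "Pp": 1.4, "Op": 1.0},
        "C4": {"Ba": 1.3, "Fu": 1.6, "Pp": 1.0, "Op": 1.1},
        "C8": {"Ba": 1.3, "Fu": 1.6, "Pp": 1.4, "Op": 1.1},
    }


@dataclass(frozen=True)
class CovariateSpec:
    """One soil/plant covariate: baseline + treatment shift + coupling + noise.

    ``coupling`` scales the z-scored abundance of ``coupling_group`` so a
    nonzero value makes the covariate track community composition (and hence
    makes community-environment Mantel tests reject at the configured power).
    """

    baseline: float
    shifts: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    coupling_group: str | None = None
    coupling: float = 0.0


def default_covariates() -> dict[str, CovariateSpec]:
    cover = lambda v: {"C2": v, "C4": v, "C8": v}  # noqa: E731
    return {
        "SMC": CovariateSpec(20.0, cover(2.0), 1.0),
        "pH": CovariateSpec(8.1, cover(-0.1), 0.05),
        "SOC": CovariateSpec(6.5, cover(1.0), 0.4, "Fu", 0.5),
        "NO3_N": CovariateSpec(10.0, cover(2.0), 1.0, "Fu", 1.2),
        "NH4_N": CovariateSpec(5.0, cover(0.5), 0.5),
        "TN": CovariateSpec(0.5, cover(0.05), 0.03),
        "CN": CovariateSpec(13.0, {}, 0.8),
        "MBC": CovariateSpec(150.0, cover(40.0), 15.0, "Ba", 20.0),
        "MBN": CovariateSpec(25.0, cover(8.0), 3.0, "Fu", 4.0),
        "cover_crop_biomass": CovariateSpec(
            0.0, {"C2": 300.0, "C4": 400.0, "C8": 500.0}, 25.0
        ),
        "weed_biomass": CovariateSpec(
            200.0, {"C2": -120.0, "C4": -150.0, "C8": -180.0}, 12.0
        ),
    }


@dataclass
class ScenarioConfig:
    """Parameters of one synthetic field scenario (all seeded, all explicit)."""

    treatments: tuple[str, ...] = ("CK", "C2", "C4", "C8")
    replicates: int = 3
    genus_pool: tuple[str, ...] | None = None
    baselines: dict[str, float] | None = None
    effects: dict[str, dict[str, float]] | None = None
    dispersion: float = 10.0  # negative-binomial size; larger = closer to Poisson
    distribution: str = "nbinom"  # or "poisson"
    subsample_size: int = 100
    dry_mass_g: float = 50.0
    covariates: dict[str, CovariateSpec] | None = None
    seed: int = 0

    def validate(self, traits: TraitTable) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2 for ANOVA testability")
        if self.distribution not in ("nbinom", "poisson"):
            raise ValueError(f"unknown distribution: {self.distribution}")
        if self.distribution == "nbinom" and not self.dispersion > 0:
            raise ValueError("dispersion must be > 0")
        if self.subsample_size < 1:
            raise ValueError("subsample_size must be >= 1")
        effects = self.effects or default_effects()
        for t in self.treatments:
            if t not in effects:
                raise ValueError(f"no effect multipliers for treatment {t!r}")
            if any(m <= 0 for m in effects[t].values()):
                raise ValueError("effect multipliers must be > 0")
        if self.genus_pool:
            traits.resolve(self.genus_pool)


@dataclass
class ScenarioResult:
    community: CommunityTable
    metadata: pd.DataFrame
    traits: TraitTable


def _draw_counts(rng: np.random.Generator, mean: float, config: ScenarioConfig) -> float:
    if mean <= 0:
        return 0.0
    if config.distribution == "poisson":
        return float(rng.poisson(mean))
    theta = config.dispersion
    return float(rng.negative_binomial(theta, theta / (theta + mean)))


def generate_community(
    config: ScenarioConfig,
    traits: TraitTable | None = None,
    rng: np.random.Generator | None = None,
) -> CommunityTable:
    """Draw per-plot genus abundances (individuals per 100 g dry soil).

    Each genus mean is ``baseline x group multiplier``; counts are
    negative-binomial (variance mu + mu^2/dispersion) or Poisson.
    Deterministic given the config seed.
    """
    traits = traits or default_traits()
    config.validate(traits)
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[0])
    pool = list(config.genus_pool) if config.genus_pool else list(traits.genera)
    baselines = config.baselines or default_baselines(traits, pool)
    effects = config.effects or default_effects()
    samples = []
    for t in config.treatments:
        for rep in range(1, config.replicates + 1):
            abundance = {}
            for genus in pool:
                group = traits.lookup(genus).trophic_group
                mean = baselines[genus] * effects[t].get(group, 1.0)
                abundance[genus] = _draw_counts(rng, mean, config)
            samples.append(
                CommunitySample(
                    sample_id=f"{t}-{rep}",
                    treatment=t,
                    abundance=abundance,
                    metadata={"replicate": rep, "dry_mass_g": config.dry_mass_g},
                )
            )
    return CommunityTable(samples)


def generate_identification_counts(
    sample: CommunitySample,
    n: int = 100,
    rng: np.random.Generator | int | None = None,
) -> dict[str, int]:
    """Multinomial identification subsample of *n* individuals from a sample."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    genera = list(sample.abundance)
    weights = np.array([sample.abundance[g] for g in genera], dtype=float)
    total = weights.sum()
    if total <= 0:
        raise ValueError("cannot subsample a zero-total community")
    draw = rng.multinomial(n, weights / total)
    return {g: int(c) for g, c in zip(genera, draw)}


def apply_identification(
    table: CommunityTable, n: int = 100, seed: int | None = None
) -> CommunityTable:
    """Re-derive genus abundances through the microscope-identification step.

    For each sample, draw an *n*-individual multinomial subsample and allocate
    the sample's total back across the identified counts — the observation
    process a field study actually applies.
    """
    rng = np.random.default_rng(seed)
    out = []
    for s in table:
        ident = generate_identification_counts(s, n=n, rng=rng)
        out.append(
            CommunitySample(
                sample_id=s.sample_id,
                treatment=s.treatment,
                abundance=expand_identification(s.total, ident),
                metadata=dict(s.metadata),
            )
        )
    return CommunityTable(out)


def generate_soil_covariates(
    config: ScenarioConfig,
    community: CommunityTable,
    traits: TraitTable | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Covariate table coupled to the community (and attached to its samples).

    covariate = baseline + treatment shift + coupling x z(group abundance)
    + Gaussian noise; z-scores are taken across all samples.
    """
    from .community import aggregate_trophic

    traits = traits or default_traits()
    rng = rng or np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])
    specs = config.covariates if config.covariates is not None else default_covariates()
    group_ab = pd.DataFrame(
        {s.sample_id: aggregate_trophic(s, traits) for s in community}
    ).T  # samples x groups
    z = (group_ab - group_ab.mean()) / group_ab.std(ddof=1).replace(0.0, 1.0)
    rows = {}
    for s in community:
        row = {}
        for name, spec in specs.items():
            val = spec.baseline + spec.shifts.get(s.treatment, 0.0)
            if spec.coupling_group and spec.coupling:
                val += spec.coupling * float(z.loc[s.sample_id, spec.coupling_group])
            row[name] = val + rng.normal(0.0, spec.noise_sd)
        rows[s.sample_id] = row
        s.metadata.update(row)
    meta = pd.DataFrame.from_dict(rows, orient="index")
    meta.insert(0, "treatment", list(community.treatments))
    meta.insert(1, "replicate", [s.metadata.get("replicate", 0) for s in community])
    meta.insert(2, "dry_mass_g", [s.metadata.get("dry_mass_g", np.nan) for s in community])
    meta.index.name = "sample_id"
    return meta


def generate_scenario(config: ScenarioConfig | None = None) -> ScenarioResult:
    """Full deterministic scenario: community + identification + covariates.

    One seed drives three independent streams (abundances, subsampling,
    covariate noise); the returned community has passed through the
    identification-subsample observation step.
    """
    config = config or ScenarioConfig()
    traits = default_traits()
    ss = np.random.SeedSequence(config.seed).spawn(3)
    community = generate_community(config, traits, rng=np.random.default_rng(ss[0]))
    observed = apply_identification(
        community, n=config.subsample_size, seed=np.random.default_rng(ss[1])
    )
    metadata = generate_soil_covariates(
        config, observed, traits, rng=np.random.default_rng(ss[2])
    )
    return ScenarioResult(community=observed, metadata=metadata, traits=traits)


# ---------------------------------------------------------------------------
# Planted-structure tables for network validation

def generate_correlated_blocks(
    n_samples: int = 12,
    block_sizes: Sequence[int] = (6, 6),
    rho: float = 0.9,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Genera x samples table with equicorrelated blocks and no cross-block link.

    Within a block every genus pair has latent Gaussian correlation *rho*
    (one shared factor, loading sqrt(rho)); abundances are the exponentials
    of the latent values, so ranks — and Spearman correlations — carry the
    planted structure exactly.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows, names = [], []
    for b, size in enumerate(block_sizes):
        factor = rng.standard_normal(n_samples)
        for g in range(size):
            eps = rng.standard_normal(n_samples)
            latent = np.sqrt(rho) * factor + np.sqrt(1 - rho) * eps
            rows.append(np.exp(latent) * 50.0)
            names.append(f"B{b + 1}G{g + 1:02d}")
    return pd.DataFrame(rows, index=pd.Index(names, name="genus"),
                        columns=[f"S{i + 1}" for i in range(n_samples)])


def generate_hub_table(
    n_spokes: int = 8,
    n_noise: int = 4,
    n_samples: int = 12,
    rho: float = 0.8,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Table with one designated hub genus correlated with all spoke genera.

    Spokes share variance only through the hub, noise genera are independent;
    the hub should come out top-ranked by degree.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hub = rng.standard_normal(n_samples)
    rows = {"Hub": np.exp(hub) * 50.0}
    for i in range(n_spokes):
        latent = np.sqrt(rho) * hub + np.sqrt(1 - rho) * rng.standard_normal(n_samples)
        rows[f"Spoke{i + 1:02d}"] = np.exp(latent) * 50.0
    for i in range(n_noise):
        rows[f"Noise{i + 1:02d}"] = np.exp(rng.standard_normal(n_samples)) * 50.0
    df = pd.DataFrame(rows).T
    df.index.name = "genus"
    df.columns = [f"S{i + 1}" for i in range(n_samples)]
    return df
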