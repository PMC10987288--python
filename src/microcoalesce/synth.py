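"""Synthetic lake-study generator with known source-mixing ground truth.

Emulates a shallow-lake survey: three sites, each contributing one water and
one sediment microbial community, and 28 fish gut communities (7 species x 4
individuals). Each gut community is a multinomial draw from a convex mixture

    p_sink = a_w * p_water(site) + a_s * p_sediment(site) + a_u * p_unknown

where the unknown component lives on a reserved taxon block absent from both
environmental sources (host-resident microbes), making it identifiable for
source tracking. Fish belong to one of two latent vertical habitat-preference
groups: pelagic fish draw most of their gut community from water
(a_w in [0.55, 0.8] by default), benthic fish from sediment. Sediment sources
are built to have higher Shannon diversity than water sources, mirroring the
usual benthic/pelagic diversity contrast.

Per-fish nitrogen isotope values (delta-15N, per mil) are drawn around
species-level means together with a primary-consumer reference value, so the
trophic-level factor is assigned independently of habitat preference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import AbundanceTable, SampleMetadata, SPECIES_CODES


class ConfigError(ValueError):
    """Raised for invalid study configurations."""


# Species nested within habitat groups: 4 pelagic species (16 fish), 3 benthic
# (12 fish). CB is the one non-cyprinid (Engraulidae).
DEFAULT_SPECIES_HABITAT: dict[str, str] = {
    "AN": "pelagic",
    "CB": "pelagic",
    "HL": "pelagic",
    "TS": "pelagic",
    "CA": "benthic",
    "CD": "benthic",
    "PS": "benthic",
}

DEFAULT_SPECIES_FAMILY: dict[str, str] = {
    "AN": "Cyprinidae",
    "CA": "Cyprinidae",
    "CB": "Engraulidae",
    "CD": "Cyprinidae",
    "HL": "Cyprinidae",
    "PS": "Cyprinidae",
    "TS": "Cyprinidae",
}

# Species mean delta-15N (per mil). With reference 8.0 and enrichment 3.4 the
# trophic threshold TL = 2.8 falls at delta-15N = 10.72, so the high-trophic
# set {CB, HL, CD} straddles both habitat groups: trophic grouping is not a
# relabelling of habitat.
DEFAULT_SPECIES_DELTA15N: dict[str, float] = {
    "AN": 10.2,
    "CA": 10.3,
    "CB": 14.0,
    "CD": 13.0,
    "HL": 14.5,
    "PS": 10.5,
    "TS": 10.1,
}


@dataclass
class SourceProfile:
    """A source community: taxon probability vector over the full taxon universe."""

    habitat_class: str  # "water" | "sediment" | "unknown"
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(self.probabilities < 0):
            raise ConfigError("negative probabilities in source profile")
        if abs(self.probabilities.sum() - 1.0) > 1e-12:
            raise ConfigError("source profile must sum to 1")

    @property
    def support(self) -> np.ndarray:
        return np.nonzero(self.probabilities > 0)[0]

    def shannon_entropy(self) -> float:
        p = self.probabilities[self.probabilities > 0]
        return float(-(p * np.log(p)).sum())


@dataclass
class StudyConfig:
    """Knobs of the synthetic study; defaults reproduce the survey design."""

    n_taxa: int = 200
    n_unknown_taxa: int = 20
    water_support: int = 80
    sediment_support: int = 120
    overlap_fraction: float = 0.3
    water_concentration: float = 0.3
    sediment_concentration: float = 5.0
    site_concentration: float = 2000.0
    n_sites: int = 3
    depth: int = 50_000
    unknown_weight: float = 0.1
    major_alpha_range: tuple[float, float] = (0.55, 0.8)
    species_habitat: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_HABITAT)
    )
    species_family: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_FAMILY)
    )
    species_delta15n: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_DELTA15N)
    )
    fish_per_species: int = 4
    delta15n_sd: float = 0.3
    reference_delta15n: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 10:
            raise ConfigError("n_taxa must be >= 10")
        if not 0 <= self.overlap_fraction <= 1:
            raise ConfigError("overlap_fraction must be in [0, 1]")
        if not 0 <= self.unknown_weight < 1:
            raise ConfigError("unknown_weight must be in [0, 1)")
        lo, hi = self.major_alpha_range
        if not (0.5 < lo <= hi <= 1 - self.unknown_weight):
            raise ConfigError(
                "major_alpha_range must lie in (0.5, 1 - unknown_weight] so the "
                "major source dominates and alphas stay feasible"
            )
        if self.water_support + self.sediment_support > self.n_taxa - self.n_unknown_taxa + min(
            self.water_support, self.sediment_support
        ):
            pass  # overlap absorbs the excess; validated in make_source_profiles
        if self.fish_per_species <= 0 or self.n_sites <= 0 or self.depth < 0:
            raise ConfigError("counts must be positive")

    @property
    def n_gut(self) -> int:
        return self.fish_per_species * len(self.species_habitat)


def _habitat_base_profiles(
    config: StudyConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Dirichlet base profiles for water and sediment over disjoint-plus-overlap supports."""
    n_env = config.n_taxa - config.n_unknown_taxa
    n_overlap = int(round(config.overlap_fraction * min(config.water_support, config.sediment_support)))
    n_water_only = config.water_support - n_overlap
    n_sed_only = config.sediment_support - n_overlap
    if n_water_only + n_sed_only + n_overlap > n_env:
        raise ConfigError("source supports exceed the environmental taxon pool")
    water_idx = np.arange(0, n_water_only + n_overlap)
    sed_idx = np.arange(n_water_only, n_water_only + n_overlap + n_sed_only)
    water = np.zeros(config.n_taxa)
    sed = np.zeros(config.n_taxa)
    water[water_idx] = rng.dirichlet(np.full(water_idx.size, config.water_concentration))
    sed[sed_idx] = rng.dirichlet(np.full(sed_idx.size, config.sediment_concentration))
    return water, sed


def make_source_profiles(
    config: StudyConfig, rng: np.random.Generator | None = None
) -> tuple[list[SourceProfile], list[SourceProfile]]:
    """Per-site water and sediment source profiles around habitat-level bases.

    Sediment uses a much larger Dirichlet concentration over a larger support
    than water, so its base profile is more even and (with overwhelming
    probability) has the higher Shannon entropy.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    water_base, sed_base = _habitat_base_profiles(config, rng)
    waters, seds = [], []
    for base, out, cls in ((water_base, waters, "water"), (sed_base, seds, "sediment")):
        support = base > 0
        for _ in range(config.n_sites):
            site = np.zeros(config.n_taxa)
            site[support] = rng.dirichlet(base[support] * config.site_concentration)
            out.append(SourceProfile(cls, site))
    return waters, seds


def sample_community(
    profile: SourceProfile | np.ndarray, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """Multinomial draw of ``depth`` reads from a probability profile."""
    p = profile.probabilities if isinstance(profile, SourceProfile) else np.asarray(profile)
    if depth < 0:
        raise ConfigError("depth must be >= 0")
    if depth == 0:
        return np.zeros(p.size, dtype=np.int64)
    return rng.multinomial(depth, p)


def make_gut_sample(
    water_profile: SourceProfile,
    sediment_profile: SourceProfile,
    unknown_profile: SourceProfile,
    alphas: Sequence[float],
    depth: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Multinomial gut community from the alpha-weighted mixture of three profiles."""
    alphas = np.asarray(alphas, dtype=float)
    if alphas.shape != (3,) or abs(alphas.sum() - 1.0) > 1e-9 or np.any(alphas < 0):
        raise ConfigError("alphas must be 3 non-negative values summing to 1")
    mix = (
        alphas[0] * water_profile.probabilities
        + alphas[1] * sediment_profile.probabilities
        + alphas[2] * unknown_profile.probabilities
    )
    mix = mix / mix.sum()
    return sample_community(SourceProfile("unknown", mix), depth, rng)


def generate_study(
    config: StudyConfig | None = None, seed: int | None = None
) -> tuple[AbundanceTable, list[SampleMetadata], pd.DataFrame]:
    """Generate the full synthetic survey.

    Returns the count table over all samples (28 gut + 3 water + 3 sediment
    under defaults), the metadata rows, and a ground-truth DataFrame with one
    row per gut sample: true mixing proportions (``alpha_water``,
    ``alpha_sediment``, ``alpha_unknown``), latent ``habitat`` group, species,
    site, true delta-15N and the study's primary-consumer reference value
    (column ``reference_delta15n``).
    """
    if config is None:
        config = StudyConfig()
    if seed is not None:
        config = StudyConfig(**{**config.__dict__, "seed": seed})
    rng = np.random.default_rng(config.seed)

    waters, seds = make_source_profiles(config, rng)
    unknown_block = np.arange(config.n_taxa - config.n_unknown_taxa, config.n_taxa)

    taxon_ids = [f"ASV{i + 1:04d}" for i in range(config.n_taxa)]
    sample_ids: list[str] = []
    columns: list[np.ndarray] = []
    meta: list[SampleMetadata] = []
    truth_rows: list[dict] = []

    species = sorted(config.species_habitat)
    fish_counter = 0
    for sp in species:
        habitat = config.species_habitat[sp]
        if habitat not in ("pelagic", "benthic"):
            raise ConfigError(f"unknown habitat group {habitat!r} for species {sp}")
        for rep in range(config.fish_per_species):
            site_i = fish_counter % config.n_sites
            fish_counter += 1
            sid = f"{sp}{rep + 1}"
            a_major = rng.uniform(*config.major_alpha_range)
            a_u = config.unknown_weight
            a_minor = 1.0 - a_major - a_u
            if habitat == "pelagic":
                a_w, a_s = a_major, a_minor
            else:
                a_w, a_s = a_minor, a_major
            unknown = np.zeros(config.n_taxa)
            unknown[unknown_block] = rng.dirichlet(np.full(unknown_block.size, 0.5))
            unknown_prof = SourceProfile("unknown", unknown)
            counts = make_gut_sample(
                waters[site_i], seds[site_i], unknown_prof, (a_w, a_s, a_u), config.depth, rng
            )
            d15n = rng.normal(config.species_delta15n[sp], config.delta15n_sd)
            sample_ids.append(sid)
            columns.append(counts)
            meta.append(
                SampleMetadata(
                    sample_id=sid,
                    sample_class="gut",
                    site=f"S{site_i + 1}",
                    species_code=sp,
                    family=config.species_family[sp],
                    delta15N=round(float(d15n), 4),
                )
            )
            truth_rows.append(
                {
                    "sample_id": sid,
                    "alpha_water": a_w,
                    "alpha_sediment": a_s,
                    "alpha_unknown": a_u,
                    "habitat": habitat,
                    "species_code": sp,
                    "site": f"S{site_i + 1}",
                    "delta15N": round(float(d15n), 4),
                    "reference_delta15n": config.reference_delta15n,
                }
            )

    for cls, profiles, prefix in (("water", waters, "W"), ("sediment", seds, "SD")):
        for i, prof in enumerate(profiles):
            sid = f"{prefix}{i + 1}"
            sample_ids.append(sid)
            columns.append(sample_community(prof, config.depth, rng))
            meta.append(SampleMetadata(sample_id=sid, sample_class=cls, site=f"S{i + 1}"))

    table = AbundanceTable(taxon_ids, sample_ids, np.column_stack(columns))
    truth = pd.DataFrame(truth_rows).set_index("sample_id")
    # habitat must equal argmax of (alpha_water, alpha_sediment) by construction
    argmax = np.where(truth["alpha_water"] > truth["alpha_sediment"], "pelagic", "benthic")
    assert (truth["habitat"] == argmax).all()
    return table, meta, truth
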