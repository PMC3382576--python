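"""Synthetic fossil assemblages with the statistical structure the pipeline assumes.

The generator emulates the three inputs of a completeness analysis:

* a character contribution table (a random composition of a character total
  over a realistic pool of skeletal element/part keys);
* an occurrence table of specimens whose element inventories follow
  per-environment Beta completeness distributions, optionally boosted in
  designated exceptional-preservation (Lagerstaette) bins;
* a per-bin sampling proxy coupled to collecting effort and observed
  richness.

Ecological truth is recorded in a ledger so recovery of richness,
environment effects and Lagerstaette signals can be tested end to end.
A per-bin lognormal collecting effort thins species detection, and the proxy
measures that effort: this is what lets sampling "drive" the observed record
while true richness stays known.

All randomness flows from ``SimulationConfig.seed`` through independent
numpy substreams, so outputs are byte-identical across repeat calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ccm import ENVIRONMENTS, SpecimenRecord
from .characters import CharacterContributionTable, ElementPartKey
from .chrono import BinSeries, TimeBinTable, make_substage_bins

# ---------------------------------------------------------------------------
# element/part pool for synthetic contribution tables
# ---------------------------------------------------------------------------

_SKULL = [
    "premaxilla", "maxilla", "nasal", "lacrimal", "frontal", "parietal",
    "jugal", "quadratojugal", "quadrate", "squamosal", "braincase",
    "palate", "dentary", "surangular", "angular", "teeth",
]
_VERTEBRAL_SECTIONS = [
    "cervical_vertebrae", "thoracic_vertebrae", "sacral_vertebrae", "caudal_vertebrae",
]
_VERTEBRAL_PARTS = ["single", "anterior", "posterior", "series", "neural_spine"]
_LIMB_PARTS = ["proximal_end", "distal_end", "shaft"]
_FORELIMB_LONG = ["humerus", "ulna", "radius"]
_HINDLIMB_LONG = ["femur", "tibiotarsus", "fibula", "tarsometatarsus"]


def _element_pool() -> list[tuple[ElementPartKey, str, float]]:
    """(key, region, weight) pool; weights shape a skull-heavy composition."""
    pool: list[tuple[ElementPartKey, str, float]] = []
    for name in _SKULL:
        pool.append((ElementPartKey(name), "skull", 2.0))
    for section in _VERTEBRAL_SECTIONS:
        for part in _VERTEBRAL_PARTS:
            pool.append((ElementPartKey(section, part), "vertebral_column_and_ribs", 0.5))
    pool.append((ElementPartKey("ribs"), "vertebral_column_and_ribs", 0.8))
    for name in ["scapula", "coracoid", "furcula", "sternum"]:
        pool.append((ElementPartKey(name), "pectoral_girdle", 1.8))
    for name in _FORELIMB_LONG:
        for part in _LIMB_PARTS:
            pool.append((ElementPartKey(name, part), "forelimbs", 1.0))
    for name in ["carpometacarpus", "manual_digits"]:
        pool.append((ElementPartKey(name), "forelimbs", 1.5))
    for name in ["ilium", "ischium", "pubis"]:
        pool.append((ElementPartKey(name), "pelvic_girdle", 2.2))
    for name in _HINDLIMB_LONG:
        for part in _LIMB_PARTS:
            pool.append((ElementPartKey(name, part), "hindlimbs", 0.8))
    pool.append((ElementPartKey("pedal_digits"), "hindlimbs", 1.2))
    pool.append((ElementPartKey("feathers"), "integument", 0.3))
    return pool


def generate_contribution_table(
    n_elements: int, total_characters: int, seed: int | np.random.Generator = 0
) -> CharacterContributionTable:
    """Random composition of *total_characters* over *n_elements* keys.

    Keys are drawn (weighted, without replacement) from a realistic skeletal
    pool, extended with generic names if the pool is exhausted; every key
    receives at least one character.  Deterministic for a fixed seed.
    """
    if n_elements < 1:
        raise ValueError("n_elements must be >= 1")
    if total_characters < n_elements:
        raise ValueError(
            f"cannot spread {total_characters} characters over {n_elements} keys "
            "with every key scorable"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = _element_pool()
    if n_elements <= len(pool):
        weights = np.array([w for _, _, w in pool])
        idx = rng.choice(len(pool), size=n_elements, replace=False, p=weights / weights.sum())
        chosen = [pool[i] for i in sorted(idx)]
    else:
        chosen = list(pool)
        for j in range(n_elements - len(pool)):
            chosen.append((ElementPartKey(f"element_{j:03d}"), "skull", 1.0))
    w = np.array([c[2] for c in chosen])
    counts = rng.multinomial(total_characters - n_elements, w / w.sum()) + 1
    entries = {key: int(c) for (key, _, _), c in zip(chosen, counts)}
    region = {key: reg for (key, reg, _) in chosen}
    return CharacterContributionTable(total_characters, entries, region)


# ---------------------------------------------------------------------------
# simulation configuration
# ---------------------------------------------------------------------------


def default_richness_profile(n_bins: int) -> np.ndarray:
    """Poisson means: a rising trend with two radiation peaks.

    Mimics a record whose richness climbs through the interval and spikes
    twice (early and late radiations), so structure exists for the residual
    method to recover.
    """
    i = np.arange(n_bins, dtype=float)
    base = 3.0 + 5.0 * i / max(n_bins - 1, 1)
    width = max(n_bins / 12.0, 1.0)
    peaks = 6.0 * np.exp(-((i - 0.35 * n_bins) ** 2) / (2 * width**2))
    peaks += 6.0 * np.exp(-((i - 0.65 * n_bins) ** 2) / (2 * width**2))
    return base + peaks


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic assemblage.

    Defaults emulate the empirical regime of a Mesozoic-bird-like record:
    26 substage bins, a species flux of a few species per bin, environment
    completeness means of roughly 0.47 (fluviolacustrine), 0.25 (marine) and
    0.31 (other terrestrial), a Northern-Hemisphere-dominated latitude
    mixture, and a fifth of specimens with stage-level age uncertainty.
    """

    seed: int = 0
    n_bins: int = 26
    richness_per_bin: np.ndarray | None = None
    environment_mix: dict[str, float] = field(
        default_factory=lambda: {
            "fluviolacustrine": 0.45,
            "marine": 0.25,
            "other_terrestrial": 0.30,
        }
    )
    completeness_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "fluviolacustrine": (2.79, 3.21),  # mean 0.465
            "marine": (1.50, 4.50),  # mean 0.25
            "other_terrestrial": (1.86, 4.14),  # mean 0.31
        }
    )
    lagerstatte_bins: dict[int, float] = field(default_factory=dict)
    latitude_model: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(0.7, 45.0, 8.0), (0.3, -28.0, 12.0)]
    )
    landmass_mix: dict[str, float] = field(
        default_factory=lambda: {
            "Asia": 0.45,
            "Europe": 0.18,
            "North_America": 0.19,
            "South_America": 0.12,
            "Antarctica": 0.02,
            "Australasia": 0.02,
            "Madagascar": 0.02,
        }
    )
    age_uncertainty_prob: float = 0.2
    specimens_per_species_mean: float = 1.5
    specimen_retention: float = 0.8
    effort_sigma: float = 0.8
    detection_rate: float = 2.0
    proxy_scale: float = 20.0
    proxy_effect: float = 0.3
    effort_weight: float = 1.0
    proxy_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.n_bins < 2 or self.n_bins % 2:
            raise ValueError("n_bins must be an even number >= 2")
        if self.richness_per_bin is None:
            self.richness_per_bin = default_richness_profile(self.n_bins)
        self.richness_per_bin = np.asarray(self.richness_per_bin, dtype=float)
        if self.richness_per_bin.size != self.n_bins:
            raise ValueError("richness_per_bin must have one Poisson mean per bin")
        if np.any(self.richness_per_bin <= 0):
            raise ValueError("richness Poisson means must be positive")
        for mix_name, mix in (("environment_mix", self.environment_mix),
                              ("landmass_mix", self.landmass_mix)):
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"{mix_name} probabilities must sum to 1")
        if set(self.environment_mix) != set(ENVIRONMENTS):
            raise ValueError(f"environment_mix must cover {ENVIRONMENTS}")
        for env, (a, b) in self.completeness_model.items():
            if a <= 0 or b <= 0:
                raise ValueError(f"Beta parameters for {env} must be positive")
        for b_idx, boost in self.lagerstatte_bins.items():
            if not 0 <= b_idx < self.n_bins:
                raise ValueError(f"Lagerstaette bin index {b_idx} out of range")
            if not 0.0 <= boost <= 1.0:
                raise ValueError("Lagerstaette boost must lie in [0, 1]")
        if not 0.0 <= self.age_uncertainty_prob <= 1.0:
            raise ValueError("age_uncertainty_prob must lie in [0, 1]")
        if not 0.0 < self.specimen_retention <= 1.0:
            raise ValueError("specimen_retention must lie in (0, 1]")
        if self.specimens_per_species_mean < 1.0:
            raise ValueError("specimens_per_species_mean must be >= 1")


@dataclass
class GroundTruth:
    """Ledger of the generative state behind one synthetic assemblage."""

    seed: int
    bin_labels: list[str]
    true_richness: np.ndarray
    effort: np.ndarray
    detection_prob: np.ndarray
    observed_richness: np.ndarray
    species: pd.DataFrame  # species, bin_index, bin, environment, landmass, ...
    lagerstatte_bins: dict[int, float]


def synthetic_stage_table(n_bins: int) -> list[tuple[str, float, float]]:
    """Evenly spaced pseudo-stages (5 Ma each) ending at 66 Ma, old -> young."""
    n_stages = n_bins // 2
    stages = []
    for i in range(n_stages):
        start = 66.0 + (n_stages - i) * 5.0
        stages.append((f"stage_{i + 1:02d}", start, start - 5.0))
    return stages


def generate_fauna(
    config: SimulationConfig, table: CharacterContributionTable
) -> tuple[list[SpecimenRecord], GroundTruth, TimeBinTable]:
    """Draw a synthetic occurrence set and its ground-truth ledger.

    Per bin: true richness is Poisson; a lognormal collecting effort sets the
    detection probability ``1 - exp(-detection_rate * effort)``; each
    detected species receives >=1 specimen.  A species' inventory is drawn
    once — each table key kept with probability equal to its Beta-drawn
    completeness fraction (Lagerstaette-boosted where configured) — and each
    specimen preserves a random subset of it, so the specimen union converges
    on the species inventory.
    """
    rng = np.random.default_rng([config.seed, 0])
    bins = TimeBinTable(
        make_substage_bins(synthetic_stage_table(config.n_bins)).bins
    )
    keys = sorted(table.keys())
    n_keys = len(keys)

    env_names = list(config.environment_mix)
    env_p = np.array([config.environment_mix[e] for e in env_names])
    land_names = list(config.landmass_mix)
    land_p = np.array([config.landmass_mix[l] for l in land_names])
    lat_weights = np.array([w for w, _, _ in config.latitude_model])
    lat_weights = lat_weights / lat_weights.sum()

    true_richness = rng.poisson(config.richness_per_bin)
    effort = rng.lognormal(0.0, config.effort_sigma, size=config.n_bins)
    detect_p = 1.0 - np.exp(-config.detection_rate * effort)
    observed = np.zeros(config.n_bins, dtype=int)

    records: list[SpecimenRecord] = []
    species_rows: list[dict] = []
    for b in range(config.n_bins):
        bin_obj = bins.bins[b]
        boost = config.lagerstatte_bins.get(b, 0.0)
        for j in range(true_richness[b]):
            name = f"sp_{b:02d}_{j:03d}"
            env = env_names[rng.choice(len(env_names), p=env_p)]
            a, bb = config.completeness_model[env]
            frac = rng.beta(a, bb)
            if boost:
                frac = frac + boost * (1.0 - frac)
            comp = rng.choice(len(lat_weights), p=lat_weights)
            _, mu, sigma = config.latitude_model[comp]
            latitude = float(np.clip(rng.normal(mu, sigma), -90.0, 90.0))
            landmass = land_names[rng.choice(len(land_names), p=land_p)]
            detected = rng.random() < detect_p[b]
            n_specimens = 0
            if detected:
                observed[b] += 1
                n_specimens = 1 + rng.poisson(config.specimens_per_species_mean - 1.0)
                species_mask = rng.random(n_keys) < frac
                species_inv = [k for k, m in zip(keys, species_mask) if m]
                for s in range(n_specimens):
                    if species_inv:
                        keep = rng.random(len(species_inv)) < config.specimen_retention
                        inventory = [k for k, m in zip(species_inv, keep) if m]
                        if not inventory:
                            inventory = [species_inv[rng.integers(len(species_inv))]]
                    else:
                        inventory = []
                    if rng.random() < config.age_uncertainty_prob:
                        age_earliest = age_latest = bin_obj.stage  # full stage
                    else:
                        age_earliest = age_latest = bin_obj.label
                    records.append(
                        SpecimenRecord(
                            specimen_id=f"{name}_spec{s:02d}",
                            species=name,
                            genus=name.rsplit("_", 1)[0],
                            inventory=frozenset(inventory),
                            age_earliest=age_earliest,
                            age_latest=age_latest,
                            environment=env,
                            latitude_deg=latitude,
                            region=landmass,
                        )
                    )
            species_rows.append(
                {
                    "species": name,
                    "bin_index": b,
                    "bin": bin_obj.label,
                    "environment": env,
                    "landmass": landmass,
                    "latitude": latitude,
                    "completeness_fraction": frac,
                    "detected": detected,
                    "n_specimens": n_specimens,
                }
            )

    truth = GroundTruth(
        seed=config.seed,
        bin_labels=bins.labels,
        true_richness=true_richness,
        effort=effort,
        detection_prob=detect_p,
        observed_richness=observed,
        species=pd.DataFrame(
            species_rows,
            columns=[
                "species", "bin_index", "bin", "environment", "landmass",
                "latitude", "completeness_fraction", "detected", "n_specimens",
            ],
        ),
        lagerstatte_bins=dict(config.lagerstatte_bins),
    )
    return records, truth, bins


def generate_proxy_series(config: SimulationConfig, truth: GroundTruth) -> BinSeries:
    """Per-bin sampling-proxy counts coupled to effort and observed richness.

    ``proxy = scale * effort**effort_weight * (observed + 1)**proxy_effect``
    with multiplicative lognormal noise, rounded to counts.  With
    ``effort_weight=0``, ``proxy_effect=1`` and zero noise the proxy is
    proportional to observed richness and residual diversity vanishes.
    """
    rng = np.random.default_rng([config.seed, 1])
    noise = np.exp(rng.normal(0.0, config.proxy_noise_sd, size=config.n_bins))
    value = (
        config.proxy_scale
        * truth.effort**config.effort_weight
        * (truth.observed_richness + 1.0) ** config.proxy_effect
        * noise
    )
    counts = np.round(value).astype(int)
    return BinSeries(list(truth.bin_labels), counts.astype(float), None, np.maximum(counts, 1))
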