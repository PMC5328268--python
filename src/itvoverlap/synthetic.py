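"""Synthetic woody-plant communities along a species-richness gradient.

The generator produces the same long-format individual trait table and
community metadata that the readers in :mod:`itvoverlap.data_model` consume,
under three phenomenological assembly scenarios:

``A_high_itv_poor`` (preset ``broadening_range``)
    Inter-species mean spacing is held constant, so the occupied trait range
    grows with richness; within-species CV is constant.  Trait overlap stays
    roughly flat and low along the gradient.
``B_shrinking_itv`` (preset ``shrinking_itv``)
    The trait range is fixed and within-species CV declines linearly with
    richness: species pack in by narrowing their niches, keeping overlap
    roughly constant.
``C_constant_itv_fixed_range`` (preset ``trait_packing``)
    The trait range is fixed and CV is constant, so added species must sit
    closer together: pairwise overlap rises with richness while ITV does
    not change.  This is the configuration that reproduces the headline
    empirical pattern (flat ITV, increasing overlap).

Species means are evenly spaced with uniform jitter on the log scale —
leaf size and SLA are positive and span orders of magnitude, so "evenly
spaced within the trait range" is applied on the scale the traits live on.
Within-species trait values are lognormal by default (right-skewed, CV
proportional to the mean) or normal when a closed-form overlap ground truth
is needed, truncated to positive values.  Climate covariates are
richness-correlated by default, mimicking the boreal-to-tropical
confounding of real gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import Dataset
from .errors import ConfigError
from .overlap import normal_overlap
from .seeding import derive_rng

#: Species-richness values (species/ha, DBH >= 10 cm) of the 21 study
#: forests, boreal to tropical; the default gradient.
STUDY_RICHNESS: tuple[int, ...] = (
    1, 1, 1, 2, 2, 2, 3, 3, 3, 4, 34, 54, 131, 148, 150, 156, 197, 213, 224, 251, 284,
)

#: Number of understory species actually measured with >= 5 individuals in
#: each study forest, aligned with STUDY_RICHNESS.  Sampling was understory
#: saplings, so species-poor canopies still yield 2-4 measured species while
#: hyperdiverse forests are heavily subsampled.
STUDY_SAMPLED: tuple[int, ...] = (
    3, 4, 4, 2, 4, 4, 2, 3, 2, 2, 52, 43, 16, 11, 35, 11, 24, 14, 10, 59, 16,
)

SCENARIOS = ("A_high_itv_poor", "B_shrinking_itv", "C_constant_itv_fixed_range")


@dataclass
class ScenarioConfig:
    """Generative parameters for one synthetic richness gradient."""

    scenario: str = "C_constant_itv_fixed_range"
    richness_values: Sequence[int] = STUDY_RICHNESS
    #: number of species measured per forest, aligned with richness_values;
    #: None uses the study's sampling design when richness_values is the
    #: study gradient, otherwise min(richness, max_species_sampled)
    n_species_sampled: Sequence[int] | None = None
    #: cap on sampled species per forest (the field campaign measured at
    #: most ~60 species even in hyperdiverse forests)
    max_species_sampled: int = 50
    #: "study_like": sampling effort mirrors the field campaign — many
    #: individuals per species in species-poor forests, close to the minimum
    #: in hyperdiverse ones; "constant": always individuals_per_species
    effort_rule: str = "study_like"
    individuals_per_species: int = 10
    trait_range: tuple[float, float] = (5.0, 250.0)  # leaf size, cm^2
    #: within-species CV of leaf size
    base_cv: float = 45.0  # percent
    #: within-species CV of SLA, a much less variable trait (~40%)
    sla_cv: float = 40.0  # percent
    cv_richness_slope: float = 0.0  # percent CV per unit richness (scenario B)
    noise_model: str = "lognormal"
    jitter_frac: float = 0.25
    climate_coupled: bool = True
    mat_intercept: float = 8.0  # deg C at richness ~0
    mat_slope: float = 0.07
    mat_sd: float = 2.5
    ap_intercept: float = 600.0  # mm
    ap_slope: float = 9.0
    ap_sd: float = 250.0
    seed: int = 0
    trait: str = "leaf_size"

    @property
    def n_forests(self) -> int:
        return len(self.richness_values)

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        r = list(self.richness_values)
        if not r or any(int(v) < 1 for v in r):
            raise ConfigError("richness_values must be positive integers")
        if sorted(r) != r:
            raise ConfigError("richness_values must be sorted ascending")
        lo, hi = self.trait_range
        if not (0 < lo < hi):
            raise ConfigError("trait_range must satisfy 0 < low < high")
        if self.base_cv <= 0:
            raise ConfigError("base_cv must be positive")
        if self.individuals_per_species < 5:
            raise ConfigError("individuals_per_species must be >= 5")
        if self.effort_rule not in ("study_like", "constant"):
            raise ConfigError(f"unknown effort_rule {self.effort_rule!r}")
        if self.noise_model not in ("normal", "lognormal"):
            raise ConfigError(f"unknown noise_model {self.noise_model!r}")
        if self.n_species_sampled is not None:
            if len(self.n_species_sampled) != len(r):
                raise ConfigError(
                    "n_species_sampled must have one entry per richness value"
                )
            if any(int(v) < 1 for v in self.n_species_sampled):
                raise ConfigError("n_species_sampled entries must be >= 1")
        for richness in r:
            if self._cv_percent(int(richness)) <= 0:
                raise ConfigError(
                    f"CV rule yields non-positive CV at richness {richness}; "
                    "adjust base_cv / cv_richness_slope"
                )

    def _cv_percent(self, richness: int) -> float:
        if self.scenario == "B_shrinking_itv":
            r_min = min(int(v) for v in self.richness_values)
            return self.base_cv + self.cv_richness_slope * (richness - r_min)
        return self.base_cv

    def sampled_counts(self) -> list[int]:
        """Measured-species count per forest, in richness_values order.

        Defaults to min(richness, max_species_sampled): the local assembly
        scenario determines who can be sampled.  The study's own sampling
        design (understory campaigns that can see a few extra neighbor
        species in species-poor forests) is available by passing
        ``n_species_sampled=STUDY_SAMPLED``.
        """
        if self.n_species_sampled is not None:
            return [int(v) for v in self.n_species_sampled]
        return [
            min(int(r), self.max_species_sampled) for r in self.richness_values
        ]


#: Named presets for the three conceptual scenarios.
PRESETS: dict[str, ScenarioConfig] = {
    "broadening_range": ScenarioConfig(scenario="A_high_itv_poor"),
    "shrinking_itv": ScenarioConfig(
        scenario="B_shrinking_itv", cv_richness_slope=-0.12
    ),
    "trait_packing": ScenarioConfig(scenario="C_constant_itv_fixed_range"),
    # smaller, faster gradient for smoke tests and examples
    "trait_packing_small": ScenarioConfig(
        scenario="C_constant_itv_fixed_range",
        richness_values=(1, 2, 4, 8, 16, 32, 64),
        max_species_sampled=20,
    ),
}


def get_preset(name: str) -> ScenarioConfig:
    if name not in PRESETS:
        raise ConfigError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    return replace(PRESETS[name])


def _forest_types(richness: np.ndarray) -> list[str]:
    """Coarse forest-type labels from richness quantile bands."""
    n_bands = min(4, len(np.unique(richness)))
    if n_bands < 2:
        return ["type_1"] * len(richness)
    codes = pd.qcut(
        pd.Series(richness).rank(method="first"), q=n_bands, labels=False
    )
    return [f"type_{c + 1}" for c in codes]


def community_parameters(cfg: ScenarioConfig) -> pd.DataFrame:
    """Per-species generative (mu, sigma) for every forest in the gradient.

    This is the ground truth the estimators are tested against: one row per
    (forest, species) with the true normal-scale mean and sd implied by the
    scenario's placement and CV rules.
    """
    cfg.validate()
    log_lo, log_hi = np.log(cfg.trait_range[0]), np.log(cfg.trait_range[1])
    counts = cfg.sampled_counts()
    rows = []
    for f_idx, richness in enumerate(cfg.richness_values):
        richness = int(richness)
        forest = f"F{f_idx + 1:02d}"
        rng = derive_rng(cfg.seed, "params", forest)
        # understory sampling can see more species than the canopy census
        # counts (saplings of neighboring canopies), so the packed trait
        # axis holds max(richness, sampled) species positions
        n_slots = max(richness, counts[f_idx])
        # means are even on the log scale: packing (scenarios B/C) divides
        # the fixed range among all resident species, scenario A keeps the
        # spacing fixed so the occupied range grows with richness instead
        if cfg.scenario == "A_high_itv_poor":
            spacing = (log_hi - log_lo) / max(cfg.richness_values)
        else:
            spacing = (log_hi - log_lo) / n_slots
        log_centers = log_lo + (np.arange(n_slots) + 0.5) * spacing
        jitter = rng.uniform(-cfg.jitter_frac, cfg.jitter_frac, size=n_slots) * spacing
        mus = np.exp(log_centers + jitter)
        # the measurement campaign samples a subset of the resident species
        s = counts[f_idx]
        sampled = np.sort(rng.choice(n_slots, size=s, replace=False))
        cv = cfg._cv_percent(richness)
        sigmas = cv / 100.0 * mus
        for rank, i in enumerate(sampled):
            rows.append(
                {
                    "forest_id": forest,
                    "species_id": f"sp{rank + 1:03d}",
                    "species_richness": richness,
                    "mu": mus[i],
                    "sigma": sigmas[i],
                    "cv_percent": cv,
                }
            )
    return pd.DataFrame(rows)


def _draw_individuals(
    rng: np.random.Generator, mu: float, sigma: float, n: int, noise_model: str
) -> np.ndarray:
    if noise_model == "normal":
        vals = rng.normal(mu, sigma, size=n)
        # truncate to positive support by redrawing the (rare) tail
        for _ in range(100):
            bad = vals <= 0
            if not bad.any():
                break
            vals[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
        vals = np.abs(vals)  # last-resort guard; mass involved is negligible
    else:  # lognormal matched to the requested mean and CV
        cv2 = (sigma / mu) ** 2
        s_log = np.sqrt(np.log1p(cv2))
        m_log = np.log(mu) - 0.5 * s_log**2
        vals = rng.lognormal(m_log, s_log, size=n)
    return vals


def _n_individuals(cfg: ScenarioConfig, richness: int, rng: np.random.Generator) -> int:
    """Sampling effort per species: heavy in poor forests, minimal in rich ones."""
    if cfg.effort_rule == "constant":
        return cfg.individuals_per_species
    if richness <= 10:
        return int(rng.integers(15, 41))
    return int(rng.integers(5, 16))


def _climate(cfg: ScenarioConfig, richness: int, rng: np.random.Generator):
    if cfg.climate_coupled:
        mat = cfg.mat_intercept + cfg.mat_slope * richness + rng.normal(0, cfg.mat_sd)
        ap = cfg.ap_intercept + cfg.ap_slope * richness + rng.normal(0, cfg.ap_sd)
    else:
        mat = rng.normal(15.0, 8.0)
        ap = rng.normal(1800.0, 700.0)
    return float(np.clip(mat, -10.0, 35.0)), float(np.clip(ap, 200.0, 5000.0))


def generate_gradient(cfg: ScenarioConfig) -> Dataset:
    """Generate the full individual-level dataset for one scenario.

    Byte-identical for identical configs (all randomness flows from
    ``cfg.seed`` through keyed substreams).  The second trait column (SLA)
    is generated with the same scenario rules on its own scale so both
    trait pipelines can run.
    """
    params = community_parameters(cfg)
    sla_scale = 250.0 / float(params["mu"].max())  # SLA ~ up to 250 cm^2/g
    rec_rows = []
    meta_rows = []
    for forest, grp in params.groupby("forest_id", sort=True):
        richness = int(grp["species_richness"].iloc[0])
        crng = derive_rng(cfg.seed, "climate", forest)
        mat, ap = _climate(cfg, richness, crng)
        lat_rng = derive_rng(cfg.seed, "latlon", forest)
        latitude = float(np.clip(62.0 - 0.25 * richness + lat_rng.normal(0, 2.0), -15.0, 66.0))
        longitude = float(lat_rng.uniform(-80.0, 30.0))
        meta_rows.append(
            {
                "forest_id": forest,
                "forest_type": None,  # filled below (needs all richness values)
                "latitude": latitude,
                "longitude": longitude,
                "mat_c": mat,
                "ap_mm": ap,
                "species_richness": richness,
            }
        )
        for _, sp in grp.iterrows():
            rng = derive_rng(cfg.seed, "traits", forest, sp["species_id"])
            n = _n_individuals(cfg, richness, rng)
            leaf = _draw_individuals(rng, sp["mu"], sp["sigma"], n, cfg.noise_model)
            # SLA shares the placement structure but has its own (smaller)
            # within-species variability; scenario-B declines scale with it
            sla_sigma = sp["sigma"] * sla_scale * (cfg.sla_cv / cfg.base_cv)
            sla = _draw_individuals(
                rng, sp["mu"] * sla_scale, sla_sigma, n, cfg.noise_model
            )
            for j in range(n):
                rec_rows.append(
                    {
                        "forest_id": forest,
                        "species_id": sp["species_id"],
                        "individual_id": f"{sp['species_id']}_{j + 1:03d}",
                        "leaf_size": leaf[j],
                        "sla": sla[j],
                    }
                )
    meta = pd.DataFrame(meta_rows)
    meta["forest_type"] = _forest_types(meta["species_richness"].to_numpy())
    records = pd.DataFrame(rec_rows)
    return Dataset(records=records, meta=meta)


def expected_overlap_profile(cfg: ScenarioConfig) -> pd.DataFrame:
    """Analytic mean pairwise normal overlap per forest, from the true (mu, sigma).

    Only defined for the normal noise model (the lognormal overlap integral
    has no closed form here).  Forests with a single species have no pairs
    and report NaN.
    """
    if cfg.noise_model != "normal":
        raise ConfigError("expected_overlap_profile requires noise_model='normal'")
    params = community_parameters(cfg)
    rows = []
    for forest, grp in params.groupby("forest_id", sort=True):
        mu = grp["mu"].to_numpy()
        sd = grp["sigma"].to_numpy()
        if len(mu) < 2:
            mean_ov = float("nan")
            n_pairs = 0
        else:
            ia, ib = np.triu_indices(len(mu), k=1)
            ov = np.atleast_1d(normal_overlap(mu[ia], sd[ia], mu[ib], sd[ib]))
            mean_ov = float(ov.mean())
            n_pairs = len(ov)
        rows.append(
            {
                "forest_id": forest,
                "species_richness": int(grp["species_richness"].iloc[0]),
                "expected_mean_overlap": mean_ov,
                "n_pairs": n_pairs,
            }
        )
    return pd.DataFrame(rows)
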