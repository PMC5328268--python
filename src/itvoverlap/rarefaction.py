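"""Rarefied trait statistics per species.

Sampling intensity varies wildly between species (5 to ~70 individuals), and
the coefficient of variation (CV = 100*sd/mean) is sample-size biased.  Each
species is therefore rarefied to a common draw size: ``n_reps`` random
subsets of ``n_draw`` individuals are taken without replacement, the
statistic of interest is computed on every subset, and the replicate
statistics are averaged.  With the default aggregation each of mean, sd and
CV is the average of its own replicate values; the ``of_averages`` variant
instead forms 100*mean(sd_r)/mean(mean_r).

Per-group random substreams are derived from a master seed and the group key
only, so results do not depend on input row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .data_model import Dataset
from .errors import InsufficientDataError, InsufficientSampleError
from .seeding import derive_rng

DEFAULT_N_DRAW = 5
DEFAULT_N_REPS = 1000


@dataclass
class RarefiedStats:
    """Rarefied mean, sd and CV for one species in one forest."""

    forest_id: str | None
    species_id: str | None
    trait: str | None
    n_available: int
    mean_r: float
    sd_r: float
    cv_r: float
    n_draw: int
    n_reps: int
    seed: int | None


_group_rng = derive_rng


def _replicate_stats(values: np.ndarray, n_draw: int, n_reps: int, rng: np.random.Generator):
    n = values.size
    # n_reps independent draws without replacement, vectorized
    idx = np.argsort(rng.random((n_reps, n)), axis=1)[:, :n_draw]
    draws = values[idx]
    means = draws.mean(axis=1)
    sds = draws.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cvs = np.where(means != 0, 100.0 * sds / means, np.nan)
    return means, sds, cvs


def rarefied_stats(
    values,
    n_draw: int = DEFAULT_N_DRAW,
    n_reps: int = DEFAULT_N_REPS,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    aggregation: str = "per_replicate",
    forest_id: str | None = None,
    species_id: str | None = None,
    trait: str | None = None,
) -> RarefiedStats:
    """Rarefy one species' trait values to ``n_draw`` individuals.

    Parameters
    ----------
    values
        Positive trait values, one per individual; must have at least
        ``n_draw`` entries.
    aggregation
        ``per_replicate`` (default): mean_r, sd_r and cv_r are each the
        average of the per-subset statistic.  ``of_averages``: cv_r is
        recomputed as 100*sd_r/mean_r from the averaged mean and sd.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < n_draw:
        raise InsufficientSampleError(
            f"need at least n_draw={n_draw} values, got {values.size}"
        )
    if aggregation not in ("per_replicate", "of_averages"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    means, sds, cvs = _replicate_stats(values, n_draw, n_reps, rng)
    mean_r = float(means.mean())
    sd_r = float(sds.mean())
    if aggregation == "per_replicate":
        cv_r = float(cvs.mean())
    else:
        cv_r = 100.0 * sd_r / mean_r
    return RarefiedStats(
        forest_id=forest_id,
        species_id=species_id,
        trait=trait,
        n_available=int(values.size),
        mean_r=mean_r,
        sd_r=sd_r,
        cv_r=cv_r,
        n_draw=n_draw,
        n_reps=n_reps,
        seed=seed,
    )


def exhaustive_stats(values, n_draw: int = DEFAULT_N_DRAW, aggregation: str = "per_replicate"):
    """Exact all-subsets average of (mean, sd, CV); the n_reps->inf limit.

    Enumerates every size-``n_draw`` subset, so only usable for small pools;
    serves as the exact reference for the Monte-Carlo estimator.
    """
    from itertools import combinations

    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size < n_draw:
        raise InsufficientSampleError(f"need at least {n_draw} values")
    subs = np.array(list(combinations(values, n_draw)))
    means = subs.mean(axis=1)
    sds = subs.std(axis=1, ddof=1)
    mean_r = means.mean()
    sd_r = sds.mean()
    if aggregation == "per_replicate":
        cv_r = float((100.0 * sds / means).mean())
    else:
        cv_r = 100.0 * sd_r / mean_r
    return float(mean_r), float(sd_r), cv_r


def rarefy_dataset(
    ds: Dataset,
    trait: str,
    n_draw: int = DEFAULT_N_DRAW,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    aggregation: str = "per_replicate",
) -> pd.DataFrame:
    """Rarefied statistics for every qualifying (forest, species) group.

    Expects a dataset already passed through ``filter_min_individuals`` for
    the same trait (groups below ``n_draw`` raise).  Returns one row per
    group with columns forest_id, species_id, trait, n_available, mean_r,
    sd_r, cv_r, n_draw, n_reps, and species_richness when metadata is
    attached.
    """
    rows = []
    for (forest, species), grp in ds.records.groupby(["forest_id", "species_id"], sort=True):
        # canonical value order so results are invariant to input row order
        vals = np.sort(grp[trait].dropna().to_numpy())
        st = rarefied_stats(
            vals,
            n_draw=n_draw,
            n_reps=n_reps,
            rng=_group_rng(seed, forest, species, trait),
            aggregation=aggregation,
            forest_id=forest,
            species_id=species,
            trait=trait,
        )
        rows.append(
            {
                "forest_id": forest,
                "species_id": species,
                "trait": trait,
                "n_available": st.n_available,
                "mean_r": st.mean_r,
                "sd_r": st.sd_r,
                "cv_r": st.cv_r,
                "n_draw": n_draw,
                "n_reps": n_reps,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "forest_id",
            "species_id",
            "trait",
            "n_available",
            "mean_r",
            "sd_r",
            "cv_r",
            "n_draw",
            "n_reps",
        ],
    )
    if ds.meta is not None and len(out):
        out = out.merge(
            ds.meta[["forest_id", "species_richness"]], on="forest_id", how="left"
        )
    return out


def rank_stability(
    values_by_species: dict,
    n_big: int = 10,
    n_small: int = DEFAULT_N_DRAW,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
) -> float:
    """r^2 of species CV ranks at a large draw size vs the standard small one.

    Only species with at least ``n_big`` individuals enter.  Rarefied CV is
    computed at both draw sizes, species are ranked under each (midranks for
    ties), and the squared Pearson correlation of the two rank vectors is
    returned; a value near 1 means the small draw preserves the CV ordering.
    """
    eligible = {
        sp: np.asarray(v, dtype=float)
        for sp, v in values_by_species.items()
        if np.sum(~np.isnan(np.asarray(v, dtype=float))) >= n_big
    }
    if len(eligible) < 3:
        raise InsufficientDataError(
            f"need >= 3 species with >= {n_big} individuals, got {len(eligible)}"
        )
    cv_small, cv_big = [], []
    for sp, vals in sorted(eligible.items()):
        cv_small.append(
            rarefied_stats(vals, n_draw=n_small, n_reps=n_reps,
                           rng=_group_rng(seed, sp, "small")).cv_r
        )
        cv_big.append(
            rarefied_stats(vals, n_draw=n_big, n_reps=n_reps,
                           rng=_group_rng(seed, sp, "big")).cv_r
        )
    r_small = scipy.stats.rankdata(cv_small)
    r_big = scipy.stats.rankdata(cv_big)
    if np.ptp(r_small) == 0 or np.ptp(r_big) == 0:
        return 1.0 if np.array_equal(r_small, r_big) else 0.0
    r, _ = scipy.stats.pearsonr(r_small, r_big)
    return float(r * r)


def sample_size_bias_check(stats: pd.DataFrame, bins=7) -> pd.DataFrame:
    """Distribution of rarefied CV by sample-size category.

    Groups species by ``n_available`` into ``bins`` (an integer number of
    equal-count categories, or explicit bin edges) and summarizes cv_r per
    bin; a systematic trend of the bin medians with sample size would flag
    residual sample-size bias in the rarefied CV.
    """
    if stats.empty:
        raise InsufficientDataError("no rarefied statistics to bin")
    n = stats["n_available"]
    if np.isscalar(bins):
        if n.nunique() == 1:
            cats = pd.Series(
                pd.Categorical([f"[{n.iloc[0]}]"] * len(stats)), index=stats.index
            )
        else:
            cats = pd.qcut(n, q=min(int(bins), n.nunique()), duplicates="drop")
    else:
        cats = pd.cut(n, bins=bins, include_lowest=True)
    out = (
        stats.assign(size_bin=cats)
        .groupby("size_bin", observed=True)
        .agg(
            n_species=("cv_r", "size"),
            median_n=("n_available", "median"),
            cv_median=("cv_r", "median"),
            cv_q1=("cv_r", lambda s: s.quantile(0.25)),
            cv_q3=("cv_r", lambda s: s.quantile(0.75)),
        )
        .reset_index()
    )
    return out
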