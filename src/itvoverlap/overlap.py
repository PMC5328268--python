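"""Pairwise trait overlap between co-occurring species.

Overlap between two species is the shared area under their trait probability
density curves, ∫ min(f1, f2) dx ∈ [0, 1]: 1 means identical trait
distributions, 0 disjoint ones.  Two estimators are provided:

* ``normal_overlap`` treats each species as N(mu, sigma^2) — here mu and
  sigma are the rarefied mean and sd — and evaluates the minimum-density
  integral in closed form from the intersection points of the two densities.
* ``kernel_overlap`` makes no shape assumption: each species' individuals
  are smoothed with a Gaussian kernel (nrd0 rule-of-thumb bandwidth), both
  densities are evaluated on a shared grid, renormalized, and the pointwise
  minimum is integrated by the trapezoid rule.

Per-community summaries reduce the S*(S-1)/2 pair values to a median and the
tail shares below 0.25 / above 0.75.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .data_model import Dataset
from .errors import InsufficientSpeciesError

LOW_THRESHOLD = 0.25
HIGH_THRESHOLD = 0.75
GRID_POINTS = 512


@dataclass
class OverlapMatrix:
    """All unordered pairwise overlaps within one forest for one trait."""

    forest_id: str
    trait: str
    method: str
    pairs: pd.DataFrame  # columns: species_a, species_b, overlap


@dataclass
class OverlapSummary:
    """Median and tail proportions of a forest's pairwise overlap values."""

    forest_id: str
    trait: str
    method: str
    median_overlap: float
    prop_low: float
    prop_high: float
    n_pairs: int


def normal_overlap(mu1, sigma1, mu2, sigma2):
    """Closed-form overlap area of two normal densities.

    Solves the log-density equality for the intersection points (one point
    for equal sigmas, two otherwise) and assembles the minimum-density mass
    from normal CDF tail/central pieces.  Vectorized; scalar inputs return a
    float.  Degenerate sigma = 0 (all individuals identical) gives 1 for
    coincident point distributions and 0 otherwise.
    """
    mu1, s1, mu2, s2 = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (mu1, sigma1, mu2, sigma2))
    )
    if (s1 < 0).any() or (s2 < 0).any():
        raise ValueError("sigma must be non-negative")
    out = np.empty(mu1.shape, dtype=float)

    degen = (s1 == 0) | (s2 == 0)
    out[degen] = np.where(
        (mu1[degen] == mu2[degen]) & (s1[degen] == s2[degen]), 1.0, 0.0
    )

    # orient so that a is the narrower (or equal) density
    swap = s1 > s2
    ma = np.where(swap, mu2, mu1)
    sa = np.where(swap, s2, s1)
    mb = np.where(swap, mu1, mu2)
    sb = np.where(swap, s1, s2)

    eq = ~degen & np.isclose(sa, sb, rtol=1e-12, atol=0.0)
    if eq.any():
        # single crossing at the midpoint: each density contributes one tail
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.abs(ma - mb) / (2.0 * np.where(sa > 0, sa, 1.0))
        out[eq] = 2.0 * ndtr(-z[eq])

    gen = ~degen & ~eq
    if gen.any():
        ma_, sa_, mb_, sb_ = ma[gen], sa[gen], mb[gen], sb[gen]
        # log f_a = log f_b  <=>  A x^2 + B x + C = 0
        ia, ib = 1.0 / sa_**2, 1.0 / sb_**2
        A = ia - ib  # > 0 since sa < sb
        B = -2.0 * (ma_ * ia - mb_ * ib)
        C = ma_**2 * ia - mb_**2 * ib - 2.0 * np.log(sb_ / sa_)
        disc = B * B - 4.0 * A * C  # always > 0 for unequal sigmas
        root = np.sqrt(np.maximum(disc, 0.0))
        x1 = (-B - root) / (2.0 * A)
        x2 = (-B + root) / (2.0 * A)
        # between the crossings the narrow density dominates -> min is f_b;
        # outside, the wide density's fatter tails dominate -> min is f_a
        out[gen] = (
            ndtr((x1 - ma_) / sa_)
            + (1.0 - ndtr((x2 - ma_) / sa_))
            + (ndtr((x2 - mb_) / sb_) - ndtr((x1 - mb_) / sb_))
        )

    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def nrd0_bandwidth(values) -> float:
    """Rule-of-thumb Gaussian-kernel bandwidth 0.9*min(sd, IQR/1.34)*n^(-1/5).

    Falls back to sd, then |mean|, then 1 when the spread estimates are zero,
    so a degenerate sample still yields a positive bandwidth.
    """
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("empty sample")
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    lo = min(sd, iqr / 1.34) if iqr > 0 else sd
    if lo == 0:
        lo = sd or abs(x.mean()) or 1.0
    return float(0.9 * lo * x.size ** (-0.2))


def _kde_on_grid(values: np.ndarray, grid: np.ndarray, bw: float) -> np.ndarray:
    z = (grid[:, None] - values[None, :]) / bw
    dens = np.exp(-0.5 * z * z).sum(axis=1) / (values.size * bw * math.sqrt(2 * math.pi))
    area = np.trapezoid(dens, grid)
    return dens / area if area > 0 else dens


def kernel_overlap(
    values1,
    values2,
    bandwidth_rule: str = "nrd0",
    grid_points: int = GRID_POINTS,
) -> float:
    """Overlap area of two Gaussian-kernel density estimates.

    Both densities are evaluated on one grid spanning the union of the two
    sample ranges extended by three bandwidths, renormalized to unit mass on
    the grid, and the trapezoid integral of their pointwise minimum is
    returned, clipped to [0, 1].
    """
    v1 = np.asarray(values1, dtype=float)
    v2 = np.asarray(values2, dtype=float)
    v1, v2 = v1[~np.isnan(v1)], v2[~np.isnan(v2)]
    if v1.size == 0 or v2.size == 0:
        raise ValueError("empty sample")
    if bandwidth_rule != "nrd0":
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    bw1, bw2 = nrd0_bandwidth(v1), nrd0_bandwidth(v2)
    pad = 3.0 * max(bw1, bw2)
    lo = min(v1.min(), v2.min()) - pad
    hi = max(v1.max(), v2.max()) + pad
    grid = np.linspace(lo, hi, grid_points)
    d1 = _kde_on_grid(v1, grid, bw1)
    d2 = _kde_on_grid(v2, grid, bw2)
    ov = np.trapezoid(np.minimum(d1, d2), grid)
    return float(np.clip(ov, 0.0, 1.0))


def pairwise_overlap(
    forest_data,
    trait: str,
    method: str = "normal",
    forest_id: str | None = None,
    **params,
) -> OverlapMatrix:
    """Overlap for every unordered species pair sampled in one forest.

    ``forest_data`` is a DataFrame: for ``method='normal'`` the per-species
    rarefied summaries (columns species_id, mean_r, sd_r); for
    ``method='kernel'`` the raw individual records (columns species_id and
    the trait column).  Fewer than two species raises
    :class:`InsufficientSpeciesError`.
    """
    df = forest_data
    if forest_id is None:
        forest_id = str(df["forest_id"].iloc[0]) if "forest_id" in df else "?"
    if method == "normal":
        sub = df.sort_values("species_id")
        species = sub["species_id"].to_numpy()
        if len(species) < 2:
            raise InsufficientSpeciesError(
                f"forest {forest_id}: need >= 2 species, got {len(species)}"
            )
        mu = sub["mean_r"].to_numpy(dtype=float)
        sd = sub["sd_r"].to_numpy(dtype=float)
        ia, ib = np.triu_indices(len(species), k=1)
        ov = normal_overlap(mu[ia], sd[ia], mu[ib], sd[ib])
        pairs = pd.DataFrame(
            {"species_a": species[ia], "species_b": species[ib], "overlap": np.atleast_1d(ov)}
        )
    elif method == "kernel":
        grid_points = int(params.pop("grid_points", GRID_POINTS))
        rule = params.pop("bandwidth_rule", "nrd0")
        if rule != "nrd0":
            raise ValueError(f"unknown bandwidth rule {rule!r}")
        if params:
            raise TypeError(f"unknown kernel parameters {sorted(params)}")
        groups = {
            sp: grp[trait].dropna().to_numpy(dtype=float)
            for sp, grp in df.groupby("species_id", sort=True)
        }
        groups = {sp: v for sp, v in groups.items() if v.size > 0}
        species = sorted(groups)
        if len(species) < 2:
            raise InsufficientSpeciesError(
                f"forest {forest_id}: need >= 2 species, got {len(species)}"
            )
        # bandwidths and ranges depend on one species only: compute once
        prep = {
            sp: (groups[sp], nrd0_bandwidth(groups[sp]), groups[sp].min(), groups[sp].max())
            for sp in species
        }
        rows = []
        for i, sa in enumerate(species):
            v1, bw1, lo1, hi1 = prep[sa]
            for sb in species[i + 1:]:
                v2, bw2, lo2, hi2 = prep[sb]
                pad = 3.0 * max(bw1, bw2)
                grid = np.linspace(min(lo1, lo2) - pad, max(hi1, hi2) + pad, grid_points)
                d1 = _kde_on_grid(v1, grid, bw1)
                d2 = _kde_on_grid(v2, grid, bw2)
                ov = np.trapezoid(np.minimum(d1, d2), grid)
                rows.append((sa, sb, float(np.clip(ov, 0.0, 1.0))))
        pairs = pd.DataFrame(rows, columns=["species_a", "species_b", "overlap"])
    else:
        raise ValueError(f"unknown method {method!r}")
    return OverlapMatrix(forest_id=str(forest_id), trait=trait, method=method, pairs=pairs)


def dataset_overlap(
    ds: Dataset,
    trait: str,
    method: str = "normal",
    rarefied: pd.DataFrame | None = None,
    **params,
) -> tuple[list[OverlapMatrix], list[str]]:
    """Pairwise overlap for every forest with >= 2 sampled species.

    Returns the per-forest matrices and the ids of forests skipped for
    having fewer than two species (they are excluded from summaries).
    """
    matrices, skipped = [], []
    if method == "normal":
        if rarefied is None:
            raise ValueError("normal method requires the rarefied summaries")
        sub = rarefied[rarefied["trait"] == trait] if "trait" in rarefied else rarefied
        groups = sub.groupby("forest_id", sort=True)
    else:
        groups = ds.records.groupby("forest_id", sort=True)
    for forest, grp in groups:
        try:
            matrices.append(
                pairwise_overlap(grp, trait=trait, method=method, forest_id=forest, **params)
            )
        except InsufficientSpeciesError:
            skipped.append(str(forest))
    return matrices, skipped


def summarize_overlap(
    m: OverlapMatrix, low: float = LOW_THRESHOLD, high: float = HIGH_THRESHOLD
) -> OverlapSummary:
    """Median and strict-inequality tail shares of one forest's pair values."""
    ov = m.pairs["overlap"].to_numpy(dtype=float)
    if ov.size == 0:
        raise InsufficientSpeciesError(f"forest {m.forest_id}: no pairs to summarize")
    return OverlapSummary(
        forest_id=m.forest_id,
        trait=m.trait,
        method=m.method,
        median_overlap=float(np.median(ov)),
        prop_low=float(np.mean(ov < low)),
        prop_high=float(np.mean(ov > high)),
        n_pairs=int(ov.size),
    )


def summaries_table(summaries) -> pd.DataFrame:
    """Stack per-forest summaries into the deposited-data sheet layout."""
    return pd.DataFrame(
        [
            {
                "forest_id": s.forest_id,
                "trait": s.trait,
                "method": s.method,
                "median_overlap": s.median_overlap,
                "prop_low": s.prop_low,
                "prop_high": s.prop_high,
                "n_pairs": s.n_pairs,
            }
            for s in summaries
        ]
    )
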