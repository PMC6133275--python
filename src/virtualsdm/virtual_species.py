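"""Virtual species: Gaussian niches and the colonization-extinction automaton.

A species is a Gaussian (bell-shaped) suitability function in environmental
space: suitability 1 at the niche centroid, falling off with squared
standardized distance, with per-variable variance equal to a tolerance
fraction of each variable's variance across the study area.  The "true"
geographic range is then grown from a seed cell by a stochastic cellular
automaton in which suitability acts both as colonization and persistence
probability, with clamps that make very good habitat (suitability > 0.9)
permanently occupied once reached and very poor habitat (< 0.1)
uncolonizable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .rasters import GridDef, Layer, RasterStack
from .rng import substream

__all__ = [
    "NicheSpec",
    "AutomatonParams",
    "OccupancyMap",
    "choose_centroids",
    "gaussian_suitability",
    "select_seed_cell",
    "simulate_range",
    "prevalence",
]


@dataclass
class NicheSpec:
    """Centroid and diagonal covariance of a species' Grinnellian niche.

    ``variances[k] = tolerance_fraction * Var_k(study area)``; narrow
    species use a fraction of 0.2, wide species 0.6.
    """

    species_id: str
    centroid: np.ndarray
    tolerance_fraction: float
    variances: np.ndarray
    tolerance_class: str = ""

    def __post_init__(self):
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        if len(self.centroid) != len(self.variances):
            raise ValueError("centroid and variances must have equal length")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive")
        if not self.tolerance_class:
            self.tolerance_class = "narrow" if self.tolerance_fraction <= 0.4 else "wide"


@dataclass(frozen=True)
class AutomatonParams:
    """Colonization-extinction automaton settings.

    Suitability below ``low_clamp`` means certain absence; above
    ``high_clamp`` certain persistence.  Each occupied cell makes
    ``attempts_per_cell`` dispersal attempts per iteration, each jumping a
    uniform 1..max_jump cells (Chebyshev distance).
    """

    low_clamp: float = 0.1
    high_clamp: float = 0.9
    attempts_per_cell: int = 3
    max_jump: int = 5
    n_iterations: int = 100
    stop_window: int | None = None
    stop_tol: float | None = None
    rng_seed: int = 0
    extinction_spares_new_colonists: bool = False

    def __post_init__(self):
        if not 0 <= self.low_clamp < self.high_clamp <= 1:
            raise ValueError("require 0 <= low_clamp < high_clamp <= 1")
        if self.max_jump < 1 or self.attempts_per_cell < 1:
            raise ValueError("max_jump and attempts_per_cell must be >= 1")


@dataclass
class OccupancyMap:
    """Boolean truth map produced by the automaton."""

    grid: GridDef
    occupied: np.ndarray  # bool, subset of the land mask
    mask: np.ndarray
    species_id: str = ""
    realization_seed: int = 0
    warning: str | None = None

    def __post_init__(self):
        self.occupied = np.asarray(self.occupied, dtype=bool)
        if np.any(self.occupied & ~self.mask):
            raise ValueError("occupied cells must lie within the mask")

    @property
    def range_size(self) -> int:
        return int(self.occupied.sum())


def _neighborhood_env_matrix(stack: RasterStack, sigma: float = 2.0) -> np.ndarray:
    """Per-cell environmental vectors averaged over a Gaussian spatial
    neighborhood (mask-aware), used to find locally typical cells."""
    from scipy import ndimage

    m = stack.mask
    weight = ndimage.gaussian_filter(m.astype(float), sigma)
    cols = []
    for lyr in stack.layers:
        s = ndimage.gaussian_filter(np.where(m, lyr.values, 0.0), sigma)
        cols.append((s / np.maximum(weight, 1e-9))[m])
    return np.column_stack(cols)


def choose_centroids(stack: RasterStack, k: int, seed: int) -> list[np.ndarray]:
    """Pick k niche centroids spread across environmental space.

    Clusters the masked cells' standardized, spatially neighborhood-
    averaged environmental vectors into k groups (k-means) and returns
    the raw environmental vector of the locally typical cell nearest each
    cluster centre — candidates are restricted to the half of cells whose
    own vector deviates least from their neighborhood mean, so centroids
    sit at the cores of coherent climatic regions rather than on isolated
    texture spikes.  Ordered by cluster size (largest first);
    deterministic per seed.
    """
    X = stack.env_matrix()
    if k < 1 or k > X.shape[0]:
        raise ValueError("k must be between 1 and the number of masked cells")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError("fewer distinct environmental vectors than k")
    Xs = _neighborhood_env_matrix(stack)
    mu, sd = Xs.mean(axis=0), Xs.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    Zs = (Xs - mu) / sd
    Z = (X - mu) / sd
    tex = np.linalg.norm(Z - Zs, axis=1)
    candidates = np.nonzero(tex <= np.quantile(tex, 0.5))[0]
    km = KMeans(
        n_clusters=k,
        n_init=4,
        random_state=int(substream(seed, "centroids").integers(2**31 - 1)),
    ).fit(Zs)
    centroids = []
    order = np.argsort(-np.bincount(km.labels_, minlength=k), kind="stable")
    for lbl in order:
        d2 = ((Z[candidates] - km.cluster_centers_[lbl]) ** 2).sum(axis=1)
        centroids.append(X[candidates[np.argmin(d2)]].copy())
    return centroids


def make_niche(
    stack: RasterStack, centroid: np.ndarray, tolerance_fraction: float, species_id: str
) -> NicheSpec:
    """NicheSpec with per-variable variance = fraction x study-area variance."""
    var = stack.env_matrix().var(axis=0, ddof=1)
    return NicheSpec(
        species_id=species_id,
        centroid=centroid,
        tolerance_fraction=tolerance_fraction,
        variances=tolerance_fraction * var,
    )


def gaussian_suitability(niche: NicheSpec, stack: RasterStack) -> Layer:
    """S(x) = exp(-1/2 * sum_k (x_k - mu_k)^2 / sigma^2_k), equal to 1 at the centroid."""
    if stack.n_layers != len(niche.centroid):
        raise ValueError("stack layer count does not match niche dimension")
    X = stack.env_matrix()
    d2 = (((X - niche.centroid) ** 2) / niche.variances).sum(axis=1)
    s = np.exp(-0.5 * d2)
    vals = np.full(stack.grid.shape, np.nan)
    vals[stack.mask] = s
    return Layer(stack.grid, vals, stack.mask.copy())


def select_seed_cell(suitability: Layer, rng: np.random.Generator) -> tuple[int, int]:
    """A cell attaining maximum suitability; ties broken uniformly at random."""
    m = suitability.mask
    if not m.any():
        raise ValueError("empty mask")
    vals = suitability.values
    best = np.nanmax(vals[m])
    rows, cols = np.nonzero(m & (vals == best))
    i = rng.integers(len(rows))
    return int(rows[i]), int(cols[i])


def _ring_offsets(d: np.ndarray, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map (distance d, index u in [0, 8d)) to a unique cell offset on the
    Chebyshev ring of radius d (the 8d cells at exactly that distance)."""
    seg, pos = u // (2 * d), u % (2 * d) - d
    dr = np.where(seg == 0, -d, np.where(seg == 1, pos, np.where(seg == 2, d, -pos)))
    dc = np.where(seg == 0, pos, np.where(seg == 1, d, np.where(seg == 2, -pos, -d)))
    return dr, dc


def effective_probability(suitability: np.ndarray, params: AutomatonParams) -> np.ndarray:
    """Clamped suitability: 0 below low_clamp, 1 above high_clamp, else S."""
    return np.where(
        suitability < params.low_clamp,
        0.0,
        np.where(suitability > params.high_clamp, 1.0, suitability),
    )


def simulate_range(
    suitability: Layer,
    params: AutomatonParams,
    species_id: str = "",
    seed_cell: tuple[int, int] | None = None,
) -> OccupancyMap:
    """Grow a range from a seed cell by iterated colonization and extinction.

    Each iteration: (1) every cell occupied at iteration start makes
    ``attempts_per_cell`` dispersal attempts, each drawing a jump distance
    uniform on 1..max_jump and a target uniform on the Chebyshev ring at
    exactly that distance; an unoccupied in-mask target is colonized with
    its clamped suitability; (2) every occupied cell (newly colonized ones
    included) then survives with its clamped suitability.  Colonization
    before extinction permits rescue effects.  Pure function of
    (suitability, params, seed cell).
    """
    g = suitability.grid
    mask = suitability.mask
    p_eff = np.where(mask, effective_probability(suitability.values, params), 0.0)
    rng = substream(params.rng_seed, "automaton", species_id)
    if seed_cell is None:
        seed_cell = select_seed_cell(suitability, rng)
    occupied = np.zeros(g.shape, dtype=bool)
    occupied[seed_cell] = True
    warning = None
    if p_eff[seed_cell] == 0.0:
        warning = "seed cell has zero effective suitability"
    sizes: list[int] = []
    for _ in range(params.n_iterations):
        src_r, src_c = np.nonzero(occupied)
        n_src = len(src_r)
        if n_src:
            A = params.attempts_per_cell
            src_r = np.repeat(src_r, A)
            src_c = np.repeat(src_c, A)
            d = rng.integers(1, params.max_jump + 1, size=n_src * A)
            u = rng.integers(0, 8 * d)
            dr, dc = _ring_offsets(d, u)
            tr, tc = src_r + dr, src_c + dc
            ok = (tr >= 0) & (tr < g.nrows) & (tc >= 0) & (tc < g.ncols)
            tr, tc = tr[ok], tc[ok]
            accept = rng.random(len(tr)) < p_eff[tr, tc]
            new_r, new_c = tr[accept], tc[accept]
            if params.extinction_spares_new_colonists:
                old = occupied.copy()
            occupied[new_r, new_c] = True
        # extinction sweep
        occ_r, occ_c = np.nonzero(occupied)
        die = rng.random(len(occ_r)) >= p_eff[occ_r, occ_c]
        if params.extinction_spares_new_colonists and n_src:
            die &= old[occ_r, occ_c]
        occupied[occ_r[die], occ_c[die]] = False
        sizes.append(int(occupied.sum()))
        if (
            params.stop_window is not None
            and params.stop_tol is not None
            and len(sizes) >= params.stop_window + 1
        ):
            ref = sizes[-params.stop_window - 1]
            if ref > 0 and all(
                abs(s - ref) / ref < params.stop_tol for s in sizes[-params.stop_window:]
            ):
                break
    if occupied.sum() <= 1 and warning is None:
        warning = "range collapsed to at most the seed cell"
    return OccupancyMap(
        grid=g,
        occupied=occupied,
        mask=mask.copy(),
        species_id=species_id,
        realization_seed=params.rng_seed,
        warning=warning,
    )


def prevalence(occ: OccupancyMap) -> float:
    """Occupied cells / masked cells."""
    return float(occ.occupied.sum() / occ.mask.sum())
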