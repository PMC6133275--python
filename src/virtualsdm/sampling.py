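"""Occurrence and background sampling.

Occurrences are cells drawn uniformly without replacement from the
occupied cells of a truth map (default 50 per replicate, 10 replicates);
background points are cells drawn uniformly from the whole land mask
(default 10,000).  Environmental values are extracted afterwards against
whichever predictor stack a model is fitted on, so switching predictor
sets never resamples cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rasters import RasterStack
from .rng import substream
from .virtual_species import OccupancyMap

__all__ = [
    "OccurrenceSample",
    "BackgroundSample",
    "sample_occurrences",
    "sample_background",
]


@dataclass
class OccurrenceSample:
    """Presence cells for one replicate of one species."""

    species_id: str
    replicate_id: int
    rows: np.ndarray
    cols: np.ndarray
    rng_seed: int = 0

    @property
    def n(self) -> int:
        return len(self.rows)

    def env_values(self, stack: RasterStack) -> np.ndarray:
        return stack.extract(self.rows, self.cols)


@dataclass
class BackgroundSample:
    """Background cells shared across models."""

    rows: np.ndarray
    cols: np.ndarray

    @property
    def n(self) -> int:
        return len(self.rows)

    def env_values(self, stack: RasterStack) -> np.ndarray:
        return stack.extract(self.rows, self.cols)


def sample_occurrences(
    occ: OccupancyMap,
    n: int,
    replicates: int,
    master_seed: int,
    strict: bool = True,
) -> list[OccurrenceSample]:
    """Uniform without-replacement samples of occupied cells.

    Each replicate draws from its own named substream, so replicate r is
    reproducible independently of how many replicates are requested.
    """
    rows, cols = np.nonzero(occ.occupied)
    n_occ = len(rows)
    if n_occ < n:
        if strict:
            raise ValueError(
                f"species {occ.species_id!r}: {n_occ} occupied cells < requested {n}"
            )
        n = n_occ
    out = []
    for rep in range(1, replicates + 1):
        rng = substream(master_seed, "occurrences", occ.species_id, rep)
        idx = rng.choice(n_occ, size=n, replace=False)
        out.append(
            OccurrenceSample(
                species_id=occ.species_id,
                replicate_id=rep,
                rows=rows[idx],
                cols=cols[idx],
                rng_seed=master_seed,
            )
        )
    return out


def sample_background(
    mask: np.ndarray, m: int, master_seed: int, purpose: str = "background"
) -> BackgroundSample:
    """Uniform without-replacement sample of masked cells (all of them if m
    exceeds the masked count)."""
    rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
    n_mask = len(rows)
    if n_mask < 1:
        raise ValueError("mask has no valid cells")
    if m >= n_mask:
        return BackgroundSample(rows=rows, cols=cols)
    rng = substream(master_seed, purpose)
    idx = rng.choice(n_mask, size=m, replace=False)
    return BackgroundSample(rows=rows[idx], cols=cols[idx])
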