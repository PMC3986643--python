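"""Sliding-window grid construction, point assignment, standardization and
top-fraction flagging.

Windows are 0-based half-open ``[start, start + width)`` intervals anchored at
bp 0 on every chromosome.  The default geometry is 250 kb windows advanced in
50 kb steps, so an interior point falls in ``width // step`` windows and the
grid decomposes into exactly that many non-overlapping tilings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core import GenomeMap

logger = logging.getLogger(__name__)

DEFAULT_WIDTH = 250_000
DEFAULT_STEP = 50_000
DEFAULT_TOP_FRACTION = 0.05


@dataclass(frozen=True)
class WindowGrid:
    """Ordered sliding windows: parallel chrom/start arrays plus geometry."""

    chrom: np.ndarray
    start: np.ndarray
    width: int
    step: int

    @property
    def end(self) -> np.ndarray:
        return self.start + self.width

    @property
    def n_windows(self) -> int:
        return int(len(self.start))

    def __len__(self) -> int:
        return self.n_windows


def expected_segment_age(map_length_morgan: float) -> float:
    """Expected age in generations of a segment of the given genetic length.

    Uses the reciprocal-map-length approximation: a segment of ``c`` Morgan is
    expected to have persisted intact for about ``1 / c`` generations (0.0025
    Morgan -> 400 generations), which motivates the default window width.
    """
    if map_length_morgan <= 0:
        raise ValueError("map length must be positive")
    return 1.0 / map_length_morgan


def build_grid(
    gmap: GenomeMap, width: int = DEFAULT_WIDTH, step: int = DEFAULT_STEP
) -> WindowGrid:
    """Build the sliding-window grid over every chromosome of the map.

    Windows start at 0, step, 2*step, ... while ``start + width`` stays within
    the chromosome length.  ``width`` must be a multiple of ``step`` so that
    the grid decomposes into exact non-overlapping subsets.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    if width % step != 0:
        raise ValueError("width must be a multiple of step")
    chroms: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    for c in gmap.chromosomes():
        length = gmap.chrom_lengths[c]
        if length < width:
            logger.warning("chromosome %s shorter than window width: 0 windows", c)
            continue
        n = (length - width) // step + 1
        starts.append(np.arange(n, dtype=np.int64) * step)
        chroms.append(np.full(n, c, dtype=np.int64))
    if chroms:
        chrom = np.concatenate(chroms)
        start = np.concatenate(starts)
    else:
        chrom = np.empty(0, dtype=np.int64)
        start = np.empty(0, dtype=np.int64)
    return WindowGrid(chrom=chrom, start=start, width=width, step=step)


def assign_points(
    grid: WindowGrid, chrom: np.ndarray, pos: np.ndarray
) -> list[np.ndarray]:
    """Assign points to every window whose half-open interval contains them.

    Returns, per window, the sorted indices of the points it contains.  Points
    falling outside every window are counted and logged, not an error.
    """
    chrom = np.asarray(chrom, dtype=np.int64)
    pos = np.asarray(pos, dtype=np.int64)
    out: list[np.ndarray] = [np.empty(0, dtype=np.int64)] * grid.n_windows
    assigned = np.zeros(len(pos), dtype=bool)
    for c in np.unique(grid.chrom):
        windows = np.flatnonzero(grid.chrom == c)
        pmask = np.flatnonzero(chrom == c)
        p = pos[pmask]  # sorted within chromosome (precondition)
        for w in windows:
            s = int(grid.start[w])
            lo = int(np.searchsorted(p, s, side="left"))
            hi = int(np.searchsorted(p, s + grid.width, side="left"))
            out[w] = pmask[lo:hi]
            assigned[pmask[lo:hi]] = True
    unassigned = int(len(pos) - np.count_nonzero(assigned))
    if unassigned:
        logger.info("%d points fell outside every window", unassigned)
    return out


def standardize(values: np.ndarray) -> np.ndarray:
    """Divide each window value by the mean over finite windows (mean -> 1).

    Non-finite entries propagate as missing and are excluded from the mean.
    """
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("no finite values to standardize")
    mean = values[finite].mean()
    if mean == 0:
        raise ValueError("mean of window values is zero; cannot standardize")
    out = np.full_like(values, np.nan)
    out[finite] = values[finite] / mean
    return out


def flag_top_fraction(
    values: np.ndarray, q: float = DEFAULT_TOP_FRACTION
) -> np.ndarray:
    """Flag the ``ceil(q * n_finite)`` largest finite values.

    Ties at the threshold are broken by genomic order: among equal values the
    earlier window wins, keeping the flagged count exact and deterministic.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values)
    n_finite = int(finite.sum())
    flags = np.zeros(len(values), dtype=bool)
    if n_finite == 0:
        return flags
    k = math.ceil(q * n_finite)
    idx = np.flatnonzero(finite)
    # stable sort by descending value; stability gives earlier-window tie-break
    order = idx[np.argsort(-values[idx], kind="stable")]
    flags[order[:k]] = True
    return flags


def nonoverlapping_subsets(grid: WindowGrid) -> list[np.ndarray]:
    """Split the grid into ``width // step`` disjoint non-overlapping tilings.

    Subset ``i`` holds the windows whose start is congruent to ``i * step``
    modulo ``width``; within a subset windows tile each chromosome without
    overlap, and the union of subsets is the original grid.
    """
    k = grid.width // grid.step
    phase = (grid.start // grid.step) % k
    return [np.flatnonzero(phase == i) for i in range(k)]
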