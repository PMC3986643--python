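"""Haplotype-homozygosity statistic (HAPH) over 30/31-SNP segments.

HAPH at a segment is the population variance of the frequencies of the
distinct haplotypes observed there:

    HAPH = (1/N) * sum_i (p_i - 1/N)^2

with ``p_i`` the within-population frequency of the i-th distinct haplotype
and ``N`` the number of distinct haplotypes.  A fixed segment (N = 1) scores
0; the score is large when one haplotype is common and the rest are rare.
Segment scores are averaged into sliding windows by segment midpoint and
mean-standardized per population; runs of top-fraction windows closer than a
gap threshold merge into sweep regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING_ALLELE, GenomeMap, HaplotypePanel
from .windows import WindowGrid, assign_points, flag_top_fraction, standardize

logger = logging.getLogger(__name__)

SEGMENT_LENGTH = 30
MERGE_GAP = 1_000_000


@dataclass(frozen=True)
class SegmentPartition:
    """Non-overlapping segments of 30-31 consecutive SNPs per chromosome."""

    chrom: np.ndarray  # per segment
    start_idx: np.ndarray  # first SNP index (into the map)
    stop_idx: np.ndarray  # one-past-last SNP index
    midpoint: np.ndarray  # bp midpoint of first/last SNP

    @property
    def n_segments(self) -> int:
        return int(len(self.start_idx))


@dataclass(frozen=True)
class SweepRegion:
    chrom: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def segment_partition(gmap: GenomeMap, base_length: int = SEGMENT_LENGTH) -> SegmentPartition:
    """Partition each chromosome's SNPs into segments of 30 or 31.

    With ``n = q * 30 + r`` SNPs the first ``r`` segments are widened to 31 so
    every segment has 30 or 31 SNPs and none is short.  Chromosomes with fewer
    than 30 SNPs yield no segments (warning logged).
    """
    chroms, starts, stops, mids = [], [], [], []
    for c in gmap.chromosomes():
        idx = gmap.snp_indices(c)
        n = len(idx)
        if n < base_length:
            logger.warning("chromosome %s has %d SNPs (<%d): skipped", c, n, base_length)
            continue
        q, r = divmod(n, base_length)
        # widen the first r segments to 31; if r exceeds the segment count a
        # terminal remainder (< base_length SNPs) stays uncovered
        wide = min(r, q)
        lengths = [base_length + 1] * wide + [base_length] * (q - wide)
        pos = idx[0]
        for seg_len in lengths:
            starts.append(pos)
            stops.append(pos + seg_len)
            first_bp = gmap.pos[pos]
            last_bp = gmap.pos[pos + seg_len - 1]
            mids.append((first_bp + last_bp) / 2.0)
            chroms.append(c)
            pos += seg_len
    return SegmentPartition(
        chrom=np.asarray(chroms, dtype=np.int64),
        start_idx=np.asarray(starts, dtype=np.int64),
        stop_idx=np.asarray(stops, dtype=np.int64),
        midpoint=np.asarray(mids, dtype=float),
    )


def haplotype_spectrum(haps: np.ndarray, min_usable: float = 0.5) -> np.ndarray | None:
    """Frequencies of the distinct haplotypes in a (haplotypes x SNPs) block.

    Haplotypes with any missing call in the block are dropped; if fewer than
    ``min_usable`` of the haplotypes remain the segment is unusable (None).
    """
    haps = np.asarray(haps)
    usable = ~(haps == MISSING_ALLELE).any(axis=1)
    if usable.sum() < min_usable * len(haps) or usable.sum() == 0:
        return None
    _, counts = np.unique(haps[usable], axis=0, return_counts=True)
    return counts / counts.sum()


def haph_raw(frequencies: np.ndarray) -> float:
    """Population variance (denominator N) of distinct-haplotype frequencies."""
    p = np.asarray(frequencies, dtype=float)
    if p.ndim != 1 or len(p) < 1:
        raise ValueError("need at least one haplotype frequency")
    if np.any(p <= 0) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("frequencies must be positive and sum to 1")
    return float(np.mean((p - 1.0 / len(p)) ** 2))


def homozygosity(frequencies: np.ndarray) -> float:
    """Haplotype homozygosity sum(p_i^2); optional companion statistic."""
    p = np.asarray(frequencies, dtype=float)
    return float(np.sum(p**2))


def segment_scores(
    panel: HaplotypePanel,
    partition: SegmentPartition,
    min_usable: float = 0.5,
    statistic: str = "variance",
) -> np.ndarray:
    """Per-segment HAPH (or homozygosity) scores for one population."""
    fn = {"variance": haph_raw, "homozygosity": homozygosity}[statistic]
    scores = np.full(partition.n_segments, np.nan)
    for s in range(partition.n_segments):
        block = panel.haplotypes[:, partition.start_idx[s] : partition.stop_idx[s]]
        spectrum = haplotype_spectrum(block, min_usable=min_usable)
        if spectrum is not None:
            scores[s] = fn(spectrum)
    return scores


def haph_windows(
    panel: HaplotypePanel,
    partition: SegmentPartition,
    grid: WindowGrid,
    min_usable: float = 0.5,
) -> pd.DataFrame:
    """Window-mean HAPH, mean-standardized, for one population.

    Segments contribute to every window containing their bp midpoint; windows
    without any segment midpoint are missing and excluded from the
    standardization mean.
    """
    scores = segment_scores(panel, partition, min_usable=min_usable)
    members = assign_points(
        grid, partition.chrom, np.floor(partition.midpoint).astype(np.int64)
    )
    raw = np.full(grid.n_windows, np.nan)
    for w, seg_idx in enumerate(members):
        if len(seg_idx) == 0:
            continue
        vals = scores[seg_idx]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            raw[w] = vals.mean()
    std = standardize(raw)
    return pd.DataFrame(
        {
            "chrom": grid.chrom,
            "start": grid.start,
            "end": grid.end,
            "raw": raw,
            "standardized": std,
        }
    )


def merge_sweep_regions(
    grid: WindowGrid, flags: np.ndarray, gap: int = MERGE_GAP
) -> list[SweepRegion]:
    """Merge flagged windows separated by less than ``gap`` bp into regions.

    Two flagged intervals on the same chromosome merge when the distance from
    the end of one to the start of the next is below ``gap``; the merged
    region spans ``[min start, max end]``.
    """
    flags = np.asarray(flags, dtype=bool)
    regions: list[SweepRegion] = []
    current: list[int] | None = None  # [chrom, start, end]
    for w in np.flatnonzero(flags):
        c, s, e = int(grid.chrom[w]), int(grid.start[w]), int(grid.start[w]) + grid.width
        if current is not None and c == current[0] and s - current[2] < gap:
            current[2] = max(current[2], e)
        else:
            if current is not None:
                regions.append(SweepRegion(*current))
            current = [c, s, e]
    if current is not None:
        regions.append(SweepRegion(*current))
    return regions


def filter_regions(regions: list[SweepRegion], min_length: int) -> list[SweepRegion]:
    """Regions strictly longer than ``min_length`` bp (e.g. 2 Mb, 5 Mb lists)."""
    return [r for r in regions if r.length > min_length]


def regions_to_bed(regions: list[SweepRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
            "length": [r.length for r in regions],
        }
    )


def scan(
    panel: HaplotypePanel,
    grid: WindowGrid,
    top_fraction: float = 0.05,
    gap: int = MERGE_GAP,
    min_usable: float = 0.5,
) -> tuple[pd.DataFrame, list[SweepRegion]]:
    """Full HAPH scan for one population: window table + merged sweep regions."""
    partition = segment_partition(panel.gmap)
    table = haph_windows(panel, partition, grid, min_usable=min_usable)
    flags = flag_top_fraction(table["standardized"].to_numpy(), q=top_fraction)
    table["top_flag"] = flags
    return table, merge_sweep_regions(grid, flags, gap=gap)
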