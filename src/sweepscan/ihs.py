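"""Ancestral-allele calling, EHH/iEHH and the integrated haplotype score.

For a core SNP and allele, EHH at a flanking position is the probability that
two randomly drawn carrier haplotypes are identical over the whole stretch
from the core to that position:

    EHH = sum_h C(n_h, 2) / C(n_A, 2)

with ``n_h`` the count of carriers in extended-haplotype class ``h`` and
``n_A`` the number of carriers.  iEHH integrates the decay curve (trapezoid,
physical bp distance) outward in both directions, truncating at the linearly
interpolated point where EHH crosses the decay threshold (default 0.5).

Raw iHS is ``log10(iEHH_derived / iEHH_ancestral)``, standardized to mean 0 /
SD 1 within 20 equal-width bins of ancestral-allele frequency; the window
statistic is the maximum |iHS| over SNPs in the window (already in SD units,
no further standardization).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MISSING_ALLELE, GenomeMap, HaplotypePanel
from .windows import WindowGrid, assign_points

logger = logging.getLogger(__name__)

DECAY_THRESHOLD = 0.5
MAF_FLOOR = 0.001
N_BINS = 20


def call_ancestral(allele_counts: np.ndarray) -> np.ndarray:
    """Majority ancestral-allele call per SNP from outgroup allele counts.

    ``allele_counts`` is (m x 2): observed outgroup calls of allele 0 and
    allele 1 at each SNP.  Exact ties and SNPs with zero calls are missing
    (-1) and are excluded from iHS downstream.
    """
    counts = np.asarray(allele_counts)
    if counts.ndim != 2 or counts.shape[1] != 2:
        raise ValueError("allele_counts must be (m, 2)")
    calls = np.full(len(counts), -1, dtype=np.int8)
    calls[counts[:, 0] > counts[:, 1]] = 0
    calls[counts[:, 1] > counts[:, 0]] = 1
    calls[counts.sum(axis=1) == 0] = -1
    return calls


@dataclass
class EhhCurve:
    """EHH decay away from a core SNP for one allele, both directions.

    ``left``/``right`` are ordered (distance bp, EHH) arrays starting at the
    core (distance 0, EHH 1) and ending at the first point below the decay
    threshold or the chromosome end (``truncated_*`` flags the latter).
    """

    core_index: int
    allele: int
    n_carriers: int
    left: np.ndarray = field(default_factory=lambda: np.zeros((1, 2)))
    right: np.ndarray = field(default_factory=lambda: np.zeros((1, 2)))
    truncated_left: bool = False
    truncated_right: bool = False


def _ehh_walk_py(
    haps: np.ndarray,
    carriers: np.ndarray,
    core: int,
    positions: np.ndarray,
    step: int,
    stop: int,
    threshold: float,
) -> tuple[np.ndarray, bool]:
    """Walk outward from ``core`` refining identity classes; returns (points, truncated).

    ``step`` is +1 (right) or -1 (left); ``stop`` is the last valid SNP index
    in that direction.  Points start at (0, 1) and include the first value
    below ``threshold`` so integration can interpolate the crossing.
    """
    n = len(carriers)
    pairs_total = n * (n - 1) / 2.0
    group = np.zeros(n, dtype=np.int64)
    own_code = 2 + np.arange(n)
    points = [(0.0, 1.0)]
    j = core
    truncated = True
    while j != stop:
        j += step
        col = haps[carriers, j].astype(np.int64)
        # a missing call isolates that haplotype in its own class from here on
        codes = np.where(col == MISSING_ALLELE, own_code, col)
        _, group = np.unique(group * (n + 2) + codes, return_inverse=True)
        counts = np.bincount(group)
        ehh = float((counts * (counts - 1) / 2.0).sum() / pairs_total)
        points.append((abs(float(positions[j] - positions[core])), ehh))
        if ehh < threshold:
            truncated = False
            break
    return np.asarray(points), truncated


try:  # optional numba acceleration; semantics identical to _ehh_walk_py
    from numba import njit

    @njit(cache=True)
    def _ehh_walk_jit(haps, carriers, core, positions, step, stop, threshold):  # pragma: no cover
        n = carriers.shape[0]
        pairs_total = n * (n - 1) / 2.0
        group = np.zeros(n, dtype=np.int64)
        keys = np.empty(n, dtype=np.int64)
        new_group = np.empty(n, dtype=np.int64)
        max_steps = abs(stop - core) + 1
        dist = np.empty(max_steps, dtype=np.float64)
        ehh_out = np.empty(max_steps, dtype=np.float64)
        dist[0] = 0.0
        ehh_out[0] = 1.0
        n_points = 1
        j = core
        truncated = True
        while j != stop:
            j += step
            for i in range(n):
                a = np.int64(haps[carriers[i], j])
                code = (2 + i) if a == 255 else a
                keys[i] = group[i] * (n + 2) + code
            order = np.argsort(keys)
            gid = 0
            new_group[order[0]] = 0
            count = 1
            homo_pairs = 0.0
            for k in range(1, n):
                if keys[order[k]] != keys[order[k - 1]]:
                    homo_pairs += count * (count - 1) / 2.0
                    count = 1
                    gid += 1
                else:
                    count += 1
                new_group[order[k]] = gid
            homo_pairs += count * (count - 1) / 2.0
            for i in range(n):
                group[i] = new_group[i]
            ehh = homo_pairs / pairs_total
            d = positions[j] - positions[core]
            dist[n_points] = d if d >= 0 else -d
            ehh_out[n_points] = ehh
            n_points += 1
            if ehh < threshold:
                truncated = False
                break
        points = np.empty((n_points, 2), dtype=np.float64)
        points[:, 0] = dist[:n_points]
        points[:, 1] = ehh_out[:n_points]
        return points, truncated

    def _ehh_walk(haps, carriers, core, positions, step, stop, threshold):
        points, truncated = _ehh_walk_jit(
            haps,
            np.asarray(carriers, dtype=np.int64),
            core,
            np.asarray(positions, dtype=np.int64),
            step,
            stop,
            threshold,
        )
        return points, bool(truncated)

except Exception:  # pragma: no cover - numba unavailable
    _ehh_walk = _ehh_walk_py


def ehh_curve(
    panel: HaplotypePanel,
    core_index: int,
    allele: int,
    threshold: float = DECAY_THRESHOLD,
    chrom_bounds: tuple[int, int] | None = None,
) -> EhhCurve | None:
    """EHH decay curve for one core SNP / allele; None with <2 carriers.

    Haplotypes missing at the core are excluded; a missing call in a flanking
    SNP puts the haplotype in its own identity class from there outward.
    ``chrom_bounds`` (first, last SNP index of the chromosome) avoids a map
    scan when the caller iterates many cores.
    """
    gmap = panel.gmap
    haps = panel.haplotypes
    carriers = np.flatnonzero(haps[:, core_index] == allele)
    if len(carriers) < 2:
        return None
    if chrom_bounds is None:
        chrom_idx = gmap.snp_indices(gmap.chrom[core_index])
        chrom_bounds = (int(chrom_idx[0]), int(chrom_idx[-1]))
    first, last = chrom_bounds
    left, trunc_l = _ehh_walk(haps, carriers, core_index, gmap.pos, -1, first, threshold)
    right, trunc_r = _ehh_walk(haps, carriers, core_index, gmap.pos, +1, last, threshold)
    return EhhCurve(
        core_index=core_index,
        allele=allele,
        n_carriers=len(carriers),
        left=left,
        right=right,
        truncated_left=trunc_l and left[-1, 1] >= threshold,
        truncated_right=trunc_r and right[-1, 1] >= threshold,
    )


def _integrate_direction(points: np.ndarray, threshold: float) -> float:
    """Trapezoidal area under one directional EHH curve, cut at the threshold."""
    area = 0.0
    for i in range(1, len(points)):
        d0, e0 = points[i - 1]
        d1, e1 = points[i]
        if e1 >= threshold:
            area += 0.5 * (e0 + e1) * (d1 - d0)
        else:
            # interpolate crossing distance; integrate only up to it
            if e0 <= threshold:
                break
            frac = (e0 - threshold) / (e0 - e1)
            d_star = d0 + frac * (d1 - d0)
            area += 0.5 * (e0 + threshold) * (d_star - d0)
            break
    return area


def iehh(curve: EhhCurve, threshold: float = DECAY_THRESHOLD) -> float:
    """Integrated EHH: both directional trapezoid areas summed (bp * EHH units)."""
    assert curve.left[0, 1] == 1.0 and curve.right[0, 1] == 1.0, "EHH at core must be 1"
    return _integrate_direction(curve.left, threshold) + _integrate_direction(
        curve.right, threshold
    )


def raw_ihs_table(
    panel: HaplotypePanel,
    ancestral: np.ndarray,
    threshold: float = DECAY_THRESHOLD,
    maf_floor: float = MAF_FLOOR,
) -> pd.DataFrame:
    """Per-SNP raw iHS for one population.

    Rows for every SNP; ``log10_ratio`` is NaN where the ancestral call is
    missing, the MAF floor is not met, or either iEHH is undefined/zero.
    """
    gmap = panel.gmap
    freq1 = panel.allele_frequencies()
    m = gmap.n_snps
    ancestral = np.asarray(ancestral)
    if len(ancestral) != m:
        raise ValueError("ancestral calls must align with the map")
    freq_anc = np.where(ancestral == 0, 1 - freq1, freq1)
    maf = np.minimum(freq1, 1 - freq1)
    iehh_a = np.full(m, np.nan)
    iehh_d = np.full(m, np.nan)
    bounds = {}
    for c in gmap.chromosomes():
        idx = gmap.snp_indices(c)
        bounds[c] = (int(idx[0]), int(idx[-1]))
    for j in range(m):
        if ancestral[j] < 0 or not maf[j] > maf_floor:
            continue
        anc = int(ancestral[j])
        cb = bounds[int(gmap.chrom[j])]
        curve_a = ehh_curve(panel, j, anc, threshold, chrom_bounds=cb)
        curve_d = ehh_curve(panel, j, 1 - anc, threshold, chrom_bounds=cb)
        if curve_a is not None:
            iehh_a[j] = iehh(curve_a, threshold)
        if curve_d is not None:
            iehh_d[j] = iehh(curve_d, threshold)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where((iehh_a > 0) & (iehh_d > 0), iehh_d / iehh_a, np.nan)
        log_ratio = np.log10(ratio)
    return pd.DataFrame(
        {
            "chrom": gmap.chrom,
            "pos": gmap.pos,
            "freq_anc": np.where(ancestral >= 0, freq_anc, np.nan),
            "iehh_anc": iehh_a,
            "iehh_der": iehh_d,
            "log10_ratio": log_ratio,
        }
    )


def standardize_ihs(table: pd.DataFrame, n_bins: int = N_BINS) -> pd.DataFrame:
    """Bin-standardize log10 iEHH ratios to mean 0 / SD 1 (sample SD).

    Bins are ``n_bins`` equal-width intervals of ancestral-allele frequency on
    (0, 1); records in bins with fewer than 2 values or zero spread stay
    missing.  Adds ``bin``, ``ihs`` and ``abs_ihs`` columns.
    """
    out = table.copy()
    freq = out["freq_anc"].to_numpy(dtype=float)
    raw = out["log10_ratio"].to_numpy(dtype=float)
    bins = np.full(len(out), -1, dtype=np.int64)
    ok = np.isfinite(freq) & np.isfinite(raw)
    bins[ok] = np.clip((freq[ok] * n_bins).astype(np.int64), 0, n_bins - 1)
    std = np.full(len(out), np.nan)
    for b in range(n_bins):
        idx = np.flatnonzero(bins == b)
        if len(idx) < 2:
            continue
        mu = raw[idx].mean()
        sigma = raw[idx].std(ddof=1)
        if sigma == 0:
            continue
        std[idx] = (raw[idx] - mu) / sigma
    out["bin"] = bins
    out["ihs"] = std
    out["abs_ihs"] = np.abs(std)
    return out


def window_abs_ihs(table: pd.DataFrame, grid: WindowGrid) -> pd.DataFrame:
    """Per-window maximum |iHS| (no further standardization; SD units)."""
    members = assign_points(
        grid, table["chrom"].to_numpy(), table["pos"].to_numpy()
    )
    abs_ihs = table["abs_ihs"].to_numpy(dtype=float)
    vals = np.full(grid.n_windows, np.nan)
    for w, idx in enumerate(members):
        v = abs_ihs[idx]
        v = v[np.isfinite(v)]
        if len(v):
            vals[w] = v.max()
    return pd.DataFrame(
        {
            "chrom": grid.chrom,
            "start": grid.start,
            "end": grid.end,
            "max_abs_ihs": vals,
        }
    )


def scan(
    panel: HaplotypePanel,
    ancestral: np.ndarray,
    grid: WindowGrid,
    threshold: float = DECAY_THRESHOLD,
    maf_floor: float = MAF_FLOOR,
    n_bins: int = N_BINS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full |iHS| scan for one population: (per-SNP table, window table)."""
    table = standardize_ihs(
        raw_ihs_table(panel, ancestral, threshold, maf_floor), n_bins
    )
    return table, window_abs_ihs(table, grid)
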