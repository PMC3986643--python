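"""Pairwise F_ST per SNP and per window, plus the dairy-vs-beef contrast.

The default estimator uses allele frequencies only:

    F_ST = [ (p1 - pbar)^2 + (p2 - pbar)^2 ] / 2 / [ pbar (1 - pbar) ]

with ``pbar = (p1 + p2) / 2`` — algebraically ``(p1 - p2)^2 / (4 pbar qbar)``.
A sample-size-corrected variant is available when haplotype counts are
supplied.  Window values are the unweighted mean over
polymorphic SNPs; per-pair standardization divides by the pair's mean over
all windows.  The group contrast compares standardized cross-group
(dairy x beef) pairs against within-group pairs window by window with a
one-sided Mann-Whitney U test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import HaplotypePanel
from .windows import WindowGrid, assign_points, standardize

EXACT_MW_LIMIT = 400  # exact U enumeration when n1*n2 <= this and no ties


@dataclass(frozen=True)
class BreedPair:
    """Unordered pair of populations with their group labels."""

    breed1: str
    breed2: str
    group1: str | None = None
    group2: str | None = None

    def __post_init__(self):
        if self.breed1 == self.breed2:
            raise ValueError("a pair needs two distinct populations")

    @property
    def label(self) -> str:
        return f"{self.breed1}~{self.breed2}"

    @property
    def is_cross_group(self) -> bool:
        return (
            self.group1 is not None
            and self.group2 is not None
            and self.group1 != self.group2
        )


def enumerate_pairs(
    breeds: list[str], groups: dict[str, str] | None = None
) -> list[BreedPair]:
    """All unordered pairs of populations (8 breeds -> 28 comparisons)."""
    groups = groups or {}
    return [
        BreedPair(a, b, groups.get(a), groups.get(b))
        for a, b in itertools.combinations(breeds, 2)
    ]


def snp_fst_pair(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Per-SNP pairwise F_ST from allele frequencies (no sample-size term).

    Monomorphic-across-the-pair SNPs (pbar in {0, 1}) come back NaN so window
    averaging can exclude them rather than treat 0/0 as signal.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 < 0) | (p1 > 1) | (p2 < 0) | (p2 > 1)):
        raise ValueError("allele frequencies must be in [0, 1]")
    pbar = (p1 + p2) / 2.0
    # qbar computed from the complements keeps relabelling (p -> 1-p) exact
    qbar = ((1.0 - p1) + (1.0 - p2)) / 2.0
    denom = pbar * qbar
    num = ((p1 - pbar) ** 2 + (p2 - pbar) ** 2) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, num / denom, np.nan)
    return out


def snp_fst_corrected(
    p1: np.ndarray, p2: np.ndarray, n1: int, n2: int
) -> np.ndarray:
    """Sample-size-corrected pairwise F_ST (ANOVA-style moment correction).

    Subtracts the sampling-noise contribution ``p_i q_i / (n_i - 1)`` from the
    squared frequency difference and adds it back into the ``4 pbar qbar``
    denominator, so numerator and denominator are unbiased moment estimates.
    Converges to :func:`snp_fst_pair` as the haploid sample sizes n1, n2 grow.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if min(n1, n2) < 2:
        raise ValueError("need at least 2 haplotypes per population")
    noise = p1 * (1 - p1) / (n1 - 1) + p2 * (1 - p2) / (n2 - 1)
    num = (p1 - p2) ** 2 - noise
    pbar = (p1 + p2) / 2.0
    den = 4.0 * pbar * (1.0 - pbar) + noise
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(den > 0, num / den, np.nan)
    return theta


def window_fst(
    panel1: HaplotypePanel,
    panel2: HaplotypePanel,
    grid: WindowGrid,
    estimator: str = "frequency",
) -> pd.DataFrame:
    """Window-mean pairwise F_ST for one breed pair, plus standardized values."""
    gmap = panel1.gmap
    p1 = panel1.allele_frequencies()
    p2 = panel2.allele_frequencies()
    if estimator == "frequency":
        snp_fst = snp_fst_pair(p1, p2)
    elif estimator == "corrected":
        snp_fst = snp_fst_corrected(p1, p2, panel1.n_haplotypes, panel2.n_haplotypes)
    else:
        raise ValueError(f"unknown estimator: {estimator}")
    members = assign_points(grid, gmap.chrom, gmap.pos)
    raw = np.full(grid.n_windows, np.nan)
    for w, idx in enumerate(members):
        vals = snp_fst[idx]
        vals = vals[np.isfinite(vals)]
        if len(vals):
            raw[w] = vals.mean()
    return pd.DataFrame(
        {
            "chrom": grid.chrom,
            "start": grid.start,
            "end": grid.end,
            "raw": raw,
            "standardized": standardize(raw),
        }
    )


def pairwise_window_fst(
    panels: dict[str, HaplotypePanel],
    grid: WindowGrid,
    groups: dict[str, str] | None = None,
    estimator: str = "frequency",
) -> tuple[pd.DataFrame, list[BreedPair]]:
    """Standardized window F_ST for every unordered pair, one column per pair."""
    pairs = enumerate_pairs(sorted(panels), groups)
    out = pd.DataFrame(
        {"chrom": grid.chrom, "start": grid.start, "end": grid.end}
    )
    for pair in pairs:
        table = window_fst(panels[pair.breed1], panels[pair.breed2], grid, estimator)
        out[pair.label] = table["standardized"].to_numpy()
    return out, pairs


def mann_whitney_greater(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """One-sided Mann-Whitney U (alternative: x stochastically greater than y).

    Exact enumeration when there are no ties and n1*n2 is small; otherwise the
    normal approximation with mid-ranks and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        return np.nan, np.nan
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # degenerate all-tied case: U at its null mean, one-sided p 1/2
        return len(x) * len(y) / 2.0, 0.5
    has_ties = len(np.unique(pooled)) < len(x) + len(y)
    method = "exact" if (not has_ties and len(x) * len(y) <= EXACT_MW_LIMIT) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


def group_contrast_test(
    window_values: pd.DataFrame, pairs: list[BreedPair]
) -> pd.DataFrame:
    """Per-window one-sided test: cross-group standardized F_ST > within-group.

    ``window_values`` is the wide table from :func:`pairwise_window_fst`.
    Windows where either sample is empty (all-NaN) are missing.
    """
    cross = [p.label for p in pairs if p.is_cross_group]
    within = [p.label for p in pairs if not p.is_cross_group]
    if not cross or not within:
        raise ValueError("need at least one cross-group and one within-group pair")
    u = np.full(len(window_values), np.nan)
    pval = np.full(len(window_values), np.nan)
    xmat = window_values[cross].to_numpy(dtype=float)
    ymat = window_values[within].to_numpy(dtype=float)
    for w in range(len(window_values)):
        x = xmat[w][np.isfinite(xmat[w])]
        y = ymat[w][np.isfinite(ymat[w])]
        if len(x) and len(y):
            u[w], pval[w] = mann_whitney_greater(x, y)
    out = window_values[["chrom", "start", "end"]].copy()
    out["U"] = u
    out["p"] = pval
    return out
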