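"""Overlap enrichment between top selection windows and top QTL windows.

Because sliding windows overlap (each genome segment is counted width/step
times), the 2x2 contingency counts are divided by the overlap factor before
the 1-df chi-squared test — equivalent to testing the average of the
non-overlapping window tilings.  The exact subset-averaged alternative is
available for sensitivity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .windows import WindowGrid, nonoverlapping_subsets

logger = logging.getLogger(__name__)

DEFAULT_OVERLAP_FACTOR = 5
ALPHA = 0.05


@dataclass
class EnrichmentResult:
    label: str
    trait: str
    a: float  # both flagged (corrected count)
    b: float  # selection only
    c: float  # qtl only
    d: float  # neither
    chi2: float
    p: float
    fold: float
    n_windows: int  # non-missing windows before correction

    @property
    def total(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def expected_overlap(self) -> float:
        return (self.a + self.b) * (self.a + self.c) / self.total if self.total else np.nan


def chi2_2x2(a: float, b: float, c: float, d: float, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared (1 df) on a 2x2 table; optional Yates correction."""
    total = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        return np.nan, np.nan
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - total / 2.0, 0.0)
    chi2 = total * diff**2 / margins
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def overlap_chi2(
    flags_selection: np.ndarray,
    flags_qtl: np.ndarray,
    overlap_factor: int = DEFAULT_OVERLAP_FACTOR,
    missing: np.ndarray | None = None,
    label: str = "",
    trait: str = "",
    yates: bool = False,
) -> EnrichmentResult | None:
    """Chi-squared enrichment of overlap between two top-window flag vectors.

    Cross-tabulates the flags over windows where both statistics are
    non-missing, divides all four cells by ``overlap_factor`` and applies the
    1-df test.  Returns None (with a warning) when a corrected margin is zero.
    """
    fa = np.asarray(flags_selection, dtype=bool)
    fb = np.asarray(flags_qtl, dtype=bool)
    if fa.shape != fb.shape:
        raise ValueError("flag vectors must align")
    ok = np.ones(fa.shape, dtype=bool) if missing is None else ~np.asarray(missing)
    fa, fb = fa[ok], fb[ok]
    a = float(np.sum(fa & fb)) / overlap_factor
    b = float(np.sum(fa & ~fb)) / overlap_factor
    c = float(np.sum(~fa & fb)) / overlap_factor
    d = float(np.sum(~fa & ~fb)) / overlap_factor
    total = a + b + c + d
    if (a + b) * (c + d) * (a + c) * (b + d) == 0:
        logger.warning("degenerate 2x2 margin for %s/%s: no test", label, trait)
        return None
    chi2, p = chi2_2x2(a, b, c, d, yates=yates)
    expected = (a + b) * (a + c) / total
    fold = a / expected if expected > 0 else np.nan
    return EnrichmentResult(label, trait, a, b, c, d, chi2, p, fold, int(ok.sum()))


def overlap_chi2_subsets(
    grid: WindowGrid,
    flags_selection: np.ndarray,
    flags_qtl: np.ndarray,
    missing: np.ndarray | None = None,
    label: str = "",
    trait: str = "",
) -> EnrichmentResult | None:
    """Exact alternative: average the 2x2 cells over the non-overlapping tilings."""
    fa = np.asarray(flags_selection, dtype=bool)
    fb = np.asarray(flags_qtl, dtype=bool)
    ok = np.ones(fa.shape, dtype=bool) if missing is None else ~np.asarray(missing)
    cells = np.zeros(4)
    subsets = nonoverlapping_subsets(grid)
    for sub in subsets:
        keep = sub[ok[sub]]
        cells += [
            np.sum(fa[keep] & fb[keep]),
            np.sum(fa[keep] & ~fb[keep]),
            np.sum(~fa[keep] & fb[keep]),
            np.sum(~fa[keep] & ~fb[keep]),
        ]
    a, b, c, d = cells / len(subsets)
    if (a + b) * (c + d) * (a + c) * (b + d) == 0:
        logger.warning("degenerate 2x2 margin for %s/%s: no test", label, trait)
        return None
    chi2, p = chi2_2x2(a, b, c, d)
    total = a + b + c + d
    expected = (a + b) * (a + c) / total
    fold = a / expected if expected > 0 else np.nan
    return EnrichmentResult(label, trait, a, b, c, d, chi2, p, fold, int(ok.sum()))


def bonferroni_adjust(p_values: np.ndarray, m: int | None = None, alpha: float = ALPHA) -> np.ndarray:
    """Significance flags at family-wise level ``alpha``: p <= alpha / m."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = len(p)
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return p <= alpha / m


def enrichment_report(
    results: list[EnrichmentResult], m: int | None = None
) -> pd.DataFrame:
    """Long-format report: one row per (statistic, trait) test.

    ``overlap`` is the corrected both-flagged count (the "average number of
    windows" over the non-overlapping tilings); Bonferroni uses ``m`` tests
    (default: the number of rows).
    """
    columns = [
        "statistic",
        "trait",
        "overlap",
        "expected",
        "fold",
        "chi2",
        "p",
        "bonferroni_significant",
        "n_windows",
    ]
    if not results:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(
        {
            "statistic": [r.label for r in results],
            "trait": [r.trait for r in results],
            "overlap": [r.a for r in results],
            "expected": [r.expected_overlap for r in results],
            "fold": [r.fold for r in results],
            "chi2": [r.chi2 for r in results],
            "p": [r.p for r in results],
            "n_windows": [r.n_windows for r in results],
        }
    )
    df["bonferroni_significant"] = bonferroni_adjust(df["p"].to_numpy(), m)
    return df[columns]
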