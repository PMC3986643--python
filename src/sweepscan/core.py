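"""Core data containers: the SNP map and phased haplotype panels.

Coordinates are 0-based half-open internally; exported text formats use the
convention documented per writer (VCF is 1-based, BED is 0-based half-open).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_ALLELE = 255  # sentinel in haplotype matrices for unobserved calls


@dataclass
class GenomeMap:
    """Ordered SNP records (chromosome, bp position) plus chromosome lengths.

    ``chrom`` and ``pos`` are parallel arrays sorted by (chromosome, position)
    with strictly increasing positions within a chromosome.  ``ancestral``
    holds a per-SNP ancestral-allele call: 0 or 1, or -1 when unknown.
    """

    chrom: np.ndarray  # int chromosome ids, sorted
    pos: np.ndarray  # int bp positions
    chrom_lengths: dict[int, int]
    ancestral: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.chrom.shape != self.pos.shape:
            raise ValueError("chrom and pos must have the same length")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(order))):
            raise ValueError("map must be sorted by (chromosome, position)")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")
            length = self.chrom_lengths.get(int(c))
            if length is not None and p.size and (p.min() < 0 or p.max() >= length):
                raise ValueError(f"position outside chromosome {c} bounds")
        if self.ancestral is not None:
            self.ancestral = np.asarray(self.ancestral, dtype=np.int8)
            if self.ancestral.shape != self.chrom.shape:
                raise ValueError("ancestral must align with the map")

    @property
    def n_snps(self) -> int:
        return int(len(self.pos))

    def chromosomes(self) -> list[int]:
        return [int(c) for c in dict.fromkeys(self.chrom.tolist())]

    def snp_indices(self, chrom: int) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"chrom": self.chrom, "pos": self.pos})
        if self.ancestral is not None:
            df["ancestral"] = self.ancestral
        return df


@dataclass
class HaplotypePanel:
    """Phased binary haplotype matrix (2n haplotypes x m SNPs) for one population.

    Haplotypes ``2i`` and ``2i+1`` belong to diploid individual ``i``.  The
    derived allele is coded 1; :data:`MISSING_ALLELE` marks missing calls.
    """

    name: str
    haplotypes: np.ndarray
    gmap: GenomeMap
    group: str | None = None  # e.g. "dairy" / "beef"

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be 2-D")
        if self.haplotypes.shape[1] != self.gmap.n_snps:
            raise ValueError("haplotype matrix does not match the map")
        valid = np.isin(self.haplotypes, (0, 1, MISSING_ALLELE))
        if not valid.all():
            raise ValueError("haplotype matrix must be binary (0/1) or missing")

    @property
    def n_haplotypes(self) -> int:
        return int(self.haplotypes.shape[0])

    @property
    def n_individuals(self) -> int:
        return self.n_haplotypes // 2

    def allele_frequencies(self) -> np.ndarray:
        """Derived (allele-1) frequency per SNP, ignoring missing calls."""
        h = self.haplotypes
        observed = h != MISSING_ALLELE
        counts = np.where(observed, h, 0).sum(axis=0, dtype=np.int64)
        denom = observed.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, counts / denom, np.nan)

    def dosages(self) -> np.ndarray:
        """(n_individuals x m) allele-1 dosage matrix in {0,1,2}."""
        h = self.haplotypes.astype(np.int16)
        h[h == MISSING_ALLELE] = 0
        return (h[0::2] + h[1::2]).astype(np.int16)

    def take_snps(self, indices: np.ndarray) -> "HaplotypePanel":
        indices = np.asarray(indices)
        sub = GenomeMap(
            self.gmap.chrom[indices],
            self.gmap.pos[indices],
            self.gmap.chrom_lengths,
            None if self.gmap.ancestral is None else self.gmap.ancestral[indices],
        )
        return HaplotypePanel(self.name, self.haplotypes[:, indices], sub, self.group)


@dataclass
class SimulationTruth:
    """Ground truth recorded by the simulator for parameter-recovery checks."""

    sweeps: list[dict] = field(default_factory=list)
    qtl: list[dict] = field(default_factory=list)
    realized_h2: float | None = None

    def to_dict(self) -> dict:
        return {
            "sweeps": self.sweeps,
            "qtl": self.qtl,
            "realized_h2": self.realized_h2,
        }
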