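"""Readers and writers for the formats the pipeline touches.

VCF carries phased GT with the ancestral allele as REF and the derived allele
as ALT (the convention is recorded in the header).  Window tables are exported
with 1-based inclusive coordinates; BED output is 0-based half-open.  VCF
reading is delegated to cyvcf2.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenomeMap, HaplotypePanel

logger = logging.getLogger(__name__)

WINDOW_COORD_COMMENT = "# coordinates: 1-based inclusive (internal representation is 0-based half-open)"


def write_phased_vcf(
    panels: dict[str, HaplotypePanel], path: str | Path
) -> None:
    """Write all populations into one phased VCF (REF=ancestral, ALT=derived)."""
    path = Path(path)
    any_panel = next(iter(panels.values()))
    gmap = any_panel.gmap
    samples = []
    for name, panel in panels.items():
        samples += [f"{name}_{i}" for i in range(panel.n_individuals)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sweepscan\n")
        fh.write(
            "##INFO=<ID=AA,Number=1,Type=String,Description=\"Ancestral allele\">\n"
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "##convention=REF is the ancestral allele (coded 0), ALT the derived allele (coded 1)\n"
        )
        for c, length in sorted(gmap.chrom_lengths.items()):
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        mats = [p.haplotypes for p in panels.values()]
        for j in range(gmap.n_snps):
            gts = []
            for mat in mats:
                col = mat[:, j]
                gts += [f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(len(col) // 2)]
            fh.write(
                f"{gmap.chrom[j]}\t{gmap.pos[j] + 1}\t.\tA\tG\t.\tPASS\tAA=A\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_phased_vcf(
    path: str | Path, sample_to_pop: dict[str, str]
) -> tuple[dict[str, HaplotypePanel], GenomeMap]:
    """Read a phased biallelic VCF into per-population haplotype panels.

    Unphased or multi-allelic records are rejected (counts logged).  Raises if
    no phased samples remain or ploidy is mixed.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    pops = [sample_to_pop.get(s) for s in samples]
    if all(p is None for p in pops):
        raise ValueError("no samples matched the sample-to-population table")
    chroms, positions = [], []
    columns = []
    rejected = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            rejected += 1
            continue
        gts = variant.genotypes  # [allele1, allele2, phased] per sample
        if any(len(g) != 3 for g in gts):
            raise ValueError("mixed ploidy is not supported")
        if not all(g[2] for g in gts):
            rejected += 1
            continue
        chroms.append(int(variant.CHROM))
        positions.append(variant.POS - 1)  # VCF 1-based -> internal 0-based
        col = np.array([[g[0], g[1]] for g in gts], dtype=np.int16).ravel()
        columns.append(col)
    if rejected:
        logger.warning("rejected %d unphased or multi-allelic records", rejected)
    if not columns:
        raise ValueError("no usable phased biallelic records")
    haps_all = np.column_stack(columns).astype(np.uint8)
    lengths = {
        int(c): int(l) for c, l in zip(vcf.seqnames, vcf.seqlens)
    }
    gmap = GenomeMap(np.array(chroms), np.array(positions), lengths)
    panels: dict[str, HaplotypePanel] = {}
    for pop in dict.fromkeys(p for p in pops if p is not None):
        rows = []
        for i, s in enumerate(samples):
            if sample_to_pop.get(s) == pop:
                rows += [2 * i, 2 * i + 1]
        panels[pop] = HaplotypePanel(pop, haps_all[rows], gmap)
    return panels, gmap


def write_window_table(df: pd.DataFrame, path: str | Path) -> None:
    """Window TSV with 1-based inclusive coordinates and a convention comment."""
    out = df.copy()
    if "start" in out.columns:
        out["start"] = out["start"] + 1
    with open(path, "w") as fh:
        fh.write(WINDOW_COORD_COMMENT + "\n")
        out.to_csv(fh, sep="\t", index=False)


def read_window_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "start" in df.columns:
        df["start"] = df["start"] - 1
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """BED (0-based half-open) for sweep regions."""
    df.to_csv(path, sep="\t", index=False, header=False)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth_dict: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth_dict, fh, indent=2)


def read_sample_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample, population) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"])
    return dict(zip(df["sample"], df["population"]))
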