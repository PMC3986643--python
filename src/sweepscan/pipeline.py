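"""End-to-end orchestration: simulate (or load), scan, enrich, report.

Every stage writes its artifacts into the output directory as it completes;
a manifest with the config hash, seed, package version and per-file SHA-256
checksums is written last, so identical config + seed means identical
outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, enrichment, fst, gebv, haph, ihs, io, windows
from .simulate import SimulationConfig, SimulatedDataset, outgroup_allele_counts, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs; defaults are the published analysis settings."""

    window_width: int = 250_000
    window_step: int = 50_000
    segment_length: int = 30
    top_fraction: float = 0.05
    decay_threshold: float = 0.5
    maf_floor: float = 0.001
    ihs_bins: int = 20
    fst_estimator: str = "frequency"
    effect_model: str = "ridge"
    effect_h2: float = 0.5
    bayesr_iterations: int = 5_000
    bayesr_burn_in: int = 2_000
    bayesr_chains: int = 3
    overlap_factor: int = 5
    bonferroni_m: int | None = None
    merge_gap: int = 1_000_000
    seed: int = 0
    output_dir: str = "sweepscan_out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        if self.window_width % self.window_step != 0:
            raise ValueError("window width must be a multiple of step")
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")
        if self.overlap_factor != self.window_width // self.window_step:
            raise ValueError("overlap_factor must equal width // step")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            from .simulate import BreedSpec, SweepSpec, TraitSpec

            breeds = sim_raw.pop("breeds", None)
            sweeps = sim_raw.pop("sweeps", None)
            trait = sim_raw.pop("trait", None)
            sim = SimulationConfig(**sim_raw)
            if breeds is not None:
                sim.breeds = [BreedSpec(**b) for b in breeds]
            if sweeps is not None:
                sim.sweeps = [SweepSpec(**{**s, "breeds": tuple(s["breeds"])}) for s in sweeps]
            if trait is not None:
                sim.trait = TraitSpec(**trait)
            cfg.simulation = sim
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: RunConfig, dataset: SimulatedDataset | None = None
) -> Path:
    """Run every stage on a simulated (or supplied) dataset; returns the output dir.

    Stage failures abort with the stage name; artifacts written before the
    failure are preserved.
    """
    config.validate()
    config.simulation.seed = config.seed
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if dataset is None:
            dataset = simulate_dataset(config.simulation)
        panels = dataset.panels
        gmap = dataset.gmap
        io.write_phased_vcf(panels, out / "panels.vcf")
        io.write_truth(dataset.truth.to_dict(), out / "truth.json")
        if dataset.outgroup is not None:
            io.write_tsv(dataset.outgroup, out / "outgroup.tsv")
        if dataset.phenotypes is not None:
            io.write_tsv(dataset.phenotypes, out / "phenotypes.tsv")

        stage = "windows"
        grid = windows.build_grid(gmap, config.window_width, config.window_step)

        stage = "haph"
        haph_flags: dict[str, np.ndarray] = {}
        haph_missing: dict[str, np.ndarray] = {}
        haph_wide = pd.DataFrame({"chrom": grid.chrom, "start": grid.start, "end": grid.end})
        all_regions = []
        for name, panel in panels.items():
            table, regions = haph.scan(
                panel, grid, top_fraction=config.top_fraction, gap=config.merge_gap
            )
            haph_wide[f"haph_{name}"] = table["standardized"]
            haph_flags[name] = table["top_flag"].to_numpy()
            haph_missing[name] = ~np.isfinite(table["standardized"].to_numpy())
            for r in regions:
                all_regions.append((name, r))
        io.write_window_table(haph_wide, out / "haph_windows.tsv")
        bed = pd.DataFrame(
            {
                "chrom": [r.chrom for _, r in all_regions],
                "start": [r.start for _, r in all_regions],
                "end": [r.end for _, r in all_regions],
                "name": [n for n, _ in all_regions],
            }
        )
        io.write_bed(bed, out / "sweep_regions.bed")

        stage = "ihs"
        ancestral = ihs.call_ancestral(outgroup_allele_counts(dataset.outgroup))
        ihs_flags: dict[str, np.ndarray] = {}
        ihs_missing: dict[str, np.ndarray] = {}
        ihs_wide = pd.DataFrame({"chrom": grid.chrom, "start": grid.start, "end": grid.end})
        for name, panel in panels.items():
            snp_table, window_table = ihs.scan(
                panel,
                ancestral,
                grid,
                threshold=config.decay_threshold,
                maf_floor=config.maf_floor,
                n_bins=config.ihs_bins,
            )
            io.write_tsv(snp_table, out / f"ihs_snps_{name}.tsv")
            vals = window_table["max_abs_ihs"].to_numpy()
            ihs_wide[f"abs_ihs_{name}"] = vals
            ihs_flags[name] = windows.flag_top_fraction(vals, q=config.top_fraction)
            ihs_missing[name] = ~np.isfinite(vals)
        io.write_window_table(ihs_wide, out / "ihs_windows.tsv")

        stage = "fst"
        groups = {name: panel.group or "beef" for name, panel in panels.items()}
        fst_wide, pairs = fst.pairwise_window_fst(
            panels, grid, groups, estimator=config.fst_estimator
        )
        io.write_window_table(fst_wide, out / "fst_windows.tsv")
        contrast = fst.group_contrast_test(fst_wide, pairs)
        io.write_window_table(contrast, out / "fst_dairy_beef_contrast.tsv")
        u_vals = contrast["U"].to_numpy(dtype=float)
        fst_flags = windows.flag_top_fraction(u_vals, q=config.top_fraction)
        fst_missing = ~np.isfinite(u_vals)

        stage = "gebv"
        qtl_flags: dict[str, np.ndarray] = {}
        qtl_missing: dict[str, np.ndarray] = {}
        trait_name = (
            config.simulation.trait.name if config.simulation.trait is not None else None
        )
        if dataset.phenotypes is not None and trait_name is not None:
            gebv_wide = pd.DataFrame(
                {"chrom": grid.chrom, "start": grid.start, "end": grid.end}
            )
            for name, panel in panels.items():
                if (panel.group or "beef") != "dairy":
                    continue
                pheno = dataset.phenotypes[dataset.phenotypes["breed"] == name]
                y = pheno[trait_name].to_numpy(dtype=float)
                X = panel.dosages().astype(float)
                if config.effect_model == "bayesr":
                    est = gebv.fit_bayesr(
                        X,
                        y,
                        h2=config.effect_h2,
                        iterations=config.bayesr_iterations,
                        burn_in=config.bayesr_burn_in,
                        chains=config.bayesr_chains,
                        seed=config.seed,
                    )
                else:
                    est = gebv.fit_ridge(X, y, h2=config.effect_h2)
                table = gebv.window_gebv_variance(
                    X, est, grid, gmap.chrom, gmap.pos, top_fraction=config.top_fraction
                )
                gebv_wide[f"gebv_var_{trait_name}_{name}"] = table["variance"]
                qtl_flags[name] = table["top_flag"].to_numpy()
                qtl_missing[name] = ~np.isfinite(table["variance"].to_numpy())
            io.write_window_table(gebv_wide, out / "gebv_variance_windows.tsv")

        stage = "enrichment"
        results = []
        if qtl_flags:
            union_qtl = np.logical_or.reduce(list(qtl_flags.values()))
            union_missing = np.logical_and.reduce(list(qtl_missing.values()))
            for name in qtl_flags:
                for stat, flags, missing in (
                    ("haph", haph_flags[name], haph_missing[name]),
                    ("abs_ihs", ihs_flags[name], ihs_missing[name]),
                ):
                    res = enrichment.overlap_chi2(
                        flags,
                        qtl_flags[name],
                        overlap_factor=config.overlap_factor,
                        missing=missing | qtl_missing[name],
                        label=f"{stat}_{name}",
                        trait=trait_name or "",
                    )
                    if res is not None:
                        results.append(res)
            res = enrichment.overlap_chi2(
                fst_flags,
                union_qtl,
                overlap_factor=config.overlap_factor,
                missing=fst_missing | union_missing,
                label="fst_dairy_beef",
                trait=trait_name or "",
            )
            if res is not None:
                results.append(res)
        report = enrichment.enrichment_report(results, m=config.bonferroni_m)
        io.write_tsv(report, out / "enrichment_report.tsv")

        stage = "manifest"
        files = sorted(p for p in out.iterdir() if p.name != "manifest.json")
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "files": {p.name: _sha256(p) for p in files},
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception:
        logger.error("pipeline failed in stage %r; partial outputs kept in %s", stage, out)
        raise
    return out
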