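"""Forward Wright-Fisher simulator for multi-breed phased haplotype panels.

A neutral base population is evolved with recombination and infinite-sites
mutation (burn-in 10*Ne generations by default), then split into breeds that
drift independently.  Optional hard sweeps apply genic selection at a single
locus in chosen breeds (deterministic frequency update followed by binomial
sampling of the next-generation allele count); an optional polygenic trait is
simulated with truncation selection.  The derived allele is always coded 1.

All randomness flows from the config seed through named substreams, so runs
are bit-reproducible.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomeMap, HaplotypePanel, SimulationTruth

logger = logging.getLogger(__name__)


@dataclass
class BreedSpec:
    name: str
    ne: int = 100
    generations: int = 100
    group: str = "beef"


@dataclass
class SweepSpec:
    chrom: int
    position: int
    s: float
    breeds: tuple[str, ...]
    generations: int = 400
    stop_frequency: float | None = None  # stop early once reached (mid-sweep)
    retry_limit: int = 100


@dataclass
class TraitSpec:
    n_qtl: int = 200
    h2: float = 0.5
    truncation_fraction: float = 1.0
    generations: int = 0
    name: str = "trait"


def default_breeds() -> list[BreedSpec]:
    return [
        BreedSpec("holstein", group="dairy"),
        BreedSpec("jersey", group="dairy"),
        BreedSpec("angus", group="beef"),
        BreedSpec("charolais", group="beef"),
        BreedSpec("hereford", group="beef"),
        BreedSpec("shorthorn", group="beef"),
    ]


@dataclass
class SimulationConfig:
    n_chromosomes: int = 1
    chrom_length: int = 10_000_000
    mutation_rate: float = 2e-7  # per bp per generation
    recombination_rate: float = 1e-8  # Morgan per bp
    base_ne: int = 100
    breeds: list[BreedSpec] = field(default_factory=default_breeds)
    sweeps: list[SweepSpec] = field(default_factory=list)
    trait: TraitSpec | None = None
    burn_in_factor: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.base_ne < 2:
            raise ValueError("base_ne must be >= 2")
        if self.n_chromosomes < 1 or self.chrom_length < 1:
            raise ValueError("need at least one chromosome of positive length")
        names = [b.name for b in self.breeds]
        if len(set(names)) != len(names):
            raise ValueError("breed names must be unique")
        for b in self.breeds:
            if b.ne < 2:
                raise ValueError(f"breed {b.name}: Ne must be >= 2")
            if b.generations < 0:
                raise ValueError(f"breed {b.name}: generations must be >= 0")
        for sw in self.sweeps:
            if sw.s < 0:
                raise ValueError("selection coefficient must be >= 0")
            if not 0 <= sw.position < self.chrom_length or not 0 <= sw.chrom < self.n_chromosomes:
                raise ValueError("sweep position outside chromosome bounds")
            unknown = set(sw.breeds) - set(names)
            if unknown:
                raise ValueError(f"sweep targets unknown breeds: {sorted(unknown)}")
        if self.trait is not None:
            t = self.trait
            if not 0 < t.h2 < 1:
                raise ValueError("h2 must be in (0, 1)")
            if not 0 < t.truncation_fraction <= 1:
                raise ValueError("truncation_fraction must be in (0, 1]")
            if t.n_qtl < 1:
                raise ValueError("need at least one QTL")

    def substream(self, name: str) -> np.random.Generator:
        # stable across processes (unlike hash()), so runs are reproducible
        digest = zlib.crc32(name.encode())
        return np.random.default_rng(np.random.SeedSequence((self.seed, digest)))


@dataclass
class _Population:
    """Mutable simulator state: haplotypes plus the (chrom, pos) column map."""

    haps: np.ndarray  # (2N, S) uint8
    chrom: np.ndarray  # (S,)
    pos: np.ndarray  # (S,)

    @property
    def n_haplotypes(self) -> int:
        return self.haps.shape[0]

    def chrom_slices(self, n_chromosomes: int) -> list[tuple[int, slice]]:
        out = []
        for c in range(n_chromosomes):
            idx = np.flatnonzero(self.chrom == c)
            if len(idx):
                out.append((c, slice(int(idx[0]), int(idx[-1]) + 1)))
            else:
                out.append((c, slice(0, 0)))
        return out


def _meiosis_with_crossovers(
    haps: np.ndarray,
    parent: int,
    gamete: np.ndarray,
    sl: slice,
    pos: np.ndarray,
    n_crossovers: int,
    start_hap: int,
    chrom_length: int,
    rng: np.random.Generator,
) -> None:
    """Fill one chromosome of a gamete from parent haplotypes with crossovers."""
    h = (haps[2 * parent + start_hap], haps[2 * parent + 1 - start_hap])
    p = pos[sl]
    breakpoints = np.sort(rng.integers(0, chrom_length, size=n_crossovers))
    switch = np.searchsorted(p, breakpoints, side="left")
    bounds = np.concatenate(([0], switch, [len(p)]))
    base = sl.start
    for k in range(len(bounds) - 1):
        a, b = int(bounds[k]), int(bounds[k + 1])
        gamete[base + a : base + b] = h[k % 2][base + a : base + b]


def _make_gametes(
    pop: _Population,
    parents: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per entry of ``parents`` (diploid indices), with recombination."""
    n_g = len(parents)
    gametes = np.empty((n_g, pop.haps.shape[1]), dtype=np.uint8)
    morgan = config.chrom_length * config.recombination_rate
    for c, sl in pop.chrom_slices(config.n_chromosomes):
        n_x = rng.poisson(morgan, size=n_g)
        start = rng.integers(0, 2, size=n_g)
        plain = np.flatnonzero(n_x == 0)
        if len(plain):
            rows = 2 * parents[plain] + start[plain]
            gametes[plain, sl.start : sl.stop] = pop.haps[rows, sl.start : sl.stop]
        for g in np.flatnonzero(n_x > 0):
            _meiosis_with_crossovers(
                pop.haps,
                int(parents[g]),
                gametes[g],
                sl,
                pop.pos,
                int(n_x[g]),
                int(start[g]),
                config.chrom_length,
                rng,
            )
    return gametes


def _add_mutations(pop: _Population, config: SimulationConfig, rng: np.random.Generator) -> None:
    """Infinite-sites mutation: new segregating columns on random haplotypes."""
    n2 = pop.n_haplotypes
    total_len = config.n_chromosomes * config.chrom_length
    n_new = rng.poisson(n2 * total_len * config.mutation_rate)
    if n_new == 0:
        return
    existing = set(zip(pop.chrom.tolist(), pop.pos.tolist()))
    new_sites: list[tuple[int, int]] = []
    attempts = 0
    while len(new_sites) < n_new and attempts < 20:
        c = int(rng.integers(0, config.n_chromosomes))
        p = int(rng.integers(0, config.chrom_length))
        if (c, p) not in existing:
            existing.add((c, p))
            new_sites.append((c, p))
            attempts = 0
        else:
            attempts += 1
    carriers = rng.integers(0, n2, size=len(new_sites))
    new_cols = np.zeros((n2, len(new_sites)), dtype=np.uint8)
    new_cols[carriers, np.arange(len(new_sites))] = 1
    chrom = np.concatenate([pop.chrom, [c for c, _ in new_sites]])
    pos = np.concatenate([pop.pos, [p for _, p in new_sites]])
    haps = np.concatenate([pop.haps, new_cols], axis=1)
    order = np.lexsort((pos, chrom))
    pop.chrom, pop.pos, pop.haps = chrom[order], pos[order], haps[:, order]


def _prune_monomorphic(pop: _Population) -> None:
    counts = pop.haps.sum(axis=0, dtype=np.int64)
    keep = (counts > 0) & (counts < pop.n_haplotypes)
    pop.haps = pop.haps[:, keep]
    pop.chrom = pop.chrom[keep]
    pop.pos = pop.pos[keep]


def _evolve_neutral(
    pop: _Population,
    ne: int,
    generations: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    mutate: bool,
    prune: bool,
) -> None:
    for _ in range(generations):
        parents = rng.integers(0, pop.n_haplotypes // 2, size=2 * ne)
        pop.haps = _make_gametes(pop, parents, config, rng)
        if mutate:
            _add_mutations(pop, config, rng)
        if prune:
            _prune_monomorphic(pop)


def simulate_neutral_panel(config: SimulationConfig) -> tuple[HaplotypePanel, GenomeMap]:
    """Burn in a neutral base population; returns 2*base_Ne phased haplotypes.

    Every returned SNP segregates (frequency strictly in (0, 1)); raises if no
    sites segregate after burn-in (e.g. mutation_rate = 0).
    """
    config.validate()
    rng = config.substream("base")
    pop = _Population(
        haps=np.zeros((2 * config.base_ne, 0), dtype=np.uint8),
        chrom=np.empty(0, dtype=np.int64),
        pos=np.empty(0, dtype=np.int64),
    )
    _evolve_neutral(
        pop, config.base_ne, config.burn_in_factor * config.base_ne, config, rng,
        mutate=True, prune=True,
    )
    if pop.haps.shape[1] == 0:
        raise RuntimeError(
            "no segregating sites after burn-in; increase the mutation rate or "
            "lengthen the burn-in"
        )
    gmap = GenomeMap(
        pop.chrom,
        pop.pos,
        {c: config.chrom_length for c in range(config.n_chromosomes)},
    )
    return HaplotypePanel("base", pop.haps, gmap), gmap


def split_breeds(
    base: HaplotypePanel, config: SimulationConfig
) -> dict[str, HaplotypePanel]:
    """Evolve each breed independently from base founders by pure drift.

    Founders are diploids resampled from the base panel; no new mutation after
    the split, so all breeds share one SNP map.  Sites monomorphic in every
    breed are dropped from the shared map.
    """
    config.validate()
    panels: dict[str, _Population] = {}
    for spec in config.breeds:
        rng = config.substream(f"breed:{spec.name}")
        founders = rng.integers(0, base.n_individuals, size=spec.ne)
        rows = np.ravel(np.column_stack((2 * founders, 2 * founders + 1)))
        pop = _Population(
            haps=base.haplotypes[rows].copy(),
            chrom=base.gmap.chrom.copy(),
            pos=base.gmap.pos.copy(),
        )
        _evolve_neutral(pop, spec.ne, spec.generations, config, rng, mutate=False, prune=False)
        panels[spec.name] = pop
    return _shared_panels(panels, config, base.gmap.chrom_lengths)


def _shared_panels(
    pops: dict[str, _Population],
    config: SimulationConfig,
    chrom_lengths: dict[int, int],
    protect: set[tuple[int, int]] | None = None,
) -> dict[str, HaplotypePanel]:
    """Drop sites monomorphic in all populations; build panels on a shared map."""
    groups = {b.name: b.group for b in config.breeds}
    any_pop = next(iter(pops.values()))
    seg = np.zeros(any_pop.haps.shape[1], dtype=bool)
    for pop in pops.values():
        counts = pop.haps.sum(axis=0, dtype=np.int64)
        seg |= (counts > 0) & (counts < pop.n_haplotypes)
    if protect:
        for c, p in protect:
            hit = np.flatnonzero((any_pop.chrom == c) & (any_pop.pos == p))
            seg[hit] = True
    keep = np.flatnonzero(seg)
    gmap = GenomeMap(any_pop.chrom[keep], any_pop.pos[keep], chrom_lengths)
    return {
        name: HaplotypePanel(name, pop.haps[:, keep], gmap, groups.get(name))
        for name, pop in pops.items()
    }


def _selection_generation(
    pop: _Population,
    site: int,
    s: float,
    ne: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> int:
    """One generation of genic selection at ``site``; returns new derived count.

    Deterministic update p* = p(1+s) / (1+sp) then k ~ Binomial(2Ne, p*); the
    next generation is assembled from gametes conditioned to carry exactly k
    derived alleles (accept-reject within carrier / non-carrier parents).
    """
    n2_parent = pop.n_haplotypes
    count = int(pop.haps[:, site].sum())
    p = count / n2_parent
    p_star = p * (1 + s) / (1 + s * p) if s > 0 else p
    k = int(rng.binomial(2 * ne, p_star))
    dosage = pop.haps[0::2, site].astype(np.int64) + pop.haps[1::2, site].astype(np.int64)
    carrier_parents = np.flatnonzero(dosage >= 1)
    noncarrier_parents = np.flatnonzero(dosage <= 1)
    if k > 0 and len(carrier_parents) == 0:
        k = 0
    if k < 2 * ne and len(noncarrier_parents) == 0:
        k = 2 * ne
    gametes = []
    for want, pool in ((1, carrier_parents), (0, noncarrier_parents)):
        need = k if want == 1 else 2 * ne - k
        got = 0
        while got < need:
            batch = max(need - got, 8)
            parents = rng.choice(pool, size=batch)
            cand = _make_gametes(pop, parents, config, rng)
            hit = cand[:, site] == want
            take = cand[hit][: need - got]
            gametes.append(take)
            got += len(take)
    allg = np.concatenate(gametes, axis=0)
    perm = rng.permutation(len(allg))
    pop.haps = allg[perm]
    return k


def impose_sweep(
    panel: HaplotypePanel, sweep: SweepSpec, config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[HaplotypePanel, float]:
    """Drive the derived allele at the sweep locus upward in one population.

    If the locus is absent from the panel's map it is inserted as a new
    mutation column (all panels sharing the map should be given the column
    first; see :func:`simulate_dataset`).  If the derived allele starts at
    frequency 0 an origin haplotype is drawn at random; runs where the allele
    is lost before reaching frequency 0.05 are restarted from the origin draw
    up to ``sweep.retry_limit`` times.  Returns the evolved panel and the
    final derived-allele frequency.
    """
    if rng is None:
        rng = config.substream(f"sweep:{panel.name}:{sweep.chrom}:{sweep.position}")
    gmap = panel.gmap
    hit = np.flatnonzero((gmap.chrom == sweep.chrom) & (gmap.pos == sweep.position))
    if len(hit) == 0:
        raise ValueError(
            "sweep locus not in the panel map; insert it into all panels first"
        )
    site = int(hit[0])
    ne = panel.n_individuals
    start_state = panel.haplotypes.copy()
    for attempt in range(sweep.retry_limit):
        pop = _Population(start_state.copy(), gmap.chrom.copy(), gmap.pos.copy())
        if pop.haps[:, site].sum() == 0:
            pop.haps[rng.integers(0, pop.n_haplotypes), site] = 1
        lost = False
        freq = pop.haps[:, site].sum() / pop.n_haplotypes
        for _ in range(sweep.generations):
            k = _selection_generation(pop, site, sweep.s, ne, config, rng)
            freq = k / (2 * ne)
            if k == 0:
                lost = True
                break
            if sweep.stop_frequency is not None and freq >= sweep.stop_frequency:
                break
            if k == 2 * ne:
                break
        if lost and freq < 0.05:
            continue
        return HaplotypePanel(panel.name, pop.haps, gmap, panel.group), float(freq)
    raise RuntimeError(
        f"sweep allele lost before frequency 0.05 in {sweep.retry_limit} attempts"
    )


def insert_site(
    panels: dict[str, HaplotypePanel], chrom: int, position: int,
    chrom_lengths: dict[int, int] | None = None,
) -> dict[str, HaplotypePanel]:
    """Insert an all-ancestral column at (chrom, position) into every panel."""
    any_panel = next(iter(panels.values()))
    gmap = any_panel.gmap
    if np.any((gmap.chrom == chrom) & (gmap.pos == position)):
        return panels
    chrom_arr = np.concatenate([gmap.chrom, [chrom]])
    pos_arr = np.concatenate([gmap.pos, [position]])
    order = np.lexsort((pos_arr, chrom_arr))
    new_map = GenomeMap(chrom_arr[order], pos_arr[order], chrom_lengths or gmap.chrom_lengths)
    out = {}
    for name, panel in panels.items():
        col = np.zeros((panel.n_haplotypes, 1), dtype=np.uint8)
        haps = np.concatenate([panel.haplotypes, col], axis=1)[:, order]
        out[name] = HaplotypePanel(name, haps, new_map, panel.group)
    return out


def simulate_trait(
    panels: dict[str, HaplotypePanel],
    trait: TraitSpec,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimulationTruth, dict[str, HaplotypePanel]]:
    """Simulate a polygenic trait, optionally under truncation selection.

    QTL are sampled from the shared map with standard-normal effects; the
    environmental noise is rescaled so the realized (in-sample) h2 equals the
    target exactly.  With ``truncation_fraction < 1`` the top fraction of each
    breed by phenotype are the parents of the next generation for the stated
    number of generations; phenotypes of the final generation are returned
    along with the evolved panels.
    """
    if rng is None:
        rng = config.substream("trait")
    any_panel = next(iter(panels.values()))
    gmap = any_panel.gmap
    m = gmap.n_snps
    if trait.n_qtl > m:
        raise ValueError("n_qtl exceeds the number of segregating SNPs")
    qtl_idx = np.sort(rng.choice(m, size=trait.n_qtl, replace=False))
    effects = rng.standard_normal(trait.n_qtl)

    def genetic_values(panel: HaplotypePanel) -> np.ndarray:
        return panel.dosages()[:, qtl_idx].astype(float) @ effects

    if trait.truncation_fraction < 1.0 and trait.generations > 0:
        evolved: dict[str, HaplotypePanel] = {}
        for name, panel in panels.items():
            pop = _Population(panel.haplotypes.copy(), gmap.chrom.copy(), gmap.pos.copy())
            ne = panel.n_individuals
            for _ in range(trait.generations):
                current = HaplotypePanel(name, pop.haps, gmap, panel.group)
                g = genetic_values(current)
                var_g = g.var(ddof=1)
                sigma_e = np.sqrt(var_g * (1 - trait.h2) / trait.h2) if var_g > 0 else 1.0
                y = g + sigma_e * rng.standard_normal(len(g))
                n_keep = max(2, int(np.ceil(trait.truncation_fraction * ne)))
                selected = np.argsort(-y)[:n_keep]
                parents = rng.choice(selected, size=2 * ne)
                pop.haps = _make_gametes(pop, parents, config, rng)
            evolved[name] = HaplotypePanel(name, pop.haps, gmap, panel.group)
        panels = evolved

    g_all, rows = [], []
    for name, panel in panels.items():
        g = genetic_values(panel)
        g_all.append(g)
        rows += [(f"{name}_{i}", name) for i in range(len(g))]
    g_all = np.concatenate(g_all)
    var_g = g_all.var(ddof=1)
    if var_g <= 1e-12 * (1.0 + float(np.mean(g_all)) ** 2):
        raise ValueError("zero genetic variance; target h2 unreachable")
    sigma2_e = var_g * (1 - trait.h2) / trait.h2
    e = rng.standard_normal(len(g_all))
    e = (e - e.mean()) / e.std(ddof=1) * np.sqrt(sigma2_e)  # exact realized h2
    y = g_all + e
    realized_h2 = float(var_g / (var_g + e.var(ddof=1)))
    pheno = pd.DataFrame(
        {
            "animal_id": [r[0] for r in rows],
            "breed": [r[1] for r in rows],
            trait.name: y,
            "genetic_value": g_all,
        }
    )
    truth = SimulationTruth(
        qtl=[
            {
                "chrom": int(gmap.chrom[j]),
                "pos": int(gmap.pos[j]),
                "effect": float(b),
            }
            for j, b in zip(qtl_idx, effects)
        ],
        realized_h2=realized_h2,
    )
    return pheno, truth, panels


def derive_outgroup(
    gmap: GenomeMap,
    n_individuals: int = 17,
    error_rate: float | None = None,
    target_single_fraction: float = 0.85,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Outgroup genotypes carrying the true ancestral allele (0) with errors.

    Each of the ``2 * n_individuals`` allele calls per site is flipped to the
    derived allele with ``error_rate``.  When no rate is given it is chosen so
    the expected fraction of sites showing a single allele across all outgroup
    calls matches ``target_single_fraction``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if error_rate is None:
        error_rate = error_rate_for_single_fraction(target_single_fraction, n_individuals)
    m = gmap.n_snps
    flips = rng.random((m, 2 * n_individuals)) < error_rate
    genotypes = flips[:, 0::2].astype(np.int8) + flips[:, 1::2].astype(np.int8)
    df = pd.DataFrame({"chrom": gmap.chrom, "pos": gmap.pos})
    for i in range(n_individuals):
        df[f"outgroup_{i}"] = genotypes[:, i]
    return df


def error_rate_for_single_fraction(target: float, n_individuals: int) -> float:
    """Flip rate such that P(all 2n calls agree) matches ``target``."""
    if not 0 < target < 1:
        raise ValueError("target fraction must be in (0, 1)")
    return 1.0 - target ** (1.0 / (2 * n_individuals))


def outgroup_allele_counts(outgroup: pd.DataFrame) -> np.ndarray:
    """(m, 2) counts of allele-0 and allele-1 calls from an outgroup table."""
    cols = [c for c in outgroup.columns if c.startswith("outgroup_")]
    geno = outgroup[cols].to_numpy(dtype=np.int64)
    derived = geno.sum(axis=1)
    total = 2 * len(cols)
    return np.column_stack([total - derived, derived])


@dataclass
class SimulatedDataset:
    panels: dict[str, HaplotypePanel]
    gmap: GenomeMap
    truth: SimulationTruth
    phenotypes: pd.DataFrame | None = None
    outgroup: pd.DataFrame | None = None
    config: SimulationConfig | None = None


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """End-to-end synthetic dataset: base -> breeds -> sweeps -> trait -> outgroup."""
    config.validate()
    base, _ = simulate_neutral_panel(config)
    panels = split_breeds(base, config)
    truth = SimulationTruth()
    for sweep in config.sweeps:
        panels = insert_site(panels, sweep.chrom, sweep.position)
        final = {}
        for breed in sweep.breeds:
            panels[breed], freq = impose_sweep(panels[breed], sweep, config)
            final[breed] = freq
        truth.sweeps.append(
            {
                "chrom": sweep.chrom,
                "pos": sweep.position,
                "s": sweep.s,
                "breeds": list(sweep.breeds),
                "final_frequency": final,
            }
        )
    if config.trait is not None:
        pheno, trait_truth, panels = simulate_trait(panels, config.trait, config)
        truth.qtl = trait_truth.qtl
        truth.realized_h2 = trait_truth.realized_h2
    else:
        pheno = None
    gmap = next(iter(panels.values())).gmap
    outgroup = derive_outgroup(gmap, rng=config.substream("outgroup"))
    return SimulatedDataset(panels, gmap, truth, pheno, outgroup, config)
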