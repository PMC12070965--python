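"""Forward-in-time breeding-population simulator.

The simulator produces, with no external data, the kind of dataset a
single-step genomic evaluation consumes: a multi-generation pedigree with
partially missing parentage, 0/1/2 genotypes for a subset of animals, and a
sex-limited quantitative trait with a known causal architecture (so true
breeding values are available for validation).

It runs in two phases on a discrete-generation Wright-Fisher model with
recombination (Haldane map, 1 crossover per Morgan) and symmetric allele
mutation:

* a **historical phase** whose population size declines into a bottleneck
  and re-expands, building linkage disequilibrium; all loci start at allele
  frequency 0.5;
* a **recent phase** started from a fixed number of male and female
  founders drawn from the end of history, with one offspring per dam per
  generation, truncation selection of replacement sires and dams on
  pedigree-BLUP EBV (or at random), and fixed sire/dam replacement rates.

The trait is strictly additive: causal loci are drawn uniformly from the
markers segregating among the recent founders, effects come from a gamma
distribution (shape 0.4, random sign) or, in the mixed architecture, from
two normal distributions for large and small effects; effects are rescaled
once so the founder true-breeding-value variance equals h^2 (phenotypic
variance 1).  Phenotypes (TBV + normal residual) are recorded for females
only.  Finally, a random half of the animals in the last generations is
flagged genotyped, a small fraction of non-founders loses both recorded
parents, and the last generation is labelled validation.

Default sizes are desk scale: they preserve the shape of a livestock
simulation study (bottleneck history, wide sire:dam ratio, truncation
selection, h^2 = 0.1) at a fraction of full scale so a replicate runs in
seconds; the scaling rationale is laid out in the methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import genotypes as gt
from . import mme
from .pedigree import Pedigree, build_A_inverse

#: causal-architecture presets: scenario -> (n_gamma, n_large, n_small)
SCENARIOS = {1: (10, 0, 0), 2: (100, 0, 0), 3: (500, 0, 0), 4: (0, 10, 500)}


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome
    n_chrom: int = 3
    chrom_length_cm: float = 100.0
    markers_per_chrom: int = 600
    mutation_rate: float = 2.5e-5
    # historical phase (bottleneck builds LD)
    hist_size_start: int = 150
    hist_size_mid: int = 25
    hist_size_end: int = 1000
    hist_generations: int = 100
    hist_decline_frac: float = 0.8  # fraction of generations spent declining
    # recent phase
    n_sires: int = 50
    n_dams: int = 750
    recent_generations: int = 6
    sire_replacement: float = 0.8
    dam_replacement: float = 0.3
    selection: str = "ebv"  # "ebv" (pedigree BLUP truncation) or "random"
    # trait
    h2: float = 0.1
    scenario: int = 1
    gamma_shape: float = 0.4
    large_effect_var: float = 0.1
    small_effect_var: float = 0.001
    # masking
    genotyped_fraction: float = 0.5
    genotyped_generations: int = 4
    pedigree_missing_rate: float = 0.05

    def __post_init__(self):
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must lie in (0, 1)")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {sorted(SCENARIOS)}")
        for r in (self.sire_replacement, self.dam_replacement,
                  self.genotyped_fraction, self.pedigree_missing_rate):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if min(self.n_chrom, self.markers_per_chrom, self.n_sires, self.n_dams,
               self.recent_generations, self.hist_generations) <= 0:
            raise ValueError("counts must be positive")

    @classmethod
    def full_scale(cls, **kw) -> "SimulationConfig":
        """Literature-scale configuration (slow: tens of minutes per replicate)."""
        base = dict(
            n_chrom=29, chrom_length_cm=80.0, markers_per_chrom=1725,
            hist_size_start=10_000, hist_size_mid=500, hist_size_end=50_000,
            hist_generations=1100, hist_decline_frac=0.909,
            n_sires=50, n_dams=4000, recent_generations=10,
        )
        base.update(kw)
        return cls(**base)

    @property
    def n_markers(self) -> int:
        return self.n_chrom * self.markers_per_chrom


@dataclass
class Trait:
    causal_idx: np.ndarray  # marker column indices
    effects: np.ndarray
    founder_freq: np.ndarray  # per causal locus, for TBV centering
    sigma_e2: float

    def tbv(self, geno_causal: np.ndarray) -> np.ndarray:
        Z = geno_causal - 2.0 * self.founder_freq
        return Z @ self.effects


@dataclass
class SimulatedPopulation:
    """Complete simulated dataset, truth retained for validation."""

    config: SimulationConfig
    markers: pd.DataFrame
    sire: np.ndarray  # true pedigree, index-based, -1 unknown
    dam: np.ndarray
    sire_masked: np.ndarray
    dam_masked: np.ndarray
    sex: np.ndarray  # 'M' / 'F'
    generation: np.ndarray  # 0 = recent founders
    genotype_matrix: np.ndarray  # all animals x markers, int8 (truth)
    tbv: np.ndarray
    phenotype: np.ndarray  # NaN for males
    genotyped: np.ndarray  # bool
    role: np.ndarray  # 'reference' / 'validation'
    trait: Trait

    @property
    def n(self) -> int:
        return self.sire.size

    @property
    def ids(self) -> np.ndarray:
        return np.arange(1, self.n + 1)

    def pedigree(self, masked: bool = True) -> Pedigree:
        s = self.sire_masked if masked else self.sire
        d = self.dam_masked if masked else self.dam
        ped = Pedigree(
            ids=self.ids.astype(object),
            sire=s.copy(),
            dam=d.copy(),
            genotyped=self.genotyped.copy(),
            sex=self.sex.astype(object),
        )
        return ped

    def genotype_data(self) -> gt.GenotypeData:
        idx = np.flatnonzero(self.genotyped)
        return gt.GenotypeData(
            self.genotype_matrix[idx].astype(float), self.markers, self.ids[idx].astype(object)
        )

    def write(self, outdir) -> None:
        """Write the standard file set (pedigree CSV, genotype + map TSV,
        phenotype TSV, truth TSV, config echo JSON)."""
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        from .pedigree import write_pedigree

        write_pedigree(self.pedigree(masked=True), out / "pedigree.csv")
        gt.write_genotypes(self.genotype_data(), out / "genotypes.tsv", out / "markers.tsv")
        pheno = pd.DataFrame(
            {
                "animal_id": self.ids,
                "trait": np.round(self.phenotype, 6),
                "generation": self.generation,
                "sex": self.sex,
                "role": self.role,
            }
        )
        pheno = pheno[~np.isnan(self.phenotype)]
        pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
        pd.DataFrame({"animal_id": self.ids, "tbv": np.round(self.tbv, 6)}).to_csv(
            out / "tbv.tsv", sep="\t", index=False
        )
        with open(out / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=1)


# ---------------------------------------------------------------------------
# meiosis machinery
# ---------------------------------------------------------------------------

def marker_map(config: SimulationConfig) -> pd.DataFrame:
    """Evenly spaced markers; positions in cM within each chromosome."""
    per = config.markers_per_chrom
    spacing = config.chrom_length_cm / per
    chrom = np.repeat(np.arange(1, config.n_chrom + 1), per)
    pos = np.tile((np.arange(per) + 0.5) * spacing, config.n_chrom)
    names = [f"c{c}m{i}" for c, i in zip(chrom, np.tile(np.arange(per), config.n_chrom))]
    return pd.DataFrame({"marker": names, "chrom": chrom, "pos": np.round(pos, 6)})


def _switch_probs(config: SimulationConfig) -> np.ndarray:
    """Per-position probability that the copied parental strand switches.

    Within a chromosome this is the Haldane interval recombination fraction
    r = (1 - exp(-2d/100)) / 2; at each chromosome start it is 0.5, which
    randomizes the starting strand (independent assortment).
    """
    per = config.markers_per_chrom
    d = config.chrom_length_cm / per  # cM between adjacent markers
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    p = np.full(config.n_markers, r)
    p[:: per] = 0.5
    return p


def _gametes(haps: np.ndarray, parent: np.ndarray, switch_p: np.ndarray,
             rng: np.random.Generator, mutation_rate: float) -> np.ndarray:
    """One recombinant (and mutated) gamete per entry of ``parent``.

    ``haps`` is (2N, L) with animal i owning rows 2i and 2i+1.  Switch
    events are sampled sparsely per gamete (Binomial counts + uniform
    positions), turned into a strand-parity mask by a cumulative sum, and
    the mask gathers from the two parental strands.
    """
    G = parent.size
    L = haps.shape[1]
    switch = np.zeros((G, L), dtype=np.int8)
    # chromosome-start phases and interior recombinations share one pass:
    starts = np.flatnonzero(switch_p >= 0.5)
    switch[:, starts] = rng.integers(0, 2, size=(G, starts.size), dtype=np.int8)
    interior = switch_p < 0.5
    n_int = int(interior.sum())
    r = float(switch_p[interior][0]) if n_int else 0.0
    counts = rng.binomial(n_int, r, size=G)
    tot = int(counts.sum())
    if tot:
        rows = np.repeat(np.arange(G), counts)
        int_pos = np.flatnonzero(interior)
        cols = int_pos[rng.integers(0, n_int, size=tot)]
        np.add.at(switch, (rows, cols), 1)
    parity = np.cumsum(switch, axis=1, dtype=np.int32) & 1
    a = haps[2 * parent]
    b = haps[2 * parent + 1]
    gam = np.where(parity == 0, a, b)
    # symmetric mutation: flip allele with the per-meiosis locus rate
    mcounts = rng.binomial(L, mutation_rate, size=G)
    mt = int(mcounts.sum())
    if mt:
        rows = np.repeat(np.arange(G), mcounts)
        cols = rng.integers(0, L, size=mt)
        gam[rows, cols] = 1 - gam[rows, cols]
    return gam


def _hist_sizes(config: SimulationConfig) -> np.ndarray:
    """Population size per historical generation, linearly interpolated
    between start, bottleneck and end sizes."""
    g = config.hist_generations
    g1 = max(int(round(config.hist_decline_frac * g)), 1)
    g2 = g - g1
    sizes = list(
        np.round(np.linspace(config.hist_size_start, config.hist_size_mid, g1 + 1)).astype(int)
    )
    if g2 > 0:
        sizes += list(
            np.round(np.linspace(config.hist_size_mid, config.hist_size_end, g2 + 1)).astype(int)[1:]
        )
    return np.array(sizes[1:])  # size of each generated generation


def simulate_historical(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Wright-Fisher history with the configured size trajectory.

    All loci start at frequency 0.5; each new individual draws two parents
    (distinct when possible) uniformly from the previous generation.
    Returns the final-generation haplotypes (2N_end, L) as uint8.
    """
    L = config.n_markers
    N0 = config.hist_size_start
    haps = (rng.random((2 * N0, L)) < 0.5).astype(np.uint8)
    if config.hist_generations == 0:
        return haps
    switch_p = _switch_probs(config)
    for N_next in _hist_sizes(config):
        N_cur = haps.shape[0] // 2
        sires = rng.integers(0, N_cur, size=N_next)
        dams = rng.integers(0, N_cur, size=N_next)
        clash = sires == dams
        dams[clash] = (dams[clash] + 1) % N_cur
        g1 = _gametes(haps, sires, switch_p, rng, config.mutation_rate)
        g2 = _gametes(haps, dams, switch_p, rng, config.mutation_rate)
        haps = np.empty((2 * N_next, L), dtype=np.uint8)
        haps[0::2] = g1
        haps[1::2] = g2
    return haps


# ---------------------------------------------------------------------------
# trait
# ---------------------------------------------------------------------------

def assign_trait(founder_geno: np.ndarray, config: SimulationConfig,
                 rng: np.random.Generator) -> Trait:
    """Draw the causal architecture and scale it to the target heritability.

    Causal loci are sampled uniformly (without replacement) from markers
    segregating among the recent founders.  Effects: gamma(shape) magnitude
    with random sign for the pure scenarios, or two normal pools for the
    mixed large/small scenario.  All effects are rescaled once so that
    Var(TBV) among the founders equals h^2 (phenotypic variance 1, so
    sigma_e^2 = 1 - h^2).
    """
    n_gamma, n_large, n_small = SCENARIOS[config.scenario]
    total = n_gamma + n_large + n_small
    freq = founder_geno.mean(axis=0) / 2.0
    seg = np.flatnonzero((freq > 0) & (freq < 1))
    if seg.size < total:
        raise ValueError(f"only {seg.size} segregating markers for {total} causal SNPs")
    causal = rng.choice(seg, size=total, replace=False)
    eff = np.empty(total)
    if n_gamma:
        mag = rng.gamma(config.gamma_shape, 1.0, size=n_gamma)
        eff[:n_gamma] = mag * rng.choice([-1.0, 1.0], size=n_gamma)
    if n_large:
        eff[n_gamma : n_gamma + n_large] = rng.normal(
            0.0, np.sqrt(config.large_effect_var), size=n_large
        )
    if n_small:
        eff[n_gamma + n_large :] = rng.normal(
            0.0, np.sqrt(config.small_effect_var), size=n_small
        )
    pfreq = freq[causal]
    Z = founder_geno[:, causal] - 2.0 * pfreq
    raw = Z @ eff
    v = raw.var()
    if v <= 0:
        raise ValueError("degenerate causal architecture: zero TBV variance")
    eff *= np.sqrt(config.h2 / v)
    return Trait(causal, eff, pfreq, sigma_e2=1.0 - config.h2)


# ---------------------------------------------------------------------------
# recent selected population
# ---------------------------------------------------------------------------

def _pedigree_blup_ebv(sire, dam, pheno, h2) -> np.ndarray:
    """EBV by pedigree-only animal model BLUP on the records available."""
    n = sire.size
    ped = Pedigree(
        ids=np.arange(n).astype(object), sire=np.asarray(sire), dam=np.asarray(dam),
        genotyped=np.zeros(n, bool),
    )
    ainv = build_A_inverse(ped)
    rec = np.flatnonzero(~np.isnan(pheno))
    spec = mme.ModelSpec(
        X=np.ones((rec.size, 1)), record_animal=rec, n_animals=n,
        hinv=ainv, sigma_u2=h2, sigma_e2=1.0 - h2,
    )
    return mme.solve_mme(spec, pheno[rec]).u


def simulate_recent(
    founder_haps: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    trait: Trait | None = None,
):
    """Recent pedigreed population under truncation selection.

    Founder sires and dams are drawn from the end-of-history haplotype
    pool.  Each generation every dam produces one offspring by a random
    sire; a fixed fraction of sires and dams is then replaced by the
    top-EBV (pedigree BLUP) young animals of that generation, the remaining
    parent slots going to the top-EBV current parents.  ``selection =
    "random"`` replaces truncation by random choice.  Phenotypes (females
    only) are generated as soon as the trait is known so that selection can
    use them.

    Returns (haplotypes, sire, dam, sex, generation, tbv, phenotype).
    """
    ns, nd = config.n_sires, config.n_dams
    n_found_hist = founder_haps.shape[0] // 2
    if n_found_hist < ns + nd:
        raise ValueError("historical population too small to supply recent founders")
    L = founder_haps.shape[1]
    switch_p = _switch_probs(config)
    pick = rng.choice(n_found_hist, size=ns + nd, replace=False)
    haps = np.empty((2 * (ns + nd + nd * config.recent_generations), L), dtype=np.uint8)
    haps[: 2 * (ns + nd)] = founder_haps[
        np.ravel(np.column_stack([2 * pick, 2 * pick + 1]))
    ]
    n_total = ns + nd + nd * config.recent_generations
    sire = np.full(n_total, -1, dtype=int)
    dam = np.full(n_total, -1, dtype=int)
    sex = np.empty(n_total, dtype=object)
    sex[:ns] = "M"
    sex[ns : ns + nd] = "F"
    generation = np.zeros(n_total, dtype=int)
    tbv = np.zeros(n_total)
    pheno = np.full(n_total, np.nan)

    def geno_of(rows):
        return haps[2 * rows] + haps[2 * rows + 1]

    def record_trait(rows):
        if trait is None:
            return
        g = geno_of(rows)[:, trait.causal_idx].astype(float)
        tbv[rows] = trait.tbv(g)
        fem = rows[sex[rows] == "F"]
        if fem.size:
            gf = geno_of(fem)[:, trait.causal_idx].astype(float)
            pheno[fem] = trait.tbv(gf) + rng.normal(0, np.sqrt(trait.sigma_e2), fem.size)

    record_trait(np.arange(ns + nd))
    cur_sires = np.arange(ns)
    cur_dams = np.arange(ns, ns + nd)
    nxt = ns + nd
    for g in range(1, config.recent_generations + 1):
        mates = cur_sires[rng.integers(0, ns, size=nd)]
        rows = np.arange(nxt, nxt + nd)
        haps[2 * rows] = _gametes(haps[: 2 * nxt], mates, switch_p, rng, config.mutation_rate)
        haps[2 * rows + 1] = _gametes(haps[: 2 * nxt], cur_dams, switch_p, rng, config.mutation_rate)
        sire[rows] = mates
        dam[rows] = cur_dams
        sex[rows] = np.where(rng.random(nd) < 0.5, "M", "F")
        generation[rows] = g
        record_trait(rows)
        nxt += nd
        # replacement: truncation on EBV (or random)
        n_new_s = int(round(config.sire_replacement * ns))
        n_new_d = int(round(config.dam_replacement * nd))
        young_m = rows[sex[rows] == "M"]
        young_f = rows[sex[rows] == "F"]
        if young_m.size < n_new_s or young_f.size < n_new_d:
            raise ValueError("not enough young candidates to meet replacement rates")
        if config.selection == "ebv" and trait is not None:
            ebv = _pedigree_blup_ebv(sire[:nxt], dam[:nxt], pheno[:nxt], config.h2)
            top = lambda cand, k: cand[np.argsort(-ebv[cand], kind="stable")[:k]]
        else:
            perm = rng.permutation
            top = lambda cand, k: perm(cand)[:k]
        cur_sires = np.concatenate([top(cur_sires, ns - n_new_s), top(young_m, n_new_s)])
        cur_dams = np.concatenate([top(cur_dams, nd - n_new_d), top(young_f, n_new_d)])
    return haps, sire, dam, sex, generation, tbv, pheno


# ---------------------------------------------------------------------------
# masking and driver
# ---------------------------------------------------------------------------

def mask_data(sire, dam, generation, config: SimulationConfig,
              rng: np.random.Generator):
    """Genotyping flags, masked-parent pedigree and reference/validation roles."""
    n = sire.size
    last = generation.max()
    window = generation > last - config.genotyped_generations
    genotyped = np.zeros(n, bool)
    cand = np.flatnonzero(window)
    take = rng.random(cand.size) < config.genotyped_fraction
    genotyped[cand[take]] = True
    sire_m, dam_m = sire.copy(), dam.copy()
    non_founder = np.flatnonzero((sire >= 0) | (dam >= 0))
    hit = non_founder[rng.random(non_founder.size) < config.pedigree_missing_rate]
    sire_m[hit] = -1
    dam_m[hit] = -1
    role = np.where(generation == last, "validation", "reference").astype(object)
    return genotyped, sire_m, dam_m, role


def simulate_population(config: SimulationConfig) -> SimulatedPopulation:
    """Run the full simulation pipeline for one replicate.

    Stage RNGs are spawned from the master seed so each stage is
    independently reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    r_hist, _r_spare, r_trait, r_recent, r_mask = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]
    hist = simulate_historical(config, r_hist)
    # the trait is anchored to the end-of-history pool (from which the
    # recent founders are drawn) so selection can act on it from the start
    founder_geno_pool = hist[0::2] + hist[1::2]
    trait = assign_trait(founder_geno_pool.astype(float), config, r_trait)
    haps, sire, dam, sex, generation, tbv, pheno = simulate_recent(
        hist, config, r_recent, trait=trait
    )
    genotyped, sire_m, dam_m, role = mask_data(sire, dam, generation, config, r_mask)
    markers = marker_map(config)
    geno = (haps[0::2] + haps[1::2]).astype(np.int8)
    return SimulatedPopulation(
        config=config,
        markers=markers,
        sire=sire,
        dam=dam,
        sire_masked=sire_m,
        dam_masked=dam_m,
        sex=sex,
        generation=generation,
        genotype_matrix=geno,
        tbv=tbv,
        phenotype=pheno,
        genotyped=genotyped,
        role=role,
        trait=trait,
    )
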