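"""Forward-in-time breeding-program simulator.

Simulates, haplotype by haplotype, the population design of a two-way
crossbreeding program in sheep-like species:

1. a historical population whose size follows a three-phase trajectory
   (constant, linear decline, constant) to build mutation-drift linkage
   disequilibrium;
2. two breeds (A, B) founded by disjoint random samples from the last
   historical generation, expanded by random mating;
3. a second bottleneck creating the "recent" populations whose generation 0
   is the pedigree base for genetic evaluation;
4. ten generations of truncation selection on pedigree-BLUP EBVs with
   age-based culling and fixed replacement rates;
5. F1 crossbreds produced from sires of breed A and dams of breed B taken
   from generations 8-10.

The simulator is haplotype-based: every individual carries two phased
haplotypes per chromosome, gametes are formed under a Haldane map (crossover
count Poisson in map length, no interference) and recurrent biallelic
mutation, and the genotype view is the 0/1/2 allele-count collapse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SimConfig

POP_A, POP_B, POP_AB, POP_HIST = 0, 1, 2, 3
MALE, FEMALE = 0, 1


class SimulationError(RuntimeError):
    """Raised when a population cannot continue (extinction, exhaustion...)."""


# ----------------------------------------------------------------------
# genome
# ----------------------------------------------------------------------

@dataclass
class GenomeArchitecture:
    """Chromosome map with marker and QTL positions.

    Loci are stored flat, sorted by (chromosome, position); ``is_qtl``
    partitions them into the marker panel and the causal loci.
    """

    chrom_lengths: np.ndarray          # cM per chromosome
    chrom: np.ndarray                  # (L,) chromosome index per locus
    positions_cm: np.ndarray           # (L,) position within chromosome
    is_qtl: np.ndarray                 # (L,) bool
    mutation_rate: float

    def __post_init__(self) -> None:
        self.chrom_lengths = np.asarray(self.chrom_lengths, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=np.int32)
        self.positions_cm = np.asarray(self.positions_cm, dtype=float)
        self.is_qtl = np.asarray(self.is_qtl, dtype=bool)
        self.validate()
        self._recomb = None

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if np.any(self.positions_cm < 0) or np.any(
            self.positions_cm > self.chrom_lengths[self.chrom]
        ):
            raise ValueError("locus positions outside chromosome bounds")
        for c in range(self.n_chromosomes):
            pos = self.positions_cm[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions on chromosome {c} not strictly sorted")
        if np.any(np.diff(self.chrom) < 0):
            raise ValueError("loci not grouped by chromosome")

    @property
    def n_loci(self) -> int:
        return self.positions_cm.size

    @property
    def n_chromosomes(self) -> int:
        return self.chrom_lengths.size

    @property
    def marker_index(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    @property
    def qtl_index(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    def marker_positions(self, c: int) -> np.ndarray:
        return self.positions_cm[(self.chrom == c) & ~self.is_qtl]

    def qtl_positions(self, c: int) -> np.ndarray:
        return self.positions_cm[(self.chrom == c) & self.is_qtl]

    # -- recombination -------------------------------------------------
    def recomb_fractions(self) -> np.ndarray:
        """Per-locus switch probabilities for gamete sampling.

        Entry ``l`` is the probability that the copied parental haplotype
        differs between locus ``l-1`` and locus ``l``: 0.5 at the first
        locus of every chromosome (independent segregation), else the
        Haldane recombination fraction of the inter-locus distance.
        """
        if self._recomb is None:
            r = np.empty(self.n_loci)
            d = np.diff(self.positions_cm)
            r[1:] = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
            first = np.r_[0, 1 + np.flatnonzero(np.diff(self.chrom) != 0)]
            r[first] = 0.5
            self._recomb = r
        return self._recomb

    def subset(self, locus_idx: np.ndarray, is_qtl: np.ndarray | None = None
               ) -> "GenomeArchitecture":
        locus_idx = np.sort(np.asarray(locus_idx))
        return GenomeArchitecture(
            self.chrom_lengths,
            self.chrom[locus_idx],
            self.positions_cm[locus_idx],
            self.is_qtl[locus_idx] if is_qtl is None else is_qtl,
            self.mutation_rate,
        )


def sample_genome(config: SimConfig, rng: np.random.Generator,
                  n_loci: int | None = None) -> GenomeArchitecture:
    """Draw a candidate locus map: uniform positions, no marker/QTL labels yet.

    More loci than the final panel are simulated (``locus_surplus``); the
    MAF filter and marker/QTL assignment happen at breed founding.
    """
    if n_loci is None:
        n_loci = int(np.ceil((config.n_markers + config.n_qtl) * config.locus_surplus))
    lengths = np.full(config.n_chromosomes, config.chrom_length_cm)
    per = np.full(config.n_chromosomes, n_loci // config.n_chromosomes)
    per[: n_loci % config.n_chromosomes] += 1
    chrom, pos = [], []
    for c in range(config.n_chromosomes):
        p = np.sort(rng.uniform(0.0, lengths[c], per[c]))
        while np.any(np.diff(p) <= 0):      # enforce strict ordering
            p = np.sort(rng.uniform(0.0, lengths[c], per[c]))
        chrom.append(np.full(per[c], c))
        pos.append(p)
    return GenomeArchitecture(
        lengths, np.concatenate(chrom), np.concatenate(pos),
        np.zeros(n_loci, dtype=bool), config.mutation_rate,
    )


def assign_marker_qtl(genome: GenomeArchitecture, keep: np.ndarray,
                      n_markers: int, n_qtl: int,
                      rng: np.random.Generator) -> tuple[GenomeArchitecture, np.ndarray]:
    """Pick the final marker panel and QTL among loci passing the MAF filter.

    Returns the finalized genome and the index of retained loci in the
    candidate genome (used to slice haplotypes).
    """
    passing = np.flatnonzero(keep)
    if passing.size < n_markers + n_qtl:
        raise SimulationError(
            f"only {passing.size} loci pass the MAF filter; "
            f"{n_markers + n_qtl} needed (increase locus_surplus)"
        )
    chosen = rng.choice(passing, size=n_markers + n_qtl, replace=False)
    qtl = rng.choice(chosen, size=n_qtl, replace=False)
    locus_idx = np.sort(chosen)
    is_qtl = np.isin(locus_idx, qtl)
    return genome.subset(locus_idx, is_qtl), locus_idx


# ----------------------------------------------------------------------
# gametes
# ----------------------------------------------------------------------

def sample_gametes(haps: np.ndarray, parent_rows: np.ndarray,
                   genome: GenomeArchitecture, rng: np.random.Generator,
                   mutate: bool = True) -> np.ndarray:
    """Form one gamete per entry of ``parent_rows`` (vectorized).

    The copied haplotype along each chromosome follows a two-state Markov
    chain whose switch probability between adjacent loci is the Haldane
    recombination fraction -- the locus-resolution law of a Poisson
    crossover process without interference.
    """
    m = parent_rows.size
    L = genome.n_loci
    r = genome.recomb_fractions()
    switch = rng.random((m, L)) < r
    h = np.cumsum(switch, axis=1, dtype=np.int32) & 1
    gam = haps[parent_rows[:, None], h, np.arange(L)[None, :]]
    if mutate and genome.mutation_rate > 0:
        n_mut = rng.poisson(genome.mutation_rate * m * L)
        if n_mut:
            flat = rng.integers(0, m * L, size=n_mut)
            g = gam.reshape(-1)
            g[flat] ^= 1             # recurrent biallelic flip
    return gam


def meiosis(parent_haplotypes: np.ndarray, genome: GenomeArchitecture,
            rng: np.random.Generator, return_crossovers: bool = False):
    """Single explicit meiosis: Poisson crossover count, uniform positions.

    ``parent_haplotypes`` is the (2, L) phased pair.  Equivalent in
    distribution to :func:`sample_gametes`; exposed for direct inspection
    of the crossover process.
    """
    L = genome.n_loci
    gam = np.empty(L, dtype=parent_haplotypes.dtype)
    total_xo = 0
    for c in range(genome.n_chromosomes):
        sel = genome.chrom == c
        pos = genome.positions_cm[sel]
        k = rng.poisson(genome.chrom_lengths[c] / 100.0)
        total_xo += k
        xo = np.sort(rng.uniform(0.0, genome.chrom_lengths[c], k))
        start = rng.integers(0, 2)
        h = (start + np.searchsorted(xo, pos)) % 2
        sub = parent_haplotypes[:, sel]
        gam[sel] = sub[h, np.arange(pos.size)]
    if genome.mutation_rate > 0:
        mut = rng.random(L) < genome.mutation_rate
        gam[mut] ^= 1
    if return_crossovers:
        return gam, total_xo
    return gam


def genotype_counts(haps: np.ndarray) -> np.ndarray:
    """Collapse phased haplotypes (n, 2, L) to allele counts (n, L)."""
    return haps.sum(axis=1, dtype=np.int8)


def allele_frequencies(haps_or_counts: np.ndarray) -> np.ndarray:
    x = haps_or_counts
    if x.ndim == 3:
        return x.mean(axis=(0, 1))
    return x.mean(axis=0) / 2.0


def apply_maf_filter(counts: np.ndarray, threshold: float) -> np.ndarray:
    """Boolean mask of loci whose minor allele frequency is >= threshold."""
    p = counts.mean(axis=0) / 2.0
    keep = np.minimum(p, 1.0 - p) >= threshold
    if threshold > 0 and not keep.any():
        raise SimulationError("MAF filter removed every locus")
    return keep


# ----------------------------------------------------------------------
# population states
# ----------------------------------------------------------------------

def _assign_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Half male / half female, randomly permuted."""
    sex = np.full(n, FEMALE, dtype=np.int8)
    sex[: n // 2] = MALE
    return rng.permutation(sex)


@dataclass
class PopState:
    """One unpedigreed generation: phased haplotypes plus sexes."""

    haps: np.ndarray       # (n, 2, L) uint8
    sex: np.ndarray        # (n,) int8

    @property
    def n(self) -> int:
        return self.haps.shape[0]

    def counts(self) -> np.ndarray:
        return genotype_counts(self.haps)


def simulate_historical(config: SimConfig, genome: GenomeArchitecture,
                        rng: np.random.Generator) -> PopState:
    """Run the three-phase historical population; return the final generation.

    Founder allele frequencies are i.i.d. uniform around 0.5; the
    generations of drift that follow take the population to mutation-drift
    equilibrium LD.  Earlier generations are discarded.
    """
    n0 = config.hist_size_start
    spread = config.founder_freq_spread
    p0 = rng.uniform(0.5 - spread, 0.5 + spread, genome.n_loci)
    haps = (rng.random((n0, 2, genome.n_loci)) < p0).astype(np.uint8)
    state = PopState(haps, _assign_sexes(n0, rng))

    sizes = np.concatenate([
        np.full(config.hist_gens_constant, config.hist_size_start),
        np.round(np.linspace(config.hist_size_start, config.hist_size_end,
                             config.hist_gens_decline + 2)[1:-1]).astype(int)
        if config.hist_gens_decline else np.empty(0, dtype=int),
        np.full(config.hist_gens_final, config.hist_size_end),
    ])
    for n_next in sizes:
        state = _random_union(state, int(n_next), genome, rng)
    return state


def _random_union(state: PopState, n_next: int, genome: GenomeArchitecture,
                  rng: np.random.Generator) -> PopState:
    if n_next < 2:
        raise SimulationError(f"historical population collapsed to {n_next}")
    males = np.flatnonzero(state.sex == MALE)
    females = np.flatnonzero(state.sex == FEMALE)
    if males.size == 0 or females.size == 0:
        raise SimulationError("one sex went extinct in the historical population")
    sires = males[rng.integers(0, males.size, n_next)]
    dams = females[rng.integers(0, females.size, n_next)]
    haps = np.stack([
        sample_gametes(state.haps, sires, genome, rng),
        sample_gametes(state.haps, dams, genome, rng),
    ], axis=1)
    return PopState(haps, _assign_sexes(n_next, rng))


def found_breeds(hist: PopState, n_males: int, n_females: int,
                 rng: np.random.Generator, disjoint: bool = True
                 ) -> tuple[PopState, PopState]:
    """Two random samples (the first bottleneck) -> breeds A and B.

    With ``disjoint`` the two founder sets share no individual (each sample
    drawn without replacement from what remains); otherwise each breed
    samples independently from the whole generation -- the only option when
    the bottleneck takes most of the population, as in scaled-down
    profiles.  Either way the breeds diverge by drift from the bottleneck
    onwards.
    """
    males = np.flatnonzero(hist.sex == MALE)
    females = np.flatnonzero(hist.sex == FEMALE)
    need = 2 if disjoint else 1
    if males.size < need * n_males:
        raise SimulationError(
            f"need {need * n_males} males for two breeds, have {males.size}")
    if females.size < need * n_females:
        raise SimulationError(
            f"need {need * n_females} females for two breeds, have {females.size}")
    if disjoint:
        m = rng.choice(males, 2 * n_males, replace=False)
        f = rng.choice(females, 2 * n_females, replace=False)
        picks = [(m[:n_males], f[:n_females]), (m[n_males:], f[n_females:])]
    else:
        picks = [(rng.choice(males, n_males, replace=False),
                  rng.choice(females, n_females, replace=False))
                 for _ in range(2)]
    out = []
    for mk, fk in picks:
        idx = np.concatenate([mk, fk])
        sex = np.r_[np.zeros(n_males, dtype=np.int8),
                    np.ones(n_females, dtype=np.int8)]
        out.append(PopState(hist.haps[idx].copy(), sex))
    return out[0], out[1]


@dataclass
class ExpansionPedigree:
    """Pedigree bookkeeping of the expansion phase (ids 1-based, 0 unknown)."""

    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    generation: np.ndarray


def expand_breed(state: PopState, n_generations: int, config: SimConfig,
                 genome: GenomeArchitecture, rng: np.random.Generator
                 ) -> tuple[ExpansionPedigree, PopState]:
    """Random mating, fixed litter size, growth capped at ``expansion_cap``."""
    ppd = config.progeny_per_dam
    sire = [np.zeros(state.n, dtype=np.int32)]
    dam = [np.zeros(state.n, dtype=np.int32)]
    sexes = [state.sex.copy()]
    gens = [np.zeros(state.n, dtype=np.int32)]
    offset = 0
    for g in range(1, n_generations + 1):
        males = np.flatnonzero(state.sex == MALE)
        females = np.flatnonzero(state.sex == FEMALE)
        if males.size == 0 or females.size == 0:
            raise SimulationError(f"breed lost one sex at expansion generation {g}")
        n_dams = min(females.size, max(1, config.expansion_cap // ppd))
        dams_loc = rng.choice(females, n_dams, replace=False)
        litter_sire = males[rng.integers(0, males.size, n_dams)]
        off_sire = np.repeat(litter_sire, ppd)
        off_dam = np.repeat(dams_loc, ppd)
        n_off = off_sire.size
        haps = np.stack([
            sample_gametes(state.haps, off_sire, genome, rng),
            sample_gametes(state.haps, off_dam, genome, rng),
        ], axis=1)
        sex = _assign_sexes(n_off, rng)
        sire.append(off_sire.astype(np.int32) + 1 + offset)
        dam.append(off_dam.astype(np.int32) + 1 + offset)
        sexes.append(sex)
        gens.append(np.full(n_off, g, dtype=np.int32))
        offset += state.n
        state = PopState(haps, sex)
    ped = ExpansionPedigree(
        np.concatenate(sire), np.concatenate(dam),
        np.concatenate(sexes), np.concatenate(gens),
    )
    return ped, state


# ----------------------------------------------------------------------
# recent (pedigreed, selected) populations
# ----------------------------------------------------------------------

class Breed:
    """A pedigreed population rooted at the second bottleneck.

    Ids are local, 1-based, dense in birth order; generation-0 animals have
    unknown parents (sire = dam = 0) -- they are the evaluation pedigree
    base.  All phased haplotypes are retained so any subset can be
    genotyped later.
    """

    def __init__(self, name: str, state: PopState):
        self.name = name
        self.sire = np.zeros(state.n, dtype=np.int32)
        self.dam = np.zeros(state.n, dtype=np.int32)
        self.sex = state.sex.copy()
        self.generation = np.zeros(state.n, dtype=np.int32)
        self._haps = [state.haps.copy()]
        self.phenotype = np.full(state.n, np.nan)
        self.base_freqs = allele_frequencies(state.haps)

    # -- views ---------------------------------------------------------
    @property
    def n(self) -> int:
        return self.sire.size

    @property
    def haps(self) -> np.ndarray:
        if len(self._haps) > 1:
            self._haps = [np.concatenate(self._haps, axis=0)]
        return self._haps[0]

    def counts(self, rows: np.ndarray | None = None) -> np.ndarray:
        h = self.haps
        return genotype_counts(h if rows is None else h[rows])

    def ids_of_generation(self, g: int, sex: int | None = None) -> np.ndarray:
        m = self.generation == g
        if sex is not None:
            m &= self.sex == sex
        return np.flatnonzero(m) + 1

    # -- growth --------------------------------------------------------
    def append(self, sire: np.ndarray, dam: np.ndarray, sex: np.ndarray,
               generation: int, haps: np.ndarray,
               phenotype: np.ndarray | None = None) -> np.ndarray:
        """Append newborns; returns their 1-based ids."""
        n_new = sire.size
        ids = np.arange(self.n + 1, self.n + n_new + 1, dtype=np.int32)
        self.sire = np.concatenate([self.sire, sire.astype(np.int32)])
        self.dam = np.concatenate([self.dam, dam.astype(np.int32)])
        self.sex = np.concatenate([self.sex, sex.astype(np.int8)])
        self.generation = np.concatenate(
            [self.generation, np.full(n_new, generation, dtype=np.int32)])
        self._haps.append(haps)
        self.phenotype = np.concatenate(
            [self.phenotype,
             np.full(n_new, np.nan) if phenotype is None else phenotype])
        return ids


def second_bottleneck(state: PopState, n_males: int, n_females: int,
                      rng: np.random.Generator, name: str = "A") -> Breed:
    """Sample the recent population base (generation 0 of the evaluation
    pedigree) from the last expansion generation."""
    males = np.flatnonzero(state.sex == MALE)
    females = np.flatnonzero(state.sex == FEMALE)
    if males.size < n_males:
        raise SimulationError(f"breed {name}: {males.size} males < {n_males}")
    if females.size < n_females:
        raise SimulationError(f"breed {name}: {females.size} females < {n_females}")
    m = rng.choice(males, n_males, replace=False)
    f = rng.choice(females, n_females, replace=False)
    idx = np.concatenate([m, f])
    sex = np.r_[np.zeros(n_males, dtype=np.int8), np.ones(n_females, dtype=np.int8)]
    return Breed(name, PopState(state.haps[idx].copy(), sex))


def breed_recent(breed: Breed, n_generations: int, trait, config: SimConfig,
                 genome: GenomeArchitecture, rng: np.random.Generator,
                 selection: str = "ebv") -> Breed:
    """Run the selected recent generations of one breed.

    Each cycle: mate active sires/dams (one random sire per litter, fixed
    litter size), phenotype the newborns, estimate EBVs by within-breed
    pedigree BLUP on all records so far, then replace a fixed fraction of
    the breeding herd -- culling animals over the breeding-cycle age cap
    first, then lowest-EBV -- with the highest-EBV newborn candidates.
    ``selection='random'`` replaces by random choice instead (null design).
    """
    from . import mme, relmat   # deferred: avoid import cycle at module load

    n_sires = config.recent_males
    n_dams = config.recent_females
    ppd = config.progeny_per_dam
    rep_s = int(round(config.sire_replacement * n_sires))
    rep_d = int(round(config.dam_replacement * n_dams))

    sires = breed.ids_of_generation(0, MALE)[:n_sires]
    dams = breed.ids_of_generation(0, FEMALE)[:n_dams]
    age_s = np.zeros(sires.size, dtype=np.int32)
    age_d = np.zeros(dams.size, dtype=np.int32)

    for g in range(1, n_generations + 1):
        litter_sires = sires[rng.integers(0, sires.size, dams.size)]
        off_sire = np.repeat(litter_sires, ppd)
        off_dam = np.repeat(dams, ppd)
        haps_all = breed.haps
        haps = np.stack([
            sample_gametes(haps_all, off_sire - 1, genome, rng),
            sample_gametes(haps_all, off_dam - 1, genome, rng),
        ], axis=1)
        sex = _assign_sexes(off_sire.size, rng)
        tbv = trait.tbv(genotype_counts(haps))
        y = trait.phenotype(tbv, sex, g, rng, breed=breed.name)
        ids = breed.append(off_sire, off_dam, sex, g, haps, y)
        age_s += 1
        age_d += 1
        if g == n_generations:
            break

        if selection == "ebv":
            ebv = _pedigree_blup_ebv(breed, config, mme, relmat)
        elif selection == "random":
            ebv = rng.random(breed.n + 1)
        else:
            raise ValueError(f"unknown selection scheme {selection!r}")

        cand_m = ids[sex == MALE]
        cand_f = ids[sex == FEMALE]
        if cand_m.size < rep_s or cand_f.size < rep_d:
            raise SimulationError(
                f"generation {g}: {cand_m.size} male / {cand_f.size} female "
                f"candidates cannot supply {rep_s}/{rep_d} replacements")
        sires, age_s = _replace(sires, age_s, cand_m, rep_s, ebv,
                                config.max_breeding_cycles)
        dams, age_d = _replace(dams, age_d, cand_f, rep_d, ebv,
                               config.max_breeding_cycles)
    return breed


def _replace(active: np.ndarray, age: np.ndarray, candidates: np.ndarray,
             n_out: int, ebv: np.ndarray, max_age: int
             ) -> tuple[np.ndarray, np.ndarray]:
    """Cull ``n_out`` of ``active`` (age-outs first, then lowest EBV) and
    recruit the ``n_out`` highest-EBV candidates."""
    aged = np.flatnonzero(age >= max_age)
    cull = list(aged[np.argsort(-age[aged])][:n_out])
    if len(cull) < n_out:
        rest = np.setdiff1d(np.arange(active.size), cull, assume_unique=False)
        order = rest[np.argsort(ebv[active[rest]])]
        cull.extend(order[: n_out - len(cull)])
    keep = np.setdiff1d(np.arange(active.size), np.array(cull, dtype=int))
    new = candidates[np.argsort(-ebv[candidates])[:n_out]]
    return (np.concatenate([active[keep], new]),
            np.concatenate([age[keep], np.zeros(n_out, dtype=np.int32)]))


def _pedigree_blup_ebv(breed: Breed, config: SimConfig, mme, relmat) -> np.ndarray:
    """Within-breed pedigree BLUP on all records so far; returns EBVs
    indexed by 1-based id (position 0 unused)."""
    import pandas as pd

    rec = np.flatnonzero(~np.isnan(breed.phenotype))
    records = pd.DataFrame({
        "id": rec + 1,
        "y": breed.phenotype[rec],
        "sex": breed.sex[rec],
        "generation": breed.generation[rec],
    })
    X, Z, y, _ = mme.build_design(records, n_animals=breed.n,
                                  factors=("sex", "generation"))
    f = relmat.inbreeding(breed.sire, breed.dam)
    a_inv = relmat.a_inverse(breed.sire, breed.dam, f=f)
    res = mme.solve_mme(X, Z, y, a_inv, config.variance_ratio)
    out = np.zeros(breed.n + 1)
    out[1:] = res.u
    return out


# ----------------------------------------------------------------------
# F1 crosses
# ----------------------------------------------------------------------

@dataclass
class CrossbredCohorts:
    """F1 animals: sires from breed A, dams from breed B, one cohort per
    source generation."""

    sire_a: np.ndarray      # local 1-based id in breed A
    dam_b: np.ndarray       # local 1-based id in breed B
    sex: np.ndarray
    cohort: np.ndarray      # 1, 2, 3 ... (source generations in order)
    haps: np.ndarray

    @property
    def n(self) -> int:
        return self.sire_a.size

    def counts(self) -> np.ndarray:
        return genotype_counts(self.haps)


def make_crosses(breed_a: Breed, breed_b: Breed, source_generations,
                 config: SimConfig, genome: GenomeArchitecture,
                 rng: np.random.Generator) -> CrossbredCohorts:
    """Produce the F1 cohorts (sire in A x dam in B, with recombination and
    mutation as everywhere else)."""
    ppd = config.progeny_per_dam
    sire_l, dam_l, sex_l, coh_l, haps_l = [], [], [], [], []
    for k, g in enumerate(source_generations, start=1):
        males = breed_a.ids_of_generation(g, MALE)
        females = breed_b.ids_of_generation(g, FEMALE)
        if males.size == 0 or females.size == 0:
            raise SimulationError(f"empty source generation {g} for crossing")
        n_s = min(config.cross_sires_per_cohort, males.size)
        n_d = min(n_s * config.cross_dams_per_sire, females.size)
        if n_d == 0:
            continue
        cs = rng.choice(males, n_s, replace=False)
        cd = rng.choice(females, n_d, replace=False)
        off_sire = np.repeat(cs, config.cross_dams_per_sire)[:n_d]
        off_sire = np.repeat(off_sire, ppd)
        off_dam = np.repeat(cd, ppd)
        gam_a = sample_gametes(breed_a.haps, off_sire - 1, genome, rng)
        gam_b = sample_gametes(breed_b.haps, off_dam - 1, genome, rng)
        haps = np.stack([gam_a, gam_b], axis=1)
        sire_l.append(off_sire)
        dam_l.append(off_dam)
        sex_l.append(_assign_sexes(off_sire.size, rng))
        coh_l.append(np.full(off_sire.size, k, dtype=np.int32))
        haps_l.append(haps)
    if not sire_l:
        L = genome.n_loci
        return CrossbredCohorts(
            np.empty(0, np.int32), np.empty(0, np.int32), np.empty(0, np.int8),
            np.empty(0, np.int32), np.empty((0, 2, L), np.uint8))
    return CrossbredCohorts(
        np.concatenate(sire_l).astype(np.int32),
        np.concatenate(dam_l).astype(np.int32),
        np.concatenate(sex_l),
        np.concatenate(coh_l),
        np.concatenate(haps_l, axis=0),
    )
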