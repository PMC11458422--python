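"""Study configuration.

A :class:`SimConfig` carries every knob of the breeding-program simulation:
the historical population trajectory that builds linkage disequilibrium, the
two-breed founding bottlenecks, the EBV-selected recent generations, the
F1 crossing design, the genome/trait architecture, and the genotyping pools.

Two profiles ship with the package:

``full``
    The full-scale design: a 26-chromosome, 3,421 cM genome with 50,000
    markers and 500 QTL; a 5,000-founder historical population declining to
    2,000 over 3,000 generations; breeds founded from 50 males + 500
    females, expanded 200 generations; recent populations of 100 sires and
    1,000 dams selected for 10 generations.  Running it takes hours.

``desk``
    A scaled-down profile with the same shape (4 x 100 cM chromosomes,
    2,000 markers, 100 QTL, historical 200 -> 100 over 300 generations,
    breeds founded from 10 males + 100 females, recent 20 sires / 200 dams)
    that keeps every qualitative feature of the design at minutes-scale
    cost.  It is the default for tests and the analysis scripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class SimConfig:
    # --- genome ---
    n_chromosomes: int = 26
    chrom_length_cm: float = 3421.0 / 26.0   # per chromosome, equal lengths
    n_markers: int = 50_000
    n_qtl: int = 500
    mutation_rate: float = 2.5e-5            # per locus per gamete
    maf_threshold: float = 0.05
    founder_freq_spread: float = 0.3         # founder freqs ~ U(0.5 +/- spread)
    locus_surplus: float = 2.5               # candidate loci per retained locus

    # --- historical population (three-phase trajectory) ---
    hist_size_start: int = 5000
    hist_size_end: int = 2000
    hist_gens_constant: int = 1000
    hist_gens_decline: int = 1500
    hist_gens_final: int = 500

    # --- breed founding and expansion ---
    breed_founder_males: int = 50
    breed_founder_females: int = 500
    breed_founders_disjoint: bool = True
    expansion_generations: int = 200
    expansion_cap: int = 2500                # max individuals per generation
    progeny_per_dam: int = 5

    # --- recent (selected) populations ---
    recent_males: int = 100
    recent_females: int = 1000
    recent_generations: int = 10
    sire_replacement: float = 0.5
    dam_replacement: float = 0.2
    max_breeding_cycles: int = 4

    # --- F1 crossing design ---
    cross_generations: tuple = (8, 9, 10)
    cross_sires_per_cohort: int = 200
    cross_dams_per_sire: int = 4

    # --- trait architecture ---
    h2: float = 0.3
    sigma2_u: float = 1.0
    gamma_shape: float = 0.4
    gamma_scale: float = 1.66
    use_gamma_magnitude: bool = False        # magnitude layer on the r_pc pairs
    fixed_effect_var_frac: float = 0.25      # Var(level effect) = frac * sigma2_u

    # --- genotyping pools ---
    geno_ab_per_cohort: int = 500            # AB1/AB2 crossbreds genotyped (SC1)
    geno_b_dams_per_cohort: int = 250        # crossing dams of B genotyped
    genotype_validation_cohort: bool = False

    # --- numerics ---
    blend_g: float = 0.95
    blend_a: float = 0.05
    tau: float = 1.0
    omega: float = 1.0

    profile: str = "full"

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError(f"h2 must be in (0,1), got {self.h2}")
        if self.sigma2_u <= 0:
            raise ValueError("sigma2_u must be positive")
        if not 0.0 < self.sire_replacement <= 1.0:
            raise ValueError("sire replacement rate must be in (0,1]")
        if not 0.0 < self.dam_replacement <= 1.0:
            raise ValueError("dam replacement rate must be in (0,1]")
        for name in ("hist_size_start", "hist_size_end", "recent_males",
                     "recent_females", "breed_founder_males",
                     "breed_founder_females", "n_markers", "n_qtl"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    # ------------------------------------------------------------------
    @property
    def sigma2_e(self) -> float:
        """Residual variance implied by h2 and sigma2_u."""
        return self.sigma2_u * (1.0 - self.h2) / self.h2

    @property
    def variance_ratio(self) -> float:
        """lambda = sigma_e^2 / sigma_u^2 used in the mixed model equations."""
        return self.sigma2_e / self.sigma2_u

    @property
    def reliability_k(self) -> float:
        """Progeny-mean correction factor k = (4 - h2) / h2."""
        return (4.0 - self.h2) / self.h2

    @property
    def genome_length_cm(self) -> float:
        return self.n_chromosomes * self.chrom_length_cm

    # ------------------------------------------------------------------
    @classmethod
    def full(cls) -> "SimConfig":
        """The full-scale study profile (hours of runtime)."""
        return cls()

    @classmethod
    def desk(cls) -> "SimConfig":
        """Desk-scale profile: same design, minutes-scale cost."""
        return cls(
            n_chromosomes=4,
            chrom_length_cm=100.0,
            n_markers=2000,
            n_qtl=100,
            hist_size_start=300,
            hist_size_end=220,
            hist_gens_constant=150,
            hist_gens_decline=100,
            hist_gens_final=50,
            breed_founder_males=10,
            breed_founder_females=100,
            breed_founders_disjoint=False,
            expansion_generations=30,
            expansion_cap=500,
            recent_males=20,
            recent_females=200,
            cross_sires_per_cohort=100,
            cross_dams_per_sire=4,
            geno_ab_per_cohort=300,
            geno_b_dams_per_cohort=150,
            profile="desk",
        )

    @classmethod
    def from_profile(cls, name: str) -> "SimConfig":
        if name == "full":
            return cls.full()
        if name == "desk":
            return cls.desk()
        raise ValueError(f"unknown profile {name!r}")

    # ------------------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["cross_generations"] = list(self.cross_generations)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "cross_generations" in d:
            d["cross_generations"] = tuple(d["cross_generations"])
        return cls(**d)
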