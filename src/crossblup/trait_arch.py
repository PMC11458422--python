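"""Trait architecture: paired purebred/crossbred QTL effects and phenotypes.

The purebred-crossbred genetic correlation r_pc is injected directly into
the QTL substitution effects: per QTL the pair (alpha_pb, alpha_cb) is drawn
from a bivariate normal with unit variances and correlation r_pc.  True
breeding values are genotype dosages summed over QTL on each scale;
purebred phenotypes are built from the purebred-scale TBV, crossbred
phenotypes from the crossbred-scale TBV.

An optional composition layer multiplies both members of a pair by a shared
Gamma-distributed magnitude with a random sign, giving heavy-tailed effect
sizes while preserving the correlation (``use_gamma_magnitude``).  The
part-1 selection trait always uses signed Gamma effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import SimConfig


@dataclass
class TraitArchitecture:
    """Paired QTL effects with target correlation, plus variance components."""

    qtl_ids: np.ndarray          # locus indices into the genome
    alpha_pb: np.ndarray         # purebred substitution effect per QTL
    alpha_cb: np.ndarray         # crossbred substitution effect per QTL
    r_pc_target: float
    h2: float
    sigma2_u: float
    sigma2_e: float

    def __post_init__(self) -> None:
        if len(self.alpha_pb) != len(self.alpha_cb) or len(self.alpha_pb) != len(self.qtl_ids):
            raise ValueError("effect vectors and qtl_ids must have equal length")
        if not -1.0 <= self.r_pc_target <= 1.0:
            raise ValueError("r_pc target outside [-1, 1]")

    @property
    def n_qtl(self) -> int:
        return self.qtl_ids.size

    @property
    def realized_r_pc(self) -> float:
        """Sample correlation of the two effect vectors."""
        return float(np.corrcoef(self.alpha_pb, self.alpha_cb)[0, 1])


def sample_correlated_effects(n_qtl: int, r_pc_target: float,
                              rng: np.random.Generator,
                              gamma_shape: float | None = None,
                              gamma_scale: float = 1.66,
                              base_normals: tuple[np.ndarray, np.ndarray] | None = None,
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Draw paired purebred/crossbred QTL effects at a target correlation.

    The pair is built from two standard-normal vectors u1, u2 as
    ``alpha_pb = u1`` and ``alpha_cb = r*u1 + sqrt(1-r^2)*u2`` -- a
    bivariate normal with unit variances and correlation ``r_pc_target``
    (its 2x2 covariance is positive semi-definite for every |r| <= 1 and
    singular only at |r| = 1, the exact-proportionality case).

    ``base_normals`` lets a caller reuse (u1, u2) across several targets so
    that effect vectors vary smoothly with r (common random numbers).
    With ``gamma_shape`` set, both members of each pair are multiplied by a
    shared Gamma(shape, scale) magnitude and a random sign, giving
    heavy-tailed effect sizes at the same correlation.
    """
    if n_qtl < 2:
        raise ValueError("need at least 2 QTL")
    if not -1.0 <= r_pc_target <= 1.0:
        raise ValueError("covariance matrix not positive semi-definite: "
                         f"|r_pc| = {abs(r_pc_target)} > 1")
    if base_normals is None:
        u1 = rng.standard_normal(n_qtl)
        u2 = rng.standard_normal(n_qtl)
    else:
        u1, u2 = base_normals
    r = r_pc_target
    alpha_pb = u1.copy()
    alpha_cb = r * u1 + np.sqrt(max(0.0, 1.0 - r * r)) * u2
    if gamma_shape is not None:
        mag = rng.gamma(gamma_shape, gamma_scale, n_qtl)
        sign = rng.choice([-1.0, 1.0], n_qtl)
        alpha_pb = alpha_pb * mag * sign
        alpha_cb = alpha_cb * mag * sign
    return alpha_pb, alpha_cb


def sample_gamma_effects(n_qtl: int, rng: np.random.Generator,
                         shape: float = 0.4, scale: float = 1.66) -> np.ndarray:
    """Signed Gamma(shape, scale) substitution effects (the part-1 trait)."""
    return rng.gamma(shape, scale, n_qtl) * rng.choice([-1.0, 1.0], n_qtl)


def true_breeding_values(qtl_counts: np.ndarray, alpha: np.ndarray,
                         center_idx: np.ndarray | None = None) -> np.ndarray:
    """TBV = sum of allele-count-weighted QTL effects, centered on the mean
    of the base-generation rows ``center_idx`` (all rows if omitted)."""
    if qtl_counts.shape[1] != alpha.size:
        raise ValueError(
            f"{alpha.size} QTL effects but {qtl_counts.shape[1]} genotype columns")
    tbv = qtl_counts @ alpha
    base = tbv if center_idx is None else tbv[center_idx]
    return tbv - base.mean()


def scale_to_base_variance(alpha_pb: np.ndarray, alpha_cb: np.ndarray,
                           base_qtl_counts: np.ndarray, sigma2_u: float
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Rescale both effect vectors by one factor so Var(TBV_pb) over the
    base generation equals ``sigma2_u`` (the purebred additive variance)."""
    v = np.var(base_qtl_counts @ alpha_pb)
    if v <= 0:
        raise ValueError("base-generation TBV variance is zero; cannot scale")
    s = np.sqrt(sigma2_u / v)
    return alpha_pb * s, alpha_cb * s


# ----------------------------------------------------------------------
# phenotypes
# ----------------------------------------------------------------------

@dataclass
class FixedEffects:
    """Per-level fixed-effect values, drawn once (modest magnitudes so the
    MME fixed-effect estimation is exercised without dominating variance)."""

    mu: float
    sex: np.ndarray              # effect per sex code
    generation: dict             # generation label -> effect
    breed: dict = field(default_factory=dict)

    @classmethod
    def sample(cls, generations, breeds, config: SimConfig,
               rng: np.random.Generator) -> "FixedEffects":
        sd = np.sqrt(config.fixed_effect_var_frac * config.sigma2_u)
        return cls(
            mu=10.0,
            sex=rng.normal(0.0, sd, 2),
            generation={g: rng.normal(0.0, sd) for g in generations},
            breed={b: rng.normal(0.0, sd) for b in breeds},
        )

    def value(self, breed, sex, generation) -> np.ndarray:
        out = np.full(np.size(sex), self.mu, dtype=float)
        out += self.sex[np.asarray(sex)]
        gen = np.asarray(generation)
        out += np.vectorize(lambda g: self.generation.get(g, 0.0))(gen)
        if self.breed and breed is not None:
            br = np.asarray(breed)
            out += np.vectorize(lambda b: self.breed.get(b, 0.0))(br)
        return out


def simulate_phenotypes(tbv: np.ndarray, breed, sex, generation,
                        effects: FixedEffects, sigma2_e: float,
                        rng: np.random.Generator,
                        residuals: np.ndarray | None = None) -> np.ndarray:
    """phenotype = mu + breed + sex + generation + TBV + N(0, sigma2_e).

    Passing ``residuals`` (standard-normal draws) re-uses noise across
    trait variants (common random numbers across r_pc levels).
    """
    if residuals is None:
        residuals = rng.standard_normal(tbv.size)
    return (effects.value(breed, sex, generation) + tbv
            + np.sqrt(sigma2_e) * residuals)


class SelectionTrait:
    """The trait whose phenotypes drive EBV selection.

    By default the QTL substitution effects are signed Gamma(0.4, 1.66)
    draws; passing ``alpha`` substitutes an externally drawn effect vector
    (the purebred member of the r_pc pair, so the same purebred records
    serve selection and the later genetic evaluation).  ``calibrate``
    rescales the effects so base-generation TBV variance equals sigma2_u.
    """

    def __init__(self, qtl_index: np.ndarray, config: SimConfig,
                 rng: np.random.Generator, alpha: np.ndarray | None = None,
                 effects: FixedEffects | None = None):
        self.qtl_index = qtl_index
        self.alpha = (sample_gamma_effects(qtl_index.size, rng,
                                           config.gamma_shape, config.gamma_scale)
                      if alpha is None else np.asarray(alpha, float).copy())
        self.sigma2_e = config.sigma2_e
        self.config = config
        self.effects = effects if effects is not None else FixedEffects.sample(
            range(0, config.recent_generations + 1), (), config, rng)
        self._scale = 1.0
        self._center = 0.0

    def calibrate(self, base_counts_all_loci: np.ndarray) -> None:
        """Scale effects so base-generation TBV variance = sigma2_u."""
        tbv = base_counts_all_loci[:, self.qtl_index] @ self.alpha
        v = tbv.var()
        if v <= 0:
            raise ValueError("selection trait has zero base variance")
        self._scale = float(np.sqrt(self.config.sigma2_u / v))
        self.alpha = self.alpha * self._scale
        self._center = float(
            (base_counts_all_loci[:, self.qtl_index] @ self.alpha).mean())

    def tbv(self, counts_all_loci: np.ndarray) -> np.ndarray:
        return counts_all_loci[:, self.qtl_index] @ self.alpha - self._center

    def phenotype(self, tbv: np.ndarray, sex, generation,
                  rng: np.random.Generator, breed=None) -> np.ndarray:
        br = None if breed is None else np.full(tbv.size, breed, dtype=object)
        return simulate_phenotypes(tbv, br, sex,
                                   np.full(tbv.size, generation),
                                   self.effects, self.sigma2_e, rng)
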