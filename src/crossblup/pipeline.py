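"""Full study orchestration.

One replicate = one simulated "world" (historical population, breeds A and
B, ten selected generations, F1 cohorts) evaluated at every purebred-
crossbred correlation level with every model/scenario cell:

* BLUP-UPG          -- pedigree relationships, unknown-parent group per breed;
* ssGBLUP-SC1..SC4  -- H^-1 with VanRaden G over the scenario's genotype set;
* ssGBLUP-MF-SC1/2  -- H_Gamma^-1 with the 0.5-frequency G and metafounders.

All r_pc levels share the replicate's pedigree, genotypes, fixed-effect
values and phenotype residuals (common random numbers); only the crossbred
effect vector changes with r.  Purebred records of all generations always
train; AB1 and AB2 crossbred records train only the SC1 cells; AB3 is the
validation cohort everywhere: sires of breed A are scored by the weighted
correlation of their EBV with their AB3 progeny's adjusted-phenotype mean,
and by the dispersion slope of TBV on EBV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import evalmetrics, mme, popsim, relmat, trait_arch
from .config import SimConfig
from .popsim import POP_A, POP_AB, POP_B

MODEL_CELLS = (
    ("BLUP-UPG", ""),
    ("ssGBLUP-MF", "SC1"),
    ("ssGBLUP-MF", "SC2"),
    ("ssGBLUP", "SC1"),
    ("ssGBLUP", "SC2"),
    ("ssGBLUP", "SC3"),
    ("ssGBLUP", "SC4"),
)

SCENARIO_POPS = {
    "SC1": ("A", "B", "AB"),
    "SC2": ("A", "B"),
    "SC3": ("A",),
    "SC4": ("B",),
}

BREED_LABEL = np.array(["A", "B", "AB"])


@dataclass
class StudyPlan:
    """The replicated grid: r_pc levels x model/scenario cells."""

    config: SimConfig
    r_pc_levels: tuple = (0.2, 0.5, 0.8)
    cells: tuple = MODEL_CELLS
    n_replicates: int = 10
    base_seed: int = 1


def cell_label(model: str, scenario: str) -> str:
    return model if not scenario else f"{model}-{scenario}"


# ----------------------------------------------------------------------
# world
# ----------------------------------------------------------------------

@dataclass
class World:
    """One simulated replicate before any r_pc level is applied."""

    config: SimConfig
    genome: popsim.GenomeArchitecture
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    generation: np.ndarray
    population: np.ndarray
    haps: np.ndarray
    qtl_counts: np.ndarray
    base_rows: np.ndarray                  # generation-0 purebreds (0-based)
    base_freqs: np.ndarray                 # (2, m) marker freqs at generation 0
    pools: dict                            # 'A'/'B'/'AB' -> 1-based global ids
    val_rows: np.ndarray                   # AB3 animals (0-based)
    ab12_rows: np.ndarray
    purebred_rows: np.ndarray              # phenotyped purebreds (0-based)
    # evaluation trait (common across r_pc levels)
    u1: np.ndarray = None
    u2: np.ndarray = None
    effect_scale: float = 1.0
    alpha_pb: np.ndarray = None
    tbv_pb: np.ndarray = None
    effects: trait_arch.FixedEffects = None
    residuals: np.ndarray = None
    pheno: np.ndarray = None                # stored purebred records (NaN for F1)

    @property
    def n(self) -> int:
        return self.sire.size

    def marker_counts(self, rows: np.ndarray) -> np.ndarray:
        return popsim.genotype_counts(self.haps[rows])[:, self.genome.marker_index]

    def alpha_cb(self, r_pc: float) -> np.ndarray:
        r = r_pc
        return self.effect_scale * (r * self.u1 + np.sqrt(max(0.0, 1 - r * r)) * self.u2)

    def tbv_cb(self, r_pc: float) -> np.ndarray:
        return trait_arch.true_breeding_values(
            self.qtl_counts, self.alpha_cb(r_pc), center_idx=self.base_rows)

    def phenotypes(self, rows: np.ndarray, tbv: np.ndarray) -> np.ndarray:
        return trait_arch.simulate_phenotypes(
            tbv[rows], BREED_LABEL[self.population[rows]], self.sex[rows],
            self.generation[rows], self.effects, self.config.sigma2_e,
            rng=None, residuals=self.residuals[rows])

    def records(self, rows: np.ndarray, y: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame({
            "id": rows + 1,
            "y": y,
            "breed": BREED_LABEL[self.population[rows]],
            "sex": self.sex[rows],
            "generation": self.generation[rows],
        })


def build_world(config: SimConfig, rng: np.random.Generator) -> World:
    """Simulate one replicate world end to end (no r_pc level yet)."""
    cand = popsim.sample_genome(config, rng)
    hist = popsim.simulate_historical(config, cand, rng)
    a0, b0 = popsim.found_breeds(hist, config.breed_founder_males,
                                 config.breed_founder_females, rng,
                                 disjoint=config.breed_founders_disjoint)
    del hist
    pooled = np.vstack([a0.counts(), b0.counts()])
    keep = popsim.apply_maf_filter(pooled, config.maf_threshold)
    genome, locus_idx = popsim.assign_marker_qtl(
        cand, keep, config.n_markers, config.n_qtl, rng)
    a0 = popsim.PopState(np.ascontiguousarray(a0.haps[:, :, locus_idx]), a0.sex)
    b0 = popsim.PopState(np.ascontiguousarray(b0.haps[:, :, locus_idx]), b0.sex)

    _, a_exp = popsim.expand_breed(a0, config.expansion_generations, config,
                                   genome, rng)
    _, b_exp = popsim.expand_breed(b0, config.expansion_generations, config,
                                   genome, rng)
    A = popsim.second_bottleneck(a_exp, config.recent_males,
                                 config.recent_females, rng, "A")
    B = popsim.second_bottleneck(b_exp, config.recent_males,
                                 config.recent_females, rng, "B")
    del a_exp, b_exp

    # part-1 trait: selection runs on an independent signed-Gamma trait;
    # the r_pc effect pairs are layered on afterwards, so the evaluated
    # trait itself is unselected (no Bulmer shrinkage of its variance)
    trait0 = trait_arch.SelectionTrait(genome.qtl_index, config, rng)
    trait0.calibrate(np.vstack([A.counts(), B.counts()]).astype(np.float64))
    popsim.breed_recent(A, config.recent_generations, trait0, config, genome, rng)
    popsim.breed_recent(B, config.recent_generations, trait0, config, genome, rng)
    crosses = popsim.make_crosses(A, B, config.cross_generations, config,
                                  genome, rng)

    nA, nB, nF = A.n, B.n, crosses.n
    sire = np.concatenate([A.sire,
                           np.where(B.sire > 0, B.sire + nA, 0),
                           crosses.sire_a])
    dam = np.concatenate([A.dam,
                          np.where(B.dam > 0, B.dam + nA, 0),
                          crosses.dam_b + nA])
    sex = np.concatenate([A.sex, B.sex, crosses.sex])
    generation = np.concatenate([A.generation, B.generation,
                                 config.recent_generations + crosses.cohort])
    population = np.concatenate([np.full(nA, POP_A, np.int8),
                                 np.full(nB, POP_B, np.int8),
                                 np.full(nF, POP_AB, np.int8)])
    haps = np.concatenate([A.haps, B.haps, crosses.haps], axis=0)
    qtl_counts = popsim.genotype_counts(haps)[:, genome.qtl_index].astype(np.float64)

    base_rows = np.flatnonzero((generation == 0) & (population != POP_AB))
    gen0_a = np.flatnonzero((generation == 0) & (population == POP_A))
    gen0_b = np.flatnonzero((generation == 0) & (population == POP_B))
    base_freqs = np.vstack([
        popsim.allele_frequencies(haps[gen0_a])[genome.marker_index],
        popsim.allele_frequencies(haps[gen0_b])[genome.marker_index],
    ])

    pools = _genotype_pools(config, A, B, crosses, nA, nB, rng)
    n_cohorts = len(config.cross_generations)
    val_rows = nA + nB + np.flatnonzero(crosses.cohort == n_cohorts)
    ab12_rows = nA + nB + np.flatnonzero(crosses.cohort < n_cohorts)
    purebred_rows = np.flatnonzero((population != POP_AB) & (generation >= 1))

    world = World(config, genome, sire, dam, sex, generation, population,
                  haps, qtl_counts, base_rows, base_freqs, pools,
                  val_rows, ab12_rows, purebred_rows)
    _draw_evaluation_trait(world, rng)
    return world


def _draw_evaluation_trait(world: World, rng: np.random.Generator) -> None:
    """Layer the r_pc effect pairs and evaluation phenotypes onto a built
    world (the post-hoc second simulation stage).  The purebred member
    alpha_pb is fixed per world; crossbred effects vary with r."""
    config = world.config
    nq = config.n_qtl
    world.u1 = rng.standard_normal(nq)
    world.u2 = rng.standard_normal(nq)
    base_counts = world.qtl_counts[world.base_rows]
    v = np.var(base_counts @ world.u1)
    if v <= 0:
        raise popsim.SimulationError("zero base TBV variance")
    world.effect_scale = float(np.sqrt(config.sigma2_u / v))
    world.alpha_pb = world.effect_scale * world.u1
    world.tbv_pb = trait_arch.true_breeding_values(
        world.qtl_counts, world.alpha_pb, center_idx=world.base_rows)
    world.effects = trait_arch.FixedEffects.sample(
        range(0, config.recent_generations + len(config.cross_generations) + 1),
        ("A", "B", "AB"), config, rng)
    world.residuals = rng.standard_normal(world.n)
    world.pheno = np.full(world.n, np.nan)
    world.pheno[world.purebred_rows] = world.phenotypes(
        world.purebred_rows, world.tbv_pb)


def _genotype_pools(config, A, B, crosses, nA, nB, rng) -> dict:
    pool_a = np.unique(np.concatenate([A.sire[A.sire > 0],
                                       crosses.sire_a]))
    b_sires = np.unique(B.sire[B.sire > 0])
    b_dams = []
    for k in np.unique(crosses.cohort):
        dams_k = np.unique(crosses.dam_b[crosses.cohort == k])
        take = min(config.geno_b_dams_per_cohort, dams_k.size)
        b_dams.append(rng.choice(dams_k, take, replace=False))
    pool_b = np.unique(np.concatenate([b_sires] + b_dams)) + nA
    ab = []
    n_cohorts = len(config.cross_generations)
    for k in np.unique(crosses.cohort):
        if k == n_cohorts and not config.genotype_validation_cohort:
            continue
        rows = np.flatnonzero(crosses.cohort == k)
        take = min(config.geno_ab_per_cohort, rows.size)
        ab.append(rng.choice(rows, take, replace=False))
    pool_ab = (np.sort(np.concatenate(ab)) + nA + nB + 1) if ab else np.empty(0, np.int64)
    return {"A": pool_a.astype(np.int64), "B": pool_b.astype(np.int64),
            "AB": pool_ab.astype(np.int64)}



# ----------------------------------------------------------------------
# relationship structures per replicate
# ----------------------------------------------------------------------

@dataclass
class CellStructure:
    K_inv: object
    u_dim: int
    id_offset: int
    n_genotyped: int


def build_structures(world: World, cells) -> dict:
    """Every relationship matrix the requested cells need (shared across
    r_pc levels)."""
    config = world.config
    f = relmat.inbreeding(world.sire, world.dam)
    out: dict = {}
    needed = {(m, s) for m, s in cells}

    if ("BLUP-UPG", "") in needed:
        group_of = np.where(world.sire == 0, world.population, -1).astype(np.int64)
        k = relmat.a_inverse_upg(world.sire, world.dam, group_of, 2)
        out["BLUP-UPG", ""] = CellStructure(k, world.n + 2, 0, 0)

    plain_scens = sorted({s for m, s in needed if m == "ssGBLUP"})
    if plain_scens:
        a_inv = relmat.a_inverse(world.sire, world.dam, f=f)
    for sc in plain_scens:
        ids = _scenario_ids(world, sc)
        rows = ids - 1
        a22 = relmat.a_submatrix(world.sire, world.dam, rows)
        counts = world.marker_counts(rows).astype(np.float64)
        p = counts.mean(axis=0) / 2.0
        poly = (p > 0) & (p < 1)
        g = relmat.g_vanraden(counts[:, poly])
        k = relmat.h_inverse(a_inv, a22, g, rows,
                             config.blend_g, config.blend_a,
                             config.tau, config.omega)
        out["ssGBLUP", sc] = CellStructure(k, world.n, 0, ids.size)

    mf_scens = sorted({s for m, s in needed if m == "ssGBLUP-MF"})
    if mf_scens:
        gamma = relmat.gamma_matrix(world.base_freqs)
        mf_of = np.where(world.sire == 0, world.population, -1).astype(np.int64)
        ag_inv = relmat.a_gamma_inverse(world.sire, world.dam, mf_of, gamma)
        s_ext, d_ext, ford = relmat.extend_with_metafounders(
            world.sire, world.dam, mf_of, 2)
        out["gamma"] = gamma
    for sc in mf_scens:
        ids = _scenario_ids(world, sc)
        rows = ids - 1
        ag22 = relmat.a_submatrix(s_ext, d_ext, rows + 2,
                                  founder_cov=gamma, founder_ord=ford)
        counts = world.marker_counts(rows).astype(np.float64)
        g05 = relmat.g_half(counts)
        k = relmat.h_inverse(ag_inv, ag22, g05, rows + 2,
                             config.blend_g, config.blend_a,
                             config.tau, config.omega)
        out["ssGBLUP-MF", sc] = CellStructure(k, world.n + 2, 2, ids.size)
    return out


def _scenario_ids(world: World, scenario: str) -> np.ndarray:
    pops = SCENARIO_POPS[scenario]
    return np.sort(np.concatenate([world.pools[p] for p in pops]))


# ----------------------------------------------------------------------
# evaluation
# ----------------------------------------------------------------------

def evaluate_world(world: World, r_pc_levels, cells, replicate: int = 0
                   ) -> pd.DataFrame:
    """Fit every cell, score every r_pc level; returns the long results."""
    config = world.config
    structures = build_structures(world, cells)
    lam = config.variance_ratio

    y_pure = world.pheno[world.purebred_rows]
    rec_pure = world.records(world.purebred_rows, y_pure)

    levels = []
    for r in r_pc_levels:
        tbv_cb = world.tbv_cb(r)
        alpha_cb = world.alpha_cb(r)
        realized = float(np.corrcoef(world.alpha_pb, alpha_cb)[0, 1])
        y_ab12 = world.phenotypes(world.ab12_rows, tbv_cb)
        y_val = world.phenotypes(world.val_rows, tbv_cb)
        levels.append({
            "r": r, "tbv_cb": tbv_cb, "realized": realized,
            "rec_ab12": world.records(world.ab12_rows, y_ab12),
            "rec_val": world.records(world.val_rows, y_val),
        })

    rows = []
    for model, sc in cells:
        st = structures[model, sc]
        trains_cb = sc == "SC1"
        rec_train0 = (pd.concat([rec_pure, levels[0]["rec_ab12"]],
                                ignore_index=True) if trains_cb else rec_pure)
        X, Z, y0, coding = mme.build_design(
            rec_train0, n_animals=world.n, u_dim=st.u_dim,
            id_offset=st.id_offset, drop_aliased=True)
        system = mme.MMESystem(X, Z, st.K_inv, lam)
        if not trains_cb:
            b_hat, u_hat = system.solve(y0)
        for lv in levels:
            if trains_cb:
                y_tr = np.concatenate([y_pure, lv["rec_ab12"]["y"].to_numpy()])
                b_hat, u_hat = system.solve(y_tr)
            res = mme.EBVResult(b_hat, u_hat, coding.columns, model, sc)
            rows.append(_score_cell(world, res, st, coding, lv, replicate))
    return pd.DataFrame(rows)


def _score_cell(world: World, res: mme.EBVResult, st: CellStructure,
                coding: mme.DesignInfo, lv: dict, replicate: int) -> dict:
    config = world.config
    rec_val = lv["rec_val"]
    X_val, _, y_val, _ = mme.build_design(
        rec_val, n_animals=world.n, u_dim=st.u_dim,
        id_offset=st.id_offset, coding=coding)
    y_adj = mme.adjust_phenotypes(X_val, y_val, res.b)
    sire_ids = world.sire[world.val_rows]
    summaries = evalmetrics.progeny_summaries(sire_ids, y_adj, config.h2)
    sids = np.array([s.sire_id for s in summaries])
    ebv_s = res.ebv(sids, st.id_offset)
    acc = evalmetrics.sire_accuracy(
        dict(zip(sids, ebv_s)), summaries, weighting="reliability")
    b1 = evalmetrics.dispersion_b1(world.tbv_pb[sids - 1], ebv_s)
    b1_cb = evalmetrics.dispersion_b1(lv["tbv_cb"][sids - 1], ebv_s)
    return {
        "model": res.model, "scenario": res.scenario,
        "cell": cell_label(res.model, res.scenario),
        "r_pc": lv["r"], "realized_r_pc": lv["realized"],
        "replicate": replicate, "accuracy": acc,
        "b1": b1, "b1_cb": b1_cb,
        "n_sires": sids.size, "n_genotyped": st.n_genotyped,
    }


def structure_summary(world: World, rng: np.random.Generator,
                      sample_size: int = 500) -> dict:
    """F_ST and PCA summaries of the simulated populations (pre-r_pc)."""
    config = world.config
    last = config.recent_generations
    rows_a = np.flatnonzero((world.population == POP_A) & (world.generation == last))
    rows_b = np.flatnonzero((world.population == POP_B) & (world.generation == last))
    rows_ab = np.flatnonzero(world.population == POP_AB)

    def take(rows):
        if rows.size > sample_size:
            rows = rng.choice(rows, sample_size, replace=False)
        return np.sort(rows)

    sa, sb, sab = take(rows_a), take(rows_b), take(rows_ab)
    ca = world.marker_counts(sa)
    cb = world.marker_counts(sb)
    cab = world.marker_counts(sab)
    fst_ab = evalmetrics.fst(ca, cb)
    half = min(sa.size, sb.size) // 2
    pure = np.vstack([ca[:half], cb[:half]])
    fst_pb_f1 = evalmetrics.fst(pure, cab)
    pca = evalmetrics.pca_summary(np.vstack([ca, cb, cab]), n_components=5)
    n_a, n_b = ca.shape[0], cb.shape[0]
    pc1 = pca.scores[:, 0]
    cen_a = pc1[:n_a].mean()
    cen_b = pc1[n_a:n_a + n_b].mean()
    cen_ab = pc1[n_a + n_b:].mean()
    lo, hi = min(cen_a, cen_b), max(cen_a, cen_b)
    pure = world.purebred_rows
    fixed = world.effects.value(BREED_LABEL[world.population[pure]],
                                world.sex[pure], world.generation[pure])
    resid = world.pheno[pure] - fixed - world.tbv_pb[pure]
    tbv_var = world.tbv_pb[pure].var()
    return {
        "fst_ab": fst_ab,
        "fst_purebred_crossbred": fst_pb_f1,
        "pc1_pct": 100.0 * pca.variance_fractions[0],
        "pc2_pct": 100.0 * pca.variance_fractions[1],
        "ab_between_parents_pc1": bool(lo <= cen_ab <= hi),
        "realized_h2": float(tbv_var / (tbv_var + resid.var())),
        "n_purebred_records": int(pure.size),
    }


# ----------------------------------------------------------------------
# replicates and aggregation
# ----------------------------------------------------------------------

def replicate_rng(base_seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([base_seed, replicate]))


def run_replicate(plan: StudyPlan, replicate: int
                  ) -> tuple[pd.DataFrame, dict]:
    rng = replicate_rng(plan.base_seed, replicate)
    world = build_world(plan.config, rng)
    results = evaluate_world(world, plan.r_pc_levels, plan.cells, replicate)
    structure = structure_summary(world, rng)
    structure["replicate"] = replicate
    return results, structure


def run_study(plan: StudyPlan, progress: bool = False
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All replicates; returns (long results, per-replicate structure)."""
    res, struct = [], []
    for rep in range(plan.n_replicates):
        if progress:
            print(f"replicate {rep + 1}/{plan.n_replicates}", flush=True)
        r, s = run_replicate(plan, rep)
        res.append(r)
        struct.append(s)
    return pd.concat(res, ignore_index=True), pd.DataFrame(struct)


def aggregate(results: pd.DataFrame, value: str = "accuracy"
              ) -> pd.DataFrame:
    """Replicate mean (SD) per r_pc level x cell, in the layout of the
    study's summary table."""
    if results["replicate"].nunique() < 2:
        raise ValueError("need >= 2 replicates for a standard deviation")
    cells = [cell_label(m, s) for m, s in MODEL_CELLS
             if cell_label(m, s) in set(results["cell"])]
    g = results.groupby(["r_pc", "cell"])[value]
    mean = g.mean().unstack("cell")
    sd = g.std().unstack("cell")
    expected = {(r, c) for r in results["r_pc"].unique() for c in cells}
    have = {(r, c) for r in mean.index for c in mean.columns
            if not np.isnan(mean.loc[r, c])}
    missing = expected - have
    if missing:
        raise ValueError(f"missing cells in results: {sorted(missing)}")
    out = mean.round(3).astype(str) + " (" + sd.round(3).astype(str) + ")"
    return out[cells]


def aggregate_long(results: pd.DataFrame) -> pd.DataFrame:
    """Machine-readable mean/SD per cell and metric."""
    g = results.groupby(["r_pc", "cell"])
    out = g.agg(accuracy_mean=("accuracy", "mean"),
                accuracy_sd=("accuracy", "std"),
                b1_mean=("b1", "mean"), b1_sd=("b1", "std"),
                b1_cb_mean=("b1_cb", "mean"),
                realized_r_pc=("realized_r_pc", "mean"),
                n_sires=("n_sires", "mean")).reset_index()
    return out
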