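"""Pedigree, genomic and combined relationship matrices.

Everything the three evaluation models need:

* tabular numerator relationship matrix A (optionally with correlated,
  self-related founders -- the metafounder extension A_Gamma);
* Henderson's sparse A^-1 with inbreeding from the Meuwissen-Luo
  algorithm, generalized to metafounder bases;
* the Quaas-Pollak unknown-parent-group augmentation of A^-1;
* the metafounder relationship Gamma estimated from base allele
  frequencies (gamma = 8 x (co)variance of frequencies across loci);
* VanRaden's genomic matrix G = ZZ'/2*sum(p(1-p)) and its 0.5-frequency
  variant compatible with the Gamma base;
* the single-step H^-1 = A^-1 + [0 0; 0 tau*(G_blended)^-1 - omega*A22^-1].

Pedigrees are passed as 1-based sire/dam arrays with 0 meaning "unknown",
sorted parents-before-offspring (ids dense in birth order).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from numba import njit
from scipy.linalg import cho_factor, cho_solve
from scipy.sparse.linalg import splu


class PedigreeError(ValueError):
    pass


def _to_internal(sire: np.ndarray, dam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """1-based/0-unknown -> 0-based/-1-unknown, with ordering checks."""
    s = np.asarray(sire, dtype=np.int64) - 1
    d = np.asarray(dam, dtype=np.int64) - 1
    n = s.size
    ids = np.arange(n)
    if np.any(s >= ids) or np.any(d >= ids):
        raise PedigreeError("pedigree not sorted parents-before-offspring "
                            "(or contains a cycle)")
    return s, d


# ----------------------------------------------------------------------
# Meuwissen-Luo diagonals (numba kernel), generalized founder base
# ----------------------------------------------------------------------

@njit(cache=True)
def _ml_diagonals(sire, dam, founder_ord, founder_cov):  # pragma: no cover
    n = sire.size
    n_cov = founder_cov.shape[0]
    adiag = np.zeros(n)
    dvec = np.ones(n)
    w = np.zeros(n)
    wf = np.zeros(max(1, n_cov))
    for i in range(n):
        s = sire[i]
        d = dam[i]
        fo = founder_ord[i]
        if fo >= 0:                      # covariant founder (metafounder)
            adiag[i] = founder_cov[fo, fo]
            continue
        if s < 0 and d < 0:              # ordinary founder
            adiag[i] = 1.0
            dvec[i] = 1.0
            continue
        di = 1.0
        if s >= 0:
            di -= 0.25 * adiag[s]
        if d >= 0:
            di -= 0.25 * adiag[d]
        dvec[i] = di
        # L-row traversal: adiag[i] = sum_j t_ij^2 k_j  (+ founder block)
        for k in range(n_cov):
            wf[k] = 0.0
        w[i] = 1.0
        acc = 0.0
        for j in range(i, -1, -1):
            wj = w[j]
            if wj == 0.0:
                continue
            fj = founder_ord[j]
            if fj >= 0:
                wf[fj] += wj
            else:
                acc += wj * wj * dvec[j]
                sj = sire[j]
                dj = dam[j]
                if sj >= 0:
                    w[sj] += 0.5 * wj
                if dj >= 0:
                    w[dj] += 0.5 * wj
            w[j] = 0.0
        if n_cov > 0:
            for a in range(n_cov):
                wa = wf[a]
                if wa != 0.0:
                    for b in range(n_cov):
                        wb = wf[b]
                        if wb != 0.0:
                            acc += wa * founder_cov[a, b] * wb
        adiag[i] = acc
    return adiag, dvec


def _diagonals(sire, dam, founder_cov=None, founder_ord=None):
    s, d = _to_internal(sire, dam)
    if founder_cov is None:
        cov = np.zeros((0, 0))
        ford = np.full(s.size, -1, dtype=np.int64)
    else:
        cov = np.asarray(founder_cov, dtype=np.float64)
        ford = np.asarray(founder_ord, dtype=np.int64)
    return _ml_diagonals(s, d, ford, cov)


def inbreeding(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Pedigree inbreeding coefficients (Meuwissen-Luo)."""
    if len(sire) == 0:
        return np.zeros(0)
    adiag, _ = _diagonals(sire, dam)
    return adiag - 1.0


# ----------------------------------------------------------------------
# dense tabular A (oracle-grade; O(n^2) memory)
# ----------------------------------------------------------------------

def a_matrix(sire, dam, subset=None, founder_cov=None, founder_ord=None
             ) -> np.ndarray:
    """Tabular-method numerator relationships (diagonal 1 + F).

    With ``founder_cov``/``founder_ord`` the designated founders carry the
    given (self-)relationships -- the related-founder recursion behind
    A_Gamma.  Intended for moderate pedigrees and as the dense oracle for
    the sparse inverses.
    """
    s, d = _to_internal(sire, dam)
    n = s.size
    A = np.zeros((n, n))
    ford = (np.full(n, -1) if founder_ord is None
            else np.asarray(founder_ord, dtype=np.int64))
    for i in range(n):
        if ford[i] >= 0:
            if np.any(ford[:i] < 0):
                raise PedigreeError("covariant founders must precede all "
                                    "other pedigree members")
            A[i, :i] = A[:i, i] = founder_cov[ford[i], ford[:i]]
            A[i, i] = founder_cov[ford[i], ford[i]]
            continue
        si, di = s[i], d[i]
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
        asd = A[si, di] if (si >= 0 and di >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * asd
    if subset is not None:
        subset = np.asarray(subset)
        return A[np.ix_(subset, subset)]
    return A


# ----------------------------------------------------------------------
# sparse inverses (Henderson's rules)
# ----------------------------------------------------------------------

def _henderson_assemble(n_dim: int, animal: np.ndarray, ps: np.ndarray,
                        pd_: np.ndarray, alpha: np.ndarray) -> sp.csr_matrix:
    """Scatter alpha * [1, -1/2, -1/2] outer products; parent slots < 0 are
    silently dropped (unknown parent, ordinary base)."""
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    add(animal, animal, alpha)
    for p in (ps, pd_):
        m = p >= 0
        add(animal[m], p[m], -0.5 * alpha[m])
        add(p[m], animal[m], -0.5 * alpha[m])
        add(p[m], p[m], 0.25 * alpha[m])
    both = (ps >= 0) & (pd_ >= 0)
    add(ps[both], pd_[both], 0.25 * alpha[both])
    add(pd_[both], ps[both], 0.25 * alpha[both])
    mat = sp.coo_matrix(
        (np.concatenate(vals),
         (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_dim, n_dim))
    return mat.tocsr()


def a_inverse(sire, dam, f: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with Meuwissen-Luo inbreeding."""
    n = len(sire)
    if n == 0:
        return sp.csr_matrix((0, 0))
    s, d = _to_internal(sire, dam)
    if f is None:
        adiag, _ = _diagonals(sire, dam)
    else:
        adiag = 1.0 + np.asarray(f)
    di = np.ones(n)
    ks = s >= 0
    kd = d >= 0
    di[ks] -= 0.25 * adiag[s[ks]]
    di[kd] -= 0.25 * adiag[d[kd]]
    return _henderson_assemble(n, np.arange(n), s, d, 1.0 / di)


def a_inverse_upg(sire, dam, group_of: np.ndarray, n_groups: int
                  ) -> sp.csr_matrix:
    """Quaas-Pollak augmented A^-1: unknown parents point to their group's
    pseudo-column; output dimension n + n_groups (groups last).

    Mendelian variances are those of the ordinary pedigree (groups carry no
    inbreeding), so with no unknown parents the animal block equals
    :func:`a_inverse` and the group rows are empty.
    """
    n = len(sire)
    s, d = _to_internal(sire, dam)
    group_of = np.asarray(group_of, dtype=np.int64)
    unknown = (s < 0) | (d < 0)
    if np.any(unknown & (group_of < 0)):
        bad = np.flatnonzero(unknown & (group_of < 0))[:5] + 1
        raise PedigreeError(f"unknown parents without a group, e.g. ids {bad}")
    adiag, _ = _diagonals(sire, dam)
    di = np.ones(n)
    ks = s >= 0
    kd = d >= 0
    di[ks] -= 0.25 * adiag[s[ks]]
    di[kd] -= 0.25 * adiag[d[kd]]
    es = np.where(ks, s, n + group_of)
    ed = np.where(kd, d, n + group_of)
    return _henderson_assemble(n + n_groups, np.arange(n), es, ed, 1.0 / di)


# ----------------------------------------------------------------------
# metafounders
# ----------------------------------------------------------------------

def gamma_matrix(base_freqs_by_pop: np.ndarray, floor: float = 1e-8
                 ) -> np.ndarray:
    """Metafounder relationships from base allele frequencies.

    gamma_bb' = 8 * Cov_loci(p_b, p_b'); diagonal 8 * Var_loci(p_b).
    Loci are the observations.  The matrix is floored to positive definite
    (eigenvalue clipping) if sampling noise pushes it to singular.
    """
    P = np.atleast_2d(np.asarray(base_freqs_by_pop, dtype=float))
    if P.shape[1] < 2:
        raise ValueError("need at least 2 loci to estimate Gamma")
    G = 8.0 * np.cov(P, ddof=0)
    G = np.atleast_2d(G)
    w, V = np.linalg.eigh(G)
    if w.min() < floor:
        w = np.maximum(w, floor)
        G = (V * w) @ V.T
    return G


def extend_with_metafounders(sire, dam, mf_of: np.ndarray, n_mf: int
                             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Prepend metafounder pseudo-individuals (both sire and dam of their
    base animals).  Returns 1-based (sire_ext, dam_ext, founder_ord) of
    dimension n_mf + n; every former unknown-parent slot now points to the
    animal's metafounder."""
    n = len(sire)
    s = np.asarray(sire, dtype=np.int64)
    d = np.asarray(dam, dtype=np.int64)
    mf_of = np.asarray(mf_of, dtype=np.int64)
    unknown = (s == 0) | (d == 0)
    if np.any(unknown & (mf_of < 0)):
        raise PedigreeError("base animals without a metafounder assignment")
    mf_col = np.where(mf_of >= 0, mf_of + 1, 0)
    s_ext = np.where(s > 0, s + n_mf, mf_col)
    d_ext = np.where(d > 0, d + n_mf, mf_col)
    sire_ext = np.concatenate([np.zeros(n_mf, dtype=np.int64), s_ext])
    dam_ext = np.concatenate([np.zeros(n_mf, dtype=np.int64), d_ext])
    founder_ord = np.concatenate([np.arange(n_mf),
                                  np.full(n, -1, dtype=np.int64)])
    return sire_ext, dam_ext, founder_ord


def a_gamma_inverse(sire, dam, mf_of: np.ndarray, gamma: np.ndarray
                    ) -> sp.csr_matrix:
    """Sparse A_Gamma^-1 over metafounders + animals (metafounders first).

    Henderson's rules with generalized inbreeding (founder self-relationship
    gamma_bb replaces the unit founder diagonal) plus Gamma^-1 on the
    metafounder block:  A_Gamma^-1 = (I-P)' blkdiag(Gamma^-1, D^-1) (I-P).
    """
    gamma = np.atleast_2d(np.asarray(gamma, dtype=float))
    n_mf = gamma.shape[0]
    try:
        np.linalg.cholesky(gamma)
    except np.linalg.LinAlgError:
        gamma = gamma_matrix_floor(gamma)
    sire_ext, dam_ext, ford = extend_with_metafounders(sire, dam, mf_of, n_mf)
    n_tot = len(sire_ext)
    adiag, dvec = _diagonals(sire_ext, dam_ext, founder_cov=gamma,
                             founder_ord=ford)
    s, d = _to_internal(sire_ext, dam_ext)
    animals = np.arange(n_mf, n_tot)
    di = np.ones(animals.size)
    sa, da = s[animals], d[animals]
    ks, kd = sa >= 0, da >= 0
    di[ks] -= 0.25 * adiag[sa[ks]]
    di[kd] -= 0.25 * adiag[da[kd]]
    out = _henderson_assemble(n_tot, animals, sa, da, 1.0 / di)
    gi = np.linalg.inv(gamma)
    block = sp.coo_matrix(
        (gi.ravel(),
         (np.repeat(np.arange(n_mf), n_mf), np.tile(np.arange(n_mf), n_mf))),
        shape=(n_tot, n_tot))
    return (out + block.tocsr()).tocsr()


def gamma_matrix_floor(gamma: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    w, V = np.linalg.eigh(gamma)
    if w.min() < floor:
        w = np.maximum(w, floor)
        gamma = (V * w) @ V.T
    try:
        np.linalg.cholesky(gamma)
    except np.linalg.LinAlgError as e:
        raise ValueError("Gamma not positive definite after flooring") from e
    return gamma


# ----------------------------------------------------------------------
# pedigree submatrices without forming A (Colleau's indirect method)
# ----------------------------------------------------------------------

def a_submatrix(sire, dam, idx: np.ndarray, founder_cov=None,
                founder_ord=None, chunk: int = 512) -> np.ndarray:
    """Dense A[idx, idx] via A = (I-P)^-1 K (I-P)^-T with two triangular
    solves per column block -- the A22 of single-step models without ever
    forming A.  ``founder_cov`` switches to the A_Gamma recursion."""
    n = len(sire)
    idx = np.asarray(idx, dtype=np.int64)
    if idx.size == 0:
        return np.zeros((0, 0))
    s, d = _to_internal(sire, dam)
    adiag, dvec = _diagonals(sire, dam, founder_cov=founder_cov,
                             founder_ord=founder_ord)
    rows, cols, vals = [np.arange(n)], [np.arange(n)], [np.ones(n)]
    for p in (s, d):
        m = p >= 0
        rows.append(np.flatnonzero(m))
        cols.append(p[m])
        vals.append(np.full(m.sum(), -0.5))
    ImP = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n)).tocsc()
    lu = splu(ImP, permc_spec="NATURAL")
    ford = (np.full(n, -1) if founder_ord is None
            else np.asarray(founder_ord, dtype=np.int64))
    mf_rows = np.flatnonzero(ford >= 0)
    k_diag = dvec.copy()
    k_diag[mf_rows] = 0.0
    out = np.empty((n, idx.size))
    for lo in range(0, idx.size, chunk):
        block = idx[lo:lo + chunk]
        E = np.zeros((n, block.size))
        E[block, np.arange(block.size)] = 1.0
        W = lu.solve(E, trans="T")          # (I-P)^-T E
        KW = k_diag[:, None] * W
        if mf_rows.size:
            KW[mf_rows] = founder_cov @ W[mf_rows]
        out[:, lo:lo + chunk] = lu.solve(KW)
    return out[idx]


# ----------------------------------------------------------------------
# genomic matrices
# ----------------------------------------------------------------------

def g_vanraden(counts: np.ndarray, freqs: np.ndarray | None = None
               ) -> np.ndarray:
    """VanRaden G = ZZ' / (2 sum p(1-p)), Z column-centered at 2p."""
    counts = np.asarray(counts, dtype=float)
    p = counts.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, float)
    if np.any((p <= 0) | (p >= 1)):
        bad = int(np.flatnonzero((p <= 0) | (p >= 1))[0])
        raise ValueError(f"monomorphic locus {bad}: filter before building G")
    Z = counts - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    return (Z @ Z.T) / denom


def g_half(counts: np.ndarray) -> np.ndarray:
    """Genomic matrix at fixed allele frequency 0.5 (metafounder scale):
    Z = counts - 1, denominator m/2."""
    counts = np.asarray(counts, dtype=float)
    Z = counts - 1.0
    return (Z @ Z.T) / (counts.shape[1] / 2.0)


def blend(g: np.ndarray, a22: np.ndarray, blend_g: float = 0.95,
          blend_a: float = 0.05) -> np.ndarray:
    return blend_g * g + blend_a * a22


def h_inverse(a_inv: sp.spmatrix, a22: np.ndarray, g: np.ndarray,
              geno_idx: np.ndarray, blend_g: float = 0.95,
              blend_a: float = 0.05, tau: float = 1.0, omega: float = 1.0
              ) -> sp.csr_matrix:
    """Single-step H^-1 = A^-1 + scatter(tau*Gb^-1 - omega*A22^-1) on the
    genotyped block, Gb = blend_g*G + blend_a*A22.

    Works identically in metafounder mode: pass A_Gamma^-1, A_Gamma22, the
    0.5-frequency G and genotyped indices offset past the metafounders.
    """
    geno_idx = np.asarray(geno_idx, dtype=np.int64)
    n_dim = a_inv.shape[0]
    if geno_idx.size == 0:
        return sp.csr_matrix(a_inv)
    gb = blend(g, a22, blend_g, blend_a)
    try:
        cf = cho_factor(gb)
    except np.linalg.LinAlgError as e:
        cond = np.linalg.cond(gb)
        raise ValueError(
            f"blended G not positive definite (cond {cond:.3e}); "
            "raise blend_a or check the genotype panel") from e
    gb_inv = cho_solve(cf, np.eye(gb.shape[0]))
    a22_inv = cho_solve(cho_factor(a22), np.eye(a22.shape[0]))
    corr = tau * gb_inv - omega * a22_inv
    r = np.repeat(geno_idx, geno_idx.size)
    c = np.tile(geno_idx, geno_idx.size)
    block = sp.coo_matrix((corr.ravel(), (r, c)), shape=(n_dim, n_dim))
    return (sp.csr_matrix(a_inv) + block.tocsr()).tocsr()
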