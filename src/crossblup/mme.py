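"""Henderson's mixed model equations for y = Xb + Zu + e.

Builds treatment-coded fixed-effect designs, assembles and solves the MME

    [X'X      X'Z        ] [b]   [X'y]
    [Z'X  Z'Z + lambda*K'] [u] = [Z'y]        (K' = K^-1, lambda = se2/su2)

under any relationship structure (A^-1, UPG-augmented A^-1, H^-1,
H_Gamma^-1), and estimates variance components either by pass-through of
the simulated truth or by exact REML (profile restricted likelihood over
the heritability, evaluated with sparse LU log-determinants).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import minimize_scalar
from scipy.sparse.linalg import cg, splu


class DesignError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass
class DesignInfo:
    """Factor level maps so a fitted coding can be re-applied to new records
    (unseen levels fold into the reference level)."""

    factors: tuple
    levels: dict                     # factor -> ordered levels (first = reference)
    columns: list = field(default_factory=list)


@dataclass
class ModelSpec:
    """One evaluation cell: model, genotyping scenario, factor coding and
    solver settings."""

    model: str                       # BLUP-UPG | ssGBLUP | ssGBLUP-MF
    scenario: str = ""               # SC1..SC4 (genomic models only)
    fixed_effects: tuple = ("breed", "sex", "generation")
    variance_ratio: float = 7.0 / 3.0
    solver: str = "direct"
    pcg_tol: float = 1e-8
    max_iter: int = 5000

    def __post_init__(self) -> None:
        if self.variance_ratio <= 0:
            raise ValueError("variance ratio must be positive")
        if self.model == "BLUP-UPG" and self.scenario:
            raise ValueError("genotyping scenarios apply to genomic models only")


@dataclass
class EBVResult:
    """Solutions of one MME solve."""

    b: np.ndarray                    # fixed-effect solutions
    u: np.ndarray                    # breeding values incl. pseudo-levels
    columns: list
    model: str = ""
    scenario: str = ""

    def ebv(self, ids: np.ndarray, id_offset: int = 0) -> np.ndarray:
        """EBVs of 1-based animal ids (offset past metafounder slots)."""
        return self.u[np.asarray(ids) - 1 + id_offset]


def build_design(records: pd.DataFrame, n_animals: int,
                 factors=("breed", "sex", "generation"),
                 u_dim: int | None = None, id_offset: int = 0,
                 coding: DesignInfo | None = None,
                 drop_aliased: bool = False):
    """Incidence matrices for records with 1-based ``id`` and ``y`` columns.

    X carries an intercept plus drop-first treatment dummies per factor;
    Z maps records to pedigree positions (column ``id_offset + id - 1``).
    Aliased (linearly dependent) fixed-effect columns raise by default or
    are dropped when ``drop_aliased`` -- equivalent to merging confounded
    factors into contemporary groups.
    """
    ids = records["id"].to_numpy()
    if ids.min() < 1 or ids.max() > n_animals:
        bad = ids[(ids < 1) | (ids > n_animals)][0]
        raise DesignError(f"record id {bad} outside pedigree 1..{n_animals}")
    y = records["y"].to_numpy(dtype=float)
    n = len(records)

    if coding is None:
        levels = {f: sorted(pd.unique(records[f])) for f in factors}
        coding = DesignInfo(tuple(factors), levels)
    cols = [np.ones(n)]
    names = ["intercept"]
    for f in coding.factors:
        vals = records[f].to_numpy()
        for lev in coding.levels[f][1:]:
            cols.append((vals == lev).astype(float))
            names.append(f"{f}:{lev}")
    X = np.column_stack(cols)

    # estimability check on the fitted coding only
    if coding.columns:
        keep = [names.index(c) for c in coding.columns]
        X = X[:, keep]
        names = list(coding.columns)
    else:
        _, R, piv = _qr_pivot(X)
        rank = int(np.sum(np.abs(np.diag(R)) > 1e-8 * abs(R[0, 0])))
        if rank < X.shape[1]:
            aliased = [names[j] for j in piv[rank:]]
            if not drop_aliased:
                raise DesignError(f"rank-deficient fixed effects; aliased: {aliased}")
            keep = sorted(piv[:rank])
            X = X[:, keep]
            names = [names[j] for j in keep]
        coding.columns = list(names)

    dim = u_dim if u_dim is not None else n_animals
    Z = sp.coo_matrix((np.ones(n), (np.arange(n), id_offset + ids - 1)),
                      shape=(n, dim)).tocsr()
    return X, Z, y, coding


def _qr_pivot(X):
    from scipy.linalg import qr
    return qr(X, mode="economic", pivoting=True)


class MMESystem:
    """Assembled MME with a reusable factorization (several phenotype
    vectors against one relationship structure)."""

    def __init__(self, X: np.ndarray, Z: sp.spmatrix, K_inv: sp.spmatrix,
                 lam: float, solver: str = "direct",
                 pcg_tol: float = 1e-8, max_iter: int = 5000):
        if lam <= 0:
            raise ValueError("variance ratio lambda must be positive")
        self.X = X
        self.Z = sp.csr_matrix(Z)
        self.p = X.shape[1]
        self.q = Z.shape[1]
        self.solver = solver
        self.pcg_tol = pcg_tol
        self.max_iter = max_iter
        XtX = sp.csr_matrix(X.T @ X) if self.p else sp.csr_matrix((0, 0))
        XtZ = sp.csr_matrix(X.T @ self.Z) if self.p else sp.csr_matrix((0, self.q))
        ZtZ = (self.Z.T @ self.Z).tocsr()
        self.lhs = sp.bmat(
            [[XtX, XtZ], [XtZ.T, ZtZ + lam * sp.csr_matrix(K_inv)]],
            format="csc") if self.p else (ZtZ + lam * sp.csr_matrix(K_inv)).tocsc()
        self._lu = None

    @property
    def lu(self):
        if self._lu is None:
            self._lu = splu(self.lhs)
        return self._lu

    def rhs(self, y: np.ndarray) -> np.ndarray:
        top = self.X.T @ y if self.p else np.empty(0)
        return np.concatenate([top, self.Z.T @ y])

    def solve(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        r = self.rhs(y)
        if self.solver == "direct":
            sol = self.lu.solve(r)
        elif self.solver == "pcg":
            d = self.lhs.diagonal()
            M = sp.diags(np.where(d > 0, 1.0 / d, 1.0))
            sol, info = cg(self.lhs, r, rtol=self.pcg_tol,
                           maxiter=self.max_iter, M=M)
            if info != 0:
                res = np.linalg.norm(self.lhs @ sol - r) / np.linalg.norm(r)
                raise ConvergenceError(
                    f"PCG failed (info={info}, rel. residual {res:.2e})")
        else:
            raise ValueError(f"unknown solver {self.solver!r}")
        return sol[: self.p], sol[self.p:]

    def logdet(self) -> float:
        lu = self.lu
        return float(np.sum(np.log(np.abs(lu.U.diagonal()))))


def solve_mme(X, Z, y, K_inv, lam, solver: str = "direct",
              pcg_tol: float = 1e-8, max_iter: int = 5000,
              model: str = "", scenario: str = "",
              columns=None) -> EBVResult:
    """One-shot MME solve; see :class:`MMESystem` for reuse."""
    sys_ = MMESystem(X, Z, K_inv, lam, solver, pcg_tol, max_iter)
    b, u = sys_.solve(np.asarray(y, dtype=float))
    return EBVResult(b, u, columns or [], model, scenario)


# ----------------------------------------------------------------------
# variance components
# ----------------------------------------------------------------------

def estimate_variances(X, Z, y, K_inv, method: str = "true",
                       sigma2_u: float | None = None,
                       sigma2_e: float | None = None,
                       h2_bounds=(0.02, 0.98)) -> tuple[float, float]:
    """Variance components for the single-trait animal model.

    ``method='true'`` passes the simulated components through (the study
    default: isolates model-structure differences from REML noise).
    ``method='reml'`` maximizes the exact restricted log-likelihood,
    profiled to one dimension (heritability); the determinant terms come
    from sparse LU factorizations of the lambda-form coefficient matrix.
    """
    if method == "true":
        if sigma2_u is None or sigma2_e is None:
            raise ValueError("method='true' needs sigma2_u and sigma2_e")
        if sigma2_u <= 0:
            raise ValueError("sigma2_u = 0 leaves the variance ratio undefined")
        return float(sigma2_u), float(sigma2_e)
    if method != "reml":
        raise ValueError(f"unknown method {method!r}")

    y = np.asarray(y, dtype=float)
    n, p = len(y), (X.shape[1] if X is not None and X.size else 0)
    q = Z.shape[1]

    def neg2_restricted_ll(h2: float) -> float:
        lam = (1.0 - h2) / h2
        sys_ = MMESystem(X, Z, K_inv, lam)
        b, u = sys_.solve(y)
        r = sys_.rhs(y)
        ssr = float(y @ y - b @ r[:p] - u @ r[p:])
        se2 = ssr / (n - p)
        return (n - p) * np.log(se2) - q * np.log(lam) + sys_.logdet()

    res = minimize_scalar(neg2_restricted_ll, bounds=h2_bounds,
                          method="bounded", options={"xatol": 1e-6})
    if not res.success:
        raise ConvergenceError(f"REML search failed: {res.message}")
    h2 = float(res.x)
    lam = (1.0 - h2) / h2
    sys_ = MMESystem(X, Z, K_inv, lam)
    b, u = sys_.solve(y)
    r = sys_.rhs(y)
    se2 = float(y @ y - b @ r[:p] - u @ r[p:]) / (n - p)
    return se2 / lam, se2


def adjust_phenotypes(X: np.ndarray, y: np.ndarray, b_hat: np.ndarray
                      ) -> np.ndarray:
    """y_adj = y - X b_hat (phenotypes corrected for fixed effects; feeds
    the progeny means of the validation step)."""
    if X.shape[1] != b_hat.size:
        raise DesignError(
            f"coding mismatch: X has {X.shape[1]} columns, b_hat {b_hat.size}")
    return np.asarray(y, float) - X @ b_hat
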