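"""Scoring of the evaluation models and population-structure summaries.

* sire-level prediction accuracy of crossbred performance: the (optionally
  reliability-weighted) Pearson correlation between sire EBVs and the mean
  fixed-effect-adjusted phenotype of their crossbred progeny;
* dispersion b1: the OLS slope of true on estimated breeding values
  (1 = unbiased scale, > 1 under-prediction, < 1 over-prediction);
* F_ST between genotype panels (Hudson ratio-of-means by default,
  Weir-Cockerham by flag);
* PCA of centered allele counts (variance fractions + scores).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ProgenySummary:
    """Per-sire summary of crossbred progeny."""

    sire_id: int
    n_progeny: int
    mean_adjusted_cp: float
    reliability_weight: float        # n / (n + k), k = (4 - h2) / h2


def reliability_k(h2: float) -> float:
    return (4.0 - h2) / h2


def progeny_summaries(sire_ids: np.ndarray, adjusted_cp: np.ndarray,
                      h2: float) -> list[ProgenySummary]:
    """Group adjusted crossbred phenotypes by sire."""
    k = reliability_k(h2)
    out = []
    for s in np.unique(sire_ids):
        m = sire_ids == s
        n = int(m.sum())
        out.append(ProgenySummary(int(s), n, float(adjusted_cp[m].mean()),
                                  n / (n + k)))
    return out


def weighted_pearson(x: np.ndarray, y: np.ndarray,
                     w: np.ndarray | None = None) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if w is None:
        w = np.ones_like(x)
    w = np.asarray(w, float) / np.sum(w)
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx = np.sum(w * (x - mx) ** 2)
    vy = np.sum(w * (y - my) ** 2)
    return float(cov / np.sqrt(vx * vy))


def sire_accuracy(ebvs: dict | np.ndarray, summaries: list[ProgenySummary],
                  weighting: str = "reliability") -> float:
    """Correlation between sire EBV and mean adjusted crossbred progeny
    phenotype, weighted by the progeny-mean reliability n/(n+k)."""
    if len(summaries) < 3:
        raise ValueError(f"accuracy undefined with {len(summaries)} sires (< 3)")
    sids = [s.sire_id for s in summaries]
    e = (np.array([ebvs[s] for s in sids])
         if isinstance(ebvs, dict) else np.asarray(ebvs, float))
    cp = np.array([s.mean_adjusted_cp for s in summaries])
    if weighting == "reliability":
        w = np.array([s.reliability_weight for s in summaries])
    elif weighting == "none":
        w = None
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return weighted_pearson(e, cp, w)


def dispersion_b1(tbv: np.ndarray, ebv: np.ndarray,
                  subset: np.ndarray | None = None) -> float:
    """OLS slope of TBV on EBV; b1 > 1 flags under-prediction (deflation)."""
    tbv = np.asarray(tbv, float)
    ebv = np.asarray(ebv, float)
    if subset is not None:
        tbv, ebv = tbv[subset], ebv[subset]
    if tbv.size < 3:
        raise ValueError("need at least 3 points for the dispersion slope")
    ve = ebv.var()
    if ve == 0:
        raise ValueError("zero EBV variance: slope undefined")
    return float(np.cov(tbv, ebv, ddof=0)[0, 1] / ve)


# ----------------------------------------------------------------------
# population structure
# ----------------------------------------------------------------------

def fst(counts1: np.ndarray, counts2: np.ndarray,
        estimator: str = "hudson") -> float:
    """F_ST between two genotype panels sharing a locus set.

    Hudson's estimator, averaged as a ratio of means across loci (low bias
    at small sample sizes); ``estimator='wc'`` switches to Weir-Cockerham.
    Loci monomorphic in both panels contribute nothing; if every locus is,
    the index is undefined.
    """
    c1 = np.asarray(counts1, float)
    c2 = np.asarray(counts2, float)
    if c1.shape[1] != c2.shape[1]:
        raise ValueError("panels must share the locus set")
    if min(c1.shape[0], c2.shape[0]) < 2:
        raise ValueError("need >= 2 individuals per population")
    n1 = 2.0 * c1.shape[0]
    n2 = 2.0 * c2.shape[0]
    p1 = c1.mean(axis=0) / 2.0
    p2 = c2.mean(axis=0) / 2.0
    # drop only loci fixed for the same allele in both panels; loci fixed
    # for alternate alleles are maximally informative
    fixed_same = (p1 == p2) & ((p1 == 0) | (p1 == 1))
    poly = ~fixed_same
    if not poly.any():
        raise ValueError("all loci monomorphic in both populations")
    p1, p2 = p1[poly], p2[poly]
    if estimator == "hudson":
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
        return float(num.sum() / den.sum())
    if estimator == "wc":
        nbar = (n1 + n2) / 2.0
        nc = (n1 + n2 - (n1 ** 2 + n2 ** 2) / (n1 + n2))  # r-1 = 1
        pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 / 2.0) / (2 * nbar - 1))
        b = (2 * nbar / (2 * nbar - 1)) * (
            pbar * (1 - pbar) - s2 / 2.0 - a * nc / (2 * nbar))
        return float(a.sum() / (a + b).sum())
    raise ValueError(f"unknown estimator {estimator!r}")


@dataclass
class PCASummary:
    variance_fractions: np.ndarray   # per component, sums to 1 over all PCs
    scores: np.ndarray               # (n, n_components)


def pca_summary(counts: np.ndarray, n_components: int = 10) -> PCASummary:
    """PCA of the centered allele-count matrix (individuals as rows)."""
    from sklearn.decomposition import PCA

    X = np.asarray(counts, float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >= 3 individuals and >= 2 loci")
    X = X - X.mean(axis=0)
    if not np.any(X):
        raise ValueError("constant genotype matrix: PCA degenerate")
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    p = PCA(n_components=k)
    scores = p.fit_transform(X)
    return PCASummary(p.explained_variance_ratio_, scores)
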