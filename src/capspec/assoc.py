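"""Per-K-locus association of protein clusters, with lineage adjustment.

For one K-locus the response is its presence indicator over isolates.
Sequence clusters (SCs) enter as unpenalized indicator covariates — one
column per SC minus the largest (reference) SC — so that associations
explained by recent shared ancestry are absorbed before the penalized
cluster columns compete.  Two elastic-net modes are run per locus, a
lasso-dominated one (alpha = 0.8) favouring a single dominant predictor
and a ridge-dominated one (alpha = 0.069) tolerant of several correlated
predictors; clusters with a positive coefficient in either mode and a
covariate-adjusted score-test p-value below the Bonferroni threshold
0.05 / N (N = clusters tested) are retained as predictors.

The per-cluster p-value is a Rao score test: the null logistic model
(intercept + SC covariates) is fitted once, and for each cluster column
x_j the statistic U_j^2 / V_j is referred to chi-squared with 1 df, where
U_j = x_j'(y - p0) and V_j is the efficient information of x_j after
projecting out the null design.  With no covariates this reduces exactly
to the Pearson chi-squared of the 2x2 carrier-by-K-locus table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .enet import EnetConfig, EnetFit, fit_enet, fit_null_logistic, _sigmoid
from .repertoire import IsolateRecord, PresenceMatrix

__all__ = [
    "AssociationResult",
    "GwasConfig",
    "encode_covariates",
    "cluster_pvalues",
    "run_gwas",
]

DEFAULT_ALPHA_LEVEL = 0.05


@dataclass(frozen=True)
class GwasConfig:
    """Settings for one GWAS run."""

    enet: EnetConfig = field(default_factory=EnetConfig)
    alpha_level: float = DEFAULT_ALPHA_LEVEL
    use_covariates: bool = True
    #: "union": retained if beta > 0 in any mode; "intersection": in all modes
    mode_combination: str = "union"


@dataclass
class AssociationResult:
    """Association evidence for one (K-locus, cluster) pair."""

    k_locus: str
    cluster_id: str
    level: str
    beta_by_mode: dict[float, float]
    p_value: float
    n_tests: int
    threshold: float
    significant: bool
    modes_retaining: list[float] = field(default_factory=list)


def encode_covariates(sc_labels: list[str]) -> tuple[np.ndarray, list[str], str | None]:
    """One indicator column per SC minus the largest (reference) SC.

    Returns (C, column SC names, reference SC).  A single-SC population
    yields an empty block.  Ties on size break to the lexicographically
    smallest label.
    """
    if not sc_labels:
        raise ValueError("sc_labels must be non-empty")
    uniq, counts = np.unique(sc_labels, return_counts=True)
    if len(uniq) == 1:
        return np.zeros((len(sc_labels), 0)), [], str(uniq[0])
    order = sorted(range(len(uniq)), key=lambda i: (-counts[i], uniq[i]))
    reference = str(uniq[order[0]])
    keep = [str(uniq[i]) for i in order[1:]]
    keep_sorted = sorted(keep)
    arr = np.asarray(sc_labels)
    C = np.column_stack([(arr == sc).astype(float) for sc in keep_sorted])
    return C, keep_sorted, reference


def cluster_pvalues(X: np.ndarray, C: np.ndarray | None, y: np.ndarray) -> np.ndarray:
    """Covariate-adjusted Rao score-test p-value for each cluster column.

    Constant columns get p = 1 by convention.  The null fit carries a tiny
    ridge so complete separation within an SC cannot break it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if C is not None and C.shape[1]:
        U = np.hstack([np.ones((n, 1)), np.asarray(C, dtype=float)])
    else:
        U = np.ones((n, 1))
    coef0 = fit_null_logistic(U, y)
    p0 = np.clip(_sigmoid(U @ coef0), 1e-10, 1 - 1e-10)
    w = p0 * (1.0 - p0)
    resid = y - p0

    scores = X.T @ resid  # U_j
    # efficient information: x' W x - x' W U (U' W U)^{-1} U' W x
    Uw = U * w[:, None]
    G = Uw.T @ U
    B = Uw.T @ X  # (q, p)
    sol = np.linalg.solve(G + 1e-12 * np.eye(G.shape[0]), B)
    info = (X * X * w[:, None]).sum(axis=0) - np.einsum("ij,ij->j", B, sol)

    pvals = np.ones(X.shape[1])
    ok = info > 1e-10
    stat = np.zeros(X.shape[1])
    stat[ok] = scores[ok] ** 2 / info[ok]
    pvals[ok] = stats.chi2.sf(stat[ok], df=1)
    const = X.std(axis=0) == 0
    pvals[const] = 1.0
    return pvals


def run_gwas(
    matrix: PresenceMatrix,
    k_locus: str,
    isolates: list[IsolateRecord],
    config: GwasConfig | None = None,
) -> list[AssociationResult]:
    """Associate every cluster in ``matrix`` with ``k_locus``.

    ``matrix`` should already be frequency-filtered; its isolate axis must
    match ``isolates``.  Returns one result per cluster, sorted by cluster
    id, with ``significant`` flagging retained predictors.
    """
    config = config or GwasConfig()
    by_id = {r.isolate_id: r for r in isolates}
    missing = [i for i in matrix.isolates if i not in by_id]
    if missing:
        raise ValueError(f"matrix isolates missing from metadata: {missing}")
    recs = [by_id[i] for i in matrix.isolates]
    y = np.asarray([1.0 if r.k_locus == k_locus else 0.0 for r in recs])
    if y.min() == y.max():
        raise ValueError(f"degenerate response: K-locus {k_locus!r} "
                         "absent or universal in the matrix isolates")
    X = matrix.df.to_numpy(dtype=float)
    clusters = matrix.clusters
    n_tests = len(clusters)
    if n_tests == 0:
        return []
    if config.use_covariates:
        C, _, _ = encode_covariates([r.sc for r in recs])
    else:
        C = None

    fits: dict[float, EnetFit] = {}
    for alpha in config.enet.alphas:
        fits[alpha] = fit_enet(X, C, y, alpha, config.enet)
    pvals = cluster_pvalues(X, C, y)
    threshold = config.alpha_level / n_tests

    results: list[AssociationResult] = []
    for j, cid in enumerate(clusters):
        beta_by_mode = {a: float(f.beta[j]) for a, f in fits.items()}
        modes = [a for a, b in beta_by_mode.items() if b > 0]
        if config.mode_combination == "union":
            positive = bool(modes)
        elif config.mode_combination == "intersection":
            positive = len(modes) == len(config.enet.alphas)
        else:
            raise ValueError(f"unknown mode_combination {config.mode_combination!r}")
        sig = positive and pvals[j] < threshold
        results.append(
            AssociationResult(
                k_locus=k_locus,
                cluster_id=cid,
                level=matrix.level.label,
                beta_by_mode=beta_by_mode,
                p_value=float(pvals[j]),
                n_tests=n_tests,
                threshold=threshold,
                significant=sig,
                modes_retaining=sorted(modes),
            )
        )
    return results
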