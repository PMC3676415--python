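"""Within-module co-expression and its contrast against random gene sets.

The summary statistic is the mean Pearson correlation over all unordered
pairs of module genes, computed across all samples jointly (conditions
pooled). It is contrasted with the mean *cross-set* correlation between the
module genes and seeded, size-matched random gene draws; the empirical
p-value uses the add-one convention so it is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from saltgenes.preprocess import ExpressionMatrix

__all__ = ["CoexpressionResult", "mean_pairwise_correlation", "correlation_contrast"]


@dataclass(frozen=True)
class CoexpressionResult:
    within_mean: float
    random_mean: float
    n_random_draws: int
    empirical_p: float
    seed: int


def _profiles(matrix: ExpressionMatrix, gene_set: list[str]) -> np.ndarray:
    missing = [g for g in gene_set if g not in matrix.values.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    X = matrix.values.loc[gene_set].to_numpy(dtype=float)
    sd = X.std(axis=1)
    flat = np.asarray(gene_set)[sd == 0]
    if flat.size:
        raise ValueError(f"constant expression profile for gene(s) {flat[:5].tolist()}")
    return X

def mean_pairwise_correlation(matrix: ExpressionMatrix, gene_set: set[str] | list[str]) -> float:
    """Mean Pearson r over all unordered pairs in ``gene_set``."""
    genes = sorted(gene_set)
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    X = _profiles(matrix, genes)
    R = np.corrcoef(X)
    iu = np.triu_indices(len(genes), k=1)
    return float(R[iu].mean())


def _cross_mean(R: np.ndarray, n_a: int) -> float:
    """Mean correlation between the first n_a rows and the rest, overlap excluded."""
    return float(R[:n_a, n_a:].mean())


def correlation_contrast(
    matrix: ExpressionMatrix,
    gene_set: set[str] | list[str],
    n_random: int = 1000,
    seed: int = 0,
    background: set[str] | None = None,
) -> CoexpressionResult:
    """Contrast within-module correlation against random size-matched sets.

    Each of ``n_random`` seeded draws samples ``|gene_set|`` genes without
    replacement from ``background`` (default: every non-module gene in the
    matrix with nonzero variance) and records the mean cross-correlation
    between module genes and the drawn set. ``empirical_p`` is
    ``(1 + #{draws with cross-mean >= within_mean}) / (n_random + 1)``.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    genes = sorted(gene_set)
    within = mean_pairwise_correlation(matrix, genes)
    if background is None:
        pool = matrix.values.index.difference(genes)
        sd = matrix.values.loc[pool].std(axis=1).to_numpy()
        pool = list(pool[sd > 0])
    else:
        pool = sorted(set(background) - set(genes))
    if len(pool) < len(genes):
        raise ValueError("background gene pool smaller than the gene set")
    X_mod = _profiles(matrix, genes)
    X_pool = matrix.values.loc[pool].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    n_a = len(genes)
    cross = np.empty(n_random)
    for i in range(n_random):
        idx = rng.choice(len(pool), size=n_a, replace=False)
        stacked = np.vstack([X_mod, X_pool[idx]])
        R = np.corrcoef(stacked)
        cross[i] = _cross_mean(R, n_a)
    n_ge = int(np.sum(cross >= within))
    return CoexpressionResult(
        within_mean=within,
        random_mean=float(cross.mean()),
        n_random_draws=n_random,
        empirical_p=(1 + n_ge) / (n_random + 1),
        seed=seed,
    )
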