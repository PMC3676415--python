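"""Improved volcano-plot gene selection.

A classical volcano plot ranks genes by fold change against t-test
significance. The "improved" variant replaces fold change with *MergeValue*,
a stability score in [0, 1] obtained by running linear SVM-RFE (recursive
feature elimination) on class-stratified bootstrap resamples of the samples
and averaging each gene's normalized reverse elimination rank:

    MergeValue_g = (1/B) * sum_b (G - r_gb) / (G - 1)

where ``r_gb`` is gene g's RFE rank (1 = eliminated last = most informative)
in bootstrap replicate b and G the number of genes. A gene eliminated first
in every replicate scores 0; a gene surviving to the end every time scores 1;
an uninformative gene drifts around 0.5. Genes are selected when they pass
both an inclusive t-test threshold (p <= p_max) and an inclusive MergeValue
threshold (MergeValue >= merge_min).

The SVM-RFE inner loop trains a soft-margin linear SVM on the surviving
features (standardized to zero mean / unit variance on the training subset),
scores features by squared weight, and drops the lowest-scoring fraction each
round (at least one feature). Chunked elimination keeps the procedure
tractable at thousands of features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from saltgenes.preprocess import ExpressionMatrix

__all__ = [
    "RfeConfig",
    "SelectionThresholds",
    "welch_t_test",
    "svm_rfe_rank",
    "merge_value",
    "merge_value_from_ranks",
    "score_genes",
    "improved_volcano_select",
]


@dataclass(frozen=True)
class RfeConfig:
    """Settings for bootstrapped SVM-RFE.

    ``elim_fraction`` is the fraction of surviving features removed per RFE
    round (never fewer than one feature). ``svm_cost`` is the soft-margin C of
    the linear SVM. Bootstraps are stratified by class, preserving per-class
    sample counts; replicate b uses the deterministic seed ``seed + b``.
    """

    n_bootstraps: int = 50
    elim_fraction: float = 0.10
    svm_cost: float = 1.0
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstraps < 1:
            raise ValueError("n_bootstraps must be >= 1")
        if not 0.0 < self.elim_fraction < 1.0:
            raise ValueError("elim_fraction must be in (0, 1)")
        if self.svm_cost <= 0:
            raise ValueError("svm_cost must be positive")


@dataclass(frozen=True)
class SelectionThresholds:
    """Inclusive selection thresholds of the improved volcano plot."""

    p_max: float = 0.05
    merge_min: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_max <= 1.0:
            raise ValueError("p_max must be a probability")


def welch_t_test(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-probe Welch two-sample t-test, class +1 minus class -1.

    Returns a DataFrame (index = probe ids) with ``t_stat`` and two-sided
    ``p_value``. Probes constant in both classes with equal means are reported
    as t = 0, p = 1 (no evidence, rather than undefined).
    """
    a_cols = matrix.class_columns(1)
    b_cols = matrix.class_columns(-1)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each class needs at least two samples for a t-test")
    a = matrix.values[a_cols].to_numpy(dtype=float)
    b = matrix.values[b_cols].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    degenerate = np.isnan(t)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    t = np.where(degenerate & equal_means, 0.0, t)
    p = np.where(degenerate & equal_means, 1.0, p)
    if np.isnan(t).any():
        raise FloatingPointError("undefined t-statistic for a non-degenerate probe")
    return pd.DataFrame({"t_stat": t, "p_value": p}, index=matrix.values.index)


def _rfe_elimination_order(
    X: np.ndarray, y: np.ndarray, cfg: RfeConfig
) -> np.ndarray:
    """Feature indices in elimination order (first eliminated first)."""
    n_features = X.shape[1]
    surviving = np.arange(n_features)
    eliminated: list[np.ndarray] = []
    if cfg.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        zero_var = sd == 0
        sd = np.where(zero_var, 1.0, sd)
        X = (X - mu) / sd
    while surviving.size > 1:
        clf = SVC(kernel="linear", C=cfg.svm_cost)
        clf.fit(X[:, surviving], y)
        scores = np.ravel(clf.coef_) ** 2
        n_drop = max(1, int(np.floor(cfg.elim_fraction * surviving.size)))
        n_drop = min(n_drop, surviving.size - 1)
        # lowest squared weight goes first; ties eliminate the higher row index
        order = np.lexsort((-surviving, scores))
        drop_local = order[:n_drop]
        eliminated.append(surviving[drop_local])
        keep = np.ones(surviving.size, dtype=bool)
        keep[drop_local] = False
        surviving = surviving[keep]
    eliminated.append(surviving)
    return np.concatenate(eliminated)


def svm_rfe_rank(
    matrix: ExpressionMatrix,
    cfg: RfeConfig | None = None,
    sample_index_subset: np.ndarray | None = None,
) -> pd.Series:
    """SVM-RFE ranks per probe (1 = most informative, eliminated last).

    ``sample_index_subset`` selects sample columns by position (bootstrap
    resamples may repeat indices); it must contain both classes. Ranks are a
    permutation of 1..G. Features tied in squared weight are eliminated
    higher-row-index first, making the ranking deterministic.
    """
    cfg = cfg or RfeConfig()
    y_all = matrix.label_vector()
    X_all = matrix.values.to_numpy(dtype=float).T  # samples x features
    if sample_index_subset is None:
        idx = np.arange(X_all.shape[0])
    else:
        idx = np.asarray(sample_index_subset, dtype=int)
    X, y = X_all[idx], y_all[idx]
    if len(np.unique(y)) < 2:
        raise ValueError("sample subset contains a single class")
    order = _rfe_elimination_order(X, y, cfg)
    g = matrix.n_probes
    ranks = np.empty(g, dtype=int)
    ranks[order] = np.arange(g, 0, -1)  # eliminated first -> rank G
    return pd.Series(ranks, index=matrix.values.index, name="rfe_rank")


def _stratified_bootstrap(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Resample with replacement within each class, preserving class counts."""
    idx = []
    for cls in (1, -1):
        members = np.flatnonzero(y == cls)
        idx.append(rng.choice(members, size=members.size, replace=True))
    return np.concatenate(idx)


def merge_value_from_ranks(ranks: np.ndarray) -> np.ndarray:
    """MergeValue from a (B, G) array of per-replicate ranks.

    ``(1/B) * sum_b (G - r_gb) / (G - 1)``; defined as 1.0 when G == 1.
    """
    ranks = np.atleast_2d(np.asarray(ranks, dtype=float))
    g = ranks.shape[1]
    if g == 0:
        raise ValueError("no features")
    if g == 1:
        return np.ones(1)
    return ((g - ranks) / (g - 1)).mean(axis=0)


def merge_value(matrix: ExpressionMatrix, cfg: RfeConfig | None = None) -> pd.Series:
    """MergeValue per probe: mean normalized reverse SVM-RFE rank over bootstraps."""
    cfg = cfg or RfeConfig()
    g = matrix.n_probes
    if g == 0:
        raise ValueError("empty matrix")
    if g == 1:
        return pd.Series([1.0], index=matrix.values.index, name="merge_value")
    y = matrix.label_vector()
    all_ranks = np.empty((cfg.n_bootstraps, g))
    for b in range(cfg.n_bootstraps):
        rng = np.random.default_rng(cfg.seed + b)
        idx = _stratified_bootstrap(y, rng)
        all_ranks[b] = svm_rfe_rank(matrix, cfg, sample_index_subset=idx).to_numpy()
    return pd.Series(
        merge_value_from_ranks(all_ranks), index=matrix.values.index, name="merge_value"
    )


def score_genes(matrix: ExpressionMatrix, cfg: RfeConfig | None = None) -> pd.DataFrame:
    """Full per-probe score table: t_stat, p_value, merge_value."""
    scores = welch_t_test(matrix)
    scores["merge_value"] = merge_value(matrix, cfg)
    return scores


def improved_volcano_select(
    scores: pd.DataFrame,
    thresholds: SelectionThresholds | None = None,
    qtl_hits: set[str] | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Apply the two inclusive thresholds and build a plot-ready table.

    Returns the selected probe-id set and a table with ``merge_value``,
    ``neg_log10_p``, a ``selected`` flag and a ``stratum`` column
    (``selected`` / ``selected_qtl`` / ``unselected``) mirroring the three
    point classes of the volcano figure.
    """
    thresholds = thresholds or SelectionThresholds()
    required = {"p_value", "merge_value"}
    if not required <= set(scores.columns):
        raise ValueError(f"scores table must contain columns {sorted(required)}")
    sel = (scores["p_value"] <= thresholds.p_max) & (
        scores["merge_value"] >= thresholds.merge_min
    )
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(scores["p_value"].to_numpy(dtype=float))
    table = pd.DataFrame(
        {
            "merge_value": scores["merge_value"],
            "neg_log10_p": neg_log10_p,
            "selected": sel,
        },
        index=scores.index,
    )
    qtl_hits = qtl_hits or set()
    stratum = np.where(
        sel & table.index.isin(sorted(qtl_hits)), "selected_qtl",
        np.where(sel, "selected", "unselected"),
    )
    table["stratum"] = stratum
    return set(table.index[sel]), table


def save_volcano_plot(table: pd.DataFrame, path: str, thresholds: SelectionThresholds | None = None) -> None:
    """Render the improved volcano plot (MergeValue vs -log10 p) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    thresholds = thresholds or SelectionThresholds()
    fig, ax = plt.subplots(figsize=(6, 5))
    groups = {
        "unselected": dict(color="#7799cc", s=6, alpha=0.5),
        "selected": dict(color="black", s=10),
        "selected_qtl": dict(color="red", marker="*", s=60),
    }
    for name, style in groups.items():
        sub = table[table["stratum"] == name]
        ax.scatter(sub["merge_value"], sub["neg_log10_p"], label=name, **style)
    ax.axvline(thresholds.merge_min, ls="--", lw=0.8, color="grey")
    ax.axhline(-np.log10(thresholds.p_max), ls="--", lw=0.8, color="grey")
    ax.set_xlabel("MergeValue")
    ax.set_ylabel("-log10 p-value (Welch t)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
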