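"""Two-step feature selection (TSFS).

Step 1 — elementary selection: rank every feature by its Fisher score
(between-class scatter over within-class scatter) and keep the top k
candidates. The Fisher score evaluates features one at a time, so the
candidate set can carry heavily redundant (mutually associated) features.

Step 2 — secondary selection: measure the pairwise maximal association
coefficient (MAC) between candidates, connect any pair with
MAC >= Rth (the redundancy threshold) in an undirected graph, score each
candidate by its degree in that graph (its "redundant score"), and remove
the m highest-scoring candidates in a single static pass.

The hyperparameters (k, m) are chosen by stratified cross-validated
accuracy of a downstream classifier, with the whole selection refit inside
each training fold so the CV estimate is leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core_io import OmicsMatrix
from .mac import MacConfig, _PartitionCache, _mac_cached, pairwise_mac

__all__ = [
    "FisherRanking",
    "RedundancyGraph",
    "SelectionReport",
    "fisher_scores",
    "select_candidates",
    "build_redundancy_graph",
    "remove_redundant",
    "two_step_select",
    "tsfs",
    "TABLE_DEFAULTS",
]

#: shipped per-task / per-modality (alpha, Rth) defaults for the two
#: neuroblastoma prognostic tasks
TABLE_DEFAULTS: dict[tuple[str, str], dict[str, float]] = {
    ("survival", "expression"): {"alpha": 0.7, "rth": 0.65},
    ("survival", "methylation"): {"alpha": 0.55, "rth": 0.9},
    ("vital", "expression"): {"alpha": 0.35, "rth": 0.2},
    ("vital", "methylation"): {"alpha": 0.6, "rth": 0.9},
}


@dataclass
class FisherRanking:
    """Per-feature Fisher scores and the descending-score order."""

    feature_ids: list[str]
    scores: np.ndarray
    order: np.ndarray  # indices sorted by descending score, ties by index

    def top(self, k: int) -> list[str]:
        return [self.feature_ids[i] for i in self.order[:k]]


@dataclass
class RedundancyGraph:
    """Thresholded MAC graph over a candidate feature set."""

    nodes: list[str]
    adjacency: np.ndarray  # symmetric 0/1, zero diagonal
    rth: float
    mac_matrix: np.ndarray

    @property
    def redundant_scores(self) -> np.ndarray:
        """Node degrees (number of candidates each feature is redundant with)."""
        return self.adjacency.sum(axis=1).astype(int)


@dataclass
class SelectionReport:
    candidate_k: int
    removed_m: int
    final_features: list[str]
    chosen_alpha: float
    chosen_rth: float
    cv_table: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "candidate_k": self.candidate_k,
            "removed_m": self.removed_m,
            "n_final": len(self.final_features),
            "final_features": list(self.final_features),
            "chosen_alpha": self.chosen_alpha,
            "chosen_rth": self.chosen_rth,
            "cv_table": list(self.cv_table),
        }


def default_evaluator() -> SVC:
    """Classifier used to score hyperparameter settings under CV."""
    return SVC(kernel="rbf", C=1.0, gamma="scale")


# ---------------------------------------------------------------------------
# step 1: Fisher-score ranking
# ---------------------------------------------------------------------------


def fisher_scores(X: OmicsMatrix | np.ndarray, y: np.ndarray) -> FisherRanking:
    """Fisher score per feature.

    S_i = sum_j n_j (mu_ij - mu_i)^2 / sum_j n_j rho_ij^2, where mu_ij and
    rho_ij^2 are the mean and the population (divide-by-n_j) variance of
    feature i in class j, n_j the class size and mu_i the overall mean. A
    zero denominator with positive numerator scores +inf (perfect
    within-class concentration with separation); 0/0 scores 0.
    """
    if isinstance(X, OmicsMatrix):
        feature_ids = list(X.feature_ids)
        V = X.values
    else:
        V = np.asarray(X, dtype=float)
        feature_ids = [f"f{i}" for i in range(V.shape[1])]
    y = np.asarray(y, dtype=int)
    if V.shape[0] != y.size:
        raise ValueError("sample count mismatch between X and y")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("Fisher score needs at least 2 classes")
    overall = V.mean(axis=0)
    num = np.zeros(V.shape[1])
    den = np.zeros(V.shape[1])
    for cls_label in classes:
        sub = V[y == cls_label]
        n_j = sub.shape[0]
        mu_j = sub.mean(axis=0)
        var_j = sub.var(axis=0)  # population variance
        num += n_j * (mu_j - overall) ** 2
        den += n_j * var_j
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(den > 0, num / np.maximum(den, 1e-300), np.where(num > 0, np.inf, 0.0))
    order = np.lexsort((np.arange(scores.size), -scores))
    return FisherRanking(feature_ids=feature_ids, scores=scores, order=order)


def select_candidates(ranking: FisherRanking, k: int) -> list[str]:
    """Top-k features by Fisher score (ties broken by original order)."""
    d = len(ranking.feature_ids)
    if not 1 <= k <= d:
        raise ValueError(f"k must be in [1, {d}], got {k}")
    return ranking.top(k)


# ---------------------------------------------------------------------------
# step 2: MAC redundancy graph and pruning
# ---------------------------------------------------------------------------


def build_redundancy_graph(
    X_cand: OmicsMatrix | np.ndarray,
    rth: float,
    mac_cfg: MacConfig | None = None,
    mac_matrix: np.ndarray | None = None,
) -> RedundancyGraph:
    """Connect every candidate pair whose MAC is >= the redundancy threshold.

    ``mac_matrix`` may supply precomputed pairwise MAC values (e.g. shared
    across several (k, m) settings); otherwise they are computed here.
    """
    if not 0.0 <= rth <= 1.0:
        raise ValueError("rth must be in [0, 1]")
    if isinstance(X_cand, OmicsMatrix):
        nodes = list(X_cand.feature_ids)
        V = X_cand.values
    else:
        V = np.asarray(X_cand, dtype=float)
        nodes = [f"f{i}" for i in range(V.shape[1])]
    if len(nodes) < 2:
        raise ValueError("need at least 2 candidate features")
    if mac_matrix is None:
        mac_matrix = pairwise_mac(V, mac_cfg or MacConfig())
    adjacency = (mac_matrix >= rth).astype(int)
    np.fill_diagonal(adjacency, 0)
    return RedundancyGraph(nodes=nodes, adjacency=adjacency, rth=rth, mac_matrix=mac_matrix)


def remove_redundant(
    graph: RedundancyGraph,
    fisher_scores_by_node: np.ndarray,
    m: int,
    iterative: bool = False,
) -> list[str]:
    """Remove the m most redundant candidates; return survivors.

    Candidates are ranked once by descending redundant score (node degree);
    ties remove the lower-Fisher-score feature first, then the larger
    original index. The default is this single static pass; ``iterative``
    recomputes degrees on the residual graph after each removal. Survivors
    are returned in Fisher-score order.
    """
    k = len(graph.nodes)
    if not 0 <= m <= k:
        raise ValueError(f"m must be in [0, {k}], got {m}")
    fs = np.asarray(fisher_scores_by_node, dtype=float)
    if fs.size != k:
        raise ValueError("fisher scores must align with graph nodes")

    removed: set[int] = set()
    if iterative:
        adj = graph.adjacency.copy()
        for _ in range(m):
            deg = adj.sum(axis=1).astype(float)
            deg[list(removed)] = -np.inf
            # highest degree; ties -> lower Fisher, then larger index
            cand = np.lexsort((-np.arange(k), fs, -deg))[0]
            removed.add(int(cand))
            adj[cand, :] = 0
            adj[:, cand] = 0
    else:
        deg = graph.redundant_scores.astype(float)
        removal_order = np.lexsort((-np.arange(k), fs, -deg))
        removed = set(int(i) for i in removal_order[:m])

    survivor_order = np.lexsort((np.arange(k), -fs))
    return [graph.nodes[i] for i in survivor_order if i not in removed]


def two_step_select(
    X: OmicsMatrix,
    y: np.ndarray,
    k: int,
    m: int,
    rth: float,
    mac_cfg: MacConfig | None = None,
    mac_matrix: np.ndarray | None = None,
    ranking: FisherRanking | None = None,
    iterative: bool = False,
) -> list[str]:
    """One deterministic TSFS pass at fixed hyperparameters (k, m, Rth).

    Fisher-rank, keep the top k, build the MAC redundancy graph among them,
    drop the m most redundant; returns the surviving feature ids in Fisher
    order. ``m = 0`` reduces to pure Fisher selection.
    """
    if ranking is None:
        ranking = fisher_scores(X, y)
    candidates = select_candidates(ranking, k)
    if m == 0:
        return candidates
    if m >= k:
        raise ValueError("m must be smaller than k")
    X_cand = X.subset_features(candidates)
    graph = build_redundancy_graph(X_cand, rth, mac_cfg, mac_matrix=mac_matrix)
    score_of = dict(zip(ranking.feature_ids, ranking.scores))
    fs = np.array([score_of[f] for f in candidates])
    return remove_redundant(graph, fs, m, iterative=iterative)


def tsfs(
    X: OmicsMatrix,
    y: np.ndarray,
    k_grid: Sequence[int],
    m_grid: Sequence[int],
    alpha: float,
    rth: float,
    cv_folds: int = 5,
    seed: int = 0,
    evaluator=None,
    iterative: bool = False,
    refit_per_fold: bool = True,
) -> SelectionReport:
    """Grid-search (k, m) by stratified cross-validated accuracy.

    For each (k, m) pair with m < k, the full two-step selection is refit on
    each training fold (no leakage) and the evaluator's accuracy is averaged
    over the held-out folds. The winner maximises mean CV accuracy; ties
    prefer fewer final features (k - m), then smaller k. The report's final
    feature set is the winning selection refit on all data.

    ``refit_per_fold=False`` selects once on the full data before CV — the
    optimistic variant some published pipelines use; off by default.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    m_grid = sorted(set(int(m) for m in m_grid))
    if not k_grid or not m_grid:
        raise ValueError("k_grid and m_grid must be non-empty")
    if cv_folds < 2:
        raise ValueError("cv_folds must be >= 2")
    y = np.asarray(y, dtype=int)
    mac_cfg = MacConfig(alpha=alpha)
    evaluator = evaluator if evaluator is not None else default_evaluator()

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X.values, y))
    for _, (tr, _te) in enumerate(folds):
        if np.unique(y[tr]).size < 2:
            raise ValueError(
                "a CV training fold contains a single class; "
                "use stratification-compatible folds or change the seed"
            )

    k_max = max(k_grid)
    # per-fold shared state: Fisher ranking + pairwise MAC among top-k_max
    fold_state = []
    for tr, te in folds:
        Xtr = X.subset_samples(tr)
        ranking = fisher_scores(Xtr, y[tr])
        top_ids = select_candidates(ranking, min(k_max, X.n_features))
        mac_full = pairwise_mac(Xtr.subset_features(top_ids).values, mac_cfg)
        fold_state.append((tr, te, ranking, top_ids, mac_full))

    cv_table: list[dict] = []
    best = None  # (mean_acc, -(k - m), -k) maximised
    for k in k_grid:
        if k > X.n_features:
            continue
        for m in m_grid:
            if m >= k or m < 0:
                continue
            accs = []
            for tr, te, ranking, top_ids, mac_full in fold_state:
                if refit_per_fold:
                    sub = mac_full[:k, :k]
                    feats = two_step_select(
                        X.subset_samples(tr), y[tr], k, m, rth,
                        mac_cfg, mac_matrix=sub if m > 0 else None,
                        ranking=ranking, iterative=iterative,
                    )
                else:
                    feats = two_step_select(X, y, k, m, rth, mac_cfg, iterative=iterative)
                cols = feats
                model = clone(evaluator)
                model.fit(X.subset_samples(tr).subset_features(cols).values, y[tr])
                pred = model.predict(X.subset_samples(te).subset_features(cols).values)
                accs.append(float((pred == y[te]).mean()))
            mean_acc = float(np.mean(accs))
            cv_table.append({"k": k, "m": m, "mean_cv_accuracy": mean_acc, "fold_accuracies": accs})
            key = (mean_acc, -(k - m), -k)
            if best is None or key > best[0]:
                best = (key, k, m)
    if best is None:
        raise ValueError("no admissible (k, m) pair in the grids")
    _, k_star, m_star = best
    final = two_step_select(X, y, k_star, m_star, rth, mac_cfg, iterative=iterative)
    return SelectionReport(
        candidate_k=k_star,
        removed_m=m_star,
        final_features=final,
        chosen_alpha=alpha,
        chosen_rth=rth,
        cv_table=cv_table,
    )
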