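"""Prediction models: single-task SVM harness, the multi-gate
mixture-of-experts (MMoE) multi-task network, and experiment orchestration.

Single-task route: each outcome (5-year survival class, vital status) gets
its own maximum-margin classifier (RBF SVM — a sensible choice at n = 88)
fit on a selected feature block; performance is averaged over several
stratified 80/20 train/test splits.

Multi-task route: one MMoE predicts both outcomes at once. E shared expert
networks transform the input; each task has a softmax gate producing a
probability vector over experts; the tower of task k consumes the
gate-weighted sum of expert outputs and emits a probability. The loss is
the equally weighted sum of the two binary cross-entropies. Because the two
outcome labels are strongly correlated (phi ~ 0.85 in the motivating
cohort), sharing experts lets each task borrow strength from the other.

The MMoE is implemented directly in numpy (hand-written backpropagation,
full-batch Adam, early stopping on a held-out validation split); it is
small enough — tens of input features, a few thousand parameters — that no
deep-learning framework is warranted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import StratifiedShuffleSplit, train_test_split
from sklearn.svm import SVC

from .core_io import ClinicalTable, LabelPair, OmicsMatrix, concatenate, encode_clinical, fit_encoding_stats
from .mac import MacConfig
from .metrics import ConfusionMatrix, absolute_accuracy, accuracy, auc
from .tsfs import fisher_scores, select_candidates, two_step_select

__all__ = [
    "MmoeSpec",
    "MMoE",
    "train_single_task",
    "train_mmoe",
    "intersect_feature_sets",
    "BlockSpec",
    "Combination",
    "ExperimentPlan",
    "run_experiment",
    "default_combination_names",
]

#: clinical fields used per prognostic task (prior-knowledge choice)
CLINICAL_FEATURES = {
    "survival": ("age_days", "inss_stage", "mycn_status"),
    "vital": ("age_days",),
}

#: the eight standard data combinations of the single-task experiments
DEFAULT_COMBINATION_NAMES = (
    "Cli",
    "Cli+G_FS",
    "Cli+G_TSFS",
    "Cli+M_FS",
    "Cli+M_TSFS",
    "Cli+G_FS+M_FS",
    "Cli+G_TSFS+M_FS",
    "Cli+G_TSFS+M_TSFS",
)


def default_combination_names() -> tuple[str, ...]:
    return DEFAULT_COMBINATION_NAMES


# ---------------------------------------------------------------------------
# single-task models
# ---------------------------------------------------------------------------


def default_classifier(seed: int = 0) -> SVC:
    """RBF SVM, C = 1, bandwidth 1/(d * mean feature variance) ("scale")."""
    return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)


def train_single_task(
    X: OmicsMatrix | np.ndarray,
    y: np.ndarray,
    classifier=None,
    seed: int = 0,
):
    """Fit a binary maximum-margin classifier; return (model, decision scores).

    The decision scores are continuous (for AUC); ``model.predict`` gives
    the 0/1 labels. Deterministic for a given seed.
    """
    V = X.values if isinstance(X, OmicsMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    model = clone(classifier) if classifier is not None else default_classifier(seed)
    model.fit(V, y)
    return model, model.decision_function(V)


def intersect_feature_sets(a: Sequence[str], b: Sequence[str]) -> list[str]:
    """Order-stable intersection (order of ``a``)."""
    in_b = set(b)
    return [x for x in a if x in in_b]


# ---------------------------------------------------------------------------
# MMoE multi-task network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MmoeSpec:
    n_experts: int = 4
    expert_hidden: int = 16
    tower_hidden: int = 8
    learning_rate: float = 1e-3
    max_epochs: int = 500
    patience: int = 25
    val_fraction: float = 0.2
    seed: int = 0
    task_names: tuple[str, str] = ("survival", "vital")

    def __post_init__(self) -> None:
        if self.n_experts < 1:
            raise ValueError("n_experts must be >= 1")
        if not 0.0 < self.val_fraction < 0.5:
            raise ValueError("val_fraction must be in (0, 0.5)")


class MMoE:
    """Multi-gate mixture-of-experts for two binary tasks (numpy)."""

    N_TASKS = 2

    def __init__(self, spec: MmoeSpec | None = None):
        self.spec = spec or MmoeSpec()
        self.params: dict[str, np.ndarray] | None = None
        self.history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}

    # -- parameter handling -------------------------------------------------

    def _init_params(self, d: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        sp = self.spec
        E, h, th = sp.n_experts, sp.expert_hidden, sp.tower_hidden

        def glorot(fan_in: int, fan_out: int) -> np.ndarray:
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, size=(fan_in, fan_out))

        p: dict[str, np.ndarray] = {}
        for e in range(E):
            p[f"We{e}"] = glorot(d, h)
            p[f"be{e}"] = np.zeros(h)
        for k in range(self.N_TASKS):
            p[f"Vg{k}"] = glorot(d, E)
            p[f"cg{k}"] = np.zeros(E)
            p[f"Ut{k}"] = glorot(h, th)
            p[f"dt{k}"] = np.zeros(th)
            p[f"uo{k}"] = glorot(th, 1)[:, 0]
            p[f"eo{k}"] = np.zeros(1)
        return p

    # -- forward ------------------------------------------------------------

    def _forward(self, X: np.ndarray, p: dict[str, np.ndarray]) -> dict:
        sp = self.spec
        E = sp.n_experts
        H = [np.maximum(X @ p[f"We{e}"] + p[f"be{e}"], 0.0) for e in range(E)]
        cache: dict = {"X": X, "H": H, "G": [], "M": [], "T": [], "prob": []}
        for k in range(self.N_TASKS):
            logits = X @ p[f"Vg{k}"] + p[f"cg{k}"]
            logits = logits - logits.max(axis=1, keepdims=True)
            G = np.exp(logits)
            G /= G.sum(axis=1, keepdims=True)
            M = np.zeros_like(H[0])
            for e in range(E):
                M += G[:, e][:, None] * H[e]
            T = np.maximum(M @ p[f"Ut{k}"] + p[f"dt{k}"], 0.0)
            z = T @ p[f"uo{k}"] + p[f"eo{k}"][0]
            with np.errstate(over="ignore"):  # saturates to 0/1, caught by the loss
                prob = 1.0 / (1.0 + np.exp(-z))
            cache["G"].append(G)
            cache["M"].append(M)
            cache["T"].append(T)
            cache["prob"].append(prob)
        return cache

    @staticmethod
    def _bce(prob: np.ndarray, y: np.ndarray) -> float:
        # exact cross-entropy: +inf iff an observed outcome gets probability
        # 0 (float-saturated logits), which is the divergence signal
        with np.errstate(divide="ignore"):
            terms = np.where(y == 1, -np.log(prob), -np.log(1.0 - prob))
        return float(np.mean(terms))

    def _loss(self, cache: dict, Y: np.ndarray) -> float:
        return sum(self._bce(cache["prob"][k], Y[:, k]) for k in range(self.N_TASKS))

    # -- backward -----------------------------------------------------------

    def _gradients(self, cache: dict, Y: np.ndarray, p: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        sp = self.spec
        E = sp.n_experts
        X, H = cache["X"], cache["H"]
        n = X.shape[0]
        g = {k: np.zeros_like(v) for k, v in p.items()}
        dH = [np.zeros_like(H[0]) for _ in range(E)]
        for k in range(self.N_TASKS):
            G, M, T, prob = cache["G"][k], cache["M"][k], cache["T"][k], cache["prob"][k]
            dz = (prob - Y[:, k]) / n  # d(mean BCE)/dz through the sigmoid
            g[f"uo{k}"] = T.T @ dz
            g[f"eo{k}"] = np.array([dz.sum()])
            dT = np.outer(dz, p[f"uo{k}"]) * (T > 0)
            g[f"Ut{k}"] = M.T @ dT
            g[f"dt{k}"] = dT.sum(axis=0)
            dM = dT @ p[f"Ut{k}"].T
            dG = np.empty_like(G)
            for e in range(E):
                dH[e] += G[:, e][:, None] * dM
                dG[:, e] = (dM * H[e]).sum(axis=1)
            dA = G * (dG - (dG * G).sum(axis=1, keepdims=True))  # softmax backward
            g[f"Vg{k}"] = X.T @ dA
            g[f"cg{k}"] = dA.sum(axis=0)
        for e in range(E):
            dpre = dH[e] * (H[e] > 0)
            g[f"We{e}"] = X.T @ dpre
            g[f"be{e}"] = dpre.sum(axis=0)
        return g

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "MMoE":
        """Train on X (n, d) and Y (n, 2) with early stopping.

        A stratified validation split (on the 4-way joint label when each
        joint class has >= 2 members, otherwise unstratified) monitors the
        loss; training stops after ``patience`` epochs without improvement
        and the best-validation parameters are restored.
        """
        sp = self.spec
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.ndim != 2 or Y.shape != (X.shape[0], 2):
            raise ValueError("X must be (n, d) and Y (n, 2)")
        if X.shape[0] < 10:
            raise ValueError("need at least 10 samples to train the MMoE")
        rng = np.random.default_rng(sp.seed)

        joint = (2 * Y[:, 0] + Y[:, 1]).astype(int)
        counts = np.bincount(joint, minlength=4)
        strat = joint if (counts[counts > 0] >= 2).all() else None
        idx_tr, idx_va = train_test_split(
            np.arange(X.shape[0]),
            test_size=sp.val_fraction,
            random_state=sp.seed,
            stratify=strat,
        )
        Xtr, Ytr = X[idx_tr], Y[idx_tr]
        Xva, Yva = X[idx_va], Y[idx_va]

        p = self._init_params(X.shape[1], rng)
        m1 = {k: np.zeros_like(v) for k, v in p.items()}
        m2 = {k: np.zeros_like(v) for k, v in p.items()}
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best_val = np.inf
        best_params = {k: v.copy() for k, v in p.items()}
        stall = 0
        self.history = {"train_loss": [], "val_loss": []}

        for epoch in range(1, sp.max_epochs + 1):
            cache = self._forward(Xtr, p)
            loss = self._loss(cache, Ytr)
            if not np.isfinite(loss):
                raise ValueError(
                    "training loss diverged (non-finite); try a smaller learning rate"
                )
            grads = self._gradients(cache, Ytr, p)
            for key in p:
                m1[key] = beta1 * m1[key] + (1 - beta1) * grads[key]
                m2[key] = beta2 * m2[key] + (1 - beta2) * grads[key] ** 2
                mhat = m1[key] / (1 - beta1**epoch)
                vhat = m2[key] / (1 - beta2**epoch)
                p[key] -= sp.learning_rate * mhat / (np.sqrt(vhat) + eps)
            val_loss = self._loss(self._forward(Xva, p), Yva)
            self.history["train_loss"].append(loss)
            self.history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-9:
                best_val = val_loss
                best_params = {k: v.copy() for k, v in p.items()}
                stall = 0
            else:
                stall += 1
                if stall >= sp.patience:
                    break
        self.params = best_params
        return self

    # -- inference ----------------------------------------------------------

    def _require_fit(self) -> dict[str, np.ndarray]:
        if self.params is None:
            raise RuntimeError("model is not fitted")
        return self.params

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-task probabilities, shape (n, 2)."""
        cache = self._forward(np.asarray(X, dtype=float), self._require_fit())
        return np.column_stack(cache["prob"])

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def gate_weights(self, X: np.ndarray) -> np.ndarray:
        """Per-task gate probability vectors over experts, shape (2, n, E)."""
        cache = self._forward(np.asarray(X, dtype=float), self._require_fit())
        return np.stack(cache["G"])


def train_mmoe(X: OmicsMatrix | np.ndarray, labels: LabelPair, spec: MmoeSpec | None = None) -> MMoE:
    """Fit an MMoE jointly predicting the survival class and vital status."""
    V = X.values if isinstance(X, OmicsMatrix) else np.asarray(X, dtype=float)
    Y = np.column_stack([labels.survival_label, labels.vital_label])
    return MMoE(spec).fit(V, Y)


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockSpec:
    """One feature block inside a data combination.

    ``block`` is "clinical" or a key of the omics dict; ``selector`` is
    "none" (use all features), "fisher" (top-k Fisher) or "tsfs" (two-step
    selection with k, m, alpha, rth).
    """

    block: str
    selector: str = "none"
    k: int | None = None
    m: int = 0
    alpha: float = 0.55
    rth: float = 0.9


@dataclass(frozen=True)
class Combination:
    name: str
    blocks: tuple[BlockSpec, ...]


@dataclass(frozen=True)
class ExperimentPlan:
    combinations: tuple[Combination, ...]
    split_fraction: float = 0.2
    seeds: tuple[int, ...] = (0, 1, 2, 3, 4)

    def __post_init__(self) -> None:
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must be in (0, 1)")


def _select_block_features(
    spec: BlockSpec,
    X_train: OmicsMatrix,
    y_train: np.ndarray,
) -> list[str]:
    if spec.selector == "none":
        return list(X_train.feature_ids)
    if spec.k is None:
        raise ValueError(f"block {spec.block!r}: selector {spec.selector!r} needs k")
    if spec.selector == "fisher":
        return select_candidates(fisher_scores(X_train, y_train), spec.k)
    if spec.selector == "tsfs":
        return two_step_select(
            X_train, y_train, spec.k, spec.m, spec.rth, MacConfig(alpha=spec.alpha)
        )
    raise ValueError(f"unknown selector {spec.selector!r}")


def run_experiment(
    clinical: ClinicalTable,
    omics: dict[str, OmicsMatrix],
    labels: LabelPair,
    plan: ExperimentPlan,
    task: str = "survival",
    classifier=None,
) -> dict:
    """Single-task experiment over data combinations and train/test splits.

    For each combination and each split seed: encode/select features on the
    training 80%, transform the held-out 20% with the training-fit
    statistics, fit the classifier, and score ACC / AUC / feature count on
    the test split. Returns per-split triples and their averages, keyed by
    combination name.
    """
    if task not in ("survival", "vital"):
        raise ValueError("task must be 'survival' or 'vital'")
    y = labels.survival_label if task == "survival" else labels.vital_label
    n = len(y)
    if clinical.n_samples != n:
        raise ValueError("clinical table and labels misaligned")
    report: dict = {}
    for comb in plan.combinations:
        split_rows = []
        for seed in plan.seeds:
            sss = StratifiedShuffleSplit(
                n_splits=1, test_size=plan.split_fraction, random_state=seed
            )
            (tr, te), = sss.split(np.zeros(n), y)
            blocks_tr: list[OmicsMatrix] = []
            blocks_te: list[OmicsMatrix] = []
            for bs in comb.blocks:
                if bs.block == "clinical":
                    feats = CLINICAL_FEATURES[task]
                    ctr = ClinicalTable(clinical.df.iloc[tr].reset_index(drop=True))
                    cte = ClinicalTable(clinical.df.iloc[te].reset_index(drop=True))
                    stats = fit_encoding_stats(ctr, feats)
                    blocks_tr.append(encode_clinical(ctr, feats, fit_stats=stats))
                    blocks_te.append(encode_clinical(cte, feats, fit_stats=stats))
                else:
                    X = omics[bs.block]
                    Xtr, Xte = X.subset_samples(tr), X.subset_samples(te)
                    feats = _select_block_features(bs, Xtr, y[tr])
                    blocks_tr.append(Xtr.subset_features(feats))
                    blocks_te.append(Xte.subset_features(feats))
            Xtr_all = concatenate(blocks_tr)
            Xte_all = concatenate(blocks_te)
            model, _ = train_single_task(Xtr_all, y[tr], classifier, seed=seed)
            pred = model.predict(Xte_all.values)
            scores = model.decision_function(Xte_all.values)
            cm = ConfusionMatrix.from_predictions(y[te], pred)
            split_rows.append(
                {
                    "seed": int(seed),
                    "acc": accuracy(cm),
                    "auc": auc(scores, y[te]),
                    "n_features": Xtr_all.n_features,
                }
            )
        report[comb.name] = {
            "splits": split_rows,
            "mean": {
                "acc": float(np.mean([r["acc"] for r in split_rows])),
                "auc": float(np.mean([r["auc"] for r in split_rows])),
                "n_features": float(np.mean([r["n_features"] for r in split_rows])),
            },
        }
    return report


def evaluate_multitask(
    model: MMoE,
    X_test: np.ndarray,
    truth: LabelPair,
) -> dict:
    """ACC/AUC per task plus the composite (absolute) accuracy."""
    probs = model.predict_proba(X_test)
    preds = (probs >= 0.5).astype(int)
    pred_pair = LabelPair(preds[:, 0], preds[:, 1], truth.threshold_years)
    out: dict = {"absolute_accuracy": absolute_accuracy(pred_pair, truth)}
    for k, (name, y) in enumerate(
        [("survival", truth.survival_label), ("vital", truth.vital_label)]
    ):
        cm = ConfusionMatrix.from_predictions(y, preds[:, k])
        out[name] = {"acc": accuracy(cm)}
        if np.unique(y).size == 2:
            out[name]["auc"] = auc(probs[:, k], y)
    return out
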