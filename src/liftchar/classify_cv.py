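"""Feature weighting, classifiers and subject-independent cross-validation.

Pipeline pieces for the four lift classification subproblems (posture, twist
asymmetry, vertical movement, load weight):

* :func:`nca_weights` -- diagonal neighborhood component analysis: learns one
  nonnegative relevance weight per feature by maximizing a softmax
  leave-one-out classification objective under the weighted L1 metric
  ``d_w(x, y) = sum_r w_r^2 |x_r - y_r|``.
* :func:`select_features` -- relative-threshold selection: keep features whose
  weight is within a fraction of the maximum weight, minus a manual exclusion
  list.
* :func:`train_predict_knn` / :func:`train_predict_gnb` -- k-nearest-neighbor
  (Euclidean, standardized) and Gaussian naive Bayes with uniform priors,
  with fully deterministic tie-breaking.
* :func:`subject_folds` / :func:`cross_validate` -- folds partition
  participants, never trials, so test subjects are unseen during training;
  standardization and training always use training-fold statistics only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.neighbors import NearestNeighbors

from .feature_extraction import SUBPROBLEMS, published_feature_set

__all__ = [
    "ModelSpec",
    "DEFAULT_MODELS",
    "MAIN_VERTICAL_CLASSES",
    "ClassificationReport",
    "nca_weights",
    "select_features",
    "train_predict_knn",
    "gnb_log_posteriors",
    "train_predict_gnb",
    "subject_folds",
    "cross_validate",
]

#: Vertical-movement categories with enough samples to classify; rows with
#: other source->destination pairs (transition-only lifts) are excluded from
#: that subproblem.
MAIN_VERTICAL_CLASSES: tuple[str, ...] = (
    "floor_to_chest", "chest_to_floor",
    "knee_to_chest", "chest_to_knee",
    "chest_to_head", "head_to_chest",
)

#: Label column of the feature table used by each subproblem.
LABEL_COLUMNS: dict[str, str] = {
    "posture": "posture",
    "asymmetry": "twist",
    "vertical_movement": "vertical_movement",
    "weight": "weight",
}


@dataclass(frozen=True)
class ModelSpec:
    """Classifier choice: ``method`` is ``"knn"`` (with ``k``) or ``"gnb"``."""

    method: str
    k: int | None = None
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("knn", "gnb"):
            raise ValueError("method must be 'knn' or 'gnb'")
        if self.method == "knn" and (self.k is None or self.k < 1):
            raise ValueError("knn requires k >= 1")

    def describe(self) -> str:
        return f"KNN, k = {self.k}" if self.method == "knn" else "Gaussian naive Bayes"


#: Best-performing model per subproblem.
DEFAULT_MODELS: dict[str, ModelSpec] = {
    "posture": ModelSpec("knn", k=30),
    "asymmetry": ModelSpec("knn", k=10),
    "vertical_movement": ModelSpec("knn", k=10),
    "weight": ModelSpec("gnb"),
}


# --- standardization helpers -------------------------------------------------

def _fit_standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return mu, sd


# --- NCA ---------------------------------------------------------------------

def nca_weights(
    table: pd.DataFrame,
    label: str,
    features: list[str] | None = None,
    reg: float | None = None,
    max_iter: int = 200,
    seed: int | None = None,
) -> pd.Series:
    """Per-feature nonnegative relevance weights from diagonal NCA.

    Features are standardized internally on the fitting rows. ``reg`` is the
    L2 penalty on the weights (default ``1/n``). The optimization (L-BFGS from
    all-ones weights) is deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic stages.

    Raises ``ValueError`` on single-class input or classes with fewer than
    two rows.
    """
    if label not in table.columns:
        raise ValueError(f"label column {label!r} not in table")
    if features is None:
        features = [c for c in table.columns if c != label]
    y = table[label].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("nca_weights requires at least 2 classes")
    if counts.min() < 2:
        raise ValueError("nca_weights requires at least 2 rows per class")
    X = table[features].to_numpy(dtype=float)
    n, d = X.shape
    mu, sd = _fit_standardizer(X)
    Z = (X - mu) / sd
    lam = (1.0 / n) if reg is None else float(reg)

    diffs = np.abs(Z[:, None, :] - Z[None, :, :])  # (n, n, d) pairwise |delta|
    same = (y[:, None] == y[None, :])
    np.fill_diagonal(same, False)

    def negobj_and_grad(w: np.ndarray) -> tuple[float, np.ndarray]:
        w2 = w * w
        D = diffs @ w2
        np.fill_diagonal(D, np.inf)
        D_shift = D - D.min(axis=1, keepdims=True)  # softmax stabilization
        K = np.exp(-D_shift)
        P = K / K.sum(axis=1, keepdims=True)
        p_i = (P * same).sum(axis=1)
        f = p_i.mean() - lam * w2.sum()
        M = P * p_i[:, None] - P * same
        grad_w2 = np.einsum("ij,ijr->r", M, diffs) / n
        grad = 2.0 * w * grad_w2 - 2.0 * lam * w
        return -f, -grad

    w0 = np.ones(d)
    res = optimize.minimize(
        negobj_and_grad,
        w0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter},
    )
    return pd.Series(np.abs(res.x), index=features, name="weight")


def select_features(
    weights: pd.Series,
    rel_threshold: float = 0.02,
    exclusions: tuple[str, ...] = (),
    mode: str = "weight",
) -> list[str]:
    """Relative-threshold feature selection.

    ``mode="weight"`` (default) keeps features whose weight is at least
    ``(1 - rel_threshold) * max(weight)``; ``mode="count"`` keeps the top
    ``ceil(rel_threshold * n)`` features by weight instead. Excluded names are
    removed afterwards. Raises ``ValueError`` if nothing survives.
    """
    weights = pd.Series(weights)
    if weights.empty:
        raise ValueError("weights must be nonempty")
    if not 0 < rel_threshold <= 1:
        raise ValueError("rel_threshold must be in (0, 1]")
    if mode == "weight":
        cutoff = (1.0 - rel_threshold) * weights.max()
        chosen = weights[weights >= cutoff]
    elif mode == "count":
        k = max(1, int(np.ceil(rel_threshold * len(weights))))
        chosen = weights.nlargest(k)
    else:
        raise ValueError("mode must be 'weight' or 'count'")
    selected = [name for name in chosen.sort_values(ascending=False).index
                if name not in set(exclusions)]
    if not selected:
        raise ValueError("all selected features were excluded")
    return selected


# --- classifiers -------------------------------------------------------------

def train_predict_knn(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    k: int,
    standardize: bool = True,
) -> np.ndarray:
    """Majority vote among the k nearest training rows (Euclidean distance).

    Standardization uses training statistics only. Vote ties are broken by
    the smallest summed distance to the query among tied labels, then
    lexicographically.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    y_train = np.asarray(y_train)
    if k > len(X_train):
        raise ValueError(f"k={k} exceeds {len(X_train)} training rows")
    if standardize:
        mu, sd = _fit_standardizer(X_train)
        X_train = (X_train - mu) / sd
        X_test = (X_test - mu) / sd
    nn = NearestNeighbors(n_neighbors=k).fit(X_train)
    dist, idx = nn.kneighbors(X_test)
    out = []
    for drow, irow in zip(dist, idx):
        labels = y_train[irow]
        uniq = np.unique(labels)
        votes = {u: int((labels == u).sum()) for u in uniq}
        best_votes = max(votes.values())
        tied = [u for u, v in votes.items() if v == best_votes]
        if len(tied) > 1:
            sums = {u: float(drow[labels == u].sum()) for u in tied}
            best_sum = min(sums.values())
            tied = sorted(u for u, v in sums.items() if v == best_sum)
        out.append(tied[0])
    return np.asarray(out)


def gnb_log_posteriors(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Unnormalized Gaussian naive Bayes log-posteriors, uniform priors.

    Returns ``(classes, log_post)`` with classes in sorted order and
    ``log_post`` of shape ``(n_test, n_classes)``. Per-class per-feature
    variances are floored at ``1e-9`` times the pooled (all-training-rows)
    variance of the feature; a feature whose variance is still zero after
    flooring triggers a degenerate-model warning and is treated as
    uninformative for that class. With uniform priors the constant prior term
    is omitted, so the values are the summed per-feature Gaussian
    log-densities.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.atleast_2d(np.asarray(X_test, dtype=float))
    y_train = np.asarray(y_train)
    classes = np.unique(y_train)
    counts = {c: int((y_train == c).sum()) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError("each class needs at least 2 training rows")
    pooled = X_train.var(axis=0)
    floor = 1e-9 * pooled
    log_post = np.zeros((len(X_test), len(classes)))
    for ci, c in enumerate(classes):
        Xc = X_train[y_train == c]
        mean = Xc.mean(axis=0)
        var = np.maximum(Xc.var(axis=0), floor)
        degenerate = var <= 0
        if degenerate.any():
            warnings.warn(
                f"class {c!r}: {int(degenerate.sum())} feature(s) with zero "
                "variance after flooring; treated as uninformative",
                RuntimeWarning,
                stacklevel=2,
            )
            var = np.where(degenerate, 1.0, var)
        ll = -0.5 * (
            np.log(2.0 * np.pi * var) + (X_test - mean) ** 2 / var
        ).sum(axis=1)
        log_post[:, ci] = ll
    return classes, log_post


def train_predict_gnb(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> np.ndarray:
    """Gaussian naive Bayes prediction with uniform class priors.

    See :func:`gnb_log_posteriors` for the model; log-posterior ties are
    broken lexicographically (classes are evaluated in sorted order and
    ``argmax`` keeps the first maximum).
    """
    classes, log_post = gnb_log_posteriors(X_train, y_train, X_test)
    return classes[np.argmax(log_post, axis=1)]


# --- cross-validation --------------------------------------------------------

def subject_folds(
    participant_ids, n_folds: int = 5, seed: int = 0
) -> dict[str, int]:
    """Assign each participant to one fold (near-equal participant counts).

    Participants are shuffled with the given seed and split so the first
    ``n % n_folds`` folds get one extra participant (24 participants into 5
    folds gives sizes 5,5,5,5,4). Every trial of a participant inherits that
    participant's fold.
    """
    unique = sorted(set(map(str, participant_ids)))
    if n_folds < 1:
        raise ValueError("n_folds must be >= 1")
    if len(unique) < n_folds:
        raise ValueError(
            f"{len(unique)} participants cannot fill {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(unique))
    assignment: dict[str, int] = {}
    for f, chunk in enumerate(np.array_split(order, n_folds)):
        for i in chunk:
            assignment[unique[i]] = f
    return assignment


@dataclass
class ClassificationReport:
    """Aggregated subject-independent cross-validation result."""

    subproblem: str
    model: str
    accuracy: float                    # percent, trace/total * 100
    confusion: pd.DataFrame            # rows = true class, cols = predicted
    fold_accuracies: list[float] = field(default_factory=list)
    fold_participants: list[list[str]] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return int(self.confusion.to_numpy().sum())


def cross_validate(
    table: pd.DataFrame,
    subproblem: str,
    model_spec: ModelSpec | None = None,
    fold_assignment: dict[str, int] | None = None,
    features: list[str] | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> ClassificationReport:
    """Subject-independent k-fold cross-validation of one subproblem.

    Each fold's trials are predicted by a model trained on the remaining
    folds; no test-fold information enters standardization or training. The
    published feature set for the subproblem is used unless ``features`` is
    given, and the best published model unless ``model_spec`` is given.
    Vertical-movement rows outside the six main categories are excluded.
    """
    if subproblem not in SUBPROBLEMS:
        raise ValueError(f"unknown subproblem {subproblem!r}")
    label = LABEL_COLUMNS[subproblem]
    if label not in table.columns:
        raise ValueError(f"label column {label!r} not in table")
    if "participant_id" not in table.columns:
        raise ValueError("table must carry a participant_id column")
    model = model_spec or DEFAULT_MODELS[subproblem]
    feats = list(features or published_feature_set(subproblem).features)
    missing = [f for f in feats if f not in table.columns]
    if missing:
        raise ValueError(f"feature column(s) missing from table: {missing}")

    data = table
    if subproblem == "vertical_movement":
        data = data[data[label].isin(MAIN_VERTICAL_CLASSES)]
    if data[feats].isna().any().any():
        raise ValueError("selected features contain missing values")

    folds = fold_assignment or subject_folds(
        data["participant_id"], n_folds=n_folds, seed=seed
    )
    fold_of_row = data["participant_id"].map(folds).to_numpy()
    X = data[feats].to_numpy(dtype=float)
    y = data[label].astype(str).to_numpy()
    classes = sorted(np.unique(y))

    confusion = pd.DataFrame(
        np.zeros((len(classes), len(classes)), dtype=int),
        index=classes,
        columns=classes,
    )
    fold_accuracies: list[float] = []
    fold_participants: list[list[str]] = []
    for f in sorted(set(folds.values())):
        test_mask = fold_of_row == f
        if not test_mask.any():
            continue
        train_mask = ~test_mask
        if model.method == "knn":
            pred = train_predict_knn(
                X[train_mask], y[train_mask], X[test_mask],
                k=model.k, standardize=model.standardize,
            )
        else:
            pred = train_predict_gnb(X[train_mask], y[train_mask], X[test_mask])
        truth = y[test_mask]
        for t_lab, p_lab in zip(truth, pred):
            confusion.loc[t_lab, p_lab] += 1
        fold_accuracies.append(100.0 * float((pred == truth).mean()))
        fold_participants.append(
            sorted(set(data.loc[test_mask, "participant_id"]))
        )

    total = confusion.to_numpy().sum()
    accuracy = 100.0 * np.trace(confusion.to_numpy()) / total
    return ClassificationReport(
        subproblem=subproblem,
        model=model.describe(),
        accuracy=float(accuracy),
        confusion=confusion,
        fold_accuracies=fold_accuracies,
        fold_participants=fold_participants,
    )
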