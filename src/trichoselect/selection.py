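"""Permutation-null random-forest feature selection.

The procedure links metabolite features to a binary resistance phenotype in
three steps:

1. **Observed importances** — a random-forest classifier (1000 trees) is run
   under stratified 6-fold cross-validation; each fold's forest yields an
   impurity-based feature-importance vector and a test-fold accuracy.  The
   whole scheme is repeated 5 times with fresh fold draws and tree seeds,
   giving each feature a mean importance (folds, then repeats) with an SD
   across repeats, and the model a mean cross-validated accuracy.
2. **Permutation null** — the class labels are randomly permuted and the
   cross-validated importance computation is re-run once per permuted model
   (100, 250 and 500 models by default), yielding a null importance
   distribution per feature that preserves the feature table, the class
   balance and the CV scheme while destroying any feature-phenotype link.
3. **Empirical p-values** — each feature's observed mean importance is
   compared against its own null: p = (1 + #{null >= observed}) / (1 + n_null)
   (the add-one estimator, which can never return exactly 0).  A feature is
   selected when p < alpha (default 0.01; 0.05 is a common laxer choice and
   every computed p-value is reported so either threshold can be applied).

With few samples and many mutually sparse features this behaves like a
shadow-feature method: the observed forest concentrates importance on truly
discriminative features, which both lifts them above their null and
suppresses the observed importance of noise features below theirs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, KFold

from .forest import fit_forest

__all__ = [
    "SelectionConfig",
    "ImportanceResult",
    "SelectionResult",
    "run_rf_repeated",
    "permutation_null",
    "feature_pvalues",
    "run_selection",
]


@dataclass
class SelectionConfig:
    """Knobs of the selection procedure; defaults are the standard protocol."""

    n_folds: int = 6
    n_trees: int = 1000
    n_repeats: int = 5
    n_permutations: tuple[int, ...] = (100, 250, 500)
    alpha: float = 0.01
    stratified: bool = True
    engine: str = "native"  # "native" (numba) or "sklearn"
    max_features: int | None = None  # per-node feature draw; None = sqrt(p)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2 or self.n_trees < 1 or self.n_repeats < 1:
            raise ValueError("n_folds >= 2, n_trees >= 1, n_repeats >= 1 required")
        self.n_permutations = tuple(sorted(int(k) for k in self.n_permutations))
        if any(k < 1 for k in self.n_permutations):
            raise ValueError("permutation counts must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.engine not in ("native", "sklearn"):
            raise ValueError("engine must be 'native' or 'sklearn'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_permutations"] = list(self.n_permutations)
        return d


@dataclass
class ImportanceResult:
    """Cross-validated importances of one (repeated) RF run."""

    mean_importance: pd.Series
    sd_importance: pd.Series
    accuracy: float
    fold_log: list = field(default_factory=list)


@dataclass
class SelectionResult:
    """Per-feature selection table plus model-level summaries."""

    table: pd.DataFrame          # mean_importance, sd, p_<k>..., selected
    accuracy: float
    null_importances: dict[int, np.ndarray]  # n_models -> (n_models, n_features)
    config: SelectionConfig
    n_null_used: int


def _check_xy(X: pd.DataFrame, y: pd.Series | np.ndarray) -> tuple[pd.DataFrame, np.ndarray]:
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X))
    if isinstance(y, pd.Series):
        y = y.reindex(X.index).to_numpy()
    else:
        y = np.asarray(y)
    if len(y) != len(X):
        raise ValueError("y is not aligned to the rows of X")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need two classes in y")
    if counts.min() < 2:
        raise ValueError("need at least two samples per class")
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    return X, y


def _one_fit(X, y, Xte, yte, n_trees, max_features, seed_seq, engine):
    """One forest fit: (importance vector, test accuracy)."""
    if engine == "sklearn":
        from sklearn.ensemble import RandomForestClassifier

        rs = int(seed_seq.generate_state(1)[0] % (2**31))
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=max_features if max_features is not None else "sqrt",
            random_state=rs,
        )
        rf.fit(X, y)
        return rf.feature_importances_, float((rf.predict(Xte) == yte).mean())
    imp, pred = fit_forest(
        X, y, Xte, n_trees=n_trees, max_features=max_features, random_state=seed_seq
    )
    proba, classes = pred
    y_hat = classes[np.argmax(proba, axis=1)]
    return imp, float((y_hat == yte).mean())


def _cv_importance(X_arr, y, cfg: SelectionConfig, split_seed_seq, tree_seed_seq,
                   max_redraw: int = 100):
    """One full CV pass: fold-averaged importances and fold accuracies.

    If a split leaves a training fold single-class (possible without
    stratification), the split is re-drawn with a fresh seed; the number of
    redraws is recorded in the returned log.  On very small studies the fold
    count is clamped so each stratified fold can hold every class (at most
    the minority-class count, never below 2).
    """
    _, class_counts = np.unique(y, return_counts=True)
    cap = int(class_counts.min()) if cfg.stratified else len(y) // 2
    n_folds = max(2, min(cfg.n_folds, cap))
    redraws = 0
    children = split_seed_seq.spawn(max_redraw)
    for attempt in range(max_redraw):
        rs = int(children[attempt].generate_state(1)[0] % (2**31))
        splitter = (
            StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
            if cfg.stratified
            else KFold(n_splits=n_folds, shuffle=True, random_state=rs)
        )
        folds = list(splitter.split(X_arr, y))
        if all(len(np.unique(y[tr])) >= 2 for tr, _ in folds):
            break
        redraws += 1
    else:
        raise RuntimeError("could not draw folds with both classes in training data")

    tree_seeds = tree_seed_seq.spawn(len(folds))
    imps = np.empty((len(folds), X_arr.shape[1]))
    accs = np.empty(len(folds))
    for i, (tr, te) in enumerate(folds):
        imps[i], accs[i] = _one_fit(
            X_arr[tr], y[tr], X_arr[te], y[te],
            cfg.n_trees, cfg.max_features, tree_seeds[i], cfg.engine,
        )
    return imps.mean(axis=0), accs, redraws


def run_rf_repeated(
    X: pd.DataFrame, y, config: SelectionConfig | None = None
) -> ImportanceResult:
    """Observed importances: ``n_repeats`` x (stratified ``n_folds``-fold CV).

    ``X`` is the accession-mean feature table (samples x features, untransformed
    abundances); ``y`` the binary class labels aligned to its rows.
    """
    cfg = config or SelectionConfig()
    X, y = _check_xy(X, y)
    X_arr = np.ascontiguousarray(X.to_numpy(dtype=np.float32))
    root = np.random.SeedSequence([int(cfg.seed), 0x0B5E]).spawn(cfg.n_repeats)

    per_repeat = np.empty((cfg.n_repeats, X.shape[1]))
    accs = []
    log = []
    for r in range(cfg.n_repeats):
        split_ss, tree_ss = root[r].spawn(2)
        per_repeat[r], fold_accs, redraws = _cv_importance(
            X_arr, y, cfg, split_ss, tree_ss
        )
        accs.extend(fold_accs.tolist())
        log.append({"repeat": r, "fold_accuracies": fold_accs.tolist(),
                    "split_redraws": redraws})
    ddof = 1 if cfg.n_repeats > 1 else 0
    return ImportanceResult(
        mean_importance=pd.Series(per_repeat.mean(axis=0), index=X.columns,
                                  name="mean_importance"),
        sd_importance=pd.Series(per_repeat.std(axis=0, ddof=ddof), index=X.columns,
                                name="sd_importance"),
        accuracy=float(np.mean(accs)),
        fold_log=log,
    )


def permutation_null(
    X: pd.DataFrame, y, config: SelectionConfig | None = None
) -> dict[int, np.ndarray]:
    """Null importance distributions from label-permuted RF models.

    Runs ``max(n_permutations)`` permuted models — each a uniformly random
    permutation of ``y`` followed by ONE full cross-validated importance pass —
    and returns, for every requested count k, the first k rows, so the smaller
    nulls are prefix-consistent subsamples of the largest under a fixed seed.
    """
    cfg = config or SelectionConfig()
    X, y = _check_xy(X, y)
    X_arr = np.ascontiguousarray(X.to_numpy(dtype=np.float32))
    n_max = max(cfg.n_permutations)

    perm_root = np.random.SeedSequence([int(cfg.seed), 0x9E11]).spawn(n_max)
    null = np.empty((n_max, X.shape[1]))
    for j in range(n_max):
        perm_ss, split_ss, tree_ss = perm_root[j].spawn(3)
        rng = np.random.default_rng(perm_ss)
        y_perm = rng.permutation(y)
        null[j], _, _ = _cv_importance(X_arr, y_perm, cfg, split_ss, tree_ss)
    return {k: null[:k] for k in cfg.n_permutations}


def feature_pvalues(
    observed: ImportanceResult | pd.Series,
    null_distributions: dict[int, np.ndarray],
    config: SelectionConfig | None = None,
) -> SelectionResult:
    """Add-one empirical p-values and the selected set.

    p_k = (1 + #{null_k >= observed}) / (1 + k) for each permutation count k;
    the ``selected`` flag applies ``alpha`` to the largest available null
    (smallest-grain p-value).
    """
    cfg = config or SelectionConfig()
    if isinstance(observed, ImportanceResult):
        obs = observed.mean_importance
        sd = observed.sd_importance
        accuracy = observed.accuracy
    else:
        obs = observed
        sd = pd.Series(np.nan, index=obs.index)
        accuracy = float("nan")
    if not null_distributions:
        raise ValueError("no null distributions supplied")
    if obs.isna().any():
        missing = obs.index[obs.isna()].tolist()
        raise ValueError(f"observed importance missing for features {missing}")

    table = pd.DataFrame({"mean_importance": obs, "sd": sd})
    obs_arr = obs.to_numpy()
    for k, null in sorted(null_distributions.items()):
        if null.shape[0] != k or null.shape[1] != len(obs):
            raise ValueError(f"null distribution for k={k} has shape {null.shape}")
        exceed = (null >= obs_arr[None, :]).sum(axis=0)
        table[f"p_{k}"] = (1.0 + exceed) / (1.0 + k)
    k_max = max(null_distributions)
    table["selected"] = table[f"p_{k_max}"] < cfg.alpha
    return SelectionResult(
        table=table,
        accuracy=accuracy,
        null_importances=null_distributions,
        config=cfg,
        n_null_used=k_max,
    )


def run_selection(
    X: pd.DataFrame, y, config: SelectionConfig | None = None
) -> SelectionResult:
    """Full procedure: observed importances, permutation null, p-values."""
    cfg = config or SelectionConfig()
    observed = run_rf_repeated(X, y, cfg)
    null = permutation_null(X, y, cfg)
    return feature_pvalues(observed, null, cfg)
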