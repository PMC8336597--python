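"""QSAR evaluators: affinity regression and BBB permeability classification.

Two property models guide the RL fine-tuning:

* an affinity model predicting pIC50 from SMILES-derived token features
  (counts and atom-normalized fractions of every token the training corpus
  contains — the SMILES string is the only descriptor);
* a permeability classifier predicting P(BBB+) from 2048-bit radius-2 Morgan
  fingerprints, trained on oversampled minority data because real BBB
  datasets are heavily skewed toward permeable molecules.

Both use multilayer perceptrons trained epoch-by-epoch with early stopping
against a clean (never oversampled) validation split.  SMOTE and ADASYN are
implemented here directly: synthetic minority points are convex combinations
x + lam*(x_nn - x) of a minority point and one of its k minority-class
nearest neighbours, left real-valued.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import log_loss, mean_squared_error, r2_score, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.preprocessing import StandardScaler

from .chemio import fingerprint, fingerprints, smiles_tokens

__all__ = [
    "AffinityConfig", "BBBConfig", "OversampleSpec", "CrossValReport",
    "AffinityModel", "PermeabilityModel", "train_affinity", "train_bbb",
    "predict_pic50", "predict_bbb", "oversample", "regression_metrics",
    "classification_metrics", "crossvalidate", "grid_search",
]


# --------------------------------------------------------------------- config
@dataclass
class AffinityConfig:
    hidden_layers: tuple[int, ...] = (64, 64)
    learning_rate: float = 1e-3
    alpha: float = 1e-2  # L2 penalty; keeps the net close to smooth fits
    batch_size: int = 32
    max_epochs: int = 300
    patience: int = 10
    validation_fraction: float = 0.15
    min_examples: int = 20


@dataclass
class BBBConfig:
    hidden_layers: tuple[int, ...] = (256, 128, 64)
    learning_rate: float = 1e-3
    alpha: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 10
    validation_fraction: float = 0.15
    n_bits: int = 2048
    radius: int = 2


@dataclass
class OversampleSpec:
    method: str = "smote"
    k_neighbors: int = 5
    target_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("smote", "adasyn"):
            raise ValueError("method must be 'smote' or 'adasyn'")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


# ------------------------------------------------------------------- features
_ATOM_CHARS = set("BCNOPSFIbcnops")


def _is_atom_token(tok: str) -> bool:
    return tok[0] in _ATOM_CHARS or tok.startswith("[") or tok in ("Cl", "Br")


class _TokenFeaturizer:
    """SMILES -> fixed vector of token counts and atom-normalized fractions."""

    def __init__(self, corpus: list[str]):
        seen: dict[str, None] = {}
        for s in corpus:
            for t in smiles_tokens(s):
                seen.setdefault(t, None)
        self.tokens = sorted(seen)
        self.index = {t: i for i, t in enumerate(self.tokens)}

    @property
    def n_features(self) -> int:
        return 2 * (len(self.tokens) + 1) + 2  # counts + fractions + totals

    def transform_one(self, s: str) -> np.ndarray:
        k = len(self.tokens)
        counts = np.zeros(k + 1)  # trailing slot collects unseen tokens
        toks = smiles_tokens(s)
        n_atoms = 0
        for t in toks:
            counts[self.index.get(t, k)] += 1
            n_atoms += _is_atom_token(t)
        n_atoms = max(n_atoms, 1)
        return np.concatenate([
            counts, counts / n_atoms, [len(toks), n_atoms]])

    def transform(self, smiles: list[str]) -> np.ndarray:
        return np.array([self.transform_one(s) for s in smiles])


# ------------------------------------------------------ early-stopped fitting
def _fit_early_stopping(net, X_tr, y_tr, X_val, y_val, val_loss_fn,
                        max_epochs: int, patience: int):
    """Epoch-wise partial_fit with patience on a clean validation split."""
    best_loss = np.inf
    best_state = None
    bad = 0
    classes = np.unique(y_tr) if isinstance(net, MLPClassifier) else None
    for _ in range(max_epochs):
        if classes is not None:
            net.partial_fit(X_tr, y_tr, classes=classes)
        else:
            net.partial_fit(X_tr, y_tr)
        loss = val_loss_fn(net, X_val, y_val)
        if loss < best_loss - 1e-6:
            best_loss = loss
            best_state = (copy.deepcopy(net.coefs_),
                          copy.deepcopy(net.intercepts_))
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                break
    if best_state is not None:  # restore best weights
        net.coefs_, net.intercepts_ = best_state
    return net


# ----------------------------------------------------------------- oversample
def oversample(X: np.ndarray, y: np.ndarray, spec: OversampleSpec
               ) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by SMOTE or ADASYN synthetic minority interpolation.

    Originals are preserved verbatim (synthetics appended after them); the
    minority:majority ratio afterwards equals ``spec.target_ratio`` within
    one sample.  Synthetic points stay real-valued.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversampling requires two classes")
    if len(classes) > 2:
        raise ValueError("only binary problems are supported")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min <= spec.k_neighbors:
        raise ValueError(
            f"k_neighbors={spec.k_neighbors} must be < minority size {n_min}")
    n_target = int(round(spec.target_ratio * n_maj))
    n_synth = n_target - n_min
    if n_synth <= 0:
        return X.copy(), y.copy()

    rng = np.random.default_rng(spec.seed)
    min_idx = np.flatnonzero(y == minority)
    X_min = X[min_idx]
    nn = NearestNeighbors(n_neighbors=spec.k_neighbors + 1).fit(X_min)
    neigh = nn.kneighbors(X_min, return_distance=False)[:, 1:]

    if spec.method == "smote":
        base = rng.integers(0, len(X_min), size=n_synth)
    else:  # ADASYN: density-weighted allocation r_i = (#majority among kNN)/k
        nn_all = NearestNeighbors(n_neighbors=spec.k_neighbors + 1).fit(X)
        neigh_all = nn_all.kneighbors(X_min, return_distance=False)[:, 1:]
        r = (y[neigh_all] != minority).mean(axis=1)
        if r.sum() == 0:
            r = np.ones(len(X_min))
        r = r / r.sum()
        alloc = np.floor(r * n_synth).astype(int)
        remainder = n_synth - alloc.sum()
        if remainder > 0:
            frac = r * n_synth - alloc
            alloc[np.argsort(-frac, kind="stable")[:remainder]] += 1
        base = np.repeat(np.arange(len(X_min)), alloc)

    pick = rng.integers(0, spec.k_neighbors, size=n_synth)
    lam = rng.random(n_synth)
    x_base = X_min[base]
    x_nn = X_min[neigh[base, pick]]
    synth = x_base + lam[:, None] * (x_nn - x_base)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_synth, minority, dtype=y.dtype)])
    return X_out, y_out


# -------------------------------------------------------------------- metrics
def regression_metrics(y: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """MSE, coefficient of determination Q2 and concordance correlation."""
    y = np.asarray(y, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if len(y) != len(y_pred) or len(y) < 2:
        raise ValueError("need equal-length arrays with >= 2 points")
    mse = float(mean_squared_error(y, y_pred))
    q2 = float(r2_score(y, y_pred))
    mx, my = y.mean(), y_pred.mean()
    sx, sy = y.var(), y_pred.var()
    sxy = ((y - mx) * (y_pred - my)).mean()
    denom = sx + sy + (mx - my) ** 2
    ccc = float(2 * sxy / denom) if denom > 0 else 1.0
    return {"MSE": mse, "Q2": q2, "CCC": ccc}


def classification_metrics(y: np.ndarray, p: np.ndarray,
                           threshold: float = 0.5) -> dict[str, float]:
    """ACC, AUC (rank-based), sensitivity, specificity and MCC.

    AUC and MCC are NaN (with a warning) when only one class is present.
    """
    y = np.asarray(y).astype(int)
    p = np.asarray(p, dtype=np.float64)
    if len(y) != len(p) or len(y) < 2:
        raise ValueError("need equal-length arrays with >= 2 points")
    pred = (p >= threshold).astype(int)
    tp = int(np.sum((y == 1) & (pred == 1)))
    tn = int(np.sum((y == 0) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    acc = (tp + tn) / len(y)
    single_class = len(np.unique(y)) < 2
    if single_class:
        warnings.warn("single-class labels: AUC and MCC undefined (NaN)")
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y, p))
    sen = tp / (tp + fn) if (tp + fn) else float("nan")
    spe = tn / (tn + fp) if (tn + fp) else float("nan")
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        if not single_class:
            warnings.warn("degenerate confusion matrix: MCC undefined (NaN)")
        mcc = float("nan")
    else:
        mcc = float((tp * tn - fp * fn) / mcc_den)
    return {"ACC": acc, "AUC": auc, "Sen": sen, "Spe": spe, "MCC": mcc}


# --------------------------------------------------------------------- models
@dataclass
class AffinityModel:
    """pIC50 regressor over token-derived SMILES features.

    Targets are standardized during fitting; ``y_mean``/``y_std`` restore the
    original pIC50 scale at prediction time.
    """

    featurizer: _TokenFeaturizer
    scaler: StandardScaler
    net: MLPRegressor
    config: AffinityConfig
    y_mean: float = 0.0
    y_std: float = 1.0

    def predict(self, smiles: str | list[str]) -> float | np.ndarray:
        single = isinstance(smiles, str)
        X = self.featurizer.transform([smiles] if single else list(smiles))
        pred = self.net.predict(self.scaler.transform(X))
        pred = pred * self.y_std + self.y_mean
        return float(pred[0]) if single else pred


@dataclass
class PermeabilityModel:
    """P(BBB+) classifier over Morgan fingerprints."""

    net: MLPClassifier
    config: BBBConfig
    oversample_spec: OversampleSpec | None = None

    def predict_proba_fp(self, X: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(np.asarray(X, dtype=np.float64))[:, 1]

    def predict(self, smiles: str | list[str]) -> float | np.ndarray:
        single = isinstance(smiles, str)
        items = [smiles] if single else list(smiles)
        X = fingerprints(items, n_bits=self.config.n_bits,
                         radius=self.config.radius)
        p = self.predict_proba_fp(X)
        return float(p[0]) if single else p


def predict_pic50(model: AffinityModel, smiles: str) -> float:
    fingerprint(smiles, 16, 1)  # raises InvalidMoleculeError on bad input
    return model.predict(smiles)


def predict_bbb(model: PermeabilityModel, smiles: str) -> float:
    return model.predict(smiles)


def train_affinity(smiles: list[str], pic50: np.ndarray,
                   config: AffinityConfig | None = None,
                   seed: int = 0) -> AffinityModel:
    """Fit the affinity regressor with early stopping on a validation split."""
    config = config or AffinityConfig()
    pic50 = np.asarray(pic50, dtype=np.float64)
    if len(smiles) < config.min_examples:
        raise ValueError(
            f"need >= {config.min_examples} examples, got {len(smiles)}")
    if not np.all(np.isfinite(pic50)):
        raise ValueError("labels must be finite")
    feat = _TokenFeaturizer(list(smiles))
    X = feat.transform(list(smiles))
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    y_mean = float(pic50.mean())
    y_std = float(pic50.std()) or 1.0  # zero-variance labels: no rescaling
    yn = (pic50 - y_mean) / y_std
    X_tr, X_val, y_tr, y_val = train_test_split(
        Xs, yn, test_size=config.validation_fraction, random_state=seed)
    net = MLPRegressor(hidden_layer_sizes=config.hidden_layers,
                       learning_rate_init=config.learning_rate,
                       alpha=config.alpha,
                       batch_size=min(config.batch_size, len(X_tr)),
                       solver="adam", random_state=seed)
    _fit_early_stopping(
        net, X_tr, y_tr, X_val, y_val,
        lambda m, Xv, yv: mean_squared_error(yv, m.predict(Xv)),
        config.max_epochs, config.patience)
    return AffinityModel(feat, scaler, net, config, y_mean, y_std)


def train_bbb(X_or_smiles, y: np.ndarray,
              spec: OversampleSpec | None = None,
              config: BBBConfig | None = None,
              seed: int = 0) -> PermeabilityModel:
    """Fit the BBB classifier; oversampling touches the training split only.

    ``X_or_smiles`` is either a fingerprint matrix or a list of SMILES (then
    fingerprinted with the config's bits/radius).  A clean 15% validation
    split is held out before oversampling and drives early stopping.
    """
    config = config or BBBConfig()
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    if len(X_or_smiles) and isinstance(X_or_smiles[0], str):
        X = fingerprints(X_or_smiles, n_bits=config.n_bits,
                         radius=config.radius).astype(np.float64)
    else:
        X = np.asarray(X_or_smiles, dtype=np.float64)
    X_tr, X_val, y_tr, y_val = train_test_split(
        X, y, test_size=config.validation_fraction, random_state=seed,
        stratify=y)
    if spec is not None:
        X_tr, y_tr = oversample(X_tr, y_tr, spec)
    net = MLPClassifier(hidden_layer_sizes=config.hidden_layers,
                        learning_rate_init=config.learning_rate,
                        alpha=config.alpha,
                        batch_size=min(config.batch_size, len(X_tr)),
                        solver="adam", random_state=seed)
    _fit_early_stopping(
        net, X_tr, y_tr, X_val, y_val,
        lambda m, Xv, yv: log_loss(yv, m.predict_proba(Xv)[:, 1], labels=[0, 1]),
        config.max_epochs, config.patience)
    return PermeabilityModel(net, config, spec)


# ------------------------------------------------------------ cross-validation
@dataclass
class CrossValReport:
    """Per-fold metrics, their mean +/- sd, and external-test metrics."""

    per_fold: list[dict[str, float]]
    aggregate: dict[str, tuple[float, float]]
    external: dict[str, float]
    fold_indices: list[np.ndarray] = field(repr=False, default_factory=list)
    n_dev: int = 0
    n_test: int = 0

    def as_dict(self) -> dict:
        return {
            "per_fold": self.per_fold,
            "aggregate": {k: {"mean": m, "sd": s}
                          for k, (m, s) in self.aggregate.items()},
            "external": self.external,
            "n_dev": self.n_dev, "n_test": self.n_test,
        }


def crossvalidate(trainer, X, y, metric_fn, folds: int = 5, seed: int = 0,
                  stratify: bool = False, test_fraction: float = 0.15
                  ) -> CrossValReport:
    """Outer 15% holdout, then k disjoint folds over the development set.

    ``trainer(X_train, y_train, seed) -> predict`` where ``predict(X)``
    returns model outputs suitable for ``metric_fn(y_true, outputs)``.
    """
    X = np.asarray(X) if not isinstance(X, list) else X
    y = np.asarray(y)
    n = len(y)
    if folds > n:
        raise ValueError(f"folds={folds} exceeds dataset size {n}")
    idx = np.arange(n)
    dev_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, random_state=seed,
        stratify=y if stratify else None)

    def take(indices):
        if isinstance(X, list):
            return [X[i] for i in indices], y[indices]
        return X[indices], y[indices]

    splitter = (StratifiedKFold if stratify else KFold)(
        n_splits=folds, shuffle=True, random_state=seed)
    y_dev = y[dev_idx]
    per_fold: list[dict[str, float]] = []
    fold_indices: list[np.ndarray] = []
    split_args = (np.zeros(len(dev_idx)), y_dev) if stratify \
        else (np.zeros(len(dev_idx)),)
    for k, (tr, va) in enumerate(splitter.split(*split_args)):
        X_tr, y_tr = take(dev_idx[tr])
        X_va, y_va = take(dev_idx[va])
        predict = trainer(X_tr, y_tr, seed + 1 + k)
        per_fold.append(metric_fn(y_va, predict(X_va)))
        fold_indices.append(dev_idx[va])

    predict = trainer(*take(dev_idx), seed)
    X_te, y_te = take(test_idx)
    external = metric_fn(y_te, predict(X_te))
    names = per_fold[0].keys()
    aggregate = {
        m: (float(np.mean([f[m] for f in per_fold])),
            float(np.std([f[m] for f in per_fold])))
        for m in names
    }
    return CrossValReport(per_fold, aggregate, external, fold_indices,
                          n_dev=len(dev_idx), n_test=len(test_idx))


def grid_search(trainer_factory, grid: list[dict], X, y, metric_fn,
                select_metric: str, maximize: bool = True, folds: int = 5,
                seed: int = 0, stratify: bool = False):
    """Evaluate a user-supplied hyper-parameter grid by cross-validation.

    ``trainer_factory(params) -> trainer`` as accepted by `crossvalidate`.
    Returns (best_params, best_report, all_reports).
    """
    results = []
    for params in grid:
        report = crossvalidate(trainer_factory(params), X, y, metric_fn,
                               folds=folds, seed=seed, stratify=stratify)
        results.append((params, report))
    key = [
        r.aggregate[select_metric][0] * (1 if maximize else -1)
        for _, r in results
    ]
    best = int(np.argmax(key))
    return results[best][0], results[best][1], results
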