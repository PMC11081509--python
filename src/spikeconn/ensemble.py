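"""Feature assembly, the ensemble classifier (eANN), and Shapley explanations.

The eANN is a small feed-forward network (12 inputs -> 10 -> 10 -> 3, ReLU
hidden units, softmax output) that maps the per-pair score/weight outputs of
the six classical inference methods to class probabilities for
{no connection, excitatory, inhibitory}. Its connectivity score is
``s = max(p_E, p_I)``; its signed weight is defined as ``p_E - p_I``.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import h5py
import numpy as np
from sklearn.neural_network import MLPClassifier

from .spike_trains import InferenceResult
from .simulate import GroundTruthNetwork

__all__ = [
    "FEATURE_COLUMNS", "FeatureTable", "TrainingSet", "EannModel",
    "ShapReport", "assemble_features", "build_training_set", "train_eann",
    "predict_eann", "shap_explain",
]

_METHODS = ("CI", "sCCG", "dSTTC", "GLMCC", "TE", "GLMPP")
FEATURE_COLUMNS = tuple(f"{m}.{k}" for m in _METHODS for k in ("s", "w"))
CLASS_NAMES = ("none", "E", "I")


@dataclass
class FeatureTable:
    """Per-ordered-pair feature matrix in the canonical 12-column order."""

    pairs: list  # [(pre_id, post_id), ...], i-major order
    X: np.ndarray  # (n_pairs, 12)
    unit_ids: list
    columns: tuple = FEATURE_COLUMNS

    @property
    def n_pairs(self) -> int:
        return self.X.shape[0]

    def pair_index(self, i, j) -> int:
        n = len(self.unit_ids)
        a = self.unit_ids.index(str(i))
        b = self.unit_ids.index(str(j))
        if a == b:
            raise KeyError("diagonal pairs are not in the table")
        return a * (n - 1) + (b if b < a else b - 1)


@dataclass
class TrainingSet:
    """Labelled feature rows: 0 = none, 1 = excitatory, 2 = inhibitory."""

    features: np.ndarray
    labels: np.ndarray
    provenance: dict = field(default_factory=dict)


class AssemblyError(ValueError):
    pass


def assemble_features(results: list) -> FeatureTable:
    """Stack six InferenceResults into the canonical 12-column table.

    The column order is fixed (CI.s, CI.w, sCCG.s, ..., GLMPP.w) regardless
    of the order in which results are passed; remaining non-finite entries
    are imputed to the column median.
    """
    by_method = {r.method: r for r in results}
    missing = [m for m in _METHODS if m not in by_method]
    if missing:
        raise AssemblyError(f"missing methods: {missing}")
    unit_ids = list(by_method[_METHODS[0]].unit_ids)
    for m in _METHODS:
        if list(by_method[m].unit_ids) != unit_ids:
            raise AssemblyError(f"unit-order mismatch for {m}")
    n = len(unit_ids)
    pairs = [(unit_ids[i], unit_ids[j])
             for i in range(n) for j in range(n) if i != j]
    off = ~np.eye(n, dtype=bool)
    cols = []
    for m in _METHODS:
        r = by_method[m]
        cols.append(r.S[off])
        cols.append(r.W[off])
    X = np.column_stack(cols)
    for c in range(X.shape[1]):
        bad = ~np.isfinite(X[:, c])
        if bad.any():
            good = X[~bad, c]
            X[bad, c] = np.median(good) if good.size else 0.0
    return FeatureTable(pairs=pairs, X=X, unit_ids=unit_ids)


def build_training_set(features: FeatureTable, gt: GroundTruthNetwork,
                       pos_fraction: float = 0.1,
                       seed: int = 0) -> TrainingSet:
    """All true connections plus randomly sampled unconnected pairs.

    True connections (labelled E/I from the presynaptic type) make up
    ``pos_fraction`` of the rows; negatives are drawn uniformly without
    replacement from the unconnected pairs.
    """
    if not 0 < pos_fraction < 1:
        raise ValueError("pos_fraction must be in (0, 1)")
    n = len(features.unit_ids)
    if gt.n_neurons != n:
        raise ValueError("feature table and ground truth disagree on units")
    off = ~np.eye(n, dtype=bool)
    adj = gt.adjacency[off]  # same i-major pair order as the feature rows
    labels_full = np.zeros(adj.size, dtype=np.int64)
    labels_full[adj > 0] = 1
    labels_full[adj < 0] = 2
    pos_idx = np.flatnonzero(labels_full != 0)
    neg_idx = np.flatnonzero(labels_full == 0)
    n_pos = pos_idx.size
    if n_pos == 0:
        raise ValueError("ground truth has no connections")
    n_total = int(round(n_pos / pos_fraction))
    n_neg = n_total - n_pos
    if n_neg > neg_idx.size:
        raise ValueError(
            f"need {n_neg} negatives but only {neg_idx.size} unconnected "
            f"pairs available")
    rng = np.random.default_rng(seed)
    chosen_neg = rng.choice(neg_idx, size=n_neg, replace=False)
    sel = np.concatenate([pos_idx, chosen_neg])
    return TrainingSet(features=features.X[sel],
                       labels=labels_full[sel],
                       provenance=dict(seed=seed, pos_fraction=pos_fraction,
                                       n_pos=int(n_pos), n_neg=int(n_neg)))


@dataclass
class EannModel:
    """Trained ensemble classifier plus its feature normalization record."""

    clf: MLPClassifier
    norm_center: np.ndarray
    norm_scale: np.ndarray
    classes: np.ndarray
    metadata: dict = field(default_factory=dict)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities (p_none, p_E, p_I) for raw feature rows."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.norm_center):
            raise ValueError(
                f"expected {len(self.norm_center)} features, "
                f"got {X.shape[1]}")
        Z = (X - self.norm_center) / self.norm_scale
        raw = self.clf.predict_proba(Z)
        out = np.zeros((X.shape[0], 3))
        for k, c in enumerate(self.clf.classes_):
            out[:, int(c)] = raw[:, k]
        return out

    @property
    def layer_shapes(self):
        return tuple(w.shape for w in self.clf.coefs_)

    def save(self, path):
        with h5py.File(path, "w") as f:
            f.create_dataset("norm_center", data=self.norm_center)
            f.create_dataset("norm_scale", data=self.norm_scale)
            f.create_dataset("classes", data=self.classes)
            g = f.create_group("weights")
            for k, (w, b) in enumerate(zip(self.clf.coefs_,
                                           self.clf.intercepts_)):
                g.create_dataset(f"W{k}", data=w)
                g.create_dataset(f"b{k}", data=b)
            f.attrs["metadata"] = json.dumps(self.metadata, default=str)
            f.attrs["mlp_classes"] = self.clf.classes_

    @classmethod
    def load(cls, path) -> "EannModel":
        with h5py.File(path, "r") as f:
            center = f["norm_center"][()]
            scale = f["norm_scale"][()]
            classes = f["classes"][()]
            ws, bs = [], []
            k = 0
            while f"W{k}" in f["weights"]:
                ws.append(f["weights"][f"W{k}"][()])
                bs.append(f["weights"][f"b{k}"][()])
                k += 1
            meta = json.loads(f.attrs.get("metadata", "{}"))
            mlp_classes = f.attrs["mlp_classes"]
        clf = MLPClassifier(hidden_layer_sizes=(10, 10), activation="relu")
        # rebuild the fitted state without retraining
        clf.coefs_ = ws
        clf.intercepts_ = bs
        clf.n_layers_ = len(ws) + 1
        clf.n_outputs_ = ws[-1].shape[1]
        clf.classes_ = np.asarray(mlp_classes)
        clf.out_activation_ = "softmax" if clf.n_outputs_ > 1 else "logistic"
        clf._label_binarizer = None
        clf.n_features_in_ = ws[0].shape[0]
        return cls(clf=clf, norm_center=center, norm_scale=scale,
                   classes=classes, metadata=meta)


def train_eann(training_sets, config: dict | None = None,
               seed: int = 0) -> EannModel:
    """Train the 12 -> 10 -> 10 -> 3 classifier on pooled training sets.

    Features are z-normalized with the pooled training statistics (stored in
    the model so that prediction is self-contained); the multinomial
    cross-entropy is minimized with Adam (rate 1e-3, batch 256, up to 500
    epochs, early stopping on a 10% validation split with patience 25).
    """
    if isinstance(training_sets, TrainingSet):
        training_sets = [training_sets]
    if not training_sets:
        raise ValueError("need at least one training set")
    cfg = dict(learning_rate_init=1e-3, batch_size=256, max_epochs=500,
               patience=25, validation_fraction=0.1)
    cfg.update(config or {})
    X = np.vstack([t.features for t in training_sets])
    y = np.concatenate([t.labels for t in training_sets])
    if np.unique(y).size < 2:
        raise ValueError("degenerate single-class training data")
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - center) / scale
    clf = MLPClassifier(
        hidden_layer_sizes=(10, 10), activation="relu", solver="adam",
        learning_rate_init=cfg["learning_rate_init"],
        batch_size=min(cfg["batch_size"], len(y)),
        max_iter=cfg["max_epochs"], early_stopping=True,
        validation_fraction=cfg["validation_fraction"],
        n_iter_no_change=cfg["patience"], random_state=seed)
    clf.fit(Z, y)
    meta = dict(seed=seed, epochs=int(clf.n_iter_),
                loss_curve=[float(v) for v in clf.loss_curve_],
                n_rows=int(len(y)),
                class_counts={int(c): int((y == c).sum())
                              for c in np.unique(y)},
                config=cfg)
    return EannModel(clf=clf, norm_center=center, norm_scale=scale,
                     classes=np.arange(3), metadata=meta)


def predict_eann(model: EannModel, features: FeatureTable):
    """Apply a trained eANN to a feature table.

    Returns ``(probs, InferenceResult)`` where ``probs`` is the
    (n_pairs, 3) class-probability array aligned with ``features.pairs``
    and the result carries ``S = max(p_E, p_I)`` and ``W = p_E - p_I``.
    """
    probs = model.predict_proba(features.X)
    n = len(features.unit_ids)
    S = np.full((n, n), np.nan)
    W = np.full((n, n), np.nan)
    off = np.flatnonzero(~np.eye(n, dtype=bool).ravel())
    S.ravel()[off] = np.maximum(probs[:, 1], probs[:, 2])
    W.ravel()[off] = probs[:, 1] - probs[:, 2]
    res = InferenceResult("eANN", S, W, list(features.unit_ids),
                          params=dict(model_seed=model.metadata.get("seed")))
    return probs, res


# ---------------------------------------------------------------------------
# Shapley explanations
# ---------------------------------------------------------------------------

@dataclass
class ShapReport:
    """Interventional Shapley attribution of one prediction.

    ``base_value + values.sum()`` equals the model output at the explained
    point (local accuracy; exact in exact mode).
    """

    values: np.ndarray
    base_value: float
    model_output: float
    output_class: int
    mode: str
    pair: tuple | None = None


def _as_function(model, output_class: int):
    if isinstance(model, EannModel):
        return lambda X: model.predict_proba(X)[:, output_class]
    if callable(model):
        def f(X):
            out = np.asarray(model(np.asarray(X)))
            if out.ndim == 2:
                return out[:, output_class]
            return out
        return f
    raise TypeError("model must be an EannModel or a callable")


def shap_explain(model, x: np.ndarray, background: np.ndarray,
                 output_class: int = 1, mode: str = "exact",
                 seed: int = 0, n_permutations: int = 2000,
                 pair=None) -> ShapReport:
    """Interventional Shapley values of one feature row.

    The value of a coalition Q is the background-mean model output with the
    features in Q taken from ``x`` and the rest from the background row.
    ``exact`` mode enumerates all 2^d coalitions with Shapley weights;
    ``sampled`` mode is a seeded Monte-Carlo permutation estimate.
    """
    if hasattr(background, "X"):
        background = background.X
    background = np.atleast_2d(np.asarray(background, dtype=np.float64))
    if background.size == 0:
        raise ValueError("background must be non-empty")
    x = np.asarray(x, dtype=np.float64).ravel()
    d = x.size
    if not 0 <= output_class <= 2:
        raise ValueError(f"unknown class index {output_class}")
    f = _as_function(model, output_class)
    nb = background.shape[0]

    if mode == "exact":
        n_coal = 1 << d
        masks = np.arange(n_coal, dtype=np.uint32)
        bits = ((masks[:, None] >> np.arange(d)) & 1).astype(bool)
        # evaluate v(Q) for every coalition
        big = np.empty((n_coal * nb, d))
        for q in range(n_coal):
            z = np.where(bits[q], x, background)
            big[q * nb:(q + 1) * nb] = z
        vals = f(big).reshape(n_coal, nb).mean(axis=1)
        fact = [math.factorial(k) for k in range(d + 1)]
        wsize = np.array([fact[s] * fact[d - s - 1] / fact[d]
                          for s in range(d)])
        pop = bits.sum(axis=1)
        phi = np.zeros(d)
        for k in range(d):
            without = np.flatnonzero(~bits[:, k])
            with_k = without + (1 << k)
            phi[k] = np.sum(wsize[pop[without]]
                            * (vals[with_k] - vals[without]))
        base = float(vals[0])
        fx = float(vals[-1])
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        rows = np.empty((n_permutations * (d + 1), d))
        perms = np.empty((n_permutations, d), dtype=int)
        for p in range(n_permutations):
            perm = rng.permutation(d)
            perms[p] = perm
            b = background[rng.integers(nb)]
            z = b.copy()
            rows[p * (d + 1)] = z
            for step, k in enumerate(perm):
                z = z.copy()
                z[k] = x[k]
                rows[p * (d + 1) + step + 1] = z
        out = f(rows).reshape(n_permutations, d + 1)
        phi = np.zeros(d)
        for p in range(n_permutations):
            contrib = np.diff(out[p])
            phi[perms[p]] += contrib
        phi /= n_permutations
        base = float(out[:, 0].mean())
        fx = float(f(x[None, :])[0])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ShapReport(values=phi, base_value=base, model_output=fx,
                      output_class=output_class, mode=mode, pair=pair)
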