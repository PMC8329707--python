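"""Recurrent sequence classifier for behavior clips.

A single LSTM layer (default 256 units) reads the per-frame feature
columns of a trial in temporal order; its final hidden state passes
through dropout (default 0.2) and a 2-neuron softmax dense layer.  The
softmax probability of the control class — the "output neuron activity"
— is bounded in [0, 1], with 1 meaning the network is certain the trial
is a control animal; 0.5 is the decision threshold.

Training uses Adam on the cross-entropy loss with backpropagation
through time, implemented directly on numpy arrays so training,
prediction, gradients and relevance propagation all share one exactly
reproducible computation.  Evaluation uses grouped k-fold
cross-validation: all trials of one animal (or litter) stay in one
fold, so a predicted animal is never in its own training set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import GroupKFold

from .features import FeatureMatrix

__all__ = [
    "ModelConfig",
    "CVResult",
    "LSTMClassifier",
    "grouped_kfold_split",
    "train_fold",
    "predict",
    "classify",
    "evaluate_cv",
]


@dataclass(frozen=True)
class ModelConfig:
    lstm_units: int = 256
    dropout_rate: float = 0.2
    n_output: int = 2
    batch_size: int = 100
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    loss: str = "binary_crossentropy"
    epochs: int = 30
    seed: int = 0
    standardize: bool = True
    # z-scoring floor: features whose training sd falls below this
    # fraction of the 90th-percentile sd are scaled by the floor instead
    # of their own sd, so near-constant background features are not
    # amplified into unit-variance noise channels
    sigma_floor_frac: float = 0.1
    # training-time temporal-crop augmentation: when > 0, each batch is
    # trained on a random contiguous window of this many frames, forcing
    # time-translation-invariant representations (the cue of interest is
    # *when movements recur*, not at which absolute frame they sit);
    # prediction always uses the full clip
    time_crop_frames: int = 0

    def __post_init__(self) -> None:
        if self.lstm_units < 1:
            raise ValueError("lstm_units must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


@dataclass
class CVResult:
    """Cross-validated predictions: one probability per trial."""

    probabilities: pd.Series  # index: trial_id; value: P(control)
    fold_assignments: pd.Series  # index: trial_id; value: fold index
    predicted_labels: pd.Series
    true_labels: pd.Series
    accuracy: float
    fold_accuracies: list[float]
    group_stats: dict  # label -> {"mean": float, "sem": float, "n": int}
    group_key: str
    control_label: str

    def __post_init__(self) -> None:
        p = self.probabilities.to_numpy()
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    def assert_no_leakage(self, manifest: pd.DataFrame) -> None:
        """Verify no group key is shared between a fold's train and test sets."""
        keys = manifest.set_index("trial_id")[self.group_key]
        for fold in sorted(self.fold_assignments.unique()):
            test_ids = self.fold_assignments.index[self.fold_assignments == fold]
            train_ids = self.fold_assignments.index[self.fold_assignments != fold]
            shared = set(keys.loc[test_ids]) & set(keys.loc[train_ids])
            if shared:
                raise AssertionError(
                    f"fold {fold}: group keys {sorted(shared)} appear in both "
                    "train and test sets"
                )


# ---------------------------------------------------------------------------
# the LSTM model
# ---------------------------------------------------------------------------


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60.0, 60.0)))


class LSTMClassifier:
    """LSTM + dropout + softmax classifier over features x frames matrices.

    ``classes_[1]`` is the control class; ``predict_proba`` returns the
    probability of that class (the output-neuron activity).
    """

    def __init__(self, n_features: int, config: ModelConfig = ModelConfig(),
                 classes: tuple[str, str] = ("mpne", "control")):
        self.config = config
        self.n_features = n_features
        self.classes_ = tuple(classes)
        H, D, C = config.lstm_units, n_features, config.n_output
        rng = np.random.default_rng(config.seed)
        glorot = lambda fan_in, fan_out, shape: rng.uniform(
            -np.sqrt(6.0 / (fan_in + fan_out)), np.sqrt(6.0 / (fan_in + fan_out)), shape
        )
        self.Wx = glorot(D, 4 * H, (D, 4 * H)).astype(np.float32)
        # orthogonal recurrent init, gate blocks independently
        self.Wh = np.concatenate(
            [np.linalg.qr(rng.standard_normal((H, H)))[0] for _ in range(4)], axis=1
        ).astype(np.float32)
        self.b = np.zeros(4 * H, dtype=np.float32)
        self.b[H : 2 * H] = 1.0  # forget-gate bias
        self.Wo = glorot(H, C, (H, C)).astype(np.float32)
        self.bo = np.zeros(C, dtype=np.float32)
        self.mu_ = np.zeros(D, dtype=np.float32)
        self.sigma_ = np.ones(D, dtype=np.float32)
        self.loss_history_: list[float] = []
        self._rng = rng

    # -- parameter plumbing -------------------------------------------------
    def _params(self) -> dict[str, np.ndarray]:
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b, "Wo": self.Wo, "bo": self.bo}

    def save(self, path) -> None:
        np.savez(
            path,
            classes=np.array(self.classes_),
            mu=self.mu_,
            sigma=self.sigma_,
            n_features=self.n_features,
            lstm_units=self.config.lstm_units,
            **self._params(),
        )

    @classmethod
    def load(cls, path, config: ModelConfig | None = None) -> "LSTMClassifier":
        data = np.load(path, allow_pickle=False)
        cfg = config or ModelConfig(lstm_units=int(data["lstm_units"]))
        model = cls(int(data["n_features"]), cfg, classes=tuple(data["classes"]))
        for k in ("Wx", "Wh", "b", "Wo", "bo"):
            setattr(model, k, data[k])
        model.mu_, model.sigma_ = data["mu"], data["sigma"]
        return model

    # -- forward / backward -------------------------------------------------
    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mu_) / self.sigma_

    def forward(self, X: np.ndarray, cache: bool = False, dropout_mask=None):
        """Run the LSTM over X (N, T, D_standardized); returns logits (N, C).

        With ``cache=True`` also returns the per-step gate activations
        needed by backpropagation and relevance propagation.
        """
        N, T, D = X.shape
        H = self.config.lstm_units
        h = np.zeros((N, H), dtype=np.float32)
        c = np.zeros((N, H), dtype=np.float32)
        steps = []
        for t in range(T):
            z = X[:, t] @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_prev, h_prev = c, h
            c = f * c + i * g
            tanh_c = np.tanh(c)
            h = o * tanh_c
            if cache:
                steps.append(
                    {"i": i, "f": f, "g": g, "o": o, "c": c, "tanh_c": tanh_c,
                     "c_prev": c_prev, "h_prev": h_prev}
                )
        h_out = h
        if dropout_mask is not None:
            h_out = h_out * dropout_mask
        logits = h_out @ self.Wo + self.bo
        if cache:
            return logits, {"steps": steps, "h_final": h, "h_out": h_out, "X": X}
        return logits

    def _backward(self, cache, dlogits, dropout_mask=None):
        """BPTT.  Returns (param gradients, dX) for upstream dlogits (N, C)."""
        X = cache["X"]
        N, T, D = X.shape
        H = self.config.lstm_units
        h_out = cache["h_out"]
        grads = {k: np.zeros_like(v) for k, v in self._params().items()}
        grads["Wo"] = h_out.T @ dlogits
        grads["bo"] = dlogits.sum(axis=0)
        dh = dlogits @ self.Wo.T
        if dropout_mask is not None:
            dh = dh * dropout_mask
        dc = np.zeros((N, H), dtype=np.float32)
        dX = np.zeros_like(X)
        for t in range(T - 1, -1, -1):
            s = cache["steps"][t]
            i, f, g, o = s["i"], s["f"], s["g"], s["o"]
            tanh_c = s["tanh_c"]
            dc = dc + dh * o * (1.0 - tanh_c**2)
            do = dh * tanh_c * o * (1.0 - o)
            di = dc * g * i * (1.0 - i)
            df = dc * s["c_prev"] * f * (1.0 - f)
            dg = dc * i * (1.0 - g**2)
            dz = np.concatenate([di, df, dg, do], axis=1)
            grads["Wx"] += X[:, t].T @ dz
            grads["Wh"] += s["h_prev"].T @ dz
            grads["b"] += dz.sum(axis=0)
            dX[:, t] = dz @ self.Wx.T
            dh = dz @ self.Wh.T
            dc = dc * f
        return grads, dX

    def input_gradient(self, X_std: np.ndarray, target_index: int) -> np.ndarray:
        """Gradient of the pre-softmax target logit w.r.t. the (standardized)
        input, for a single trial X_std of shape (T, D)."""
        X = X_std[None].astype(np.float32)
        logits, cache = self.forward(X, cache=True)
        dlogits = np.zeros_like(logits)
        dlogits[0, target_index] = 1.0
        _, dX = self._backward(cache, dlogits)
        return dX[0]

    # -- training -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMClassifier":
        """Train on X (N, T, D) raw feature sequences with labels y in {0, 1}
        (1 = control).  Standardization statistics come from this set only."""
        cfg = self.config
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        if cfg.standardize:
            self.mu_ = X.reshape(-1, X.shape[-1]).mean(axis=0).astype(np.float32)
            sd = X.reshape(-1, X.shape[-1]).std(axis=0).astype(np.float32)
            floor = max(cfg.sigma_floor_frac * float(np.percentile(sd, 90)), 1e-6)
            self.sigma_ = np.maximum(sd, floor)
        Xs = self._standardize(X)
        N = Xs.shape[0]
        H = self.config.lstm_units
        rng = np.random.default_rng(cfg.seed + 1)
        opt_m = {k: np.zeros_like(v) for k, v in self._params().items()}
        opt_v = {k: np.zeros_like(v) for k, v in self._params().items()}
        step = 0
        for _epoch in range(cfg.epochs):
            order = rng.permutation(N)
            epoch_loss = 0.0
            for start in range(0, N, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                xb, yb = Xs[idx], y[idx]
                L = cfg.time_crop_frames
                if 0 < L < xb.shape[1]:
                    off = rng.integers(xb.shape[1] - L + 1)
                    xb = xb[:, off : off + L]
                mask = None
                if cfg.dropout_rate > 0:
                    keep = 1.0 - cfg.dropout_rate
                    mask = (
                        rng.random((len(idx), H)) < keep
                    ).astype(np.float32) / keep
                logits, cache = self.forward(xb, cache=True, dropout_mask=mask)
                probs = _softmax(logits)
                eps = 1e-12
                epoch_loss += -np.log(probs[np.arange(len(idx)), yb] + eps).sum()
                dlogits = (probs - np.eye(2, dtype=np.float32)[yb]) / len(idx)
                grads, _ = self._backward(cache, dlogits, dropout_mask=mask)
                step += 1
                b1, b2, lr = 0.9, 0.999, cfg.learning_rate
                params = self._params()
                for k, gval in grads.items():
                    np.clip(gval, -5.0, 5.0, out=gval)
                    opt_m[k] = b1 * opt_m[k] + (1 - b1) * gval
                    opt_v[k] = b2 * opt_v[k] + (1 - b2) * gval**2
                    mhat = opt_m[k] / (1 - b1**step)
                    vhat = opt_v[k] / (1 - b2**step)
                    params[k] -= (lr * mhat / (np.sqrt(vhat) + 1e-7)).astype(np.float32)
            self.loss_history_.append(epoch_loss / N)
        return self

    # -- inference ----------------------------------------------------------
    @property
    def control_index(self) -> int:
        return 1

    def _as_sequences(self, features) -> np.ndarray:
        if isinstance(features, FeatureMatrix):
            features = [features]
        if isinstance(features, (list, tuple)):
            arrs = []
            for fm in features:
                v = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm)
                if v.shape[0] != self.n_features:
                    raise ValueError(
                        f"feature dimension {v.shape[0]} does not match model "
                        f"n_features {self.n_features}"
                    )
                arrs.append(v.T)  # (T, D)
            return np.stack(arrs).astype(np.float32)
        arr = np.asarray(features, dtype=np.float32)
        if arr.ndim == 2:
            arr = arr[None]
        return arr

    def predict_proba(self, features) -> np.ndarray:
        """P(control) for each trial — the output-neuron activity in [0, 1]."""
        X = self._as_sequences(features)
        logits = self.forward(self._standardize(X))
        return _softmax(logits)[:, self.control_index]


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def grouped_kfold_split(
    manifest: pd.DataFrame, k: int = 5, group_key: str = "animal_id", seed: int = 0
) -> pd.Series:
    """Assign each trial to one of ``k`` folds, keeping all trials that
    share a group key in the same fold.  Returns fold index per trial_id."""
    groups = manifest[group_key].to_numpy()
    n_groups = len(np.unique(groups))
    if n_groups < k:
        raise ValueError(
            f"grouped {k}-fold split needs >= {k} distinct {group_key} values, "
            f"got {n_groups}"
        )
    splitter = GroupKFold(n_splits=k, shuffle=True, random_state=seed)
    fold = np.empty(len(manifest), dtype=int)
    for f, (_, test_idx) in enumerate(
        splitter.split(np.zeros(len(manifest)), groups=groups)
    ):
        fold[test_idx] = f
    return pd.Series(fold, index=manifest["trial_id"].to_numpy(), name="fold")


def train_fold(
    features: list[FeatureMatrix],
    labels,
    config: ModelConfig = ModelConfig(),
    classes: tuple[str, str] | None = None,
) -> LSTMClassifier:
    """Train one model on a training fold.

    ``labels`` are class-name strings; ``classes`` orders them as
    (treated, control) — by default the sorted unique labels with
    "control" placed last if present.
    """
    labels = np.asarray(labels)
    uniq = sorted(set(labels))
    if len(uniq) != 2:
        raise ValueError(f"training labels must contain exactly 2 classes, got {uniq}")
    if classes is None:
        if "control" in uniq:
            uniq.remove("control")
            classes = (uniq[0], "control")
        else:
            classes = tuple(uniq)
    y = (labels == classes[1]).astype(int)
    n_features = features[0].n_features
    model = LSTMClassifier(n_features, config, classes=classes)
    X = model._as_sequences(list(features))
    model.fit(X, y)
    return model


def predict(model: LSTMClassifier, features) -> float | np.ndarray:
    """Output-neuron activity: P(control) in [0, 1]."""
    p = model.predict_proba(features)
    return float(p[0]) if p.shape[0] == 1 and isinstance(features, FeatureMatrix) else p


def classify(probability: float, threshold: float = 0.5,
             classes: tuple[str, str] = ("mpne", "control")) -> str:
    """Threshold the output-neuron activity: >= threshold -> control.

    The paper-style rule is strict above/below; exactly at the boundary
    we assign control (>= rule), a measure-zero tie-break.
    """
    if not 0.0 <= probability <= 1.0:
        raise ValueError("probability must lie in [0, 1]")
    return classes[1] if probability >= threshold else classes[0]


def evaluate_cv(
    manifest: pd.DataFrame,
    features: dict[str, FeatureMatrix],
    config: ModelConfig = ModelConfig(),
    k: int = 5,
    group_key: str = "animal_id",
    control_label: str = "control",
    fold_assignments: pd.Series | None = None,
) -> CVResult:
    """Grouped k-fold cross-validation of the sequence classifier.

    Every trial is predicted exactly once, by the model trained on the
    folds that do not contain its group.  Accuracy is the fraction of
    correctly classified trials pooled over folds; per-group mean ± SEM
    of the output-neuron activity is also reported.
    """
    if fold_assignments is None:
        fold_assignments = grouped_kfold_split(manifest, k=k, group_key=group_key,
                                               seed=config.seed)
    trial_ids = manifest["trial_id"].to_numpy()
    labels = pd.Series(manifest["group"].to_numpy(), index=trial_ids)
    other = sorted(set(labels) - {control_label})
    classes = (other[0], control_label)

    probs = pd.Series(np.nan, index=trial_ids, dtype=float)
    fold_accs = []
    for fold in sorted(fold_assignments.unique()):
        test_ids = fold_assignments.index[fold_assignments == fold]
        train_ids = fold_assignments.index[fold_assignments != fold]
        model = train_fold(
            [features[t] for t in train_ids], labels.loc[train_ids].to_numpy(),
            config=config, classes=classes,
        )
        p = model.predict_proba([features[t] for t in test_ids])
        probs.loc[test_ids] = p
        pred = np.array([classify(pi, classes=classes) for pi in p])
        fold_accs.append(float(np.mean(pred == labels.loc[test_ids].to_numpy())))

    predicted = pd.Series(
        [classify(p, classes=classes) for p in probs.to_numpy()], index=trial_ids
    )
    accuracy = float(np.mean(predicted.to_numpy() == labels.to_numpy()))
    group_stats = {}
    for gname in sorted(set(labels)):
        vals = probs[labels == gname].to_numpy()
        group_stats[gname] = {
            "mean": float(vals.mean()),
            "sem": float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0,
            "n": int(len(vals)),
        }
    result = CVResult(
        probabilities=probs,
        fold_assignments=fold_assignments,
        predicted_labels=predicted,
        true_labels=labels,
        accuracy=accuracy,
        fold_accuracies=fold_accs,
        group_stats=group_stats,
        group_key=group_key,
        control_label=control_label,
    )
    result.assert_no_leakage(manifest)
    return result
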