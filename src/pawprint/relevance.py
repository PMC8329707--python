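"""Knowledge extraction: layer-wise relevance propagation (LRP).

LRP decomposes a trained network's pre-softmax output score for one
class into additive per-input relevances, by recursively redistributing
the score backward through the layers in proportion to each input's
contribution (activation x weight) to every neuron it feeds, with an
epsilon stabilizer in each denominator.  For the LSTM the established
recurrent convention is used: at multiplicative gate interactions all
relevance is routed to the signal path (cell input / cell state) and
none to the gate activations; the linear maps inside each gate then use
the epsilon rule.  A gradient x input fallback is provided and agrees
with LRP exactly on purely linear models.

Aggregating the relevance matrix column-wise gives a per-frame
importance curve — the object in which initial-posture and periodic
stereotypy signatures show up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import LSTMClassifier
from .features import FeatureMatrix, PatchFeatureBackend

__all__ = [
    "RelevanceMatrix",
    "FrameImportance",
    "GroupImportance",
    "DenseNet",
    "lrp_explain",
    "gradient_explain",
    "frame_importance",
    "group_average_importance",
    "pixel_relevance",
]


@dataclass
class RelevanceMatrix:
    """Signed features x frames importance array for one trial."""

    values: np.ndarray  # (n_features, n_frames)
    target_class: str | int
    method: str  # "lrp-epsilon" | "gradient_input"
    stabilizer_epsilon: float = 0.0
    trial_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("relevance values must be 2-D (n_features, n_frames)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("relevance values must be finite")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class FrameImportance:
    """One non-negative (under magnitude aggregation) value per frame."""

    values: np.ndarray
    aggregation: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("frame importance must be a 1-D vector")
        if self.aggregation in ("abs_sum", "positive_sum") and np.any(self.values < -1e-12):
            raise ValueError("magnitude aggregation must be non-negative")


@dataclass
class GroupImportance:
    """Per-group mean importance curves ± SEM plus their difference."""

    groups: dict  # label -> {"mean": (T,), "sem": (T,), "n": int}
    difference: np.ndarray  # mean(first label) - mean(second label), sorted labels

    @property
    def labels(self) -> list[str]:
        return sorted(self.groups)


# ---------------------------------------------------------------------------
# toy dense network (oracle model for closed-form and conservation checks)
# ---------------------------------------------------------------------------


class DenseNet:
    """Small fully-connected scorer over flattened feature matrices.

    ``weights`` is a list of (fan_in, fan_out) arrays; hidden layers use
    ReLU, the final layer is linear with one column per class.  Used as
    the oracle model for closed-form LRP checks (a single linear layer
    has the exact decomposition w_i * x_i) and conservation tests.
    """

    def __init__(self, weights: list[np.ndarray], biases: list[np.ndarray] | None = None):
        self.weights = [np.asarray(w, dtype=np.float64) for w in weights]
        self.biases = (
            [np.asarray(b, dtype=np.float64) for b in biases]
            if biases is not None
            else [np.zeros(w.shape[1]) for w in self.weights]
        )

    def activations(self, x: np.ndarray) -> list[np.ndarray]:
        a = [np.asarray(x, dtype=np.float64).ravel()]
        for li, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a[-1] @ W + b
            if li < len(self.weights) - 1:
                z = np.maximum(z, 0.0)
            a.append(z)
        return a

    def score(self, x: np.ndarray, target_index: int) -> float:
        return float(self.activations(x)[-1][target_index])

    def lrp(self, x: np.ndarray, target_index: int, epsilon: float) -> np.ndarray:
        acts = self.activations(x)
        R = np.zeros_like(acts[-1])
        R[target_index] = acts[-1][target_index]
        for li in range(len(self.weights) - 1, -1, -1):
            a, W, b = acts[li], self.weights[li], self.biases[li]
            z = a @ W + b
            denom = z + epsilon * np.where(z >= 0, 1.0, -1.0)
            R = (a[:, None] * W) @ (R / denom)
        return R

    def gradient(self, x: np.ndarray, target_index: int) -> np.ndarray:
        acts = self.activations(x)
        grad = np.zeros_like(acts[-1])
        grad[target_index] = 1.0
        for li in range(len(self.weights) - 1, -1, -1):
            if li < len(self.weights) - 1:
                grad = grad * (acts[li + 1] > 0)
            grad = self.weights[li] @ grad
        return grad


# ---------------------------------------------------------------------------
# explanation operations
# ---------------------------------------------------------------------------


def _target_index(model, target_class) -> int:
    if isinstance(target_class, (int, np.integer)):
        return int(target_class)
    if isinstance(model, LSTMClassifier) and target_class in model.classes_:
        return model.classes_.index(target_class)
    if target_class == "control":
        return 1
    raise ValueError(f"unknown target class {target_class!r}")


def _trial_input(model, features) -> tuple[np.ndarray, str]:
    fm = features
    if isinstance(fm, FeatureMatrix):
        values, trial_id = fm.values, fm.trial_id
    else:
        values, trial_id = np.asarray(fm, dtype=np.float64), ""
    if isinstance(model, LSTMClassifier) and values.shape[0] != model.n_features:
        raise ValueError(
            f"feature dimension {values.shape[0]} does not match model "
            f"n_features {model.n_features}"
        )
    return values, trial_id


def lrp_explain(
    model, features, target_class="control", epsilon: float = 1e-6
) -> RelevanceMatrix:
    """Epsilon-LRP of the target class's pre-softmax score down to every
    feature x frame cell.

    Supported models: :class:`LSTMClassifier` (recurrent signal-take-all
    rule) and :class:`DenseNet` (plain epsilon rule).  The summed input
    relevance matches the propagated score up to the epsilon leak and
    the share absorbed by bias terms and the initial recurrent state.
    """
    values, trial_id = _trial_input(model, features)
    tc = _target_index(model, target_class)

    if isinstance(model, DenseNet):
        R = model.lrp(values.ravel(), tc, epsilon).reshape(values.shape)
        return RelevanceMatrix(R, target_class, "lrp-epsilon", epsilon, trial_id)

    if not isinstance(model, LSTMClassifier):
        raise TypeError(
            f"unsupported model type {type(model).__name__}: lrp_explain supports "
            "LSTMClassifier (LSTM + dropout + dense softmax) and DenseNet "
            "(dense ReLU stacks)"
        )

    X = model._standardize(values.T[None].astype(np.float32))
    logits, cache = model.forward(X, cache=True)
    H = model.config.lstm_units
    steps = cache["steps"]
    T = len(steps)

    def stab(z):
        return z + epsilon * np.where(z >= 0, 1.0, -1.0)

    # dense output layer: epsilon rule from the target logit to h_T
    score = float(logits[0, tc])
    h_T = cache["h_final"][0].astype(np.float64)
    w_out = model.Wo[:, tc].astype(np.float64)
    Rh = (h_T * w_out) * (score / stab(score))

    Wx = model.Wx.astype(np.float64)
    Wh = model.Wh.astype(np.float64)
    Wxg, Whg = Wx[:, 2 * H : 3 * H], Wh[:, 2 * H : 3 * H]

    Rx = np.zeros((T, values.shape[0]))
    Rc = np.zeros(H)
    for t in range(T - 1, -1, -1):
        s = steps[t]
        i = s["i"][0].astype(np.float64)
        f = s["f"][0].astype(np.float64)
        g = s["g"][0].astype(np.float64)
        c = s["c"][0].astype(np.float64)
        c_prev = s["c_prev"][0].astype(np.float64)
        h_prev = s["h_prev"][0].astype(np.float64)
        x_t = X[0, t].astype(np.float64)

        # h_t = o_t * tanh(c_t): signal-take-all -> all relevance to c_t
        Rc = Rc + Rh
        # c_t = f*c_prev + i*g: split by contribution
        denom = stab(c)
        Rg = (i * g / denom) * Rc
        Rc = (f * c_prev / denom) * Rc
        # g_t = tanh(Wxg x_t + Whg h_prev + b): epsilon rule on the linear map
        a = x_t @ Wxg + h_prev @ Whg + model.b[2 * H : 3 * H].astype(np.float64)
        share = Rg / stab(a)
        Rx[t] = (x_t[:, None] * Wxg) @ share
        Rh = (h_prev[:, None] * Whg) @ share

    return RelevanceMatrix(Rx.T, target_class, "lrp-epsilon", epsilon, trial_id)


def gradient_explain(model, features, target_class="control") -> RelevanceMatrix:
    """Gradient x input attribution of the target's pre-softmax score."""
    values, trial_id = _trial_input(model, features)
    tc = _target_index(model, target_class)
    if isinstance(model, DenseNet):
        R = (model.gradient(values.ravel(), tc) * values.ravel()).reshape(values.shape)
        return RelevanceMatrix(R, target_class, "gradient_input", 0.0, trial_id)
    if not isinstance(model, LSTMClassifier):
        raise TypeError(f"unsupported model type {type(model).__name__}")
    X_std = model._standardize(values.T.astype(np.float32))
    grad = model.input_gradient(X_std, tc)  # (T, D)
    R = (grad.astype(np.float64) * X_std.astype(np.float64)).T
    return RelevanceMatrix(R, target_class, "gradient_input", 0.0, trial_id)


_AGG_RULES = {
    "abs_sum": lambda v: np.abs(v).sum(axis=0),
    "signed_sum": lambda v: v.sum(axis=0),
    "positive_sum": lambda v: np.clip(v, 0.0, None).sum(axis=0),
}


def frame_importance(relevance: RelevanceMatrix, rule: str = "abs_sum") -> FrameImportance:
    """Collapse the relevance matrix to one importance value per frame."""
    if rule not in _AGG_RULES:
        raise ValueError(f"unknown aggregation rule {rule!r}; options: {sorted(_AGG_RULES)}")
    return FrameImportance(values=_AGG_RULES[rule](relevance.values), aggregation=rule)


def group_average_importance(importances, labels) -> GroupImportance:
    """Mean ± SEM importance curve per group, plus the between-group
    difference curve (first minus second label in sorted order)."""
    curves = [
        imp.values if isinstance(imp, FrameImportance) else np.asarray(imp, dtype=float)
        for imp in importances
    ]
    labels = list(labels)
    if len(curves) != len(labels):
        raise ValueError("importances and labels must have the same length")
    lengths = {len(c) for c in curves}
    if len(lengths) != 1:
        raise ValueError(f"importance curves have mismatched lengths {sorted(lengths)}")
    groups = {}
    for g in sorted(set(labels)):
        arr = np.stack([c for c, l in zip(curves, labels) if l == g])
        sem = (
            arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
            if arr.shape[0] > 1
            else np.zeros(arr.shape[1])
        )
        groups[g] = {"mean": arr.mean(axis=0), "sem": sem, "n": arr.shape[0]}
    names = sorted(groups)
    if len(names) != 2:
        raise ValueError("group_average_importance expects exactly 2 groups")
    diff = groups[names[0]]["mean"] - groups[names[1]]["mean"]
    return GroupImportance(groups=groups, difference=diff)


def peak_frames(
    importance, top_fraction: float = 0.1, baseline_window: int = 9
) -> np.ndarray:
    """Frames whose importance stands out above the curve's slow baseline.

    Importance curves from recurrent models ride on a slow drift (memory
    of a frame fades with distance to the decision), so peaks are ranked
    after subtracting a running-median baseline; the window only needs
    to exceed the peak width while staying below the drift scale.
    Returns the top ``ceil(top_fraction * n)`` frame indices, sorted.
    """
    from scipy.signal import medfilt

    values = importance.values if isinstance(importance, FrameImportance) else np.asarray(importance, dtype=float)
    if baseline_window % 2 == 0:
        raise ValueError("baseline_window must be odd")
    corrected = values - medfilt(values, baseline_window)
    k = int(np.ceil(top_fraction * len(values)))
    return np.sort(np.argsort(corrected)[-k:])


def pixel_relevance(backbone, frame: np.ndarray, feature_relevance_column: np.ndarray) -> np.ndarray:
    """Propagate one frame's feature relevances down to pixels.

    For the patch backend the mapping is exact: each feature's relevance
    is spread uniformly over its patch.  (A differentiable pretrained
    backbone would instead use gradient x input of the relevance-weighted
    feature sum; no such backbone is available offline.)
    """
    rel = np.asarray(feature_relevance_column, dtype=np.float64)
    if isinstance(backbone, PatchFeatureBackend):
        if rel.shape[0] != backbone.spec.n_features:
            raise ValueError("relevance column length does not match backend features")
        heat = np.zeros(frame.shape[:2], dtype=np.float64)
        for fi in np.nonzero(rel)[0]:
            mask = backbone.patch_mask(int(fi), frame.shape[:2])
            heat[mask] += rel[fi] / mask.sum()
        return heat
    raise RuntimeError(
        "pixel relevance requires a differentiable backbone or the patch "
        "backend; got " + type(backbone).__name__
    )
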