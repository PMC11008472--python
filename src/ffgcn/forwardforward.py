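"""Forward-forward training for a dense classifier stack.

Instead of backpropagating errors, each dense layer is trained by two
forward passes: a *positive* pass on real samples carrying their true
label (embedded one-hot in the first C feature slots) whose "goodness"
— the sum of squared unit activities — is pushed above a threshold
theta, and a *negative* pass on corrupted samples (wrong-label
embeddings and/or mask-blended feature hybrids) whose goodness is
pushed below theta.  Between layers only the orientation of the
activity vector is transmitted (length normalized away), so every layer
must find its own evidence.  Inference embeds each candidate label in
turn and picks the one with the largest accumulated goodness.

Two trainer paths exist: the default minimizes the softplus contrastive
loss with an adaptive-moment optimizer; the alternative applies the
literal per-neuron manual update rule ``dw_j = 2 eps d(log p)/dS y_j x``
with an optional goodness-target-steered rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, log_expit

from ._optim import Adam

__all__ = [
    "FFLayer",
    "LabeledSample",
    "GoodnessReport",
    "BinaryMask",
    "layer_forward",
    "goodness",
    "positive_probability",
    "layer_loss",
    "normalize_activity",
    "generate_mask",
    "make_positive",
    "make_negative",
    "adaptive_rate",
    "ff_manual_update",
    "train_ff_layer",
    "FFConfig",
    "ForwardForwardClassifier",
]


@dataclass
class FFLayer:
    """One dense layer under forward-forward training.

    weights: (n_in, n_out); bias: (n_out,); threshold: the goodness
    threshold theta > 0; epsilon: step size of the manual update rule;
    target_goodness: optional S* steering the manual rule's rate.
    """

    weights: np.ndarray
    bias: np.ndarray
    threshold: float = 2.0
    epsilon: float = 0.01
    target_goodness: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.weights.ndim != 2 or self.bias.shape != (self.weights.shape[1],):
            raise ValueError("weights must be (n_in, n_out) with matching bias")
        if not (np.all(np.isfinite(self.weights)) and np.all(np.isfinite(self.bias))):
            raise ValueError("non-finite layer parameters")
        if self.threshold <= 0:
            raise ValueError("goodness threshold theta must be positive")


@dataclass
class LabeledSample:
    """Feature vector whose first C slots hold an embedded one-hot label."""

    features: np.ndarray
    polarity: str  # "positive" | "negative"
    true_label: int
    n_classes: int

    @property
    def embedded_label(self) -> int:
        return int(np.argmax(self.features[: self.n_classes]))


@dataclass
class GoodnessReport:
    """Per-label accumulated goodness from label-probe inference."""

    per_layer_goodness: np.ndarray  # (n_labels, n_layers)
    scores: np.ndarray  # (n_labels,) accumulated over scored layers
    probabilities: np.ndarray  # (n_labels, n_layers) logistic link per layer


@dataclass
class BinaryMask:
    """0/1 mask with large constant regions (for hybrid negative samples)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if not np.isin(m, (0, 1)).all():
            raise ValueError("mask entries must be exactly 0 or 1")
        self.mask = m.astype(float)

    @property
    def mean_run_length(self) -> float:
        m = self.mask
        if m.size == 0:
            return 0.0
        n_runs = 1 + int(np.count_nonzero(np.diff(m)))
        return m.size / n_runs


# ------------------------------------------------------------- primitives

def layer_forward(layer: FFLayer, x: np.ndarray) -> np.ndarray:
    """Rectified affine map ``h = relu(W^T x + b)``; x is (n_in,) or (B, n_in)."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != layer.weights.shape[0]:
        raise ValueError(f"input width {x.shape[-1]} != layer fan-in "
                         f"{layer.weights.shape[0]}")
    return np.maximum(x @ layer.weights + layer.bias, 0.0)


def goodness(h: np.ndarray) -> np.ndarray | float:
    """Sum of squared activities per sample (the layer's goodness S_L)."""
    h = np.asarray(h, dtype=float)
    s = np.sum(h * h, axis=-1)
    return float(s) if s.ndim == 0 else s


def positive_probability(S_L, theta: float):
    """Logistic link ``p(positive) = sigma(S_L - theta)``."""
    return expit(np.asarray(S_L, dtype=float) - theta)


def layer_loss(S_P: np.ndarray, S_N: np.ndarray, theta: float) -> float:
    """Contrastive softplus loss pushing S_P above and S_N below theta.

    ``mean(softplus(theta - S_P) + softplus(S_N - theta))`` with the
    overflow-safe softplus ``log(1 + e^z) = -log_sigmoid(-z)``.
    """
    S_P = np.atleast_1d(np.asarray(S_P, dtype=float))
    S_N = np.atleast_1d(np.asarray(S_N, dtype=float))
    if S_P.size == 0 or S_N.size == 0:
        raise ValueError("empty goodness batch")
    if S_P.shape != S_N.shape:
        raise ValueError("positive and negative batches must have equal length")
    return float(np.mean(-log_expit(-(theta - S_P)) - log_expit(-(S_N - theta))))


def normalize_activity(h: np.ndarray) -> np.ndarray:
    """Unit-length activity: orientation kept, magnitude discarded.

    Near-zero vectors (norm below 1e-12) come back as zeros, with a
    warning, rather than dividing by zero.
    """
    h = np.asarray(h, dtype=float)
    norm = np.linalg.norm(h, axis=-1, keepdims=True)
    tiny = norm < 1e-12
    if np.any(tiny):
        warnings.warn("zero-norm activity vector; returning zeros",
                      RuntimeWarning, stacklevel=2)
    safe = np.where(tiny, 1.0, norm)
    out = h / safe
    return np.where(tiny, 0.0, out)


# ---------------------------------------------------- negative-data machinery

def generate_mask(length: int, smoothing_passes: int = 4,
                  seed: int | np.random.Generator = 0) -> BinaryMask:
    """Binary mask with large constant regions.

    Starts from i.i.d. fair bits and repeatedly blurs with the
    [1/4, 1/2, 1/4] neighbor-averaging kernel (edges replicated), then
    thresholds at 0.5.  More smoothing passes give longer constant runs;
    zero passes leave i.i.d. bits (mean run length 2 in expectation).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = rng.integers(0, 2, size=length).astype(float)
    for _ in range(smoothing_passes):
        padded = np.concatenate([v[:1], v, v[-1:]])
        v = 0.25 * padded[:-2] + 0.5 * padded[1:-1] + 0.25 * padded[2:]
    return BinaryMask((v >= 0.5).astype(float))


def make_positive(feature_vector: np.ndarray, label: int, C: int) -> LabeledSample:
    """Embed the true one-hot label into the first C slots (positive sample)."""
    f = np.asarray(feature_vector, dtype=float).copy()
    if f.shape[-1] < C:
        raise ValueError("feature vector shorter than the label prefix C")
    if not 0 <= label < C:
        raise ValueError(f"label {label} outside 0..{C - 1}")
    f[:C] = 0.0
    f[label] = 1.0
    return LabeledSample(f, "positive", label, C)


def make_negative(feature_a: np.ndarray, feature_b: np.ndarray,
                  labels: tuple[int, int], C: int, mode: str = "wrong_label",
                  mask: BinaryMask | None = None,
                  rng: int | np.random.Generator = 0) -> LabeledSample:
    """Corrupted sample: wrong-label embedding and/or masked feature hybrid.

    wrong_label: feature_a's payload with a uniformly drawn incorrect
    one-hot prefix.  mask_hybrid: payload ``mask*a + (1-mask)*b`` (over
    the slots past the prefix) with a label drawn to match neither
    source when possible.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    a = np.asarray(feature_a, dtype=float).copy()
    b = np.asarray(feature_b, dtype=float)
    la, lb = labels
    if mode not in ("wrong_label", "mask_hybrid"):
        raise ValueError("mode must be 'wrong_label' or 'mask_hybrid'")
    if mode == "wrong_label":
        if C < 2:
            raise ValueError("wrong_label mode needs at least 2 classes")
        candidates = [c for c in range(C) if c != la]
        wrong = int(rng.choice(candidates))
        a[:C] = 0.0
        a[wrong] = 1.0
        return LabeledSample(a, "negative", la, C)
    if a.shape != b.shape:
        raise ValueError("hybrid sources must have equal shape")
    payload_len = a.shape[-1] - C
    if mask is None:
        mask = generate_mask(payload_len, seed=rng)
    if mask.mask.shape[-1] != payload_len:
        raise ValueError("mask length must equal the payload length")
    hybrid = a.copy()
    hybrid[C:] = mask.mask * a[C:] + (1.0 - mask.mask) * b[C:]
    candidates = [c for c in range(C) if c not in (la, lb)] or \
        [c for c in range(C) if c != la]
    lab = int(rng.choice(candidates)) if candidates else la
    hybrid[:C] = 0.0
    hybrid[lab] = 1.0
    return LabeledSample(hybrid, "negative", la, C)


# ----------------------------------------------------------- manual FF update

def adaptive_rate(S_L: float, S_star: float) -> float:
    """Target-steered rate ``alpha = (S* - S_L)/S_L``: zero at target,
    positive below it, negative above it."""
    if S_L <= 0:
        raise ValueError("goodness must be positive to define the rate")
    return (S_star - S_L) / S_L


def ff_manual_update(layer: FFLayer, x: np.ndarray, polarity: str,
                     epsilon: float | None = None) -> FFLayer:
    """One literal per-neuron update ``dw_j = 2 eps d(log p)/dS y_j x``.

    With the logistic link, ``d(log p)/dS = 1 - p`` for a positive
    sample; for a negative sample the sign flips and the magnitude is
    ``p`` (pushing goodness down).  The bias follows the same rule with
    a constant unit input.  When ``target_goodness`` is set, the
    positive-sample step is additionally scaled by the Eq-style rate
    ``(S* - S_L)/S_L`` so updates vanish at the target.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("manual rule operates on a single sample vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("stale/non-finite input state")
    eps = layer.epsilon if epsilon is None else epsilon
    y = layer_forward(layer, x)
    s = goodness(y)
    p = positive_probability(s, layer.threshold)
    if polarity == "positive":
        coef = 2.0 * eps * (1.0 - p)
        if layer.target_goodness is not None and s > 0:
            coef *= adaptive_rate(s, layer.target_goodness)
    elif polarity == "negative":
        coef = -2.0 * eps * p
    else:
        raise ValueError("polarity must be 'positive' or 'negative'")
    dw = coef * np.outer(x, y)
    db = coef * y
    return replace(layer, weights=layer.weights + dw, bias=layer.bias + db)


# ------------------------------------------------------------- layer training

@dataclass
class FFConfig:
    """Training schedule for the forward-forward stack."""

    epochs: int = 100
    batch_size: int = 64  # split evenly between positives and negatives
    learning_rate: float = 0.03
    tol: float = 1e-4
    patience: int = 10
    trainer: str = "gradient"  # or "manual"
    negative_mode: str = "both"  # wrong_label | mask_hybrid | both
    theta: float = 2.0
    mask_smoothing: int = 4
    seed: int = 0


def _ff_layer_grads(layer: FFLayer, xp: np.ndarray, xn: np.ndarray):
    """Analytic gradient of the contrastive loss w.r.t. weights and bias."""
    hp = layer_forward(layer, xp)
    hn = layer_forward(layer, xn)
    sp, sn = goodness(hp), goodness(hn)
    B = xp.shape[0]
    # d loss / dS_P = -(1 - p_P)/B ; d loss / dS_N = p_N / B
    cp = -(1.0 - positive_probability(sp, layer.threshold)) / B
    cn = positive_probability(sn, layer.threshold) / B
    gp = (cp[:, None] * 2.0 * hp) * (hp > 0)
    gn = (cn[:, None] * 2.0 * hn) * (hn > 0)
    dW = xp.T @ gp + xn.T @ gn
    db = gp.sum(axis=0) + gn.sum(axis=0)
    loss = layer_loss(sp, sn, layer.threshold)
    return dW, db, loss


def train_ff_layer(layer: FFLayer, positives: np.ndarray, negatives: np.ndarray,
                   config: FFConfig | None = None) -> tuple[FFLayer, list[float]]:
    """Train one layer to saturation on positive/negative inputs.

    Default path: adaptive-moment descent on the contrastive softplus
    loss.  Manual path (``config.trainer='manual'``): per-sample literal
    updates.  Stops at ``epochs`` or when relative loss improvement
    stays below ``tol`` for ``patience`` consecutive epochs.
    """
    cfg = config or FFConfig()
    positives = np.atleast_2d(np.asarray(positives, dtype=float))
    negatives = np.atleast_2d(np.asarray(negatives, dtype=float))
    if positives.size == 0 or negatives.size == 0:
        raise ValueError("need nonempty positive and negative batches")
    if np.allclose(positives, positives[0]) and np.allclose(negatives, negatives[0]) \
            and np.allclose(positives[0], negatives[0]):
        warnings.warn("positives and negatives are identical; the layer "
                      "cannot separate them", RuntimeWarning, stacklevel=2)
    rng = np.random.default_rng(cfg.seed)
    params = {"w": layer.weights.copy(), "b": layer.bias.copy()}
    work = replace(layer, weights=params["w"], bias=params["b"])
    opt = Adam(lr=cfg.learning_rate)
    half = max(cfg.batch_size // 2, 1)
    trace: list[float] = []
    stale = 0
    for _ in range(cfg.epochs):
        pi = rng.permutation(positives.shape[0])
        ni = rng.permutation(negatives.shape[0])
        ep = 0.0
        nb = 0
        for start in range(0, min(pi.size, ni.size), half):
            xp = positives[pi[start:start + half]]
            xn = negatives[ni[start:start + half]]
            m = min(xp.shape[0], xn.shape[0])
            if m == 0:
                break
            xp, xn = xp[:m], xn[:m]
            if cfg.trainer == "manual":
                for row in xp:
                    work = ff_manual_update(work, row, "positive")
                for row in xn:
                    work = ff_manual_update(work, row, "negative")
                ep += layer_loss(goodness(layer_forward(work, xp)),
                                 goodness(layer_forward(work, xn)), work.threshold)
            else:
                work = replace(work, weights=params["w"], bias=params["b"])
                dW, db, loss = _ff_layer_grads(work, xp, xn)
                opt.step(params, {"w": dW, "b": db})
                ep += loss
            nb += 1
        trace.append(ep / max(nb, 1))
        if len(trace) > 1:
            rel = (trace[-2] - trace[-1]) / max(abs(trace[-2]), 1e-12)
            stale = stale + 1 if rel < cfg.tol else 0
            if stale >= cfg.patience:
                break
    if cfg.trainer == "manual":
        final = work
    else:
        final = replace(layer, weights=params["w"], bias=params["b"])
    return final, trace


# ------------------------------------------------------------------ the stack

class ForwardForwardClassifier:
    """Dense stack trained layer-wise by the forward-forward mechanism.

    scikit-learn style: ``fit(F, y)`` on feature vectors (the label gets
    embedded into the first ``n_classes`` slots internally), then
    ``predict`` probes every candidate label and returns the one with
    the highest goodness accumulated over the scored layers (all but
    the first by default, since the label prefix trivially drives the
    first layer's goodness).  Ties break toward the lowest label index.

    widths are the layer output sizes, e.g. (512, 256, 256, 4).
    """

    def __init__(self, widths: tuple[int, ...] = (512, 256, 256, 4),
                 n_classes: int = 4, theta: float = 2.0, epochs: int = 100,
                 batch_size: int = 64, learning_rate: float = 0.03,
                 negative_mode: str = "both", trainer: str = "gradient",
                 label_scale: float = 1.0, exclude_first_layer: bool = True,
                 mask_smoothing: int = 4, seed: int = 0) -> None:
        self.widths = tuple(widths)
        self.n_classes = n_classes
        self.theta = theta
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.negative_mode = negative_mode
        self.trainer = trainer
        self.label_scale = label_scale
        self.exclude_first_layer = exclude_first_layer
        self.mask_smoothing = mask_smoothing
        self.seed = seed

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "widths", "n_classes", "theta", "epochs", "batch_size",
            "learning_rate", "negative_mode", "trainer", "label_scale",
            "exclude_first_layer", "mask_smoothing", "seed")}

    def set_params(self, **kw) -> "ForwardForwardClassifier":
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- sample synthesis
    def _embed(self, F: np.ndarray, labels: np.ndarray) -> np.ndarray:
        out = F.copy()
        out[:, : self.n_classes] = 0.0
        out[np.arange(F.shape[0]), labels] = self.label_scale
        return out

    def _negatives(self, F: np.ndarray, y: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
        n, C = F.shape[0], self.n_classes
        rows = []
        for i in range(n):
            mode = self.negative_mode
            if mode == "both":
                mode = "wrong_label" if rng.random() < 0.5 else "mask_hybrid"
            j = int(rng.integers(n - 1))
            j = j if j < i else j + 1
            mask = None
            if mode == "mask_hybrid":
                mask = generate_mask(F.shape[1] - C, self.mask_smoothing, rng)
            s = make_negative(F[i], F[j], (int(y[i]), int(y[j])), C,
                              mode=mode, mask=mask, rng=rng)
            s.features[:C] *= self.label_scale
            rows.append(s.features)
        return np.asarray(rows)

    # -- training
    def fit(self, F: np.ndarray, y: np.ndarray) -> "ForwardForwardClassifier":
        F = np.asarray(F, dtype=float)
        y = np.asarray(y, dtype=int)
        if F.ndim != 2 or F.shape[0] != y.shape[0]:
            raise ValueError("F must be (n_samples, n_features) matching y")
        if F.shape[1] < self.n_classes:
            raise ValueError("feature width smaller than the label prefix")
        dims = [F.shape[1], *self.widths]
        rng = np.random.default_rng(self.seed)
        self._mu = F.mean(axis=0)
        self._sd = np.where(F.std(axis=0) < 1e-12, 1.0, F.std(axis=0))
        Fz = (F - self._mu) / self._sd
        pos = self._embed(Fz, y)
        neg = self._negatives(Fz, y, rng)
        self.layers_ = []
        self.loss_traces_ = []
        cfg = FFConfig(epochs=self.epochs, batch_size=self.batch_size,
                       learning_rate=self.learning_rate, trainer=self.trainer,
                       negative_mode=self.negative_mode, theta=self.theta,
                       mask_smoothing=self.mask_smoothing, seed=self.seed)
        xp, xn = pos, neg
        for ell, (din, dout) in enumerate(zip(dims[:-1], dims[1:])):
            s = np.sqrt(2.0 / din)
            layer = FFLayer(rng.normal(0.0, s, size=(din, dout)),
                            np.zeros(dout), threshold=self.theta)
            cfg_l = replace(cfg, seed=cfg.seed + 101 * ell)
            layer, trace = train_ff_layer(layer, xp, xn, cfg_l)
            self.layers_.append(layer)
            self.loss_traces_.append(trace)
            with warnings.catch_warnings():
                # dead samples (all-zero activity) are expected mid-stack
                warnings.simplefilter("ignore", RuntimeWarning)
                xp = normalize_activity(layer_forward(layer, xp))
                xn = normalize_activity(layer_forward(layer, xn))
        self.n_features_in_ = F.shape[1]
        return self

    # -- inference
    def _label_scores(self, F: np.ndarray) -> np.ndarray:
        """Accumulated goodness per candidate label; (n_samples, C)."""
        Fz = (np.asarray(F, dtype=float) - self._mu) / self._sd
        n, C = Fz.shape[0], self.n_classes
        scores = np.zeros((n, C))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for c in range(C):
                x = self._embed(Fz, np.full(n, c))
                for ell, layer in enumerate(self.layers_):
                    h = layer_forward(layer, x)
                    if not (self.exclude_first_layer and ell == 0):
                        scores[:, c] += goodness(h)
                    x = normalize_activity(h)
        return scores

    def predict(self, F: np.ndarray) -> np.ndarray:
        self._check_fitted()
        return self._label_scores(F).argmax(axis=1)

    def goodness_report(self, feature_vector: np.ndarray) -> tuple[int, GoodnessReport]:
        """Per-label, per-layer goodness for one sample, plus the decision."""
        self._check_fitted()
        f = np.atleast_2d(np.asarray(feature_vector, dtype=float))
        Fz = (f - self._mu) / self._sd
        C, L = self.n_classes, len(self.layers_)
        per = np.zeros((C, L))
        prob = np.zeros((C, L))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for c in range(C):
                x = self._embed(Fz, np.array([c]))
                for ell, layer in enumerate(self.layers_):
                    h = layer_forward(layer, x)
                    per[c, ell] = goodness(h)[0]
                    prob[c, ell] = positive_probability(per[c, ell],
                                                        layer.threshold)
                    x = normalize_activity(h)
        score_layers = slice(1, None) if self.exclude_first_layer else slice(None)
        scores = per[:, score_layers].sum(axis=1)
        return int(scores.argmax()), GoodnessReport(per, scores, prob)

    def _check_fitted(self) -> None:
        if not hasattr(self, "layers_"):
            raise RuntimeError("network is not trained")

    # -- persistence
    def save(self, path) -> None:
        import json

        self._check_fitted()
        manifest = json.dumps({"params": {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in self.get_params().items()}})
        arrays = {"manifest": np.frombuffer(manifest.encode(), dtype=np.uint8),
                  "mu": self._mu, "sd": self._sd}
        for i, lay in enumerate(self.layers_):
            arrays[f"w{i}"] = lay.weights
            arrays[f"b{i}"] = lay.bias
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ForwardForwardClassifier":
        import json

        with np.load(path) as z:
            manifest = json.loads(bytes(z["manifest"]).decode())
            params = manifest["params"]
            params["widths"] = tuple(params["widths"])
            model = cls(**params)
            model._mu = z["mu"]
            model._sd = z["sd"]
            model.layers_ = []
            i = 0
            while f"w{i}" in z.files:
                model.layers_.append(FFLayer(z[f"w{i}"], z[f"b{i}"],
                                             threshold=model.theta))
                i += 1
        model.n_features_in_ = model._mu.shape[0]
        return model
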