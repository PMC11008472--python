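"""End-to-end experiment orchestration.

Wires the stages together: EDF (or synthetic) trials in, stratified
7:2:1 split, |PCC| channel graph from the training split only, GCN
pretraining and output-head fine-tuning, feature extraction, forward-
forward training of the dense stack, and goodness-based evaluation on
the held-out test split.  Everything downstream of the split is a
function of the training data and the seed, so runs are reproducible
bit for bit and leak nothing from the test set.

The GCN's node features are configurable: ``"connectivity"`` (default)
feeds each node its row of the trial's own |PCC| matrix — the trial's
functional-topology profile, computed per trial with no cross-trial
statistics — while ``"signal"`` feeds the raw time series.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .chebnet import ChebGCNClassifier
from .forwardforward import ForwardForwardClassifier
from .graph import MultichannelRecording, WeightedGraph, compute_pcc_adjacency

__all__ = [
    "ExperimentConfig",
    "EvaluationResult",
    "load_edf_dataset",
    "split_dataset",
    "trial_features",
    "accuracy",
    "FFGCNClassifier",
    "run_experiment",
]


@dataclass
class ExperimentConfig:
    """Run parameters: batch 64, learning rate 0.03, adaptive-moment
    optimizer, 300 epochs, F-F stack 512-256-256-4, stratified 7:2:1
    train/validation/test split."""

    split_ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    epochs: int = 300
    batch_size: int = 64
    learning_rate: float = 0.03
    optimizer: str = "adam"
    order: int = 3
    gcn_maps: tuple[int, ...] = (64, 128, 128, 512)
    feature_width: int = 512
    ff_widths: tuple[int, ...] = (512, 256, 256, 4)
    theta: float = 2.0
    negative_mode: str = "both"
    node_features: str = "connectivity"  # or "signal"
    gcn_learning_rate: float | None = 1e-3
    gcn_epochs: int | None = None
    fine_tune_epochs: int | None = None
    seed: int = 0
    n_classes: int = 4
    data_dir: str | None = None  # EDF directory; None -> caller supplies trials
    output_dir: str | None = None

    def __post_init__(self) -> None:
        r = self.split_ratios
        if len(r) != 3 or any(x <= 0 for x in r) or abs(sum(r) - 1.0) > 1e-9:
            raise ValueError("split ratios must be three positives summing to 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer.lower() != "adam":
            raise ValueError("only the adaptive-moment (adam) optimizer is supported")


@dataclass
class EvaluationResult:
    """Test-set outcome: overall accuracy plus one-vs-rest tallies."""

    accuracy: float
    confusion: np.ndarray
    per_class: dict[int, dict[str, int]]
    n_test: int


# ------------------------------------------------------------------- data IO

def load_edf_dataset(directory, montage_order: list[str] | None = None,
                     ) -> list[MultichannelRecording]:
    """One recording per annotated trial window across an EDF directory.

    Annotations ``T<k>`` mark trials of class ``k``.  Channel order is
    canonicalized (to ``montage_order`` if given, else sorted labels)
    and amplitudes are converted to microvolts.  Files without trial
    annotations are skipped with a warning; unreadable files raise,
    naming the file.
    """
    import mne

    directory = Path(directory)
    files = sorted(directory.glob("*.edf"))
    if not files:
        raise ValueError(f"no EDF files in {directory}")
    out: list[MultichannelRecording] = []
    for f in files:
        try:
            raw = mne.io.read_raw_edf(f, preload=True, verbose="error")
        except Exception as exc:  # pragma: no cover - malformed input path
            raise ValueError(f"malformed EDF file {f.name}: {exc}") from exc
        names = list(raw.ch_names)
        order = montage_order if montage_order is not None else sorted(names)
        if set(order) != set(names):
            raise ValueError(f"{f.name}: channels do not match the montage")
        idx = [names.index(ch) for ch in order]
        fs = float(raw.info["sfreq"])
        data = raw.get_data() * 1e6  # volts -> microvolts
        events = [(a["onset"], a["duration"], a["description"])
                  for a in raw.annotations
                  if a["description"].startswith("T")
                  and a["description"][1:].isdigit()]
        if not events:
            warnings.warn(f"{f.name}: no trial annotations; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        for onset, duration, desc in events:
            lo = int(round(onset * fs))
            hi = int(round((onset + duration) * fs))
            hi = min(hi, data.shape[1])
            if hi - lo < 2:
                continue
            out.append(MultichannelRecording(
                data[idx, lo:hi], list(order), fs, label=int(desc[1:])))
    return out


def split_dataset(dataset: list[MultichannelRecording],
                  ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
                  seed: int = 0):
    """Stratified shuffled train/val/test partition, deterministic per seed.

    Within each class, trials are shuffled and cut by the ratios with
    largest-remainder rounding, so per-class proportions match the
    global ratios to within one trial and the three parts are disjoint
    and exhaustive.
    """
    if len(dataset) < 3:
        raise ValueError("need at least 3 trials to split")
    if any(r <= 0 for r in ratios) or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[int]] = {}
    for i, t in enumerate(dataset):
        by_class.setdefault(-1 if t.label is None else t.label, []).append(i)
    parts: tuple[list[int], list[int], list[int]] = ([], [], [])
    for _, idxs in sorted(by_class.items()):
        idxs = np.asarray(idxs)[rng.permutation(len(idxs))]
        n = len(idxs)
        raw = [r * n for r in ratios]
        counts = [int(np.floor(x)) for x in raw]
        rema = np.argsort([-(x - np.floor(x)) for x in raw], kind="stable")
        for k in rema[: n - sum(counts)]:
            counts[k] += 1
        lo = 0
        for part, c in zip(parts, counts):
            part.extend(idxs[lo:lo + c].tolist())
            lo += c
    return tuple([dataset[i] for i in sorted(p)] for p in parts)


def trial_features(trials: list[MultichannelRecording],
                   mode: str = "connectivity") -> np.ndarray:
    """Per-trial GCN node features, shape (n_trials, n_channels, F).

    ``connectivity``: each node's row of the trial's own |PCC| matrix
    (its functional-topology profile within that single trial);
    ``signal``: the raw time series.
    """
    if mode == "signal":
        return np.stack([t.signals for t in trials])
    if mode == "connectivity":
        feats = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for t in trials:
                feats.append(compute_pcc_adjacency(t).adjacency)
        return np.stack(feats)
    raise ValueError("node_features must be 'connectivity' or 'signal'")


# ----------------------------------------------------------------- metrics

def accuracy(confusion: np.ndarray):
    """Overall accuracy (trace/total) and per-class one-vs-rest tallies.

    Per class c the multiclass confusion collapses to TP (diagonal),
    FP (rest of the column), FN (rest of the row) and TN (everything
    else); each class's accuracy is (TP+TN)/(TP+TN+FP+FN).
    """
    confusion = np.asarray(confusion)
    if confusion.size == 0 or confusion.ndim != 2 or \
            confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion matrix must be square and nonempty")
    if (confusion < 0).any() or not np.issubdtype(confusion.dtype, np.integer):
        raise ValueError("confusion matrix must hold nonnegative integer counts")
    total = int(confusion.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = float(np.trace(confusion)) / total
    per_class: dict[int, dict[str, float]] = {}
    for c in range(confusion.shape[0]):
        tp = int(confusion[c, c])
        fn = int(confusion[c].sum()) - tp
        fp = int(confusion[:, c].sum()) - tp
        tn = total - tp - fn - fp
        per_class[c] = {"TP": tp, "TN": tn, "FP": fp, "FN": fn,
                        "accuracy": (tp + tn) / total}
    return acc, per_class


# ------------------------------------------------------------- the estimator

class FFGCNClassifier:
    """Full F-FGCN: |PCC| graph -> Chebyshev GCN features -> F-F classifier.

    scikit-learn style wrapper over the two stage estimators.  ``fit``
    takes raw trials as ``X`` of shape (n_trials, n_channels, n_samples)
    (the channel graph and node features are derived internally from
    the training data only) and class labels ``y``.
    """

    def __init__(self, config: ExperimentConfig | None = None) -> None:
        self.config = config or ExperimentConfig()

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **kw) -> "FFGCNClassifier":
        for k, v in kw.items():
            if k != "config":
                raise ValueError(f"unknown parameter {k!r}")
            self.config = v
        return self

    def _node_features(self, X: np.ndarray) -> np.ndarray:
        if self.config.node_features == "signal":
            return X
        trials = [MultichannelRecording(x, [f"c{i}" for i in range(X.shape[1])],
                                        1.0) for x in X]
        return trial_features(trials, "connectivity")

    def fit(self, X: np.ndarray, y: np.ndarray,
            graph: WeightedGraph | None = None) -> "FFGCNClassifier":
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if graph is None:
            names = [f"c{i}" for i in range(X.shape[1])]
            pooled = MultichannelRecording(
                np.concatenate(list(X), axis=1), names, 1.0)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                graph = compute_pcc_adjacency(pooled)
        self.graph_ = graph
        feats = self._node_features(X)
        gcn_epochs = cfg.gcn_epochs if cfg.gcn_epochs is not None else cfg.epochs
        self.gcn_ = ChebGCNClassifier(
            order=cfg.order, n_maps=cfg.gcn_maps,
            feature_width=cfg.feature_width, n_classes=cfg.n_classes,
            epochs=gcn_epochs, batch_size=cfg.batch_size,
            learning_rate=(cfg.gcn_learning_rate
                           if cfg.gcn_learning_rate is not None
                           else cfg.learning_rate),
            seed=cfg.seed)
        self.gcn_.fit(feats, y, graph=graph)
        ft = cfg.fine_tune_epochs
        self.gcn_.fine_tune_output(feats, y, epochs=ft)
        train_feats = self.gcn_.transform(feats)
        self.ff_ = ForwardForwardClassifier(
            widths=cfg.ff_widths, n_classes=cfg.n_classes, theta=cfg.theta,
            epochs=cfg.epochs, batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate, negative_mode=cfg.negative_mode,
            seed=cfg.seed + 17)
        self.ff_.fit(train_feats, y)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.gcn_.transform(self._node_features(np.asarray(X, float)))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.ff_.predict(self.transform(X))

    def score(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))


# ------------------------------------------------------------ orchestration

def run_experiment(cfg: ExperimentConfig,
                   trials: list[MultichannelRecording] | None = None,
                   ) -> tuple[EvaluationResult, dict]:
    """Execute the full protocol and return the evaluation plus artifacts.

    Stages: load (or accept) trials; stratified split; |PCC| graph and
    all statistics from the training split only; GCN pretrain +
    output-head fine-tune; F-F training on extracted features; test-set
    evaluation.  If ``cfg.output_dir`` is set, checkpoints, loss traces
    and a result manifest are written there.
    """
    t0 = time.time()
    if trials is None:
        if cfg.data_dir is None:
            raise ValueError("run_experiment needs trials or cfg.data_dir")
        trials = load_edf_dataset(cfg.data_dir)
    train, val, test = split_dataset(trials, cfg.split_ratios, cfg.seed)
    if not test:
        raise ValueError("test split is empty")

    def _stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        graph = _stage("graph", compute_pcc_adjacency, train)
    Xtr = np.stack([t.signals for t in train])
    ytr = np.array([t.label for t in train])
    Xte = np.stack([t.signals for t in test])
    yte = np.array([t.label for t in test])
    model = FFGCNClassifier(cfg)
    _stage("train", model.fit, Xtr, ytr, graph=graph)
    pred = _stage("evaluate", model.predict, Xte)
    C = cfg.n_classes
    confusion = np.zeros((C, C), dtype=int)
    for t_lab, p_lab in zip(yte, pred):
        confusion[t_lab, p_lab] += 1
    acc, per_class = accuracy(confusion)
    result = EvaluationResult(acc, confusion, per_class, len(test))
    artifacts = {
        "model": model,
        "graph": graph,
        "val_accuracy": (model.score(
            np.stack([t.signals for t in val]),
            np.array([t.label for t in val])) if val else None),
        "gcn_loss_history": model.gcn_.loss_history_,
        "ff_loss_traces": model.ff_.loss_traces_,
        "elapsed_s": time.time() - t0,
    }
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        model.gcn_.save(out / "gcn.npz")
        model.ff_.save(out / "ff.npz")
        np.savetxt(out / "gcn_loss.tsv", np.asarray(model.gcn_.loss_history_),
                   delimiter="\t")
        for i, tr in enumerate(model.ff_.loss_traces_):
            np.savetxt(out / f"ff_loss_layer{i}.tsv", np.asarray(tr),
                       delimiter="\t")
        manifest = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(cfg).items()},
            "accuracy": acc,
            "confusion": confusion.tolist(),
            "n_train": len(train), "n_val": len(val), "n_test": len(test),
            "elapsed_s": artifacts["elapsed_s"],
        }
        (out / "result.json").write_text(json.dumps(manifest, indent=2))
    return result, artifacts
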