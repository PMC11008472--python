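"""Chebyshev spectral graph convolution and the GCN feature extractor.

A graph signal ``x`` (one value, or feature vector, per node) is
filtered in the graph's spectral domain: the Laplacian eigenbasis ``U``
defines the graph Fourier transform ``x_hat = U^T x``, and a filter is a
per-eigenvalue gain.  Dense spectral filtering costs ``O(N^2)`` and
needs the eigendecomposition, so the working path parameterizes the
filter as a truncated Chebyshev expansion ``g(lam) = sum_k theta_k
T_k(lam_rescaled)`` and evaluates it with the three-term recursion
``xbar_k = 2 L_tilde xbar_{k-1} - xbar_{k-2}`` — no eigenvectors ever
materialized.  The dense spectral route is kept as the exact oracle for
testing the recursion against.

The :class:`ChebGCNClassifier` stacks conv + graph-max-pool stages over
a greedy heavy-edge-matching coarsening hierarchy (node count roughly
halves per stage), flattens, projects to a fixed-width feature vector
and classifies with a softmax head trained by categorical cross-entropy.
After pretraining, the output head alone can be fine-tuned with the
earlier stages frozen; the penultimate feature vector is what feeds the
forward-forward dense block downstream.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._optim import Adam
from .graph import (
    GraphSpectrum,
    WeightedGraph,
    combinatorial_laplacian,
    normalized_laplacian,
    rescale_laplacian,
    spectrum,
)

__all__ = [
    "ChebConvLayer",
    "PoolingMap",
    "gft",
    "inverse_gft",
    "spectral_filter",
    "cheb_stack",
    "chebyshev_apply",
    "build_pooling_hierarchy",
    "graph_max_pool",
    "ChebGCNClassifier",
]


# ---------------------------------------------------------------- spectral ops

def gft(x: np.ndarray, spec: GraphSpectrum) -> np.ndarray:
    """Graph Fourier transform ``x_hat = U^T x``."""
    x = np.asarray(x, dtype=float)
    u = spec.eigenvectors
    if x.shape[0] != u.shape[0]:
        raise ValueError(f"signal has {x.shape[0]} rows, graph has {u.shape[0]} nodes")
    return u.T @ x


def inverse_gft(x_hat: np.ndarray, spec: GraphSpectrum) -> np.ndarray:
    """Inverse graph Fourier transform ``x = U x_hat``."""
    x_hat = np.asarray(x_hat, dtype=float)
    u = spec.eigenvectors
    if x_hat.shape[0] != u.shape[0]:
        raise ValueError("coefficient length does not match node count")
    return u @ x_hat


def spectral_filter(x: np.ndarray, gains: np.ndarray, spec: GraphSpectrum) -> np.ndarray:
    """Exact spectral filtering ``y = U diag(gains) U^T x`` (test oracle)."""
    gains = np.asarray(gains, dtype=float)
    if gains.shape != (spec.eigenvectors.shape[0],):
        raise ValueError("need exactly one gain per eigenvalue")
    return inverse_gft(gains[:, None] * gft(x, spec) if np.ndim(x) == 2
                       else gains * gft(x, spec), spec)


# --------------------------------------------------------- Chebyshev recursion

def cheb_stack(L_tilde: np.ndarray, x: np.ndarray, K: int) -> np.ndarray:
    """Stack ``[T_0(Lt) x, ..., T_{K-1}(Lt) x]`` via the three-term recursion.

    ``x`` may be ``(N, F)`` or batched ``(B, N, F)``; the node axis is the
    second-to-last.  Returns shape ``(K, *x.shape)``.
    """
    if K < 1:
        raise ValueError("Chebyshev order K must be >= 1")
    x = np.asarray(x, dtype=float)
    out = np.empty((K, *x.shape))
    out[0] = x
    if K > 1:
        out[1] = np.einsum("nm,...mf->...nf", L_tilde, x)
    for k in range(2, K):
        out[k] = 2.0 * np.einsum("nm,...mf->...nf", L_tilde, out[k - 1]) - out[k - 2]
    return out


@dataclass
class ChebConvLayer:
    """One Chebyshev graph convolution: ``sum_k T_k(Lt) X theta_k + b``.

    coefficients: ``(K, F_in, F_out)`` — shared across nodes; bias is one
    value per output map, shared across nodes; activation is a rectifier
    by default ("identity" disables it).
    """

    coefficients: np.ndarray
    bias: np.ndarray | None = None
    activation: str = "relu"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 3:
            raise ValueError("coefficients must be (K, F_in, F_out)")
        if self.order < 1:
            raise ValueError("Chebyshev order K must be >= 1")
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=float)
            if self.bias.shape != (self.coefficients.shape[2],):
                raise ValueError("bias must be one value per output map")
        if self.activation not in ("relu", "identity"):
            raise ValueError("activation must be 'relu' or 'identity'")

    @property
    def order(self) -> int:
        return self.coefficients.shape[0]


def chebyshev_apply(x: np.ndarray, layer: ChebConvLayer,
                    L_tilde: np.ndarray) -> np.ndarray:
    """Apply a Chebyshev convolution layer through the recursion.

    Never touches the eigenbasis; cost is K sparse-style multiplies by
    the rescaled Laplacian.  Warns if ``L_tilde`` looks un-rescaled
    (Gershgorin bound outside [-1, 1] by a wide margin).
    """
    x = np.asarray(x, dtype=float)
    n = L_tilde.shape[0]
    if x.shape[-2] != n:
        raise ValueError("signal node count does not match Laplacian")
    radius = np.max(np.abs(L_tilde).sum(axis=1))
    if radius > n:  # crude but cheap: a rescaled Laplacian stays well below this
        warnings.warn("L_tilde spectrum may exceed [-1, 1]; did you rescale?",
                      RuntimeWarning, stacklevel=2)
    xb = cheb_stack(L_tilde, x, layer.order)
    y = np.einsum("k...nf,kfo->...no", xb, layer.coefficients)
    if layer.bias is not None:
        y = y + layer.bias
    if layer.activation == "relu":
        y = np.maximum(y, 0.0)
    return y


# ------------------------------------------------------------------ coarsening

@dataclass
class PoolingMap:
    """Assignment of input nodes to super-nodes (groups of size 1 or 2)."""

    groups: list[tuple[int, ...]]
    n_in: int

    def __post_init__(self) -> None:
        seen = sorted(i for g in self.groups for i in g)
        if seen != list(range(self.n_in)):
            raise ValueError("groups must partition the input nodes exactly")

    @property
    def n_out(self) -> int:
        return len(self.groups)


def build_pooling_hierarchy(
    g: WeightedGraph, levels: int
) -> list[tuple[PoolingMap, WeightedGraph]]:
    """Greedy heavy-edge-matching coarsening, one (map, graph) per level.

    Scanning nodes in index order, each unmatched node pairs with its
    heaviest-weight unmatched neighbor (lowest index breaks ties);
    nodes left without an unmatched neighbor become singletons.  Merged
    edge weights are summed; if a summed weight exceeds 1 the coarse
    adjacency is rescaled by its maximum (the Laplacian is rescaled by
    its top eigenvalue later anyway, so only relative weights matter).
    Deterministic given node ordering.
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    out: list[tuple[PoolingMap, WeightedGraph]] = []
    cur = g
    for _ in range(levels):
        a = cur.adjacency
        n = cur.n_nodes
        matched = np.zeros(n, dtype=bool)
        groups: list[tuple[int, ...]] = []
        for i in range(n):
            if matched[i]:
                continue
            matched[i] = True
            w = a[i].copy()
            w[matched] = -1.0
            j = int(np.argmax(w))
            if w[j] > 0.0:
                matched[j] = True
                groups.append((i, j))
            else:
                groups.append((i,))
        m = len(groups)
        coarse = np.zeros((m, m))
        for gi, mem_i in enumerate(groups):
            for gj in range(gi + 1, m):
                wsum = float(a[np.ix_(mem_i, groups[gj])].sum())
                coarse[gi, gj] = coarse[gj, gi] = wsum
        peak = coarse.max()
        if peak > 1.0:
            coarse /= peak
        names = ["+".join(cur.node_names[i] for i in mem) for mem in groups]
        nxt = WeightedGraph(coarse, names)
        out.append((PoolingMap(groups, n), nxt))
        cur = nxt
    return out


def graph_max_pool(x: np.ndarray, pm: PoolingMap) -> np.ndarray:
    """Per-super-node elementwise maximum over member nodes."""
    x = np.asarray(x, dtype=float)
    if x.shape[-2] != pm.n_in:
        raise ValueError(f"signal has {x.shape[-2]} nodes, pooling map expects {pm.n_in}")
    cols = []
    for mem in pm.groups:
        cols.append(x[..., list(mem), :].max(axis=-2))
    return np.stack(cols, axis=-2)


# ----------------------------------------------------------------- GCN network

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _glorot(rng: np.random.Generator, *shape: int) -> np.ndarray:
    fan_in = int(np.prod(shape[:-1]))
    fan_out = shape[-1]
    s = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-s, s, size=shape)


class ChebGCNClassifier:
    """Stacked Chebyshev-conv + graph-max-pool feature extractor/classifier.

    scikit-learn style estimator: hyperparameters in ``__init__``,
    fitted state in trailing-underscore attributes, ``fit`` /
    ``predict`` / ``predict_proba`` / ``transform``.  ``transform``
    returns the penultimate feature vector (width ``feature_width``)
    consumed by the forward-forward block.

    Parameters
    ----------
    order : Chebyshev polynomial order K per conv layer.
    n_maps : feature maps (F1..F4) per conv stage; its length sets the
        number of conv+pool stages.
    feature_width : width of the flattened-features projection feeding
        the classifier head (and, downstream, the first F-F layer).
    laplacian : "normalized" (eigenvalues in [0,2]) or "combinatorial".
    lambda_max : "exact" (eigendecomposition per level) or "bound2"
        (the normalized-Laplacian upper bound, skipping the solve).
    epochs, batch_size, learning_rate : training schedule (adaptive-
        moment optimizer on categorical cross-entropy).
    """

    def __init__(self, order: int = 3, n_maps: tuple[int, ...] = (8, 16, 16, 32),
                 feature_width: int = 64, n_classes: int = 4,
                 laplacian: str = "normalized", lambda_max: str = "exact",
                 epochs: int = 60, batch_size: int = 64,
                 learning_rate: float = 1e-3, seed: int = 0) -> None:
        self.order = order
        self.n_maps = tuple(n_maps)
        self.feature_width = feature_width
        self.n_classes = n_classes
        self.laplacian = laplacian
        self.lambda_max = lambda_max
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    # -- sklearn plumbing
    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in (
            "order", "n_maps", "feature_width", "n_classes", "laplacian",
            "lambda_max", "epochs", "batch_size", "learning_rate", "seed")}

    def set_params(self, **kw) -> "ChebGCNClassifier":
        for k, v in kw.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # -- architecture setup
    def _laplacian_of(self, g: WeightedGraph) -> np.ndarray:
        if self.laplacian == "normalized":
            return normalized_laplacian(g)
        if self.laplacian == "combinatorial":
            return combinatorial_laplacian(g)
        raise ValueError("laplacian must be 'normalized' or 'combinatorial'")

    def _build(self, graph: WeightedGraph, n_feats_in: int) -> None:
        levels = len(self.n_maps)
        hier = build_pooling_hierarchy(graph, levels)
        graphs = [graph] + [gg for _, gg in hier]
        self.pooling_maps_ = [pm for pm, _ in hier]
        self.L_tildes_ = []
        for gg in graphs[:levels]:
            L = self._laplacian_of(gg)
            if self.lambda_max == "bound2":
                if self.laplacian != "normalized":
                    raise ValueError("lambda_max='bound2' requires the normalized Laplacian")
                lmax = 2.0
            else:
                lmax = max(spectrum(L).lambda_max, 1e-12)
            self.L_tildes_.append(rescale_laplacian(L, lmax))
        self.graphs_ = graphs
        rng = np.random.default_rng(self.seed)
        p: dict[str, np.ndarray] = {}
        f_in = n_feats_in
        for ell, f_out in enumerate(self.n_maps):
            p[f"conv{ell}_w"] = _glorot(rng, self.order, f_in, f_out)
            p[f"conv{ell}_b"] = np.zeros(f_out)
            f_in = f_out
        flat = graphs[levels].n_nodes * self.n_maps[-1]
        p["feat_w"] = _glorot(rng, flat, self.feature_width)
        p["feat_b"] = np.zeros(self.feature_width)
        p["out_w"] = _glorot(rng, self.feature_width, self.n_classes)
        p["out_b"] = np.zeros(self.n_classes)
        self.params_ = p
        self._rng = rng

    # -- forward / backward
    def _forward(self, X: np.ndarray, want_cache: bool = False):
        p = self.params_
        levels = len(self.n_maps)
        h = X
        cache = {"inputs": [], "xbars": [], "pre": [], "pooled_arg": []}
        for ell in range(levels):
            w = p[f"conv{ell}_w"]
            xb = cheb_stack(self.L_tildes_[ell], h, w.shape[0])
            pre = np.einsum("kbnf,kfo->bno", xb, w) + p[f"conv{ell}_b"]
            act = np.maximum(pre, 0.0)
            pm = self.pooling_maps_[ell]
            pooled_cols, arg_cols = [], []
            for mem in pm.groups:
                sub = act[:, list(mem), :]
                am = sub.argmax(axis=1)
                pooled_cols.append(np.take_along_axis(sub, am[:, None, :], axis=1)[:, 0, :])
                arg_cols.append(am)
            pooled = np.stack(pooled_cols, axis=1)
            if want_cache:
                cache["inputs"].append(h)
                cache["xbars"].append(xb)
                cache["pre"].append(pre)
                cache["pooled_arg"].append(arg_cols)
            h = pooled
        B = X.shape[0]
        flat = h.reshape(B, -1)
        feat_pre = flat @ p["feat_w"] + p["feat_b"]
        feat = np.maximum(feat_pre, 0.0)
        scores = feat @ p["out_w"] + p["out_b"]
        if want_cache:
            cache.update(flat=flat, feat_pre=feat_pre, feat=feat,
                         pooled_shape=h.shape)
            return scores, feat, cache
        return scores, feat

    def _backward(self, X, y_onehot, cache, scores, head_only: bool = False):
        p = self.params_
        B = X.shape[0]
        g: dict[str, np.ndarray] = {}
        prob = _softmax(scores)
        dscores = (prob - y_onehot) / B
        g["out_w"] = cache["feat"].T @ dscores
        g["out_b"] = dscores.sum(axis=0)
        if head_only:
            return g
        dfeat = dscores @ p["out_w"].T
        dfeat_pre = dfeat * (cache["feat_pre"] > 0)
        g["feat_w"] = cache["flat"].T @ dfeat_pre
        g["feat_b"] = dfeat_pre.sum(axis=0)
        dh = (dfeat_pre @ p["feat_w"].T).reshape(cache["pooled_shape"])
        levels = len(self.n_maps)
        for ell in reversed(range(levels)):
            pm = self.pooling_maps_[ell]
            pre = cache["pre"][ell]
            dact = np.zeros_like(pre)
            for gi, mem in enumerate(pm.groups):
                am = cache["pooled_arg"][ell][gi]  # (B, F) index into mem
                mem_arr = np.asarray(mem)
                rows = mem_arr[am]  # (B, F) node indices
                bidx = np.arange(B)[:, None]
                fidx = np.arange(pre.shape[2])[None, :]
                np.add.at(dact, (bidx, rows, fidx), dh[:, gi, :])
            dpre = dact * (pre > 0)
            xb = cache["xbars"][ell]
            w = p[f"conv{ell}_w"]
            g[f"conv{ell}_w"] = np.einsum("kbnf,bno->kfo", xb, dpre)
            g[f"conv{ell}_b"] = dpre.sum(axis=(0, 1))
            if ell > 0:
                K = w.shape[0]
                dX = np.zeros_like(cache["inputs"][ell])
                for k in range(K):
                    ak = dpre @ w[k].T
                    dX += cheb_stack(self.L_tildes_[ell], ak, k + 1)[k]
                dh = dX
        return g

    # -- training
    def _run_epochs(self, X, y, epochs: int, head_only: bool, opt: Adam,
                    rng: np.random.Generator) -> list[float]:
        n = X.shape[0]
        onehot = np.eye(self.n_classes)[y]
        losses = []
        for _ in range(epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                scores, _, cache = self._forward(X[idx], want_cache=True)
                prob = _softmax(scores)
                ep_loss += float(-np.sum(
                    onehot[idx] * np.log(np.clip(prob, 1e-12, None))))
                grads = self._backward(X[idx], onehot[idx], cache, scores,
                                       head_only=head_only)
                opt.step(self.params_, grads)
            losses.append(ep_loss / n)
        return losses

    def fit(self, X: np.ndarray, y: np.ndarray,
            graph: WeightedGraph | None = None) -> "ChebGCNClassifier":
        """Pretrain end to end with categorical cross-entropy.

        X: (n_trials, n_nodes, n_node_features); y: class indices.
        ``graph`` is the channel graph (typically the |PCC| graph of the
        training split); required on first fit.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 3:
            raise ValueError("X must be (n_trials, n_nodes, n_features)")
        if X.shape[0] == 0:
            raise ValueError("empty dataset")
        if graph is None:
            raise ValueError("a channel WeightedGraph is required")
        if graph.n_nodes != X.shape[1]:
            raise ValueError("graph node count does not match X")
        self._build(graph, X.shape[2])
        opt = Adam(lr=self.learning_rate)
        rng = np.random.default_rng(self.seed + 1)
        self.loss_history_ = self._run_epochs(X, y, self.epochs, False, opt, rng)
        self.n_features_in_ = X.shape[2]
        self.pretrained_ = True
        return self

    def fine_tune_output(self, X: np.ndarray, y: np.ndarray,
                         epochs: int | None = None) -> "ChebGCNClassifier":
        """Retrain only the output head; conv stages and feature projection frozen."""
        if not getattr(self, "pretrained_", False):
            raise RuntimeError("fine_tune_output requires a pretrained model")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        opt = Adam(lr=self.learning_rate)
        rng = np.random.default_rng(self.seed + 2)
        self.fine_tune_loss_history_ = self._run_epochs(
            X, y, epochs if epochs is not None else max(self.epochs // 4, 1),
            True, opt, rng)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Penultimate feature vectors, shape (n_trials, feature_width)."""
        self._check_fitted()
        _, feat = self._forward(np.asarray(X, dtype=float))
        return feat

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        self._check_fitted()
        scores, _ = self._forward(np.asarray(X, dtype=float))
        return scores

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self.decision_function(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.decision_function(X).argmax(axis=1)

    def _check_fitted(self) -> None:
        if not hasattr(self, "params_"):
            raise RuntimeError("model is not fitted")

    # -- persistence
    def save(self, path) -> None:
        """Checkpoint (npz) with an embedded config manifest; bit-exact round-trip."""
        self._check_fitted()
        manifest = json.dumps({
            "params": self.get_params(),
            "groups": [[list(g) for g in pm.groups] for pm in self.pooling_maps_],
            "n_in": [pm.n_in for pm in self.pooling_maps_],
            "node_names": self.graphs_[0].node_names,
        })
        arrays = {f"param::{k}": v for k, v in self.params_.items()}
        arrays.update({f"lt::{i}": lt for i, lt in enumerate(self.L_tildes_)})
        arrays.update({f"adj::{i}": g.adjacency for i, g in enumerate(self.graphs_)})
        np.savez(path, manifest=np.frombuffer(manifest.encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "ChebGCNClassifier":
        with np.load(path) as z:
            manifest = json.loads(bytes(z["manifest"]).decode())
            model = cls(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in manifest["params"].items()})
            model.params_ = {k.split("::", 1)[1]: z[k]
                             for k in z.files if k.startswith("param::")}
            model.L_tildes_ = [z[f"lt::{i}"]
                               for i in range(len(manifest["n_in"]))]
            adjs = [z[k] for k in sorted(
                (k for k in z.files if k.startswith("adj::")),
                key=lambda s: int(s.split("::")[1]))]
        model.pooling_maps_ = [
            PoolingMap([tuple(g) for g in groups], n_in)
            for groups, n_in in zip(manifest["groups"], manifest["n_in"])]
        names = manifest["node_names"]
        model.graphs_ = [WeightedGraph(adjs[0], names)] + [
            WeightedGraph(a) for a in adjs[1:]]
        model.pretrained_ = True
        return model
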