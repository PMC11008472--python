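"""Synthetic multichannel trials with class-dependent connectivity.

The generator emulates the structure the classifier is premised on:
each class is a different partition of the channels into communities,
channels within a community share a band-limited latent oscillation, a
weak global source gives a floor of between-community correlation, and
independent white noise dilutes both.  With unit-variance sources and
noise standard deviation ``sigma``, mixing gains are solved so the
population correlations hit the configured within/between targets
exactly:

    within  r_w = (a^2 + b^2) / (a^2 + b^2 + sigma^2)
    between r_b =        b^2  / (a^2 + b^2 + sigma^2)

Class information therefore lives purely in the correlation structure
— channel means and marginal variances are uninformative — so the task
is solvable only through the functional-connectivity graph.  Per-channel
gains (random magnitude and sign) exercise the affine invariance of the
Pearson graph.  Tiny fixture graphs with closed-form Laplacian spectra
round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .edf import write_edf
from .graph import MultichannelRecording, WeightedGraph

__all__ = [
    "SynthConfig",
    "FixtureGraph",
    "generate_trials",
    "fixture_graphs",
    "write_edf_fixture",
    "save_dataset",
    "load_dataset",
]


def _default_templates(n_channels: int, n_classes: int,
                       n_communities: int) -> list[np.ndarray]:
    """One balanced channel->community partition per class, all distinct.

    Drawn from a fixed generator so the templates are a stable part of
    the default configuration, independent of the data seed.
    """
    out = []
    base = np.repeat(np.arange(n_communities),
                     int(np.ceil(n_channels / n_communities)))[:n_channels]
    for c in range(n_classes):
        if c == 0:
            out.append(base.copy())  # contiguous blocks
        else:
            rng = np.random.default_rng(7_654_321 + c)
            out.append(base[rng.permutation(n_channels)])
    return out


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    Defaults mirror the four-class 64-channel motor-imagery setting
    (160 Hz, 4-second trials, 21 trials per class as in one subject's
    worth of recordings); the oscillation band is the mu rhythm.
    """

    n_channels: int = 64
    samples_per_trial: int = 640
    n_trials_per_class: int = 21
    n_classes: int = 4
    n_communities: int = 4
    within_corr: float = 0.8
    between_corr: float = 0.1
    oscillation_band: tuple[float, float] = (8.0, 12.0)
    sampling_rate: float = 160.0
    noise_sd: float = 1.0
    seed: int = 0
    templates: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.between_corr <= self.within_corr < 1.0):
            raise ValueError(
                "need 0 <= between_corr <= within_corr < 1 "
                f"(got {self.between_corr}, {self.within_corr})")
        if self.templates is None:
            self.templates = _default_templates(
                self.n_channels, self.n_classes, self.n_communities)
        if len(self.templates) != self.n_classes:
            raise ValueError("one community template per class required")
        for t in self.templates:
            if len(t) != self.n_channels:
                raise ValueError("template length must equal n_channels")


def _bandlimited(rng: np.random.Generator, n: int, fs: float,
                 band: tuple[float, float], size: int) -> np.ndarray:
    """(size, n) unit-variance noise bandpassed to ``band`` via the FFT."""
    white = rng.standard_normal((size, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ValueError("oscillation band contains no resolvable frequency")
    spec[:, ~keep] = 0.0
    s = np.fft.irfft(spec, n=n, axis=1)
    sd = s.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return s / sd


def generate_trials(cfg: SynthConfig) -> list[MultichannelRecording]:
    """Labeled trials whose inter-channel |PCC| structure encodes the class.

    With ``noise_sd == 0`` the channels are pure community sources
    (all within-community |PCC| exactly 1); otherwise the mixing gains
    are solved for the configured correlation targets.  Deterministic
    per seed; trials are returned class-interleaved.
    """
    rng = np.random.default_rng(cfg.seed)
    sigma = cfg.noise_sd
    if sigma > 0:
        tot = sigma ** 2 / (1.0 - cfg.within_corr)
        b2 = cfg.between_corr * tot
        a2 = cfg.within_corr * tot - b2
        a, b = np.sqrt(a2), np.sqrt(b2)
    else:
        a, b = 1.0, 0.0
    # fixed per-channel gains: random magnitude and sign; |PCC| is
    # invariant to them, so they only stress the pipeline's invariances
    gains = rng.uniform(0.5, 1.5, size=cfg.n_channels) * \
        rng.choice([-1.0, 1.0], size=cfg.n_channels)
    names = [f"SYN{i:03d}" for i in range(cfg.n_channels)]
    trials: list[MultichannelRecording] = []
    for k in range(cfg.n_trials_per_class):
        for c in range(cfg.n_classes):
            part = cfg.templates[c]
            src = _bandlimited(rng, cfg.samples_per_trial, cfg.sampling_rate,
                               cfg.oscillation_band, cfg.n_communities + 1)
            communities, glob = src[:-1], src[-1]
            x = a * communities[part] + b * glob[None, :]
            if sigma > 0:
                x = x + sigma * rng.standard_normal(x.shape)
            x = gains[:, None] * x
            trials.append(MultichannelRecording(
                x, names, cfg.sampling_rate, label=c))
    return trials


# ------------------------------------------------------------------ fixtures

@dataclass
class FixtureGraph:
    """Tiny graph with a closed-form Laplacian spectrum, for oracle tests."""

    name: str
    graph: WeightedGraph
    eigenvalues: np.ndarray  # closed form, ascending
    laplacian: str  # which Laplacian the closed form refers to
    connected: bool = True


def fixture_graphs() -> list[FixtureGraph]:
    """Reference graphs whose spectra are known in closed form.

    * 2-node unit edge: normalized-Laplacian eigenvalues {0, 2}.
    * Path P3 (unit weights): combinatorial eigenvalues {0, 1, 3}.
    * Complete K4: normalized eigenvalues {0, 4/3, 4/3, 4/3}.
    * 6-node two-community graph (within weight w=0.9 on each in-block
      pair, between weight b=0.05 on every cross pair): combinatorial
      eigenvalues {0, 6b, 3w+3b (x4)} from the block structure.
    * 2-node edge plus an isolated node (flagged disconnected):
      normalized eigenvalues {0, 1, 2} under the identity-row
      convention for degree-0 nodes.
    """
    w, b = 0.9, 0.05
    blocks = np.zeros((6, 6))
    blocks[:3, :3] = w
    blocks[3:, 3:] = w
    blocks[:3, 3:] = b
    blocks[3:, :3] = b
    np.fill_diagonal(blocks, 0.0)
    k4 = np.ones((4, 4)) - np.eye(4)
    edge_iso = np.zeros((3, 3))
    edge_iso[0, 1] = edge_iso[1, 0] = 1.0
    return [
        FixtureGraph("edge2", WeightedGraph(np.array([[0.0, 1.0], [1.0, 0.0]])),
                     np.array([0.0, 2.0]), "normalized"),
        FixtureGraph("path3",
                     WeightedGraph(np.array([[0.0, 1.0, 0.0],
                                             [1.0, 0.0, 1.0],
                                             [0.0, 1.0, 0.0]])),
                     np.array([0.0, 1.0, 3.0]), "combinatorial"),
        FixtureGraph("complete4", WeightedGraph(k4),
                     np.array([0.0, 4 / 3, 4 / 3, 4 / 3]), "normalized"),
        FixtureGraph("two_community6", WeightedGraph(blocks),
                     np.array(sorted([0.0, 6 * b] + [3 * w + 3 * b] * 4)),
                     "combinatorial"),
        FixtureGraph("edge2_isolated", WeightedGraph(edge_iso),
                     np.array([0.0, 1.0, 2.0]), "normalized", connected=False),
    ]


# ------------------------------------------------------------------------ IO

def write_edf_fixture(dataset: list[MultichannelRecording], path) -> None:
    """Serialize labeled trials as one EDF+ file with trial annotations.

    Trials are concatenated along time; each contributes an annotation
    ``T<label>`` at its onset with its duration.  Amplitudes survive to
    within one 16-bit quantization step of the physical range.
    """
    if not dataset:
        raise ValueError("empty dataset")
    fs = dataset[0].sampling_rate
    names = dataset[0].channel_names
    for t in dataset:
        if t.channel_names != names or t.sampling_rate != fs:
            raise ValueError("all trials must share montage and sampling rate")
    sig = np.concatenate([t.signals for t in dataset], axis=1)
    dur = [t.n_samples / fs for t in dataset]
    onsets = np.concatenate([[0.0], np.cumsum(dur)[:-1]])
    labels = [t.label if t.label is not None else 0 for t in dataset]
    write_edf(path, sig, names, fs, onsets, dur, labels)


def save_dataset(dataset: list[MultichannelRecording], path,
                 config: SynthConfig | None = None) -> None:
    """Portable container (npz) with a manifest for exact regeneration."""
    import json

    manifest = {"channel_names": dataset[0].channel_names,
                "sampling_rate": dataset[0].sampling_rate}
    if config is not None:
        d = {k: v for k, v in vars(config).items() if k != "templates"}
        d["oscillation_band"] = list(config.oscillation_band)
        manifest["config"] = d
    np.savez(path,
             manifest=np.frombuffer(json.dumps(manifest).encode(), np.uint8),
             signals=np.stack([t.signals for t in dataset]),
             labels=np.array([-1 if t.label is None else t.label
                              for t in dataset]))


def load_dataset(path) -> list[MultichannelRecording]:
    import json

    with np.load(path) as z:
        manifest = json.loads(bytes(z["manifest"]).decode())
        signals = z["signals"]
        labels = z["labels"]
    return [MultichannelRecording(
        s, list(manifest["channel_names"]), manifest["sampling_rate"],
        label=None if lab < 0 else int(lab))
        for s, lab in zip(signals, labels)]
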