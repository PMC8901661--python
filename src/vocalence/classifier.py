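"""Spectrogram computation and CNN training for valence/context labels.

The spectrogram recipe mirrors the study protocol for real calls: each
call is centrally zero-padded to the duration of the longest recording
(3.595 s), short-time Fourier transformed with a 3 ms window, a hop of 1%
of the window length (i.e. 99% overlap) and a 512-point DFT, then
log-scaled and resized to the classifier's input resolution.  Training
follows the published protocol: stratified 70/30 split per trial, 20
epochs, minibatch 32, initial learning rate 0.001 with a drop factor of
10^-0.5, best-validation-accuracy checkpointing, and metrics summarized
over repeated trials (mean +/- standard error).

The default backbone is ``small_cnn`` (three conv blocks in numpy); a
large pretrained transfer backbone is intentionally not bundled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from skimage.transform import resize
from sklearn import metrics as skm
from sklearn.model_selection import train_test_split

from ._nn import SmallCNN

__all__ = [
    "SpectrogramConfig", "SpectrogramImage", "TrainConfig",
    "TrialMetrics", "MetricsSummary",
    "make_spectrogram", "spectrogram_stack", "train_classifier", "summarize_trials",
]

PAD_TARGET_S = 3.595  # duration of the longest recording in the study dataset


@dataclass
class SpectrogramConfig:
    pad_target: float = PAD_TARGET_S  # s
    window_s: float = 0.003  # 3 ms analysis window
    hop_fraction: float = 0.01  # hop as a fraction of the window (99% overlap)
    n_dft: int = 512
    img_size: int = 48  # square input resolution fed to the CNN
    db_floor: float = -80.0


@dataclass
class SpectrogramImage:
    matrix: np.ndarray  # freq x time, log magnitude (dB)
    freqs: np.ndarray  # Hz
    times: np.ndarray  # s
    pad_target: float
    pad_left_samples: int
    pad_right_samples: int
    image: np.ndarray  # resized img_size x img_size float32


def make_spectrogram(call, cfg: SpectrogramConfig | None = None) -> SpectrogramImage:
    """Fixed-size log spectrogram of one call.

    The call is centered in a zero buffer of ``pad_target`` seconds (left
    pad = right pad up to one sample); calls longer than the buffer are an
    error, mirroring the "pad to the longest recording" convention.
    """
    cfg = cfg or SpectrogramConfig()
    x = np.asarray(call.waveform, float)
    sr = call.sample_rate
    n_target = int(round(cfg.pad_target * sr))
    if x.size > n_target:
        raise ValueError(f"call of {x.size / sr:.3f}s exceeds pad target {cfg.pad_target}s")
    pad_total = n_target - x.size
    left = pad_total // 2
    right = pad_total - left
    xp = np.pad(x, (left, right))

    win = max(2, int(round(cfg.window_s * sr)))
    hop = max(1, int(round(cfg.hop_fraction * win)))
    nfft = max(cfg.n_dft, win)
    freqs, times, Z = signal.stft(xp, fs=sr, window="hann", nperseg=win,
                                  noverlap=win - hop, nfft=nfft, boundary=None,
                                  padded=True)
    mag_db = 20.0 * np.log10(np.abs(Z) + 10 ** (cfg.db_floor / 20.0))
    img = resize(mag_db, (cfg.img_size, cfg.img_size), order=1, mode="reflect",
                 anti_aliasing=True, preserve_range=True).astype(np.float32)
    # normalize to [0, 1] per image for stable optimization
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    return SpectrogramImage(matrix=mag_db, freqs=freqs, times=times,
                            pad_target=cfg.pad_target,
                            pad_left_samples=left, pad_right_samples=right,
                            image=img)


def spectrogram_stack(calls, cfg: SpectrogramConfig | None = None) -> np.ndarray:
    """(n, 1, img, img) float32 stack of resized spectrogram images."""
    cfg = cfg or SpectrogramConfig()
    imgs = [make_spectrogram(c, cfg).image for c in calls]
    return np.stack(imgs)[:, None, :, :]


@dataclass
class TrainConfig:
    task: str = "valence"  # "valence" (binary) | "context" (multi-class)
    backbone: str = "small_cnn"
    epochs: int = 20
    batch: int = 32
    lr: float = 0.001
    lr_drop_factor: float = 10 ** -0.5
    lr_drop_period: int = 10  # epochs between drops
    split: float = 0.7  # train fraction
    n_trials: int = 10
    hidden: int = 64
    rng_seed: int = 0

    def validate(self):
        if not 0 < self.split < 1:
            raise ValueError("split must be in (0,1)")
        if min(self.epochs, self.batch, self.n_trials) < 1:
            raise ValueError("epochs, batch and n_trials must be >= 1")
        if self.backbone != "small_cnn":
            raise NotImplementedError(
                f"backbone {self.backbone!r} is not bundled; only 'small_cnn' is available")


@dataclass
class TrialMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    best_epoch: int


@dataclass
class MetricsSummary:
    mean: dict
    uncertainty: dict  # standard error over trials
    n_trials: int


def _trial_metrics(y_true, y_pred, task, classes):
    if task == "valence":
        # binary scores treating the positive-valence class as positive
        pos = list(classes).index("positive") if "positive" in classes else 1
        kw = dict(average="binary", pos_label=pos, zero_division=0)
    else:
        kw = dict(average="weighted", zero_division=0)
    return (
        float(skm.accuracy_score(y_true, y_pred)),
        float(skm.precision_score(y_true, y_pred, **kw)),
        float(skm.recall_score(y_true, y_pred, **kw)),
        float(skm.f1_score(y_true, y_pred, **kw)),
    )


def _train_one(X, y, classes, cfg, seed):
    rng = np.random.default_rng(seed)
    idx = np.arange(len(y))
    tr, va = train_test_split(idx, train_size=cfg.split, stratify=y,
                              random_state=int(seed % (2**31)))
    model = SmallCNN(input_hw=X.shape[2:], n_classes=len(classes),
                     hidden=cfg.hidden, seed=int(seed % (2**31)))
    lr = cfg.lr
    best_acc, best_params, best_epoch = -1.0, model.get_params(), 0
    for epoch in range(cfg.epochs):
        if epoch > 0 and epoch % cfg.lr_drop_period == 0:
            lr *= cfg.lr_drop_factor
        order = rng.permutation(tr)
        for i in range(0, order.size, cfg.batch):
            b = order[i:i + cfg.batch]
            model.train_step(X[b], y[b], lr)
        acc = float(np.mean(model.predict(X[va]) == y[va]))
        if acc > best_acc:
            best_acc, best_params, best_epoch = acc, model.get_params(), epoch
    model.set_params(best_params)
    y_pred = model.predict(X[va])
    a, p, r, f = _trial_metrics(y[va], y_pred, cfg.task, classes)
    return model, TrialMetrics(a, p, r, f, best_epoch), va


def train_classifier(X: np.ndarray, labels, cfg: TrainConfig):
    """Train the CNN ``cfg.n_trials`` times on fresh stratified splits.

    ``X`` is the (n, 1, h, w) spectrogram stack, ``labels`` the per-call
    valence or context strings.  Every class must be able to appear in
    both split halves (so at least 2 calls per class).  Returns the model
    of the last trial, the list of per-trial metrics, and the summary.
    """
    cfg.validate()
    labels = np.asarray(labels, dtype=object)
    classes = sorted(np.unique(labels.astype(str)))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    counts = {c: int(np.sum(labels == c)) for c in classes}
    if min(counts.values()) < 2:
        raise ValueError(f"every class needs >= 2 calls for a stratified split: {counts}")
    y = np.array([classes.index(l) for l in labels.astype(str)])
    trials = []
    model = None
    root = np.random.SeedSequence(cfg.rng_seed)
    for t, child in enumerate(root.spawn(cfg.n_trials)):
        seed = int(child.generate_state(1)[0] % (2**31))
        model, tm, _ = _train_one(X, y, classes, cfg, seed)
        trials.append(tm)
    summary = summarize_trials(trials) if len(trials) >= 2 else None
    return model, classes, trials, summary


def summarize_trials(trials) -> MetricsSummary:
    """Mean and standard error of each metric across trials."""
    if len(trials) < 2:
        raise ValueError("need >= 2 trials to summarize")
    arr = {m: np.array([getattr(t, m) for t in trials])
           for m in ("accuracy", "precision", "recall", "f1")}
    mean = {m: float(v.mean()) for m, v in arr.items()}
    se = {m: float(v.std(ddof=1) / np.sqrt(len(trials))) for m, v in arr.items()}
    return MetricsSummary(mean=mean, uncertainty=se, n_trials=len(trials))
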