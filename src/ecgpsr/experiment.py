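"""Training/validation protocol and the time-delay x grid-density sweep.

Per subject, the first 100 beats train the network and the next 25
validate it (chronological, no shuffling across the boundary).  Training
uses Adam on cross-entropy for 75 epochs with dropout 0.5; validation
accuracy is recorded after every epoch.  The factorial sweep regenerates
portraits for every (tau, grid) combination — by default the ten delays
2..36 ms times five grids 16..256, i.e. 50 cells — and summarizes each
accuracy trace over the four 15-epoch stages 16-30, 31-45, 46-60, 61-75.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import preprocess
from .nn import Adam, Model, cross_entropy_grad
from .network import NetworkSpec, build_original_spec, build_scaled_spec
from .phase_space import beat_to_portrait
from .preprocess import BeatSegment
from .synthetic import EcgRecord

DEFAULT_TAUS_MS = (2, 4, 8, 12, 16, 20, 24, 28, 32, 36)
DEFAULT_GRIDS = (16, 32, 64, 128, 256)
STAGES = ((16, 30), (31, 45), (46, 60), (61, 75))  # 1-based inclusive epochs


@dataclass(frozen=True)
class ExperimentConfig:
    tau_list: tuple = DEFAULT_TAUS_MS
    grid_list: tuple = DEFAULT_GRIDS
    out_pixels: int = 256
    epochs: int = 75
    dropout: float = 0.5
    train_beats: int = 100
    val_beats: int = 25
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    seed: int = 0
    arch: str = "original"  # original | scaled
    min_beats: int = preprocess.MIN_BEATS

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if any(t <= 0 for t in self.tau_list):
            raise ValueError("all time delays must be positive")
        if any(g < 2 for g in self.grid_list):
            raise ValueError("all grids must be >= 2")


@dataclass
class SweepResult:
    """Per-(tau, grid) per-epoch validation accuracies plus stage averages."""

    traces: dict = field(default_factory=dict)    # (tau, grid) -> [acc %]
    stage_avgs: dict = field(default_factory=dict)  # (tau, grid) -> tuple
    failures: dict = field(default_factory=dict)  # (tau, grid) -> reason

    def __eq__(self, other):
        if not isinstance(other, SweepResult):
            return NotImplemented
        if set(self.traces) != set(other.traces):
            return False
        # accuracies are persisted at 2 decimals, so compare at that precision
        return all(np.allclose(np.round(self.traces[k], 2),
                               np.round(other.traces[k], 2))
                   for k in self.traces)


def split_beats(beats: list[BeatSegment], train_n: int, val_n: int):
    """Chronological split: first ``train_n`` beats train, next ``val_n``
    validate; any remainder is unused."""
    if len(beats) < train_n + val_n:
        raise ValueError(
            f"subject {beats[0].subject_id if beats else '?'}: "
            f"{len(beats)} beats < train {train_n} + val {val_n}")
    return beats[:train_n], beats[train_n:train_n + val_n]


def _portrait_images(beats, tau_ms, grid, out_pixels, fs):
    return np.stack([
        beat_to_portrait(b, tau_ms, grid, out_pixels, fs).image
        for b in beats]).astype(np.float32)


def evaluate(model: Model, images: np.ndarray, labels: np.ndarray) -> float:
    """Identification accuracy: percentage of arg-max-correct predictions."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("validation set must be non-empty")
    pred = np.argmax(model.forward(images), axis=1)
    return 100.0 * float(np.mean(pred == labels))


def train_model(spec: NetworkSpec, train_images, train_labels,
                val_images, val_labels, config: ExperimentConfig):
    """Train with Adam/cross-entropy; returns (model, per-epoch val accuracy %).

    Deterministic given ``config.seed``: weight init, per-epoch shuffling
    and dropout all draw from seeded streams.
    """
    train_labels = np.asarray(train_labels)
    val_labels = np.asarray(val_labels)
    classes = np.unique(np.concatenate([train_labels, val_labels]))
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    for c in range(spec.num_classes):
        if not np.any(train_labels == c):
            raise ValueError(f"class {c} has no training portraits")

    model = Model(spec, seed=config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.PCG64(config.seed + 1))
    dropout_rng = np.random.default_rng(np.random.PCG64(config.seed + 2))

    n = train_images.shape[0]
    trace = []
    for _ in range(config.epochs):
        order = shuffle_rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward_logits(train_images[idx], train=True,
                                          rng=dropout_rng)
            _, dlogits = cross_entropy_grad(logits, train_labels[idx])
            model.backward(dlogits)
            opt.step(model.gradients())
        trace.append(evaluate(model, val_images, val_labels))
    return model, trace


def prepare_beats(cohort: list[EcgRecord], min_beats: int | None = None,
                  enforce_screening: bool = False):
    """Preprocess a cohort into per-subject verified beat segments.

    Returns (beats_per_subject dict, label map subject_id -> class index).
    Subjects failing the duration/beat-count screen are dropped when
    ``enforce_screening`` is set; otherwise only ``min_beats`` is required.
    """
    beats_by_subject = {}
    for rec in cohort:
        filt = preprocess.bandlimit(rec)
        fid = preprocess.detect_qrs(filt)
        if fid.size < 3:
            continue
        kept = preprocess.verify_beats(filt, fid)
        if enforce_screening and not preprocess.screen_recording(filt, kept):
            continue
        segs = preprocess.segment_beats(filt, kept)
        if min_beats is not None and len(segs) < min_beats:
            continue
        beats_by_subject[rec.subject_id] = segs
    labels = {sid: i for i, sid in enumerate(sorted(beats_by_subject))}
    return beats_by_subject, labels


def run_identification(cohort: list[EcgRecord], tau_ms: float, grid: int,
                       config: ExperimentConfig):
    """End-to-end: preprocess, portrait, train, validate for one (tau, grid).

    Returns (model, per-epoch validation accuracy trace).
    """
    need = config.train_beats + config.val_beats
    beats_by_subject, labels = prepare_beats(cohort, min_beats=need)
    if len(labels) < 2:
        raise ValueError("fewer than 2 subjects survived preprocessing")
    fs = cohort[0].fs

    tr_imgs, tr_lab, va_imgs, va_lab = [], [], [], []
    for sid, segs in beats_by_subject.items():
        train, val = split_beats(segs, config.train_beats, config.val_beats)
        tr_imgs.append(_portrait_images(train, tau_ms, grid,
                                        config.out_pixels, fs))
        va_imgs.append(_portrait_images(val, tau_ms, grid,
                                        config.out_pixels, fs))
        tr_lab += [labels[sid]] * len(train)
        va_lab += [labels[sid]] * len(val)
    tr_imgs = np.concatenate(tr_imgs)
    va_imgs = np.concatenate(va_imgs)

    builder = build_scaled_spec if config.arch == "scaled" else build_original_spec
    spec = builder(len(labels))
    if spec.input_shape[0] != config.out_pixels:
        raise ValueError(
            f"{config.arch} network expects {spec.input_shape[0]} px input, "
            f"config.out_pixels is {config.out_pixels}")
    return train_model(spec, tr_imgs, np.array(tr_lab), va_imgs,
                       np.array(va_lab), config)


def stage_averages(trace: list[float]) -> tuple[float, ...]:
    """Mean validation accuracy over the four 15-epoch training stages.

    Stages are epochs 16-30, 31-45, 46-60 and 61-75 (1-based, inclusive);
    incomplete stages are omitted for shorter traces.
    """
    out = []
    for lo, hi in STAGES:
        if len(trace) >= hi:
            out.append(float(np.mean(trace[lo - 1:hi])))
    return tuple(out)


def run_sweep(cohort: list[EcgRecord], config: ExperimentConfig) -> SweepResult:
    """One training run per (tau, grid) cell; failures are recorded and the
    sweep continues."""
    result = SweepResult()
    for tau in config.tau_list:
        for grid in config.grid_list:
            try:
                _, trace = run_identification(cohort, tau, grid, config)
                result.traces[(tau, grid)] = trace
                result.stage_avgs[(tau, grid)] = stage_averages(trace)
            except Exception as exc:  # cell fails, sweep survives
                result.failures[(tau, grid)] = str(exc)
    return result
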