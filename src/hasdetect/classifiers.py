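"""Training and inference for the three seizure detectors.

Each detector couples a front-end (``features``) with a CNN spec (``arch``)
and trains with RMSProp (lr 1e-3, squared-gradient decay 0.9) over up to 60
epochs, two-class softmax cross-entropy, no denoising and no data
augmentation.  Inputs are scaled once by a constant estimated from the
training set (images by 1/255; time-series by their global standard
deviation); the constant travels with the trained classifier.

Two scale profiles exist: ``paper`` (full-length 51,302-sample segments,
500x333 scalograms, full filter counts) and ``desk`` (shortened segments,
small rasters and filter counts) so that the full pipeline can run on a
single CPU in minutes.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import arch, features
from .arch import CnnSpec
from .core import EegSegment
from .nn import Network, RMSProp, cross_entropy_grad, softmax

DETECTORS = ("ws", "wf", "1d")

LABEL_TO_INT = {"non-HAS": 0, "HAS": 1}


@dataclass
class FeatureProfile:
    """Front-end geometry for one scale profile."""

    scales: np.ndarray
    image_size: tuple[int, int]  # (width, height)
    segment_length: int

    @classmethod
    def paper(cls) -> "FeatureProfile":
        return cls(
            scales=features.SCALES,
            image_size=features.IMAGE_SIZE,
            segment_length=51_302,
        )

    @classmethod
    def desk(cls, segment_length: int = 2560) -> "FeatureProfile":
        return cls(
            scales=np.arange(1, 500, 16),  # 32 scales, same span
            image_size=(64, 48),
            segment_length=segment_length,
        )


@dataclass
class TrainConfig:
    """Optimizer and schedule; defaults follow the study settings."""

    learning_rate: float = 1e-3
    squared_gradient_decay: float = 0.9
    epochs: int = 60
    batch_size: int = 32
    validation_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.epochs, self.batch_size) <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class TrainedClassifier:
    """A trained detector: spec, parameters, scaling, history, provenance."""

    detector: str
    spec: CnnSpec
    network: Network
    config: TrainConfig
    input_scale: float
    history: dict = field(default_factory=dict)
    data_hash: str = ""


def build_spec(
    detector: str, profile: FeatureProfile, desk: bool = False
) -> CnnSpec:
    """Architecture spec for a detector under a feature profile."""
    if detector == "ws":
        w, h = profile.image_size
        if desk:
            return arch.build_ws_cnn_desk(input_shape=(h, w, 3))
        return arch.build_ws_cnn(input_shape=(h, w, 3))
    if detector == "wf":
        filters = (8, 8, 16, 16, 24, 24) if desk else arch.WF_FILTERS
        return arch.build_wf_cnn(L=profile.segment_length, filters=filters)
    if detector == "1d":
        filters = (8, 12, 16, 24, 32, 48) if desk else arch.ONED_FILTERS
        return arch.build_1d_cnn(L=profile.segment_length, filters=filters)
    raise ValueError(f"unknown detector {detector!r}; expected one of {DETECTORS}")


def featurize(
    detector: str,
    segments: list[EegSegment],
    profile: FeatureProfile,
) -> np.ndarray:
    """Front-end tensors (NCHW float32, unscaled) for a list of segments."""
    if detector == "ws":
        out = np.empty(
            (len(segments), 3, profile.image_size[1], profile.image_size[0]),
            dtype=np.float32,
        )
        for i, seg in enumerate(segments):
            sc = features.compute_scalogram(seg, scales=profile.scales)
            img = features.render_scalogram_image(sc, size=profile.image_size)
            out[i] = img.transpose(2, 0, 1)
        return out
    if detector == "wf":
        out = np.empty(
            (len(segments), 1, profile.segment_length, 3), dtype=np.float32
        )
        for i, seg in enumerate(segments):
            out[i, 0] = features.compute_wf_matrix(seg).matrix
        return out
    if detector == "1d":
        out = np.empty(
            (len(segments), 1, profile.segment_length, 1), dtype=np.float32
        )
        for i, seg in enumerate(segments):
            out[i, 0, :, 0] = seg.samples
        return out
    raise ValueError(f"unknown detector {detector!r}")


def labels_to_int(labels) -> np.ndarray:
    return np.array([LABEL_TO_INT[l] if isinstance(l, str) else int(l) for l in labels])


def train_classifier(
    spec: CnnSpec,
    X: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
    detector: str = "",
) -> TrainedClassifier:
    """Train one detector on featurized data.

    ``X`` is NCHW (unscaled front-end output); ``y`` holds int labels
    (1 = HAS).  Raises on empty or single-class data; aborts on NaN loss.
    """
    if config is None:
        config = TrainConfig()
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError(
            f"training data must contain both classes, got only {classes}"
        )

    scale = _input_scale(X)
    Xs = (X / scale).astype(np.float32)
    data_hash = hashlib.sha256(
        np.ascontiguousarray(Xs[: min(len(Xs), 8)]).tobytes()
        + y.astype(np.int64).tobytes()
    ).hexdigest()[:16]

    rng = np.random.default_rng(config.seed)
    n = Xs.shape[0]
    order = rng.permutation(n)
    # stratified validation split
    val_idx, train_idx = [], []
    for c in classes:
        c_idx = order[y[order] == c]
        n_val = max(1, int(round(config.validation_fraction * c_idx.size)))
        val_idx.extend(c_idx[:n_val])
        train_idx.extend(c_idx[n_val:])
    train_idx = np.array(train_idx)
    val_idx = np.array(val_idx)

    net = Network(spec, seed=config.seed)
    opt = RMSProp(
        net,
        lr=config.learning_rate,
        rho=config.squared_gradient_decay,
    )
    history = {"loss": [], "train_acc": [], "val_acc": []}
    for epoch in range(config.epochs):
        rng.shuffle(train_idx)
        losses, hits, seen = [], 0, 0
        for start in range(0, train_idx.size, config.batch_size):
            idx = train_idx[start : start + config.batch_size]
            if idx.size < 2:
                continue  # batch-norm needs more than one sample
            logits = net.forward(Xs[idx], train=True)
            loss, dlogits = cross_entropy_grad(logits.copy(), y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf loss at epoch {epoch}; lower the learning rate"
                )
            hits += int((logits.argmax(axis=1) == y[idx]).sum())
            seen += idx.size
            losses.append(loss)
            net.backward(dlogits)
            opt.step()
        val_scores = _batched_scores(net, Xs[val_idx], config.batch_size)
        val_acc = float(((val_scores > 0.5).astype(int) == y[val_idx]).mean())
        history["loss"].append(float(np.mean(losses)))
        history["train_acc"].append(hits / max(seen, 1))
        history["val_acc"].append(val_acc)

    return TrainedClassifier(
        detector=detector,
        spec=spec,
        network=net,
        config=config,
        input_scale=scale,
        history=history,
        data_hash=data_hash,
    )


def predict(
    classifier: TrainedClassifier, X: np.ndarray, batch_size: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """HAS-class softmax scores and hard labels for featurized inputs.

    The label is the argmax; an exact tie (score 0.5) resolves to non-HAS.
    Order-preserving over the batch.
    """
    expected = X.shape[1:]
    h, w, c = classifier.spec.input_shape
    if expected != (c, h, w):
        raise ValueError(
            f"feature shape {expected} does not match spec input {(c, h, w)}"
        )
    Xs = (X / classifier.input_scale).astype(np.float32)
    scores = _batched_scores(classifier.network, Xs, batch_size)
    labels = (scores > 0.5).astype(int)
    return scores, labels


def _batched_scores(net: Network, X: np.ndarray, batch_size: int) -> np.ndarray:
    scores = np.empty(X.shape[0])
    for start in range(0, X.shape[0], batch_size):
        logits = net.forward(X[start : start + batch_size], train=False)
        scores[start : start + batch_size] = softmax(logits)[:, 1]
    return scores


def _input_scale(X: np.ndarray) -> float:
    """One global scale constant: 255 for uint8-range images, else the std."""
    if X.max() > 10.0 and X.min() >= 0.0:  # image raster
        return 255.0
    return float(max(X.std(), 1e-12))


def save_checkpoint(classifier: TrainedClassifier, path) -> None:
    """Persist a trained detector: parameters + config + provenance hash."""
    import json

    arrays = {
        f"p_{li}_{name}": p for (li, name), p in classifier.network.parameters()
    }
    # batch-norm running statistics are state, not parameters
    for li, layer in enumerate(classifier.network.layers):
        if hasattr(layer, "run_mean"):
            arrays[f"s_{li}_run_mean"] = layer.run_mean
            arrays[f"s_{li}_run_var"] = layer.run_var
    meta = {
        "detector": classifier.detector,
        "input_shape": list(classifier.spec.input_shape),
        "input_scale": classifier.input_scale,
        "data_hash": classifier.data_hash,
        "config": {
            "learning_rate": classifier.config.learning_rate,
            "squared_gradient_decay": classifier.config.squared_gradient_decay,
            "epochs": classifier.config.epochs,
            "batch_size": classifier.config.batch_size,
            "validation_fraction": classifier.config.validation_fraction,
            "seed": classifier.config.seed,
        },
        "history": classifier.history,
    }
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path, spec: CnnSpec) -> TrainedClassifier:
    """Rebuild a trained detector from a checkpoint and its spec."""
    import json

    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        if list(spec.input_shape) != meta["input_shape"]:
            raise ValueError(
                f"spec input shape {spec.input_shape} does not match "
                f"checkpoint {meta['input_shape']}"
            )
        config = TrainConfig(**meta["config"])
        net = Network(spec, seed=config.seed)
        params = dict(net.parameters())
        for key in data.files:
            if key.startswith("p_"):
                li, name = key[2:].split("_", 1)
                params[(int(li), name)][...] = data[key]
            elif key.startswith("s_"):
                li, name = key[2:].split("_", 1)
                setattr(net.layers[int(li)], name, data[key])
    return TrainedClassifier(
        detector=meta["detector"],
        spec=spec,
        network=net,
        config=config,
        input_scale=meta["input_scale"],
        history=meta["history"],
        data_hash=meta["data_hash"],
    )
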