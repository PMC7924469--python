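"""End-to-end orchestration: image -> mask -> border -> descriptor -> decision.

The flow mirrors the package's four stages.  ``process_image`` runs the
deterministic image-analysis front end (grayscale, segmentation, border
trace, 27-value descriptor); ``train_pipeline`` fits the Gaussian naive
Bayes on descriptors and the CNN on (mask, border) image pairs plus the
descriptor; ``predict_pipeline`` fuses both models per sample and
applies the adaptive batch threshold.  Per-image failures during batch
prediction are logged and skipped so a single degenerate input cannot
abort a run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import border as border_mod
from . import classify, features, segmentation
from .cnn import CNNSpec, SmallCNN

log = logging.getLogger("dermoborder")


@dataclass
class PipelineConfig:
    """Every stage parameter in one JSON-serializable document."""

    # segmentation
    c: int = 2
    m: float = 2.0
    alpha: float = 2.0
    bandwidth: float = 63.75
    window: int = 3
    smoothing_scale: int = 2
    darker_is_lesion: bool = True
    threshold_on: str = "membership"
    # border
    canny_sigma: float = 1.4
    canny_low: float | None = None
    canny_high: float | None = None
    # features
    zernike_order: int = 8
    # classifier
    cnn_input_size: int = 128
    cnn_epochs: int = 1
    cnn_filters: tuple[int, ...] = (16, 32, 64, 128, 256)
    cnn_batch_size: int = 8
    seed: int = 0

    def cnn_spec(self) -> CNNSpec:
        return CNNSpec(
            filters=tuple(self.cnn_filters),
            epochs=self.cnn_epochs,
            batch_size=self.cnn_batch_size,
            input_size=self.cnn_input_size,
            seed=self.seed,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "cnn_filters" in d:
            d["cnn_filters"] = tuple(d["cnn_filters"])
        return cls(**d)


@dataclass
class StageResult:
    """Per-image artifacts mirroring the pipeline's intermediate stages."""

    mask: np.ndarray
    trace: border_mod.BorderTrace
    vector: np.ndarray


def process_image(image: np.ndarray, config: PipelineConfig | None = None) -> StageResult:
    """Grayscale -> lesion mask -> border trace -> 27-value descriptor."""
    config = config or PipelineConfig()
    mask = segmentation.extract_lesion_mask(
        image,
        c=config.c,
        m=config.m,
        alpha=config.alpha,
        bandwidth=config.bandwidth,
        window=config.window,
        smoothing_scale=config.smoothing_scale,
        seed=config.seed,
        darker_is_lesion=config.darker_is_lesion,
        threshold_on=config.threshold_on,
    )
    params = border_mod.CannyParams(
        sigma=config.canny_sigma, low=config.canny_low, high=config.canny_high
    )
    trace = border_mod.canny_border(mask.astype(float), params)
    vector = features.irregularity_vector(mask, trace)
    return StageResult(mask=mask, trace=trace, vector=vector)


def cnn_channels(result: StageResult, size: int) -> np.ndarray:
    """Stack the smoothed segmented mask and border map as a 2-channel
    image of the CNN's input size (nearest-style resampling keeps both
    channels binary)."""
    from skimage.transform import resize

    border_img = np.zeros(result.mask.shape, dtype=float)
    pts = result.trace.points
    border_img[pts[:, 0], pts[:, 1]] = 1.0
    mask_r = resize(result.mask.astype(float), (size, size), order=1, anti_aliasing=False)
    border_r = resize(border_img, (size, size), order=1, anti_aliasing=False)
    return np.stack([(mask_r > 0.5).astype(np.float32), (border_r > 0).astype(np.float32)])


@dataclass
class TrainedModels:
    gnb: classify.GaussianNBModel
    cnn: SmallCNN
    config: PipelineConfig
    threshold: float | None = None  # training-batch threshold for single-sample use

    def save(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.gnb.to_json(out / "gnb.json")
        self.cnn.save(out / "cnn.npz")
        self.config.to_json(out / "config.json")
        with open(out / "threshold.json", "w") as fh:
            json.dump({"threshold": self.threshold}, fh)
        return out

    @classmethod
    def load(cls, model_dir) -> "TrainedModels":
        d = Path(model_dir)
        with open(d / "threshold.json") as fh:
            thr = json.load(fh)["threshold"]
        return cls(
            gnb=classify.GaussianNBModel.from_json(d / "gnb.json"),
            cnn=SmallCNN.load(d / "cnn.npz"),
            config=PipelineConfig.from_json(d / "config.json"),
            threshold=thr,
        )


def train_pipeline(
    samples, labels, config: PipelineConfig | None = None,
    precomputed: list[StageResult] | None = None,
) -> TrainedModels:
    """Fit the GnB on descriptors and the CNN on (mask, border, descriptor).

    ``samples`` is a list of grayscale images (or objects with an
    ``image`` attribute, e.g. fixtures); each one is run through the
    image-analysis front end unless ``precomputed`` stage results are
    supplied.
    """
    config = config or PipelineConfig()
    labels = np.asarray(labels)
    if precomputed is None:
        precomputed = [
            process_image(getattr(s, "image", s), config) for s in samples
        ]
    vectors = np.array([r.vector for r in precomputed])
    gnb = classify.gnb_fit(vectors, labels)
    images = np.stack([cnn_channels(r, config.cnn_input_size) for r in precomputed])
    cnn = SmallCNN(config.cnn_spec()).fit(images, vectors, labels)
    models = TrainedModels(gnb=gnb, cnn=cnn, config=config)
    train_scores = _scores(models, precomputed)
    models.threshold = classify.decision_threshold(train_scores)
    return models


def _scores(models: TrainedModels, results: list[StageResult]) -> list[float]:
    vectors = np.array([r.vector for r in results])
    images = np.stack(
        [cnn_channels(r, models.config.cnn_input_size) for r in results]
    )
    s = models.cnn.predict_proba(images, vectors)
    scores = []
    for i, r in enumerate(results):
        cnn_p = (1.0 - float(s[i]), float(s[i]))  # (irregular, regular)
        gnb_p = classify.gnb_predict(models.gnb, r.vector)
        scores.append(classify.ensemble_score(cnn_p, gnb_p))
    return scores


def predict_pipeline(
    models: TrainedModels, inputs, ids=None, batch_threshold: bool = True
):
    """Score a batch and decide regular/irregular per sample.

    Returns (records, threshold): one record per successfully processed
    input with its fused score, decision, descriptor and artifacts.
    With ``batch_threshold`` the adaptive threshold is computed over
    this test batch; otherwise the stored training-time threshold is
    used (single-sample mode).
    """
    config = models.config
    ids = list(ids) if ids is not None else list(range(len(inputs)))
    results, kept_ids = [], []
    for i, item in enumerate(inputs):
        try:
            results.append(process_image(getattr(item, "image", item), config))
            kept_ids.append(ids[i])
        except Exception as exc:  # noqa: BLE001 - batch runs skip bad images
            log.warning("skipping %s: %s", ids[i], exc)
    if not results:
        raise RuntimeError("every input failed the image-analysis front end")
    scores = _scores(models, results)
    if batch_threshold:
        threshold = classify.decision_threshold(scores)
    else:
        if models.threshold is None:
            raise ValueError("no stored training-time threshold available")
        threshold = models.threshold
    records = [
        {
            "id": kept_ids[i],
            "score": scores[i],
            "decision": classify.decide(scores[i], threshold),
            "vector": results[i].vector,
            "result": results[i],
        }
        for i in range(len(results))
    ]
    return records, threshold
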