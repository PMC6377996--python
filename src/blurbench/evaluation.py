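"""Linear-separability benchmark of the two representations over blur sizes.

For each blur size, a balanced horizontal/vertical motion-blur dataset is
built from randomly sampled natural-image windows, each window is encoded
by the thalamic (LGN) and/or cortical (L4) representation, and a linear
maximum-margin classifier is trained and scored on repeated stratified
50/50 holdout splits.  The mean held-out accuracy per (representation,
blur size) is the benchmark output: chance (50%) means the blur
orientation is not linearly decodable from that representation, and the
gap between the L4 and thalamic curves measures how much the recurrent
cortical stage linearises the problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from . import l4_model, lgn_model, motion_blur, synthetic_images
from .exceptions import ConfigError
from .synthetic_images import GrayImage, WindowSample

__all__ = [
    "BenchmarkResult",
    "MisclassificationReport",
    "EvalSplit",
    "evaluate_once",
    "train_l4_on_images",
    "run_benchmark",
    "threshold_report",
    "misclassification_gallery",
    "derive_seed",
    "THALAMIC",
    "L4",
]

THALAMIC = "thalamic"
L4 = "l4"

DEFAULT_SVM_C = 1.0
DEFAULT_SPLIT_FRACTION = 0.5


def derive_seed(master_seed: int, *stage: int | str) -> int:
    """Deterministic per-stage seed derived from the master seed.

    Stage labels are hashed into the entropy pool so that every
    (blur size, representation, repetition, ...) combination receives an
    independent, reproducible stream.  The result fits in 31 bits.
    """
    parts = [int(master_seed)]
    for s in stage:
        if isinstance(s, str):
            parts.append(int.from_bytes(s.encode(), "little") % (2**32))
        else:
            parts.append(int(s))
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class EvalSplit:
    """Outcome of one train/test split: accuracy and held-out predictions."""

    accuracy: float
    predictions: np.ndarray  # predicted labels on the held-out half
    test_indices: np.ndarray  # row indices (into the feature matrix) held out
    true_labels: np.ndarray


def evaluate_once(
    features: np.ndarray,
    labels: Sequence[int] | np.ndarray,
    split_fraction: float = DEFAULT_SPLIT_FRACTION,
    seed: int = 0,
    svm_c: float = DEFAULT_SVM_C,
) -> EvalSplit:
    """One stratified holdout evaluation with a linear SVM.

    The split is stratified at ``split_fraction`` (training share); features
    are z-scored with statistics fit on the training half only, and a linear
    SVM (squared hinge, primal, C=1 by default) is fit and scored on the
    held-out half.  Deterministic given the inputs and seed.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ConfigError("features must be 2-D with one row per label")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ConfigError("need samples from both classes")
    if counts.min() < 2:
        raise ConfigError("need at least 2 samples per class")
    idx = np.arange(x.shape[0])
    train_idx, test_idx = train_test_split(
        idx, train_size=split_fraction, stratify=y, random_state=seed
    )
    clf = make_pipeline(
        StandardScaler(),
        LinearSVC(C=svm_c, dual=False, max_iter=10_000),
    )
    clf.fit(x[train_idx], y[train_idx])
    pred = clf.predict(x[test_idx])
    acc = float((pred == y[test_idx]).mean())
    return EvalSplit(
        accuracy=acc,
        predictions=pred,
        test_indices=test_idx,
        true_labels=y[test_idx],
    )


@dataclass
class BenchmarkResult:
    """Per-repetition accuracies keyed by (representation, blur size).

    ``table`` is tidy: one row per (representation, blur_size, repetition)
    with the held-out accuracy as a fraction.  ``gallery_data`` retains, per
    key, the material needed for misclassification galleries from the last
    repetition: original and blurred windows, held-out indices, predictions
    and true labels.
    """

    table: pd.DataFrame
    gallery_data: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Mean and SD of accuracy over repetitions, per representation and size."""
        g = self.table.groupby(["representation", "blur_size"])["accuracy"]
        out = g.agg(mean_accuracy="mean", sd_accuracy="std", n_repetitions="count")
        return out.reset_index()

    def accuracies(self, representation: str, blur_size: int) -> np.ndarray:
        mask = (self.table["representation"] == representation) & (
            self.table["blur_size"] == blur_size
        )
        if not mask.any():
            raise ConfigError(
                f"no results for representation={representation!r}, "
                f"blur_size={blur_size}"
            )
        return self.table.loc[mask, "accuracy"].to_numpy()

    def mean_accuracy(self, representation: str, blur_size: int) -> float:
        return float(self.accuracies(representation, blur_size).mean())

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def _representation_features(
    representation: str,
    lgn_features: np.ndarray,
    network: l4_model.L4Network | None,
    dt: float,
    tol: float,
    max_steps: int,
) -> np.ndarray:
    if representation == THALAMIC:
        return lgn_features
    if representation == L4:
        if network is None:
            raise ConfigError("an L4 network is required for the l4 representation")
        return l4_model.l4_represent(network, lgn_features, dt=dt, tol=tol,
                                     max_steps=max_steps)
    raise ConfigError(f"unknown representation {representation!r}")


def train_l4_on_images(
    images: Sequence[GrayImage],
    corpus_size: int = 2000,
    window_size: int = 25,
    max_blur: int = 8,
    mosaic: lgn_model.LgnMosaic | None = None,
    profile: lgn_model.RFProfile | None = None,
    theta: float = l4_model.DEFAULT_THETA,
    lam: float = l4_model.DEFAULT_LAMBDA,
    epochs: int = 10,
    seed: int = 0,
) -> l4_model.L4Network:
    """Train an L4 network on the motion ensemble of a set of images.

    The corpus is a fresh draw of ``corpus_size`` windows (independent of
    any benchmark pool), each experienced under the motion ensemble the
    visual environment presents: one third unblurred, one third under
    horizontal and one third under vertical motion with extents drawn
    uniformly from 2..``max_blur``.  This gives the network the
    horizontally and vertically adapted units that carry the orientation
    signal; no class labels are involved.
    """
    mosaic = mosaic or lgn_model.hex_mosaic(window_size=window_size)
    profile = profile or lgn_model.dog_profile()
    margin = max(max_blur // 2, 0)
    windows = synthetic_images.sample_windows(
        images, corpus_size, window_size, margin=margin,
        seed=derive_seed(seed, "draw"),
    )
    rng = np.random.default_rng(derive_seed(seed, "ensemble"))
    fields = []
    for w in windows:
        mode = int(rng.integers(3))
        if mode == 0 or max_blur < 2:
            fields.append(w.core.pixels)
        else:
            size = int(rng.integers(2, max_blur + 1))
            orient = motion_blur.HORIZONTAL if mode == 1 else motion_blur.VERTICAL
            fields.append(
                motion_blur.apply_blur(w, motion_blur.BlurSpec(orient, size)).pixels
            )
    corpus = lgn_model.lgn_represent(np.stack(fields), mosaic, profile)
    return l4_model.train_l4(
        corpus, n_units=2 * mosaic.n_centers, theta=theta, lam=lam,
        seed=derive_seed(seed, "adapt"), epochs=epochs,
    )


def run_benchmark(
    images: Sequence[GrayImage],
    n_windows: int = 4000,
    window_size: int = 25,
    blur_sizes: Iterable[int] = range(1, 9),
    representations: Sequence[str] = (THALAMIC, L4),
    n_repetitions: int = 10,
    master_seed: int = 0,
    *,
    margin: int | None = None,
    mosaic: lgn_model.LgnMosaic | None = None,
    profile: lgn_model.RFProfile | None = None,
    network: l4_model.L4Network | None = None,
    train_corpus_size: int = 2000,
    theta: float = l4_model.DEFAULT_THETA,
    lam: float = l4_model.DEFAULT_LAMBDA,
    epochs: int = 20,
    dt: float = l4_model.DEFAULT_DT,
    tol: float = l4_model.DEFAULT_TOL,
    max_steps: int = l4_model.DEFAULT_MAX_STEPS,
    split_fraction: float = DEFAULT_SPLIT_FRACTION,
    svm_c: float = DEFAULT_SVM_C,
    keep_gallery: bool = False,
) -> BenchmarkResult:
    """Run the full accuracy-vs-blur-size benchmark.

    One pool of ``n_windows`` windows is drawn once (margin defaulting to
    the largest requested blur size) and re-used across blur sizes; the
    horizontal/vertical assignment is re-drawn per blur size, and every
    repetition uses an independently derived split seed.  If the L4
    representation is requested and no pre-trained ``network`` is supplied,
    one is trained on the LGN vectors of a separate draw of unblurred
    windows (never the benchmark windows).
    """
    blur_sizes = list(blur_sizes)
    if not blur_sizes or min(blur_sizes) < 1:
        raise ConfigError("blur_sizes must be integers >= 1")
    if margin is None:
        margin = max(blur_sizes)
    mosaic = mosaic or lgn_model.hex_mosaic(window_size=window_size)
    profile = profile or lgn_model.dog_profile()

    windows = synthetic_images.sample_windows(
        images, n_windows, window_size, margin=margin,
        seed=derive_seed(master_seed, "windows"),
    )

    if L4 in representations and network is None:
        network = train_l4_on_images(
            images,
            corpus_size=train_corpus_size,
            window_size=window_size,
            max_blur=max(blur_sizes),
            mosaic=mosaic,
            profile=profile,
            theta=theta,
            lam=lam,
            epochs=epochs,
            seed=derive_seed(master_seed, "train-corpus"),
        )

    rows = []
    gallery: dict = {}
    for size in blur_sizes:
        dataset = motion_blur.build_dataset(
            windows, size, assignment_seed=derive_seed(master_seed, "assign", size)
        )
        labels = np.array([s.label for s in dataset])
        blurred = np.stack([s.window.pixels for s in dataset])
        lgn_features = lgn_model.lgn_represent(blurred, mosaic, profile)
        for representation in representations:
            feats = _representation_features(
                representation, lgn_features, network, dt, tol, max_steps
            )
            for rep in range(n_repetitions):
                split = evaluate_once(
                    feats, labels, split_fraction,
                    seed=derive_seed(master_seed, "split", size, representation, rep),
                    svm_c=svm_c,
                )
                rows.append(
                    dict(representation=representation, blur_size=size,
                         repetition=rep, accuracy=split.accuracy)
                )
            if keep_gallery:
                gallery[(representation, size)] = dict(
                    split=split,
                    originals=np.stack([w.core.pixels for w in windows]),
                    blurred=blurred,
                    labels=labels,
                )
    return BenchmarkResult(table=pd.DataFrame(rows), gallery_data=gallery)


def threshold_report(
    result: BenchmarkResult,
    reference_size: int = 8,
    threshold: float = 0.80,
) -> pd.DataFrame:
    """Accuracy at the reference blur size against the pass threshold.

    Returns one row per representation with the mean accuracy at
    ``reference_size`` and whether it reaches ``threshold`` (default 0.80,
    the score level below which performance is considered impaired); the
    full per-size curve stays available via ``result.summary()``.
    """
    if result.table.empty:
        raise ConfigError("empty benchmark result")
    if reference_size not in set(result.table["blur_size"]):
        raise ConfigError(f"reference blur size {reference_size} not in results")
    summary = result.summary()
    ref = summary[summary["blur_size"] == reference_size].copy()
    ref["threshold"] = threshold
    ref["passes_threshold"] = ref["mean_accuracy"] >= threshold
    return ref.reset_index(drop=True)


@dataclass(frozen=True)
class MisclassificationReport:
    """Held-out samples the classifier got wrong (plus correct exemplars)."""

    misclassified: pd.DataFrame
    correct: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.misclassified) and (
            self.misclassified["predicted"] == self.misclassified["true"]
        ).any():
            raise ConfigError("misclassified table contains correct predictions")


def misclassification_gallery(
    result: BenchmarkResult,
    representation: str,
    blur_size: int,
    k: int = 8,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> MisclassificationReport:
    """Sample k misclassified and k correctly classified held-out windows.

    Only held-out (never training) samples appear.  If fewer than k are
    available in a category, all of them are returned.  With ``out_dir``
    set, each selected sample is exported as an original/blurred PNG pair.
    """
    key = (representation, blur_size)
    if key not in result.gallery_data:
        raise ConfigError(
            "no retained predictions for this key; rerun with keep_gallery=True"
        )
    data = result.gallery_data[key]
    split: EvalSplit = data["split"]
    rng = np.random.default_rng(seed)

    wrong_mask = split.predictions != split.true_labels
    frames = {}
    for name, mask in (("miss", wrong_mask), ("hit", ~wrong_mask)):
        pool = np.flatnonzero(mask)
        take = pool if pool.size <= k else rng.choice(pool, size=k, replace=False)
        frames[name] = pd.DataFrame(
            dict(
                sample_index=split.test_indices[take],
                true=split.true_labels[take],
                predicted=split.predictions[take],
            )
        )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, frame in frames.items():
            for _, row in frame.iterrows():
                i = int(row["sample_index"])
                stem = f"{representation}_b{blur_size}_{name}_{i:05d}"
                synthetic_images.write_image(
                    GrayImage(data["originals"][i]), out_dir / f"{stem}_orig.png"
                )
                synthetic_images.write_image(
                    GrayImage(data["blurred"][i]), out_dir / f"{stem}_blur.png"
                )
    return MisclassificationReport(
        misclassified=frames["miss"], correct=frames["hit"]
    )
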