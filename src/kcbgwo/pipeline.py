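"""End-to-end KCBGWO-ELM classification pipeline on feature tables.

Covers the bookkeeping around the optimizer/classifier couple: fusion of
named CNN-style feature blocks by column concatenation, a synthetic
class-conditional Gaussian feature generator emulating fused deep features
for the five diabetic-retinopathy grades, oversampling-based class
balancing, KCBGWO tuning of ELM input weights/biases under an MSE fitness,
and split-based evaluation with the standard one-vs-rest metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import elm
from .gwo import OptimizationResult
from .metrics import MetricReport, multiclass_report
from .optimizer import KCBGWOConfig, minimize

__all__ = [
    "DR_CLASS_NAMES",
    "IDRID_GRADE_COUNTS",
    "FUSION_STRATEGIES",
    "BLOCK_WIDTHS",
    "FeatureBlock",
    "LabeledFeatureSet",
    "SyntheticSpec",
    "PipelineConfig",
    "fuse",
    "generate_synthetic_features",
    "balance_classes",
    "split_train_test",
    "tune_elm",
    "evaluate_split",
    "run_pipeline",
    "load_feature_csv",
    "save_feature_csv",
]

DR_CLASS_NAMES = ("Normal", "Mild", "Moderate", "Severe", "PDR")

# per-grade image counts of the IDRiD training distribution (grades 0..4)
IDRID_GRADE_COUNTS = (134, 20, 84, 74, 49)

# declared dimensionality of each named feature block
BLOCK_WIDTHS = {
    "K1": 2048, "K2": 1920, "K3": 512, "K4": 1536,
    "L1": 1024, "L2": 1792, "L3": 512,
    "M1": 512, "M2": 512, "M3": 256,
}

# named fusion strategies: required blocks in their printed order
FUSION_STRATEGIES = {
    "FS1": ("K1", "K2", "K3", "K4"),  # fused width 6016
    "FS2": ("L1", "L2", "L3"),        # fused width 3328
    "FS3": ("M1", "M2", "M3"),        # fused width 1280
}


@dataclass
class FeatureBlock:
    """One named block of per-sample features (e.g. one backbone layer)."""

    block_id: str
    width: int
    matrix: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[1] != self.width:
            raise ValueError(
                f"block {self.block_id!r}: declared width {self.width} but "
                f"matrix has {self.matrix.shape[1]} columns"
            )


@dataclass
class LabeledFeatureSet:
    """Feature matrix with integer grade labels (0=Normal .. 4=PDR)."""

    features: np.ndarray
    labels: np.ndarray
    class_names: tuple = DR_CLASS_NAMES
    synthetic: np.ndarray | None = None  # per-sample provenance flag

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape[0] != self.features.shape[0]:
            raise ValueError("label count must equal sample count")
        n_classes = len(self.class_names)
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= n_classes
        ):
            raise ValueError(f"labels must lie in [0, {n_classes - 1}]")
        if self.synthetic is None:
            self.synthetic = np.zeros(self.labels.shape[0], dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=len(self.class_names))


@dataclass
class SyntheticSpec:
    """Class-conditional Gaussian generator settings.

    Class means sit on mutually orthogonal directions scaled so every pair
    of means is ``separation`` apart; features are isotropic Gaussian with
    standard deviation ``noise_scale`` around the class mean.  Default
    per-class counts follow the IDRiD grade distribution.
    """

    counts: tuple = IDRID_GRADE_COUNTS
    dim: int = 20
    separation: float = 3.0
    noise_scale: float = 1.0
    seed: int = 0


@dataclass
class PipelineConfig:
    """Settings for the full generate/balance/tune/evaluate pipeline."""

    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)
    n_hidden: int = 40
    activation: str = "sigmoid"
    tuner: KCBGWOConfig = field(default_factory=lambda: KCBGWOConfig(
        pop_size=30, iterations=50, n_clusters=3, mode="continuous",
        bounds=(-1.0, 1.0),
    ))
    test_fraction: float = 0.3
    split_seed: int = 0
    fitness_split: str = "train"  # or "holdout"
    balance: bool = True
    jitter_scale: float = 0.1

    def validate(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.fitness_split not in ("train", "holdout"):
            raise ValueError("fitness_split must be 'train' or 'holdout'")


def fuse(blocks: list[FeatureBlock], strategy: str = "custom") -> np.ndarray:
    """Column-concatenate sample-aligned blocks in the given order.

    A named strategy (FS1/FS2/FS3) additionally enforces the identity and
    order of its required blocks; no scaling is applied.
    """
    if not blocks:
        raise ValueError("fuse requires at least one block")
    if strategy != "custom":
        try:
            required = FUSION_STRATEGIES[strategy]
        except KeyError:
            raise ValueError(f"unknown fusion strategy {strategy!r}") from None
        got = tuple(b.block_id for b in blocks)
        if got != required:
            raise ValueError(
                f"strategy {strategy} requires blocks {required} in order, got {got}"
            )
        for b in blocks:
            if b.width != BLOCK_WIDTHS[b.block_id]:
                raise ValueError(
                    f"block {b.block_id} must have width {BLOCK_WIDTHS[b.block_id]}, "
                    f"got {b.width}"
                )
    n_samples = {b.matrix.shape[0] for b in blocks}
    if len(n_samples) > 1:
        raise ValueError(f"blocks are not sample-aligned: row counts {n_samples}")
    return np.concatenate([b.matrix for b in blocks], axis=1)


def _class_means(n_classes: int, dim: int, separation: float) -> np.ndarray:
    if dim < n_classes:
        raise ValueError(f"dim must be >= {n_classes} to place orthogonal means")
    # orthogonal unit directions scaled so pairwise distances all equal
    # `separation`: |s*e_i - s*e_j| = s*sqrt(2)
    means = np.zeros((n_classes, dim))
    scale = separation / np.sqrt(2.0)
    for c in range(n_classes):
        means[c, c] = scale
    return means


def generate_synthetic_features(spec: SyntheticSpec) -> LabeledFeatureSet:
    """Sample class-conditional Gaussian features emulating fused CNN vectors."""
    counts = np.asarray(spec.counts, dtype=int)
    if counts.min() < 0:
        raise ValueError("per-class counts must be >= 0")
    if counts.sum() == 0:
        raise ValueError("at least one class must have samples")
    if spec.dim < 2:
        raise ValueError("dim must be >= 2")
    rng = np.random.default_rng(spec.seed)
    means = _class_means(len(counts), spec.dim, spec.separation)
    feats, labels = [], []
    for c, n_c in enumerate(counts):
        if n_c == 0:
            continue
        feats.append(
            means[c] + spec.noise_scale * rng.standard_normal((n_c, spec.dim))
        )
        labels.append(np.full(n_c, c))
    return LabeledFeatureSet(
        features=np.concatenate(feats),
        labels=np.concatenate(labels),
        class_names=DR_CLASS_NAMES
        if len(counts) == 5
        else tuple(f"class{c}" for c in range(len(counts))),
    )


def balance_classes(
    dataset: LabeledFeatureSet,
    jitter_scale: float = 0.1,
    rng: np.random.Generator | int | None = None,
) -> LabeledFeatureSet:
    """Top every minority class up to the majority count by jittered resampling.

    New rows are existing class members plus Gaussian noise scaled by
    ``jitter_scale`` times the per-feature standard deviation of that class;
    they are flagged synthetic.  Original rows are kept bit-exactly.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    counts = dataset.class_counts()
    present = np.flatnonzero(counts)
    target = int(counts.max())
    feats = [dataset.features]
    labels = [dataset.labels]
    flags = [np.asarray(dataset.synthetic, dtype=bool)]
    for c in range(counts.size):
        deficit = target - counts[c]
        if deficit <= 0:
            continue
        if counts[c] == 0:
            raise ValueError(
                f"class {c} has no samples; cannot synthesize from nothing"
            )
        members = dataset.features[dataset.labels == c]
        idx = rng.integers(0, members.shape[0], size=deficit)
        sd = members.std(axis=0, ddof=0)
        jitter = jitter_scale * sd * rng.standard_normal((deficit, members.shape[1]))
        feats.append(members[idx] + jitter)
        labels.append(np.full(deficit, c))
        flags.append(np.ones(deficit, dtype=bool))
    if len(feats) == 1:
        return replace(dataset)
    return LabeledFeatureSet(
        features=np.concatenate(feats),
        labels=np.concatenate(labels),
        class_names=dataset.class_names,
        synthetic=np.concatenate(flags),
    )


def split_train_test(
    dataset: LabeledFeatureSet, test_fraction: float, seed: int
) -> tuple[LabeledFeatureSet, LabeledFeatureSet]:
    """Stratified train/test split preserving class proportions."""
    idx_train, idx_test = train_test_split(
        np.arange(dataset.n_samples),
        test_size=test_fraction,
        random_state=seed,
        stratify=dataset.labels,
    )
    def take(idx):
        return LabeledFeatureSet(
            features=dataset.features[idx],
            labels=dataset.labels[idx],
            class_names=dataset.class_names,
            synthetic=np.asarray(dataset.synthetic)[idx],
        )
    return take(idx_train), take(idx_test)


def tune_elm(
    train_set: LabeledFeatureSet, config: PipelineConfig
) -> tuple[elm.ELMModel, OptimizationResult]:
    """Optimize ELM input weights and biases with continuous KCBGWO.

    Each candidate is the flattened (G x n) input-weight matrix followed by
    the G biases, all in [-1, 1].  Candidate fitness is the training MSE of
    the ELM whose output weights are solved by pseudoinverse against the
    one-hot targets (on the training split, or on an internal holdout when
    ``fitness_split='holdout'``).  The returned model is trained with the
    best candidate's weights and biases.
    """
    config.validate()
    g = config.n_hidden
    n = train_set.n_features
    dim = g * (n + 1)
    if dim > 1_000_000:
        raise ValueError(
            f"candidate dimension {dim} exceeds 1e6; reduce n_hidden or the "
            f"feature dimension"
        )

    if config.fitness_split == "holdout":
        fit_train, fit_eval = split_train_test(
            train_set, 0.25, config.split_seed + 1
        )
    else:
        fit_train = fit_eval = train_set

    enc_train = elm.one_hot_targets(fit_train.labels)
    # evaluation targets in the same class order as the training encoding
    t_eval = (
        fit_eval.labels[:, None] == enc_train.class_labels[None, :]
    ).astype(float)

    def unflatten(vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return vec[: g * n].reshape(g, n), vec[g * n :]

    def fitness(vec: np.ndarray) -> float:
        weights, biases = unflatten(vec)
        model = elm.train(
            fit_train.features,
            enc_train,
            n_hidden=g,
            activation=config.activation,
            input_weights=weights,
            biases=biases,
        )
        return elm.mean_squared_error(t_eval, elm.predict(model, fit_eval.features))

    tuner_cfg = replace(
        config.tuner, mode="continuous", bounds=(-1.0, 1.0), dim=dim
    )
    result = minimize(fitness, tuner_cfg)

    weights, biases = unflatten(result.best_position)
    enc_full = elm.one_hot_targets(train_set.labels)
    model = elm.train(
        train_set.features,
        enc_full,
        n_hidden=g,
        activation=config.activation,
        input_weights=weights,
        biases=biases,
    )
    return model, result


def evaluate_split(model: elm.ELMModel, test_set: LabeledFeatureSet) -> MetricReport:
    """Arg-max predictions on a held-out set with one-vs-rest metrics."""
    if test_set.n_samples == 0:
        raise ValueError("cannot evaluate an empty test set")
    scores = elm.predict(model, test_set.features)
    y_pred = model.class_labels[np.argmax(scores, axis=1)]
    observed = np.unique(np.concatenate([test_set.labels, y_pred]))
    names = [test_set.class_names[c] for c in observed]
    return multiclass_report(
        test_set.labels, y_pred, class_names=names, scores=scores
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Generate, balance, split, tune and evaluate in one seeded sweep."""
    config.validate()
    data = generate_synthetic_features(config.synthetic)
    if config.balance:
        data = balance_classes(
            data, config.jitter_scale,
            np.random.default_rng(config.synthetic.seed + 1),
        )
    train_set, test_set = split_train_test(
        data, config.test_fraction, config.split_seed
    )
    model, result = tune_elm(train_set, config)
    report = evaluate_split(model, test_set)
    return {
        "model": model,
        "optimization": result,
        "report": report,
        "train_set": train_set,
        "test_set": test_set,
    }


def load_feature_csv(path, label_col: str = "label") -> LabeledFeatureSet:
    """Read a headered CSV with one integer label column into a feature set."""
    df = pd.read_csv(path)
    if label_col not in df.columns:
        raise ValueError(f"column {label_col!r} not found in {path}")
    labels = df[label_col].to_numpy(dtype=int)
    feats = df.drop(columns=[label_col]).to_numpy(dtype=float)
    return LabeledFeatureSet(features=feats, labels=labels)


def save_feature_csv(dataset: LabeledFeatureSet, path, label_col: str = "label") -> None:
    df = pd.DataFrame(
        dataset.features,
        columns=[f"f{i}" for i in range(dataset.n_features)],
    )
    df[label_col] = dataset.labels
    df.to_csv(path, index=False)
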