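"""Training protocol, cross-validation and model comparison.

The protocol mirrors the study it re-implements: mini-batch training of
a softmax/cross-entropy classifier (Adam), a stratified 50/50
train/test split for the MLP and FCN baselines, stratified k-fold
cross-validation (k = 5) with the mean per-fold accuracy (MPCE) for
ERISNet, per-epoch learning curves, and a three-way comparison.  Every
stochastic element — splitting, fold assignment, batch shuffling,
weight initialization, dropout — is a pure function of the configured
seed, so a run is bit-reproducible on one platform.

Two presentation layers coexist: plain functions
(:func:`split_train_test`, :func:`train`, :func:`kfold_cv`,
:func:`compare_models`) and a thin model-object API
(:class:`PixelClassifier` → :class:`FitResult`) for interactive use.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from sargnet.dataset import NoDataError, SpectralDataset
from sargnet.nn import Adam, Network, build
from sargnet.specs import ArchitectureSpec, erisnet_spec, fcn_spec, mlp_spec


@dataclass(frozen=True)
class TrainingConfig:
    """Training protocol settings.

    Defaults follow the published protocol: 3000 epochs with mini-batches
    of 100 pixels and a 50/50 stratified split.  The optimizer was not
    published; Adam at learning rate 1e-3 is the default.  Inputs are
    raw reflectances unless ``standardize_inputs`` is set (per-feature
    z-scoring fitted on the training split).
    """

    epochs: int = 3000
    batch_size: int = 100
    seed: int = 0
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    l2_coefficient: float = 1e-3
    standardize_inputs: bool = False
    split_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")

    def with_(self, **changes) -> "TrainingConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class LearningCurves:
    """Per-epoch train/test accuracy; both sequences have length = epochs."""

    train_accuracy: tuple[float, ...]
    test_accuracy: tuple[float, ...]

    @property
    def final_test_accuracy(self) -> float:
        return self.test_accuracy[-1]

    @property
    def best_test_accuracy(self) -> float:
        return float(np.nanmax(self.test_accuracy))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, len(self.train_accuracy) + 1),
            "train_accuracy": self.train_accuracy,
            "test_accuracy": self.test_accuracy,
        })


@dataclass(frozen=True)
class CVResult:
    """Stratified k-fold outcome: per-fold correct counts e_i, fold
    sizes c_i, per-fold accuracies e_i/c_i, and their mean (MPCE)."""

    k: int
    per_fold_correct: tuple[int, ...]
    per_fold_total: tuple[int, ...]
    per_fold_accuracy: tuple[float, ...]
    mpce: float
    curves: tuple[LearningCurves, ...] = ()

    def __post_init__(self) -> None:
        if not (len(self.per_fold_correct) == len(self.per_fold_total)
                == len(self.per_fold_accuracy) == self.k):
            raise ValueError("per-fold sequences must have length k")


def split_train_test(
    ds: SpectralDataset, fraction: float, seed: int
) -> tuple[SpectralDataset, SpectralDataset]:
    """Seeded stratified split; rounding goes toward the training side.

    Per class, ``ceil(fraction * n_class)`` pixels are assigned to the
    training set.  The two halves are disjoint, exhaustive, and each
    preserves the original row order.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    labels = ds.labels
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5417]))
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for label in (0, 1):
        idx = np.flatnonzero(labels == label)
        if idx.size < 2:
            raise ValueError(
                f"class {label} has {idx.size} member(s); need >= 2 to stratify"
            )
        perm = rng.permutation(idx)
        n_train = int(np.ceil(fraction * idx.size))
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    train = np.sort(np.concatenate(train_idx))
    test = np.sort(np.concatenate(test_idx))
    return ds.subset(train), ds.subset(test)


def _accuracy(model: Network, features: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean(model.predict(features) == labels))


def train(
    model: Network,
    train_set: SpectralDataset,
    test_set: SpectralDataset | None,
    config: TrainingConfig,
) -> tuple[Network, LearningCurves]:
    """Mini-batch cross-entropy training with per-epoch accuracy curves.

    Each epoch is one full pass over the training set in seeded-shuffled
    mini-batches of ``config.batch_size``; there is no early stopping.
    The trained weights are a pure function of (data, config.seed,
    model build seed).  A non-finite loss aborts with the offending
    epoch and batch named.
    """
    if len(train_set) == 0:
        raise NoDataError("training set is empty")
    x_train = train_set.features()
    y_train = train_set.labels
    if config.standardize_inputs:
        model.input_mean = x_train.mean(axis=0)
        model.input_std = np.maximum(x_train.std(axis=0), 1e-9)
    x_test = test_set.features() if test_set is not None and len(test_set) else None
    y_test = test_set.labels if x_test is not None else None

    optimizer = Adam(model.params(), learning_rate=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0x7a11]))
    n = len(train_set)
    train_curve: list[float] = []
    test_curve: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for batch_index, start in enumerate(range(0, n, config.batch_size)):
            idx = order[start:start + config.batch_size]
            loss = model.loss_and_grad(x_train[idx], y_train[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch + 1}, batch {batch_index + 1}"
                )
            optimizer.step()
        train_curve.append(_accuracy(model, x_train, y_train))
        test_curve.append(
            _accuracy(model, x_test, y_test) if x_test is not None else float("nan")
        )
    return model, LearningCurves(tuple(train_curve), tuple(test_curve))


def evaluate_accuracy(model: Network, test_set: SpectralDataset) -> float:
    """Fraction of pixels whose hard call matches the label.

    A predicted probability of exactly 0.5 counts as class 0.
    """
    if len(test_set) == 0:
        raise NoDataError("test set is empty")
    return _accuracy(model, test_set.features(), test_set.labels)


def mpce(per_fold_correct, per_fold_total) -> float:
    """Mean per-fold accuracy: (1/k) Σ e_i / c_i."""
    e = np.asarray(per_fold_correct, dtype=float)
    c = np.asarray(per_fold_total, dtype=float)
    if e.shape != c.shape or e.ndim != 1 or e.size == 0:
        raise ValueError("inputs must be equal-length non-empty 1D sequences")
    if np.any(c <= 0):
        raise ValueError("every fold total must be positive")
    if np.any(e < 0) or np.any(e > c):
        raise ValueError("correct counts must lie in [0, total] per fold")
    return float(np.mean(e / c))


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Seeded stratified partition into k folds (index arrays).

    Folds are disjoint and exhaustive, and each class is spread across
    folds to within one pixel of the global proportion.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xf01d]))
    per_fold: list[list[np.ndarray]] = [[] for _ in range(k)]
    sizes = np.zeros(k, dtype=int)
    for label in np.unique(labels):
        idx = np.flatnonzero(labels == label)
        if idx.size < k:
            raise ValueError(f"class {label} has {idx.size} member(s); need >= k={k}")
        shuffled = rng.permutation(idx)
        base, remainder = divmod(idx.size, k)
        # leftover pixels go to the currently smallest folds, so overall
        # fold sizes stay as even as the dataset allows
        fold_sizes = np.full(k, base)
        fold_sizes[np.argsort(sizes, kind="stable")[:remainder]] += 1
        for fold, chunk in enumerate(np.split(shuffled, np.cumsum(fold_sizes)[:-1])):
            per_fold[fold].append(chunk)
            sizes[fold] += len(chunk)
    return [np.sort(np.concatenate(chunks)) for chunks in per_fold]


def _fold_seed(seed: int, fold: int) -> int:
    state = np.random.SeedSequence([int(seed), int(fold)]).generate_state(1)[0]
    return int(state % (2**31))


def kfold_cv(
    spec: ArchitectureSpec,
    ds: SpectralDataset,
    k: int,
    config: TrainingConfig,
) -> CVResult:
    """Stratified, seeded k-fold cross-validation of one architecture.

    For each fold a fresh network is built (fold-derived seed), trained
    on the other k−1 folds, and scored on the held-out fold; the result
    carries the per-fold correct counts e_i, fold sizes c_i, accuracies
    e_i/c_i and their mean (MPCE), plus each fold's learning curves.
    """
    folds = stratified_folds(ds.labels, k, config.seed)
    all_idx = np.arange(len(ds))
    correct: list[int] = []
    total: list[int] = []
    curves: list[LearningCurves] = []
    for fold_index, held_out in enumerate(folds):
        fold_seed = _fold_seed(config.seed, fold_index)
        train_set = ds.subset(np.setdiff1d(all_idx, held_out))
        test_set = ds.subset(held_out)
        model = build(spec, seed=fold_seed)
        model, fold_curves = train(
            model, train_set, test_set, config.with_(seed=fold_seed)
        )
        predictions = model.predict(test_set.features())
        correct.append(int(np.sum(predictions == test_set.labels)))
        total.append(len(test_set))
        curves.append(fold_curves)
    accuracies = tuple(e / c for e, c in zip(correct, total))
    return CVResult(
        k=k,
        per_fold_correct=tuple(correct),
        per_fold_total=tuple(total),
        per_fold_accuracy=accuracies,
        mpce=mpce(correct, total),
        curves=tuple(curves),
    )


ARCHITECTURES = ("mlp", "fcn", "erisnet")


def architecture_spec(name: str, input_layout=(14, 1), **kwargs) -> ArchitectureSpec:
    """Look up one of the three named architectures."""
    if name == "mlp":
        return mlp_spec()
    if name == "fcn":
        return fcn_spec(input_layout)
    if name == "erisnet":
        return erisnet_spec(input_layout, **kwargs)
    raise ValueError(f"unknown architecture {name!r}; expected one of {ARCHITECTURES}")


@dataclass(frozen=True)
class ComparisonRow:
    model: str
    protocol: str
    accuracy: float
    best_accuracy: float
    curves: tuple[LearningCurves, ...] = ()


@dataclass(frozen=True)
class ComparisonResult:
    """Three-way (or fewer) model comparison under a shared seed."""

    rows: tuple[ComparisonRow, ...]

    def accuracy(self, model: str) -> float:
        for row in self.rows:
            if row.model == model:
                return row.accuracy
        raise KeyError(model)

    def deltas(self) -> dict[tuple[str, str], float]:
        """Pairwise accuracy differences (a, b) → acc(a) − acc(b)."""
        out = {}
        for a in self.rows:
            for b in self.rows:
                if a.model != b.model:
                    out[(a.model, b.model)] = a.accuracy - b.accuracy
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"model": r.model, "protocol": r.protocol,
                 "accuracy": r.accuracy, "best_accuracy": r.best_accuracy}
                for r in self.rows
            ]
        )

    def summary(self) -> str:
        frame = self.to_frame()
        lines = ["model comparison", frame.to_string(index=False)]
        ranked = sorted(self.rows, key=lambda r: -r.accuracy)
        lines.append("ordering: " + " > ".join(r.model for r in ranked))
        return "\n".join(lines)


def compare_models(
    ds: SpectralDataset,
    config: TrainingConfig,
    models=ARCHITECTURES,
    protocol: str = "study",
    k: int = 5,
    input_layout=(14, 1),
) -> ComparisonResult:
    """Run the model comparison under a shared seed.

    ``protocol="study"`` mirrors the original evaluation asymmetry: MLP and FCN
    are trained on the stratified 50/50 split and scored on the held-out
    half, while ERISNet is scored by k-fold cross-validation (its
    accuracy is the MPCE).  ``protocol="split"`` runs every model on the
    split; ``protocol="kfold"`` cross-validates every model.
    """
    if protocol not in ("study", "split", "kfold"):
        raise ValueError(f"unknown protocol {protocol!r}")
    train_set, test_set = split_train_test(ds, config.split_fraction, config.seed)
    rows: list[ComparisonRow] = []
    for name in models:
        spec = architecture_spec(name, input_layout)
        use_kfold = protocol == "kfold" or (protocol == "study" and name == "erisnet")
        if use_kfold:
            cv = kfold_cv(spec, ds, k, config)
            rows.append(ComparisonRow(
                model=name, protocol=f"{k}-fold", accuracy=cv.mpce,
                best_accuracy=max(c.best_test_accuracy for c in cv.curves),
                curves=cv.curves,
            ))
        else:
            model = build(spec, seed=config.seed)
            model, curves = train(model, train_set, test_set, config)
            rows.append(ComparisonRow(
                model=name, protocol=f"{config.split_fraction:g} split",
                accuracy=curves.final_test_accuracy,
                best_accuracy=curves.best_test_accuracy,
                curves=(curves,),
            ))
    return ComparisonResult(rows=tuple(rows))


# ---------------------------------------------------------------------------
# Model-object presentation layer


class PixelClassifier:
    """A classifier bound to an architecture and a training protocol.

    Thin object wrapper over :func:`sargnet.nn.build` and
    :func:`train`::

        clf = PixelClassifier(mlp_spec(), TrainingConfig(epochs=50, seed=1))
        result = clf.fit(train_set, test_set)
        print(result.summary())
    """

    def __init__(self, spec: ArchitectureSpec, config: TrainingConfig | None = None) -> None:
        self.spec = spec
        self.config = config or TrainingConfig()

    def fit(
        self, train_set: SpectralDataset, test_set: SpectralDataset | None = None
    ) -> "FitResult":
        model = build(self.spec, seed=self.config.seed)
        model, curves = train(model, train_set, test_set, self.config)
        return FitResult(model=model, spec=self.spec, config=self.config, curves=curves)

    def cross_validate(self, ds: SpectralDataset, k: int = 5) -> CVResult:
        return kfold_cv(self.spec, ds, k, self.config)


@dataclass(frozen=True)
class FitResult:
    """A fitted classifier: weights, protocol, and learning curves."""

    model: Network
    spec: ArchitectureSpec
    config: TrainingConfig
    curves: LearningCurves

    @property
    def train_accuracy(self) -> float:
        return self.curves.train_accuracy[-1]

    @property
    def test_accuracy(self) -> float:
        return self.curves.test_accuracy[-1]

    def predict_proba(self, data: SpectralDataset | np.ndarray) -> np.ndarray:
        features = data.features() if isinstance(data, SpectralDataset) else np.asarray(data)
        return self.model.predict_proba(features)

    def predict(self, data: SpectralDataset | np.ndarray) -> np.ndarray:
        features = data.features() if isinstance(data, SpectralDataset) else np.asarray(data)
        return self.model.predict(features)

    def accuracy(self, ds: SpectralDataset) -> float:
        return evaluate_accuracy(self.model, ds)

    def summary(self) -> str:
        lines = [
            f"PixelClassifier fit: {self.spec.name}",
            f"  trainable parameters : {self.model.n_parameters:,}",
            f"  epochs x batch size  : {self.config.epochs} x {self.config.batch_size}",
            f"  seed                 : {self.config.seed}",
            f"  final train accuracy : {self.train_accuracy:.4f}",
        ]
        if np.isfinite(self.test_accuracy):
            lines.append(f"  final test accuracy  : {self.test_accuracy:.4f}")
            lines.append(f"  best test accuracy   : {self.curves.best_test_accuracy:.4f}")
        return "\n".join(lines)
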