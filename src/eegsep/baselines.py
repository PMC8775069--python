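"""Handcrafted sub-band features and the six comparison classifiers.

Per channel and sub-band, six statistics are computed over the 512-sample
reconstructed signal: Min, Max, Energy (sum of squares), Mean, Std
(population) and Skewness (Fisher, bias-uncorrected; 0 for zero-variance
signals).  With 19 channels and 6 bands this yields a flat vector of
19 * 6 * 6 = 684 features in channel-major layout (channel, then band, then
statistic).

The comparison classifiers are thin wrappers over scikit-learn estimators
with the study's hyperparameters; all expose the same
``fit`` / ``predict_proba_epochs`` protocol as the CNN adapter so they plug
into the same LOOCV driver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .wavelet import BAND_ORDER, SubBandTensor

STATISTICS = ("min", "max", "energy", "mean", "std", "skewness")
N_STATISTICS = len(STATISTICS)

BASELINE_NAMES = ("MLP1", "MLP2", "MLP3", "SVMrbf", "LDA", "QDA")


@dataclass(frozen=True)
class BaselineConfig:
    """Name + hyperparameters of one comparison classifier."""

    name: str
    hidden_layers: Tuple[int, ...] = ()
    batch_size: int = 214
    max_iter: int = 10
    learning_rate: float = 1e-2
    svm_gamma: float = 0.001
    qda_reg_param: float = 0.0
    scale_features: bool = False  # optional z-scoring, off by default

    def __post_init__(self) -> None:
        if self.name not in BASELINE_NAMES:
            raise ValueError(f"name must be one of {BASELINE_NAMES}")


DEFAULT_CONFIGS: Dict[str, BaselineConfig] = {
    "MLP1": BaselineConfig("MLP1", hidden_layers=(300,)),
    "MLP2": BaselineConfig("MLP2", hidden_layers=(300, 50)),
    "MLP3": BaselineConfig("MLP3", hidden_layers=(300, 100, 50)),
    "SVMrbf": BaselineConfig("SVMrbf"),
    "LDA": BaselineConfig("LDA"),
    "QDA": BaselineConfig("QDA"),
}


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def _stats_stack(x: np.ndarray) -> np.ndarray:
    """The six statistics along axis -2 (samples) of a (..., S, B) array.

    Returns (..., B, 6) ordered as :data:`STATISTICS`.
    """
    mn = x.min(axis=-2)
    mx = x.max(axis=-2)
    energy = np.sum(x * x, axis=-2)
    mean = x.mean(axis=-2)
    centered = x - mean[..., None, :]
    m2 = np.mean(centered ** 2, axis=-2)
    m3 = np.mean(centered ** 3, axis=-2)
    std = np.sqrt(m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = m3 / m2 ** 1.5
    # zero-variance (to numerical tolerance) -> skewness 0
    scale = np.mean(x * x, axis=-2)
    skew = np.where(m2 <= 1e-20 * np.maximum(scale, 1e-300), 0.0, skew)
    skew = np.nan_to_num(skew, nan=0.0, posinf=0.0, neginf=0.0)
    return np.stack([mn, mx, energy, mean, std, skew], axis=-1)


def extract_features(epoch_subbands: np.ndarray) -> np.ndarray:
    """Feature vector of one epoch slice shaped (channels, samples, bands).

    Layout is channel-major: index = (channel * n_bands + band) *
    n_statistics + statistic.
    """
    x = np.asarray(epoch_subbands, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("expected a (channels, samples, bands) slice")
    return _stats_stack(x).reshape(-1)


def feature_matrix(tensor: SubBandTensor) -> np.ndarray:
    """(n_epochs, n_channels * n_bands * 6) feature matrix for a tensor."""
    vals = np.asarray(tensor.values, dtype=np.float64)
    ne = vals.shape[0]
    return _stats_stack(vals).reshape(ne, -1)


def feature_index(channel: int, band: str, statistic: str,
                  n_bands: int = len(BAND_ORDER)) -> int:
    """Flat index of (channel, band, statistic) in the feature layout."""
    b = BAND_ORDER.index(band)
    s = STATISTICS.index(statistic)
    return (channel * n_bands + b) * N_STATISTICS + s


def feature_layout(n_channels: int = 19) -> list:
    """Ordered (channel, band, statistic) triples matching the flat layout."""
    return [
        (c, band, stat)
        for c in range(n_channels)
        for band in BAND_ORDER
        for stat in STATISTICS
    ]


# ---------------------------------------------------------------------------
# Classifiers
# ---------------------------------------------------------------------------

class BaselineModel:
    """Fitted comparison classifier exposing per-epoch ES probabilities."""

    def __init__(self, cfg: BaselineConfig, seed: int = 0) -> None:
        self.cfg = cfg
        self.seed = seed
        self._est = self._build()
        self._mu: Optional[np.ndarray] = None
        self._sigma: Optional[np.ndarray] = None
        self.fitted = False

    def _build(self):
        cfg = self.cfg
        if cfg.name.startswith("MLP"):
            return MLPClassifier(
                hidden_layer_sizes=cfg.hidden_layers,
                activation="relu",
                solver="adam",
                batch_size=cfg.batch_size,
                max_iter=cfg.max_iter,
                learning_rate_init=cfg.learning_rate,
                beta_1=0.9,
                beta_2=0.999,
                random_state=self.seed,
            )
        if cfg.name == "SVMrbf":
            return SVC(kernel="rbf", gamma=cfg.svm_gamma)
        if cfg.name == "LDA":
            return LinearDiscriminantAnalysis(solver="svd")
        if cfg.name == "QDA":
            return QuadraticDiscriminantAnalysis(reg_param=cfg.qda_reg_param)
        raise AssertionError(cfg.name)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BaselineModel":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).ravel()
        if np.unique(y).size < 2:
            raise ValueError("training set must contain both classes")
        if self.cfg.scale_features:
            self._mu = X.mean(axis=0)
            self._sigma = X.std(axis=0)
            self._sigma[self._sigma == 0] = 1.0
            X = (X - self._mu) / self._sigma
        with warnings.catch_warnings():
            # the study trains MLPs for a fixed 10 passes; non-convergence
            # at that budget is expected, not an error
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._est.fit(X, y.astype(int))
        self.fitted = True
        return self

    def predict_proba_epochs(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise ValueError("classifier has not been fitted")
        X = np.asarray(X, dtype=np.float64)
        if self.cfg.scale_features:
            X = (X - self._mu) / self._sigma
        if hasattr(self._est, "predict_proba"):
            return self._est.predict_proba(X)[:, 1]
        # margin classifiers: squash the decision function
        z = self._est.decision_function(X)
        return 1.0 / (1.0 + np.exp(-z))


def train_baseline(cfg: BaselineConfig, X: np.ndarray, y: np.ndarray,
                   seed: int = 0) -> BaselineModel:
    """Fit one comparison classifier on an (epochs x features) matrix."""
    return BaselineModel(cfg, seed=seed).fit(X, y)


def make_baseline(name: str, seed: int = 0,
                  scale_features: bool = False) -> BaselineModel:
    """Unfitted classifier with the study's default hyperparameters."""
    cfg = DEFAULT_CONFIGS[name]
    if scale_features:
        cfg = BaselineConfig(**{**cfg.__dict__, "scale_features": True})
    return BaselineModel(cfg, seed=seed)
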