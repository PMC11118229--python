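"""Scikit-learn style estimators over the finite-class Bayesian recognizer.

Two estimators are provided:

* :class:`FiniteClassBayesRecognizer` — one limb.  ``X`` is the limb's
  (n, F) filtered feature stream, ``y`` the (n, 2) integer
  (activity, event) labels.  ``predict`` replays the stream online and
  returns per-sample thresholded decisions (0 where undecided).
* :class:`BilateralGaitRecognizer` — both limbs, optionally coupled through
  the bilateral elimination rules.  ``X`` stacks the right then left feature
  blocks column-wise; ``y`` is (n, 4): right activity, right event, left
  activity, left event.

Both follow the sklearn contract (``get_params``/``set_params``, fitted
attributes with trailing underscores, ``clone``-compatible constructors), so
they compose with pipelines and model selection.  Prediction is sequential —
samples are a time series, not i.i.d. rows.
"""

from __future__ import annotations



import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .evaluate import ReplayConfig, replay
from .likelihood import HistogramLikelihoodModel
from .simulator import GaitDataset

__all__ = ["FiniteClassBayesRecognizer", "BilateralGaitRecognizer"]


def _label_frame(times, y_right, y_left) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time": times,
            "right_activity": y_right[:, 0],
            "right_event": y_right[:, 1],
            "left_activity": y_left[:, 0],
            "left_event": y_left[:, 1],
        }
    )


def _feature_frame(times, X_right, X_left) -> pd.DataFrame:
    cols = {"time": times}
    for i in range(X_right.shape[1]):
        cols[f"r{i}"] = X_right[:, i]
    for i in range(X_left.shape[1]):
        cols[f"l{i}"] = X_left[:, i]
    return pd.DataFrame(cols)


class _BaseRecognizer(BaseEstimator):
    def __init__(
        self,
        n_bins: int = 20,
        alpha: float = 1.0,
        tau1: float = 0.01,
        theta: float = 0.9,
        mass_floor: float = 1e-3,
        use_rule1: bool = True,
        fs: float = 100.0,
    ):
        self.n_bins = n_bins
        self.alpha = alpha
        self.tau1 = tau1
        self.theta = theta
        self.mass_floor = mass_floor
        self.use_rule1 = use_rule1
        self.fs = fs

    def _config(self) -> ReplayConfig:
        # features handed to estimators are taken as already preprocessed
        return ReplayConfig(
            tau1=self.tau1,
            theta=self.theta,
            mass_floor=self.mass_floor,
            use_rule1_ratio=self.use_rule1,
            use_rule1_event=self.use_rule1,
            fs=self.fs,
            filter_input=False,
        )

    def _check_fitted(self):
        if not hasattr(self, "models_"):
            raise ValueError("estimator is not fitted; call fit first")


class FiniteClassBayesRecognizer(_BaseRecognizer):
    """Single-limb finite-class Bayesian recognizer (within-limb rules only)."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 2 or y.ndim != 2 or y.shape != (len(X), 2):
            raise ValueError("X must be (n, F) and y (n, 2)")
        model = HistogramLikelihoodModel(n_bins=self.n_bins, alpha=self.alpha).fit(X, y)
        self.models_ = {"right": model, "left": model}
        self.n_features_in_ = X.shape[1]
        return self

    def _replay(self, X):
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"X must be (n, {self.n_features_in_})")
        n = len(X)
        times = np.arange(n) / self.fs
        zeros = np.zeros((n, 2), dtype=np.int64)
        dataset = GaitDataset(
            frames=_feature_frame(times, X, X),
            labels=_label_frame(times, zeros, zeros),
            fs=self.fs,
        )
        # the engine reads per-side features by column blocks
        return replay(
            _SplitDataset(dataset, self.n_features_in_), self.models_,
            mode="fc", config=self._config(),
        )

    def predict(self, X) -> np.ndarray:
        """(n, 2) thresholded per-sample (activity, event) codes; 0 = undecided."""
        return self._replay(X).decisions["right"]

    def predict_map(self, X) -> np.ndarray:
        """(n, 2) forced argmax decisions (never undecided)."""
        return self._replay(X).map_decisions["right"]

    def score(self, X, y) -> float:
        """Per-sample activity accuracy; undecided samples count as wrong."""
        y = np.asarray(y, dtype=np.int64)
        pred = self.predict(X)
        return float(np.mean(pred[:, 0] == y[:, 0]))


class BilateralGaitRecognizer(_BaseRecognizer):
    """Two-limb recognizer, optionally coupled by the bilateral rules.

    ``use_bers=True`` (default) applies elimination rules 2-3 between the
    limbs at every sample; ``False`` degrades to two independent unilateral
    systems on the same interface.
    """

    def __init__(
        self,
        n_bins: int = 20,
        alpha: float = 1.0,
        tau1: float = 0.01,
        theta: float = 0.9,
        mass_floor: float = 1e-3,
        use_rule1: bool = True,
        fs: float = 100.0,
        use_bers: bool = True,
    ):
        super().__init__(
            n_bins=n_bins, alpha=alpha, tau1=tau1, theta=theta,
            mass_floor=mass_floor, use_rule1=use_rule1, fs=fs,
        )
        self.use_bers = use_bers

    def _split(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] % 2:
            raise ValueError("X must be (n, 2F): right block then left block")
        F = X.shape[1] // 2
        return X[:, :F], X[:, F:]

    def fit(self, X, y):
        Xr, Xl = self._split(X)
        y = np.asarray(y, dtype=np.int64)
        if y.shape != (len(Xr), 4):
            raise ValueError("y must be (n, 4): right act, right evt, left act, left evt")
        self.models_ = {
            "right": HistogramLikelihoodModel(self.n_bins, self.alpha).fit(Xr, y[:, :2]),
            "left": HistogramLikelihoodModel(self.n_bins, self.alpha).fit(Xl, y[:, 2:]),
        }
        self.n_features_in_ = X.shape[1]
        return self

    def replay(self, X):
        """Full :class:`~gaitbayes.evaluate.ReplayResult` for a stream."""
        self._check_fitted()
        Xr, Xl = self._split(X)
        if Xr.shape[1] != self.models_["right"].n_features_:
            raise ValueError("feature width does not match the fitted models")
        n = len(Xr)
        times = np.arange(n) / self.fs
        zeros = np.zeros((n, 2), dtype=np.int64)
        dataset = GaitDataset(
            frames=_feature_frame(times, Xr, Xl),
            labels=_label_frame(times, zeros, zeros),
            fs=self.fs,
        )
        mode = "ber-fc" if self.use_bers else "fc"
        return replay(
            _SplitDataset(dataset, Xr.shape[1]), self.models_,
            mode=mode, config=self._config(),
        )

    def predict(self, X) -> np.ndarray:
        """(n, 4) thresholded codes: right act, right evt, left act, left evt."""
        res = self.replay(X)
        return np.hstack([res.decisions["right"], res.decisions["left"]])

    def score(self, X, y) -> float:
        """Mean per-sample activity accuracy over both limbs."""
        y = np.asarray(y, dtype=np.int64)
        pred = self.predict(X)
        return float(np.mean((pred[:, 0] == y[:, 0]) & (pred[:, 2] == y[:, 2])))


class _SplitDataset:
    """Adapter presenting column blocks of a feature frame as per-side features.

    Lets the replay engine run on estimator input that is already
    preprocessed and has no named IMU channels.
    """

    def __init__(self, dataset: GaitDataset, n_features: int):
        self._dataset = dataset
        self._n = n_features
        self.frames = dataset.frames
        self.labels = dataset.labels
        self.fs = dataset.fs

    def __len__(self):
        return len(self._dataset)

    @property
    def times(self):
        return self._dataset.times

    def label_codes(self, side):
        return self._dataset.label_codes(side)

    def features(self, side):
        cols = [c for c in self.frames.columns if c != "time"]
        X = self.frames[cols].to_numpy(dtype=float)
        return X[:, : self._n] if side == "right" else X[:, self._n :]
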