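"""Histogram likelihoods per (feature, class) and the observation likelihood.

For every class pair m and feature f the model keeps an equal-width histogram
h_{f,m}(b) over the feature's training range.  A feature value's likelihood
is the smoothed, normalized mass of the bin containing it,

    P_f(l_f | g_m) = (h_{f,m}(b) + alpha) / (sum_b h_{f,m}(b) + alpha * B),

with add-alpha smoothing (alpha = 1 by default).  Per-feature likelihoods are
combined into a single per-class observation likelihood as their geometric
mean,

    P(s_t | g_m) = ( prod_f P_f(l_f | g_m) )^(1/F),

computed in log space.  The geometric mean is a strictly monotone transform
of the naive-Bayes log-sum, so it induces the same class ranking while
staying in (0, 1] and therefore composes with the Bayesian update as a
likelihood.  Values outside the training range clamp to the nearest end bin;
with alpha = 0, zero-probability bins are floored at ``likelihood_floor``.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .core import ALL_CLASS_PAIRS, CLASS_INDEX, ClassPair, GaitEvent, WalkingActivity

__all__ = ["HistogramLikelihoodModel"]


class HistogramLikelihoodModel:
    """Per-feature, per-class histogram likelihood model.

    Parameters
    ----------
    n_bins : number of equal-width bins per feature (>= 1); default 20
    alpha : add-alpha smoothing mass per bin (>= 0); default 1.0
    likelihood_floor : floor applied to zero bin probabilities when
        ``alpha == 0`` so log-likelihoods stay finite; default 1e-9

    Fitted attributes
    -----------------
    edges_ : (F, n_bins + 1) ascending bin edges per feature
    counts_ : (M, F, n_bins) raw per-class histogram counts
    log_prob_ : (M, F, n_bins) log of smoothed, normalized bin probabilities
    classes_ : tuple of the M class pairs, aligned with axis 0
    feature_names_ : optional feature names
    """

    def __init__(self, n_bins: int = 20, alpha: float = 1.0, likelihood_floor: float = 1e-9):
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        self.n_bins = int(n_bins)
        self.alpha = float(alpha)
        self.likelihood_floor = float(likelihood_floor)

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        X,
        y,
        classes: Optional[Sequence[ClassPair]] = None,
        feature_names: Optional[Sequence[str]] = None,
    ) -> "HistogramLikelihoodModel":
        """Tally per-class histograms from a labeled feature stream.

        ``X`` is (n, F); ``y`` is (n, 2) integer (activity, event) codes.
        Every class in ``classes`` (default: all 56 pairs) must be observed
        at least once, otherwise the training set is incomplete and a
        ``ValueError`` is raised.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or y.ndim != 2 or y.shape[1] != 2 or len(X) != len(y):
            raise ValueError("X must be (n, F) and y (n, 2) with matching n")
        if classes is None:
            classes = ALL_CLASS_PAIRS
        classes = tuple(
            ClassPair(WalkingActivity(int(a)), GaitEvent(int(e))) for a, e in classes
        )
        n, F = X.shape
        M, B = len(classes), self.n_bins

        lo = X.min(axis=0)
        hi = X.max(axis=0)
        degenerate = hi <= lo
        hi = np.where(degenerate, lo + 1.0, hi)  # avoid zero-width ranges
        self.edges_ = np.linspace(lo, hi, B + 1).T  # (F, B+1)

        class_codes = {(int(p.activity), int(p.event)): i for i, p in enumerate(classes)}
        labels = np.array(
            [class_codes.get((int(a), int(e)), -1) for a, e in y], dtype=np.int64
        )
        known = labels >= 0

        bins = self._bin_indices(X)  # (n, F)
        counts = np.zeros((M, F, B), dtype=np.int64)
        for f in range(F):
            flat = labels[known] * B + bins[known, f]
            counts[:, f, :] += np.bincount(flat, minlength=M * B).reshape(M, B)

        observed = counts[:, 0, :].sum(axis=1) > 0
        if not observed.all():
            missing = [classes[i] for i in np.flatnonzero(~observed)]
            names = ", ".join(f"({p.activity.name},{p.event.name})" for p in missing)
            raise ValueError(f"incomplete training set: no samples for class(es) {names}")

        totals = counts.sum(axis=2, keepdims=True).astype(float)
        prob = (counts + self.alpha) / (totals + self.alpha * B)
        if self.alpha == 0:
            prob = np.maximum(prob, self.likelihood_floor)
        self.log_prob_ = np.log(prob)
        self.counts_ = counts
        self.classes_ = classes
        self.n_features_ = F
        self.feature_names_ = tuple(feature_names) if feature_names is not None else None
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "log_prob_"):
            raise ValueError("model is not fitted")

    def _bin_indices(self, X: np.ndarray) -> np.ndarray:
        """(n, F) bin index of each value, clamped to the end bins."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, F = X.shape
        out = np.empty((n, F), dtype=np.int64)
        for f in range(F):
            idx = np.searchsorted(self.edges_[f], X[:, f], side="right") - 1
            out[:, f] = np.clip(idx, 0, self.n_bins - 1)
        return out

    # -- evaluation --------------------------------------------------------

    def class_index(self, m: ClassPair) -> int:
        self._check_fitted()
        if self.classes_ is ALL_CLASS_PAIRS:
            return CLASS_INDEX[m]
        return self.classes_.index(m)

    def bin_probabilities(self, f: int, m: ClassPair) -> np.ndarray:
        """Smoothed, normalized probabilities of all bins for (f, m)."""
        self._check_fitted()
        return np.exp(self.log_prob_[self.class_index(m), f])

    def feature_likelihood(self, f: int, value: float, m: ClassPair) -> float:
        """P_f(value | m): probability of the bin containing ``value``."""
        self._check_fitted()
        b = int(
            np.clip(
                np.searchsorted(self.edges_[f], value, side="right") - 1,
                0,
                self.n_bins - 1,
            )
        )
        return float(np.exp(self.log_prob_[self.class_index(m), f, b]))

    def log_likelihood_matrix(self, X) -> np.ndarray:
        """(n, M) per-sample, per-class log observation likelihoods."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_:
            raise ValueError(
                f"expected {self.n_features_} features, got {X.shape[1]}"
            )
        bins = self._bin_indices(X)  # (n, F)
        M = len(self.classes_)
        total = np.zeros((X.shape[0], M))
        for f in range(self.n_features_):
            total += self.log_prob_[:, f, bins[:, f]].T
        return total / self.n_features_

    def log_likelihoods(self, s) -> np.ndarray:
        """(M,) log observation likelihoods of one feature vector."""
        return self.log_likelihood_matrix(np.atleast_2d(s))[0]

    def likelihoods(self, s) -> np.ndarray:
        """(M,) observation likelihoods (geometric means) of one vector."""
        return np.exp(self.log_likelihoods(s))

    def observation_likelihood(self, s, m: ClassPair) -> float:
        """Geometric-mean observation likelihood of ``s`` under class ``m``."""
        return float(self.likelihoods(s)[self.class_index(m)])

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Serialize to a single NPZ archive (counts/edges bit-exact)."""
        self._check_fitted()
        np.savez(
            path,
            edges=self.edges_,
            counts=self.counts_,
            alpha=np.array(self.alpha),
            n_bins=np.array(self.n_bins),
            likelihood_floor=np.array(self.likelihood_floor),
            class_codes=np.array(
                [(int(p.activity), int(p.event)) for p in self.classes_], dtype=np.int64
            ),
            feature_names=np.array(
                list(self.feature_names_) if self.feature_names_ else [], dtype="U64"
            ),
        )

    @classmethod
    def load(cls, path) -> "HistogramLikelihoodModel":
        with np.load(path, allow_pickle=False) as z:
            model = cls(
                n_bins=int(z["n_bins"]),
                alpha=float(z["alpha"]),
                likelihood_floor=float(z["likelihood_floor"]),
            )
            model.edges_ = z["edges"]
            model.counts_ = z["counts"]
            codes = z["class_codes"]
            names = [str(s) for s in z["feature_names"]]
        model.classes_ = tuple(
            ClassPair(WalkingActivity(int(a)), GaitEvent(int(e))) for a, e in codes
        )
        model.n_features_ = model.edges_.shape[0]
        model.feature_names_ = tuple(names) if names else None
        B = model.n_bins
        totals = model.counts_.sum(axis=2, keepdims=True).astype(float)
        prob = (model.counts_ + model.alpha) / (totals + model.alpha * B)
        if model.alpha == 0:
            prob = np.maximum(prob, model.likelihood_floor)
        model.log_prob_ = np.log(prob)
        return model
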