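"""Probabilistic neural network (Parzen-window classifier).

Two training modes:

* ``mode="dda"`` (default): constructive dynamic-decay-adjustment training
  (Berthold & Diamond).  Prototypes are committed on demand; a training
  sample covered by a same-class prototype with activation >= ``theta_plus``
  only increments that prototype's weight, otherwise a new prototype is
  committed.  Radii of conflicting-class prototypes shrink so their
  activation at the sample drops to <= ``theta_minus``.  The two theta
  thresholds are the model's only sensitive hyperparameters.
* ``mode="parzen"``: the classic Specht network - every training point is a
  prototype of unit weight with a common kernel width ``bandwidth`` times
  the data scale.

Class scores are normalized Gaussian mixture evaluations, i.e.
probability-like posteriors.  Training is deterministic (fixed sample
order), so repeated fits on identical data are identical.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigError

__all__ = ["PNNClassifier"]


class PNNClassifier(BaseEstimator, ClassifierMixin):
    """Parzen-window probabilistic classifier with optional DDA training.

    Parameters
    ----------
    mode:
        ``"dda"`` or ``"parzen"``.
    theta_minus, theta_plus:
        DDA conflict and coverage activation thresholds,
        0 < theta_minus < theta_plus < 1.
    max_epochs:
        Upper bound on DDA passes over the data; training stops earlier
        once no prototype is added and no radius shrinks.
    bandwidth:
        Kernel width for ``mode="parzen"``, as a fraction of the total
        data standard deviation.
    """

    def __init__(
        self,
        mode: str = "dda",
        theta_minus: float = 0.109,
        theta_plus: float = 0.928,
        max_epochs: int = 5,
        bandwidth: float = 0.1,
    ):
        self.mode = mode
        self.theta_minus = theta_minus
        self.theta_plus = theta_plus
        self.max_epochs = max_epochs
        self.bandwidth = bandwidth

    # ------------------------------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.mode not in ("dda", "parzen"):
            raise ConfigError(f"unknown PNN mode {self.mode!r}")
        if not (0 < self.theta_minus < self.theta_plus < 1):
            raise ConfigError("need 0 < theta_minus < theta_plus < 1")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        # overall data scale; initial kernel radius before any shrinking
        scale = float(np.sqrt(X.var(axis=0).sum()))
        if scale == 0:
            scale = 1.0
        if self.mode == "parzen":
            self.centers_ = X.copy()
            self.proto_class_ = y_idx.copy()
            self.sigmas_ = np.full(len(X), self.bandwidth * scale)
            self.weights_ = np.ones(len(X))
            return self
        self._fit_dda(X, y_idx, sigma0=scale)
        return self

    def _fit_dda(self, X, y_idx, sigma0: float) -> None:
        # shrink factor: sigma <= d / shrink_k gives activation <= theta_minus
        shrink_k = np.sqrt(2.0 * np.log(1.0 / self.theta_minus))
        n, dim = X.shape
        # preallocated prototype pool, grown as prototypes are committed
        centers = np.empty((n, dim))
        sigmas = np.empty(n)
        weights = np.empty(n)
        pclass = np.empty(n, dtype=int)
        m = 0

        for _ in range(self.max_epochs):
            changed = False
            weights[:m] = 0.0
            for x, c in zip(X, y_idx):
                d = np.linalg.norm(centers[:m] - x, axis=1)
                same = pclass[:m] == c
                act = np.exp(-0.5 * (d / sigmas[:m]) ** 2)
                covered = same & (act >= self.theta_plus)
                if covered.any():
                    # strengthen the best-matching prototype
                    best = int(np.argmax(np.where(covered, act, -1.0)))
                    weights[best] += 1.0
                else:
                    sig = sigma0
                    if (~same).any():
                        sig = min(sig, float(d[~same].min()) / shrink_k)
                    centers[m] = x
                    sigmas[m] = max(sig, 1e-12)
                    weights[m] = 1.0
                    pclass[m] = c
                    m += 1
                    changed = True
                    d = np.append(d, 0.0)
                    same = np.append(same, True)
                # conflict resolution: shrink opposite-class prototypes
                opp = ~same
                if opp.any():
                    limits = np.maximum(d[:m][opp] / shrink_k, 1e-12)
                    cur = sigmas[:m][opp]
                    if (cur > limits).any():
                        sigmas[:m][opp] = np.minimum(cur, limits)
                        changed = True
            if not changed:
                break

        self.centers_ = centers[:m].copy()
        self.sigmas_ = sigmas[:m].copy()
        self.weights_ = weights[:m].copy()
        pclass = pclass[:m]
        # an epoch may leave a prototype with zero weight if its samples got
        # re-covered elsewhere; keep it with a minimal vote
        self.weights_ = np.maximum(self.weights_, 1.0)
        self.proto_class_ = np.asarray(pclass)

    # ------------------------------------------------------------------
    def _class_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        d2 = cdist(X, self.centers_, metric="sqeuclidean")
        act = np.exp(-0.5 * d2 / self.sigmas_**2) * self.weights_
        scores = np.zeros((len(X), len(self.classes_)))
        for ci in range(len(self.classes_)):
            mask = self.proto_class_ == ci
            if mask.any():
                scores[:, ci] = act[:, mask].sum(axis=1)
        return scores

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "centers_")
        scores = self._class_scores(X)
        totals = scores.sum(axis=1, keepdims=True)
        # a point outside every kernel: fall back to the nearest prototype
        dead = totals[:, 0] <= 0
        if dead.any():
            d = cdist(np.asarray(X, float)[dead], self.centers_)
            nearest = self.proto_class_[np.argmin(d, axis=1)]
            scores[dead] = 0.0
            scores[np.flatnonzero(dead), nearest] = 1.0
            totals = scores.sum(axis=1, keepdims=True)
        return scores / totals

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
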