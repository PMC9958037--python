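"""Radial basis function network for reflux vs. normal limb classification.

Architecture and training follow the classic recipe:

* hidden-unit centers mu_j placed by seeded Lloyd's k-means on the training
  inputs (default k = 16);
* Gaussian activations phi_j(x) = exp(-||x - mu_j||^2 / (2 sigma^2)) with a
  shared scalar width sigma = the standard deviation of the input vectors
  (root mean squared distance from the global mean, per dimension);
* a single linear output y(x) = sum_j w_j phi_j(x), no bias term, with the
  weights trained sample-by-sample by the normalized least-mean-squares
  (NLMS) rule  w <- w + eta / (eps + ||phi||^2) * (d - w.phi) * phi;
* desired outputs d = 1 (reflux limb) / 0 (healthy limb), and a decision
  threshold chosen on the training scores by sweeping 0..1 in steps of 0.01
  and maximizing the F-measure (a limb is called refluxing when the output
  strictly exceeds the threshold).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

NLMS_EPS = 1e-6
THRESHOLD_GRID = np.round(np.arange(101) / 100.0, 2)


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------

def kmeans_centers(X: np.ndarray, k: int, seed=0,
                   max_iter: int = 100) -> np.ndarray:
    """Lloyd's k-means centers, initialized from k distinct training points.

    Empty clusters are re-seeded to the point currently farthest from its
    assigned center.  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2D (n_samples, n_features)")
    distinct = np.unique(X, axis=0)
    if k < 1 or k > len(distinct):
        raise ValueError(f"k={k} must lie in [1, n_distinct={len(distinct)}]")
    rng = np.random.default_rng(seed)
    centers = distinct[rng.choice(len(distinct), size=k, replace=False)].copy()
    prev = None
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        if prev is not None and np.array_equal(assign, prev):
            break
        prev = assign
        own = d2[np.arange(len(X)), assign]
        for j in range(k):
            members = X[assign == j]
            if len(members):
                centers[j] = members.mean(axis=0)
            else:
                centers[j] = X[own.argmax()]
    return centers


def compute_sigma(X: np.ndarray) -> float:
    """Scalar Gaussian width: the standard deviation of the input vectors.

    sigma^2 = mean_i ||x_i - xbar||^2 / p, i.e. the average per-dimension
    variance; equals 1 on standardized features by construction.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 input vectors")
    xbar = X.mean(axis=0)
    sigma2 = np.mean(((X - xbar) ** 2).sum(axis=1)) / X.shape[1]
    if sigma2 == 0:
        raise ValueError("all input vectors identical: sigma would be 0")
    return float(np.sqrt(sigma2))


def rbf_activations(x: np.ndarray, centers: np.ndarray,
                    sigma: Union[float, np.ndarray]) -> np.ndarray:
    """Gaussian hidden-unit outputs phi_j = exp(-||x - mu_j||^2 / 2 sigma^2).

    ``x`` may be a single point (p,) or a batch (n, p); ``sigma`` a scalar or
    per-center widths (k,).  All activations lie in (0, 1].
    """
    x = np.asarray(x, dtype=float)
    centers = np.asarray(centers, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input point")
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != centers.shape[1]:
        raise ValueError("input dimension does not match centers")
    sig = np.asarray(sigma, dtype=float)
    if np.any(sig <= 0):
        raise ValueError("sigma must be positive")
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    phi = np.exp(-d2 / (2.0 * sig ** 2))
    return phi[0] if single else phi


def nlms_update(w: np.ndarray, phi: np.ndarray, d: float, eta: float,
                eps: float = NLMS_EPS) -> np.ndarray:
    """One normalized-LMS step on a single (phi, d) sample."""
    err = d - w @ phi
    return w + (eta / (eps + phi @ phi)) * err * phi


def train_weights_nlms(Phi: np.ndarray, d: np.ndarray, eta: float = 0.5,
                       epochs: int = 200, seed=0, eps: float = NLMS_EPS,
                       step_decay_tau: Optional[float] = 25.0,
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Train output weights by cycling NLMS over the activation table.

    Weights start at zero; sample order is reshuffled each epoch from the
    seed.  Returns the final weights and the per-epoch mean-squared-error
    trace.  ``eta`` must lie in (0, 2), the mean-square stability region.

    The per-epoch step follows the harmonic schedule
    ``eta_ep = eta / (1 + ep / step_decay_tau)`` (Robbins-Monro style): a
    fixed step leaves a gradient-noise misadjustment floor of order
    eta/(2 - eta) above the attainable squared error, while the decaying
    step drives the weights to the NLMS fixed point.  ``step_decay_tau=None``
    keeps the step fixed at ``eta``.
    """
    Phi = np.asarray(Phi, dtype=float)
    d = np.asarray(d, dtype=float)
    if Phi.ndim != 2 or len(d) != Phi.shape[0]:
        raise ValueError("Phi must be (n, k) with one target per row")
    if not 0.0 < eta < 2.0:
        raise ValueError("eta must lie in (0, 2) for NLMS stability")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    rng = np.random.default_rng(seed)
    n, k = Phi.shape
    w = np.zeros(k)
    trace = np.empty(epochs)
    for ep in range(epochs):
        eta_ep = eta if step_decay_tau is None else \
            eta / (1.0 + ep / step_decay_tau)
        for i in rng.permutation(n):
            w = nlms_update(w, Phi[i], d[i], eta_ep, eps)
        trace[ep] = np.mean((d - Phi @ w) ** 2)
    return w, trace


def select_threshold(scores: np.ndarray,
                     labels: np.ndarray) -> tuple[float, float]:
    """Sweep the decision threshold over {0, 0.01, ..., 1} by F-measure.

    A sample is predicted positive when its score strictly exceeds the
    threshold.  Returns (threshold, F) with ties broken toward the smallest
    threshold; F is taken as 0 when no true positive exists at a threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos, neg = labels == 1, labels == 0
    if not (pos.any() and neg.any()):
        raise ValueError("both classes must be present to pick a threshold")
    best_thr, best_f = 0.0, -1.0
    for thr in THRESHOLD_GRID:
        pred = scores > thr
        tp = int(np.sum(pred & pos))
        fp = int(np.sum(pred & neg))
        fn = int(np.sum(~pred & pos))
        f = 0.0 if tp == 0 else 2.0 * tp / (2.0 * tp + fp + fn)
        if f > best_f:
            best_thr, best_f = float(thr), f
    return best_thr, best_f


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class RBFNNModel:
    """Trained network: centers, width(s), output weights and threshold."""

    centers: np.ndarray
    sigma: Union[float, np.ndarray]
    weights: np.ndarray
    threshold: float
    metadata: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Raw network scores y(x); not clipped to [0, 1]."""
        phi = rbf_activations(X, self.centers, self.sigma)
        return phi @ self.weights

    def classify(self, X: np.ndarray) -> np.ndarray:
        """Binary decisions: 1 when the score strictly exceeds the threshold."""
        return (self.predict(X) > self.threshold).astype(int)

    def to_json(self) -> str:
        sig = self.sigma
        payload = {
            "centers": np.asarray(self.centers).tolist(),
            "sigma": sig.tolist() if isinstance(sig, np.ndarray) else float(sig),
            "weights": np.asarray(self.weights).tolist(),
            "threshold": float(self.threshold),
            "metadata": self.metadata,
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RBFNNModel":
        d = json.loads(text)
        sigma = d["sigma"]
        if isinstance(sigma, list):
            sigma = np.asarray(sigma, dtype=float)
        return cls(centers=np.asarray(d["centers"], dtype=float),
                   sigma=sigma,
                   weights=np.asarray(d["weights"], dtype=float),
                   threshold=float(d["threshold"]),
                   metadata=d.get("metadata", {}))


def forward(model: RBFNNModel, X: np.ndarray) -> np.ndarray:
    """Functional alias of :meth:`RBFNNModel.predict`."""
    return model.predict(X)


def fit(X: np.ndarray, d: np.ndarray, k: int = 16, eta: float = 0.5,
        epochs: int = 200, seed: int = 0,
        threshold: Union[str, float] = "sweep",
        per_center_sigma: bool = False) -> RBFNNModel:
    """Train the full network: k-means -> sigma -> NLMS -> threshold.

    ``threshold`` is either "sweep" (F-measure-optimal on the training
    scores) or a fixed value in [0, 1].  ``per_center_sigma`` replaces the
    shared scalar width by sigma_j = mean distance of cluster members to
    their center (sensitivity option).  Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    d = np.asarray(d, dtype=int)
    if set(np.unique(d)) - {0, 1}:
        raise ValueError("targets must be 0/1")
    if not ((d == 1).any() and (d == 0).any()):
        raise ValueError("both classes must be present for training")
    root = np.random.SeedSequence(seed)
    seq_km, seq_nlms = root.spawn(2)
    centers = kmeans_centers(X, k, seed=seq_km)
    sigma: Union[float, np.ndarray] = compute_sigma(X)
    if per_center_sigma:
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        widths = np.full(len(centers), float(sigma))
        for j in range(len(centers)):
            members = X[assign == j]
            if len(members):
                dist = np.sqrt(((members - centers[j]) ** 2).sum(axis=1))
                if dist.mean() > 0:
                    widths[j] = dist.mean()
        sigma = widths
    Phi = rbf_activations(X, centers, sigma)
    w, trace = train_weights_nlms(Phi, d, eta=eta, epochs=epochs,
                                  seed=seq_nlms)
    scores = Phi @ w
    if threshold == "sweep":
        thr, f = select_threshold(scores, d)
        mode = "sweep"
    else:
        thr = float(threshold)
        if not 0.0 <= thr <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")
        _, f = _f_at(scores, d, thr)
        mode = "fixed"
    meta = {"k": int(k), "eta": float(eta), "epochs": int(epochs),
            "seed": int(seed), "threshold_mode": mode,
            "final_mse": float(trace[-1]), "train_f_measure": float(f),
            "per_center_sigma": bool(per_center_sigma)}
    return RBFNNModel(centers=centers, sigma=sigma, weights=w, threshold=thr,
                      metadata=meta)


def _f_at(scores: np.ndarray, labels: np.ndarray,
          thr: float) -> tuple[np.ndarray, float]:
    pred = np.asarray(scores) > thr
    pos = np.asarray(labels) == 1
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    f = 0.0 if tp == 0 else 2.0 * tp / (2.0 * tp + fp + fn)
    return pred.astype(int), f
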