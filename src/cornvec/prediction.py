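"""Prediction of postoperative total-corneal-power astigmatism from
preoperative keratometry.

Two predictors map the preoperative keratometric astigmatism components
(C0, C45) to the postoperative real-power components:

* a multivariate linear regression ``y = A x + b`` with a 2x2 coefficient
  matrix and 2-vector intercept, fitted by least squares (optionally by
  iteratively-reweighted bisquare for robustness), and
* a shallow feedforward network (2 - 10 - 8 - 2, tanh hidden layers, linear
  output) trained with the Levenberg-Marquardt algorithm under validation-
  based early stopping.

Both minimise the mean squared prediction error per eye,
``PE = 1/2 ((dC0)^2 + (dC45)^2)``, on a random 70/15/15
train/validation/test split.  Models are fitted in right-eye orientation;
the left-eye counterpart of a regression model follows from mirror symmetry
by negating both off-diagonal matrix entries and the second intercept entry.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence

import numpy as np

__all__ = [
    "SplitIndices",
    "RegressionModel",
    "NetworkModel",
    "DegenerateLikelihoodError",
    "split_dataset",
    "mean_squared_pe",
    "fit_multivariate_regression",
    "mirror_model_for_eye",
    "apply_regression",
    "gaussian_log_likelihood",
    "init_network",
    "network_forward",
    "train_network_lm",
    "predict",
    "prediction_error_stats",
    "load_published_models",
]


class DegenerateLikelihoodError(ValueError):
    """Residual covariance is singular (e.g. a perfect fit)."""


# ---------------------------------------------------------------------------
# data split


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/validation/test index arrays covering 0..n-1."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    @property
    def n(self) -> int:
        return len(self.train) + len(self.val) + len(self.test)


def split_dataset(
    n: int,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int | None = 0,
) -> SplitIndices:
    """Random train/validation/test split.

    The training size is the rounded training fraction of n; the remainder is
    split as evenly as possible with the validation set taking the odd
    element.  For n = 88 at 70/15/15 this gives 62/13/13.  Deterministic
    under ``seed``.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 to split, got {n}")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    n_train = int(math.floor(fractions[0] * n + 0.5))
    rem = n - n_train
    n_val = (rem + 1) // 2
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndices(
        train=np.sort(perm[:n_train]),
        val=np.sort(perm[n_train : n_train + n_val]),
        test=np.sort(perm[n_train + n_val :]),
    )


def mean_squared_pe(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Mean over eyes of the per-eye squared prediction error
    ``1/2 ((dC0)^2 + (dC45)^2)``, in dpt^2."""
    pred = np.atleast_2d(np.asarray(predicted, dtype=float))
    obs = np.atleast_2d(np.asarray(observed, dtype=float))
    if pred.shape != obs.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {obs.shape}")
    if pred.size == 0:
        raise ValueError("empty input")
    return float(np.mean(0.5 * np.sum((obs - pred) ** 2, axis=1)))


# ---------------------------------------------------------------------------
# multivariate regression


@dataclass(frozen=True)
class RegressionModel:
    """Linear map y = matrix @ x + intercept for one eye side."""

    matrix: np.ndarray  # (2, 2)
    intercept: np.ndarray  # (2,)
    eye_side: str = "OD"
    logL: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "intercept", np.asarray(self.intercept, dtype=float))
        if self.matrix.shape != (2, 2) or self.intercept.shape != (2,):
            raise ValueError("matrix must be 2x2 and intercept length 2")


def apply_regression(m: RegressionModel, x: np.ndarray) -> np.ndarray:
    """Apply the linear model to one (C0, C45) pair or an (n, 2) batch."""
    x = np.asarray(x, dtype=float)
    return x @ m.matrix.T + m.intercept


def mirror_model_for_eye(m: RegressionModel) -> RegressionModel:
    """The fellow-eye model: negate both off-diagonal entries and the second
    intercept entry (conjugation with diag(1, -1)); an involution."""
    s = np.diag([1.0, -1.0])
    return RegressionModel(
        matrix=s @ m.matrix @ s,
        intercept=s @ m.intercept,
        eye_side="OS" if m.eye_side == "OD" else "OD",
        logL=m.logL,
    )


def _bisquare_weights(r: np.ndarray, c: float = 4.685) -> np.ndarray:
    scale = np.median(np.abs(r)) / 0.6745
    if scale <= 0:
        return np.ones_like(r)
    u = r / (c * scale)
    w = np.where(np.abs(u) < 1.0, (1.0 - u**2) ** 2, 0.0)
    return np.maximum(w, 1e-8)


def fit_multivariate_regression(
    X: np.ndarray,
    Y: np.ndarray,
    eye_side: str = "OD",
    robust: bool = False,
) -> RegressionModel:
    """Least-squares 2-input/2-output linear fit with intercept.

    Inputs must already be mirrored into right-eye orientation.  With
    ``robust`` the fit is refined by iteratively-reweighted least squares
    with bisquare weights on the radial residual.  The Gaussian
    log-likelihood of the residuals is stored when the residual covariance
    is nonsingular.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2 or Y.shape != X.shape:
        raise ValueError(f"expected (n, 2) X and Y, got {X.shape}, {Y.shape}")
    n = X.shape[0]
    if n < 4:
        raise ValueError(f"need n >= 4 eyes, got {n}")
    design = np.column_stack([X, np.ones(n)])
    if np.linalg.matrix_rank(design) < 3:
        # minimum-norm solution: degenerate predictors get zero coefficients
        # (an all-zero X reduces to intercept = column means of Y)
        warnings.warn("rank-deficient design (collinear inputs); using minimum-norm fit",
                      stacklevel=2)
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    if robust:
        for _ in range(50):
            resid = Y - design @ beta
            w = _bisquare_weights(np.linalg.norm(resid, axis=1))
            sw = np.sqrt(w)[:, None]
            beta_new, *_ = np.linalg.lstsq(design * sw, Y * sw, rcond=None)
            if np.max(np.abs(beta_new - beta)) < 1e-10:
                beta = beta_new
                break
            beta = beta_new
    model = RegressionModel(matrix=beta[:2].T, intercept=beta[2], eye_side=eye_side)
    try:
        logL = gaussian_log_likelihood(model, X, Y)
    except DegenerateLikelihoodError:
        logL = None
    return replace(model, logL=logL)


def gaussian_log_likelihood(
    m: RegressionModel, X: np.ndarray, Y: np.ndarray
) -> float:
    """Bivariate Gaussian log-likelihood of the model residuals.

    Uses the maximum-likelihood residual covariance (denominator n), giving
    the closed form ``-(n/2) (2 ln(2 pi) + ln det S + 2)``.  A (near-)
    perfect fit has a singular covariance and raises.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if n <= 2:
        raise ValueError(f"need n > 2, got {n}")
    resid = Y - apply_regression(m, X)
    sigma = resid.T @ resid / n
    det = np.linalg.det(sigma)
    # residual scales below ~1e-6 dpt are numerically a perfect fit
    if not math.isfinite(det) or det <= 1e-24:
        raise DegenerateLikelihoodError("singular residual covariance")
    return float(-0.5 * n * (2.0 * math.log(2.0 * math.pi) + math.log(det) + 2.0))


def load_published_models() -> dict[str, RegressionModel]:
    """The right-eye regression coefficient sets published for this analysis
    (IOLM- and CASIA-keratometry-based), bundled for replay."""
    text = resources.files("cornvec.data").joinpath("published_models.json").read_text()
    raw = json.loads(text)
    return {
        key: RegressionModel(
            matrix=np.array(entry["matrix"]),
            intercept=np.array(entry["intercept"]),
            eye_side=entry["eye_side"],
            logL=entry.get("logL"),
        )
        for key, entry in raw.items()
    }


# ---------------------------------------------------------------------------
# shallow network with Levenberg-Marquardt training


@dataclass
class NetworkModel:
    """Feedforward network (tanh hidden layers, linear output) with its
    training-set input standardisation and training history."""

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_mean: np.ndarray | None = None
    x_std: np.ndarray | None = None
    best_epoch: int | None = None
    history: np.ndarray | None = None  # (epochs, 3): train/val/test objective
    seed: int | None = None


def init_network(
    layer_sizes: tuple[int, ...] = (2, 10, 8, 2), seed: int | None = 0
) -> NetworkModel:
    """Reproducible small random weights (scaled by 1/sqrt(fan-in)), zero biases."""
    if len(layer_sizes) < 2:
        raise ValueError("need at least input and output layers")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        weights.append(rng.standard_normal((fan_in, fan_out)) / math.sqrt(fan_in))
        biases.append(np.zeros(fan_out))
    return NetworkModel(
        layer_sizes=tuple(layer_sizes), weights=weights, biases=biases, seed=seed
    )


def _standardise(net: NetworkModel, X: np.ndarray) -> np.ndarray:
    if net.x_mean is None:
        return X
    return (X - net.x_mean) / net.x_std


def _forward_acts(
    weights: Sequence[np.ndarray], biases: Sequence[np.ndarray], Xs: np.ndarray
) -> list[np.ndarray]:
    acts = [Xs]
    for W, b in zip(weights[:-1], biases[:-1]):
        acts.append(np.tanh(acts[-1] @ W + b))
    acts.append(acts[-1] @ weights[-1] + biases[-1])
    return acts


def network_forward(net: NetworkModel, X: np.ndarray) -> np.ndarray:
    """Predict (n, 2) outputs from (n, 2) inputs (standardised if trained)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return _forward_acts(net.weights, net.biases, _standardise(net, X))[-1]


def _pack(weights: Sequence[np.ndarray], biases: Sequence[np.ndarray]) -> np.ndarray:
    return np.concatenate(
        [w.ravel() for w in weights] + [b.ravel() for b in biases]
    )


def _unpack(
    theta: np.ndarray, layer_sizes: Sequence[int]
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    weights, biases = [], []
    pos = 0
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        weights.append(theta[pos : pos + fan_in * fan_out].reshape(fan_in, fan_out))
        pos += fan_in * fan_out
    for fan_out in layer_sizes[1:]:
        biases.append(theta[pos : pos + fan_out])
        pos += fan_out
    return weights, biases


def _jacobian_and_residuals(
    theta: np.ndarray,
    layer_sizes: Sequence[int],
    Xs: np.ndarray,
    Y: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled residuals r (objective = r.r) and their Jacobian d r / d theta.

    Residuals are the per-eye output errors scaled by 1/sqrt(2 n) so that the
    squared norm equals the mean squared prediction error.  The Jacobian is
    assembled by one backward pass per output component, vectorised over
    eyes.
    """
    weights, biases = _unpack(theta, layer_sizes)
    acts = _forward_acts(weights, biases, Xs)
    n, n_out = Y.shape
    scale = 1.0 / math.sqrt(2.0 * n)
    resid = (acts[-1] - Y) * scale  # (n, n_out)

    n_layers = len(weights)
    jac_blocks: list[np.ndarray] = []
    for k in range(n_out):
        delta = np.zeros((n, n_out))
        delta[:, k] = scale
        deltas = [None] * n_layers
        deltas[-1] = delta
        for l in range(n_layers - 1, 0, -1):
            back = deltas[l] @ weights[l].T
            deltas[l - 1] = back * (1.0 - acts[l] ** 2)  # tanh'
        w_grads = [
            np.einsum("ni,nj->nij", acts[l], deltas[l]).reshape(n, -1)
            for l in range(n_layers)
        ]
        b_grads = [deltas[l] for l in range(n_layers)]
        jac_blocks.append(np.concatenate(w_grads + b_grads, axis=1))
    # interleave rows to match resid.ravel() ordering (eye-major, component-minor)
    jac = np.stack(jac_blocks, axis=1).reshape(n * n_out, -1)
    return jac, resid.ravel()


def _objective(
    theta: np.ndarray, layer_sizes: Sequence[int], Xs: np.ndarray, Y: np.ndarray
) -> float:
    weights, biases = _unpack(theta, layer_sizes)
    out = _forward_acts(weights, biases, Xs)[-1]
    return mean_squared_pe(out, Y)


def train_network_lm(
    net: NetworkModel,
    X: np.ndarray,
    Y: np.ndarray,
    split: SplitIndices,
    max_epochs: int = 1000,
    lambda0: float = 1e-3,
    patience: int = 6,
) -> NetworkModel:
    """Train by Levenberg-Marquardt with validation-based early stopping.

    Each epoch takes one accepted damped Gauss-Newton step on the training
    objective (damping x10 on rejection, /10 on acceptance), so the training
    objective is non-increasing across epochs.  Per-epoch train/validation/
    test objectives are recorded; training stops when the validation
    objective has not improved for ``patience`` consecutive epochs, and the
    returned model carries the weights of the validation-optimal epoch.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    tr, va, te = split.train, split.val, split.test
    if len(tr) == 0:
        raise ValueError("empty training set")
    if set(tr) & set(va) or set(tr) & set(te) or set(va) & set(te):
        raise ValueError("split sets must be disjoint")

    x_mean = X[tr].mean(axis=0)
    x_std = np.maximum(X[tr].std(axis=0), 1e-8)
    Xs = (X - x_mean) / x_std

    sizes = net.layer_sizes
    theta = _pack(net.weights, net.biases)
    identity = np.eye(theta.size)
    lam = lambda0
    train_obj = _objective(theta, sizes, Xs[tr], Y[tr])
    if not math.isfinite(train_obj):
        raise RuntimeError(f"non-finite initial objective {train_obj}")

    history: list[tuple[float, float, float]] = []
    best_val = math.inf
    best_theta = theta.copy()
    best_epoch = 0
    stall = 0

    for epoch in range(1, max_epochs + 1):
        jac, resid = _jacobian_and_residuals(theta, sizes, Xs[tr], Y[tr])
        jtj = jac.T @ jac
        jtr = jac.T @ resid
        accepted = False
        for _ in range(40):
            try:
                step = np.linalg.solve(jtj + lam * identity, -jtr)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            cand = theta + step
            cand_obj = _objective(cand, sizes, Xs[tr], Y[tr])
            if not math.isfinite(cand_obj):
                raise RuntimeError(
                    f"non-finite objective at epoch {epoch} (lambda={lam:g})"
                )
            if cand_obj < train_obj:
                theta, train_obj = cand, cand_obj
                lam = max(lam / 10.0, 1e-14)
                accepted = True
                break
            lam *= 10.0
            if lam > 1e12:
                break
        if not accepted:
            break  # converged: no acceptable step at any damping

        val_obj = _objective(theta, sizes, Xs[va], Y[va]) if len(va) else math.nan
        test_obj = _objective(theta, sizes, Xs[te], Y[te]) if len(te) else math.nan
        history.append((train_obj, val_obj, test_obj))
        monitor = val_obj if len(va) else train_obj
        if monitor < best_val - 1e-15:
            best_val = monitor
            best_theta = theta.copy()
            best_epoch = epoch
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break

    weights, biases = _unpack(best_theta, sizes)
    return NetworkModel(
        layer_sizes=sizes,
        weights=weights,
        biases=biases,
        x_mean=x_mean,
        x_std=x_std,
        best_epoch=best_epoch,
        history=np.array(history) if history else np.empty((0, 3)),
        seed=net.seed,
    )


# ---------------------------------------------------------------------------
# error reporting


def predict(model: RegressionModel | NetworkModel, X: np.ndarray) -> np.ndarray:
    """Dispatch prediction for either model family."""
    if isinstance(model, RegressionModel):
        return apply_regression(model, X)
    if isinstance(model, NetworkModel):
        return network_forward(model, X)
    raise TypeError(f"unsupported model type {type(model)!r}")


def prediction_error_stats(
    models: dict[str, RegressionModel | NetworkModel],
    X: np.ndarray,
    Y: np.ndarray,
    level: float = 0.90,
) -> dict[str, dict]:
    """Fit-error summary per model: observed-minus-predicted components.

    Returns, per model, the raw (n, 2) error cloud, a
    :class:`~cornvec.descriptive.SummaryStats` per component (C0, C45), and
    the error cloud's confidence :class:`~cornvec.ellipse.EllipseParams`
    (``None`` when degenerate, e.g. a perfect fit).
    """
    from .descriptive import component_summary
    from .ellipse import DegenerateEllipseError, confidence_ellipse

    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    out: dict[str, dict] = {}
    for name, model in models.items():
        err = Y - predict(model, X)
        try:
            ell = confidence_ellipse(err, level=level)
        except DegenerateEllipseError:
            ell = None
        out[name] = {
            "errors": err,
            "summary": {
                "C0": component_summary(err[:, 0]),
                "C45": component_summary(err[:, 1]),
            },
            "ellipse": ell,
        }
    return out
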