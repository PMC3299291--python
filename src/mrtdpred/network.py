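"""Feedforward dose networks: the published 6-2-1 scorer and a backprop trainer.

Architecture
------------
A network maps the six molecular property descriptors to MRTD through a
single hidden layer.  Each weighted hidden unit computes

    h_j = post_scale_j * activation(w_j . x + b_j)

with activation ``tanh`` or ``identity``; additional constant units
contribute a fixed value.  The hidden-layer sum ``S`` is averaged over the
weighted units and mapped back to dose units through the min-max
denormalization of the training targets:

    MRTD = ((S / divisor) + 0.5) * out_range + out_offset

where ``out_offset`` is the minimum and ``out_offset + out_range`` the
maximum training MRTD.  Predictions are *not* clipped to that range: an
unbounded (identity) unit can leave it, and the published model indeed
produces negative external-test predictions.

The published model has two weighted units -- one affine (identity) and
one tanh-squashed -- plus one constant unit, with divisor 2 and the
training-dose range 0.0375 .. 200.0 mg/kg/day.

:class:`TanhNetworkRegressor` retrains the same representation from data
with stochastic (per-pattern) error backpropagation, learning rate 0.7 by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sklearn.base import BaseEstimator, RegressorMixin

from .datasets import DESCRIPTOR_COLUMNS, descriptor_matrix, subset_frame

ACTIVATIONS = ("tanh", "identity")


@dataclass
class HiddenUnit:
    """One weighted hidden unit: post_scale * activation(w . x + b)."""

    weights: np.ndarray  # (6,) in canonical descriptor order
    bias: float
    activation: str = "tanh"
    post_scale: float = 1.0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(DESCRIPTOR_COLUMNS),):
            raise ValueError("hidden unit needs exactly six input weights")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if not np.isfinite(self.post_scale):
            raise ValueError("post_scale must be finite")

    def output(self, X: np.ndarray) -> np.ndarray:
        z = X @ self.weights + self.bias
        if self.activation == "tanh":
            z = np.tanh(z)
        return self.post_scale * z


@dataclass
class NetworkSpec:
    """Full network: hidden units, constant units, output denormalization."""

    hidden: list[HiddenUnit]
    constants: list[float] = field(default_factory=list)
    divisor: float = 1.0
    out_range: float = 1.0
    out_offset: float = 0.0

    def __post_init__(self):
        if self.divisor < 1:
            raise ValueError("divisor must be >= 1")

    def hidden_sum(self, X: np.ndarray) -> np.ndarray:
        S = np.zeros(X.shape[0])
        for unit in self.hidden:
            S += unit.output(X)
        S += sum(self.constants)
        return S

    def predict(self, X) -> np.ndarray:
        """Predicted MRTD in mg/kg/day (unclipped)."""
        A = descriptor_matrix(X)
        S = self.hidden_sum(A)
        return ((S / self.divisor) + 0.5) * self.out_range + self.out_offset

    def to_dict(self) -> dict:
        return {
            "kind": "network",
            "hidden": [
                {
                    "weights": dict(zip(DESCRIPTOR_COLUMNS, map(float, u.weights))),
                    "bias": float(u.bias),
                    "activation": u.activation,
                    "post_scale": float(u.post_scale),
                }
                for u in self.hidden
            ],
            "constants": [float(c) for c in self.constants],
            "divisor": float(self.divisor),
            "out_range": float(self.out_range),
            "out_offset": float(self.out_offset),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "NetworkSpec":
        hidden = [
            HiddenUnit(
                weights=np.array([float(u["weights"][c]) for c in DESCRIPTOR_COLUMNS]),
                bias=float(u["bias"]),
                activation=u["activation"],
                post_scale=float(u["post_scale"]),
            )
            for u in doc["hidden"]
        ]
        return cls(
            hidden=hidden,
            constants=[float(c) for c in doc.get("constants", [])],
            divisor=float(doc["divisor"]),
            out_range=float(doc["out_range"]),
            out_offset=float(doc["out_offset"]),
        )


# -- the published 6-2-1 model -------------------------------------------------
#
# Constants as printed in the published scoring code.  The per-input
# additive offsets of each unit are folded into a single bias; the fold is
# an arithmetic identity, proven against the verbatim statement-by-statement
# interpreter in the test suite rather than assumed.

_VAR1_WEIGHTS = {
    "oxid_hl": -0.543086558961242,
    "p_bd": -5.67413921537257,
    "log_bio_hl": 0.40828801067156,
    "alogp": -0.848110602763694,
    "asol": -2.55399028293542e-02,
    "mw": 1.40343495376914e-02,
}
_VAR1_OFFSETS = (
    3.63976611815824,
    2.81153598121711,
    0.747514104338025,
    1.43330691867064,
    0.517313285798853,
    -5.94322423917294,
    3.86733992096867,
)
_VAR1_POST_SCALE = 0.108990429907616

_VAR2_WEIGHTS = {
    "oxid_hl": 8.23491975851945e-02,
    "p_bd": 3.12529587401663,
    "log_bio_hl": 0.431493610228662,
    "alogp": -0.04107624611641,
    "asol": 4.12997852313067e-02,
    "mw": 1.05078568602304e-03,
}
_VAR2_OFFSETS = (
    -0.551904322215974,
    -1.54858410557524,
    0.790000076287146,
    6.94188559367329e-02,
    -0.836531279838639,
    -0.444983569959981,
    9.28741349960935e-02,
)
_VAR2_POST_SCALE = 1.44376333322051

_VAR3_CONSTANT = -0.535249116383622

PUBLISHED_DIVISOR = 2.0
PUBLISHED_OUT_RANGE = 199.9625
PUBLISHED_OUT_OFFSET = 0.0375  # the minimum training MRTD


def published_network() -> NetworkSpec:
    """The published 6-2-1 network with its exact printed weights.

    Unit 1 is purely affine (identity activation), unit 2 is
    tanh-squashed, and a third, constant unit contributes a fixed value;
    the output denormalization spans the training-dose range
    0.0375 .. 200.0 mg/kg/day.
    """
    return NetworkSpec(
        hidden=[
            HiddenUnit(
                weights=np.array([_VAR1_WEIGHTS[c] for c in DESCRIPTOR_COLUMNS]),
                bias=float(np.sum(_VAR1_OFFSETS)),
                activation="identity",
                post_scale=_VAR1_POST_SCALE,
            ),
            HiddenUnit(
                weights=np.array([_VAR2_WEIGHTS[c] for c in DESCRIPTOR_COLUMNS]),
                bias=float(np.sum(_VAR2_OFFSETS)),
                activation="tanh",
                post_scale=_VAR2_POST_SCALE,
            ),
        ],
        constants=[_VAR3_CONSTANT],
        divisor=PUBLISHED_DIVISOR,
        out_range=PUBLISHED_OUT_RANGE,
        out_offset=PUBLISHED_OUT_OFFSET,
    )


def predict_network(net: NetworkSpec, descriptors) -> np.ndarray:
    """Evaluate a network on descriptor input."""
    return net.predict(descriptors)


# -- trainable network ---------------------------------------------------------


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss."""


def _forward(params: dict, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized network output u = (sum_j a_j tanh(W_j.x+b_j) + c)/H + 0.5.

    Returns (u, H) where H is the (n_patterns, hidden) tanh matrix.
    """
    Hmat = np.tanh(X @ params["W"].T + params["b"])
    u = (Hmat @ params["a"] + params["c"]) / params["W"].shape[0] + 0.5
    return u, Hmat


def _pattern_gradients(params: dict, x: np.ndarray, t: float) -> dict:
    """Gradients of (u - t)**2 for a single pattern x, normalized target t."""
    nh = params["W"].shape[0]
    h = np.tanh(params["W"] @ x + params["b"])
    u = (params["a"] @ h + params["c"]) / nh + 0.5
    g = 2.0 * (u - t) / nh
    sech2 = 1.0 - h * h
    return {
        "W": np.outer(g * params["a"] * sech2, x),
        "b": g * params["a"] * sech2,
        "a": g * h,
        "c": g,
    }


class TanhNetworkRegressor(RegressorMixin, BaseEstimator):
    """6-H-1 dose network trained by online error backpropagation.

    All weighted hidden units use the tanh activation; the unit post-scales
    act as output-layer weights and a single constant unit acts as the
    output bias.  Targets are min-max scaled from the training subset, so
    the fitted network carries ``out_offset = min(y)`` and
    ``out_range = max(y) - min(y)``.  Inputs are standardized internally
    (training-set z-scores); the standardization is folded into the
    exported weights so the fitted :attr:`network_` consumes raw
    descriptors.

    Parameters
    ----------
    hidden_units : int, default 2
        Number of weighted (tanh) hidden units; the published model's
        minimalistic architecture uses 2.
    learning_rate : float, default 0.7
        Step size for the per-pattern gradient updates (published value).
    max_epochs : int, default 2000
    patience : int, default 200
        Stop when the best training RMSE has not improved by more than
        ``tol`` for this many epochs.
    tol : float, default 1e-6
        Minimum RMSE improvement (mg/kg/day) that counts as progress.
    init_scale : float, default 0.5
        Initial weights are drawn uniformly from [-init_scale, init_scale].
    random_state : int or None
        Seed for initialization and pattern shuffling; identical seeds
        give bit-identical fits.

    Fitted attributes
    -----------------
    network_ : NetworkSpec
        Raw-descriptor representation (same form as the published model).
    rmse_path_ : ndarray
        Training RMSE after each epoch, original dose units.
    best_rmse_path_ : ndarray
        Running minimum of ``rmse_path_`` (non-increasing by construction);
        the returned weights are the best-so-far ones.
    n_epochs_ : int
    """

    def __init__(
        self,
        hidden_units: int = 2,
        learning_rate: float = 0.7,
        max_epochs: int = 2000,
        patience: int = 200,
        tol: float = 1e-6,
        init_scale: float = 0.5,
        random_state: int | None = None,
    ):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.tol = tol
        self.init_scale = init_scale
        self.random_state = random_state

    @classmethod
    def from_spec(cls, spec: NetworkSpec) -> "TanhNetworkRegressor":
        """Wrap an existing network (e.g. the published one) as an estimator."""
        est = cls(hidden_units=len(spec.hidden))
        est.network_ = spec
        est.n_features_in_ = len(DESCRIPTOR_COLUMNS)
        return est

    def fit(self, X, y):
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        A = descriptor_matrix(X)
        y = np.asarray(y, dtype=float).ravel()
        if A.shape[0] != y.shape[0]:
            raise ValueError("X and y have different lengths")
        if np.isnan(y).any():
            raise ValueError("training targets must not contain missing MRTD")
        ymin, ymax = float(np.min(y)), float(np.max(y))
        if ymax == ymin:
            raise ValueError("degenerate target range: max(y) == min(y)")
        out_offset, out_range = ymin, ymax - ymin
        t = (y - out_offset) / out_range  # normalized targets in [0, 1]

        mu = A.mean(axis=0)
        sigma = A.std(axis=0)
        sigma[sigma == 0] = 1.0
        Z = (A - mu) / sigma

        rng = np.random.default_rng(self.random_state)
        nh = self.hidden_units
        params = {
            "W": rng.uniform(-self.init_scale, self.init_scale, size=(nh, Z.shape[1])),
            "b": rng.uniform(-self.init_scale, self.init_scale, size=nh),
            "a": rng.uniform(-self.init_scale, self.init_scale, size=nh),
            "c": float(rng.uniform(-self.init_scale, self.init_scale)),
        }

        n = Z.shape[0]
        lr = self.learning_rate
        best_rmse = np.inf
        best_params = {k: np.copy(v) if isinstance(v, np.ndarray) else v for k, v in params.items()}
        since_improved = 0
        rmse_path, best_path = [], []

        for epoch in range(self.max_epochs):
            for i in rng.permutation(n):
                grads = _pattern_gradients(params, Z[i], t[i])
                params["W"] -= lr * grads["W"]
                params["b"] -= lr * grads["b"]
                params["a"] -= lr * grads["a"]
                params["c"] -= lr * grads["c"]
            u, _ = _forward(params, Z)
            rmse = float(np.sqrt(np.mean((u * out_range + out_offset - y) ** 2)))
            if not np.isfinite(rmse):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            rmse_path.append(rmse)
            if rmse < best_rmse - self.tol:
                best_rmse = rmse
                best_params = {
                    k: np.copy(v) if isinstance(v, np.ndarray) else v
                    for k, v in params.items()
                }
                since_improved = 0
            else:
                best_rmse = min(best_rmse, rmse)
                since_improved += 1
            best_path.append(best_rmse)
            if since_improved >= self.patience:
                break

        # Fold the input standardization into raw-descriptor weights:
        # tanh(W.((x-mu)/sigma) + b) = tanh((W/sigma).x + (b - W.(mu/sigma))).
        Wraw = best_params["W"] / sigma
        braw = best_params["b"] - best_params["W"] @ (mu / sigma)
        self.network_ = NetworkSpec(
            hidden=[
                HiddenUnit(
                    weights=Wraw[j],
                    bias=float(braw[j]),
                    activation="tanh",
                    post_scale=float(best_params["a"][j]),
                )
                for j in range(nh)
            ],
            constants=[float(best_params["c"])],
            divisor=float(nh),
            out_range=out_range,
            out_offset=out_offset,
        )
        self.rmse_path_ = np.asarray(rmse_path)
        self.best_rmse_path_ = np.asarray(best_path)
        self.n_epochs_ = len(rmse_path)
        self.train_rmse_ = best_rmse
        self.n_features_in_ = A.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        return self.network_.predict(X)


def train_network(
    ds: pd.DataFrame,
    subset: str = "train",
    hidden_units: int = 2,
    learning_rate: float = 0.7,
    max_epochs: int = 2000,
    patience: int = 200,
    seed: int | None = 0,
) -> TanhNetworkRegressor:
    """Retrain a 6-H-1 network on one subset of a dataset."""
    sub = subset_frame(ds, subset)
    est = TanhNetworkRegressor(
        hidden_units=hidden_units,
        learning_rate=learning_rate,
        max_epochs=max_epochs,
        patience=patience,
        random_state=seed,
    )
    return est.fit(sub, sub["mrtd"].to_numpy())
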