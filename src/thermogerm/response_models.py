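"""Baseline thermal-germination predictors and their fitting routines.

Three families map a diurnal regime (T1 = cool-period, T2 = warm-period
temperature, °C) to a germination fraction:

* a generalized quadratic surface
  Y = A0 + A1·T1 + A2·T2 + A3·T1² + A4·T2² + A5·T1·T2,
* a general quintic surface over all 21 bivariate monomials of total
  degree ≤ 5, and
* a three-layer feed-forward network (2 inputs → H hidden → 1 sigmoid
  output) trained by back-propagation (full-batch gradient descent on
  mean squared error, "BP").

Polynomials are fit by ordinary least squares, optionally followed by
gradient refinement (the "BP-refined" variants).  Targets are always
germination fractions in [0, 1]; polynomial predictions are clamped to
[0, 1] only at the prediction interface, never during fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PolynomialModel",
    "NetworkModel",
    "TrainConfig",
    "quadratic_features",
    "quintic_features",
    "feature_matrix",
    "n_coefficients",
    "fit_ols",
    "refine_polynomial_bp",
    "init_network",
    "forward",
    "train_bp",
    "save_model",
    "load_model",
]

#: Divisor applied to both temperature inputs before a network sees them,
#: keeping the 5–40 °C assay grid inside [0.125, 1] and the hidden-layer
#: sigmoids out of saturation.
DEFAULT_INPUT_DIVISOR = 40.0


def quadratic_features(t1, t2) -> np.ndarray:
    """[1, T1, T2, T1², T2², T1·T2] — the generalized quadratic basis."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    return np.stack(
        [np.ones_like(t1), t1, t2, t1**2, t2**2, t1 * t2], axis=-1
    )


def quintic_features(t1, t2) -> np.ndarray:
    """Intercept plus all monomials T1ⁿ·T2^(m−n), m = 1..5, n = 0..m.

    21 features in a fixed, documented order (m ascending, n ascending
    within m) so serialized coefficient vectors are portable.
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    cols = [np.ones_like(t1)]
    for m in range(1, 6):
        for n in range(0, m + 1):
            cols.append(t1**n * t2 ** (m - n))
    return np.stack(cols, axis=-1)


_FEATURE_FNS = {2: quadratic_features, 5: quintic_features}
_N_COEF = {2: 6, 5: 21}


def n_coefficients(degree: int) -> int:
    try:
        return _N_COEF[degree]
    except KeyError:
        raise ValueError(f"degree must be 2 or 5, got {degree}") from None


def feature_matrix(pairs, degree: int) -> tuple[np.ndarray, np.ndarray]:
    """(design matrix, target vector) from (t1, t2, fraction) triples."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("pairs must be (t1, t2, fraction) triples")
    n_coefficients(degree)  # validates the degree
    return _FEATURE_FNS[degree](arr[:, 0], arr[:, 1]), arr[:, 2]


@dataclass(frozen=True)
class PolynomialModel:
    """Quadratic (6 coefficients) or quintic (21) germination surface."""

    degree: int
    coefficients: tuple[float, ...]
    clamp_output: bool = True

    def __post_init__(self) -> None:
        expected = n_coefficients(self.degree)
        if len(self.coefficients) != expected:
            raise ValueError(
                f"degree-{self.degree} model needs {expected} coefficients, "
                f"got {len(self.coefficients)}"
            )

    def evaluate(self, t1, t2) -> np.ndarray:
        """Raw (unclamped) surface value — used during fitting."""
        feats = _FEATURE_FNS[self.degree](t1, t2)
        return feats @ np.asarray(self.coefficients)

    def predict(self, t1, t2):
        """Predicted germination fraction, clamped to [0, 1] if configured."""
        y = self.evaluate(t1, t2)
        if self.clamp_output:
            y = np.clip(y, 0.0, 1.0)
        return float(y) if np.ndim(y) == 0 else y


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters for full-batch gradient (BP) fitting.

    ``momentum`` is the classic BP momentum term (applied to network
    training only; polynomial refinement is plain guarded descent).
    """

    learning_rate: float = 0.5
    epochs: int = 2000
    momentum: float = 0.9
    tol: float = 0.0  # stop when |ΔMSE| per epoch falls below this
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")


def fit_ols(pairs, degree: int) -> PolynomialModel:
    """Ordinary-least-squares polynomial fit on (t1, t2, fraction) pairs.

    Requires at least as many pairs as coefficients and a full-rank
    design matrix (the quintic on the 36-point half grid is full rank).
    """
    X, y = feature_matrix(pairs, degree)
    p = n_coefficients(degree)
    if X.shape[0] < p:
        raise ValueError(
            f"degree-{degree} fit needs >= {p} pairs, got {X.shape[0]}"
        )
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise ValueError(
            f"rank-deficient design for degree-{degree} model on "
            f"{X.shape[0]} points (rank {rank} < {p})"
        )
    return PolynomialModel(degree=degree, coefficients=tuple(coef))


def _mse(residuals: np.ndarray) -> float:
    return float(np.mean(residuals**2))


def refine_polynomial_bp(
    model: PolynomialModel, pairs, config: TrainConfig | None = None
) -> PolynomialModel:
    """Gradient refinement of polynomial coefficients on MSE.

    Features are z-scored internally (the raw monomials span ~10 orders
    of magnitude for the quintic) and coefficients mapped back to the raw
    basis on output.  Steps are guarded: a step that raises the training
    MSE is undone and the learning rate halved, so the returned model's
    training MSE never exceeds the input model's.
    """
    config = config or TrainConfig(learning_rate=0.1)
    X, y = feature_matrix(pairs, model.degree)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    mu[0], sd[0] = 0.0, 1.0  # keep the intercept column as-is
    Z = (X - mu) / sd
    # express the starting model in the standardized basis
    b = np.asarray(model.coefficients) * sd
    b[0] = model.coefficients[0] + float(mu @ np.asarray(model.coefficients))
    lr = config.learning_rate
    n = len(y)
    mse = _mse(Z @ b - y)
    for _ in range(config.epochs):
        grad = 2.0 / n * Z.T @ (Z @ b - y)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite gradient in polynomial BP")
        trial = b - lr * grad
        trial_mse = _mse(Z @ trial - y)
        if trial_mse > mse:
            lr *= 0.5
            continue
        if mse - trial_mse < config.tol:
            b, mse = trial, trial_mse
            break
        b, mse = trial, trial_mse
    # map back to the raw basis
    coef = b / sd
    coef[0] = b[0] - float((mu / sd)[1:] @ b[1:])
    return replace(model, coefficients=tuple(coef))


# --------------------------------------------------------------------------
# Three-layer BP network


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class NetworkModel:
    """2 → H → 1 feed-forward network with sigmoid units.

    Hidden unit h computes sigmoid(w_in[h]·x − input_thresholds[h]); the
    output unit computes sigmoid(Σ w_out[h]·z_h − output_threshold), so
    predictions lie in (0, 1) by construction.  Inputs are scaled as
    (t − offset) / divisor before the first layer.
    """

    input_weights: tuple[tuple[float, float], ...]  # H × 2
    input_thresholds: tuple[float, ...]  # H
    output_weights: tuple[float, ...]  # H
    output_threshold: float
    input_offset: tuple[float, float] = (0.0, 0.0)
    input_divisor: tuple[float, float] = (DEFAULT_INPUT_DIVISOR, DEFAULT_INPUT_DIVISOR)

    def __post_init__(self) -> None:
        h = len(self.input_weights)
        if h < 1:
            raise ValueError("network needs at least one hidden unit")
        if len(self.input_thresholds) != h or len(self.output_weights) != h:
            raise ValueError("inconsistent hidden-layer sizes")
        flat = np.concatenate(
            [
                np.ravel(self.input_weights),
                self.input_thresholds,
                self.output_weights,
                [self.output_threshold],
            ]
        )
        if not np.all(np.isfinite(flat)):
            raise ValueError("network parameters must be finite")

    @property
    def n_hidden(self) -> int:
        return len(self.input_weights)

    def predict(self, t1, t2):
        return forward(self, t1, t2)


def init_network(
    n_hidden: int,
    rng: np.random.Generator | int = 0,
    weight_scale: float = 1.0,
) -> NetworkModel:
    """Random network with weights and thresholds ~ U(−scale, scale)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    w_in = rng.uniform(-weight_scale, weight_scale, size=(n_hidden, 2))
    b_in = rng.uniform(-weight_scale, weight_scale, size=n_hidden)
    w_out = rng.uniform(-weight_scale, weight_scale, size=n_hidden)
    b_out = rng.uniform(-weight_scale, weight_scale)
    return NetworkModel(
        input_weights=tuple(map(tuple, w_in)),
        input_thresholds=tuple(b_in),
        output_weights=tuple(w_out),
        output_threshold=float(b_out),
    )


def _net_arrays(net: NetworkModel):
    return (
        np.asarray(net.input_weights, dtype=float),
        np.asarray(net.input_thresholds, dtype=float),
        np.asarray(net.output_weights, dtype=float),
        float(net.output_threshold),
    )


def _scale_inputs(net: NetworkModel, t1, t2) -> np.ndarray:
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    off = np.asarray(net.input_offset)
    div = np.asarray(net.input_divisor)
    return (np.stack([t1, t2], axis=-1) - off) / div


def forward(net: NetworkModel, t1, t2):
    """Network output (germination fraction in (0, 1)); vectorized."""
    w_in, b_in, w_out, b_out = _net_arrays(net)
    x = _scale_inputs(net, t1, t2)
    hidden = _sigmoid(x @ w_in.T - b_in)
    y = _sigmoid(np.atleast_1d(hidden @ w_out - b_out))
    return float(y[0]) if np.ndim(t1) == 0 and np.size(y) == 1 else y


def train_bp(
    net: NetworkModel,
    pairs,
    config: TrainConfig | None = None,
    return_history: bool = False,
):
    """Full-batch back-propagation from an existing network's weights.

    Gradient descent on MSE with a momentum term and an adaptive ("bold
    driver") step: a step that increases the MSE is undone, the learning
    rate halved and the velocity reset; a successful step grows the rate
    by 5 %.  The returned network's training MSE therefore never exceeds
    the starting network's.
    """
    config = config or TrainConfig()
    arr = np.asarray(pairs, dtype=float)
    if arr.size == 0:
        raise ValueError("pairs must be nonempty")
    x = _scale_inputs(net, arr[:, 0], arr[:, 1])
    g = arr[:, 2]
    w_in, b_in, w_out, b_out = _net_arrays(net)
    n = len(g)
    lr = config.learning_rate
    v_wi = np.zeros_like(w_in)
    v_bi = np.zeros_like(b_in)
    v_wo = np.zeros_like(w_out)
    v_bo = 0.0

    def mse_of(wi, bi, wo, bo) -> float:
        hid = _sigmoid(x @ wi.T - bi)
        return _mse(_sigmoid(hid @ wo - bo) - g)

    mse = mse_of(w_in, b_in, w_out, b_out)
    if not np.isfinite(mse):
        raise FloatingPointError(
            "training diverged (non-finite MSE); reduce the learning rate"
        )
    history = [mse]
    for _ in range(config.epochs):
        hidden = _sigmoid(x @ w_in.T - b_in)
        y = _sigmoid(hidden @ w_out - b_out)
        # backprop through sigmoid output and hidden layers
        dy = 2.0 / n * (y - g) * y * (1.0 - y)  # N
        gw_out = hidden.T @ dy
        gb_out = -dy.sum()
        dh = np.outer(dy, w_out) * hidden * (1.0 - hidden)  # N × H
        gw_in = dh.T @ x
        gb_in = -dh.sum(axis=0)
        if not all(
            np.all(np.isfinite(a)) for a in (gw_out, gw_in, gb_in)
        ) or not np.isfinite(gb_out):
            raise FloatingPointError(
                "training diverged (non-finite gradient); reduce the learning rate"
            )
        v_wi = config.momentum * v_wi - lr * gw_in
        v_bi = config.momentum * v_bi - lr * gb_in
        v_wo = config.momentum * v_wo - lr * gw_out
        v_bo = config.momentum * v_bo - lr * gb_out
        trial = mse_of(w_in + v_wi, b_in + v_bi, w_out + v_wo, b_out + v_bo)
        if trial > mse:
            lr *= 0.5
            v_wi[:], v_bi[:], v_wo[:], v_bo = 0.0, 0.0, 0.0, 0.0
            history.append(mse)
            continue
        improved = mse - trial
        w_in = w_in + v_wi
        b_in = b_in + v_bi
        w_out = w_out + v_wo
        b_out = b_out + v_bo
        mse = trial
        lr *= 1.05
        history.append(mse)
        if improved < config.tol:
            break
    out = NetworkModel(
        input_weights=tuple(map(tuple, w_in)),
        input_thresholds=tuple(b_in),
        output_weights=tuple(w_out),
        output_threshold=float(b_out),
        input_offset=net.input_offset,
        input_divisor=net.input_divisor,
    )
    return (out, history) if return_history else out


# --------------------------------------------------------------------------
# Plain-text model serialization


def save_model(model, path, metadata: dict | None = None) -> None:
    """Serialize a polynomial or network model as plain key/value text."""
    lines: list[str] = []
    if isinstance(model, PolynomialModel):
        lines.append("family: polynomial")
        lines.append(f"degree: {model.degree}")
        lines.append(f"clamp_output: {int(model.clamp_output)}")
        lines.append(
            "coefficients: " + " ".join(f"{c:.17g}" for c in model.coefficients)
        )
    elif isinstance(model, NetworkModel):
        lines.append("family: network")
        lines.append(f"n_hidden: {model.n_hidden}")
        lines.append(
            "input_offset: " + " ".join(f"{v:.17g}" for v in model.input_offset)
        )
        lines.append(
            "input_divisor: " + " ".join(f"{v:.17g}" for v in model.input_divisor)
        )
        for h, row in enumerate(model.input_weights):
            lines.append(f"input_weights_{h}: " + " ".join(f"{v:.17g}" for v in row))
        lines.append(
            "input_thresholds: "
            + " ".join(f"{v:.17g}" for v in model.input_thresholds)
        )
        lines.append(
            "output_weights: " + " ".join(f"{v:.17g}" for v in model.output_weights)
        )
        lines.append(f"output_threshold: {model.output_threshold:.17g}")
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    for key, value in (metadata or {}).items():
        lines.append(f"meta_{key}: {value}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)


def load_model(path):
    """Load a model written by :func:`save_model`."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    kv: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition(":")
        kv[key.strip()] = value.strip()
    family = kv.get("family")
    if family == "polynomial":
        return PolynomialModel(
            degree=int(kv["degree"]),
            coefficients=tuple(float(v) for v in kv["coefficients"].split()),
            clamp_output=bool(int(kv.get("clamp_output", "1"))),
        )
    if family == "network":
        h = int(kv["n_hidden"])
        return NetworkModel(
            input_weights=tuple(
                tuple(float(v) for v in kv[f"input_weights_{i}"].split())
                for i in range(h)
            ),
            input_thresholds=tuple(
                float(v) for v in kv["input_thresholds"].split()
            ),
            output_weights=tuple(float(v) for v in kv["output_weights"].split()),
            output_threshold=float(kv["output_threshold"]),
            input_offset=tuple(float(v) for v in kv["input_offset"].split()),
            input_divisor=tuple(float(v) for v in kv["input_divisor"].split()),
        )
    raise ValueError(f"unknown model family {family!r}")
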