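"""The five weight regressors and their comparison harness.

The centrepiece is a from-scratch 5-input / 10-hidden-neuron / 1-output
feed-forward (BP) network trained with Levenberg-Marquardt damped
Gauss-Newton on the sum of squared residuals — the standard training
recipe for small regression networks.  Alongside it: multiple linear
regression (closed-form least squares), RBF support-vector regression,
a decision tree and Gaussian-process regression (the latter three
delegated to scikit-learn), all evaluated on identical train/test
splits with R^2 / RMSE / MSE / MAE in pounds.

A published hidden-layer weight matrix for the same 5-feature network
ships as a fixture for structural forward-pass checks.  Its output
layer and input scaling were never published, so it cannot be used for
actual weight prediction — only (W1, b1) load; W2/b2 are flagged absent.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .metrics import EvalReport, regression_metrics
from .morphometry import FEATURE_NAMES, FeatureScaler, fit_scaler

_HIDDEN_FIXTURE = "published_bp_hidden_layer.csv"
_HIDDEN_FIXTURE_SHA256 = "b06d507e977d5b793a80747a7628f50365a80ffc7d8c99a7e51abe3a40905f36"

#: fixture column order -> canonical (A_t, A_b, H_t, H_b, age) order
_FIXTURE_TO_CANONICAL = {"age": 4, "top_view_height": 2, "top_view_area": 0,
                         "back_view_distance": 3, "back_view_area": 1}


# ---------------------------------------------------------------------
# BP network
# ---------------------------------------------------------------------

@dataclass
class BPNetParams:
    """Parameters of the 5 -> n_hidden -> 1 regression network.

    ``W2``/``b2`` may be ``None`` when only the hidden layer is known
    (as for the published reference weights).
    """

    W1: np.ndarray            # (n_hidden, 5)
    b1: np.ndarray            # (n_hidden,)
    W2: np.ndarray | None     # (1, n_hidden)
    b2: np.ndarray | None     # (1,)
    hidden_activation: str = "tanh"

    def __post_init__(self):
        self.W1 = np.asarray(self.W1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float).reshape(-1)
        if self.W1.ndim != 2:
            raise ValueError("W1 must be 2-D (n_hidden, n_features)")
        if self.b1.shape[0] != self.W1.shape[0]:
            raise ValueError("b1 length must equal n_hidden")
        if self.W2 is not None:
            self.W2 = np.asarray(self.W2, dtype=float).reshape(1, -1)
            if self.W2.shape[1] != self.W1.shape[0]:
                raise ValueError("W2 width must equal n_hidden")
            self.b2 = np.asarray(self.b2, dtype=float).reshape(1)
        if self.hidden_activation not in ("tanh", "logistic"):
            raise ValueError("hidden_activation must be 'tanh' or 'logistic'")

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def n_features(self) -> int:
        return self.W1.shape[1]

    @property
    def output_layer_known(self) -> bool:
        return self.W2 is not None

    def to_json(self, path: str | Path) -> None:
        doc = {"W1": self.W1.tolist(), "b1": self.b1.tolist(),
               "W2": None if self.W2 is None else self.W2.tolist(),
               "b2": None if self.b2 is None else self.b2.tolist(),
               "hidden_activation": self.hidden_activation}
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "BPNetParams":
        doc = json.loads(Path(path).read_text())
        return cls(W1=np.array(doc["W1"]), b1=np.array(doc["b1"]),
                   W2=None if doc["W2"] is None else np.array(doc["W2"]),
                   b2=None if doc["b2"] is None else np.array(doc["b2"]),
                   hidden_activation=doc["hidden_activation"])


def _act(h: np.ndarray, kind: str) -> np.ndarray:
    return np.tanh(h) if kind == "tanh" else 1.0 / (1.0 + np.exp(-h))


def _act_deriv(a: np.ndarray, kind: str) -> np.ndarray:
    return 1.0 - a ** 2 if kind == "tanh" else a * (1.0 - a)


def bp_forward(params: BPNetParams, x: np.ndarray) -> tuple[np.ndarray | None, np.ndarray]:
    """Forward pass; returns (predictions, hidden pre-activations).

    ``x`` is one feature vector or an (n, n_features) batch of scaled
    features.  Hidden pre-activations are exposed for testability; the
    output layer is linear.  When the output layer is unknown (the
    published reference ships the hidden layer only) the prediction is
    ``None`` and only the pre-activations are usable.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != params.n_features:
        raise ValueError(f"expected {params.n_features} features, got {x.shape[1]}")
    pre = x @ params.W1.T + params.b1
    if params.W2 is None:
        return None, pre
    y = _act(pre, params.hidden_activation) @ params.W2.T + params.b2
    return y.reshape(-1), pre


def bp_hidden_preactivation(params: BPNetParams, x: np.ndarray) -> np.ndarray:
    """Hidden pre-activations W1 x + b1 (works without an output layer)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return (x @ params.W1.T + params.b1)


def load_published_hidden_layer(path: str | Path | None = None) -> BPNetParams:
    """Load the published reference hidden layer (W1, b1 only).

    The fixture stores one row per hidden neuron with columns in the
    published order (age, top-view height, top-view area, back-view
    distance, back-view area, bias); columns are permuted into the
    canonical (A_t, A_b, H_t, H_b, age) feature order.  A checksum guards
    the transcription.
    """
    if path is None:
        ref = resources.files("cowseg") / "fixtures" / _HIDDEN_FIXTURE
        data = ref.read_bytes()
    else:
        data = Path(path).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if path is None and digest != _HIDDEN_FIXTURE_SHA256:
        raise ValueError("reference hidden-layer fixture failed its checksum")
    from io import BytesIO

    df = pd.read_csv(BytesIO(data))
    n_hidden = len(df)
    W1 = np.zeros((n_hidden, 5))
    for col, canon in _FIXTURE_TO_CANONICAL.items():
        W1[:, canon] = df[col].to_numpy()
    b1 = df["bias"].to_numpy()
    return BPNetParams(W1=W1, b1=b1, W2=None, b2=None, hidden_activation="tanh")


# ---------------------------------------------------------------------
# Levenberg-Marquardt training
# ---------------------------------------------------------------------

def _pack(params: BPNetParams) -> np.ndarray:
    return np.concatenate([params.W1.ravel(), params.b1,
                           params.W2.ravel(), params.b2])


def _unpack(theta: np.ndarray, n_hidden: int, n_feat: int, act: str) -> BPNetParams:
    i = 0
    W1 = theta[i:i + n_hidden * n_feat].reshape(n_hidden, n_feat); i += n_hidden * n_feat
    b1 = theta[i:i + n_hidden]; i += n_hidden
    W2 = theta[i:i + n_hidden].reshape(1, n_hidden); i += n_hidden
    b2 = theta[i:i + 1]
    return BPNetParams(W1=W1, b1=b1, W2=W2, b2=b2, hidden_activation=act)


def _residuals_and_jacobian(theta, X, y, n_hidden, act):
    n, n_feat = X.shape
    p = _unpack(theta, n_hidden, n_feat, act)
    pre = X @ p.W1.T + p.b1          # (n, h)
    a = _act(pre, act)
    yhat = (a @ p.W2.T + p.b2).reshape(-1)
    r = yhat - y
    da = _act_deriv(a, act)          # (n, h)
    w2 = p.W2.reshape(-1)            # (h,)
    gpre = da * w2                   # d yhat / d pre, (n, h)
    J = np.empty((n, theta.size))
    J[:, : n_hidden * n_feat] = (gpre[:, :, None] * X[:, None, :]).reshape(n, -1)
    i = n_hidden * n_feat
    J[:, i:i + n_hidden] = gpre; i += n_hidden
    J[:, i:i + n_hidden] = a; i += n_hidden
    J[:, i] = 1.0
    return r, J


def train_bp_lm(X: np.ndarray, y: np.ndarray, n_hidden: int = 10, seed: int = 0,
                max_epochs: int = 200, lam0: float = 1e-3, lam_max: float = 1e10,
                grad_tol: float = 1e-7, hidden_activation: str = "tanh",
                init_scale: float = 0.5) -> BPNetParams:
    """Train the BP network by Levenberg-Marquardt on the SSE.

    Damped normal equations (J'J + lam I) dtheta = -J'r with a
    multiplicative damping schedule: divide lam by 10 on an accepted
    step, multiply by 10 on a rejected one.  Stops on gradient
    infinity-norm < ``grad_tol``, lam exceeding ``lam_max`` or
    ``max_epochs``.  Training SSE is non-increasing over accepted steps.
    Features (and ideally targets) should be pre-scaled.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    n, n_feat = X.shape
    n_params = n_hidden * n_feat + 2 * n_hidden + 1
    if n < n_params / 2:
        warnings.warn(f"only {n} samples for {n_params} parameters; fit may be unstable")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(-init_scale, init_scale, size=n_params)
    if max_epochs == 0:
        return _unpack(theta, n_hidden, n_feat, hidden_activation)
    lam = lam0
    r, J = _residuals_and_jacobian(theta, X, y, n_hidden, hidden_activation)
    sse = float(r @ r)
    eye = np.eye(n_params)
    for _ in range(max_epochs):
        g = J.T @ r
        if np.max(np.abs(g)) < grad_tol:
            break
        H = J.T @ J
        accepted = False
        while lam <= lam_max:
            try:
                step = np.linalg.solve(H + lam * eye, -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            r_new, J_new = _residuals_and_jacobian(theta + step, X, y,
                                                   n_hidden, hidden_activation)
            sse_new = float(r_new @ r_new)
            if sse_new < sse:
                theta = theta + step
                r, J, sse = r_new, J_new, sse_new
                lam = max(lam / 10.0, 1e-12)
                accepted = True
                break
            lam *= 10.0
        if not accepted:
            break
    if lam > lam_max and not np.isfinite(sse):
        raise RuntimeError("LM diverged: singular normal equations at maximum damping")
    return _unpack(theta, n_hidden, n_feat, hidden_activation)


# ---------------------------------------------------------------------
# model wrappers with a common fit/predict surface
# ---------------------------------------------------------------------

@dataclass
class MLRModel:
    """Ordinary least-squares linear model Y = b0 + b.Z."""

    intercept: float
    coef: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + np.asarray(X, dtype=float) @ self.coef


def fit_mlr(X: np.ndarray, y: np.ndarray) -> MLRModel:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    A = np.column_stack([np.ones(len(X)), X])
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn("rank-deficient design: minimum-norm least-squares solution")
    return MLRModel(intercept=float(beta[0]), coef=beta[1:])


class BPRegressor:
    """BP network regressor with internal min-max [-1, 1] scaling of
    features and target (inverted at prediction time)."""

    def __init__(self, n_hidden: int = 10, seed: int = 0, max_epochs: int = 200,
                 hidden_activation: str = "tanh"):
        self.n_hidden = n_hidden
        self.seed = seed
        self.max_epochs = max_epochs
        self.hidden_activation = hidden_activation
        self.params_: BPNetParams | None = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).reshape(-1)
        self.x_scaler_ = self._tolerant_scaler(X)
        self.y_scaler_ = fit_scaler(y.reshape(-1, 1), "minmax_pm1", names=["weight"])
        Xs = self.x_scaler_.apply(X)
        ys = self.y_scaler_.apply(y.reshape(-1, 1)).reshape(-1)
        self.params_ = train_bp_lm(Xs, ys, n_hidden=self.n_hidden, seed=self.seed,
                                   max_epochs=self.max_epochs,
                                   hidden_activation=self.hidden_activation)
        return self

    def predict(self, X):
        Xs = self.x_scaler_.apply(np.asarray(X, dtype=float))
        ys, _ = bp_forward(self.params_, Xs)
        return self.y_scaler_.invert(ys.reshape(-1, 1)).reshape(-1)

    @staticmethod
    def _tolerant_scaler(X: np.ndarray) -> FeatureScaler:
        """Min-max scaler that maps constant (uninformative) features to the
        scale midpoint instead of failing, so degraded upstream inputs —
        e.g. empty predicted masks giving all-zero areas — still train."""
        lo, hi = X.min(axis=0), X.max(axis=0)
        const = hi <= lo
        if const.any():
            warnings.warn(f"constant feature column(s) {np.where(const)[0].tolist()} "
                          "carry no information; scaled to 0")
            lo = lo.copy(); hi = hi.copy()
            hi[const] = lo[const] + 1.0
            lo[const] = lo[const] - 1.0
        return FeatureScaler(mode="minmax_pm1", lo=lo, hi=hi)


class _SklearnScaled:
    """Standardize features (and optionally target) around a sklearn model."""

    def __init__(self, model, scale_y: bool):
        self.model = model
        self.scale_y = scale_y

    def fit(self, X, y):
        self.xs_ = StandardScaler().fit(X)
        y = np.asarray(y, dtype=float).reshape(-1)
        if self.scale_y:
            self.y_mean_, self.y_sd_ = y.mean(), y.std() or 1.0
            y = (y - self.y_mean_) / self.y_sd_
        self.model.fit(self.xs_.transform(X), y)
        return self

    def predict(self, X):
        y = self.model.predict(self.xs_.transform(X))
        if self.scale_y:
            y = y * self.y_sd_ + self.y_mean_
        return y


def fit_svr(X, y, C: float = 3.0, epsilon: float = 0.05, gamma="scale"):
    """RBF support-vector regression on standardized features/target."""
    m = _SklearnScaled(SVR(kernel="rbf", C=C, epsilon=epsilon, gamma=gamma), scale_y=True)
    return m.fit(X, y)


def fit_tree(X, y, max_depth: int | None = None, seed: int = 0):
    m = DecisionTreeRegressor(max_depth=max_depth, random_state=seed)
    m.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float).reshape(-1))
    return m


def fit_gpr(X, y, seed: int = 0):
    """Gaussian-process regression, RBF + white-noise kernel."""
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(1.0, (1e-2, 1e3)) \
        + WhiteKernel(1e-2, (1e-8, 1e1))
    gpr = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                   random_state=seed, n_restarts_optimizer=2)
    return _SklearnScaled(gpr, scale_y=False).fit(X, y)


DEFAULT_MODELS = ("MLR", "DT", "SVM", "GR", "BP")


def _make_model(tag: str, seed: int):
    if tag == "MLR":
        return None  # closed form, handled separately
    if tag == "DT":
        return ("fit", lambda X, y: fit_tree(X, y, seed=seed))
    if tag == "SVM":
        return ("fit", lambda X, y: fit_svr(X, y))
    if tag == "GR":
        return ("fit", lambda X, y: fit_gpr(X, y, seed=seed))
    if tag == "BP":
        return ("fit", lambda X, y: BPRegressor(seed=seed).fit(X, y))
    raise ValueError(f"unknown model tag {tag!r}")


def compare_models(train: pd.DataFrame, test: pd.DataFrame,
                   models: tuple[str, ...] = DEFAULT_MODELS, seed: int = 0
                   ) -> tuple[pd.DataFrame, dict[str, dict[str, np.ndarray]]]:
    """Fit all requested models on the train split, evaluate on both splits.

    ``train``/``test`` are feature tables with columns A_t, A_b, H_t,
    H_b, age, weight.  Returns the metric table (R^2/RMSE/MSE/MAE per
    model per split) and per-model predicted-vs-actual arrays for
    scatter plots.  A model failure is recorded in the table; the
    remaining models still run.
    """
    def xy(df):
        return df[FEATURE_NAMES].to_numpy(dtype=float), df["weight"].to_numpy(dtype=float)

    Xtr, ytr = xy(train)
    Xte, yte = xy(test)
    reports: list[EvalReport] = []
    scatter: dict[str, dict[str, np.ndarray]] = {}
    for tag in models:
        try:
            if tag == "MLR":
                model = fit_mlr(Xtr, ytr)
            else:
                _, fitter = _make_model(tag, seed)
                model = fitter(Xtr, ytr)
            ptr, pte = model.predict(Xtr), model.predict(Xte)
            reports.append(regression_metrics(ytr, ptr, tag, "train"))
            reports.append(regression_metrics(yte, pte, tag, "test"))
            scatter[tag] = {"y_train": ytr, "yhat_train": ptr,
                            "y_test": yte, "yhat_test": pte}
        except Exception as e:  # record failure, keep going
            warnings.warn(f"model {tag} failed: {e}")
            for split in ("train", "test"):
                reports.append(EvalReport(r2=None, rmse=float("nan"), mse=float("nan"),
                                          mae=float("nan"), model_tag=tag,
                                          split_tag=split, n=0, error=str(e)))
    table = pd.DataFrame([r.as_dict() | ({"error": r.error} if r.error else {})
                          for r in reports])
    return table, scatter
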