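"""Robust nonlinear CCA with biweight midcorrelation.

Linear CCA projects two views through weight vectors; nonlinear CCA
replaces each projection with a single-hidden-layer tanh network (the
"double-barreled" pair mapping ``x -> u`` and ``y -> v``) and a pair of
inverse-mapping networks reconstructing each view from its canonical
variate.  Training alternates three costs:

* ``C1``: minus the correlation between ``u`` and ``v``, plus terms
  pinning both variates to zero mean and unit variance, plus an L2
  penalty ``P1`` on the hidden-layer weights of both barrels (larger
  ``P1`` drives the maps toward linearity);
* ``C2``/``C3``: the reconstruction error of each inverse map plus an L2
  penalty on its input weights.

The robust variant — the one used here by default — replaces the Pearson
correlation in ``C1`` with the biweight midcorrelation (bicor) and the
squared reconstruction error with the mean absolute error, making the
fit resistant to outlying samples and to overfitting on short windows.

Classification stores, per stimulus, the trained network pair and the
canonical variate ``v_k`` of the stimulus's harmonic reference (the
template).  A new window is pushed through each stimulus's ``x`` barrel
and the decision is the template with the highest ``bicor(u_hat, v_k)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import optimize

from .epochs import EpochArray, ValidationError
from .preprocessing import DEFAULT_N_HARMONICS, ReferenceSet, build_references
from .detectors import DetectionResult

__all__ = [
    "DegenerateScaleError",
    "BicorIntermediate",
    "lp_norm",
    "bicor",
    "bicor_gradient",
    "ForwardNet",
    "InverseNet",
    "forward_map",
    "cost_c1",
    "cost_reconstruction",
    "NLCCAHyper",
    "NLCCAModel",
    "train_nlcca",
    "train_stimulus_models",
    "nlcca_classify",
    "NLCCADetector",
]


class DegenerateScaleError(ValueError):
    """A vector's median absolute deviation is zero; bicor is undefined."""


def lp_norm(e: np.ndarray, p: float) -> float:
    """The Lp norm ``(sum |e_i|^p)^(1/p)``, p >= 1."""
    e = np.asarray(e, dtype=float).ravel()
    if e.size == 0:
        raise ValidationError("lp_norm of an empty vector")
    if p < 1:
        raise ValidationError("p must be >= 1")
    return float(np.sum(np.abs(e) ** p) ** (1.0 / p))


@dataclass(frozen=True)
class BicorIntermediate:
    """All intermediate quantities of one biweight midcorrelation."""

    med_x: float
    med_y: float
    mad_x: float
    mad_y: float
    u: np.ndarray
    v: np.ndarray
    w_x: np.ndarray
    w_y: np.ndarray
    x_tilde: np.ndarray
    y_tilde: np.ndarray
    delta: float


def _mad(x: np.ndarray) -> float:
    """Median absolute deviation (no consistency factor)."""
    return float(np.median(np.abs(x - np.median(x))))


def _biweights(u: np.ndarray, strict_paper_indicator: bool) -> np.ndarray:
    # Standard biweight: zero outside |u| < 1.  The strict variant keeps
    # the indicator one-sided (zero only for u >= 1), reproducing the
    # printed form; it can yield weights above 1 for u < -1.
    indicator = (1 - u > 0) if strict_paper_indicator else (1 - np.abs(u) > 0)
    return (1 - u**2) ** 2 * indicator


def _bicor_parts(
    x: np.ndarray, y: np.ndarray, strict_paper_indicator: bool
) -> BicorIntermediate:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValidationError("bicor needs at least 3 samples")
    med_x, med_y = float(np.median(x)), float(np.median(y))
    mad_x, mad_y = _mad(x), _mad(y)
    if mad_x <= 0 or mad_y <= 0:
        raise DegenerateScaleError("zero median absolute deviation")
    u = (x - med_x) / (9 * mad_x)
    v = (y - med_y) / (9 * mad_y)
    w_x = _biweights(u, strict_paper_indicator)
    w_y = _biweights(v, strict_paper_indicator)
    a_x = (x - med_x) * w_x
    a_y = (y - med_y) * w_y
    s_x = float(np.sqrt(a_x @ a_x))
    s_y = float(np.sqrt(a_y @ a_y))
    if s_x == 0 or s_y == 0:
        raise DegenerateScaleError("all biweights vanished")
    x_tilde, y_tilde = a_x / s_x, a_y / s_y
    return BicorIntermediate(
        med_x=med_x, med_y=med_y, mad_x=mad_x, mad_y=mad_y,
        u=u, v=v, w_x=w_x, w_y=w_y,
        x_tilde=x_tilde, y_tilde=y_tilde,
        delta=float(x_tilde @ y_tilde),
    )


def bicor(
    x: np.ndarray,
    y: np.ndarray,
    *,
    strict_paper_indicator: bool = False,
    return_intermediate: bool = False,
):
    """Biweight midcorrelation of two equal-length vectors.

    Deviations are scaled by nine times the median absolute deviation,
    downweighted by the squared biweight kernel (weights vanish where the
    scaled deviation reaches 1), normalized to unit sum of squares and
    correlated by their inner product.  Bounded in [-1, 1]; invariant to
    positive affine transforms of either argument; robust to gross
    outliers, which simply receive zero weight.
    """
    parts = _bicor_parts(x, y, strict_paper_indicator)
    return (parts.delta, parts) if return_intermediate else parts.delta


def bicor_gradient(
    x: np.ndarray, y: np.ndarray, *, strict_paper_indicator: bool = False
) -> np.ndarray:
    """Gradient of ``bicor(x, y)`` with respect to each ``x_i``.

    The median and MAD are treated as locally constant, so the derivative
    chains only through the weighted deviation ``a_i = (x_i - med) w_i``
    and the unit normalization:

        d delta / d x_i
            = (y~_i - delta x~_i) * (w_i - 4 u_i^2 (1 - u_i^2) I_i)
              / sqrt(sum_j a_j^2)
    """
    parts = _bicor_parts(x, y, strict_paper_indicator)
    u = parts.u
    if strict_paper_indicator:
        indicator = (1 - u > 0).astype(float)
    else:
        indicator = (1 - np.abs(u) > 0).astype(float)
    da_dx = parts.w_x - 4 * u**2 * (1 - u**2) * indicator
    a_x = (np.asarray(x, dtype=float).ravel() - parts.med_x) * parts.w_x
    s_x = np.sqrt(a_x @ a_x)
    return (parts.y_tilde - parts.delta * parts.x_tilde) * da_dx / s_x


# ---------------------------------------------------------------------------
# Networks


@dataclass
class ForwardNet:
    """One barrel: input vector -> tanh hidden layer -> scalar variate."""

    weights: np.ndarray   # [d, m] hidden-layer weights
    bias: np.ndarray      # [m]
    out_weights: np.ndarray  # [m]
    out_bias: float

    @property
    def input_dim(self) -> int:
        return self.weights.shape[0]

    @property
    def hidden_dim(self) -> int:
        return self.weights.shape[1]


@dataclass
class InverseNet:
    """Inverse map: scalar variate -> tanh hidden layer -> reconstruction."""

    in_weights: np.ndarray   # [m]
    in_bias: np.ndarray      # [m]
    out_weights: np.ndarray  # [m, d]
    out_bias: np.ndarray     # [d]


def forward_map(net: ForwardNet, x: np.ndarray) -> np.ndarray:
    """Map standardized inputs ``[n, d]`` (or a single ``[d]`` vector)
    through one barrel, returning the canonical variate samples."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    x = np.atleast_2d(x)
    if x.shape[1] != net.input_dim:
        raise ValidationError(
            f"input has {x.shape[1]} variables, network expects {net.input_dim}"
        )
    hidden = np.tanh(x @ net.weights + net.bias)
    u = hidden @ net.out_weights + net.out_bias
    return u[0] if single else u


def inverse_map(net: InverseNet, z: np.ndarray) -> np.ndarray:
    """Reconstruct view samples ``[n, d]`` from variate samples ``[n]``."""
    z = np.asarray(z, dtype=float).ravel()
    hidden = np.tanh(np.outer(z, net.in_weights) + net.in_bias)
    return hidden @ net.out_weights + net.out_bias


# ---------------------------------------------------------------------------
# Costs


def _safe_corr_and_grads(u, v, correlation):
    """Correlation and its gradients wrt u and v; 0 on degenerate scale."""
    if correlation == "bicor":
        try:
            value = bicor(u, v)
            gu = bicor_gradient(u, v)
            gv = bicor_gradient(v, u)
        except DegenerateScaleError:
            return 0.0, np.zeros_like(u), np.zeros_like(v)
        return value, gu, gv
    if correlation == "pearson":
        uc = u - u.mean()
        vc = v - v.mean()
        bu, bv = uc @ uc, vc @ vc
        if bu <= 0 or bv <= 0:
            return 0.0, np.zeros_like(u), np.zeros_like(v)
        denom = np.sqrt(bu * bv)
        r = float(uc @ vc / denom)
        gu = vc / denom - r * uc / bu
        gv = uc / denom - r * vc / bv
        return r, gu, gv
    raise ValueError(f"unknown correlation {correlation!r}")


def _moment_penalty_and_grad(u: np.ndarray):
    """``<u>^2 + (sqrt(<u^2>) - 1)^2`` and its gradient."""
    n = u.size
    mean = u.mean()
    rms = np.sqrt(np.mean(u**2))
    value = mean**2 + (rms - 1.0) ** 2
    grad = 2 * mean / n * np.ones_like(u)
    if rms > 0:
        grad = grad + 2 * (rms - 1.0) * u / (n * rms)
    return value, grad


def cost_c1(
    u: np.ndarray,
    v: np.ndarray,
    hidden_weights: Sequence[np.ndarray],
    p1: float,
    correlation: str = "bicor",
) -> float:
    """Double-barrel cost: minus correlation, moment constraints, penalty.

    ``hidden_weights`` are the hidden-layer weight matrices of both
    barrels — the only parameters the ``P1`` penalty touches.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size:
        raise ValidationError(f"variate length mismatch: {u.size} vs {v.size}")
    if correlation == "bicor":
        corr = bicor(u, v)  # raises DegenerateScaleError on flat variates
    else:
        corr, _, _ = _safe_corr_and_grads(u, v, correlation)
    mu, _ = _moment_penalty_and_grad(u)
    mv, _ = _moment_penalty_and_grad(v)
    penalty = p1 * sum(float(np.sum(w**2)) for w in hidden_weights)
    return float(-corr + mu + mv + penalty)


def cost_reconstruction(
    reconstructed: np.ndarray,
    target: np.ndarray,
    penalty: float,
    input_weights: np.ndarray,
    loss: str = "mae",
) -> float:
    """Inverse-map cost: mean reconstruction error plus weight penalty.

    The error is the mean over all entries — absolute (``mae``, the
    robust default) or squared (``mse``).  ``penalty`` multiplies the sum
    of squared input-layer weights of the inverse network.
    """
    reconstructed = np.asarray(reconstructed, dtype=float)
    target = np.asarray(target, dtype=float)
    if reconstructed.shape != target.shape:
        raise ValidationError(
            f"shape mismatch: {reconstructed.shape} vs {target.shape}"
        )
    err = reconstructed - target
    if loss == "mae":
        base = float(np.mean(np.abs(err)))
    elif loss == "mse":
        base = float(np.mean(err**2))
    else:
        raise ValueError(f"unknown loss {loss!r}")
    return base + penalty * float(np.sum(np.asarray(input_weights) ** 2))


# ---------------------------------------------------------------------------
# Training


@dataclass(frozen=True)
class NLCCAHyper:
    """Training hyperparameters.

    ``hidden`` nodes per barrel and inverse map (small networks resist
    overfitting on one-second windows); ``p1`` trades nonlinearity
    against regularity — large values drive the barrels linear; ``p2``
    and ``p3`` regularize the inverse maps; ``restarts`` independent
    random initializations, the best final ``C1`` wins.
    """

    hidden: int = 4
    p1: float = 0.1
    p2: float = 0.01
    p3: float = 0.01
    correlation: str = "bicor"
    loss: str = "mae"
    restarts: int = 5
    max_iter: int = 500
    tol: float = 1e-6
    init_scale: float = 0.1
    seed: int = 0


def _pack_forward(nx: ForwardNet, ny: ForwardNet) -> np.ndarray:
    return np.concatenate([
        nx.weights.ravel(), nx.bias, nx.out_weights, [nx.out_bias],
        ny.weights.ravel(), ny.bias, ny.out_weights, [ny.out_bias],
    ])


def _unpack_forward(theta, dx, dy, m):
    def take(offset, shape):
        size = int(np.prod(shape))
        return theta[offset : offset + size].reshape(shape), offset + size

    wx, o = take(0, (dx, m))
    bx, o = take(o, (m,))
    wox, o = take(o, (m,))
    box, o = take(o, (1,))
    wy, o = take(o, (dy, m))
    by, o = take(o, (m,))
    woy, o = take(o, (m,))
    boy, o = take(o, (1,))
    return (
        ForwardNet(wx, bx, wox, float(box[0])),
        ForwardNet(wy, by, woy, float(boy[0])),
    )


def _forward_cost_grad(theta, x, y, m, p1, correlation):
    """C1 and its gradient over the packed parameters of both barrels."""
    dx, dy = x.shape[1], y.shape[1]
    nx, ny = _unpack_forward(theta, dx, dy, m)
    hx = np.tanh(x @ nx.weights + nx.bias)
    u = hx @ nx.out_weights + nx.out_bias
    hy = np.tanh(y @ ny.weights + ny.bias)
    v = hy @ ny.out_weights + ny.out_bias

    corr, gcu, gcv = _safe_corr_and_grads(u, v, correlation)
    mu, gmu = _moment_penalty_and_grad(u)
    mv, gmv = _moment_penalty_and_grad(v)
    cost = (
        -corr + mu + mv
        + p1 * (np.sum(nx.weights**2) + np.sum(ny.weights**2))
    )

    def backprop(net, hidden, inputs, g_out):
        d_wout = hidden.T @ g_out
        d_bout = g_out.sum()
        d_hidden = np.outer(g_out, net.out_weights) * (1 - hidden**2)
        d_w = inputs.T @ d_hidden + 2 * p1 * net.weights
        d_b = d_hidden.sum(axis=0)
        return np.concatenate([d_w.ravel(), d_b, d_wout, [d_bout]])

    gu = -gcu + gmu
    gv = -gcv + gmv
    grad = np.concatenate([
        backprop(nx, hx, x, gu), backprop(ny, hy, y, gv)
    ])
    return float(cost), grad


def _pack_inverse(net: InverseNet) -> np.ndarray:
    return np.concatenate([
        net.in_weights, net.in_bias, net.out_weights.ravel(), net.out_bias
    ])


def _unpack_inverse(theta, m, d) -> InverseNet:
    o = 0
    w_in = theta[o : o + m]; o += m
    b_in = theta[o : o + m]; o += m
    w_out = theta[o : o + m * d].reshape(m, d); o += m * d
    b_out = theta[o : o + d]
    return InverseNet(w_in, b_in, w_out, b_out)


def _inverse_cost_grad(theta, z, target, m, penalty, loss):
    net = _unpack_inverse(theta, m, target.shape[1])
    hidden = np.tanh(np.outer(z, net.in_weights) + net.in_bias)
    recon = hidden @ net.out_weights + net.out_bias
    err = recon - target
    n_entries = err.size
    if loss == "mae":
        base = np.mean(np.abs(err))
        d_recon = np.sign(err) / n_entries
    else:
        base = np.mean(err**2)
        d_recon = 2 * err / n_entries
    cost = base + penalty * np.sum(net.in_weights**2)
    d_wout = hidden.T @ d_recon
    d_bout = d_recon.sum(axis=0)
    d_hidden = (d_recon @ net.out_weights.T) * (1 - hidden**2)
    d_win = d_hidden.T @ z + 2 * penalty * net.in_weights
    d_bin = d_hidden.sum(axis=0)
    return float(cost), np.concatenate([d_win, d_bin, d_wout.ravel(), d_bout])


@dataclass
class NLCCAModel:
    """A trained double-barreled network pair with its inverse maps.

    Holds the standardization constants of both views, the stored
    template variate of the reference view, and training diagnostics
    (initial/final ``C1`` per restart, final ``C2``/``C3``).
    """

    x_net: ForwardNet
    y_net: ForwardNet
    inv_u: InverseNet
    inv_v: InverseNet
    hyper: NLCCAHyper
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray
    template_v: np.ndarray | None = None
    diagnostics: dict = field(default_factory=dict)

    def standardize_x(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.x_mean) / self.x_std

    def standardize_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_std

    def map_x(self, x: np.ndarray) -> np.ndarray:
        """Raw x-view samples ``[n, d]`` -> canonical variate ``u``."""
        return forward_map(self.x_net, self.standardize_x(x))

    def map_y(self, y: np.ndarray) -> np.ndarray:
        """Raw y-view samples ``[n, d]`` -> canonical variate ``v``."""
        return forward_map(self.y_net, self.standardize_y(y))

    def reconstruct_x(self, u: np.ndarray) -> np.ndarray:
        """Variate ``u`` -> standardized x-view reconstruction."""
        return inverse_map(self.inv_u, u)

    def reconstruct_y(self, v: np.ndarray) -> np.ndarray:
        return inverse_map(self.inv_v, v)

    def to_json(self) -> dict:
        """JSON-serializable representation (nested lists for weights)."""

        def arrays(obj):
            return {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in vars(obj).items()
            }

        return {
            "x_net": arrays(self.x_net),
            "y_net": arrays(self.y_net),
            "inv_u": arrays(self.inv_u),
            "inv_v": arrays(self.inv_v),
            "hyper": asdict(self.hyper),
            "x_mean": self.x_mean.tolist(),
            "x_std": self.x_std.tolist(),
            "y_mean": self.y_mean.tolist(),
            "y_std": self.y_std.tolist(),
            "template_v": None if self.template_v is None else self.template_v.tolist(),
            "diagnostics": self.diagnostics,
        }

    @classmethod
    def from_json(cls, payload: dict) -> "NLCCAModel":
        def fnet(d):
            return ForwardNet(
                np.asarray(d["weights"]), np.asarray(d["bias"]),
                np.asarray(d["out_weights"]), float(d["out_bias"]),
            )

        def inet(d):
            return InverseNet(
                np.asarray(d["in_weights"]), np.asarray(d["in_bias"]),
                np.asarray(d["out_weights"]), np.asarray(d["out_bias"]),
            )

        template = payload["template_v"]
        return cls(
            x_net=fnet(payload["x_net"]),
            y_net=fnet(payload["y_net"]),
            inv_u=inet(payload["inv_u"]),
            inv_v=inet(payload["inv_v"]),
            hyper=NLCCAHyper(**payload["hyper"]),
            x_mean=np.asarray(payload["x_mean"]),
            x_std=np.asarray(payload["x_std"]),
            y_mean=np.asarray(payload["y_mean"]),
            y_std=np.asarray(payload["y_std"]),
            template_v=None if template is None else np.asarray(template),
            diagnostics=payload["diagnostics"],
        )


class TrainingError(RuntimeError):
    """Every restart produced non-finite costs; carries the diagnostics."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


def _standardize(a: np.ndarray):
    mean = a.mean(axis=0)
    std = a.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return (a - mean) / std, mean, std


def train_nlcca(
    x: np.ndarray, y: np.ndarray, hyper: NLCCAHyper | None = None
) -> NLCCAModel:
    """Fit a robust nonlinear CCA model on paired view samples.

    ``x`` is ``[n, d_x]`` (one row per sample), ``y`` is ``[n, d_y]``.
    Both views are standardized internally.  The barrels are fitted by
    quasi-Newton minimization of ``C1`` with analytic gradients (the
    correlation term's gradient holds the median/MAD locally constant),
    best of ``hyper.restarts`` random initializations; the inverse maps
    are then fitted by minimizing ``C2`` and ``C3``.  Deterministic given
    ``hyper.seed``.
    """
    hyper = hyper or NLCCAHyper()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise ValidationError(
            f"views have {x.shape[0]} and {y.shape[0]} samples; must match"
        )
    if x.shape[0] < 30:
        raise ValidationError("need at least 30 samples to train")
    xs, x_mean, x_std = _standardize(x)
    ys, y_mean, y_std = _standardize(y)
    m = hyper.hidden
    dx, dy = xs.shape[1], ys.shape[1]
    n_params = (dx * m + 2 * m + 1) + (dy * m + 2 * m + 1)
    rng = np.random.default_rng(hyper.seed)

    options = {"maxiter": hyper.max_iter, "ftol": hyper.tol * 1e-3,
               "gtol": hyper.tol}
    restart_log = []
    best = None
    for restart in range(hyper.restarts):
        theta0 = hyper.init_scale * rng.standard_normal(n_params)
        c0, _ = _forward_cost_grad(theta0, xs, ys, m, hyper.p1, hyper.correlation)
        theta_start = theta0
        if hyper.correlation == "bicor":
            # The robust objective's gradient holds median/MAD locally
            # constant, which stalls line searches far from a solution;
            # warm-start it from the smooth Pearson surrogate.
            warm = optimize.minimize(
                _forward_cost_grad, theta0,
                args=(xs, ys, m, hyper.p1, "pearson"),
                method="L-BFGS-B", jac=True, options=options,
            )
            if np.isfinite(warm.fun):
                theta_start = warm.x
        result = optimize.minimize(
            _forward_cost_grad,
            theta_start,
            args=(xs, ys, m, hyper.p1, hyper.correlation),
            method="L-BFGS-B",
            jac=True,
            options=options,
        )
        entry = {"restart": restart, "initial_c1": float(c0),
                 "final_c1": float(result.fun), "iterations": int(result.nit)}
        restart_log.append(entry)
        if np.isfinite(result.fun) and (best is None or result.fun < best[0]):
            best = (float(result.fun), result.x)
    if best is None:
        raise TrainingError(
            "all restarts diverged to non-finite costs",
            {"restarts": restart_log},
        )
    final_c1, theta = best
    x_net, y_net = _unpack_forward(theta, dx, dy, m)

    u = forward_map(x_net, xs)
    v = forward_map(y_net, ys)

    def fit_inverse(z, target, penalty):
        theta0 = hyper.init_scale * rng.standard_normal(2 * m + m * target.shape[1] + target.shape[1])
        result = optimize.minimize(
            _inverse_cost_grad,
            theta0,
            args=(z, target, m, penalty, hyper.loss),
            method="L-BFGS-B",
            jac=True,
            options={"maxiter": hyper.max_iter, "ftol": hyper.tol * 1e-3,
                     "gtol": hyper.tol},
        )
        return _unpack_inverse(result.x, m, target.shape[1]), float(result.fun)

    inv_u, final_c2 = fit_inverse(u, xs, hyper.p2)
    inv_v, final_c3 = fit_inverse(v, ys, hyper.p3)

    return NLCCAModel(
        x_net=x_net,
        y_net=y_net,
        inv_u=inv_u,
        inv_v=inv_v,
        hyper=hyper,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        template_v=v,
        diagnostics={
            "final_c1": final_c1,
            "final_c2": final_c2,
            "final_c3": final_c3,
            "restarts": restart_log,
        },
    )


# ---------------------------------------------------------------------------
# Per-stimulus templates and classification


def train_stimulus_models(
    epochs: EpochArray,
    length: int,
    n_harmonics: int = DEFAULT_N_HARMONICS,
    hyper: NLCCAHyper | None = None,
    refs: ReferenceSet | None = None,
) -> list[NLCCAModel]:
    """One NLCCA model per stimulus, trained on that stimulus's trials.

    For stimulus ``k``, the x-view pools the first ``length`` samples of
    every trial labeled ``k`` (one observation per time point, one
    variable per channel); the y-view is the stimulus's harmonic
    reference, repeated per trial.  The stored template ``v_k`` is the
    variate of one reference block, so classification windows of the
    same length compare directly against it.
    """
    hyper = hyper or NLCCAHyper()
    if refs is None:
        refs = build_references(
            epochs.grid, n_harmonics, length, epochs.sample_rate
        )
    models = []
    for k in range(1, epochs.grid.k + 1):
        idx = np.flatnonzero(epochs.labels == k)
        if idx.size == 0:
            raise ValidationError(f"no training trials for stimulus {k}")
        x_view = np.concatenate(
            [epochs.data[i, :, :length].T for i in idx], axis=0
        )
        ref_block = refs[k - 1].T  # [length, 2*Nh]
        y_view = np.tile(ref_block, (idx.size, 1))
        model = train_nlcca(
            x_view, y_view,
            NLCCAHyper(**{**asdict(hyper), "seed": hyper.seed + k}),
        )
        model.template_v = model.map_y(ref_block)
        models.append(model)
    return models


def nlcca_classify(
    window: np.ndarray,
    models: Sequence[NLCCAModel],
    *,
    confidence_threshold: float = 0.3,
) -> DetectionResult:
    """Decide the stimulus of one window against per-stimulus templates.

    The window is standardized with each model's training constants,
    pushed through its ``x`` barrel and compared with the stored template
    variate by biweight midcorrelation; the decision is the argmax (ties
    to the lowest index).  Flat variates score 0; a best score below
    ``confidence_threshold`` flags the decision as low-confidence.
    """
    window = np.atleast_2d(np.asarray(window, dtype=float))
    scores = np.zeros(len(models))
    for k, model in enumerate(models):
        if model.template_v is None:
            raise ValidationError(f"model {k} has no stored template variate")
        if model.template_v.size != window.shape[1]:
            raise ValidationError(
                f"window has {window.shape[1]} samples, template {k} has "
                f"{model.template_v.size}"
            )
        u_hat = model.map_x(window.T)
        try:
            scores[k] = bicor(u_hat, model.template_v)
        except DegenerateScaleError:
            scores[k] = 0.0
    best = int(np.argmax(scores))
    return DetectionResult(
        scores=scores,
        decided=best + 1,
        kind="nlcca_bicor",
        low_confidence=scores[best] < confidence_threshold,
    )


@dataclass
class NLCCADetector:
    """Evaluation-facing wrapper around a bank of per-stimulus models."""

    models: Sequence[NLCCAModel]
    confidence_threshold: float = 0.3
    name: str = "NLCCA"

    def classify(self, window: np.ndarray) -> DetectionResult:
        return nlcca_classify(
            window, self.models, confidence_threshold=self.confidence_threshold
        )
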