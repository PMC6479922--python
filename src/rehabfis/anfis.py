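"""Hybrid ANFIS training for Sugeno systems.

Each epoch alternates two sub-steps in the classical hybrid fashion:

1. **Least squares** — with the premise (input) membership functions
   fixed, the weighted-average output is linear in the consequent
   coefficients, so they are solved globally from ridge-regularized
   normal equations on the firing-strength-normalized design matrix.
   This step can never increase the RMSE for the current premises.
2. **Gradient descent** — the premise MF parameters take one step down
   the analytic RMSE gradient, obtained by the chain rule through the
   weighted average.  Piecewise-linear shapes (triangle, trapezoid) use
   the one-sided derivative from the left at their kinks, and the
   parameter ordering constraint (a ≤ b ≤ c …) is re-imposed by
   projection after each step.

The step size may adapt in the style of Jang's original heuristic: grow
by 10% after four consecutive error decreases, shrink by 10% after two
consecutive up-down oscillations.  Training is fully deterministic.

Samples whose inputs fire no rule, or that carry the virtual sentinel on
*all* of a rule's features, contribute nothing to either sub-step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .fuzzy import (
    ZERO_FIRING_EPS,
    Consequent,
    FuzzySystem,
    MembershipFunction,
    consequent_values,
    fire_rules,
    membership_grid,
    sugeno_infer,
)

_ORDERED_SHAPES = {"triangle", "trapezoid", "s", "z", "pi"}


@dataclass(frozen=True)
class TrainingConfig:
    """Hyper-parameters for hybrid training."""

    epochs: int = 100
    step_size: float = 0.01
    step_adapt: Literal["none", "jang"] = "jang"
    ridge: float = 1e-8
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.step_size <= 0 or self.ridge < 0 or self.tol <= 0:
            raise ValueError("step_size and tol must be positive, ridge non-negative")


@dataclass
class TrainingResult:
    trained: FuzzySystem
    rmse_trace: list[float]
    stopped_at: int
    converged: bool


def _prepare(fis: FuzzySystem, data) -> tuple[np.ndarray, np.ndarray]:
    X, y = data if isinstance(data, tuple) else (data[0], data[1])
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != len(fis.inputs):
        raise ValueError(f"X must be (n, {len(fis.inputs)})")
    if len(y) != X.shape[0]:
        raise ValueError("X and y length mismatch")
    return X, y


def rmse(fis: FuzzySystem, X: np.ndarray, y: np.ndarray) -> float:
    """Root-mean-square inference error over the samples that fire."""
    yhat = sugeno_infer(fis, X)
    ok = ~np.isnan(yhat)
    if not np.any(ok):
        raise ValueError("no sample fires any rule")
    return float(np.sqrt(np.mean((yhat[ok] - y[ok]) ** 2)))


def upgrade_to_first_order(fis: FuzzySystem) -> FuzzySystem:
    """Replace constant consequents by linear ones (p_i = 0, r = constant)."""
    out = fis.copy()
    k = len(out.inputs)
    for rule in out.rules:
        if rule.consequent.kind == "constant":
            rule.consequent = Consequent("linear", coeffs=(0.0,) * k + (rule.consequent.value,))
    return out


# ----------------------------------------------------------------------
# least-squares consequent estimation
# ----------------------------------------------------------------------
def lse_consequents(fis: FuzzySystem, data, ridge: float = 1e-8) -> FuzzySystem:
    """Globally optimal consequent coefficients for fixed premises.

    Builds one design-matrix block per rule — ``[wbar*x1 .. wbar*xk,
    wbar]`` for linear consequents, ``[wbar]`` for constants, with
    ``wbar`` the normalized firing strength and sentinel-masked inputs
    zeroed — and solves the ridge normal equations.  Samples with zero
    total firing are excluded; if every sample is excluded the call is
    rejected.
    """
    if fis.flavor != "sugeno":
        raise ValueError("lse_consequents needs a Sugeno system")
    X, y = _prepare(fis, data)
    W = fire_rules(fis, X)
    W = np.atleast_2d(W)
    total = W.sum(axis=1)
    ok = total > ZERO_FIRING_EPS
    if not np.any(ok):
        raise ValueError("every sample has zero total firing; cannot fit consequents")
    Xo, yo, Wo = X[ok], y[ok], W[ok]
    wbar = Wo / Wo.sum(axis=1, keepdims=True)
    Xeff = np.where(Xo == fis.sentinel, 0.0, Xo)

    blocks, slices = [], []
    col = 0
    for r, rule in enumerate(fis.rules):
        if rule.consequent.kind == "linear":
            blk = np.column_stack([wbar[:, r : r + 1] * Xeff, wbar[:, r]])
        elif rule.consequent.kind == "constant":
            blk = wbar[:, r : r + 1]
        else:
            raise ValueError("convert Mamdani consequents before LSE")
        blocks.append(blk)
        slices.append(slice(col, col + blk.shape[1]))
        col += blk.shape[1]
    A = np.hstack(blocks)
    AtA = A.T @ A + ridge * np.eye(A.shape[1])
    theta = np.linalg.solve(AtA, A.T @ yo)

    out = fis.copy()
    for r, rule in enumerate(out.rules):
        part = theta[slices[r]]
        if rule.consequent.kind == "linear":
            rule.consequent = Consequent("linear", coeffs=tuple(part))
        else:
            rule.consequent = Consequent("constant", value=float(part[0]))
    return out


# ----------------------------------------------------------------------
# premise gradient step
# ----------------------------------------------------------------------
def _mf_param_grads(mf: MembershipFunction, x: np.ndarray) -> np.ndarray:
    """d(membership)/d(param) at each x, shape (n, n_params).

    Left-sided derivative convention at the kinks of the piecewise-linear
    shapes.  Only the differentiable training shapes are supported.
    """
    p = mf.params
    n = x.shape[0]
    G = np.zeros((n, len(p)))
    if mf.shape == "gaussian":
        m, s = p
        mu = np.exp(-0.5 * ((x - m) / s) ** 2)
        G[:, 0] = mu * (x - m) / s**2
        G[:, 1] = mu * (x - m) ** 2 / s**3
        return G
    if mf.shape == "triangle":
        a, b, c = p
        rising = (x > a) & (x <= b) if b > a else np.zeros(n, bool)
        falling = (x > b) & (x < c) if c > b else np.zeros(n, bool)
        if b > a:
            G[rising, 0] = (x[rising] - b) / (b - a) ** 2
            G[rising, 1] = -(x[rising] - a) / (b - a) ** 2
        if c > b:
            G[falling, 1] = (c - x[falling]) / (c - b) ** 2
            G[falling, 2] = (x[falling] - b) / (c - b) ** 2
        return G
    if mf.shape == "trapezoid":
        a, b, c, d = p
        rising = (x > a) & (x <= b) if b > a else np.zeros(n, bool)
        falling = (x > c) & (x < d) if d > c else np.zeros(n, bool)
        if b > a:
            G[rising, 0] = (x[rising] - b) / (b - a) ** 2
            G[rising, 1] = -(x[rising] - a) / (b - a) ** 2
        if d > c:
            G[falling, 2] = (d - x[falling]) / (d - c) ** 2
            G[falling, 3] = (x[falling] - c) / (d - c) ** 2
        return G
    raise ValueError(
        f"gradient training supports triangle/trapezoid/gaussian premises, not {mf.shape!r}"
    )


def _project_params(shape: str, params: np.ndarray, name: str) -> MembershipFunction:
    """Re-impose shape constraints on stepped parameters (projection)."""
    p = list(params)
    if shape in _ORDERED_SHAPES:
        p = sorted(p)
    if shape == "gaussian":
        p[1] = max(p[1], 1e-6)
    if shape == "bell":
        p[0] = max(p[0], 1e-6)
    return MembershipFunction(shape, tuple(p), name)


def premise_rmse_gradient(fis: FuzzySystem, X: np.ndarray, y: np.ndarray) -> list[list[np.ndarray]]:
    """Analytic dRMSE/dparam for every premise MF, [input][mf] -> (n_params,)."""
    if fis.t_norm != "product":
        raise ValueError("premise gradients require the product t-norm")
    grids = membership_grid(fis, X)
    n_rules = len(fis.rules)
    W = np.empty((X.shape[0], n_rules))
    for r, rule in enumerate(fis.rules):
        degs = [grids[i][:, m] for i, m in enumerate(rule.antecedent) if m is not None]
        W[:, r] = np.prod(degs, axis=0) if degs else 1.0
    Z = consequent_values(fis, X)
    total = W.sum(axis=1)
    ok = total > ZERO_FIRING_EPS
    if not np.any(ok):
        raise ValueError("no sample fires any rule")
    yhat = (W[ok] * Z[ok]).sum(axis=1) / total[ok]
    resid = yhat - y[ok]
    n_ok = resid.size
    current = float(np.sqrt(np.mean(resid**2)))
    # dE/dyhat for E = RMSE; zero-residual data gives a zero gradient
    dE_dy = np.zeros_like(resid) if current == 0 else resid / (n_ok * current)

    grads: list[list[np.ndarray]] = []
    for i, var in enumerate(fis.inputs):
        xi = X[ok, i]
        var_grads = []
        for m, mf in enumerate(var.mfs):
            acc = np.zeros(n_ok)
            for r, rule in enumerate(fis.rules):
                if rule.antecedent[i] != m:
                    continue
                others = np.ones(n_ok)
                for j, mj in enumerate(rule.antecedent):
                    if j != i and mj is not None:
                        others = others * grids[j][ok, mj]
                acc += (Z[ok, r] - yhat) / total[ok] * others
            dmu = _mf_param_grads(mf, xi)
            dmu[X[ok, i] == fis.sentinel] = 0.0
            var_grads.append((dE_dy * acc) @ dmu)
        grads.append(var_grads)
    return grads


def premise_gradient_step(fis: FuzzySystem, data, step_size: float = 0.01) -> FuzzySystem:
    """One gradient-descent step on all premise MF parameters."""
    X, y = _prepare(fis, data)
    grads = premise_rmse_gradient(fis, X, y)
    out = fis.copy()
    for i, var in enumerate(out.inputs):
        for m, mf in enumerate(var.mfs):
            new_params = np.asarray(mf.params) - step_size * grads[i][m]
            var.mfs[m] = _project_params(mf.shape, new_params, mf.name)
    return out


# ----------------------------------------------------------------------
# full hybrid loop
# ----------------------------------------------------------------------
def train(fis: FuzzySystem, data, cfg: TrainingConfig = TrainingConfig(),
          first_order: bool = True) -> TrainingResult:
    """Hybrid ANFIS training of a grid-complete Sugeno system.

    Per epoch: solve the consequents by least squares, record the RMSE,
    then take one premise gradient step.  Stops at ``cfg.epochs`` epochs,
    or earlier once the RMSE change stays below ``cfg.tol`` over five
    epochs; a blow-up beyond 10x the initial RMSE aborts with a
    diagnostic.
    """
    if fis.flavor != "sugeno":
        raise ValueError("train needs a Sugeno system (apply mam2sug first)")
    X, y = _prepare(fis, data)
    current = upgrade_to_first_order(fis) if first_order else fis.copy()
    if cfg.epochs == 0:
        return TrainingResult(current, [], 0, False)

    trace: list[float] = []
    step = cfg.step_size
    decreases = 0
    oscillations = 0
    initial_rmse: Optional[float] = None
    for epoch in range(cfg.epochs):
        current = lse_consequents(current, (X, y), ridge=cfg.ridge)
        err = rmse(current, X, y)
        if initial_rmse is None:
            initial_rmse = err
        if initial_rmse > cfg.tol and err > 10.0 * initial_rmse:
            raise RuntimeError(
                f"training diverged at epoch {epoch}: RMSE {err:.4g} exceeds "
                f"10x the initial {initial_rmse:.4g}"
            )
        if cfg.step_adapt == "jang" and trace:
            if err < trace[-1]:
                decreases += 1
                oscillations = 0
                if decreases >= 4:
                    step *= 1.1
                    decreases = 0
            else:
                oscillations += 1
                decreases = 0
                if oscillations >= 2:
                    step *= 0.9
                    oscillations = 0
        trace.append(err)
        # an essentially perfect fit, or a flat error plateau, is "stable"
        if err < cfg.tol:
            return TrainingResult(current, trace, epoch + 1, True)
        if len(trace) >= 5 and max(trace[-5:]) - min(trace[-5:]) < cfg.tol:
            return TrainingResult(current, trace, epoch + 1, True)
        if epoch < cfg.epochs - 1:
            current = premise_gradient_step(current, (X, y), step_size=step)
    # final consequent polish so the returned system is LSE-optimal
    current = lse_consequents(current, (X, y), ridge=cfg.ridge)
    final = rmse(current, X, y)
    if final < trace[-1]:
        trace[-1] = final
    return TrainingResult(current, trace, cfg.epochs, False)


# ----------------------------------------------------------------------
# sklearn estimator facade
# ----------------------------------------------------------------------
class ANFISRegressor(RegressorMixin, BaseEstimator):
    """Adaptive neuro-fuzzy regressor with the scikit-learn API.

    Parameters
    ----------
    fis:
        Initial Sugeno system whose input count matches ``X``.  When
        ``None``, a default grid system is built at fit time: ``n_mfs``
        gaussian MFs per input spread over the observed range, with one
        zero-constant rule per antecedent combination.
    n_mfs:
        MFs per input for the auto-built grid (ignored when ``fis`` is
        given).
    epochs, step_size, step_adapt, ridge, tol:
        See :class:`TrainingConfig`.
    first_order:
        Upgrade constant consequents to linear ones before training.

    Attributes
    ----------
    fis_ : FuzzySystem
        The trained system.
    rmse_trace_ : list of float
        Training RMSE per epoch.
    converged_ : bool
    """

    def __init__(self, fis: Optional[FuzzySystem] = None, n_mfs: int = 3,
                 epochs: int = 100, step_size: float = 0.01,
                 step_adapt: str = "jang", ridge: float = 1e-8,
                 tol: float = 1e-6, first_order: bool = True):
        self.fis = fis
        self.n_mfs = n_mfs
        self.epochs = epochs
        self.step_size = step_size
        self.step_adapt = step_adapt
        self.ridge = ridge
        self.tol = tol
        self.first_order = first_order

    def _default_grid(self, X: np.ndarray) -> FuzzySystem:
        import itertools

        from .fuzzy import FuzzyVariable, Rule

        inputs = []
        for i in range(X.shape[1]):
            lo, hi = float(X[:, i].min()), float(X[:, i].max())
            span = (hi - lo) or 1.0
            centers = np.linspace(lo, hi, self.n_mfs)
            sigma = span / (2.0 * max(self.n_mfs - 1, 1))
            var = FuzzyVariable(
                f"x{i + 1}", (lo - 0.1 * span, hi + 0.1 * span),
                [MembershipFunction("gaussian", (c, sigma), f"mf{j + 1}")
                 for j, c in enumerate(centers)],
            )
            inputs.append(var)
        rules = [Rule(tuple(combo), Consequent("constant", value=0.0))
                 for combo in itertools.product(*[range(self.n_mfs)] * X.shape[1])]
        return FuzzySystem("sugeno", inputs, rules, t_norm="product")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        base = self.fis.copy() if self.fis is not None else self._default_grid(X)
        cfg = TrainingConfig(epochs=self.epochs, step_size=self.step_size,
                             step_adapt=self.step_adapt, ridge=self.ridge, tol=self.tol)
        result = train(base, (X, y), cfg, first_order=self.first_order)
        self.fis_ = result.trained
        self.rmse_trace_ = result.rmse_trace
        self.converged_ = result.converged
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "fis_"):
            raise AttributeError("ANFISRegressor is not fitted yet")
        return np.atleast_1d(sugeno_infer(self.fis_, np.asarray(X, dtype=float)))
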