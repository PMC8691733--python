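"""Feature selection and the class-weighted squared-hinge linear SVM.

The classifier minimizes the primal objective

    min_{w,b}  1/2 w'w  +  Sum_i  C * cost(y_i) * max(1 - y_i (w'x_i + b), 0)^2

i.e. an L2-regularized squared-hinge SVM whose per-sample penalty is scaled
per class, so misclassifying the minority (decline, y = -1) class costs
more. ``cost(class) = N_train / (2 * N_class)``: a balanced sample gives
(1, 1) and the convention is invariant to the total sample size.

The solver is a damped Newton method on the representer parametrization
``w = X' beta`` (the optimum lies in the span of the training rows, so the
problem is solved in N+1 dimensions regardless of feature count), with a
backtracking line search; the objective is smooth and convex, and the
iteration stops on a relative objective decrease below 1e-8. A
general-purpose quasi-Newton solve of the identical objective
(:func:`qp_oracle`) is provided for verification.

Feature selection is a per-column two-sample t-test between classes on the
training rows only (pooled-variance Student's t by default, Welch as an
option), keeping columns with two-sided p < alpha and no multiple-testing
correction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import optimize, stats

from .features import Standardizer, apply_standardizer, fit_standardizer

__all__ = [
    "SelectionMask",
    "LinearSVMModel",
    "ttest_filter",
    "class_cost_from_counts",
    "train_weighted_linear_svm",
    "qp_oracle",
    "predict",
    "svm_objective",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

REL_TOL = 1e-8  # convergence: relative objective decrease below this


@dataclass(frozen=True)
class SelectionMask:
    """Result of the fold-internal univariate t-test filter."""

    keep: np.ndarray  # (P,) bool
    t_stat: np.ndarray  # (P,) float (NaN where undefined)
    p_value: np.ndarray  # (P,) float (NaN where undefined)
    alpha: float
    fitted_on: tuple[int, ...]

    @property
    def n_selected(self) -> int:
        return int(self.keep.sum())


@dataclass(frozen=True)
class LinearSVMModel:
    """Fitted classifier: ``f(x) = sgn(w'x + b)`` over selected features.

    ``selection`` and ``standardizer`` (both fitted on training rows only)
    are carried with the model so a raw full-dimensional feature vector can
    be scored directly.
    """

    w: np.ndarray
    b: float
    C: float
    class_cost: dict[int, float]
    selection: SelectionMask | None = None
    standardizer: Standardizer | None = None
    objective: float = float("nan")


def ttest_filter(
    X: np.ndarray,
    y: np.ndarray,
    train_rows,
    alpha: float = 0.01,
    variant: str = "student",
) -> SelectionMask:
    """Per-column two-sample t-test between classes on training rows.

    Columns with two-sided p < ``alpha`` are kept. Columns whose pooled
    standard error is zero with equal group means (e.g. constant columns)
    have an undefined t statistic and are excluded; zero standard error
    with unequal means yields p = 0 and the column is kept.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    train_rows = np.asarray(sorted(int(i) for i in train_rows))
    yt = y[train_rows]
    Xt = X[train_rows]
    g1 = Xt[yt == 1]
    g2 = Xt[yt == -1]
    n1, n2 = g1.shape[0], g2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"need >= 2 training members per class, got {n1} stable / {n2} decline"
        )

    m1, m2 = g1.mean(axis=0), g2.mean(axis=0)
    v1 = g1.var(axis=0, ddof=1)
    v2 = g2.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if variant == "student":
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
            df = np.full(X.shape[1], n1 + n2 - 2, dtype=np.float64)
        elif variant == "welch":
            se2_1, se2_2 = v1 / n1, v2 / n2
            se = np.sqrt(se2_1 + se2_2)
            df = (se2_1 + se2_2) ** 2 / (
                se2_1**2 / (n1 - 1) + se2_2**2 / (n2 - 1)
            )
        else:
            raise ValueError(f"unknown t-test variant {variant!r}")
        t = (m1 - m2) / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # 0/0 -> NaN -> excluded; nonzero/0 -> +-inf -> p = 0 -> kept
    keep = p < alpha  # NaN compares False
    return SelectionMask(
        keep=keep,
        t_stat=t,
        p_value=p,
        alpha=float(alpha),
        fitted_on=tuple(train_rows.tolist()),
    )


def class_cost_from_counts(y_train: np.ndarray) -> dict[int, float]:
    """Per-class penalty multipliers ``N / (2 * N_class)``.

    The minority class receives the larger multiplier; a balanced sample
    gives (1, 1) and scaling both counts leaves the multipliers unchanged.
    """
    y_train = np.asarray(y_train)
    n_pos = int((y_train == 1).sum())
    n_neg = int((y_train == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to derive class costs")
    N = n_pos + n_neg
    return {1: N / (2.0 * n_pos), -1: N / (2.0 * n_neg)}


def svm_objective(
    w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray, sample_cost: np.ndarray
) -> float:
    """Value of the weighted squared-hinge primal objective."""
    margin = 1.0 - y * (X @ w + b)
    hinge = np.maximum(margin, 0.0)
    return 0.5 * float(w @ w) + float(sample_cost @ hinge**2)


def _sample_costs(y: np.ndarray, C: float, class_cost: dict[int, float]) -> np.ndarray:
    return C * np.where(y == 1, class_cost[1], class_cost[-1])


def _fit_kernel(
    K: np.ndarray,
    y: np.ndarray,
    c: np.ndarray,
    max_iter: int = 200,
    warm_start: tuple[np.ndarray, float] | None = None,
) -> tuple[np.ndarray, float, float]:
    """Damped Newton on the representer form; returns (beta, b, objective).

    K is the training Gram matrix X X'; c the per-sample penalty weights.
    ``warm_start`` seeds the iteration (e.g. from a neighbouring C on a
    grid sweep); the minimizer is unique, so it affects speed only.
    """
    n = K.shape[0]
    if warm_start is not None:
        beta = warm_start[0].copy()
        b = float(warm_start[1])
    else:
        beta = np.zeros(n)
        b = 0.0

    def objective(beta: np.ndarray, b: float) -> tuple[float, np.ndarray]:
        f = K @ beta + b
        m = 1.0 - y * f
        active = m > 0
        obj = 0.5 * float(beta @ K @ beta) + float(c[active] @ m[active] ** 2)
        return obj, m

    obj, m = objective(beta, b)
    damp = 1e-10 * (np.trace(K) / n + 1.0)
    for _ in range(max_iter):
        active = m > 0
        cm = np.zeros(n)
        cm[active] = c[active] * m[active]
        grad_beta = K @ beta - 2.0 * (K[:, active] @ (cm[active] * y[active]))
        grad_b = -2.0 * float(cm[active] @ y[active])
        grad = np.concatenate([grad_beta, [grad_b]])
        if np.linalg.norm(grad) < 1e-12 * (1.0 + abs(obj)):
            break

        KA = K[active]
        cA = c[active]
        H = np.empty((n + 1, n + 1))
        H[:n, :n] = K + 2.0 * (KA.T * cA) @ KA
        hb = 2.0 * KA.T @ cA
        H[:n, n] = hb
        H[n, :n] = hb
        H[n, n] = 2.0 * float(cA.sum())
        H[np.diag_indices(n + 1)] += damp
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            step = -grad

        # backtracking line search on the true objective
        t_ls = 1.0
        for _ in range(50):
            nb = beta + t_ls * step[:n]
            nbias = b + t_ls * step[n]
            new_obj, new_m = objective(nb, nbias)
            if new_obj <= obj - 1e-4 * t_ls * max(-(grad @ step), 0.0):
                break
            t_ls *= 0.5
        if new_obj > obj:
            break  # no descent possible at machine precision
        decrease = obj - new_obj
        beta, b, m = nb, nbias, new_m
        prev_obj, obj = obj, new_obj
        if decrease < REL_TOL * max(abs(prev_obj), 1.0):
            break
    return beta, b, obj


def _fit_hinge_kernel(
    K: np.ndarray, y: np.ndarray, c: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Unsquared-hinge fit in the representer form, as a constrained QP.

    Variables z = (beta, b, xi): minimize ½ β'Kβ + c·ξ subject to
    ξ >= 0 and y_i(K_i β + b) + ξ_i >= 1. Sensitivity-analysis option,
    restricted to small instances like the oracle.
    """
    n = K.shape[0]
    if n > 200:
        raise ValueError("hinge option restricted to <= 200 samples")

    def objective(z):
        beta = z[:n]
        return 0.5 * beta @ K @ beta + c @ z[n + 1 :]

    def grad(z):
        g = np.zeros(2 * n + 1)
        g[:n] = K @ z[:n]
        g[n + 1 :] = c
        return g

    H = np.zeros((2 * n + 1, 2 * n + 1))
    H[:n, :n] = K

    A = np.zeros((n, 2 * n + 1))
    A[:, :n] = y[:, None] * K
    A[:, n] = y
    A[:, n + 1 :] = np.eye(n)
    constraint = optimize.LinearConstraint(A, lb=1.0, ub=np.inf)
    bounds = optimize.Bounds(
        lb=np.r_[np.full(n + 1, -np.inf), np.zeros(n)], ub=np.full(2 * n + 1, np.inf)
    )
    res = optimize.minimize(
        objective,
        np.r_[np.zeros(n + 1), np.ones(n)],
        jac=grad,
        hess=lambda z: H,
        method="trust-constr",
        constraints=[constraint],
        bounds=bounds,
        options={
            "gtol": 1e-12,
            "xtol": 1e-16,
            "barrier_tol": 1e-14,
            "maxiter": 10000,
        },
    )
    beta, b = res.x[:n], float(res.x[n])
    # report the true hinge objective at the solution
    margin = np.maximum(1.0 - y * (K @ beta + b), 0.0)
    obj = 0.5 * float(beta @ K @ beta) + float(c @ margin)
    return beta, b, obj


def train_weighted_linear_svm(
    X_sel: np.ndarray,
    y: np.ndarray,
    C: float,
    class_cost: dict[int, float] | None = None,
    selection: SelectionMask | None = None,
    standardizer: Standardizer | None = None,
    loss: str = "squared_hinge",
) -> LinearSVMModel:
    """Fit the weighted squared-hinge linear SVM on selected features.

    ``X_sel`` must already be reduced to the selected columns and
    standardized; ``selection``/``standardizer`` are attached to the model
    for scoring raw vectors later. ``loss="hinge"`` switches to the
    unsquared hinge for sensitivity analysis (small instances only).
    """
    X_sel = np.asarray(X_sel, dtype=np.float64)
    y = np.asarray(y)
    if not np.isfinite(X_sel).all():
        raise ValueError("non-finite feature values")
    if C <= 0:
        raise ValueError("C must be positive")
    if class_cost is None:
        class_cost = class_cost_from_counts(y)
    c = _sample_costs(y, C, class_cost)

    K = X_sel @ X_sel.T
    if loss == "squared_hinge":
        beta, b, obj = _fit_kernel(K, y.astype(np.float64), c)
    elif loss == "hinge":
        beta, b, obj = _fit_hinge_kernel(K, y.astype(np.float64), c)
    else:
        raise ValueError(f"unknown loss {loss!r}")
    w = X_sel.T @ beta
    return LinearSVMModel(
        w=w,
        b=float(b),
        C=float(C),
        class_cost={int(k): float(v) for k, v in class_cost.items()},
        selection=selection,
        standardizer=standardizer,
        objective=float(obj),
    )


def qp_oracle(
    X_sel: np.ndarray,
    y: np.ndarray,
    C: float,
    class_cost: dict[int, float] | None = None,
) -> LinearSVMModel:
    """Solve the identical convex objective with a general-purpose
    quasi-Newton method (verification oracle; small instances only)."""
    X_sel = np.asarray(X_sel, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X_sel.shape
    if n > 200 or p > 200:
        raise ValueError("oracle restricted to instances <= 200 x 200")
    if C <= 0:
        raise ValueError("C must be positive")
    if class_cost is None:
        class_cost = class_cost_from_counts(y)
    c = _sample_costs(y, C, class_cost)

    def fun(theta: np.ndarray) -> tuple[float, np.ndarray]:
        w, b = theta[:p], theta[p]
        margin = 1.0 - y * (X_sel @ w + b)
        h = np.maximum(margin, 0.0)
        val = 0.5 * w @ w + c @ h**2
        coef = -2.0 * c * h * y
        grad_w = w + X_sel.T @ coef
        grad_b = coef.sum()
        return float(val), np.concatenate([grad_w, [grad_b]])

    res = optimize.minimize(
        fun,
        np.zeros(p + 1),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12},
    )
    # the squared hinge is C1 but not C2, so the line search can stop with
    # an "abnormal" status at machine precision; judge by the gradient
    _, grad = fun(res.x)
    if np.linalg.norm(grad) > 1e-5 * (1.0 + abs(res.fun)):
        raise RuntimeError(f"oracle solver failed to converge: {res.message}")
    return LinearSVMModel(
        w=res.x[:p],
        b=float(res.x[p]),
        C=float(C),
        class_cost={int(k): float(v) for k, v in class_cost.items()},
        objective=float(res.fun),
    )


def predict(
    model: LinearSVMModel, x_raw: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Score raw full-dimensional feature vectors.

    Applies the model's own selection mask, then its standardizer, then
    ``sgn(w'x + b)``. A decision value of exactly zero is reported as +1
    (stable) and logged as a tie.

    Returns ``(labels, decision_values)``; scalar inputs give scalars.
    """
    x = np.atleast_2d(np.asarray(x_raw, dtype=np.float64))
    if model.selection is not None:
        if x.shape[1] != model.selection.keep.shape[0]:
            raise ValueError(
                f"expected {model.selection.keep.shape[0]} raw features, got {x.shape[1]}"
            )
        x = x[:, model.selection.keep]
    if x.shape[1] != model.w.shape[0]:
        raise ValueError(
            f"expected {model.w.shape[0]} selected features, got {x.shape[1]}"
        )
    if model.standardizer is not None:
        x = apply_standardizer(model.standardizer, x)
    decision = x @ model.w + model.b
    ties = decision == 0.0
    if ties.any():
        logger.info("decision value exactly 0 for %d sample(s); reported as stable (+1)", int(ties.sum()))
    labels = np.where(decision >= 0.0, 1, -1)
    if np.ndim(x_raw) == 1:
        return labels[0], decision[0]
    return labels, decision


def fit_fold_model(
    X: np.ndarray,
    y: np.ndarray,
    train_rows,
    C: float,
    alpha: float = 0.01,
    t_variant: str = "student",
) -> LinearSVMModel:
    """Full fold-internal pipeline: t-test filter -> z-score -> weighted SVM.

    Everything (mask, standardizer, class costs, fit) is derived from
    ``train_rows`` only.
    """
    train_rows = np.asarray(sorted(int(i) for i in train_rows))
    mask = ttest_filter(X, y, train_rows, alpha=alpha, variant=t_variant)
    X_sel = np.asarray(X)[:, mask.keep]
    std = fit_standardizer(X_sel, train_rows)
    Xz = apply_standardizer(std, X_sel[train_rows])
    cost = class_cost_from_counts(np.asarray(y)[train_rows])
    return train_weighted_linear_svm(
        Xz, np.asarray(y)[train_rows], C, cost, selection=mask, standardizer=std
    )


# ---------------------------------------------------------------------------
# serialization: JSON scalars + .npz arrays, enough to score new subjects
# ---------------------------------------------------------------------------

def save_model(model: LinearSVMModel, prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    json_path = prefix.with_suffix(".json")
    npz_path = prefix.with_suffix(".npz")
    meta = {
        "b": model.b,
        "C": model.C,
        "class_cost": {str(k): v for k, v in model.class_cost.items()},
        "objective": model.objective,
        "alpha": model.selection.alpha if model.selection else None,
        "selection_fitted_on": list(model.selection.fitted_on) if model.selection else None,
        "standardizer_fitted_on": list(model.standardizer.fitted_on) if model.standardizer else None,
    }
    arrays = {"w": model.w}
    if model.selection is not None:
        arrays.update(
            keep=model.selection.keep,
            t_stat=model.selection.t_stat,
            p_value=model.selection.p_value,
        )
    if model.standardizer is not None:
        arrays.update(std_mean=model.standardizer.mean, std_sd=model.standardizer.sd)
    json_path.write_text(json.dumps(meta, indent=2))
    np.savez(npz_path, **arrays)
    return json_path, npz_path


def load_model(prefix: str | Path) -> LinearSVMModel:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    arrays = np.load(prefix.with_suffix(".npz"))
    selection = None
    if "keep" in arrays:
        selection = SelectionMask(
            keep=arrays["keep"],
            t_stat=arrays["t_stat"],
            p_value=arrays["p_value"],
            alpha=float(meta["alpha"]),
            fitted_on=tuple(meta["selection_fitted_on"]),
        )
    standardizer = None
    if "std_mean" in arrays:
        standardizer = Standardizer(
            mean=arrays["std_mean"],
            sd=arrays["std_sd"],
            fitted_on=tuple(meta["standardizer_fitted_on"]),
        )
    return LinearSVMModel(
        w=arrays["w"],
        b=float(meta["b"]),
        C=float(meta["C"]),
        class_cost={int(k): float(v) for k, v in meta["class_cost"].items()},
        selection=selection,
        standardizer=standardizer,
        objective=float(meta["objective"]),
    )
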