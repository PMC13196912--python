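"""Method-of-moments weight estimation for population adjustment.

The matching step reweights index-trial participants so that the
weighted moments of the prespecified effect modifiers equal the
comparator population's reported summaries.  Writing the centered
moment matrix as Z (one column per matched moment, shifted so the
target maps to zero), the weights are

    w_i(theta) = exp(z_i' theta),

and theta is the minimiser of the strictly convex objective

    Q(theta) = (1/N) sum_i exp(z_i' theta),

whose gradient is exactly the vector of weighted moment residuals.  At
the optimum the residuals vanish: the weighted sample matches the
target moments exactly.  This is the method-of-moments solution of the
logistic propensity model in which each selected modifier enters
linearly.

Weights are reported normalised to mean one, and the effective sample
size ESS = (sum w)^2 / sum w^2 quantifies how much information the
reweighted sample retains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConvergenceError, EstimationError, ValidationError
from .trial_data import AggregateTarget, IPDTable, ModifierSet

#: Gradient-norm convergence tolerance.  The gradient of the (mean-scaled)
#: objective equals the weighted moment residual vector, so this is also
#: the guaranteed moment-balance accuracy at convergence.
GRADIENT_TOL = 1e-10
MAX_ITERATIONS = 500


@dataclass(frozen=True)
class WeightSolution:
    """Fitted weight-model coefficients with per-patient weights and diagnostics.

    Attributes
    ----------
    theta
        One coefficient per matched moment (the centered moment-matrix
        columns).
    weights
        Strictly positive per-participant weights, normalised to mean 1.
    ess
        Effective sample size (sum w)^2 / sum w^2, in (0, N].
    moment_residuals
        Weighted moment minus target, one entry per matched moment.
    moment_labels
        Human-readable label per matched moment.
    converged
        True when the gradient norm met tolerance.
    n_iterations
        Newton iterations used.
    """

    theta: np.ndarray
    weights: np.ndarray
    ess: float
    moment_residuals: np.ndarray
    moment_labels: tuple[str, ...]
    converged: bool
    n_iterations: int

    @property
    def n(self) -> int:
        return len(self.weights)


def build_moment_matrix(
    ipd: IPDTable, mset: ModifierSet, target: AggregateTarget
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Assemble the centered moment matrix Z (N x K) and its column labels.

    For a mean-matched covariate j the column is ``x_ij - m_j``; variance
    matching adds a second column ``(x_ij - m_j)^2 - v_j``.  A column's
    weighted mean is therefore zero exactly when the weighted moment hits
    its target.
    """
    ipd.require_covariates(mset.covariate_names)
    target.require_for(mset)
    cols: list[np.ndarray] = []
    labels: list[str] = []
    for cov in mset.covariate_names:
        x = ipd.data[cov].to_numpy(dtype=float)
        m = float(target.means[cov])
        centered = x - m
        if np.ptp(x) == 0.0 and abs(float(centered.mean())) > 0:
            # constant covariate that misses the target: no reweighting can fix it
            import warnings

            warnings.warn(
                f"covariate '{cov}' is constant in the IPD but differs from its "
                "target mean; the moment problem is infeasible",
                stacklevel=2,
            )
        cols.append(centered)
        labels.append(f"{cov}:mean")
        if mset.moments_for(cov) == "mean_var":
            v = float(target.variances[cov])
            cols.append(centered**2 - v)
            labels.append(f"{cov}:var")
    Z = np.column_stack(cols)
    if not np.all(np.isfinite(Z)):
        raise ValidationError("moment matrix contains non-finite values")
    return Z, tuple(labels)


def estimate_maic_weights(
    Z: np.ndarray,
    labels: tuple[str, ...] | None = None,
    tol: float = GRADIENT_TOL,
    max_iter: int = MAX_ITERATIONS,
) -> WeightSolution:
    """Solve the convex moment-matching problem by damped Newton iteration.

    The objective is smooth and strictly convex in theta whenever Z has
    full column rank, so Newton steps with a backtracking line search
    converge quadratically from theta = 0 (no randomness anywhere).  If
    a target moment lies outside the convex hull of the sample values,
    no finite theta balances it; the solver then exhausts its iteration
    budget and returns ``converged=False`` with diagnostics intact.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValidationError("Z must be a 2-d array")
    n, k = Z.shape
    if not np.all(np.isfinite(Z)):
        raise ValidationError("Z contains non-finite values")
    if k >= n:
        raise EstimationError(f"need more participants than moments: N={n}, K={k}")
    if labels is None:
        labels = tuple(f"moment_{j}" for j in range(k))

    theta = np.zeros(k)

    def objective_parts(th):
        u = np.clip(Z @ th, -700.0, 700.0)
        w = np.exp(u)
        q = w.mean()
        grad = Z.T @ w / n
        return q, grad, w

    def newton_step(w, grad):
        hess = (Z * w[:, None]).T @ Z / n
        # tiny ridge guards rank deficiency (e.g. duplicated moments)
        try:
            return np.linalg.solve(hess + 1e-12 * np.eye(k), -grad)
        except np.linalg.LinAlgError:
            return -grad

    # convergence is judged on the *normalized* residual grad/q — the
    # weighted moment residual itself.  The raw gradient also vanishes
    # along infeasible directions (Q -> 0 at infinity) and would declare
    # false convergence there; the normalized residual does not.
    def residual_norm(q, grad):
        return float(np.linalg.norm(grad / q, ord=np.inf))

    q, grad, w = objective_parts(theta)
    it = 0
    converged = residual_norm(q, grad) <= tol
    while not converged and it < max_iter:
        it += 1
        step = newton_step(w, grad)
        t = 1.0
        for _ in range(60):
            q_new, grad_new, w_new = objective_parts(theta + t * step)
            if q_new <= q + 1e-4 * t * float(grad @ step) or q_new < q:
                break
            t *= 0.5
        else:
            break  # line search failed: cannot descend further
        theta = theta + t * step
        q, grad, w = q_new, grad_new, w_new
        converged = residual_norm(q, grad) <= tol

    if converged:
        # polish: in the quadratic regime each full Newton step squares the
        # error, pushing theta to machine precision
        for _ in range(2):
            theta_new = theta + newton_step(w, grad)
            q_new, grad_new, w_new = objective_parts(theta_new)
            if residual_norm(q_new, grad_new) <= residual_norm(q, grad):
                theta, q, grad, w = theta_new, q_new, grad_new, w_new

    weights = w / w.mean()  # mean-1 normalisation
    residuals = Z.T @ weights / n  # weighted moment minus target
    sol = WeightSolution(
        theta=theta,
        weights=weights,
        ess=effective_sample_size(weights),
        moment_residuals=residuals,
        moment_labels=labels,
        converged=bool(converged),
        n_iterations=it,
    )
    return sol


def effective_sample_size(weights: np.ndarray) -> float:
    """Kish effective sample size (sum w)^2 / sum w^2 of a positive weight vector."""
    w = np.asarray(weights, dtype=float)
    if w.size == 0 or np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValidationError("weights must be a non-empty vector of positive finite values")
    s = w.sum()
    return float(s * s / (w @ w))


def weight_diagnostics(sol: WeightSolution) -> dict:
    """Machine-readable diagnostics block for one fitted modifier set."""
    w = sol.weights
    q = np.quantile(w, [0.0, 0.25, 0.5, 0.75, 1.0])
    return {
        "converged": sol.converged,
        "n_iterations": sol.n_iterations,
        "n": sol.n,
        "ess": sol.ess,
        "ess_fraction": sol.ess / sol.n,
        "theta": {lab: float(t) for lab, t in zip(sol.moment_labels, sol.theta)},
        "moment_residuals": {
            lab: float(r) for lab, r in zip(sol.moment_labels, sol.moment_residuals)
        },
        "weights": {
            "min": float(q[0]),
            "q1": float(q[1]),
            "median": float(q[2]),
            "q3": float(q[3]),
            "max": float(q[4]),
        },
    }


def format_diagnostics(diag: dict, set_name: str) -> str:
    """Plain-text rendering of :func:`weight_diagnostics`."""
    lines = [
        f"Weight diagnostics — modifier set '{set_name}'",
        f"  converged: {diag['converged']} in {diag['n_iterations']} iterations",
        f"  N = {diag['n']}, ESS = {diag['ess']:.2f} (ESS/N = {diag['ess_fraction']:.3f})",
        "  coefficients:",
    ]
    for lab, t in diag["theta"].items():
        lines.append(f"    {lab:<28s} {t:+.6f}  (residual {diag['moment_residuals'][lab]:+.2e})")
    wq = diag["weights"]
    lines.append(
        "  weights: min {min:.4f} | q1 {q1:.4f} | median {median:.4f} | "
        "q3 {q3:.4f} | max {max:.4f}".format(**wq)
    )
    return "\n".join(lines)


def fit_weights(
    ipd: IPDTable, mset: ModifierSet, target: AggregateTarget, **kwargs
) -> WeightSolution:
    """Convenience wrapper: build the moment matrix and estimate weights.

    Raises :class:`~maiclab.errors.ConvergenceError` (carrying the
    partial solution) when the solver does not meet tolerance.
    """
    Z, labels = build_moment_matrix(ipd, mset, target)
    sol = estimate_maic_weights(Z, labels=labels, **kwargs)
    if not sol.converged:
        raise ConvergenceError(
            f"weight solver did not converge for modifier set '{mset.name}' "
            f"(max |residual| = {np.max(np.abs(sol.moment_residuals)):.3e}); "
            "the target moments may lie outside the span of the IPD",
            diagnostics=sol,
        )
    return sol
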