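"""Gradient-descent refinement of the spring-constant matrix.

The inverse transform alone reproduces a *noise-free* forward-generated
matrix exactly, but experimental contact matrices are noisy and generally
not realisable by any stable network.  The optimizer therefore minimises
the least-squares cost

    cost(K) = 1/2 * sum_{i<j} (C_model_ij(K) - C_input_ij)^2

over valid K in two phases, both with step-halving backtracking so the
accepted cost history is non-increasing:

1. *Projection phase*: move the model contact matrix a fraction eta toward
   the input and pull the target back through the invertible transform
   (:func:`~hicdyn.mapping.project_to_model`).  Because the transform is
   exact, a realisable input is recovered in one full step; a noisy input
   converges within a few steps to (near) its projection onto the manifold
   of realisable contact matrices.  This generalises the inverse-transform
   initialisation and is what makes the fit fast.
2. *Descent phase*: plain gradient descent on K with the analytic O(N^3)
   gradient (chain rule through the Laplacian pseudo-inverse) and a
   validity projection after every step, polishing the least-squares cost
   locally.  Descent on K is well behaved near the optimum but stalls in
   ill-conditioned valleys when started far away, which is why it runs
   after the projection phase.

Null bins stay in the cost as zero rows/columns.

Similarity between matrices is scored with the Pearson correlation of the
off-diagonal elements (PCC) and a distance-corrected PCC that removes the
genomic-distance decay trend by correlating within each diagonal stratum
and combining the per-stratum coefficients with variance-aware weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mapping import (
    ModelConventions,
    laplacian_from_k,
    k_from_laplacian,
    project_to_model,
    pseudo_inverse,
    squared_distances,
)

__all__ = [
    "OptimizationConfig",
    "OptimizationResult",
    "cost",
    "gradient",
    "project_valid",
    "optimize",
    "pearson_cc",
    "distance_corrected_cc",
    "contact_decay",
]

_TINY = 1e-300


@dataclass
class OptimizationConfig:
    """Descent hyper-parameters.

    learning_rate : float or None
        Step size eta; ``None`` selects 1e-4 * N^2, which scales with the
        problem because gradient magnitudes shrink roughly as 1/N^2.
    stop_epsilon : float
        Relative cost-change threshold for convergence.
    init_mode : {"inverse_transform", "backbone"}
        Either start from the inverse transform of the (floored) input —
        exploiting the invertible map, usually within noise of the optimum
        already — or from a bare backbone chain with spring ``backbone_k0``.
    projection_floor : float
        Eigenvalue floor delta applied to non-uniform Laplacian modes when
        projecting onto valid models.
    seed : int
        Reserved; the descent itself is deterministic.
    """

    learning_rate: float | None = None
    stop_epsilon: float = 1e-6
    max_iterations: int = 10000
    init_mode: str = "inverse_transform"
    backbone_k0: float = 0.5
    c_min: float = 1e-4
    projection_floor: float = 1e-8
    max_halvings: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate is not None and self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.stop_epsilon <= 0:
            raise ValueError("stop_epsilon must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.init_mode not in ("inverse_transform", "backbone"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")


@dataclass
class OptimizationResult:
    K_opt: np.ndarray
    C_opt: np.ndarray
    cost_history: np.ndarray
    n_iterations: int
    pcc: float
    distance_corrected_pcc: float
    converged: bool
    final_learning_rate: float = field(default=float("nan"))


def cost(C_model, C_input) -> float:
    """Half the sum of squared upper-triangle differences."""
    C_model = np.asarray(C_model, dtype=float)
    C_input = np.asarray(C_input, dtype=float)
    if C_model.shape != C_input.shape:
        raise ValueError("shape mismatch")
    diff = C_model - C_input
    iu = np.triu_indices(diff.shape[0], k=1)
    return 0.5 * float(np.sum(diff[iu] ** 2))


def _model_state(K, conv):
    """Sigma, d2 and C_model for the current K (one eigh)."""
    Sigma = pseudo_inverse(laplacian_from_k(K))
    d2 = squared_distances(Sigma)
    np.clip(d2, 0.0, None, out=d2)
    s2 = conv.contact_scale**2
    C_model = (1.0 + d2 / s2) ** conv.exponent
    np.fill_diagonal(C_model, 1.0)
    return Sigma, d2, C_model


def gradient(K, C_input, conv: ModelConventions | None = None) -> np.ndarray:
    """Analytic d(cost)/dK.

    With residual weights
    ``W_ij = 3/(2 sigma_c^2) * (C_model - C_input)_ij * (1 + d2_ij/sigma_c^2)^(-5/2)``
    and ``P = Sigma L(W) Sigma``, the gradient is
    ``g_mn = P_mm + P_nn - 2 P_mn`` (zero diagonal) — the closed form of the
    pair sum ``sum_{i<j} W_ij (Sigma_im - Sigma_in - Sigma_jm + Sigma_jn)^2``.
    """
    conv = conv or ModelConventions()
    C_input = np.asarray(C_input, dtype=float)
    Sigma, d2, C_model = _model_state(K, conv)
    s2 = conv.contact_scale**2
    R = C_model - C_input
    np.fill_diagonal(R, 0.0)
    W = (1.5 / s2) * R * (1.0 + d2 / s2) ** (conv.exponent - 1.0)
    L_W = laplacian_from_k(W)  # W is symmetric zero-diagonal like K
    P = Sigma @ L_W @ Sigma
    dp = np.diag(P)
    g = dp[:, None] + dp[None, :] - P - P.T
    np.fill_diagonal(g, 0.0)
    return g


def project_valid(K, delta=1e-8) -> np.ndarray:
    """Project K onto the valid set by flooring Laplacian eigenvalues.

    The uniform mode keeps its exact zero; every other eigenvalue is raised
    to at least ``delta``.  Identity (to round-off) on already-valid K, and
    idempotent.
    """
    L = laplacian_from_k(K)
    lam, V = np.linalg.eigh(L)
    n = L.shape[0]
    overlap = np.abs(V.sum(axis=0)) / np.sqrt(n)
    p0 = int(np.argmax(overlap))
    lam_f = np.maximum(lam, delta)
    lam_f[p0] = 0.0
    if np.array_equal(lam_f[np.arange(n) != p0], lam[np.arange(n) != p0]):
        out = K.copy() if isinstance(K, np.ndarray) else np.array(K, dtype=float)
        np.fill_diagonal(out, 0.0)
        return out
    L_new = (V * lam_f) @ V.T
    return k_from_laplacian(0.5 * (L_new + L_new.T))


def optimize(C_input, config: OptimizationConfig | None = None,
             conv: ModelConventions | None = None) -> OptimizationResult:
    """Fit a valid spring-constant matrix to a normalized contact matrix.

    Deterministic given the configuration.  Both phases backtrack by
    halving their step size (up to ``max_halvings`` per step) whenever the
    trial cost increases; an accepted step doubles it back (the projection
    phase caps its fraction at 1).  Each phase stops when the relative cost
    change drops below ``stop_epsilon``, when no acceptable step exists, or
    when the shared ``max_iterations`` budget runs out.
    """
    config = config or OptimizationConfig()
    conv = conv or ModelConventions()
    C_input = np.asarray(C_input, dtype=float)
    n = C_input.shape[0]

    if config.init_mode == "inverse_transform":
        K = project_to_model(C_input, conv, c_min=config.c_min)
    else:
        K = np.zeros((n, n))
        idx = np.arange(n - 1)
        K[idx, idx + 1] = K[idx + 1, idx] = config.backbone_k0

    _, _, C_model = _model_state(K, conv)
    cost_cur = cost(C_model, C_input)
    history = [cost_cur]
    n_iter = 0
    budget = config.max_iterations

    # -- phase 1: projected steps in contact space through the inverse map
    eta_c = 1.0
    converged = False
    while n_iter < budget:
        accepted = False
        for _h in range(config.max_halvings + 1):
            target = C_model + eta_c * (C_input - C_model)
            np.fill_diagonal(target, 1.0)
            K_trial = project_to_model(target, conv, c_min=config.c_min)
            _, _, C_trial = _model_state(K_trial, conv)
            cost_trial = cost(C_trial, C_input)
            if np.isfinite(cost_trial) and cost_trial <= cost_cur:
                accepted = True
                break
            eta_c *= 0.5
        if not accepted:
            break
        n_iter += 1
        eta_c = min(eta_c * 2.0, 1.0)
        K, C_model = K_trial, C_trial
        rel_change = abs(cost_trial - cost_cur) / max(cost_cur, _TINY)
        cost_cur = cost_trial
        history.append(cost_cur)
        if rel_change < config.stop_epsilon:
            converged = True
            break

    # -- phase 2: gradient descent on K from the near-optimal start
    eta = (config.learning_rate if config.learning_rate is not None
           else 1e-4 * n * n)
    while n_iter < budget:
        g = gradient(K, C_input, conv)
        accepted = False
        for _h in range(config.max_halvings + 1):
            K_trial = project_valid(K - eta * g, config.projection_floor)
            _, _, C_trial = _model_state(K_trial, conv)
            cost_trial = cost(C_trial, C_input)
            if np.isfinite(cost_trial) and cost_trial <= cost_cur:
                accepted = True
                break
            eta *= 0.5
        if not accepted:
            break
        n_iter += 1
        eta *= 2.0
        K, C_model = K_trial, C_trial
        rel_change = abs(cost_trial - cost_cur) / max(cost_cur, _TINY)
        cost_cur = cost_trial
        history.append(cost_cur)
        if rel_change < config.stop_epsilon:
            converged = True
            break

    def _metric(fn):
        try:
            return fn(C_model, C_input)
        except ValueError:  # zero variance / all strata degenerate
            return float("nan")

    return OptimizationResult(
        K_opt=K,
        C_opt=C_model,
        cost_history=np.asarray(history),
        n_iterations=n_iter,
        pcc=_metric(pearson_cc),
        distance_corrected_pcc=_metric(distance_corrected_cc),
        converged=converged,
        final_learning_rate=eta,
    )


def _upper_offdiag(A, bin_valid=None):
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    if bin_valid is not None:
        m = np.asarray(bin_valid, dtype=bool)
        keep = m[iu] & m[ju]
        iu, ju = iu[keep], ju[keep]
    return A[iu, ju]


def pearson_cc(A, B, bin_valid=None) -> float:
    """Pearson correlation of upper-triangle off-diagonal elements."""
    a = _upper_offdiag(A, bin_valid)
    b = _upper_offdiag(B, bin_valid)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("zero variance: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def distance_corrected_cc(A, B, bin_valid=None) -> float:
    """Stratum-adjusted correlation removing the genomic-distance trend.

    Elements are stratified by separation s = |i-j|; per-stratum Pearson
    coefficients r_s are combined as sum(w_s r_s)/sum(w_s) with
    ``w_s = n_s * sigma_{A,s} * sigma_{B,s}`` (population std), so strata
    with no signal contribute nothing.  Strata with zero variance in either
    matrix are skipped.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("shape mismatch")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 bins")
    mask = (
        np.ones(n, dtype=bool) if bin_valid is None
        else np.asarray(bin_valid, dtype=bool)
    )
    num = 0.0
    den = 0.0
    for s in range(1, n):
        keep = mask[:-s] & mask[s:]
        a = np.diagonal(A, s)[keep]
        b = np.diagonal(B, s)[keep]
        if a.size < 2:
            continue
        sa, sb = a.std(), b.std()
        # constant-to-round-off strata carry no signal; correlating their
        # float noise would poison the weighted sum
        if sa <= 1e-9 * np.abs(a).max() or sb <= 1e-9 * np.abs(b).max():
            continue
        r_s = float(np.corrcoef(a, b)[0, 1])
        w_s = a.size * sa * sb
        num += w_s * r_s
        den += w_s
    if den == 0.0:
        raise ValueError("all strata degenerate: correlation undefined")
    return float(num / den)


def contact_decay(C, bin_valid=None):
    """Mean contact probability P(s) per genomic separation s = 1..N-1.

    Pairs involving null bins are excluded from the mean; a separation with
    no valid pair yields NaN.  Returns ``(s, P)`` arrays.
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    mask = (
        np.ones(n, dtype=bool) if bin_valid is None
        else np.asarray(bin_valid, dtype=bool)
    )
    seps = np.arange(1, n)
    means = np.full(n - 1, np.nan)
    for s in seps:
        keep = mask[:-s] & mask[s:]
        if keep.any():
            means[s - 1] = np.diagonal(C, s)[keep].mean()
    return seps, means
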