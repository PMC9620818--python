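"""The invertible transform between contact probabilities and spring constants.

The chromatin region is modelled as N beads coupled by pairwise harmonic
springs with (possibly negative) dimensionless constants ``k_ij``, collected
in the symmetric zero-diagonal matrix K — the model's full parameter set.
With thermal energy and per-bead friction set to 1, the equilibrium bead
positions are a degenerate multivariate Gaussian whose per-axis covariance
(center of mass fixed) is the Moore-Penrose pseudo-inverse Sigma of the
network Laplacian L(K).  Squared mean distances follow as

    d2_ij = Sigma_ii + Sigma_jj - 2 Sigma_ij,

and the contact probability of a Gaussian pair at contact scale sigma_c is

    C_ij = (1 + d2_ij / sigma_c^2)^(-3/2).

Every step is invertible: C -> d2 by inverting the kernel, d2 -> Gram matrix
by classical-scaling double centering (which reproduces Sigma exactly, since
Sigma has zero row sums), and Sigma -> L by pseudo-inversion.  Forward and
inverse maps here realise that correspondence to machine precision for any
valid K (Laplacian PSD with the uniform mode as its only kernel vector).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelConventions",
    "InvalidModelError",
    "DisconnectedNetworkError",
    "laplacian_from_k",
    "k_from_laplacian",
    "pseudo_inverse",
    "squared_distances",
    "forward_map",
    "inverse_map",
    "floor_contacts",
    "project_to_model",
    "min_nonuniform_eigenvalue",
    "check_valid_k",
]

#: relative eigenvalue floor used for rank decisions in pseudo-inversion
EIG_FLOOR_REL = 1e-10
#: eigenvalues above -PSD_TOL_REL * spectral_radius count as non-negative
PSD_TOL_REL = 1e-8


class InvalidModelError(ValueError):
    """The spring-constant matrix does not define a stable (PSD) network."""


class DisconnectedNetworkError(InvalidModelError):
    """The Laplacian kernel has dimension > 1: the bead network is split."""


@dataclass
class ModelConventions:
    """Dimensionless conventions of the contact kernel.

    contact_scale : float
        Contact length sigma_c in units of the model length; contacts are
        counted when two beads overlap within this scale.  Default 1.
    exponent : float
        Kernel exponent; -3/2 is the Gaussian-overlap value and is the only
        exponent for which the map is analytically invertible in this form.
    """

    contact_scale: float = 1.0
    exponent: float = -1.5

    def __post_init__(self):
        if self.contact_scale <= 0:
            raise ValueError("contact_scale must be positive")


_DEFAULT_CONV = ModelConventions()


def _as_symmetric_zero_diag(K, what="K"):
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError(f"{what} must be square")
    scale = max(1.0, float(np.abs(K).max()) if K.size else 0.0)
    if np.abs(K - K.T).max() > 1e-8 * scale:
        raise ValueError(f"{what} must be symmetric")
    return 0.5 * (K + K.T)  # absorb round-off drift


def laplacian_from_k(K) -> np.ndarray:
    """Network Laplacian: ``L_ij = -k_ij`` off-diagonal, rows sum to zero."""
    K = _as_symmetric_zero_diag(K)
    L = -K.copy()
    np.fill_diagonal(L, 0.0)
    np.fill_diagonal(L, -L.sum(axis=1))
    return L


def k_from_laplacian(L) -> np.ndarray:
    """Inverse of :func:`laplacian_from_k` (diagonal information discarded)."""
    K = -np.asarray(L, dtype=float).copy()
    np.fill_diagonal(K, 0.0)
    return K


def pseudo_inverse(L, eig_floor=None, *, require_connected=False) -> np.ndarray:
    """Moore-Penrose pseudo-inverse of a symmetric matrix via eigh.

    Eigenvalues with magnitude below ``eig_floor`` (default: 1e-10 times the
    spectral radius) are treated as exact zeros.  With
    ``require_connected=True``, more than one zero eigenvalue raises
    :class:`DisconnectedNetworkError`.
    """
    L = _as_symmetric_zero_diag(L, "L")
    lam, V = np.linalg.eigh(L)
    radius = np.abs(lam).max() if lam.size else 0.0
    if radius == 0.0:
        return np.zeros_like(L)
    if eig_floor is None:
        eig_floor = EIG_FLOOR_REL * radius
    keep = np.abs(lam) > eig_floor
    if require_connected and (~keep).sum() > 1:
        raise DisconnectedNetworkError(
            f"Laplacian kernel has dimension {(~keep).sum()}"
        )
    inv = np.zeros_like(lam)
    inv[keep] = 1.0 / lam[keep]
    S = (V * inv) @ V.T
    return 0.5 * (S + S.T)


def squared_distances(Sigma) -> np.ndarray:
    """Per-axis mean squared distances ``d2_ij = S_ii + S_jj - 2 S_ij``."""
    Sigma = np.asarray(Sigma, dtype=float)
    d = np.diag(Sigma)
    d2 = d[:, None] + d[None, :] - 2.0 * Sigma
    np.fill_diagonal(d2, 0.0)
    return d2


def min_nonuniform_eigenvalue(K) -> float:
    """Smallest Laplacian eigenvalue outside the uniform mode."""
    L = laplacian_from_k(K)
    lam, V = np.linalg.eigh(L)
    n = L.shape[0]
    uniform_overlap = np.abs(V.sum(axis=0)) / np.sqrt(n)
    p0 = int(np.argmax(uniform_overlap))
    return float(np.delete(lam, p0).min()) if n > 1 else 0.0


def check_valid_k(K, tol_rel=PSD_TOL_REL) -> None:
    """Raise :class:`InvalidModelError` unless L(K) is PSD with rank N-1."""
    L = laplacian_from_k(K)
    lam = np.linalg.eigh(L)[0]
    radius = np.abs(lam).max()
    if radius == 0.0:
        return  # K = 0: degenerate but harmless (all modes free)
    if lam.min() < -tol_rel * radius:
        raise InvalidModelError(
            f"Laplacian has negative eigenvalue {lam.min():.3e}"
        )
    if (np.abs(lam) <= EIG_FLOOR_REL * radius).sum() > 1:
        raise DisconnectedNetworkError("bead network is disconnected")


def forward_map(K, conv: ModelConventions | None = None) -> np.ndarray:
    """Contact matrix of a spring-constant matrix.

    ``C_ij = (1 + d2_ij/sigma_c^2)^(-3/2)``, with an exact unit diagonal.
    """
    conv = conv or _DEFAULT_CONV
    L = laplacian_from_k(K)
    Sigma = pseudo_inverse(L)
    d2 = squared_distances(Sigma)
    if d2.min() < -1e-10 * max(1.0, np.abs(d2).max()):
        raise InvalidModelError(
            f"negative squared distance {d2.min():.3e}: K is not a valid model"
        )
    np.clip(d2, 0.0, None, out=d2)
    C = (1.0 + d2 / conv.contact_scale**2) ** conv.exponent
    np.fill_diagonal(C, 1.0)
    return 0.5 * (C + C.T)


def floor_contacts(C, c_min=1e-4) -> np.ndarray:
    """Raise all entries to at least ``c_min``.

    A zero contact probability maps to an infinite distance; flooring keeps
    the Gram matrix finite.  Only meant for building an *initial* model —
    the optimizer refines it afterwards.
    """
    C = np.asarray(C, dtype=float).copy()
    C[C < c_min] = c_min
    np.fill_diagonal(C, 1.0)
    return C


@dataclass
class InverseDiagnostics:
    """Validity report of :func:`inverse_map`.

    ``min_gram_eigenvalue`` is the smallest eigenvalue of the reconstructed
    Gram matrix; the contact matrix is realisable by a stable network iff it
    is >= -PSD tolerance.  ``degenerate`` marks an all-contacts-1 input
    (zero distances, K undetermined and returned as 0).
    """

    min_gram_eigenvalue: float
    valid: bool
    degenerate: bool


def inverse_map(C, conv: ModelConventions | None = None):
    """Spring-constant matrix reproducing a unit-diagonal contact matrix.

    Returns ``(K, InverseDiagnostics)``.  Entries must lie in (0, 1]; floor
    zeros with :func:`floor_contacts` first.
    """
    conv = conv or _DEFAULT_CONV
    C = _as_symmetric_zero_diag(C, "C")
    if np.any(C <= 0.0):
        raise ValueError(
            "C contains non-positive entries; apply floor_contacts first"
        )
    if np.any(C > 1.0 + 1e-12):
        raise ValueError("C contains entries above 1")
    n = C.shape[0]
    d2 = conv.contact_scale**2 * (C ** (1.0 / conv.exponent) - 1.0)
    np.fill_diagonal(d2, 0.0)
    # classical-scaling Gram construction
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = -0.5 * (J @ d2 @ J)
    G = 0.5 * (G + G.T)
    lam_min = float(np.linalg.eigvalsh(G).min())
    radius = float(np.abs(G).max())
    degenerate = radius < 1e-14
    L = pseudo_inverse(G)
    K = k_from_laplacian(L)
    valid = degenerate or lam_min >= -PSD_TOL_REL * max(radius, 1e-300)
    return K, InverseDiagnostics(
        min_gram_eigenvalue=lam_min, valid=valid, degenerate=degenerate
    )


def project_to_model(C, conv: ModelConventions | None = None, c_min=1e-4,
                     gram_floor_rel=1e-8) -> np.ndarray:
    """Inverse transform with a guaranteed-valid result.

    Like :func:`inverse_map`, but the reconstructed Gram matrix has its
    non-uniform eigenvalues floored at ``gram_floor_rel`` times the largest
    one before pseudo-inversion.  A noisy contact matrix generally encodes
    non-Euclidean distances (negative Gram eigenvalues); flooring them on
    the *Gram* side turns them into very stiff, near-zero-extent modes,
    which barely perturb the contact matrix — whereas flooring on the
    Laplacian side would create pathologically soft modes.  Always returns
    a valid spring-constant matrix.
    """
    conv = conv or _DEFAULT_CONV
    C = floor_contacts(np.minimum(np.asarray(C, dtype=float), 1.0), c_min)
    n = C.shape[0]
    d2 = conv.contact_scale**2 * (C ** (1.0 / conv.exponent) - 1.0)
    np.fill_diagonal(d2, 0.0)
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    G = -0.5 * (J @ d2 @ J)
    G = 0.5 * (G + G.T)
    lam, V = np.linalg.eigh(G)
    overlap = np.abs(V.sum(axis=0)) / np.sqrt(n)
    p0 = int(np.argmax(overlap))
    lam_f = np.maximum(lam, gram_floor_rel * max(lam.max(), 1e-300))
    lam_f[p0] = 0.0
    inv = np.zeros(n)
    pos = lam_f > 0
    inv[pos] = 1.0 / lam_f[pos]
    L = (V * inv) @ V.T
    return k_from_laplacian(0.5 * (L + L.T))
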