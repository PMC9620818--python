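"""Per-locus microrheology of the fitted network.

Each bead's mean squared displacement is an exponential-sum relaxation

    MSD_n(t) = A_n t + sum_p c_p (1 - e^(-lambda_p t)),
    A_n = 6/N (0 with the center of mass fixed),  c_p = 6 V_np^2 / lambda_p,

and the generalized Stokes-Einstein relation (dimensionless, prefactor 1)
turns it into a creep compliance J_n(t) = MSD_n(t)/6.  Because J is an
exponential sum, its Fourier-Laplace transform is available in closed form:

    s Jhat(s) = (A/s + sum_p c_p lambda_p / (s + lambda_p)) / 6,   s = i omega,
    G*(omega) = 1 / (s Jhat(s)),

giving the storage modulus G' = Re G*, loss modulus G'' = Im G* and loss
tangent tan(delta) = G''/G' without numerical integration.  The spectra are
Kramers-Kronig consistent by construction since the relaxation spectrum is
completely monotone.  Scanning all beads yields rheology spectra along the
genomic coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import normal_modes

__all__ = [
    "MsdDecomposition",
    "RheologySpectra",
    "msd_decomposition",
    "compliance",
    "complex_modulus",
    "loss_tangent",
    "spectra_along_genome",
    "default_time_grid",
    "default_frequency_grid",
]


def default_time_grid(n=64):
    return np.logspace(-3, 3, n)


def default_frequency_grid(n=64):
    return np.logspace(-3, 3, n)


@dataclass
class MsdDecomposition:
    """Exponential-sum coefficients of one bead's MSD.

    ``diffusive_coefficient`` is A_n (6/N or 0); ``amplitudes``/``rates``
    are the per-mode (c_p, lambda_p), all non-negative with positive rates.
    """

    bead_index: int
    diffusive_coefficient: float
    amplitudes: np.ndarray
    rates: np.ndarray

    def msd(self, times) -> np.ndarray:
        t = np.atleast_1d(np.asarray(times, dtype=float))
        decay = 1.0 - np.exp(-self.rates[None, :] * t[:, None])
        return self.diffusive_coefficient * t + (self.amplitudes[None, :] * decay).sum(axis=1)


@dataclass
class RheologySpectra:
    times: np.ndarray
    omegas: np.ndarray
    compliance: np.ndarray   # (N, len(times))
    storage: np.ndarray      # (N, len(omegas)) G'
    loss: np.ndarray         # G''
    tan_delta: np.ndarray


def msd_decomposition(K, bead_index, include_com=True) -> MsdDecomposition:
    modes = normal_modes(K)
    lam, V = modes.eigenvalues, modes.eigenvectors
    return MsdDecomposition(
        bead_index=int(bead_index),
        diffusive_coefficient=6.0 / modes.n_beads if include_com else 0.0,
        amplitudes=6.0 * V[bead_index, 1:] ** 2 / lam[1:],
        rates=lam[1:].copy(),
    )


def compliance(decomp: MsdDecomposition, times) -> np.ndarray:
    """Creep compliance J(t) = MSD(t)/6; non-decreasing in t."""
    return decomp.msd(times) / 6.0


def complex_modulus(decomp: MsdDecomposition, omegas):
    """Storage and loss moduli from the closed-form transform of J.

    Returns ``(G_storage, G_loss)`` arrays over the frequency grid.
    """
    w = np.atleast_1d(np.asarray(omegas, dtype=float))
    if np.any(w <= 0):
        raise ValueError("frequencies must be positive")
    s = 1j * w
    sJ = decomp.diffusive_coefficient / s
    if decomp.rates.size:
        sJ = sJ + (
            decomp.amplitudes[None, :]
            * decomp.rates[None, :]
            / (s[:, None] + decomp.rates[None, :])
        ).sum(axis=1)
    sJ = sJ / 6.0
    G = 1.0 / sJ
    return G.real, G.imag


def loss_tangent(G_storage, G_loss, tiny=1e-300) -> np.ndarray:
    """tan(delta) = G''/G'; +inf where the storage modulus vanishes."""
    Gp = np.asarray(G_storage, dtype=float)
    Gpp = np.asarray(G_loss, dtype=float)
    if Gp.shape != Gpp.shape:
        raise ValueError("shape mismatch")
    out = np.full_like(Gp, np.inf)
    ok = Gp > tiny
    out[ok] = Gpp[ok] / Gp[ok]
    return out


def spectra_along_genome(K, times=None, omegas=None, include_com=True) -> RheologySpectra:
    """J, G', G'' and tan(delta) for every bead of the chain."""
    times = default_time_grid() if times is None else np.asarray(times, dtype=float)
    omegas = default_frequency_grid() if omegas is None else np.asarray(omegas, dtype=float)
    modes = normal_modes(K)
    lam, V = modes.eigenvalues, modes.eigenvectors
    n = modes.n_beads
    J = np.empty((n, times.size))
    Gp = np.empty((n, omegas.size))
    Gpp = np.empty((n, omegas.size))
    for bead in range(n):
        decomp = MsdDecomposition(
            bead_index=bead,
            diffusive_coefficient=6.0 / n if include_com else 0.0,
            amplitudes=6.0 * V[bead, 1:] ** 2 / lam[1:],
            rates=lam[1:],
        )
        J[bead] = compliance(decomp, times)
        Gp[bead], Gpp[bead] = complex_modulus(decomp, omegas)
    return RheologySpectra(
        times=times,
        omegas=omegas,
        compliance=J,
        storage=Gp,
        loss=Gpp,
        tan_delta=loss_tangent(Gp, Gpp),
    )
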