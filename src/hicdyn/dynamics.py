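"""Normal-mode Langevin dynamics and equilibrium conformation sampling.

A fitted network relaxes like a generalised Rouse chain: projecting the
overdamped Langevin equation onto the Laplacian eigenvectors decouples it
into independent Ornstein-Uhlenbeck processes, one per mode and axis, with
relaxation rate equal to the eigenvalue.  The simulator advances each mode
with the *exact* OU transition kernel

    x_p(t+dt) = x_p(t) e^(-lambda_p dt) + xi sqrt((1 - e^(-2 lambda_p dt)) / lambda_p)

so the stationary distribution is exact for any time step.  The uniform
mode (center of mass) either stays pinned at the origin or diffuses freely
with per-axis variance 2 dt per step.

Units are dimensionless: thermal energy = friction per bead = contact
scale = 1; one time unit is friction * length^2 / energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .mapping import check_valid_k, laplacian_from_k

__all__ = [
    "NormalModes",
    "Trajectory",
    "ConformationSet",
    "normal_modes",
    "sample_conformations",
    "simulate_dynamics",
    "analytic_msd",
    "write_xyz",
    "read_xyz",
    "write_psf",
]


@dataclass
class NormalModes:
    """Eigendecomposition of the network Laplacian.

    ``eigenvalues`` ascending with the uniform (zero) mode first;
    ``eigenvectors`` orthonormal columns, sign-fixed so the first component
    of each column exceeding 1e-10 in magnitude is positive.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def n_beads(self) -> int:
        return self.eigenvectors.shape[0]


def normal_modes(K) -> NormalModes:
    """Deterministically ordered, sign-fixed Laplacian eigendecomposition."""
    check_valid_k(K)
    lam, V = np.linalg.eigh(laplacian_from_k(K))
    order = np.argsort(lam, kind="stable")
    lam, V = lam[order], V[:, order]
    lam[0] = 0.0
    for p in range(V.shape[1]):
        col = V[:, p]
        nz = np.nonzero(np.abs(col) > 1e-10)[0]
        if nz.size and col[nz[0]] < 0:
            V[:, p] = -col
    return NormalModes(eigenvalues=lam, eigenvectors=V)


@dataclass
class Trajectory:
    frames: np.ndarray  # (F, N, 3)
    dt: float
    seed: int
    fix_com: bool = True


@dataclass
class ConformationSet:
    samples: np.ndarray  # (S, N, 3)
    seed: int


def _mode_rng(seed):
    return np.random.default_rng(seed)


def sample_conformations(K, n_samples, seed=0) -> ConformationSet:
    """Draw independent equilibrium conformations.

    Per sample and axis, mode amplitudes are Normal(0, 1/lambda_p) for
    p >= 1 and zero for the uniform mode, so every sample has its center of
    mass at the origin by construction.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    modes = normal_modes(K)
    lam, V = modes.eigenvalues, modes.eigenvectors
    rng = _mode_rng(seed)
    std = np.zeros_like(lam)
    std[1:] = 1.0 / np.sqrt(lam[1:])
    x = rng.standard_normal((n_samples, lam.size, 3)) * std[None, :, None]
    x[:, 0, :] = 0.0
    samples = np.einsum("np,spd->snd", V, x)
    return ConformationSet(samples=samples, seed=seed)


def simulate_dynamics(K, n_frames, dt=0.01, seed=0, fix_com=True) -> Trajectory:
    """Exact-in-distribution OU trajectory of the bead network.

    The initial state is drawn from equilibrium, so statistics are
    stationary from frame 0.  ``fix_com=True`` pins the center of mass at
    the origin; otherwise it performs free diffusion with per-axis step
    variance 2 dt.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    modes = normal_modes(K)
    lam, V = modes.eigenvalues, modes.eigenvectors
    n = lam.size
    rng = _mode_rng(seed)
    x = np.zeros((n_frames, n, 3))
    # internal modes: exact OU recursion via linear filtering per mode
    for p in range(1, n):
        a = np.exp(-lam[p] * dt)
        x0 = rng.standard_normal(3) / np.sqrt(lam[p])
        if n_frames > 1:
            u = rng.standard_normal((n_frames - 1, 3)) * np.sqrt(
                (1.0 - a * a) / lam[p]
            )
            zi = (a * x0)[None, :]
            y, _ = lfilter([1.0], [1.0, -a], u, axis=0, zi=zi)
            x[1:, p, :] = y
        x[0, p, :] = x0
    if not fix_com:
        steps = rng.standard_normal((n_frames - 1, 3)) * np.sqrt(2.0 * dt)
        x[1:, 0, :] = np.cumsum(steps, axis=0)
    frames = np.einsum("np,fpd->fnd", V, x)
    return Trajectory(frames=frames, dt=dt, seed=seed, fix_com=fix_com)


def analytic_msd(K, bead_index, times, include_com=True) -> np.ndarray:
    """Closed-form mean squared displacement of one bead.

    ``MSD_n(t) = 6 t / N + sum_{p>=1} (6 V_np^2 / lambda_p)(1 - e^(-lambda_p t))``;
    the diffusive center-of-mass term is dropped when ``include_com=False``
    (matching trajectories run with ``fix_com=True``).
    """
    modes = normal_modes(K)
    lam, V = modes.eigenvalues, modes.eigenvectors
    t = np.atleast_1d(np.asarray(times, dtype=float))
    amp = 6.0 * V[bead_index, 1:] ** 2 / lam[1:]
    msd = (amp[None, :] * (1.0 - np.exp(-lam[None, 1:] * t[:, None]))).sum(axis=1)
    if include_com:
        msd = msd + 6.0 * t / modes.n_beads
    return msd


# ---------------------------------------------------------------------------
# trajectory file formats


def _coords_iter(obj):
    if isinstance(obj, Trajectory):
        arr = obj.frames
    elif isinstance(obj, ConformationSet):
        arr = obj.samples
    else:
        arr = np.asarray(obj, dtype=float)
        if arr.ndim == 2:
            arr = arr[None]
    return arr


def write_xyz(obj, path) -> None:
    """Multi-frame XYZ: per frame a bead count, a comment, then C x y z."""
    arr = _coords_iter(obj)
    n = arr.shape[1]
    with open(path, "w") as fh:
        for f, frame in enumerate(arr):
            fh.write(f"{n}\nframe {f}\n")
            for xyz in frame:
                fh.write("C {:.6f} {:.6f} {:.6f}\n".format(*xyz))


def read_xyz(path) -> np.ndarray:
    """Parse a file written by :func:`write_xyz` back to (F, N, 3)."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        block = lines[i + 2 : i + 2 + n]
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        i += 2 + n
    return np.asarray(frames)


def write_psf(n_beads, path) -> None:
    """CHARMM-style topology: N carbon pseudo-atoms, N-1 backbone bonds."""
    with open(path, "w") as fh:
        fh.write("PSF\n\n")
        fh.write("{:8d} !NTITLE\n".format(1))
        fh.write(" REMARKS bead-spring chromatin chain\n\n")
        fh.write("{:8d} !NATOM\n".format(n_beads))
        for i in range(n_beads):
            fh.write(
                "{:8d} {:<4s} {:<4d} {:<4s} {:<4s} {:<4s} "
                "{:10.6f} {:13.6f} {:11d}\n".format(
                    i + 1, "A", i + 1, "GEN", "C", "C", 0.0, 12.011, 0
                )
            )
        fh.write("\n{:8d} !NBOND: bonds\n".format(max(n_beads - 1, 0)))
        pairs = [(i + 1, i + 2) for i in range(n_beads - 1)]
        for row in range(0, len(pairs), 4):
            fh.write(
                "".join("{:8d}{:8d}".format(*p) for p in pairs[row : row + 4])
                + "\n"
            )
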