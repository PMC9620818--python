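"""Synthetic ground-truth models and contact matrices.

Generators for spring-constant matrices with the features real Hi-C maps
show — a backbone chain, TAD-like dense blocks on the diagonal and loop
contacts — plus noisy/sparsified contact matrices derived from them through
the exact forward map.  Every generated model is checked for validity
(positive semidefinite Laplacian of rank N-1) before release, so any test
or pipeline stage can consume these fixtures in place of downloaded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mapping import InvalidModelError, check_valid_k, forward_map

__all__ = [
    "SyntheticModelSpec",
    "make_rouse_chain",
    "make_tad_model",
    "make_noisy_contacts",
    "default_fixture_spec",
    "random_valid_k",
]


@dataclass
class SyntheticModelSpec:
    """Recipe for a synthetic polymer network.

    ``blocks`` are (start, end, k) with inclusive bead ranges; ``loops`` are
    (i, j, k) single extra springs.  ``noise`` is one of "none",
    "lognormal" (parameter ``noise_sigma``) or "binomial" (parameter
    ``depth`` counts per matrix element).
    """

    n_beads: int = 60
    backbone_k: float = 1.0
    blocks: tuple = ()
    loops: tuple = ()
    noise: str = "none"
    noise_sigma: float = 0.1
    depth: int = 10000
    null_bins: tuple = ()
    seed: int = 0


def make_rouse_chain(n_beads, k=1.0) -> np.ndarray:
    """Uniform bead-spring chain: k between consecutive beads only."""
    if n_beads < 2:
        raise ValueError("need at least 2 beads")
    if k <= 0:
        raise ValueError("backbone spring constant must be positive")
    K = np.zeros((n_beads, n_beads))
    idx = np.arange(n_beads - 1)
    K[idx, idx + 1] = K[idx + 1, idx] = k
    return K


def make_tad_model(spec: SyntheticModelSpec) -> np.ndarray:
    """Backbone + uniform intra-block couplings + loop springs.

    Raises :class:`InvalidModelError` if the resulting network is unstable
    (e.g. strongly negative couplings); reduce the couplings in that case.
    """
    K = make_rouse_chain(spec.n_beads, spec.backbone_k)
    for start, end, k in spec.blocks:
        if not (0 <= start <= end < spec.n_beads):
            raise ValueError(f"block ({start}, {end}) out of range")
        for i in range(start, end + 1):
            for j in range(i + 1, end + 1):
                K[i, j] += k
                K[j, i] += k
    # blocks also add to adjacent-bead pairs inside them; backbone stays
    for i, j, k in spec.loops:
        if i == j:
            raise ValueError("loop endpoints must differ")
        K[i, j] += k
        K[j, i] += k
    try:
        check_valid_k(K)
    except InvalidModelError as exc:
        raise InvalidModelError(
            f"generated model is invalid ({exc}); reduce the couplings"
        ) from exc
    return K


def make_noisy_contacts(K, noise="lognormal", noise_sigma=0.1, depth=10000,
                        null_bins=(), seed=0) -> np.ndarray:
    """Forward-map K and perturb the contact matrix.

    lognormal: elementwise multiply by exp(sigma*xi) on the upper triangle,
    mirror, clip to (0, 1], reset the diagonal to 1.  binomial: per-element
    counts at the stated depth, renormalized by the depth.  ``null_bins``
    rows/columns are zeroed afterwards.
    """
    C = forward_map(K)
    rng = np.random.default_rng(seed)
    n = C.shape[0]
    if noise == "lognormal":
        if noise_sigma > 0:
            xi = rng.standard_normal((n, n))
            xi = np.triu(xi, 1)
            xi = xi + xi.T
            C = C * np.exp(noise_sigma * xi)
    elif noise == "binomial":
        counts = rng.binomial(depth, np.clip(C, 0.0, 1.0))
        counts = np.triu(counts, 1)
        C = (counts + counts.T) / depth
    elif noise != "none":
        raise ValueError(f"unknown noise model {noise!r}")
    np.clip(C, 0.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    for b in null_bins:
        C[b, :] = 0.0
        C[:, b] = 0.0
    return C


def default_fixture_spec(noise_sigma=0.0) -> SyntheticModelSpec:
    """Standard benchmark model: N=60, two TAD blocks and one loop.

    Backbone k=1, blocks at beads 5-25 and 35-55 with intra-block k=0.3,
    a loop (10, 50) with k=0.5.  Exhibits two diagonal squares and a loop
    dot, and optimizes in seconds.
    """
    return SyntheticModelSpec(
        n_beads=60,
        backbone_k=1.0,
        blocks=((5, 25, 0.3), (35, 55, 0.3)),
        loops=((10, 50, 0.5),),
        noise="none" if noise_sigma == 0 else "lognormal",
        noise_sigma=noise_sigma,
    )


def random_valid_k(n_beads, seed=0, density=0.3, scale=0.5) -> np.ndarray:
    """Random valid network: backbone plus sparse positive extra springs.

    Used for property tests of the invertible transform; validity is
    guaranteed by construction (connected chain, non-negative couplings)
    and re-checked.
    """
    rng = np.random.default_rng(seed)
    K = make_rouse_chain(n_beads, k=1.0)
    extra = rng.random((n_beads, n_beads)) < density
    vals = rng.uniform(0.0, scale, (n_beads, n_beads))
    upper = np.triu(extra & (vals > 0), 2)
    K[upper] += vals[upper]
    K = np.triu(K, 1)
    K = K + K.T
    check_valid_k(K)
    return K
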