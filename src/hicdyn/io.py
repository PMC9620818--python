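"""Reading sparse contact dumps and dense matrix text files.

Input is the three-column ``pos1 pos2 score`` text produced by dumping an
intra-chromosomal region of a ``.hic`` file (e.g. with Juicer/Straw) at a
fixed binning resolution.  Scores may be raw or balanced counts; balancing
(ICE/KR) is an upstream concern and this module is agnostic to it.  The
pipeline needs a dense, symmetric, unit-diagonal contact-probability matrix,
which :func:`normalize_unit_diagonal` produces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawContactRecords",
    "NormalizedContactMatrix",
    "ContactDumpFormatError",
    "read_contact_dump",
    "assemble_dense",
    "normalize_unit_diagonal",
    "write_matrix",
    "read_matrix",
    "write_bin_track",
    "read_bin_track",
]


class ContactDumpFormatError(ValueError):
    """Raised when a dump line or a matrix file violates the expected format."""


@dataclass
class RawContactRecords:
    """Sparse upper-triangle contact records for one genomic region.

    Positions are bin *start* coordinates in bp, multiples of
    ``resolution_bp`` inside the half-open interval ``[start_bp, end_bp)``.
    """

    chrom: str
    start_bp: int
    end_bp: int
    resolution_bp: int
    pos1_bp: np.ndarray
    pos2_bp: np.ndarray
    score: np.ndarray
    n_dropped: int = 0

    @property
    def n_bins(self) -> int:
        return (self.end_bp - self.start_bp) // self.resolution_bp

    def __len__(self) -> int:
        return self.pos1_bp.size


@dataclass
class NormalizedContactMatrix:
    """Dense symmetric contact-probability matrix with unit diagonal.

    ``bin_valid[i]`` is False for null bins (no observed contact in row i);
    their rows and columns are identically zero.
    """

    C: np.ndarray
    bin_valid: np.ndarray
    resolution_bp: int = 1
    chrom: str = ""
    start_bp: int = 0
    end_bp: int = field(default=0)

    @property
    def n_bins(self) -> int:
        return self.C.shape[0]


def read_contact_dump(path, resolution_bp, region):
    """Read a whitespace-separated ``pos1 pos2 score`` dump.

    Parameters
    ----------
    path : str or Path
        Text file, one triplet per line.
    resolution_bp : int
        Bin width; positions must be multiples of it.
    region : tuple
        ``(chrom, start_bp, end_bp)``; triplets outside the half-open
        interval are discarded.

    Lines whose score is non-numeric or NaN are dropped (counted in
    ``n_dropped``).  Positions that are not multiples of the resolution raise
    :class:`ContactDumpFormatError` naming the offending line.
    """
    chrom, start_bp, end_bp = region
    pos1, pos2, score = [], [], []
    n_dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 3:
                raise ContactDumpFormatError(
                    f"{path}:{lineno}: expected 3 columns, got {len(parts)}"
                )
            try:
                p1 = int(float(parts[0]))
                p2 = int(float(parts[1]))
            except ValueError as exc:
                raise ContactDumpFormatError(
                    f"{path}:{lineno}: unparseable position"
                ) from exc
            if p1 % resolution_bp or p2 % resolution_bp:
                raise ContactDumpFormatError(
                    f"{path}:{lineno}: position not a multiple of "
                    f"{resolution_bp} bp"
                )
            try:
                s = float(parts[2])
            except ValueError:
                n_dropped += 1
                continue
            if not np.isfinite(s):
                n_dropped += 1
                continue
            if not (start_bp <= p1 < end_bp and start_bp <= p2 < end_bp):
                continue
            if p1 > p2:  # store upper triangle
                p1, p2 = p2, p1
            pos1.append(p1)
            pos2.append(p2)
            score.append(s)
    return RawContactRecords(
        chrom=chrom,
        start_bp=start_bp,
        end_bp=end_bp,
        resolution_bp=resolution_bp,
        pos1_bp=np.asarray(pos1, dtype=np.int64),
        pos2_bp=np.asarray(pos2, dtype=np.int64),
        score=np.asarray(score, dtype=float),
        n_dropped=n_dropped,
    )


def assemble_dense(records: RawContactRecords):
    """Place sparse records into a dense symmetric matrix.

    Unobserved pairs are zeros.  A bin whose entire row is zero is flagged
    null.  Returns ``(matrix, bin_valid)``.
    """
    n = records.n_bins
    if n < 3:
        raise ValueError(f"region spans {n} bins; at least 3 are required")
    i = (records.pos1_bp - records.start_bp) // records.resolution_bp
    j = (records.pos2_bp - records.start_bp) // records.resolution_bp
    mat = np.zeros((n, n))
    # duplicate triplets for the same pair accumulate
    np.add.at(mat, (i, j), records.score)
    mat = np.triu(mat) + np.triu(mat, 1).T
    bin_valid = mat.any(axis=1)
    return mat, bin_valid


def normalize_unit_diagonal(raw, bin_valid, *, resolution_bp=1, chrom="",
                            start_bp=0, end_bp=None) -> NormalizedContactMatrix:
    """Rescale a raw symmetric matrix so valid diagonal entries equal 1.

    Uses the unique symmetric diagonal rescaling
    ``C_ij = raw_ij / sqrt(raw_ii * raw_jj)``; values above 1 are clipped
    (contact probabilities cannot exceed 1) and null rows/columns stay zero.
    A valid bin with a zero diagonal gets the mean of the nonzero diagonal
    entries imputed, with a warning.
    """
    raw = np.asarray(raw, dtype=float)
    bin_valid = np.asarray(bin_valid, dtype=bool).copy()
    n = raw.shape[0]
    if end_bp is None:
        end_bp = start_bp + n * resolution_bp
    diag = np.diag(raw).copy()
    bad = bin_valid & (diag <= 0)
    if bad.any():
        nz = diag[diag > 0]
        fill = nz.mean() if nz.size else 1.0
        warnings.warn(
            f"{bad.sum()} valid bin(s) with zero diagonal; imputing with the "
            f"mean nonzero diagonal {fill:.6g}",
            stacklevel=2,
        )
        diag[bad] = fill
    scale = np.zeros(n)
    scale[bin_valid] = 1.0 / np.sqrt(diag[bin_valid])
    C = raw * np.outer(scale, scale)
    np.clip(C, 0.0, 1.0, out=C)
    idx = np.where(bin_valid)[0]
    C[idx, idx] = 1.0
    C[~bin_valid, :] = 0.0
    C[:, ~bin_valid] = 0.0
    return NormalizedContactMatrix(
        C=C,
        bin_valid=bin_valid,
        resolution_bp=resolution_bp,
        chrom=chrom,
        start_bp=start_bp,
        end_bp=end_bp,
    )


def write_matrix(path, matrix) -> None:
    """Write a dense matrix as tab-separated text at full double precision."""
    np.savetxt(path, np.atleast_2d(matrix), fmt="%.17g", delimiter="\t")


def read_matrix(path) -> np.ndarray:
    """Read a matrix written by :func:`write_matrix` (round-trips to <1e-12)."""
    try:
        mat = np.loadtxt(path, delimiter="\t", ndmin=2)
    except ValueError as exc:
        raise ContactDumpFormatError(f"{path}: ragged or non-numeric rows") from exc
    return mat


def write_bin_track(path, bin_valid) -> None:
    """One line per bin: 1 for valid, 0 for null."""
    np.savetxt(path, np.asarray(bin_valid, dtype=int), fmt="%d")


def read_bin_track(path) -> np.ndarray:
    return np.loadtxt(path, dtype=int, ndmin=1).astype(bool)
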