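"""Contact-matrix data model, standard-format I/O, replicate merging, ICE
balancing and per-sample coverage quality control.

A Hi-C experiment yields, per chromosome, a symmetric matrix of contact
counts between fixed-width genomic bins (100 kb by default throughout this
package).  This module holds that matrix as :class:`ContactMatrix` together
with the plumbing every downstream stage relies on:

* reading/writing HiC-Pro style sparse triplets (with a BED bin table) and
  dense TSV matrices,
* summing replicate matrices into a merged sample,
* iterative-correction (ICE) matrix balancing, which removes multiplicative
  per-bin biases by equalising row marginals,
* the coverage quality gate: a sample is analysable at a given resolution
  only if at least 80% of bins have more than 1000 contacts.

Conventions: bins are 0-based; genomic coordinates are 0-based half-open
(BED).  Only intra-chromosomal matrices are modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ContactMatrix",
    "BinTable",
    "QualityReport",
    "ICEResult",
    "HiCValidationError",
    "MatrixParseError",
    "read_contact_matrix",
    "write_contact_matrix",
    "merge_replicates",
    "ice_normalize",
    "coverage_quality_check",
]

_SYMMETRY_ATOL = 1e-9


class HiCValidationError(ValueError):
    """A contact matrix or bin table violates a structural invariant."""


class MatrixParseError(ValueError):
    """A matrix/bin file could not be parsed; message names the line."""


@dataclass
class ContactMatrix:
    """Symmetric non-negative intra-chromosomal contact matrix.

    Parameters
    ----------
    chrom : str
        Chromosome label.
    bin_size : int
        Bases per bin (e.g. 100000 for 100-kb resolution).
    counts : ndarray of shape (n_bins, n_bins)
        Raw counts (integers) or normalized contact values (reals).
    """

    chrom: str
    bin_size: int
    counts: np.ndarray
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.validate:
            self._check()

    def _check(self) -> None:
        c = self.counts
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise HiCValidationError(f"counts must be square, got shape {c.shape}")
        if c.shape[0] < 1:
            raise HiCValidationError("matrix must have at least one bin")
        if int(self.bin_size) < 1:
            raise HiCValidationError(f"bin_size must be >= 1, got {self.bin_size}")
        if not np.all(np.isfinite(c)):
            raise HiCValidationError("counts contain NaN or Inf")
        if np.any(c < 0):
            raise HiCValidationError("counts contain negative entries")
        if not np.allclose(c, c.T, atol=_SYMMETRY_ATOL, rtol=0):
            raise HiCValidationError("counts matrix is not symmetric")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def is_integer(self) -> bool:
        return np.issubdtype(self.counts.dtype, np.integer) or bool(
            np.all(self.counts == np.round(self.counts))
        )

    def marginals(self, include_diagonal: bool = True) -> np.ndarray:
        """Per-bin contact totals (row sums, diagonal counted once)."""
        m = self.counts.sum(axis=1)
        if not include_diagonal:
            m = m - np.diag(self.counts)
        return m

    def copy_with(self, counts: np.ndarray) -> "ContactMatrix":
        return ContactMatrix(self.chrom, self.bin_size, counts)

    def same_grid(self, other: "ContactMatrix") -> bool:
        return (
            self.chrom == other.chrom
            and self.bin_size == other.bin_size
            and self.n_bins == other.n_bins
        )


@dataclass
class BinTable:
    """Tiled genomic bins backing the rows/columns of a contact matrix.

    Rows are (chrom, start, end, bin_id) with 0-based half-open coordinates,
    contiguous 0-based bin ids, and ``end - start == bin_size`` for all but
    possibly the last bin.
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if len(self.starts) != len(self.ends) or len(self.starts) == 0:
            raise HiCValidationError("bin table must be non-empty and aligned")
        if np.any(self.ends <= self.starts):
            raise HiCValidationError("bin intervals must be non-empty")
        if np.any(self.starts[1:] != self.ends[:-1]):
            raise HiCValidationError("bins must tile the chromosome contiguously")

    @property
    def n_bins(self) -> int:
        return len(self.starts)

    @property
    def bin_size(self) -> int:
        return int(self.ends[0] - self.starts[0])

    @classmethod
    def from_grid(
        cls, chrom: str, bin_size: int, n_bins: int, chrom_length: int | None = None
    ) -> "BinTable":
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = starts + bin_size
        if chrom_length is not None:
            ends[-1] = min(ends[-1], chrom_length)
        return cls(chrom, starts, ends)

    def to_bed(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.starts,
                "end": self.ends,
                "bin_id": np.arange(self.n_bins),
            }
        )
        df.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def from_bed(cls, path: str | Path) -> "BinTable":
        try:
            df = pd.read_csv(path, sep="\t", header=None, comment="#")
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise MatrixParseError(f"cannot parse bin table {path}: {exc}") from exc
        if df.shape[1] < 4:
            raise MatrixParseError(f"bin table {path} needs 4 columns (chrom,start,end,bin_id)")
        chroms = df.iloc[:, 0].unique()
        if len(chroms) != 1:
            raise HiCValidationError("bin table must cover exactly one chromosome")
        order = np.argsort(df.iloc[:, 3].to_numpy())
        df = df.iloc[order]
        ids = df.iloc[:, 3].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise HiCValidationError("bin_ids must be contiguous and 0-based")
        return cls(str(chroms[0]), df.iloc[:, 1].to_numpy(), df.iloc[:, 2].to_numpy())


@dataclass
class QualityReport:
    """Outcome of the per-sample coverage gate."""

    n_bins: int
    n_passing_bins: int
    fraction_passing: float
    passed: bool
    threshold_contacts: int
    threshold_fraction: float


class ICEResult(NamedTuple):
    matrix: ContactMatrix
    bias: np.ndarray
    converged: bool
    n_iter: int


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_contact_matrix(
    matrix_path: str | Path,
    bins_path: str | Path | None = None,
    format: str = "hicpro_sparse",
    chrom: str = "chr1",
    bin_size: int = 100_000,
) -> ContactMatrix:
    """Read a contact matrix from HiC-Pro sparse triplets or a dense TSV.

    For ``hicpro_sparse``, ``bins_path`` (a 4-column BED bin table) is
    required; triplets may be upper-triangular (mirrored on read) or fully
    symmetric.  For ``dense_tsv``, ``chrom`` and ``bin_size`` identify the
    grid since the file carries no metadata.
    """
    if format == "hicpro_sparse":
        if bins_path is None:
            raise ValueError("hicpro_sparse format requires bins_path")
        table = BinTable.from_bed(bins_path)
        n = table.n_bins
        counts = np.zeros((n, n), dtype=np.float64)
        with open(matrix_path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t") if "\t" in line else line.split()
                if len(parts) != 3:
                    raise MatrixParseError(
                        f"{matrix_path}: line {lineno}: expected 3 fields, got {len(parts)}"
                    )
                try:
                    i, j, v = int(parts[0]), int(parts[1]), float(parts[2])
                except ValueError as exc:
                    raise MatrixParseError(
                        f"{matrix_path}: line {lineno}: malformed triplet {parts!r}"
                    ) from exc
                if not (0 <= i < n and 0 <= j < n):
                    raise IndexError(
                        f"{matrix_path}: line {lineno}: bin_id ({i},{j}) outside 0..{n - 1}"
                    )
                counts[i, j] = v
        upper = np.triu(counts, 1)
        lower = np.tril(counts, -1)
        if np.any(lower):
            if not np.allclose(lower.T, upper, atol=_SYMMETRY_ATOL, rtol=0):
                raise HiCValidationError(f"{matrix_path}: asymmetric sparse input")
        else:
            counts = counts + upper.T
        if np.all(counts == np.round(counts)):
            counts = counts.astype(np.int64)
        return ContactMatrix(table.chrom, table.bin_size, counts)
    elif format == "dense_tsv":
        arr = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
        if arr.shape[0] != arr.shape[1]:
            raise HiCValidationError(f"{matrix_path}: dense matrix not square: {arr.shape}")
        if not np.allclose(arr, arr.T, atol=_SYMMETRY_ATOL, rtol=0):
            raise HiCValidationError(f"{matrix_path}: dense matrix asymmetric beyond 1e-9")
        arr = 0.5 * (arr + arr.T)  # kill <=1e-9 write/read wobble
        if np.all(arr == np.round(arr)):
            arr = arr.astype(np.int64)
        return ContactMatrix(chrom, bin_size, arr)
    raise ValueError(f"unknown format {format!r}")


def write_contact_matrix(
    m: ContactMatrix,
    matrix_path: str | Path,
    bins_path: str | Path | None = None,
    format: str = "hicpro_sparse",
) -> None:
    """Write ``m`` as HiC-Pro sparse triplets (+ BED bin table) or dense TSV.

    Sparse output is upper-triangular (i <= j), tab-separated, zero entries
    omitted; integer matrices round-trip exactly.
    """
    if format == "hicpro_sparse":
        iu, ju = np.triu_indices(m.n_bins)
        vals = m.counts[iu, ju]
        keep = vals != 0
        with open(matrix_path, "w") as fh:
            if m.is_integer:
                for i, j, v in zip(iu[keep], ju[keep], vals[keep]):
                    fh.write(f"{i}\t{j}\t{int(round(v))}\n")
            else:
                for i, j, v in zip(iu[keep], ju[keep], vals[keep]):
                    fh.write(f"{i}\t{j}\t{float(v)!r}\n")
        if bins_path is not None:
            BinTable.from_grid(m.chrom, m.bin_size, m.n_bins).to_bed(bins_path)
    elif format == "dense_tsv":
        if m.is_integer:
            np.savetxt(matrix_path, m.counts.astype(np.int64), fmt="%d", delimiter="\t")
        else:
            np.savetxt(matrix_path, m.counts, fmt="%.17g", delimiter="\t")
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Merging, balancing, quality
# ---------------------------------------------------------------------------


def merge_replicates(ms: Sequence[ContactMatrix]) -> ContactMatrix:
    """Entrywise sum of replicate count matrices (one merged sample)."""
    if len(ms) == 0:
        raise ValueError("merge_replicates requires at least one matrix")
    first = ms[0]
    for m in ms[1:]:
        if not first.same_grid(m):
            raise HiCValidationError(
                "replicates disagree on chrom/bin_size/n_bins: "
                f"({first.chrom},{first.bin_size},{first.n_bins}) vs "
                f"({m.chrom},{m.bin_size},{m.n_bins})"
            )
    total = np.sum([m.counts for m in ms], axis=0)
    return ContactMatrix(first.chrom, first.bin_size, total)


def ice_normalize(
    m: ContactMatrix, tol: float = 1e-6, max_iter: int = 200
) -> ICEResult:
    """Iterative-correction (ICE) balancing of a raw contact matrix.

    Factorises the observed counts as ``counts[i,j] = bias[i] * bias[j] *
    W[i,j]`` and returns W with all non-zero-marginal rows summing to 1
    (unit mean row sum).  Convergence: maximum relative change of the bias
    vector below ``tol``.  All-zero rows (unmappable bins) keep bias 1, stay
    zero, and are excluded from the equal-row-sum contract.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    counts = np.asarray(m.counts, dtype=np.float64)
    n = counts.shape[0]
    marg = counts.sum(axis=1)
    nz = marg > 0
    if not np.any(nz):
        raise ValueError("cannot balance an all-zero matrix")

    bias = np.ones(n)
    W = counts.copy()
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        s = W.sum(axis=1)
        target = s[nz].mean()
        delta = np.ones(n)
        delta[nz] = s[nz] / target
        if np.max(np.abs(delta[nz] - 1.0)) < tol:
            converged = True
            break
        bias *= delta
        W = counts / np.outer(bias, bias)
        W[~nz, :] = 0.0
        W[:, ~nz] = 0.0
    if not converged:
        warnings.warn(
            f"ICE did not converge in {max_iter} iterations (chrom {m.chrom})",
            RuntimeWarning,
            stacklevel=2,
        )
    # scale so that non-zero rows sum to 1 exactly in expectation
    s = W.sum(axis=1)
    scale = s[nz].mean()
    if scale > 0:
        bias[nz] = bias[nz] * np.sqrt(scale)
        W = counts / np.outer(bias, bias)
        W[~nz, :] = 0.0
        W[:, ~nz] = 0.0
    bias[~nz] = 1.0  # unusable bins are flagged with unit bias
    W = 0.5 * (W + W.T)
    return ICEResult(m.copy_with(W), bias, converged, n_iter)


def coverage_quality_check(
    m: ContactMatrix,
    min_contacts: int = 1000,
    min_fraction: float = 0.80,
    include_diagonal: bool = True,
) -> QualityReport:
    """Coverage gate: does the sample have enough contacts per bin?

    A bin passes when its marginal contact count strictly exceeds
    ``min_contacts``; the sample passes when the fraction of passing bins is
    at least ``min_fraction``.
    """
    if m.n_bins == 0:
        raise ValueError("empty matrix")
    marg = m.marginals(include_diagonal=include_diagonal)
    n_pass = int(np.sum(marg > min_contacts))
    frac = n_pass / m.n_bins
    return QualityReport(
        n_bins=m.n_bins,
        n_passing_bins=n_pass,
        fraction_passing=frac,
        passed=frac >= min_fraction,
        threshold_contacts=min_contacts,
        threshold_fraction=min_fraction,
    )
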