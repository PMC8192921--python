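"""Square-grid reshaping and raw / central / Hahn moments of a matrix.

An encoded sequence of length ``n`` is written row-major into a
``k x k`` grid with ``k = ceil(sqrt(n))``; the trailing ``k*k - n`` cells
are zero.  From any real matrix three families of order-<=3 moments are
computed, each reported at the same fixed set of ten ``(a, b)`` index
pairs:

* raw moments      ``U_ab = sum_e sum_f e^a f^b M[e, f]`` (1-based e, f)
* central moments  ``V_ab = sum_e sum_f (e - xbar)^a (f - ybar)^b M[e, f]``
* Hahn moments     ``H_pq = sum_i sum_j M[i, j] htilde_p(i) htilde_q(j)``
  (0-based i, j) where ``htilde_p`` are weighted, orthonormalized discrete
  Hahn polynomial values on the grid ``0 .. N-1``.

The Hahn basis is orthonormal, so the full ``N x N`` moment transform is
exactly invertible — the grid can be reconstructed from its moments.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import ceil, isqrt

import numpy as np
from scipy.special import gammaln

from .sequence_io import EncodedSequence

#: The ten (a, b) order pairs reported for every moment family.
ORDER_PAIRS: tuple[tuple[int, int], ...] = (
    (0, 0), (0, 1), (1, 0), (1, 1), (2, 0),
    (0, 2), (2, 1), (1, 2), (0, 3), (3, 0),
)

FAMILIES = ("raw", "central", "hahn")


@dataclass(frozen=True)
class SquareGrid:
    """Row-major square embedding of an encoded sequence, zero-padded."""

    entries: np.ndarray
    fill_count: int

    @property
    def side(self) -> int:
        return self.entries.shape[0]


@dataclass(frozen=True)
class MomentSet:
    """Ten order-<=3 moment coefficients of one family for one matrix."""

    family: str
    coefficients: np.ndarray  # aligned with ORDER_PAIRS

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown moment family {self.family!r}")
        if self.coefficients.shape != (len(ORDER_PAIRS),):
            raise ValueError("expected exactly 10 coefficients")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("moment coefficients must be finite")

    def __getitem__(self, pair: tuple[int, int]) -> float:
        return float(self.coefficients[ORDER_PAIRS.index(pair)])


@dataclass(frozen=True)
class Centroid:
    x: float  # mean row coordinate (1-based)
    y: float  # mean column coordinate (1-based)


def reshape_to_grid(enc: EncodedSequence) -> SquareGrid:
    """Embed an encoded sequence into the smallest square grid holding it."""
    n = len(enc)
    if n < 4:
        raise ValueError(f"sequence too short to reshape: {n} < 4")
    k = isqrt(n)
    if k * k < n:
        k += 1
    padded = np.zeros(k * k, dtype=float)
    padded[:n] = enc.values
    return SquareGrid(entries=padded.reshape(k, k), fill_count=n)


def raw_moments(grid: np.ndarray | SquareGrid) -> MomentSet:
    """Raw moments U_ab at the ten order pairs, with 1-based indices."""
    m = _as_matrix(grid)
    k = m.shape[0]
    e = np.arange(1, k + 1, dtype=float)
    f = np.arange(1, m.shape[1] + 1, dtype=float)
    coeffs = np.array(
        [np.sum((e[:, None] ** a) * (f[None, :] ** b) * m) for a, b in ORDER_PAIRS]
    )
    return MomentSet(family="raw", coefficients=coeffs)


def central_moments(grid: np.ndarray | SquareGrid) -> tuple[Centroid, MomentSet]:
    """Centroid and central moments V_ab.

    For a zero-mass matrix the centroid falls back to the geometric center
    and all order >= 1 coefficients are zero; V00 always equals U00.
    """
    m = _as_matrix(grid)
    rows, cols = m.shape
    e = np.arange(1, rows + 1, dtype=float)
    f = np.arange(1, cols + 1, dtype=float)
    total = float(np.sum(m))
    if total != 0.0:
        xbar = float(np.sum(e[:, None] * m)) / total
        ybar = float(np.sum(f[None, :] * m)) / total
    else:
        xbar = (rows + 1) / 2
        ybar = (cols + 1) / 2
    de = e - xbar
    df = f - ybar
    coeffs = np.array(
        [np.sum((de[:, None] ** a) * (df[None, :] ** b) * m) for a, b in ORDER_PAIRS]
    )
    return Centroid(x=xbar, y=ybar), MomentSet(family="central", coefficients=coeffs)


@dataclass(frozen=True)
class HahnBasis:
    """Orthonormal discrete Hahn polynomial table on the grid 0 .. N-1.

    ``table[p, x]`` holds the weighted, norm-1 polynomial of order ``p``
    evaluated at ``x``; rows satisfy ``table @ table.T == I``.
    """

    N: int
    a: float
    b: float
    table: np.ndarray


def build_hahn_basis(N: int, a: float = 0.0, b: float = 0.0) -> HahnBasis:
    """Construct the orthonormal Hahn basis of side ``N``.

    The Hahn weight on ``x = 0 .. N-1`` is
    ``w(x) = C(a+x, x) * C(b+N-1-x, N-1-x)`` (uniform when ``a = b = 0``).
    Rows are built by the Stieltjes three-term recurrence for the
    orthonormal polynomials of that weight, with the square-rooted weight
    folded in so the table rows are orthonormal under the plain dot
    product.  Full reorthogonalization keeps the recurrence stable for the
    grid sides that long sequences produce.
    """
    if N < 2:
        raise ValueError(f"Hahn basis needs N >= 2, got {N}")
    if a < 0 or b < 0:
        raise ValueError("Hahn parameters a, b must be >= 0")
    return _hahn_basis_cached(int(N), float(a), float(b))


@lru_cache(maxsize=128)
def _hahn_basis_cached(N: int, a: float, b: float) -> HahnBasis:
    x = np.arange(N, dtype=float)
    log_w = (
        gammaln(a + x + 1) - gammaln(x + 1) - gammaln(a + 1)
        + gammaln(b + N - x) - gammaln(N - x) - gammaln(b + 1)
    )
    log_w -= log_w.max()  # scale out before exponentiating; rows get renormed
    sqrt_w = np.exp(0.5 * log_w)

    table = np.zeros((N, N))
    table[0] = sqrt_w / np.linalg.norm(sqrt_w)
    beta_prev = 0.0
    for p in range(1, N):
        prev = table[p - 1]
        alpha = float(np.dot(x * prev, prev))
        v = (x - alpha) * prev - (beta_prev * table[p - 2] if p >= 2 else 0.0)
        v -= table[:p].T @ (table[:p] @ v)  # reorthogonalize
        beta = float(np.linalg.norm(v))
        if beta == 0.0:
            raise ValueError(f"Hahn recurrence broke down at order {p} (N={N})")
        table[p] = v / beta
        beta_prev = beta
    return HahnBasis(N=N, a=a, b=b, table=table)


def hahn_moments(grid: np.ndarray | SquareGrid, basis: HahnBasis) -> MomentSet:
    """Hahn moments H_pq at the ten order pairs.

    Order pairs with ``p >= N`` or ``q >= N`` (possible only for grids
    smaller than 4x4) are reported as exact zeros: the basis has no such
    polynomial, and the slot must still exist for the fixed-length layout.
    """
    m = _as_matrix(grid)
    if m.shape[0] != basis.N or m.shape[1] != basis.N:
        raise ValueError(
            f"grid side {m.shape} does not match basis N={basis.N}"
        )
    full = basis.table @ m @ basis.table.T  # full[p, q] = H_pq
    coeffs = np.array(
        [full[p, q] if p < basis.N and q < basis.N else 0.0 for p, q in ORDER_PAIRS]
    )
    return MomentSet(family="hahn", coefficients=coeffs)


def hahn_transform(grid: np.ndarray, basis: HahnBasis) -> np.ndarray:
    """All N*N Hahn moments of a grid (used for the reconstruction check)."""
    m = _as_matrix(grid)
    return basis.table @ m @ basis.table.T


def hahn_reconstruct(moments: np.ndarray, basis: HahnBasis) -> np.ndarray:
    """Invert :func:`hahn_transform` via the transposed orthonormal basis."""
    return basis.table.T @ np.asarray(moments, dtype=float) @ basis.table


def _as_matrix(grid: np.ndarray | SquareGrid) -> np.ndarray:
    m = grid.entries if isinstance(grid, SquareGrid) else np.asarray(grid, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix entries must be finite")
    return m.astype(float, copy=False)
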