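"""Cell–cell similarity, NNLS decomposition, diffusion smoothing, ranks.

One denoising pass works as follows. Cells are correlated over the top
5% most dispersed peaks; correlations below the matrix mean are zeroed
and each row is normalised to sum 1, giving a row-stochastic similarity
matrix S. The measured ClockAcc vector c is decomposed by non-negative
least squares, x = argmin ||S x - c||, x >= 0 (Lawson–Hanson), then x
is relaxed by the diffusion iteration x <- w x + (1 - w) S x until the
update is below tolerance. S x at convergence is the smoothed ClockAcc;
its rank, scaled to [0, 1], is the relative mitotic age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.optimize
import scipy.sparse as sp
from scipy.stats import rankdata

from .io import PeakMatrix


@dataclass
class SimilarityMatrix:
    """Row-stochastic, non-negative cell–cell weight matrix.

    Rows that were all-zero after mean-thresholding (isolated cells)
    are replaced by identity rows so every row sums to 1.
    """

    weights: np.ndarray
    threshold_used: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n, m = self.weights.shape
        if n != m:
            raise ValueError("similarity matrix must be square")
        if np.any(self.weights < 0):
            raise ValueError("similarity weights must be non-negative")
        rs = self.weights.sum(axis=1)
        if not np.allclose(rs, 1.0, atol=1e-9):
            raise ValueError("similarity rows must sum to 1")

    @property
    def n_cells(self) -> int:
        return self.weights.shape[0]

    @classmethod
    def identity(cls, n: int) -> "SimilarityMatrix":
        return cls(np.eye(n), threshold_used=0.0)


def select_variable_peaks(
    matrix: PeakMatrix,
    fraction: float = 0.05,
    method: str = "fano",
) -> np.ndarray:
    """Top-dispersion peaks: the ceil(fraction * n_peaks) peaks with the
    highest variance/mean (Fano factor; ``method="cv"`` uses sd/mean).

    All-zero peaks have dispersion 0. Ties are broken toward the lower
    peak index so runs are reproducible.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    X = matrix.dense()
    mean = X.mean(axis=1)
    var = X.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "fano":
            disp = np.where(mean > 0, var / mean, 0.0)
        elif method == "cv":
            disp = np.where(mean > 0, np.sqrt(var) / mean, 0.0)
        else:
            raise ValueError(f"unknown dispersion method {method!r}")
    k = math.ceil(fraction * matrix.n_peaks)
    # stable sort on -disp keeps lower indices first among ties
    order = np.argsort(-disp, kind="stable")
    return np.sort(order[:k])


def _pearson_columns(X: np.ndarray) -> np.ndarray:
    """Pearson correlation between columns; constant columns get 0."""
    Xc = X - X.mean(axis=0, keepdims=True)
    sd = Xc.std(axis=0)
    ok = sd > 0
    Xn = np.zeros_like(Xc)
    Xn[:, ok] = Xc[:, ok] / (sd[ok] * np.sqrt(X.shape[0]))
    corr = Xn.T @ Xn
    corr[~ok, :] = 0.0
    corr[:, ~ok] = 0.0
    # exact unit diagonal for non-constant cells, 0 for constant ones
    np.fill_diagonal(corr, np.where(ok, 1.0, 0.0))
    return np.clip(corr, -1.0, 1.0)


def build_similarity(
    matrix: PeakMatrix,
    var_idx: np.ndarray,
    correlation: str = "pearson",
) -> SimilarityMatrix:
    """Mean-thresholded, row-normalised cell–cell correlation matrix.

    Correlation of cells over ``var_idx`` peaks; entries strictly below
    the mean of the full matrix (diagonal included) are set to zero;
    each row is divided by its sum. Spearman is available for heavy-
    tailed counts via ``correlation="spearman"``.
    """
    if matrix.n_cells < 2:
        raise ValueError("similarity undefined for a single cell")
    var_idx = np.asarray(var_idx, dtype=int)
    if var_idx.size < 2:
        raise ValueError("need >= 2 variable peaks to correlate cells")
    X = matrix.dense()[var_idx, :]
    if correlation == "spearman":
        X = np.apply_along_axis(rankdata, 0, X)
    elif correlation != "pearson":
        raise ValueError(f"unknown correlation {correlation!r}")
    corr = _pearson_columns(X)
    thr = float(corr.mean())
    W = np.where(corr < thr, 0.0, corr)
    W = np.maximum(W, 0.0)  # negative corr >= mean can only occur if thr < 0
    rs = W.sum(axis=1)
    dead = rs <= 0
    W[dead, :] = 0.0
    W[dead, dead] = 1.0
    rs = W.sum(axis=1)
    W = W / rs[:, None]
    return SimilarityMatrix(W, threshold_used=thr)


def nnls_solve(S: SimilarityMatrix | np.ndarray, c: np.ndarray) -> tuple[np.ndarray, float]:
    """Solve x = argmin ||S x - c||_2 subject to x >= 0.

    Returns (x, residual). Uses the Lawson–Hanson active-set algorithm.
    """
    A = S.weights if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    c = np.asarray(c, dtype=float)
    if not (np.all(np.isfinite(A)) and np.all(np.isfinite(c))):
        raise ValueError("non-finite entries in NNLS system")
    if A.shape[0] != c.shape[0]:
        raise ValueError("dimension mismatch between S and c")
    x, res = scipy.optimize.nnls(A, c)
    return x, float(res)


def diffusion_smooth(
    S: SimilarityMatrix | np.ndarray,
    x0: np.ndarray,
    w: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 100,
    mode: str = "reaction",
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Reaction-diffusion relaxation of x over the similarity graph.

    The default ``"reaction"`` mode iterates

        x <- w * x0 + (1 - w) * S @ x

    until max|Δx| < tol: each step blends the measured signal (the
    reaction source x0) with a similarity-weighted average of the
    current state. The fixed point x* = w (I - (1-w) S)^{-1} x0 borrows
    strength from neighbouring cells without collapsing to a constant,
    which is what makes the relaxation a regression rather than plain
    blurring. ``mode="pure"`` drops the source term
    (x <- w x + (1 - w) S x); its fixed point for a connected
    row-stochastic S is the constant consensus vector, so it is useful
    mainly as the degenerate averaging limit.

    Returns ``(x_final, smoothed, n_iters, converged)`` where
    ``smoothed = S @ x_final`` is the regressed measure. With a
    row-stochastic S every iterate (either mode) stays within
    [min(x0), max(x0)].
    """
    A = S.weights if isinstance(S, SimilarityMatrix) else np.asarray(S, dtype=float)
    if not 0 <= w < 1:
        raise ValueError(f"diffusion weight must be in [0, 1), got {w}")
    if mode not in ("reaction", "pure"):
        raise ValueError(f"mode must be 'reaction' or 'pure', got {mode!r}")
    x0 = np.asarray(x0, dtype=float)
    x = x0.copy()
    converged = False
    n_iters = 0
    source = w * x0
    for n_iters in range(1, max_iter + 1):
        if mode == "reaction":
            x_new = source + (1.0 - w) * (A @ x)
        else:
            x_new = w * x + (1.0 - w) * (A @ x)
        if not np.all(np.isfinite(x_new)) or np.max(np.abs(x_new)) > 1e12:
            raise FloatingPointError("diffusion iteration diverged")
        delta = float(np.max(np.abs(x_new - x)))
        x = x_new
        if delta < tol:
            converged = True
            break
    smoothed = A @ x
    return x, smoothed, n_iters, converged


def rank_normalize(values: np.ndarray, mode: str = "single_cell") -> np.ndarray:
    """Rank values and scale to [0, 1]; bulk mode reverses as 1 - rank.

    Ties receive average ranks; scaling is (rank - 1)/(n - 1) so the
    extremes hit exactly 0 and 1. A single value maps to 0.5.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values in rank_normalize")
    if mode not in ("single_cell", "bulk"):
        raise ValueError(f"mode must be single_cell or bulk, got {mode!r}")
    if values.size == 1:
        r = np.array([0.5])
    else:
        r = (rankdata(values, method="average") - 1.0) / (values.size - 1.0)
    return 1.0 - r if mode == "bulk" else r
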