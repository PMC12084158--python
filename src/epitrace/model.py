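"""The iterative age-inference model and its results object.

:class:`EpiTraceModel` bundles a peak count matrix with a reference set
of clock-like loci; ``fit()`` runs the full algorithm — ClockAcc
measurement, similarity-constrained NNLS, diffusion smoothing, rank
normalisation, and iterative expansion of the reference by Z-scored
peak–age correlation — and returns an :class:`EpiTraceResults` holding
per-cell ages, the per-iteration trace and diagnostics.

The functional entry points ``run_epitrace`` / ``run_epitrace_bulk``
wrap the model for script use.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .clockacc import ClockAccVector, compute_clockacc, reference_peaks
from .config import EpiTraceConfig
from .intervals import GenomicInterval, GenomicIntervalSet
from .io import PeakMatrix, write_bed
from .smoothing import (
    SimilarityMatrix,
    build_similarity,
    diffusion_smooth,
    nnls_solve,
    rank_normalize,
    select_variable_peaks,
)

logger = logging.getLogger(__name__)


@dataclass
class AgeEstimate:
    """One smoothing pass: raw ClockAcc, NNLS solution, smoothed values
    and the rank-normalised age in [0, 1]."""

    raw_clockacc: ClockAccVector
    nnls_solution: np.ndarray
    smoothed_clockacc: np.ndarray
    age: np.ndarray
    n_diffusion_iters: int
    converged: bool

    def __post_init__(self) -> None:
        if np.any(self.nnls_solution < 0):
            raise ValueError("NNLS solution must be non-negative")
        if np.any((self.age < 0) | (self.age > 1)):
            raise ValueError("ages must lie in [0, 1]")


@dataclass
class IterationState:
    """Snapshot of one outer iteration of the reference-expansion loop."""

    iteration: int
    ref_idx: np.ndarray
    age: AgeEstimate
    age_correlation_with_previous: float
    n_new_peaks: int


class EpiTraceResults:
    """Fitted ages with the iteration trace and run diagnostics.

    Attributes
    ----------
    age : ndarray
        Final per-cell (or per-sample) mitotic-age rank in [0, 1].
    trace : list of IterationState
        One entry per outer iteration (single entry in bulk mode).
    final_ref_idx : ndarray
        Peak indices of the final reference clock-like set.
    converged : bool
        Whether the outer loop reached the Spearman-rho criterion.
    """

    def __init__(
        self,
        model: "EpiTraceModel",
        trace: list[IterationState],
        converged: bool,
    ) -> None:
        self.model = model
        self.trace = trace
        self.converged = converged
        self.age = trace[-1].age.age
        self.final_ref_idx = trace[-1].ref_idx
        # cell ids come from the fitted matrix (QC filtering may drop cells)
        self.cell_ids = list(trace[-1].age.raw_clockacc.cell_ids)

    @property
    def n_iterations(self) -> int:
        return len(self.trace)

    @property
    def clockacc(self) -> np.ndarray:
        """Raw ClockAcc over the final reference set."""
        return self.trace[-1].age.raw_clockacc.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "epitrace_age": self.age,
                "clockacc": self.clockacc,
                "iteration_converged": self.converged,
            }
        )

    def expanded_reference(self) -> list[GenomicInterval]:
        return [self.model.matrix.peak_intervals[i] for i in self.final_ref_idx]

    def run_metadata(self) -> dict:
        return {
            "mode": self.model.matrix.mode,
            "n_cells": self.model.matrix.n_cells,
            "n_peaks": self.model.matrix.n_peaks,
            "config": self.model.config.to_dict(),
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "iterations": [
                {
                    "iteration": st.iteration,
                    "n_reference_peaks": int(len(st.ref_idx)),
                    "n_new_peaks": int(st.n_new_peaks),
                    "rho_vs_previous": (
                        None
                        if np.isnan(st.age_correlation_with_previous)
                        else float(st.age_correlation_with_previous)
                    ),
                    "diffusion_iters": st.age.n_diffusion_iters,
                    "diffusion_converged": st.age.converged,
                }
                for st in self.trace
            ],
        }

    def save(self, out_dir: str | Path) -> None:
        """Write ages.tsv, run_meta.json and expanded_reference.bed."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "ages.tsv", sep="\t", index=False)
        (out / "run_meta.json").write_text(json.dumps(self.run_metadata(), indent=2))
        write_bed(self.expanded_reference(), out / "expanded_reference.bed")

    def summary(self) -> str:
        lines = [
            "EpiTrace age estimation",
            "=" * 46,
            f"mode:                {self.model.matrix.mode}",
            f"cells/samples:       {self.model.matrix.n_cells}",
            f"peaks:               {self.model.matrix.n_peaks}",
            f"initial reference:   {len(self.trace[0].ref_idx)} peaks",
            f"final reference:     {len(self.final_ref_idx)} peaks",
            f"outer iterations:    {self.n_iterations}",
            f"converged:           {self.converged}",
            "-" * 46,
            "iter  n_ref  n_new  rho_vs_prev  diffusion",
        ]
        for st in self.trace:
            rho = st.age_correlation_with_previous
            rho_s = "   --" if np.isnan(rho) else f"{rho:5.3f}"
            lines.append(
                f"{st.iteration:4d}  {len(st.ref_idx):5d}  {st.n_new_peaks:5d}  "
                f"{rho_s:>11}  {st.age.n_diffusion_iters:4d} steps"
            )
        return "\n".join(lines)


def correlate_peaks_with_age(
    matrix: PeakMatrix, age: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Pearson r of each peak's counts vs the age vector, with the r
    values z-scored across peaks.

    Zero-variance peaks get r = 0. Raises if the age vector is constant.
    """
    age = np.asarray(age, dtype=float)
    if matrix.n_cells < 3:
        raise ValueError("need >= 3 cells to correlate peaks with age")
    if np.ptp(age) == 0:
        raise ValueError("age estimate degenerate: constant age vector")
    X = matrix.dense()
    a = age - age.mean()
    a_norm = np.sqrt((a**2).sum())
    Xc = X - X.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((Xc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ a) / (x_norm * a_norm)
    r = np.where(x_norm > 0, r, 0.0)
    sd = r.std()
    z = (r - r.mean()) / sd if sd > 0 else np.zeros_like(r)
    return r, z


def expand_reference(
    current_ref: np.ndarray,
    r: np.ndarray,
    z: np.ndarray,
    z_cutoff: float = 3.0,
    signed: bool = False,
) -> np.ndarray:
    """Union of the current reference with peaks whose scaled
    correlation exceeds ``z_cutoff`` (Z > 3 by default; 2.5 is the
    common alternative). Unless ``signed``, only positively
    age-correlated peaks are admitted — the method counts opened loci,
    so closing peaks are not clock-like in the same sense.
    """
    if z_cutoff <= 0:
        raise ValueError("z_cutoff must be positive")
    high = z > z_cutoff
    if not signed:
        high &= r > 0
    new = np.union1d(np.asarray(current_ref, dtype=int), np.flatnonzero(high))
    return new.astype(int)


class EpiTraceModel:
    """Mitotic-age model for an ATAC count matrix and clock-like loci.

    Parameters
    ----------
    matrix : PeakMatrix
        Peaks x cells counts (``mode="bulk"`` for bulk samples).
    clock_loci : GenomicIntervalSet
        Reference clock-like loci (e.g. ClockDML positions).
    config : EpiTraceConfig, optional

    Examples
    --------
    >>> model = EpiTraceModel(matrix, loci)
    >>> res = model.fit()
    >>> res.age              # per-cell rank age in [0, 1]
    >>> print(res.summary())
    """

    def __init__(
        self,
        matrix: PeakMatrix,
        clock_loci: GenomicIntervalSet,
        config: EpiTraceConfig | None = None,
    ) -> None:
        self.matrix = matrix
        self.clock_loci = clock_loci
        self.config = config or EpiTraceConfig()
        self.initial_ref_idx = reference_peaks(matrix, clock_loci)

    @classmethod
    def from_files(
        cls,
        mtx_path,
        peaks_bed_path,
        barcodes_path,
        clock_bed_path,
        config: EpiTraceConfig | None = None,
        mode: str = "single_cell",
    ) -> "EpiTraceModel":
        from .io import read_bed, read_peak_matrix

        matrix = read_peak_matrix(mtx_path, peaks_bed_path, barcodes_path, mode=mode)
        loci = read_bed(clock_bed_path)
        return cls(matrix, loci, config=config)

    # ------------------------------------------------------------------
    def _qc_matrix(self) -> PeakMatrix:
        cfg = self.config
        if cfg.min_fragments <= 0:
            return self.matrix
        depth = np.asarray(self.matrix.counts.sum(axis=0)).ravel()
        keep = depth >= cfg.min_fragments
        if keep.all():
            return self.matrix
        logger.info("QC: dropping %d cells below %d fragments", (~keep).sum(), cfg.min_fragments)
        return PeakMatrix(
            self.matrix.counts[:, keep],
            self.matrix.peak_intervals,
            [c for c, k in zip(self.matrix.cell_ids, keep) if k],
            mode=self.matrix.mode,
        )

    def _one_pass(
        self, matrix: PeakMatrix, S: SimilarityMatrix, ref_idx: np.ndarray, mode: str
    ) -> AgeEstimate:
        cfg = self.config
        cacc = compute_clockacc(
            matrix, ref_idx, censor=cfg.clockacc_censor,
            censor_quantile=cfg.clockacc_censor_quantile,
        )
        x, _res = nnls_solve(S, cacc.values)
        if cfg.resolve_nnls_in_loop:
            x, smoothed, n_it, conv = self._diffuse_with_resolve(S, x, cacc.values)
        else:
            x, smoothed, n_it, conv = diffusion_smooth(
                S, x, w=cfg.diffusion_w, tol=cfg.diffusion_tol,
                max_iter=cfg.diffusion_max_iter, mode=cfg.diffusion_mode,
            )
        # snap to 12 relative digits so FP dust from column ordering cannot
        # flip ranks of effectively tied cells
        scale = max(float(np.max(np.abs(smoothed))), 1.0)
        smoothed = np.round(smoothed / scale, 12) * scale
        age = rank_normalize(smoothed, mode=mode)
        return AgeEstimate(
            raw_clockacc=cacc,
            nnls_solution=x,
            smoothed_clockacc=smoothed,
            age=age,
            n_diffusion_iters=n_it,
            converged=conv,
        )

    def _diffuse_with_resolve(
        self, S: SimilarityMatrix, x: np.ndarray, c: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, int, bool]:
        """Variant that re-solves NNLS against the diffused target each step."""
        cfg = self.config
        converged = False
        n_it = 0
        for n_it in range(1, cfg.diffusion_max_iter + 1):
            target = cfg.diffusion_w * c + (1 - cfg.diffusion_w) * (S.weights @ c)
            x_new, _ = nnls_solve(S, target)
            delta = float(np.max(np.abs(x_new - x)))
            x, c = x_new, target
            if delta < cfg.diffusion_tol:
                converged = True
                break
        return x, S.weights @ x, n_it, converged

    def fit(self) -> EpiTraceResults:
        """Run the iterative algorithm on single-cell data.

        Iterates ClockAcc -> NNLS -> diffusion -> rank -> peak-age
        correlation -> reference expansion until the Spearman rho
        between successive age vectors exceeds the convergence
        threshold or the iteration cap is reached. The rank is never
        reversed for single-cell data.
        """
        cfg = self.config
        matrix = self._qc_matrix()
        var_idx = select_variable_peaks(
            matrix, fraction=cfg.similarity_fraction, method=cfg.dispersion_method
        )
        S = build_similarity(matrix, var_idx, correlation=cfg.similarity_correlation)
        ref_idx = self.initial_ref_idx.copy()
        trace: list[IterationState] = []
        prev_age: np.ndarray | None = None
        converged = False
        for it in range(1, cfg.max_outer_iter + 1):
            est = self._one_pass(matrix, S, ref_idx, mode="single_cell")
            rho = (
                float(spearmanr(prev_age, est.age).statistic)
                if prev_age is not None
                else float("nan")
            )
            n_new = 0
            next_ref = ref_idx
            if it < cfg.max_outer_iter and not (
                prev_age is not None and rho > cfg.convergence_rho
            ):
                r, z = correlate_peaks_with_age(matrix, est.age)
                next_ref = expand_reference(
                    ref_idx, r, z, z_cutoff=cfg.z_cutoff, signed=cfg.signed_expansion
                )
                n_new = int(len(next_ref) - len(ref_idx))
            trace.append(
                IterationState(
                    iteration=it,
                    ref_idx=ref_idx,
                    age=est,
                    age_correlation_with_previous=rho,
                    n_new_peaks=n_new,
                )
            )
            logger.info(
                "iteration %d: %d reference peaks, %d new, rho vs previous = %s",
                it, len(ref_idx), n_new, f"{rho:.4f}" if not np.isnan(rho) else "--",
            )
            if prev_age is not None and rho > cfg.convergence_rho:
                converged = True
                break
            prev_age = est.age
            ref_idx = next_ref
        return EpiTraceResults(self, trace, converged)

    def fit_bulk(self) -> EpiTraceResults:
        """Single smoothing pass for bulk samples; rank reversed as 1 - rank."""
        cfg = self.config
        matrix = self.matrix
        if matrix.n_cells < 2:
            raise ValueError("bulk mode needs >= 2 samples")
        var_idx = select_variable_peaks(
            matrix, fraction=cfg.similarity_fraction, method=cfg.dispersion_method
        )
        S = build_similarity(matrix, var_idx, correlation=cfg.similarity_correlation)
        mode = "bulk" if cfg.bulk_reverse else "single_cell"
        est = self._one_pass(matrix, S, self.initial_ref_idx, mode=mode)
        state = IterationState(
            iteration=1,
            ref_idx=self.initial_ref_idx,
            age=est,
            age_correlation_with_previous=float("nan"),
            n_new_peaks=0,
        )
        return EpiTraceResults(self, [state], converged=True)


def run_epitrace(
    matrix: PeakMatrix,
    loci: GenomicIntervalSet,
    config: EpiTraceConfig | None = None,
) -> EpiTraceResults:
    """Fit the iterative single-cell age model (functional wrapper)."""
    return EpiTraceModel(matrix, loci, config=config).fit()


def run_epitrace_bulk(
    matrix: PeakMatrix,
    loci: GenomicIntervalSet,
    config: EpiTraceConfig | None = None,
) -> EpiTraceResults:
    """Single-pass bulk age estimation with rank reversal."""
    return EpiTraceModel(matrix, loci, config=config).fit_bulk()
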