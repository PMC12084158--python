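"""Synthetic data with planted ground truth for every pipeline input.

The single-cell generator emulates the core premise of clock-like
accessibility: each cell carries a latent mitotic age in [0, 1], and
the probability that a clock-like reference peak is open in a cell
rises linearly with that age (from ``p0`` at age 0 to ``p1`` at age 1;
a logistic curve is available). Open entries receive
Poisson-distributed read counts, so shallow sequencing produces
dropout of truly open loci — the depth parameter controls how often an
open peak is actually seen.

Beyond the reference peaks, two classes of non-clock peaks shape the
cell–cell similarity structure:

* *age-responsive program peaks* open in a fixed order along the age
  axis — peak j is open once a cell's age exceeds a per-peak threshold
  τ_j (with a small state-flip rate). Cells of similar age therefore
  share open-peak programs and correlate, which is exactly the premise
  that lets similarity-based smoothing work, and gives the iterative
  reference expansion genuinely age-correlated peaks to recruit that
  are not part of the initial reference;
* *cell-type block peaks* open with per-block probabilities drawn once
  per peak, independent of age (three latent blocks by default),
  providing the confounding phenotype structure.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .intervals import GenomicInterval, GenomicIntervalSet
from .io import BetaMatrix, PeakMatrix

_PEAK_SPACING = 2_000   # bp between synthetic peak starts
_PEAK_WIDTH = 500


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated dataset."""

    true_age: np.ndarray                 # latent age per cell/sample in [0, 1]
    clock_peak_ids: np.ndarray           # indices of planted clock peaks/loci
    opening_curve: dict                  # parameters of age -> open probability
    seed: int
    blocks: np.ndarray | None = None     # latent cell-type block per cell
    slopes: np.ndarray | None = None     # per-locus beta slopes (beta generator)


def _make_peaks(n_peaks: int, chrom: str = "chr1") -> list[GenomicInterval]:
    return [
        GenomicInterval(chrom, i * _PEAK_SPACING, i * _PEAK_SPACING + _PEAK_WIDTH)
        for i in range(n_peaks)
    ]


def _opening_prob(age: np.ndarray, p0: float, p1: float, curve: str) -> np.ndarray:
    if curve == "linear":
        return p0 + (p1 - p0) * age
    if curve == "logistic":
        z = 8.0 * (age - 0.5)
        return p0 + (p1 - p0) / (1.0 + np.exp(-z))
    raise ValueError(f"unknown opening curve {curve!r}")


def simulate_sc_atac(
    n_cells: int = 500,
    n_peaks: int = 2000,
    n_clock_peaks: int = 200,
    depth: float = 2.3,
    seed: int = 0,
    p0: float = 0.1,
    p1: float = 0.9,
    n_blocks: int = 3,
    curve: str = "linear",
    n_age_peaks: int = 100,
    age_peak_gain: float = 2.0,
    flip_rate: float = 0.05,
    block_open_range: tuple[float, float] = (0.5, 0.8),
) -> tuple[PeakMatrix, GenomicIntervalSet, SyntheticTruth]:
    """Single-cell ATAC counts with a planted latent mitotic age.

    Clock (reference) peak p is open in cell c with probability
    ``p0 + (p1 - p0) * age_c``; open entries draw counts from
    Poisson(depth), so an open peak escapes detection with probability
    exp(-depth) (~10% at the default depth of 2.3).

    ``n_age_peaks`` non-reference peaks form an ordered opening
    program: peak j is open in cells older than a threshold
    τ_j ~ Uniform(0, 1), with each open/closed state flipped with
    probability ``flip_rate``; their read rate is
    ``depth * age_peak_gain`` (strong program peaks). The remaining
    peaks are cell-type block peaks with per-block open probabilities
    drawn from ``block_open_range``. The returned clock-loci BED
    overlaps exactly the planted clock peaks.
    """
    if not 0 < n_clock_peaks < n_peaks:
        raise ValueError("need 0 < n_clock_peaks < n_peaks")
    if n_clock_peaks + n_age_peaks > n_peaks:
        raise ValueError("n_clock_peaks + n_age_peaks must not exceed n_peaks")
    if n_cells < 2:
        raise ValueError("need >= 2 cells")
    rng = np.random.default_rng(seed)
    true_age = rng.uniform(0.0, 1.0, size=n_cells)
    blocks = rng.integers(0, n_blocks, size=n_cells)
    clock_ids = np.sort(rng.choice(n_peaks, size=n_clock_peaks, replace=False))

    X = np.zeros((n_peaks, n_cells), dtype=np.int64)

    p_open = _opening_prob(true_age, p0, p1, curve)          # per cell
    open_clock = rng.random((n_clock_peaks, n_cells)) < p_open[None, :]
    reads = rng.poisson(depth, size=open_clock.shape)
    X[clock_ids, :] = np.where(open_clock, reads, 0)

    other_ids = np.setdiff1d(np.arange(n_peaks), clock_ids)
    resp_ids = other_ids[:n_age_peaks]
    block_ids = other_ids[n_age_peaks:]

    tau = rng.uniform(0.0, 1.0, size=n_age_peaks)
    open_resp = (true_age[None, :] > tau[:, None]) ^ (
        rng.random((n_age_peaks, n_cells)) < flip_rate
    )
    reads_resp = rng.poisson(depth * age_peak_gain, size=open_resp.shape)
    X[resp_ids, :] = np.where(open_resp, reads_resp, 0)

    lo, hi = block_open_range
    block_probs = rng.uniform(lo, hi, size=(len(block_ids), n_blocks))
    p_block = block_probs[:, blocks]                          # peak x cell
    open_block = rng.random(p_block.shape) < p_block
    reads_block = rng.poisson(depth, size=open_block.shape)
    X[block_ids, :] = np.where(open_block, reads_block, 0)

    peaks = _make_peaks(n_peaks)
    loci = GenomicIntervalSet(
        [
            GenomicInterval(peaks[i].chrom, peaks[i].start + 200, peaks[i].start + 300)
            for i in clock_ids
        ],
        name="synthetic_clock_loci",
    )
    matrix = PeakMatrix(
        sp.csc_matrix(X),
        peaks,
        [f"cell_{i:05d}" for i in range(n_cells)],
        mode="single_cell",
    )
    truth = SyntheticTruth(
        true_age=true_age,
        clock_peak_ids=clock_ids,
        opening_curve={
            "curve": curve,
            "p0": p0,
            "p1": p1,
            "depth": depth,
            "age_peak_ids": resp_ids,
            "age_peak_thresholds": tau,
            "flip_rate": flip_rate,
        },
        seed=seed,
        blocks=blocks,
    )
    return matrix, loci, truth


def simulate_bulk_series(
    n_samples: int = 8,
    monotone: bool = True,
    seed: int = 0,
    n_peaks: int = 2000,
    n_clock_peaks: int = 500,
    depth: float = 20.0,
    p0: float = 0.1,
    p1: float = 0.9,
) -> tuple[PeakMatrix, GenomicIntervalSet, SyntheticTruth]:
    """Bulk ATAC series with a planted opening fraction per sample.

    With ``monotone=True`` the clock-peak opening fraction rises
    linearly from p0 to p1 across the sample index; otherwise each
    sample draws an opening fraction at random. Counts are deep
    (1 + Poisson(depth) on open peaks), so there is no dropout of open
    peaks.

    In a pooled population, mitotic ageing *reduces* the heterogeneity
    of clock-locus accessibility: a young population's cells open
    diverse subsets of the loci, so the pooled sample covers many of
    them, while an old population converges on fewer. The planted
    mitotic age in ``truth.true_age`` therefore *decreases* with the
    opening fraction — which is why bulk rank estimates are reversed as
    1 − rank to recover sample age.
    """
    if n_samples < 2:
        raise ValueError("need >= 2 bulk samples")
    rng = np.random.default_rng(seed)
    if monotone:
        frac = np.linspace(p0, p1, n_samples)
    else:
        frac = rng.uniform(p0, p1, size=n_samples)
    clock_ids = np.arange(n_clock_peaks)

    X = np.zeros((n_peaks, n_samples), dtype=np.int64)
    open_clock = rng.random((n_clock_peaks, n_samples)) < frac[None, :]
    X[clock_ids, :] = np.where(
        open_clock, 1 + rng.poisson(depth, size=open_clock.shape), 0
    )
    other = np.arange(n_clock_peaks, n_peaks)
    p_other = rng.uniform(0.2, 0.8, size=(len(other), 1))
    open_other = rng.random((len(other), n_samples)) < p_other
    X[other, :] = np.where(open_other, 1 + rng.poisson(depth, size=open_other.shape), 0)

    peaks = _make_peaks(n_peaks)
    loci = GenomicIntervalSet(
        [
            GenomicInterval(peaks[i].chrom, peaks[i].start + 200, peaks[i].start + 300)
            for i in clock_ids
        ],
        name="synthetic_clock_loci",
    )
    matrix = PeakMatrix(
        sp.csc_matrix(X),
        peaks,
        [f"sample_{i:02d}" for i in range(n_samples)],
        mode="bulk",
    )
    mitotic_age = 1.0 - (frac - p0) / (p1 - p0)
    truth = SyntheticTruth(
        true_age=mitotic_age,
        clock_peak_ids=clock_ids,
        opening_curve={
            "curve": "linear", "p0": p0, "p1": p1, "depth": depth,
            "opening_fraction": frac,
        },
        seed=seed,
    )
    return matrix, loci, truth


def simulate_beta(
    n_loci: int = 200,
    n_samples: int = 24,
    n_clock_loci: int = 40,
    noise_sd: float = 0.02,
    seed: int = 0,
    low_coverage_fraction: float = 0.25,
) -> tuple[BetaMatrix, SyntheticTruth]:
    """CpG beta matrix with planted age-linear clock loci.

    Donor ages are Uniform(20, 70) years. Clock loci split into a
    rising family (beta = 0.25 + 0.5 * (age - 20)/50 + noise) and a
    falling family (beta = 0.75 - 0.5 * (age - 20)/50 + noise), with
    small per-locus slope jitter; betas are clipped to [0, 1]. The
    remaining loci are age-independent noise around a random baseline.
    A ``low_coverage_fraction`` of loci draws coverage <= 30x so the
    strict > 30x filter of the DNAm age model has something to remove.
    """
    if not 0 < n_clock_loci <= n_loci:
        raise ValueError("need 0 < n_clock_loci <= n_loci")
    if n_samples < 3:
        raise ValueError("need >= 3 samples")
    rng = np.random.default_rng(seed)
    ages = rng.uniform(20.0, 70.0, size=n_samples)
    t = (ages - 20.0) / 50.0                                  # in [0, 1]

    clock_ids = np.arange(n_clock_loci)
    n_fall = n_clock_loci // 2
    signs = np.array([-1.0] * n_fall + [1.0] * (n_clock_loci - n_fall))
    jitter = rng.uniform(0.9, 1.1, size=n_clock_loci)
    slopes = signs * 0.5 * jitter
    base = np.where(signs > 0, 0.25, 0.75)

    beta = np.empty((n_loci, n_samples))
    beta[clock_ids, :] = base[:, None] + slopes[:, None] * t[None, :]
    other = np.arange(n_clock_loci, n_loci)
    beta[other, :] = rng.uniform(0.2, 0.8, size=(len(other), 1))
    if noise_sd > 0:
        beta[clock_ids, :] += rng.normal(0.0, noise_sd, size=(n_clock_loci, n_samples))
    beta[other, :] += rng.normal(0.0, 0.05, size=(len(other), n_samples))
    beta = np.clip(beta, 0.0, 1.0)

    n_low = int(round(low_coverage_fraction * n_loci))
    coverage = np.empty(n_loci)
    low = rng.choice(n_loci, size=n_low, replace=False)
    coverage[:] = rng.uniform(31.0, 100.0, size=n_loci)
    coverage[low] = rng.uniform(5.0, 30.0, size=n_low)

    loci = [GenomicInterval("chr1", 1_000 + 100 * i, 1_001 + 100 * i) for i in range(n_loci)]
    bm = BetaMatrix(
        beta=beta,
        locus_intervals=loci,
        sample_ids=[f"donor_{i:02d}" for i in range(n_samples)],
        sample_ages=ages,
        coverage=coverage,
    )
    truth = SyntheticTruth(
        true_age=ages,
        clock_peak_ids=clock_ids,
        opening_curve={"family_split": n_fall, "noise_sd": noise_sd},
        seed=seed,
        slopes=slopes,
    )
    return bm, truth
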