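import numpy as np
import pytest
from scipy.stats import pearsonr, spearmanr

from epitrace.clockacc import compute_clockacc, reference_peaks
from epitrace.config import EpiTraceConfig
from epitrace.intervals import GenomicInterval, GenomicIntervalSet
from epitrace.io import PeakMatrix
from epitrace.model import (
    EpiTraceModel,
    correlate_peaks_with_age,
    expand_reference,
    run_epitrace,
    run_epitrace_bulk,
)
from epitrace.smoothing import rank_normalize
from epitrace.synthetic import simulate_bulk_series, simulate_sc_atac

import scipy.sparse as sp

from conftest import make_matrix


class TestCorrelatePeaksWithAge:
    def test_self_correlated_peak_has_r_one_and_max_z(self):
        age = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        X = np.vstack([age, np.array([1, 0, 2, 0, 1.0]), np.array([3, 3, 3, 3, 3.0])])
        r, z = correlate_peaks_with_age(make_matrix(X), age)
        assert r[0] == pytest.approx(1.0)
        assert z[0] == z.max()
        assert r[2] == 0.0  # constant peak

    def test_hand_computed_pearson(self):
        age = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        counts = np.array([0.0, 1, 1, 2, 4])
        X = np.vstack([counts, np.zeros(5)])
        r, _ = correlate_peaks_with_age(make_matrix(X), age)
        assert r[0] == pytest.approx(pearsonr(counts, age).statistic, abs=1e-12)
        assert r[0] == pytest.approx(0.9383, abs=5e-5)

    def test_z_scores_standardised(self, rng):
        X = rng.poisson(2.0, size=(50, 10)).astype(float)
        age = rng.uniform(size=10)
        _, z = correlate_peaks_with_age(make_matrix(X), age)
        assert abs(z.mean()) < 1e-9
        assert z.std() == pytest.approx(1.0, abs=1e-9)

    def test_constant_age_rejected(self, small_matrix):
        with pytest.raises(ValueError, match="degenerate"):
            correlate_peaks_with_age(small_matrix, np.full(5, 0.3))


class TestExpandReference:
    def test_no_peak_above_cutoff_is_fixed_point(self):
        ref = np.array([1, 4])
        r = np.array([0.1, 0.2, 0.1, 0.0, 0.3])
        z = np.array([0.5, 1.0, 0.5, -1.0, 2.0])
        assert expand_reference(ref, r, z).tolist() == [1, 4]

    def test_planted_filter_oracle(self, rng):
        ref = np.array([0, 1])
        r = rng.uniform(-1, 1, size=10)
        z = (r - r.mean()) / r.std()
        got = expand_reference(ref, r, z, z_cutoff=0.5)
        expected = sorted(set(ref) | {i for i in range(10) if z[i] > 0.5 and r[i] > 0})
        assert got.tolist() == expected

    def test_negative_r_excluded_unless_signed(self):
        ref = np.array([0])
        r = np.array([0.0, -0.9])
        z = np.array([0.0, 5.0])
        assert expand_reference(ref, r, z).tolist() == [0]
        assert expand_reference(ref, r, z, signed=True).tolist() == [0, 1]

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError, match="z_cutoff"):
            expand_reference(np.array([0]), np.zeros(1), np.zeros(1), z_cutoff=0)


def _loci_for(matrix, peak_ids):
    return GenomicIntervalSet(
        [
            GenomicInterval(
                matrix.peak_intervals[i].chrom,
                matrix.peak_intervals[i].start + 10,
                matrix.peak_intervals[i].start + 20,
            )
            for i in peak_ids
        ]
    )


class TestRunEpitrace:
    def test_single_outer_iteration_equals_one_pass(self):
        m, loci, truth = simulate_sc_atac(n_cells=60, n_peaks=300, n_clock_peaks=40, seed=3)
        cfg = EpiTraceConfig(max_outer_iter=1)
        res = run_epitrace(m, loci, config=cfg)
        assert res.n_iterations == 1
        full = run_epitrace(m, loci)
        np.testing.assert_allclose(res.age, full.trace[0].age.age)

    def test_recovers_planted_age(self):
        m, loci, truth = simulate_sc_atac(seed=1)  # 500 cells, 2000 peaks
        res = run_epitrace(m, loci)
        rho = spearmanr(res.age, truth.true_age).statistic
        assert rho >= 0.8

    def test_deterministic_across_runs(self):
        m, loci, _ = simulate_sc_atac(n_cells=80, n_peaks=400, n_clock_peaks=50, seed=5)
        a = run_epitrace(m, loci).age
        b = run_epitrace(m, loci).age
        assert np.array_equal(a, b)

    def test_cell_permutation_permutes_ages(self):
        m, loci, _ = simulate_sc_atac(n_cells=80, n_peaks=400, n_clock_peaks=50, seed=5)
        res = run_epitrace(m, loci)
        rng = np.random.default_rng(0)
        perm = rng.permutation(m.n_cells)
        m_perm = PeakMatrix(
            m.counts[:, perm],
            m.peak_intervals,
            [m.cell_ids[i] for i in perm],
            mode=m.mode,
        )
        res_perm = run_epitrace(m_perm, loci)
        np.testing.assert_allclose(res_perm.age, res.age[perm], atol=1e-9)

    def test_reference_size_non_decreasing(self):
        m, loci, _ = simulate_sc_atac(n_cells=150, n_peaks=600, n_clock_peaks=60, seed=2)
        res = run_epitrace(m, loci, config=EpiTraceConfig(convergence_rho=1.1, max_outer_iter=4))
        sizes = [len(st.ref_idx) for st in res.trace]
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))
        assert set(res.trace[0].ref_idx.tolist()) <= set(res.final_ref_idx.tolist())

    def test_identity_similarity_degenerates_to_clockacc_rank(self, monkeypatch):
        # with S = I the whole machinery must reproduce the raw ClockAcc rank
        m, loci, _ = simulate_sc_atac(n_cells=40, n_peaks=200, n_clock_peaks=30, seed=4)
        from epitrace import model as model_mod
        from epitrace.smoothing import SimilarityMatrix

        monkeypatch.setattr(
            model_mod,
            "build_similarity",
            lambda matrix, var_idx, correlation="pearson": SimilarityMatrix.identity(
                matrix.n_cells
            ),
        )
        cfg = EpiTraceConfig(max_outer_iter=1)
        res = run_epitrace(m, loci, config=cfg)
        ref = reference_peaks(m, loci)
        expected = rank_normalize(compute_clockacc(m, ref).values)
        np.testing.assert_allclose(res.age, expected, atol=1e-6)

    def test_zero_count_cells_retained_with_age(self):
        m, loci, _ = simulate_sc_atac(n_cells=50, n_peaks=200, n_clock_peaks=30, seed=6)
        X = m.dense()
        X[:, 0] = 0.0  # silence one cell entirely
        m2 = PeakMatrix(sp.csc_matrix(X), m.peak_intervals, m.cell_ids)
        res = run_epitrace(m2, loci)
        assert len(res.age) == 50
        assert np.isfinite(res.age).all()

    def test_stable_under_reference_subsampling(self):
        m, loci, _ = simulate_sc_atac(seed=1)
        full = run_epitrace(m, loci)
        rng = np.random.default_rng(1)
        keep = rng.random(len(loci)) > 0.1  # drop a random 10% of loci
        sub_loci = GenomicIntervalSet([iv for iv, k in zip(loci, keep) if k])
        sub = run_epitrace(m, sub_loci)
        assert spearmanr(full.age, sub.age).statistic >= 0.9

    def test_run_metadata_records_config_and_trace(self):
        m, loci, _ = simulate_sc_atac(n_cells=40, n_peaks=200, n_clock_peaks=30, seed=7)
        res = run_epitrace(m, loci)
        meta = res.run_metadata()
        assert meta["config"]["diffusion_w"] == 0.5
        assert len(meta["iterations"]) == res.n_iterations

    def test_results_save_outputs(self, tmp_path):
        m, loci, _ = simulate_sc_atac(n_cells=40, n_peaks=200, n_clock_peaks=30, seed=8)
        res = run_epitrace(m, loci)
        res.save(tmp_path)
        assert (tmp_path / "ages.tsv").exists()
        assert (tmp_path / "run_meta.json").exists()
        assert (tmp_path / "expanded_reference.bed").exists()


class TestRunEpitraceBulk:
    def test_two_sample_reversal(self):
        # raw ClockAcc (10, 30) -> single-cell ranks (0, 1) -> bulk ages (1, 0)
        X = np.zeros((40, 2))
        X[:10, 0] = 1.0
        X[:30, 1] = 1.0
        X[30:, :] = [[2.0, 2.0]] * 10  # shared background peaks
        m = make_matrix(X, mode="bulk")
        loci = _loci_for(m, range(40))
        res = run_epitrace_bulk(m, loci)
        assert res.age[0] > res.age[1]

    def test_monotone_series_recovered_after_reversal(self):
        m, loci, truth = simulate_bulk_series(n_samples=8, monotone=True, seed=2)
        res = run_epitrace_bulk(m, loci)
        assert spearmanr(res.age, truth.true_age).statistic == pytest.approx(1.0)
        # before reversal the ranking is exactly opposite
        cfg = EpiTraceConfig(bulk_reverse=False)
        raw = run_epitrace_bulk(m, loci, config=cfg)
        assert spearmanr(raw.age, truth.true_age).statistic == pytest.approx(-1.0)

    def test_single_sample_rejected(self):
        X = np.ones((10, 1))
        m = make_matrix(X, mode="bulk")
        with pytest.raises(ValueError, match=">= 2"):
            run_epitrace_bulk(m, _loci_for(m, range(10)))


class TestModelObject:
    def test_fit_matches_functional_wrapper(self):
        m, loci, _ = simulate_sc_atac(n_cells=50, n_peaks=250, n_clock_peaks=40, seed=9)
        np.testing.assert_array_equal(
            EpiTraceModel(m, loci).fit().age, run_epitrace(m, loci).age
        )

    def test_missing_reference_overlap_raises_at_construction(self):
        X = np.ones((4, 3))
        m = make_matrix(X)
        loci = GenomicIntervalSet([GenomicInterval("chrZ", 0, 100)])
        with pytest.raises(ValueError, match="no reference peaks"):
            EpiTraceModel(m, loci)

    def test_summary_mentions_iterations(self):
        m, loci, _ = simulate_sc_atac(n_cells=40, n_peaks=200, n_clock_peaks=30, seed=10)
        s = EpiTraceModel(m, loci).fit().summary()
        assert "outer iterations" in s and "reference" in s
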