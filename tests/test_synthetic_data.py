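import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neuromast.synthetic_data import (
    CohortParams,
    CountMatrixParams,
    DurationModel,
    GroupRates,
    StackParams,
    TrajectoryParams,
    cohort_preset,
    generate_cohort,
    generate_count_matrix,
    generate_pair_trajectory,
    generate_protrusion_stack,
)
from neuromast.track_geometry import compute_angles


class TestPairTrajectory:
    def test_no_roll_never_leaves_the_rock_band(self):
        tp = TrajectoryParams(outcome_class="no_roll", roll_duration_min=0.0,
                              rock_duration_min=90.0, rock_amplitude_deg=20.0, seed=0)
        tr, seg, out = generate_pair_trajectory(tp)
        ang = compute_angles(tr)
        assert np.all(np.abs(ang.theta_unwrapped_deg) <= 30.0)
        assert out.outcome_class == "no_roll" and not out.exchanged
        assert set(seg.per_frame_label) == {"rock"}

    def test_roll_phase_frame_arithmetic(self):
        # 90 min rock / 75 min roll at 3 min sampling: onset frame 30, end frame 55
        tp = TrajectoryParams(outcome_class="roll", rock_duration_min=90.0,
                              roll_duration_min=75.0, frame_interval_min=3.0, seed=1)
        _, seg, _ = generate_pair_trajectory(tp)
        assert seg.roll_onset_idx == 30
        assert seg.roll_end_idx == 55
        assert seg.rock_duration_min == pytest.approx(90.0)
        assert seg.roll_duration_min == pytest.approx(75.0)

    def test_same_seed_gives_identical_tracks(self):
        tp = TrajectoryParams(angle_noise_deg=4.0, seed=7)
        tr1, _, _ = generate_pair_trajectory(tp)
        tr2, _, _ = generate_pair_trajectory(tp)
        assert np.array_equal(tr1.cell_a_xy, tr2.cell_a_xy)
        assert np.array_equal(tr1.cell_b_xy, tr2.cell_b_xy)

    def test_rock_amplitude_at_or_above_band_rejected(self):
        with pytest.raises(ValueError, match="30"):
            TrajectoryParams(rock_amplitude_deg=30.0)

    def test_roll_duration_zero_iff_no_roll(self):
        with pytest.raises(ValueError):
            TrajectoryParams(outcome_class="roll", roll_duration_min=0.0)
        with pytest.raises(ValueError):
            TrajectoryParams(outcome_class="no_roll", roll_duration_min=10.0)

    def test_roll_back_returns_to_start(self):
        tp = TrajectoryParams(outcome_class="roll_back", seed=3)
        tr, seg, out = generate_pair_trajectory(tp)
        ang = compute_angles(tr)
        assert abs(abs(ang.theta_unwrapped_deg[seg.roll_end_idx]) - 360.0) < 1e-6
        assert out.outcome_class == "roll_back" and not out.exchanged
        np.testing.assert_allclose(tr.cell_a_xy[seg.roll_end_idx], tr.cell_a_xy[0], atol=1e-9)

    def test_reporter_position_encodes_mislocation_truth(self):
        tp = TrajectoryParams(outcome_class="roll", emx2_initial_position="posterior", seed=4)
        _, _, out = generate_pair_trajectory(tp)
        # posterior emx2 cell of a rolling pair ends anterior: normally located
        assert out.mislocated is False
        tp = TrajectoryParams(outcome_class="no_roll", roll_duration_min=0.0,
                              emx2_initial_position="posterior", seed=4)
        _, _, out = generate_pair_trajectory(tp)
        assert out.mislocated is True


class TestCohort:
    def test_degenerate_probs_all_roll(self):
        cohort = generate_cohort(CohortParams(n_pairs=5, class_probs=(1.0, 0.0, 0.0), seed=0))
        assert all(out.outcome_class == "roll" for _, _, out in cohort)

    def test_zero_pairs_rejected(self):
        with pytest.raises(ValueError):
            CohortParams(n_pairs=0, class_probs=(1.0, 0.0, 0.0))

    def test_class_counts_inside_multinomial_99pct_region(self):
        probs = (0.57, 0.40, 0.03)
        cohort = generate_cohort(CohortParams(n_pairs=67, class_probs=probs, seed=5))
        counts = pd.Series([o.outcome_class for _, _, o in cohort]).value_counts()
        for cls, p in zip(("roll", "no_roll", "roll_back"), probs):
            lo = sps.binom.ppf(0.005, 67, p)
            hi = sps.binom.ppf(0.995, 67, p)
            assert lo <= counts.get(cls, 0) <= hi

    def test_frequencies_converge_to_class_probs(self):
        probs = (0.57, 0.40, 0.03)
        cohort = generate_cohort(CohortParams(n_pairs=10_000, class_probs=probs, seed=9))
        labels = pd.Series([o.outcome_class for _, _, o in cohort])
        freq = labels.value_counts(normalize=True)
        for cls, p in zip(("roll", "no_roll", "roll_back"), probs):
            assert abs(freq.get(cls, 0.0) - p) < 0.02

    def test_duration_draws_center_on_preset_mean(self):
        params = cohort_preset("WT", n_pairs=400, seed=2)
        cohort = generate_cohort(params)
        rocks = np.array([
            seg.rock_duration_min for _, seg, out in cohort if out.outcome_class != "no_roll"
        ])
        sem = rocks.std(ddof=1) / np.sqrt(rocks.size)
        assert abs(rocks.mean() - 90.0) < 3 * sem + 3.0  # 3 min sampling quantization


class TestStack:
    def test_zero_growth_gives_zero_length_truth(self):
        params = StackParams(protrusion_lengths=(0.0,) * 10, seed=0)
        _, truth = generate_protrusion_stack(params)
        assert (truth["length_vox"] == 0).all()

    def test_linear_growth_truth_matches_schedule(self):
        lengths = tuple(2.0 * k for k in range(10))
        _, truth = generate_protrusion_stack(StackParams(protrusion_lengths=lengths, seed=0))
        np.testing.assert_allclose(truth["length_vox"], lengths)

    def test_same_seed_identical_bytes(self, tmp_path):
        import tifffile

        params = StackParams(noise_scale=8.0, seed=11)
        for name in ("a.tif", "b.tif"):
            stack, _ = generate_protrusion_stack(params)
            tifffile.imwrite(tmp_path / name, stack)
        assert (tmp_path / "a.tif").read_bytes() == (tmp_path / "b.tif").read_bytes()

    def test_growth_beyond_geometric_bound_rejected(self):
        with pytest.raises(ValueError, match="geometric bound"):
            StackParams(protrusion_lengths=(0.0,) * 9 + (60.0,))


class TestCountMatrix:
    def _params(self, **kw):
        defaults = dict(
            n_cells_per_group=(30, 30),
            group_rates=(
                GroupRates(n_unique_genes=900, n_umi=4000, mito_fraction=0.02, emx2_prob=1.0),
                GroupRates(n_unique_genes=150, n_umi=700, mito_fraction=0.0, emx2_prob=0.0),
            ),
            seed=3,
        )
        defaults.update(kw)
        return CountMatrixParams(**defaults)

    def test_low_gene_group_flagged_should_fail(self):
        _, truth, _ = generate_count_matrix(self._params())
        g1 = truth[truth["group"] == "group1"]
        assert g1["should_fail_qc"].all()  # ~150 unique genes < 400
        g0 = truth[truth["group"] == "group0"]
        assert not g0["should_fail_qc"].any()

    def test_zero_mito_rate_gives_zero_mito_fraction(self):
        _, truth, _ = generate_count_matrix(self._params())
        assert (truth.loc[truth["group"] == "group1", "mito_fraction"] == 0).all()

    def test_emx2_probability_extremes(self):
        matrix, truth, genes = generate_count_matrix(self._params())
        emx2_col = np.asarray(matrix[:, genes.index("emx2")].todense()).ravel()
        g0 = truth["group"] == "group0"
        assert truth.loc[g0, "emx2_positive"].sum() == g0.sum()
        assert (emx2_col[g0.to_numpy()] > 0).all()
        assert (emx2_col[~g0.to_numpy()] == 0).all()

    def test_truth_metrics_match_matrix(self):
        matrix, truth, genes = generate_count_matrix(self._params())
        mito_mask = np.array([g.startswith("mt-") for g in genes])
        n_unique = np.asarray((matrix > 0).sum(axis=1)).ravel()
        umi = np.asarray(matrix.sum(axis=1)).ravel()
        np.testing.assert_array_equal(n_unique, truth["n_unique_genes"])
        np.testing.assert_array_equal(umi, truth["n_umi"])
        mito = np.asarray(matrix[:, mito_mask].sum(axis=1)).ravel()
        np.testing.assert_allclose(mito / umi, truth["mito_fraction"], atol=1e-12)

    def test_determinism(self):
        m1, t1, _ = generate_count_matrix(self._params())
        m2, t2, _ = generate_count_matrix(self._params())
        assert (m1 != m2).nnz == 0
        pd.testing.assert_frame_equal(t1, t2)
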