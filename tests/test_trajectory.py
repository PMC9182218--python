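"""Endpoint extraction, per-frame analysis, segmentation, summaries, heatmaps."""

import numpy as np
import pandas as pd
import pytest

from dyescreen import (
    EmptyAnalysisError,
    EndpointTable,
    PeriodicImageError,
    SelectionError,
    ValidationError,
    analyze,
    extract_endpoints,
    heatmap,
    segment_states,
    summarize,
)
from dyescreen.fixtures import (
    DUMBBELL_SELECTION_SPEC,
    StatePrescription,
    TrajectoryPrescription,
    cy5_o2_prescription,
    gen_dimer_trajectory,
    intercalation_prescription,
    write_dumbbell_pdb,
)


def h_stack_table(n=10, R=1.26, stride=10.0):
    """Constant H-geometry table: parallel z-axis dipoles, centers along x."""
    time = stride * np.arange(n)
    r_m = np.tile([0.0, 0.0, -0.5], (n, 1))
    s_m = np.tile([0.0, 0.0, 0.5], (n, 1))
    r_n = np.tile([R, 0.0, -0.5], (n, 1))
    s_n = np.tile([R, 0.0, 0.5], (n, 1))
    return EndpointTable(time=time, r_m=r_m, s_m=s_m, r_n=r_n, s_n=s_n)


class TestEndpointTable:
    def test_stride_inferred_from_uniform_times(self):
        assert h_stack_table(stride=10.0).stride_ps == 10.0

    def test_nonincreasing_times_rejected(self):
        t = h_stack_table(3)
        with pytest.raises(ValidationError):
            EndpointTable(
                time=np.array([0.0, 10.0, 10.0]),
                r_m=t.r_m, s_m=t.s_m, r_n=t.r_n, s_n=t.s_n,
            )

    def test_csv_round_trip_bit_exact(self, tmp_path):
        table, _ = gen_dimer_trajectory(cy5_o2_prescription(n_frames=25, seed=9))
        path = tmp_path / "endpoints.csv"
        table.to_csv(path)
        back = EndpointTable.from_csv(path)
        for key in ("time", "r_m", "s_m", "r_n", "s_n"):
            np.testing.assert_allclose(getattr(back, key), getattr(table, key),
                                       rtol=0, atol=1e-12)


class TestAnalyze:
    def test_constant_h_geometry_gives_constant_unit_kappa(self):
        series = analyze(h_stack_table(), 15.35, 15.35, equilibration_cutoff=0.0)
        np.testing.assert_allclose(series.kappa_abs, 1.0, atol=1e-12)
        np.testing.assert_allclose(series.R, 1.26, atol=1e-12)
        assert np.all(series.J_abs > 0)

    def test_cutoff_excludes_early_frames(self):
        series = analyze(h_stack_table(n=10), 15.35, 15.35, equilibration_cutoff=50.0)
        assert len(series) == 5
        assert series.time.min() == 50.0

    def test_cutoff_beyond_last_frame_raises(self):
        with pytest.raises(EmptyAnalysisError):
            analyze(h_stack_table(n=10), 15.35, 15.35, equilibration_cutoff=1e6)

    def test_pipeline_equivalence_csv_vs_direct(self, tmp_path):
        # same fixture through the CSV round-trip gives bit-identical series
        table, _ = gen_dimer_trajectory(cy5_o2_prescription(n_frames=50, seed=2))
        path = tmp_path / "e.csv"
        table.to_csv(path)
        direct = analyze(table, 15.35, 15.35, equilibration_cutoff=0.0)
        via_csv = analyze(EndpointTable.from_csv(path), 15.35, 15.35,
                          equilibration_cutoff=0.0)
        np.testing.assert_allclose(via_csv.kappa_abs, direct.kappa_abs, atol=1e-12)
        np.testing.assert_allclose(via_csv.J_abs, direct.J_abs, atol=1e-12)

    def test_pre_cutoff_frames_do_not_influence_results(self):
        table, _ = gen_dimer_trajectory(cy5_o2_prescription(n_frames=40, seed=4))
        cutoff = 200.0
        series = analyze(table, 15.35, 15.35, equilibration_cutoff=cutoff)
        perturbed = EndpointTable(
            time=table.time,
            r_m=np.where((table.time < cutoff)[:, None], table.r_m + 3.3, table.r_m),
            s_m=np.where((table.time < cutoff)[:, None], table.s_m + 3.3, table.s_m),
            r_n=table.r_n,
            s_n=table.s_n,
        )
        series_p = analyze(perturbed, 15.35, 15.35, equilibration_cutoff=cutoff)
        np.testing.assert_array_equal(series_p.kappa_abs, series.kappa_abs)
        np.testing.assert_array_equal(series_p.J_abs, series.J_abs)
        s = summarize(series, window_start=cutoff)
        s_p = summarize(series_p, window_start=cutoff)
        assert s_p.kappa_mean == s.kappa_mean and s_p.J_mean == s.J_mean

    def test_two_state_fixture_recovers_prescription_means(self):
        # 20% O1 (R = 2.7, kappa ~ 0.5) / 80% O2 (R = 1.26, kappa ~ 1.35)
        presc = intercalation_prescription(n_frames=2000, seed=12, o2_occupancy=0.8)
        table, sidecar = gen_dimer_trajectory(presc)
        series = analyze(table, 15.35, 15.35, equilibration_cutoff=0.0)
        for name, state in zip(("O1", "O2"), presc.states):
            mask = (sidecar["state"] == name).to_numpy()
            k = series.kappa_abs[mask]
            r = series.R[mask]
            se_k = state.kappa_std / np.sqrt(mask.sum())
            se_r = state.R_std / np.sqrt(mask.sum())
            assert abs(k.mean() - state.kappa_mean) < 3 * se_k + 1e-3
            assert abs(r.mean() - state.R_mean) < 3 * se_r + 1e-3


class TestSegmentStates:
    def test_all_far_frames_are_o1(self):
        series = analyze(h_stack_table(R=2.7), 15.35, 15.35, equilibration_cutoff=0.0)
        seg = segment_states(series, R_threshold=2.0)
        assert seg.occupancy == {"O1": 1.0, "O2": 0.0}

    def test_all_near_frames_are_o2(self):
        series = analyze(h_stack_table(R=1.3), 15.35, 15.35, equilibration_cutoff=0.0)
        seg = segment_states(series, R_threshold=2.0)
        assert seg.occupancy == {"O1": 0.0, "O2": 1.0}

    def test_alternating_frames_give_half_occupancy_and_n_intervals(self):
        n = 10
        base = h_stack_table(n=n)
        shift = np.where((np.arange(n) % 2 == 0)[:, None],
                         np.array([[0.0, 0.0, 0.0]]), np.array([[1.5, 0.0, 0.0]]))
        table = EndpointTable(
            time=base.time, r_m=base.r_m, s_m=base.s_m,
            r_n=base.r_n + shift, s_n=base.s_n + shift,
        )
        series = analyze(table, 15.35, 15.35, equilibration_cutoff=0.0)
        seg = segment_states(series, R_threshold=2.0)
        assert seg.occupancy == {"O1": 0.5, "O2": 0.5}
        assert len(seg.intervals) == n

    def test_blockwise_fixture_has_one_transition(self):
        presc = intercalation_prescription(n_frames=500, seed=6, o2_occupancy=0.8)
        table, _ = gen_dimer_trajectory(presc)
        series = analyze(table, 15.35, 15.35, equilibration_cutoff=0.0)
        seg = segment_states(series, R_threshold=2.0)
        assert [s for s, *_ in seg.intervals] == ["O1", "O2"]
        assert seg.occupancy["O2"] == pytest.approx(0.8, abs=0.01)


class TestSummarize:
    def test_constant_series(self):
        series = analyze(h_stack_table(), 15.35, 15.35, equilibration_cutoff=0.0)
        s = summarize(series)
        assert s.kappa_mean == pytest.approx(1.0)
        assert s.kappa_std == pytest.approx(0.0, abs=1e-12)

    def test_two_value_mean(self):
        base = h_stack_table(n=2)
        table = EndpointTable(
            time=base.time, r_m=base.r_m, s_m=base.s_m,
            r_n=base.r_n + np.array([[0.0], [2.0]]) * np.array([[1.0, 0.0, 0.0]]),
            s_n=base.s_n + np.array([[0.0], [2.0]]) * np.array([[1.0, 0.0, 0.0]]),
        )
        series = analyze(table, 15.35, 15.35, equilibration_cutoff=0.0)
        s = summarize(series)
        assert s.R_mean == pytest.approx((1.26 + 3.26) / 2)

    def test_window_with_too_few_frames_raises(self):
        series = analyze(h_stack_table(n=5), 15.35, 15.35, equilibration_cutoff=0.0)
        with pytest.raises(EmptyAnalysisError):
            summarize(series, window_start=45.0)


class TestHeatmap:
    def test_single_frame_single_cell(self):
        series = analyze(h_stack_table(n=1), 15.35, 15.35, equilibration_cutoff=0.0)
        grid = heatmap(series, y="kappa")
        assert grid.counts.sum() == 1
        assert (grid.counts > 0).sum() == 1

    def test_counts_sum_to_frame_count(self):
        table, _ = gen_dimer_trajectory(cy5_o2_prescription(n_frames=300, seed=8))
        series = analyze(table, 15.35, 15.35, equilibration_cutoff=0.0)
        for y in ("kappa", "J"):
            assert heatmap(series, y=y).counts.sum() == len(series)

    def test_bimodal_fixture_separates_in_R(self):
        presc = intercalation_prescription(n_frames=1000, seed=3, o2_occupancy=0.5)
        table, _ = gen_dimer_trajectory(presc)
        series = analyze(table, 15.35, 15.35, equilibration_cutoff=0.0)
        grid = heatmap(series, y="kappa", bin_R=0.1)
        occupancy_by_R = grid.counts.sum(axis=1)
        centers = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
        # two occupied clusters with an empty gap between them around 2 nm
        gap = (centers > 1.8) & (centers < 2.2)
        assert occupancy_by_R[centers < 1.8].sum() > 0
        assert occupancy_by_R[centers > 2.2].sum() > 0
        assert occupancy_by_R[gap].sum() < 0.01 * len(series)

    def test_nonpositive_bins_rejected(self):
        series = analyze(h_stack_table(), 15.35, 15.35, equilibration_cutoff=0.0)
        with pytest.raises(ValidationError):
            heatmap(series, bin_R=0.0)


class TestExtractEndpoints:
    def test_centroid_of_three_atom_group(self, tmp_path):
        # hand-built single-frame PDB with a 3-atom group: centroid (1, 0, 0) nm
        import MDAnalysis as mda
        from MDAnalysis.coordinates.memory import MemoryReader

        u = mda.Universe.empty(6, n_residues=2, atom_resindex=[0, 0, 0, 1, 1, 1],
                               trajectory=True)
        u.add_TopologyAttr("name", ["A1", "A2", "A3", "B1", "B2", "B3"])
        u.add_TopologyAttr("resname", ["GRP", "GRQ"])
        u.add_TopologyAttr("resid", [1, 2])
        u.add_TopologyAttr("element", ["C"] * 6)
        coords = np.array(
            [[[0, 0, 0], [5, 0, 0], [10, 0, 0],
              [0, 10, 0], [5, 10, 0], [10, 10, 0]]], dtype=np.float32
        )
        u.load_new(coords, format=MemoryReader)
        path = tmp_path / "groups.pdb"
        with mda.Writer(str(path), 6, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
        spec = {
            "dye_m_r": {"resname": "GRP", "names": ["A1", "A2", "A3"]},
            "dye_m_s": {"resname": "GRQ", "names": ["B1", "B2", "B3"]},
            "dye_n_r": "resname GRP and name A1",
            "dye_n_s": "resname GRQ and name B3",
        }
        table = extract_endpoints(path, spec, dt_ps=10.0)
        np.testing.assert_allclose(table.r_m[0], [0.5, 0.0, 0.0], atol=1e-4)
        np.testing.assert_allclose(table.s_m[0], [0.5, 1.0, 0.0], atol=1e-4)

    def test_absent_selection_raises(self, tmp_path):
        table, _ = gen_dimer_trajectory(cy5_o2_prescription(n_frames=3, seed=1))
        path = tmp_path / "d.pdb"
        write_dumbbell_pdb(table, path)
        bad = dict(DUMBBELL_SELECTION_SPEC)
        bad["dye_m_r"] = {"resname": "NOPE", "names": ["E1"]}
        with pytest.raises(SelectionError):
            extract_endpoints(path, bad, dt_ps=10.0)

    def test_fixture_round_trip_through_pdb(self, tmp_path):
        # recovery limited only by the PDB format's 0.001 A quantization
        table, _ = gen_dimer_trajectory(cy5_o2_prescription(n_frames=10, seed=5))
        path = tmp_path / "d.pdb"
        write_dumbbell_pdb(table, path)
        back = extract_endpoints(path, DUMBBELL_SELECTION_SPEC, dt_ps=10.0)
        for key in ("r_m", "s_m", "r_n", "s_n"):
            np.testing.assert_allclose(getattr(back, key), getattr(table, key),
                                       atol=1.1e-4)
        np.testing.assert_allclose(back.time, table.time)

    def test_broken_molecule_raises_periodic_image_error(self, tmp_path):
        import MDAnalysis as mda
        from MDAnalysis.coordinates.memory import MemoryReader

        u = mda.Universe.empty(4, n_residues=2, atom_resindex=[0, 0, 1, 1],
                               trajectory=True)
        u.add_TopologyAttr("name", ["E1", "E1B", "E2", "E2B"])
        u.add_TopologyAttr("resname", ["DYM", "DYN"])
        u.add_TopologyAttr("resid", [1, 2])
        u.add_TopologyAttr("element", ["C"] * 4)
        # first group atoms 40 A apart: split across the periodic boundary
        coords = np.array(
            [[[0, 0, 0], [40, 0, 0], [5, 5, 5], [6, 5, 5]]], dtype=np.float32
        )
        u.load_new(coords, format=MemoryReader)
        path = tmp_path / "broken.pdb"
        with mda.Writer(str(path), 4, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
        spec = {
            "dye_m_r": {"resname": "DYM", "names": ["E1", "E1B"]},
            "dye_m_s": {"resname": "DYN", "names": ["E2"]},
            "dye_n_r": {"resname": "DYN", "names": ["E2B"]},
            "dye_n_s": {"resname": "DYM", "names": ["E1"]},
        }
        with pytest.raises(PeriodicImageError):
            extract_endpoints(path, spec, dt_ps=10.0)
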