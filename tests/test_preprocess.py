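"""Compensation, gating hierarchy and barcode deconvolution against truth."""

import numpy as np
import pandas as pd
import pytest

from catscreen.plate import make_scheme
from catscreen.preprocess import (
    FLUOR_CHANNELS,
    GateSet,
    SpilloverError,
    SpilloverMatrix,
    assign_barcodes,
    compensate,
    default_spillover,
    estimate_spillover,
    exclude_doublets,
    gate_live,
    gate_sperm,
    preprocess_tube,
)
from catscreen.simulate import WellSimSpec, simulate_well, single_stain_controls


class TestSpilloverEstimation:
    def test_orthogonal_dyes_give_identity(self):
        tabs = single_stain_controls(SpilloverMatrix.identity(), seed=0)
        s = estimate_spillover(tabs)
        off = s.matrix[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.005)

    def test_recovers_true_bleed_within_one_percent(self, spillover):
        tabs = single_stain_controls(spillover, n_events=10_000, seed=1)
        s = estimate_spillover(tabs)
        assert np.all(np.abs(s.matrix - spillover.matrix) < 0.01)

    def test_missing_control_names_the_dye(self):
        tabs = single_stain_controls(seed=0)
        del tabs["violet"]
        with pytest.raises(SpilloverError, match="violet"):
            estimate_spillover(tabs)

    def test_dead_primary_channel_is_singular_error(self):
        tabs = single_stain_controls(seed=0)
        for dye in ("cfse", "violet"):
            tabs[dye] = tabs[dye].copy()
            tabs[dye][dye] = 0.0  # both dyes emit nothing in their own channel
        with pytest.raises(SpilloverError, match="cfse"):
            estimate_spillover(tabs)


class TestCompensate:
    @staticmethod
    def _true_table(rng, n=500):
        data = {ch: rng.lognormal(5, 1, n) for ch in FLUOR_CHANNELS}
        df = pd.DataFrame(data)
        df["time"] = np.linspace(0, 30, n)
        df["fsc_a"] = 1.0
        return df

    def test_identity_leaves_table_unchanged(self):
        rng = np.random.default_rng(0)
        df = self._true_table(rng)
        out = compensate(df, SpilloverMatrix.identity())
        pd.testing.assert_frame_equal(out, df)

    def test_mix_then_compensate_round_trip(self, spillover):
        rng = np.random.default_rng(1)
        true = self._true_table(rng)
        mixed = true.copy()
        mixed[list(FLUOR_CHANNELS)] = (
            true[list(FLUOR_CHANNELS)].to_numpy() @ spillover.matrix
        )
        rec = compensate(mixed, spillover)
        np.testing.assert_allclose(
            rec[list(FLUOR_CHANNELS)], true[list(FLUOR_CHANNELS)], rtol=1e-10
        )

    def test_round_trip_random_spillovers(self):
        # property over random invertible mixing matrices
        rng = np.random.default_rng(2)
        for _ in range(20):
            m = np.eye(4)
            m[~np.eye(4, dtype=bool)] = rng.uniform(0, 0.3, 12)
            s = SpilloverMatrix(m)
            true = self._true_table(rng, n=200)
            mixed = true.copy()
            mixed[list(FLUOR_CHANNELS)] = true[list(FLUOR_CHANNELS)].to_numpy() @ m
            rec = compensate(mixed, s)
            np.testing.assert_allclose(
                rec[list(FLUOR_CHANNELS)], true[list(FLUOR_CHANNELS)], rtol=1e-10
            )

    def test_scatter_and_time_untouched_negatives_preserved(self, spillover):
        df = self._true_table(np.random.default_rng(3))
        df.loc[0, "pi"] = 0.0  # compensation can push this below zero
        out = compensate(df, spillover)
        pd.testing.assert_series_equal(out["time"], df["time"])
        pd.testing.assert_series_equal(out["fsc_a"], df["fsc_a"])
        assert out.loc[0, "pi"] < 0  # bleed subtraction went negative, not clipped


class TestGates:
    def test_all_debris_yields_empty(self):
        spec = WellSimSpec(n_events=2000, debris_fraction=1.0,
                           doublet_fraction=0, dead_fraction=0)
        df = simulate_well(spec, seed=0)
        assert len(gate_sperm(df)) / len(df) < 0.05

    def test_sperm_gate_quality_on_default_simulation(self, neg_well):
        _, df = neg_well
        gated = gate_sperm(df)
        true_sperm = df["is_sperm"]
        retained = gated["is_sperm"].sum() / true_sperm.sum()
        admitted = (~gated["is_sperm"]).sum() / max((~true_sperm).sum(), 1)
        assert retained >= 0.99
        assert admitted <= 0.05

    def test_empty_input_passes_through(self):
        empty = simulate_well(WellSimSpec(n_events=0), seed=0)
        assert len(gate_sperm(empty)) == 0
        assert len(exclude_doublets(empty)) == 0
        assert len(gate_live(empty)) == 0

    def test_doublet_exclusion_retains_singlets(self):
        spec = WellSimSpec(n_events=20_000, debris_fraction=0,
                           doublet_fraction=0, dead_fraction=0)
        df = simulate_well(spec, seed=1)
        assert len(exclude_doublets(df)) / len(df) >= 0.99

    def test_doublet_exclusion_removes_injected_doublets(self, neg_well):
        _, df = neg_well
        sperm = gate_sperm(df)
        singlets = exclude_doublets(sperm)
        n_doublets_before = sperm["is_doublet"].sum()
        n_doublets_after = singlets["is_doublet"].sum()
        assert 1 - n_doublets_after / n_doublets_before >= 0.95
        retained_singlets = (
            singlets[~singlets["is_doublet"]].shape[0]
            / sperm[~sperm["is_doublet"]].shape[0]
        )
        assert retained_singlets >= 0.99

    def test_live_gate_retains_all_when_no_dead(self):
        spec = WellSimSpec(n_events=5000, dead_fraction=0.0, debris_fraction=0,
                           doublet_fraction=0)
        df = simulate_well(spec, seed=2)
        assert len(gate_live(df)) == len(df)

    def test_live_gate_share_tracks_dead_fraction(self):
        spec = WellSimSpec(n_events=20_000, dead_fraction=0.2, debris_fraction=0,
                           doublet_fraction=0)
        df = simulate_well(spec, seed=3)
        share = len(gate_live(df)) / len(df)
        sd = np.sqrt(0.2 * 0.8 / len(df))
        assert abs(share - 0.8) < 3 * sd

    def test_live_gate_auto_threshold_matches_truth(self):
        spec = WellSimSpec(n_events=20_000, dead_fraction=0.25, debris_fraction=0,
                           doublet_fraction=0)
        df = simulate_well(spec, seed=4)
        live = gate_live(df, GateSet(pi_threshold=None))
        assert (~live["is_dead"]).mean() > 0.995

    def test_zero_threshold_empties_table(self, neg_well):
        _, df = neg_well
        assert len(gate_live(df, GateSet(pi_threshold=0.0))) == 0


class TestBarcodeAssignment:
    def test_twelve_plex_accuracy(self, matrix_tube, spillover):
        layout, tube = matrix_tube
        labeled, report = preprocess_tube(
            tube, scheme=layout.scheme, spillover=spillover
        )
        assert report.assignment_purity >= 0.99
        assert report.assignment_yield >= 0.95
        report.validate_monotone()

    def test_no_sperm_signature_nearly_empty(self, matrix_tube, spillover):
        layout, tube = matrix_tube
        labeled, report = preprocess_tube(
            tube, scheme=layout.scheme, spillover=spillover
        )
        assert report.per_barcode.get("V3-C3", 0) <= 0.005 * len(tube)

    def test_single_signature_tube_all_assigned(self, neg_well, single_sig_scheme):
        spec, df = neg_well
        singlets = df[df["is_sperm"] & ~df["is_doublet"] & ~df["is_dead"]]
        labeled, report = assign_barcodes(singlets, single_sig_scheme)
        assigned = labeled["barcode"] == "V1-C1"
        assert assigned.mean() > 0.99

    def test_gain_rescaling_leaves_assignment_unchanged(self, matrix_tube, spillover):
        # instrument gain is arbitrary: scaling both barcode channels only
        # shifts the log-intensity clusters, so assignments must not move
        layout, tube = matrix_tube
        live, _ = preprocess_tube(tube, spillover=spillover)
        labeled, _ = assign_barcodes(live, layout.scheme)
        scaled = live.copy()
        for ch in ("cfse", "violet"):
            scaled[ch] = scaled[ch] * 4.0
        labeled2, _ = assign_barcodes(scaled, layout.scheme)
        agree = (labeled["barcode"].to_numpy() == labeled2["barcode"].to_numpy()).mean()
        assert agree >= 0.999

    def test_hierarchy_counts_monotone(self, matrix_tube, spillover):
        layout, tube = matrix_tube
        _, report = preprocess_tube(tube, scheme=layout.scheme, spillover=spillover)
        assert (
            report.n_total >= report.n_sperm >= report.n_singlet >= report.n_live
        )
        assert sum(report.per_barcode.values()) <= report.n_live

    def test_overlapping_levels_flagged(self):
        scheme = make_scheme([0.25], [1.0, 1.01])  # indistinguishable violet levels
        spec = WellSimSpec(n_events=4000, signature="V1-C1")
        df = simulate_well(spec, seed=5)
        with pytest.warns(UserWarning, match="centroid"):
            _, report = assign_barcodes(df, scheme)
        assert any("overlapping" in f for f in report.flags)
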