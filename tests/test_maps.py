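"""Evidence maps, winner percentages, FDR maps, ROI and Braak summaries."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import atnseq as a
from atnseq.errors import ValidationError


def reference_bh(p, q):
    """Independent Benjamini-Hochberg step-up (textbook form)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    thresh = q * np.arange(1, m + 1) / m
    below = np.nonzero(ranked <= thresh)[0]
    k = below.max() + 1 if below.size else 0
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    qvals_sorted = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    qvals = np.empty(m)
    qvals[order] = np.minimum(qvals_sorted, 1.0)
    return reject, qvals


def make_dataset(grid, groups, voxel_means, noise_sd=0.0, seed=0, baseline=0.5):
    """Dataset where voxel_means maps grid index -> per-position means."""
    rng = np.random.default_rng(seed)
    seq_pos = {g: i for i, g in enumerate(a.AD_CONTINUUM)}
    n = len(groups)
    values = np.full((n,) + grid, baseline)
    for idx, means in voxel_means.items():
        for s, g in enumerate(groups):
            values[(s,) + idx] = means[seq_pos[g]]
    values += rng.normal(0.0, noise_sd, size=values.shape) if noise_sd else 0.0
    return a.VoxelDataset(values=values)


class TestGMMask:
    def test_all_below_threshold_rejected(self):
        ds = a.VoxelDataset(np.full((3, 4, 4, 4), 0.04))
        with pytest.raises(ValidationError, match="empty"):
            a.gm_mask(ds)

    def test_half_in_half_out(self):
        values = np.full((2, 4, 4, 4), 0.01)
        values[:, :2] = 0.2
        mask = a.gm_mask(a.VoxelDataset(values))
        assert mask.n_voxels == 32
        assert mask.data[:2].all() and not mask.data[2:].any()

    def test_tiny_threshold_keeps_full_grid(self):
        ds = a.VoxelDataset(np.full((2, 3, 3, 3), 0.5))
        assert a.gm_mask(ds, threshold=1e-9).n_voxels == 27


class TestVoxelwiseCompare:
    def test_uniform_decline_wins_everywhere(self):
        groups = np.repeat(list(a.AD_CONTINUUM), 5)
        means = {
            (i, j, k): (4.0, 3.0, 2.0, 1.0)
            for i in range(3) for j in range(3) for k in range(3)
        }
        ds = make_dataset((3, 3, 3), groups, means)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ev = a.voxelwise_compare(ds, groups, None, a.permutation_sequences())
        pct = a.winner_percentages(ev)
        assert pct["ACH"] == pytest.approx(100.0)
        assert pct.sum() == pytest.approx(100.0)

    def test_planted_60_40_split(self):
        """60% of voxels decline along the reference order, 40% reversed."""
        groups = np.repeat(list(a.AD_CONTINUUM), 6)
        grid = (5, 2, 1)  # 10 voxels: 6 forward, 4 reversed
        means = {}
        flat = [(i, j, 0) for i in range(5) for j in range(2)]
        for v, idx in enumerate(flat):
            means[idx] = (4, 3, 2, 1) if v < 6 else (1, 2, 3, 4)
        ds = make_dataset(grid, groups, means, noise_sd=0.05, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ev = a.voxelwise_compare(ds, groups, None, a.permutation_sequences())
        pct = a.winner_percentages(ev)
        rev = a.permutation_sequences()
        rev_name = next(
            s.name for s in rev if s.states == tuple(reversed(a.AD_CONTINUUM))
        )
        assert pct["ACH"] == pytest.approx(60.0, abs=2.0)
        assert pct[rev_name] == pytest.approx(40.0, abs=2.0)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(4)
        groups = np.repeat(list(a.AD_CONTINUUM), 5)
        ds = a.VoxelDataset(0.5 + 0.1 * rng.normal(size=(20, 3, 3, 3)))
        seqs = a.conversion_paths()
        perm = rng.permutation(20)
        ds_p = a.VoxelDataset(ds.values[perm])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ev = a.voxelwise_compare(ds, groups, None, seqs, min_per_group=5)
            ev_p = a.voxelwise_compare(ds_p, groups[perm], None, seqs, min_per_group=5)
        assert np.array_equal(ev.winner, ev_p.winner)

    def test_every_masked_voxel_has_one_winner(self):
        rng = np.random.default_rng(5)
        groups = np.repeat(list(a.AD_CONTINUUM), 5)
        values = 0.5 + 0.1 * rng.normal(size=(20, 4, 4, 4))
        values[:, 0] = 0.01  # excluded from GM
        ds = a.VoxelDataset(values)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ev = a.voxelwise_compare(ds, groups, None, a.permutation_sequences())
        assert (ev.winner[ev.mask.data] >= 0).all()
        assert (ev.winner[~ev.mask.data] == -1).all()
        assert a.winner_percentages(ev).sum() == pytest.approx(100.0)


class TestROISummary:
    def test_noiseless_roi_prefers_reference(self):
        groups = np.repeat(list(a.AD_CONTINUUM), 5)
        means = {(0, 0, 0): (4.0, 3.0, 2.0, 1.0)}
        ds = make_dataset((2, 2, 2), groups, means)
        roi = a.ROIMask("test_roi", np.ones((2, 2, 2), dtype=bool))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summary = a.roi_summary(
                ds, groups, None, roi, a.permutation_sequences()
            )
        assert summary.best_sequence == "ACH"
        assert summary.reference_rank == 1

    def test_trend_t_matches_hand_ols(self):
        rng = np.random.default_rng(10)
        groups = np.repeat(list(a.AD_CONTINUUM), 4)  # 16 subjects
        roi_vol = rng.normal(size=16)
        seqs = a.SequenceSet([a.permutation_sequences().get("ACH")], "ACH")
        summary = a.roi_summary(
            None, groups, None, None, seqs, roi_volumes=roi_vol
        )
        pos = np.repeat([1.0, 2, 3, 4], 4)
        X = np.column_stack([np.ones(16), pos - pos.mean()])
        ref = sm.OLS(roi_vol, X).fit()
        assert summary.t == pytest.approx(ref.tvalues[1], abs=1e-10)
        assert summary.p == pytest.approx(
            stats.t.cdf(ref.tvalues[1], ref.df_resid), abs=1e-12
        )

    def test_vx_percent_of_planted_roi(self):
        groups = np.repeat(list(a.AD_CONTINUUM), 5)
        means = {
            (i, j, k): (4.0, 3.0, 2.0, 1.0)
            for i in range(2) for j in range(2) for k in range(2)
        }
        ds = make_dataset((2, 2, 2), groups, means)
        roi = a.ROIMask("planted", np.ones((2, 2, 2), dtype=bool))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ev = a.voxelwise_compare(ds, groups, None, a.permutation_sequences())
            summary = a.roi_summary(
                ds, groups, None, roi, a.permutation_sequences(), evidence=ev
            )
        assert summary.reference_vx_pct == pytest.approx(100.0)


class TestLogPMap:
    def _planted(self, direction=-1.0, noise=0.3, seed=0):
        rng = np.random.default_rng(seed)
        groups = np.repeat(list(a.AD_CONTINUUM), 25)
        deltas = direction * np.array([0.0, 1.0, 2.0, 3.0])
        values = np.full((100, 3, 3, 3), 10.0)  # keep voxel means positive
        for s, g in enumerate(groups):
            values[s] += deltas[list(a.AD_CONTINUUM).index(g)]
        values += rng.normal(0, noise, size=values.shape)
        return a.VoxelDataset(values=values), groups

    def test_strong_decline_all_significant(self, ach):
        ds, groups = self._planted(direction=-1.0)
        sm_map = a.logp_map(ds, groups, None, ach, gm_threshold=1e-6)
        assert sm_map.significant[sm_map.mask.data].all()
        assert (sm_map.neglog10p[sm_map.mask.data] > 5).all()

    def test_reversed_decline_nothing_significant(self, ach):
        ds, groups = self._planted(direction=+1.0)
        sm_map = a.logp_map(ds, groups, None, ach, gm_threshold=1e-6)
        assert not sm_map.significant.any()

    def test_null_rarely_rejects_anything(self, ach):
        """BH under the global null: any-rejection probability <= q."""
        rng = np.random.default_rng(12)
        groups = np.repeat(list(a.AD_CONTINUUM), 10)
        any_reject = 0
        reps = 200
        for _ in range(reps):
            Y = rng.normal(size=(40, 500))
            _, p, _ = a.trend_test_many(Y, groups, None, ach)
            reject, _ = a.fdr_bh(p, 0.05)
            any_reject += bool(reject.any())
        assert any_reject / reps < 0.10


class TestFdrBH:
    def test_hand_step_up_example(self):
        reject, q = a.fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]), 0.05)
        assert reject.all()

    def test_flat_half_p_never_rejected(self):
        reject, _ = a.fdr_bh(np.full(10, 0.5), 0.05)
        assert not reject.any()

    def test_single_p_below_q_rejected(self):
        reject, _ = a.fdr_bh(np.array([0.04]), 0.05)
        assert reject.all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            a.fdr_bh(np.array([0.1, 1.2]), 0.05)

    def test_matches_reference_step_up(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            m = rng.integers(1, 60)
            p = rng.random(m)
            reject, qv = a.fdr_bh(p, 0.05)
            ref_r, ref_q = reference_bh(p, 0.05)
            assert np.array_equal(reject, ref_r)
            assert np.allclose(qv, ref_q, atol=1e-12)


class TestBraakComposites:
    def _roi_table(self, n=8, seed=0):
        rng = np.random.default_rng(seed)
        cols = ["entorhinal", "hippocampus", "amygdala", "insula", "temporal",
                "precuneus", "frontal"]
        return pd.DataFrame(rng.uniform(1, 5, size=(n, len(cols))), columns=cols)

    def test_early_stage_is_entorhinal_plus_hippocampus(self):
        table = self._roi_table()
        comps = a.braak_composites(table)
        early = next(c for c in comps if c.stage == "I/II")
        assert set(early.rois) == {"entorhinal", "hippocampus"}
        assert np.allclose(
            early.volumes, table["entorhinal"] + table["hippocampus"]
        )

    def test_composites_partition_total_volume(self):
        table = self._roi_table()
        comps = a.braak_composites(table)
        used = [r for c in comps for r in c.rois]
        assert len(used) == len(set(used))
        total = sum(c.volumes.sum() for c in comps)
        assert total == pytest.approx(table[used].to_numpy().sum())

    def test_duplicate_assignment_rejected(self):
        table = self._roi_table()
        with pytest.raises(ValidationError, match="both"):
            a.braak_composites(
                table,
                {"I/II": ("entorhinal", "hippocampus"),
                 "III/IV": ("hippocampus", "amygdala")},
            )

    def test_empty_stage_rejected(self):
        table = self._roi_table()
        with pytest.raises(ValidationError, match="no constituent"):
            a.braak_composites(table, {"I/II": ("entorhinal",), "V/VI": ()})
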