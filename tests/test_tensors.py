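import numpy as np
import pytest

from eegmse.montage import DEAP_CHANNELS, DEAP_GRID, MontageGrid
from eegmse.tensors import (
    HIGH,
    LOW,
    EntropyTensorizer,
    SegmentationPlan,
    binarize_labels,
    build_tensor,
    remove_baseline,
    segment,
)


class TestSegmentation:
    @pytest.mark.parametrize("fs", [128, 256])
    def test_tiling_counts(self, fs):
        x = np.arange(63 * fs, dtype=float)
        base, trial = segment(x, fs)
        assert base.shape == (3, fs)
        assert trial.shape == (60, fs)
        # non-overlapping tiling covers the record exactly, in order
        np.testing.assert_array_equal(
            np.concatenate([base.ravel(), trial.ravel()]), x
        )

    def test_deap_scale_segment_count(self):
        """32 subjects x 40 trials x 60 windows = 76,800 trial segments."""
        plan = SegmentationPlan()
        assert 32 * 40 * plan.n_trial_segments == 76_800
        assert round(128 * plan.total_seconds) == 8064

    def test_non_tiling_length_rejected(self):
        with pytest.raises(ValueError):
            segment(np.zeros(63 * 128 + 5), 128)

    def test_multichannel_layout(self):
        x = np.zeros((32, 63 * 128))
        base, trial = segment(x, 128)
        assert base.shape == (32, 3, 128)
        assert trial.shape == (32, 60, 128)


class TestBaselineRemoval:
    @pytest.mark.parametrize(
        "trial, baseline, expected",
        [
            ([[0.5, 0.7]], [[0.2, 0.3]], [[0.3, 0.4]]),
            ([[1.0, 2.0]], [[0, 0], [0, 3], [0, 3]], [[1.0, 0.0]]),
            ([[0.2, 0.3]], [[0.2, 0.3]], [[0.0, 0.0]]),
        ],
    )
    def test_examples(self, trial, baseline, expected):
        np.testing.assert_allclose(
            remove_baseline(np.array(trial, float), np.array(baseline, float)),
            expected,
        )

    def test_translation_equivariance(self, rng):
        trial = rng.standard_normal((60, 32, 4))
        base = rng.standard_normal((3, 32, 4))
        c = 2.317
        np.testing.assert_allclose(
            remove_baseline(trial + c, base + c),
            remove_baseline(trial, base),
            atol=1e-12,
        )

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            remove_baseline(np.zeros((60, 32)), np.zeros((3, 31)))


class TestMontage:
    def test_all_deap_channels_mapped_injectively(self):
        grid = MontageGrid()
        assert set(DEAP_GRID) == set(DEAP_CHANNELS)
        cells = [grid.cell(ch) for ch in DEAP_CHANNELS]
        assert len(set(cells)) == 32
        assert grid.grid_shape == (10, 10)

    def test_border_ring_is_never_assigned(self):
        grid = MontageGrid()
        for ch in DEAP_CHANNELS:
            r, c = grid.cell(ch)
            assert 1 <= r <= 8 and 1 <= c <= 8

    def test_duplicate_cell_rejected(self):
        with pytest.raises(ValueError):
            MontageGrid(mapping={"A": (0, 0), "B": (0, 0)})

    def test_json_roundtrip(self, tmp_path):
        grid = MontageGrid()
        path = tmp_path / "montage.json"
        grid.to_json(str(path))
        again = MontageGrid.from_json(str(path))
        assert again.mapping == grid.mapping


class TestBuildTensor:
    def test_conservation_and_zero_count(self, rng):
        values = rng.standard_normal((32, 4))
        tensor = build_tensor(values, list(DEAP_CHANNELS))
        assert tensor.shape == (10, 10, 4)
        for b in range(4):
            assert tensor[:, :, b].sum() == pytest.approx(values[:, b].sum())
            assert (tensor[:, :, b] == 0).sum() == 100 - 32

    def test_readback_recovers_inputs(self, rng):
        grid = MontageGrid()
        values = rng.standard_normal((32, 4))
        tensor = build_tensor(values, list(DEAP_CHANNELS), grid)
        for i, ch in enumerate(DEAP_CHANNELS):
            r, c = grid.cell(ch)
            np.testing.assert_array_equal(tensor[r, c], values[i])

    def test_zero_input_gives_zero_tensor(self):
        tensor = build_tensor(np.zeros((32, 4)), list(DEAP_CHANNELS))
        np.testing.assert_array_equal(tensor, 0.0)

    def test_single_nonzero_channel(self):
        values = np.zeros((32, 4))
        values[5] = 1.0
        tensor = build_tensor(values, list(DEAP_CHANNELS))
        for b in range(4):
            assert (tensor[:, :, b] != 0).sum() == 1

    def test_unknown_channel_named_in_error(self):
        with pytest.raises(KeyError, match="Xq9"):
            build_tensor(np.zeros((1, 4)), ["Xq9"])

    def test_border_stays_zero(self, rng):
        tensor = build_tensor(rng.standard_normal((32, 4)), list(DEAP_CHANNELS))
        assert np.all(tensor[0] == 0) and np.all(tensor[-1] == 0)
        assert np.all(tensor[:, 0] == 0) and np.all(tensor[:, -1] == 0)


class TestBinarizeLabels:
    @pytest.mark.parametrize(
        "rating, expected",
        [(5.0, LOW), (5.1, HIGH), (9.0, HIGH), (1.0, LOW), (4.999, LOW)],
    )
    def test_threshold_boundary(self, rating, expected):
        assert binarize_labels(np.array([rating]))[0] == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            binarize_labels(np.array([0.5]))
        with pytest.raises(ValueError):
            binarize_labels(np.array([9.5]))

    def test_per_dimension_independence(self):
        ratings = np.array([[[2.0, 8.0, 5.0]]])
        np.testing.assert_array_equal(
            binarize_labels(ratings), [[[LOW, HIGH, LOW]]]
        )


class TestEntropyTensorizer:
    def test_output_shape_and_finiteness(self, rng):
        channels = ("F3", "F4", "C3", "C4")
        x = rng.standard_normal((2, 4, 63 * 128))
        tz = EntropyTensorizer(fs=128.0, channel_names=channels)
        out = tz.transform(x)
        assert out.shape == (2, 60, 10, 10, 4)
        assert np.all(np.isfinite(out))

    def test_degenerate_channel_imputed_zero(self, rng, caplog):
        """A flat channel has r = 0.2 * std = 0 at every segment; its
        cells must come out 0, not nan."""
        channels = ("F3", "F4")
        x = rng.standard_normal((1, 2, 63 * 128))
        x[0, 1] = 0.0
        tz = EntropyTensorizer(fs=128.0, channel_names=channels)
        out = tz.transform(x)
        assert np.all(np.isfinite(out))
        grid = MontageGrid()
        r, c = grid.cell("F4")
        np.testing.assert_array_equal(out[0, :, r, c, :], 0.0)

    def test_channel_count_mismatch_rejected(self, rng):
        tz = EntropyTensorizer(fs=128.0, channel_names=("F3",))
        with pytest.raises(ValueError):
            tz.transform(rng.standard_normal((1, 2, 63 * 128)))
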