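"""k-space transforms, echo-train scheduling, and line-substitution corruption."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from kmotion import (
    STILL,
    CorruptionConfig,
    ImageGrid,
    MotionBankConfig,
    MotionTimeline,
    build_motion_bank,
    corrupt_image,
    from_kspace,
    make_echo_train_schedule,
    sample_motion_timeline,
    simulate_pair,
    to_kspace,
    translate_image,
)
from kmotion.types import InvalidConfigError


class TestFourier:
    def test_constant_image_concentrates_at_center(self):
        n, c = 8, 3.0
        k = to_kspace(ImageGrid(np.full((n, n), c)))
        center = np.zeros((n, n))
        center[n // 2, n // 2] = n * n * c
        np.testing.assert_allclose(np.abs(k.values), center, atol=1e-9)

    def test_round_trip(self, phantom64):
        back = from_kspace(to_kspace(phantom64))
        np.testing.assert_allclose(back.pixels, phantom64.pixels, rtol=1e-9, atol=1e-9)

    def test_real_input_conjugate_symmetry(self, rng):
        x = rng.random((16, 16))
        k = np.fft.fft2(x)  # unshifted: K[-u, -v] = conj(K[u, v])
        np.testing.assert_allclose(
            k, np.conj(k[(-np.arange(16)) % 16][:, (-np.arange(16)) % 16]), atol=1e-8)

    def test_all_zero_kspace_gives_zero_image(self):
        from kmotion.kspace import KSpaceGrid

        img = from_kspace(KSpaceGrid(np.zeros((8, 8), complex)))
        assert np.all(img.pixels == 0)

    def test_center_line_only_is_nonnegative_lowpass(self, phantom64):
        k = to_kspace(phantom64)
        keep = np.zeros_like(k.values)
        keep[32, :] = k.values[32, :]
        k.values = keep
        img = from_kspace(k)
        assert np.all(img.pixels >= 0)
        # constant along the vertical axis (only DC row kept)
        assert np.allclose(img.pixels, img.pixels[0:1, :], atol=1e-9)


class TestEchoTrainSchedule:
    def test_fse_default_blocks(self):
        sched = make_echo_train_schedule(256, 13)
        assert sched.n_blocks == 20
        lengths = [len(b) for b in sched.blocks]
        assert lengths.count(13) == 19 and lengths.count(9) == 1

    def test_single_block(self):
        sched = make_echo_train_schedule(4, 4)
        assert sched.blocks == [[0, 1, 2, 3]]

    @given(n_pe=st.integers(1, 300), etl=st.integers(1, 40),
           ordering=st.sampled_from(["linear", "interleaved"]))
    def test_blocks_partition_lines(self, n_pe, etl, ordering):
        if etl > n_pe:
            return
        sched = make_echo_train_schedule(n_pe, etl, ordering)
        flat = sorted(i for b in sched.blocks for i in b)
        assert flat == list(range(n_pe))

    def test_bad_etl_rejected(self):
        with pytest.raises(InvalidConfigError):
            make_echo_train_schedule(16, 0)
        with pytest.raises(InvalidConfigError):
            make_echo_train_schedule(16, 17)


class TestMotionTimeline:
    def test_p_zero_all_still(self):
        sched = make_echo_train_schedule(64, 13)
        tl = sample_motion_timeline(sched, 80, CorruptionConfig(p_motion=0.0, seed=1))
        assert all(c == STILL for c in tl.choices)

    def test_p_one_single_bank_entry(self):
        sched = make_echo_train_schedule(64, 13)
        tl = sample_motion_timeline(sched, 1, CorruptionConfig(p_motion=1.0, seed=1))
        assert all(c == 0 for c in tl.choices)

    def test_corrupted_fraction_binomial(self):
        sched = make_echo_train_schedule(10000, 1)
        tl = sample_motion_timeline(sched, 80, CorruptionConfig(p_motion=0.5, seed=7))
        frac = tl.n_corrupted / len(tl)
        se = np.sqrt(0.25 / 10000)
        assert abs(frac - 0.5) < 3 * se

    def test_protect_center_forces_still(self):
        sched = make_echo_train_schedule(64, 8)
        cfg = CorruptionConfig(p_motion=1.0, seed=3, protect_center=8)
        tl = sample_motion_timeline(sched, 80, cfg)
        protected = set(range(28, 36))
        for b, lines in enumerate(sched.blocks):
            if protected & set(lines):
                assert tl.choices[b] == STILL

    def test_deterministic_for_seed(self):
        sched = make_echo_train_schedule(64, 13)
        cfg = CorruptionConfig(p_motion=0.5, seed=9)
        a = sample_motion_timeline(sched, 80, cfg)
        b = sample_motion_timeline(sched, 80, cfg)
        assert a.choices == b.choices

    def test_empty_bank_with_motion_rejected(self):
        sched = make_echo_train_schedule(64, 13)
        with pytest.raises(InvalidConfigError):
            sample_motion_timeline(sched, 0, CorruptionConfig(p_motion=0.5))


class TestCorruptImage:
    def _setup(self, phantom64, pe="vertical"):
        bank = build_motion_bank(phantom64, MotionBankConfig(max_shift=3, max_rot=1.0))
        n_pe = 64
        sched = make_echo_train_schedule(n_pe, 13)
        return bank, sched

    def test_all_still_reproduces_original(self, phantom64):
        bank, sched = self._setup(phantom64)
        tl = MotionTimeline([STILL] * sched.n_blocks)
        out = corrupt_image(phantom64, bank, sched, tl, "vertical")
        np.testing.assert_allclose(out.pixels, phantom64.pixels, rtol=1e-9, atol=1e-9)

    def test_single_source_timeline_equals_bank_image(self, phantom64):
        # key oracle: every block from bank entry j == bank entry j's image
        bank, sched = self._setup(phantom64)
        j = 4
        tl = MotionTimeline([j] * sched.n_blocks)
        out = corrupt_image(phantom64, bank, sched, tl, "vertical")
        np.testing.assert_allclose(out.pixels, np.abs(bank.image(j).pixels),
                                   rtol=1e-8, atol=1e-8)

    def test_still_lines_bitwise_preserved_in_kspace(self, phantom64):
        from kmotion.kspace import assemble_kspace

        bank, sched = self._setup(phantom64)
        choices = [STILL if b % 2 == 0 else 3 for b in range(sched.n_blocks)]
        k_mixed = assemble_kspace(phantom64, bank, sched, MotionTimeline(choices),
                                  "vertical")
        k_orig = to_kspace(phantom64)
        for b, lines in enumerate(sched.blocks):
            for line in lines:
                same = np.array_equal(k_mixed.values[line], k_orig.values[line])
                if choices[b] == STILL:
                    assert same
                else:
                    assert not same

    @staticmethod
    def _active_fractions(diff: np.ndarray) -> tuple[float, float]:
        """Fraction of rows / columns carrying non-negligible difference energy."""
        thr = 1e-4 * (diff**2).sum()
        row_frac = float(((diff**2).sum(axis=1) > thr).mean())
        col_frac = float(((diff**2).sum(axis=0) > thr).mean())
        return row_frac, col_frac

    def test_ghosting_runs_along_pe_axis(self, phantom64):
        # single bank entry: a pure horizontal 2-px shift.  Substituting
        # k-space lines smears the difference along the PE axis only, so the
        # PE axis saturates while the cross axis stays near the head support.
        from kmotion.motion import MotionBank, RigidMotionParams

        entry = (RigidMotionParams(dx=2, dy=0, kind="translation_horizontal"),
                 translate_image(phantom64, 2, 0))
        bank = MotionBank(source=phantom64, entries=[entry])
        sched = make_echo_train_schedule(64, 13)
        tl = sample_motion_timeline(sched, 1, CorruptionConfig(
            p_motion=0.6, seed=5))
        out_v = corrupt_image(phantom64, bank, sched, tl, "vertical")
        out_h = corrupt_image(phantom64, bank, sched, tl, "horizontal")
        rf_v, cf_v = self._active_fractions(out_v.pixels - phantom64.pixels)
        rf_h, cf_h = self._active_fractions(out_h.pixels - phantom64.pixels)
        assert rf_v > cf_v    # vertical PE: ghosts fill the rows
        assert cf_h > rf_h    # horizontal PE: ghosts fill the columns

    def test_fourier_shift_theorem_wraparound(self, rng):
        # circular shift <-> linear phase ramp in k-space
        x = ImageGrid(rng.random((32, 32)))
        dx, dy = 5, -3
        shifted = translate_image(x, dx, dy, mode="wrap")
        k0 = np.fft.fft2(x.pixels)
        k1 = np.fft.fft2(shifted.pixels)
        fy = np.fft.fftfreq(32)[:, None]
        fx = np.fft.fftfreq(32)[None, :]
        ramp = np.exp(-2j * np.pi * (fy * dy + fx * dx))
        np.testing.assert_allclose(k1, k0 * ramp, atol=1e-8)

    def test_pe_direction_transpose_symmetry(self, phantom64):
        # corrupting X along horizontal == transpose of corrupting X^T along
        # vertical, when the bank entries are transposed accordingly
        from kmotion.motion import MotionBank, RigidMotionParams

        sched = make_echo_train_schedule(64, 13)
        cfg = CorruptionConfig(p_motion=0.7, seed=21)
        shifts = [(2, 0), (0, 3), (-1, -1)]
        entries_h = [(RigidMotionParams(dx=dx, dy=dy, kind="translation_diagonal")
                      if abs(dx) == abs(dy) else
                      RigidMotionParams(dx=dx, dy=dy,
                                        kind="translation_horizontal" if dy == 0
                                        else "translation_vertical"),
                      translate_image(phantom64, dx, dy)) for dx, dy in shifts]
        xt = phantom64.transposed()
        entries_v = [(p, translate_image(xt, p.dy, p.dx)) for p, _ in entries_h]
        bank_h = MotionBank(source=phantom64, entries=entries_h)
        bank_v = MotionBank(source=xt, entries=entries_v)
        tl = sample_motion_timeline(sched, 3, cfg)
        out_h = corrupt_image(phantom64, bank_h, sched, tl, "horizontal")
        out_v = corrupt_image(xt, bank_v, sched, tl, "vertical")
        np.testing.assert_allclose(out_h.pixels, out_v.pixels.T, rtol=1e-8, atol=1e-8)

    def test_shape_mismatch_rejected(self, phantom64):
        from kmotion.motion import MotionBank, RigidMotionParams
        from kmotion.phantom import PhantomConfig, generate_phantom

        small = generate_phantom(PhantomConfig(size=32, seed=1))
        bank = MotionBank(source=small, entries=[
            (RigidMotionParams(dx=1, dy=0, kind="translation_horizontal"),
             translate_image(small, 1, 0))])
        sched = make_echo_train_schedule(64, 13)
        tl = MotionTimeline([0] * sched.n_blocks)
        with pytest.raises(Exception):
            corrupt_image(phantom64, bank, sched, tl, "vertical")


class TestSimulatePair:
    def test_deterministic_for_seed(self, phantom64):
        cfg = CorruptionConfig(p_motion=0.5, seed=13, pe_direction="vertical")
        a = simulate_pair(phantom64, corruption_config=cfg)
        b = simulate_pair(phantom64, corruption_config=cfg)
        np.testing.assert_array_equal(a.corrupted.pixels, b.corrupted.pixels)

    def test_seed_variation_changes_output(self, phantom64):
        a = simulate_pair(phantom64, corruption_config=CorruptionConfig(seed=1))
        b = simulate_pair(phantom64, corruption_config=CorruptionConfig(seed=2))
        assert np.any(a.corrupted.pixels != b.corrupted.pixels)

    def test_directions_ghost_along_own_axis(self, phantom64):
        def active(pair):
            diff = pair.corrupted.pixels - pair.clean.pixels
            thr = 1e-4 * (diff**2).sum()
            return (float(((diff**2).sum(axis=1) > thr).mean()),
                    float(((diff**2).sum(axis=0) > thr).mean()))

        v = simulate_pair(phantom64, corruption_config=CorruptionConfig(
            seed=5, pe_direction="vertical", p_motion=0.6))
        h = simulate_pair(phantom64, corruption_config=CorruptionConfig(
            seed=5, pe_direction="horizontal", p_motion=0.6))
        assert np.any(v.corrupted.pixels != h.corrupted.pixels)
        rf_v, cf_v = active(v)
        rf_h, cf_h = active(h)
        # each direction's ghosts spread at least as widely along its own
        # PE axis as the other direction's do
        assert rf_v >= rf_h and cf_h >= cf_v
        assert rf_v > cf_v
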