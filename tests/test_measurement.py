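import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fdot.measurement import (
    CalibrationTable,
    ChannelMask,
    ProbeGeometry,
    RawFrame,
    apply_calibration,
    compute_calibration,
    default_probe_geometry,
    homogeneous_channel_model,
    iq_to_amplitude_phase,
    load_measurement_set,
    load_raw_frame,
    read_raw_csv,
    save_measurement_set,
    save_raw_frame,
    select_channels,
)
from fdot.optics import OpticalProperties
from fdot.phantom import NoiseModel, peripheral_airgap_channels, simulate_exam

BACKGROUND = OpticalProperties(0.005, 1.0)


def toy_geometry(n_src=2, n_det=3, thickness=30.0, n_wl=1):
    src = np.array([[10.0 * i, 0.0, 0.0] for i in range(n_src)])
    det = np.array([[8.0 * j, 5.0, thickness] for j in range(n_det)])
    return ProbeGeometry(src, det, thickness,
                         wavelengths=(785.0, 808.0, 850.0)[:n_wl])


class TestGeometry:
    def test_default_layout_counts_and_invariants(self):
        g = default_probe_geometry()
        assert g.n_sources == 64 and g.n_detectors == 40
        assert g.wavelengths == (785.0, 808.0, 850.0)
        assert g.modulation_frequency == 7.0e7
        # parallel-plate geometry: every channel at least one slab apart
        assert np.all(g.rho() >= g.slab_thickness)

    def test_non_coplanar_sources_rejected(self):
        src = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 2.0]])
        det = np.array([[0.0, 0.0, 30.0]])
        with pytest.raises(ValueError, match="coplanar"):
            ProbeGeometry(src, det, 30.0)

    def test_plane_separation_must_match_thickness(self):
        src = np.array([[0.0, 0.0, 0.0]])
        det = np.array([[0.0, 0.0, 25.0]])
        with pytest.raises(ValueError, match="separated"):
            ProbeGeometry(src, det, 30.0)


class TestIQConversion:
    def test_pythagorean_pair(self):
        g = toy_geometry(1, 1)
        meas = iq_to_amplitude_phase(RawFrame(np.full((1, 1, 1), 3 + 4j), g))
        assert meas.amplitude[0, 0, 0] == pytest.approx(5.0)
        assert meas.phase[0, 0, 0] == pytest.approx(np.arctan2(4, 3), abs=1e-12)

    def test_real_axis(self):
        g = toy_geometry(1, 1)
        meas = iq_to_amplitude_phase(RawFrame(np.full((1, 1, 1), 1 + 0j), g))
        assert meas.amplitude[0, 0, 0] == 1.0
        assert meas.phase[0, 0, 0] == 0.0

    def test_inversion_reproduces_iq(self):
        g = toy_geometry(3, 4)
        rng = np.random.default_rng(0)
        iq = rng.standard_normal((3, 4, 1)) + 1j * rng.standard_normal((3, 4, 1))
        meas = iq_to_amplitude_phase(RawFrame(iq, g))
        # modulo the 2*pi unwrapping, amplitude*exp(i*phase) is the raw IQ
        rebuilt = meas.amplitude * np.exp(1j * meas.phase)
        assert np.abs(rebuilt - iq).max() / np.abs(iq).max() < 1e-12

    def test_zero_modulus_channel_is_masked_not_fatal(self):
        g = toy_geometry(2, 2)
        iq = np.ones((2, 2, 1), dtype=complex)
        iq[0, 1, 0] = 0.0
        meas = iq_to_amplitude_phase(RawFrame(iq, g))
        assert not meas.mask.keep[0, 1, 0]
        assert meas.mask.n_retained == 3

    def test_simulator_roundtrip_matches_stored_clean_data(
        self, clean_homogeneous_exam
    ):
        meas = iq_to_amplitude_phase(clean_homogeneous_exam.raw)
        rel = np.abs(
            meas.amplitude - clean_homogeneous_exam.clean_amplitude
        ) / clean_homogeneous_exam.clean_amplitude
        assert rel.max() < 1e-10
        assert np.abs(
            meas.phase - clean_homogeneous_exam.clean_phase
        ).max() < 1e-10

    def test_phase_unwrapped_without_branch_jumps(
        self, clean_homogeneous_exam
    ):
        """Along increasing distance the unwrapped lag rises overall and
        never jumps by a wrap (boundary proximity makes it only roughly
        monotone in a finite slab, so strict monotonicity is not asserted)."""
        meas = iq_to_amplitude_phase(clean_homogeneous_exam.raw)
        rho = meas.rho
        for s in range(meas.geometry.n_sources):
            order = np.argsort(rho[s])
            lags = meas.phase[s, order, 0]
            assert np.abs(np.diff(lags)).max() < np.pi / 2
            assert lags[-1] > lags[0]


class TestCalibration:
    def test_uniform_ratio_gives_unit_factors(self, small_geometry):
        amp, lag = homogeneous_channel_model(small_geometry, BACKGROUND)
        frame = RawFrame(2.5 * amp * np.exp(1j * lag), small_geometry)
        cal = compute_calibration(frame, BACKGROUND)
        assert np.allclose(cal.cf_amplitude, 1.0, atol=1e-12)
        assert np.allclose(cal.phase_offset, 0.0, atol=1e-10)
        assert cal.amplitude_scale[0] == pytest.approx(2.5)

    def test_cf_formula_on_three_channel_toy(self, small_geometry):
        # model-divided amplitudes {1, 2, 3} -> CF {0.5, 1.0, 1.5}
        amp, lag = homogeneous_channel_model(small_geometry, BACKGROUND)
        gains = np.ones_like(amp)
        flat = gains.reshape(-1)
        flat[:] = 2.0
        flat[0], flat[1], flat[2] = 1.0, 2.0, 3.0
        frame = RawFrame(gains * amp * np.exp(1j * lag), small_geometry)
        cal = compute_calibration(frame, BACKGROUND)
        mean = gains.mean()
        assert cal.cf_amplitude.reshape(-1)[:3] == pytest.approx(
            np.array([1.0, 2.0, 3.0]) / mean
        )

    def test_mean_of_cf_is_one_exactly(self, exam_pair):
        _, cal_exam = exam_pair
        cal = compute_calibration(cal_exam.raw, BACKGROUND)
        assert cal.cf_amplitude.mean(axis=(0, 1)) == pytest.approx(1.0, abs=1e-12)
        assert np.all(cal.cf_amplitude > 0)

    def test_injected_gains_recovered_proportionally(self, small_geometry):
        amp, lag = homogeneous_channel_model(small_geometry, BACKGROUND)
        rng = np.random.default_rng(3)
        gains = np.exp(0.2 * rng.standard_normal(amp.shape))
        frame = RawFrame(gains * amp * np.exp(1j * lag), small_geometry)
        cal = compute_calibration(frame, BACKGROUND)
        assert np.allclose(cal.cf_amplitude, gains / gains.mean(), rtol=1e-12)

    def test_identity_calibration_is_identity(self, exam_pair):
        exam, _ = exam_pair
        meas = iq_to_amplitude_phase(exam.raw)
        shape = meas.amplitude.shape
        identity = CalibrationTable(
            cf_amplitude=np.ones(shape),
            cf_phase=np.ones(shape),
            phase_offset=np.zeros(shape),
            amplitude_scale=np.ones(shape[2]),
            phantom_props=(BACKGROUND,),
        )
        out = apply_calibration(meas, identity)
        assert np.array_equal(out.amplitude, meas.amplitude)
        assert np.array_equal(out.phase, meas.phase)

    def test_componentwise_division(self, small_geometry):
        meas = iq_to_amplitude_phase(
            RawFrame(
                np.full(small_geometry.channel_shape, 2.0 + 0j),
                small_geometry,
            )
        )
        meas.amplitude.reshape(-1)[:2] = [2.0, 4.0]
        shape = meas.amplitude.shape
        cf = np.ones(shape)
        cf.reshape(-1)[:2] = [2.0, 1.0]
        cal = CalibrationTable(
            cf_amplitude=cf,
            cf_phase=np.ones(shape),
            phase_offset=np.zeros(shape),
            amplitude_scale=np.ones(shape[2]),
            phantom_props=(BACKGROUND,),
        )
        out = apply_calibration(meas, cal)
        assert out.amplitude.reshape(-1)[:2] == pytest.approx([1.0, 4.0])

    def test_shape_mismatch_rejected(self, exam_pair, small_geometry):
        exam, cal_exam = exam_pair
        cal = compute_calibration(cal_exam.raw, BACKGROUND)
        bad = iq_to_amplitude_phase(
            RawFrame(np.ones((2, 3, 1), dtype=complex), toy_geometry(2, 3))
        )
        with pytest.raises(ValueError, match="shape"):
            apply_calibration(bad, cal)

    def test_gain_removal_on_paired_exam(self, exam_pair, homogeneous_exam):
        """Calibration built from one exam removes the shared channel gains
        of a second homogeneous exam down to the paired random-noise floor
        (both exams contribute their 1% amplitude noise, hence sqrt(2)
        times the single-exam level), measured against the homogeneous
        reference model whose units the calibrated data carry."""
        _, cal_exam = exam_pair
        cal = compute_calibration(cal_exam.raw, BACKGROUND)
        meas = apply_calibration(
            iq_to_amplitude_phase(homogeneous_exam.raw), cal
        )
        model_amp, _ = homogeneous_channel_model(meas.geometry, BACKGROUND)
        ratio = meas.amplitude / model_amp
        spread = ratio.std() / ratio.mean()
        noise_floor = np.sqrt(2.0) * homogeneous_exam.noise.amplitude_noise
        assert spread <= 1.15 * noise_floor
        # without calibration the gain spread (20%) dominates
        raw_ratio = (
            iq_to_amplitude_phase(homogeneous_exam.raw).amplitude / model_amp
        )
        assert raw_ratio.std() / raw_ratio.mean() > 5 * spread

    def test_json_roundtrip(self, exam_pair, tmp_path):
        _, cal_exam = exam_pair
        cal = compute_calibration(cal_exam.raw, BACKGROUND)
        path = tmp_path / "cal.json"
        cal.to_json(path)
        back = CalibrationTable.from_json(path)
        assert np.array_equal(back.cf_amplitude, cal.cf_amplitude)
        assert np.array_equal(back.phase_offset, cal.phase_offset)
        assert back.phantom_props[0].mu_a == BACKGROUND.mu_a


class TestChannelSelection:
    @pytest.fixture()
    def calibrated(self, exam_pair):
        exam, cal_exam = exam_pair
        cal = compute_calibration(cal_exam.raw, BACKGROUND)
        return apply_calibration(iq_to_amplitude_phase(exam.raw), cal)

    def test_clean_exam_retains_everything(self, clean_homogeneous_exam):
        meas = iq_to_amplitude_phase(clean_homogeneous_exam.raw)
        mask = select_channels(meas, BACKGROUND)
        assert mask.n_retained == mask.keep.size

    def test_airgap_channels_masked_exactly(self, small_geometry, small_phantom):
        airgaps = peripheral_airgap_channels(small_geometry, 5)
        exam = simulate_exam(
            small_phantom,
            small_geometry,
            NoiseModel(seed=21, gain_seed=22, airgap_channels=airgaps),
            mesh_spacing=2.0,
        )
        meas = iq_to_amplitude_phase(exam.raw)
        mask = select_channels(meas, BACKGROUND)
        rejected = {tuple(i[:2]) for i in np.argwhere(~mask.keep)}
        assert rejected == set(airgaps)

    def test_floor_above_maximum_raises(self, calibrated):
        with pytest.raises(ValueError, match="loosen"):
            select_channels(
                calibrated, BACKGROUND,
                floor=10.0 * calibrated.amplitude.max(),
            )

    @settings(max_examples=20, deadline=None)
    @given(
        tol=st.floats(min_value=0.05, max_value=2.0),
        bump=st.floats(min_value=0.01, max_value=2.0),
    )
    def test_mask_monotone_in_tolerance(self, tol, bump):
        geometry = default_probe_geometry(
            slab_thickness=40.0, wavelengths=(785.0,),
            source_grid=(3, 3), detector_grid=(2, 2), pitch=15.0,
        )
        amp, lag = homogeneous_channel_model(geometry, BACKGROUND)
        rng = np.random.default_rng(5)
        amp = amp * np.exp(0.5 * rng.standard_normal(amp.shape))
        meas = iq_to_amplitude_phase(
            RawFrame(amp * np.exp(1j * lag), geometry)
        )
        try:
            narrow = select_channels(meas, BACKGROUND, rel_tolerance=tol).keep
        except ValueError:
            narrow = np.zeros(meas.amplitude.shape, dtype=bool)
        wide = select_channels(meas, BACKGROUND, rel_tolerance=tol + bump).keep
        assert np.all(wide[narrow])


class TestIO:
    def test_hdf5_raw_roundtrip(self, exam_pair, tmp_path):
        exam, _ = exam_pair
        path = tmp_path / "exam.h5"
        save_raw_frame(path, exam.raw, meta={"subject": "phantom-01"})
        back = load_raw_frame(path)
        assert np.array_equal(back.iq, exam.raw.iq)
        assert back.geometry.slab_thickness == exam.geometry.slab_thickness
        assert back.geometry.wavelengths == exam.geometry.wavelengths

    def test_csv_import(self, tmp_path):
        g = toy_geometry(2, 2)
        rows = ["source,detector,wavelength_nm,I,Q"]
        rng = np.random.default_rng(1)
        iq = rng.standard_normal((2, 2, 1)) + 1j * rng.standard_normal((2, 2, 1))
        for s in range(2):
            for d in range(2):
                rows.append(
                    f"{s},{d},785.0,{iq[s, d, 0].real},{iq[s, d, 0].imag}"
                )
        path = tmp_path / "raw.csv"
        path.write_text("\n".join(rows))
        frame = read_raw_csv(path, g)
        assert np.allclose(frame.iq, iq)

    def test_measurement_set_roundtrip(self, exam_pair, tmp_path):
        exam, _ = exam_pair
        meas = iq_to_amplitude_phase(exam.raw)
        meas = meas.with_mask(
            ChannelMask(np.random.default_rng(0).random(meas.amplitude.shape) > 0.1)
        )
        path = tmp_path / "meas.h5"
        save_measurement_set(path, meas)
        back = load_measurement_set(path)
        assert np.array_equal(back.amplitude, meas.amplitude)
        assert np.array_equal(back.mask.keep, meas.mask.keep)
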