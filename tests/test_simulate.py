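"""Simulator: printed calibration behaviour, determinism, log round-trips."""

import math

import numpy as np
import pandas as pd
import pytest

from enzisfet import (
    SimParams,
    carbaryl_signal,
    generate_blanks,
    generate_dataset,
    inhibition_from_concentration,
    percent_inhibition,
    ph_response,
    read_sensor_log,
    reference_signal,
    write_sensor_log,
)
from enzisfet.exceptions import DomainError, UsageError
from enzisfet.simulate import DEFAULT_CONCENTRATIONS, DEFAULT_TEMPERATURES


class TestPhResponse:
    @pytest.mark.parametrize(
        "ph,expected",
        [(0.0, 418.98), (7.0, 768.00), (4.0, 49.86 * 4 + 418.98)],
    )
    def test_line_evaluation(self, ph, expected):
        assert ph_response(ph, SimParams()) == pytest.approx(expected, abs=1e-9)

    def test_slope_times_delta_ph(self):
        p = SimParams()
        assert ph_response(10, p) - ph_response(4, p) == pytest.approx(299.16, abs=1e-9)

    @pytest.mark.parametrize("ph", [-0.1, 14.5])
    def test_out_of_range_ph(self, ph):
        with pytest.raises(DomainError):
            ph_response(ph, SimParams())


class TestReferenceSignal:
    def test_mean_at_25(self):
        p = SimParams(ref_sd=0.0, ref_temp_coeff=0.0)
        assert reference_signal(25.0, p) == pytest.approx(45.35)

    def test_coefficient_irrelevant_at_25(self):
        p = SimParams(ref_sd=0.0, ref_temp_coeff=7.0)
        assert reference_signal(25.0, p) == pytest.approx(45.35)

    def test_temperature_drift(self):
        p = SimParams(ref_sd=0.0, ref_temp_coeff=0.3)
        assert reference_signal(30.0, p) == pytest.approx(46.85)

    def test_sample_mean_close_to_population_mean(self):
        p = SimParams()
        n = 2000
        draws = reference_signal(np.full(n, 25.0), p, np.random.default_rng(42))
        assert abs(draws.mean() - 45.35) < 3 * p.ref_sd / math.sqrt(n)

    def test_nonfinite_temperature_rejected(self):
        with pytest.raises(DomainError):
            reference_signal(float("nan"), SimParams())


class TestInhibition:
    @pytest.mark.parametrize("c,expected", [(1e-5, 58.52), (1e-4, 73.74)])
    def test_calibration_line(self, c, expected):
        assert inhibition_from_concentration(c, 25.0, SimParams()) == pytest.approx(
            expected, abs=5e-3
        )

    def test_clamped_to_100_at_huge_concentration(self):
        assert inhibition_from_concentration(1.0, 25.0, SimParams()) == 100.0

    def test_clamped_to_0_at_tiny_concentration(self):
        assert inhibition_from_concentration(1e-12, 25.0, SimParams()) == 0.0

    @pytest.mark.parametrize("c", [0.0, -1e-6])
    def test_nonpositive_concentration_rejected(self, c):
        with pytest.raises(DomainError):
            inhibition_from_concentration(c, 25.0, SimParams())


class TestCarbarylSignal:
    def test_matches_printed_minimum_signal(self, noiseless_params):
        # concentration whose inhibition is exactly 36.54 % on the default line
        p = noiseless_params
        c = math.exp((36.54 - p.inhib_intercept) / p.inhib_slope)
        assert carbaryl_signal(c, 25.0, "buffer", p) == pytest.approx(28.78, abs=5e-3)

    def test_zero_inhibition_returns_reference(self, noiseless_params):
        # far below the linear range the clamp pins inhibition at 0
        sig = carbaryl_signal(1e-12, 25.0, "buffer", noiseless_params)
        assert sig == pytest.approx(reference_signal(25.0, noiseless_params))

    def test_extract_reads_higher_by_gap_equivalent(self):
        p = SimParams(
            ref_sd=0.0, signal_noise_sd=0.0, temp_noise_sd=0.0, matrix_offset_range=(2.68, 2.68)
        )
        buffer = carbaryl_signal(1e-5, 25.0, "buffer", p)
        extract = carbaryl_signal(1e-5, 25.0, "extract", p)
        diff = extract - buffer
        assert diff == pytest.approx(p.ref_mean_25c * 2.68 / 100.0, abs=1e-9)
        # the 0.45 mV/% equivalence reproduces the printed 1.206 mV within 2 %
        assert diff == pytest.approx(1.206, rel=0.02)

    @pytest.mark.parametrize("c,t", [(1e-6, 20.0), (1e-5, 25.0), (3e-5, 31.5), (1e-4, 35.0)])
    def test_inhibition_roundtrip_through_signal(self, noiseless_params, c, t):
        ref = reference_signal(t, noiseless_params)
        sig = carbaryl_signal(c, t, "buffer", noiseless_params)
        assert percent_inhibition(ref, sig) == pytest.approx(
            inhibition_from_concentration(c, t, noiseless_params), abs=1e-9
        )

    def test_monotone_decreasing_in_concentration(self, noiseless_params):
        cs = np.logspace(-6, -4, 15)
        sigs = [carbaryl_signal(c, 25.0, "buffer", noiseless_params) for c in cs]
        assert np.all(np.diff(sigs) < 0)

    def test_unknown_matrix_rejected(self):
        with pytest.raises(UsageError):
            carbaryl_signal(1e-5, 25.0, "plasma", SimParams())


class TestGenerateDataset:
    def test_campaign_size(self):
        df = generate_dataset(DEFAULT_CONCENTRATIONS, DEFAULT_TEMPERATURES, 10, "buffer")
        assert len(df) == 200
        assert df.groupby("temp_stratum").size().eq(50).all()
        assert (df["concentration_m"] > 0).all()

    def test_single_cell(self):
        assert len(generate_dataset([1e-5], [25.0], 1, "buffer")) == 1

    def test_bit_reproducible_from_seed(self):
        p = SimParams(seed=7)
        a = generate_dataset(DEFAULT_CONCENTRATIONS, DEFAULT_TEMPERATURES, 3, "buffer", p)
        b = generate_dataset(DEFAULT_CONCENTRATIONS, DEFAULT_TEMPERATURES, 3, "buffer", p)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_inputs_rejected(self):
        with pytest.raises(UsageError):
            generate_dataset([], DEFAULT_TEMPERATURES, 3, "buffer")
        with pytest.raises(UsageError):
            generate_dataset(DEFAULT_CONCENTRATIONS, DEFAULT_TEMPERATURES, 0, "buffer")


class TestSensorLogIO:
    def test_csv_roundtrip_with_blanks(self, tmp_path):
        df = generate_dataset([1e-7, 1e-3], [25.0], 2, "buffer")
        blanks = generate_blanks([25.0], 2)
        log = pd.concat([df, blanks], ignore_index=True)
        path = tmp_path / "log.csv"
        write_sensor_log(log, path)
        text = path.read_text()
        assert "delta_vgs_mv,temperature_c,matrix,concentration_m,replicate" in text
        assert "e-07" in text  # scientific notation
        back = read_sensor_log(path)
        assert back["concentration_m"].isna().sum() == 2
        np.testing.assert_allclose(
            back["delta_vgs_mv"].to_numpy(), log["delta_vgs_mv"].to_numpy(), rtol=1e-6
        )

    def test_simparams_yaml_roundtrip(self, tmp_path):
        p = SimParams(ref_sd=0.7, matrix_offset_range=(2.0, 3.0), seed=11)
        path = tmp_path / "sim.yaml"
        p.to_yaml(path)
        assert SimParams.from_yaml(path) == p

    def test_invalid_params_rejected(self):
        with pytest.raises(UsageError):
            SimParams(matrix_offset_range=(3.0, 2.0))
        with pytest.raises(UsageError):
            SimParams(ref_sd=-1.0)
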