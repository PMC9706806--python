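import numpy as np
import pytest

import etongue as et
from etongue.errors import ValidationError
from etongue.simulate import AnalyteResponse, Baseline, SensorSpec


@pytest.fixture(scope="module")
def flat_sensor():
    """Single-analyte sensor with zero baseline, peak well inside the window."""
    return SensorSpec(
        "S",
        {"CFX": AnalyteResponse(b_max=10.0, k_d=50.0, e_peak=1.0, width=0.05)},
        baseline=Baseline(),
    )


class TestPeakHeight:
    def test_langmuir_identities(self, flat_sensor):
        assert et.peak_height(flat_sensor, "CFX", 0.0) == 0.0
        assert et.peak_height(flat_sensor, "CFX", 50.0) == pytest.approx(5.0)
        assert et.peak_height(flat_sensor, "CFX", 150.0) == pytest.approx(7.5)

    def test_monotone_concave_below_bmax(self, flat_sensor):
        concs = np.linspace(0.0, 1000.0, 200)
        h = np.array([et.peak_height(flat_sensor, "CFX", c) for c in concs])
        assert np.all(np.diff(h) > 0)
        assert np.all(np.diff(h, 2) < 1e-12)
        assert h.max() < 10.0

    def test_unknown_analyte(self, flat_sensor):
        with pytest.raises(KeyError):
            et.peak_height(flat_sensor, "NA", 1.0)

    def test_negative_conc_rejected(self, flat_sensor):
        with pytest.raises(ValidationError):
            et.peak_height(flat_sensor, "CFX", -1.0)


class TestSimulateVoltammogram:
    def test_zero_conc_zero_noise_gives_baseline(self, zero_noise):
        sensor = SensorSpec(
            "S", {"CFX": AnalyteResponse(5.0, 50.0, 1.0)},
            baseline=Baseline(intercept=0.3, slope=0.2, exp_amplitude=0.5),
        )
        sample = et.MixtureSample(np.array([0.0]))
        v = et.simulate_voltammogram(sensor, sample, ("CFX",), noise=zero_noise)
        np.testing.assert_allclose(
            v.currents, sensor.baseline.currents(v.potentials), rtol=0, atol=0)

    def test_peak_max_matches_langmuir_height(self, flat_sensor, zero_noise):
        # E_peak = 1.0 V lies exactly on a 901-point 1 mV grid and sits
        # 8 widths from both edges: tail error < 1e-6 relative
        grid = et.GridSpec(n_points=901)
        j = int(np.argmin(np.abs(grid.potentials() - 1.0)))
        for conc in (10.0, 100.0):
            v = et.simulate_voltammogram(
                flat_sensor, et.MixtureSample(np.array([conc])), ("CFX",),
                grid=grid, noise=zero_noise)
            expected = et.peak_height(flat_sensor, "CFX", conc)
            assert v.currents[j] == pytest.approx(expected, rel=1e-6)

    def test_saturation_limit(self, flat_sensor, zero_noise):
        grid = et.GridSpec(n_points=901)
        j = int(np.argmin(np.abs(grid.potentials() - 1.0)))
        v = et.simulate_voltammogram(
            flat_sensor, et.MixtureSample(np.array([50.0 * 1e6])), ("CFX",),
            grid=grid, noise=zero_noise)
        assert v.currents[j] == pytest.approx(10.0, rel=1e-4)

    def test_monotone_in_concentration(self, flat_sensor, zero_noise):
        v1 = et.simulate_voltammogram(
            flat_sensor, et.MixtureSample(np.array([10.0])), ("CFX",),
            noise=zero_noise)
        v2 = et.simulate_voltammogram(
            flat_sensor, et.MixtureSample(np.array([100.0])), ("CFX",),
            noise=zero_noise)
        assert v2.currents.max() >= v1.currents.max()

    def test_mixture_response_is_additive(self, bank, zero_noise):
        sensor = bank[0]
        base = sensor.baseline.currents(et.GridSpec().potentials())

        def trace(conc_vec):
            return et.simulate_voltammogram(
                sensor, et.MixtureSample(np.array(conc_vec)), noise=zero_noise
            ).currents

        mix = trace([50.0, 80.0, 120.0])
        singles = trace([50.0, 0, 0]) + trace([0, 80.0, 0]) + trace([0, 0, 120.0])
        np.testing.assert_allclose(mix, singles - 2 * base, rtol=1e-12)

    def test_analyte_count_mismatch(self, flat_sensor):
        with pytest.raises(ValidationError):
            et.simulate_voltammogram(
                flat_sensor, et.MixtureSample(np.array([1.0, 2.0])), ("CFX",))


class TestSimulateArray:
    def test_four_traces_shared_grid(self, bank):
        m = et.simulate_array(bank, et.MixtureSample(np.array([10.0, 10.0, 10.0])))
        assert len(m.traces) == 4
        for t in m.traces[1:]:
            np.testing.assert_array_equal(t.potentials, m.traces[0].potentials)

    def test_seeded_determinism(self, bank):
        sample = et.MixtureSample(np.array([5.0, 50.0, 200.0]))
        noise = et.NoiseSpec(seed=123)
        m1 = et.simulate_array(bank, sample, noise=noise)
        m2 = et.simulate_array(bank, sample, noise=noise)
        for t1, t2 in zip(m1.traces, m2.traces):
            np.testing.assert_array_equal(t1.currents, t2.currents)

    def test_duplicate_sensor_rejected(self, bank):
        with pytest.raises(ValidationError):
            et.simulate_array([bank[0], bank[0]],
                              et.MixtureSample(np.array([1.0, 1.0, 1.0])))

    def test_mip_cfx_beats_nip_at_cfx_peak(self, bank, zero_noise):
        sample = et.MixtureSample(np.array([10.0, 10.0, 10.0]))
        m = et.simulate_array(bank, sample, noise=zero_noise)
        grid = et.GridSpec().potentials()
        j = int(np.argmin(np.abs(grid - 1.0)))  # CFX peak potential
        corrected = {
            t.sensor_id: et.correct_baseline(t).currents[j] for t in m.traces
        }
        assert corrected["MIP-CFX"] > corrected["NIP"]


class TestDefaultBank:
    def test_template_selectivity(self, bank):
        by_id = {s.sensor_id: s for s in bank}
        for analyte, own in (("CFX", "MIP-CFX"), ("LFX", "MIP-LFX")):
            bmax = {sid: s.responses[analyte].b_max for sid, s in by_id.items()}
            assert max(bmax, key=bmax.get) == own
        for analyte in et.ANALYTES:
            bmax = {sid: s.responses[analyte].b_max for sid, s in by_id.items()}
            assert min(bmax, key=bmax.get) == "NIP"

    def test_mfx_intrinsically_weaker(self, bank):
        for s in bank:
            assert s.responses["MFX"].b_max < s.responses["CFX"].b_max
            assert s.responses["MFX"].b_max < s.responses["LFX"].b_max

    def test_parameters_valid(self, bank):
        for s in bank:
            assert set(s.responses) == set(et.ANALYTES)
            for r in s.responses.values():
                assert r.k_d > 0 and r.width > 0
                assert 0.6 < r.e_peak < 1.5


def test_langmuir_roundtrip_with_simulator(zero_noise):
    """Simulated zero-noise calibration curves refit to the generating
    (B_max, k_D) to better than 1e-4 relative."""
    sensor = SensorSpec(
        "S", {"CFX": AnalyteResponse(b_max=8.0, k_d=350.0, e_peak=1.0)},
        baseline=Baseline(),
    )
    concs = np.array([2.0, 10.0, 30.0, 80.0, 150.0, 220.0, 300.0])
    grid = et.GridSpec(n_points=901)  # samples E_peak = 1.0 V exactly
    j = int(np.argmin(np.abs(grid.potentials() - 1.0)))
    heights = []
    for c in concs:
        v = et.simulate_voltammogram(
            sensor, et.MixtureSample(np.array([c])), ("CFX",), grid=grid,
            noise=zero_noise)
        heights.append(v.currents[j])
    fit = et.fit_langmuir(concs, np.array(heights))
    assert fit.b_max == pytest.approx(8.0, rel=1e-4)
    assert fit.k_d == pytest.approx(350.0, rel=1e-4)
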