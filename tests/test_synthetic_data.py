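"""Forward model against the Legendre-series oracle; generator ground truth;
bistable Langevin physics."""

import numpy as np
import pytest
from scipy.special import eval_legendre

from eznetsi.synthetic_data import (SimScenario, SphericalHeadSpec,
                                    choose_driver, default_head,
                                    dipole_potential, make_lead_field,
                                    project_to_scalp, simulate_bistable,
                                    simulate_sources)

SIGMA = 0.33


def _series_potential(sensors, r0, moment, nmax=400, eps=1e-6):
    """Brute-force oracle: dipole potential as the source-position gradient
    of the Legendre monopole expansion for the insulated sphere."""
    def monopole(r0):
        b = np.linalg.norm(r0)
        if b < 1e-12:
            return np.zeros(len(sensors))
        c = (sensors @ r0) / (np.linalg.norm(sensors, axis=1) * b)
        out = np.zeros(len(sensors))
        for n in range(1, nmax):
            out += (2 * n + 1) / n * b ** n * eval_legendre(n, c)
        return out / (4 * np.pi * SIGMA)

    grad = np.zeros((len(sensors), 3))
    for k in range(3):
        e = np.zeros(3)
        e[k] = eps
        grad[:, k] = (monopole(r0 + e) - monopole(r0 - e)) / (2 * eps)
    return grad @ moment


class TestLeadField:
    def test_against_series_oracle(self, rng):
        sensors = rng.standard_normal((9, 3))
        sensors /= np.linalg.norm(sensors, axis=1, keepdims=True)
        for _ in range(5):
            r0 = rng.standard_normal(3)
            r0 *= 0.7 * rng.random() / np.linalg.norm(r0)
            m = rng.standard_normal(3)
            got = dipole_potential(sensors, r0, m, 1.0, SIGMA)
            want = _series_potential(sensors, r0, m)
            np.testing.assert_allclose(got, want, atol=1e-8)

    def test_central_dipole_closed_form(self, rng):
        """A central dipole keeps only the n=1 Legendre term:
        V = 3 m.r_hat / (4 pi sigma R^2) -- a dipolar (cos) pattern, not
        zero (the silent radial source belongs to magnetic recordings)."""
        sensors = rng.standard_normal((12, 3))
        sensors /= np.linalg.norm(sensors, axis=1, keepdims=True)
        m = np.array([0.3, -0.2, 0.5])
        got = dipole_potential(sensors, np.zeros(3), m, 1.0, SIGMA)
        np.testing.assert_allclose(
            got, 3.0 * (sensors @ m) / (4 * np.pi * SIGMA), atol=1e-12)

    def test_mirror_symmetry(self):
        sensors = np.array([[0.6, 0.0, 0.8], [-0.6, 0.0, 0.8],
                            [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        src = np.array([[0.4, 0.1, 0.3], [-0.4, 0.1, 0.3]])
        ori = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0]])
        head = SphericalHeadSpec(sensors, list("abcd"), src, ori)
        G = make_lead_field(head).G
        # reflecting x <-> -x swaps the first two sensors and the sources
        np.testing.assert_allclose(G[0, 0], G[1, 1], atol=1e-12)
        np.testing.assert_allclose(G[1, 0], G[0, 1], atol=1e-12)
        np.testing.assert_allclose(G[2, 0], G[2, 1], atol=1e-12)

    def test_source_outside_rejected(self):
        with pytest.raises(ValueError, match="inside"):
            SphericalHeadSpec(np.array([[0.0, 0.0, 1.0]]), ["a"],
                              np.array([[0.0, 0.0, 1.0]]),
                              np.array([[0.0, 0.0, 1.0]]))

    def test_default_head_geometry(self, head16):
        assert head16.sensor_positions.shape == (21, 3)
        assert np.all(head16.source_positions[:, 2] >= -0.2 * 0.75 - 1e-9)

    def test_choose_driver_deterministic(self, lf16):
        assert choose_driver(lf16) == choose_driver(lf16)


class TestSimulateSources:
    def test_zero_coupling_uncorrelated(self):
        scn = SimScenario.reduced(seed=5, coupling=np.zeros((16, 16)),
                                  band_profile={})
        x = simulate_sources(scn).x
        r = np.corrcoef(x)
        np.fill_diagonal(r, 0)
        assert np.abs(r).max() < 0.05

    def test_driver_delta_power_elevated(self):
        """Welch delta power of the driver, via an independent
        periodogram-averaging implementation."""
        scn = SimScenario.reduced(seed=7)
        x = simulate_sources(scn).x
        rate = scn.rate
        seg = 512
        n_seg = x.shape[1] // seg
        chunks = x[:, :n_seg * seg].reshape(x.shape[0], n_seg, seg)
        win = np.hanning(seg)
        spec = np.abs(np.fft.rfft(chunks * win, axis=2)) ** 2
        psd = spec.mean(axis=1) / (rate * (win ** 2).sum())
        freqs = np.fft.rfftfreq(seg, 1 / rate)
        band = (freqs >= 1) & (freqs < 4)
        delta = psd[:, band].mean(axis=1)
        driver = next(iter(scn.driver_regions))
        others = np.delete(delta, driver)
        assert delta[driver] > 2 * np.median(others)

    def test_same_seed_bitwise_identical(self):
        a = simulate_sources(SimScenario.reduced(seed=9)).x
        b = simulate_sources(SimScenario.reduced(seed=9)).x
        assert np.array_equal(a, b)

    def test_unstable_coupling_rejected(self):
        with pytest.raises(ValueError, match="spectral radius"):
            SimScenario.reduced(coupling=1.2 * np.eye(16))


class TestProjectToScalp:
    def test_noise_free_limit(self, lf16):
        scn = SimScenario.reduced(seed=1)
        src = simulate_sources(scn)
        rec = project_to_scalp(src, lf16, snr=np.inf)
        np.testing.assert_allclose(rec.samples, lf16.G @ src.x, atol=1e-12)

    def test_empirical_snr(self, lf16):
        scn = SimScenario.reduced(seed=2)
        src = simulate_sources(scn)
        rec = project_to_scalp(src, lf16, snr=5.0, seed=11)
        clean = lf16.G @ src.x
        noise = rec.samples - clean
        snr = np.mean(clean ** 2) / np.mean(noise ** 2)
        assert abs(snr - 5.0) / 5.0 < 0.1

    def test_zero_sources_pure_noise(self, lf16):
        src = simulate_sources(SimScenario.reduced(seed=3))
        src.x[:] = 0.0
        rec = project_to_scalp(src, lf16, snr=4.0, seed=12)
        assert abs(np.var(rec.samples) - 1.0) < 0.05  # unit fallback sd

    def test_dimension_mismatch(self, lf16):
        src = simulate_sources(SimScenario.reduced(n_regions=8, seed=0))
        with pytest.raises(ValueError, match="sources"):
            project_to_scalp(src, lf16)


class TestBistable:
    def test_noiseless_fixed_point(self):
        _, x = simulate_bistable(np.zeros((1, 1)), 0.0, seed=0, t_max=5.0)
        np.testing.assert_allclose(x, -1.0, atol=1e-12)

    def test_basin_of_attraction(self):
        _, x = simulate_bistable(np.zeros((1, 1)), 0.0, seed=0, t_max=20.0,
                                 x0=0.5)
        assert abs(x[0, -1] - 1.0) < 1e-6

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            simulate_bistable(np.zeros((1, 1)), -0.1, seed=0, t_max=1.0)

    def test_stationary_density_matches_boltzmann(self):
        """Long-run histogram vs the closed-form exp(-V/D) density at
        D = 0.25 (Kolmogorov-Smirnov distance below 0.05)."""
        D = 0.25
        n_rep = 64
        _, x = simulate_bistable(np.zeros((n_rep, n_rep)), D, seed=42,
                                 t_max=400.0)
        samples = x[:, 2000::25].ravel()      # burn-in 20 tu, thin 0.25 tu

        grid = np.linspace(-3, 3, 4001)
        V = grid ** 4 / 4 - grid ** 2 / 2
        dens = np.exp(-V / D)
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        emp = np.searchsorted(np.sort(samples), grid) / samples.size
        ks = np.abs(emp - cdf).max()
        assert ks < 0.05
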