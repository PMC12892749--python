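"""Ground-truthed synthetic preictal EEG.

Every downstream stage (filtering, sLORETA, PSD, DTF, centrality, seizure
index) is exercised against recordings generated here, where the driver
region, its directed outflow and its spectral signature are known exactly.

The generator emulates the study conditions the pipeline targets: a 10-min
preictal window sampled at 256 Hz over 68 cortical regions, with one driver
region showing elevated delta-band (1--4 Hz) power and directed lag-1
outflow to a set of target regions.  A reduced 16-region / 60-s profile is
provided for fast tests.

The forward model is the closed-form surface potential of a current dipole
inside a homogeneous conducting sphere (insulating exterior).  For a dipole
with moment ``m`` at position ``r0`` inside a sphere of radius ``R`` and
conductivity ``sigma``, the potential at a surface point ``r_e`` is

    V = (1 / 4 pi sigma) * m . [ 2 d / |d|^3
        + (1/R) (r_hat + d/|d|) / (R - r0.r_hat + |d|) ]

with ``d = r_e - r0`` and ``r_hat = r_e / R`` -- the gradient with respect
to the source position of the classical monopole solution
``2/|d| + (1/R) log(2R / (R - r0.r_hat + |d|))``.  A central dipole reduces
to ``V = 3 m.r_hat / (4 pi sigma R^2)`` (only the n = 1 term of the
Legendre expansion survives).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .io_formats import EEGRecording
from .inverse_imaging import LeadField, RegionTimeSeries

__all__ = [
    "SphericalHeadSpec",
    "SimScenario",
    "default_head",
    "make_lead_field",
    "simulate_sources",
    "project_to_scalp",
    "simulate_scenario",
    "simulate_bistable",
    "choose_driver",
    "TEN_TWENTY_21",
    "BAND_CENTERS",
]

#: The 21 electrodes of the international 10--20 montage used throughout.
TEN_TWENTY_21 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2", "Fpz", "Oz",
]

#: Resonator center frequencies (Hz) for band-shaped innovations.
BAND_CENTERS = {
    "delta": 2.5, "theta": 6.0, "alpha": 10.5,
    "beta": 21.5, "low_gamma": 39.0, "high_gamma": 66.0,
}


# ---------------------------------------------------------------------------
# Spherical head model
# ---------------------------------------------------------------------------

@dataclass
class SphericalHeadSpec:
    """Electrode and source geometry on/inside the unit sphere."""

    sensor_positions: np.ndarray       # (n_sensors, 3), |pos| = radius
    sensor_names: list[str]
    source_positions: np.ndarray       # (n_sources, 3), strictly inside
    source_orientations: np.ndarray    # (n_sources, 3), unit vectors
    radius: float = 1.0
    conductivity: float = 0.33         # S/m, brain-tissue convention

    def __post_init__(self) -> None:
        self.sensor_positions = np.asarray(self.sensor_positions, float)
        self.source_positions = np.asarray(self.source_positions, float)
        self.source_orientations = np.asarray(self.source_orientations, float)
        r_sens = np.linalg.norm(self.sensor_positions, axis=1)
        if not np.allclose(r_sens, self.radius, rtol=1e-6):
            raise ValueError("all sensors must lie on the sphere surface")
        r_src = np.linalg.norm(self.source_positions, axis=1)
        if np.any(r_src >= self.radius):
            raise ValueError("all sources must be strictly inside the sphere")
        norms = np.linalg.norm(self.source_orientations, axis=1)
        if not np.allclose(norms, 1.0, rtol=1e-6):
            raise ValueError("source orientations must be unit vectors")


def _fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere (center, radius) through a point cloud."""
    A = np.c_[2 * points, np.ones(len(points))]
    b = (points ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


def _ten_twenty_unit_sphere(names: list[str]) -> np.ndarray:
    """Idealized 10--20 positions projected onto the unit sphere."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    all_pts = np.array([pos[n] for n in montage.ch_names])
    center, _ = _fit_sphere(all_pts)
    pts = np.array([pos[n] for n in names]) - center
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z ** 2)
    return np.c_[r * np.cos(phi), r * np.sin(phi), z]


def default_head(n_sources: int = 68, source_radius: float = 0.75,
                 sensor_names: list[str] | None = None,
                 z_min: float | None = -0.2) -> SphericalHeadSpec:
    """21-sensor 10--20 montage with ``n_sources`` radially oriented sources
    on a quasi-uniform shell at ``source_radius`` (cortical centroids).

    By default the shell is a cortical cap (``z >= z_min``): cortex does not
    extend to the inferior pole of the head, and sources placed there are
    essentially unsensed by a 10--20 montage, which makes their standardized
    reconstructions pure leakage.  Pass ``z_min=None`` for a full sphere.
    """
    names = list(sensor_names or TEN_TWENTY_21)
    sensors = _ten_twenty_unit_sphere(names)
    if z_min is None:
        shell = _fibonacci_sphere(n_sources)
    else:
        dense = _fibonacci_sphere(max(40 * n_sources, 400))
        dense = dense[dense[:, 2] >= z_min]
        idx = np.linspace(0, len(dense) - 1, n_sources).astype(int)
        shell = dense[idx]
    return SphericalHeadSpec(
        sensor_positions=sensors,
        sensor_names=names,
        source_positions=source_radius * shell,
        source_orientations=shell,
    )


def choose_driver(lf: LeadField, alpha="auto", snr: float = 3.0) -> int:
    """Index of the best-resolved source under the sLORETA operator.

    Resolution quality is the worst standardized crosstalk of the source's
    column of the resolution matrix (how strongly its activity leaks into
    any other source).  Planting the synthetic driver at the best-resolved
    region evaluates the pipeline in its domain of applicability: scalp-EEG
    localization is not expected to recover drivers the montage barely
    senses (deep foci are a documented failure mode of the approach).
    """
    from .inverse_imaging import build_inverse

    inv = build_inverse(lf, alpha=alpha, snr=snr)
    n = lf.n_sensors
    H = np.eye(n) - np.full((n, n), 1.0 / n)
    M = (inv.T @ (H @ lf.G)) / np.sqrt(inv.R_diag)[:, None]
    Mn = np.abs(M) / np.abs(np.diag(M))[None, :]
    crosstalk = np.sort(Mn, axis=0)[-2, :]
    return int(np.argmin(crosstalk))


def dipole_potential(sensors: np.ndarray, r0: np.ndarray, moment: np.ndarray,
                     radius: float = 1.0, conductivity: float = 0.33
                     ) -> np.ndarray:
    """Closed-form surface potential of one dipole in a homogeneous sphere."""
    r0 = np.asarray(r0, float)
    moment = np.asarray(moment, float)
    d = sensors - r0[None, :]
    dn = np.linalg.norm(d, axis=1)
    r_hat = sensors / radius
    denom = radius - sensors @ r0 / radius + dn
    g = 2.0 * d / dn[:, None] ** 3 \
        + (r_hat + d / dn[:, None]) / (radius * denom[:, None])
    return (g @ moment) / (4.0 * np.pi * conductivity)


def make_lead_field(head: SphericalHeadSpec) -> LeadField:
    """Sensors x sources matrix from the analytic spherical-head formula."""
    cols = [
        dipole_potential(head.sensor_positions, p, m,
                         radius=head.radius, conductivity=head.conductivity)
        for p, m in zip(head.source_positions, head.source_orientations)
    ]
    return LeadField(
        G=np.array(cols).T,
        sensor_names=list(head.sensor_names),
        source_ids=list(range(1, len(head.source_positions) + 1)),
    )


# ---------------------------------------------------------------------------
# Source dynamics
# ---------------------------------------------------------------------------

@dataclass
class SimScenario:
    """Ground-truth description of a synthetic preictal recording.

    ``coupling[i, j]`` is the lag-1 MVAR coefficient from region *j* (past)
    to region *i* (present), so the driver's outflow lives in the driver's
    *column*.  ``band_profile`` maps region index (0-based) to
    ``{band: power multiplier}`` applied to that region's band-shaped
    innovation component; unlisted regions get multiplier 1 in every band
    present anywhere in the profile.
    """

    n_regions: int = 68
    driver_regions: frozenset = frozenset({4})
    coupling: np.ndarray | None = None
    band_profile: dict | None = None   # default: delta x4 on every driver
    burst_depth: float = 0.8
    noise_sd: float = 1.0
    sensor_snr: float = 5.0
    duration: float = 600.0
    rate: float = 256.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not self.driver_regions:
            raise ValueError("driver_regions must be non-empty")
        self.driver_regions = frozenset(int(d) for d in self.driver_regions)
        if any(not 0 <= d < self.n_regions for d in self.driver_regions):
            raise ValueError("driver indices out of range")
        if self.band_profile is None:
            self.band_profile = {d: {"delta": 4.0}
                                 for d in sorted(self.driver_regions)}
        if self.coupling is None:
            self.coupling = self._default_coupling()
        self.coupling = np.asarray(self.coupling, float)
        if self.coupling.shape != (self.n_regions, self.n_regions):
            raise ValueError("coupling must be n_regions x n_regions")
        rho = np.max(np.abs(np.linalg.eigvals(self.coupling)))
        if rho >= 1.0:
            raise ValueError(
                f"coupling matrix is unstable: spectral radius {rho:.3f} >= 1"
            )

    def _default_coupling(self, self_coef: float = 0.2,
                          drive_coef: float = 0.3,
                          n_targets: int = 4) -> np.ndarray:
        C = self_coef * np.eye(self.n_regions)
        for d in sorted(self.driver_regions):
            targets = [(d + k) % self.n_regions for k in range(1, n_targets + 1)]
            for t in targets:
                C[t, d] = drive_coef
        return C

    @classmethod
    def reduced(cls, seed: int = 0, **kw) -> "SimScenario":
        """16-region / 60-s fast-test profile with the same structure."""
        kw.setdefault("n_regions", 16)
        kw.setdefault("duration", 60.0)
        return cls(seed=seed, **kw)


def _resonator(white: np.ndarray, f0: float, rate: float,
               pole_radius: float = 0.96) -> np.ndarray:
    """Unit-variance AR(2) resonator output centered at ``f0`` Hz."""
    theta = 2.0 * np.pi * f0 / rate
    a = [1.0, -2.0 * pole_radius * np.cos(theta), pole_radius ** 2]
    y = lfilter([1.0], a, white, axis=-1)
    sd = y.std(axis=-1, keepdims=True)
    return y / np.where(sd > 0, sd, 1.0)


def _burst_envelope(rng: np.random.Generator, n_t: int, rate: float,
                    depth: float, f_mod: float = 0.3) -> np.ndarray:
    """Slow non-negative amplitude modulation emulating intermittent
    (burst-like) rhythmic activity; unit mean drive, fluctuation ~depth."""
    from scipy.signal import butter, sosfiltfilt

    sos = butter(2, f_mod, btype="low", fs=rate, output="sos")
    slow = sosfiltfilt(sos, rng.standard_normal(n_t))
    slow = slow / slow.std()
    return np.maximum(0.0, 1.0 + depth * slow)


def simulate_sources(scn: SimScenario) -> RegionTimeSeries:
    """Region x time signals from the lag-1 MVAR recursion with band-shaped
    innovations; bit-reproducible given ``scn.seed``.

    Driver regions receive their boosted band component as *bursts*: the
    resonator output is multiplied by a slow non-negative envelope
    (``burst_depth`` controls its fluctuation) before scaling to the target
    power.  This emulates intermittent preictal rhythmic delta and gives
    the driver an elevated Hilbert-envelope coefficient of variation -- the
    signature the seizure-index noise map reads.  (For unmodulated Gaussian
    signals the envelope CV is power-invariant, so a constant-amplitude
    driver would be invisible to a CV-based map by construction.)
    """
    rng = np.random.default_rng(scn.seed)
    n = scn.n_regions
    n_t = int(round(scn.duration * scn.rate))
    burn = int(round(2.0 * scn.rate))
    total = n_t + burn

    bands_used = sorted({b for prof in scn.band_profile.values() for b in prof})
    innov = rng.standard_normal((n, total))
    for band in bands_used:
        f0 = BAND_CENTERS[band]
        res = _resonator(rng.standard_normal((n, total)), f0, scn.rate)
        mult = np.ones(n)
        for region, prof in scn.band_profile.items():
            mult[region] = prof.get(band, 1.0)
        for region in sorted(scn.driver_regions):
            if mult[region] != 1.0 and scn.burst_depth > 0:
                env = _burst_envelope(rng, total, scn.rate, scn.burst_depth)
                burst = env * res[region]
                res[region] = burst / burst.std()
        innov += np.sqrt(mult)[:, None] * res
    innov *= scn.noise_sd

    x = np.zeros((n, total))
    C = scn.coupling
    x[:, 0] = innov[:, 0]
    for t in range(1, total):
        x[:, t] = C @ x[:, t - 1] + innov[:, t]
    return RegionTimeSeries(x=x[:, burn:], region_ids=list(range(1, n + 1)),
                            rate=scn.rate)


def project_to_scalp(src: RegionTimeSeries, lf: LeadField,
                     snr: float = 5.0, seed: int = 0) -> EEGRecording:
    """Forward-project sources and add white sensor noise at a broadband
    signal-to-noise power ratio ``snr`` (``np.inf`` for noise-free)."""
    if lf.n_sources != src.n_regions:
        raise ValueError(
            f"lead field has {lf.n_sources} sources but {src.n_regions} "
            "region series were given"
        )
    clean = lf.G @ src.x
    if np.isinf(snr):
        noisy = clean
    else:
        if snr <= 0:
            raise ValueError("snr must be positive")
        sig_power = float(np.mean(clean ** 2))
        noise_sd = np.sqrt(sig_power / snr) if sig_power > 0 else 1.0
        rng = np.random.default_rng(seed)
        noisy = clean + noise_sd * rng.standard_normal(clean.shape)
    return EEGRecording(samples=noisy, rate=src.rate,
                        channel_names=list(lf.sensor_names))


def simulate_scenario(scn: SimScenario,
                      head: SphericalHeadSpec | None = None
                      ) -> tuple[EEGRecording, RegionTimeSeries, LeadField]:
    """Sources -> lead field -> scalp recording, all from one scenario."""
    if head is None:
        head = default_head(n_sources=scn.n_regions)
    lf = make_lead_field(head)
    src = simulate_sources(scn)
    # per-stage seeds derived from the scenario seed
    rec = project_to_scalp(src, lf, snr=scn.sensor_snr, seed=scn.seed + 1)
    return rec, src, lf


# ---------------------------------------------------------------------------
# Bistable Langevin oracle
# ---------------------------------------------------------------------------

def simulate_bistable(coupling: np.ndarray, D, seed: int, t_max: float,
                      dt: float = 0.01, x0=-1.0,
                      coupling_gain: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Euler--Maruyama trajectories of the coupled double-well system

        dx_i = (x_i - x_i^3 + c * sum_j W[j, i] x_j) dt + sqrt(2 D_i dt) xi

    starting at the resting attractor (or given ``x0``).  Returns
    ``(t, X)`` with ``X`` of shape (n_nodes, n_steps + 1).  This is the
    plain direct-coupling form used as an independent oracle for the
    seizure-index integrator.
    """
    W = np.asarray(coupling, float)
    n = W.shape[0]
    D = np.broadcast_to(np.asarray(D, float), (n,)).copy()
    if np.any(D < 0):
        raise ValueError("noise intensity D must be non-negative")
    n_steps = int(round(t_max / dt))
    rng = np.random.default_rng(seed)
    x = np.broadcast_to(np.asarray(x0, float), (n,)).astype(float).copy()
    out = np.empty((n, n_steps + 1))
    out[:, 0] = x
    amp = np.sqrt(2.0 * D * dt)
    WT = W.T  # (W.T @ x)_i = sum_j W[j, i] x_j
    for k in range(1, n_steps + 1):
        drift = x - x ** 3 + coupling_gain * (WT @ x)
        x = x + dt * drift + amp * rng.standard_normal(n)
        out[:, k] = x
    t = dt * np.arange(n_steps + 1)
    return t, out
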