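"""sLORETA inverse solution and region time-series extraction.

The forward model is a lead field ``G`` (sensors x sources) mapping unit
dipole moments to scalp potentials.  The minimum-norm kernel is

    T = G' (G G' + alpha I)^+

optionally after projecting out the common-average reference.  sLORETA
standardizes the minimum-norm estimate by the square root of the
resolution-derived variance ``R_jj = (T G)_jj`` (the diagonal of the model
covariance of the estimate under the assumed data covariance
``G G' + alpha I``):

    s_hat_j(t) = (T y(t))_j / sqrt(R_jj)

With scalar (fixed-orientation) sources this estimator has zero
localization error for a noiseless single dipole at any alpha >= 0: the
resolution matrix ``R = T G`` is positive semidefinite, so by
Cauchy--Schwarz ``R_ij^2 <= R_ii R_jj`` and the standardized response peaks
at the true source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io_formats import EEGRecording, ParcellationTable

logger = logging.getLogger(__name__)

__all__ = [
    "LeadField",
    "InverseOperator",
    "SourceEstimate",
    "RegionTimeSeries",
    "build_inverse",
    "apply_sloreta",
    "extract_regions",
    "read_lead_field",
    "write_lead_field",
]


@dataclass
class LeadField:
    """Forward operator: scalp potential per unit dipole moment."""

    G: np.ndarray                      # (n_sensors, n_sources)
    sensor_names: list[str]
    source_ids: list[int]              # 1-based source/region ids

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.ndim != 2:
            raise ValueError("lead field must be 2-D (sensors x sources)")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("lead field contains non-finite entries")
        norms = np.linalg.norm(self.G, axis=0)
        if np.any(norms == 0):
            bad = int(np.flatnonzero(norms == 0)[0])
            raise ValueError(f"lead-field column {bad} is all-zero")
        if len(self.sensor_names) != self.G.shape[0]:
            raise ValueError("sensor_names length mismatch")
        if len(self.source_ids) != self.G.shape[1]:
            raise ValueError("source_ids length mismatch")

    @property
    def n_sensors(self) -> int:
        return self.G.shape[0]

    @property
    def n_sources(self) -> int:
        return self.G.shape[1]


@dataclass
class InverseOperator:
    T: np.ndarray                      # (n_sources, n_sensors)
    alpha: float
    R_diag: np.ndarray                 # per-source standardization variance
    sensor_names: list[str]
    avg_ref: bool

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if np.any(self.R_diag <= 0):
            raise ValueError("standardization factors must be positive")


@dataclass
class SourceEstimate:
    """Standardized current-density time courses, sources x time."""

    s_hat: np.ndarray
    rate: float


@dataclass
class RegionTimeSeries:
    """Per-region source signals (rows ordered by ``region_ids``)."""

    x: np.ndarray                      # (n_regions, n_times)
    region_ids: list[int]
    rate: float

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 2:
            raise ValueError("region series must be 2-D")
        if len(self.region_ids) != self.x.shape[0]:
            raise ValueError("region_ids length mismatch")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("region series contain non-finite values")

    @property
    def n_regions(self) -> int:
        return self.x.shape[0]


def _avg_ref_projector(n: int) -> np.ndarray:
    return np.eye(n) - np.full((n, n), 1.0 / n)


def build_inverse(lf: LeadField, alpha: float | str = "auto",
                  avg_ref: bool = True, snr: float = 3.0) -> InverseOperator:
    """Assemble the sLORETA kernel and standardization factors.

    ``alpha="auto"`` sets the Tikhonov parameter from an assumed amplitude
    SNR (default 3): ``alpha = trace(G G') / (n_sensors * snr**2)``.
    """
    G = lf.G.copy()
    if avg_ref:
        G = _avg_ref_projector(lf.n_sensors) @ G
    gram = G @ G.T
    if alpha == "auto":
        alpha_val = float(np.trace(gram)) / (lf.n_sensors * snr ** 2)
    else:
        alpha_val = float(alpha)
        if alpha_val < 0:
            raise ValueError("alpha must be non-negative")
    if not np.any(G):
        raise ValueError("lead field is zero after referencing")
    # pinv covers the alpha = 0 / average-referenced (rank-deficient) case
    T = G.T @ np.linalg.pinv(gram + alpha_val * np.eye(lf.n_sensors),
                             hermitian=True)
    R_diag = np.einsum("ij,ji->i", T, G)
    if np.any(R_diag <= 0):
        raise ValueError("non-positive resolution variance; check lead field")
    return InverseOperator(T=T, alpha=alpha_val, R_diag=R_diag,
                           sensor_names=list(lf.sensor_names), avg_ref=avg_ref)


def apply_sloreta(inv: InverseOperator, rec: EEGRecording) -> SourceEstimate:
    """Standardized source estimate for every sample of ``rec``."""
    if list(rec.channel_names) != list(inv.sensor_names):
        unmatched = [a for a, b in zip(rec.channel_names, inv.sensor_names)
                     if a != b]
        extra = set(rec.channel_names).symmetric_difference(inv.sensor_names)
        raise ValueError(
            "channel order does not match inverse operator sensors; "
            f"mismatched: {sorted(extra) or unmatched}"
        )
    y = rec.samples
    if inv.avg_ref:
        y = y - y.mean(axis=0, keepdims=True)
    s = (inv.T @ y) / np.sqrt(inv.R_diag)[:, None]
    return SourceEstimate(s_hat=s, rate=rec.rate)


def extract_regions(src: SourceEstimate,
                    parc: ParcellationTable) -> RegionTimeSeries:
    """Average member-vertex series per region with sign alignment.

    Fixed-orientation source series carry an arbitrary sign; each member
    vertex is flipped when negatively correlated with the region's first
    member before averaging, so anti-phase vertices reinforce instead of
    cancelling.
    """
    n_src = src.s_hat.shape[0]
    rows = []
    for rid, verts in zip(parc.region_ids, parc.vertex_ids):
        if any(v < 0 or v >= n_src for v in verts):
            raise ValueError(
                f"region {rid} references a vertex outside 0..{n_src - 1}"
            )
        member = src.s_hat[verts]
        ref = member[0]
        signs = np.ones(len(verts))
        denom = np.linalg.norm(ref)
        for k in range(1, len(verts)):
            other = member[k]
            if denom > 0 and np.linalg.norm(other) > 0:
                if float(ref @ other) < 0:
                    signs[k] = -1.0
        rows.append((signs[:, None] * member).mean(axis=0))
    order = np.argsort(parc.region_ids)
    x = np.array(rows)[order]
    ids = [parc.region_ids[i] for i in order]
    return RegionTimeSeries(x=x, region_ids=ids, rate=src.rate)


# ---------------------------------------------------------------------------
# Lead-field TSV
# ---------------------------------------------------------------------------

def write_lead_field(lf: LeadField, path) -> None:
    """Sensors x sources TSV; first row source ids, first column sensor names."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sensor\t" + "\t".join(str(s) for s in lf.source_ids) + "\n")
        for name, row in zip(lf.sensor_names, lf.G):
            fh.write(name + "\t" + "\t".join("%.17g" % v for v in row) + "\n")


def read_lead_field(path) -> LeadField:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return LeadField(
        G=df.to_numpy(dtype=float),
        sensor_names=[str(s) for s in df.index],
        source_ids=[int(c) for c in df.columns],
    )
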