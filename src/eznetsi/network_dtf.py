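"""MVAR fitting, directed transfer function, band networks and
degree-centrality hub detection.

The directed transfer function (DTF) of a stable MVAR model
``x_t = sum_k A_k x_{t-k} + e_t`` is computed from the transfer matrix
``H(f) = (I - sum_k A_k exp(-i 2 pi f k / rate))^{-1}`` with the
Kaminski--Blinowska normalization

    gamma2[i, j](f) = |H_ij(f)|^2 / sum_m |H_im(f)|^2

where *i* is the sink and *j* the source, so inflows to every sink sum to
one at each frequency.  Band-averaged networks are stored with the
``W[source, sink]`` convention (the DTF tensor is transposed on ingestion),
which makes out-degree a row sum.

Because 68 regions are reconstructed from 21 sensors, the per-epoch least
squares problem is rank deficient; the estimator is therefore
ridge-regularized multichannel least squares pooling 2-s epochs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .inverse_imaging import RegionTimeSeries
from .preprocessing import EpochSet
from .spectral import BandScheme

logger = logging.getLogger(__name__)

__all__ = [
    "MVARModel", "DTFTensor", "AdjacencyMatrix", "NodeMetrics",
    "fit_mvar", "compute_dtf", "band_network", "epochwise_band_network",
    "sparsity_threshold", "degree_metrics", "auc_over_thresholds",
    "normalize_and_hub", "node_metrics", "default_densities",
    "random_stable_var",
]


@dataclass
class MVARModel:
    A: np.ndarray                      # (p, n, n) coefficient matrices
    rate: float
    Sigma: np.ndarray                  # innovation covariance
    ridge: float
    stable: bool = True

    @property
    def p(self) -> int:
        return self.A.shape[0]

    @property
    def n(self) -> int:
        return self.A.shape[1]

    def companion_radius(self) -> float:
        p, n = self.p, self.n
        comp = np.zeros((n * p, n * p))
        comp[:n, :] = np.concatenate(list(self.A), axis=1)
        if p > 1:
            comp[n:, :-n] = np.eye(n * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass
class DTFTensor:
    """Normalized DTF, indexed ``gamma2[sink, source, freq]``."""

    gamma2: np.ndarray
    freqs: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.gamma2 < -1e-12) or np.any(self.gamma2 > 1 + 1e-12):
            raise ValueError("gamma2 values must lie in [0, 1]")


@dataclass
class AdjacencyMatrix:
    """Directed band network, ``W[source, sink]`` non-negative weights."""

    W: np.ndarray
    band: str
    density: float = 1.0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, float)
        if np.any(np.diag(self.W) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if np.any(self.W < 0):
            raise ValueError("adjacency weights must be non-negative")

    @property
    def n(self) -> int:
        return self.W.shape[0]


@dataclass
class NodeMetrics:
    """Per-region centrality scores for one band.

    ``raw`` holds unthresholded degree sums, ``auc`` the sparsity-sweep
    integrals, ``normalized`` the AUC scaled to max 1, ``hubs`` the 0-based
    region indices with normalized value >= the hub cutoff.
    """

    band: str
    raw: dict = field(default_factory=dict)
    auc: dict = field(default_factory=dict)
    normalized: dict = field(default_factory=dict)
    hubs: dict = field(default_factory=dict)
    cutoff: float = 0.95


# ---------------------------------------------------------------------------
# MVAR estimation
# ---------------------------------------------------------------------------

def _segments(x) -> tuple[list[np.ndarray], float]:
    if isinstance(x, RegionTimeSeries):
        return [x.x], x.rate
    if isinstance(x, EpochSet):
        return [ep for ep in x.epochs], x.rate
    arr = np.asarray(x, float)
    if arr.ndim == 2:
        return [arr], float("nan")
    raise TypeError("expected RegionTimeSeries, EpochSet or 2-D array")


def _design(segments: list[np.ndarray], p: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack lagged predictors across segments: Y_t ~ [x_{t-1}..x_{t-p}]."""
    Xs, Ys = [], []
    for seg in segments:
        n, T = seg.shape
        if T <= p:
            continue
        Y = seg[:, p:].T                               # (T-p, n)
        X = np.concatenate([seg[:, p - k:T - k].T for k in range(1, p + 1)],
                           axis=1)                     # (T-p, n*p)
        Xs.append(X)
        Ys.append(Y)
    if not Xs:
        raise ValueError(f"no segment long enough for order {p}")
    return np.concatenate(Xs), np.concatenate(Ys)


def _fit_order(segments, p, ridge, rate) -> MVARModel:
    X, Y = _design(segments, p)
    n = Y.shape[1]
    XtX = X.T @ X
    lam = ridge * float(np.mean(np.diag(XtX))) if ridge > 0 else 0.0
    M = XtX + lam * np.eye(XtX.shape[0])
    try:
        B = np.linalg.solve(M, X.T @ Y)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular MVAR design; refit with ridge > 0"
        ) from exc
    if ridge == 0 and np.linalg.matrix_rank(XtX) < XtX.shape[0]:
        raise np.linalg.LinAlgError(
            "rank-deficient MVAR design; refit with ridge > 0"
        )
    resid = Y - X @ B
    dof = max(X.shape[0] - n * p, 1)
    Sigma = resid.T @ resid / dof
    A = np.stack([B[k * n:(k + 1) * n, :].T for k in range(p)])
    model = MVARModel(A=A, rate=rate, Sigma=Sigma, ridge=ridge)
    radius = model.companion_radius()
    if radius >= 1.0:
        logger.warning("fitted MVAR is unstable (spectral radius %.3f)", radius)
        model.stable = False
    return model


def _bic(segments, p, ridge, rate, trim: int) -> float:
    """BIC with a common effective sample (all orders trimmed at ``trim``)."""
    trimmed = [seg[:, trim - p:] for seg in segments]
    model = _fit_order(trimmed, p, ridge, rate)
    X, Y = _design(trimmed, p)
    N, n = Y.shape
    sign, logdet = np.linalg.slogdet(model.Sigma)
    if sign <= 0:
        logdet = np.sum(np.log(np.maximum(
            np.linalg.eigvalsh(model.Sigma), 1e-12)))
    return N * logdet + math.log(N) * p * n * n


def fit_mvar(x, p: int | str = "auto", ridge: float = 1e-3,
             max_order: int = 10, rate: float | None = None) -> MVARModel:
    """Ridge-regularized least-squares MVAR, pooling epochs as independent
    realizations.  ``p="auto"`` minimizes BIC over orders 1..max_order."""
    segments, own_rate = _segments(x)
    rate = own_rate if rate is None else rate
    if p == "auto":
        usable = min(seg.shape[1] for seg in segments) - 1
        orders = range(1, min(max_order, usable) + 1)
        trim = max(orders)
        scores = {q: _bic(segments, q, ridge, rate, trim) for q in orders}
        p = min(scores, key=scores.get)
        logger.info("auto MVAR order: %d (BIC)", p)
    p = int(p)
    if p < 1:
        raise ValueError("model order must be >= 1")
    return _fit_order(segments, p, ridge, rate)


# ---------------------------------------------------------------------------
# DTF
# ---------------------------------------------------------------------------

def compute_dtf(m: MVARModel, freqs: np.ndarray) -> DTFTensor:
    """Normalized DTF on a frequency grid (Hz)."""
    freqs = np.asarray(freqs, float)
    n, p = m.n, m.p
    gamma2 = np.empty((n, n, freqs.size))
    eye = np.eye(n)
    for fi, f in enumerate(freqs):
        z = np.exp(-2j * np.pi * f * np.arange(1, p + 1) / m.rate)
        Af = eye - np.tensordot(z, m.A, axes=(0, 0))
        try:
            H = np.linalg.inv(Af)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"A(f) singular at f = {f} Hz; model on the unit circle"
            ) from exc
        P = np.abs(H) ** 2
        gamma2[:, :, fi] = P / P.sum(axis=1, keepdims=True)
    return DTFTensor(gamma2=gamma2, freqs=freqs)


def band_network(dtf: DTFTensor, scheme: BandScheme, band: str,
                 ) -> AdjacencyMatrix:
    """Band-mean DTF, transposed to ``W[source, sink]``, diagonal zeroed."""
    lo, hi = scheme.edges(band)
    mask = (dtf.freqs >= lo) & (dtf.freqs < hi)
    if not mask.any():
        raise ValueError(f"band {band} contains no DTF frequencies")
    mean_sink_source = dtf.gamma2[:, :, mask].mean(axis=2)
    W = mean_sink_source.T.copy()
    np.fill_diagonal(W, 0.0)
    return AdjacencyMatrix(W=W, band=band, density=1.0)


def epochwise_band_network(epochs: EpochSet, scheme: BandScheme, band: str,
                           order: int | str = "auto", ridge: float = 1e-3,
                           max_order: int = 10, n_freqs: int = 81,
                           f_max: float | None = None) -> AdjacencyMatrix:
    """Dynamic directed network: per-epoch MVAR/DTF, band networks averaged
    over the window.  The model order is selected once on the pooled epochs
    and reused for every epoch."""
    if order == "auto":
        pooled = fit_mvar(epochs, p="auto", ridge=ridge, max_order=max_order)
        order = pooled.p
    f_max = f_max if f_max is not None else epochs.rate / 2.0
    freqs = np.linspace(0.0, f_max, n_freqs)
    acc = None
    for ep in epochs.epochs:
        m = _fit_order([ep], int(order), ridge, epochs.rate)
        W = band_network(compute_dtf(m, freqs), scheme, band).W
        acc = W if acc is None else acc + W
    return AdjacencyMatrix(W=acc / epochs.n_epochs, band=band, density=1.0)


# ---------------------------------------------------------------------------
# Graph metrics
# ---------------------------------------------------------------------------

def default_densities() -> np.ndarray:
    """Proportional-threshold sweep 0.05..0.50 in steps of 0.05."""
    return np.round(np.arange(0.05, 0.501, 0.05), 10)


def sparsity_threshold(adj: AdjacencyMatrix, density: float) -> AdjacencyMatrix:
    """Keep the ``ceil(density * n_offdiag)`` strongest directed edges
    (weights retained); ties broken by (source, sink) index order."""
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    n = adj.n
    src, snk = np.where(~np.eye(n, dtype=bool))
    w = adj.W[src, snk]
    keep = math.ceil(density * len(w))
    order = np.lexsort((snk, src, -w))       # weight desc, then index order
    sel = order[:keep]
    W = np.zeros_like(adj.W)
    W[src[sel], snk[sel]] = w[sel]
    return AdjacencyMatrix(W=W, band=adj.band, density=density)


def degree_metrics(adj: AdjacencyMatrix) -> dict[str, np.ndarray]:
    """Weighted degree centralities: dc = dc_in + dc_out per region."""
    if np.any(adj.W < 0):
        raise ValueError("negative edge weight")
    dc_out = adj.W.sum(axis=1)
    dc_in = adj.W.sum(axis=0)
    return {"dc": dc_in + dc_out, "dc_in": dc_in, "dc_out": dc_out}


def auc_over_thresholds(adj: AdjacencyMatrix, densities
                        ) -> dict[str, np.ndarray]:
    """Trapezoidal integral of each metric over the density grid."""
    densities = np.asarray(densities, float)
    if densities.size < 2:
        raise ValueError("need at least two densities")
    if np.any(np.diff(densities) < 0):
        logger.info("sorting unsorted density grid")
        densities = np.sort(densities)
    curves: dict[str, list[np.ndarray]] = {"dc": [], "dc_in": [], "dc_out": []}
    for d in densities:
        mets = degree_metrics(sparsity_threshold(adj, float(d)))
        for k in curves:
            curves[k].append(mets[k])
    return {
        k: np.trapezoid(np.array(v), densities, axis=0)
        for k, v in curves.items()
    }


def normalize_and_hub(scores: np.ndarray, cutoff: float = 0.95
                      ) -> tuple[np.ndarray, set[int]]:
    """Scale to max 1 and flag regions at or above the hub cutoff."""
    scores = np.asarray(scores, float)
    top = scores.max() if scores.size else 0.0
    if top <= 0:
        logger.warning("all-zero scores: empty hub set")
        return np.zeros_like(scores), set()
    normalized = scores / top
    hubs = set(np.flatnonzero(normalized >= cutoff).tolist())
    if len(hubs) == len(scores):
        logger.info("degenerate scores: every region is a hub")
    return normalized, hubs


def node_metrics(adj: AdjacencyMatrix, densities=None,
                 cutoff: float = 0.95) -> NodeMetrics:
    """Full scoring of one band network: raw degrees, threshold-sweep AUC,
    normalization and >= cutoff hub sets for dc, dc_in and dc_out."""
    densities = default_densities() if densities is None else densities
    out = NodeMetrics(band=adj.band, cutoff=cutoff)
    out.raw = degree_metrics(adj)
    out.auc = auc_over_thresholds(adj, densities)
    for key, auc in out.auc.items():
        norm, hubs = normalize_and_hub(auc, cutoff)
        out.normalized[key] = norm
        out.hubs[key] = hubs
    return out


# ---------------------------------------------------------------------------
# Test/simulation helper
# ---------------------------------------------------------------------------

def random_stable_var(n: int, p: int, seed: int, scale: float = 0.9
                      ) -> np.ndarray:
    """Random VAR coefficients rescaled to companion spectral radius
    ``scale`` (< 1)."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((p, n, n)) / np.sqrt(n * p)
    for _ in range(100):
        model = MVARModel(A=A, rate=1.0, Sigma=np.eye(n), ridge=0.0)
        rho = model.companion_radius()
        if rho < scale:
            break
        A = A * (scale / rho) ** (1.0 / 1.0)
    return A
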