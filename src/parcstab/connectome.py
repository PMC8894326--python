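"""Vertex time series → parcel time series → thresholded connectivity matrices.

The functional-connectome pipeline is deliberately minimal: per-vertex BOLD
series are detrended with an ordinary least-squares line (low-frequency drift
removal), averaged within parcels, correlated (Pearson) between parcels, and
thresholded at a fixed correlation cutoff τ to produce weighted and binary
adjacency matrices.  Inputs are assumed otherwise preprocessed.

Thresholding policy: by default an edge is kept iff ``r > τ`` on the *signed*
correlation — negative correlations are never kept, and ties at exactly τ are
dropped.  An absolute-value policy (``|r| > τ``) is available via
``policy="absolute"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import Parcellation

__all__ = [
    "ConnectivityMatrix",
    "AdjacencyMatrix",
    "detrend_linear",
    "extract_parcel_timeseries",
    "correlation_matrix",
    "threshold_matrix",
    "build_adjacencies",
]

THRESHOLDS = (0.1, 0.2, 0.3, 0.4)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """P×P Pearson correlation matrix between parcel-mean time series."""

    values: np.ndarray
    parcel_ids: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("connectivity matrix must be symmetric")


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Thresholded connectivity: ``mode`` is 'weighted' or 'binary' at threshold τ."""

    values: np.ndarray
    mode: str
    threshold: float
    parcel_ids: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.values, k=1)))


def detrend_linear(ts: np.ndarray) -> np.ndarray:
    """Remove the least-squares line (intercept + slope) from each column.

    ``ts`` is time × vertices.  Residuals have zero mean and zero linear trend.
    """
    ts = np.asarray(ts, float)
    if ts.ndim == 1:
        ts = ts[:, None]
    t_len = ts.shape[0]
    if t_len < 3:
        raise ValueError(f"need at least 3 time points, got {t_len}")
    t = np.arange(t_len, dtype=float)
    design = np.column_stack([np.ones(t_len), t])
    coef, *_ = np.linalg.lstsq(design, ts, rcond=None)
    return ts - design @ coef


def extract_parcel_timeseries(ts: np.ndarray, parc: Parcellation
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted mean vertex series per parcel.

    Returns ``(time × parcels array, parcel_ids)`` with columns ordered by
    ``parc.parcel_ids``.
    """
    ts = np.asarray(ts, float)
    if ts.ndim != 2 or ts.shape[1] != parc.v_tot:
        raise ValueError(
            f"time series must be time × {parc.v_tot} vertices, got {ts.shape}")
    dense = parc.dense_labels()
    p = parc.n_parcels
    sums = np.zeros((ts.shape[0], p))
    for k in range(p):
        sums[:, k] = ts[:, dense == k].mean(axis=1)
    return sums, parc.parcel_ids.copy()


def correlation_matrix(parcel_ts: np.ndarray,
                       parcel_ids: np.ndarray | None = None) -> ConnectivityMatrix:
    """Pearson correlation between parcel time-series columns."""
    parcel_ts = np.asarray(parcel_ts, float)
    stds = parcel_ts.std(axis=0)
    if (stds == 0).any():
        dead = np.flatnonzero(stds == 0)
        names = parcel_ids[dead] if parcel_ids is not None else dead
        raise ValueError(f"zero-variance parcel time series: {names.tolist()}")
    c = np.corrcoef(parcel_ts, rowvar=False)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    if parcel_ids is None:
        parcel_ids = np.arange(parcel_ts.shape[1])
    return ConnectivityMatrix(values=c, parcel_ids=np.asarray(parcel_ids))


def threshold_matrix(conn: ConnectivityMatrix, tau: float, mode: str = "weighted",
                     policy: str = "signed") -> AdjacencyMatrix:
    """Apply a fixed correlation threshold τ ∈ (0, 1).

    ``mode='weighted'`` keeps the correlation as edge weight, ``'binary'``
    writes 1; the diagonal is always zero.
    """
    if not 0 < tau < 1:
        raise ValueError(f"threshold must be in (0, 1), got {tau}")
    if mode not in ("weighted", "binary"):
        raise ValueError(f"mode must be 'weighted' or 'binary', got {mode!r}")
    if policy not in ("signed", "absolute"):
        raise ValueError(f"policy must be 'signed' or 'absolute', got {policy!r}")
    c = conn.values
    keep = (np.abs(c) > tau) if policy == "absolute" else (c > tau)
    np.fill_diagonal(keep, False)
    if mode == "binary":
        a = keep.astype(float)
    else:
        a = np.where(keep, c, 0.0)
    return AdjacencyMatrix(values=a, mode=mode, threshold=tau,
                           parcel_ids=conn.parcel_ids)


def build_adjacencies(ts: np.ndarray, parc: Parcellation,
                      thresholds: tuple[float, ...] = THRESHOLDS,
                      policy: str = "signed", detrend: bool = True
                      ) -> dict[float, tuple[AdjacencyMatrix, AdjacencyMatrix]]:
    """Full pipeline: detrend → parcel means → Pearson → (weighted, binary) per τ."""
    if detrend:
        ts = detrend_linear(ts)
    pts, ids = extract_parcel_timeseries(ts, parc)
    conn = correlation_matrix(pts, ids)
    return {tau: (threshold_matrix(conn, tau, "weighted", policy),
                  threshold_matrix(conn, tau, "binary", policy))
            for tau in thresholds}
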