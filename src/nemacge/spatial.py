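"""Distances, equiprobable binning, distance curves and exponential fits.

Connection probability and CGE are examined as a function of Euclidean
separation, stratified by the anatomical regions of the two neurons
(head/body/tail).  Curves are estimated in equiprobable (quantile) bins
and summarized by a bounded least-squares fit of

    f(x) = A exp(-lambda x) + B,     A >= 0, lambda >= 0.

Connection probability uses ordered (directed) pairs; CGE curves use
unordered pairs with masked (bilateral) entries excluded.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial.distance import squareform, pdist

from .cge import CGEMatrix
from .connectome import Connectome
from .errors import ArgumentError, DataError

logger = logging.getLogger(__name__)

#: default strata for connection-probability curves (source, target)
DEFAULT_STRATA = [
    ("head", "head"), ("head", "tail"), ("tail", "head"), ("tail", "tail"),
    ("body", "body"), ("body", "head"), ("body", "tail"),
    ("head", "body"), ("tail", "body"),
]


@dataclass
class ExponentialFit:
    """Parameters of f(x) = A exp(-lambda x) + B with the fit's SSE."""

    A: float
    lam: float
    B: float
    sse: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.A * np.exp(-self.lam * np.asarray(x, dtype=float)) + self.B

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["lambda"] = d.pop("lam")
        Path(path).write_text(json.dumps(d, indent=2))


def pairwise_distances(neurons: pd.DataFrame) -> np.ndarray:
    """Symmetric 2-D Euclidean distance matrix (micrometres) from a neuron table."""
    pos = neurons[["x_um", "y_um"]].to_numpy(dtype=float)
    if np.isnan(pos).any():
        missing = neurons.loc[np.isnan(pos).any(axis=1), "neuron"].tolist()
        raise DataError(f"missing coordinates for neurons: {missing}")
    return squareform(pdist(pos))


def equiprobable_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile-based bin edges so per-bin counts differ by at most one.

    Ties are assigned to the lower bin (np.digitize right=True below).
    Degenerate inputs (all values identical) collapse to one effective bin
    with a warning.
    """
    values = np.asarray(values, dtype=float)
    if n_bins < 1:
        raise ArgumentError("n_bins must be >= 1")
    if n_bins > len(values):
        raise ArgumentError(f"n_bins={n_bins} exceeds number of values ({len(values)})")
    edges = np.quantile(values, np.linspace(0, 1, n_bins + 1))
    if np.unique(edges).size < edges.size:
        warnings.warn("degenerate bin edges (mass ties); fewer effective bins")
        edges = np.unique(edges)
        if edges.size == 1:
            edges = np.array([edges[0], edges[0]])
    return edges


def _bin_table(
    d: np.ndarray, v: np.ndarray, edges: np.ndarray, statistic: str
) -> pd.DataFrame:
    """Per-bin centre/extent plus probability or mean +/- sd of ``v``."""
    # right-closed bins assign ties to the lower bin; clip puts the
    # minimum into bin 0
    which = np.clip(np.digitize(d, edges[1:-1], right=True), 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        if not sel.any():
            continue
        db = d[sel]
        vb = v[sel]
        row = {
            "bin_center": float(db.mean()),
            "bin_min": float(db.min()),
            "bin_max": float(db.max()),
            "count": int(sel.sum()),
        }
        if statistic == "probability":
            row["value"] = float(vb.mean())
            # binomial standard error as dispersion
            row["dispersion"] = float(np.sqrt(row["value"] * (1 - row["value"]) / len(vb)))
        else:
            row["value"] = float(np.nanmean(vb))
            row["dispersion"] = float(np.nanstd(vb))
        rows.append(row)
    return pd.DataFrame(rows, columns=["bin_center", "bin_min", "bin_max",
                                       "value", "dispersion", "count"])


def fit_exponential(x: np.ndarray, y: np.ndarray) -> ExponentialFit | None:
    """Bounded least-squares exponential fit on bin centres.

    Initialization: A0 = max(y) - min(y), B0 = min(y),
    lambda0 = 1 / median(x); bounds A >= 0, lambda >= 0.  Returns None
    (with a warning) when fewer than three points are available.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        warnings.warn("fewer than 3 bins; exponential fit skipped")
        return None
    a0 = max(y.max() - y.min(), 1e-12)
    b0 = y.min()
    lam0 = 1.0 / max(np.median(x), 1e-12)

    def f(x, a, lam, b):
        return a * np.exp(-lam * x) + b

    try:
        popt, _ = curve_fit(
            f, x, y, p0=[a0, lam0, b0],
            bounds=([0, 0, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=20000, xtol=1e-8, ftol=1e-8,
        )
    except RuntimeError:
        warnings.warn("exponential fit did not converge")
        return None
    sse = float(((f(x, *popt) - y) ** 2).sum())
    return ExponentialFit(A=float(popt[0]), lam=float(popt[1]), B=float(popt[2]), sse=sse)


def connection_probability_curve(
    c: Connectome,
    distances: np.ndarray,
    source_region: str,
    target_region: str,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, ExponentialFit | None]:
    """Binned connection probability vs distance for one region stratum.

    Probability per bin is connected ordered pairs / total ordered pairs
    whose source lies in ``source_region`` and target in ``target_region``.
    """
    if c.neuron_table is None:
        raise DataError("connectome carries no neuron table with regions")
    region = c.neuron_table.set_index("neuron").loc[c.neurons, "region"].to_numpy()
    src_sel = np.nonzero(region == source_region)[0]
    dst_sel = np.nonzero(region == target_region)[0]
    if len(src_sel) == 0 or len(dst_sel) == 0:
        raise DataError(f"empty stratum {source_region}->{target_region}")
    A = c.adjacency()
    ii, jj = np.meshgrid(src_sel, dst_sel, indexing="ij")
    keep = ii != jj
    ii, jj = ii[keep], jj[keep]
    if len(ii) == 0:
        raise DataError(f"stratum {source_region}->{target_region} has no ordered pairs")
    d = distances[ii, jj]
    connected = A[ii, jj].astype(float)
    n_bins_eff = min(n_bins, len(d))
    edges = equiprobable_bins(d, n_bins_eff)
    curve = _bin_table(d, connected, edges, statistic="probability")
    fit = fit_exponential(curve["bin_center"].to_numpy(), curve["value"].to_numpy())
    return curve, fit


def cge_distance_curve(
    cge: CGEMatrix,
    distances: np.ndarray,
    stratum: np.ndarray | None = None,
    n_bins: int = 7,
) -> tuple[pd.DataFrame, ExponentialFit | None]:
    """Mean +/- sd of unmasked CGE in equiprobable distance bins.

    ``stratum`` is an optional boolean neuron mask restricting to pairs
    within a subset (e.g. head neurons).  Masked (bilateral, undefined)
    pair values never contribute.
    """
    n = len(cge.neurons)
    iu, ju = np.triu_indices(n, 1)
    if stratum is not None:
        stratum = np.asarray(stratum, dtype=bool)
        keep = stratum[iu] & stratum[ju]
        iu, ju = iu[keep], ju[keep]
    v = cge.values[iu, ju]
    ok = ~np.isnan(v)
    if ok.sum() == 0:
        raise DataError("no unmasked pairs in stratum")
    d = distances[iu, ju][ok]
    v = v[ok]
    n_bins_eff = min(n_bins, len(d))
    edges = equiprobable_bins(d, n_bins_eff)
    curve = _bin_table(d, v, edges, statistic="mean")
    fit = fit_exponential(curve["bin_center"].to_numpy(), curve["value"].to_numpy())
    return curve, fit


def residualize(
    values: np.ndarray, distances: np.ndarray, fit: ExponentialFit
) -> np.ndarray:
    """Residuals value - f(distance); NaN (masked) entries stay NaN."""
    return np.asarray(values, dtype=float) - fit.predict(distances)
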