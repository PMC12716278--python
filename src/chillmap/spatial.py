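"""Suitability mapping: ordinary kriging of station mortalities onto a
lat/lon lattice, five-class habitat labelling, and occurrence handling.

Distances are great-circle (haversine, mean Earth radius 6371.0088 km).
The kriging neighbourhood follows the GIS convention of a *variable search
radius with 12 points*: each grid cell is predicted from its 12 nearest
stations; a dense all-station solve is available (``k_neighbors=None``) and
serves as the reference implementation in tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "EARTH_RADIUS_KM",
    "SUITABILITY_CLASSES",
    "SuitabilityGrid",
    "haversine_km",
    "empirical_variogram",
    "fit_spherical",
    "spherical",
    "krige",
    "make_grid",
    "classify",
    "thin_occurrences",
    "extract_and_summarize",
]

EARTH_RADIUS_KM = 6371.0088

#: class label -> (lower, upper]; the first interval is closed at 0.
#: Mortality <= 0.25 is highly suitable habitat; > 0.95 completely
#: unsuitable.  The published bin edges have printer's gaps/overlaps; this
#: half-open partition keeps the lower anchors and covers [0, 1] exactly.
SUITABILITY_CLASSES = (
    ("highly suitable", 0.00, 0.25),
    ("moderately suitable", 0.25, 0.50),
    ("moderately unsuitable", 0.50, 0.75),
    ("highly unsuitable", 0.75, 0.95),
    ("completely unsuitable", 0.95, 1.00),
)

SUITABLE_LABELS = frozenset({"highly suitable", "moderately suitable"})


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km; broadcasts over arrays."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def _pairwise_km(lat, lon):
    return haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])


# ---------------------------------------------------------------------------
# variogram


def empirical_variogram(points: np.ndarray, values: np.ndarray, n_bins: int = 12):
    """Matheron semivariance estimator binned by great-circle distance.

    ``points`` is (n, 2) of (lat, lon).  Bin edges are equal-width from 0 to
    half the maximum pairwise distance.  Returns a DataFrame with columns
    ``distance_km`` (bin centre), ``semivariance``, ``n_pairs`` and a
    ``flat`` attribute flag when every value is identical.
    """
    points = np.asarray(points, float)
    values = np.asarray(values, float)
    if len(points) < 2:
        raise ValueError("need at least two points")
    lat, lon = points[:, 0], points[:, 1]
    D = _pairwise_km(lat, lon)
    iu = np.triu_indices(len(values), k=1)
    d = D[iu]
    sq = (values[iu[0]] - values[iu[1]]) ** 2 / 2.0
    flat = bool(np.all(values == values[0]))
    hmax = d.max() / 2.0
    if not np.any(d <= hmax):  # e.g. a single pair: keep it rather than nothing
        hmax = d.max()
    if hmax <= 0:
        raise ValueError("all points are co-located")
    edges = np.linspace(0.0, hmax, n_bins + 1)
    which = np.digitize(d, edges[1:-1])
    inside = d <= hmax
    rows = []
    for b in range(n_bins):
        m = inside & (which == b)
        if not m.any():
            continue
        rows.append(
            {
                "distance_km": 0.5 * (edges[b] + edges[b + 1]),
                "semivariance": float(sq[m].mean()),
                "n_pairs": int(m.sum()),
            }
        )
    vg = pd.DataFrame(rows)
    vg.attrs["flat"] = flat
    return vg


def spherical(h, nugget, psill, rng):
    """Spherical semivariogram model; sill = nugget + psill at h >= range."""
    h = np.asarray(h, float)
    hr = np.clip(h / max(rng, 1e-12), 0.0, 1.0)
    return nugget + psill * (1.5 * hr - 0.5 * hr**3)


def fit_spherical(variogram: pd.DataFrame):
    """Weighted least-squares spherical fit (weights = pair counts).

    Returns ``(nugget, psill, range_km)``; on failure or a flat variogram,
    falls back to a pure-nugget-free ``(0, var, half-max-distance)`` guess
    with ``fallback=True`` in the returned dict.
    """
    h = variogram["distance_km"].to_numpy()
    g = variogram["semivariance"].to_numpy()
    w = variogram["n_pairs"].to_numpy().astype(float)
    if len(h) < 3:
        raise ValueError("need at least 3 variogram bins")
    fallback = {"nugget": 0.0, "psill": float(max(g.max(), 1e-12)), "range_km": float(h.max()), "fallback": True}
    if variogram.attrs.get("flat") or np.allclose(g, 0.0):
        return {"nugget": 0.0, "psill": 0.0, "range_km": float(h.max()), "fallback": True}
    try:
        p0 = [0.0, float(g.max()), float(h.max() / 2)]
        popt, _ = curve_fit(
            spherical, h, g, p0=p0, sigma=1.0 / np.sqrt(w),
            bounds=([0, 0, 1e-6], [np.inf, np.inf, np.inf]), maxfev=20000,
        )
    except RuntimeError:
        return fallback
    return {
        "nugget": float(popt[0]),
        "psill": float(popt[1]),
        "range_km": float(popt[2]),
        "fallback": False,
    }


# ---------------------------------------------------------------------------
# kriging


@dataclass
class SuitabilityGrid:
    """Lat/lon lattice of predicted winter mortality with habitat classes."""

    table: pd.DataFrame  # lat, lon, mortality, class
    resolution: float

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, resolution: float | None = None) -> "SuitabilityGrid":
        t = pd.read_csv(path)
        if resolution is None:
            lats = np.sort(t["lat"].unique())
            resolution = float(np.min(np.diff(lats))) if len(lats) > 1 else 1.0
        return cls(t, resolution)


def make_grid(lat_range, lon_range, resolution: float = 0.25) -> np.ndarray:
    """Regular (lat, lon) cell-centre lattice covering the given ranges."""
    lats = np.arange(lat_range[0], lat_range[1] + 1e-9, resolution)
    lons = np.arange(lon_range[0], lon_range[1] + 1e-9, resolution)
    g = np.array([(la, lo) for la in lats for lo in lons])
    return g


def _ok_solve(gamma_mat, gamma_vec):
    n = gamma_mat.shape[0]
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = gamma_mat
    A[n, :n] = 1.0
    A[:n, n] = 1.0
    A[n, n] = 0.0
    rhs = np.append(gamma_vec, 1.0)
    try:
        sol = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:
        A[:n, :n] += 1e-10 * np.eye(n)
        sol = np.linalg.solve(A, rhs)  # second failure propagates
    return sol[:n]


def krige(
    points: np.ndarray,
    values: np.ndarray,
    grid: np.ndarray,
    model: dict,
    k_neighbors: int | None = 12,
    clip: tuple | None = (0.0, 1.0),
    return_weights: bool = False,
):
    """Ordinary kriging of ``values`` at ``points`` onto ``grid``.

    Each target cell is predicted from its ``k_neighbors`` nearest stations
    (all stations when ``k_neighbors`` is None or exceeds the station
    count) by solving the standard OK system — the semivariance matrix
    augmented with the unbiasedness row, weights summing to one.  A
    singular system is retried once with a 1e-10 diagonal jitter; a cell
    still singular is returned as NaN.
    """
    points = np.asarray(points, float)
    values = np.asarray(values, float)
    grid = np.asarray(grid, float)
    n = len(points)
    k = n if k_neighbors is None else min(k_neighbors, n)
    D = _pairwise_km(points[:, 0], points[:, 1])
    preds = np.full(len(grid), np.nan)
    weights_out = [] if return_weights else None
    for gi, (glat, glon) in enumerate(grid):
        d0 = haversine_km(glat, glon, points[:, 0], points[:, 1])
        idx = np.argsort(d0)[:k]
        gmat = spherical(D[np.ix_(idx, idx)], model["nugget"], model["psill"], model["range_km"])
        np.fill_diagonal(gmat, 0.0)
        gvec = spherical(d0[idx], model["nugget"], model["psill"], model["range_km"])
        # exact interpolation: a zero distance to a station must carry zero
        # semivariance even with a nugget fitted
        gvec = np.where(d0[idx] == 0.0, 0.0, gvec)
        try:
            w = _ok_solve(gmat, gvec)
        except np.linalg.LinAlgError:
            continue
        preds[gi] = float(w @ values[idx])
        if return_weights:
            weights_out.append(w)
    if clip is not None:
        preds = np.clip(preds, clip[0], clip[1])
    if return_weights:
        return preds, weights_out
    return preds


def krige_to_grid(
    stations: pd.DataFrame,
    resolution: float = 0.25,
    k_neighbors: int | None = 12,
    value_col: str = "mean_peak_mortality",
) -> SuitabilityGrid:
    """Convenience: variogram fit + kriging over the station bounding box."""
    pts = stations[["lat", "lon"]].to_numpy()
    vals = stations[value_col].to_numpy()
    vg = empirical_variogram(pts, vals)
    model = fit_spherical(vg)
    grid = make_grid(
        (pts[:, 0].min(), pts[:, 0].max()),
        (pts[:, 1].min(), pts[:, 1].max()),
        resolution,
    )
    preds = krige(pts, vals, grid, model, k_neighbors=k_neighbors)
    table = pd.DataFrame(
        {
            "lat": grid[:, 0],
            "lon": grid[:, 1],
            "mortality": preds,
            "class": [classify(v) if np.isfinite(v) else "" for v in preds],
        }
    )
    return SuitabilityGrid(table, resolution)


# ---------------------------------------------------------------------------
# classification, thinning, extraction


def classify(mortality: float) -> str:
    """Map predicted mortality to its habitat-suitability class."""
    if not 0.0 <= mortality <= 1.0:
        raise ValueError("mortality must lie in [0, 1]")
    for label, lo, hi in SUITABILITY_CLASSES:
        if (mortality == 0.0 and lo == 0.0) or lo < mortality <= hi:
            return label
    raise AssertionError("unreachable: classes partition [0, 1]")


def thin_occurrences(records: pd.DataFrame, radius_km: float = 15.0) -> pd.DataFrame:
    """Greedy spatial thinning: scanning in ascending id order, keep a
    record iff it is at least ``radius_km`` from every record already kept.
    Deterministic; returns the retained rows."""
    if not {"id", "lat", "lon"}.issubset(records.columns):
        raise ValueError("occurrence records need columns id, lat, lon")
    recs = records.sort_values("id", kind="mergesort").reset_index(drop=True)
    kept_lat, kept_lon, kept_idx = [], [], []
    for i, r in recs.iterrows():
        if kept_idx:
            d = haversine_km(r.lat, r.lon, np.array(kept_lat), np.array(kept_lon))
            if np.min(d) < radius_km:
                continue
        kept_idx.append(i)
        kept_lat.append(r.lat)
        kept_lon.append(r.lon)
    return recs.loc[kept_idx].reset_index(drop=True)


def extract_and_summarize(grid: SuitabilityGrid, records: pd.DataFrame):
    """Assign each occurrence the mortality of its nearest grid cell and
    summarise class membership.

    Records farther than one cell diagonal from any predicted cell are
    counted as outside the grid and excluded from the percentages.
    Returns ``(per-record DataFrame, summary dict)``; the summary carries
    ``percent_by_class``, ``percent_suitable`` (highly + moderately
    suitable combined), ``percent_unsuitable``, ``n_used`` and
    ``n_outside``.
    """
    t = grid.table.dropna(subset=["mortality"])
    out_rows = []
    n_outside = 0
    max_km = grid.resolution * 111.32 * math.sqrt(2)  # one cell diagonal
    glat = t["lat"].to_numpy()
    glon = t["lon"].to_numpy()
    gmort = t["mortality"].to_numpy()
    for r in records.itertuples(index=False):
        if len(t) == 0:
            n_outside += 1
            continue
        d = haversine_km(r.lat, r.lon, glat, glon)
        j = int(np.argmin(d))
        if d[j] > max_km:
            n_outside += 1
            continue
        m = float(gmort[j])
        out_rows.append(
            {"id": r.id, "lat": r.lat, "lon": r.lon, "mortality": m, "class": classify(m)}
        )
    per_record = pd.DataFrame(out_rows, columns=["id", "lat", "lon", "mortality", "class"])
    n_used = len(per_record)
    pct = {label: 0.0 for label, _, _ in SUITABILITY_CLASSES}
    if n_used:
        counts = per_record["class"].value_counts()
        for label in pct:
            pct[label] = 100.0 * counts.get(label, 0) / n_used
    pct_suit = sum(v for k, v in pct.items() if k in SUITABLE_LABELS)
    summary = {
        "percent_by_class": pct,
        "percent_suitable": pct_suit,
        "percent_unsuitable": 100.0 - pct_suit if n_used else 0.0,
        "n_used": n_used,
        "n_outside": n_outside,
    }
    return per_record, summary
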