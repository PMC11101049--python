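"""Spatial predictor system for lake metacommunities.

Builds everything downstream models need from raw lake coordinates:
planar (Cartesian) coordinates, the Euclidean inter-lake distance matrix,
the minimum-spanning-tree threshold distance, the PCNM eigenbasis
(principal coordinates of neighbour matrices, a.k.a. Moran eigenvector
maps with distance truncation), a large/medium/small scale label per
axis, and the binary connectivity matrix used by Moran's I.

PCNM axes are orthogonal spatial predictors ordered from broad to fine
spatial scale by decreasing eigenvalue; only positive-eigenvalue axes
(positive spatial autocorrelation) are retained.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

__all__ = [
    "WGS84_A",
    "WGS84_F",
    "PlanarCoords",
    "DistanceMatrix",
    "SpatialBasis",
    "ConnectivityMatrix",
    "load_lakes",
    "project_to_cartesian",
    "distance_matrix",
    "mst_threshold",
    "pcnm",
    "classify_scale",
    "connectivity",
]

# WGS84 ellipsoid
WGS84_A = 6378.137  # equatorial radius, km
WGS84_F = 1 / 298.257223563  # flattening


@dataclass
class PlanarCoords:
    """Planar lake coordinates in km, with the projection origin."""

    lake_id: list[str]
    x: np.ndarray  # km, eastings
    y: np.ndarray  # km, northings
    origin: tuple[float, float]  # (lat, lon) mapped to (0, 0)


@dataclass
class DistanceMatrix:
    """Symmetric Euclidean distance matrix between lakes, km."""

    ids: list[str]
    d: np.ndarray


@dataclass
class SpatialBasis:
    """Retained PCNM axes: eigenvalues (descending), unit-norm vectors.

    ``index`` is the 1-based PCNM number in descending-eigenvalue order;
    ``scale_label`` (filled by :func:`classify_scale`) is one of
    ``large``/``medium``/``small``.
    """

    ids: list[str]
    eigenvalues: np.ndarray
    vectors: np.ndarray  # n_lakes x n_retained, unit columns
    threshold_t: float  # km
    index: np.ndarray = field(default=None)  # 1-based axis numbers
    scale_label: list[str] = field(default=None)

    def __post_init__(self):
        if self.index is None:
            self.index = np.arange(1, len(self.eigenvalues) + 1)

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    def axis_names(self) -> list[str]:
        return [f"PCNM_{i}" for i in self.index]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.vectors, index=self.ids, columns=self.axis_names())

    def axes_for_scale(self, label: str) -> pd.DataFrame:
        if self.scale_label is None:
            raise ValueError("scale labels not assigned; run classify_scale first")
        keep = [i for i, lab in enumerate(self.scale_label) if lab == label]
        return self.frame().iloc[:, keep]


@dataclass
class ConnectivityMatrix:
    """Binary lake adjacency under a distance threshold (zero diagonal)."""

    ids: list[str]
    w: np.ndarray
    threshold_t: float
    isolated: list[str] = field(default_factory=list)


def geodesic_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """WGS84 inverse geodesic distance (km), Vincenty's iteration.

    Used for reporting true ellipsoid distances (e.g. the maximal
    inter-lake distance); the planar pipeline itself works on projected
    Euclidean distances.
    """
    if (lat1, lon1) == (lat2, lon2):
        return 0.0
    a = WGS84_A
    f = WGS84_F
    b = a * (1 - f)
    u1 = math.atan((1 - f) * math.tan(math.radians(lat1)))
    u2 = math.atan((1 - f) * math.tan(math.radians(lat2)))
    ell = math.radians(lon2 - lon1)
    lam = ell
    su1, cu1 = math.sin(u1), math.cos(u1)
    su2, cu2 = math.sin(u2), math.cos(u2)
    for _ in range(200):
        sl, cl = math.sin(lam), math.cos(lam)
        sin_sigma = math.hypot(cu2 * sl, cu1 * su2 - su1 * cu2 * cl)
        if sin_sigma == 0:
            return 0.0
        cos_sigma = su1 * su2 + cu1 * cu2 * cl
        sigma = math.atan2(sin_sigma, cos_sigma)
        sin_alpha = cu1 * cu2 * sl / sin_sigma
        cos2_alpha = 1 - sin_alpha**2
        cos_2sm = cos_sigma - 2 * su1 * su2 / cos2_alpha if cos2_alpha != 0 else 0.0
        c = f / 16 * cos2_alpha * (4 + f * (4 - 3 * cos2_alpha))
        lam_prev = lam
        lam = ell + (1 - c) * f * sin_alpha * (
            sigma + c * sin_sigma * (cos_2sm + c * cos_sigma * (-1 + 2 * cos_2sm**2)))
        if abs(lam - lam_prev) < 1e-12:
            break
    u_sq = cos2_alpha * (a**2 - b**2) / b**2
    big_a = 1 + u_sq / 16384 * (4096 + u_sq * (-768 + u_sq * (320 - 175 * u_sq)))
    big_b = u_sq / 1024 * (256 + u_sq * (-128 + u_sq * (74 - 47 * u_sq)))
    delta_sigma = big_b * sin_sigma * (cos_2sm + big_b / 4 * (
        cos_sigma * (-1 + 2 * cos_2sm**2)
        - big_b / 6 * cos_2sm * (-3 + 4 * sin_sigma**2) * (-3 + 4 * cos_2sm**2)))
    return b * big_a * (sigma - delta_sigma)


def max_ellipsoid_distance(lakes: pd.DataFrame) -> float:
    """Largest pairwise WGS84 geodesic distance (km) among the lakes."""
    lat = np.asarray(lakes["lat"], dtype=float)
    lon = np.asarray(lakes["lon"], dtype=float)
    best = 0.0
    for i in range(len(lat)):
        for j in range(i + 1, len(lat)):
            best = max(best, geodesic_km(lat[i], lon[i], lat[j], lon[j]))
    return best


def load_lakes(path) -> pd.DataFrame:
    """Read a lake table CSV with columns ``lake_id,lat,lon,altitude_m,...``."""
    lakes = pd.read_csv(path, dtype={"lake_id": str})
    required = {"lake_id", "lat", "lon", "altitude_m"}
    missing = required - set(lakes.columns)
    if missing:
        raise ValueError(f"lake table missing columns: {sorted(missing)}")
    _validate_lakes(lakes)
    return lakes


def _validate_lakes(lakes: pd.DataFrame) -> None:
    if lakes["lake_id"].duplicated().any():
        dups = lakes.loc[lakes["lake_id"].duplicated(), "lake_id"].tolist()
        raise ValueError(f"duplicate lake_id: {dups}")
    if (lakes["lat"].abs() > 90).any():
        raise ValueError("latitude outside [-90, 90]")
    if (lakes["lon"].abs() > 180).any():
        raise ValueError("longitude outside [-180, 180]")
    if not np.isfinite(lakes["altitude_m"]).all():
        raise ValueError("non-finite altitude")


def project_to_cartesian(lakes: pd.DataFrame, origin: tuple[float, float] | None = None) -> PlanarCoords:
    """Project WGS84 lat/lon to a local plane (km).

    Equirectangular ellipsoidal approximation about the domain's mean
    latitude: x = N(lat̄)·cos(lat̄)·Δlon, y = M(lat̄)·Δlat, with M and N
    the WGS84 meridional and prime-vertical curvature radii. Over a
    ≲300 km extent this reproduces geodesic distances to well under
    0.5%. Default origin is (min lat, min lon) of the input, so all
    coordinates are nonnegative.
    """
    _validate_lakes(lakes)
    if len(lakes) < 2:
        raise ValueError("need at least two lakes")
    lat = np.asarray(lakes["lat"], dtype=float)
    lon = np.asarray(lakes["lon"], dtype=float)
    if origin is None:
        origin = (float(lat.min()), float(lon.min()))
    lat0, lon0 = origin
    latbar = math.radians(lat.mean())
    e2 = WGS84_F * (2 - WGS84_F)
    s = math.sin(latbar)
    # curvature radii at the mean latitude
    m_rad = WGS84_A * (1 - e2) / (1 - e2 * s * s) ** 1.5
    n_rad = WGS84_A / math.sqrt(1 - e2 * s * s)
    x = n_rad * math.cos(latbar) * np.radians(lon - lon0)
    y = m_rad * np.radians(lat - lat0)
    return PlanarCoords(lake_id=list(lakes["lake_id"]), x=x, y=y, origin=origin)


def distance_matrix(coords: PlanarCoords) -> DistanceMatrix:
    """Pairwise Euclidean distances (km) between projected lakes."""
    if len(coords.lake_id) < 2:
        raise ValueError("need at least two lakes")
    pts = np.column_stack([coords.x, coords.y])
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=list(coords.lake_id), d=d)


def mst_threshold(d: DistanceMatrix) -> float:
    """Longest edge of a minimum spanning tree over the lakes (km).

    This is the smallest threshold for which the binary connectivity
    graph is guaranteed connected, and the canonical PCNM truncation
    distance.
    """
    n = d.d.shape[0]
    if n < 2:
        raise ValueError("need at least two lakes")
    if not np.isfinite(d.d).all():
        raise ValueError("distances must be finite")
    tree = minimum_spanning_tree(d.d)
    return float(tree.data.max())


def pcnm(d: DistanceMatrix, t: float, tol_pos: float = 1e-8) -> SpatialBasis:
    """PCNM eigenbasis of a threshold-truncated distance matrix.

    Distances above ``t`` are replaced by ``4t`` (the standard PCNM
    convention), the truncated matrix is Gower double-centered
    (B = −½ C d*² C with C the centering projector), and the positive
    eigenpairs of B are retained (eigenvalue > ``tol_pos``·λ_max).
    Vectors are returned unit-norm, ordered by descending eigenvalue
    and numbered PCNM-1, PCNM-2, ...; eigenvalues are on the km² scale
    of B, the scale on which the large/medium/small cuts are defined.
    """
    if t <= 0:
        raise ValueError("threshold t must be > 0")
    dm = d.d
    n = dm.shape[0]
    if np.allclose(dm, 0):
        raise ValueError("degenerate geometry: all distances zero")
    dstar = np.where(dm > t, 4.0 * t, dm)
    np.fill_diagonal(dstar, 0.0)
    a = -0.5 * dstar**2
    c = np.eye(n) - np.full((n, n), 1.0 / n)
    b = c @ a @ c
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > tol_pos * evals.max()
    evals, evecs = evals[keep], evecs[:, keep]
    evecs = evecs / np.linalg.norm(evecs, axis=0)
    # deterministic sign: largest-magnitude component positive
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return SpatialBasis(ids=list(d.ids), eigenvalues=evals, vectors=evecs, threshold_t=float(t))


def classify_scale(basis: SpatialBasis, cut_large: float = 25000.0, cut_small: float = 1000.0) -> SpatialBasis:
    """Label each axis large/medium/small by its eigenvalue.

    large: λ > cut_large; medium: cut_small ≤ λ ≤ cut_large (closed
    interval); small: λ < cut_small. With descending eigenvalues the
    labels form three contiguous blocks from broad to fine scale.
    """
    if cut_small > cut_large:
        raise ValueError("cut_small must not exceed cut_large")
    labels = []
    for lam in basis.eigenvalues:
        if lam > cut_large:
            labels.append("large")
        elif lam >= cut_small:
            labels.append("medium")
        else:
            labels.append("small")
    basis.scale_label = labels
    return basis


def connectivity(d: DistanceMatrix, t: float) -> ConnectivityMatrix:
    """Binary adjacency: lakes within ``t`` km are directly connected.

    A lake with no neighbour within ``t`` is kept (warning recorded in
    ``isolated``); at the MST threshold the graph is always connected.
    """
    if t <= 0:
        raise ValueError("threshold t must be > 0")
    w = ((d.d > 0) & (d.d <= t)).astype(float)
    np.fill_diagonal(w, 0.0)
    isolated = [d.ids[i] for i in range(len(d.ids)) if w[i].sum() == 0]
    if isolated:
        warnings.warn(f"isolated lakes under threshold {t}: {isolated}", stacklevel=2)
    return ConnectivityMatrix(ids=list(d.ids), w=w, threshold_t=float(t), isolated=isolated)
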