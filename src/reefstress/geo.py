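"""Great-circle geometry helpers (haversine point distance, cross-track segment distance).

All distances are kilometers on a sphere of radius ``EARTH_RADIUS_KM``.
"""
from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _unit_vector(lon_deg, lat_deg):
    lon = np.radians(np.asarray(lon_deg, dtype=float))
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    return np.stack(
        [np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)], axis=-1
    )


def point_segments_km(lon: float, lat: float, seg_a: np.ndarray, seg_b: np.ndarray) -> np.ndarray:
    """Great-circle distances from one point to many minor arcs.

    ``seg_a``/``seg_b`` are (m, 2) arrays of (lon, lat) arc endpoints. Uses
    the cross-track distance when the point's along-track projection falls
    inside an arc, otherwise the nearer endpoint distance.
    """
    seg_a = np.atleast_2d(np.asarray(seg_a, dtype=float))
    seg_b = np.atleast_2d(np.asarray(seg_b, dtype=float))
    p = _unit_vector(lon, lat)
    a = _unit_vector(seg_a[:, 0], seg_a[:, 1])
    b = _unit_vector(seg_b[:, 0], seg_b[:, 1])
    d_a = haversine_km(lon, lat, seg_a[:, 0], seg_a[:, 1])
    d_b = haversine_km(lon, lat, seg_b[:, 0], seg_b[:, 1])
    out = np.minimum(d_a, d_b)

    n = np.cross(a, b)
    nn = np.linalg.norm(n, axis=1)
    ok = nn > 1e-12  # non-degenerate arcs
    if ok.any():
        n_ok = n[ok] / nn[ok][:, None]
        # signed angular cross-track distance
        sin_xt = np.clip(n_ok @ p, -1.0, 1.0)
        # projection of p onto each great circle
        proj = p[None, :] - sin_xt[:, None] * n_ok
        pn = np.linalg.norm(proj, axis=1)
        good = pn > 1e-12
        proj[good] /= pn[good][:, None]

        def ang(u, v):
            return np.arccos(np.clip(np.sum(u * v, axis=1), -1.0, 1.0))

        a_ok, b_ok = a[ok], b[ok]
        # inside the minor arc iff angle(a,proj)+angle(proj,b) == angle(a,b)
        inside = good & (np.abs(ang(a_ok, proj) + ang(proj, b_ok) - ang(a_ok, b_ok)) < 1e-9)
        xt = np.abs(np.arcsin(sin_xt)) * EARTH_RADIUS_KM
        sub = out[ok]
        sub[inside] = np.minimum(sub[inside], xt[inside])
        out[ok] = sub
    return out


def point_segment_km(lon, lat, lon_a, lat_a, lon_b, lat_b) -> float:
    """Great-circle distance from a point to the minor arc between two vertices."""
    return float(
        point_segments_km(lon, lat, np.array([[lon_a, lat_a]]), np.array([[lon_b, lat_b]]))[0]
    )


def polyline_segments(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a polyline into (start, end) arrays of arc endpoints."""
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 2 or len(vertices) == 0:
        raise ValueError("polyline must be a non-empty (m, 2) array of lon/lat")
    if len(vertices) == 1:  # degenerate: a point
        return vertices, vertices
    return vertices[:-1], vertices[1:]


def point_polyline_km(lon: float, lat: float, vertices: np.ndarray) -> float:
    """Minimum great-circle distance from a point to a polyline.

    ``vertices`` is an (m, 2) array of (lon, lat) in degrees; consecutive rows
    are connected by arcs. A single-vertex polyline degenerates to a point.
    """
    seg_a, seg_b = polyline_segments(vertices)
    return float(np.min(point_segments_km(lon, lat, seg_a, seg_b)))
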