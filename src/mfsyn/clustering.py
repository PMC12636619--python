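"""DBSCAN clustering of bouton-relative molecules and active-zone classification.

DBSCAN is implemented here from first principles (it is the load-bearing
statistic of the spatial analysis): a point is *core* iff its closed
eps-neighborhood, including itself, holds at least ``min_pts`` points;
clusters are the maximal density-connected sets grown from core points in
scan order, and unreachable points are noise.  Cluster centroids are then
classified against an active-zone ellipse (default 500 x 200 nm axis
diameters, axis-aligned, centered on the bouton centroid) in the XY
projection.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ValidationError

NOISE = -1


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN parameters: 3D Euclidean metric, eps in nm.

    ``count_self`` includes the point itself in its eps-neighborhood count
    (standard DBSCAN); disabling it reads ``min_pts`` as a strict neighbor
    count instead.
    """

    eps_nm: float = 22.5
    min_pts: int = 5
    count_self: bool = True

    def __post_init__(self):
        if self.eps_nm <= 0:
            raise ValidationError("eps must be positive")
        if self.min_pts < 1:
            raise ValidationError("min_pts must be >= 1")


@dataclass(frozen=True)
class AZEllipse:
    """Active-zone ellipse in the bouton-relative XY plane (semi-axes, nm)."""

    semi_major_nm: float = 250.0
    semi_minor_nm: float = 100.0
    orientation_rad: float = 0.0  # major axis along +X by default
    center: tuple = (0.0, 0.0)

    def __post_init__(self):
        if not (self.semi_major_nm >= self.semi_minor_nm > 0):
            raise ValidationError("need semi_major >= semi_minor > 0")


def dbscan(points, params: ClusterParams = ClusterParams()) -> np.ndarray:
    """Label 3D points with DBSCAN cluster ids (noise = -1).

    Labels are deterministic given input order: clusters are seeded from core
    points in scan order and border-point ties go to the first cluster that
    reaches them.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(pts)
    labels = np.full(n, NOISE, dtype=int)
    if n == 0:
        return labels

    tree = cKDTree(pts)
    neighbors = tree.query_ball_point(pts, params.eps_nm)  # closed ball, incl. self
    need = params.min_pts if params.count_self else params.min_pts + 1
    core = np.array([len(nb) >= need for nb in neighbors])

    cluster_id = 0
    visited = np.zeros(n, dtype=bool)
    for i in range(n):
        if visited[i] or not core[i]:
            continue
        # grow a new cluster from this unvisited core point
        labels[i] = cluster_id
        visited[i] = True
        queue = deque([i])
        while queue:
            j = queue.popleft()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == NOISE:
                    labels[k] = cluster_id
                    if core[k] and not visited[k]:
                        visited[k] = True
                        queue.append(k)
        cluster_id += 1
    return labels


def summarize_clusters(labels: np.ndarray, traces: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster unweighted centroid of member trace positions.

    Positions are taken from the bouton-relative columns when present
    (``rel_x_nm`` ...), else the absolute ones.  Noise points are excluded.
    Returns columns ``cluster_id, channel, n_members, x_nm, y_nm, z_nm``.
    """
    cols = (["rel_x_nm", "rel_y_nm", "rel_z_nm"]
            if "rel_x_nm" in traces.columns else ["x_nm", "y_nm", "z_nm"])
    labels = np.asarray(labels)
    rows = []
    for cid in sorted(set(labels[labels != NOISE])):
        members = traces.iloc[np.flatnonzero(labels == cid)]
        ch = members["channel"].iloc[0] if "channel" in members.columns else ""
        cx, cy, cz = members[cols].to_numpy(dtype=float).mean(axis=0)
        rows.append({"cluster_id": int(cid), "channel": ch,
                     "n_members": len(members), "x_nm": cx, "y_nm": cy, "z_nm": cz})
    return pd.DataFrame(rows, columns=["cluster_id", "channel", "n_members",
                                       "x_nm", "y_nm", "z_nm"])


def classify_az(clusters: pd.DataFrame, ellipse: AZEllipse = AZEllipse()):
    """Label each cluster centroid inside / periphery of the AZ ellipse.

    The test is the XY-projected ellipse inequality
    (x'/a)^2 + (y'/b)^2 <= 1 in ellipse-frame coordinates; the boundary
    counts as inside.  Returns ``(labels, counts)`` with counts keyed
    ``inside`` / ``periphery``.
    """
    if len(clusters) == 0:
        return [], {"inside": 0, "periphery": 0}
    dx = clusters["x_nm"].to_numpy(dtype=float) - ellipse.center[0]
    dy = clusters["y_nm"].to_numpy(dtype=float) - ellipse.center[1]
    c, s = np.cos(ellipse.orientation_rad), np.sin(ellipse.orientation_rad)
    xp = c * dx + s * dy
    yp = -s * dx + c * dy
    inside = (xp / ellipse.semi_major_nm) ** 2 + (yp / ellipse.semi_minor_nm) ** 2 <= 1.0
    labels = ["inside" if v else "periphery" for v in inside]
    return labels, {"inside": int(inside.sum()),
                    "periphery": int(len(inside) - inside.sum())}


_PLANES = {"XY": (0, 1), "XZ": (0, 2), "YZ": (1, 2)}


def project(points, plane: str = "XY") -> np.ndarray:
    """Drop one coordinate: project 3D points onto the named plane."""
    try:
        i, j = _PLANES[plane.upper()]
    except KeyError:
        raise ValidationError(f"unknown projection plane {plane!r}; use XY, XZ or YZ")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return pts[:, [i, j]]
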