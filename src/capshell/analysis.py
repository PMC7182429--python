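"""Classification of simulation outcomes.

Final configurations of an assembly run are reduced to clusters
(single-linkage on the pair distance), and the largest cluster is
classified geometrically as a spherical cap, a closed shell, a ribbon, a
tube (cylinder), a cone or an amorphous aggregate, using the gyration
tensor together with sphere/cylinder surface fits.  Interior members with
exactly five neighbors are counted as disclinations; a closed icosahedral
shell carries exactly twelve.

Quantitative thresholds are calibrated on the synthetic fixture
generators at the bottom of this module and frozen here; the shapes
themselves are the same ones a visual inspection of trajectories would
label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

__all__ = [
    "ShapeClass",
    "ClusterReport",
    "find_clusters",
    "classify_shape",
    "count_disclinations",
    "analyze_state",
    "make_sphere_shell",
    "make_cap",
    "make_tube",
    "make_cone",
    "make_ribbon",
]

DEFAULT_CUTOFF = 1.4       # neighbor cutoff, units of sigma
_BOUNDARY_GAP_DEG = 100.0  # angular gap marking an open rim (interior
                           # members have gaps of 60 deg, 72 at a pentamer)


class ShapeClass(Enum):
    CAP = "cap"
    CLOSED_SHELL = "closed_shell"
    RIBBON = "ribbon"
    TUBE = "tube"
    CONE = "cone"
    AMORPHOUS = "amorphous"


@dataclass
class ClusterReport:
    """Cluster decomposition and shape classification of a configuration."""

    cluster_sizes: list
    largest_cluster_members: list
    coordination: np.ndarray | None = None
    n_fivefold: int | None = None
    shape_class: ShapeClass | None = None
    shape_metrics: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

def _neighbor_pairs(positions, cutoff, box=None):
    positions = np.asarray(positions, dtype=float)
    if box:
        pts = np.mod(positions, box)
        tree = cKDTree(pts, boxsize=box)
    else:
        tree = cKDTree(positions)
    return tree.query_pairs(cutoff, output_type="ndarray")


def find_clusters(positions, cutoff=DEFAULT_CUTOFF, box=None) -> ClusterReport:
    """Single-linkage clusters by pair distance; deterministic ordering.

    ``positions`` may also be a ``SimulationState`` (its box is then used).
    Clusters are ordered by decreasing size, ties by smallest member index.
    """
    if hasattr(positions, "positions"):
        box = box if box is not None else positions.box
        positions = positions.positions
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    pairs = _neighbor_pairs(positions, cutoff, box)
    if len(pairs):
        data = np.ones(len(pairs))
        adj = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n)
    uniq, counts = np.unique(labels, return_counts=True)
    order = sorted(range(len(uniq)),
                   key=lambda k: (-counts[k],
                                  int(np.min(np.nonzero(labels == uniq[k])[0]))))
    sizes = [int(counts[k]) for k in order]
    members = np.nonzero(labels == uniq[order[0]])[0].tolist()
    return ClusterReport(cluster_sizes=sizes, largest_cluster_members=members)


# --------------------------------------------------------------------------
# local topology: coordination, boundary detection, disclinations
# --------------------------------------------------------------------------

def _local_analysis(points, cutoff):
    """Per-member coordination numbers and open-boundary flags."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    tree = cKDTree(points)
    neigh = [sorted(tree.query_ball_point(points[i], cutoff)) for i in range(n)]
    coord = np.zeros(n, dtype=int)
    boundary = np.zeros(n, dtype=bool)
    for i in range(n):
        nb = [j for j in neigh[i] if j != i]
        coord[i] = len(nb)
        if len(nb) < 3:
            boundary[i] = True
            continue
        disp = points[nb] - points[i]
        # local normal from the best-fit plane of the neighbor shell
        _, _, vt = np.linalg.svd(disp - disp.mean(axis=0), full_matrices=False)
        normal = vt[-1]
        e1 = vt[0]
        e2 = np.cross(normal, e1)
        ang = np.sort(np.arctan2(disp @ e2, disp @ e1))
        gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
        boundary[i] = math.degrees(float(np.max(gaps))) > _BOUNDARY_GAP_DEG
    return coord, boundary


def count_disclinations(points, cutoff=DEFAULT_CUTOFF) -> int:
    """Number of interior members with exactly five neighbors.

    Members on an open rim (angular gap above the boundary threshold) are
    excluded: their low coordination is an edge effect, not a disclination.
    """
    coord, boundary = _local_analysis(points, cutoff)
    return int(np.sum((coord == 5) & ~boundary))


# --------------------------------------------------------------------------
# shape classification
# --------------------------------------------------------------------------

def _fit_sphere(points):
    """Algebraic least-squares sphere fit; returns (center, radius, rel_resid)."""
    A = np.hstack([2.0 * points, np.ones((len(points), 1))])
    b = np.einsum("ij,ij->i", points, points)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = math.sqrt(max(sol[3] + center @ center, 0.0))
    d = np.linalg.norm(points - center, axis=1)
    rel = float(np.std(d) / max(np.mean(d), 1e-12))
    return center, radius, rel


def classify_shape(points, cutoff=DEFAULT_CUTOFF):
    """Classify one cluster's geometry.

    Returns ``(ShapeClass, metrics)`` where the metrics carry the gyration
    tensor eigenvalues, fitted radii and fit residuals used in the decision.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 12:
        return ShapeClass.AMORPHOUS, {"reason": "cluster too small"}
    c = points.mean(axis=0)
    X = points - c
    gyr = X.T @ X / len(points)
    evals, evecs = np.linalg.eigh(gyr)
    l3, l2, l1 = np.maximum(evals, 0.0)
    metrics = {"gyration_eigenvalues": (float(l1), float(l2), float(l3))}
    if l1 <= 0 or l2 / l1 < 1e-4:
        return ShapeClass.AMORPHOUS, metrics
    _, boundary = _local_analysis(points, cutoff)
    metrics["n_boundary"] = int(boundary.sum())

    center, radius, rel_sphere = _fit_sphere(points)
    metrics["sphere_radius"] = float(radius)
    metrics["sphere_resid"] = rel_sphere
    span = math.sqrt(l1)
    if rel_sphere < 0.12 and radius < 6.0 * span:
        if metrics["n_boundary"] <= max(2, 0.03 * len(points)):
            return ShapeClass.CLOSED_SHELL, metrics
        if l2 / l1 > 0.45:
            return ShapeClass.CAP, metrics
        return ShapeClass.RIBBON, metrics

    # cylinder-family: distance from the principal axis
    axis = evecs[:, -1]
    z = X @ axis
    rho = np.linalg.norm(X - np.outer(z, axis), axis=1)
    rel_cyl = float(np.std(rho) / max(np.mean(rho), 1e-12))
    metrics["cyl_radius"] = float(np.mean(rho))
    metrics["cyl_resid"] = rel_cyl
    # angular coverage about the axis
    e1 = evecs[:, 0]
    e2 = np.cross(axis, e1)
    ang = np.sort(np.arctan2(X @ e2, X @ e1))
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * np.pi]]))
    closed_around_axis = math.degrees(float(np.max(gaps))) < 60.0
    # cross-section radius trend along the axis -> cone
    slope = float(np.polyfit(z, rho, 1)[0])
    taper = abs(slope) * (z.max() - z.min()) / max(np.mean(rho), 1e-12)
    metrics["taper"] = taper
    if closed_around_axis:
        if taper > 0.5 and rel_cyl >= 0.08:
            return ShapeClass.CONE, metrics
        if rel_cyl < 0.25:
            return ShapeClass.TUBE, metrics
    if l3 / l2 < 0.25:
        return ShapeClass.RIBBON, metrics
    return ShapeClass.AMORPHOUS, metrics


def analyze_state(state_or_positions, cutoff=DEFAULT_CUTOFF, box=None) -> ClusterReport:
    """Full report: clusters, coordination, disclinations, shape class."""
    rep = find_clusters(state_or_positions, cutoff, box)
    if hasattr(state_or_positions, "positions"):
        positions = state_or_positions.positions
        box = box if box is not None else state_or_positions.box
    else:
        positions = np.asarray(state_or_positions, dtype=float)
    pts = positions[rep.largest_cluster_members]
    if box:
        # unwrap the cluster around its first member for geometry
        ref = pts[0]
        pts = ref + (pts - ref) - box * np.round((pts - ref) / box)
    coord, bnd = _local_analysis(pts, cutoff)
    rep.coordination = coord
    rep.n_fivefold = int(np.sum((coord == 5) & ~bnd))
    rep.shape_class, rep.shape_metrics = classify_shape(pts, cutoff)
    return rep


# --------------------------------------------------------------------------
# synthetic fixtures (unit nearest-neighbor spacing)
# --------------------------------------------------------------------------

def _icosahedron():
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    v = []
    for a in (-1.0, 1.0):
        for b in (-phi, phi):
            v += [(0, a, b), (a, b, 0), (b, 0, a)]
    v = np.array(v)
    return v / np.linalg.norm(v[0])


def make_sphere_shell(frequency=3):
    """Geodesic (subdivided icosahedral) closed shell, NN distance ~ 1.

    Carries exactly 12 five-coordinated vertices, like a T = frequency^2
    capsid's pentamer arrangement.
    """
    base = _icosahedron()
    tree = cKDTree(base)
    edge = np.sort(tree.query(base, k=2)[0][:, 1])[0]
    pairs = tree.query_pairs(edge * 1.05)
    # faces: triples of mutually adjacent vertices
    adj = {i: set() for i in range(12)}
    for i, j in pairs:
        adj[i].add(j)
        adj[j].add(i)
    faces = set()
    for i in range(12):
        for j in adj[i]:
            for k in adj[i] & adj[j]:
                faces.add(tuple(sorted((i, j, k))))
    pts = {}
    f = frequency
    for (i, j, k) in faces:
        for a in range(f + 1):
            for b in range(f + 1 - a):
                cvec = (a * base[i] + b * base[j] + (f - a - b) * base[k]) / f
                cvec = cvec / np.linalg.norm(cvec)
                pts[tuple(np.round(cvec, 9))] = cvec
    P = np.array(list(pts.values()))
    tree = cKDTree(P)
    nn = np.median(tree.query(P, k=2)[0][:, 1])
    return P / nn


def make_cap(frequency=4, z_min=0.35):
    """Open spherical cap: the upper part of a geodesic shell."""
    P = make_sphere_shell(frequency)
    R = np.linalg.norm(P[0])
    return P[P[:, 2] > z_min * R]


def make_tube(radius=2.0, length=20.0):
    """Hexagonal lattice rolled into a cylinder of given radius and length."""
    m = max(int(round(2.0 * math.pi * radius)), 3)
    a = 2.0 * math.pi / m
    R = 1.0 / (2.0 * math.sin(a / 2.0))   # chord spacing = 1
    dz = math.sqrt(3.0) / 2.0
    rows = int(round(length / dz))
    pts = []
    for irow in range(rows):
        off = 0.5 * a if irow % 2 else 0.0
        for k in range(m):
            th = k * a + off
            pts.append((R * math.cos(th), R * math.sin(th), irow * dz))
    return np.array(pts)


def make_cone(r_small=1.5, r_big=4.0, length=12.0):
    """Rings of unit-spaced points with linearly growing radius."""
    dz = math.sqrt(3.0) / 2.0
    rows = int(round(length / dz))
    pts = []
    for irow in range(rows):
        rr = r_small + (r_big - r_small) * irow / max(rows - 1, 1)
        m = max(int(round(2.0 * math.pi * rr)), 3)
        off = 0.5 * (2.0 * math.pi / m) if irow % 2 else 0.0
        for k in range(m):
            th = k * 2.0 * math.pi / m + off
            pts.append((rr * math.cos(th), rr * math.sin(th), irow * dz))
    return np.array(pts)


def make_ribbon(width=3, length=20, sphere_radius=8.0):
    """Curved strip: a width x length hexagonal patch bent onto a sphere."""
    pts = []
    R = sphere_radius
    for irow in range(width):
        for k in range(length):
            x = k + (0.5 if irow % 2 else 0.0)
            y = irow * math.sqrt(3.0) / 2.0
            # wrap the strip onto the sphere by arc length
            th = x / R
            ph = y / R
            pts.append((R * math.cos(ph) * math.sin(th),
                        R * math.sin(ph),
                        R * math.cos(ph) * math.cos(th)))
    return np.array(pts)
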