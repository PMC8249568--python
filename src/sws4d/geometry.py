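"""Vessel geometry: centerlines, lumen frames, structured tube meshes and
diameter-stenosis profiling.

A vessel at one cardiac time point is a :class:`VesselFrame` — an ordered 3D
centerline with one lumen radius per centerline point (cross-sections are
modelled as circles) and a cardiac-phase label. Frames are discretized into
:class:`StructuredSurfaceMesh` grids of L rings × C circumferential nodes;
every mesh in a cardiac sequence shares the same (L, C) so that node (i, j)
denotes the same material point in every configuration.

Circumferential node placement uses rotation-minimizing frames (minimal
rotation transport): parallel transport of the ring basis along the centerline avoids
the torsion-induced spin a Frenet frame would introduce on helical segments,
which would otherwise contaminate the strain field with artificial twist.

Units are millimetres throughout; ring index 0 is the proximal (ostial) end
and arclength is measured from it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .errors import InvalidGeometryError

Phase = Literal[
    "diastasis", "end_diastole", "early_systole", "end_systole", "early_diastole", "other"
]

#: Cardiac phases in cycle order, starting at the reference configuration.
PHASE_ORDER = ("diastasis", "end_diastole", "early_systole", "end_systole", "early_diastole")

#: Default mesh density for a 50 mm vessel (~0.5 mm axial spacing).
DEFAULT_RINGS = 101
DEFAULT_CIRCUMFERENTIAL = 32


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InvalidGeometryError(f"expected an (n, 3) point array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise InvalidGeometryError("centerline points contain non-finite values")
    return pts


def _chord_arclength(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass(frozen=True)
class Centerline:
    """Ordered 3D curve with cumulative arclength.

    Invariants: at least 4 points, consecutive points distinct, arclength
    strictly increasing with ``arclength[0] == 0``.
    """

    points: np.ndarray
    arclength: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        pts = _as_points(self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 4:
            raise InvalidGeometryError(f"centerline needs >= 4 points, got {len(pts)}")
        arc = self.arclength
        if arc is None:
            arc = _chord_arclength(pts)
        arc = np.asarray(arc, dtype=float)
        if arc.shape != (len(pts),):
            raise InvalidGeometryError("arclength length must match point count")
        if arc[0] != 0.0 or np.any(np.diff(arc) <= 0.0):
            raise InvalidGeometryError("arclength must start at 0 and be strictly increasing")
        object.__setattr__(self, "arclength", arc)

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class VesselFrame:
    """One time point's lumen geometry: centerline + per-ring radius + phase."""

    centerline: Centerline
    ring_radius: np.ndarray
    phase: Phase = "other"
    time_index: int = 0

    def __post_init__(self):
        r = np.asarray(self.ring_radius, dtype=float)
        if r.shape != (len(self.centerline),):
            raise InvalidGeometryError(
                f"ring_radius length {r.shape} does not match centerline ({len(self.centerline)})"
            )
        if not np.all(np.isfinite(r)) or np.any(r <= 0.0):
            raise InvalidGeometryError("all lumen radii must be finite and > 0")
        object.__setattr__(self, "ring_radius", r)

    @property
    def diameter(self) -> np.ndarray:
        return 2.0 * self.ring_radius


@dataclass(frozen=True)
class StructuredSurfaceMesh:
    """L×C grid of surface nodes forming closed quad rings.

    Element (i, j) has corners (i,j), (i,j+1), (i+1,j+1), (i+1,j) with j+1
    taken modulo C, so each ring of elements is circumferentially closed.
    """

    nodes: np.ndarray  # (L, C, 3)
    frame_ref: Optional[VesselFrame] = None
    self_intersecting: bool = False

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=float)
        if nodes.ndim != 3 or nodes.shape[2] != 3:
            raise InvalidGeometryError(f"mesh nodes must be (L, C, 3), got {nodes.shape}")
        if nodes.shape[0] < 2 or nodes.shape[1] < 3:
            raise InvalidGeometryError("mesh needs >= 2 rings and >= 3 circumferential nodes")
        object.__setattr__(self, "nodes", nodes)
        circ = np.linalg.norm(np.roll(nodes, -1, axis=1) - nodes, axis=2)
        axial = np.linalg.norm(nodes[1:] - nodes[:-1], axis=2)
        if np.any(circ <= 0.0) or np.any(axial <= 0.0):
            raise InvalidGeometryError("mesh contains degenerate (zero-length) quad edges")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nodes.shape[0], self.nodes.shape[1]

    @property
    def L(self) -> int:
        return self.nodes.shape[0]

    @property
    def C(self) -> int:
        return self.nodes.shape[1]

    def ring_centroids(self) -> np.ndarray:
        return self.nodes.mean(axis=1)

    def ring_mean_radius(self) -> np.ndarray:
        c = self.ring_centroids()[:, None, :]
        return np.linalg.norm(self.nodes - c, axis=2).mean(axis=1)

    def ring_arclength(self) -> np.ndarray:
        return _chord_arclength(self.ring_centroids())


@dataclass(frozen=True)
class StenosisProfile:
    """Per-ring percent diameter stenosis against an interpolated healthy
    reference, with normal/stenotic labels (stenotic iff %DS > threshold)."""

    percent_ds: np.ndarray
    reference_diameter: np.ndarray
    labels: np.ndarray  # array of {"normal", "stenotic"}
    threshold: float = 20.0
    arclength: np.ndarray = None  # type: ignore[assignment]

    @property
    def stenotic(self) -> np.ndarray:
        return self.labels == "stenotic"

    @property
    def throat_index(self) -> int:
        """Ring of minimum diameter among stenotic rings (global min if none)."""
        d = self.reference_diameter * (1.0 - self.percent_ds / 100.0)
        if self.stenotic.any():
            idx = np.flatnonzero(self.stenotic)
            return int(idx[np.argmin(d[idx])])
        return int(np.argmin(d))


def resample_centerline(points, n: int) -> Centerline:
    """Resample a polyline to ``n`` points equally spaced in arclength.

    Endpoints are preserved; the input is treated as piecewise linear.
    """
    pts = _as_points(points)
    # collapse exactly coincident consecutive points
    keep = np.concatenate([[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 0.0])
    pts = pts[keep]
    if len(pts) < 2:
        raise InvalidGeometryError("need at least 2 distinct points to resample")
    if n < 4:
        raise InvalidGeometryError(f"resampled centerline needs n >= 4, got {n}")
    arc = _chord_arclength(pts)
    s = np.linspace(0.0, arc[-1], n)
    out = np.column_stack([np.interp(s, arc, pts[:, k]) for k in range(3)])
    return Centerline(points=out)


def local_frames(centerline: Centerline) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-point orthonormal frames (tangent, normal1, normal2) along a curve.

    Tangents are normalized central differences of the points (third-order
    one-sided stencils at the ends); the normal pair is propagated by exact
    minimal-rotation parallel transport, so a helix accumulates no
    torsion-induced spin of normal1 about the tangent.
    """
    pts = centerline.points
    n = len(pts)
    tangents = np.empty_like(pts)
    tangents[1:-1] = pts[2:] - pts[:-2]
    # third-order one-sided differences at the ends (uniform-spacing stencil;
    # resampled centerlines are uniform, and the direction is normalized)
    tangents[0] = -11.0 * pts[0] + 18.0 * pts[1] - 9.0 * pts[2] + 2.0 * pts[3]
    tangents[-1] = 11.0 * pts[-1] - 18.0 * pts[-2] + 9.0 * pts[-3] - 2.0 * pts[-4]
    norms = np.linalg.norm(tangents, axis=1, keepdims=True)
    if np.any(norms == 0.0):
        raise InvalidGeometryError("zero tangent encountered (coincident points)")
    tangents /= norms

    # initial normal: fixed global reference axis projected onto the normal
    # plane, with a hysteresis-style fallback — choosing the reference by
    # argmin(|t0|) would flip between axes under tiny tangent perturbations
    # and inject a spurious quarter-turn twist between frames of a sequence
    t0 = tangents[0]
    ref = np.array([1.0, 0.0, 0.0]) if abs(t0[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    n1 = ref - np.dot(ref, t0) * t0
    n1 /= np.linalg.norm(n1)

    normal1 = np.empty_like(pts)
    normal1[0] = n1
    for i in range(n - 1):
        # exact discrete parallel transport: rotate the normal by the minimal
        # rotation taking tangent i onto tangent i+1 (zero twist per step by
        # construction; straight stretches are the identity rotation)
        axis = np.cross(tangents[i], tangents[i + 1])
        sin_a = np.linalg.norm(axis)
        cos_a = float(np.dot(tangents[i], tangents[i + 1]))
        if sin_a < 1e-15:
            normal1[i + 1] = normal1[i]
        else:
            k = axis / sin_a
            v = normal1[i]
            normal1[i + 1] = (
                v * cos_a + np.cross(k, v) * sin_a + k * np.dot(k, v) * (1.0 - cos_a)
            )
        # re-orthonormalize against accumulated floating error
        normal1[i + 1] -= np.dot(normal1[i + 1], tangents[i + 1]) * tangents[i + 1]
        normal1[i + 1] /= np.linalg.norm(normal1[i + 1])

    normal2 = np.cross(tangents, normal1)
    return tangents, normal1, normal2


def _curvature(points: np.ndarray, arclength: np.ndarray) -> np.ndarray:
    """Discrete curvature magnitude per point (second arclength derivative)."""
    kappa = np.zeros(len(points))
    for i in range(1, len(points) - 1):
        a = points[i] - points[i - 1]
        b = points[i + 1] - points[i]
        la, lb = np.linalg.norm(a), np.linalg.norm(b)
        cross = np.linalg.norm(np.cross(a, b))
        denom = la * lb * np.linalg.norm(points[i + 1] - points[i - 1])
        if denom > 0:
            kappa[i] = 2.0 * cross / denom
    if len(points) > 2:
        kappa[0] = kappa[1]
        kappa[-1] = kappa[-2]
    return kappa


def build_structured_mesh(
    frame: VesselFrame,
    L: int = DEFAULT_RINGS,
    C: int = DEFAULT_CIRCUMFERENTIAL,
) -> StructuredSurfaceMesh:
    """Discretize a vessel frame into an L×C structured surface mesh.

    node(i, j) = c(s_i) + r_i (cos θ_j n1_i + sin θ_j n2_i) with θ_j = 2πj/C
    and s_i equally spaced in arclength. A tube whose radius exceeds the local
    radius of curvature self-intersects; this is flagged with a warning, not an
    error, since downstream strain extraction remains well defined on the grid.
    """
    if L < 4 or C < 8:
        raise InvalidGeometryError(f"mesh density too low: need L >= 4, C >= 8 (got {L}, {C})")
    cl = resample_centerline(frame.centerline.points, L)
    radii = np.interp(cl.arclength, frame.centerline.arclength, frame.ring_radius)
    tangents, n1, n2 = local_frames(cl)
    theta = 2.0 * np.pi * np.arange(C) / C
    ring_dirs = (
        np.cos(theta)[None, :, None] * n1[:, None, :]
        + np.sin(theta)[None, :, None] * n2[:, None, :]
    )
    nodes = cl.points[:, None, :] + radii[:, None, None] * ring_dirs

    kappa = _curvature(cl.points, cl.arclength)
    intersecting = bool(np.any(kappa * radii >= 1.0))
    if intersecting:
        warnings.warn(
            "tube radius exceeds local radius of curvature: surface self-intersects",
            RuntimeWarning,
            stacklevel=2,
        )
    return StructuredSurfaceMesh(nodes=nodes, frame_ref=frame, self_intersecting=intersecting)


def mesh_to_frame(mesh: StructuredSurfaceMesh, phase: Phase = "other", time_index: int = 0) -> VesselFrame:
    """Extract per-ring centroid + mean radius from a mesh (round-trip of
    :func:`build_structured_mesh` for circular cross-sections)."""
    return VesselFrame(
        centerline=Centerline(points=mesh.ring_centroids()),
        ring_radius=mesh.ring_mean_radius(),
        phase=phase,
        time_index=time_index,
    )


def compute_stenosis_profile(frame: VesselFrame, threshold: float = 20.0) -> StenosisProfile:
    """Percent diameter stenosis per ring against a shoulder-interpolated
    reference diameter.

    The healthy reference is constructed by locating the proximal and distal
    lesion shoulders — the nearest rings on each side of the global minimum
    where the diameter recovers to >= 90% of that side's segmental median —
    and interpolating linearly between them; outside the shoulders the vessel
    is its own reference. If no healthy shoulder exists on either side the
    maximum diameter serves as a flat reference and a warning is emitted.
    """
    if not (0.0 < threshold < 100.0):
        raise InvalidGeometryError(f"stenosis threshold must lie in (0, 100), got {threshold}")
    d = frame.diameter
    n = len(d)
    i_min = int(np.argmin(d))
    reference = d.copy()

    prox = d[:i_min]
    dist = d[i_min + 1 :]
    p_idx = None
    if prox.size:
        med = np.median(prox)
        cands = np.flatnonzero(prox >= 0.9 * med)
        if cands.size:
            # nearest ring proximal of the minimum that has recovered to 90%
            # of the segmental median, extended outward along the recovery
            # slope to the local diameter plateau (the true healthy shoulder)
            p_idx = int(cands[-1])
            while p_idx > 0 and d[p_idx - 1] >= d[p_idx] - 1e-12:
                p_idx -= 1
    d_idx = None
    if dist.size:
        med = np.median(dist)
        cands = np.flatnonzero(dist >= 0.9 * med)
        if cands.size:
            d_idx = int(cands[0]) + i_min + 1
            while d_idx < n - 1 and d[d_idx + 1] >= d[d_idx] - 1e-12:
                d_idx += 1

    if p_idx is None and d_idx is None:
        warnings.warn(
            "no healthy shoulder found; falling back to max-diameter reference",
            RuntimeWarning,
            stacklevel=2,
        )
        reference = np.full(n, d.max())
    else:
        # a missing shoulder (minimum at the vessel border) degenerates to the
        # minimum ring itself, so a border taper is its own reference
        pi = i_min if p_idx is None else p_idx
        di = i_min if d_idx is None else d_idx
        span = np.arange(pi, di + 1)
        if di > pi:
            reference[span] = np.interp(span, [pi, di], [d[pi], d[di]])

    percent_ds = np.clip((1.0 - d / reference) * 100.0, 0.0, None)
    labels = np.where(percent_ds > threshold, "stenotic", "normal")
    return StenosisProfile(
        percent_ds=percent_ds,
        reference_diameter=reference,
        labels=labels,
        threshold=threshold,
        arclength=frame.centerline.arclength.copy(),
    )


# ---------------------------------------------------------------------------
# mesh export (plain-text VTK legacy polydata / Wavefront OBJ)


def _quad_connectivity(L: int, C: int) -> np.ndarray:
    i, j = np.meshgrid(np.arange(L - 1), np.arange(C), indexing="ij")
    jn = (j + 1) % C
    return np.stack(
        [i * C + j, i * C + jn, (i + 1) * C + jn, (i + 1) * C + j], axis=-1
    ).reshape(-1, 4)


def export_mesh(mesh: StructuredSurfaceMesh, path, fmt: str = "vtk") -> None:
    """Write the mesh as VTK legacy ASCII polydata (``fmt='vtk'``) or
    Wavefront OBJ with quad faces (``fmt='obj'``)."""
    pts = mesh.nodes.reshape(-1, 3)
    quads = _quad_connectivity(mesh.L, mesh.C)
    if fmt == "vtk":
        lines = [
            "# vtk DataFile Version 3.0",
            "sws4d structured vessel surface (mm)",
            "ASCII",
            "DATASET POLYDATA",
            f"POINTS {len(pts)} double",
        ]
        lines += [f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}" for p in pts]
        lines.append(f"POLYGONS {len(quads)} {len(quads) * 5}")
        lines += [f"4 {q[0]} {q[1]} {q[2]} {q[3]}" for q in quads]
    elif fmt == "obj":
        lines = ["# sws4d structured vessel surface (mm)"]
        lines += [f"v {p[0]:.12g} {p[1]:.12g} {p[2]:.12g}" for p in pts]
        lines += [f"f {q[0] + 1} {q[1] + 1} {q[2] + 1} {q[3] + 1}" for q in quads]
    else:
        raise ValueError(f"unknown mesh export format: {fmt!r} (expected 'vtk' or 'obj')")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
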