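"""Idealized stenotic coronary vessels and forward-simulated cardiac motion.

The in-silico design emulates the classical bench configuration: a 50 mm
straight vessel with 3 mm lumen and a 10 mm concentric mid-vessel lesion at
50% diameter stenosis, built in three plaque compositions (calcified,
fibrous, lipid-rich), three plaque-burden levels (50.9, 62.6, 69.1 percent
volume) and three arterial-remodeling types (negative, none, positive).

Geometry model. Cross-sections are circular; the lumen tapers into the lesion
with a raised-cosine bump. The external elastic membrane (EEM) follows a
remodeling trend (a multiplicative factor on the interpolated reference EEM
across the lesion: 0.95 negative, 1.00 none, 1.05 positive) plus a signed
raised-cosine offset whose amplitude is solved so the achieved plaque burden
(EEM volume − lumen volume)/(EEM volume) over the lesion matches the target
exactly; with the lumen and wall thickness fixed, burden and remodeling are
geometrically coupled, and the solved offset is what reconciles them.

Motion model. Cardiac deformation is kinematic with diastasis as the
zero-deformation reference: radial pulsation (peak fractional diameter change
~10-15%, attenuated inside the lesion), axial stretch about the proximal end,
smooth transverse bending of the centerline, and rigid-body motion, each
scaled by a per-phase weight (0 at diastasis). The lesion attenuation encodes
the clinical observation that stiffer plaque pulsates less while softer
plaque and larger burden show more lumen-diameter variation; defaults are
calcified 0.02, fibrous 0.18, lipid-rich 0.85, scaled linearly with burden.
Ground-truth node grids (the material motion of every mesh node) are stored
with each sequence so the inverse pipeline can be scored against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .errors import InfeasibleSpecError, InvalidGeometryError, SequenceValidationError
from .geometry import (
    Centerline,
    PHASE_ORDER,
    StructuredSurfaceMesh,
    VesselFrame,
    _curvature,
    build_structured_mesh,
)

COMPOSITIONS = ("calcified", "fibrous", "lipid_rich")
REMODELING_TYPES = ("negative", "none", "positive")
BURDEN_LEVELS = (0.509, 0.626, 0.691)

#: Remodeling trend multiplier on the interpolated reference EEM.
REMODELING_MULTIPLIER = {"negative": 0.95, "none": 1.00, "positive": 1.05}

#: Lesion pulsation multipliers per plaque composition (fraction of the
#: normal-segment pulsation), before burden scaling.
DEFAULT_ATTENUATION = {"calcified": 0.02, "fibrous": 0.18, "lipid_rich": 0.85}

#: Per-phase motion weights: a smooth cycle, zero at diastasis, extremum at
#: end-systole.
DEFAULT_PHASE_WEIGHTS = {
    "diastasis": 0.0,
    "end_diastole": 0.35,
    "early_systole": 0.8,
    "end_systole": 1.0,
    "early_diastole": 0.45,
}

MIN_WALL_THICKNESS = 0.1  # mm, feasibility floor for EEM − lumen


@dataclass(frozen=True)
class PlaqueSpec:
    """In-silico lesion description."""

    composition: str = "fibrous"
    burden_target: float = 0.509
    remodeling: str = "none"

    def __post_init__(self):
        if self.composition not in COMPOSITIONS:
            raise InvalidGeometryError(f"unknown plaque composition {self.composition!r}")
        if self.remodeling not in REMODELING_TYPES:
            raise InvalidGeometryError(f"unknown remodeling type {self.remodeling!r}")
        if not (0.0 < self.burden_target < 0.95):
            raise InvalidGeometryError(
                f"burden_target must lie in (0, 0.95), got {self.burden_target}"
            )


@dataclass(frozen=True)
class InSilicoVessel:
    """Diastasis lumen geometry + EEM envelope + lesion bookkeeping."""

    lumen: VesselFrame
    eem_radius: np.ndarray
    lesion_span: tuple[int, int]  # inclusive ring-index interval
    spec: PlaqueSpec

    def __post_init__(self):
        eem = np.asarray(self.eem_radius, dtype=float)
        if eem.shape != self.lumen.ring_radius.shape:
            raise InvalidGeometryError("eem_radius must match lumen ring count")
        object.__setattr__(self, "eem_radius", eem)

    @property
    def wall_thickness(self) -> np.ndarray:
        return self.eem_radius - self.lumen.ring_radius

    @property
    def arclength(self) -> np.ndarray:
        return self.lumen.centerline.arclength


def _lesion_bump(s: np.ndarray, center: float, length: float) -> np.ndarray:
    """Raised-cosine bump: 1 at the lesion center, 0 at and beyond the edges."""
    x = (s - center) / length
    out = np.where(np.abs(x) <= 0.5, 0.5 * (1.0 + np.cos(2.0 * np.pi * x)), 0.0)
    return out


def _frustum_volume(s: np.ndarray, r: np.ndarray) -> float:
    """Volume of the solid of revolution by exact conical frusta."""
    r1, r2 = r[:-1], r[1:]
    h = np.diff(s)
    return float(np.pi / 3.0 * np.sum(h * (r1**2 + r1 * r2 + r2**2)))


def make_stenosis_model(
    spec: PlaqueSpec = PlaqueSpec(),
    lumen_diameter: float = 3.0,
    length: float = 50.0,
    lesion_length: float = 10.0,
    ds: float = 50.0,
    n_rings: int = 101,
    wall_thickness: float = 0.5,
    lesion_center: Optional[float] = None,
    solve_burden: bool = True,
) -> InSilicoVessel:
    """Build the idealized concentric stenosis model.

    The lumen radius is nominal outside the lesion and cosine-tapered to
    (1 − ds/100) × nominal at the lesion midpoint. The EEM is the nominal
    lumen + wall thickness, modulated across the lesion by the remodeling
    trend and a solved burden offset (module docstring). ``ds = 0`` is the
    degenerate no-narrowing lesion whose burden is carried entirely by the
    EEM envelope.

    With ``solve_burden=False`` the EEM carries the pure remodeling trend
    (lesion EEM equals the interpolated reference for remodeling='none', is
    strictly smaller for 'negative' and larger for 'positive') and the
    achieved burden is whatever that geometry yields — burden and remodeling
    are geometrically coupled and cannot be prescribed independently.
    """
    if not (0.0 <= ds < 95.0):
        raise InvalidGeometryError(f"diameter stenosis must lie in [0, 95), got {ds}")
    if lesion_length >= length:
        raise InvalidGeometryError("lesion_length must be smaller than vessel length")
    r0 = lumen_diameter / 2.0
    s = np.linspace(0.0, length, n_rings)
    center = length / 2.0 if lesion_center is None else lesion_center
    bump = _lesion_bump(s, center, lesion_length)
    lumen_r = r0 * (1.0 - (ds / 100.0) * bump)

    eem_ref = np.full(n_rings, r0 + wall_thickness)
    m = REMODELING_MULTIPLIER[spec.remodeling]
    eem_base = eem_ref * (1.0 + (m - 1.0) * bump)

    span_mask = np.abs(s - center) <= lesion_length / 2.0
    i0, i1 = int(np.argmax(span_mask)), int(len(s) - 1 - np.argmax(span_mask[::-1]))
    sl = slice(i0, i1 + 1)

    # Solve the EEM bump amplitude h so that the lesion plaque burden matches
    # the target: V_eem(h) is quadratic in h under frustum integration.
    b = bump[sl]
    e0 = eem_base[sl]
    ss = s[sl]
    v_lumen = _frustum_volume(ss, lumen_r[sl])
    v_target = v_lumen / (1.0 - spec.burden_target)

    if solve_burden:
        h_seg = np.diff(ss)
        b1, b2 = b[:-1], b[1:]
        e1, e2 = e0[:-1], e0[1:]
        A = np.pi / 3.0 * np.sum(h_seg * (b1**2 + b1 * b2 + b2**2))
        B = np.pi / 3.0 * np.sum(h_seg * (2.0 * e1 * b1 + e1 * b2 + e2 * b1 + 2.0 * e2 * b2))
        C0 = _frustum_volume(ss, e0)
        disc = B**2 - 4.0 * A * (C0 - v_target)
        if disc < 0.0:
            raise InfeasibleSpecError(
                f"burden target {spec.burden_target} unreachable for remodeling "
                f"{spec.remodeling!r} (discriminant < 0)"
            )
        h = (-B + np.sqrt(disc)) / (2.0 * A)
    else:
        h = 0.0

    eem = eem_base + h * bump
    min_wall = float(np.min(eem - lumen_r))
    if min_wall < MIN_WALL_THICKNESS:
        raise InfeasibleSpecError(
            f"burden target {spec.burden_target} with remodeling {spec.remodeling!r} "
            f"needs wall thinner than the {MIN_WALL_THICKNESS} mm floor "
            f"(min wall would be {min_wall:.3f} mm)"
        )

    frame = VesselFrame(
        centerline=Centerline(points=np.column_stack([np.zeros(n_rings), np.zeros(n_rings), s])),
        ring_radius=lumen_r,
        phase="diastasis",
        time_index=0,
    )
    return InSilicoVessel(lumen=frame, eem_radius=eem, lesion_span=(i0, i1), spec=spec)


def plaque_burden(vessel: InSilicoVessel) -> float:
    """(EEM volume − lumen volume)/EEM volume over the lesion span, by frustum
    integration along the centerline."""
    i0, i1 = vessel.lesion_span
    if i1 <= i0:
        raise InvalidGeometryError("lesion span is empty; plaque burden undefined")
    sl = slice(i0, i1 + 1)
    s = vessel.arclength[sl]
    v_eem = _frustum_volume(s, vessel.eem_radius[sl])
    v_lum = _frustum_volume(s, vessel.lumen.ring_radius[sl])
    return (v_eem - v_lum) / v_eem


def lesion_attenuation(composition: str, burden: float) -> float:
    """Default lesion pulsation multiplier: composition base scaled by burden.

    Softer plaque and larger burden give more lumen-diameter variation; the
    multiplier is clipped to (0.005, 0.95) so the lesion always pulsates, but
    always less than the normal segment.
    """
    base = DEFAULT_ATTENUATION[composition]
    return float(np.clip(base * burden / 0.691, 0.005, 0.95))


@dataclass(frozen=True)
class MotionSpec:
    """Cardiac-cycle motion amplitudes (peak values; per-phase weights scale
    all components simultaneously)."""

    diameter_pulsation: float = 0.12  # peak fractional diameter change
    axial_stretch: float = 0.02  # peak fractional length change
    bending_amplitude: float = 0.004  # peak added curvature, 1/mm
    bend_center_mm: Optional[float] = None  # None -> vessel midpoint
    bend_width_mm: float = 8.0  # Gaussian width of the bend
    bend_direction_deg: float = 0.0  # direction of deflection in the x-y plane
    rigid_translation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # peak, mm
    rigid_rotation: float = 0.0  # peak rotation, rad
    rotation_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    stiffness_attenuation: Optional[float] = None  # None -> composition/burden default
    phase_weights: Optional[dict[str, float]] = None  # None -> DEFAULT_PHASE_WEIGHTS

    def weights(self) -> dict[str, float]:
        w = dict(DEFAULT_PHASE_WEIGHTS if self.phase_weights is None else self.phase_weights)
        if w.get("diastasis", 0.0) != 0.0:
            raise SequenceValidationError("diastasis phase weight must be 0 (reference state)")
        return w


@dataclass(frozen=True)
class CardiacSequence:
    """Ordered vessel frames over one cycle, diastasis first.

    ``ground_truth`` (when forward-simulated) holds the material node grids
    per frame — ``node_grids`` with shape (n_frames, L, C, 3) — plus the
    parameters that generated them; frame-to-frame true displacements are
    differences of consecutive grids and compose to zero around the cycle.
    """

    frames: Sequence[VesselFrame]
    ground_truth: Optional[dict] = None
    mesh_L: int = 0
    mesh_C: int = 32
    profile_frame: int = 0  # frame used for stenosis profiling (diastasis)

    def __post_init__(self):
        phases = [f.phase for f in self.frames]
        if len(self.frames) < 2:
            raise SequenceValidationError("a cardiac sequence needs >= 2 frames")
        if phases[0] != "diastasis":
            raise SequenceValidationError("first frame must be diastasis")
        if phases.count("diastasis") != 1:
            raise SequenceValidationError("exactly one frame may carry phase=diastasis")
        npts = {len(f.centerline) for f in self.frames}
        if len(npts) != 1:
            raise SequenceValidationError("all frames must share the centerline point count")
        if self.mesh_L == 0:
            object.__setattr__(self, "mesh_L", len(self.frames[0].centerline))

    @property
    def diastasis_index(self) -> int:
        return 0

    def meshes(self) -> list[StructuredSurfaceMesh]:
        """Structured meshes with identical (L, C) for every frame."""
        return [build_structured_mesh(f, L=self.mesh_L, C=self.mesh_C) for f in self.frames]


def _rotation_matrix(axis, angle: float) -> np.ndarray:
    a = np.asarray(axis, dtype=float)
    n = np.linalg.norm(a)
    if n == 0.0:
        raise InvalidGeometryError("rotation axis must be nonzero")
    x, y, z = a / n
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + np.sin(angle) * K + (1.0 - np.cos(angle)) * (K @ K)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def generate_cardiac_sequence(
    vessel: InSilicoVessel,
    motion: MotionSpec = MotionSpec(),
    phases: Optional[Sequence[str]] = None,
    seed: int = 0,
    mesh_C: int = 32,
) -> CardiacSequence:
    """Forward-simulate one cardiac cycle with known ground truth.

    Each frame applies, scaled by its phase weight: radial pulsation
    (attenuated inside the lesion), axial stretch about the proximal end,
    transverse Gaussian bending of the centerline, and rigid-body motion.
    Ground-truth node grids are the torsion-free material motion of the mesh
    nodes (ring-following with parallel-transported circumferential frames).
    """
    phases = list(PHASE_ORDER) if phases is None else list(phases)
    if phases[0] != "diastasis":
        raise SequenceValidationError("phase list must start with diastasis")
    weights = motion.weights()
    missing = [p for p in phases if p not in weights]
    if missing:
        raise SequenceValidationError(f"no phase weight for {missing}")

    base = vessel.lumen
    s = base.centerline.arclength
    pts0 = base.centerline.points
    r0 = base.ring_radius
    length = float(s[-1])
    burden = plaque_burden(vessel)
    a_eff = (
        motion.stiffness_attenuation
        if motion.stiffness_attenuation is not None
        else lesion_attenuation(vessel.spec.composition, burden)
    )

    # Lesion compliance mask with smoothed edges; pulsation multiplier per
    # ring. The 2.5 mm edge keeps the compliance transition resolved by
    # several mesh rings (an abrupt, grid-scale transition would alias under
    # the matching's surface resampling), and the ramp is shifted 1 mm
    # outward so that full attenuation is reached before the stenotic
    # segmentation boundary (%DS > 20): the plaque material and the plaque
    # compliance then cover the same rings.
    i0, i1 = vessel.lesion_span
    s0, s1 = s[i0], s[i1]
    edge = 2.5
    mask = _smoothstep((s - (s0 - 1.0)) / edge) * _smoothstep(((s1 + 1.0) - s) / edge)
    pulsation_mult = 1.0 - (1.0 - a_eff) * mask

    center = length / 2.0 if motion.bend_center_mm is None else motion.bend_center_mm
    w_b = motion.bend_width_mm
    phi = np.deg2rad(motion.bend_direction_deg)
    bend_dir = np.array([np.cos(phi), np.sin(phi), 0.0])
    # Gaussian deflection with unit peak second derivative: the peak added
    # curvature equals bending_amplitude. Only the pressure-driven radial
    # pulsation is attenuated inside the lesion; axial stretch and bending
    # are imposed kinematically by myocardial tethering and apply uniformly.
    deflection_shape = w_b**2 * np.exp(-((s - center) ** 2) / (2.0 * w_b**2))

    tvec = np.asarray(motion.rigid_translation, dtype=float)

    frames: list[VesselFrame] = []
    grids: list[np.ndarray] = []
    L = len(s)
    for k, phase in enumerate(phases):
        w = weights[phase]
        radii = r0 * (1.0 + w * motion.diameter_pulsation * pulsation_mult)
        pts = pts0[0] + (pts0 - pts0[0]) * (1.0 + w * motion.axial_stretch)
        pts = pts + (w * motion.bending_amplitude * deflection_shape)[:, None] * bend_dir

        kappa = _curvature(pts, s)
        bad = kappa * radii >= 1.0
        if np.any(bad):
            raise InvalidGeometryError(
                f"motion produces a self-intersecting surface first at frame {k} "
                f"({phase}), ring {int(np.argmax(bad))}"
            )

        unrotated = VesselFrame(
            centerline=Centerline(points=pts), ring_radius=radii, phase=phase, time_index=k
        )
        grid = build_structured_mesh(unrotated, L=L, C=mesh_C).nodes

        if motion.rigid_rotation != 0.0 or np.any(tvec != 0.0):
            R = _rotation_matrix(motion.rotation_axis, w * motion.rigid_rotation)
            centroid = pts.mean(axis=0)
            pts = (pts - centroid) @ R.T + centroid + w * tvec
            grid = (grid - centroid) @ R.T + centroid + w * tvec

        frames.append(
            VesselFrame(
                centerline=Centerline(points=pts), ring_radius=radii, phase=phase, time_index=k
            )
        )
        grids.append(grid)

    ground_truth = {
        "node_grids": np.stack(grids),
        "burden": burden,
        "attenuation": a_eff,
        "lesion_span": vessel.lesion_span,
        "phase_weights": {p: weights[p] for p in phases},
        "seed": seed,
    }
    return CardiacSequence(
        frames=frames, ground_truth=ground_truth, mesh_L=L, mesh_C=mesh_C
    )


def make_validation_cohort(
    n: int = 16,
    seed: int = 0,
    mesh_L: int = 101,
    mesh_C: int = 32,
    bend_site: str = "random",
) -> list[tuple[InSilicoVessel, CardiacSequence]]:
    """Seeded cohort of stenotic vessels with randomized lesion and motion.

    Plaque specs are drawn stratified over the 3×3×3 composition × burden ×
    remodeling design (all three compositions appear whenever n >= 9 since a
    shuffled full factorial is cycled). Motion amplitudes are drawn from
    documented physiological ranges: pulsation 10-15%, axial stretch 1-3%,
    bending curvature 0.002-0.008 /mm, rigid translation up to 2 mm and
    rotation up to 0.05 rad. ``bend_site='proximal_shoulder'`` concentrates a
    stronger, narrower bend at the proximal lesion shoulder (the configuration
    for peak-stress localization experiments).
    """
    if n < 1:
        raise InvalidGeometryError("cohort size must be >= 1")
    rng = np.random.default_rng(seed)
    design = [
        (c, b, r) for c in COMPOSITIONS for b in BURDEN_LEVELS for r in REMODELING_TYPES
    ]
    order = rng.permutation(len(design))

    out = []
    for i in range(n):
        comp, burden, remod = design[order[i % len(design)]]
        spec = PlaqueSpec(composition=comp, burden_target=burden, remodeling=remod)
        vessel = make_stenosis_model(spec, n_rings=mesh_L)
        length = float(vessel.arclength[-1])
        throat_s = length / 2.0

        if bend_site == "proximal_shoulder":
            # the stenotic band (%DS > 20) of the 50%-DS cosine lesion spans
            # ±2.8 mm around the throat; the proximal shoulder band is its
            # proximal half, so the bend is centered ~2.5 mm before the throat
            bend_center = throat_s - 2.5 + rng.uniform(-0.5, 0.5)
            bend_width = rng.uniform(2.5, 4.0)
            bend_amp = rng.uniform(0.05, 0.09)
        elif bend_site == "random":
            bend_center = rng.uniform(0.3, 0.7) * length
            bend_width = rng.uniform(6.0, 10.0)
            bend_amp = rng.uniform(0.002, 0.008)
        else:
            raise InvalidGeometryError(f"unknown bend_site {bend_site!r}")

        t_dir = rng.normal(size=3)
        t_dir /= np.linalg.norm(t_dir)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        motion = MotionSpec(
            diameter_pulsation=rng.uniform(0.10, 0.15),
            axial_stretch=rng.uniform(0.01, 0.03),
            bending_amplitude=bend_amp,
            bend_center_mm=bend_center,
            bend_width_mm=bend_width,
            bend_direction_deg=rng.uniform(0.0, 360.0),
            rigid_translation=tuple(rng.uniform(0.5, 2.0) * t_dir),
            rigid_rotation=rng.uniform(0.0, 0.05),
            rotation_axis=tuple(axis),
        )
        seq_seed = int(rng.integers(2**31))
        seq = generate_cardiac_sequence(vessel, motion, seed=seq_seed, mesh_C=mesh_C)
        if mesh_L != len(vessel.arclength):
            seq = replace(seq, mesh_L=mesh_L)
        out.append((vessel, seq))
    return out
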