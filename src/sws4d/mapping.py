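"""Node correspondence between consecutive configurations by minimum
potential energy.

Because every frame of a sequence is discretized into a structured mesh with
identical node dimensions, the one-to-one correspondence search reduces to a
re-parameterization of the surface: a continuous axial shift of the ring
coordinate plus a circumferential twist. The global displacement functional

    E(matching) = α_deform · Σ_elements W_MR(stretch under the matching) A_ref
                  / ((C1+C2) Σ A_ref)
                + α_kinetic · Σ_nodes ‖d_n − d̄‖² / (L·C·d_nom²)

is minimized over matchings; W_MR uses nominal normal-tissue constants, d_nom
is the nominal diameter and d̄ the mean displacement. The deformation term is
zero exactly when the matched correspondence is an isometry of the element
edges; the kinetic-proxy term penalizes motion heterogeneity and selects the
physically smallest motion among (near-)isometric matches. The mean is
removed from the kinetic term because bulk translation between frames is
cardiac motion of the whole vessel and carries no correspondence information;
penalizing it would bias the matching away from zero-deformation optima.

Minimization is a coarse grid over all C circumferential offsets × axial
offsets within ±2 ring spacings (ties broken toward the smaller-magnitude
axial offset, then the smaller circumferential index) followed by
Nelder-Mead refinement of the continuous (axial, twist) pair.

Starting from diastasis, correspondences are propagated pair-by-pair around
the cycle on the previously matched configuration, making the mapping
transitive; the cycle-closure residual (how far the composed motion misses
the diastasis nodes) is measured and reported, never corrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import minimize

from .errors import ConvergenceError, InvalidGeometryError, SequenceValidationError
from .geometry import Centerline, StructuredSurfaceMesh
from .materials import MaterialModel, default_materials
from .strain_stress import _element_edges_2d, _inv2x2
from .synthetic import CardiacSequence

__all__ = [
    "Matching",
    "SearchConfig",
    "DisplacementField",
    "CycleResult",
    "matching_energy",
    "map_displacements",
    "propagate_cycle",
    "predict_frame",
]


@dataclass(frozen=True)
class Matching:
    """Surface re-parameterization: axial shift (mm) + circumferential twist
    (rad, in [0, 2π))."""

    axial_offset: float = 0.0
    circumferential_offset: float = 0.0
    monotone_map: Optional[np.ndarray] = None  # reserved; global shift only

    def __post_init__(self):
        object.__setattr__(
            self, "circumferential_offset", float(self.circumferential_offset) % (2.0 * np.pi)
        )
        if self.monotone_map is not None:
            m = np.asarray(self.monotone_map, dtype=float)
            if np.any(np.diff(m) <= 0.0):
                raise InvalidGeometryError("monotone_map must be strictly increasing")
            object.__setattr__(self, "monotone_map", m)


@dataclass(frozen=True)
class SearchConfig:
    """Matching-search settings."""

    alpha_deform: float = 1.0
    alpha_kinetic: float = 0.1
    axial_halfwidth_rings: float = 2.0
    axial_step_rings: float = 1.0
    refine: bool = True
    max_refine_iter: int = 200
    xatol: float = 1e-9
    fatol: float = 1e-16
    tie_tolerance: float = 1e-12


@dataclass(frozen=True)
class DisplacementField:
    """Per-node displacement between two matched configurations."""

    vectors: np.ndarray  # (L, C, 3), mm
    from_index: int
    to_index: int
    energy: float
    matching: Matching

    def __post_init__(self):
        if self.energy < 0.0:
            raise InvalidGeometryError("matching energy must be >= 0")


@dataclass(frozen=True)
class CycleResult:
    """Propagated correspondences for a full cardiac cycle."""

    fields: list[DisplacementField]  # one per consecutive pair, incl. closure
    grids: list[np.ndarray]  # matched node grids per frame (material nodes)
    closure_residual_mm: float  # max node distance after composing the cycle


def _nodes(mesh: Union[StructuredSurfaceMesh, np.ndarray]) -> np.ndarray:
    if isinstance(mesh, StructuredSurfaceMesh):
        return mesh.nodes
    arr = np.asarray(mesh, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise InvalidGeometryError("expected an (L, C, 3) node grid")
    return arr


def resample_grid(nodes: np.ndarray, axial_offset: float, circ_offset: float) -> np.ndarray:
    """Sample a structured grid at shifted surface coordinates.

    Node (i, j) of the output sits at ring coordinate i + axial_offset/h̄
    (h̄ = mean ring spacing; linear inter-/extrapolation axially) and angle
    θ_j + circ_offset (periodic linear interpolation circumferentially).
    """
    L, C, _ = nodes.shape
    g = (circ_offset % (2.0 * np.pi)) / (2.0 * np.pi / C)
    j0 = int(np.floor(g))
    wg = g - j0
    tmp = (1.0 - wg) * np.roll(nodes, -j0, axis=1) + wg * np.roll(nodes, -(j0 + 1), axis=1)
    if wg != 0.0:
        # chord-consistent correction: linear interpolation at fraction wg of
        # a node spacing pulls a circular ring's points inward by the factor
        # |(1-wg) + wg e^{iα}| (α = 2π/C), shrinking the ring circumference;
        # left uncorrected, an inflating vessel would reward spurious
        # half-node twists. Rescaling about the ring centroid restores a
        # congruent ring (exact for circular cross-sections).
        alpha = 2.0 * np.pi / C
        factor = np.hypot(1.0 - wg * (1.0 - np.cos(alpha)), wg * np.sin(alpha))
        centroids = tmp.mean(axis=1, keepdims=True)
        tmp = centroids + (tmp - centroids) / factor

    if axial_offset != 0.0:
        centroids = nodes.mean(axis=1)
        h_bar = float(np.linalg.norm(np.diff(centroids, axis=0), axis=1).mean())
        fi = np.arange(L) + axial_offset / h_bar
        i0 = np.clip(np.floor(fi).astype(int), 0, L - 2)
        w = (fi - i0)[:, None, None]
        # Catmull-Rom axial interpolation (linear beyond the ends): linear
        # interpolation would low-pass the deformed surface and systematically
        # lower the apparent deformation energy at fractional shifts, biasing
        # the matching; the cubic keeps the smoothing error at 4th order.
        ext = np.concatenate(
            [2 * tmp[:1] - tmp[1:2], tmp, 2 * tmp[-1:] - tmp[-2:-1]], axis=0
        )  # index shift +1
        p0, p1, p2, p3 = ext[i0], ext[i0 + 1], ext[i0 + 2], ext[i0 + 3]
        inside = ((fi >= 0.0) & (fi <= L - 1.0))[:, None, None]
        cubic = 0.5 * (
            2.0 * p1
            + (-p0 + p2) * w
            + (2.0 * p0 - 5.0 * p1 + 4.0 * p2 - p3) * w**2
            + (-p0 + 3.0 * p1 - 3.0 * p2 + p3) * w**3
        )
        linear = (1.0 - w) * p1 + w * p2
        tmp = np.where(inside, cubic, linear)
    return tmp


class _EnergyEvaluator:
    """Caches the reference-side quantities of the matching functional."""

    def __init__(
        self,
        nodes_a: np.ndarray,
        nodes_b: np.ndarray,
        weights: tuple[float, float],
        material: Optional[MaterialModel] = None,
    ):
        if nodes_a.shape != nodes_b.shape:
            raise InvalidGeometryError(
                "meshes must share identical node dimensions "
                f"(got {nodes_a.shape[:2]} vs {nodes_b.shape[:2]})"
            )
        self.nodes_a = nodes_a
        self.nodes_b = nodes_b
        self.alpha_deform, self.alpha_kinetic = weights
        self.material = material or default_materials()["normal"]

        quads = self._quads(nodes_a)
        e_ref = _element_edges_2d(quads)  # (L-1, C, 2, 4)
        ee = np.einsum("...ie,...je->...ij", e_ref, e_ref)
        self._eref = e_ref
        self._ee_inv = _inv2x2(ee)
        u = quads[..., 1, :] - quads[..., 0, :] + quads[..., 2, :] - quads[..., 3, :]
        v = quads[..., 3, :] - quads[..., 0, :] + quads[..., 2, :] - quads[..., 1, :]
        self._area = 0.25 * np.linalg.norm(np.cross(u, v), axis=-1)
        self._area_total = float(self._area.sum())
        c = nodes_a.mean(axis=1)[:, None, :]
        self.d_nom = 2.0 * float(np.linalg.norm(nodes_a - c, axis=2).mean())
        self._n_nodes = nodes_a.shape[0] * nodes_a.shape[1]

    @staticmethod
    def _quads(nodes: np.ndarray) -> np.ndarray:
        a = nodes[:-1]
        b = np.roll(nodes, -1, axis=1)[:-1]
        c = np.roll(nodes, -1, axis=1)[1:]
        d = nodes[1:]
        return np.stack([a, b, c, d], axis=2)

    def __call__(self, axial_offset: float, circ_offset: float) -> float:
        matched = resample_grid(self.nodes_b, axial_offset, circ_offset)
        e_def = _element_edges_2d(self._quads(matched))
        de = np.einsum("...ie,...je->...ij", e_def, self._eref)
        F = np.einsum("...ij,...jk->...ik", de, self._ee_inv)
        det = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
        if np.any(det <= 0.0):
            return np.inf
        g11 = F[..., 0, 0] ** 2 + F[..., 1, 0] ** 2
        g22 = F[..., 0, 1] ** 2 + F[..., 1, 1] ** 2
        lam1sq_lam2sq = g11 * g22 - (F[..., 0, 0] * F[..., 0, 1] + F[..., 1, 0] * F[..., 1, 1]) ** 2
        i1 = g11 + g22 + 1.0 / lam1sq_lam2sq
        i2 = lam1sq_lam2sq + (g11 + g22) / lam1sq_lam2sq
        w_density = self.material.c1 * (i1 - 3.0) + self.material.c2 * (i2 - 3.0)
        e_deform = float(np.sum(w_density * self._area)) / (
            (self.material.c1 + self.material.c2) * self._area_total
        )

        disp = matched - self.nodes_a
        disp = disp - disp.mean(axis=(0, 1))
        e_kin = float(np.sum(disp**2)) / (self._n_nodes * self.d_nom**2)
        return self.alpha_deform * e_deform + self.alpha_kinetic * e_kin

    def displacement(self, matching: Matching) -> np.ndarray:
        matched = resample_grid(
            self.nodes_b, matching.axial_offset, matching.circumferential_offset
        )
        return matched - self.nodes_a


def matching_energy(
    mesh_a: Union[StructuredSurfaceMesh, np.ndarray],
    mesh_b: Union[StructuredSurfaceMesh, np.ndarray],
    matching: Matching = Matching(),
    weights: tuple[float, float] = (1.0, 0.1),
    material: Optional[MaterialModel] = None,
) -> float:
    """Value of the matching functional for one candidate correspondence."""
    ev = _EnergyEvaluator(_nodes(mesh_a), _nodes(mesh_b), weights, material)
    return ev(matching.axial_offset, matching.circumferential_offset)


def map_displacements(
    mesh_a: Union[StructuredSurfaceMesh, np.ndarray],
    mesh_b: Union[StructuredSurfaceMesh, np.ndarray],
    search: Optional[SearchConfig] = None,
    from_index: int = 0,
    to_index: int = 1,
) -> DisplacementField:
    """Energy-minimizing one-to-one node correspondence between two meshes.

    Coarse stage: all C circumferential offsets × axial offsets on a grid of
    ±``axial_halfwidth_rings`` ring spacings. Refinement: Nelder-Mead on the
    continuous (axial, twist) pair, accepted only if it improves the energy.
    An exactly-zero coarse optimum (an exact isometric match) short-circuits
    refinement. Non-convergence of the refinement raises
    :class:`ConvergenceError` carrying the best matching found.
    """
    cfg = search or SearchConfig()
    nodes_a, nodes_b = _nodes(mesh_a), _nodes(mesh_b)
    ev = _EnergyEvaluator(nodes_a, nodes_b, (cfg.alpha_deform, cfg.alpha_kinetic))

    L, C, _ = nodes_a.shape
    centroids = nodes_b.mean(axis=1)
    h_bar = float(np.linalg.norm(np.diff(centroids, axis=0), axis=1).mean())
    n_steps = int(round(cfg.axial_halfwidth_rings / cfg.axial_step_rings))
    deltas = np.arange(-n_steps, n_steps + 1) * cfg.axial_step_rings * h_bar
    phis = 2.0 * np.pi * np.arange(C) / C

    best = (np.inf, 0.0, 0.0, 0)  # (energy, |delta|, delta, j)
    energy_best = np.inf
    for d in deltas:
        for j, phi in enumerate(phis):
            e = ev(d, phi)
            # tie-break: smaller-magnitude axial offset, then smaller circ index
            if e < energy_best - cfg.tie_tolerance or (
                e <= energy_best + cfg.tie_tolerance
                and (abs(d), j) < (best[1], best[3])
            ):
                best = (e, abs(d), d, j)
                energy_best = min(e, energy_best)
    e0, _, d0, j0 = best
    if not np.isfinite(e0):
        raise ConvergenceError("no valid matching found in coarse search", best=None)
    # unwrap the twist toward the smaller-magnitude angle for refinement
    phi0 = phis[j0] if j0 <= C // 2 else phis[j0] - 2.0 * np.pi

    matching = Matching(axial_offset=d0, circumferential_offset=phi0)
    energy = e0
    if cfg.refine and e0 > 1e-15:
        res = minimize(
            lambda x: ev(x[0], x[1]),
            x0=np.array([d0, phi0]),
            method="Nelder-Mead",
            options={
                "xatol": cfg.xatol,
                "fatol": cfg.fatol,
                "maxiter": cfg.max_refine_iter,
                "maxfev": 4 * cfg.max_refine_iter,
            },
        )
        # accept only a meaningful improvement: along flat (symmetry)
        # directions of the functional the simplex otherwise drifts on
        # floating-point noise, and the tie-broken coarse point is the answer
        if res.fun < e0 - (1e-10 * abs(e0) + 1e-18):
            matching = Matching(axial_offset=float(res.x[0]), circumferential_offset=float(res.x[1]))
            energy = float(res.fun)
        if not res.success and res.fun > e0:
            raise ConvergenceError(
                "matching refinement did not converge",
                best=matching,
                trace={"coarse_energy": e0, "refined_energy": float(res.fun)},
            )

    return DisplacementField(
        vectors=ev.displacement(matching),
        from_index=from_index,
        to_index=to_index,
        energy=max(energy, 0.0),
        matching=matching,
    )


def propagate_cycle(
    sequence: CardiacSequence,
    search: Optional[SearchConfig] = None,
) -> CycleResult:
    """Propagate the correspondence from diastasis around the whole cycle.

    Pair k → k+1 is matched on the previously matched configuration (the
    material node grid carried forward), so the correspondence is transitive
    through the cycle. The final pair maps back onto the diastasis mesh; the
    closure residual is the largest distance between a composed node position
    and its diastasis origin.
    """
    if sequence.frames[0].phase != "diastasis":
        raise SequenceValidationError("cycle propagation must start at diastasis")
    meshes = sequence.meshes()
    n = len(meshes)
    grids = [meshes[0].nodes]
    fields: list[DisplacementField] = []
    for k in range(n):
        nxt = (k + 1) % n
        try:
            fld = map_displacements(
                grids[k] if k < len(grids) else grids[-1],
                meshes[nxt],
                search=search,
                from_index=k,
                to_index=nxt,
            )
        except (ConvergenceError, InvalidGeometryError) as exc:
            raise ConvergenceError(
                f"cycle propagation failed on pair ({k} -> {nxt}): {exc}",
                best=getattr(exc, "best", None),
            ) from exc
        fields.append(fld)
        new_grid = grids[k] + fld.vectors
        if nxt != 0:
            grids.append(new_grid)
        else:
            closure = float(np.max(np.linalg.norm(new_grid - grids[0], axis=2)))
    return CycleResult(fields=fields, grids=grids, closure_residual_mm=closure)


def predict_frame(
    sequence: CardiacSequence,
    k: int,
    search: Optional[SearchConfig] = None,
) -> Centerline:
    """Predict the held-out frame k's centerline from its neighbors.

    The meshes adjacent to k are matched directly and node positions at k's
    time fraction are interpolated piecewise-linearly in time; the predicted
    centerline is the ring-centroid curve of the interpolated grid. Frame k's
    own geometry is never touched. The diastasis frame is the reference
    configuration and cannot be held out.
    """
    n = len(sequence.frames)
    if n < 4:
        raise SequenceValidationError("frame prediction needs >= 3 frames besides the target")
    if k == sequence.diastasis_index:
        raise SequenceValidationError("the diastasis reference frame cannot be held out")
    if not (0 < k < n):
        raise SequenceValidationError(f"frame index {k} out of range")

    a = k - 1
    b = (k + 1) % n
    meshes = sequence.meshes()
    fld = map_displacements(meshes[a], meshes[b], search=search, from_index=a, to_index=b)
    # uniform frame spacing: the held-out instant lies midway between its
    # neighbors (the wrap to diastasis closes the cycle one step after the end)
    frac = 0.5
    grid_k = meshes[a].nodes + frac * fld.vectors
    return Centerline(points=grid_k.mean(axis=1))
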