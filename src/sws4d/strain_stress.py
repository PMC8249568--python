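"""Superficial wall strain and stress from corresponded node grids.

Strain follows the stretch-ratio construction: each structured-mesh quad is a
membrane element whose in-plane deformation gradient F (2×2) is the
least-squares linear map sending the element's reference edge vectors —
expressed in the element's own tangent basis — to the deformed edge vectors.
Principal stretches are the singular values of F; incompressibility supplies
λ3 = 1/(λ1 λ2). Strain relative to the diastasis reference ("cumulative") is
the default for reported maximum principal strain; frame-to-frame increments
("incremental") are also available, and cumulative stretch equals the ordered
product of incremental stretch tensors.

Stress applies the lesion-aware Mooney-Rivlin material assignment: rings are
segmented into normal vs. stenotic by percent diameter stenosis, stenotic
elements receive the lesion-composition material, and plane-stress principal
Cauchy and von Mises stresses follow from the stretches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidGeometryError
from .geometry import StenosisProfile
from .materials import MaterialModel, mooney_rivlin_cauchy, von_mises

__all__ = [
    "DeformationState",
    "StrainField",
    "StressField",
    "PulseStressResult",
    "FieldSummary",
    "element_deformation_gradient",
    "grid_deformation_gradients",
    "principal_stretches",
    "compute_strain_series",
    "compute_stress_series",
    "pulse_stress",
    "summarize_fields",
]

PEAK_CLASSES = ("proximal_shoulder", "throat", "distal_shoulder", "normal")


# ---------------------------------------------------------------------------
# element kinematics


def _element_edges_2d(quads: np.ndarray) -> np.ndarray:
    """Project the 4 edge vectors of each quad onto its own tangent basis.

    ``quads``: (..., 4, 3) with corner order a=(i,j), b=(i,j+1), c=(i+1,j+1),
    d=(i+1,j). Returns (..., 2, 4): the circumferential edges (b−a, c−d) and
    axial edges (d−a, c−b) in 2D coordinates. The basis is anchored on the
    mean circumferential edge, so it co-rotates exactly under rigid motion.
    """
    a, b, c, d = quads[..., 0, :], quads[..., 1, :], quads[..., 2, :], quads[..., 3, :]
    e_circ1, e_circ2 = b - a, c - d
    e_ax1, e_ax2 = d - a, c - b
    u = e_circ1 + e_circ2
    v = e_ax1 + e_ax2
    e1 = u / np.linalg.norm(u, axis=-1, keepdims=True)
    n = np.cross(e1, v)
    n_norm = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(n_norm == 0.0):
        raise InvalidGeometryError("degenerate quad: edges are collinear")
    n /= n_norm
    e2 = np.cross(n, e1)
    edges = np.stack([e_circ1, e_circ2, e_ax1, e_ax2], axis=-2)  # (..., 4, 3)
    x = np.einsum("...ek,...k->...e", edges, e1)
    y = np.einsum("...ek,...k->...e", edges, e2)
    return np.stack([x, y], axis=-2)  # (..., 2, 4)


def grid_deformation_gradients(ref_nodes: np.ndarray, def_nodes: np.ndarray) -> np.ndarray:
    """In-plane deformation gradients for every quad of an L×C grid.

    Returns F with shape (L-1, C, 2, 2); raises on inverted elements.
    """
    if ref_nodes.shape != def_nodes.shape:
        raise InvalidGeometryError("reference and deformed grids must share (L, C)")

    def quads(nodes):
        a = nodes[:-1]
        b = np.roll(nodes, -1, axis=1)[:-1]
        c = np.roll(nodes, -1, axis=1)[1:]
        d = nodes[1:]
        return np.stack([a, b, c, d], axis=2)  # (L-1, C, 4, 3)

    e_ref = _element_edges_2d(quads(ref_nodes))  # (L-1, C, 2, 4)
    e_def = _element_edges_2d(quads(def_nodes))
    # least squares over the 4 edges: F = (D E^T)(E E^T)^{-1}
    de = np.einsum("...ie,...je->...ij", e_def, e_ref)  # (.., 2, 2)
    ee = np.einsum("...ie,...je->...ij", e_ref, e_ref)
    F = np.einsum("...ij,...jk->...ik", de, _inv2x2(ee))
    det = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    if np.any(det <= 0.0):
        bad = np.argwhere(det <= 0.0)[0]
        raise InvalidGeometryError(
            f"inverted element at (ring {bad[0]}, column {bad[1]}): det F <= 0"
        )
    return F


def _inv2x2(m: np.ndarray) -> np.ndarray:
    det = m[..., 0, 0] * m[..., 1, 1] - m[..., 0, 1] * m[..., 1, 0]
    if np.any(det == 0.0):
        raise InvalidGeometryError("singular edge system in deformation-gradient fit")
    inv = np.empty_like(m)
    inv[..., 0, 0] = m[..., 1, 1]
    inv[..., 1, 1] = m[..., 0, 0]
    inv[..., 0, 1] = -m[..., 0, 1]
    inv[..., 1, 0] = -m[..., 1, 0]
    return inv / det[..., None, None]


def element_deformation_gradient(ref_element, def_element) -> np.ndarray:
    """2×2 in-plane deformation gradient for one quad element.

    Corner order: (i,j), (i,j+1), (i+1,j+1), (i+1,j). The result is the
    least-squares linear map over the element's four edge vectors.
    """
    ref = np.asarray(ref_element, dtype=float).reshape(4, 3)
    dfm = np.asarray(def_element, dtype=float).reshape(4, 3)
    e_ref = _element_edges_2d(ref[None])  # (1, 2, 4)
    e_def = _element_edges_2d(dfm[None])
    de = np.einsum("nie,nje->nij", e_def, e_ref)
    ee = np.einsum("nie,nje->nij", e_ref, e_ref)
    F = (de @ _inv2x2(ee))[0]
    if np.linalg.det(F) <= 0.0:
        raise InvalidGeometryError("inverted element: det F <= 0")
    return F


def principal_stretches(F) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(λ1, λ2, λ3) with λ1 >= λ2 the singular values of F and λ3 = 1/(λ1 λ2).

    Closed-form 2×2 SVD via the eigenvalues of FᵀF; broadcasts over leading
    axes of an (..., 2, 2) array.
    """
    F = np.asarray(F, dtype=float)
    g11 = F[..., 0, 0] ** 2 + F[..., 1, 0] ** 2
    g22 = F[..., 0, 1] ** 2 + F[..., 1, 1] ** 2
    g12 = F[..., 0, 0] * F[..., 0, 1] + F[..., 1, 0] * F[..., 1, 1]
    tr = g11 + g22
    disc = np.sqrt(np.maximum((g11 - g22) ** 2 + 4.0 * g12**2, 0.0))
    lam1 = np.sqrt((tr + disc) / 2.0)
    detF = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    if np.any(detF <= 0.0):
        raise InvalidGeometryError("principal stretches require det F > 0")
    # λ2 from the determinant rather than the small eigenvalue: better
    # conditioned, and it makes λ1·λ2 = det F exact so that λ1λ2λ3 = 1 holds
    # to machine precision.
    lam2 = detF / lam1
    lam3 = 1.0 / (lam1 * lam2)
    return lam1, lam2, lam3


@dataclass(frozen=True)
class DeformationState:
    """Per-element kinematic state of a membrane deformation."""

    F: np.ndarray  # (L-1, C, 2, 2)
    stretches: tuple[np.ndarray, np.ndarray, np.ndarray]
    green_strain: tuple[np.ndarray, np.ndarray]  # principal Green-Lagrange strains
    invariants_bar: tuple[np.ndarray, np.ndarray]

    @classmethod
    def from_gradients(cls, F: np.ndarray) -> "DeformationState":
        lam1, lam2, lam3 = principal_stretches(F)
        e1, e2 = (lam1**2 - 1.0) / 2.0, (lam2**2 - 1.0) / 2.0
        i1 = lam1**2 + lam2**2 + lam3**2
        i2 = (lam1 * lam2) ** 2 + (lam1 * lam3) ** 2 + (lam2 * lam3) ** 2
        return cls(F=F, stretches=(lam1, lam2, lam3), green_strain=(e1, e2), invariants_bar=(i1, i2))


@dataclass(frozen=True)
class StrainField:
    """Per-element strain state of one frame.

    ``cumulative`` is True when stretches are measured relative to diastasis,
    False for frame-to-frame increments.
    """

    deformation: DeformationState
    frame_index: int
    cumulative: bool
    element_arclength: np.ndarray  # (L-1,) element-row mid arclength, mm

    @property
    def max_principal_strain(self) -> np.ndarray:
        return self.deformation.stretches[0] - 1.0

    @property
    def stretches(self):
        return self.deformation.stretches


@dataclass(frozen=True)
class StressField:
    """Per-element plane-stress state of one frame (kPa)."""

    principal_cauchy: tuple[np.ndarray, np.ndarray]
    von_mises: np.ndarray
    material_map: np.ndarray  # (L-1, C) tissue-class strings
    frame_index: int
    element_arclength: np.ndarray


@dataclass(frozen=True)
class PulseStressResult:
    """|von Mises(end-systole) − von Mises(end-diastole)| per element."""

    values: np.ndarray  # (L-1, C) kPa
    argmax_element: tuple[int, int]
    argmax_arclength_mm: float


@dataclass(frozen=True)
class FieldSummary:
    """Cycle summary: per-segment time averages and the peak-stress location."""

    strain_by_class: dict[str, float]  # time-averaged mean max principal strain
    stress_by_class: dict[str, float]  # time-averaged mean von Mises, kPa
    peak_von_mises_kpa: float
    peak_frame_index: int
    peak_element: tuple[int, int]
    peak_arclength_mm: float
    peak_location_class: str


def _element_arclength(grid: np.ndarray) -> np.ndarray:
    centroids = grid.mean(axis=1)
    seg = np.linalg.norm(np.diff(centroids, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return (arc[:-1] + arc[1:]) / 2.0


def compute_strain_series(
    grids: Sequence[np.ndarray],
    mode: str = "cumulative",
) -> list[StrainField]:
    """Strain fields for frames 1..n-1 of a cycle of corresponded node grids.

    ``grids`` are the (L, C, 3) node positions of the *same material nodes* at
    each frame, grids[0] being diastasis (the reference). In cumulative mode
    each frame's F maps diastasis directly to that frame; in incremental mode
    it maps the previous frame to the current one. Composing increments equals
    the cumulative gradient, so two half-steps of 6% inflation accumulate to
    1.06² − 1 = 12.36%, not 12%.
    """
    if mode not in ("cumulative", "incremental"):
        raise ConfigurationError(f"unknown strain mode {mode!r}")
    ref_arc = _element_arclength(np.asarray(grids[0], dtype=float))
    out = []
    for k in range(1, len(grids)):
        ref = grids[0] if mode == "cumulative" else grids[k - 1]
        F = grid_deformation_gradients(np.asarray(ref, float), np.asarray(grids[k], float))
        out.append(
            StrainField(
                deformation=DeformationState.from_gradients(F),
                frame_index=k,
                cumulative=(mode == "cumulative"),
                element_arclength=ref_arc,
            )
        )
    return out


def _element_labels(profile: StenosisProfile, n_rows: int) -> np.ndarray:
    """Label element row i by the more diseased of rings i, i+1 (captures the
    shoulders, consistent with assigning plaque material to any element that
    touches a stenotic ring)."""
    ds = profile.percent_ds
    if len(ds) != n_rows + 1:
        raise ConfigurationError(
            f"stenosis profile has {len(ds)} rings but strain field has {n_rows} element rows"
        )
    row_ds = np.maximum(ds[:-1], ds[1:])
    return np.where(row_ds > profile.threshold, "stenotic", "normal")


def compute_stress_series(
    strain_series: Sequence[StrainField],
    profile: StenosisProfile,
    materials: dict[str, MaterialModel],
    lesion_class: Optional[str] = None,
) -> list[StressField]:
    """Stress fields from a strain series with lesion-aware material assignment.

    Stenotic element rows receive the lesion composition's material; the
    composition is ``lesion_class`` or, if omitted, the unique non-normal key
    of ``materials``.
    """
    if "normal" not in materials:
        raise ConfigurationError("material map must cover tissue class 'normal'")
    if lesion_class is None:
        plaque_keys = [k for k in materials if k != "normal"]
        if len(plaque_keys) == 1:
            lesion_class = plaque_keys[0]
        elif profile.stenotic.any():
            raise ConfigurationError(
                "ambiguous lesion material: pass lesion_class or a two-entry material map"
            )
        else:
            lesion_class = "normal"
    if lesion_class not in materials:
        raise ConfigurationError(f"material map does not cover lesion class {lesion_class!r}")

    out = []
    for sf in strain_series:
        lam1, lam2, lam3 = sf.stretches
        n_rows, n_cols = lam1.shape
        row_labels = _element_labels(profile, n_rows)
        classes = np.where(row_labels == "stenotic", lesion_class, "normal")
        s1 = np.empty_like(lam1)
        s2 = np.empty_like(lam1)
        for cls in np.unique(classes):
            rows = classes == cls
            a, b = mooney_rivlin_cauchy((lam1[rows], lam2[rows], lam3[rows]), materials[cls])
            s1[rows], s2[rows] = a, b
        out.append(
            StressField(
                principal_cauchy=(s1, s2),
                von_mises=von_mises(s1, s2),
                material_map=np.repeat(classes[:, None], n_cols, axis=1),
                frame_index=sf.frame_index,
                element_arclength=sf.element_arclength,
            )
        )
    return out


def pulse_stress(stress_es: StressField, stress_ed: StressField) -> PulseStressResult:
    """Pulse stress: per-element |σ_vm(end-systole) − σ_vm(end-diastole)|.

    The reported argmax position is the element-row arclength from the
    proximal (ostial) end in mm — the along-vessel location a fatigue or
    fracture candidate site would be quoted at.
    """
    if stress_es.von_mises.shape != stress_ed.von_mises.shape:
        raise InvalidGeometryError("pulse stress requires identical mesh topology")
    values = np.abs(stress_es.von_mises - stress_ed.von_mises)
    flat = int(np.argmax(values))
    ij = np.unravel_index(flat, values.shape)
    return PulseStressResult(
        values=values,
        argmax_element=(int(ij[0]), int(ij[1])),
        argmax_arclength_mm=float(stress_es.element_arclength[ij[0]]),
    )


def classify_peak_location(profile: StenosisProfile, element_row: int) -> str:
    """Assign an element row to proximal_shoulder / throat / distal_shoulder /
    normal using the stenosis geometry (throat = minimum-diameter ring ±1,
    shoulders = remaining stenotic rings on each side)."""
    n_rings = len(profile.percent_ds)
    row_ds = np.maximum(profile.percent_ds[:-1], profile.percent_ds[1:])
    if not (0 <= element_row < n_rings - 1):
        raise ConfigurationError(f"element row {element_row} out of range")
    if row_ds[element_row] <= profile.threshold or not profile.stenotic.any():
        return "normal"
    throat = profile.throat_index
    ring = element_row if profile.percent_ds[element_row] >= profile.percent_ds[element_row + 1] else element_row + 1
    if abs(ring - throat) <= 1:
        return "throat"
    return "proximal_shoulder" if ring < throat else "distal_shoulder"


def summarize_fields(
    strain_series: Sequence[StrainField],
    stress_series: Sequence[StressField],
    profile: StenosisProfile,
) -> FieldSummary:
    """Time-averaged per-segment strain/stress and the cycle-peak stress site.

    Averages run over the non-reference frames of the cycle; the peak is the
    single largest von Mises element over all frames, classified against the
    lesion geometry. With no stenotic rings all elements are 'normal' and the
    location classes collapse accordingly.
    """
    if len(strain_series) != len(stress_series) or not strain_series:
        raise ConfigurationError("strain and stress series must be non-empty and aligned")
    n_rows = strain_series[0].max_principal_strain.shape[0]
    row_labels = _element_labels(profile, n_rows)
    classes_present = ["normal", "stenotic"] if (row_labels == "stenotic").any() else ["normal"]

    strain_by, stress_by = {}, {}
    for cls in classes_present:
        rows = row_labels == cls
        strain_by[cls] = float(np.mean([sf.max_principal_strain[rows].mean() for sf in strain_series]))
        stress_by[cls] = float(np.mean([st.von_mises[rows].mean() for st in stress_series]))

    peak_val, peak_frame, peak_ij = -np.inf, -1, (0, 0)
    for st in stress_series:
        flat = int(np.argmax(st.von_mises))
        ij = np.unravel_index(flat, st.von_mises.shape)
        if st.von_mises[ij] > peak_val:
            peak_val = float(st.von_mises[ij])
            peak_frame = st.frame_index
            peak_ij = (int(ij[0]), int(ij[1]))
    st0 = stress_series[0]
    return FieldSummary(
        strain_by_class=strain_by,
        stress_by_class=stress_by,
        peak_von_mises_kpa=peak_val,
        peak_frame_index=peak_frame,
        peak_element=peak_ij,
        peak_arclength_mm=float(st0.element_arclength[peak_ij[0]]),
        peak_location_class=classify_peak_location(profile, peak_ij[0]),
    )
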