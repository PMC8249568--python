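"""Force-based comparator: Laplace hoop stress and a quasi-static
axisymmetric Mooney-Rivlin membrane solver.

This is the conventional direction of vascular mechanics — pressure is the
known condition and deformation/stress the unknowns — used here both to
validate the motion-based inverse pipeline (closed-loop: forward-simulate a
pressurized cycle, then recover the stress from the motion alone) and to
generate equilibrium-consistent synthetic sequences.

Each ring is an incompressible cylindrical membrane with reference radius r
(lumen) and thickness t (EEM − lumen). With circumferential stretch λθ, fixed
axial stretch λz (coronary arteries are tethered; default 1) and thickness
stretch 1/(λθ λz), quasi-static equilibrium of the pressurized ring is

    P · r_def = σθ(λθ, λz) · t_def,   r_def = λθ r,  t_def = t/(λθ λz),

with σθ the plane-stress Mooney-Rivlin hoop stress. The deformed state is
found by bracketed scalar root-finding on λθ per ring. In the thin-wall,
small-stretch limit this reduces to Laplace's law σθ = P r / t.

The reference configuration is the diastasis geometry and pressures are
transmural increments above diastasis, matching the inverse method's
convention that diastasis is the zero-strain state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import ConvergenceError, InvalidGeometryError, SequenceValidationError
from .geometry import Centerline, VesselFrame
from .materials import MaterialModel, default_materials, mooney_rivlin_cauchy
from .synthetic import CardiacSequence, DEFAULT_PHASE_WEIGHTS, InSilicoVessel, PHASE_ORDER

MMHG_TO_KPA = 0.13332

__all__ = [
    "PressureLoad",
    "EquilibriumSolution",
    "laplace_hoop_stress",
    "solve_membrane_equilibrium",
    "forward_pressurized_sequence",
]


@dataclass(frozen=True)
class PressureLoad:
    """Transmural pressure (kPa), optionally per cardiac phase."""

    pressure: float
    waveform: Optional[dict[str, float]] = None

    def __post_init__(self):
        if self.pressure < 0.0:
            raise InvalidGeometryError("transmural pressure must be >= 0")


@dataclass(frozen=True)
class EquilibriumSolution:
    """Per-ring equilibrium state of a pressurized vessel."""

    deformed_radius: np.ndarray  # mm
    hoop_stress: np.ndarray  # kPa
    circumferential_stretch: np.ndarray
    residual: np.ndarray  # |P r_def − σθ t_def| per ring, kPa·mm


def laplace_hoop_stress(P: float, r: float, t: float) -> float:
    """Thin-wall hoop stress σθ = P·r/t (kPa for P in kPa, r and t in mm)."""
    if t <= 0.0:
        raise InvalidGeometryError(f"wall thickness must be > 0, got {t}")
    return P * r / t


def _hoop(lam_theta, lam_z: float, mat: MaterialModel):
    lam3 = 1.0 / (np.asarray(lam_theta, float) * lam_z)
    lam1 = np.maximum(lam_theta, lam_z)
    lam2 = np.minimum(lam_theta, lam_z)
    s1, s2 = mooney_rivlin_cauchy((lam1, lam2, lam3), mat)
    return np.where(lam_theta >= lam_z, s1, s2)


def _ring_stretch(P: float, r: float, t: float, mat: MaterialModel, lam_z: float,
                  lam_max: float = 3.0) -> float:
    """Solve P λ² λz r/t = σθ(λ, λz) for λ ∈ [1, lam_max]."""
    if P == 0.0 and lam_z == 1.0:
        return 1.0

    def g(lam):
        return float(_hoop(lam, lam_z, mat)) - P * lam**2 * lam_z * r / t

    lo = 1.0 if lam_z == 1.0 else 1e-3
    if g(lo) >= 0.0 and P == 0.0:
        return 1.0
    if g(lam_max) < 0.0:
        raise ConvergenceError(
            f"no equilibrium below λθ = {lam_max} at P = {P:.3f} kPa "
            "(limit-point instability)"
        )
    return float(brentq(g, lo, lam_max, xtol=1e-14, rtol=8.9e-16))


def solve_membrane_equilibrium(
    vessel: InSilicoVessel,
    load: PressureLoad,
    materials: Optional[dict[str, MaterialModel]] = None,
    lesion_class: Optional[str] = None,
    axial_stretch: float = 1.0,
) -> EquilibriumSolution:
    """Per-ring pressurized equilibrium of the vessel membrane.

    Lesion-span rings carry the plaque composition's material, the rest the
    normal wall material. Raises :class:`ConvergenceError` naming the ring if
    a ring has no equilibrium in the bracket (limit-point instability).
    """
    materials = materials or default_materials()
    lesion_class = lesion_class or vessel.spec.composition
    r = vessel.lumen.ring_radius
    t = vessel.wall_thickness
    if np.any(t <= 0.0):
        raise InvalidGeometryError("wall thickness (EEM − lumen) must be > 0 everywhere")
    i0, i1 = vessel.lesion_span
    lam = np.empty_like(r)
    for i in range(len(r)):
        mat = materials[lesion_class if i0 <= i <= i1 else "normal"]
        try:
            lam[i] = _ring_stretch(load.pressure, r[i], t[i], mat, axial_stretch)
        except ConvergenceError as exc:
            raise ConvergenceError(f"ring {i}: {exc}") from exc
    hoop = _hoop(lam, axial_stretch, materials["normal"]).copy()
    # recompute hoop with each ring's own material
    for i in range(len(r)):
        mat = materials[lesion_class if i0 <= i <= i1 else "normal"]
        hoop[i] = float(_hoop(lam[i], axial_stretch, mat))
    r_def = lam * r
    t_def = t / (lam * axial_stretch)
    residual = np.abs(load.pressure * r_def - hoop * t_def)
    return EquilibriumSolution(
        deformed_radius=r_def,
        hoop_stress=hoop,
        circumferential_stretch=lam,
        residual=residual,
    )


def calibrate_pressure(
    vessel: InSilicoVessel,
    target_pulsation: float = 0.12,
    materials: Optional[dict[str, MaterialModel]] = None,
    axial_stretch: float = 1.0,
    p_max_kpa: float = 60.0,
) -> float:
    """Peak transmural pressure giving the requested normal-segment fractional
    diameter pulsation (proximal reference ring)."""
    materials = materials or default_materials()
    mat = materials["normal"]
    r, t = float(vessel.lumen.ring_radius[0]), float(vessel.wall_thickness[0])

    def f(P):
        return _ring_stretch(P, r, t, mat, axial_stretch) - (1.0 + target_pulsation)

    # expand the bracket upward, staying below the membrane limit point
    p_hi, p_last = 1.0, 0.0
    while p_hi <= p_max_kpa:
        try:
            if f(p_hi) > 0.0:
                break
        except ConvergenceError:
            if p_hi - p_last < 1e-9:
                raise ConvergenceError(
                    f"membrane limit point below the pressure needed for "
                    f"pulsation {target_pulsation}"
                ) from None
            p_hi = (p_last + p_hi) / 2.0
            continue
        p_last, p_hi = p_hi, 2.0 * p_hi
    else:
        raise ConvergenceError(
            f"no pressure below {p_max_kpa} kPa reaches pulsation {target_pulsation}"
        )
    return float(brentq(f, p_last, p_hi, xtol=1e-12))


def forward_pressurized_sequence(
    vessel: InSilicoVessel,
    waveform: Optional[dict[str, float]] = None,
    materials: Optional[dict[str, MaterialModel]] = None,
    target_pulsation: Optional[float] = None,
    phases: Optional[Sequence[str]] = None,
    axial_stretch: float = 1.0,
    mesh_C: int = 32,
) -> CardiacSequence:
    """Assemble per-phase equilibrium states into a cardiac sequence.

    ``waveform`` maps phase → transmural pressure (kPa) above diastasis and
    must contain a diastasis entry; alternatively ``target_pulsation`` scales
    the default phase-weight waveform so the normal-segment diameter pulsation
    hits the requested fraction at the peak phase. Ground truth carries the
    forward hoop stresses and stretches per phase.
    """
    materials = materials or default_materials()
    phases = list(PHASE_ORDER) if phases is None else list(phases)
    if waveform is None:
        if target_pulsation is None:
            raise SequenceValidationError("provide either a waveform or target_pulsation")
        p_peak = calibrate_pressure(vessel, target_pulsation, materials, axial_stretch)
        waveform = {p: DEFAULT_PHASE_WEIGHTS[p] * p_peak for p in phases}
    if "diastasis" not in waveform:
        raise SequenceValidationError("waveform must contain a diastasis entry")

    base = vessel.lumen
    frames = []
    hoop_all, lam_all, pressures = [], [], []
    for k, phase in enumerate(phases):
        sol = solve_membrane_equilibrium(
            vessel, PressureLoad(pressure=waveform[phase]), materials,
            axial_stretch=axial_stretch,
        )
        frames.append(
            VesselFrame(
                centerline=Centerline(points=base.centerline.points.copy()),
                ring_radius=sol.deformed_radius,
                phase=phase,
                time_index=k,
            )
        )
        hoop_all.append(sol.hoop_stress)
        lam_all.append(sol.circumferential_stretch)
        pressures.append(waveform[phase])

    ground_truth = {
        "hoop_stress": np.stack(hoop_all),  # (n_phases, L) kPa
        "lambda_theta": np.stack(lam_all),
        "pressure_kpa": np.asarray(pressures),
        "lesion_span": vessel.lesion_span,
        "axial_stretch": axial_stretch,
    }
    return CardiacSequence(
        frames=frames, ground_truth=ground_truth, mesh_L=len(base.centerline), mesh_C=mesh_C
    )
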