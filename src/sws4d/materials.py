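"""Incompressible Mooney-Rivlin membrane constitutive model.

The arterial wall is treated as nearly incompressible, homogeneous, isotropic
and hyperelastic with strain-energy density

    W = C1 (I1 - 3) + C2 (I2 - 3)

over the invariants of the (unimodular) left Cauchy-Green tensor; under exact
incompressibility (λ1 λ2 λ3 = 1, enforced here to machine precision) the
unimodular and full invariants coincide. The superficial wall is a membrane in
plane stress (σ3 = 0), which eliminates the pressure-like Lagrange multiplier
and yields the principal Cauchy stresses

    σk = 2 C1 (λk² − λ3²) − 2 C2 (λk⁻² − λ3⁻²),   k = 1, 2.

C1 and C2 are empirically determined; the shipped defaults are placeholders in
the physiological range for coronary tissue (normal wall C1 = 18.9 kPa,
C2 = 2.75 kPa, with fibrous/calcified/lipid-rich plaque at 2×/10×/0.5× the
normal constants). Results that matter in this package depend on these values
only through ratios and orderings, never through absolute magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

TISSUE_CLASSES = ("normal", "fibrous", "calcified", "lipid_rich")


@dataclass(frozen=True)
class MaterialModel:
    """Mooney-Rivlin constants (kPa) for one tissue class."""

    c1: float
    c2: float
    tissue_class: str = "normal"

    def __post_init__(self):
        if self.c1 <= 0.0:
            raise ConfigurationError(f"C1 must be > 0 (got {self.c1})")
        if self.c2 < 0.0:
            raise ConfigurationError(f"C2 must be >= 0 (got {self.c2})")
        if self.tissue_class not in TISSUE_CLASSES:
            raise ConfigurationError(
                f"unknown tissue class {self.tissue_class!r}; expected one of {TISSUE_CLASSES}"
            )


def default_materials() -> dict[str, MaterialModel]:
    """Shipped default material table (kPa). Override freely via RunConfig."""
    base_c1, base_c2 = 18.9, 2.75
    mult = {"normal": 1.0, "fibrous": 2.0, "calcified": 10.0, "lipid_rich": 0.5}
    return {
        k: MaterialModel(c1=base_c1 * m, c2=base_c2 * m, tissue_class=k)
        for k, m in mult.items()
    }


def strain_energy_density(lam1, lam2, material: MaterialModel):
    """W(λ1, λ2) per unit reference volume (kPa), with λ3 = 1/(λ1 λ2).

    Zero at the reference state and positive elsewhere for C1 > 0, C2 >= 0
    (both invariants are >= 3 with equality only at identity).
    """
    lam1 = np.asarray(lam1, dtype=float)
    lam2 = np.asarray(lam2, dtype=float)
    lam3 = 1.0 / (lam1 * lam2)
    i1 = lam1**2 + lam2**2 + lam3**2
    i2 = (lam1 * lam2) ** 2 + (lam1 * lam3) ** 2 + (lam2 * lam3) ** 2
    return material.c1 * (i1 - 3.0) + material.c2 * (i2 - 3.0)


def mooney_rivlin_cauchy(stretches, material: MaterialModel):
    """Plane-stress principal Cauchy stresses (σ1, σ2) in kPa.

    ``stretches`` is (λ1, λ2, λ3) with λ3 = 1/(λ1 λ2); arrays broadcast.
    """
    lam1, lam2, lam3 = (np.asarray(x, dtype=float) for x in stretches)
    c1, c2 = material.c1, material.c2
    s1 = 2.0 * c1 * (lam1**2 - lam3**2) - 2.0 * c2 * (lam1**-2 - lam3**-2)
    s2 = 2.0 * c1 * (lam2**2 - lam3**2) - 2.0 * c2 * (lam2**-2 - lam3**-2)
    return s1, s2


def von_mises(sigma1, sigma2):
    """Equivalent (von Mises) stress under plane stress: sqrt(σ1² − σ1σ2 + σ2²)."""
    s1 = np.asarray(sigma1, dtype=float)
    s2 = np.asarray(sigma2, dtype=float)
    return np.sqrt(s1**2 - s1 * s2 + s2**2)
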