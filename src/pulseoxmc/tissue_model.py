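"""Wavelength-resolved optical model of the transilluminated finger.

The finger is represented as a stack of plane-parallel slabs -- six skin
sublayers on each side (stratum corneum, epidermis, papillary dermis,
upper blood-net dermis, reticular dermis, deep blood-net dermis), a
subcutaneous fat layer on each side, and a central muscle slab with an
embedded bone cylinder.  Epidermal absorption is driven by the melanosome
volume fraction, dermal absorption by arterial/venous blood content and
its oxygen saturation, so the same geometry serves all skin phenotypes,
saturation levels and cardiac phases.

All lengths are millimetres; absorption and scattering coefficients are
mm^-1; volume fractions are dimensionless in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "WAVELENGTHS",
    "ChromophoreConstants",
    "SkinPhenotype",
    "PHENOTYPES",
    "HemodynamicState",
    "LayerSpec",
    "BoneCylinder",
    "TissueStack",
    "FingerGeometry",
    "epidermis_mu_a",
    "dermis_mu_a",
    "pulsatile_blood_volumes",
    "build_finger_model",
    "similarity_reduced",
    "make_homogeneous_phantom",
]

#: The two pulse-oximetry operating wavelengths (nm).
WAVELENGTHS = (660, 940)

DERMIS_SUBLAYERS = (
    "papillary_dermis",
    "upper_blood_net",
    "reticular_dermis",
    "deep_blood_net",
)


@dataclass(frozen=True)
class ChromophoreConstants:
    """Chromophore absorption constants entering the skin absorption model.

    The melanin term is the standard melanosome power law
    ``6.6e10 * lambda**-3.33`` (mm^-1, lambda in nm); the pigment-free
    baseline is ``7.84e7 * lambda**-3.255``.  Hemoglobin values are
    whole-blood absorption coefficients at a hematocrit of 45%.
    """

    melanin_prefactor: float = 6.6e10
    melanin_exponent: float = -3.33
    baseline_prefactor: float = 7.84e7
    baseline_exponent: float = -3.255
    mu_a_water: Mapping[int, float] = field(
        default_factory=lambda: {660: 4.15e-4, 940: 2.67e-2}
    )
    mu_a_hbo2: Mapping[int, float] = field(
        default_factory=lambda: {660: 0.15, 940: 0.65}
    )
    mu_a_hhb: Mapping[int, float] = field(
        default_factory=lambda: {660: 1.64, 940: 0.43}
    )
    hematocrit: float = 0.45

    def __post_init__(self) -> None:
        if self.melanin_prefactor <= 0 or self.baseline_prefactor <= 0:
            raise ValueError("power-law prefactors must be positive")
        for name in ("mu_a_water", "mu_a_hbo2", "mu_a_hhb"):
            table = getattr(self, name)
            if any(v < 0 for v in table.values()):
                raise ValueError(f"{name} contains negative absorption")
        if not 0 < self.hematocrit < 1:
            raise ValueError("hematocrit must be a fraction in (0, 1)")

    def melanin_mu_a(self, wavelength: float) -> float:
        """Absorption coefficient of a pure melanosome interior (mm^-1)."""
        return self.melanin_prefactor * wavelength**self.melanin_exponent

    def baseline_mu_a(self, wavelength: float) -> float:
        """Absorption of pigment-, blood- and water-free tissue (mm^-1)."""
        return self.baseline_prefactor * wavelength**self.baseline_exponent

    def blood_mu_a(self, saturation: float, wavelength: int) -> float:
        """Whole-blood absorption at the given oxygen saturation fraction."""
        return saturation * self.mu_a_hbo2[wavelength] + (
            1.0 - saturation
        ) * self.mu_a_hhb[wavelength]


@dataclass(frozen=True)
class SkinPhenotype:
    """Skin colour group, characterised by melanosome volume fraction."""

    label: str
    vmel: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.vmel <= 1.0:
            raise ValueError("melanosome volume fraction must be in [0, 1]")


#: Fitzpatrick-scale phenotypes: type I (light), type IV (moderate), type VI
#: (dark), mapped to epidermal melanosome volume fractions.
PHENOTYPES: dict[str, SkinPhenotype] = {
    "light": SkinPhenotype("light", 0.0255),
    "moderate": SkinPhenotype("moderate", 0.155),
    "dark": SkinPhenotype("dark", 0.305),
}

VENOUS_SATURATION_OFFSET = 0.10


@dataclass(frozen=True)
class HemodynamicState:
    """Arterial/venous oxygenation and cardiac phase.

    Venous saturation defaults to the arterial value minus 10 percentage
    points, the conventional arteriovenous gap.
    """

    sat_a: float
    phase: str = "diastole"
    sat_v: float | None = None

    def __post_init__(self) -> None:
        if not 0.70 <= self.sat_a <= 1.00:
            raise ValueError("arterial saturation must lie in [0.70, 1.00]")
        if self.phase not in ("diastole", "systole"):
            raise ValueError(f"unknown cardiac phase {self.phase!r}")
        if self.sat_v is None:
            object.__setattr__(
                self, "sat_v", self.sat_a - VENOUS_SATURATION_OFFSET
            )
        if self.sat_v < 0:
            raise ValueError("venous saturation must be non-negative")


@dataclass(frozen=True)
class LayerSpec:
    """One plane-parallel slab with per-wavelength optical coefficients."""

    name: str
    thickness: float
    mu_a: Mapping[int, float]
    mu_s: Mapping[int, float]
    g: Mapping[int, float]
    vb_diastolic: float = 0.0
    vw: float = 0.0
    refractive_index: float = 1.4

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise ValueError(f"layer {self.name!r}: thickness must be > 0")
        if not 0 <= self.vb_diastolic <= 1 or not 0 <= self.vw <= 1:
            raise ValueError(f"layer {self.name!r}: fractions must be in [0, 1]")
        for lam, v in self.mu_a.items():
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"layer {self.name!r}: bad mu_a at {lam} nm")
        for lam, v in self.mu_s.items():
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"layer {self.name!r}: bad mu_s at {lam} nm")
        if any(abs(v) > 1 for v in self.g.values()):
            raise ValueError(f"layer {self.name!r}: |g| must be <= 1")


@dataclass(frozen=True)
class BoneCylinder:
    """Infinite circular cylinder embedded in the muscle slab.

    The axis runs parallel to the tissue surfaces (perpendicular to the
    source-detector axis), so in the (y, z) plane the bone is the disc
    ``y**2 + (z - center_z)**2 <= radius**2``.
    """

    radius: float
    center_z: float
    mu_a: Mapping[int, float]
    mu_s: Mapping[int, float]
    g: Mapping[int, float]

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("bone radius must be positive")


@dataclass(frozen=True)
class TissueStack:
    """Ordered slab stack traversed by photons along +z from z = 0.

    ``lateral_half_width`` bounds the tissue in y (photons crossing
    |y| = half-width escape through the flank); infinite for idealized
    slab phantoms.  The x direction stays unbounded, matching the
    translation symmetry of the bone cylinder axis.
    """

    layers: tuple[LayerSpec, ...]
    bone: BoneCylinder | None = None
    ambient_index: float = 1.0
    lateral_half_width: float = math.inf

    @property
    def total_thickness(self) -> float:
        return sum(layer.thickness for layer in self.layers)

    @property
    def tissue_index(self) -> float:
        return self.layers[0].refractive_index

    def boundaries(self) -> list[float]:
        """z coordinates of the layer interfaces, starting at 0."""
        edges = [0.0]
        for layer in self.layers:
            edges.append(edges[-1] + layer.thickness)
        return edges

    def layer_span(self, name: str) -> tuple[float, float]:
        z = 0.0
        for layer in self.layers:
            if layer.name == name:
                return z, z + layer.thickness
            z += layer.thickness
        raise KeyError(name)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        if self.bone is not None:
            z0, z1 = self.layer_span("muscle")
            if (
                self.bone.center_z - self.bone.radius < z0
                or self.bone.center_z + self.bone.radius > z1
            ):
                raise ValueError("bone cylinder must lie inside the muscle slab")


@dataclass(frozen=True)
class FingerGeometry:
    """Layer thicknesses and fixed per-layer optical constants.

    Thicknesses follow published layered finger/skin models; the muscle
    thickness is derived so the slabs sum exactly to ``total_thickness``,
    the only printed geometric constraint.  Dermal (and epidermal)
    scattering defaults are taken from the same skin-optics sources as the
    stratum-corneum anisotropy row.
    """

    total_thickness: float = 13.0
    stratum_corneum: float = 0.02
    epidermis: float = 0.08
    papillary_dermis: float = 0.18
    upper_blood_net: float = 0.08
    reticular_dermis: float = 1.5
    deep_blood_net: float = 0.1
    fat: float = 0.8
    bone_radius: float = 2.0
    half_width: float = 6.5
    refractive_index: float = 1.4
    ambient_index: float = 1.0
    dermal_mu_s: Mapping[int, float] = field(
        default_factory=lambda: {660: 18.7, 940: 12.0}
    )
    dermal_g: Mapping[int, float] = field(
        default_factory=lambda: {660: 0.91, 940: 0.94}
    )

    @property
    def skin_thickness(self) -> float:
        return (
            self.stratum_corneum
            + self.epidermis
            + self.papillary_dermis
            + self.upper_blood_net
            + self.reticular_dermis
            + self.deep_blood_net
        )

    @property
    def muscle_thickness(self) -> float:
        t = self.total_thickness - 2.0 * (self.skin_thickness + self.fat)
        if t <= 0:
            raise ValueError("skin and fat layers exceed the total thickness")
        return t


# Fixed per-layer constants: mu_a / mu_s (mm^-1) and anisotropy per wavelength.
_STRATUM_CORNEUM = {
    "mu_a": {660: 0.0495, 940: 0.0170},
    "mu_s": {660: 25.62, 940: 5.68},
    "g": {660: 0.91, 940: 0.94},
}
_FAT = {
    "mu_a": {660: 0.0104, 940: 0.0170},
    "mu_s": {660: 6.20, 940: 5.42},
    "g": {660: 0.90, 940: 0.90},
}
_MUSCLE = {
    "mu_a": {660: 0.0816, 940: 0.0401},
    "mu_s": {660: 8.61, 940: 5.81},
    "g": {660: 0.88, 940: 0.91},
}
_BONE = {
    "mu_a": {660: 0.0351, 940: 0.0457},
    "mu_s": {660: 34.45, 940: 24.70},
    "g": {660: 0.92, 940: 0.93},
}

# Diastolic blood and water volume fractions per skin sublayer.
_SKIN_FRACTIONS = {
    "stratum_corneum": (0.00, 0.05),
    "epidermis": (0.00, 0.20),
    "papillary_dermis": (0.04, 0.50),
    "upper_blood_net": (0.30, 0.60),
    "reticular_dermis": (0.04, 0.60),
    "deep_blood_net": (0.10, 0.70),
}


def epidermis_mu_a(
    vmel: float,
    vw: float,
    wavelength: float,
    constants: ChromophoreConstants | None = None,
) -> float:
    """Epidermal absorption coefficient (mm^-1).

    Sum of the melanosome power-law term, water absorption, and the
    pigment-free baseline weighted by the residual volume fraction:

        mu_a = vmel * 6.6e10 * lambda**-3.33
             + mu_a_water(lambda) * vw
             + (1 - vmel - vw) * 7.84e7 * lambda**-3.255
    """
    constants = constants or ChromophoreConstants()
    if vmel < 0 or vw < 0 or vmel + vw > 1:
        raise ValueError("volume fractions must be non-negative with sum <= 1")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    mu_w = constants.mu_a_water[wavelength]
    return (
        vmel * constants.melanin_mu_a(wavelength)
        + mu_w * vw
        + (1.0 - vmel - vw) * constants.baseline_mu_a(wavelength)
    )


def dermis_mu_a(
    state: HemodynamicState,
    v_arterial: float,
    v_venous: float,
    vw: float,
    wavelength: int,
    constants: ChromophoreConstants | None = None,
) -> float:
    """Dermal sublayer absorption coefficient (mm^-1).

    Four contributions: arterial blood at saturation ``sat_a``, venous
    blood at ``sat_v``, water, and the pigment-free baseline weighted by
    the residual volume fraction.  In the systolic upper blood-net layer
    the doubled blood volume plus water can nominally exceed unit volume;
    the baseline residual is clamped at zero in that case rather than
    contributing negative absorption.
    """
    constants = constants or ChromophoreConstants()
    if min(v_arterial, v_venous, vw) < 0:
        raise ValueError("volume fractions must be non-negative")
    if v_arterial + v_venous > 1 or vw > 1:
        raise ValueError("blood and water volume fractions must not exceed 1")
    residual = max(0.0, 1.0 - (v_arterial + v_venous + vw))
    return (
        v_arterial * constants.blood_mu_a(state.sat_a, wavelength)
        + v_venous * constants.blood_mu_a(state.sat_v, wavelength)
        + constants.mu_a_water[wavelength] * vw
        + residual * constants.baseline_mu_a(wavelength)
    )


def pulsatile_blood_volumes(
    vb_diastolic: float, phase: str
) -> tuple[float, float]:
    """Arterial and venous blood volume fractions for a cardiac phase.

    Systole doubles the diastolic blood volume; in both phases the total
    is split equally between the arterial and venous compartments.
    """
    if not 0 <= vb_diastolic <= 0.5:
        raise ValueError("diastolic blood volume must be in [0, 0.5]")
    if phase == "diastole":
        total = vb_diastolic
    elif phase == "systole":
        total = 2.0 * vb_diastolic
    else:
        raise ValueError(f"unknown cardiac phase {phase!r}")
    if total > 1:
        raise ValueError("systolic blood volume exceeds unit fraction")
    return total / 2.0, total / 2.0


def _skin_sublayers(
    phenotype: SkinPhenotype,
    state: HemodynamicState,
    geometry: FingerGeometry,
    constants: ChromophoreConstants,
) -> list[LayerSpec]:
    """The six skin sublayers, outermost (stratum corneum) first."""
    layers = []
    for name in ("stratum_corneum", "epidermis") + DERMIS_SUBLAYERS:
        vb, vw = _SKIN_FRACTIONS[name]
        thickness = getattr(geometry, name)
        if name == "stratum_corneum":
            mu_a = dict(_STRATUM_CORNEUM["mu_a"])
            mu_s = dict(_STRATUM_CORNEUM["mu_s"])
            g = dict(_STRATUM_CORNEUM["g"])
        elif name == "epidermis":
            mu_a = {
                lam: epidermis_mu_a(phenotype.vmel, vw, lam, constants)
                for lam in WAVELENGTHS
            }
            mu_s = dict(geometry.dermal_mu_s)
            g = dict(geometry.dermal_g)
        else:
            v_a, v_v = pulsatile_blood_volumes(vb, state.phase)
            mu_a = {
                lam: dermis_mu_a(state, v_a, v_v, vw, lam, constants)
                for lam in WAVELENGTHS
            }
            mu_s = dict(geometry.dermal_mu_s)
            g = dict(geometry.dermal_g)
        layers.append(
            LayerSpec(
                name=name,
                thickness=thickness,
                mu_a=mu_a,
                mu_s=mu_s,
                g=g,
                vb_diastolic=vb,
                vw=vw,
                refractive_index=geometry.refractive_index,
            )
        )
    return layers


def build_finger_model(
    phenotype: SkinPhenotype | str,
    state: HemodynamicState,
    geometry: FingerGeometry | None = None,
    constants: ChromophoreConstants | None = None,
) -> TissueStack:
    """Assemble the full finger stack for one phenotype/state condition.

    Layer order along +z: six skin sublayers, fat, muscle (with the bone
    cylinder centred in it), fat, then the six skin sublayers mirrored so
    the stratum corneum faces outward on the detector side.  Both skin
    stacks carry identical pigmentation.
    """
    if isinstance(phenotype, str):
        phenotype = PHENOTYPES[phenotype]
    geometry = geometry or FingerGeometry()
    constants = constants or ChromophoreConstants()

    skin = _skin_sublayers(phenotype, state, geometry, constants)
    fat = LayerSpec(
        name="fat",
        thickness=geometry.fat,
        mu_a=dict(_FAT["mu_a"]),
        mu_s=dict(_FAT["mu_s"]),
        g=dict(_FAT["g"]),
        refractive_index=geometry.refractive_index,
    )
    muscle = LayerSpec(
        name="muscle",
        thickness=geometry.muscle_thickness,
        mu_a=dict(_MUSCLE["mu_a"]),
        mu_s=dict(_MUSCLE["mu_s"]),
        g=dict(_MUSCLE["g"]),
        refractive_index=geometry.refractive_index,
    )
    mirrored = [replace(layer, name=layer.name + "_distal") for layer in reversed(skin)]
    layers = tuple(skin + [fat, muscle, replace(fat, name="fat_distal")] + mirrored)

    muscle_z0 = geometry.skin_thickness + geometry.fat
    bone = BoneCylinder(
        radius=geometry.bone_radius,
        center_z=muscle_z0 + geometry.muscle_thickness / 2.0,
        mu_a=dict(_BONE["mu_a"]),
        mu_s=dict(_BONE["mu_s"]),
        g=dict(_BONE["g"]),
    )
    stack = TissueStack(
        layers=layers,
        bone=bone,
        ambient_index=geometry.ambient_index,
        lateral_half_width=geometry.half_width,
    )
    if abs(stack.total_thickness - geometry.total_thickness) > 1e-9:
        raise ValueError("layer thicknesses do not sum to the finger thickness")
    return stack


def similarity_reduced(stack: TissueStack) -> TissueStack:
    """Similarity-transformed stack: ``(mu_s, g) -> (mu_s * (1 - g), 0)``.

    The first-order similarity relation of radiative transport preserves
    the reduced scattering coefficient ``mu_s' = mu_s * (1 - g)``, and
    with it the diffuse transmittance of optically thick media, while the
    number of scattering events per photon packet drops by roughly
    ``1 / (1 - g)``.  Used by the scaled-down simulation preset; the
    full-fidelity preset keeps the anisotropic phase function.
    """

    def reduce_maps(mu_s, g):
        new_mu_s = {lam: mu_s[lam] * (1.0 - g[lam]) for lam in mu_s}
        new_g = {lam: 0.0 for lam in g}
        return new_mu_s, new_g

    layers = []
    for layer in stack.layers:
        mu_s, g = reduce_maps(layer.mu_s, layer.g)
        layers.append(replace(layer, mu_s=mu_s, g=g))
    bone = None
    if stack.bone is not None:
        mu_s, g = reduce_maps(stack.bone.mu_s, stack.bone.g)
        bone = replace(stack.bone, mu_s=mu_s, g=g)
    return TissueStack(
        layers=tuple(layers),
        bone=bone,
        ambient_index=stack.ambient_index,
        lateral_half_width=stack.lateral_half_width,
    )


def make_homogeneous_phantom(
    mu_a: float,
    mu_s: float,
    g: float,
    thickness: float,
    index: float = 1.4,
    wavelengths: tuple[int, ...] = WAVELENGTHS,
) -> TissueStack:
    """Single uniform slab, used for analytic engine validation.

    With ``mu_s = 0`` and matched refractive indices the transmittance has
    the closed Beer-Lambert form ``exp(-mu_a * thickness)``.
    """
    if min(mu_a, mu_s) < 0:
        raise ValueError("optical coefficients must be non-negative")
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    layer = LayerSpec(
        name="phantom",
        thickness=thickness,
        mu_a={lam: mu_a for lam in wavelengths},
        mu_s={lam: mu_s for lam in wavelengths},
        g={lam: g for lam in wavelengths},
        refractive_index=index,
    )
    return TissueStack(layers=(layer,), bone=None, ambient_index=1.0)
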