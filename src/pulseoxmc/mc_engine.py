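"""Weighted Monte Carlo photon transport through a :class:`TissueStack`.

Photon packets are launched from a Gaussian beam on the proximal face,
random-walk through the slab stack (hop-drop-spin with partial absorption
per interaction), undergo unpolarized Fresnel reflection at the two outer
tissue-ambient surfaces, and are terminated unbiasedly by Russian
roulette.  Packets exiting the distal face inside the detector aperture
are tallied as detected; the transmittance is the detected weight per
unit launched weight.

The per-packet loop lives in :mod:`pulseoxmc._kernel`; this module owns
the run protocol (seeded batches until the target detected count is
reached) and the small, individually testable transport primitives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernel
from .tissue_model import TissueStack

__all__ = [
    "SourceSpec",
    "DetectorSpec",
    "RunConfig",
    "Photon",
    "Tally",
    "BudgetExhaustedError",
    "specular_reflectance",
    "fresnel_reflectance",
    "launch_photon",
    "sample_free_path",
    "deposit_weight",
    "sample_hg_deflection",
    "update_direction",
    "roulette",
    "detect",
    "run_simulation",
    "run_condition_family",
    "transmittance",
]


@dataclass(frozen=True)
class SourceSpec:
    """Gaussian beam entering the proximal face along +z.

    ``beam_radius`` is the 1/e^2 intensity radius, so the Gaussian sigma
    of each transverse coordinate is half of it.
    """

    beam_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.beam_radius <= 0:
            raise ValueError("beam radius must be positive")

    @property
    def sigma(self) -> float:
        return self.beam_radius / 2.0


@dataclass(frozen=True)
class DetectorSpec:
    """Circular detector on the distal face, coaxial with the source."""

    radius: float = 1.0
    acceptance_half_angle: float = 90.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("detector radius must be positive")
        if not 0 < self.acceptance_half_angle <= 90:
            raise ValueError("acceptance half-angle must be in (0, 90] degrees")

    @property
    def cos_min(self) -> float:
        if self.acceptance_half_angle >= 90.0:
            return 0.0
        return math.cos(math.radians(self.acceptance_half_angle))


@dataclass(frozen=True)
class RunConfig:
    """Photon budget, roulette parameters and RNG seeding for one run.

    ``n_split_planes`` enables geometric splitting at that many equally
    spaced interior planes (0 disables it): packets crossing a plane
    toward the detector split in two, packets crossing back are rouletted
    at survival 1/2.  Expectation-preserving; used to keep the detected-
    count efficiency workable for the thick absorbing finger stack.
    """

    target_detected: int = 1_000_000
    max_launched: int = 4_000_000_000
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1
    seed: int = 0
    batch_size: int = 100_000
    n_split_planes: int = 0

    def __post_init__(self) -> None:
        if self.target_detected < 1:
            raise ValueError("target_detected must be >= 1")
        if not 0 < self.roulette_survival <= 1:
            raise ValueError("roulette survival must be in (0, 1]")
        if self.batch_size < 1 or self.max_launched < 1:
            raise ValueError("batch_size and max_launched must be >= 1")
        if self.n_split_planes < 0:
            raise ValueError("n_split_planes must be >= 0")


@dataclass
class Photon:
    """Transport state of one photon packet."""

    position: np.ndarray
    direction: np.ndarray
    weight: float
    layer_ref: int = 0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must be in [0, 1]")


@dataclass(frozen=True)
class Tally:
    """Weight bookkeeping for a completed (or partial) run.

    The conservation contract is
    ``specular + absorbed + detected + escaped + residual == launched``
    to 1e-9 relative: every unit of launched weight is accounted for.
    """

    launched: int = 0
    specular_weight: float = 0.0
    absorbed_weight: float = 0.0
    detected_weight: float = 0.0
    detected_count: int = 0
    escaped_weight: float = 0.0
    residual_weight: float = 0.0
    seed: int | None = None
    n_batches: int = 0

    def __add__(self, other: "Tally") -> "Tally":
        return Tally(
            launched=self.launched + other.launched,
            specular_weight=self.specular_weight + other.specular_weight,
            absorbed_weight=self.absorbed_weight + other.absorbed_weight,
            detected_weight=self.detected_weight + other.detected_weight,
            detected_count=self.detected_count + other.detected_count,
            escaped_weight=self.escaped_weight + other.escaped_weight,
            residual_weight=self.residual_weight + other.residual_weight,
            seed=self.seed if self.seed is not None else other.seed,
            n_batches=self.n_batches + other.n_batches,
        )

    @property
    def total_weight(self) -> float:
        return (
            self.specular_weight
            + self.absorbed_weight
            + self.detected_weight
            + self.escaped_weight
            + self.residual_weight
        )

    def conservation_defect(self) -> float:
        """Relative imbalance between accounted and launched weight."""
        if self.launched == 0:
            return 0.0
        return abs(self.total_weight - self.launched) / self.launched


class BudgetExhaustedError(RuntimeError):
    """Raised when max_launched is hit before the detected-count target."""

    def __init__(self, tally: Tally, target: int):
        self.tally = tally
        self.target = target
        super().__init__(
            f"launched {tally.launched} photons but detected only "
            f"{tally.detected_count} of the targeted {target}"
        )


def specular_reflectance(n_ambient: float, n_tissue: float) -> float:
    """Normal-incidence Fresnel reflectance at the entry surface."""
    if n_ambient < 1 or n_tissue < 1:
        raise ValueError("refractive indices must be >= 1")
    return ((n_ambient - n_tissue) / (n_ambient + n_tissue)) ** 2


def fresnel_reflectance(n_in: float, n_out: float, cos_incidence: float) -> float:
    """Unpolarized Fresnel reflectance; 1 beyond the critical angle."""
    r, _ = _kernel.fresnel_unpolarized(n_in, n_out, cos_incidence)
    return r


def launch_photon(
    source: SourceSpec,
    rng: np.random.Generator,
    n_ambient: float = 1.0,
    n_tissue: float = 1.4,
) -> Photon:
    """Draw one photon from the Gaussian source on the z = 0 face.

    The packet starts normal to the surface with weight reduced by the
    normal-incidence specular reflection.
    """
    sigma = source.sigma
    x, y = rng.normal(0.0, sigma, size=2)
    weight = 1.0 - specular_reflectance(n_ambient, n_tissue)
    return Photon(
        position=np.array([x, y, 0.0]),
        direction=np.array([0.0, 0.0, 1.0]),
        weight=weight,
    )


def sample_free_path(mu_t: float, rng: np.random.Generator, size=None):
    """Exponential free-flight length(s) ``-ln(xi)/mu_t`` in mm."""
    if mu_t <= 0:
        raise ValueError("mu_t must be positive to sample a free path")
    xi = rng.random(size)
    return -np.log1p(-xi) / mu_t


def deposit_weight(photon: Photon, mu_a: float, mu_s: float):
    """Albedo-weighted absorption drop at an interaction site."""
    mu_t = mu_a + mu_s
    if mu_t <= 0:
        raise ValueError("mu_a + mu_s must be positive")
    absorbed = photon.weight * mu_a / mu_t
    survivor = Photon(
        position=photon.position.copy(),
        direction=photon.direction.copy(),
        weight=photon.weight - absorbed,
        layer_ref=photon.layer_ref,
    )
    return survivor, absorbed


def sample_hg_deflection(g: float, rng: np.random.Generator, size=None):
    """Henyey-Greenstein deflection cosine(s) with anisotropy g."""
    if abs(g) > 1:
        raise ValueError("|g| must be <= 1")
    xi = rng.random(size)
    if size is None:
        return _kernel.hg_cos_from_uniform(g, float(xi))
    if abs(g) < 1e-6:
        return 2.0 * xi - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    return np.clip((1.0 + g * g - tmp**2) / (2.0 * g), -1.0, 1.0)


def update_direction(direction: np.ndarray, cos_theta: float, phi: float) -> np.ndarray:
    """Rotate a unit direction by the sampled deflection and azimuth."""
    ux, uy, uz = (float(v) for v in direction)
    return np.array(_kernel.rotate_direction(ux, uy, uz, cos_theta, phi))


def roulette(
    photon: Photon,
    threshold: float,
    survival: float,
    rng: np.random.Generator,
) -> Photon | None:
    """Unbiased termination of low-weight packets.

    Below the threshold the packet survives with probability ``survival``
    and its weight is boosted by ``1/survival``, preserving the expected
    weight; otherwise it is terminated (``None``).
    """
    if not 0 < survival <= 1:
        raise ValueError("survival probability must be in (0, 1]")
    if photon.weight >= threshold:
        return photon
    if rng.random() < survival:
        return Photon(
            position=photon.position.copy(),
            direction=photon.direction.copy(),
            weight=photon.weight / survival,
            layer_ref=photon.layer_ref,
        )
    return None


def detect(
    exit_x: float, exit_y: float, cos_exit: float, detector: DetectorSpec
) -> bool:
    """Whether a distal-face exit lands in the detector aperture."""
    if exit_x * exit_x + exit_y * exit_y > detector.radius**2:
        return False
    return cos_exit >= detector.cos_min


def _stack_arrays(stack: TissueStack, wavelength: int):
    edges = np.array(stack.boundaries(), dtype=np.float64)
    mu_a = np.array([lay.mu_a[wavelength] for lay in stack.layers])
    mu_s = np.array([lay.mu_s[wavelength] for lay in stack.layers])
    g = np.array([lay.g[wavelength] for lay in stack.layers])
    if stack.bone is not None:
        bone_layer = next(
            i for i, lay in enumerate(stack.layers) if lay.name == "muscle"
        )
        bone = stack.bone
        bone_params = (
            bone_layer,
            bone.center_z,
            bone.radius,
            bone.mu_a[wavelength],
            bone.mu_s[wavelength],
            bone.g[wavelength],
        )
    else:
        bone_params = (-1, 0.0, 0.0, 0.0, 0.0, 0.0)
    return edges, mu_a, mu_s, g, bone_params


def _batch_seed(seed: int, batch_index: int) -> int:
    """Independent per-batch substream seed from the run seed."""
    return int(np.random.SeedSequence([seed, batch_index]).generate_state(1)[0])


def run_simulation(
    stack: TissueStack,
    source: SourceSpec,
    detector: DetectorSpec,
    config: RunConfig,
    wavelength: int = 660,
) -> Tally:
    """Launch seeded batches until the detected-count target is reached.

    Each batch owns an independent RNG substream derived from
    ``(config.seed, batch_index)``, so the merged tally is reproducible
    bit-exactly for a fixed seed and batch size, independent of how
    batches would be scheduled across workers.

    Raises :class:`BudgetExhaustedError` (carrying the partial tally) if
    ``max_launched`` is exhausted first.
    """
    tally, _ = _run_batches(
        stack,
        source,
        detector,
        config,
        wavelength,
        reweight_class=np.full(len(stack.layers), -1, dtype=np.int64),
        delta_mu_a=np.zeros((1, 1)),
    )
    return tally


def _run_batches(
    stack: TissueStack,
    source: SourceSpec,
    detector: DetectorSpec,
    config: RunConfig,
    wavelength: int,
    reweight_class: np.ndarray,
    delta_mu_a: np.ndarray,
) -> tuple[Tally, np.ndarray]:
    edges, mu_a, mu_s, g, bone_params = _stack_arrays(stack, wavelength)
    thickness = edges[-1]
    n_sp = config.n_split_planes
    split_z = thickness * np.arange(1, n_sp + 1) / (n_sp + 1)
    total = Tally(seed=config.seed)
    detected_cond = np.zeros(delta_mu_a.shape[0])
    batch_index = 0
    while total.detected_count < config.target_detected:
        if total.launched >= config.max_launched:
            raise BudgetExhaustedError(total, config.target_detected)
        n = min(config.batch_size, config.max_launched - total.launched)
        raw, cond = _kernel.transport_batch(
            n,
            _batch_seed(config.seed, batch_index),
            edges,
            mu_a,
            mu_s,
            g,
            *bone_params,
            stack.ambient_index,
            stack.tissue_index,
            source.sigma,
            detector.radius,
            detector.cos_min,
            config.roulette_threshold,
            config.roulette_survival,
            split_z,
            reweight_class,
            delta_mu_a,
            stack.lateral_half_width,
        )
        total = total + Tally(
            launched=n,
            specular_weight=raw[0],
            absorbed_weight=raw[1],
            detected_weight=raw[2],
            detected_count=int(raw[3]),
            escaped_weight=raw[4],
            residual_weight=raw[5],
            n_batches=1,
        )
        detected_cond += cond
        batch_index += 1
    return total, detected_cond


def run_condition_family(
    stacks: "list[TissueStack]",
    perturbed_layers: "tuple[str, ...]",
    source: SourceSpec,
    detector: DetectorSpec,
    config: RunConfig,
    wavelength: int = 660,
) -> tuple[Tally, np.ndarray]:
    """Correlated transport of stacks differing only in some layer mu_a.

    The family members (e.g. the 14 saturation-by-cardiac-phase variants
    of one skin phenotype) must share geometry, scattering and anisotropy
    and may differ only in the absorption of the layers named in
    ``perturbed_layers`` (a mirrored ``<name>_distal`` twin shares its
    class).  One reference stack with the family-mean absorption is
    transported; per-packet pathlengths in each perturbed class are
    recorded and every detection is reweighted by ``exp(-delta_mu_a . L)``
    per member.  All members therefore share identical photon paths,
    which suppresses the Monte Carlo noise in *differences* between
    members — the pulsatile AC/DC signal above all.

    Returns ``(reference_tally, detected_weights)`` with one detected
    weight per family member; member transmittance is that weight over
    ``reference_tally.launched``.
    """
    from dataclasses import replace as _replace

    if not stacks:
        raise ValueError("empty condition family")
    base = stacks[0]
    n_layers = len(base.layers)
    classes = {name: k for k, name in enumerate(perturbed_layers)}
    reweight_class = np.full(n_layers, -1, dtype=np.int64)
    for i, layer in enumerate(base.layers):
        stem = layer.name.removesuffix("_distal")
        if stem in classes:
            reweight_class[i] = classes[stem]

    for other in stacks[1:]:
        if len(other.layers) != n_layers:
            raise ValueError("family stacks must share the layer structure")
        for i, (a, b) in enumerate(zip(base.layers, other.layers)):
            if a.name != b.name or a.thickness != b.thickness:
                raise ValueError("family stacks must share geometry")
            if a.mu_s != b.mu_s or a.g != b.g:
                raise ValueError("family stacks must share scattering")
            if reweight_class[i] < 0 and a.mu_a != b.mu_a:
                raise ValueError(
                    f"layer {a.name!r} differs in mu_a but is not a "
                    "perturbed class"
                )

    # Reference stack: the family minimum absorption in each perturbed
    # class, so every member reweight exp(-delta . L) is <= 1.  Larger
    # reference absorption would require up-weighting long paths that the
    # reference undersamples — a heavy-tailed estimator; downweighting
    # only is safe.
    n_cond = len(stacks)
    mu_by_stack = np.array(
        [[s.layers[i].mu_a[wavelength] for i in range(n_layers)] for s in stacks]
    )
    mu_ref = mu_by_stack.min(axis=0)
    ref_layers = []
    for i, layer in enumerate(base.layers):
        if reweight_class[i] >= 0:
            new_mu = dict(layer.mu_a)
            new_mu[wavelength] = mu_ref[i]
            ref_layers.append(_replace(layer, mu_a=new_mu))
        else:
            ref_layers.append(layer)
    reference = _replace(base, layers=tuple(ref_layers))

    n_class = len(perturbed_layers)
    delta = np.zeros((n_cond, n_class))
    for c in range(n_cond):
        for i in range(n_layers):
            k = reweight_class[i]
            if k >= 0:
                # mirrored twins share the class; their deltas agree
                delta[c, k] = mu_by_stack[c, i] - mu_ref[i]

    return _run_batches(
        reference, source, detector, config, wavelength, reweight_class, delta
    )


def transmittance(tally: Tally) -> float:
    """Detected weight per unit launched weight (incident weight 1/photon)."""
    if tally.launched <= 0:
        raise ValueError("tally has no launched photons")
    return tally.detected_weight / tally.launched
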