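"""Compiled photon-transport primitives.

The hop-drop-spin random walk is implemented as one numba kernel so that
per-condition budgets of 1e4-1e6 detected photon packets stay tractable on
a single CPU.  The small pure functions (Henyey-Greenstein inverse CDF,
unpolarized Fresnel, direction rotation, ray-circle intersection) are
exported separately so they can be unit-tested against closed forms and
reused by the Python-level API.

Conventions: z runs along the source-detector axis with z = 0 at the
illuminated surface; all lengths in mm; internal layer interfaces are
index-matched, Fresnel reflection happens only at the two outer
tissue-ambient surfaces.

Detector estimator.  The geometry (slabs plus a bone cylinder whose axis
runs along x) is invariant under translations in x, so a packet's lateral
displacement is independent of where on the x axis it was launched.  The
kernel therefore launches every packet at x = 0 and, at each distal-face
exit, integrates the Gaussian source-offset distribution analytically:
the transmitted weight is multiplied by the probability that a Gaussian
launch offset lands the exit point inside the circular aperture.  This is
an expected-value (variance-reduced) form of the binary accept/reject
detector with an identical expectation, in the same spirit as the
deterministic weight splitting used at the exit surfaces.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_INF = 1.0e30
_EPS_SURF = 1.0e-9  # nudge (mm) across the bone surface after a crossing


@njit(cache=False)
def hg_cos_from_uniform(g: float, xi: float) -> float:
    """Scattering deflection cosine from a uniform deviate (HG inverse CDF)."""
    if abs(g) < 1.0e-6:
        return 2.0 * xi - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    c = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


@njit(cache=False)
def fresnel_unpolarized(n_in: float, n_out: float, cos_i: float):
    """Unpolarized Fresnel reflectance and refracted cosine.

    Returns ``(R, cos_t)``; beyond the critical angle ``R = 1`` and the
    refracted cosine is reported as 0.
    """
    if cos_i < 0.0:
        cos_i = -cos_i
    if abs(n_in - n_out) < 1.0e-12:
        return 0.0, cos_i
    sin_i2 = 1.0 - cos_i * cos_i
    sin_t2 = (n_in / n_out) * (n_in / n_out) * sin_i2
    if sin_t2 >= 1.0:
        return 1.0, 0.0
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n_in * cos_i - n_out * cos_t) / (n_in * cos_i + n_out * cos_t)
    rp = (n_in * cos_t - n_out * cos_i) / (n_in * cos_t + n_out * cos_i)
    return 0.5 * (rs * rs + rp * rp), cos_t


@njit(cache=False)
def rotate_direction(
    ux: float, uy: float, uz: float, cos_t: float, phi: float
):
    """Rotate a unit vector by polar angle acos(cos_t) and azimuth phi."""
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cos_p = math.cos(phi)
    sin_p = math.sin(phi)
    if abs(uz) > 0.99999:
        # polar-singularity-safe branch
        nx = sin_t * cos_p
        ny = sin_t * sin_p
        nz = cos_t if uz > 0.0 else -cos_t
    else:
        den = math.sqrt(1.0 - uz * uz)
        nx = sin_t * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_t
        ny = sin_t * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_t
        nz = -sin_t * cos_p * den + uz * cos_t
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=False)
def ray_circle_distance(
    y: float,
    z: float,
    uy: float,
    uz: float,
    center_z: float,
    radius: float,
    inside: bool,
) -> float:
    """Distance along (uy, uz) to the circle y^2 + (z-cz)^2 = r^2.

    The bone cylinder axis is parallel to x, so the intersection reduces
    to 2-D.  Returns a large sentinel when there is no forward crossing.
    """
    a = uy * uy + uz * uz
    if a <= 0.0:
        return _INF
    oy = y
    oz = z - center_z
    b = oy * uy + oz * uz
    c = oy * oy + oz * oz - radius * radius
    disc = b * b - a * c
    if disc <= 0.0:
        return _INF
    sq = math.sqrt(disc)
    t_near = (-b - sq) / a
    t_far = (-b + sq) / a
    if inside:
        if t_far > 1.0e-12:
            return t_far
        return _INF
    if t_near > 1.0e-12:
        return t_near
    if t_far > 1.0e-12:
        return t_far
    return _INF


@njit(cache=False)
def gaussian_aperture_probability(
    dx: float, y: float, sigma: float, radius2: float
) -> float:
    """P[(x0 + dx)^2 + y^2 <= r^2] for a Gaussian launch offset x0.

    ``dx`` is the packet's lateral displacement along the cylinder axis,
    ``y`` its exit ordinate; ``sigma`` is the per-axis Gaussian sigma of
    the source.  Degenerates to a sharp aperture test for sigma -> 0.
    """
    half_chord2 = radius2 - y * y
    if half_chord2 <= 0.0:
        return 0.0
    b = math.sqrt(half_chord2)
    if sigma <= 1.0e-12:
        return 1.0 if abs(dx) <= b else 0.0
    inv = 1.0 / (sigma * math.sqrt(2.0))
    return 0.5 * (math.erf((b - dx) * inv) + math.erf((b + dx) * inv))


_STACK_SIZE = 512


@njit(cache=False)
def transport_batch(
    n_photons: int,
    seed: int,
    edges: np.ndarray,
    mu_a: np.ndarray,
    mu_s: np.ndarray,
    g: np.ndarray,
    bone_layer: int,
    bone_center_z: float,
    bone_radius: float,
    bone_mu_a: float,
    bone_mu_s: float,
    bone_g: float,
    n_ambient: float,
    n_tissue: float,
    source_sigma: float,
    detector_radius: float,
    detector_cos_min: float,
    roulette_threshold: float,
    roulette_survival: float,
    split_z: np.ndarray,
    reweight_class: np.ndarray,
    delta_mu_a: np.ndarray,
    lateral_half_width: float,
):
    """Trace one seeded batch of photon packets through the slab stack.

    ``split_z`` holds the z positions (sorted, strictly interior) of
    optional geometric-splitting planes: a packet crossing one toward the
    detector is split in two (half weight each); a packet crossing back
    is rouletted with survival 1/2 (doubling the survivor's weight).
    Expected weights are unchanged, but the packet population no longer
    decays exponentially toward the detector, which raises the
    detected-count efficiency for thick absorbing stacks.  Pass an empty
    array to disable splitting (analytic validation runs do).

    Correlated condition families: ``reweight_class[layer]`` assigns each
    layer to an absorption-perturbation class (-1: none), and
    ``delta_mu_a[c, k]`` is the absorption offset of family condition
    ``c`` in class ``k`` relative to the simulated reference stack.  The
    kernel records the per-packet pathlength in each class and, at every
    detection, scores ``exp(-sum_k delta[c, k] * L_k)`` times the
    detected weight into condition ``c``.  All conditions thus share one
    set of paths, which makes differences between them (the pulsatile
    AC signal in particular) nearly noise-free.  For a plain run pass a
    single all-zero condition row.

    Returns ``(tally, detected_per_condition)`` where ``tally`` is
    ``[specular, absorbed, detected_weight, detected_count, escaped, residual]``
    for the reference stack, summing to ``n_photons`` up to float64
    rounding, and ``detected_per_condition`` holds the reweighted
    detected weights.
    """
    np.random.seed(seed)
    n_layers = edges.shape[0] - 1
    n_split = split_z.shape[0]
    n_cond = delta_mu_a.shape[0]
    n_class = delta_mu_a.shape[1]
    z_exit = edges[n_layers]
    det_r2 = detector_radius * detector_radius

    dn = n_ambient - n_tissue
    sm = n_ambient + n_tissue
    r_specular = (dn / sm) * (dn / sm)

    specular = 0.0
    absorbed = 0.0
    detected_w = 0.0
    detected_n = 0.0
    escaped = 0.0
    residual = 0.0
    detected_cond = np.zeros(n_cond)
    path_len = np.zeros(n_class)

    # pending-packet stack for split progeny
    px = np.empty(_STACK_SIZE)
    py = np.empty(_STACK_SIZE)
    pz = np.empty(_STACK_SIZE)
    pux = np.empty(_STACK_SIZE)
    puy = np.empty(_STACK_SIZE)
    puz = np.empty(_STACK_SIZE)
    pw = np.empty(_STACK_SIZE)
    ptau = np.empty(_STACK_SIZE)
    playe = np.empty(_STACK_SIZE, dtype=np.int64)
    plevel = np.empty(_STACK_SIZE, dtype=np.int64)
    pbone = np.empty(_STACK_SIZE, dtype=np.uint8)
    ppath = np.empty((_STACK_SIZE, n_class))

    for _ in range(n_photons):
        # the Gaussian x-offset is integrated analytically at detection
        x = 0.0
        y = np.random.normal() * source_sigma
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = 1.0 - r_specular
        specular += r_specular
        layer = 0
        level = 0
        pending = 0
        in_bone = False
        for k in range(n_class):
            path_len[k] = 0.0
        xi = np.random.random()
        while xi <= 0.0:
            xi = np.random.random()
        tau = -math.log(xi)  # dimensionless optical path to next interaction

        alive = True
        while True:
            if not alive:
                if pending == 0:
                    break
                pending -= 1
                x = px[pending]
                y = py[pending]
                z = pz[pending]
                ux = pux[pending]
                uy = puy[pending]
                uz = puz[pending]
                w = pw[pending]
                tau = ptau[pending]
                layer = playe[pending]
                level = plevel[pending]
                in_bone = pbone[pending] != 0
                for k in range(n_class):
                    path_len[k] = ppath[pending, k]
                alive = True
            if in_bone:
                ma = bone_mu_a
                ms = bone_mu_s
                gg = bone_g
                cls = -1
            else:
                ma = mu_a[layer]
                ms = mu_s[layer]
                gg = g[layer]
                cls = reweight_class[layer]
            mt = ma + ms

            s = tau / mt if mt > 0.0 else _INF

            # distance to the bounding z-plane of the current layer
            if uz > 0.0:
                d_plane = (edges[layer + 1] - z) / uz
                plane_step = 1
            elif uz < 0.0:
                d_plane = (edges[layer] - z) / uz
                plane_step = -1
            else:
                d_plane = _INF
                plane_step = 0
            if d_plane < 0.0:
                d_plane = 0.0

            d_bone = _INF
            if bone_layer >= 0 and layer == bone_layer:
                d_bone = ray_circle_distance(
                    y, z, uy, uz, bone_center_z, bone_radius, in_bone
                )

            # lateral escape through the sides of the finger (finite in y;
            # x stays unbounded to preserve the translation symmetry the
            # detector estimator relies on)
            if lateral_half_width < _INF:
                if y >= lateral_half_width or y <= -lateral_half_width:
                    escaped += w
                    alive = False
                    continue
                if uy > 0.0:
                    d_lat = (lateral_half_width - y) / uy
                elif uy < 0.0:
                    d_lat = (-lateral_half_width - y) / uy
                else:
                    d_lat = _INF
            else:
                d_lat = _INF

            # distance to the next geometric-splitting plane
            d_split = _INF
            if n_split > 0:
                if uz > 0.0 and level < n_split:
                    d_split = (split_z[level] - z) / uz
                elif uz < 0.0 and level > 0:
                    d_split = (split_z[level - 1] - z) / uz
                if d_split < 0.0:
                    d_split = 0.0

            if (
                s <= d_plane
                and s <= d_bone
                and s <= d_split
                and s <= d_lat
            ):
                # hop to the interaction site, drop, spin
                x += ux * s
                y += uy * s
                z += uz * s
                if cls >= 0:
                    path_len[cls] += s
                absorbed += w * ma / mt
                w *= ms / mt
                if w <= 0.0:
                    alive = False
                    continue
                xi = np.random.random()
                cos_t = hg_cos_from_uniform(gg, xi)
                phi = 2.0 * math.pi * np.random.random()
                ux, uy, uz = rotate_direction(ux, uy, uz, cos_t, phi)
                if w < roulette_threshold:
                    if np.random.random() < roulette_survival:
                        residual -= w * (1.0 / roulette_survival - 1.0)
                        w /= roulette_survival
                    else:
                        residual += w
                        alive = False
                        continue
                xi = np.random.random()
                while xi <= 0.0:
                    xi = np.random.random()
                tau = -math.log(xi)
            elif d_lat <= d_plane and d_lat <= d_bone and d_lat <= d_split:
                # side escape: the packet leaves through the finger's flank
                x += ux * d_lat
                y += uy * d_lat
                z += uz * d_lat
                escaped += w
                alive = False
                continue
            elif d_bone < d_plane and d_bone <= d_split:
                # cross the bone surface; index-matched, direction unchanged
                x += ux * d_bone
                y += uy * d_bone
                z += uz * d_bone
                if cls >= 0:
                    path_len[cls] += d_bone
                tau -= d_bone * mt
                if tau < 0.0:
                    tau = 0.0
                in_bone = not in_bone
                x += ux * _EPS_SURF
                y += uy * _EPS_SURF
                z += uz * _EPS_SURF
            elif d_split < d_plane:
                x += ux * d_split
                y += uy * d_split
                z += uz * d_split
                if cls >= 0:
                    path_len[cls] += d_split
                tau -= d_split * mt
                if tau < 0.0:
                    tau = 0.0
                if uz > 0.0:
                    # toward the detector: split in two, half weight each
                    level += 1
                    if pending < _STACK_SIZE:
                        w *= 0.5
                        px[pending] = x
                        py[pending] = y
                        pz[pending] = z
                        pux[pending] = ux
                        puy[pending] = uy
                        puz[pending] = uz
                        pw[pending] = w
                        xi = np.random.random()
                        while xi <= 0.0:
                            xi = np.random.random()
                        ptau[pending] = -math.log(xi)
                        playe[pending] = layer
                        plevel[pending] = level
                        pbone[pending] = 1 if in_bone else 0
                        for k in range(n_class):
                            ppath[pending, k] = path_len[k]
                        pending += 1
                    # stack full: carry on unsplit (still unbiased)
                else:
                    # away from the detector: roulette with survival 1/2
                    level -= 1
                    if np.random.random() < 0.5:
                        residual -= w
                        w *= 2.0
                    else:
                        residual += w
                        alive = False
                        continue
            else:
                if d_plane >= _INF:
                    # direction exactly parallel to the slabs in a void
                    # region: no interaction possible, drop the packet
                    residual += w
                    alive = False
                    continue
                x += ux * d_plane
                y += uy * d_plane
                z += uz * d_plane
                if cls >= 0:
                    path_len[cls] += d_plane
                tau -= d_plane * mt
                if tau < 0.0:
                    tau = 0.0
                at_exit = plane_step > 0 and layer == n_layers - 1
                at_entry = plane_step < 0 and layer == 0
                if at_exit or at_entry:
                    refl, cos_t = fresnel_unpolarized(n_tissue, n_ambient, uz)
                    transmitted = (1.0 - refl) * w
                    if transmitted > 0.0:
                        if at_exit and cos_t >= detector_cos_min:
                            p = gaussian_aperture_probability(
                                x, y, source_sigma, det_r2
                            )
                            if p > 0.0:
                                detected_w += transmitted * p
                                escaped += transmitted * (1.0 - p)
                                detected_n += 1.0
                                for c in range(n_cond):
                                    arg = 0.0
                                    for k in range(n_class):
                                        arg += delta_mu_a[c, k] * path_len[k]
                                    detected_cond[c] += (
                                        transmitted * p * math.exp(-arg)
                                    )
                            else:
                                escaped += transmitted
                        else:
                            escaped += transmitted
                    w *= refl
                    if w <= 0.0:
                        alive = False
                        continue
                    uz = -uz
                    z = z_exit if at_exit else 0.0
                    if w < roulette_threshold:
                        if np.random.random() < roulette_survival:
                            residual -= w * (1.0 / roulette_survival - 1.0)
                            w /= roulette_survival
                        else:
                            residual += w
                            alive = False
                            continue
                else:
                    layer += plane_step

    out = np.empty(6, dtype=np.float64)
    out[0] = specular
    out[1] = absorbed
    out[2] = detected_w
    out[3] = detected_n
    out[4] = escaped
    out[5] = residual
    return out, detected_cond
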