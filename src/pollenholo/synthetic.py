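"""Synthetic pollen scenes, forward-simulated holograms, and reading-session records.

No pollen hologram dataset accompanies this package, so validation runs on
stand-ins generated here: stylised six-species pollen phantoms placed on a
clear background, forward-propagated to the sensor plane under unit
plane-wave illumination, and digitised with a simple shot-noise/read-noise
sensor model; plus synthetic two-evaluator, two-modality classification
records drawn from per-modality confusion matrices.

The six shape families are caricatures of the species' textbook
morphology — timothy grass as an oval grain with a single pore, common
ragweed as a round grain with radial spikes, silver birch and hazel as
rounded triangles (birch more variable), common alder as a rounded
pentagon, olive as a bean with a central furrow.  Grain diameters default
to the 20–40 μm range typical of these taxa; the source study prints no
size measurements, so these are literature-typical values, not measured
ones.  Every phantom is passive: |T| ≤ 1 everywhere, matching the object
constraint assumed by the GS reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .exceptions import InvalidArgumentError, PlacementError
from .optics import ComplexField, FieldGeometry, propagate
from .reconstruction import HologramFrame
from .stats import EvaluationRecord, POLLEN_CLASSES

__all__ = [
    "PollenPhantomSpec", "GrainPlacement", "ScenePhantom", "NoiseModel",
    "EvaluationStudySpec", "DEFAULT_SPECS", "render_phantom",
    "simulate_hologram", "generate_study_records", "reference_study_records",
]

SHAPE_FAMILIES = ("oval_single_pore", "round_spiked", "triangular_3pore",
                  "pentagonal_5pore", "bean_furrowed", "triangular_3pore_variant")


@dataclass(frozen=True)
class PollenPhantomSpec:
    """Geometry and optical parameters of one species' phantom."""

    species: str
    diameter_mean: float            # μm
    diameter_sd: float              # μm
    shape_family: str
    amplitude_contrast: float = 0.3  # minimum transmission inside the grain
    phase_shift_max: float = 1.0     # rad, peak phase delay inside the grain
    spike_count: int = 0             # round_spiked only
    spike_length: float = 0.0        # μm, round_spiked only

    def __post_init__(self) -> None:
        if self.diameter_mean <= 0 or self.diameter_sd < 0:
            raise InvalidArgumentError("diameter parameters must be positive")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise InvalidArgumentError("amplitude_contrast must lie in [0, 1]")
        if self.shape_family not in SHAPE_FAMILIES:
            raise InvalidArgumentError(f"unknown shape family {self.shape_family!r}")


DEFAULT_SPECS: dict[str, PollenPhantomSpec] = {
    "timothy_grass": PollenPhantomSpec("timothy_grass", 32.0, 3.0, "oval_single_pore"),
    "common_ragweed": PollenPhantomSpec("common_ragweed", 20.0, 2.0, "round_spiked",
                                        spike_count=12, spike_length=2.0),
    "silver_birch": PollenPhantomSpec("silver_birch", 24.0, 2.5, "triangular_3pore"),
    "common_alder": PollenPhantomSpec("common_alder", 26.0, 2.5, "pentagonal_5pore"),
    "olive_tree": PollenPhantomSpec("olive_tree", 22.0, 2.0, "bean_furrowed"),
    "hazel": PollenPhantomSpec("hazel", 25.0, 2.5, "triangular_3pore_variant"),
}


@dataclass(frozen=True)
class GrainPlacement:
    species: str
    x: float        # μm, grain centre, origin at top-left pixel centre
    y: float        # μm
    diameter: float  # μm
    rotation: float  # rad


@dataclass
class ScenePhantom:
    """A rendered slide: grain list, complex transmission, truth mask."""

    geometry: FieldGeometry
    grains: list[GrainPlacement]
    transmission: ComplexField
    truth_mask: np.ndarray


@dataclass(frozen=True)
class NoiseModel:
    """Sensor model: Poisson shot noise, Gaussian read noise, quantisation.

    `photons_at_unit_intensity` is the expected photon count for a pixel at
    normalised intensity 1.0; 0 selects the exact noiseless path.
    """

    photons_at_unit_intensity: float = 5000.0
    read_noise_sd: float = 2.0      # counts
    bit_depth: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.photons_at_unit_intensity < 0 or self.read_noise_sd < 0:
            raise InvalidArgumentError("noise parameters must be non-negative")


def _boundary_radius(theta: np.ndarray, spec: PollenPhantomSpec,
                     radius: float) -> np.ndarray:
    """Silhouette boundary radius r(θ) for each shape family."""
    fam = spec.shape_family
    if fam == "oval_single_pore":
        a, b = radius, 0.72 * radius
        return a * b / np.sqrt((b * np.cos(theta))**2 + (a * np.sin(theta))**2)
    if fam == "round_spiked":
        return np.full_like(theta, radius)
    if fam == "triangular_3pore":
        return radius * (1.0 + 0.18 * np.cos(3.0 * theta)) / 1.18
    if fam == "triangular_3pore_variant":
        return radius * (1.0 + 0.12 * np.cos(3.0 * theta + np.pi / 3.0)) / 1.12
    if fam == "pentagonal_5pore":
        return radius * (1.0 + 0.10 * np.cos(5.0 * theta)) / 1.10
    # bean_furrowed
    a, b = radius, 0.60 * radius
    return a * b / np.sqrt((b * np.cos(theta))**2 + (a * np.sin(theta))**2)


def _render_grain(amp: np.ndarray, phase: np.ndarray, mask: np.ndarray,
                  grain: GrainPlacement, spec: PollenPhantomSpec,
                  pitch: float) -> None:
    """Paint one grain into the amplitude/phase/mask canvases in place."""
    n_y, n_x = amp.shape
    radius = grain.diameter / 2.0
    reach = radius + spec.spike_length + 3.0 * pitch
    j0 = max(0, int((grain.x - reach) / pitch))
    j1 = min(n_x, int((grain.x + reach) / pitch) + 2)
    i0 = max(0, int((grain.y - reach) / pitch))
    i1 = min(n_y, int((grain.y + reach) / pitch) + 2)
    yy = (np.arange(i0, i1) * pitch - grain.y)[:, None]
    xx = (np.arange(j0, j1) * pitch - grain.x)[None, :]
    # rotate the local frame
    c, s = np.cos(grain.rotation), np.sin(grain.rotation)
    xr = c * xx + s * yy
    yr = -s * xx + c * yy
    r = np.hypot(xr, yr)
    theta = np.arctan2(yr, xr)
    rb = _boundary_radius(theta, spec, radius)

    ramp_w = 1.5 * pitch  # edge softness, ~1 pixel
    depth = np.clip((rb - r) / ramp_w, 0.0, 1.0)
    inside = r <= rb

    if spec.shape_family == "round_spiked" and spec.spike_count > 0:
        ang = (theta % (2.0 * np.pi)) * spec.spike_count / (2.0 * np.pi)
        near_spike = np.abs(ang - np.round(ang)) < 0.12
        on_spike = near_spike & (r > rb) & (r <= rb + spec.spike_length)
        depth = np.where(on_spike, 0.8, depth)
        inside = inside | on_spike

    local_amp = 1.0 - (1.0 - spec.amplitude_contrast) * depth

    # lighter internal features: pores / furrow
    if spec.shape_family == "oval_single_pore":
        px, py = 0.8 * radius, 0.0
        pore = np.hypot(xr - px, yr - py) < 0.15 * radius
        local_amp = np.where(pore & inside, 1.0 - 0.3 * (1.0 - spec.amplitude_contrast),
                             local_amp)
    elif spec.shape_family in ("triangular_3pore", "triangular_3pore_variant"):
        offs = 0.0 if spec.shape_family == "triangular_3pore" else -np.pi / 3.0
        for k in range(3):
            a_k = 2.0 * np.pi * k / 3.0 - offs
            px, py = 0.85 * radius * np.cos(a_k), 0.85 * radius * np.sin(a_k)
            pore = np.hypot(xr - px, yr - py) < 0.14 * radius
            local_amp = np.where(pore & inside,
                                 1.0 - 0.35 * (1.0 - spec.amplitude_contrast), local_amp)
    elif spec.shape_family == "bean_furrowed":
        furrow = (np.abs(yr) < 0.12 * radius) & inside
        local_amp = np.where(furrow, 1.0 - 0.35 * (1.0 - spec.amplitude_contrast),
                             local_amp)

    view_a = amp[i0:i1, j0:j1]
    np.minimum(view_a, local_amp, out=view_a)
    phase[i0:i1, j0:j1] += spec.phase_shift_max * depth
    mask[i0:i1, j0:j1] |= inside


def render_phantom(specs: Mapping[str, PollenPhantomSpec] | None,
                   geometry: FieldGeometry, n_grains: int,
                   rng_seed: int = 0,
                   species: Optional[Sequence[str]] = None,
                   max_retries: int = 100) -> ScenePhantom:
    """Place non-overlapping pollen grains and build the slide transmission.

    Grain species cycle through `species` (default: all six), diameters are
    drawn from each species' normal law (clipped to ±2 sd), positions are
    uniform inside the field of view with the whole grain kept in frame.
    Deterministic for a fixed seed.  Raises PlacementError when a grain
    cannot be placed without overlap within `max_retries` attempts.
    """
    if n_grains < 0:
        raise InvalidArgumentError("n_grains must be >= 0")
    specs = dict(DEFAULT_SPECS if specs is None else specs)
    species = list(species if species is not None else POLLEN_CLASSES)
    rng = np.random.default_rng(rng_seed)

    width = geometry.n_x * geometry.pitch
    height = geometry.n_y * geometry.pitch
    grains: list[GrainPlacement] = []
    for i in range(n_grains):
        sp = specs[species[i % len(species)]]
        d = float(np.clip(rng.normal(sp.diameter_mean, sp.diameter_sd),
                          sp.diameter_mean - 2 * sp.diameter_sd,
                          sp.diameter_mean + 2 * sp.diameter_sd))
        reach = d / 2.0 + sp.spike_length + 4.0 * geometry.pitch
        placed = False
        for _ in range(max_retries):
            x = float(rng.uniform(reach, width - reach))
            y = float(rng.uniform(reach, height - reach))
            clear = all(np.hypot(x - g.x, y - g.y) >
                        (d + g.diameter) / 2.0 + specs[g.species].spike_length
                        + sp.spike_length + 2.0 * geometry.pitch
                        for g in grains)
            if clear:
                grains.append(GrainPlacement(sp.species, x, y, d,
                                             float(rng.uniform(0, 2 * np.pi))))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place grain {i + 1}/{n_grains} without overlap "
                f"after {max_retries} retries")

    amp = np.ones(geometry.shape, dtype=np.float64)
    phase = np.zeros(geometry.shape, dtype=np.float64)
    mask = np.zeros(geometry.shape, dtype=bool)
    for g in grains:
        _render_grain(amp, phase, mask, g, specs[g.species], geometry.pitch)
    np.clip(amp, 0.0, 1.0, out=amp)
    transmission = ComplexField(geometry, amp * np.exp(1j * phase),
                                plane_offset=0.0)
    return ScenePhantom(geometry, grains, transmission, mask)


def simulate_hologram(scene: ScenePhantom, h: float,
                      noise: Optional[NoiseModel] = None,
                      pad_factor: int = 2) -> HologramFrame:
    """Forward-simulate the in-line hologram of a scene at distance h (μm).

    The transmission is propagated by +h under unit plane-wave
    illumination; the sensor records |U|² scaled so the brightest pixel
    sits at full scale.  With a noise model, per-pixel Poisson photon
    counts, Gaussian read noise and quantisation to the sensor bit depth
    are applied; without one (or with zero photons) the scaled intensity
    is returned exactly.
    """
    if not (np.isfinite(h) and h > 0):
        raise InvalidArgumentError("propagation distance h must be positive")
    sensor = propagate(scene.transmission, h, pad_factor)
    intensity = np.abs(sensor.values)**2
    bit_depth = noise.bit_depth if noise is not None else 12
    full = float(2**bit_depth - 1)
    scale = full / intensity.max()
    if noise is None or noise.photons_at_unit_intensity == 0:
        counts = intensity * scale
    else:
        rng = np.random.default_rng(noise.seed)
        photons = rng.poisson(intensity * noise.photons_at_unit_intensity)
        counts = photons * (scale / noise.photons_at_unit_intensity)
        counts = counts + rng.normal(0.0, noise.read_noise_sd, counts.shape)
        counts = np.clip(np.round(counts), 0.0, full)
    return HologramFrame(scene.geometry, counts, bit_depth=bit_depth)


@dataclass(frozen=True)
class EvaluationStudySpec:
    """Design of a synthetic two-modality reading session.

    Mirrors the validation study's layout: 6 classes × 8 test images per
    class per modality, read independently by each evaluator, so each
    confusion-matrix row rests on 16 evaluations per modality.
    """

    n_test_per_class: int = 8
    n_evaluators: int = 2
    modalities: tuple[str, ...] = ("DIHM", "optical")
    confusion_probs: Mapping[str, np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_test_per_class < 1 or self.n_evaluators < 1:
            raise InvalidArgumentError("counts must be positive")


def generate_study_records(spec: EvaluationStudySpec) -> list[EvaluationRecord]:
    """Draw classification records from per-modality confusion matrices.

    Image identities are shared between evaluators within a modality (and
    across modalities — the same slides are imaged twice), which is what
    makes Cohen's κ well defined downstream.  Deterministic per seed.
    """
    n_cls = len(POLLEN_CLASSES)
    probs: dict[str, np.ndarray] = {}
    for m in spec.modalities:
        p = (np.eye(n_cls) if spec.confusion_probs is None
             else np.asarray(spec.confusion_probs[m], dtype=np.float64))
        if p.shape != (n_cls, n_cls) or np.any(p < 0) or \
                not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise InvalidArgumentError(
                f"confusion matrix for {m!r} must be {n_cls}x{n_cls} row-stochastic")
        probs[m] = p
    rng = np.random.default_rng(spec.seed)
    records: list[EvaluationRecord] = []
    for modality in spec.modalities:
        p = probs[modality]
        for ci, cls in enumerate(POLLEN_CLASSES):
            for k in range(spec.n_test_per_class):
                image_id = f"{cls}_{k + 1:02d}"
                for e in range(spec.n_evaluators):
                    assigned = POLLEN_CLASSES[rng.choice(n_cls, p=p[ci])]
                    records.append(EvaluationRecord(
                        image_id=image_id, modality=modality,
                        evaluator=f"expert_{e + 1}", true_species=cls,
                        assigned_species=assigned))
    return records


# Deterministic error layout of the reference reading session: seven
# misclassifications, six of them among the morphologically overlapping
# birch/alder/hazel trio, all on distinct images.
_REFERENCE_ERRORS: dict[tuple[str, str], dict[str, str]] = {
    ("DIHM", "expert_1"): {"silver_birch_01": "hazel"},
    ("DIHM", "expert_2"): {"silver_birch_02": "hazel",
                           "silver_birch_03": "common_alder",
                           "common_alder_01": "silver_birch"},
    ("optical", "expert_1"): {"silver_birch_04": "common_alder",
                              "common_alder_02": "silver_birch"},
    ("optical", "expert_2"): {"olive_tree_01": "silver_birch"},
}


def reference_study_records() -> list[EvaluationRecord]:
    """The reference two-expert, two-modality reading session (192 records).

    A deterministic record set encoding the published summary of the
    validation study: 48 test images per modality (8 per class), two
    expert readers, and seven misclassifications — two birch→hazel, two
    birch→alder, two alder→birch and one olive→birch — distributed so that
    expert 1 makes 1 DIHM and 2 optical errors and expert 2 makes 3 DIHM
    and 1 optical error.  From these records the package recomputes the
    per-expert accuracies (97.9/93.8 DIHM, 95.8/97.9 optical), the pooled
    accuracies (95.8/96.9), the pooled per-class F1 scores and the
    inter-observer/inter-modality κ values.
    """
    records: list[EvaluationRecord] = []
    for modality in ("DIHM", "optical"):
        for evaluator in ("expert_1", "expert_2"):
            errors = _REFERENCE_ERRORS[(modality, evaluator)]
            for cls in POLLEN_CLASSES:
                for k in range(8):
                    image_id = f"{cls}_{k + 1:02d}"
                    assigned = errors.get(image_id, cls)
                    records.append(EvaluationRecord(
                        image_id=image_id, modality=modality,
                        evaluator=evaluator, true_species=cls,
                        assigned_species=assigned))
    return records
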