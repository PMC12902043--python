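"""Hologram normalisation, backpropagation, GS phase retrieval, autofocus.

An in-line hologram H(x,y) records the interference between the unscattered
illumination and the light scattered by the object.  A single angular-
spectrum backpropagation of √H to the object plane focuses the "real"
image but superimposes the defocused conjugate ("twin") image.  The
Gerchberg–Saxton (GS) loop implemented here suppresses the twin image by
alternating propagation between the two planes while enforcing, at the
sensor, the measured amplitude √H and, at the object, passivity: the
transmission amplitude may not exceed 1 (a non-amplifying object), so
pixels whose modulus exceeds the clip level are set to the clip level with
their phase reset to zero (at those pixels only).

One GS iteration reads: backpropagate → object constraint; between
iterations the field returns to the sensor plane (forward propagation +
amplitude replacement).  The reconstruction is taken from the object plane
of the final pass, so `n_iterations=1` coincides with a single
backpropagation followed by one clipping.  The iteration count is fixed
(default 200, which converges for scenes like these); no early stopping.

Phase reference: the measured √H carries no phase, so a raw angular-
spectrum backpropagation would put the plane-wave carrier phase
exp(−i 2π h/λ) on the background, and "reset the phase to zero" would then
be inconsistent between clipped and unclipped pixels.  All reconstruction
steps therefore use carrier-removed kernels (the on-axis plane-wave phase
divided out), which is exactly the convention in which T̃ of an empty
scene is 1 + 0i.  Amplitudes are unaffected; retrieved phases are relative
to the illuminating wave, which is what a transmission function means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .exceptions import DegenerateInputError, InvalidArgumentError
from .optics import (ComplexField, FieldGeometry, border_width,
                     make_transfer_function, propagate, backpropagate)

__all__ = [
    "HologramFrame", "GSConfig", "ReconstructionResult", "FocusScan",
    "normalize_hologram", "initial_wavefield", "apply_object_constraint",
    "apply_sensor_constraint", "single_backpropagation", "gs_reconstruct",
    "sharpness_score", "autofocus", "twin_suppression_ratio",
]

BACKGROUND_METHODS = ("frame_mean", "border_mean", "reference_frame")


@dataclass
class HologramFrame:
    """Measured or simulated intensity frame.

    Raw frames hold sensor counts (12-bit values in a 16-bit container);
    normalised frames have a background level of ~1.
    """

    geometry: FieldGeometry
    intensity: np.ndarray
    bit_depth: int = 12
    background: Optional[float | np.ndarray] = None
    source_path: Optional[str] = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.shape != self.geometry.shape:
            raise InvalidArgumentError(
                f"intensity shape {self.intensity.shape} does not match geometry "
                f"{self.geometry.shape}")
        if not np.all(np.isfinite(self.intensity)):
            raise InvalidArgumentError("intensity must be finite")
        if np.any(self.intensity < 0):
            raise InvalidArgumentError("intensity must be non-negative")

    @property
    def full_scale(self) -> int:
        return 2**self.bit_depth - 1


@dataclass
class GSConfig:
    """Settings of the GS phase-retrieval loop."""

    n_iterations: int = 200
    clip_level: float = 1.0
    pad_factor: int = 2
    background_method: str = "frame_mean"
    record_misfit: bool = False

    def __post_init__(self) -> None:
        if self.n_iterations < 0:
            raise InvalidArgumentError("n_iterations must be >= 0")
        if not self.clip_level > 0:
            raise InvalidArgumentError("clip_level must be positive")
        if self.pad_factor < 1:
            raise InvalidArgumentError("pad_factor must be >= 1")
        if self.background_method not in BACKGROUND_METHODS:
            raise InvalidArgumentError(
                f"background_method must be one of {BACKGROUND_METHODS}")


@dataclass
class ReconstructionResult:
    """Recovered object transmission: amplitude T̃(x,y) and phase φ̃(x,y)."""

    amplitude: np.ndarray
    phase: np.ndarray
    h: float
    iterations_run: int
    misfit_trace: Optional[list[float]] = None


@dataclass
class FocusScan:
    """Outcome of an autofocus sweep over candidate refocus distances."""

    candidates: list[float]
    scores: list[float]
    best_h: float


def normalize_hologram(raw: HologramFrame, method: str = "frame_mean",
                       reference: Optional[HologramFrame] = None) -> HologramFrame:
    """Divide a raw hologram by a background estimate so background ≈ 1.

    Methods: ``frame_mean`` (mean of the whole frame — appropriate when
    objects are sparse), ``border_mean`` (mean over the outer border
    frame), ``reference_frame`` (pixelwise division by an object-free
    frame; divisor guarded against values below 1% of its mean).
    """
    if method not in BACKGROUND_METHODS:
        raise InvalidArgumentError(f"unknown background method {method!r}")
    if not np.any(raw.intensity > 0):
        raise DegenerateInputError("cannot normalise an all-zero frame")
    if method == "frame_mean":
        bg: float | np.ndarray = float(raw.intensity.mean())
        out = raw.intensity / bg
    elif method == "border_mean":
        n_y, n_x = raw.intensity.shape
        w = border_width(n_y, n_x)
        mask = np.zeros((n_y, n_x), dtype=bool)
        mask[:w, :] = mask[-w:, :] = True
        mask[:, :w] = mask[:, -w:] = True
        bg = float(raw.intensity[mask].mean())
        if bg == 0:
            raise DegenerateInputError("border of the frame is all zero")
        out = raw.intensity / bg
    else:  # reference_frame
        if reference is None:
            raise InvalidArgumentError("reference_frame method requires a reference")
        ref = np.asarray(reference.intensity, dtype=np.float64)
        if ref.shape != raw.intensity.shape:
            raise InvalidArgumentError("reference frame shape mismatch")
        floor = 0.01 * ref.mean()
        if floor <= 0:
            raise DegenerateInputError("reference frame is all zero")
        bg = np.maximum(ref, floor)
        out = raw.intensity / bg
    return HologramFrame(raw.geometry, out, raw.bit_depth, background=bg,
                         source_path=raw.source_path, normalized=True)


def initial_wavefield(holo: HologramFrame) -> ComplexField:
    """Initial sensor-plane guess: √H with zero phase."""
    if np.any(holo.intensity < 0):
        raise InvalidArgumentError("intensity must be non-negative")
    return ComplexField(holo.geometry,
                        np.sqrt(holo.intensity).astype(np.complex128),
                        plane_offset=0.0)


def apply_object_constraint(field: ComplexField, clip_level: float = 1.0) -> ComplexField:
    """Passivity constraint at the object plane.

    Pixels with modulus above `clip_level` are replaced by
    `clip_level + 0i` (amplitude clipped and phase zeroed at those pixels
    only — the retrieved phase elsewhere is untouched).
    """
    values = field.values.copy()
    over = np.abs(values) > clip_level
    values[over] = clip_level
    return ComplexField(field.geometry, values, field.plane_offset)


def apply_sensor_constraint(field: ComplexField, measured_amplitude: np.ndarray) -> ComplexField:
    """Replace the modulus with the measured amplitude, keeping the phase.

    Zero-modulus pixels (undefined phase) adopt phase 0.
    """
    measured_amplitude = np.asarray(measured_amplitude, dtype=np.float64)
    if measured_amplitude.shape != field.values.shape:
        raise InvalidArgumentError("measured amplitude shape mismatch")
    if np.any(measured_amplitude < 0):
        raise InvalidArgumentError("measured amplitude must be non-negative")
    # np.angle(0) == 0, so zero pixels come out as measured + 0i directly
    values = measured_amplitude * np.exp(1j * np.angle(field.values))
    return ComplexField(field.geometry, values, field.plane_offset)


def _carrier_removed_transfer(geometry: FieldGeometry, distance: float):
    """Angular-spectrum kernel with the on-axis plane-wave phase divided out.

    Leaves the zero-frequency component untouched, so a unit background
    stays 1 + 0i under propagation; conjugate symmetry in ±distance holds.
    """
    tf = make_transfer_function(geometry, distance)
    tf.values = tf.values * np.exp(-1j * 2.0 * np.pi * distance
                                   / geometry.wavelength)
    return tf


def single_backpropagation(holo: HologramFrame, h: float,
                           pad_factor: int = 2) -> ReconstructionResult:
    """One angular-spectrum backpropagation of √H; twin image retained.

    No clipping is applied, so the background halo statistics of this
    result serve as the reference when quantifying twin-image suppression.
    The phase is referenced to the illuminating wave (carrier removed).
    """
    if not (np.isfinite(h) and h > 0):
        raise InvalidArgumentError("refocus distance h must be positive")
    tf = _carrier_removed_transfer(holo.geometry.scaled(pad_factor), -h)
    obj = backpropagate(initial_wavefield(holo), h, pad_factor, _transfer=tf)
    return ReconstructionResult(np.abs(obj.values), np.angle(obj.values),
                                h=h, iterations_run=0)


def gs_reconstruct(holo: HologramFrame, h: float,
                   config: GSConfig | None = None) -> ReconstructionResult:
    """Iterative GS phase retrieval between sensor and object planes.

    Starting from √H at the sensor, each iteration backpropagates by h and
    applies the passivity constraint; between iterations the field is
    propagated forward and its amplitude replaced by √H.  With
    `record_misfit`, the RMS sensor-plane amplitude residual
    rms(|U| − √H), evaluated just before each amplitude replacement, is
    logged (a diagnostic, never a stopping rule).

    `n_iterations = 0` degenerates to a single backpropagation plus one
    clipping, as does `n_iterations = 1`.
    """
    config = config or GSConfig()
    if not (np.isfinite(h) and h > 0):
        raise InvalidArgumentError("refocus distance h must be positive")
    geom = holo.geometry
    measured = np.sqrt(holo.intensity)
    pf = config.pad_factor
    padded_geom = geom.scaled(pf)
    tf_back = _carrier_removed_transfer(padded_geom, -h)
    tf_fwd = _carrier_removed_transfer(padded_geom, +h)

    sensor = initial_wavefield(holo)
    trace: Optional[list[float]] = [] if config.record_misfit else None
    n_passes = max(config.n_iterations, 1)
    obj = None
    for i in range(n_passes):
        obj = apply_object_constraint(
            backpropagate(sensor, h, pf, _transfer=tf_back), config.clip_level)
        if i == n_passes - 1:
            break
        sensor = propagate(obj, h, pf, _transfer=tf_fwd)
        if trace is not None:
            resid = np.abs(sensor.values) - measured
            trace.append(float(np.sqrt(np.mean(resid**2))))
        sensor = apply_sensor_constraint(sensor, measured)
    return ReconstructionResult(np.abs(obj.values), np.angle(obj.values),
                                h=h, iterations_run=config.n_iterations,
                                misfit_trace=trace)


def sharpness_score(amplitude: np.ndarray) -> float:
    """Tamura coefficient of the gradient magnitude: √(std(g)/mean(g)).

    g = |∇amplitude| via central differences.  Larger means sharper; the
    score is invariant to constant offsets and returns 0 for a constant
    image.  A well-established focus metric for holographic refocusing.
    """
    amplitude = np.asarray(amplitude, dtype=np.float64)
    if not np.all(np.isfinite(amplitude)):
        raise InvalidArgumentError("amplitude must be finite")
    gy, gx = np.gradient(amplitude)
    g = np.hypot(gx, gy)
    m = float(g.mean())
    if m == 0.0:
        return 0.0
    return float(np.sqrt(g.std() / m))


def _bp_sharpness(holo: HologramFrame, h: float, pad_factor: int) -> float:
    return sharpness_score(single_backpropagation(holo, h, pad_factor).amplitude)


def autofocus(holo: HologramFrame, h_min: float, h_max: float, step: float,
              refine: bool = True, pad_factor: int = 2) -> FocusScan:
    """Select the refocus distance by maximising backpropagation sharpness.

    Evaluates the Tamura-of-gradient score of the single-backpropagation
    amplitude on the grid h_min..h_max (inclusive, spacing `step`); ties go
    to the smallest h.  With `refine`, a golden-section pass within ±step
    of the coarse optimum polishes the estimate and the refined candidate
    is appended to the scan.
    """
    if not (0 < h_min <= h_max):
        raise InvalidArgumentError("need 0 < h_min <= h_max")
    if not step > 0:
        raise InvalidArgumentError("step must be positive")
    candidates = list(np.arange(h_min, h_max + 0.5 * step, step))
    if not candidates:
        raise InvalidArgumentError("empty focus grid")
    scores = [_bp_sharpness(holo, h, pad_factor) for h in candidates]
    best_score = max(scores)
    best_h = candidates[scores.index(best_score)]  # first max = smallest h

    if refine and len(candidates) > 1:
        lo = max(h_min, best_h - step)
        hi = min(h_max, best_h + step)
        invphi = (math.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = _bp_sharpness(holo, c, pad_factor), _bp_sharpness(holo, d, pad_factor)
        for _ in range(24):
            if b - a < step / 50.0:
                break
            if fc >= fd:  # keep the left interval on ties (smaller h)
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = _bp_sharpness(holo, c, pad_factor)
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = _bp_sharpness(holo, d, pad_factor)
        h_ref = c if fc >= fd else d
        s_ref = fc if fc >= fd else fd
        candidates.append(float(h_ref))
        scores.append(float(s_ref))
        if s_ref > best_score or (s_ref == best_score and h_ref < best_h):
            best_h, best_score = float(h_ref), float(s_ref)
    return FocusScan(candidates=[float(c) for c in candidates],
                     scores=[float(s) for s in scores], best_h=float(best_h))


def twin_suppression_ratio(bp: ReconstructionResult, gs: ReconstructionResult,
                           object_mask: np.ndarray) -> float:
    """Background-noise ratio std(backprop bg) / std(GS bg).

    The background is the complement of the object mask eroded by 5 px (to
    keep grain edges and their immediate ramps out).  Values above 1 mean
    the GS loop produced a cleaner background, i.e. suppressed the twin
    image.
    """
    object_mask = np.asarray(object_mask, dtype=bool)
    if bp.amplitude.shape != gs.amplitude.shape or object_mask.shape != bp.amplitude.shape:
        raise InvalidArgumentError("shape mismatch between reconstructions and mask")
    background = ndimage.binary_erosion(~object_mask, iterations=5)
    if not background.any():
        raise DegenerateInputError("background region is empty after erosion")
    s_bp = float(bp.amplitude[background].std())
    s_gs = float(gs.amplitude[background].std())
    if s_bp == s_gs:
        return 1.0
    if s_gs == 0.0:
        return float("inf")
    return s_bp / s_gs
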