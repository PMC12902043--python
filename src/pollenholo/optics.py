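"""Scalar-diffraction propagation by the angular spectrum method.

A monochromatic field sampled on a regular grid is decomposed into plane
waves by a 2-D discrete Fourier transform, each component is multiplied by
the exact propagation phase factor

    exp(+i 2π d √(1/λ² − f_x² − f_y²)),

and the field is recomposed.  The square-root (non-paraxial) kernel is used
throughout: at the geometries this package targets (millimetre propagation
over a multi-millimetre sensor) the Fresnel approximation is not safely
deep-paraxial.  Spatial frequencies beyond the propagating band
(f_x² + f_y² > 1/λ²) are evanescent and are hard-zeroed, which prevents
exponential blow-up when propagating backwards.

Sign convention: forward propagation (object → sensor, positive distance)
uses the +i exponent.  Lengths are in micrometres, spatial frequencies in
cycles per micrometre; the frequency grid follows standard DFT ordering
with spacing 1/(n·pitch) per axis.  Coordinates are pixel-centred,
row-major, origin at the top-left corner.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.fft as _fft

from .exceptions import InvalidArgumentError

__all__ = [
    "FieldGeometry",
    "ComplexField",
    "TransferFunction",
    "make_transfer_function",
    "propagate",
    "backpropagate",
]


@dataclass(frozen=True)
class FieldGeometry:
    """Sampling grid shared by every optics operation.

    Parameters
    ----------
    n_x, n_y : int
        Pixel counts (columns, rows); each at least 2.
    pitch : float
        Pixel spacing in μm (2.0 for the Sony IMX334 sensor used here).
    wavelength : float
        Illumination wavelength in μm (0.658 for the red laser diode).

    Sub-Nyquist fringes (wavelength < 2*pitch) are physically meaningful
    and deliberately not forbidden; the geometry never silently resamples.
    """

    n_x: int
    n_y: int
    pitch: float = 2.0
    wavelength: float = 0.658

    def __post_init__(self) -> None:
        if self.n_x < 2 or self.n_y < 2:
            raise InvalidArgumentError("grid must be at least 2x2 pixels")
        if not (self.pitch > 0 and np.isfinite(self.pitch)):
            raise InvalidArgumentError("pitch must be positive and finite")
        if not (self.wavelength > 0 and np.isfinite(self.wavelength)):
            raise InvalidArgumentError("wavelength must be positive and finite")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape (rows, columns)."""
        return (self.n_y, self.n_x)

    def frequency_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Spatial-frequency grids (f_y, f_x) in cycles/μm, DFT ordering."""
        fx = _fft.fftfreq(self.n_x, d=self.pitch)
        fy = _fft.fftfreq(self.n_y, d=self.pitch)
        return fy[:, None], fx[None, :]

    def scaled(self, factor: int) -> "FieldGeometry":
        """Geometry of the same pitch enlarged `factor`-fold per axis."""
        return FieldGeometry(self.n_x * factor, self.n_y * factor,
                             self.pitch, self.wavelength)


@dataclass
class ComplexField:
    """Complex wavefield on a grid.

    `plane_offset` is the axial coordinate of the plane the field lives in,
    in μm relative to the sensor plane (negative towards the object).
    """

    geometry: FieldGeometry
    values: np.ndarray
    plane_offset: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != self.geometry.shape:
            raise InvalidArgumentError(
                f"values shape {self.values.shape} does not match geometry "
                f"{self.geometry.shape}")
        if not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("field values must be finite")

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    def copy(self) -> "ComplexField":
        return ComplexField(self.geometry, self.values.copy(), self.plane_offset)


@dataclass
class TransferFunction:
    """Angular-spectrum filter for one signed propagation distance.

    `values` are complex coefficients in DFT frequency ordering; unit
    modulus on the propagating band, exactly zero on the evanescent band.
    """

    geometry: FieldGeometry
    distance: float
    values: np.ndarray = dc_field(repr=False, default=None)


def make_transfer_function(geometry: FieldGeometry, distance: float) -> TransferFunction:
    """Build the angular-spectrum transfer function for a signed distance in μm.

    The kernel at frequency (f_x, f_y) is
    exp(i 2π distance √(1/λ² − f_x² − f_y²)) on the propagating band and 0
    outside it.  `transfer(-d)` is the complex conjugate of `transfer(+d)`.
    """
    if not np.isfinite(distance):
        raise InvalidArgumentError("propagation distance must be finite")
    fy, fx = geometry.frequency_grids()
    inv_lam2 = 1.0 / geometry.wavelength**2
    arg = inv_lam2 - fx**2 - fy**2
    values = np.zeros(geometry.shape, dtype=np.complex128)
    band = arg >= 0.0
    values[band] = np.exp(1j * 2.0 * np.pi * distance * np.sqrt(arg[band]))
    return TransferFunction(geometry=geometry, distance=distance, values=values)


def border_width(n_y: int, n_x: int, nominal: int = 8) -> int:
    """Width of the outer frame used for edge statistics.

    Nominally 8 px; shrinks on tiny grids so a border and interior both
    exist (a 4x4 frame gets a 1-px border).
    """
    return min(nominal, max(1, min(n_y, n_x) // 4))


def edge_mean_amplitude(values: np.ndarray, nominal: int = 8) -> float:
    """Mean modulus over the outer border frame of a 2-D array."""
    n_y, n_x = values.shape
    w = border_width(n_y, n_x, nominal)
    mask = np.zeros((n_y, n_x), dtype=bool)
    mask[:w, :] = mask[-w:, :] = True
    mask[:, :w] = mask[:, -w:] = True
    return float(np.mean(np.abs(values[mask])))


def _embed(values: np.ndarray, pad_factor: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Centre `values` in a grid enlarged pad_factor-fold per axis.

    The border is filled with the field's edge-mean amplitude (zero phase):
    zero-padding a unit-background hologram would create a spurious hard
    aperture edge, while background-fill keeps the surround seamless.
    """
    n_y, n_x = values.shape
    big = np.full((n_y * pad_factor, n_x * pad_factor),
                  edge_mean_amplitude(values), dtype=np.complex128)
    oy = (big.shape[0] - n_y) // 2
    ox = (big.shape[1] - n_x) // 2
    big[oy:oy + n_y, ox:ox + n_x] = values
    return big, (oy, ox)


def propagate(field: ComplexField, distance: float, pad_factor: int = 2,
              *, _transfer: TransferFunction | None = None) -> ComplexField:
    """Propagate a field by a signed axial distance (μm).

    The field is embedded in a pad_factor-enlarged grid (border filled with
    its edge-mean amplitude), transformed, multiplied by the angular
    spectrum kernel, transformed back and cropped.  `plane_offset` advances
    by `distance`.

    `_transfer` lets iterative callers reuse a precomputed kernel for the
    padded geometry; it must match the padded shape and the distance.
    """
    if not np.isfinite(distance):
        raise InvalidArgumentError("propagation distance must be finite")
    if not (isinstance(pad_factor, (int, np.integer)) and pad_factor >= 1):
        raise InvalidArgumentError("pad_factor must be a positive integer")
    geom = field.geometry
    if pad_factor == 1:
        work, (oy, ox) = field.values, (0, 0)
    else:
        work, (oy, ox) = _embed(field.values, pad_factor)
    if _transfer is None:
        _transfer = make_transfer_function(geom.scaled(pad_factor), distance)
    if _transfer.values.shape != work.shape:
        raise InvalidArgumentError("transfer function shape mismatch")
    out = _fft.ifft2(_fft.fft2(work) * _transfer.values)
    cropped = out[oy:oy + geom.n_y, ox:ox + geom.n_x]
    return ComplexField(geom, cropped, field.plane_offset + distance)


def backpropagate(field: ComplexField, distance: float, pad_factor: int = 2,
                  *, _transfer: TransferFunction | None = None) -> ComplexField:
    """Propagate towards the object plane: alias for `propagate(-distance)`.

    `distance` is the non-negative sensor-to-object separation in μm.
    """
    if not (np.isfinite(distance) and distance >= 0):
        raise InvalidArgumentError("backpropagation distance must be >= 0")
    return propagate(field, -distance, pad_factor, _transfer=_transfer)
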