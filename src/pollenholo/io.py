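"""File I/O: TIFF holograms and reconstructions, CSV records, PNG previews.

Holograms travel as single-channel, uncompressed, little-endian 16-bit
TIFFs holding 12-bit sensor counts (values above 4095 are rejected for raw
frames).  Reconstructed amplitudes are written as 16-bit TIFFs with the
clip level mapped linearly to 65535; phases as lossless 32-bit float
TIFFs.  Evaluation records use a fixed CSV schema with a mandatory header:
image_id, modality, evaluator, true_species, assigned_species.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .exceptions import InvalidArgumentError
from .optics import FieldGeometry
from .reconstruction import HologramFrame
from .stats import EvaluationRecord, records_from_dataframe, records_to_dataframe

__all__ = [
    "read_hologram", "write_hologram", "write_amplitude", "write_phase",
    "write_preview_png", "read_records_csv", "write_records_csv",
    "RECORD_COLUMNS",
]

RECORD_COLUMNS = ("image_id", "modality", "evaluator", "true_species",
                  "assigned_species")


def read_hologram(path, pitch: float = 2.0, wavelength: float = 0.658,
                  bit_depth: int = 12) -> HologramFrame:
    """Read a raw hologram from a single-channel TIFF.

    The container is 16-bit but the data must respect the sensor bit depth
    (≤ 4095 for 12-bit); larger values indicate a mis-scaled file and are
    rejected.
    """
    data = tifffile.imread(str(path))
    if data.ndim != 2:
        raise InvalidArgumentError(
            f"expected a single-channel 2-D image, got shape {data.shape}")
    data = data.astype(np.float64)
    full = 2**bit_depth - 1
    if data.max() > full:
        raise InvalidArgumentError(
            f"frame contains values above {full} and is not a valid "
            f"{bit_depth}-bit hologram")
    geometry = FieldGeometry(n_x=data.shape[1], n_y=data.shape[0],
                             pitch=pitch, wavelength=wavelength)
    return HologramFrame(geometry, data, bit_depth=bit_depth,
                         source_path=str(path))


def write_hologram(frame: HologramFrame, path) -> None:
    """Write sensor counts as an uncompressed little-endian uint16 TIFF."""
    counts = np.round(frame.intensity).astype("<u2")
    tifffile.imwrite(str(path), counts, compression=None)


def write_amplitude(amplitude: np.ndarray, path, clip_level: float = 1.0) -> None:
    """Write a reconstruction amplitude as uint16, clip_level → 65535."""
    scaled = np.clip(amplitude / clip_level, 0.0, 1.0) * 65535.0
    tifffile.imwrite(str(path), np.round(scaled).astype("<u2"), compression=None)


def write_phase(phase: np.ndarray, path) -> None:
    """Write a phase map (radians) as a lossless float32 TIFF."""
    tifffile.imwrite(str(path), phase.astype("<f4"), compression=None)


def write_preview_png(image: np.ndarray, path, vmax: Optional[float] = None) -> None:
    """Write an 8-bit PNG preview of a non-negative image."""
    import imageio.v3 as iio
    vmax = float(image.max()) if vmax is None else vmax
    if vmax <= 0:
        vmax = 1.0
    scaled = np.clip(image / vmax, 0.0, 1.0) * 255.0
    iio.imwrite(str(path), np.round(scaled).astype(np.uint8))


def read_records_csv(path) -> list[EvaluationRecord]:
    """Read evaluation records, validating the mandatory header."""
    df = pd.read_csv(path, dtype=str)
    for col in RECORD_COLUMNS:
        if col not in df.columns:
            raise InvalidArgumentError(f"records CSV is missing column {col!r}")
    if df.isna().any().any():
        bad = int(df.isna().any(axis=1).sum())
        raise InvalidArgumentError(f"records CSV contains {bad} malformed row(s)")
    return records_from_dataframe(df)


def write_records_csv(records: Sequence[EvaluationRecord], path) -> None:
    records_to_dataframe(records).to_csv(path, index=False)
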