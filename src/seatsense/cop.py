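"""Centre-of-Pressure (CoP) computation from the six seat pressure channels.

The CoP is the point of application of the resultant vertical seat-reaction
force: the force-weighted average of the sensor positions,

    CoP_x = sum_i f_i x_i / sum_i f_i,    CoP_y = sum_i f_i y_i / sum_i f_i,

with f_i the reading of sensor i and (x_i, y_i) its grid coordinate.  Its
displacement over time indexes postural sway, which is what the downstream
features quantify.  Because the f_i appear homogeneously, the CoP is
invariant to any positive rescaling of the forces — no calibration from raw
FSR readings to newtons is needed.

Samples whose total force is (near-)zero — an unoccupied seat — have no
defined CoP and are flagged invalid rather than yielding NaN; windows
containing such samples are dropped during feature extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import DEFAULT_GEOMETRY, CushionGeometry, RawStream, ValidationError

__all__ = ["CoPSeries", "compute_cop"]

#: Total-force threshold below which a sample counts as an empty seat.
DEFAULT_EMPTY_THRESHOLD = 1e-9


@dataclass
class CoPSeries:
    """Per-sample CoP coordinates on the seat grid, with a validity mask.

    Where ``valid`` is True, (cop_x, cop_y) is a convex combination of the
    sensor coordinates, so it lies inside their bounding box; with the
    default geometry both coordinates are in [-2, 2].  Where ``valid`` is
    False (empty seat) the coordinates are 0 by convention and must not be
    used.
    """

    cop_x: np.ndarray
    cop_y: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.cop_x)


def compute_cop(
    stream: RawStream,
    geometry: CushionGeometry = DEFAULT_GEOMETRY,
    empty_threshold: float = DEFAULT_EMPTY_THRESHOLD,
) -> CoPSeries:
    """Compute the CoP time series of a stream.

    Parameters
    ----------
    stream : validated raw stream (forces non-negative).
    geometry : the six sensor coordinates; must match the six force channels.
    empty_threshold : samples with total force <= this are flagged invalid.
    """
    if stream.fsr.shape[1] != len(geometry.coords):
        raise ValidationError(
            "geometry/channel count mismatch: "
            f"{len(geometry.coords)} coordinates vs {stream.fsr.shape[1]} channels"
        )
    total = stream.fsr.sum(axis=1)
    valid = total > empty_threshold
    safe_total = np.where(valid, total, 1.0)
    cop_x = np.where(valid, stream.fsr @ geometry.x / safe_total, 0.0)
    cop_y = np.where(valid, stream.fsr @ geometry.y / safe_total, 0.0)
    return CoPSeries(cop_x=cop_x, cop_y=cop_y, valid=valid)
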