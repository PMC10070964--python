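"""Per-pixel quality decoding and cloud/scene filtering.

Thermal products ship a bit-encoded quality-control (QC) band: bits 0-1 are
the mandatory QA flag (0 good, 1 produced but other quality, 2 not produced
due to clouds, 3 not produced), bits 2-3 the data-quality flag.  Optical
scenes instead carry a scene-classification layer (SCL) of small class
integers (cloud, cloud shadow, vegetation, water, ...).  Everything here
turns those layers into nodata masks before any science computation, and
decides scene eligibility from whole-scene cloud cover.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

from .grids import RasterLayer

__all__ = [
    "QCPolicy",
    "SceneMeta",
    "SCL_CLASSES",
    "decode_qc_bits",
    "decode_qc_layer",
    "apply_qc_mask",
    "apply_scl_mask",
    "scene_eligible",
]

#: Scene-classification class codes (Sentinel-2 L2A convention).
SCL_CLASSES = {
    "NO_DATA": 0,
    "SATURATED": 1,
    "DARK_AREA": 2,
    "CLOUD_SHADOW": 3,
    "VEGETATION": 4,
    "NOT_VEGETATED": 5,
    "WATER": 6,
    "UNCLASSIFIED": 7,
    "CLOUD_MEDIUM": 8,
    "CLOUD_HIGH": 9,
    "THIN_CIRRUS": 10,
    "SNOW": 11,
}

_DEFAULT_REJECTED_SCL = frozenset(
    {
        SCL_CLASSES["NO_DATA"],
        SCL_CLASSES["SATURATED"],
        SCL_CLASSES["CLOUD_SHADOW"],
        SCL_CLASSES["CLOUD_MEDIUM"],
        SCL_CLASSES["CLOUD_HIGH"],
        SCL_CLASSES["THIN_CIRRUS"],
    }
)


@dataclass(frozen=True)
class QCPolicy:
    """Quality filtering policy.

    ``accepted_mandatory_qa`` — 2-bit mandatory-QA codes retained (default
    {0, 1}: good quality plus produced-but-check-other-quality).
    ``accepted_scl_classes`` — SCL classes retained (default: everything
    except no-data/saturated, cloud shadow, medium/high-probability cloud
    and thin cirrus).
    ``cloud_cover_max_pct`` — scenes at or above this whole-scene cloud
    cover are not eligible (strict "lower than" comparison; default 80%).
    """

    accepted_mandatory_qa: frozenset = frozenset({0, 1})
    accepted_scl_classes: frozenset = frozenset(
        set(SCL_CLASSES.values()) - _DEFAULT_REJECTED_SCL
    )
    cloud_cover_max_pct: float = 80.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.cloud_cover_max_pct <= 100.0):
            raise ValueError("cloud_cover_max_pct must be in [0, 100]")
        if not self.accepted_mandatory_qa or not self.accepted_scl_classes:
            raise ValueError("accepted sets must be non-empty")
        object.__setattr__(
            self, "accepted_mandatory_qa", frozenset(self.accepted_mandatory_qa)
        )
        object.__setattr__(
            self, "accepted_scl_classes", frozenset(self.accepted_scl_classes)
        )


@dataclass(frozen=True)
class SceneMeta:
    scene_id: str
    acquisition_date: _dt.date
    cloud_cover_pct: float
    footprint: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.cloud_cover_pct <= 100.0):
            raise ValueError("cloud_cover_pct must be in [0, 100]")


def decode_qc_bits(qc_value: int) -> dict[str, int]:
    """Split an 8-bit QC code into its mandatory-QA and data-quality fields.

    Bits 0-1 carry the mandatory QA flag, bits 2-3 the data-quality flag.
    The upper four bits (emissivity/LST error classes) are returned raw and
    are not acted on by the default policy.
    """
    qc_value = int(qc_value)
    if not (0 <= qc_value <= 255):
        raise ValueError(f"QC value {qc_value} outside [0, 255]")
    return {
        "mandatory_qa": qc_value & 0b11,
        "data_quality": (qc_value >> 2) & 0b11,
        "raw_upper_bits": qc_value >> 4,
    }


def decode_qc_layer(qc_values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (mandatory_qa, data_quality) fields of a QC array."""
    arr = np.asarray(qc_values).astype(np.int64)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("QC values outside [0, 255]")
    return arr & 0b11, (arr >> 2) & 0b11


def _require_same_grid(a: RasterLayer, b: RasterLayer) -> None:
    if a.grid != b.grid:
        raise ValueError("layers must share a GridSpec")


def apply_qc_mask(
    layer: RasterLayer, qc_layer: RasterLayer, policy: QCPolicy = QCPolicy()
) -> RasterLayer:
    """Mask pixels whose mandatory-QA code is not accepted.

    Retained pixels are bitwise-unchanged.
    """
    _require_same_grid(layer, qc_layer)
    mandatory, _ = decode_qc_layer(np.where(qc_layer.nodata_mask, 0, qc_layer.values))
    rejected = ~np.isin(mandatory, list(policy.accepted_mandatory_qa))
    rejected |= qc_layer.nodata_mask
    return layer.replace(
        values=layer.values.copy(), nodata_mask=layer.nodata_mask | rejected
    )


def apply_scl_mask(
    layer: RasterLayer, scl_layer: RasterLayer, policy: QCPolicy = QCPolicy()
) -> RasterLayer:
    """Mask pixels whose scene-classification class is rejected."""
    _require_same_grid(layer, scl_layer)
    classes = np.where(scl_layer.nodata_mask, -1, scl_layer.values).astype(np.int64)
    accepted = np.isin(classes, list(policy.accepted_scl_classes))
    return layer.replace(
        values=layer.values.copy(), nodata_mask=layer.nodata_mask | ~accepted
    )


def scene_eligible(meta: SceneMeta, policy: QCPolicy = QCPolicy()) -> bool:
    """Whether a scene's cloud cover is strictly below the policy maximum."""
    return meta.cloud_cover_pct < policy.cloud_cover_max_pct
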