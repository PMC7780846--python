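"""Core containers shared across the pipeline.

Volumes are plain float arrays on a cubic voxel grid; the only metadata the
analysis needs is the isotropic spacing (mm) and which array axis is the
left-right axis (axis 0 throughout, by convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

#: array axis treated as left-right everywhere in the package
LR_AXIS = 0

EffectKind = Literal["intensity_shift", "volume_scale"]
EffectDriver = Literal["sex", "age", "pds", "ses", "mediator"]


@dataclass(frozen=True)
class BrainVolume:
    """A 3D scalar field on a cubic grid with isotropic spacing in mm."""

    data: np.ndarray
    spacing: float = 2.0

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim != 3 or len(set(data.shape)) != 1:
            raise ValueError(f"expected a cubic 3D grid, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("volume contains non-finite values")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "data", data)

    @property
    def grid(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class HemispherePair:
    """A volume together with its left-right mirror.

    Sex effects on brain structure are modelled as bilateral: the left
    hemisphere is flipped to create a second "right" hemisphere, and the
    model scores both copies.
    """

    native_right: BrainVolume
    flipped_left: BrainVolume

    def __post_init__(self) -> None:
        if self.native_right.data.shape != self.flipped_left.data.shape:
            raise ValueError("hemisphere copies must share the grid")
        if self.native_right.spacing != self.flipped_left.spacing:
            raise ValueError("hemisphere copies must share the spacing")


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effect injected into synthetic volumes.

    ``magnitude`` is in units of the voxel-noise SD for ``intensity_shift``
    and a fractional volume change for ``volume_scale``.  ``driver`` selects
    which subject covariate modulates the effect.
    """

    region_label: int
    effect_kind: EffectKind
    driver: EffectDriver
    magnitude: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.magnitude):
            raise ValueError("effect magnitude must be finite")
        if self.effect_kind not in ("intensity_shift", "volume_scale"):
            raise ValueError(f"unknown effect kind {self.effect_kind!r}")
        if self.driver not in ("sex", "age", "pds", "ses", "mediator"):
            raise ValueError(f"unknown effect driver {self.driver!r}")


@dataclass(frozen=True)
class Atlas:
    """Integer label volume plus the spherical-region geometry used to build it.

    ``regions`` maps each label to (list of centre coordinates, base radius);
    mirrored centres share one label so every region is bilateral.
    """

    labels: np.ndarray
    regions: dict[int, tuple[list[tuple[float, float, float]], float]]
    spacing: float = 2.0

    @property
    def grid(self) -> int:
        return self.labels.shape[0]

    @property
    def roi_labels(self) -> list[int]:
        return sorted(self.regions)


@dataclass
class SyntheticCohort:
    """Generated cohort: one volume per subject plus covariates and ground truth."""

    records: pd.DataFrame
    volumes: np.ndarray  # (n, G, G, G) float32
    atlas: Atlas
    truth: list[EffectSpec] = field(default_factory=list)
    seed: int = 0
    spacing: float = 2.0

    def __post_init__(self) -> None:
        if len(self.records) != len(self.volumes):
            raise ValueError("one volume per record required")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def grid(self) -> int:
        return self.volumes.shape[1]
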