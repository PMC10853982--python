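"""Fixel template container.

A *fixel* is a single fibre population within a voxel; voxels crossed by
several bundles hold several fixels (at most three here, mirroring common
fibre-orientation segmentation limits). The template is shared by every
subject of a study: each subject contributes scalar values (fibre density,
warp Jacobians) *per template fixel*. Tract membership follows a 20-tract
white-matter parcellation in the style of the JHU tractography atlas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: The 20 white-matter tract labels (JHU-style): bilateral anterior thalamic
#: radiation, corticospinal tract, cingulum (cingulate gyrus), cingulum
#: (hippocampal), inferior fronto-occipital fasciculus, inferior longitudinal
#: fasciculus, superior longitudinal fasciculus, SLF temporal part, uncinate
#: fasciculus, plus forceps major and forceps minor.
TRACT_NAMES: tuple[str, ...] = (
    "ATR_L", "ATR_R",
    "CGC_L", "CGC_R",
    "CGH_L", "CGH_R",
    "CST_L", "CST_R",
    "Fmajor", "Fminor",
    "IFOF_L", "IFOF_R",
    "ILF_L", "ILF_R",
    "SLF_L", "SLF_R",
    "SLFT_L", "SLFT_R",
    "UNC_L", "UNC_R",
)

MAX_FIXELS_PER_VOXEL = 3


@dataclass
class FixelTemplate:
    """Shared fixel template: voxel grid, fixels and streamlines.

    Attributes
    ----------
    grid_shape:
        Voxel grid dimensions (nx, ny, nz); all coordinates are 0-based.
    voxel_size_mm:
        Isotropic voxel edge length in millimetres.
    voxels:
        ``(F, 3)`` int array, voxel index triple of each fixel.
    directions:
        ``(F, 3)`` float array of unit direction vectors. Directions are
        antipodally symmetric: ``v`` and ``-v`` denote the same fixel.
    tracts:
        length-``F`` array of tract labels (members of :data:`TRACT_NAMES`).
    streamlines:
        list of 1-D int arrays, each an ordered sequence of fixel ids.
    """

    grid_shape: tuple[int, int, int]
    voxel_size_mm: float
    voxels: np.ndarray
    directions: np.ndarray
    tracts: np.ndarray
    streamlines: list[np.ndarray] = field(default_factory=list)

    @property
    def n_fixels(self) -> int:
        return len(self.voxels)

    def tract_fixel_ids(self, tract: str) -> np.ndarray:
        """0-based fixel ids belonging to *tract*, in id order."""
        return np.flatnonzero(self.tracts == tract)

    def voxel_fixel_counts(self) -> dict[tuple[int, int, int], int]:
        """Number of fixels in each occupied voxel."""
        counts: dict[tuple[int, int, int], int] = {}
        for v in map(tuple, self.voxels):
            counts[v] = counts.get(v, 0) + 1
        return counts

    def fixels_in_voxels(self, voxel_set) -> np.ndarray:
        """Boolean mask over fixels whose voxel is in *voxel_set*."""
        vs = {tuple(int(c) for c in v) for v in voxel_set}
        return np.array([tuple(v) in vs for v in self.voxels], dtype=bool)

    def validate(self) -> None:
        """Enforce the template invariants; raise ValidationError on breach."""
        if self.voxels.shape != (self.n_fixels, 3):
            raise ValidationError("voxels must be an (F, 3) array")
        if self.directions.shape != (self.n_fixels, 3):
            raise ValidationError("directions must be an (F, 3) array")
        if np.any(self.voxels < 0) or np.any(
            self.voxels >= np.asarray(self.grid_shape)
        ):
            raise ValidationError("fixel voxel indices outside the grid")
        norms = np.linalg.norm(self.directions, axis=1)
        bad = np.flatnonzero(np.abs(norms - 1.0) > 1e-9)
        if bad.size:
            raise ValidationError(
                f"non-unit direction for fixel ids {bad[:5].tolist()}"
            )
        unknown = set(map(str, self.tracts)) - set(TRACT_NAMES)
        if unknown:
            raise ValidationError(
                f"unknown tract labels {sorted(unknown)}; "
                f"valid labels: {list(TRACT_NAMES)}"
            )
        missing = set(TRACT_NAMES) - set(map(str, self.tracts))
        if missing:
            raise ValidationError(f"tracts without fixels: {sorted(missing)}")
        for count in self.voxel_fixel_counts().values():
            if count > MAX_FIXELS_PER_VOXEL:
                raise ValidationError(
                    f"voxel with {count} fixels exceeds the "
                    f"{MAX_FIXELS_PER_VOXEL}-fixel limit"
                )
        for sl in self.streamlines:
            if len(sl) == 0:
                raise ValidationError("empty streamline")
            if np.any(sl < 0) or np.any(sl >= self.n_fixels):
                raise ValidationError("streamline references unknown fixel id")
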