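"""Fibre-specific fixel metrics: FC from warp Jacobians, logFC, FDC.

Fibre density (FD) is a microstructural input (proportional to intra-axonal
volume of the fixel's fibre population). Fibre cross-section (FC) measures
the macroscopic change in a bundle's cross-sectional area induced by the
subject-to-template warp: for the local Jacobian J and fibre direction v,

    FC = det(J) / ||J v||

(volume scaling divided by length scaling along the fibre equals the scaling
of the area of a perpendicular cross-section; exact for affine maps).
FC is analysed on the natural-log scale; FDC = FD * FC combines micro- and
macrostructure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidFixelError, InvalidWarpError
from .simulate import SubjectFixelData
from .template import FixelTemplate


@dataclass
class FixelMetrics:
    """Per-fixel metric vectors for one subject/timepoint."""

    subject_id: str
    timepoint: int
    fd: np.ndarray
    fc: np.ndarray
    logfc: np.ndarray
    fdc: np.ndarray


def compute_fc(jacobian: np.ndarray, direction: np.ndarray) -> float:
    """Fibre cross-section change of a single fixel.

    Parameters
    ----------
    jacobian:
        3x3 local Jacobian of the subject-to-template warp; must have
        positive determinant (orientation-preserving, non-singular).
    direction:
        Unit fibre direction; antipodally symmetric (v and -v equivalent).
    """
    jacobian = np.asarray(jacobian, dtype=float)
    direction = np.asarray(direction, dtype=float)
    nv = np.linalg.norm(direction)
    if nv < 1e-12:
        raise InvalidFixelError("zero fixel direction")
    if abs(nv - 1.0) > 1e-9:
        raise InvalidFixelError(f"fixel direction norm {nv} != 1")
    det = np.linalg.det(jacobian)
    if det <= 0:
        raise InvalidWarpError(
            f"Jacobian determinant {det} <= 0 (singular or reflecting warp)")
    return float(det / np.linalg.norm(jacobian @ direction))


def compute_fc_many(jacobians: np.ndarray, directions: np.ndarray) -> np.ndarray:
    """Vectorized :func:`compute_fc` over ``(F, 3, 3)`` and ``(F, 3)``."""
    jacobians = np.asarray(jacobians, dtype=float)
    directions = np.asarray(directions, dtype=float)
    norms = np.linalg.norm(directions, axis=1)
    if np.any(norms < 1e-12):
        raise InvalidFixelError("zero fixel direction")
    if np.any(np.abs(norms - 1.0) > 1e-9):
        raise InvalidFixelError("non-unit fixel direction")
    dets = np.linalg.det(jacobians)
    if np.any(dets <= 0):
        bad = int(np.flatnonzero(dets <= 0)[0])
        raise InvalidWarpError(
            f"Jacobian determinant <= 0 at fixel {bad} "
            "(singular or reflecting warp)")
    jv = np.einsum("fij,fj->fi", jacobians, directions)
    return dets / np.linalg.norm(jv, axis=1)


def compute_fdc(fd: float, fc: float) -> float:
    """Combined fibre density and cross-section, FDC = FD * FC."""
    if fd < 0:
        raise InvalidFixelError("FD must be >= 0")
    if fc <= 0:
        raise InvalidWarpError("FC must be > 0")
    return fd * fc


def fixel_metrics(data: SubjectFixelData,
                  template: FixelTemplate) -> FixelMetrics:
    """Derive FC (from Jacobians if not precomputed), logFC and FDC."""
    fd = np.asarray(data.fd, dtype=float)
    if np.any(fd < 0):
        raise InvalidFixelError("FD must be >= 0")
    fc = (np.asarray(data.fc, dtype=float) if data.fc is not None
          else compute_fc_many(data.jacobians, template.directions))
    return FixelMetrics(
        subject_id=data.subject_id, timepoint=data.timepoint,
        fd=fd, fc=fc, logfc=np.log(fc), fdc=fd * fc,
    )


def aggregate_tracts(metrics: FixelMetrics | list[FixelMetrics],
                     template: FixelTemplate,
                     lesion_mask=None,
                     fc_aggregate: str = "logfc") -> pd.DataFrame:
    """Average fixel metrics over each atlas tract.

    Parameters
    ----------
    metrics:
        one or several :class:`FixelMetrics` covering all template fixels.
    lesion_mask:
        optional voxel set (iterable of (i, j, k)); fixels sitting in masked
        voxels are excluded before averaging (lesions live in voxel space,
        so a lesioned voxel removes all its fixels). For per-subject masks
        pass a dict ``subject_id -> voxel set``.
    fc_aggregate:
        ``"logfc"`` (default; FC is analysed on the log scale) or ``"fc"``.

    Returns
    -------
    DataFrame with columns subject_id, timepoint, tract, mean_fd,
    mean_logfc (or mean_fc), mean_fdc, n_fixels_used. Tracts with zero
    surviving fixels are omitted and a warning is emitted.
    """
    if fc_aggregate not in ("logfc", "fc"):
        raise ValueError("fc_aggregate must be 'logfc' or 'fc'")
    if isinstance(metrics, FixelMetrics):
        metrics = [metrics]
    tract_ids = {t: template.tract_fixel_ids(t)
                 for t in np.unique(template.tracts)}
    fc_col = f"mean_{fc_aggregate}"
    rows = []
    for m in metrics:
        if len(m.fd) != template.n_fixels:
            raise InvalidFixelError(
                f"metrics for {m.subject_id} do not cover all "
                f"{template.n_fixels} template fixels")
        if isinstance(lesion_mask, dict):
            mask_vox = lesion_mask.get(m.subject_id)
        else:
            mask_vox = lesion_mask
        keep = np.ones(template.n_fixels, dtype=bool)
        if mask_vox is not None and len(mask_vox):
            keep = ~template.fixels_in_voxels(mask_vox)
        fcvals = m.logfc if fc_aggregate == "logfc" else m.fc
        for tract, ids in tract_ids.items():
            use = ids[keep[ids]]
            if use.size == 0:
                warnings.warn(
                    f"tract {tract} has no surviving fixels after lesion "
                    f"masking for subject {m.subject_id}; row omitted",
                    stacklevel=2)
                continue
            rows.append({
                "subject_id": m.subject_id, "timepoint": m.timepoint,
                "tract": str(tract),
                "mean_fd": float(m.fd[use].mean()),
                fc_col: float(fcvals[use].mean()),
                "mean_fdc": float(m.fdc[use].mean()),
                "n_fixels_used": int(use.size),
            })
    return pd.DataFrame(rows)
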