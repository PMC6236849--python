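"""Diaphragm tracking and closest-phase pairing between 4D-CT and 4D-CBCT.

Before deformable registration, each daily 4D-CBCT phase is paired with the
planning 4D-CT phase whose diaphragm sits at the closest superior-inferior
position, which minimizes the anatomic difference the registration has to
explain.  The diaphragm position of a phase is read from a lung mask: for
every axial column through the lung the most inferior lung voxel is found, and
the diaphragm is the mean SI coordinate of these column minima over the
central half of each lung's columns (central by in-plane distance to that
lung's column centroid, which rejects thin lateral columns).

Lung masks are segmented per phase with an automatic three-class Otsu
threshold (air / lung / soft tissue), which is invariant to the global
intensity scale and offset a CBCT acquires relative to CT; a fixed HU
threshold can be supplied instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu

from .grids import Phase4DSet, ROIMask, ScalarGrid, mask_from_bool


@dataclass
class PhasePairing:
    """CBCT-phase -> CT-phase assignment with the diaphragm positions used."""

    pairs: list[tuple[int, int]]      # (ct_phase_index, cbct_phase_index)
    diaphragm_ct: list[float]         # per CT phase, mm
    diaphragm_cbct: list[float]       # per CBCT phase, mm

    def ct_phase_for(self, cbct_phase: int) -> int:
        for ct_i, cb_i in self.pairs:
            if cb_i == cbct_phase:
                return ct_i
        raise KeyError(f"CBCT phase {cbct_phase} not in pairing")

    def total_cost_mm(self) -> float:
        return float(sum(abs(self.diaphragm_ct[ct] - self.diaphragm_cbct[cb])
                         for ct, cb in self.pairs))


def segment_lungs(image: ScalarGrid, threshold_hu: float | None = None,
                  region: ROIMask | None = None) -> ROIMask:
    """Binary lung mask from an HU-valued image.

    With ``threshold_hu=None`` the air/lung and lung/soft thresholds are found
    by three-class Otsu on the intensity histogram; otherwise lung is every
    voxel between the 5th-percentile (air) midpoint and the fixed threshold.
    ``region`` restricts the search (e.g. a dilated planning lung contour).
    """
    vals = image.values
    if threshold_hu is None:
        t_air, t_soft = threshold_multiotsu(vals.ravel(), classes=3)
        lung = (vals > t_air) & (vals < t_soft)
    else:
        t_air = np.percentile(vals, 5) / 2.0 + threshold_hu / 2.0
        lung = (vals > t_air) & (vals < threshold_hu)
    if region is not None:
        grown = ndimage.binary_dilation(region.mask, iterations=3)
        lung &= grown
    # drop partial-volume shells at air/soft interfaces and noise speckle:
    # a one-voxel opening erases thin structures, then only components of
    # appreciable size survive
    lung = ndimage.binary_opening(lung)
    labels, n_lab = ndimage.label(lung)
    if n_lab:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        keep = np.flatnonzero(counts >= max(8, counts.max() // 20))
        lung = np.isin(labels, keep)
    return mask_from_bool(image.geometry, lung, "LUNGS_AUTO", "OAR")


def diaphragm_position(phase: ScalarGrid, lung_mask: ROIMask) -> float:
    """Superior-inferior diaphragm position (mm) of one phase image.

    Deterministic: depends only on the lung mask geometry, not intensities.
    """
    mask = lung_mask.mask
    if not mask.any():
        raise ValueError("lung mask is empty")
    geom = phase.geometry
    has_lung = mask.any(axis=2)
    min_idx = np.argmax(mask, axis=2)  # first True along z = most inferior voxel
    z_coords = geom.axis_coords(2)

    cols = np.array(np.nonzero(has_lung)).T  # (n_cols, 2) in-plane indices
    labels, n_lab = ndimage.label(has_lung)
    minima = []
    for lab in range(1, n_lab + 1):
        sel = labels[cols[:, 0], cols[:, 1]] == lab
        sub = cols[sel]
        centroid = sub.mean(axis=0)
        d2 = np.sum((sub - centroid) ** 2, axis=1)
        order = np.argsort(d2, kind="stable")
        keep = sub[order[: max(1, len(sub) // 2)]]
        minima.append(z_coords[min_idx[keep[:, 0], keep[:, 1]]])
    return float(np.concatenate(minima).mean())


def match_phases(ct4d: Phase4DSet, cbct4d: Phase4DSet,
                 lung_mask: ROIMask | None = None,
                 threshold_hu: float | None = None) -> PhasePairing:
    """Pair every CBCT phase with the CT phase of closest diaphragm position.

    A cosine breathing trace visits every non-extreme diaphragm height twice
    (phases k and n-k), so exact distance ties are common; among tied CT
    phases the one with the CBCT phase's own index is preferred, then the
    smaller index.  Many CBCT phases may share one CT phase.  ``lung_mask``
    (planning lung contour) restricts the per-phase automatic lung
    segmentation if provided.
    """
    d_ct = [diaphragm_position(ph, segment_lungs(ph, threshold_hu, lung_mask))
            for ph in ct4d]
    d_cbct = [diaphragm_position(ph, segment_lungs(ph, threshold_hu, lung_mask))
              for ph in cbct4d]
    pairs = []
    for cb_i, d in enumerate(d_cbct):
        diffs = np.array([abs(dc - d) for dc in d_ct])
        tied = np.flatnonzero(diffs <= diffs.min() + 1e-12)
        ct_i = int(cb_i) if cb_i in tied else int(tied[0])
        pairs.append((ct_i, cb_i))
    return PhasePairing(pairs=pairs, diaphragm_ct=d_ct, diaphragm_cbct=d_cbct)
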