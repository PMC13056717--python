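"""Region-wise GMV feature extraction from voxel maps, an atlas and a GM mask.

Two complementary feature sets are produced from spatially normalized
grey-matter-volume maps: the per-region mean GMV (input of the global
brain-age model) and the per-region voxel-wise GMV signature (input of the
regional models).  Voxels are taken in C scan order over the volume so that
voxel-feature columns correspond across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GmMask", "AtlasVolume", "RegionFeatureSet",
           "build_gm_mask", "extract_features", "AlignmentError"]


class AlignmentError(ValueError):
    """Volumes do not share a grid shape and affine."""


def _as_array_and_affine(vol, affine=None):
    """Accept a nibabel image, a path, or a plain array (+ optional affine)."""
    if hasattr(vol, "get_fdata"):
        return np.asanyarray(vol.dataobj), vol.affine
    if isinstance(vol, (str, bytes)) or hasattr(vol, "__fspath__"):
        import nibabel as nib
        img = nib.load(vol)
        return np.asanyarray(img.dataobj), img.affine
    arr = np.asarray(vol)
    return arr, (np.eye(4) if affine is None else np.asarray(affine))


@dataclass
class GmMask:
    data: np.ndarray               # boolean volume
    threshold: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, bool)
        if not self.data.any():
            raise ValueError("grey-matter mask is empty (no voxel above threshold)")


@dataclass
class AtlasVolume:
    data: np.ndarray               # integer labels, 0 = background
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    label_names: dict[int, str] | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("atlas volume must contain integer labels")
            self.data = rounded.astype(np.int64)
        if (self.data < 0).any():
            raise ValueError("atlas labels must be non-negative integers")

    @property
    def labels(self) -> np.ndarray:
        labs = np.unique(self.data)
        return labs[labs > 0]


@dataclass
class RegionFeatureSet:
    """Per-subject region means plus per-region voxel matrices, fixed label order."""

    region_means: np.ndarray               # (n_subjects, n_regions)
    voxel_features: dict[int, np.ndarray]  # label -> (n_subjects, n_voxels)
    region_labels: np.ndarray              # retained labels, ascending
    dropped_regions: list[int] = field(default_factory=list)

    def voxel_counts(self) -> dict[int, int]:
        return {lab: m.shape[1] for lab, m in self.voxel_features.items()}


def build_gm_mask(mean_probability_map, threshold: float = 0.2,
                  affine=None) -> GmMask:
    """Binary GM mask: voxels with probability strictly above ``threshold``.

    The strict inequality excludes boundary voxels at exactly the threshold
    ("exclude low-probability" voxels).
    """
    prob, aff = _as_array_and_affine(mean_probability_map, affine)
    prob = np.asarray(prob, float)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    return GmMask(prob > threshold, threshold=float(threshold), affine=aff)


def extract_features(gmv_maps, atlas: AtlasVolume, mask: GmMask) -> RegionFeatureSet:
    """Extract region means and voxel-wise signatures for every subject.

    Parameters
    ----------
    gmv_maps : sequence of images/paths/arrays, or a (n_subjects, *grid) array
    atlas : integer-labelled parcellation on the same grid
    mask : GM inclusion mask on the same grid

    Regions with zero voxels surviving the mask are dropped from both feature
    sets and listed in ``dropped_regions`` (never silently imputed).
    """
    arrays = []
    if isinstance(gmv_maps, np.ndarray) and gmv_maps.ndim == atlas.data.ndim + 1:
        arrays = [(gmv_maps[i], atlas.affine) for i in range(gmv_maps.shape[0])]
    else:
        arrays = [_as_array_and_affine(m) for m in gmv_maps]
    if not arrays:
        raise ValueError("no GMV maps provided")

    shape = atlas.data.shape
    if mask.data.shape != shape:
        raise AlignmentError(f"mask shape {mask.data.shape} != atlas shape {shape}")
    if not np.allclose(mask.affine, atlas.affine, atol=1e-6):
        raise AlignmentError("mask affine does not match atlas affine")
    for i, (arr, aff) in enumerate(arrays):
        if arr.shape != shape:
            raise AlignmentError(f"GMV map {i} shape {arr.shape} != atlas shape {shape}")
        if not np.allclose(aff, atlas.affine, atol=1e-6):
            raise AlignmentError(f"GMV map {i} affine does not match atlas affine")

    data = np.stack([np.asarray(a, float).ravel(order="C") for a, _ in arrays])
    atlas_flat = atlas.data.ravel(order="C")
    mask_flat = mask.data.ravel(order="C")

    kept_labels, dropped = [], []
    voxel_features: dict[int, np.ndarray] = {}
    means = []
    for lab in atlas.labels:
        idx = np.flatnonzero((atlas_flat == lab) & mask_flat)
        if idx.size == 0:
            dropped.append(int(lab))
            continue
        block = data[:, idx]
        if np.isnan(block).any():
            raise ValueError(f"NaN voxel values inside region {lab}")
        voxel_features[int(lab)] = block
        means.append(block.mean(axis=1))
        kept_labels.append(int(lab))
    if dropped:
        warnings.warn(f"{len(dropped)} region(s) fully removed by the GM mask: "
                      f"{dropped[:10]}{'...' if len(dropped) > 10 else ''}")
    if not kept_labels:
        raise ValueError("no region survived the mask")
    return RegionFeatureSet(
        region_means=np.column_stack(means),
        voxel_features=voxel_features,
        region_labels=np.asarray(kept_labels),
        dropped_regions=dropped,
    )
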