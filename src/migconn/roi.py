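"""Seed-to-network connectivity for hypothalamus, dorsal raphe nucleus
(DRN), and periaqueductal gray (PAG).

Seed regions are spherical masks around literature MNI centroids (the
hypothalamus as a migraine generator, the PAG as a pain-modulatory center,
and the DRN as the main serotonergic center).  The mean time series of each
seed is correlated with the target network node's time series per subject,
Fisher z-transformed, and the group contrast is tested with the permutation
machinery, FDR-corrected across the seed family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from nibabel.affines import apply_affine

from .inference import PermutationResult, permutation_group_test

__all__ = [
    "RoiSpec",
    "DEFAULT_ROIS",
    "build_sphere_mask",
    "extract_mean_timeseries",
    "seed_network_edges",
]


@dataclass(frozen=True)
class RoiSpec:
    name: str
    centroid_mni_mm: tuple[float, float, float]
    radius_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius_mm must be positive")


#: Literature MNI centroids of the three seed regions (mm).
DEFAULT_ROIS: tuple[RoiSpec, ...] = (
    RoiSpec("hypothalamus", (0.0, -4.0, -9.0)),
    RoiSpec("pag", (1.0, -31.0, -9.0)),
    RoiSpec("drn", (1.0, -32.0, -17.0)),
)


def build_sphere_mask(
    spec: RoiSpec, affine: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    """Boolean mask of voxels whose center lies within the ROI sphere.

    ``affine`` maps voxel indices to world (MNI) millimetre coordinates.
    Raises if no voxel center falls inside the sphere.
    """
    ijk = np.indices(shape).reshape(3, -1).T
    xyz = apply_affine(np.asarray(affine, float), ijk)
    dist2 = ((xyz - np.asarray(spec.centroid_mni_mm)) ** 2).sum(axis=1)
    mask = (dist2 <= spec.radius_mm**2).reshape(shape)
    if not mask.any():
        raise ValueError(
            f"ROI {spec.name!r}: no voxel center within {spec.radius_mm} mm "
            f"of {spec.centroid_mni_mm}"
        )
    return mask


def extract_mean_timeseries(volumes: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-frame mean over mask voxels of an (X, Y, Z, T) run."""
    volumes = np.asarray(volumes, float)
    mask = np.asarray(mask, bool)
    if volumes.shape[:-1] != mask.shape:
        raise ValueError(
            f"grid mismatch: volumes {volumes.shape[:-1]} vs mask {mask.shape}"
        )
    if not mask.any():
        raise ValueError("empty mask")
    return volumes[mask].mean(axis=0)


@dataclass
class SeedContrast:
    """Per-subject Fisher-z seed couplings and their group contrast."""

    z_table: pd.DataFrame  # subjects x ROIs
    result: PermutationResult


def seed_network_edges(
    roi_series: Mapping[str, np.ndarray],
    node_series: np.ndarray,
    groups,
    n_permutations: int = 5000,
    q: float = 0.05,
    seed: int | None = None,
) -> SeedContrast:
    """Seed-to-node coupling per subject and its EM-vs-CM contrast.

    ``roi_series`` maps each ROI name to an (n_subjects, T) array;
    ``node_series`` is the target network node's (n_subjects, T) series.
    Per subject, the Pearson correlation between ROI and node is Fisher
    z-transformed; the group difference is then tested by permutation with
    FDR correction across the ROI family.
    """
    node = np.asarray(node_series, float)
    names = list(roi_series)
    n, T = node.shape
    z = np.empty((n, len(names)))
    for j, name in enumerate(names):
        series = np.asarray(roi_series[name], float)
        if series.shape != node.shape:
            raise ValueError(
                f"ROI {name!r}: series shape {series.shape} does not match "
                f"node series {node.shape}"
            )
        for i in range(n):
            r = np.corrcoef(series[i], node[i])[0, 1]
            if abs(r) >= 1.0 - 1e-12:
                raise ValueError(
                    f"degenerate coupling |r| ~ 1 for ROI {name!r}, "
                    f"subject {i}: Fisher z diverges"
                )
            z[i, j] = np.arctanh(r)
    z_table = pd.DataFrame(z, columns=names)
    result = permutation_group_test(
        z_table, groups, n_permutations=n_permutations, q=q, seed=seed
    )
    return SeedContrast(z_table=z_table, result=result)
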