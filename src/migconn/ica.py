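"""Network-node definition by temporal-concatenation group ICA.

The preprocessed runs of all subjects are concatenated along time and a
spatial independent component analysis is performed: voxels are treated as
samples and time points as features, so the recovered sources are K spatial
maps with an associated group-level time course each.  Subject-specific node
time series are obtained by dual-regression stage 1 (per-frame least-squares
loadings of the group maps).  Components are classified as signal or noise
by their best absolute spatial correlation against a set of reference
network templates, with 0.25 as the decision threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import FastICA
from sklearn.utils.validation import check_is_fitted, check_random_state

__all__ = [
    "GroupICA",
    "ComponentLabel",
    "classify_components",
    "subregion_importance",
    "match_components",
]


def _to_timeseries_matrix(volumes: np.ndarray) -> tuple[np.ndarray, tuple]:
    """(..., T) volumes or (T, V) matrix -> (T, V) matrix + spatial shape."""
    arr = np.asarray(volumes, dtype=float)
    if arr.ndim == 2:  # already (T, V)
        return arr, (arr.shape[1],)
    spatial = arr.shape[:-1]
    return arr.reshape(-1, arr.shape[-1]).T, spatial


class GroupICA(BaseEstimator, TransformerMixin):
    """Spatial group ICA on temporally concatenated runs.

    Parameters
    ----------
    n_components : int
        Number of components K (fixed, configured dimensionality).
    random_state : int
        Seed for the stochastic unmixing initialization; results are
        deterministic given the seed, with component sign fixed so each
        map's maximum-magnitude voxel loads positively.
    max_iter : int
        FastICA iteration cap.

    Attributes
    ----------
    components_ : (K, V) spatial maps.
    zmaps_ : (K, V) z-scored maps (loadings standardized across voxels).
    mixing_ : (sum_T, K) concatenated group time courses.
    spatial_shape_ : grid shape the maps live on.
    """

    def __init__(self, n_components: int = 7, random_state: int = 0,
                 max_iter: int = 1000, tol: float = 1e-6):
        self.n_components = n_components
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X: Sequence[np.ndarray], y=None) -> "GroupICA":
        """Fit on a list of subject runs (each (..., T) or (T, V))."""
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")
        mats, shapes = zip(*(_to_timeseries_matrix(v) for v in X))
        if len(set(shapes)) != 1:
            raise ValueError("subjects are not on a common voxel grid")
        # per-subject voxelwise demeaning before concatenation
        concat = np.vstack([m - m.mean(axis=0, keepdims=True) for m in mats])
        if self.n_components > min(concat.shape):
            raise ValueError(
                f"n_components={self.n_components} exceeds the rank bound "
                f"min{concat.shape} of the concatenated data"
            )
        ica = FastICA(
            n_components=self.n_components,
            random_state=check_random_state(self.random_state),
            max_iter=self.max_iter,
            tol=self.tol,
            whiten="unit-variance",
        )
        sources = ica.fit_transform(concat.T)  # voxels as samples
        maps = sources.T  # (K, V)
        mixing = ica.mixing_  # (sum_T, K)
        # sign convention: peak-magnitude voxel of each map is positive
        for k in range(self.n_components):
            if maps[k, np.argmax(np.abs(maps[k]))] < 0:
                maps[k] = -maps[k]
                mixing[:, k] = -mixing[:, k]
        self.components_ = maps
        self.zmaps_ = (maps - maps.mean(axis=1, keepdims=True)) / maps.std(
            axis=1, keepdims=True
        )
        self.mixing_ = mixing
        self.spatial_shape_ = shapes[0]
        self.order_ = np.arange(self.n_components)
        return self

    def transform(self, volumes: np.ndarray) -> np.ndarray:
        """Dual-regression stage 1: subject node time series.

        Each frame's voxel vector is regressed on the K group maps; the
        least-squares loadings form the subject's T x K node series.
        """
        check_is_fitted(self, "components_")
        mat, shape = _to_timeseries_matrix(volumes)
        if np.prod(shape) != self.components_.shape[1]:
            raise ValueError("subject grid does not match the component grid")
        G = self.components_.T  # (V, K)
        if np.linalg.matrix_rank(G) < self.n_components:
            raise ValueError("rank-deficient spatial map matrix")
        loadings, *_ = np.linalg.lstsq(G, mat.T, rcond=None)
        return loadings.T  # (T, K)


@dataclass(frozen=True)
class ComponentLabel:
    index: int
    label: str  # 'signal' | 'noise'
    template: str | None
    correlation: float
    heuristics: dict = field(default_factory=dict)


def classify_components(
    zmaps: np.ndarray,
    templates: Mapping[str, np.ndarray],
    threshold: float = 0.25,
    *,
    spatial_shape: tuple | None = None,
    mixing: np.ndarray | None = None,
    tr_s: float | None = None,
) -> list[ComponentLabel]:
    """Label components as signal or noise by template cross-correlation.

    A component is noise iff its maximum absolute spatial correlation over
    the reference templates falls below ``threshold`` (default 0.25).
    Advisory heuristics are reported alongside but never decide the label:
    the fraction of |z| loading on the volume's boundary ring (when the grid
    shape is known) and the high-frequency (> 0.1 Hz) fraction of the
    component's time-course power (when the mixing matrix and TR are given).
    """
    if not templates:
        raise ValueError("template set is empty")
    zmaps = np.atleast_2d(np.asarray(zmaps, dtype=float))
    names = list(templates)
    tmpl = np.vstack([np.asarray(templates[n], float).ravel() for n in names])
    if tmpl.shape[1] != zmaps.shape[1]:
        raise ValueError("templates are not on the analysis grid")
    labels = []
    for k, z in enumerate(zmaps):
        r = np.array([np.corrcoef(z, t)[0, 1] for t in tmpl])
        best = int(np.argmax(np.abs(r)))
        is_signal = abs(r[best]) >= threshold
        heur: dict[str, float] = {}
        if spatial_shape is not None and len(spatial_shape) == 3:
            vol = np.abs(z).reshape(spatial_shape)
            interior = np.zeros(spatial_shape, bool)
            interior[1:-1, 1:-1, 1:-1] = True
            heur["edge_fraction"] = float(vol[~interior].sum() / vol.sum())
        if mixing is not None and tr_s is not None:
            freqs = np.fft.rfftfreq(mixing.shape[0], d=tr_s)
            power = np.abs(np.fft.rfft(mixing[:, k] - mixing[:, k].mean())) ** 2
            heur["hf_fraction"] = float(
                power[freqs > 0.1].sum() / power.sum()
            )
        labels.append(
            ComponentLabel(
                index=k,
                label="signal" if is_signal else "noise",
                template=names[best] if is_signal else None,
                correlation=float(abs(r[best])),
                heuristics=heur,
            )
        )
    return labels


def subregion_importance(
    z_map: np.ndarray, region_masks: Mapping[str, np.ndarray]
) -> list[tuple[str, float]]:
    """Rank anatomical sub-regions by mean z-statistic within each mask.

    Returns (region, mean z) pairs sorted by descending mean; exact ties are
    broken alphabetically by region name.
    """
    z = np.asarray(z_map, dtype=float).ravel()
    out = []
    for name, mask in region_masks.items():
        m = np.asarray(mask, dtype=bool).ravel()
        if not m.any():
            raise ValueError(f"empty mask for region {name!r}")
        out.append((name, float(z[m].mean())))
    return sorted(out, key=lambda item: (-item[1], item[0]))


def match_components(
    recovered: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of recovered maps to planted maps.

    Returns the permutation (truth index per recovered component) and the
    matched absolute spatial correlations.
    """
    recovered = np.atleast_2d(recovered)
    truth = np.atleast_2d(truth)
    C = np.zeros((recovered.shape[0], truth.shape[0]))
    for i, r in enumerate(recovered):
        for j, t in enumerate(truth):
            C[i, j] = abs(np.corrcoef(r, t)[0, 1])
    rows, cols = linear_sum_assignment(-C)
    return cols, C[rows, cols]
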