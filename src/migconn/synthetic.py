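"""Synthetic migraine cohorts with controlled connectivity structure.

Every downstream stage of the pipeline (preprocessing, group ICA, network
construction, group inference) is exercised on cohorts generated here, so
that the statistical machinery can be validated without access to scanner
data.  The default cohort emulates the study conditions of the analysis this
package implements: 44 episodic-migraine (EM) and 18 chronic-migraine (CM)
subjects, TR = 3 s, 100 volumes per run.

Node time series are drawn from a zero-mean stationary Gaussian process whose
*inverse covariance* (precision matrix) is planted exactly, because the
pipeline's edge statistic is the partial correlation, which is a pure
function of the precision matrix.  A group difference is planted by scaling
the precision entries incident to one node (the "effect node") in the CM
group by ``1 + effect_size``.

All generators are pure functions of ``(spec, seed)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "planted_precision",
    "generate_node_timeseries_cohort",
    "generate_4d_dataset",
    "generate_motion_traces",
    "generate_clinical_table",
    "coupled_series",
    "write_cohort",
    "load_cohort",
]

#: Baseline partial correlation on edges incident to the effect node.
HUB_PARTIAL_R = 0.15
#: Baseline partial correlation within disjoint pairs of non-effect nodes.
PAIR_PARTIAL_R = 0.45


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults reproduce the emulated study conditions: 44 EM vs. 18 CM
    subjects, 100 volumes at TR = 3 s, seven network nodes.
    """

    n_em: int = 44
    n_cm: int = 18
    n_nodes: int = 7
    n_volumes: int = 100
    tr_s: float = 3.0
    n_voxels_per_axis: int = 20
    effect_node: int | None = None
    effect_size: float = 0.0
    noise_sd: float = 0.5
    motion_spike_rate: float = 0.0
    ar_coeff: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_em < 2 or self.n_cm < 2:
            raise ValueError("each group needs at least 2 subjects")
        if not 0.0 <= self.motion_spike_rate <= 1.0:
            raise ValueError("motion_spike_rate must lie in [0, 1]")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.effect_node is not None and not (
            0 <= self.effect_node < self.n_nodes
        ):
            raise ValueError(
                f"effect_node {self.effect_node} out of range for "
                f"{self.n_nodes} nodes"
            )
        if not 0.0 <= self.ar_coeff < 1.0:
            raise ValueError("ar_coeff must lie in [0, 1)")

    @property
    def n_subjects(self) -> int:
        return self.n_em + self.n_cm


@dataclass
class SyntheticCohort:
    """A generated cohort together with its ground truth.

    ``truth`` records whatever was planted (precision matrices, spatial maps,
    motion-spike frames) so tests can compare recovered quantities against it.
    """

    spec: CohortSpec
    node_timeseries: np.ndarray  # (n_subjects, T, K)
    motion: np.ndarray  # (n_subjects, 6, T)
    clinical: pd.DataFrame
    truth: dict
    volumes: np.ndarray | None = None  # (n_subjects, X, Y, Z, T)

    @property
    def groups(self) -> np.ndarray:
        return self.clinical["group"].to_numpy()


def _rng(spec: CohortSpec, stream: int) -> np.random.Generator:
    # Independent, reproducible substreams per generator.
    return np.random.default_rng([spec.seed, stream])


def planted_precision(spec: CohortSpec, group: str) -> np.ndarray:
    """Planted precision matrix for ``group`` ('EM' or 'CM').

    Structure: the effect node (node 0 when none is set) is a hub whose
    incident edges carry partial correlation ``HUB_PARTIAL_R``; the remaining
    nodes are split into disjoint pairs with partial correlation
    ``PAIR_PARTIAL_R``; every other off-diagonal entry is zero.  In the CM
    group the hub's incident precision magnitudes are scaled by
    ``1 + effect_size``.

    Raises ``ValueError`` if the resulting matrix is not positive definite.
    """
    if group not in ("EM", "CM"):
        raise ValueError(f"unknown group {group!r}")
    K = spec.n_nodes
    hub = spec.effect_node if spec.effect_node is not None else 0
    boost = 1.0 + spec.effect_size if group == "CM" else 1.0
    P = np.eye(K)
    others = [i for i in range(K) if i != hub]
    for j in others:
        P[hub, j] = P[j, hub] = -HUB_PARTIAL_R * boost
    for a, b in zip(others[0::2], others[1::2]):
        P[a, b] = P[b, a] = -PAIR_PARTIAL_R
    eigvals = np.linalg.eigvalsh(P)
    if eigvals.min() <= 0:
        raise ValueError(
            "planted precision matrix is not positive definite "
            f"(min eigenvalue {eigvals.min():.4g}); reduce effect_size "
            "or the baseline partial correlations"
        )
    return P


def _draw_series(
    rng: np.random.Generator, T: int, cov_chol: np.ndarray, ar: float
) -> np.ndarray:
    """T x K draw with planted covariance, optionally AR(1)-coloured.

    The AR(1) recursion x_t = a x_{t-1} + sqrt(1-a^2) e_t with e ~ N(0, S)
    leaves the stationary covariance equal to S, so temporal autocorrelation
    can be added without disturbing the planted partial correlations.
    """
    K = cov_chol.shape[0]
    innov = rng.standard_normal((T, K)) @ cov_chol.T
    if ar == 0.0:
        return innov
    out = np.empty_like(innov)
    scale = np.sqrt(1.0 - ar * ar)
    out[0] = innov[0]
    for t in range(1, T):
        out[t] = ar * out[t - 1] + scale * innov[t]
    return out


def generate_node_timeseries_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate per-subject node time series with planted group structure.

    Each subject's T x K series is a stationary zero-mean Gaussian process
    whose inverse covariance equals the group's planted precision matrix.
    """
    rng = _rng(spec, 1)
    precisions = {g: planted_precision(spec, g) for g in ("EM", "CM")}
    chols = {g: np.linalg.cholesky(np.linalg.inv(P)) for g, P in precisions.items()}
    T, K = spec.n_volumes, spec.n_nodes
    series = np.empty((spec.n_subjects, T, K))
    labels = ["EM"] * spec.n_em + ["CM"] * spec.n_cm
    for i, g in enumerate(labels):
        series[i] = _draw_series(rng, T, chols[g], spec.ar_coeff)
    motion, spike_frames = generate_motion_traces(spec)
    clinical = generate_clinical_table(spec)
    truth = {
        "precision": precisions,
        "groups": np.array(labels),
        "effect_node": spec.effect_node,
        "spike_frames": spike_frames,
    }
    return SyntheticCohort(
        spec=spec,
        node_timeseries=series,
        motion=motion,
        clinical=clinical,
        truth=truth,
    )


def _blob_maps(n_components: int, axis: int) -> np.ndarray:
    """Spatially disjoint box-shaped component maps on an axis^3 grid."""
    if n_components == 0:
        return np.zeros((0, axis**3))
    m = int(np.ceil(n_components ** (1.0 / 3.0)))
    cell = axis // m
    if cell < 2:
        raise ValueError(
            f"cannot place {n_components} disjoint blobs on a {axis}^3 grid"
        )
    half = max(1, cell // 2)
    maps = np.zeros((n_components, axis, axis, axis))
    for k in range(n_components):
        i, j, l = np.unravel_index(k, (m, m, m))
        sl = tuple(
            slice(c * cell + (cell - half) // 2, c * cell + (cell - half) // 2 + half)
            for c in (i, j, l)
        )
        maps[k][sl] = 1.0
    return maps.reshape(n_components, -1)


def generate_4d_dataset(spec: CohortSpec) -> SyntheticCohort:
    """Generate 4D volumes as planted maps x time series plus white noise.

    ``volumes[s] = sum_k map_k (x) timeseries_k + noise`` with spatially
    disjoint box blobs as maps; the blobs are stored in ``truth['maps']``.
    With ``n_nodes=0`` the volumes are pure noise (used to test component
    noise-classification).
    """
    axis = spec.n_voxels_per_axis
    maps = _blob_maps(spec.n_nodes, axis)
    if spec.n_nodes > 0:
        cohort = generate_node_timeseries_cohort(spec)
    else:
        null_spec = dataclasses.replace(spec, n_nodes=1)
        cohort = generate_node_timeseries_cohort(null_spec)
        cohort.node_timeseries = cohort.node_timeseries[:, :, :0]
        cohort.spec = spec
    rng = _rng(spec, 2)
    n, T = spec.n_subjects, spec.n_volumes
    vols = np.empty((n, axis, axis, axis, T))
    for s in range(n):
        signal = cohort.node_timeseries[s] @ maps  # (T, V)
        signal = signal + spec.noise_sd * rng.standard_normal(signal.shape)
        vols[s] = signal.T.reshape(axis, axis, axis, T)
    cohort.volumes = vols
    cohort.truth["maps"] = maps
    return cohort


def generate_motion_traces(spec: CohortSpec) -> tuple[np.ndarray, list[np.ndarray]]:
    """Per-subject 6 x T motion traces: smooth drift plus step spikes.

    Spikes occur at Bernoulli(``motion_spike_rate``) frames (never frame 0)
    and are persistent 0.8 mm translation steps, so exactly the spike frame's
    framewise displacement exceeds 0.5 mm.  Returns the traces and the
    per-subject planted spike-frame indices.
    """
    rng = _rng(spec, 3)
    T, n = spec.n_volumes, spec.n_subjects
    t = np.arange(T)
    traces = np.empty((n, 6, T))
    spike_frames: list[np.ndarray] = []
    for s in range(n):
        drift = np.empty((6, T))
        for p in range(6):
            amp = 0.05 if p < 3 else 5e-4  # mm vs. rad
            phase = rng.uniform(0, 2 * np.pi)
            period = rng.uniform(40, 80)
            drift[p] = amp * np.sin(2 * np.pi * t / period + phase)
        spikes = np.flatnonzero(rng.random(T) < spec.motion_spike_rate)
        spikes = spikes[spikes > 0]
        steps = np.zeros(T)
        sign = 1.0
        for f in spikes:
            steps[f:] += sign * 0.8
            sign = -sign
        drift[0] += steps
        traces[s] = drift
        spike_frames.append(spikes)
    return traces, spike_frames


# Target prevalences/moments for the clinical table, per group; chosen to
# mirror a typical specialist headache-clinic cohort (EM vs. CM).
_CLINICAL_PARAMS = {
    "EM": dict(female=0.82, aura=0.09, allodynia=0.18, phq9=(4.5, 3.0),
               hads_a=(6.5, 3.3), hads_d=(5.5, 3.0), asc12=(2.0, 2.5),
               headache_days=(6.3, 3.6, 1, 14), drug_days=4.0),
    "CM": dict(female=0.61, aura=0.22, allodynia=0.28, phq9=(6.0, 3.5),
               hads_a=(8.0, 3.5), hads_d=(6.5, 3.5), asc12=(3.0, 3.0),
               headache_days=(23.0, 5.9, 15, 31), drug_days=9.0),
}


def generate_clinical_table(spec: CohortSpec) -> pd.DataFrame:
    """Phenotype table emulating a baseline-characteristics table.

    Chronic-migraine subjects have >= 15 monthly headache days by
    construction (the ICHD-3 beta chronic-migraine definition); depression and
    anxiety are defined from the drawn questionnaire scores by the standard
    cutoffs (PHQ-9 >= 8, HADS-A >= 8).  Covariates are drawn independently of
    the planted network effect.
    """
    rng = _rng(spec, 4)
    rows = []
    labels = ["EM"] * spec.n_em + ["CM"] * spec.n_cm
    for i, g in enumerate(labels):
        p = _CLINICAL_PARAMS[g]
        mu, sd, lo, hi = p["headache_days"]
        phq9 = int(np.clip(round(rng.normal(*p["phq9"])), 0, 27))
        hads_a = int(np.clip(round(rng.normal(*p["hads_a"])), 0, 21))
        rows.append(
            dict(
                subject_id=f"sub-{i:03d}",
                group=g,
                age=float(np.clip(round(rng.normal(40.5, 10.4), 1), 19, 57)),
                sex_female=int(rng.random() < p["female"]),
                aura=int(rng.random() < p["aura"]),
                allodynia=int(rng.random() < p["allodynia"]),
                phq9=phq9,
                hads_a=hads_a,
                hads_d=int(np.clip(round(rng.normal(*p["hads_d"])), 0, 21)),
                asc12=int(np.clip(round(rng.normal(*p["asc12"])), 0, 12)),
                depression=int(phq9 >= 8),
                anxiety=int(hads_a >= 8),
                disease_duration_y=float(round(rng.gamma(1.8, 6.7), 1)),
                headache_days=int(np.clip(round(rng.normal(mu, sd)), lo, hi)),
                headache_intensity=int(np.clip(round(rng.normal(6, 1.8)), 1, 10)),
                acute_drug_days=int(rng.poisson(p["drug_days"])),
            )
        )
    return pd.DataFrame(rows)


def coupled_series(
    node_series: np.ndarray,
    coupling: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """A series correlated with ``node_series`` at the planted level.

    Returns ``c * standardized(node) + sqrt(1 - c^2) * noise`` so the
    population Pearson correlation with the node series equals ``coupling``.
    Used to plant seed-region couplings (e.g. hypothalamus-to-network).
    """
    if not -1.0 < coupling < 1.0:
        raise ValueError("coupling must lie in (-1, 1)")
    x = np.asarray(node_series, float)
    z = (x - x.mean()) / x.std()
    return coupling * z + np.sqrt(1.0 - coupling**2) * rng.standard_normal(x.shape)


# ---------------------------------------------------------------------------
# On-disk round trip


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write a cohort to ``out_dir``: NIfTI volumes (4D mode), 6-column
    motion text files, a phenotype TSV, node time series TSVs, and a JSON
    manifest of the planted truth."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = cohort.spec
    affine = np.diag([2.0, 2.0, 2.0, 1.0])  # 2 mm isotropic grid
    for i in range(spec.n_subjects):
        sid = cohort.clinical["subject_id"].iloc[i]
        np.savetxt(out / f"{sid}_motion.txt", cohort.motion[i].T, fmt="%.6f")
        np.savetxt(
            out / f"{sid}_nodes.tsv", cohort.node_timeseries[i], delimiter="\t"
        )
        if cohort.volumes is not None:
            img = nib.Nifti1Image(cohort.volumes[i], affine)
            img.header.set_zooms((2.0, 2.0, 2.0, spec.tr_s))
            nib.save(img, out / f"{sid}_bold.nii.gz")
    cohort.clinical.to_csv(out / "phenotype.tsv", sep="\t", index=False)
    manifest = {
        "spec": dataclasses.asdict(spec),
        "groups": list(cohort.truth["groups"]),
        "precision": {g: P.tolist() for g, P in cohort.truth["precision"].items()},
        "spike_frames": [f.tolist() for f in cohort.truth["spike_frames"]],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def load_cohort(in_dir: str | Path) -> SyntheticCohort:
    """Inverse of :func:`write_cohort` (volumes included when present)."""
    import nibabel as nib

    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    spec = CohortSpec(**manifest["spec"])
    clinical = pd.read_csv(src / "phenotype.tsv", sep="\t")
    series, motion, vols = [], [], []
    for sid in clinical["subject_id"]:
        motion.append(np.loadtxt(src / f"{sid}_motion.txt").T)
        series.append(np.loadtxt(src / f"{sid}_nodes.tsv", delimiter="\t", ndmin=2))
        nii = src / f"{sid}_bold.nii.gz"
        if nii.exists():
            vols.append(np.asarray(nib.load(nii).dataobj, dtype=float))
    shapes = {s.shape for s in series}
    if len(shapes) > 1:
        raise ValueError(
            "inconsistent frame counts across subjects: "
            f"{sorted(s[0] for s in shapes)}"
        )
    truth = {
        "precision": {
            g: np.asarray(P) for g, P in manifest["precision"].items()
        },
        "groups": np.asarray(manifest["groups"]),
        "effect_node": spec.effect_node,
        "spike_frames": [np.asarray(f, int) for f in manifest["spike_frames"]],
    }
    return SyntheticCohort(
        spec=spec,
        node_timeseries=np.stack(series),
        motion=np.stack(motion),
        clinical=clinical,
        truth=truth,
        volumes=np.stack(vols) if vols else None,
    )
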