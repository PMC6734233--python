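"""End-to-end orchestration of the connectivity analysis.

A run executes, in order: cohort acquisition (synthetic or from disk),
preprocessing (4D mode), group ICA node definition (4D mode), network
construction, degree-centrality group inference with covariate adjustment,
seed-to-network contrasts, and the baseline clinical table.  Every run
writes TSV outputs plus a JSON manifest carrying the seed and a hash of the
configuration, so identical configurations reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clinical import compare_baseline_table
from .ica import GroupICA, classify_components
from .inference import (
    adjusted_group_effect,
    correlate_clinical,
    interaction_effect,
    permutation_group_test,
)
from .network import NetworkParams, connectivity_chain
from .preprocess import PreprocConfig, bandpass_filter, intensity_normalize, \
    spatial_smooth, trim_and_scrub
from .roi import seed_network_edges
from .synthetic import CohortSpec, SyntheticCohort, coupled_series, \
    generate_4d_dataset, generate_node_timeseries_cohort, load_cohort

logger = logging.getLogger("migconn")

__all__ = ["RunConfig", "run_pipeline", "load_dataset", "TABLE3_COVARIATE_SETS"]

#: Nested covariate sets for the multivariable group-effect analysis.
TABLE3_COVARIATE_SETS: tuple[tuple[str, ...], ...] = (
    (),
    ("age", "sex_female", "aura"),
    ("age", "sex_female", "aura", "allodynia"),
    ("age", "sex_female", "aura", "depression", "anxiety"),
    ("age", "sex_female", "aura", "allodynia", "depression", "anxiety"),
    ("age", "sex_female", "aura", "allodynia", "depression", "anxiety",
     "disease_duration_y"),
    ("age", "sex_female", "aura", "allodynia", "depression", "anxiety",
     "disease_duration_y", "headache_intensity"),
    ("age", "sex_female", "aura", "allodynia", "depression", "anxiety",
     "disease_duration_y", "headache_intensity", "acute_drug_days"),
)

#: Planted seed-region couplings (EM, CM) used in synthetic mode: the
#: hypothalamus couples more strongly in CM, the DRN in EM, the PAG equally.
DEFAULT_ROI_COUPLINGS: dict[str, tuple[float, float]] = {
    "hypothalamus": (0.1, 0.5),
    "drn": (0.5, 0.1),
    "pag": (0.3, 0.3),
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    mode: str = "nodes"  # 'nodes' | 'volumes' | 'dataset'
    dataset_dir: str | None = None
    cohort: CohortSpec = field(default_factory=CohortSpec)
    preproc: PreprocConfig = field(default_factory=PreprocConfig)
    network: NetworkParams = field(default_factory=NetworkParams)
    n_components: int = 7
    n_permutations: int = 5000
    alpha: float = 0.05
    q: float = 0.05
    roi_couplings: dict = field(
        default_factory=lambda: dict(DEFAULT_ROI_COUPLINGS)
    )
    target_node: int | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, klass in (
            ("cohort", CohortSpec),
            ("preproc", PreprocConfig),
            ("network", NetworkParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = klass(**raw[key])
        cfg = cls(**raw)
        if cfg.mode == "dataset":
            if not cfg.dataset_dir or not Path(cfg.dataset_dir).exists():
                raise FileNotFoundError(
                    f"dataset mode requires an existing dataset_dir, "
                    f"got {cfg.dataset_dir!r}"
                )
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_dataset(dataset_dir: str | Path) -> SyntheticCohort:
    """Load a cohort directory (NIfTI/TSV layout written by the simulator).

    Validates that every phenotype subject has data files, that all runs
    share a voxel grid and frame count, and reports offenders by id.
    """
    src = Path(dataset_dir)
    if not src.exists():
        raise FileNotFoundError(f"dataset directory {src} does not exist")
    pheno = src / "phenotype.tsv"
    if not pheno.exists():
        raise FileNotFoundError(f"missing phenotype table {pheno}")
    table = pd.read_csv(pheno, sep="\t")
    if "group" not in table.columns:
        raise ValueError("phenotype table lacks the required 'group' column")
    missing = [
        sid
        for sid in table["subject_id"]
        if not (src / f"{sid}_nodes.tsv").exists()
        and not (src / f"{sid}_bold.nii.gz").exists()
    ]
    if missing:
        raise ValueError(f"subjects present in phenotype but without data: {missing}")
    cohort = load_cohort(src)
    T = {s.shape[0] for s in cohort.node_timeseries}
    if len(T) > 1:
        raise ValueError(f"inconsistent frame counts across subjects: {sorted(T)}")
    return cohort


def _stage(name: str, **counts) -> None:
    kv = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage=%s %s", name, kv)


def _preprocess_volumes(cohort: SyntheticCohort, cfg: RunConfig):
    """Scrub/trim, normalize, band-pass and smooth each subject's run."""
    pp = cfg.preproc
    spec = cohort.spec
    runs = []
    retained_all = []
    for i in range(spec.n_subjects):
        vol = cohort.volumes[i]  # (X, Y, Z, T)
        series = np.moveaxis(vol, -1, 0)  # time-first
        retained, series, _ = trim_and_scrub(
            series, cohort.motion[i], pp, spec.tr_s
        )
        vol = np.moveaxis(series, 0, -1)
        shifted = vol - vol.min() + 1.0  # strictly positive for scaling
        vol, _ = intensity_normalize(shifted, pp.target_mean)
        series = bandpass_filter(
            np.moveaxis(vol, -1, 0), spec.tr_s, pp.band_low_hz,
            pp.band_high_hz, pp.filter_order,
        )
        vol = spatial_smooth(
            np.moveaxis(series, 0, -1), pp.smoothing_fwhm_mm, 2.0
        )
        runs.append(vol)
        retained_all.append(retained)
        _stage("preprocess", subject=i, frames_retained=len(retained))
    return runs, retained_all


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis and write all stage outputs to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    spec = config.cohort

    # ---- cohort ----------------------------------------------------------
    if config.mode == "nodes":
        cohort = generate_node_timeseries_cohort(spec)
    elif config.mode == "volumes":
        cohort = generate_4d_dataset(spec)
    elif config.mode == "dataset":
        cohort = load_dataset(config.dataset_dir)
        spec = cohort.spec
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    groups = cohort.groups
    _stage("cohort", subjects=spec.n_subjects, mode=config.mode)

    # ---- imaging stages (volumes only) ----------------------------------
    if cohort.volumes is not None:
        runs, _ = _preprocess_volumes(cohort, config)
        ica = GroupICA(
            n_components=config.n_components, random_state=config.seed
        ).fit(runs)
        node_ts = [ica.transform(r) for r in runs]
        templates = {
            f"planted{k}": m for k, m in enumerate(cohort.truth.get("maps", []))
        }
        if templates:
            labels = classify_components(ica.zmaps_, templates)
            pd.DataFrame(
                [dataclasses.asdict(l) for l in labels]
            ).to_csv(out / "component_labels.tsv", sep="\t", index=False)
            signal_idx = [l.index for l in labels if l.label == "signal"]
        else:
            signal_idx = list(range(config.n_components))
        node_ts = [ts[:, signal_idx] for ts in node_ts]
        _stage("group_ica", components=config.n_components,
               signal=len(signal_idx))
    else:
        node_ts = list(cohort.node_timeseries)

    # ---- network ---------------------------------------------------------
    dc_rows, z_mats = [], []
    for ts in node_ts:
        z, dc = connectivity_chain(ts, config.network)
        dc_rows.append(dc)
        z_mats.append(z.edges)
    K = dc_rows[0].shape[0]
    node_names = [f"node{k}" for k in range(K)]
    dc_table = pd.DataFrame(dc_rows, columns=node_names)
    degree_table = pd.concat(
        [cohort.clinical.reset_index(drop=True), dc_table], axis=1
    )
    degree_table.to_csv(out / "degree_table.tsv", sep="\t", index=False)
    _stage("connectome", nodes=K, edges=K * (K - 1) // 2)

    # ---- inference -------------------------------------------------------
    perm = permutation_group_test(
        dc_table, groups, n_permutations=config.n_permutations,
        alpha=config.alpha, q=config.q,
        seed=np.random.default_rng([config.seed, 10]).integers(2**31),
    )
    perm.to_frame().to_csv(out / "permutation_result.tsv", sep="\t")
    results["permutation"] = perm

    cov_cols = {c for s in TABLE3_COVARIATE_SETS for c in s}
    if cov_cols <= set(cohort.clinical.columns):
        # drop covariates that are constant in this cohort (no contrast)
        usable = {
            c for c in cov_cols if cohort.clinical[c].nunique() > 1
        }
        sets = []
        for s in TABLE3_COVARIATE_SETS:
            kept = [c for c in s if c in usable]
            if kept not in sets:
                sets.append(kept)
        try:
            adjusted = adjusted_group_effect(
                dc_table, cohort.clinical, sets, q=config.q
            )
        except ValueError as err:  # collinear small-cohort designs
            logger.warning("adjusted-effect stage skipped: %s", err)
        else:
            adjusted.to_csv(out / "adjusted_effects.tsv", sep="\t", index=False)
            results["adjusted"] = adjusted

    target = config.target_node
    if target is None:
        target = spec.effect_node if spec.effect_node is not None else 0
    target_dc = dc_table.iloc[:, target].to_numpy()
    clin_corr = {}
    for col in ("headache_days", "hads_d", "hads_a", "phq9", "asc12",
                "disease_duration_y"):
        if col in cohort.clinical.columns:
            r, p = correlate_clinical(target_dc, cohort.clinical[col].to_numpy())
            clin_corr[col] = {"r": r, "p": p}
    results["clinical_correlations"] = clin_corr
    interactions = {}
    for col in ("depression", "anxiety"):
        if col in cohort.clinical.columns:
            try:
                interactions[col] = interaction_effect(
                    target_dc, groups, cohort.clinical[col].to_numpy()
                )
            except ValueError:
                interactions[col] = None
    results["interactions"] = interactions
    _stage("inference", nodes=K, permutations=perm.n_permutations)

    # ---- seed-to-network -------------------------------------------------
    if config.roi_couplings:
        rng = np.random.default_rng([config.seed, 11])
        node_mat = np.stack([ts[:, target] for ts in node_ts])
        roi_series = {}
        for name, (c_em, c_cm) in config.roi_couplings.items():
            roi_series[name] = np.stack(
                [
                    coupled_series(
                        node_mat[i], c_cm if groups[i] == "CM" else c_em, rng
                    )
                    for i in range(len(node_mat))
                ]
            )
        contrast = seed_network_edges(
            roi_series, node_mat, groups,
            n_permutations=config.n_permutations, q=config.q,
            seed=np.random.default_rng([config.seed, 12]).integers(2**31),
        )
        contrast.result.to_frame().to_csv(out / "roi_contrast.tsv", sep="\t")
        results["roi"] = contrast
        _stage("roi_seed", rois=len(roi_series))

    # ---- baseline table --------------------------------------------------
    baseline_cols = [
        c for c in ("age", "sex_female", "aura", "allodynia", "anxiety",
                    "depression", "disease_duration_y", "headache_days",
                    "headache_intensity")
        if c in cohort.clinical.columns
    ]
    baseline = compare_baseline_table(
        cohort.clinical[["group", *baseline_cols]]
    )
    baseline.to_csv(out / "baseline_table.tsv", sep="\t", index=False)
    results["baseline"] = baseline
    _stage("clinical_stats", variables=len(baseline))

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "n_permutations": int(perm.n_permutations),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
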