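"""End-to-end orchestration: simulate → filter → oversample → cluster →
speciate → classify, with a manifest tying every output to its seeds
and configuration.

A single top-level seed is fanned out to one child seed per stage
through ``numpy.random.SeedSequence.spawn``, so one integer reproduces
a whole run byte-for-byte.  Every output table carries the
configuration hash as a leading comment line.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import DEFAULT_THRESHOLD_GRID, ClassifierReport, per_cluster_classify
from .instrument import Frame, InstrumentConfig
from .io import write_frames_csv
from .simulate import (
    ContaminationModel,
    NON_POLLEN_CLASSES,
    POLLEN_SPECIES,
    Session,
    builtin_profiles,
    simulate_session,
)
from .sizing import (
    ClusterModel,
    CumulativeDataset,
    LOFParams,
    build_cumulative_dataset,
    default_lof_grid,
    filter_session,
    hierarchical_cluster,
    hopkins,
    pca_project,
)
from .speciation import SIGNATURE_COLUMNS, signature_from_frame
from .validity import optimal_k_vote

logger = logging.getLogger(__name__)

STAGES = ("simulate", "lof", "oversample", "hopkins", "k_vote", "classify")


@dataclass
class PipelineConfig:
    """Everything one run needs, in one (YAML-serialisable) place."""

    species: tuple[str, ...] = POLLEN_SPECIES
    non_pollen: tuple[str, ...] = NON_POLLEN_CLASSES
    n_frames_range: tuple[int, int] = (180, 300)
    contamination: ContaminationModel = field(default_factory=ContaminationModel)
    noise_sigma: float = 0.15
    sizing_sigma: float = 0.20
    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    lof_grid: tuple[LOFParams, ...] = field(default_factory=lambda: tuple(default_lof_grid()))
    n_draws: int = 30
    min_per_bin: int = 20
    k: int | str = "auto"
    k_range: tuple[int, int] = (2, 8)
    f1_policy: str = "flank"
    folds: int = 10
    repeats: int = 5
    threshold_grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID
    inner_folds: int = 3

    def __post_init__(self) -> None:
        registry = builtin_profiles()
        unknown = [s for s in (*self.species, *self.non_pollen) if s not in registry]
        if unknown:
            raise ValueError(f"species not in the profile registry: {unknown}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["instrument"] = {
            "n_bins": self.instrument.n_bins,
            "size_range": list(self.instrument.size_range),
            "angles": list(self.instrument.scattering_angles),
            "calibration": {
                "a": self.instrument.calibration.scale,
                "b": self.instrument.calibration.exponent,
            },
        }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        kwargs = dict(d)
        if "instrument" in kwargs:
            kwargs["instrument"] = InstrumentConfig.from_dict({"instrument": kwargs["instrument"]})
        if "contamination" in kwargs and isinstance(kwargs["contamination"], Mapping):
            kwargs["contamination"] = ContaminationModel(**kwargs["contamination"])
        if "lof_grid" in kwargs:
            kwargs["lof_grid"] = tuple(
                LOFParams(**g) if isinstance(g, Mapping) else g for g in kwargs["lof_grid"]
            )
        for key in ("species", "non_pollen", "threshold_grid"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        for key in ("n_frames_range", "k_range"):
            if key in kwargs:
                kwargs[key] = tuple(int(x) for x in kwargs[key])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def spawn_stage_seeds(seed: int) -> dict[str, np.random.Generator]:
    """One child generator per pipeline stage from a single seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: np.random.default_rng(child) for name, child in zip(STAGES, children)}


@dataclass
class PipelineResult:
    """Bundle of everything a run computed."""

    config: PipelineConfig
    seed: int
    sessions: dict[str, Session]
    lof_params: dict[str, LOFParams]
    lof_silhouette: dict[str, float]
    frames_kept: dict[str, int]
    dataset: CumulativeDataset
    hopkins: float
    k: int
    k_votes: dict[str, int]
    cluster_model: ClusterModel
    species_clusters: dict[str, int]
    pca_coords: np.ndarray
    pca_variance: np.ndarray
    signatures: pd.DataFrame
    rosters: dict[int, tuple[str, ...]]
    reports: dict[int, ClassifierReport]


def default_rosters(
    cluster_mean_diameter: Mapping[int, float], non_pollen: Sequence[str]
) -> dict[int, tuple[str, ...]]:
    """Assign the non-pollen classes to every size cluster, except that
    carbonaceous particles are left out of the largest-diameter cluster
    (they rarely occur that large in ambient air)."""
    if not cluster_mean_diameter:
        return {}
    largest = max(cluster_mean_diameter, key=lambda k: cluster_mean_diameter[k])
    rosters = {}
    for cid in cluster_mean_diameter:
        roster = [s for s in non_pollen if not (cid == largest and s == "carbonaceous")]
        rosters[cid] = tuple(roster)
    return rosters


def _signature_rows(
    frames: Sequence[Frame], label: str, cfg: InstrumentConfig, f1_policy: str
) -> list[dict]:
    rows = []
    for i, frame in enumerate(frames):
        sig = signature_from_frame(frame, cfg, f1_policy=f1_policy)
        row = dict(zip(SIGNATURE_COLUMNS, sig.as_vector()))
        row.update(label=label, draw=i, F1=sig.f1, valid=sig.valid)
        rows.append(row)
    return rows


def run_pipeline(config: PipelineConfig, seed: int, out_dir=None) -> PipelineResult:
    """Execute the full analysis; optionally write the report bundle."""
    rngs = spawn_stage_seeds(seed)
    registry = builtin_profiles()
    cfg = config.instrument

    # -- simulate ----------------------------------------------------------
    sim_rng = rngs["simulate"]
    lo, hi = config.n_frames_range
    sessions: dict[str, Session] = {}
    for name in (*config.species, *config.non_pollen):
        n_frames = int(sim_rng.integers(lo, hi + 1))
        sessions[name] = simulate_session(
            registry[name], config.contamination, n_frames, cfg, sim_rng,
            config.noise_sigma, config.sizing_sigma,
        )
    logger.info("simulated %d sessions", len(sessions))

    # -- LOF filter --------------------------------------------------------
    lof_rng = rngs["lof"]
    inliers: dict[str, list[Frame]] = {}
    lof_params: dict[str, LOFParams] = {}
    lof_sil: dict[str, float] = {}
    kept: dict[str, int] = {}
    for name, session in sessions.items():
        frames, mask, params, sil = filter_session(session, grid=config.lof_grid, rng=lof_rng)
        inliers[name] = frames
        lof_params[name] = params
        lof_sil[name] = sil
        kept[name] = len(frames)

    # -- oversample + cluster (pollen only drives the size clustering) -----
    ov_rng = rngs["oversample"]
    pollen_frames = {s: inliers[s] for s in config.species}
    dataset = build_cumulative_dataset(
        pollen_frames, n_draws=config.n_draws, min_per_bin=config.min_per_bin, rng=ov_rng
    )
    normalized = dataset.normalized_copy()
    h = hopkins(normalized.matrix, rng=rngs["hopkins"])

    if config.k == "auto":
        k, votes = optimal_k_vote(
            normalized.matrix, k_range=range(config.k_range[0], config.k_range[1] + 1),
            rng=rngs["k_vote"],
        )
    else:
        k, votes = int(config.k), {}
    model = hierarchical_cluster(normalized.matrix, k)
    species_clusters = model.majority_cluster(normalized.species)
    coords, variance = pca_project(normalized.matrix)
    logger.info("hopkins=%.3f, k=%d, clusters=%s", h, k, species_clusters)

    # -- speciate ----------------------------------------------------------
    # pollen signatures come from the same cumulative frames that were
    # clustered; each row carries its species' majority size cluster (a
    # species is classified within the cluster it belongs to)
    rows: list[dict] = []
    for i, (frame, label) in enumerate(zip(dataset.frames, dataset.species)):
        sig = signature_from_frame(frame, cfg, f1_policy=config.f1_policy)
        row = dict(zip(SIGNATURE_COLUMNS, sig.as_vector()))
        row.update(label=label, draw=i, F1=sig.f1, valid=sig.valid,
                   cluster=species_clusters[label])
        rows.append(row)
    # non-pollen signatures from their own oversampled sessions
    np_dataset = build_cumulative_dataset(
        {s: inliers[s] for s in config.non_pollen},
        n_draws=config.n_draws, min_per_bin=config.min_per_bin, rng=ov_rng,
    ) if config.non_pollen else None
    if np_dataset is not None:
        for frame, label in zip(np_dataset.frames, np_dataset.species):
            sig = signature_from_frame(frame, cfg, f1_policy=config.f1_policy)
            row = dict(zip(SIGNATURE_COLUMNS, sig.as_vector()))
            row.update(label=label, draw=-1, F1=sig.f1, valid=sig.valid, cluster=np.nan)
            rows.append(row)
    signatures = pd.DataFrame(rows)

    # -- classify per size cluster -----------------------------------------
    cluster_mean_d = {}
    d_centers = cfg.diameter_edges
    centers = np.sqrt(d_centers[:-1] * d_centers[1:])
    for cid in range(1, k + 1):
        rows_c = normalized.matrix[model.labels == cid]
        if len(rows_c):
            mean_hist = rows_c.mean(axis=0)
            cluster_mean_d[cid] = float((mean_hist * centers).sum() / mean_hist.sum())
    rosters = default_rosters(cluster_mean_d, config.non_pollen)
    reports = per_cluster_classify(
        signatures, rosters, SIGNATURE_COLUMNS,
        seed=int(rngs["classify"].integers(2**31)),
        folds=config.folds, repeats=config.repeats,
        threshold_grid=config.threshold_grid, inner_folds=config.inner_folds,
    )

    result = PipelineResult(
        config=config, seed=seed, sessions=sessions, lof_params=lof_params,
        lof_silhouette=lof_sil, frames_kept=kept, dataset=dataset, hopkins=h,
        k=k, k_votes=votes, cluster_model=model, species_clusters=species_clusters,
        pca_coords=coords, pca_variance=variance, signatures=signatures,
        rosters=rosters, reports=reports,
    )
    if out_dir is not None:
        write_report_bundle(result, out_dir)
    return result


def _write_table(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False)


def write_report_bundle(result: PipelineResult, out_dir) -> Path:
    """Write all intermediate tables, per-cluster reports and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = result.config.config_hash()

    sessions_dir = out / "sessions"
    sessions_dir.mkdir(exist_ok=True)
    for name, session in result.sessions.items():
        safe = name.replace(" ", "_")
        write_frames_csv(sessions_dir / f"{safe}.csv", session.frames,
                         header_comment=f"config_hash={chash}")
        truth = {"species": name, "inlier": session.inlier.tolist()}
        (sessions_dir / f"{safe}.truth.json").write_text(json.dumps(truth))

    _write_table(result.dataset.to_frame(), out / "cumulative.csv", chash)
    clusters = pd.DataFrame({
        "row": np.arange(len(result.dataset.species)),
        "species": result.dataset.species,
        "cluster": result.cluster_model.labels,
        "pc1": result.pca_coords[:, 0],
        "pc2": result.pca_coords[:, 1],
    })
    _write_table(clusters, out / "clusters.csv", chash)
    _write_table(result.signatures, out / "signatures.csv", chash)

    (out / "linkage.json").write_text(json.dumps({
        "config_hash": chash,
        "method": result.cluster_model.method,
        "metric": result.cluster_model.metric,
        "merges": result.cluster_model.linkage.tolist(),
    }))

    for cid, report in result.reports.items():
        _write_table(report.confusion.reset_index(names="true_class"),
                     out / f"cluster{cid}_confusion.csv", chash)

    report_json = {
        "config_hash": chash,
        "hopkins": result.hopkins,
        "k": result.k,
        "k_votes": result.k_votes,
        "species_clusters": result.species_clusters,
        "lof": {
            name: {"n_neighbors": p.n_neighbors, "minkowski_p": p.minkowski_p,
                   "score_threshold": p.score_threshold,
                   "silhouette": result.lof_silhouette[name],
                   "frames_kept": result.frames_kept[name],
                   "frames_total": len(result.sessions[name].frames)}
            for name, p in result.lof_params.items()
        },
        "pca_explained_variance": result.pca_variance.tolist(),
        "rosters": {str(k): list(v) for k, v in result.rosters.items()},
        "recall": {str(cid): rep.recall.to_dict() for cid, rep in result.reports.items()},
    }
    (out / "report.json").write_text(json.dumps(report_json, indent=2))

    manifest = {
        "package_version": __version__,
        "seed": result.seed,
        "stage_seed_derivation": f"SeedSequence({result.seed}).spawn({len(STAGES)}) -> {list(STAGES)}",
        "config_hash": chash,
        "config": result.config.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    return out
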