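"""Pipeline orchestration: ensemble -> filter -> features -> cluster ->
(dynamics) -> AMINO -> SPIB, driven by one YAML config.

Each stage writes its artifacts plus a ``manifest.json`` recording the
parameters and a chained content hash of everything upstream; re-running
with an unchanged config skips stages whose manifests match (idempotent
resume).  The dynamics stage is an explicit external boundary: the pipeline
emits cluster-center structures and a CV watch-list, then ingests time
series — either user-provided files from real MD, or the built-in toy
emulation of short runs around each center.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .amino import amino_reduce
from .cluster import regular_space_cluster, suggest_d_min
from .features import (
    compute_features,
    enumerate_pair_features,
    rank_by_cov,
    rmsd_filter,
    select_reference,
)
from .selection import AtomSelection
from .spib import SPIB, SpibConfig
from .structure_io import load_ensemble, load_timeseries, write_structure, write_timeseries
from .toy_dynamics import emulate_md_from_centers

logger = logging.getLogger("statefinder.pipeline")

STAGES = ["load", "filter", "features", "cluster", "dynamics", "amino", "spib"]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Validated stage-block configuration for a full pipeline run."""

    output_dir: str
    seed: int = 0
    io: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    dynamics: dict = field(default_factory=dict)
    amino: dict = field(default_factory=dict)
    spib: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        """Check every numeric parameter before any stage runs."""
        if "structures" not in self.io:
            raise ValueError("io.structures (file list or glob) is required")
        if "selection" not in self.io:
            raise ValueError("io.selection is required")
        AtomSelection(self.io["selection"])  # parse errors surface here
        if "cutoff" not in self.filter:
            raise ValueError(
                "filter.cutoff (RMSD cutoff in Angstrom) is required; "
                "there is no default"
            )
        if self.filter["cutoff"] <= 0:
            raise ValueError("filter.cutoff must be positive")
        if self.features.get("min_residue_separation", 3) < 0:
            raise ValueError("features.min_residue_separation must be >= 0")
        d_min = self.cluster.get("d_min")
        if d_min is not None and d_min < 0:
            raise ValueError("cluster.d_min must be >= 0")
        if self.amino.get("k_max", 20) < 1:
            raise ValueError("amino.k_max must be >= 1")
        if self.amino.get("n_bins", 20) < 2:
            raise ValueError("amino.n_bins must be >= 2")
        spib_cfg = self.spib_config()  # SpibConfig validates its own fields
        n_frames = self._dynamics_frame_counts()
        if n_frames is not None and spib_cfg.lag_steps >= min(n_frames):
            raise ValueError(
                f"spib.lag_steps={spib_cfg.lag_steps} is not smaller than the "
                f"shortest trajectory ({min(n_frames)} frames)"
            )

    def _dynamics_frame_counts(self) -> list[int] | None:
        mode = self.dynamics.get("mode", "emulate")
        if mode == "files":
            files = self.dynamics.get("files", [])
            if not files:
                raise ValueError("dynamics.files required when mode is 'files'")
            counts = []
            for f in files:
                if not Path(f).exists():
                    raise FileNotFoundError(f"dynamics file not found: {f}")
                with open(f) as fh:
                    counts.append(
                        sum(
                            1
                            for line in fh
                            if line.strip() and not line.startswith("#")
                        )
                    )
            return counts
        if mode == "emulate":
            return [int(self.dynamics.get("n_frames", 5000))]
        raise ValueError(f"unknown dynamics.mode {mode!r}")

    def spib_config(self) -> SpibConfig:
        kwargs = dict(self.spib)
        kwargs.setdefault("lag_steps", 10)
        kwargs.setdefault("seed", self.seed)
        return SpibConfig(**kwargs)


# ---------------------------------------------------------------------------
# Manifest helpers
# ---------------------------------------------------------------------------

def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_hash(params: dict, seed: int, upstream: str, file_hashes: list[str]) -> str:
    payload = json.dumps(
        {"params": params, "seed": seed, "upstream": upstream, "files": file_hashes},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def _write_manifest(
    out_root: Path, stage_dir: Path, stage: str, digest: str, params: dict, outputs: list[str]
) -> dict:
    # outputs are stored relative to the run directory so that two runs of
    # the same config in different locations produce identical manifests
    import os

    rel = [
        os.path.relpath(o, out_root) if os.path.isabs(o) else o for o in outputs
    ]
    manifest = {"stage": stage, "hash": digest, "params": params, "outputs": rel}
    stage_dir.mkdir(parents=True, exist_ok=True)
    with open(stage_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _manifest_matches(out_root: Path, stage_dir: Path, digest: str) -> bool:
    mf = stage_dir / "manifest.json"
    if not mf.exists():
        return False
    with open(mf) as fh:
        manifest = json.load(fh)
    if manifest.get("hash") != digest:
        return False
    return all((out_root / o).exists() or Path(o).exists() for o in manifest["outputs"])


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------

def run_pipeline(
    config: PipelineConfig | str | Path,
    from_stage: str | None = None,
    to_stage: str | None = None,
) -> dict:
    """Run the workflow, returning a manifest dict keyed by stage name."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    config.validate()
    out_root = Path(config.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)

    start = STAGES.index(from_stage) if from_stage else 0
    stop = STAGES.index(to_stage) if to_stage else len(STAGES) - 1
    if start > 0:
        for prior in STAGES[:start]:
            if not (out_root / prior / "manifest.json").exists():
                raise FileNotFoundError(
                    f"missing upstream artifacts for stage {prior!r}; "
                    f"re-run from stage {prior!r}"
                )

    manifests: dict[str, dict] = {}
    upstream_hash = ""
    state: dict = {}
    selection = AtomSelection(config.io["selection"])

    for stage in STAGES[: stop + 1]:
        stage_dir = out_root / stage
        params = getattr(config, stage if stage != "load" else "io", {})
        if stage == "load":
            paths = config.io["structures"]
            if isinstance(paths, str):
                import glob as _glob

                paths = sorted(_glob.glob(paths)) or [paths]
            file_hashes = [_hash_file(Path(p)) for p in paths]
        else:
            file_hashes = []
        digest = _stage_hash(dict(params), config.seed, upstream_hash, file_hashes)
        skip = _manifest_matches(out_root, stage_dir, digest)

        runner = _STAGE_RUNNERS[stage]
        outputs = runner(config, selection, state, stage_dir, reuse=skip)
        if skip:
            logger.info("stage %s: unchanged, reusing artifacts", stage)
            with open(stage_dir / "manifest.json") as fh:
                manifests[stage] = json.load(fh)
        else:
            logger.info("stage %s: computed %d outputs", stage, len(outputs))
            manifests[stage] = _write_manifest(out_root, stage_dir, stage, digest, dict(params), outputs)
        upstream_hash = digest

    with open(out_root / "run_manifest.json", "w") as fh:
        json.dump(manifests, fh, indent=2, default=str)
    return manifests


# ---------------------------------------------------------------------------
# Stage implementations (each recomputes state; artifacts written once)
# ---------------------------------------------------------------------------

def _stage_load(config, selection, state, stage_dir, reuse):
    ensemble = load_ensemble(config.io["structures"], selection)
    state["ensemble"] = ensemble
    out = stage_dir / "ensemble_ids.csv"
    if not reuse:
        stage_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"source_id": ensemble.source_ids, "mean_plddt": ensemble.mean_plddt}
        ).to_csv(out, index=False)
    return [str(out)]


def _stage_filter(config, selection, state, stage_dir, reuse):
    ensemble = state["ensemble"]
    ref = config.filter.get("reference")
    ref = select_reference(ensemble) if ref is None else int(ref)
    filtered, rmsds = rmsd_filter(ensemble, ref, config.filter["cutoff"])
    state["ensemble"] = filtered
    state["reference_index"] = ref
    out = stage_dir / "rmsd_filter.csv"
    if not reuse:
        stage_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {
                "source_id": ensemble.source_ids,
                "rmsd": rmsds,
                "kept": [sid in set(filtered.source_ids) for sid in ensemble.source_ids],
            }
        ).to_csv(out, index=False)
    return [str(out)]


def _stage_features(config, selection, state, stage_dir, reuse):
    ensemble = state["ensemble"]
    specs = enumerate_pair_features(
        ensemble.atoms,
        min_residue_separation=config.features.get("min_residue_separation", 3),
    )
    matrix = compute_features(ensemble, specs)
    top, stats = rank_by_cov(matrix, top_m=config.features.get("top_m"))
    state["features"] = top
    outputs = []
    if not reuse:
        stage_dir.mkdir(parents=True, exist_ok=True)
        stats.to_csv(stage_dir / "feature_stats.csv", index=False)
        pd.DataFrame(top.values, columns=top.labels).assign(
            source_id=top.source_ids
        ).to_csv(stage_dir / "feature_matrix.csv", index=False)
        (stage_dir / "cv_watchlist.txt").write_text("\n".join(top.labels) + "\n")
    outputs = [
        str(stage_dir / "feature_stats.csv"),
        str(stage_dir / "feature_matrix.csv"),
        str(stage_dir / "cv_watchlist.txt"),
    ]
    return outputs


def _stage_cluster(config, selection, state, stage_dir, reuse):
    top = state["features"]
    ensemble = state["ensemble"]
    d_min = config.cluster.get("d_min")
    if d_min is None:
        target = tuple(config.cluster.get("target_centers", (5, 20)))
        d_min, _ = suggest_d_min(top, target_centers=target)
    result = regular_space_cluster(top, d_min)
    state["cluster"] = result
    outputs = []
    if not reuse:
        centers_dir = stage_dir / "centers"
        if centers_dir.exists():
            shutil.rmtree(centers_dir)
        for idx in result.center_indices:
            name = top.source_ids[idx].replace("#", "_")
            if not name.endswith(".pdb"):
                name += ".pdb"
            write_structure(
                ensemble.coords[idx], ensemble.atoms, ensemble.b_factors[idx],
                centers_dir / name,
            )
        pd.DataFrame(
            {
                "center_index": result.center_indices,
                "source_id": [top.source_ids[i] for i in result.center_indices],
            }
        ).to_csv(stage_dir / "centers.csv", index=False)
        pd.DataFrame(
            {"source_id": top.source_ids, "center": result.assignments}
        ).to_csv(stage_dir / "assignments.csv", index=False)
    outputs = [str(stage_dir / "centers.csv"), str(stage_dir / "assignments.csv")]
    return outputs


def _stage_dynamics(config, selection, state, stage_dir, reuse):
    mode = config.dynamics.get("mode", "emulate")
    top = state["features"]
    if mode == "files":
        ts = load_timeseries(
            config.dynamics["files"],
            dt=config.dynamics.get("dt", 1.0),
            column_names=top.labels,
        )
        state["timeseries"] = ts
        return [str(f) for f in config.dynamics["files"]]
    result = state["cluster"]
    centers = top.values[result.center_indices]
    ts = emulate_md_from_centers(
        centers,
        top.labels,
        n_frames=int(config.dynamics.get("n_frames", 5000)),
        kappa=float(config.dynamics.get("kappa", 1.0)),
        temperature=float(config.dynamics.get("temperature", 0.05)),
        dt=float(config.dynamics.get("dt", 0.1)),
        seed=config.seed,
    )
    state["timeseries"] = ts
    traj_dir = stage_dir / "trajectories"
    if not reuse:
        if traj_dir.exists():
            shutil.rmtree(traj_dir)
        write_timeseries(ts, traj_dir)
    return [str(traj_dir / f"{tid}.dat") for tid in ts.traj_ids]


def _stage_amino(config, selection, state, stage_dir, reuse):
    ts = state["timeseries"]
    result = amino_reduce(
        ts,
        k_max=int(config.amino.get("k_max", 20)),
        n_bins=int(config.amino.get("n_bins", 20)),
        seed=config.seed,
    )
    state["amino"] = result
    state["timeseries_reduced"] = ts.select_columns(result.selected)
    if not reuse:
        stage_dir.mkdir(parents=True, exist_ok=True)
        (stage_dir / "selected_cvs.txt").write_text("\n".join(result.selected) + "\n")
        pd.DataFrame(
            result.distance_matrix, index=ts.column_names, columns=ts.column_names
        ).to_csv(stage_dir / "mi_distance.csv")
    return [str(stage_dir / "selected_cvs.txt"), str(stage_dir / "mi_distance.csv")]


def _stage_spib(config, selection, state, stage_dir, reuse):
    from .spib import SpibResult

    ts = state["timeseries_reduced"]
    if reuse:
        # model retraining is the expensive step; reload the checkpoint
        state["spib"] = SpibResult.load(stage_dir / "model.npz")
        return sorted(str(p) for p in stage_dir.glob("*") if p.name != "manifest.json")
    cfg = config.spib_config()
    result = SPIB(ts, cfg).fit()
    state["spib"] = result
    outputs = [str(stage_dir / "model.npz"), str(stage_dir / "summary.txt")]
    if not reuse:
        stage_dir.mkdir(parents=True, exist_ok=True)
        result.save(stage_dir / "model.npz")
        (stage_dir / "summary.txt").write_text(result.summary() + "\n")
        for tid, lab, lat in zip(
            ts.traj_ids, result.labels.labels, result.labels.latent
        ):
            df = pd.DataFrame(lat, columns=[f"latent{i}" for i in range(lat.shape[1])])
            df.insert(0, "state", lab)
            df.to_csv(stage_dir / f"labels_{tid}.csv", index=False)
            outputs.append(str(stage_dir / f"labels_{tid}.csv"))
        # project the (filtered) ensemble structures into the learned states
        top = state["features"]
        reduced = [top.labels.index(c) for c in result.column_names]
        latent, _, states = result.project(top.values[:, reduced])
        pd.DataFrame(
            {
                "source_id": top.source_ids,
                "state": states,
                "latent0": latent[:, 0],
                "latent1": latent[:, min(1, latent.shape[1] - 1)],
            }
        ).to_csv(stage_dir / "ensemble_states.csv", index=False)
    outputs.append(str(stage_dir / "ensemble_states.csv"))
    return outputs


_STAGE_RUNNERS = {
    "load": _stage_load,
    "filter": _stage_filter,
    "features": _stage_features,
    "cluster": _stage_cluster,
    "dynamics": _stage_dynamics,
    "amino": _stage_amino,
    "spib": _stage_spib,
}
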