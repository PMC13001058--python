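"""End-to-end orchestration: corpus stats → maps → tests → networks.

A run is described by a structured config (YAML/dict). Every enabled stage
writes its outputs under the run directory and the run ends with a manifest
recording the package version, a hash of the resolved config, the seeds
used, and a checksum per output file; re-running an identical config
reproduces identical checksums for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .corpus import corpus_summary, filter_for_synthesis, packaged_corpus, read_corpus
from .inference import InsufficientGroupsError, kruskal_outcome, pairwise_roi_fisher
from .connectivity import external_network, internal_network
from .simulate import NetworkSpec, make_normative_sample, make_synthetic_atlas
from .synthesis import directionality_map, frequency_map, outcome_map


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    output_dir: str = "lesionsynth-run"
    corpus_path: str | None = None  # None -> packaged corpus
    procedure: str | None = None
    alpha: float = 0.05
    overlap_fraction: float = 0.5
    linkage: str = "average"
    cut_k: int = 2
    seed: int = 0
    top_k_rois: int = 4
    min_studies: int = 3
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_rois: int = 6
    roi_radius_voxels: int = 2
    n_subjects: int = 10
    n_timepoints: int = 500
    stages: dict[str, bool] = field(default_factory=lambda: {
        "corpus": True, "maps": True, "inference": True, "networks": True,
    })

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid_shape" in raw:
            raw["grid_shape"] = tuple(raw["grid_shape"])
        stages = cls().stages | raw.get("stages", {})
        raw["stages"] = stages
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages in dependency order and write a manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "lesionsynth",
        "version": __version__,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
    }
    outputs: list[Path] = []

    corpus = None
    if any(config.stages.get(s) for s in ("corpus", "maps", "inference")):
        corpus = packaged_corpus() if config.corpus_path is None else read_corpus(config.corpus_path)

    if config.stages.get("corpus"):
        try:
            summary = corpus_summary(corpus)
            path = out / "corpus_summary.json"
            path.write_text(json.dumps(dataclasses.asdict(summary), indent=2, sort_keys=True))
            outputs.append(path)
            manifest["stages"]["corpus"] = "ok"
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise StageError(f"stage 'corpus' failed: {exc}") from exc

    synth = filter_for_synthesis(corpus) if corpus is not None else None

    if config.stages.get("maps"):
        try:
            jobs = {
                "frequency_predictor": frequency_map(synth, "preoperative_predictor", config.procedure),
                "frequency_postop": frequency_map(synth, "postoperative_change", config.procedure),
                "directionality_volume": directionality_map(synth, "volume", config.procedure),
                "directionality_metabolism": directionality_map(synth, "glucose_metabolism", config.procedure),
                "outcome": outcome_map(synth, config.procedure),
            }
            for name, stat_map in jobs.items():
                path = out / f"map_{name}.tsv"
                stat_map.to_frame().to_csv(path, sep="\t", index=False)
                outputs.append(path)
            manifest["stages"]["maps"] = "ok"
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage 'maps' failed: {exc}") from exc

    if config.stages.get("inference"):
        try:
            freq = frequency_map(synth, "postoperative_change", config.procedure)
            ranked = sorted(freq.values, key=lambda r: (-freq.values[r], r))
            top = ranked[: config.top_k_rois]
            result: dict = {"top_rois": [str(r) for r in top]}
            if len(top) >= 2:
                pairs = pairwise_roi_fisher(synth, top, "postoperative_change", config.procedure)
                result["pairwise_fisher"] = [
                    {
                        "roi_a": str(res.roi_a),
                        "roi_b": str(res.roi_b),
                        "table": res.table,
                        "p": res.p_value,
                    }
                    for (a, b), res in sorted(pairs.items(), key=lambda kv: str(kv[0]))
                    if a < b
                ]
            try:
                kw = kruskal_outcome(synth, config.min_studies, config.procedure)
                result["kruskal"] = {
                    "H": kw.H,
                    "p": kw.p_value,
                    "groups": {str(r): list(v) for r, v in sorted(kw.groups.items())},
                }
            except InsufficientGroupsError as exc:
                result["kruskal"] = {"error": str(exc)}
            path = out / "inference.json"
            path.write_text(json.dumps(result, indent=2, sort_keys=True))
            outputs.append(path)
            manifest["stages"]["inference"] = "ok"
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage 'inference' failed: {exc}") from exc

    if config.stages.get("networks"):
        try:
            import nibabel as nib
            import pandas as pd

            atlas = make_synthetic_atlas(config.grid_shape, config.n_rois,
                                         config.roi_radius_voxels, seed=config.seed)
            spec = NetworkSpec(n_modules=2, rois_per_module=max(1, config.n_rois // 2),
                               n_subjects=config.n_subjects, n_timepoints=config.n_timepoints,
                               seed=config.seed)
            sample = make_normative_sample(atlas, spec)
            rois = atlas.rois
            net = internal_network(sample, atlas, rois, config.linkage, config.cut_k)
            rows = [
                {
                    "roi": str(r),
                    "cluster": net.cluster_assignment[r],
                    "betweenness": net.betweenness[r],
                    "closeness": net.closeness[r],
                }
                for r in net.nodes
            ]
            path = out / "internal_network.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            outputs.append(path)

            overlap = external_network(sample, atlas, rois, config.alpha, config.overlap_fraction)
            for name, vol in (("overlap_count", overlap.count_volume.astype("int16")),
                              ("overlap_threshold", overlap.threshold_volume.astype("uint8"))):
                path = out / f"external_{name}.nii"
                nib.save(nib.Nifti1Image(vol, atlas.affine), str(path))
                outputs.append(path)
            manifest["stages"]["networks"] = "ok"
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage 'networks' failed: {exc}") from exc

    for path in outputs:
        manifest["outputs"][path.name] = _sha256(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
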