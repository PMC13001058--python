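"""Synthetic inputs: parcellations, normative BOLD samples with planted
network structure, and random corpora.

The BOLD generator emulates the statistical skeleton of a normative
resting-state dataset: latent module signals shared by the voxels of the
ROIs belonging to a module, optional hub voxels loading on *all* module
signals, and independent Gaussian noise everywhere else. Population
voxel–latent correlation equals ``within_module_corr``, so two voxels
sharing a latent correlate at ``within_module_corr**2``. Everything is a
pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import Atlas, ROIRef
from .connectivity import NormativeSample
from .corpus import Corpus, Finding, StudyRecord


class PackingError(ValueError):
    """Requested parcels do not fit in the grid without overlap."""


@dataclass(frozen=True)
class NetworkSpec:
    n_modules: int = 2
    rois_per_module: int = 3
    within_module_corr: float = 0.8
    across_module_corr: float = 0.0
    hub_fraction: float = 0.02
    noise_sd: float = 1.0
    n_subjects: int = 10
    n_timepoints: int = 500
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.within_module_corr < 1.0:
            raise ValueError("within_module_corr must lie in (0, 1)")
        if not 0.0 <= self.across_module_corr < 1.0:
            raise ValueError("across_module_corr must lie in [0, 1)")
        if self.within_module_corr <= self.across_module_corr:
            raise ValueError("within_module_corr must exceed across_module_corr")
        if not 0.0 <= self.hub_fraction <= 1.0:
            raise ValueError("hub_fraction must lie in [0, 1]")
        if self.noise_sd <= 0.0:
            raise ValueError("noise_sd must be positive")
        if self.n_timepoints < 50:
            raise ValueError("need n_timepoints >= 50 for recovery tests")


@dataclass(frozen=True)
class CorpusSpec:
    n_studies: int = 20
    n_range: tuple[int, int] = (3, 53)
    roi_pool: tuple[ROIRef, ...] = ()
    citation_probs: dict[ROIRef, float] = field(default_factory=dict)
    direction_prob_increase: float = 0.3
    ybocs_delta_mean: float = 14.0
    ybocs_delta_sd: float = 3.0
    missing_ybocs_prob: float = 0.3
    mixed_cohort_prob: float = 0.0
    eegmeg_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_range[0] < 1 or self.n_range[0] > self.n_range[1]:
            raise ValueError("n_range must satisfy 1 <= min <= max")
        for p in (self.direction_prob_increase, self.missing_ybocs_prob,
                  self.mixed_cohort_prob, self.eegmeg_prob, *self.citation_probs.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


# --- synthetic parcellation ----------------------------------------------

def make_synthetic_atlas(
    grid_shape: tuple[int, int, int] = (32, 32, 32),
    n_rois: int = 6,
    roi_radius_voxels: int = 2,
    seed: int = 0,
    voxel_size_mm: float = 2.0,
) -> Atlas:
    """Disjoint spherical parcels on a centered grid.

    Candidate centers sit on a regular lattice with spacing 2r + 2 so
    spheres can never touch; a seeded shuffle picks ``n_rois`` of them.
    Hemisphere names follow the sign of the world x coordinate.
    """
    shape = tuple(int(s) for s in grid_shape)
    r = int(roi_radius_voxels)
    spacing = 2 * r + 2
    axes = [np.arange(r + 1, s - r - 1, spacing) for s in shape]
    if any(a.size == 0 for a in axes):
        raise PackingError(f"no room for radius-{r} parcels in grid {shape}")
    centers = np.array(np.meshgrid(*axes, indexing="ij")).reshape(3, -1).T
    if len(centers) < n_rois:
        raise PackingError(f"grid {shape} fits only {len(centers)} radius-{r} parcels, not {n_rois}")
    rng = np.random.default_rng(seed)
    centers = centers[rng.permutation(len(centers))[:n_rois]]

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = -voxel_size_mm * (np.array(shape) - 1) / 2.0
    vol = np.zeros(shape, dtype=np.int32)
    grid = np.indices(shape)
    rows = []
    for label, c in enumerate(centers, start=1):
        sphere = ((grid - c.reshape(3, 1, 1, 1)) ** 2).sum(axis=0) <= r * r
        vol[sphere] = label
        world_x = affine[0, 0] * c[0] + affine[0, 3]
        hemi = "midline" if world_x == 0 else ("L" if world_x < 0 else "R")
        rows.append({"label_id": label, "name": f"parcel-{label:02d}", "hemisphere": hemi})
    return Atlas("synthetic", vol, affine, pd.DataFrame(rows))


# --- synthetic normative BOLD sample -------------------------------------

def make_normative_sample(atlas: Atlas, spec: NetworkSpec) -> NormativeSample:
    """Planted-module BOLD sample on the atlas grid.

    The first ``n_modules × rois_per_module`` parcels (label order) are
    assigned to modules in contiguous blocks. Module latents are unit
    variance with pairwise correlation ``across_module_corr``. Each ROI
    voxel is α·latent + noise_sd·ε with α set so the voxel–latent
    correlation is ``within_module_corr``; hub voxels (a seeded fixed subset
    of non-ROI brain voxels) load the same way on the equal mix of all
    module latents; remaining voxels are pure noise.
    """
    rois = atlas.rois
    needed = spec.n_modules * spec.rois_per_module
    if needed > len(rois):
        raise ValueError(f"atlas has {len(rois)} parcels; spec needs {needed}")
    module_of_roi = {
        roi: i // spec.rois_per_module for i, roi in enumerate(rois[:needed])
    }
    shape = atlas.label_volume.shape
    rho, sigma = spec.within_module_corr, spec.noise_sd
    alpha = sigma * rho / math.sqrt(1.0 - rho * rho)

    roi_voxels = {
        roi: np.argwhere(atlas.label_volume == roi.label_id) for roi in rois
    }
    nonroi = np.argwhere(atlas.label_volume == 0)
    rng = np.random.default_rng(spec.seed)
    n_hub = int(math.floor(spec.hub_fraction * len(nonroi)))
    hub_idx = nonroi[rng.choice(len(nonroi), size=n_hub, replace=False)] if n_hub else np.empty((0, 3), int)
    hub_mask = np.zeros(shape, dtype=bool)
    if n_hub:
        hub_mask[tuple(hub_idx.T)] = True

    m, t = spec.n_modules, spec.n_timepoints
    cov = np.full((m, m), spec.across_module_corr) + (1.0 - spec.across_module_corr) * np.eye(m)
    chol = np.linalg.cholesky(cov)
    # unit-variance equal mix of all module latents
    hub_var = (np.ones(m) @ cov @ np.ones(m)) / (m * m)

    subjects = []
    for _ in range(spec.n_subjects):
        latents = rng.standard_normal((t, m)) @ chol.T
        data = (sigma * rng.standard_normal((*shape, t))).astype(np.float32)
        for roi, module in module_of_roi.items():
            idx = roi_voxels[roi]
            data[tuple(idx.T)] += (alpha * latents[:, module]).astype(np.float32)
        if n_hub:
            hub_latent = latents.mean(axis=1) / math.sqrt(hub_var)
            data[tuple(hub_idx.T)] += (alpha * hub_latent).astype(np.float32)
        subjects.append(data)

    return NormativeSample(
        subjects=subjects,
        affine=atlas.affine,
        brain_mask=np.ones(shape, dtype=bool),
        module_of_roi=module_of_roi,
        hub_mask=hub_mask,
    )


# --- synthetic corpora ----------------------------------------------------

def make_synthetic_corpus(spec: CorpusSpec, return_ledger: bool = False):
    """Random corpus of single-procedure studies over an ROI pool.

    Each pool ROI is cited independently per study with its citation
    probability (one volume finding per cited ROI, direction +1 with
    probability ``direction_prob_increase``). Y-BOCS: pre fixed at 30,
    post = 30 − Δ with Δ ~ Normal(mean, sd) truncated to [0, 30]. With
    ``return_ledger`` the generator also returns its internal citation
    record {roi: set of citing study_ids} as a self-consistency oracle.
    """
    if not spec.roi_pool:
        raise ValueError("roi_pool must be nonempty")
    rng = np.random.default_rng(spec.seed)
    lo, sc = 0.0, 30.0
    a = (lo - spec.ybocs_delta_mean) / spec.ybocs_delta_sd
    b = (sc - spec.ybocs_delta_mean) / spec.ybocs_delta_sd

    studies, findings = [], []
    ledger: dict[ROIRef, set[str]] = {roi: set() for roi in spec.roi_pool}
    for i in range(spec.n_studies):
        sid = f"synth{i:03d}"
        n = int(rng.integers(spec.n_range[0], spec.n_range[1] + 1))
        mixed = bool(rng.random() < spec.mixed_cohort_prob)
        eegmeg = bool(rng.random() < spec.eegmeg_prob)
        if rng.random() < spec.missing_ybocs_prob:
            pre = post = None
        else:
            delta = float(stats.truncnorm.rvs(
                a, b, loc=spec.ybocs_delta_mean, scale=spec.ybocs_delta_sd, random_state=rng
            ))
            pre, post = 30.0, 30.0 - delta
        studies.append(StudyRecord(
            study_id=sid,
            citation=f"Synthetic study {i}",
            n_treated=n,
            procedure="capsulotomy",
            lesion_modality="RF",
            imaging_modalities=frozenset({"EEG"} if eegmeg else {"sMRI"}),
            mixed_cohort=mixed,
            ybocs_pre_mean=pre,
            ybocs_post_mean=post,
        ))
        for j, roi in enumerate(spec.roi_pool):
            p = spec.citation_probs.get(roi, 0.5)
            if rng.random() >= p:
                continue
            ledger[roi].add(sid)
            direction = 1 if rng.random() < spec.direction_prob_increase else -1
            findings.append(Finding(
                finding_id=f"{sid}-f{j:03d}",
                study_id=sid,
                phase="postoperative_change",
                rois=(roi,),
                measure="band_power" if eegmeg else "volume",
                direction=None if eegmeg else direction,
                description="synthetic finding",
            ))
    corpus = Corpus(tuple(studies), tuple(findings))
    return (corpus, ledger) if return_ledger else corpus
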