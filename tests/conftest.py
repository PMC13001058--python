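from __future__ import annotations

import numpy as np
import pytest

import lesionsynth as ls


def make_roi(label_id: int, name: str, hemisphere: str = "L", atlas: str = "toy") -> ls.ROIRef:
    return ls.ROIRef(atlas, label_id, name, hemisphere)


def make_study(study_id, n, procedure="capsulotomy", ybocs=None, **kwargs):
    pre, post = (None, None) if ybocs is None else ybocs
    return ls.StudyRecord(
        study_id=study_id,
        citation=f"{study_id} et al.",
        n_treated=n,
        procedure=procedure,
        lesion_modality=kwargs.pop("lesion_modality", "RF"),
        imaging_modalities=frozenset(kwargs.pop("imaging_modalities", {"sMRI"})),
        ybocs_pre_mean=pre,
        ybocs_post_mean=post,
        **kwargs,
    )


def make_finding(study_id, rois, fid=None, phase="postoperative_change",
                 measure="volume", direction=None):
    return ls.Finding(
        finding_id=fid or f"{study_id}-f",
        study_id=study_id,
        phase=phase,
        rois=tuple(rois),
        measure=measure,
        direction=direction,
    )


@pytest.fixture(scope="session")
def fixture_corpus():
    return ls.packaged_corpus()


@pytest.fixture(scope="session")
def synthesis_corpus(fixture_corpus):
    return ls.filter_for_synthesis(fixture_corpus)


@pytest.fixture(scope="session")
def small_atlas():
    return ls.make_synthetic_atlas(grid_shape=(16, 16, 16), n_rois=4, roi_radius_voxels=1, seed=7)


@pytest.fixture(scope="session")
def small_sample(small_atlas):
    spec = ls.NetworkSpec(n_modules=2, rois_per_module=2, n_subjects=4,
                          n_timepoints=80, hub_fraction=0.01, seed=7)
    return ls.make_normative_sample(small_atlas, spec)


def random_corpus(seed: int, n_studies: int = 12) -> ls.Corpus:
    """Small random corpus with multi-ROI findings, both phases and
    occasional duplicate citations, for map-oracle equivalence tests."""
    rng = np.random.default_rng(seed)
    pool = [make_roi(i, f"region-{i}", "L" if i % 2 else "R") for i in range(1, 7)]
    studies, findings = [], []
    for i in range(n_studies):
        sid = f"s{i:02d}"
        has_scores = rng.random() > 0.3
        ybocs = (30.0, float(30.0 - rng.uniform(5, 20))) if has_scores else None
        studies.append(make_study(sid, int(rng.integers(3, 54)), ybocs=ybocs))
        for j in range(int(rng.integers(1, 4))):
            rois = list(rng.choice(len(pool), size=int(rng.integers(1, 4)), replace=False))
            phase = "postoperative_change" if rng.random() < 0.8 else "preoperative_predictor"
            if phase == "postoperative_change":
                measure = str(rng.choice(["volume", "glucose_metabolism", "perfusion"]))
                direction = None if measure == "perfusion" else int(rng.choice([-1, 1]))
            else:
                measure, direction = "functional_connectivity", None
            findings.append(make_finding(
                sid, [pool[k] for k in rois], fid=f"{sid}-f{j}",
                phase=phase, measure=measure, direction=direction,
            ))
    return ls.Corpus(tuple(studies), tuple(findings))
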