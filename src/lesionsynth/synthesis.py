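"""Composite ROI maps: frequency-weighted, directionality, and clinical
outcome, plus rendering to atlas-space volumes.

Three descriptive aggregation strategies over the corpus:

* frequency — for each ROI, the sum of treated-patient counts over the
  studies citing it (each study counts once per ROI no matter how many of
  its findings cite that ROI);
* directionality — the sample-size-weighted mean of ±1 increase/decrease
  labels per ROI for one directional measure, a normalized index in [-1, 1];
* outcome — the sample-size-weighted mean absolute Y-BOCS reduction over
  score-reporting studies citing the ROI in a postoperative finding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import Atlas, ROIRef, roi_mask
from .corpus import (
    DIRECTIONAL_MEASURES,
    Corpus,
    absolute_ybocs_reduction,
)


class UnsupportedMeasureError(ValueError):
    """Directionality is defined only for volume and glucose metabolism."""


class UnresolvableROIError(ValueError):
    """Stat map references a parcel the target atlas does not carry."""


@dataclass(frozen=True)
class ROIStatMap:
    """Mapping ROI → scalar with per-ROI support bookkeeping."""

    stat_kind: str  # frequency | directionality | outcome
    values: dict[ROIRef, float]
    support: dict[ROIRef, tuple[int, float]]  # (n_studies, total_weight)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        for roi, (n, _) in self.support.items():
            if n < 1:
                raise ValueError(f"{roi}: support must cover at least one study")
        if self.stat_kind == "directionality":
            for roi, v in self.values.items():
                if not -1.0 <= v <= 1.0 + 1e-12:
                    raise ValueError(f"{roi}: directionality {v} outside [-1, 1]")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "atlas": roi.atlas_name,
                "label_id": roi.label_id,
                "name": roi.name,
                "hemisphere": roi.hemisphere,
                "value": self.values[roi],
                "n_studies": self.support[roi][0],
                "total_weight": self.support[roi][1],
            }
            for roi in sorted(self.values)
        ]
        return pd.DataFrame(
            rows,
            columns=["atlas", "label_id", "name", "hemisphere", "value", "n_studies", "total_weight"],
        )


def _scope(corpus: Corpus, phase: str | None, procedure: str | None):
    """Findings (with their study records) matching phase/procedure filters."""
    by_id = {s.study_id: s for s in corpus.studies}
    for f in corpus.findings:
        if phase is not None and f.phase != phase:
            continue
        s = by_id[f.study_id]
        if procedure is not None and s.procedure != procedure:
            continue
        yield s, f


def frequency_map(corpus: Corpus, phase: str, procedure: str | None = None) -> ROIStatMap:
    """Patient-weighted citation frequency per ROI.

    F(roi) = Σ n_treated over studies with at least one qualifying finding
    citing the ROI. For the postoperative phase the corpus is expected to
    have passed :func:`~lesionsynth.corpus.filter_for_synthesis` first.
    """
    citing: dict[ROIRef, set[str]] = {}
    for s, f in _scope(corpus, phase, procedure):
        for roi in f.rois:
            citing.setdefault(roi, set()).add(s.study_id)
    by_id = {s.study_id: s for s in corpus.studies}
    values, support = {}, {}
    for roi, sids in citing.items():
        total = sum(by_id[sid].n_treated for sid in sids)
        values[roi] = float(total)
        support[roi] = (len(sids), float(total))
    return ROIStatMap("frequency", values, support, {"phase": phase, "procedure": procedure})


def directionality_map(corpus: Corpus, measure: str, procedure: str | None = None) -> ROIStatMap:
    """Normalized directionality index D(roi) ∈ [-1, 1].

    D = (Σ n_s·d_s) / (Σ n_s) over distinct (study, ROI, direction) terms
    with d ∈ {-1, +1}; a study reporting both directions for the same ROI
    contributes both terms and partially cancels itself.
    """
    if measure not in DIRECTIONAL_MEASURES:
        raise UnsupportedMeasureError(
            f"directionality defined for {sorted(DIRECTIONAL_MEASURES)}, not {measure!r}"
        )
    terms: set[tuple[str, ROIRef, int]] = set()
    for s, f in _scope(corpus, "postoperative_change", procedure):
        if f.measure != measure or f.direction is None:
            continue
        for roi in f.rois:
            terms.add((s.study_id, roi, f.direction))
    by_id = {s.study_id: s for s in corpus.studies}
    num: dict[ROIRef, float] = {}
    den: dict[ROIRef, float] = {}
    studies_of: dict[ROIRef, set[str]] = {}
    for sid, roi, d in terms:
        n = by_id[sid].n_treated
        num[roi] = num.get(roi, 0.0) + n * d
        den[roi] = den.get(roi, 0.0) + n
        studies_of.setdefault(roi, set()).add(sid)
    values = {roi: num[roi] / den[roi] for roi in num}
    support = {roi: (len(studies_of[roi]), den[roi]) for roi in num}
    return ROIStatMap("directionality", values, support, {"measure": measure, "procedure": procedure})


def outcome_map(corpus: Corpus, procedure: str | None = None) -> ROIStatMap:
    """Sample-size-weighted mean absolute Y-BOCS reduction per ROI.

    Only studies with a postoperative finding citing the ROI *and* reported
    cohort pre/post scores contribute; ROIs with no score-reporting citing
    study are absent from the map.
    """
    citing: dict[ROIRef, set[str]] = {}
    for s, f in _scope(corpus, "postoperative_change", procedure):
        if s.ybocs_pre_mean is None:
            continue
        for roi in f.rois:
            citing.setdefault(roi, set()).add(s.study_id)
    by_id = {s.study_id: s for s in corpus.studies}
    values, support = {}, {}
    for roi, sids in citing.items():
        weights = np.array([by_id[sid].n_treated for sid in sorted(sids)], dtype=float)
        deltas = np.array([absolute_ybocs_reduction(by_id[sid]) for sid in sorted(sids)])
        values[roi] = float(np.average(deltas, weights=weights))
        support[roi] = (len(sids), float(weights.sum()))
    return ROIStatMap("outcome", values, support, {"procedure": procedure})


def render_map(stat_map: ROIStatMap, atlas: Atlas, background_value: float = 0.0) -> nib.Nifti1Image:
    """Paint each ROI's voxels with its statistic on the atlas grid."""
    vol = np.full(atlas.label_volume.shape, float(background_value), dtype=np.float64)
    for roi, value in stat_map.values.items():
        if roi.atlas_name != atlas.name or not (atlas.labels["label_id"] == roi.label_id).any():
            raise UnresolvableROIError(f"cannot render {roi} on atlas {atlas.name!r}")
        vol[roi_mask(atlas, roi).data] = value
    return nib.Nifti1Image(vol, atlas.affine)


def write_map(stat_map: ROIStatMap, atlas: Atlas, volume_path, table_path, background_value=0.0) -> None:
    """Export a stat map as a NIfTI volume plus a delimited ROI table."""
    nib.save(render_map(stat_map, atlas, background_value), str(volume_path))
    stat_map.to_frame().to_csv(table_path, sep="\t", index=False)
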