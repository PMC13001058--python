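"""Inferential layer: exact tests on ROI citation frequencies and a
Kruskal–Wallis comparison of ROI-wise Y-BOCS reductions.

Each study is the unit of observation. ROI presence/absence per study is a
binary variable; citation proportions of two ROIs are compared with a
two-sided Fisher exact test over the same study denominator. Clinical
response per ROI is the multiset of study-level absolute Y-BOCS reductions
of the studies citing it; groups are *not* disjoint (a study feeds every ROI
it cites), which the Kruskal–Wallis p-value does not correct for — it is a
descriptive screen, not a strict test of independent groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .atlas import ROIRef
from .corpus import Corpus, StudyRecord, absolute_ybocs_reduction


class InsufficientGroupsError(ValueError):
    """Fewer than two ROI groups meet the minimum-study threshold."""


class MissingHemisphereError(ValueError):
    """Laterality test needs both L and R parcels for the base name."""


@dataclass(frozen=True)
class PairwiseFrequencyResult:
    roi_a: ROIRef
    roi_b: ROIRef
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: A, B; cols: cited, not cited
    p_value: float

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class KruskalResult:
    groups: dict[ROIRef, tuple[float, ...]]
    H: float
    p_value: float
    min_studies: int


def _scope_studies(corpus: Corpus, procedure: str | None) -> list[StudyRecord]:
    return [s for s in corpus.studies if procedure is None or s.procedure == procedure]


def _cited_study_ids(corpus: Corpus, roi: ROIRef, phase: str | None) -> set[str]:
    return {
        f.study_id
        for f in corpus.findings
        if (phase is None or f.phase == phase) and roi in f.rois
    }


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p (probability-mass rule)."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def _pair_result(corpus, roi_a, roi_b, phase, scope) -> PairwiseFrequencyResult:
    n = len(scope)
    sids = {s.study_id for s in scope}
    cited_a = len(_cited_study_ids(corpus, roi_a, phase) & sids)
    cited_b = len(_cited_study_ids(corpus, roi_b, phase) & sids)
    table = ((cited_a, n - cited_a), (cited_b, n - cited_b))
    if n == 0:
        warnings.warn(f"empty study scope for {roi_a} vs {roi_b}; p = 1", stacklevel=3)
        p = 1.0
    else:
        p = fisher_2x2(table)
    return PairwiseFrequencyResult(roi_a, roi_b, table, p)


def pairwise_roi_fisher(
    corpus: Corpus,
    rois: list[ROIRef],
    phase: str = "postoperative_change",
    procedure: str | None = None,
) -> dict[tuple[ROIRef, ROIRef], PairwiseFrequencyResult]:
    """Fisher exact test for every unordered ROI pair.

    The denominator is the studies of the (optionally procedure-restricted)
    corpus; citation means at least one finding of the given phase cites the
    ROI. Results are stored under both key orders.
    """
    if len(rois) < 2:
        raise ValueError("need at least two ROIs")
    scope = _scope_studies(corpus, procedure)
    out: dict[tuple[ROIRef, ROIRef], PairwiseFrequencyResult] = {}
    for i, roi_a in enumerate(rois):
        for roi_b in rois[i + 1:]:
            res = _pair_result(corpus, roi_a, roi_b, phase, scope)
            out[(roi_a, roi_b)] = res
            out[(roi_b, roi_a)] = PairwiseFrequencyResult(
                roi_b, roi_a, (res.table[1], res.table[0]), res.p_value
            )
    return out


def laterality_fisher(
    corpus: Corpus,
    roi_base_name: str,
    phase: str = "postoperative_change",
    procedure: str | None = None,
) -> PairwiseFrequencyResult:
    """Compare citation frequency of the left vs right parcel of a structure."""
    from .atlas import load_label_table, roi_from_label

    table = load_label_table()
    rows = table.loc[table["name"].str.lower() == roi_base_name.strip().lower()]
    by_hemi = {str(r["hemisphere"]): r for _, r in rows.iterrows()}
    if "L" not in by_hemi or "R" not in by_hemi:
        raise MissingHemisphereError(f"no L/R parcel pair for {roi_base_name!r}")
    left = roi_from_label(str(by_hemi["L"]["atlas"]), int(by_hemi["L"]["label_id"]), table)
    right = roi_from_label(str(by_hemi["R"]["atlas"]), int(by_hemi["R"]["label_id"]), table)
    return _pair_result(corpus, left, right, phase, _scope_studies(corpus, procedure))


def kruskal_outcome(
    corpus: Corpus,
    min_studies: int = 3,
    procedure: str | None = None,
) -> KruskalResult:
    """Kruskal–Wallis H over ROI-wise absolute Y-BOCS reductions.

    Groups are ROIs cited in postoperative findings by at least
    ``min_studies`` score-reporting studies; each such study contributes its
    cohort Δ to every ROI it cites. Tie-corrected H, chi-squared reference
    with (groups − 1) degrees of freedom.
    """
    by_id = {s.study_id: s for s in corpus.studies}
    scope_ids = {s.study_id for s in _scope_studies(corpus, procedure)}
    citing: dict[ROIRef, set[str]] = {}
    for f in corpus.findings:
        if f.phase != "postoperative_change" or f.study_id not in scope_ids:
            continue
        if by_id[f.study_id].ybocs_pre_mean is None:
            continue
        for roi in f.rois:
            citing.setdefault(roi, set()).add(f.study_id)
    groups = {
        roi: tuple(absolute_ybocs_reduction(by_id[sid]) for sid in sorted(sids))
        for roi, sids in citing.items()
        if len(sids) >= min_studies
    }
    if len(groups) < 2:
        raise InsufficientGroupsError(
            f"only {len(groups)} ROI group(s) have >= {min_studies} score-reporting studies"
        )
    ordered = sorted(groups)
    H, p = stats.kruskal(*[groups[roi] for roi in ordered])
    return KruskalResult(groups, float(H), float(p), min_studies)
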