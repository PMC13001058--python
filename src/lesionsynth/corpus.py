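"""Data model and I/O for the literature-extraction corpus.

The unit of observation is the *study*: a cohort of lesioned OCD patients
with one or more tabulated imaging findings, each finding citing one or more
atlas parcels (ROIs). Direction labels (+1 increase / -1 decrease) exist
only for postoperative volume and glucose-metabolism findings; every other
measure carries no direction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .atlas import ROIRef, load_label_table, roi_from_label

PROCEDURES = ("capsulotomy", "cingulotomy", "limbic_leukotomy", "subcaudate_tractotomy")
LESION_MODALITIES = ("RF", "GK", "MRgFUS", "LITT")
IMAGING_MODALITIES = ("sMRI", "dMRI", "rs_fMRI", "t_fMRI", "FDG_PET", "SPECT", "EEG", "MEG")
PHASES = ("preoperative_predictor", "postoperative_change")
MEASURES = (
    "volume",
    "glucose_metabolism",
    "perfusion",
    "functional_connectivity",
    "structural_connectivity",
    "fractional_anisotropy",
    "task_activation",
    "band_power",
)
#: measures for which an increase/decrease label is defined
DIRECTIONAL_MEASURES = frozenset({"volume", "glucose_metabolism"})

STUDY_COLUMNS = [
    "study_id", "citation", "n_treated", "procedure", "lesion_modality",
    "imaging_modalities", "mixed_cohort", "ybocs_pre_mean", "ybocs_post_mean",
]
FINDING_COLUMNS = [
    "finding_id", "study_id", "phase", "atlas", "label_id", "hemisphere",
    "measure", "direction", "description",
]


class SchemaError(ValueError):
    """Corpus table violates the documented schema."""


class EmptyCorpusError(ValueError):
    """Operation requires at least one study."""


class YbocsUnavailableError(ValueError):
    """Study does not report cohort-level pre/post Y-BOCS scores."""


@dataclass(frozen=True)
class StudyRecord:
    study_id: str
    citation: str
    n_treated: int
    procedure: str
    lesion_modality: str
    imaging_modalities: frozenset[str]
    mixed_cohort: bool = False
    ybocs_pre_mean: float | None = None
    ybocs_post_mean: float | None = None

    def __post_init__(self):
        if self.n_treated < 1:
            raise SchemaError(f"{self.study_id}: n_treated must be >= 1")
        if self.procedure not in PROCEDURES:
            raise SchemaError(f"{self.study_id}: unknown procedure {self.procedure!r}")
        if self.lesion_modality not in LESION_MODALITIES:
            raise SchemaError(f"{self.study_id}: unknown lesion modality {self.lesion_modality!r}")
        if not self.imaging_modalities:
            raise SchemaError(f"{self.study_id}: imaging_modalities must be nonempty")
        unknown = set(self.imaging_modalities) - set(IMAGING_MODALITIES)
        if unknown:
            raise SchemaError(f"{self.study_id}: unknown imaging modalities {sorted(unknown)}")
        if (self.ybocs_pre_mean is None) != (self.ybocs_post_mean is None):
            raise SchemaError(f"{self.study_id}: Y-BOCS pre/post must be present together")
        for v in (self.ybocs_pre_mean, self.ybocs_post_mean):
            if v is not None and not 0.0 <= v <= 40.0:
                raise SchemaError(f"{self.study_id}: Y-BOCS score {v} outside [0, 40]")


@dataclass(frozen=True)
class Finding:
    finding_id: str
    study_id: str
    phase: str
    rois: tuple[ROIRef, ...]
    measure: str
    direction: int | None = None
    description: str = ""

    def __post_init__(self):
        if self.phase not in PHASES:
            raise SchemaError(f"{self.finding_id}: unknown phase {self.phase!r}")
        if self.measure not in MEASURES:
            raise SchemaError(f"{self.finding_id}: unknown measure {self.measure!r}")
        if not self.rois:
            raise SchemaError(f"{self.finding_id}: finding must cite at least one ROI")
        if self.direction is not None:
            if self.direction not in (-1, 1):
                raise SchemaError(f"{self.finding_id}: direction must be -1, +1 or absent")
            if self.measure not in DIRECTIONAL_MEASURES:
                raise SchemaError(
                    f"{self.finding_id}: direction defined only for "
                    f"{sorted(DIRECTIONAL_MEASURES)}, not {self.measure!r}"
                )
            if self.phase == "preoperative_predictor":
                raise SchemaError(f"{self.finding_id}: predictor findings carry no direction")


@dataclass(frozen=True)
class Corpus:
    studies: tuple[StudyRecord, ...]
    findings: tuple[Finding, ...]

    def __post_init__(self):
        ids = [s.study_id for s in self.studies]
        dup = [i for i, c in Counter(ids).items() if c > 1]
        if dup:
            raise SchemaError(f"duplicate study_ids: {dup}")
        known = set(ids)
        for f in self.findings:
            if f.study_id not in known:
                raise SchemaError(f"{f.finding_id}: unresolvable study_id {f.study_id!r}")

    def study(self, study_id: str) -> StudyRecord:
        for s in self.studies:
            if s.study_id == study_id:
                return s
        raise KeyError(study_id)

    def findings_of(self, study_id: str) -> list[Finding]:
        return [f for f in self.findings if f.study_id == study_id]


@dataclass(frozen=True)
class CorpusSummary:
    n_studies: int
    total_patients: int
    median_n: float
    min_n: int
    max_n: int
    counts_by_procedure: dict[str, int] = field(default_factory=dict)
    counts_by_phase: dict[str, int] = field(default_factory=dict)
    counts_by_lesion_modality: dict[str, int] = field(default_factory=dict)
    counts_by_imaging_modality: dict[str, int] = field(default_factory=dict)


# --- I/O ------------------------------------------------------------------

def _parse_bool(value, context: str) -> bool:
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise SchemaError(f"{context}: cannot parse boolean {value!r}")


def read_corpus(path, label_table: pd.DataFrame | None = None) -> Corpus:
    """Read a corpus from a directory holding ``studies.tsv`` and ``findings.tsv``.

    ROI references in the findings table are resolved to named parcels
    through the curated vocabulary (or a caller-supplied label table).
    """
    root = Path(path)
    studies_df = pd.read_csv(root / "studies.tsv", sep="\t", dtype={"study_id": str},
                             float_precision="round_trip")
    findings_df = pd.read_csv(root / "findings.tsv", sep="\t", dtype={"study_id": str, "finding_id": str})
    return corpus_from_frames(studies_df, findings_df, label_table=label_table)


def corpus_from_frames(
    studies_df: pd.DataFrame,
    findings_df: pd.DataFrame,
    label_table: pd.DataFrame | None = None,
) -> Corpus:
    missing = set(STUDY_COLUMNS) - set(studies_df.columns)
    if missing:
        raise SchemaError(f"studies table missing columns {sorted(missing)}")
    missing = set(FINDING_COLUMNS) - set(findings_df.columns)
    if missing:
        raise SchemaError(f"findings table missing columns {sorted(missing)}")
    table = label_table if label_table is not None else load_label_table()

    studies = []
    for _, row in studies_df.iterrows():
        sid = str(row["study_id"])
        pre, post = row["ybocs_pre_mean"], row["ybocs_post_mean"]
        studies.append(
            StudyRecord(
                study_id=sid,
                citation=str(row["citation"]),
                n_treated=int(row["n_treated"]),
                procedure=str(row["procedure"]),
                lesion_modality=str(row["lesion_modality"]),
                imaging_modalities=frozenset(str(row["imaging_modalities"]).split(";")),
                mixed_cohort=_parse_bool(row["mixed_cohort"], sid),
                ybocs_pre_mean=None if pd.isna(pre) else float(pre),
                ybocs_post_mean=None if pd.isna(post) else float(post),
            )
        )

    findings = []
    for (fid, sid), group in findings_df.groupby(["finding_id", "study_id"], sort=False):
        phases = group["phase"].unique()
        measures = group["measure"].unique()
        directions = group["direction"].astype(str).str.strip().unique()
        if len(phases) > 1 or len(measures) > 1 or len(directions) > 1:
            raise SchemaError(f"{fid}: rows of one finding must share phase/measure/direction")
        raw_dir = directions[0]
        if raw_dir in ("NA", "nan", ""):
            direction = None
        else:
            try:
                direction = int(float(raw_dir))
            except ValueError as exc:
                raise SchemaError(f"{fid}: bad direction {raw_dir!r}") from exc
        rois = tuple(
            roi_from_label(str(r["atlas"]), int(r["label_id"]), table) for _, r in group.iterrows()
        )
        for roi, (_, r) in zip(rois, group.iterrows()):
            if str(r["hemisphere"]) != roi.hemisphere:
                raise SchemaError(
                    f"{fid}: hemisphere {r['hemisphere']!r} does not match parcel "
                    f"{roi.atlas_name}:{roi.label_id} ({roi.hemisphere})"
                )
        findings.append(
            Finding(
                finding_id=str(fid),
                study_id=str(sid),
                phase=str(phases[0]),
                rois=rois,
                measure=str(measures[0]),
                direction=direction,
                description="" if pd.isna(group.iloc[0]["description"]) else str(group.iloc[0]["description"]),
            )
        )
    return Corpus(tuple(studies), tuple(findings))


def corpus_to_frames(corpus: Corpus) -> tuple[pd.DataFrame, pd.DataFrame]:
    srows = []
    for s in corpus.studies:
        srows.append({
            "study_id": s.study_id,
            "citation": s.citation,
            "n_treated": s.n_treated,
            "procedure": s.procedure,
            "lesion_modality": s.lesion_modality,
            "imaging_modalities": ";".join(sorted(s.imaging_modalities)),
            "mixed_cohort": s.mixed_cohort,
            "ybocs_pre_mean": float("nan") if s.ybocs_pre_mean is None else s.ybocs_pre_mean,
            "ybocs_post_mean": float("nan") if s.ybocs_post_mean is None else s.ybocs_post_mean,
        })
    frows = []
    for f in corpus.findings:
        for roi in f.rois:
            frows.append({
                "finding_id": f.finding_id,
                "study_id": f.study_id,
                "phase": f.phase,
                "atlas": roi.atlas_name,
                "label_id": roi.label_id,
                "hemisphere": roi.hemisphere,
                "measure": f.measure,
                "direction": "NA" if f.direction is None else f.direction,
                "description": f.description,
            })
    return pd.DataFrame(srows, columns=STUDY_COLUMNS), pd.DataFrame(frows, columns=FINDING_COLUMNS)


def write_corpus(corpus: Corpus, path) -> None:
    """Write ``studies.tsv`` / ``findings.tsv`` under a directory."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    studies_df, findings_df = corpus_to_frames(corpus)
    studies_df.to_csv(root / "studies.tsv", sep="\t", index=False, float_format="%.17g")
    findings_df.to_csv(root / "findings.tsv", sep="\t", index=False, float_format="%.17g")


def packaged_corpus() -> Corpus:
    """The packaged 24-study OCD lesioning corpus."""
    from .atlas import _data_path

    return read_corpus(_data_path("studies.tsv").parent)


# --- filtering and descriptives ------------------------------------------

def filter_for_synthesis(corpus: Corpus) -> Corpus:
    """Drop mixed-cohort studies and studies with only EEG/MEG imaging.

    Idempotent; findings of removed studies are removed with them.
    """
    keep = [
        s for s in corpus.studies
        if not s.mixed_cohort and not s.imaging_modalities <= {"EEG", "MEG"}
    ]
    kept_ids = {s.study_id for s in keep}
    return Corpus(tuple(keep), tuple(f for f in corpus.findings if f.study_id in kept_ids))


def corpus_summary(corpus: Corpus) -> CorpusSummary:
    """Descriptive statistics over unique studies.

    The even-count median is the mean of the two central order statistics.
    """
    if not corpus.studies:
        raise EmptyCorpusError("corpus has no studies")
    ns = sorted(s.n_treated for s in corpus.studies)
    k = len(ns)
    median = float(ns[k // 2]) if k % 2 else (ns[k // 2 - 1] + ns[k // 2]) / 2.0
    by_phase = Counter()
    for phase in PHASES:
        cited = {f.study_id for f in corpus.findings if f.phase == phase}
        by_phase[phase] = len(cited)
    by_imaging = Counter()
    for s in corpus.studies:
        for m in s.imaging_modalities:
            by_imaging[m] += 1
    return CorpusSummary(
        n_studies=k,
        total_patients=int(sum(ns)),
        median_n=median,
        min_n=ns[0],
        max_n=ns[-1],
        counts_by_procedure=dict(Counter(s.procedure for s in corpus.studies)),
        counts_by_phase=dict(by_phase),
        counts_by_lesion_modality=dict(Counter(s.lesion_modality for s in corpus.studies)),
        counts_by_imaging_modality=dict(by_imaging),
    )


def absolute_ybocs_reduction(study: StudyRecord) -> float:
    """Mean absolute Y-BOCS reduction (pre − post); negative if scores worsened."""
    if study.ybocs_pre_mean is None or study.ybocs_post_mean is None:
        raise YbocsUnavailableError(f"{study.study_id}: cohort Y-BOCS scores not reported")
    return float(study.ybocs_pre_mean - study.ybocs_post_mean)
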