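"""Parcellation handling: label volumes, label tables, ROI masks and name
resolution.

An :class:`Atlas` couples a deterministic integer label image (0 =
background) with a label table giving each parcel a name and hemisphere.
Probabilistic atlases must be reduced to a maximum-probability label image
by the caller before loading; this module never thresholds.

Structure names reported in the literature are resolved to parcels through a
curated lexicon (shipped as package data), never by fuzzy string matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

HEMISPHERES = ("L", "R", "bilateral", "midline")


class AtlasError(ValueError):
    """Malformed atlas input (orphan labels, bad table)."""


class EmptyROIError(ValueError):
    """Requested parcel has no voxels in the label volume."""


class OutOfBoundsError(ValueError):
    """World coordinate falls outside the image grid."""


class UnresolvedNameError(KeyError):
    """Structure name absent from the lexicon."""


@dataclass(frozen=True, order=True)
class ROIRef:
    """Handle to one lateralized parcel of a named atlas."""

    atlas_name: str
    label_id: int
    name: str
    hemisphere: str

    def __post_init__(self):
        if self.hemisphere not in HEMISPHERES:
            raise AtlasError(f"bad hemisphere {self.hemisphere!r} for {self.name!r}")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.hemisphere} {self.name} [{self.atlas_name}:{self.label_id}]"


@dataclass(frozen=True)
class ROIMask:
    """Binary mask on the grid of its parent atlas."""

    data: np.ndarray
    affine: np.ndarray

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.data))


@dataclass
class Atlas:
    """Deterministic label image plus label table.

    ``labels`` has columns label_id, name, hemisphere; 0 is background and
    never appears in the table.
    """

    name: str
    label_volume: np.ndarray
    affine: np.ndarray
    labels: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.label_volume = np.asarray(self.label_volume)
        if self.label_volume.ndim != 3:
            raise AtlasError("label volume must be 3-D")
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            raise AtlasError("label volume must be an integer image")
        ids = self.labels["label_id"].to_numpy()
        if (ids <= 0).any():
            raise AtlasError("label_ids must be positive (0 is background)")
        if len(set(ids)) != len(ids):
            raise AtlasError("duplicate label_ids in label table")
        present = set(np.unique(self.label_volume)) - {0}
        orphans = sorted(present - set(int(i) for i in ids))
        if orphans:
            raise AtlasError(f"labels in volume but not in table: {orphans}")
        missing = sorted(set(int(i) for i in ids) - present)
        if missing:
            warnings.warn(
                f"atlas {self.name!r}: labels in table with no voxels: {missing}",
                stacklevel=2,
            )

    def roi_ref(self, label_id: int) -> ROIRef:
        row = self.labels.loc[self.labels["label_id"] == label_id]
        if row.empty:
            raise AtlasError(f"label {label_id} not in atlas {self.name!r}")
        r = row.iloc[0]
        return ROIRef(self.name, int(r["label_id"]), str(r["name"]), str(r["hemisphere"]))

    @property
    def rois(self) -> list[ROIRef]:
        return [self.roi_ref(int(i)) for i in self.labels["label_id"]]


def load_atlas(label_image_path, label_table_path, name: str | None = None) -> Atlas:
    """Load a NIfTI label image together with its delimited label table."""
    img = nib.load(str(label_image_path))
    vol = np.asanyarray(img.dataobj)
    if not np.issubdtype(vol.dtype, np.integer):
        rounded = np.rint(vol)
        if not np.allclose(vol, rounded):
            raise AtlasError("label image has non-integer voxel values")
        vol = rounded.astype(np.int32)
    table = pd.read_csv(label_table_path, sep="\t")
    required = {"label_id", "name", "hemisphere"}
    if not required.issubset(table.columns):
        raise AtlasError(f"label table missing columns {sorted(required - set(table.columns))}")
    atlas_name = name if name is not None else Path(str(label_image_path)).name.split(".")[0]
    return Atlas(atlas_name, vol, np.asarray(img.affine), table)


def roi_mask(atlas: Atlas, roi: ROIRef) -> ROIMask:
    """Binary mask of the voxels carrying the parcel's label."""
    if roi.atlas_name != atlas.name:
        raise AtlasError(f"ROI {roi} does not belong to atlas {atlas.name!r}")
    if roi.label_id == 0:
        raise AtlasError("label 0 is background, not a parcel")
    atlas.roi_ref(roi.label_id)  # raises if absent from table
    mask = atlas.label_volume == roi.label_id
    if not mask.any():
        raise EmptyROIError(f"parcel {roi} has no voxels in the label volume")
    return ROIMask(mask, atlas.affine)


def locate_roi(atlas: Atlas, world_coordinate) -> ROIRef:
    """Parcel at a world-space (mm) coordinate.

    Background coordinates are assigned to the nearest labeled voxel by
    Euclidean world distance; exact ties break to the smallest label_id.
    """
    xyz = np.asarray(world_coordinate, dtype=float)
    ijk = np.linalg.inv(atlas.affine) @ np.append(xyz, 1.0)
    idx = np.rint(ijk[:3]).astype(int)
    if (idx < 0).any() or (idx >= np.array(atlas.label_volume.shape)).any():
        raise OutOfBoundsError(f"coordinate {tuple(xyz)} outside the image grid")
    label = int(atlas.label_volume[tuple(idx)])
    if label != 0:
        return atlas.roi_ref(label)
    lab_idx = np.argwhere(atlas.label_volume > 0)
    if lab_idx.size == 0:
        raise AtlasError("atlas volume contains no labeled voxels")
    hom = np.c_[lab_idx, np.ones(len(lab_idx))]
    world = hom @ atlas.affine.T
    dist = np.linalg.norm(world[:, :3] - xyz, axis=1)
    best = dist.min()
    tied = np.isclose(dist, best, rtol=0.0, atol=1e-9)
    labels = atlas.label_volume[tuple(lab_idx[tied].T)]
    return atlas.roi_ref(int(labels.min()))


# --- curated name lexicon -------------------------------------------------

def _data_path(fname: str) -> Path:
    return Path(resources.files("lesionsynth.data").joinpath(fname))


def load_label_table(path=None) -> pd.DataFrame:
    """Curated lateralized parcel vocabulary (atlas, label_id, name, hemisphere)."""
    return pd.read_csv(path if path is not None else _data_path("roi_labels.tsv"), sep="\t")


def load_lexicon(path=None) -> pd.DataFrame:
    """Structure-name lexicon joined against the parcel vocabulary."""
    lex = pd.read_csv(path if path is not None else _data_path("lexicon.tsv"), sep="\t")
    labels = load_label_table()
    merged = lex.merge(labels, on=["atlas", "label_id"], how="left", validate="many_to_one")
    if merged["name"].isna().any():
        bad = merged.loc[merged["name"].isna(), "phrase"].tolist()
        raise AtlasError(f"lexicon phrases pointing at unknown parcels: {bad}")
    return merged


def roi_from_label(atlas_name: str, label_id: int, label_table: pd.DataFrame | None = None) -> ROIRef:
    """ROIRef for an (atlas, label_id) pair of the curated vocabulary."""
    table = label_table if label_table is not None else load_label_table()
    row = table.loc[(table["atlas"] == atlas_name) & (table["label_id"] == label_id)]
    if row.empty:
        raise AtlasError(f"unknown parcel {atlas_name}:{label_id}")
    r = row.iloc[0]
    return ROIRef(atlas_name, int(label_id), str(r["name"]), str(r["hemisphere"]))


_SIDE_PREFIXES = {"left": "L", "right": "R"}


def resolve_name(structure_name: str, lexicon: pd.DataFrame | None = None) -> list[ROIRef]:
    """Resolve a reported structure name to parcels.

    Case-insensitive exact lookup; ``"bilateral X"`` expands to the L and R
    entries, ``"left X"`` / ``"right X"`` select one hemisphere. Unknown
    names raise :class:`UnresolvedNameError` — there is no fuzzy matching.
    """
    lex = lexicon if lexicon is not None else load_lexicon()
    text = " ".join(structure_name.strip().lower().split())
    side = None
    first, _, rest = text.partition(" ")
    if first == "bilateral" and rest:
        text = rest
    elif first in _SIDE_PREFIXES and rest:
        side, text = _SIDE_PREFIXES[first], rest
    rows = lex.loc[lex["phrase"] == text]
    if side is not None:
        rows = rows.loc[rows["hemisphere"] == side]
    if rows.empty:
        raise UnresolvedNameError(f"structure name {structure_name!r} not in lexicon")
    refs = [
        ROIRef(str(r["atlas"]), int(r["label_id"]), str(r["name"]), str(r["hemisphere"]))
        for _, r in rows.iterrows()
    ]
    return sorted(set(refs), key=lambda r: (r.hemisphere, r.atlas_name, r.label_id))
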