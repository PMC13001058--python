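"""Normative-connectome stage: seed r-maps, group t-maps with whole-brain
Bonferroni control, external overlap networks, and internal ROI graphs.

The construction follows the standard normative seed-connectivity recipe:
per subject, the seed time series is the spatial mean BOLD signal over the
ROI's voxels and the r-map is the voxelwise Pearson correlation with that
series; group maps average Fisher-z transformed r over subjects; group
t-maps are one-sample t statistics of the subject z values (df = n − 1).
"significantly connected" is read as positive connectivity, so the
Bonferroni threshold is one-sided by default (two-sided by flag).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .atlas import Atlas, ROIMask, ROIRef, roi_mask

_ATANH_CLIP = 1.0 - 1e-7


class ConstantSeedError(ValueError):
    """Seed time series has zero variance."""


class TooFewSubjectsError(ValueError):
    """Group statistics need a minimal number of subjects."""


@dataclass
class NormativeSample:
    """Per-subject 4-D BOLD volumes sharing one grid and brain mask."""

    subjects: list[np.ndarray]
    affine: np.ndarray
    brain_mask: np.ndarray
    tr_seconds: float = 2.0
    # planted ground truth carried by synthetic samples (None for real data)
    module_of_roi: dict[ROIRef, int] | None = None
    hub_mask: np.ndarray | None = None

    def __post_init__(self):
        if not self.subjects:
            raise ValueError("sample has no subjects")
        shape = self.subjects[0].shape
        for s in self.subjects:
            if s.ndim != 4 or s.shape != shape:
                raise ValueError("all subjects must share one 4-D grid")
        if shape[3] < 8:
            raise ValueError("time series too short (need >= 8 volumes)")
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.brain_mask.shape != shape[:3]:
            raise ValueError("brain mask must match the subject grid")
        if not self.brain_mask.any():
            raise ValueError("brain mask is empty")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


@dataclass
class SeedMap:
    roi: ROIRef | None
    subject_maps: list[np.ndarray]
    group_map: np.ndarray


@dataclass
class GroupTMap:
    roi: ROIRef | None
    t_volume: np.ndarray
    df: int
    n_subjects: int

    def __post_init__(self):
        if self.df != self.n_subjects - 1:
            raise ValueError("df must equal n_subjects - 1")


@dataclass
class OverlapMap:
    count_volume: np.ndarray
    threshold_volume: np.ndarray
    n_rois: int
    alpha: float
    tau: int


@dataclass
class ROINetwork:
    nodes: list[ROIRef]
    similarity: np.ndarray
    linkage: np.ndarray
    cluster_assignment: dict[ROIRef, int]
    betweenness: dict[ROIRef, float]
    closeness: dict[ROIRef, float]
    graph: nx.Graph = field(repr=False)
    disconnected: bool = False


# --- seed correlation maps ------------------------------------------------

def seed_rmap(subject_4d: np.ndarray, roi: ROIMask | np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Voxelwise Pearson r with the ROI's mean time series.

    Returns a 3-D volume, NaN outside the brain mask and at zero-variance
    voxels (flagged undefined, excluded downstream).
    """
    seed_mask = roi.data if isinstance(roi, ROIMask) else np.asarray(roi, dtype=bool)
    if not seed_mask.any():
        raise ValueError("empty seed mask")
    data = np.asarray(subject_4d)
    mask = np.asarray(brain_mask, dtype=bool)
    seed = data[seed_mask].mean(axis=0).astype(np.float64)
    seed -= seed.mean()
    seed_ss = float(seed @ seed)
    if seed_ss <= 0.0:
        raise ConstantSeedError("seed time series has zero variance")
    vox = data[mask].astype(np.float64)
    vox -= vox.mean(axis=1, keepdims=True)
    vox_ss = np.einsum("ij,ij->i", vox, vox)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (vox @ seed) / np.sqrt(vox_ss * seed_ss)
    r[vox_ss <= 0.0] = np.nan
    out = np.full(data.shape[:3], np.nan)
    out[mask] = np.clip(r, -1.0, 1.0)
    return out


def group_rmap(
    sample: NormativeSample,
    roi_mask_or_ref,
    atlas: Atlas | None = None,
    combine: str = "fisher_z",
) -> SeedMap:
    """Per-subject seed r-maps and their group average.

    The group map is the voxelwise mean of Fisher-z transformed r,
    back-transformed to r (``combine="mean_r"`` switches to a plain mean).
    Voxels undefined in every subject stay NaN.
    """
    if sample.n_subjects < 2:
        raise TooFewSubjectsError("group map needs >= 2 subjects")
    roi_ref = None
    if isinstance(roi_mask_or_ref, ROIRef):
        if atlas is None:
            raise ValueError("resolving an ROIRef requires an atlas")
        roi_ref, mask = roi_mask_or_ref, roi_mask(atlas, roi_mask_or_ref)
    else:
        mask = roi_mask_or_ref
    maps = [seed_rmap(s, mask, sample.brain_mask) for s in sample.subjects]
    stack = np.stack(maps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN voxels
        if combine == "fisher_z":
            z = np.arctanh(np.clip(stack, -_ATANH_CLIP, _ATANH_CLIP))
            group = np.tanh(np.nanmean(z, axis=0))
        elif combine == "mean_r":
            group = np.nanmean(stack, axis=0)
        else:
            raise ValueError(f"unknown combine rule {combine!r}")
    group[~sample.brain_mask] = np.nan
    return SeedMap(roi_ref, maps, group)


def group_tmap(seedmap: SeedMap) -> GroupTMap:
    """One-sample t across subjects' Fisher-z values, voxelwise.

    t = mean(z) / (sd(z)/√n) with df = n − 1; voxels with zero variance
    across subjects (including constant nonzero z) are undefined (NaN) and
    are never declared significant downstream.
    """
    n = len(seedmap.subject_maps)
    if n < 3:
        raise TooFewSubjectsError("group t-map needs >= 3 subjects")
    z = np.arctanh(np.clip(np.stack(seedmap.subject_maps), -_ATANH_CLIP, _ATANH_CLIP))
    mean = z.mean(axis=0)  # NaN wherever any subject is undefined
    sd = z.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / math.sqrt(n))
    t[~np.isfinite(t)] = np.nan
    return GroupTMap(seedmap.roi, t, n - 1, n)


def bonferroni_mask(
    tmap: GroupTMap,
    brain_mask: np.ndarray,
    alpha: float = 0.05,
    two_sided: bool = False,
) -> np.ndarray:
    """Voxels surviving whole-brain Bonferroni control.

    The denominator V is the number of in-mask voxels with a defined t
    statistic (background voxels carry no test); a voxel is significant iff
    its tail p is strictly below alpha / V.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    t = tmap.t_volume
    defined = mask & np.isfinite(t)
    v = int(defined.sum())
    if v == 0:
        raise ValueError("no defined voxels under the brain mask")
    with np.errstate(invalid="ignore"):
        if two_sided:
            p = 2.0 * stats.t.sf(np.abs(t), tmap.df)
        else:
            p = stats.t.sf(t, tmap.df)
    out = np.zeros_like(mask)
    out[defined] = p[defined] < (alpha / v)
    return out


# --- external overlap network --------------------------------------------

def external_network(
    sample: NormativeSample,
    atlas: Atlas,
    rois: list[ROIRef],
    alpha: float = 0.05,
    fraction: float = 0.5,
    two_sided: bool = False,
) -> OverlapMap:
    """Count, per voxel, the seed ROIs it is significantly connected to.

    The threshold volume keeps voxels connected to at least
    ``ceil(fraction × n_rois)`` of the seeds.
    """
    if not rois:
        raise ValueError("need at least one ROI")
    counts = np.zeros(sample.brain_mask.shape, dtype=np.int32)
    for roi in rois:
        tm = group_tmap(group_rmap(sample, roi, atlas))
        counts += bonferroni_mask(tm, sample.brain_mask, alpha=alpha, two_sided=two_sided)
    tau = math.ceil(fraction * len(rois))
    return OverlapMap(counts, counts >= tau, len(rois), alpha, tau)


# --- internal ROI network -------------------------------------------------

def _spatial_similarity(group_maps, seed_masks, brain_mask) -> np.ndarray:
    """Pairwise Pearson correlation between group seed maps.

    For each pair, the correlation runs over in-mask voxels where both maps
    are defined, excluding the seed voxels of either ROI (their trivially
    high self-correlation would inflate similarity).
    """
    k = len(group_maps)
    sim = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            keep = brain_mask & ~seed_masks[i] & ~seed_masks[j]
            keep &= np.isfinite(group_maps[i]) & np.isfinite(group_maps[j])
            a, b = group_maps[i][keep], group_maps[j][keep]
            if a.size < 3 or a.std() == 0 or b.std() == 0:
                sim[i, j] = sim[j, i] = 0.0
                continue
            sim[i, j] = sim[j, i] = float(np.corrcoef(a, b)[0, 1])
    return sim


def centrality_from_similarity(nodes: list, similarity: np.ndarray):
    """Graph metrics on the positive-similarity graph.

    Edges are node pairs with similarity > 0, with path length
    1 − similarity. Returns (graph, betweenness, closeness, disconnected):
    normalized shortest-path betweenness and closeness as the inverse mean
    shortest-path length (harmonic variant, flagged, for disconnected
    graphs).
    """
    sim = np.asarray(similarity, dtype=float)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, node_a in enumerate(nodes):
        for j in range(i + 1, len(nodes)):
            if sim[i, j] > 0.0:
                g.add_edge(node_a, nodes[j], weight=float(sim[i, j]), length=float(1.0 - sim[i, j]))
    betweenness = dict(nx.betweenness_centrality(g, weight="length", normalized=True))
    disconnected = not nx.is_connected(g)
    if disconnected:
        warnings.warn("ROI graph is disconnected; closeness uses the harmonic variant", stacklevel=3)
        harm = nx.harmonic_centrality(g, distance="length")
        closeness = {n: v / (len(nodes) - 1) for n, v in harm.items()}
    else:
        closeness = dict(nx.closeness_centrality(g, distance="length"))
    return g, betweenness, closeness, disconnected


def internal_network(
    sample: NormativeSample,
    atlas: Atlas,
    rois: list[ROIRef],
    linkage_method: str = "average",
    cut_k: int = 2,
) -> ROINetwork:
    """ROI graph from the cross-correlation of group seed maps.

    Hierarchical clustering runs on distance 1 − similarity; the weighted
    graph keeps positive-similarity edges with length 1 − similarity.
    Betweenness is normalized shortest-path betweenness; closeness is the
    inverse mean shortest-path length (harmonic variant, flagged, when the
    graph is disconnected).
    """
    if len(rois) < 3:
        raise ValueError("internal network needs >= 3 ROIs")
    seed_masks = [roi_mask(atlas, roi).data for roi in rois]
    group_maps = [group_rmap(sample, roi, atlas).group_map for roi in rois]
    sim = _spatial_similarity(group_maps, seed_masks, sample.brain_mask)

    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    linkage = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    flat = hierarchy.fcluster(linkage, t=cut_k, criterion="maxclust")
    assignment = {roi: int(c) for roi, c in zip(rois, flat)}

    g, betweenness, closeness, disconnected = centrality_from_similarity(rois, sim)
    return ROINetwork(
        nodes=list(rois),
        similarity=sim,
        linkage=linkage,
        cluster_assignment=assignment,
        betweenness=dict(betweenness),
        closeness=dict(closeness),
        graph=g,
        disconnected=disconnected,
    )
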