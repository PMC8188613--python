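"""Mapping image voxels to skeleton compartments and extracting channel
statistics.

A compartment is the frustum (truncated cone) between a node and its
parent, defined by the two node positions and radii of the basic SWC
reconstruction; the root contributes its own sphere. Every voxel whose
center falls inside at least one frustum is assigned to exactly one
compartment (the one whose axis is nearest; ties go to the smaller node
id). Within each compartment the acquisition step finds the voxels whose
*primary*-channel intensity passes threshold, then reads the *secondary*
channel at those same voxels, recording

* ``fraction_above`` (F) — fraction of primary-passing voxels whose
  secondary intensity also passes threshold,
* ``mean_intensity`` (ASI) — mean secondary intensity over that fraction,
* ``sd_intensity`` — population SD of the same.

Thresholds are inclusive: intensity exactly at the threshold is counted.
Running the acquisition once per signal channel accumulates channels on
the same tree, one run per distinct signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

from .treeio import ChannelStats, MultiSignalTree, NeuronTree

__all__ = [
    "ImageStack",
    "AcquisitionParams",
    "CompartmentVoxelSet",
    "add_channels",
    "assign_voxels",
    "compute_channel_stats",
    "read_tiff_stack",
    "write_tiff_stack",
]


@dataclass
class ImageStack:
    """Multi-channel 3D voxel grid of 8-bit intensities.

    ``channels`` maps a label to a uint8 array indexed ``[x, y, z]``.
    ``voxel_size`` is the physical voxel edge length in μm per axis; voxel
    ``(i, j, k)`` has its center at ``((i+0.5)·vx, (j+0.5)·vy, (k+0.5)·vz)``
    in the micron frame shared with scaled reconstructions.
    """

    channels: dict[str, np.ndarray] = field(default_factory=dict)
    voxel_size: tuple[float, float, float] = (0.593, 0.593, 1.0)

    def __post_init__(self):
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels have differing shapes: {shapes}")
        for label, arr in self.channels.items():
            if arr.dtype != np.uint8:
                raise ValueError(f"channel {label!r} is not 8-bit (dtype {arr.dtype})")

    @property
    def shape(self) -> tuple[int, int, int]:
        if not self.channels:
            return (0, 0, 0)
        return next(iter(self.channels.values())).shape

    def channel(self, label: str) -> np.ndarray:
        if label not in self.channels:
            raise KeyError(
                f"unknown channel {label!r}; have {sorted(self.channels)}"
            )
        return self.channels[label]


@dataclass(frozen=True)
class AcquisitionParams:
    """One acquisition run: primary gates eligibility, secondary is measured."""

    primary_channel: str
    secondary_channel: str
    threshold_primary: int = 10
    threshold_secondary: int = 10

    def __post_init__(self):
        for t in (self.threshold_primary, self.threshold_secondary):
            if not 0 <= t <= 255:
                raise ValueError(f"threshold {t} outside 0–255")


#: node id -> (N, 3) integer array of voxel indices assigned to that compartment
CompartmentVoxelSet = dict[int, np.ndarray]


def add_channels(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """8-bit saturating sum of two channels (the tracing pseudo-channel).

    Matches image-calculator behavior on 8-bit images: per-voxel sum
    clamped at 255.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return np.minimum(a.astype(np.uint16) + b.astype(np.uint16), 255).astype(np.uint8)


def _compartments(tree: NeuronTree):
    """Yield (node_id, p0, r0, p1, r1) per compartment; the root yields a
    degenerate segment (its own sphere)."""
    by_id = {n.id: n for n in tree.nodes}
    for n in tree.nodes:
        p1 = np.array([n.x, n.y, n.z])
        if n.parent_id == -1 or n.parent_id not in by_id:
            yield n.id, p1, n.radius, p1, n.radius
        else:
            par = by_id[n.parent_id]
            yield n.id, np.array([par.x, par.y, par.z]), par.radius, p1, n.radius


def assign_voxels(tree: NeuronTree, stack: ImageStack) -> CompartmentVoxelSet:
    """Assign each in-tube voxel center to exactly one compartment.

    A voxel is *eligible* for a compartment if the distance from its
    center to the parent→node axis, measured at the clamped projection
    parameter t, is at most the radius linearly interpolated at t. An
    eligible voxel is assigned to the compartment whose axis is nearest
    (margin ``radius(t) − distance`` is largest); exact ties go to the
    smaller node id. Raises ``ValueError`` if the tree lies entirely
    outside the stack bounds.
    """
    nx, ny, nz = stack.shape
    vx, vy, vz = stack.voxel_size
    vsize = np.array([vx, vy, vz])
    extent = np.array([nx, ny, nz]) * vsize

    pts = np.array([[n.x, n.y, n.z] for n in tree.nodes])
    if np.all((pts < 0).any(axis=1) | (pts >= extent).any(axis=1)):
        raise ValueError(
            f"tree lies entirely outside the stack bounds {extent} μm"
        )

    # best (smallest) axis distance per voxel, and the winning node id
    best_dist = np.full((nx, ny, nz), np.inf)
    best_id = np.full((nx, ny, nz), -1, dtype=np.int64)

    for nid, p0, r0, p1, r1 in _compartments(tree):
        rmax = max(r0, r1)
        lo = np.minimum(p0, p1) - rmax
        hi = np.maximum(p0, p1) + rmax
        i0 = np.maximum(np.floor(lo / vsize - 0.5).astype(int), 0)
        i1 = np.minimum(np.ceil(hi / vsize - 0.5).astype(int) + 1, [nx, ny, nz])
        if np.any(i0 >= i1):
            continue
        ix = np.arange(i0[0], i1[0])
        iy = np.arange(i0[1], i1[1])
        iz = np.arange(i0[2], i1[2])
        cx = (ix + 0.5) * vx
        cy = (iy + 0.5) * vy
        cz = (iz + 0.5) * vz
        gx, gy, gz = np.meshgrid(cx, cy, cz, indexing="ij")
        centers = np.stack([gx, gy, gz], axis=-1)  # (bx,by,bz,3)

        axis = p1 - p0
        # explicit left-to-right sums keep the arithmetic identical to a
        # scalar evaluation of the same formula
        L2 = axis[0] * axis[0] + axis[1] * axis[1] + axis[2] * axis[2]
        rel = centers - p0
        if L2 == 0.0:
            t = np.zeros(centers.shape[:-1])
        else:
            dot = (rel[..., 0] * axis[0] + rel[..., 1] * axis[1]
                   + rel[..., 2] * axis[2])
            t = np.clip(dot / L2, 0.0, 1.0)
        diff = centers - (p0 + t[..., None] * axis)
        dist = np.sqrt(diff[..., 0] ** 2 + diff[..., 1] ** 2
                       + diff[..., 2] ** 2)
        rad = r0 + t * (r1 - r0)
        inside = dist <= rad

        sub_best = best_dist[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        sub_id = best_id[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
        # strict improvement wins; equal distance keeps the smaller node id
        win = inside & (
            (dist < sub_best) | ((dist == sub_best) & (nid < sub_id))
        )
        sub_best[win] = dist[win]
        sub_id[win] = nid

    out: CompartmentVoxelSet = {n.id: np.empty((0, 3), dtype=int) for n in tree.nodes}
    assigned = np.argwhere(best_id >= 0)
    if assigned.size:
        ids_flat = best_id[assigned[:, 0], assigned[:, 1], assigned[:, 2]]
        order = np.argsort(ids_flat, kind="stable")
        assigned, ids_flat = assigned[order], ids_flat[order]
        bounds = np.searchsorted(ids_flat, np.unique(ids_flat))
        uniq = np.unique(ids_flat)
        for i, nid in enumerate(uniq):
            stop = bounds[i + 1] if i + 1 < len(uniq) else len(ids_flat)
            out[int(nid)] = assigned[bounds[i]:stop]
    return out


def compute_channel_stats(
    tree: NeuronTree | MultiSignalTree,
    stack: ImageStack,
    params: AcquisitionParams,
    voxel_sets: CompartmentVoxelSet | None = None,
    channel_label: str | None = None,
) -> MultiSignalTree:
    """One acquisition run: annotate every compartment with the secondary
    channel's (fraction_above, mean, SD).

    For a compartment with assigned voxels V, let
    ``S = {v ∈ V : primary(v) ≥ threshold_primary}`` and
    ``T = {v ∈ S : secondary(v) ≥ threshold_secondary}``. Then
    F = |T|/|S|, ASI = mean secondary over T, SD = population SD over T;
    all three are 0 when S (or T) is empty, and SD is 0 when |T| ≤ 1.

    Accepts a bare :class:`NeuronTree` (first run) or an existing
    :class:`MultiSignalTree` (subsequent runs append a channel). The new
    channel is labelled ``channel_label`` (default: the secondary channel
    name). Precomputed ``voxel_sets`` may be passed to amortize
    assignment across runs.
    """
    if isinstance(tree, MultiSignalTree):
        mstree, skeleton = tree, tree.tree
    else:
        mstree, skeleton = MultiSignalTree(tree=tree), tree
    primary = stack.channel(params.primary_channel)
    secondary = stack.channel(params.secondary_channel)
    if voxel_sets is None:
        voxel_sets = assign_voxels(skeleton, stack)

    label = channel_label or params.secondary_channel
    stats_by_node: dict[int, ChannelStats] = {}
    for n in skeleton.nodes:
        vox = voxel_sets.get(n.id)
        if vox is None or len(vox) == 0:
            stats_by_node[n.id] = ChannelStats(0.0, 0.0, 0.0)
            continue
        prim = primary[vox[:, 0], vox[:, 1], vox[:, 2]]
        sec = secondary[vox[:, 0], vox[:, 1], vox[:, 2]]
        s_mask = prim >= params.threshold_primary
        n_s = int(s_mask.sum())
        if n_s == 0:
            stats_by_node[n.id] = ChannelStats(0.0, 0.0, 0.0)
            continue
        sec_s = sec[s_mask]
        t_mask = sec_s >= params.threshold_secondary
        n_t = int(t_mask.sum())
        if n_t == 0:
            stats_by_node[n.id] = ChannelStats(0.0, 0.0, 0.0)
            continue
        vals = sec_s[t_mask].astype(float)
        mean = float(vals.mean())
        sd = 0.0 if n_t <= 1 else float(vals.std())  # population SD
        stats_by_node[n.id] = ChannelStats(n_t / n_s, mean, sd)
    mstree.add_channel(label, stats_by_node)
    return mstree


# ---------------------------------------------------------------------------
# TIFF I/O — multi-channel stacks stored as (z, c, y, x) per TIFF convention


def read_tiff_stack(
    path,
    channel_labels: list[str] | None = None,
    voxel_size: tuple[float, float, float] = (0.593, 0.593, 1.0),
) -> ImageStack:
    """Read an 8-bit multi-channel TIFF into an :class:`ImageStack`.

    Accepts (z, c, y, x), (c, z, y, x) with explicit axes metadata, or a
    single-channel (z, y, x) stack. Axes are transposed to the internal
    ``[x, y, z]`` layout.
    """
    arr = tifffile.imread(path)
    if arr.ndim == 3:
        arr = arr[:, None, :, :]
    if arr.ndim != 4:
        raise ValueError(f"expected 3D or 4D TIFF, got shape {arr.shape}")
    nzc = arr.shape[:2]
    # heuristic: the channel axis is the smaller of the two leading axes
    if nzc[0] < nzc[1]:
        arr = arr.transpose(1, 0, 2, 3)  # -> (z, c, y, x)
    nc = arr.shape[1]
    labels = channel_labels or [f"ch{i+1}" for i in range(nc)]
    if len(labels) != nc:
        raise ValueError(f"{len(labels)} labels for {nc} channels")
    channels = {
        lab: np.ascontiguousarray(arr[:, i].transpose(2, 1, 0)).astype(np.uint8)
        for i, lab in enumerate(labels)
    }
    return ImageStack(channels=channels, voxel_size=voxel_size)


def write_tiff_stack(path, stack: ImageStack, channel_order: list[str] | None = None):
    """Write an :class:`ImageStack` as an 8-bit (z, c, y, x) TIFF."""
    order = channel_order or list(stack.channels)
    data = np.stack(
        [stack.channel(lab).transpose(2, 1, 0) for lab in order], axis=1
    )
    tifffile.imwrite(path, data, metadata={"axes": "ZCYX"})
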