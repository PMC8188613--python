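"""Synthetic trees, ground-truth signal profiles and rendered two-channel
stacks.

Every pipeline stage can be exercised without any download: a random
binary tree is generated at uniform node spacing, painted with a
per-compartment ground truth that mirrors the biological structure the
quantification stage targets — a microtubule signal that decays with path
distance from the soma and an F-actin signal enriched at branch points —
and rendered into a two-channel 8-bit image stack whose tube voxels carry
the painted intensity plus optional Gaussian noise. Because the painted
(F, ASI) per compartment is known exactly, the full
render → acquire → quantify loop is checkable against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .quantify import classify_events, compartment_lengths, _path_metrics
from .signal_acquisition import ImageStack, assign_voxels
from .treeio import NeuronTree, SwcNode

__all__ = [
    "SynthTreeParams",
    "SignalPaintParams",
    "GroundTruth",
    "make_tree",
    "paint_signals",
    "render_stack",
    "translate_tree",
    "center_tree_in_stack",
]


@dataclass(frozen=True)
class SynthTreeParams:
    """Random binary tree: ``n_leaves`` tips, branch lengths around
    ``mean_branch_length`` μm, radii shrinking by ``taper`` per
    bifurcation, nodes every ``node_spacing`` μm. Growth stays close to
    the xy-plane (z deflections scaled by ``z_flatness``) so trees fit
    thin confocal stacks."""

    n_leaves: int = 8
    mean_branch_length: float = 12.0
    taper: float = 0.85
    seed: int = 0
    root_radius: float = 2.5
    node_spacing: float = 2.0
    z_flatness: float = 0.1

    def __post_init__(self):
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")
        if self.mean_branch_length <= 0 or self.node_spacing <= 0:
            raise ValueError("lengths must be > 0")


@dataclass(frozen=True)
class SignalPaintParams:
    """Ground-truth signal model: microtubule ASI decays exponentially
    with path distance from ``mt_root_level``; F-actin ASI is
    ``fa_baseline`` everywhere and ``fa_branch_enrichment``-fold at
    bifurcation compartments. Painted intensities are integer-rounded and
    clamped to [min_level, 255] so every compartment carries signal above
    the detection threshold, with F = 1 inside the tube."""

    mt_root_level: int = 200
    mt_distal_decay: float = 0.008  # per μm
    fa_baseline: int = 80
    fa_branch_enrichment: float = 2.0
    noise_sd: float = 0.0
    min_level: int = 12


@dataclass
class GroundTruth:
    """Painted per-compartment (F, ASI) per channel, for recovery tests."""

    per_node: dict[int, dict[str, tuple[float, int]]] = field(default_factory=dict)

    def expected_cq(self, tree: NeuronTree, channel: str) -> dict[int, float]:
        """CQ = F · ASI · W implied by the painted truth and the skeleton."""
        return {
            n.id: self.per_node[n.id][channel][0]
            * self.per_node[n.id][channel][1]
            * 2.0
            * n.radius
            for n in tree.nodes
        }


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def make_tree(p: SynthTreeParams) -> NeuronTree:
    """Grow a seeded random binary tree with exactly ``n_leaves`` tips
    (hence n_leaves − 1 bifurcations), uniform node spacing, and radii
    tapering per branch order. Passes topology validation by
    construction."""
    rng = np.random.default_rng(p.seed)
    nodes: list[SwcNode] = [
        SwcNode(id=1, type_tag=1, x=0.0, y=0.0, z=0.0, radius=p.root_radius,
                parent_id=-1)
    ]
    next_id = 2

    def flatten(d: np.ndarray) -> np.ndarray:
        return _unit(np.array([d[0], d[1], d[2] * p.z_flatness]))

    def grow_branch(parent_id: int, pos: np.ndarray, direction: np.ndarray,
                    depth: int, leaves: int) -> None:
        nonlocal next_id
        length = max(p.node_spacing,
                     float(rng.normal(p.mean_branch_length,
                                      0.3 * p.mean_branch_length)))
        n_steps = max(1, int(round(length / p.node_spacing)))
        radius = p.root_radius * (p.taper ** depth)
        cur_parent, cur_pos, cur_dir = parent_id, pos.copy(), direction.copy()
        for _ in range(n_steps):
            cur_dir = flatten(cur_dir + rng.normal(scale=0.15, size=3))
            cur_pos = cur_pos + p.node_spacing * cur_dir
            nodes.append(
                SwcNode(id=next_id, type_tag=3, x=float(cur_pos[0]),
                        y=float(cur_pos[1]), z=float(cur_pos[2]), radius=radius,
                        parent_id=cur_parent)
            )
            cur_parent = next_id
            next_id += 1
        if leaves == 1:
            return
        left = int(rng.integers(1, leaves))  # split quota, both sides >= 1
        perp = _unit(np.cross(cur_dir, np.array([0.0, 0.0, 1.0])))
        if not np.isfinite(perp).all() or np.linalg.norm(perp) == 0:
            perp = np.array([0.0, 1.0, 0.0])
        angle = 0.55
        ca, sa = math.cos(angle), math.sin(angle)
        d1 = flatten(ca * cur_dir + sa * perp)
        d2 = flatten(ca * cur_dir - sa * perp)
        grow_branch(cur_parent, cur_pos, d1, depth + 1, left)
        grow_branch(cur_parent, cur_pos, d2, depth + 1, leaves - left)

    theta = float(rng.uniform(0, 2 * math.pi))
    d0 = np.array([math.cos(theta), math.sin(theta), 0.0])
    grow_branch(1, np.zeros(3), d0, 0, p.n_leaves)
    return NeuronTree(nodes=nodes)


def translate_tree(tree: NeuronTree, offset: tuple[float, float, float]) -> NeuronTree:
    ox, oy, oz = offset
    return NeuronTree(
        nodes=[replace(n, x=n.x + ox, y=n.y + oy, z=n.z + oz) for n in tree.nodes],
        metadata=list(tree.metadata),
    )


def center_tree_in_stack(
    tree: NeuronTree,
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float] = (0.593, 0.593, 1.0),
) -> NeuronTree:
    """Translate the tree so its bounding-box center sits at the stack
    center (micron frame)."""
    pts = np.array([[n.x, n.y, n.z] for n in tree.nodes])
    center = (pts.min(axis=0) + pts.max(axis=0)) / 2
    target = np.array(shape) * np.array(voxel_size) / 2
    off = target - center
    return translate_tree(tree, (float(off[0]), float(off[1]), float(off[2])))


def fit_stack_shape(
    tree: NeuronTree,
    voxel_size: tuple[float, float, float] = (0.593, 0.593, 1.0),
    margin: float = 2.0,
) -> tuple[int, int, int]:
    """Smallest stack shape (voxels) that contains the tree's tubes plus a
    margin (μm) on every side. Pair with :func:`center_tree_in_stack`."""
    pts = np.array([[n.x, n.y, n.z] for n in tree.nodes])
    radii = np.array([n.radius for n in tree.nodes])
    span = (pts + radii[:, None]).max(axis=0) - (pts - radii[:, None]).min(axis=0)
    return tuple(int(np.ceil((span[i] + 2 * margin) / voxel_size[i]))
                 for i in range(3))


def paint_signals(tree: NeuronTree, p: SignalPaintParams) -> GroundTruth:
    """Assign ground-truth (F, ASI) per compartment for the "mt" and "fa"
    channels. F is 1 inside every tube; ASI values are integers so a
    noise-free render reproduces them exactly."""
    _, pdist, _ = _path_metrics(tree)
    events = classify_events(tree)
    truth = GroundTruth()
    for n in tree.nodes:
        mt_asi = p.mt_root_level * math.exp(-p.mt_distal_decay * pdist[n.id])
        mt_asi = int(round(min(255, max(p.min_level, mt_asi))))
        enrich = p.fa_branch_enrichment if events[n.id] == "bifurcation" else 1.0
        fa_asi = int(round(min(255, max(p.min_level, p.fa_baseline * enrich))))
        truth.per_node[n.id] = {"mt": (1.0, mt_asi), "fa": (1.0, fa_asi)}
    return truth


def render_stack(
    tree: NeuronTree,
    truth: GroundTruth,
    shape: tuple[int, int, int] = (128, 128, 32),
    voxel_size: tuple[float, float, float] = (0.593, 0.593, 1.0),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ImageStack:
    """Render the painted tree into a two-channel 8-bit stack.

    Voxels inside a compartment's frustum receive that compartment's
    painted ASI plus Gaussian noise (clamped to [0,255]); background
    voxels receive |N(0, noise_sd)| noise only. Raises ``ValueError`` if
    the tree (including radii) exceeds the stack bounds.
    """
    extent = np.array(shape) * np.array(voxel_size)
    for n in tree.nodes:
        pos = np.array([n.x, n.y, n.z])
        if np.any(pos - n.radius < 0) or np.any(pos + n.radius > extent):
            raise ValueError(
                f"node {n.id} at {pos} (r={n.radius}) exceeds stack bounds {extent}"
            )
    rng = np.random.default_rng(seed)
    channels: dict[str, np.ndarray] = {}
    # channel grids start as background noise
    for ch in ("mt", "fa"):
        if noise_sd > 0:
            bg = np.abs(rng.normal(0.0, noise_sd, size=shape))
            channels[ch] = np.clip(np.round(bg), 0, 255).astype(np.uint8)
        else:
            channels[ch] = np.zeros(shape, dtype=np.uint8)

    stack = ImageStack(channels=channels, voxel_size=voxel_size)
    voxel_sets = assign_voxels(tree, stack)
    for n in tree.nodes:
        vox = voxel_sets[n.id]
        if len(vox) == 0:
            continue
        for ch in ("mt", "fa"):
            asi = truth.per_node[n.id][ch][1]
            vals = np.full(len(vox), float(asi))
            if noise_sd > 0:
                vals = vals + rng.normal(0.0, noise_sd, size=len(vox))
            channels[ch][vox[:, 0], vox[:, 1], vox[:, 2]] = np.clip(
                np.round(vals), 0, 255
            ).astype(np.uint8)
    return stack
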