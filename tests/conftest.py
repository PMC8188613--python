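"""Shared fixtures: hand-built trees, randomized tree/stack factories, and
the independent brute-force voxel oracle used against the vectorized
acquisition path."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cytomorph.signal_acquisition import ImageStack
from cytomorph.treeio import NeuronTree, SwcNode


def make_node(nid, parent, x=0.0, y=0.0, z=0.0, r=1.0, tag=3):
    return SwcNode(id=nid, type_tag=tag, x=x, y=y, z=z, radius=r, parent_id=parent)


@pytest.fixture
def straight_branch():
    """Root at origin plus a straight 10 μm branch along x (2 nodes)."""
    return NeuronTree(nodes=[
        make_node(1, -1, 0, 0, 0, r=2.0, tag=1),
        make_node(2, 1, 10, 0, 0, r=1.0),
    ])


@pytest.fixture
def y_tree():
    """Root → stem → bifurcation with two tips; 5 nodes, all unit radius."""
    return NeuronTree(nodes=[
        make_node(1, -1, 0, 0, 0, r=2.0, tag=1),
        make_node(2, 1, 4, 0, 0),
        make_node(3, 2, 8, 0, 0),
        make_node(4, 3, 11, 3, 0),
        make_node(5, 3, 11, -3, 0),
    ])


def random_tree(rng: np.random.Generator, n_nodes: int, box: float = 10.0,
                r_lo: float = 0.5, r_hi: float = 2.0) -> NeuronTree:
    """Random connected tree: each node's parent is a uniformly chosen
    earlier node, positions uniform in [0, box]^3 (μm)."""
    nodes = [make_node(1, -1, *rng.uniform(1, box - 1, 3),
                       r=float(rng.uniform(r_lo, r_hi)), tag=1)]
    for i in range(2, n_nodes + 1):
        parent = int(rng.integers(1, i))
        nodes.append(make_node(i, parent, *rng.uniform(1, box - 1, 3),
                               r=float(rng.uniform(r_lo, r_hi))))
    return NeuronTree(nodes=nodes)


def random_binary_tree(rng: np.random.Generator, n_nodes: int,
                       box: float = 40.0) -> NeuronTree:
    """Random tree in which no node acquires more than two children."""
    nodes = [make_node(1, -1, *rng.uniform(0, box, 3), r=2.0, tag=1)]
    child_count = {1: 0}
    for i in range(2, n_nodes + 1):
        candidates = [nid for nid, c in child_count.items() if c < 2]
        parent = int(rng.choice(candidates))
        child_count[parent] += 1
        child_count[i] = 0
        nodes.append(make_node(i, parent, *rng.uniform(0, box, 3),
                               r=float(rng.uniform(0.5, 2.0))))
    return NeuronTree(nodes=nodes)


def random_stack(rng: np.random.Generator, shape, voxel_size=(1.0, 1.0, 1.0),
                 labels=("primary", "secondary")) -> ImageStack:
    channels = {
        lab: rng.integers(0, 256, size=shape).astype(np.uint8) for lab in labels
    }
    return ImageStack(channels=channels, voxel_size=voxel_size)


# ---------------------------------------------------------------------------
# independent brute-force oracle: plain-Python voxel loop


def brute_force_assignment(tree: NeuronTree, stack: ImageStack):
    """Reference voxel→compartment assignment by exhaustive enumeration.

    For every voxel center, test membership in every compartment frustum
    (clamped projection onto the axis, linearly interpolated radius);
    assign to the nearest axis, ties to the smaller node id.
    """
    by_id = {n.id: n for n in tree.nodes}
    segments = []
    for n in tree.nodes:
        if n.parent_id == -1 or n.parent_id not in by_id:
            segments.append((n.id, n.position, n.radius, n.position, n.radius))
        else:
            p = by_id[n.parent_id]
            segments.append((n.id, p.position, p.radius, n.position, n.radius))
    nx, ny, nz = stack.shape
    vx, vy, vz = stack.voxel_size
    assign: dict[int, list[tuple[int, int, int]]] = {n.id: [] for n in tree.nodes}
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = ((i + 0.5) * vx, (j + 0.5) * vy, (k + 0.5) * vz)
                best_d, best_id = None, None
                for nid, p0, r0, p1, r1 in segments:
                    ax = (p1[0] - p0[0], p1[1] - p0[1], p1[2] - p0[2])
                    L2 = ax[0] ** 2 + ax[1] ** 2 + ax[2] ** 2
                    rel = (c[0] - p0[0], c[1] - p0[1], c[2] - p0[2])
                    t = 0.0 if L2 == 0 else max(
                        0.0, min(1.0, (rel[0] * ax[0] + rel[1] * ax[1]
                                       + rel[2] * ax[2]) / L2))
                    q = (p0[0] + t * ax[0], p0[1] + t * ax[1], p0[2] + t * ax[2])
                    d = math.sqrt((c[0] - q[0]) ** 2 + (c[1] - q[1]) ** 2
                                  + (c[2] - q[2]) ** 2)
                    if d <= r0 + t * (r1 - r0):
                        if best_d is None or d < best_d or (d == best_d
                                                           and nid < best_id):
                            best_d, best_id = d, nid
                if best_id is not None:
                    assign[best_id].append((i, j, k))
    return assign


def brute_force_stats(tree, stack, primary, secondary, thr_p, thr_s):
    """Reference channel statistics from the brute-force assignment."""
    assign = brute_force_assignment(tree, stack)
    prim = stack.channels[primary]
    sec = stack.channels[secondary]
    out = {}
    for nid, voxels in assign.items():
        s_vals = [int(sec[v]) for v in voxels if int(prim[v]) >= thr_p]
        t_vals = [v for v in s_vals if v >= thr_s]
        if not s_vals or not t_vals:
            out[nid] = (0.0, 0.0, 0.0)
            continue
        arr = np.array(t_vals, dtype=float)
        sd = 0.0 if len(arr) <= 1 else float(arr.std())
        out[nid] = (len(t_vals) / len(s_vals), float(arr.mean()), sd)
    return out
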