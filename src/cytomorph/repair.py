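"""Topological repair, sorting, resampling and scaling of reconstructions.

Raw tracings routinely carry defects that break downstream morphometrics:
disconnected fragments, branch points with more than two children,
child-before-parent file order, and uneven node spacing. The repair
pipeline fixes them in a fixed order — connect fragments, split
multifurcations, sort anterogradely, resample at uniform spacing — after
which :func:`cytomorph.treeio.validate_topology` reports no violations.

Pixel-to-micron conversion is a separate step (:func:`scale`) applied with
per-axis factors; the defaults are the protocol's hardcoded
``(0.593, 0.593, 1, 0.593)`` for (x, y, z, radius).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .treeio import DENDRITE, NeuronTree, SwcNode, segment_length

__all__ = [
    "ScalingFactors",
    "RepairConfig",
    "DEFAULT_SCALING",
    "sort_anterograde",
    "connect_fragments",
    "split_multifurcations",
    "resample",
    "scale",
    "repair_tree",
]


@dataclass(frozen=True)
class ScalingFactors:
    """Microns per pixel (x, y), per z-step (z), and the radius factor."""

    sx: float
    sy: float
    sz: float
    sr: float

    def __post_init__(self):
        if min(self.sx, self.sy, self.sz, self.sr) <= 0:
            raise ValueError("scaling factors must be strictly positive")

    def inverse(self) -> "ScalingFactors":
        return ScalingFactors(1 / self.sx, 1 / self.sy, 1 / self.sz, 1 / self.sr)


#: Protocol default: 0.593 μm pixels in x/y, 1 μm z-steps, radius in x/y pixels.
DEFAULT_SCALING = ScalingFactors(0.593, 0.593, 1.0, 0.593)


@dataclass(frozen=True)
class RepairConfig:
    resample_spacing: float = 2.0  # μm; the protocol resamples at 2 μm
    connect_fragments: bool = True
    default_type_tag: int = DENDRITE

    def __post_init__(self):
        if self.resample_spacing <= 0:
            raise ValueError("resample_spacing must be > 0")


def _pos(n: SwcNode) -> np.ndarray:
    return np.array([n.x, n.y, n.z], dtype=float)


def sort_anterograde(tree: NeuronTree) -> NeuronTree:
    """Reorder nodes so every parent precedes its children; renumber 1..N.

    The order is a breadth-first traversal from the root, so a parent of a
    compartment is always closer to the soma than the compartment itself.
    Geometry is untouched. Raises ``ValueError`` on disconnected input —
    run :func:`connect_fragments` first.
    """
    if not tree.nodes:
        return tree.copy()
    roots = tree.roots()
    if len(roots) != 1:
        raise ValueError(
            f"tree has {len(roots)} roots; run connect_fragments before sorting"
        )
    by_id = {n.id: n for n in tree.nodes}
    kids = tree.children_map()
    order: list[SwcNode] = []
    queue = [roots[0].id]
    while queue:
        nid = queue.pop(0)
        order.append(by_id[nid])
        queue.extend(kids[nid])
    if len(order) != len(tree.nodes):
        raise ValueError("tree is disconnected; run connect_fragments before sorting")
    mapping = {n.id: i for i, n in enumerate(order, start=1)}
    new_nodes = [
        replace(n, id=mapping[n.id],
                parent_id=mapping[n.parent_id] if n.parent_id != -1 else -1)
        for n in order
    ]
    return NeuronTree(nodes=new_nodes, metadata=list(tree.metadata))


def _components(tree: NeuronTree) -> list[list[SwcNode]]:
    """Connected components over parent links, component of first root first."""
    ids = {n.id for n in tree.nodes}
    by_id = {n.id: n for n in tree.nodes}
    adj: dict[int, list[int]] = {n.id: [] for n in tree.nodes}
    for n in tree.nodes:
        if n.parent_id != -1 and n.parent_id in ids:
            adj[n.id].append(n.parent_id)
            adj[n.parent_id].append(n.id)
    seen: set[int] = set()
    comps: list[list[SwcNode]] = []
    for n in tree.nodes:
        if n.id in seen:
            continue
        stack, members = [n.id], []
        seen.add(n.id)
        while stack:
            cur = stack.pop()
            members.append(by_id[cur])
            for nb in adj[cur]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        comps.append(members)
    return comps


def _reroot(nodes: list[SwcNode], new_root_id: int) -> list[SwcNode]:
    """Reverse parent links along the path from the old root to new_root."""
    parent_of = {n.id: n.parent_id for n in nodes}
    ids = {n.id for n in nodes}
    path = [new_root_id]
    cur = new_root_id
    while parent_of[cur] != -1 and parent_of[cur] in ids:
        cur = parent_of[cur]
        path.append(cur)
    flip = {path[i + 1]: path[i] for i in range(len(path) - 1)}
    out = []
    for n in nodes:
        if n.id == new_root_id:
            out.append(replace(n, parent_id=-1))
        elif n.id in flip:
            out.append(replace(n, parent_id=flip[n.id]))
        else:
            out.append(n)
    return out


def connect_fragments(tree: NeuronTree, root_id: int | None = None) -> NeuronTree:
    """Attach disconnected fragments to the main component at the closest
    node pair.

    The component containing the designated soma root (``root_id``, default:
    the first root in file order) is the seed. Remaining fragments are
    attached greedily in order of increasing gap distance: at each step the
    fragment whose closest node is nearest to the connected component is
    re-rooted at that node and joined there. The original soma root is
    preserved. Already-connected trees are returned unchanged.
    """
    comps = _components(tree)
    if len(comps) <= 1:
        return tree.copy()
    if root_id is None:
        roots = tree.roots()
        if not roots:
            raise ValueError("no root node found")
        root_id = roots[0].id

    main_idx = next(i for i, c in enumerate(comps) if any(n.id == root_id for n in c))
    connected = list(comps[main_idx])
    pending = [c for i, c in enumerate(comps) if i != main_idx]

    new_parent: dict[int, int] = {}
    rerooted_nodes: dict[int, SwcNode] = {}
    while pending:
        best = None  # (dist, frag_idx, frag_node_id, conn_node_id)
        conn_pos = np.array([_pos(n) for n in connected])
        conn_ids = [n.id for n in connected]
        for fi, frag in enumerate(pending):
            for fn in frag:
                d = np.linalg.norm(conn_pos - _pos(fn), axis=1)
                j = int(np.argmin(d))
                # ties broken by order of scan: first fragment, first node
                if best is None or d[j] < best[0] - 1e-15:
                    best = (float(d[j]), fi, fn.id, conn_ids[j])
        dist, fi, frag_nid, conn_nid = best
        frag = pending.pop(fi)
        frag_nodes = _reroot(frag, frag_nid)
        for n in frag_nodes:
            if n.id == frag_nid:
                n = replace(n, parent_id=conn_nid)
            rerooted_nodes[n.id] = n
        connected.extend(frag_nodes)

    out_nodes = [rerooted_nodes.get(n.id, n) for n in tree.nodes]
    # make sure the designated root stays the root
    fixed = []
    for n in out_nodes:
        if n.id == root_id and n.parent_id != -1:
            fixed.append(replace(n, parent_id=-1))
        else:
            fixed.append(n)
    return NeuronTree(nodes=fixed, metadata=list(tree.metadata))


def split_multifurcations(tree: NeuronTree) -> NeuronTree:
    """Rewrite nodes with more than two children as chains of bifurcations.

    For a node with children ``c1..ck`` (k > 2), a zero-length helper node
    is inserted at the parent's own coordinates: the parent keeps ``c1``
    and the helper; the helper carries ``c2..ck`` and is split recursively.
    Zero-length compartments are permitted internally and contribute 0 to
    length sums. Binary trees are returned unchanged.
    """
    nodes = list(tree.nodes)
    next_id = max((n.id for n in nodes), default=0) + 1
    changed = True
    while changed:
        changed = False
        by_parent: dict[int, list[SwcNode]] = {}
        for n in nodes:
            by_parent.setdefault(n.parent_id, []).append(n)
        by_id = {n.id: n for n in nodes}
        for pid, kids in by_parent.items():
            if pid == -1 or len(kids) <= 2 or pid not in by_id:
                continue
            parent = by_id[pid]
            helper = SwcNode(
                id=next_id, type_tag=parent.type_tag, x=parent.x, y=parent.y,
                z=parent.z, radius=parent.radius, parent_id=pid,
            )
            next_id += 1
            reassign = {k.id for k in kids[1:]}
            new_nodes = []
            for n in nodes:
                if n.id in reassign:
                    new_nodes.append(replace(n, parent_id=helper.id))
                else:
                    new_nodes.append(n)
                if n.id == pid:
                    new_nodes.append(helper)
            nodes = new_nodes
            changed = True
            break  # restart scan with updated child map
    return NeuronTree(nodes=nodes, metadata=list(tree.metadata))


def _branches(tree: NeuronTree) -> list[list[SwcNode]]:
    """Decompose a sorted tree into root/branch-point → branch-point/tip
    polylines. Each polyline starts at a root or bifurcation node and ends
    at the next bifurcation or tip."""
    by_id = {n.id: n for n in tree.nodes}
    kids = tree.children_map()
    roots = tree.roots()
    if len(roots) != 1:
        raise ValueError("resample requires a single-rooted tree")
    root = roots[0]
    anchors = [root.id]
    branches = []
    while anchors:
        a = anchors.pop(0)
        for child in kids[a]:
            poly = [by_id[a], by_id[child]]
            cur = child
            while len(kids[cur]) == 1:
                cur = kids[cur][0]
                poly.append(by_id[cur])
            branches.append(poly)
            if kids[cur]:
                anchors.append(cur)
    return branches


def resample(tree: NeuronTree, spacing: float = 2.0) -> NeuronTree:
    """Resample every branch at uniform node spacing (default 2 μm).

    Branch points and terminal tips are preserved exactly; internal nodes
    are re-placed along the branch polyline at arc-length multiples of
    ``spacing``, with radius linearly interpolated. The final compartment
    of each branch carries the sub-spacing remainder so that total branch
    length is preserved exactly. The tree must be single-rooted; output is
    anterograde-sorted with ids 1..N.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if not tree.nodes:
        return tree.copy()
    tree = sort_anterograde(tree)
    root = tree.roots()[0]
    out_nodes: list[SwcNode] = [replace(root, id=1, parent_id=-1)]
    id_map = {root.id: 1}
    next_id = 2

    for poly in _branches(tree):
        # arc-length parameterization of the polyline
        pts = np.array([_pos(n) for n in poly])
        radii = np.array([n.radius for n in poly])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        total = float(cum[-1])
        tag = poly[-1].type_tag  # branch nodes inherit the distal type

        if total <= spacing or total == 0.0:
            targets = [total]
        else:
            n_full = int(total // spacing)
            if abs(total - n_full * spacing) < 1e-9 * max(1.0, total):
                targets = [spacing * i for i in range(1, n_full)] + [total]
            else:
                targets = [spacing * i for i in range(1, n_full + 1)] + [total]

        parent_new = id_map[poly[0].id]
        for t in targets:
            if total == 0.0:
                x, y, z = pts[-1]
                r = radii[-1]
            else:
                x, y, z = [float(np.interp(t, cum, pts[:, k])) for k in range(3)]
                r = float(np.interp(t, cum, radii))
            if t >= total - 1e-12:  # branch endpoint: preserve exactly
                x, y, z, r = poly[-1].x, poly[-1].y, poly[-1].z, poly[-1].radius
            node = SwcNode(
                id=next_id, type_tag=tag, x=x, y=y, z=z, radius=r,
                parent_id=parent_new,
            )
            out_nodes.append(node)
            parent_new = next_id
            next_id += 1
        id_map[poly[-1].id] = parent_new
    return NeuronTree(nodes=out_nodes, metadata=list(tree.metadata))


def scale(tree: NeuronTree, factors: ScalingFactors = DEFAULT_SCALING) -> NeuronTree:
    """Convert coordinates and radii from pixel to micron units.

    ``x*sx, y*sy, z*sz, radius*sr``; topology and ids are unchanged.
    """
    new_nodes = [
        replace(n, x=n.x * factors.sx, y=n.y * factors.sy, z=n.z * factors.sz,
                radius=n.radius * factors.sr)
        for n in tree.nodes
    ]
    return NeuronTree(nodes=new_nodes, metadata=list(tree.metadata))


def repair_tree(tree: NeuronTree, config: RepairConfig = RepairConfig()) -> NeuronTree:
    """Full repair pipeline: connect → split → sort → resample.

    Root type tag is forced to soma (1); untagged (type 0) non-root nodes
    receive the default dendrite tag so the output passes validation.
    """
    t = tree.copy()
    if config.connect_fragments:
        t = connect_fragments(t)
    t = split_multifurcations(t)
    t = sort_anterograde(t)
    t = resample(t, config.resample_spacing)
    fixed = []
    for n in t.nodes:
        if n.parent_id == -1:
            fixed.append(replace(n, type_tag=1))
        elif n.type_tag not in (1, 2, 3):
            fixed.append(replace(n, type_tag=config.default_type_tag))
        else:
            fixed.append(n)
    return NeuronTree(nodes=fixed, metadata=t.metadata)


def total_length(tree: NeuronTree) -> float:
    """Sum of all compartment (parent→node) lengths in the tree's units."""
    by_id = {n.id: n for n in tree.nodes}
    return sum(
        segment_length(by_id[n.parent_id], n)
        for n in tree.nodes
        if n.parent_id != -1 and n.parent_id in by_id
    )
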