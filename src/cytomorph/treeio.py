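"""Reading, writing and validation of SWC-family neuron reconstruction files.

Three dialects are supported:

* **SWC** — the standard 7-column text format
  (``id type x y z radius parent``), one node per line, ``#`` comments.
* **ESWC** — extended SWC carrying, for each signal channel, three extra
  per-node columns: fraction of compartment voxels above threshold, mean
  intensity, and standard deviation of intensity (7 + 3k columns).
* **channel-SWC** — a back-compatible dialect: a regular 7-column SWC body
  followed by a ``#CHANNELSWC`` trailer listing ``(id, fraction, mean)``
  rows per channel. Standard SWC parsers skip the trailer as comments, so
  the morphology stays readable everywhere.

The in-memory containers are :class:`NeuronTree` (skeleton only) and
:class:`MultiSignalTree` (skeleton plus per-node, per-channel statistics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "SwcNode",
    "NeuronTree",
    "ChannelStats",
    "MultiSignalTree",
    "SwcFormatError",
    "TopologyViolation",
    "read_swc",
    "write_swc",
    "read_eswc",
    "write_eswc",
    "read_channel_swc",
    "write_channel_swc",
    "validate_topology",
]

SOMA, AXON, DENDRITE = 1, 2, 3


class SwcFormatError(ValueError):
    """Raised on malformed SWC/ESWC/channel-SWC content."""


@dataclass(frozen=True)
class SwcNode:
    """One reconstruction node: a sphere sample of the neurite skeleton.

    Coordinates and radius are in pixels before scaling and in microns
    after. ``parent_id`` is ``-1`` for a root.
    """

    id: int
    type_tag: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    @property
    def position(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


@dataclass
class NeuronTree:
    """An ordered collection of SWC nodes plus the free-text header.

    Node order is file order; after anterograde sorting every node's
    parent precedes it. The class imposes no validity by itself —
    :func:`validate_topology` reports violations as data.
    """

    nodes: list[SwcNode] = field(default_factory=list)
    metadata: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.nodes)

    def node_by_id(self, node_id: int) -> SwcNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise KeyError(f"no node with id {node_id}")

    def children_map(self) -> dict[int, list[int]]:
        """Map node id -> list of child ids, in file order."""
        out: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id != -1 and n.parent_id in out:
                out[n.parent_id].append(n.id)
        return out

    def roots(self) -> list[SwcNode]:
        ids = {n.id for n in self.nodes}
        return [n for n in self.nodes if n.parent_id == -1 or n.parent_id not in ids]

    def copy(self) -> "NeuronTree":
        return NeuronTree(nodes=list(self.nodes), metadata=list(self.metadata))


@dataclass(frozen=True)
class ChannelStats:
    """Per-compartment statistics of one signal channel.

    ``fraction_above`` is F of the CQ formula — the fraction of eligible
    compartment voxels whose channel intensity passes threshold.
    ``mean_intensity`` is ASI, the average intensity within that fraction.
    """

    fraction_above: float
    mean_intensity: float
    sd_intensity: float

    def __post_init__(self):
        if not 0.0 <= self.fraction_above <= 1.0:
            raise ValueError(f"fraction_above {self.fraction_above} not in [0,1]")
        if self.sd_intensity < 0:
            raise ValueError("sd_intensity must be >= 0")


@dataclass
class MultiSignalTree:
    """A skeleton annotated with per-node statistics for named channels."""

    tree: NeuronTree
    channels: list[str] = field(default_factory=list)
    per_node_stats: dict[int, dict[str, ChannelStats]] = field(default_factory=dict)

    def stats(self, node_id: int, channel: str) -> ChannelStats:
        return self.per_node_stats[node_id][channel]

    def add_channel(self, label: str, stats_by_node: dict[int, ChannelStats]) -> None:
        if label in self.channels:
            raise ValueError(f"channel {label!r} already present")
        missing = {n.id for n in self.tree.nodes} - set(stats_by_node)
        if missing:
            raise ValueError(f"stats missing for nodes {sorted(missing)[:5]}...")
        self.channels.append(label)
        for nid, st in stats_by_node.items():
            self.per_node_stats.setdefault(nid, {})[label] = st


@dataclass(frozen=True)
class TopologyViolation:
    """A single topology problem; ``kind`` is one of multiple_roots,
    fragment, multifurcation, dangling_parent, cycle, bad_type_tag."""

    kind: str
    node_ids: tuple[int, ...]
    message: str


# ---------------------------------------------------------------------------
# parsing helpers


def _iter_body_lines(text: str):
    """Yield (lineno, fields) for non-comment lines; collect comments."""
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        yield lineno, line


def _parse_node_fields(fields: list[str], lineno: int) -> SwcNode:
    try:
        return SwcNode(
            id=int(fields[0]),
            type_tag=int(fields[1]),
            x=float(fields[2]),
            y=float(fields[3]),
            z=float(fields[4]),
            radius=float(fields[5]),
            parent_id=int(fields[6]),
        )
    except (ValueError, IndexError) as exc:
        raise SwcFormatError(f"line {lineno}: malformed node row: {exc}") from exc


def read_swc(text: str) -> NeuronTree:
    """Parse standard 7-column SWC text.

    Comment header lines are preserved verbatim (without the newline).
    The tree is returned exactly as read: no sorting, no repair. Duplicate
    ids and wrong column counts raise :class:`SwcFormatError` with the
    line number; dangling parents do *not* — they are the validator's job.
    """
    tree = NeuronTree()
    seen: set[int] = set()
    for lineno, line in _iter_body_lines(text):
        if line.startswith("#"):
            tree.metadata.append(line)
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SwcFormatError(
                f"line {lineno}: expected 7 columns, found {len(fields)}"
            )
        node = _parse_node_fields(fields, lineno)
        if node.id in seen:
            raise SwcFormatError(f"line {lineno}: duplicate node id {node.id}")
        seen.add(node.id)
        tree.nodes.append(node)
    return tree


def _renumber(tree: NeuronTree) -> NeuronTree:
    """Renumber ids 1..N in stored order, remapping parent references.

    For a sorted tree the stored order is anterograde, so this yields the
    conventional consecutive anterograde numbering.
    """
    mapping = {n.id: i for i, n in enumerate(tree.nodes, start=1)}
    new_nodes = [
        replace(
            n,
            id=mapping[n.id],
            parent_id=mapping.get(n.parent_id, -1) if n.parent_id != -1 else -1,
        )
        for n in tree.nodes
    ]
    return NeuronTree(nodes=new_nodes, metadata=list(tree.metadata))


def _fmt(v: float) -> str:
    """Format a float compactly but round-trip exactly (repr of float)."""
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def _body_lines(tree: NeuronTree) -> list[str]:
    return [
        f"{n.id} {n.type_tag} {_fmt(n.x)} {_fmt(n.y)} {_fmt(n.z)} "
        f"{_fmt(n.radius)} {n.parent_id}"
        for n in tree.nodes
    ]


def write_swc(tree: NeuronTree) -> str:
    """Serialize to standard 7-column SWC.

    Node ids are renumbered 1..N in stored order (resampling and
    multifurcation splitting invalidate original numbering); geometry and
    topology are untouched. Fields are single-space separated; floats are
    written so that a re-read reproduces them bit-exactly.
    """
    t = _renumber(tree)
    lines = list(t.metadata) + _body_lines(t)
    return "\n".join(lines) + ("\n" if lines else "")


def write_eswc(mstree: MultiSignalTree) -> str:
    """Serialize to ESWC: 7 + 3·k columns.

    Per channel, in acquisition order, the three columns are
    ``fraction_above mean_intensity sd_intensity``.
    """
    t = _renumber(mstree.tree)
    old_ids = [n.id for n in mstree.tree.nodes]
    lines = list(t.metadata)
    for new_node, old_id in zip(t.nodes, old_ids):
        parts = [
            f"{new_node.id} {new_node.type_tag} {_fmt(new_node.x)} "
            f"{_fmt(new_node.y)} {_fmt(new_node.z)} {_fmt(new_node.radius)} "
            f"{new_node.parent_id}"
        ]
        for ch in mstree.channels:
            st = mstree.per_node_stats[old_id][ch]
            parts.append(
                f"{_fmt(st.fraction_above)} {_fmt(st.mean_intensity)} "
                f"{_fmt(st.sd_intensity)}"
            )
        lines.append(" ".join(parts))
    return "\n".join(lines) + ("\n" if lines else "")


def read_eswc(text: str, channels: list[str] | None = None) -> MultiSignalTree:
    """Parse ESWC text. Column count must be 7 + 3k for some k ≥ 1.

    ``channels`` supplies the k labels; defaults to ``ch1..chk``.
    """
    tree = NeuronTree()
    rows: list[list[float]] = []
    ncols: int | None = None
    seen: set[int] = set()
    for lineno, line in _iter_body_lines(text):
        if line.startswith("#"):
            tree.metadata.append(line)
            continue
        fields = line.split()
        if ncols is None:
            ncols = len(fields)
            if ncols < 10 or (ncols - 7) % 3 != 0:
                raise SwcFormatError(
                    f"line {lineno}: ESWC needs 7+3k columns (k>=1), found {ncols}"
                )
        elif len(fields) != ncols:
            raise SwcFormatError(
                f"line {lineno}: expected {ncols} columns, found {len(fields)}"
            )
        node = _parse_node_fields(fields[:7], lineno)
        if node.id in seen:
            raise SwcFormatError(f"line {lineno}: duplicate node id {node.id}")
        seen.add(node.id)
        tree.nodes.append(node)
        rows.append([float(v) for v in fields[7:]])
    k = 0 if ncols is None else (ncols - 7) // 3
    labels = channels if channels is not None else [f"ch{i+1}" for i in range(k)]
    if len(labels) != k:
        raise SwcFormatError(f"{len(labels)} channel labels given for {k} channels")
    mstree = MultiSignalTree(tree=tree, channels=list(labels))
    for node, extras in zip(tree.nodes, rows):
        mstree.per_node_stats[node.id] = {
            lab: ChannelStats(*extras[3 * i : 3 * i + 3])
            for i, lab in enumerate(labels)
        }
    return mstree


CHANNEL_TAG = "#CHANNELSWC"


def write_channel_swc(mstree: MultiSignalTree, channels: list[str] | None = None) -> str:
    """Serialize to the back-compatible #CHANNELSWC dialect.

    The body is a regular 7-column SWC. After the last node row a single
    ``#CHANNELSWC`` tag line is emitted, followed by one
    ``#<id> <fraction> <mean>`` row per node per channel, blocked per
    channel in order. Because the trailer rows are ``#``-prefixed, any
    standard SWC parser still reads the morphology.

    ``channels`` selects/orders the annotated channels (default: all).
    """
    chans = list(mstree.channels) if channels is None else list(channels)
    for ch in chans:
        if ch not in mstree.channels:
            raise KeyError(f"unknown channel {ch!r}")
    t = _renumber(mstree.tree)
    old_ids = [n.id for n in mstree.tree.nodes]
    lines = list(t.metadata) + _body_lines(t)
    lines.append(CHANNEL_TAG)
    for ch in chans:
        for new_node, old_id in zip(t.nodes, old_ids):
            st = mstree.per_node_stats[old_id][ch]
            lines.append(
                f"#{new_node.id} {_fmt(st.fraction_above)} {_fmt(st.mean_intensity)}"
            )
    return "\n".join(lines) + "\n"


def read_channel_swc(text: str, channels: list[str] | None = None) -> MultiSignalTree:
    """Parse a #CHANNELSWC file back into a :class:`MultiSignalTree`.

    The trailer stores fraction and mean only; SD is restored as 0. A
    file written with one channel can be re-read, annotated with a second
    channel, and written again — mirroring the one-run-per-signal
    acquisition workflow.
    """
    if CHANNEL_TAG not in text:
        raise SwcFormatError(f"no {CHANNEL_TAG} trailer found")
    head, _, trailer = text.partition(CHANNEL_TAG)
    tree = read_swc(head)
    n = len(tree.nodes)
    rows: list[tuple[int, float, float]] = []
    for lineno, line in _iter_body_lines(trailer):
        if not line.startswith("#"):
            raise SwcFormatError(f"trailer line {lineno}: expected '#'-prefixed row")
        fields = line.lstrip("#").split()
        if len(fields) != 3:
            raise SwcFormatError(
                f"trailer line {lineno}: expected 3 fields (id fraction mean), "
                f"found {len(fields)}"
            )
        rows.append((int(fields[0]), float(fields[1]), float(fields[2])))
    if n == 0 or len(rows) % n != 0:
        raise SwcFormatError(
            f"trailer has {len(rows)} rows, not a multiple of {n} nodes"
        )
    k = len(rows) // n
    labels = channels if channels is not None else [f"ch{i+1}" for i in range(k)]
    if len(labels) != k:
        raise SwcFormatError(f"{len(labels)} channel labels given for {k} channels")
    mstree = MultiSignalTree(tree=tree, channels=list(labels))
    for i, lab in enumerate(labels):
        block = rows[i * n : (i + 1) * n]
        for nid, frac, mean in block:
            mstree.per_node_stats.setdefault(nid, {})[lab] = ChannelStats(
                frac, mean, 0.0
            )
    return mstree


# ---------------------------------------------------------------------------
# topology validation


def validate_topology(
    tree: NeuronTree, allowed_type_tags: frozenset[int] = frozenset({1, 2, 3})
) -> list[TopologyViolation]:
    """Check the protocol's structural rules; violations are data.

    A conformant single neuron has exactly one root, is fully connected
    and acyclic, every branch point has at most two children, every
    parent reference resolves, and type tags are soma/axon/dendrite.
    """
    violations: list[TopologyViolation] = []
    ids = {n.id for n in tree.nodes}

    dangling = [n for n in tree.nodes if n.parent_id != -1 and n.parent_id not in ids]
    for n in dangling:
        violations.append(
            TopologyViolation(
                "dangling_parent", (n.id,), f"node {n.id} references missing parent "
                f"{n.parent_id}"
            )
        )

    roots = [n for n in tree.nodes if n.parent_id == -1]
    if len(roots) > 1:
        violations.append(
            TopologyViolation(
                "multiple_roots",
                tuple(n.id for n in roots),
                f"{len(roots)} nodes have parent -1; a single neuron has one root",
            )
        )

    # connected components over the undirected parent links
    parent_of = {n.id: n.parent_id for n in tree.nodes}
    comp: dict[int, int] = {}

    def find_root_of(nid: int) -> int:
        seen_path = []
        cur = nid
        while cur in parent_of and cur not in comp:
            seen_path.append(cur)
            p = parent_of[cur]
            if p == -1 or p not in ids or p in seen_path:
                break
            cur = p
        label = comp.get(cur, cur)
        for s in seen_path:
            comp[s] = label
        comp.setdefault(cur, label)
        return label

    for n in tree.nodes:
        find_root_of(n.id)
    components = set(comp.values())
    if len(components) > 1:
        # every component not containing a designated root is a fragment
        root_comp = comp.get(roots[0].id) if roots else None
        for label in sorted(components):
            if label == root_comp:
                continue
            members = tuple(sorted(i for i, c in comp.items() if c == label))
            violations.append(
                TopologyViolation(
                    "fragment", members, f"disconnected fragment of {len(members)} "
                    f"nodes rooted near node {label}"
                )
            )

    # cycles: a node is on a cycle if walking parents never reaches a root
    for n in tree.nodes:
        seen_walk: set[int] = set()
        cur = n.id
        cyc = False
        while True:
            if cur in seen_walk:
                cyc = True
                break
            seen_walk.add(cur)
            p = parent_of.get(cur, -1)
            if p == -1 or p not in ids:
                break
            cur = p
        if cyc:
            violations.append(
                TopologyViolation("cycle", (n.id,), f"node {n.id} lies on a cycle")
            )
            break  # one report is enough

    for nid, kids in tree.children_map().items():
        if len(kids) > 2:
            violations.append(
                TopologyViolation(
                    "multifurcation",
                    (nid,),
                    f"node {nid} has {len(kids)} children; bifurcations must have "
                    f"exactly two",
                )
            )

    for n in tree.nodes:
        if n.type_tag not in allowed_type_tags:
            violations.append(
                TopologyViolation(
                    "bad_type_tag", (n.id,), f"node {n.id} has type tag {n.type_tag}"
                )
            )
    return violations


def segment_length(a: SwcNode, b: SwcNode) -> float:
    return math.dist(a.position, b.position)
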