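"""Cytoskeleton-constrained stochastic growth of virtual dendritic arbors.

Each growing branch tip carries a local cytoskeletal state: a microtubule
quantity ``mt`` that is consumed as the branch extends, and an F-actin
quantity ``fa`` that promotes branching. At every iteration a tip either
elongates, bifurcates, or terminates, stochastically as a function of that
state:

* ``p_term = exp(−k_term · mt)`` — termination becomes certain as the
  microtubule supply is depleted;
* ``p_bif = (1 − p_term) · min(1, k_bif · fa)`` — branching is promoted
  by local F-actin;
* ``p_elong = 1 − p_term − p_bif``.

On elongation the tip advances one step (the resampling spacing, so
simulated and real trees share compartment granularity), microtubule
decays by a fixed fraction and F-actin is resampled around its mean. On
bifurcation the parent's microtubule is partitioned between the two
daughters by a symmetric Beta draw (conserving the total) and the branch
compartment's F-actin is multiplied by an enrichment factor. Growth is
breadth-first and fully determined by one integer seed.

These functional forms are this package's concrete instantiation of
growth "depending stochastically on cytoskeletal composition"; they are
parameterized and swappable (see :func:`sample_event`).

Virtual neurons are exported as *two* SWC files with identical topology,
the radius column repurposed to carry the per-compartment microtubule and
F-actin quantity respectively, and re-quantified with 17 of the 20 real-
neuron metrics (no imaging exists, so the two image-intensity
normalizations and the compartment-type column are dropped).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from .quantify import (
    DistributionProfile,
    metrics_table_from_quantities,
)
from .treeio import NeuronTree, SwcNode, read_swc, write_swc

__all__ = [
    "TipState",
    "SimParams",
    "VirtualNeuron",
    "PRESETS",
    "event_probabilities",
    "sample_event",
    "grow",
    "export_sim_trees",
    "quantify_simulated",
    "compare_distributions",
    "ComparisonResult",
]


@dataclass
class TipState:
    """The local state of one growing branch tip."""

    node_id: int
    position: np.ndarray  # (3,) μm
    direction: np.ndarray  # unit vector
    mt: float
    fa: float
    branch_order: int = 0
    path_distance: float = 0.0


@dataclass(frozen=True)
class SimParams:
    """Growth-model parameters.

    ``step_length`` equals the reconstruction resampling spacing (2 μm) so
    simulated compartments match real-tree granularity. ``mt_decay`` is
    the fraction of microtubule consumed per elongation step;
    ``mt_split_concentration`` is the symmetric Beta concentration of the
    microtubule partition at bifurcations (larger → more even splits);
    ``fa_branch_boost`` multiplies F-actin at branch compartments;
    ``k_term``/``k_bif`` set the event-probability scales;
    ``direction_jitter`` is the per-step angular noise (SD of the isotropic
    Gaussian perturbation added to the unit direction).
    """

    initial_mt: float = 200.0
    initial_fa: float = 1.0
    step_length: float = 2.0
    mt_decay: float = 0.01
    mt_split_concentration: float = 5.0
    fa_branch_boost: float = 2.0
    fa_sd: float = 0.25
    k_bif: float = 0.10
    k_term: float = 0.5
    direction_jitter: float = 0.25
    branch_half_angle: float = 0.5  # radians, daughters diverge ±this
    max_compartments: int = 2000
    seed: int = 0

    def __post_init__(self):
        if self.step_length <= 0:
            raise ValueError("step_length must be > 0")
        if not 0 <= self.mt_decay < 1:
            raise ValueError("mt_decay must be in [0,1)")


def _load_presets() -> dict[str, SimParams]:
    from importlib import resources

    out = {}
    for entry in resources.files(__package__).joinpath("presets").iterdir():
        if entry.name.endswith(".json"):
            out[entry.name[:-5]] = SimParams(**json.loads(entry.read_text()))
    return out


#: Three neuron-class presets shipped as JSON config files: a simple arbor
#: (class1-like), a complex space-filling arbor (class4-like), and a
#: class4 variant with reduced F-actin branch enrichment (form3
#: overexpression-like). Calibrated against this package's synthetic
#: target profiles, not claimed to equal any published fit.
PRESETS: dict[str, SimParams] = _load_presets()


@dataclass
class VirtualNeuron:
    """A simulated tree with per-compartment cytoskeletal quantities and
    the full growth-event log (step, tip node id, event)."""

    tree: NeuronTree
    mt: dict[int, float]
    fa: dict[int, float]
    event_log: list[tuple[int, int, str]] = field(default_factory=list)
    truncated: bool = False
    params: SimParams | None = None


def event_probabilities(mt: float, fa: float, p: SimParams) -> tuple[float, float, float]:
    """Closed-form (p_term, p_bif, p_elong) for a tip state."""
    p_term = math.exp(-p.k_term * mt)
    p_bif = (1.0 - p_term) * min(1.0, p.k_bif * fa)
    return p_term, p_bif, 1.0 - p_term - p_bif


def sample_event(tip: TipState, p: SimParams, rng: np.random.Generator) -> str:
    """Draw one growth event for a tip; consumes exactly one uniform."""
    p_term, p_bif, _ = event_probabilities(tip.mt, tip.fa, p)
    u = rng.random()
    if u < p_term:
        return "terminate"
    if u < p_term + p_bif:
        return "bifurcate"
    return "elongate"


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _perpendicular(d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A random unit vector perpendicular to d; consumes 3 normals."""
    r = rng.normal(size=3)
    r -= d * (r @ d)
    return _unit(r)


def _resample_fa(p: SimParams, rng: np.random.Generator) -> float:
    return max(0.0, float(rng.normal(p.initial_fa, p.fa_sd)))


def grow(p: SimParams, rng: np.random.Generator | None = None) -> VirtualNeuron:
    """Grow one virtual neuron breadth-first from a soma root.

    Tips are processed FIFO; per event the generator is consumed in a
    fixed documented order (event uniform, then the event's own draws), so
    an identical seed reproduces the tree byte-for-byte. Growth stops when
    every tip has terminated or ``max_compartments`` is reached (the
    neuron is then flagged truncated).
    """
    if rng is None:
        rng = np.random.default_rng(p.seed)
    root = SwcNode(id=1, type_tag=1, x=0.0, y=0.0, z=0.0, radius=1.0, parent_id=-1)
    nodes: list[SwcNode] = [root]
    mt: dict[int, float] = {1: p.initial_mt}
    fa: dict[int, float] = {1: p.initial_fa}
    d0 = _unit(rng.normal(size=3))
    tips: list[TipState] = [
        TipState(node_id=1, position=np.zeros(3), direction=d0,
                 mt=p.initial_mt, fa=p.initial_fa)
    ]
    log: list[tuple[int, int, str]] = []
    truncated = False
    step = 0
    next_id = 2

    def add_node(tip: TipState, direction: np.ndarray, new_mt: float,
                 new_fa: float) -> TipState:
        nonlocal next_id
        pos = tip.position + p.step_length * direction
        node = SwcNode(id=next_id, type_tag=3, x=float(pos[0]), y=float(pos[1]),
                       z=float(pos[2]), radius=1.0, parent_id=tip.node_id)
        nodes.append(node)
        mt[next_id] = new_mt
        fa[next_id] = new_fa
        new_tip = TipState(
            node_id=next_id, position=pos, direction=direction, mt=new_mt,
            fa=new_fa, branch_order=tip.branch_order,
            path_distance=tip.path_distance + p.step_length,
        )
        next_id += 1
        return new_tip

    while tips:
        tip = tips.pop(0)
        step += 1
        event = sample_event(tip, p, rng)
        if event == "terminate":
            log.append((step, tip.node_id, "terminate"))
            continue
        if event == "bifurcate":
            if len(nodes) + 2 > p.max_compartments:
                truncated = True
                break
            log.append((step, tip.node_id, "bifurcate"))
            # enrichment acts on the branch compartment itself
            fa[tip.node_id] = tip.fa * p.fa_branch_boost
            w = float(rng.beta(p.mt_split_concentration, p.mt_split_concentration))
            perp = _perpendicular(tip.direction, rng)
            ca, sa = math.cos(p.branch_half_angle), math.sin(p.branch_half_angle)
            d1 = _unit(ca * tip.direction + sa * perp)
            d2 = _unit(ca * tip.direction - sa * perp)
            fa1, fa2 = _resample_fa(p, rng), _resample_fa(p, rng)
            t1 = add_node(tip, d1, w * tip.mt, fa1)
            t2 = add_node(tip, d2, (1.0 - w) * tip.mt, fa2)
            t1.branch_order = t2.branch_order = tip.branch_order + 1
            tips.extend([t1, t2])
            continue
        # elongate
        if len(nodes) + 1 > p.max_compartments:
            truncated = True
            break
        log.append((step, tip.node_id, "elongate"))
        jitter = rng.normal(scale=p.direction_jitter, size=3)
        new_dir = _unit(tip.direction + jitter)
        new_fa = _resample_fa(p, rng)
        tips.append(add_node(tip, new_dir, tip.mt * (1.0 - p.mt_decay), new_fa))

    return VirtualNeuron(
        tree=NeuronTree(nodes=nodes), mt=mt, fa=fa, event_log=log,
        truncated=truncated, params=p,
    )


def export_sim_trees(vn: VirtualNeuron) -> tuple[str, str]:
    """Two SWC serializations with identical topology: the radius column
    holds the microtubule quantity in the first and the F-actin quantity
    in the second."""
    mt_nodes = [replace(n, radius=vn.mt[n.id]) for n in vn.tree.nodes]
    fa_nodes = [replace(n, radius=vn.fa[n.id]) for n in vn.tree.nodes]
    meta = list(vn.tree.metadata)
    return (
        write_swc(NeuronTree(nodes=mt_nodes, metadata=meta)),
        write_swc(NeuronTree(nodes=fa_nodes, metadata=meta)),
    )


def quantify_simulated(swc_mt: str, swc_fa: str) -> pd.DataFrame:
    """The 17-column metric table of a simulated neuron from its paired
    SWC exports; the quantities are read back from the repurposed radius
    columns. Raises on any topology mismatch between the pair."""
    t_mt = read_swc(swc_mt)
    t_fa = read_swc(swc_fa)
    if len(t_mt) != len(t_fa):
        raise ValueError("paired SWC files differ in node count")
    for a, b in zip(t_mt.nodes, t_fa.nodes):
        if (a.id, a.type_tag, a.x, a.y, a.z, a.parent_id) != (
            b.id, b.type_tag, b.x, b.y, b.z, b.parent_id
        ):
            raise ValueError(f"topology mismatch at node {a.id}")
    mt_q = {n.id: n.radius for n in t_mt.nodes}
    fa_q = {n.id: n.radius for n in t_fa.nodes}
    return metrics_table_from_quantities(t_mt, mt_q, fa_q)


# ---------------------------------------------------------------------------
# real-vs-simulated comparison


@dataclass
class ComparisonResult:
    """Aligned per-bin group means and a symmetric normalized divergence.

    Per quantity q ∈ {length, mt, fa} and bin i the divergence is
    ``|real_i − sim_i| / max(|real_i|, |sim_i|)`` (0 when both are 0):
    symmetric in its arguments and 0 iff the means agree.
    """

    axis: str
    bins: np.ndarray
    real_mean: dict[str, np.ndarray]
    sim_mean: dict[str, np.ndarray]
    divergence: dict[str, np.ndarray]

    def mean_divergence(self, quantity: str = "length") -> float:
        return float(np.mean(self.divergence[quantity]))


def _group_mean(profiles: list[DistributionProfile], n_bins: int):
    out = {}
    for name, attr in (("length", "length_per_bin"), ("mt", "mt_per_bin"),
                       ("fa", "fa_per_bin")):
        acc = np.zeros(n_bins)
        for p in profiles:
            v = getattr(p, attr)
            acc[: len(v)] += v
        out[name] = acc / len(profiles)
    return out


def compare_distributions(
    real: list[DistributionProfile], sim: list[DistributionProfile]
) -> ComparisonResult:
    """Compare a set of real-tree profiles with a set of simulated ones.

    All profiles must share the axis (and bin width for path-distance
    axes); shorter profiles are zero-padded to the longest.
    """
    if not real or not sim:
        raise ValueError("both profile sets must be non-empty")
    axes = {p.axis for p in real + sim}
    if len(axes) != 1:
        raise ValueError(f"mixed axes: {axes}")
    widths = {p.bin_width for p in real + sim}
    if len(widths) != 1:
        raise ValueError(f"binning mismatch: bin widths {widths}")
    longest = max(real + sim, key=lambda p: len(p.bins))
    n_bins = len(longest.bins)
    rm = _group_mean(real, n_bins)
    sm = _group_mean(sim, n_bins)
    div = {}
    for q in ("length", "mt", "fa"):
        denom = np.maximum(np.abs(rm[q]), np.abs(sm[q]))
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(denom > 0, np.abs(rm[q] - sm[q]) / np.where(denom > 0, denom, 1.0), 0.0)
        div[q] = d
    return ComparisonResult(
        axis=longest.axis, bins=longest.bins.copy(), real_mean=rm, sim_mean=sm,
        divergence=div,
    )


def plot_comparison(result: ComparisonResult, quantity: str = "length", ax=None):
    """Overlay plot: real group mean as a thick light line in the
    background, simulated group mean as a thin dark line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(result.bins, result.real_mean[quantity], color="0.7", linewidth=4,
            label="real", zorder=1)
    ax.plot(result.bins, result.sim_mean[quantity], color="0.1", linewidth=1,
            label="simulated", zorder=2)
    ax.set_xlabel(result.axis.replace("_", " "))
    ax.set_ylabel(quantity)
    ax.legend()
    return ax


def params_to_json(p: SimParams) -> str:
    return json.dumps(asdict(p), indent=2)


def params_from_json(text: str) -> SimParams:
    return SimParams(**json.loads(text))
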