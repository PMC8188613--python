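"""Per-compartment morphometrics, cytoskeletal quantification, topological
distribution profiles, normalization, correlations and relative-change
cumulative curves.

The central quantity is the local cytoskeletal quantity

    CQ = F · ASI · W

where F is the fraction of the compartment volume occupied by signal, ASI
the average signal intensity within that fraction, and W the local
dendrite width (compartment diameter). *Intensity* is CQ normalized for
branch thickness, i.e. F · ASI. The relative local change of any such
quantity between a compartment (Fc) and its parent (Fp) is

    FΔ = (Fc − Fp) / Fp

undefined (NaN) at the root and wherever Fp = 0.

:func:`metrics_table` assembles the full 20-column per-compartment table;
the remaining functions consume it: Strahler/path-distance distribution
profiles, group normalization against reference totals, Pearson
correlations of arbor length against local predictors, and per-event-class
empirical cumulative curves of FΔ.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .treeio import MultiSignalTree, NeuronTree, segment_length

__all__ = [
    "METRIC_COLUMNS",
    "SIMULATED_METRIC_COLUMNS",
    "DistributionProfile",
    "NormalizationReference",
    "cytoskeletal_quantity",
    "relative_change",
    "arbor_length",
    "classify_events",
    "strahler_order",
    "metrics_table",
    "metrics_table_from_quantities",
    "distribution_profile",
    "compute_reference",
    "normalize_profiles",
    "arborlength_correlations",
    "fdelta_cumulative_curves",
    "plot_profiles",
]

#: The 20 per-compartment metrics, in canonical column order.
METRIC_COLUMNS = [
    "topological_distance",
    "microtubule_quantity",
    "factin_quantity",
    "diameter",
    "branch_order",
    "topo_event",
    "arbor_length",
    "microtubule_intensity",
    "factin_intensity",
    "rel_change_mt_quantity",
    "rel_change_fa_quantity",
    "rel_change_mt_intensity",
    "rel_change_fa_intensity",
    "path_distance",
    "compartment_length",
    "strahler_order",
    "parent_id",
    "compartment_type",
    "integral_microtubule",
    "integral_factin",
]

#: The 17 metrics retained for simulated neurons: the two image-intensity
#: normalizations and the compartment-type column are dropped (simulated
#: trees are all-dendrite and carry no imaging data).
SIMULATED_METRIC_COLUMNS = [
    c
    for c in METRIC_COLUMNS
    if c not in ("microtubule_intensity", "factin_intensity", "compartment_type")
]

_TYPE_NAMES = {1: "soma", 2: "axon", 3: "dendrite"}


def cytoskeletal_quantity(F: float, ASI: float, W: float) -> float:
    """CQ = F · ASI · W (arbitrary units)."""
    if not 0.0 <= F <= 1.0:
        raise ValueError(f"fraction F={F} outside [0,1]")
    return F * ASI * W


def relative_change(current: float, parent: float) -> float:
    """(current − parent) / parent; NaN when the parent value is 0 or NaN."""
    if parent is None or not math.isfinite(parent) or parent == 0.0:
        return math.nan
    return (current - parent) / parent


# ---------------------------------------------------------------------------
# per-tree topological helpers


def _structure(tree: NeuronTree):
    by_id = {n.id: n for n in tree.nodes}
    kids = tree.children_map()
    roots = tree.roots()
    if len(roots) != 1:
        raise ValueError("metrics require a single-rooted tree (run repair first)")
    return by_id, kids, roots[0]


def compartment_lengths(tree: NeuronTree) -> dict[int, float]:
    """Length of each compartment (parent→node Euclidean distance); root = 0."""
    by_id = {n.id: n for n in tree.nodes}
    return {
        n.id: (
            0.0
            if n.parent_id == -1 or n.parent_id not in by_id
            else segment_length(by_id[n.parent_id], n)
        )
        for n in tree.nodes
    }


def arbor_length(tree: NeuronTree) -> dict[int, float]:
    """Total downstream neurite length per compartment.

    Sum of compartment lengths strictly downstream of each node: the soma
    value equals the neuron's total neurite length and every terminal tip
    is 0.
    """
    by_id, kids, root = _structure(tree)
    lengths = compartment_lengths(tree)
    out: dict[int, float] = {}

    order = []
    stack = [root.id]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(kids[nid])
    for nid in reversed(order):  # children before parents
        out[nid] = sum(out[c] + lengths[c] for c in kids[nid])
    return out


def classify_events(tree: NeuronTree) -> dict[int, str]:
    """Topological event per compartment: 2 children → bifurcation,
    1 → elongation, 0 → termination. The root is labelled ``root`` and is
    excluded from event statistics downstream."""
    by_id, kids, root = _structure(tree)
    out = {}
    for n in tree.nodes:
        k = len(kids[n.id])
        if k > 2:
            raise ValueError(
                f"node {n.id} has {k} children; repair (split_multifurcations) "
                f"was not run"
            )
        if n.id == root.id:
            out[n.id] = "root"
        else:
            out[n.id] = {2: "bifurcation", 1: "elongation", 0: "termination"}[k]
    return out


def strahler_order(tree: NeuronTree) -> dict[int, int]:
    """Standard Strahler stream order: leaves are 1; a parent of two
    children with orders (a, b) gets max(a, b) if a ≠ b else a + 1;
    elongation compartments inherit their single child's order."""
    by_id, kids, root = _structure(tree)
    out: dict[int, int] = {}
    order = []
    stack = [root.id]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(kids[nid])
    for nid in reversed(order):
        ks = kids[nid]
        if not ks:
            out[nid] = 1
        elif len(ks) == 1:
            out[nid] = out[ks[0]]
        else:
            a, b = out[ks[0]], out[ks[1]]
            out[nid] = max(a, b) if a != b else a + 1
    return out


def _path_metrics(tree: NeuronTree):
    """(topological_distance, path_distance, branch_order) per node."""
    by_id, kids, root = _structure(tree)
    lengths = compartment_lengths(tree)
    topo = {root.id: 0}
    pdist = {root.id: 0.0}
    border = {root.id: 0}
    stack = [root.id]
    while stack:
        nid = stack.pop()
        bifurcates = len(kids[nid]) == 2
        for c in kids[nid]:
            topo[c] = topo[nid] + 1
            pdist[c] = pdist[nid] + lengths[c]
            border[c] = border[nid] + (1 if bifurcates else 0)
            stack.append(c)
    return topo, pdist, border


def _downstream_integral(tree: NeuronTree, density: dict[int, float]) -> dict[int, float]:
    """Downstream sum of density·compartment_length, including the node itself."""
    by_id, kids, root = _structure(tree)
    lengths = compartment_lengths(tree)
    out: dict[int, float] = {}
    order = []
    stack = [root.id]
    while stack:
        nid = stack.pop()
        order.append(nid)
        stack.extend(kids[nid])
    for nid in reversed(order):
        out[nid] = density[nid] * lengths[nid] + sum(out[c] for c in kids[nid])
    return out


# ---------------------------------------------------------------------------
# the 20-column table


def _assemble(
    tree: NeuronTree,
    mt_q: dict[int, float],
    fa_q: dict[int, float],
    diameter: dict[int, float],
    mt_i: dict[int, float] | None,
    fa_i: dict[int, float] | None,
    columns: list[str],
) -> pd.DataFrame:
    by_id, kids, root = _structure(tree)
    topo, pdist, border = _path_metrics(tree)
    events = classify_events(tree)
    strahler = strahler_order(tree)
    arbor = arbor_length(tree)
    lengths = compartment_lengths(tree)
    int_mt = _downstream_integral(tree, mt_q)
    int_fa = _downstream_integral(tree, fa_q)

    def rel(values: dict[int, float], n) -> float:
        if n.parent_id == -1 or n.parent_id not in by_id:
            return math.nan
        return relative_change(values[n.id], values[n.parent_id])

    rows = []
    for n in tree.nodes:
        full = {
            "topological_distance": topo[n.id],
            "microtubule_quantity": mt_q[n.id],
            "factin_quantity": fa_q[n.id],
            "diameter": diameter[n.id],
            "branch_order": border[n.id],
            "topo_event": events[n.id],
            "arbor_length": arbor[n.id],
            "microtubule_intensity": mt_i[n.id] if mt_i is not None else math.nan,
            "factin_intensity": fa_i[n.id] if fa_i is not None else math.nan,
            "rel_change_mt_quantity": rel(mt_q, n),
            "rel_change_fa_quantity": rel(fa_q, n),
            "rel_change_mt_intensity": rel(mt_i, n) if mt_i is not None else math.nan,
            "rel_change_fa_intensity": rel(fa_i, n) if fa_i is not None else math.nan,
            "path_distance": pdist[n.id],
            "compartment_length": lengths[n.id],
            "strahler_order": strahler[n.id],
            "parent_id": n.parent_id,
            "compartment_type": _TYPE_NAMES.get(n.type_tag, "dendrite"),
            "integral_microtubule": int_mt[n.id],
            "integral_factin": int_fa[n.id],
        }
        rows.append({c: full[c] for c in columns})
    return pd.DataFrame(rows, index=[n.id for n in tree.nodes], columns=columns)


def metrics_table(
    mstree: MultiSignalTree,
    mt_channel: str = "mt",
    fa_channel: str = "fa",
) -> pd.DataFrame:
    """The 20 per-compartment metrics of a multi-signal reconstruction.

    One row per compartment (indexed by node id), columns in
    :data:`METRIC_COLUMNS` order. Quantities are CQ = F·ASI·W with
    W = 2·radius; intensities are F·ASI.
    """
    for ch in (mt_channel, fa_channel):
        if ch not in mstree.channels:
            raise KeyError(f"channel {ch!r} missing; have {mstree.channels}")
    tree = mstree.tree
    diameter = {n.id: 2.0 * n.radius for n in tree.nodes}
    mt_q, fa_q, mt_i, fa_i = {}, {}, {}, {}
    for n in tree.nodes:
        st_mt = mstree.stats(n.id, mt_channel)
        st_fa = mstree.stats(n.id, fa_channel)
        mt_i[n.id] = st_mt.fraction_above * st_mt.mean_intensity
        fa_i[n.id] = st_fa.fraction_above * st_fa.mean_intensity
        mt_q[n.id] = mt_i[n.id] * diameter[n.id]
        fa_q[n.id] = fa_i[n.id] * diameter[n.id]
    return _assemble(tree, mt_q, fa_q, diameter, mt_i, fa_i, METRIC_COLUMNS)


def metrics_table_from_quantities(
    tree: NeuronTree,
    mt_q: dict[int, float],
    fa_q: dict[int, float],
    diameter: dict[int, float] | None = None,
) -> pd.DataFrame:
    """The 17-column metric table for trees whose cytoskeletal quantities
    are given directly (simulated neurons, where no imaging exists).

    With no modelled branch thickness the nominal width is W = 1, making
    quantity and intensity numerically equal; the intensity relative
    changes therefore coincide with the quantity ones.
    """
    if diameter is None:
        diameter = {n.id: 1.0 for n in tree.nodes}
    df = _assemble(tree, mt_q, fa_q, diameter, mt_q, fa_q, METRIC_COLUMNS)
    return df[SIMULATED_METRIC_COLUMNS]


# ---------------------------------------------------------------------------
# distribution profiles


@dataclass
class DistributionProfile:
    """Topological distribution of dendritic length and cytoskeletal mass.

    Per bin: summed compartment length (μm), and summed CQ·length for
    microtubule and F-actin. ``axis`` is ``strahler`` (integer orders) or
    ``path_distance`` (μm bins of width ``bin_width``, label = upper edge).
    """

    axis: str
    bins: np.ndarray
    length_per_bin: np.ndarray
    mt_per_bin: np.ndarray
    fa_per_bin: np.ndarray
    bin_width: float | None = None

    @property
    def total_length(self) -> float:
        return float(self.length_per_bin.sum())

    @property
    def total_mt(self) -> float:
        return float(self.mt_per_bin.sum())

    @property
    def total_fa(self) -> float:
        return float(self.fa_per_bin.sum())


def distribution_profile(
    metrics: pd.DataFrame,
    axis: str = "strahler",
    bin_width: float = 25.0,
    dendrites_only: bool = False,
) -> DistributionProfile:
    """Bin compartments by Strahler order or path distance and sum, per
    bin, compartment length and the two cytoskeletal masses
    (CQ · compartment length).

    Total length is conserved: the bin sums add up to the neuron's total
    neurite length. ``dendrites_only`` drops soma/axon compartments first
    (only meaningful for tables that carry the compartment_type column).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    df = metrics
    if dendrites_only and "compartment_type" in df.columns:
        df = df[df["compartment_type"] == "dendrite"]
    length = df["compartment_length"].to_numpy(float)
    mt_mass = np.nan_to_num(df["microtubule_quantity"].to_numpy(float)) * length
    fa_mass = np.nan_to_num(df["factin_quantity"].to_numpy(float)) * length

    if axis == "strahler":
        orders = df["strahler_order"].to_numpy(int)
        max_order = int(orders.max()) if len(orders) else 1
        bins = np.arange(1, max_order + 1)
        idx = orders - 1
        width = None
    elif axis == "path_distance":
        pd_vals = df["path_distance"].to_numpy(float)
        max_pd = float(pd_vals.max()) if len(pd_vals) else 0.0
        n_bins = max(1, int(np.ceil(max_pd / bin_width - 1e-9)))
        bins = bin_width * np.arange(1, n_bins + 1)  # upper edges
        idx = np.clip(np.ceil(pd_vals / bin_width - 1e-12).astype(int) - 1, 0, n_bins - 1)
        width = bin_width
    else:
        raise ValueError(f"axis must be 'strahler' or 'path_distance', got {axis!r}")

    n_bins = len(bins)
    return DistributionProfile(
        axis=axis,
        bins=bins,
        length_per_bin=np.bincount(idx, weights=length, minlength=n_bins)[:n_bins],
        mt_per_bin=np.bincount(idx, weights=mt_mass, minlength=n_bins)[:n_bins],
        fa_per_bin=np.bincount(idx, weights=fa_mass, minlength=n_bins)[:n_bins],
        bin_width=width,
    )


@dataclass(frozen=True)
class NormalizationReference:
    """Group means of per-neuron total microtubule and F-actin used to
    express all groups relative to a reference population."""

    mean_total_mt: float
    mean_total_fa: float

    def __post_init__(self):
        if self.mean_total_mt <= 0 or self.mean_total_fa <= 0:
            raise ValueError("reference totals must be > 0")


def compute_reference(profiles: list[DistributionProfile]) -> NormalizationReference:
    """Reference totals from one neuron group (e.g. the wild-type class):
    mean over neurons of each per-neuron cytoskeletal total."""
    if not profiles:
        raise ValueError("need at least one profile")
    return NormalizationReference(
        mean_total_mt=float(np.mean([p.total_mt for p in profiles])),
        mean_total_fa=float(np.mean([p.total_fa for p in profiles])),
    )


def normalize_profiles(
    profiles: list[DistributionProfile], ref: NormalizationReference
) -> list[DistributionProfile]:
    """Divide every microtubule (resp. F-actin) bin value by the reference
    group's mean total, so the reference group's mean normalized total is 1
    and other groups are expressed relative to it. Lengths are untouched."""
    out = []
    for p in profiles:
        out.append(
            DistributionProfile(
                axis=p.axis,
                bins=p.bins.copy(),
                length_per_bin=p.length_per_bin.copy(),
                mt_per_bin=p.mt_per_bin / ref.mean_total_mt,
                fa_per_bin=p.fa_per_bin / ref.mean_total_fa,
                bin_width=p.bin_width,
            )
        )
    return out


# ---------------------------------------------------------------------------
# correlations and FΔ curves

#: The five local predictors correlated against arbor length.
CORRELATION_PARAMS = [
    "path_distance",
    "branch_order",
    "diameter",
    "microtubule_quantity",
    "factin_quantity",
]


def arborlength_correlations(metrics: pd.DataFrame) -> dict[str, float]:
    """Pearson r of arbor length against each of path distance, branch
    order, diameter, local microtubule quantity and local F-actin
    quantity, pooled over all compartments (rows with NaN in a pair are
    dropped pairwise). Zero-variance predictors yield NaN."""
    if len(metrics) < 3:
        raise ValueError("need at least 3 compartments")
    y = metrics["arbor_length"].to_numpy(float)
    out: dict[str, float] = {}
    for col in CORRELATION_PARAMS:
        x = metrics[col].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            out[col] = math.nan
            continue
        out[col] = float(sps.pearsonr(x[ok], y[ok]).statistic)
    return out


def fdelta_cumulative_curves(
    metrics: pd.DataFrame, column: str = "rel_change_fa_quantity"
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Empirical cumulative distribution of the relative local change
    (default: F-actin quantity FΔ), separately for bifurcating, elongating
    and terminating compartments.

    Root compartments and undefined changes (NaN) are excluded. Each curve
    is a pair of arrays ``(sorted values, cumulative fraction)``; an empty
    class yields empty arrays with a warning.
    """
    curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for event in ("bifurcation", "elongation", "termination"):
        vals = metrics.loc[metrics["topo_event"] == event, column].to_numpy(float)
        vals = np.sort(vals[np.isfinite(vals)])
        if len(vals) == 0:
            warnings.warn(f"no finite {column} values for event class {event!r}")
            curves[event] = (vals, vals)
            continue
        cum = np.arange(1, len(vals) + 1) / len(vals)
        curves[event] = (vals, cum)
    return curves


def plot_profiles(profiles_by_group: dict[str, list[DistributionProfile]],
                  quantity: str = "length", ax=None):
    """Sholl-like plot: per-group mean of a profile quantity per bin.

    ``quantity`` ∈ {length, mt, fa}. Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    attr = {"length": "length_per_bin", "mt": "mt_per_bin", "fa": "fa_per_bin"}[quantity]
    if ax is None:
        _, ax = plt.subplots()
    for group, profiles in profiles_by_group.items():
        n_bins = max(len(p.bins) for p in profiles)
        acc = np.zeros(n_bins)
        for p in profiles:
            v = getattr(p, attr)
            acc[: len(v)] += v
        acc /= len(profiles)
        bins = max(profiles, key=lambda p: len(p.bins)).bins
        ax.plot(bins, acc, marker="o", label=group)
    ax.set_xlabel(profiles[0].axis.replace("_", " "))
    ax.set_ylabel(quantity)
    ax.legend()
    return ax
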