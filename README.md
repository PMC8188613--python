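# cytomorph

Multi-signal neuron morphology: cytoskeletal quantification along SWC
dendritic reconstructions, channel-aware morphometrics, and a
cytoskeleton-constrained stochastic growth model for virtual arbors.

## The problem

Neuronal arbors are usually studied as bare skeletons, but the
cytoskeleton that builds them — microtubules in the shafts, F-actin at
growing and branching sites — is spatially structured along the tree.
This package quantifies subcellular fluorescence signals (e.g. a
microtubule channel and an F-actin channel) *per dendritic compartment*
of a traced reconstruction, so that cytoskeletal composition can be
analyzed with the same topological machinery as morphology itself: by
Strahler order, path distance, branch order, and downstream arbor
length. It targets workflows like Drosophila larval class I / class IV
dendritic arborization neurons imaged in multi-channel confocal stacks,
but is agnostic to organism and signal identity.

## The model

A *compartment* is the frustum between a reconstruction node and its
parent. Image voxels are assigned to compartments (nearest frustum axis,
disjointly), and for each compartment and signal channel the acquisition
records the fraction **F** of above-threshold voxels, their mean
intensity **ASI**, and its SD. The local cytoskeletal quantity is

> CQ = F · ASI · W

with **W** the compartment diameter; *intensity* is CQ normalized for
branch thickness, F · ASI. The relative local change of a quantity
between a compartment (Fc) and its parent (Fp) is

> FΔ = (Fc − Fp) / Fp.

Twenty per-compartment metrics (topological distance, quantities,
intensities, relative changes, arbor length, Strahler order, …) feed
distribution profiles, group normalization, arbor-length correlations,
and per-event-class FΔ cumulative curves.

Virtual arbors are grown tip-by-tip: at each step a tip terminates with
probability `exp(−k_term·mt)`, bifurcates with probability
`(1−p_term)·min(1, k_bif·fa)`, and elongates otherwise. Microtubule is
consumed along branches and partitioned (conserved) between daughters at
bifurcations; F-actin is enriched at branch compartments. Simulated
neurons are exported as paired SWC files (radius column repurposed for
the microtubule and F-actin quantity) and re-quantified with 17 of the
20 metrics for comparison against real trees.

## Worked example

Everything below is synthetic — no downloads. Generate a tree, paint it
with a known ground truth (distally decaying microtubule, branch-point-
enriched F-actin), render a two-channel stack, acquire, and quantify:

```python
from cytomorph import synthdata as sd, quantify as q, simulate as sim
from cytomorph.signal_acquisition import (
    AcquisitionParams, add_channels, assign_voxels, compute_channel_stats)

tree = sd.make_tree(sd.SynthTreeParams(n_leaves=8, seed=7, mean_branch_length=10.0))
shape = sd.fit_stack_shape(tree)
tree = sd.center_tree_in_stack(tree, shape)
truth = sd.paint_signals(tree, sd.SignalPaintParams())
stack = sd.render_stack(tree, truth, shape=shape, seed=7)

# tracing pseudo-channel = saturating sum; one acquisition run per signal
stack.channels["pseudo"] = add_channels(stack.channels["mt"], stack.channels["fa"])
vox = assign_voxels(tree, stack)
ms = compute_channel_stats(tree, stack, AcquisitionParams("pseudo", "mt"), voxel_sets=vox)
ms = compute_channel_stats(ms, stack, AcquisitionParams("pseudo", "fa"), voxel_sets=vox)

m = q.metrics_table(ms)          # 75 rows x 20 columns
print(q.arborlength_correlations(m))
```

prints (node 6 is the first branch point — note the doubled F-actin):

```
   microtubule_quantity  factin_quantity  ...  strahler_order   topo_event
1                1000.0            400.0  ...               3         root
2                 985.0            400.0  ...               3   elongation
...
6                 925.0            800.0  ...               3  bifurcation

{'path_distance': -0.789, 'branch_order': -0.678, 'diameter': 0.74,
 'microtubule_quantity': 0.807, 'factin_quantity': 0.578}
```

The microtubule quantity is the strongest correlate of downstream arbor
length (r = 0.807), ahead of path distance, branch order, diameter and
F-actin — the signature the quantification is designed to expose. A
virtual class-IV-like neuron grows with one call:

```python
vn = sim.grow(sim.PRESETS["class4"])   # 465 compartments, 57 tips
mt_swc, fa_swc = sim.export_sim_trees(vn)
```

The same pipeline also runs from the shell: `cytomorph synth`,
`cytomorph repair`, `cytomorph acquire`, `cytomorph quantify`,
`cytomorph simulate`, `cytomorph compare` (see `cytomorph --help`).

## Format notes

* **SWC**: standard 7 columns (`id type x y z radius parent`).
* **ESWC**: 7 + 3·k columns; per channel `(fraction, mean, SD)`.
* **#CHANNELSWC**: regular SWC body plus a `#CHANNELSWC` trailer of
  `(id, fraction, mean)` rows per channel — standard parsers still read
  the morphology.
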