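# binrefine

Assembly-graph-aware refinement of metagenomic bin assignments.

Metagenomic binners (MetaBAT2, VAMB, MetaWRAP, …) cluster assembled
scaffolds into bins by composition and coverage, but they leave short
contigs unbinned and assign each scaffold to exactly one bin even when it
contains interspecies repeats. `binrefine` takes the assembly graph (GFA
1.0) together with an initial scaffold binning (two-column TSV) and
propagates and corrects the bin labels over the graph, producing:

- a refined **soft edge binning** — a weight vector over bins for every
  assembly-graph edge (unitig), so repeats can carry several labels;
- refined **scaffold assignments** (single or multiple bins per scaffold,
  with raw scores);
- a **prob-Jaccard distance matrix** between bins, measuring bin overlap
  on the graph (useful for spotting strain mixtures and contamination);
- optional **per-bin read sets** extracted from a paired-end library for
  downstream reassembly.

It is intended for anyone post-processing MAGs who has the assembler's
graph at hand: the graph's connectivity is the information binners throw
away, and exploiting it increases bin completeness without sacrificing
purity.

## Model

Let `G` be the assembly graph with edges (unitigs) `e_1 … e_n`, and let the
initial scaffold binning map scaffolds to bins `C = {c_1 … c_m}`. The
scaffold binning is first pushed down to edges (matrix `Y`): the row of
edge `e` is uniform over `C(e)`, the set of bin labels of all scaffolds
containing `e` — `Y_ij = 1/|C(e_i)|` if `c_j ∈ C(e_i)`, else 0.

Connectivity lives in a weighted **link graph** `H` whose nodes are the
edges of `G`: weight 1 for graph adjacency and for scaffold joins that
jump over assembly gaps, plus `ln(1 + N_ij)` when `N_ij` read pairs
(paired-end or Hi-C, aligned by unique 31-mers) co-map to `e_i` and `e_j`.

The refined binning `F̃` minimizes a smoothness-plus-fidelity cost

```
tr(Fᵀ D^{-1/2} (D − L) D^{-1/2} F)  +  Σ_i μ_i ‖F_i − Y_i‖²
```

(`L` = adjacency of `H`, `D` its degree matrix). With per-edge
regularization `α_i = 1/μ_i ∈ [0, 1]` the minimizer is computed by the
damped diffusion

```
F(k+1) = diag(α) · S · F(k) + diag(1 − α) · Y,    S = D^{-1/2} L D^{-1/2}
```

starting from `F(0) = Y`. Repetitive edges (≥2 scaffold-path occurrences)
and unbinned edges always get `α = 1` (fully determined by neighbors);
binned unique edges get `α = 0` in **propagation** mode (initial labels
preserved) or `α = 0.6`, tapering to 1 below 1 kb, in **correction** mode.
A **sparse** mode damps `α` by graph-distance coefficients `β` so that
labels never spread farther than a distance threshold (default 10 kb) from
the initially binned edges.

Scaffold assignments are scored per bin either as
`Score(s, c_j) = Σ_{e∈s} length(e)·F̃_ij` (maximum likelihood, default) or
by argmax voting (majority length); multiple assignment reports the
smallest set of top bins covering ≥95% of the total score. Bin distances
are `1 − J_p` where `J_p` is the prob-Jaccard similarity of the bins'
column-normalized edge distributions.

## Worked example

Simulate a mock community (5 circular genomes × 40 unitigs of 3–10 kb, 5%
interspecies repeats, half of the contigs unbinned) and refine it:

```
$ binrefine simulate --output-dir sim --seed 0
fixture bundle written to sim

$ binrefine refine --graph sim/assembly.gfa --binning sim/binning.tsv \
    --output-dir refined --mode propagation --multiple \
    --bin-dist refined/bin_dist.csv --max-iter 5000 --tolerance 1e-8
refined binning written to refined/refined_binning.tsv
```

The initial binning covers 53 of 105 contigs; the refined output assigns
all of them (157 rows in multiple mode — repeat-adjacent contigs pick up a
second label). The run manifest records convergence:

```
n_segments: 210
n_scaffolds: 105
converged: True
iterations: 320
final_delta: 9.51e-09
```

`refined_binning.tsv` lists each scaffold with its assigned bin(s) and raw
bp-weighted scores:

```
#scaffold	bin	score
genome1_scaffold1	genome1	8955
genome1_scaffold10	genome1	6611
```

and `bin_dist.csv` holds the pairwise `1 − J_p` bin distances (here all
≥ 0.90: the five bins barely overlap on the graph, as expected for a
community whose genomes share only a handful of repeats):

```
,genome1,genome2,genome3,genome4,genome5
genome1,0.0,0.9776,0.9470,0.9789,1.0
```

Evaluated against the simulation's ground truth (`binrefine.evaluate_binning`),
this run raises the length-weighted mean F1 from 73.5% (initial binning) to
94.4%, with mean purity dropping only from 100% to 99.0% — refinement fills
the bins without contaminating them.

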