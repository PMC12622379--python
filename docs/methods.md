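# Methods

This note records the models and procedures modscape implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical conventions a maintainer needs to know.

## Feature-based family clustering

Every protein is summarized as a vector of composition means over a bundle
of amino-acid propensity indices (one value per index; default width 60).
The default bundle is assembled deterministically from the published
per-residue scales shipped with Biopython (32 distinct tables after
removing exact duplicates: Kyte–Doolittle and the other hydropathy scales,
Hopp–Woods hydrophilicity, Emini accessibility, Janin interior-to-surface,
Vihinen flexibility, ...), plus exactly-stated physicochemical tables
(average residue mass, net side-chain charge at pH 7 with His at +0.1,
ten residue-class indicators), padded to the configured width with seeded
synthetic scales named `synthetic_NN`. The synthetic padding adds
discriminative coordinates but corresponds to no measured property; any
curated bundle can be substituted via `load_index_set`, and the bundle's
names and content hash are recorded in run metadata. Unknown residues (`X`)
take each index's mean over the 20 canonical residues.

Families are seeded one-per-reference-protein: a panel protein joins the
seed it matches, where a match requires at least a fraction *f* = 0.9 of
features to agree within tolerance δ = 0.05. The tolerance is applied as
|x − s| / max(|s|, σ<sub>index</sub>) ≤ δ, where σ<sub>index</sub> is the
standard deviation of the index's 20 residue values. The σ floor matters:
several scales are zero-centred, so their composition means sit near zero
and a bare relative difference explodes under tiny absolute shifts; the
index's own spread is its natural unit there. With this definition,
descendant pairs at ≤ 2% pairwise sequence divergence match ≥ 0.98 of
features on simulated data while unrelated random sequences match ≤ 0.73,
so *f* = 0.9 separates the two cleanly. Ties between seeds go to the
smallest mean relative difference, then the lexicographically smallest
family id. Matching degrades for short, unusually diverged proteins — a
conservative failure mode that loses true edges rather than inventing
false ones.

Seed-centric assignment (rather than global clustering) keeps the network a
projection onto the reference proteome and the cost linear in panel size; a
non-reference protein can join only one family, and proteins matching no
seed become singleton families that never generate reference edges.

## Edge inference

*Profile edges* connect reference proteins whose family profiles are
identical by default (Hamming *h* = 0), each supported by ≥ *g*<sub>min</sub> = 3
genomes and absent from at least one genome (the ubiquity filter; without it
universal housekeeping families form an uninformative clique). *h*,
*g*<sub>min</sub> and the filter are run parameters; edge sets are monotone
in them (larger *h*, smaller *g*<sub>min</sub> only add edges).

*Neighbourhood edges* connect families found within *w* = 1 gene ranks on
the same contig in ≥ *n*<sub>min</sub> = 3 distinct genomes. Gene order is
the record order of the proteome FASTA; positions are 0-based ranks per
contig, nucleotide coordinates and strand are not modelled (strand is absent
from protein FASTA input), and adjacency never crosses contigs.

The assembled network carries per-edge evidence sets ⊆ {neighbourhood,
profile} and unit weights; reference proteins with no edge are excluded from
the network and reported as isolated. All inference is deterministic.

## Subnetwork extraction

Given a target set, the subnetwork is the induced subgraph on the targets
plus their distance-1 neighbours (neighbour–neighbour edges retained). Edges
whose evidence is exactly {neighbourhood} and whose endpoints share a
predicted operon are then removed — within-operon adjacency without
independent profile support is weak evidence — and non-target nodes left
with degree 0 are pruned and reported with reason codes. Targets are never
pruned; targets absent from the network are reported, not fatal. The operon
rule's scope is configurable (`all` edges, the default, or only
target-incident ones). Note that the literal degree-0 pruning rule makes
repeated extraction a contraction, not an identity, in one corner: a
neighbour that loses its target edge to the operon filter but keeps a
neighbour–neighbour edge survives the first extraction yet is no longer
distance-1 from a target. Extraction is exactly idempotent whenever no edge
was removed.

## Community detection

Modularity is resolution-scaled Newman modularity,
Q(γ) = Σ_c [e_c/m − γ(d_c/2m)²], with γ in the null-model term
(Reichardt–Bornholdt convention, the lineage Gephi implements). Self-loops
contribute their weight to e_c and twice to d_c. Networks are treated as
unweighted by default since inferred edge weights are nominal.

The Louvain optimizer is the standard two-phase scheme: seeded-shuffle node
visits, local moves accepted only on strict gain (> 1e-12, asserted), ties
keeping the current community then the smallest label, aggregation, repeat.
Fixed seed ⇒ identical partition; labels are contiguous integers numbered by
first appearance over sorted node ids, so order-preserving renames yield the
same partition up to that relabeling. Greedy local moving can stall in local
optima that no single-node move or aggregation escapes (verified against an
exhaustive-enumeration oracle on small graphs, where networkx's
implementation stalls identically); `restarts = R` runs seeds
`seed..seed+R−1` and keeps the best Q, still deterministically.

The resolution sweep reproduces empirical resolution selection: over an
ascending γ grid (default 0.50–1.50 in steps of 0.05, 10 repeats per γ) it
records median module count, median modularity and median coverage by
modules of at least `min_size` nodes, then selects the smallest γ with
median count ≤ `max_modules` and median coverage ≥ `min_coverage`. If no γ
qualifies it falls back, with a logged warning, to the γ maximizing median
modularity. Functional coherence of modules is not machine-checkable here;
the criterion operationalizes only size and count, and coherence is left to
the enrichment report.

## Enrichment, inventories, completeness

Each (module, pathway) pair with pathway background count K ≥ `min_K`
(default 2, suppressing singleton-pathway noise) and module count k ≥ 1
(a pathway absent from a module cannot be over-represented one-tailed) is
scored with the exact hypergeometric upper tail P[X ≥ k], X ~ HG(N, K, M),
computed via `scipy.stats.hypergeom.sf`; k = 0 returns 1. The p-value is
floored at 5e-324 so the (0, 1] range survives double underflow.
Benjamini–Hochberg adjustment (a direct numpy step-up; statsmodels serves
as an independent oracle in the tests) runs pooled across all emitted tests
by default, or within each module with `scope="per_module"`. Unannotated
proteins count toward M and N but never toward k or K, so the background N
(the whole proteome) may exceed the annotated count; N smaller than the
partition is an error.

KO inventories are unique-KO unions per module, with categories counted by
unique KO rather than by protein. Pathway completeness is the fraction of a
pathway's essential EC numbers carried by at least one background protein,
regardless of copy number (a multifunctional protein may satisfy several
ECs), with each carrier localised to its module or to "outside".

## Topology

Degree summaries use the lower central order statistic as the even-count
median, keeping integer medians integral. The power-law exponent is the
discrete MLE α̂ = 1 + n/Σ ln(d_i/(x_min − 0.5)) over the tail d_i ≥ x_min
with user-fixed x_min (≥ 10 tail points required; an all-equal tail is
degenerate and raises). Goodness-of-fit testing is out of scope. Bridging
centrality is the product form BC(v) = betweenness(v) ×
[(1/deg v)/Σ_{u∈N(v)} 1/deg u], with exact unnormalized betweenness
(networkx Brandes); isolated nodes get 0 with a flag.

## Synthetic generators

`gen_panel` emulates a pangenome: per-family ancestor sequences (uniform
residues, lengths uniform on 80–300), presence/absence per genome (profile
blocks share one planted pattern; other families are present independently
with probability 0.8; the reference genome carries everything), operon
blocks emitted adjacently and in order in their listed genomes, gene order
otherwise a seeded shuffle, and member sequences derived by i.i.d. uniform
substitution at the mutation rate. It does **not** emulate phylogenetic
correlation between genomes, indels, paralogy, gene fission/fusion, or
contig fragmentation — so passing tests demonstrate algorithmic
correctness on clean signals, not robustness to those real-data effects.
`gen_planted_network` is a two-rate planted partition (chosen over a
degree-corrected SBM for analytic tractability of expected densities);
`gen_annotations` sprays pathway labels at a base rate multiplied by a
capped odds factor for planted (module, pathway) enrichments, with
background size equal to the node count. All generators are pure functions
of (parameters, seed).

## Problem sizes and defaults in the acceptance script

`scripts/acceptance.py` uses an 8-genome, 24-family panel (three 3-family
profile blocks, two operon blocks, mutation rate 0.01 — about 2% pairwise
divergence between family members, a conservative operating point where
occasional short-protein matches fail and planted-profile recovery sits
below 1), a 4 × 40 planted partition at p_in = 0.3 / p_out = 0.02 for
clustering and the sweep, 10 planted-enrichment replicates (module of 50 in
a background of 500, odds 10, base rate 0.05) plus 200 null replicates for
the false-positive rate, and a 20,000-draw zipf(2.5) sample for exponent
recovery. These sizes keep a full run under half a minute on one CPU while
leaving every statistic well away from small-sample artifacts.

## Known limitations

* Family assignment is reference-seeded; paralogs collapse onto one seed
  and reference-absent families never form edges.
* Gene order comes from FASTA record order; misordered deposits silently
  bias neighbourhood evidence.
* The default propensity bundle pads with synthetic scales (see above);
  results depend on the bundle only through match fractions, but runs
  should record the bundle hash.
* Louvain is greedy; without restarts small graphs can stall in local
  optima, and stochastic tie patterns make module *labels* (not contents)
  seed-dependent.
* Enrichment assumes exchangeable annotation under the null; annotation
  correlation between proteins of one operon violates it and inflates
  significance, as in any over-representation analysis.
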