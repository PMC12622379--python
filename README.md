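# modscape

Genomic-context protein-interaction landscapes for microbial proteomes:
network inference from conserved gene neighbourhoods and phylogenetic
profiles, target-seeded subnetwork extraction, resolution-tuned Louvain
modules, and module-level pathway enrichment and completeness.

## The problem

For organisms that cannot be cultured — anaerobic methane-oxidizing archaea
(ANME) being a canonical example — protein function must be read off the
genome. Two comparative-genomics signals carry most of that information:

* **Phylogenetic profiles.** Protein families that are present and absent in
  the *same* subset of a related genome panel tend to work together: the
  profile of family *i* is the binary vector over genomes
  *p*<sub>*i*</sub> ∈ {0,1}<sup>*G*</sup>, and matching profiles
  (Hamming distance ≤ *h*, support ≥ *g*<sub>min</sub>, not ubiquitous) are
  evidence of functional association.
* **Conserved gene neighbourhood.** Families encoded within *w* gene ranks of
  each other on the same contig in ≥ *n*<sub>min</sub> distinct genomes are
  linked by operon-like organization.

modscape builds these families by matching every panel protein to seeds from
a reference proteome on a 60-dimensional vector of amino-acid propensity
means (hydropathy, flexibility, charge, residue classes, ...), projects both
edge kinds onto the reference genome as an evidence-tagged undirected network,
and then analyses that network:

* **Subnetworks.** The distance-1 ego network of a curated target set (e.g.
  the methane-metabolism machinery), with edges supported *only* by
  neighbourhood evidence removed when their endpoints share a predicted
  operon — co-localisation alone is weak evidence of a specific link.
* **Modules.** Louvain maximization of resolution-scaled modularity
  *Q*(γ) = Σ<sub>c</sub> [ *e*<sub>c</sub>/*m* − γ(*d*<sub>c</sub>/2*m*)² ]
  (Reichardt–Bornholdt convention; γ = 1 is Newman modularity), with an
  empirical resolution sweep that picks the smallest γ consistently giving a
  small number of large modules.
* **Enrichment.** One-tailed hypergeometric over-representation
  P[X ≥ k], X ~ HG(N, K, M), per (module, pathway), Benjamini–Hochberg
  adjusted across all tests; KO parts-list inventories per module; pathway
  completeness as the fraction of essential EC numbers present, with module
  localisation of the carriers.
* **Topology.** Degree summaries, discrete-MLE power-law exponent
  α̂ = 1 + *n* / Σ ln(*d*<sub>i</sub>/(*x*<sub>min</sub>−0.5)), and bridging
  centrality (betweenness × bridging coefficient) to flag proteins that
  stitch modules together.

A synthetic-data module generates pangenomes, planted-partition networks and
annotations with known ground truth, so every stage is testable offline.

## Worked example

```bash
modscape simulate --out panel --n-genomes 8 --n-families 30 \
    --mutation-rate 0.01 --seed 11
modscape infer --panel panel --reference G00 --out net.tsv
modscape cluster --network net.tsv --gamma 1.0 --seed 7 --out part.tsv
modscape topology --network net.tsv
```

prints

```
wrote 8 genomes to panel
network: 20 nodes, 43 edges (neighbourhood 3, profile 40); 10 isolated proteins
5 modules, sizes [9, 4, 3, 2, 2], modularity 0.2910 at gamma 1.0 (seed 7)
degrees: min 1, median 2, mean 4.30, max 8
```

The simulated panel plants three profile blocks and one conserved operon in
an 8-genome pangenome; inference recovers them as 40 profile-tagged and 3
neighbourhood-tagged edges among 20 of the 30 reference proteins (the rest
have no conserved context and are reported isolated). Clustering the network
at γ = 1 groups the planted blocks into modules; `part.tsv` holds the
protein → module table, and the degree summary describes the network's
connectivity. Full runs — subnetwork extraction, enrichment, completeness,
centrality — are driven from one YAML file with `modscape run --config
run.yaml` (see `modscape run --help` and `modscape.pipeline.RunConfig`).

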