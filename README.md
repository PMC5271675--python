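# dyncomp

**Decompose an MD trajectory into a network of coupled dynamic components.**

Long molecular-dynamics simulations of tightly packed proteins — the
motivating case is a G protein-coupled receptor's transmembrane helix bundle —
hide two kinds of functionally important motion in thousands of inter-residue
distance time series: *side-chain rearrangements*, where a contact switches
abruptly between discrete distance substates, and *global domain motions*,
where many backbone distances drift together over long stretches of the run.
`dyncomp` extracts both systematically, couples them to each other, and
reduces the trajectory to a small community network that can be inspected by
eye — replacing the manual scanning of distance plots that such analyses
otherwise require.

The package is aimed at computational structural biologists analyzing
equilibrium MD of receptors, transporters and other compact folds, and works
entirely on scalar distance series, so no structure superposition is ever
needed.

## Method

1. **Contacts.** Every residue pair at least 3 apart in sequence whose
   minimum side-chain heavy-atom distance drops below 5 Å in ≥ 1 frame gives
   a distance time series *d(t)* = min over atom pairs of the inter-residue
   distance (van der Waals mode: all non-hydrogen side-chain atoms; polar
   mode: the non-hydrogen polar head-group atoms, e.g. Nε/Cζ/Nη1/Nη2 for Arg).
2. **Substate switches.** Each series' density *p(d)* is fit with Gaussian
   mixtures ∑ₖ wₖ 𝒩(d; μₖ, σₖ²) by EM for k = 1…5; the Bayesian information
   criterion BIC = (3k−1)·ln n − 2·ln L selects k. After dropping components
   with weight < 0.05 and merging means closer than 1 Å, a series with ≥ 2
   surviving substates is a *side-chain dynamic component*; unimodal series
   are stable contacts.
3. **Domain motions.** All Cα–Cα series within 15 Å in ≥ 1 frame enter a
   dynamic cross-correlation matrix, rᵢⱼ = corr(dᵢ, dⱼ) (zero-lag Pearson).
   Nearest-point (single-linkage) hierarchical clustering on 1 − r, cut at
   r ≥ 0.95, yields clusters of co-moving series: the *domain components*.
4. **Network.** Components x, y are coupled by c(x,y) = |mean over all cross
   pairs of rᵢⱼ| — average first, absolute value second. Edges connect
   components with c ≥ 0.75; Girvan–Newman edge-betweenness partitioning (cut
   at maximum modularity) yields the communities, each one a protein sector
   whose switches and domain motions move together.
5. **Export.** CSV tables, GraphML, a reproducibility manifest, and one PDB
   per community in which every tracked series is a CONECT pseudobond between
   representative atoms, with the community id in the B-factor column.

## Worked example

`examples/04_full_pipeline.py` generates the built-in benchmark — a
12-residue, 500-frame coarse-grained trajectory with one planted 2.7/5.5 Å
side-chain switch riding one planted domain motion — and runs every stage at
the default cutoffs (5 Å, 15 Å, 0.95, 0.75):

```text
n_sidechain_vdw_series: 1
n_calpha_series: 33
n_multimodal: 1
n_domain_components: 1
n_edges: 1
n_communities: 1
switch-domain coupling: 0.939
```

The pipeline recovers exactly the planted structure: the one multimodal
side-chain series (the switch), one cluster of 27 co-drifting Cα–Cα series
(the domain motion), one edge coupling them at |mean r| ≈ 0.94, and a single
community containing both — the molecular-switch motif the framework is
designed to isolate. `examples/01–03` demonstrate each stage on its own.

The same run is available from the shell:

```bash
dyncomp synth --outdir bench                     # write the benchmark PDB
dyncomp run --topology bench/trajectory.pdb --outdir results
dyncomp gmm --series results/series_sidechain_vdw.csv --out modality.csv
dyncomp domains --series results/series_calpha.csv --outdir domains_out
```

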