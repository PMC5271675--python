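# Methods

This note documents what `dyncomp` computes, the assumptions behind each
stage, every tunable that matters, the synthetic benchmark the tests rely
on, and the numerical and design choices made where more than one reasonable
option existed.

## Model and assumptions

The framework assumes that the functionally relevant dynamics of a packed
protein can be summarized by scalar inter-residue distance time series, and
that two signal classes exhaust what matters:

* **Side-chain rearrangements** — a contact's minimum heavy-atom distance
  switches between a small number of well-separated, persistent substates.
  In the density domain this is multimodality, so the classification is
  *time-blind*: it asks whether multiple substates were sampled, not when
  the transitions happened. Change-point localization is deliberately out of
  scope.
* **Global domain motions** — many Cα–Cα distances change together, slowly,
  as rigid-ish sub-bodies move. These appear as blocks of highly correlated
  series, not as multimodal single series, which is why the two detectors
  are separate: a switch local to one contact would be invisible in a
  correlation screen, and a slow collective drift rarely produces clean
  multimodality in any one series.

Working on distances makes the whole pipeline invariant to rigid-body motion
of the protein, so trajectory alignment is never performed and alignment
noise never enters the correlations. The cost is that a distance is a
degenerate projection of 3-D motion; two motions that leave a distance
unchanged are invisible to it.

## Stages and parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| `contact_cutoff` | 5.0 | Å | side-chain/polar contact threshold (any frame) |
| `calpha_cutoff` | 15.0 | Å | Cα–Cα pair threshold (any frame) |
| `min_seq_sep` | 3 | residues | same-chain pairs only; inter-chain pairs always eligible |
| `k_max` | 5 | — | largest mixture size tried |
| `gmm_min_weight` | 0.05 | fraction | substate weight floor |
| `gmm_min_separation` | 1.0 | Å | substate mean-separation floor |
| `r_min` | 0.95 | — | DCC cutoff for domain clusters |
| `min_cluster_size` | 2 | series | smallest collective domain motion |
| `coupling_cutoff` | 0.75 | — | absolute average DCC for network edges |
| `seed` | 0 | — | EM initialization; recorded in every output |

**Contacts.** A pair qualifies if its minimum cross-pair distance is ≤ the
cutoff in at least one frame; the screen evaluates every frame by default
(`screen_stride` trades exactness for speed and is logged). Both the van der
Waals and the polar head-group series of a pair are kept as separate series
and both feed the modality screen. Glycine (no side-chain heavy atoms) and
non-polar residues in polar mode are skipped silently. Hydrogens are
identified by the element field when present, else by name; unknown heavy
side-chain atoms of standard residues are included (conservative). Altloc
records keep the highest-occupancy conformer; hetero residues, waters,
lipids and ions are skipped with a logged count.

**GMM screen.** EM (scikit-learn `GaussianMixture`, full 1-D covariances)
with tolerance 1e-4 on the per-sample log-likelihood gain, 500 iterations
maximum, k-means initialization from the stated seed, and up to 3 re-seeded
retries on non-convergence (a never-converged fit is returned flagged).
BIC = (3k−1)·ln n − 2·ln L; ties prefer smaller k; a candidate k whose
smallest weight is < 1e-6 (an empty component) is rejected; series shorter
than 10·k samples skip that k. Samples are sorted before fitting — the
verdict is density-based, so sorting loses nothing and makes the
classification exactly invariant under frame-order permutation. Constant
series are classified unimodal without fitting (variance floored at 1e-12 so
the fit object stays well-formed). The weight floor (0.05) and separation
floor (1.0 Å, merged by moment matching: weights summed, means
weight-averaged, variances matched to the pooled second moment) exist
because BIC happily splits heavy-tailed unimodal densities into overlapping
components; setting both to 0 recovers the raw BIC verdict.

**Domain clustering.** The DCC is the zero-lag Pearson coefficient of two
scalar series. Clustering is agglomerative single-linkage on the
dissimilarity d = 1 − r, cut at d = 1 − r_min inclusive. Two consequences
are load-bearing: (i) at a cutoff this construction is exactly equivalent to
taking connected components of the graph {(i,j): r ≥ r_min}, which the tests
use as an independent oracle; (ii) clustering uses *signed* r —
anti-correlated series do not cluster together; absolute values enter only
at the network stage. Zero-variance series are excluded with a logged list.
Singleton clusters are discarded (`min_cluster_size` = 2): a domain motion
is by definition collective.

**Network.** Coupling is |mean r| over all cross pairs of member series —
average first, absolute second, so cross pairs of opposite sign cancel
(two ±0.9 pairs couple at 0, not 0.9). The edge rule is inclusive
(c ≥ cutoff). Isolated nodes are kept by default and the community count is
reported both with and without them; `drop_isolates` removes them before
detection. Girvan–Newman betweenness runs on the unweighted topology
(weights retained as attributes; the weighted option treats 1/weight as
length); the partition returned is the modularity maximum over the removal
sequence, ties resolved toward fewer communities, labels renumbered by node
insertion order for determinism. An edgeless graph yields one community per
node.

**Export.** Community PDBs carry one CONECT pseudobond per series between
representative atoms (CA for Cα series; for side-chain series the
side-chain heavy atom nearest the side chain's geometric center at the
written frame — glycine falls back to CA). The community id is written to
the B-factor column. The visualization frame defaults to the last frame.
The run manifest records every cutoff, the seed, the stride, a SHA-256 of
the input coordinates, per-stage counts and library versions, and contains
no timestamps, so a rerun reproduces every output byte for byte.

## The synthetic benchmark

The generator plants exactly the structures the pipeline claims to detect:

* **Switches**: piecewise-constant means (default 2.7 and 5.5 Å — the
  distance signature of an aromatic contact forming and breaking) with
  Gaussian noise (σ = 0.3 Å).
* **Domain blocks**: a shared latent drift, scaled per member (0.7–1.3×)
  around per-member baselines, plus independent noise (σ = 0.2 Å; amplitude
  4 Å in series mode, 2.8 Å for the geometric benchmark). The latent is a
  sigmoid plus a small low-pass-filtered wiggle rather than white noise,
  emulating domain shifts that accumulate over hundreds of nanoseconds when
  compressed to a few hundred frames; *follower* switches transition at the
  latent's steepest frame, so switch/domain coupling is high by
  construction.
* **Geometry**: the trajectory generator realizes one block as an
  antiparallel two-segment polyalanine hairpin (Cα spacing 3.8 Å, resting
  inter-segment gap 7.5 Å) whose second segment translates along the
  inter-segment axis by the latent — so every cross-segment Cα distance
  co-increases, forming one signed-correlation cluster — and realizes each
  switch by placing the mobile partner's side-chain tip directly at the
  planted distance from the static partner's tip. Switch pairs must span
  the two segments (anything else is reported as geometrically infeasible).
  All atoms get independent 0.03 Å jitter. The canonical benchmark is 12
  residues × 500 frames; the two-community benchmark uses blocks
  transitioning at 15% and 85% of a 1000-frame run with a sharpened latent
  (τ = n/60), which places within-block couplings ≥ 0.9 and cross-block
  couplings ≤ 0.3.

What the synthetic data does *not* emulate: realistic force-field dynamics,
anharmonic or heavy-tailed noise (an option exists for the noise but not
for the physics), membrane/solvent effects, gradual (non-switch-like)
side-chain drift, overlapping domain motions sharing residues, and the
sheer series count of a real receptor trajectory (~10³–10⁴ series). Passing
tests therefore demonstrate that the statistical machinery recovers planted
structure at realistic signal-to-noise ratios — not that the biological
interpretation of any particular trajectory is correct, and not how the
method behaves when domain motions are mutually correlated (those merge, by
design, into one cluster or one community).

## Problem sizes

The test suite and the acceptance script run everything on generated data
sized for a desk machine: 100 + 100 series of 1000 frames for the modality
benchmark, ≤ 50 series × 40 frames for the clustering-duality instances,
8-component networks over 1000-frame series for community recovery, and the
12-residue × 500-frame trajectory end to end. These sizes were chosen so the
statistical targets (≥ 95% detection, ≤ 5% false positives, exact oracle
agreement) are meaningful while a full run completes in well under a minute
per stage on one CPU; the algorithms themselves are O(pairs × frames) for
contacts and O(series²) for the DCC matrix, and frame down-sampling for the
matrix is config-exposed for larger systems.

## Known limitations

* Pearson DCC captures linear, zero-lag co-variation only; lagged or
  nonlinear coupling (mutual information) is out of scope.
* BIC model selection on strongly autocorrelated series treats frames as
  i.i.d. samples; effective sample sizes are overstated, which the
  weight/separation floors partially offset.
* Single linkage chains: two tight clusters bridged by one intermediate
  series merge at the cutoff. This is inherent to the nearest-point
  criterion (and to its threshold-graph equivalence) and is the reason the
  cluster cutoff is set as high as 0.95.
* Edge betweenness is O(V·E²)-ish and suits the intended scale (hundreds of
  nodes); for much larger networks a different community algorithm would be
  needed.
* The CLI exposes the pipeline (`run`, `synth`) and the two stages that
  operate naturally on distance-series CSV files (`gmm`, `domains`);
  everything else is library API, which is how the package is meant to be
  driven.
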