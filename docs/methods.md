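# Methods

## Problem and model

`strandscape` reconstructs the conformational landscape of an RNA from
single-molecule chemical-probing data.  Chemical probing (e.g. SHAPE
reagents such as NAI) modifies flexible, predominantly unpaired
nucleotides; after reverse transcription each modification appears as a
mutation in the read.  High-accuracy long reads cover whole transcript
molecules, so each read carries a full-length *mutational fingerprint*
of one molecule's structure at the moment of probing.  Instead of
averaging fingerprints into one reactivity profile and folding once,
the pipeline folds **every molecule separately** under its own
constraints and then clusters the resulting structures, which resolves
mixtures of coexisting conformations that a population average would
blur together.

Pipeline stages:

1. **Bit vectors** — each aligned read becomes a length-L vector over
   {0 match, 1 mutation, MASK uninformative}.  Mismatches and
   unambiguously aligned deletions count as mutations; soft-clipped or
   uncovered positions, read `N` bases and ambiguous deletions are
   masked and excluded from every denominator.
2. **Reactivity** — positionwise mutation rates MR = ones/(ones+zeros)
   per channel; raw reactivity `R = (MR+ − MR−)/(1 − MR−)` (a
   positive-likelihood-ratio estimate of modification, clamped at 0);
   2%/8% normalisation to a 0-to-~1 scale.
3. **Per-molecule folding** — each bit vector's mutated positions are
   forced unpaired and structures are drawn from a weighted SCFG by
   inside/stochastic-traceback sampling.
4. **Element encoding** — each structure becomes a per-position string
   over {f,t,s,h,i,m}; one-hot expansion yields the numeric matrix.
5. **Landscape** — PCA embedding, k-means clustering, per-cluster
   population proportions, consensus element string and a
   representative member structure.
6. **Ensemble statistics** — pair probabilities `P_ij` by counting,
   positional pairing probability `P_i = Σ_j P_ij`, single-strandedness
   `1 − P_i`, Shannon entropy `E_i = Σ_j −P_ij log10 P_ij`.

## The structure grammar

The sampler uses a deliberately small, unambiguous nested grammar
rather than an externally trained one, so that its semantics are fully
specified here and every sampling statement can be checked against
brute-force enumeration.  A structure's weight is

    u^(#unpaired) × Π_pairs w(base_i, base_j) × γ^(#helices)

* `u = 1` — unpaired emission weight (the reference scale);
* `w` — canonical pair weights on the stacked scale
  (GC/CG 6.0, AU/UA 3.0, GU/UG 1.5 by default; all other pairs 0);
* `γ = 0.02` — helix initiation penalty, paid once per maximal stack
  (a pair (i,j) with (i−1,j+1) unpaired starts a helix);
* hairpin loops enclose ≥ 3 nt (steric minimum).

The initiation penalty is what makes the grammar favour stacked
canonical helices: without it, the combinatorial mass of isolated-pair
clutter dominates any designed helix (the partition function of a
120-nt sequence is astronomically larger than any single basin's
weight).  With γ ≪ 1 an isolated pair costs `w·γ < 1` and is rare,
while long helices pay γ only once.  The defaults were chosen by
piloting the grammar on the bundled synthetic mixture before the test
thresholds were frozen; they are deliberately simple round numbers, are
pluggable through a YAML parameter table, and make no claim of
thermodynamic accuracy — the pipeline's contracts (exact sampling,
constraint soundness, landscape recovery) are grammar-agnostic.

The inside algorithm fills two tables over intervals (O(L³) time,
O(L²) space): `W(i,j)`, the total weight of the subsequence, and
`V(i,j)`, the weight with (i,j) paired, via the unambiguous leftmost
decomposition

    W(i,j) = u·W(i+1,j) + Σ_k V(i,k)·W(k+1,j)
    V(i,j) = w(i,j)·[ γ·(W(i+1,j−1) − V(i+1,j−1)) + V(i+1,j−1) ]

Stochastic traceback then draws each structure with probability
proportional to its weight.  Hard constraints zero the pair weights of
force-unpaired positions, so constraint violations are impossible by
construction (and asserted anyway).  An open chain is always derivable,
so constrained sampling never fails.

Per-molecule randomness: molecule seeds are
`SeedSequence([root_seed, crc32(read_id)])`, so results are independent
of processing order and stable under subsetting.

## Synthetic data: what it emulates and what it does not

The simulator draws each molecule's conformation from stated mixture
weights, then modifies positions independently: unpaired positions at
`p_unpaired_mod = 0.06`, paired at `p_paired_mod = 0.005` in the (+)
channel, and everything at `p_background = 0.002` in the (−) control
channel.  These defaults emulate the sparse per-molecule signal of
single-hit chemical probing on high-accuracy long reads.  Reads are
emitted error-free apart from the encoded modifications (consensus
long reads are treated as high accuracy); the simulator does not model
reverse-transcription drop-off, amplification bias, reagent chemistry
kinetics or position-dependent modification preferences.  Passing
tests on this generator therefore demonstrates the pipeline's
statistical machinery, not robustness to those real-data artefacts.

### The bundled three-state toy

The bundled ~120-nt fixture (`three_state_fixture`) places six blocks
`B1 B2 B3 rc(B1) rc(B2) rc(B3)`; helix k joins block k to block k+3,
so any two of the three helices **cross** and the three conformations
are mutually exclusive with pairwise disjoint paired sets.  This
geometry maximises what probing can see: every paired region of one
state is unpaired in the other two, so each modification there is
direct evidence against one competing state.  At the default rates a
molecule carries only ~2–3 such discriminative modifications, which
bounds per-molecule assignment accuracy no matter the method — a
molecule with zero modifications in a competitor's helix region is
genuinely uninformative about that competitor.  Concretely, an exact
Bayes classifier given the true conformations, true modification rates
and true mixture prior reaches an adjusted Rand index of only about
0.78–0.82 against ground truth on this fixture family (roughly 8% of
molecules carry no evidence against the major state), so per-molecule
label agreement in the high 0.7s is the information ceiling of these
simulation conditions, not a pipeline deficiency; the pipeline
typically realises ~95% of that ceiling.  The validation script
computes this Bayes reference on the same simulated molecules and
reports it next to the pipeline's own label agreement.  Proportion estimates are far
less limited because uninformative molecules are distributed by a
calibrated prior (below) and their errors largely cancel.

Design choices that realise this:

* helix stabilities are tiered (state 1 > state 2 > state 3, matching
  the 70/20/10 abundances), and the words are calibrated so that the
  *measured* unconstrained sampling ensemble populates the three
  states at approximately the mixture weights — the Bayes-consistent
  prior for evidence-free molecules, which keeps recovered proportions
  unbiased;
* cross-block word complementarity — including shifted registers of
  the intended helices, which would otherwise let a competitor helix
  slide around a forced-unpaired position instead of breaking — was
  minimised by randomised search, so off-pathway helices carry at most
  about two to three GC pairs' worth of weight and no spurious basin
  competes with the three designed states;
* the landscape for this fixture is built with several samples per bit
  vector (15 in the validation runs); per-molecule proportions are
  fractional (each molecule spreads unit mass over its samples'
  clusters) and the per-molecule label is the modal cluster, which
  approaches the maximum-a-posteriori assignment as the number of
  samples grows.

## Numerical and algorithmic choices

* Coordinates are 1-based in every interface and report; pairs `(i,j)`
  satisfy `i < j`.
* Ambiguous deletions: a deletion adjacent to or inside a homopolymer
  run ≥ 2 of the deleted base masks the whole run (the aligner could
  place the gap anywhere in it).  This is this package's operational
  definition of "unambiguously aligned": anything else codes 1.
* Reads covering < 90% of the reference are dropped so every bit
  vector informs full-length structure; base-quality masking is off by
  default (consensus long reads are high accuracy).
* Negative raw reactivities are clamped to 0: the reactivity scale
  starts at "no reactivity" and downstream constraint logic consumes
  only non-negative evidence.
* 2%/8% normalisation: with n defined values, discard the top
  ⌊0.02·n⌋ and divide by the mean of the next max(⌊0.08·n⌋, 1); a
  boxplot variant is available.  Profiles with fewer than 20 defined
  positions are left unnormalised with a warning, and profiles whose
  positive-reactivity fraction is below 5% are flagged as likely
  unmodified rather than force-normalised.
* MASK positions are unconstrained in folding (absence of evidence is
  not evidence of pairing); only code-1 positions are forced unpaired.
* PCA sign convention: the largest-magnitude loading of each component
  is made positive, so embeddings are bit-reproducible.  k-means uses
  k-means++ with 10 restarts and a fixed seed; clusters are relabelled
  by decreasing per-molecule proportion, making cluster numbering
  invariant to initialisation.  Clustering operates in the embedded
  space by default (full-matrix clustering behind a flag).
* Representative selection prioritises Hamming distance to the
  consensus element string, then distance to the cluster centroid,
  then read id.  The consensus (positionwise modal element, ties
  broken in the fixed order f<t<s<h<i<m) is the maximum-expected-
  accuracy object; the centroid is secondary.
* Entropy sums over pairing partners only, exactly as defined; terms
  with `P_ij = 0` contribute 0 by continuity.  An extended entropy
  that adds the unpaired-state term `−(1−P_i) log10(1−P_i)` is
  computed alongside and clearly labelled as the non-standard variant.
* Structures with no pairs are element-coded all-`f` (the element
  taxonomy is undefined for pairless chains); unpaired stretches
  between top-level helices are multiloop (`m`) segments of the
  exterior loop.
* PPV matches pairs exactly by default; a slip-tolerant mode (± 1
  position on either strand) exists because some published PPV
  variants allow it.

## Problem sizes

Validation uses structure spaces small enough for exact enumeration
(sequences ≤ 14 nt, 50,000 draws for goodness-of-fit) and a 2,000-
molecule mixture of the 122-nt three-state toy for end-to-end
recovery; these sizes keep every check exact or well-powered while the
whole suite runs on a single CPU in minutes.

## Known limitations

* The grammar is a minimal stand-in with hand-set weights: sampled
  ensembles are not thermodynamic predictions, and no claim is made
  that they reproduce any particular trained engine's output.
* Pseudoknots are outside the model (nested grammar, dot-bracket
  representation throughout).
* Tree-alignment topological similarity is not implemented; structure
  comparison is pair-level (PPV/sensitivity) only.
* Per-base reagent bias correction is not modelled.
* The per-molecule information ceiling discussed above means landscape
  recovery degrades gracefully but inevitably as modification rates
  fall, molecules shorten, or conformations overlap in pairedness.
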