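# Methods

This note documents the models, algorithms and parameter choices behind
`markerdiv`, in the order the pipeline applies them, together with the
package's numerical conventions and known limitations.

## Substitution model

All protein-level machinery (the simulator, the distance correction, the
placement likelihood) shares one model: a 20-state Poisson process with
uniform stationary frequencies and uniform exchangeabilities, scaled so
branch lengths are expected substitutions per site. Its transition kernel
has the closed form

    P(x→y | t) = e(t)·δ(x,y) + (1 − e(t))/20,   e(t) = exp(−(20/19)·t)

so the expected p-distance at path length t is p = (19/20)(1 − e(t)), and
the corrected distance is d(p) = −(19/20)·ln(1 − (20/19)·p), capped at
d_max = 5 substitutions/site for saturated pairs. Matching the simulator
and the inference model is deliberate: it keeps every stage checkable
against closed forms and makes test failures attributable to the code
rather than to model misspecification. Real marker proteins evolve under
non-uniform exchangeabilities (LG/WAG-like) with rate heterogeneity across
sites; nothing in the pipeline's logic depends on the choice, but absolute
PD values and placement likelihoods on real data would differ.

## Synthetic communities

The generator emulates the inputs of a marker-gene metagenome survey:

- **Reference families.** Per group, a Yule (pure-birth) topology with
  `n_lineages` leaves is rescaled so every root-to-tip path equals
  `radiation_depth`; each group hangs off a shared root by a `stem_depth`
  branch (default 1.0 substitutions/site, enough to keep groups
  phylogenetically distinct). Reference sequences are evolved indel-free,
  so the reference alignment is gapless and every column index is a truth
  coordinate.
- **Fragments.** A fragment picks a lineage, evolves a hidden "strain" at
  `within_lineage_depth` (default 0.05 — within-species divergence), and
  cuts a contiguous region of at least `fragment_min_len = 150` residues
  (the conventional ORF length floor for marker screens) at a uniform
  random start. Group, lineage, start column and length are recorded as
  ground truth. Fragments are distributed round-robin across groups so
  windowed comparisons are never starved of members.
- **Paralog scenarios.** An ancient duplication is grafted onto one group:
  a second "B" copy branches off the duplicated lineages' common ancestor
  with a stem of 2·`dup_depth` (i.e. `dup_depth` of divergence on each side
  of the duplication event) and re-radiates along a copy of their subtree.
  The original references and fragments stay bit-identical — required so
  that a zero-duplication call is the identity — and fragments from
  duplicated lineages are doubled with B-copy draws. The restructured tree
  keeps the two paralog clades as disjoint subtrees (an explicit zero-length
  edge roots the A side), which is what the downstream splitter consumes.
- **Codon pairs.** A GY94-style Markov process over the 61 sense codons
  (uniform codon frequencies; rate κ for transitions, ×ω for
  non-synonymous changes, zero to/from stops), normalized so branch length
  is expected substitutions per codon. The pair diverges t/2 on each side
  of a uniform-random ancestor. Sampling uses the exact matrix exponential
  of the generator rather than event-by-event simulation — the contract is
  distributional, and `expm` sampling is distributionally exact.

What the generator does **not** emulate: indels, site-rate heterogeneity,
compositional bias, sequencing/ORF-calling error, uneven group abundances,
database contamination. Passing tests therefore demonstrate that the
analysis machinery is correct under its stated model, not that it is robust
to every artifact of real metagenomes.

## Profile screening

One profile per group is estimated from the group's reference alignment
("Plan7-lite": match/insert/delete states, local entry/exit, no
forward/posterior decoding):

- Columns with gap fraction < 0.5 (`match_gap_frac`) become match states.
- Emissions are Dirichlet-smoothed counts with pseudocount 1.0 against a
  uniform background; transitions are Laplace-smoothed counts from the
  observed state paths (rare D→I / I→D steps are folded into D→M / I→M,
  which the dynamic program does not model).
- Scoring is local Viterbi in log-odds (bits). The alignment of an accepted
  fragment is its Viterbi path mapped back to reference columns; flank and
  insert residues carry an explicit "insertion" marker.
- E-values come from a Gumbel fit (method of moments) to the Viterbi scores
  of `n_null` i.i.d. background sequences (default 1,000; pipeline runs use
  300, which is ample for the four-decade extrapolation the E < 10⁻⁵
  threshold requires at these score separations). The E-value convention is
  E(S) = N_eff·exp(−λ(S−μ)) with N_eff the number of fragments scanned in
  the current search, recorded in output metadata.

Fragments below `min_len = 150` residues are excluded before scoring, and
hits require E < 10⁻⁵ — both thresholds are the standard gates for this
kind of screen and are exposed as parameters.

## Placement and group assignment

Queries are placed on the fixed reference tree by maximizing the pruning
likelihood over attachment edges, restricted to the query's ungapped
columns. For each edge the query attaches at the edge midpoint; its pendant
branch is optimized by golden-section search on [0, 5] substitutions/site
to tolerance 1e-4 (the zero endpoint is checked explicitly, so identical
queries report pendant 0). Per-edge "inside/outside" partial vectors are
precomputed once per query, making each pendant evaluation O(sites).
Ties (within 1e-9 log-likelihood) resolve toward the root, then by edge id.

Edges are painted by strict monophyly: an edge is labelled with group G iff
every leaf below it is G, otherwise "unclassified". Placements on deep
mixed edges therefore drop out of the per-group analyses rather than being
forced into a group. Paralog splitting classifies placements into two
disjoint clades (each including its subtending stem edge); anything
elsewhere in the group is "unassigned".

## Windowed richness and PD

- **Windows** are 100 alignment columns wide with step 10. A fragment is a
  window member iff its aligned span covers the whole window and it has
  gaps at ≤ 10% of window sites (boundary inclusive: 10/100 gaps retained,
  11/100 discarded).
- **OTU clustering** is greedy and centroid-based, processing sequences in
  decreasing ungapped-length order (ties by id), each joining the first
  centroid with identity ≥ the cutoff (70/80/90%). Identity is matches
  over columns ungapped in *both* sequences — the denominator is ambiguous
  in common clustering tools, so the choice is documented and configurable.
  Greedy clustering is order-sensitive; tests quantify the sensitivity with
  an order-perturbation envelope instead of hiding it.
- **Rarefaction** resamples sequences without replacement against the fixed
  clustering (cluster once, then subsample — the standard convention; the
  alternative of re-clustering per replicate is far more expensive and was
  not adopted). Each replicate draws one permutation and reads every depth
  as its first d entries, so the per-depth marginal is an exact uniform
  subset while every curve, and hence the mean curve, is exactly
  non-decreasing in depth. Default 10 replicates.
- **Log-rank comparison.** Richness curves are compared by treating each
  OTU as a subject whose event time is its cluster size (all events
  observed, no censoring) and applying the standard two-sample
  (O−E)²/V chi-squared test with 1 df (via lifelines). This concrete
  realization of "compare richness curves with a log-rank test" is one
  reasonable construction; its null calibration is verified empirically
  (type-I error 0.05 ± 0.02 at α = 0.05).
- **PD** is the total branch length of a neighbor-joining tree over
  Poisson-corrected distances of up to `n_subsample` window members
  (default 1,000; desk-scale runs and the acceptance study use 80–100,
  which preserves the between-group ordering while keeping the O(n³) NJ
  step fast). Pairs with no shared ungapped columns are imputed with the
  maximum observed distance and the window is flagged.

Neighbor joining is the package's own Saitou–Nei implementation: exact on
additive matrices, deterministic label-order tie-breaking, negative branch
lengths clamped to zero with the deficit transferred to the sibling. An
independent implementation (scikit-bio) is used as a cross-check in the
test suite, not as the code path.

## Ka/Ks and group comparison

Pairwise ω uses Nei–Gojobori (1986) counting rather than codon-model
maximum likelihood: the downstream use — comparing ω distributions between
groups — needs a consistent estimator, and counting is exhaustively
testable against enumeration oracles. Specifics:

- Site counts: per codon position, the fraction of the possible single-
  nucleotide changes that are synonymous, with changes to stop codons
  excluded from the denominator (so S + N = 3 per codon).
- Differences: averaged over all minimal-length substitution pathways that
  avoid stops, equally weighted.
- Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)p) per class; p ≥ 3/4
  raises a saturation error; Ks = 0 leaves ω undefined (reported missing).
- The percent standard error of ω is a codon bootstrap (500 replicates,
  seeded); replicates that saturate or have Ks = 0 are dropped.
- Inclusion filters: Ka > 0.01, Ks < 5.0 (virus-style) or 10.0
  (bacteria-style), SE% < 25 — all exposed on `PairFilter`.
- Group contrast: two-sided Mann–Whitney U, exact by enumeration when
  n_a + n_b ≤ 12 with no ties, otherwise the normal approximation with tie
  and continuity corrections (scipy).

NG86 with JC correction is known to be mildly conservative at high
divergence and ignores transition/transversion bias in the *counting* step;
recovery tests show the median estimate stays within ±30% of the simulated
ω at t = 0.3 over 2,000 codons, which is sufficient for rank-based group
comparisons.

## Numerical conventions and degenerate inputs

- Column coordinates are 0-based half-open everywhere, including TSVs.
- Per-site likelihood vectors are rescaled during pruning to avoid
  underflow; scale factors are carried in log space.
- Empty windows produce empty clusterings; windows with fewer members than
  the resampling depth are flagged and carry NaN rather than being silently
  dropped; groups with fewer than three window members skip PD.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; windowed profiles derive one seed per (window, group, cutoff) cell
  from integer coordinates, so results are independent of processing order.
- The pipeline is single-threaded by contract; re-running a config
  reproduces every output file byte for byte.

## Problem sizes

The shipped study configurations use communities of 600 fragments over a
300-column marker (three groups; the focal group with 18 lineages at
radiation depth 1.6, comparison groups with 6 at 0.8), richness resampling
at depth 60 and PD subsamples of 80; statistical calibration uses 1,000
(log-rank) and 2,000 (Mann–Whitney) null replicates, and ω recovery 50
replicates of 2,000 codons per ω. These sizes make the designed orderings
and calibration bands sharply resolvable while a full analysis completes in
about a minute on a single core.

## Known limitations

- The matched simulator/inference model means accuracy numbers are upper
  bounds relative to real, model-misspecified data.
- The profile HMM has no forward/posterior decoding or domain splitting;
  E-values extrapolate a Viterbi-score Gumbel fit rather than an exact
  forward-score distribution.
- The log-rank construction over OTU cluster sizes is one explicit reading
  of "comparing richness curves"; other constructions could give different
  p-values (the qualitative orderings tested here do not depend on it).
- Greedy OTU counts depend on processing order; the envelope across orders
  is typically ±1–2 clusters at the sizes used here.
- NJ trees are distance-based; no ML tree refinement or branch support is
  computed.
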