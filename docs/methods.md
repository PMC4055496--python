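# Methods

This note documents the models implemented in `fishauth`, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the design decisions taken where the underlying
procedures left room for choice.

## Endpoint qPCR calling (`fishauth.qpcr`)

A sample well is positive on a dye layer when its endpoint (cycle 40)
ΔRn is **strictly larger** than the no-template-control threshold

```
z*M = M + 3.89 · SD + C
```

- `M`, `SD`: mean and sample standard deviation (n−1 denominator, as a
  spreadsheet STDEV gives) of the NTC endpoint ΔRn values, computed
  **per plate and per dye layer**, never pooled across plates. At least
  two NTC endpoints are required for `SD` to exist.
- `3.89`: the one-tailed normal quantile for 99.999% confidence. It is
  stored as a literal constant rather than recomputed from a quantile
  function, so the threshold matches the published formula digit for
  digit.
- `C` (default 0.3, fluorescence units): a constant offset absorbing
  spectral bleed between dye layers.

Ties at the threshold are negative ("larger than" is strict). The
threshold is linear in its inputs, so scaling all fluorescence values
and `C` by a common factor preserves every call (tested as a property).

Plate QC requires ≥ 8 NTC wells, both positive controls per target
species above their dye's threshold, and no NTC above threshold.
QC failure is a report state, not an exception; samples on failed
plates are marked UNRESOLVED rather than silently dropped. NEGATIVE
means "neither cod nor haddock", not assay failure. No Ct/Cq
estimation, baseline subtraction or efficiency modelling is done — the
method uses endpoint ΔRn only.

The dye→species mapping (`COD` → *Gadus morhua*, `HAD` →
*Melanogrammus aeglefinus*) is configuration on `PlateData`, not
hard-coded, since published primer/probe tables are ambiguous about
which oligo carries which reporter.

## Barcode identity and assignment (`fishauth.barcode`)

**Identity.** Queries are fixed-region ~655 bp COI amplicons.
Equal-length sequences are compared position by position — the region
itself defines the homology, and coding COI essentially never gaps at
this scale. Unequal-length pairs are aligned semi-globally (free end
gaps; match +1, mismatch −1, gap −2) and identity is

```
matched columns / aligned columns, excluding terminal-gap columns
```

with internal gap columns counted as mismatches and `N` matching
nothing. If the optimal alignment leaves the sequences disjoint (no
overlap scores positively), identity is 0. Pairwise alignment is
delegated to Biopython's `PairwiseAligner`; co-optimal alignments are
resolved by its deterministic enumeration order. Under this scoring a
mismatch (−1) and a gap (−2) can never tie at equal score, so only
gap-placement ties remain; they cannot change the score and only in
contrived repeats the identity, which is why the simpler tie rule was
accepted.

**Assignment.** A query is scored against every reference in both
orientations (sequencing direction is not assumed) and the better
orientation used. The best hit's congener group is reported. Statuses:

- `UNAMBIGUOUS`: one group at the top, identity ≥ 0.995. The threshold
  is inclusive at exactly 0.995; observed failures in real data sit
  strictly below it, so inclusivity is unconstrained and the simpler
  convention is used.
- `AMBIGUOUS_GROUP`: two or more references from different groups tie
  *exactly* at the best identity (identities are ratios of integers, so
  exact ties are well-defined); the union of tied groups is reported.
- `BELOW_THRESHOLD`: best identity < 0.995.

The runner-up is the best hit outside the winning group(s).

**Mixed detection.** A BELOW_THRESHOLD assignment whose runner-up is
not the best hit's nearest relative (`sister_map`) is flagged as a
mixed-template signature. The sister map is explicit configuration —
by default derived from the panel as each species' nearest other-group
neighbour — rather than read off the NJ tree, so detection is
deterministic and testable in isolation. Degraded single-species
sequences fall below threshold occasionally, but their runner-up is
the sister, so they are not flagged (specificity is tested at zero
false alarms over 200 clean samples at error rate 0.003).

**Reconciliation.** Two independent extractions per sample: agreeing
groups with no mixed flag keep the group; disagreeing groups → MIXED
over both; any mixed flag → MIXED over best + runner-up groups; one
missing replicate stands alone (tagged); none → UNRESOLVED. An exact
cross-group tie propagates as AMBIGUOUS.

## Trees (`fishauth.tree`)

Distances: p-distance and Kimura 2-parameter,
`d = −½·ln((1−2P−Q)·√(1−2Q))` with `P`/`Q` the transition/transversion
fractions; sites with `N` or gaps are excluded pairwise; a non-positive
log argument raises a saturation error naming the pair. K2P is the
barcoding convention and the default; p-distance is selectable.
K2P ≥ p-distance always (tested).

Neighbour joining is the Saitou–Nei agglomeration on the Q-criterion.
Exact ties are broken by the lexicographic order of the clusters'
smallest leaf labels; taxa are canonically sorted on input, so the
result is independent of input order. Negative branch-length estimates
are clamped to zero. The Q-matrix tie scan uses the upper triangle
only, because floating-point evaluation of `−r_i − r_j` is not exactly
symmetric. For additive matrices the tree reproduces the input
distances exactly (tested on random trees up to 12 taxa, and
cross-checked against dendropy's NJ as an independent oracle).

Bootstrap: alignment columns are resampled with replacement, a tree is
rebuilt per replicate, and each internal bipartition of the full-data
tree receives the percentage of replicates containing it (supports
mapped onto the full-data tree, not a consensus tree). Replicates with
saturated distances are skipped and counted. Trees are emitted as
Newick with branch lengths and integer supports as internal node
labels. Default 1000 replicates.

Tree building assumes gap-free equal-length amplicons (a common-overlap
trim stands in for a multiple aligner, which coding COI does not need
at this scale).

## Concordance (`fishauth.concordance`)

The shipped rule table: generic "Cod" → {morhua, macrocephalus-group};
"Cod" + Atlantic → {morhua}; "Cod" + Pacific → {macrocephalus-group};
"Haddock" → {aeglefinus}; "Alaskan Pollack" → {chalcogramma-group};
"Hake (M. capensis)" → {capensis}; "Whiting" → {merlangus}. A rule
with an explicit catch area beats the wildcard rule for the same label.

The sequencing-based reconciled ID is authoritative for verdicts; the
qPCR call is corroborating evidence carried through the outputs. MIXED
reconciliations always count as mislabelled. UNRESOLVED samples (DNA
failed entirely) are excluded from rate denominators; the packaged
survey fixture accordingly uses the 371 DNA-analysable samples as its
denominator. Rates are kept as raw fractions; display percentages are
rounded half-up to two decimals (one decimal where the published table
prints one). Confidence intervals are exact binomial
(Clopper–Pearson, via scipy's beta quantiles).

Quota extrapolation: `excess = rate × reference_landings`, optionally
expressed as a percentage of a quota. The default reference volumes
(56 537 t haddock landings, 75 448 t Atlantic cod quota, 2011) are the
values implied by the published extrapolation; both are ordinary user
inputs.

The fixture itself (21 mislabelled products + stratum totals) is
checksum-verified at load. Its totals carry explicit discrepancy
flags where the published numbers are internally inconsistent: the
"97.4%" analysable fraction (371/386 = 96.1%), and the fish-finger and
pre-cooked-meal strata, whose printed rates (6.45% of 31; 5.47% of
128) imply 2 and 7 samples while the mislabelled table lists 1 and 8 —
the row-to-stratum assignment for one or two products cannot be
reconstructed, so those two strata are reported as computed from the
table (3.23%, 6.25%) and not asserted against print.

## Synthetic data (`fishauth.synthetic`)

**Reference panel.** Target pairwise p-distances are realised by
reconstructing a guide tree (via the package's own NJ) from the
group-level distance matrix and dropping mutations on its edges, each
edge owning a disjoint set of sites: realised distances then equal the
summed edge counts and hit targets to within rounding (±0.005 is
verified; triangle-inequality violations are reported with the
offending triple). Congeners are byte-identical; all cross-group
divergences in the default panel exceed 2% (identities < 0.98).
Mutations are uniform over sites and substitution types — no
transition bias; the generator targets p-distances, not a
substitution-model likelihood. The default guide geometry is chosen so
each species' nearest panel neighbour is its biological sister
(haddock ↔ whiting in particular), which makes the mixed-detection
rule well-posed.

**Queries.** Two replicates per sample with independent per-base
errors (default rate 0.002; uniform substitutions). Chimeric samples
(default fraction 5/371, matching the mixed-composition products in
the survey's mislabelled table) take one of two forms, both observed
in real data: *replicate disagreement* (each extraction amplifies a
different component) or a *mosaic* trace (the minority component's
alleles blended into the majority sequence at 45% of their differing
sites, yielding a sub-threshold identity in both replicates).

**Plates.** ΔRn follows a logistic curve `A/(1+exp(−(c−c50)/k))`
(defaults A = 3.0, c50 = 25, k = 1.5) on target wells, plus zero-mean
Gaussian cycle noise (sd 0.02) everywhere and a constant bleed offset
(0.05) on non-template signals. No raw fluorescence magnitudes are
published for the assay, so the scale is free; the defaults put
positive endpoints ~60 noise-sd above threshold, representing a
well-run assay. 96-well plates carry 8 NTCs, 2+2 positive controls
and up to 84 samples; larger studies split across plates.

**Metadata.** Labels, catch areas and processing levels follow the
survey's observed frequencies; substitution probabilities are the
survey's per-label substitution counts, conditioned on the sample not
being chimeric so the overall planted expectation stays at
21/371 = 5.66%. All randomness derives from one master seed through
spawned child streams; a fixed configuration is byte-identical across
runs (tested at file level).

**What passing tests do and do not show.** The generator produces
substitution-only errors on a small panel with well-separated species,
cleanly sigmoidal fluorescence, and complete metadata. It does not
emulate chromatogram quality, indels, primer-binding failure,
heteroplasmy, contamination gradients, or reference databases with
misidentified vouchers. Pipeline accuracy of ~100% on synthetic data
therefore validates the *logic* (thresholding, assignment, ambiguity,
reconciliation, stratified accounting), not field performance on
degraded traces or incomplete panels.

## Simulation sizes and numerical choices

- Parameter recovery: 100 surveys of n = 371 in the test suite (50 in
  the acceptance script); recovery is judged by exact binomial 95% CI
  coverage of the realised planted rate (≥ 93/100).
- Mixed detection: 200 chimeric + 200 clean samples. The ≥ 95%
  sensitivity property is assessed in replicate-disagreement mode
  (observed 100%). Mosaic-mode sensitivity is intrinsically lower
  (~75–85%): when the minority component *is* the majority's sister —
  or sits close to it — the runner-up heuristic cannot distinguish a
  mixture from ordinary divergence. This is a limitation of the
  detection rule itself, not of the implementation.
- NJ oracle: 200 random additive matrices, 4–12 taxa; recovery judged
  on bipartition sets and path-length reproduction (atol 1e−8).
- Bootstrap tests use 20–100 replicates to keep the suite fast; the
  pipeline default remains 1000.
- Exact float equality is used deliberately for identity ties (ratios
  with a common denominator) and for Q-criterion ties (crafted
  equal-distance matrices); everything else uses explicit tolerances.

## Known limitations

- Group-level reporting cannot separate congeners with identical
  barcodes (by construction); catches of the rarer congener are
  attributed to the group.
- The mixed-detection rule needs the panel's sister structure to be
  correct; a panel missing the true nearest relative degrades
  specificity.
- The semi-global aligner is quadratic; it is used for unequal-length
  pairs only, which suits amplicon data but not long references.
- Bootstrap supports are computed for moderate taxon counts (tens);
  the NJ implementation is O(n³) with dense matrices.
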