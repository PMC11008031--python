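# Methods

This note documents the models, decision rules, parameter defaults and known
limitations of `httscan`. It states nothing that the test suite and
`scripts/acceptance.py` do not themselves compute.

## Problem setting

A DNA transposon found in two species can have arrived there in two ways:
vertical descent from their common ancestor, or horizontal transfer (HTT)
after the species split. The two histories leave different signatures in
sequence divergence, taxonomic distribution, tree topology and insertion-site
orthology. `httscan` measures all four signatures and integrates them.

## Substitution model and divergence estimation

All divergence, simulation and tree distances use the Kimura 2-parameter
(K2P) model: independent sites, transition rate α (A↔G, C↔T), transversion
rate β per type. We parameterise the process by the total expected
substitutions per site *d* and the transition/transversion ratio
κ = α/(2β); κ = 0.5 is the unbiased Jukes–Cantor limit, and the default
κ = 2.0 is a typical vertebrate neutral value.

The estimator takes two aligned strings, excludes every column containing a
gap or N, counts the transition proportion P and transversion proportion Q,
and returns

    K = −½ · ln((1 − 2P − Q) · √(1 − 2Q))

When `1 − 2P − Q ≤ 0` or `1 − 2Q ≤ 0` (saturation) the result is flagged
undefined rather than silently dropped. The generative simulator
(`evolve_seq`) draws per-site outcomes from the exact K2P transition
probabilities, so the estimator and the simulator are model twins; the test
suite verifies that 200 replicates at 10 kb recover *d* ∈ {0.01, 0.05,
0.1, 0.2} within 3 standard errors, and that K2P and Jukes–Cantor estimates
agree at κ = 0.5.

**Alignment for divergence measurement.** The model has no indels, but a
score-optimal global alignment with permissive gap costs will pair identical
letters across true substitutions ("gap attraction"), deflating K — at a
true K = 0.30 the measured value dropped to ~0.21 with the search scoring.
Divergence-measurement alignments (copy-to-consensus, representative pairs,
TE distance matrices) therefore use stiff affine gaps (open −16, extend −4)
with the pipeline's +4/−5 match/mismatch scores, which removes the bias on
simulated truth. CpG-aware corrections are deliberately not applied; plain
K2P is the documented behaviour.

## Homology search

TE copies are found by seed-and-extend local alignment: exact 7-mer seeds on
both strands, an ungapped X-drop extension that must reach a trigger score
(default 64) to open a window, then full affine-gap Smith–Waterman over the
window (match +4, mismatch −5, a gap of length L costs 8 + 2L). Within a
window the best alignment is extracted and the remainder searched
recursively, so multiple copies per window are reported. On desk-scale
instances the top-hit score equals the exhaustive Smith–Waterman optimum
computed by an independent aligner; the suite asserts this on 20 seeded
instances.

Identity is matches over aligned columns excluding gap columns. E-values are
not computed: a raw minimum score (default 80) replaces database-size
statistics, which are meaningless at this scale. Candidate full-length
copies must reach 75% identity and 90% query coverage; hits under 100 bp
are removed before the presence/absence stage. Overlapping same-strand hits
(≥ 50% of the shorter) are merged to the best-scoring one.

## Structural hallmarks

* **TIR**: the longest arm length L in [10, 30] for which the 5′ L bases
  match the reverse complement of the 3′ L bases with at most ⌊0.2·L⌋
  mismatches (N counts as mismatch). With a mismatch tolerance the
  longest-L rule can report arms a few bases beyond a planted 15 bp repeat;
  detection is therefore asserted as "found, ≥ 15 bp".
* **TSD**: the longest k in [4, 12] with the left flank's k-suffix exactly
  equal to the right flank's k-prefix. Exact matching is the conservative
  reading of an ~8 bp duplication with no stated tolerance. A chance match
  of the adjacent host base extends a planted 8-mer to 9 in ~¼ of cases,
  so calibration checks use the modal length over several copies.
* **Full length** requires TIR found, TSD found, and ≥ 90% consensus
  coverage, where coverage counts consensus positions aligned to copy bases
  in a global alignment (match +4, mismatch −5, linear gap −6). Note that
  an exact TSD decays quickly with host divergence (each flank mutates
  independently), so old vertical copies legitimately classify as
  fragments — matching how real degraded copies present.
* **ORF screen**: longest open reading frame over 6 frames, counted in
  residues from the first ATG of a stop-free stretch to the codon before
  the stop (unterminated trailing stretches count); ≥ 600 aa flags a copy
  as coding-capable, the size range of intact hAT transposases.

Detected hit boundaries are refined to the full query extent before
structure classification, because local alignment trims mutated terminal
bases while both hallmarks live exactly at the termini.

## Trees and discordance

Representative copies (best-scoring full-length hit per species, falling
back to the best clean hit) are compared by K2P distance on global
alignments, and an unrooted tree is built by neighbor joining. NJ is fully
deterministic here: ties in the Q criterion are broken by the
lexicographically smallest label pair, negative branch lengths are clamped
to zero. Likelihood-based tree inference is deliberately not used — the
discordance argument needs topology only, and NJ on an additive matrix
provably recovers it (tested on 50 random 6–8 taxon additive matrices and
cross-checked against an independent NJ implementation).

Discordance is the Robinson–Foulds distance between the TE tree and the
species tree pruned to the TE-bearing taxa, normalised by the maximum
2(n−3); it requires ≥ 4 shared leaves. Nodes are not collapsed by support
before comparison.

## Orthologous presence/absence test

For every TE locus the flanking 1500 bp on each side is searched in the
target genome (flank hits must be ≥ 100 bp at ≥ 75% identity). The
best-scoring co-linear flank pair (same contig, same strand, correct order)
defines the inter-flank gap, and the call is:

* **shared** — gap within [0.5, 1.5] × TE length (the element sits between
  the flanks in the target too);
* **absent_empty_site** — gap ≤ 50 bp; a gap of −8 bp is the typical
  empty-site signature, because both flank queries carry one copy of the
  8 bp TSD that overlaps at the unoccupied target site;
* **unresolved** — flanks missing, too short (< 200 bp after contig-edge
  clipping), rearranged, or an ambiguous gap. Unresolved loci support
  neither hypothesis.

The original visual (dot-plot) judgment is replaced by this explicit rule
precisely so it can be tested: on a two-species scenario with 10 ancestral
and 10 post-split insertions per species and no fragmentation, the
classification is 100% correct in both directions.

## Evidence integration

For a species pair (a, b) with divergence time T (from the input tree, MY)
and a user-supplied neutral rate r (subs/site/MY — there is no default; the
choice is the user's), the expected neutral divergence is `2·r·T`. The
criteria are:

* **identity**: K2P between representatives ≤ 0.5 × expected;
* **patchy**: some surveyed species closer to a (or b) than the pair are to
  each other lacks the element (patristic distances when branch lengths
  exist, topological otherwise);
* **discordance**: RF > 0;
* **independence**: shared orthologous insertions ≤ 0.

The verdict is **HTT** when identity holds plus ≥ 1 corroborating
criterion; identity alone is never sufficient, mirroring the multi-evidence
argument of the field. Without a rate the identity test is skipped and HTT
requires all three remaining criteria, flagged as weaker evidence.
**vertical** requires the divergence ratio ≥ 0.5 *and* at least one shared
insertion. Everything else is **inconclusive**. Direction of transfer is
never inferred; calls are symmetric. The 0.5 ratio threshold is an
operationalisation of "anomalously similar" — no quantitative bar exists in
the literature — and the ratio is always reported so users can apply their
own.

## The synthetic-data generator

Host genomes (default 100 kb, GC 0.44) evolve along an ultrametric species
tree under K2P with no indels outside insertion events. The default element
is 3 kb with 15 bp TIRs, an 8 bp TSD on insertion, and a planted 620-codon
ORF. Events are *vertical* (insertion on an internal branch, inherited
orthologously by all descendants) or *horizontal* (arrival from an external
donor pool on a terminal branch at age t, so two recipients show cross
species TE divergence ≈ 2t regardless of host divergence; no simulated
species acts as donor, since no donor is identifiable in practice). A
fraction of copies (default 0.2) is truncated on one side (uniform retained
fraction in [0.3, 0.9]) with the TSD omitted, destroying the hallmarks as
real fragments do; the truncation decision is made once at insertion and
inherited, keeping orthologous coordinates indel-free.

Insertion anchors are drawn in ancestral (root) coordinates with a global
minimum spacing (default 3500 bp) across all events and lineages. This
guarantees clean, non-interleaved 1500 bp flanks for every locus — the
regime in which the presence/absence decision rule is exact — and avoids
nested insertions. Canonical scenarios use a four-species tree
((A:25,B:25):25,(C:25,D:25):25) in MY with rate 0.002 subs/site/MY: old
enough that flanks remain alignable (orthologous flanks differ by K ≈ 0.2
at the deepest split) while the vertical TE background (K ≈ 0.11 to the
consensus) is clearly separated from a 2 MY transfer (K ≈ 0.004).

**What the simulator does not emulate**: insertion-site preference,
nested/segmental duplication of copies, indel mutation, rearrangements,
assembly gaps and errors, polymorphic (unfixed) insertions, selection, and
within-family subfamily structure. Passing tests therefore demonstrate the
correctness of the algorithms under the stated model, not robustness to
every artefact of real assemblies; on real data the unresolved category and
the configurable thresholds absorb much of that slack.

## Problem sizes and determinism

Test and acceptance runs use desk-scale sizes chosen to keep the full suite
in minutes on one CPU: 60–250 kb genomes, 3 kb elements, 3–4 copies per
event, 20-scenario verdict batteries, 200-replicate estimator calibrations.
Every stochastic stage takes an explicit seed; identical (inputs, config,
seed) give byte-identical outputs, and run manifests record the config hash
and seed.

## Known limitations

* TSD/TIR detection is exact-match/threshold based; highly diverged copies
  lose their hallmarks and are classified as fragments rather than being
  rescued by probabilistic models.
* The landscape's top bin aggregates saturated (undefined-K) copies; peak
  *attribution* (e.g. deciding that an old peak belongs to unrelated
  degraded elements rather than the focal family) is left to the user.
* The presence/absence rule assumes a mostly co-linear target locus; true
  rearrangements land in `unresolved`.
* `blastn`-style E-value statistics, translated searches and protein
  structure prediction are out of scope.
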