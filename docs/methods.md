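# Methods

This note documents the models and procedures implemented in `gazelang`,
the assumptions behind them, the parameters that matter, and the design
choices made where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Scan-pattern encoding

Fixations arrive as (x, y, t_start, t_end) in pixels and milliseconds,
origin top-left, y increasing downward. A trial's image is tiled by an
`n_cols × n_rows` grid (default 6 × 4) of equal cells; labels are a row
letter (a.. top to bottom) followed by a column letter (a.. left to
right). Cells are half-open; the right/bottom image edge closes into the
final cell. Because the grid is defined over each trial's own image
extent, labels are comparable across recording setups with different
resolutions (1024×768 vs 1920×1080).

Time is partitioned into consecutive `bin_ms` bins (default 25 ms) from
scene onset. Decisions that the binning rule leaves open and how they are
resolved:

* **Bin membership** is by the bin's *start instant*: a bin belongs to the
  fixation whose `[t_start, t_end)` interval contains its start. This is
  simple, order-preserving, and assigns no fractional bins. Fixations that
  straddle utterance onset are split naturally at the bin level.
* **Saccade/blink gaps**: bins covered by no fixation are dropped, not
  forward-filled — only fixated time carries a location label.
* **Repeats**: consecutive identical tokens are retained, so dwell time
  weights the sequence.
* **Out-of-image fixations** (tracker overshoots) are clamped to the
  nearest edge cell; the pipeline logs how many were clamped.
* **Phases**: bins with start < utterance onset are BEFORE; onset ≤ start
  < offset are DURING; bins at or after the offset are discarded. The two
  phases partition the retained bins exhaustively and exclusively.

An alternative encoding maps fixations to labeled object rectangles
(regions of interest) instead of grid cells, with overlaps resolved by a
priority order and a `background` label elsewhere; it exists as a
robustness variant and exercises the same downstream machinery.

## 2. LCS similarity

Similarity between two token sequences is the length of their longest
common subsequence divided by the geometric mean of the lengths,
`LCS(x, y)/√(mn)`, which is 1 exactly when the sequences are identical and
0 when they share no token. Two implementations coexist deliberately:

* `lcs_length` / `lcs_witness`: the classic O(mn) dynamic program, with
  traceback for a witness subsequence;
* `lcs_length_packed`: a bit-parallel row update over per-symbol bit
  masks, used for the all-pairs sweep (a pair costs O(m) big-integer
  operations after masks are precomputed once per trial).

The two routes are cross-checked against each other and against an
exhaustive subsequence-enumeration oracle in the property tests. Pairs in
which either sequence is empty have undefined similarity and are excluded
upstream by the fixation-count filter.

## 3. Semantic similarity

Trials carry fixed-length sentence-embedding vectors (any constant
dimension; the generator uses d = 32). The default similarity is the raw
dot product; cosine similarity is available by configuration and is
identical when vectors are unit-normalized. Embeddings are used exactly
as provided — no re-normalization — so the dot product's scale is the
embedding's own. Descriptive binned summaries min-max rescale the
predictor to [0, 1] per study (recorded in the output metadata); the model
consumes the raw values.

## 4. Syntactic similarity

Dependency parses are read from CoNLL-U (multiword tokens and empty nodes
skipped; a `# trial_id = …` comment carries the trial identifier, with
`sent_id` as fallback). Labels are normalized in two steps: full-label
aliases first (`nsubj:pass → nsubjpass`), then truncation of
language-specific subtypes at ":", then base aliases (`obj → dobj`), so
both the older and the current label inventories map onto one scheme.

**Delexicalization.** Words and POS tags are removed; each node keeps only
its dependency relation (the root token becomes `ROOT`); children are
ordered by the dependent tokens' surface positions. Every node with
dependents additionally receives a reserved `HEAD` marker child at the
head token's own linear slot. The marker is what makes the representation
order-complete: a verb-medial transitive clause becomes
`(ROOT (nsubj) (HEAD) (dobj))` and its verb-final counterpart
`(ROOT (nsubj) (dobj) (HEAD))`, so constructions with identical relation
sets but different orders are distinct trees. The marker is inserted
uniformly (never only when "needed"), keeping the rule deterministic.

**Kernel.** The Subset Tree Kernel counts tree fragments shared by two
trees, where a fragment keeps either all of a node's children or none.
With Δ(n₁, n₂) = 0 when the productions (label + full ordered child-label
list) differ, Δ = λ for matching leaf productions, and
Δ = λ·Π(1 + Δ(c₁ᵢ, c₂ᵢ)) for matching internal productions,
K(t₁, t₂) = Σ Δ over all node pairs. Matching is all-or-none over the
ordered child list, which is what makes the similarity order-dependent.
The decay λ ∈ (0, 1] discounts large fragments; λ is not dictated by
anything in the data, so the package follows common tree-kernel practice
with **λ = 0.4** and exposes it in `KernelConfig` (the kernel is
monotonically nondecreasing in λ; a property test asserts this).
Similarity is reported normalized, K(t₁,t₂)/√(K(t₁,t₁)K(t₂,t₂)) ∈ [0, 1],
since self-kernels grow with tree size. The implementation is verified
against a brute-force fragment-enumeration oracle and for positive
semidefiniteness of Gram matrices.

**Core-dependency sequences.** Walking tokens in surface order and keeping
only the obligatory relations {nsubj, nsubjpass, dobj, iobj, csubj,
csubjpass, ccomp, xcomp} plus `ROOT` for the root token yields word-order
profiles such as `nsubj ROOT dobj` (verb-medial transitive) or
`nsubj dobj ROOT` (head-final). Per-language frequency tables of these
sequences summarize typological differences; in a strictly head-final
template every sequence ends in `ROOT`. A POS-sequence LCS
(`pos_lcs_similarity`) provides a coarser, order-sensitive syntactic
measure reusing the LCS core.

## 5. Pair assembly and exclusions

Trials whose descriptions have fewer than 4 or more than 77 words are
excluded (inclusive bounds; a percentile mode recomputes the band from the
study's own distribution at the 2nd/99th percentiles). Word counts use
whitespace tokens for space-delimited transcripts and the parse's token
count for scripts without spaces. Phase-sequences built from fewer than
two fixations are excluded per phase (a trial can lose BEFORE and keep
DURING). All exclusions are logged with reasons.

Every surviving trial is paired with every other, independently per phase;
cross-phase pairs are never formed. Each unordered pair appears once (no
mirrored rows). Labels: `same_scene` (reference: different/between),
`same_language` (reference: different). Grouping keys are unordered pairs
of participant ids, scene ids and cue words; self-pairs such as {p, p}
(two trials of one participant) are retained, so a k-participant study has
k(k+1)/2 distinct participant-pair levels. Semantic and syntactic
similarities are phase-independent, so the two phase records of a pair
share them; scan similarity differs.

**Shuffle control.** A uniform seeded permutation reassigns each trial's
linguistic bundle (transcript, embedding, dependency tree) to another
trial's scan data; participant, scene, language, cue and utterance timings
stay with the scan side, and pair assembly runs unchanged. With one trial
the permutation is the identity.

## 6. The association model

The response is scan similarity; fixed effects are Semantics, Syntax,
Language, Scene and Phase with *all* interactions up to the five-way term
(32 columns including the intercept), treatment-coded at the reference
levels different-language / different-scene / before-phase. Random
intercepts: participant pair, item pair, cue pair (crossed).

Estimation is maximum likelihood, not REML, so fixed-effect tests are
comparable across fits. For random intercepts the marginal covariance is
σ²(I + Σₖ γₖ ZₖZₖᵀ); the likelihood is profiled over β and σ², leaving an
optimization in the three log variance ratios log γₖ (L-BFGS-B, bounds
e⁻¹⁴…e⁸, start γ = 0.1). Each likelihood evaluation reduces, via the
Woodbury identity, to a Cholesky factorization of the q × q system
G⁻¹ + ZᵀZ (q = total number of random-effect levels, a few hundred here),
so a fit on the full ~80 000-row pair table takes seconds. The routine is
validated against statsmodels' `MixedLM` (ML, same variance-component
structure) on a smaller problem where the general-purpose optimizer
converges; coefficients, log-likelihood, variance components and standard
errors agree to at least three decimals.

Inference is by asymptotic Wald statistics conditional on the estimated
variance ratios — t = β/se and 95% CIs from σ̂²(XᵀV̂⁻¹X)⁻¹ — the convention
of standard mixed-model software. Variance components estimated at the
boundary (≈ 0) set a `boundary` flag; the intercept-only random structure
is kept rather than refit. Constant or collinear fixed-effect columns
(e.g. a single-language study) are dropped and reported in
`dropped_terms`; a constant response short-circuits to intercept = the
constant with zero slopes. Per-phase slopes of a continuous predictor are
linear combinations (BEFORE: the main effect; DURING: main effect + term ×
Phase), with CIs from the coefficient covariance.

**Standardized coefficients.** The recipe behind "standardized β" is not
uniquely determined by convention, so the package declares one: refit the
identical model with all continuous variables (response included)
z-scored and the three binary factors coded −0.5/+0.5.

**Binned summaries.** Mean scan similarity over predictor bins of width
0.1 (last bin closed), stratified by Scene × Language × Phase, with n and
standard error per bin; empty bins omitted. Dot products are min-max
rescaled to [0, 1] per study first, and the output records that this
happened.

## 7. The synthetic-study generator

The generator emulates a 3-language × 8-participant × 12-scene production
study (288 trials before exclusions) and is the package's test bed: every
format reader, the encoders, both similarity channels, the pair assembly
and the model see only its output.

* **Objects** come from a global pool (16) with a fixed anchor grid cell
  and a fixed unit semantic vector each; every scene samples 4 objects, so
  scenes overlap in content and semantic–gaze coupling is recoverable
  between scenes as well as within.
* **Message**: per trial, a relation type (transitive with probability
  0.5) and an agent (plus patient) with weights 0.65/0.35.
* **Durations**: planning phase ~N(3.0 s, 0.9 s) truncated at 1 s;
  utterance duration per language ~N(μ, 0.3 μ) truncated at 1.5 s with
  μ = 3.4 / 8.1 / 5.1 s for the SVO / verb-initial-mix / SOV languages —
  means chosen so sequence lengths (~120 BEFORE tokens) are realistic for
  production studies of this kind.
* **Gaze**: a fixation walk (Gamma-distributed durations, mean ≈ 330 ms,
  30 ms saccade gaps; positions jittered around cell centers). Each
  fixation targets, with probability `g_sem`, an object of the message
  (weighted); otherwise a uniformly random cell. During the planning phase
  a routine with probability `g_syn_before` instead follows the *planned
  utterance* token by token in surface order, dwelling at each token's
  governing constituent's referent region: subject subtree → agent's cell,
  object/passive-subject subtree → patient's cell, verbs and adverbs → the
  image-center "action region", obliques → a corner "setting region".
  Phrase elaboration and word order thereby shape planning gaze, which is
  precisely the structure whose recovery the acceptance suite tests.
* **Embedding**: a language-independent map — weighted sum of object
  vectors plus 0.4 × a relation vector — plus N(0, noise_sd/√d) noise per
  component (noise_sd = 0.2), so the same message in different languages
  yields nearby vectors.
* **Trees**: instantiated from per-language templates. The SVO language is
  rigidly verb-medial; the verb-initial mix produces predicative
  (root-first) clauses half the time; the SOV language is strictly
  head-final (the root token is last in every tree — an invariant the
  tests assert). Within-language word-order alternations (short passives
  in the space-delimited languages, object scrambling in the head-final
  one; rate 0.25) give the syntax channel variance that is independent of
  the message. Complexity varies per trial: determiners (p = 0.85),
  adjectives (Poisson 0.5), adverbs (p = 0.4), oblique adjuncts (p = 0.6),
  embedded complement clauses (p = 0.15). Transcripts are pseudo-word
  strings; one language is written without spaces to exercise the
  parse-based word count.
* **Cues**: 8 cue words shared round-robin across the 12 scenes, so cue
  pairs and item pairs are distinct grouping factors.
* **Determinism**: a single `numpy` generator seeded from the config;
  identical configs produce byte-identical written bundles.

What the generator does *not* emulate: center-of-screen onset bias,
saccade dynamics and measurement noise of real trackers, natural-language
lexical statistics, embedding anisotropy, and speech-rate variability
within a trial. Short descriptions are somewhat more frequent than in
adult production data (the length filter removes ~5–12% of trials rather
than ~2%). Passing recovery tests therefore show that the pipeline
measures what it claims under the generator's assumptions — not that
real data satisfy those assumptions.

## 8. Problem sizes and numerical choices

Tests and the acceptance script use the default study size (288 trials,
~65–75 k pair records after exclusions), 20 shuffle repetitions, a
coupling ladder g ∈ {0, 0.3, 0.6, 0.9}, exhaustive LCS-oracle sweeps to
length 4 plus 2 000 random pairs to length 8, and 200 random tree pairs
for the kernel oracle — sizes at which every check runs in minutes on one
CPU while leaving the planted effects far from the decision boundaries.
Tolerances: kernel/oracle agreement to 1e-9 relative; fitter/statsmodels
agreement to 1e-4 absolute on coefficients; Gram-matrix eigenvalues
≥ −1e-9; CI checks are exact interval containment. Ties in the region
encoding resolve by explicit priority; degenerate inputs (empty
sequences, zero vectors, single-node trees with zero self-kernel) raise
typed `SimilarityUndefined` errors and are excluded by the filters rather
than silently scored.

## 9. Known limitations

* The Wald CIs condition on the estimated variance ratios and ignore
  their sampling variability, as in standard mixed-model practice;
  coverage under permutation is approximately nominal here (the
  acceptance script measures it) but is not guaranteed for other designs.
* The pairwise design induces dyadic dependence that three crossed
  random intercepts absorb only partly; this mirrors the modeling choice
  the pipeline implements rather than a claim of full efficiency.
* The delexicalized HEAD-marker representation makes the kernel strictly
  order-sensitive; languages with genuinely free word order will score
  low syntactic similarity even for equivalent constructions.
* `filter_sentences` in percentile mode uses linear-interpolated
  percentiles; with small studies the band can sit between attested
  lengths.
* The CoNLL-U reader covers the subset needed here (HEAD/DEPREL/UPOS,
  comments, MWT/empty-node skipping); enhanced dependencies and
  morphological features are ignored.
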