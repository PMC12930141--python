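# gazelang

Cross-modal coordination between eye movements and speech in multilingual
scene description.

When speakers describe a visual scene, where they look and what they say
are tightly coupled. This package quantifies that coupling at the level of
*pairs of trials*: if two speakers (possibly of different languages)
produce semantically or syntactically similar descriptions, are their scan
patterns over the scene also similar — and does the relationship differ
between the planning phase (before speech onset) and the articulation
phase (during speech)? The package is aimed at researchers in
psycholinguistics and visual cognition who have per-trial fixation
records, transcripts with dependency parses (CoNLL-U), and sentence
embeddings, and want a tested, reproducible pipeline from raw tables to a
fitted association model.

## The three similarity measures

**Scan patterns.** The image is tiled by a 6×4 grid of equal cells; time is
cut into consecutive 25 ms bins from scene onset, and each bin whose start
falls inside a fixation receives that fixation's cell label ("aa", "bc",
…). Bins are split at utterance onset/offset into BEFORE and DURING
sequences. Two sequences *x* (length *m*) and *y* (length *n*) are
compared by their longest common subsequence:

    sim(x, y) = LCS(x, y) / sqrt(m · n)  ∈ [0, 1]

computed by the standard dynamic program (`C[i][j] = C[i−1][j−1]+1` on a
match, else `max(C[i−1][j], C[i][j−1])`); an equivalent bit-parallel
routine handles the all-pairs sweep. An object-region (ROI) encoding is
available as a robustness variant.

**Semantics.** The dot product ⟨u, v⟩ between the trials' sentence-embedding
vectors (cosine similarity selectable; identical on unit-norm vectors).

**Syntax.** An order-dependent Subset Tree Kernel (SST) over delexicalized
dependency trees: words and POS tags are stripped, nodes keep only their
relation label, children are ordered by surface position, and a reserved
HEAD marker records the head's own slot, so SVO and SOV clauses with
identical relations delexicalize to different ordered trees. The kernel
counts shared tree fragments (each node keeps all of its children or
none), with decay λ (default 0.4), normalized to [0, 1] by
K(t₁,t₂)/√(K(t₁,t₁)K(t₂,t₂)). Core-dependency sequences
("nsubj ROOT dobj") summarize word-order profiles per language, and a
POS-sequence LCS offers a coarser syntactic measure.

## The association model

All C(k, 2) unordered trial pairs are assembled per phase (after excluding
descriptions of < 4 or > 77 words and phase-sequences built from fewer
than two fixations). Each pair record carries scan/semantic/syntactic
similarity, Scene (same vs different; reference different), Language (same
vs different; reference different) and Phase (during vs before; reference
before). Scan similarity is modeled by a linear mixed model with the full
factorial fixed-effect structure — Semantics × Syntax × Language × Scene ×
Phase, all interactions up to the five-way term — and random intercepts
for participant pair, item pair and cue-word pair. The model is fitted by
profiled maximum likelihood over the three variance ratios (Woodbury
identity on the random-effect cross-product system), which handles the
~450 crossed levels of an 80 000-row pair table in seconds; Wald t
statistics and 95% CIs are reported, plus standardized coefficients from a
refit on z-scored variables with ±0.5-coded factors. A shuffle control
re-pairs sentences with scan patterns at random to verify that the
association is carried by the true gaze–speech correspondence.

Because no public dataset ships with the package, a first-class synthetic
generator produces complete studies (fixations, transcripts, CoNLL-U
parses, embeddings, region maps) in which a latent per-trial *message*
jointly drives gaze, embedding and utterance structure, with controllable
semantic coupling `g_sem` and planning-phase syntactic coupling
`g_syn_before`. Recovery of these planted couplings is what the test
suite and acceptance script verify.

## Worked example

```python
from gazelang import (
    SynthConfig, StudyConfig, generate_study, run_all,
    lcs_length, lcs_similarity, lcs_witness,
)

a, b = "ABCBDAB", "BDCABC"
print(f"LCS({a}, {b}) = {''.join(lcs_witness(a, b))}"
      f" (length {lcs_length(a, b)}, similarity {lcs_similarity(a, b):.4f})")

bundle = generate_study(SynthConfig(seed=1, g_sem=0.8))
result = run_all(StudyConfig(seed=1), bundle=bundle)
print(result.fit.summary().head(6).round(4).to_string(index=False))
```

prints

```
LCS(ABCBDAB, BDCABC) = BCAB (length 4, similarity 0.6172)

       term    beta  std_beta  ci_low  ci_high  t_value
(Intercept)  0.0811    0.1436  0.0681   0.0940  12.2919
  Semantics  0.3449    0.6839  0.3116   0.3783  20.2608
     Syntax -0.0380   -0.0256 -0.0585  -0.0174  -3.6212
   Language -0.0057    0.0500 -0.0221   0.0108  -0.6761
      Scene  0.0609    0.3620  0.0205   0.1014   2.9517
      Phase  0.0007    0.0116 -0.0114   0.0127   0.1060
```

The Semantics row is the planted effect recovered: with coupling
`g_sem = 0.8` the fitted slope of scan similarity on semantic similarity
is 0.345 with a CI far from zero (it is ≈ 0 when the study is generated
with `g_sem = 0`, and it vanishes under the shuffle control). Scene and
Language rows quantify how much more similar scan patterns are within the
same scene and language group.

The same pipeline runs from the shell:

```bash
gazelang simulate --out study/ --seed 1
gazelang run-all --config study/study.yaml --out-dir results/
# or stage by stage:
gazelang pairs --config study/study.yaml --out pairs.tsv
gazelang fit --pairs pairs.tsv --out coefficients.tsv
gazelang report --pairs pairs.tsv --out-dir report/
```

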