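# Methods

## The model

`gazealign` casts gaze–speech fusion as unsupervised bitext word
alignment.  For one image, each observer contributes a pair of parallel
"sentences": the sequence of fixated region labels (visual units) and the
sequence of filtered content words with onsets (linguistic units).  Two
directional translation models are estimated per image:

- **IBM Model 1** — alignment-independent lexical translation table
  t(target | source), fit by EM from a uniform initialisation.  Every
  source sentence implicitly contains a NULL token, so target tokens with
  no grounded counterpart need not be forced onto a region.
- **HMM aligner** — hidden states are the source positions (plus one NULL
  state per position that remembers the last lexical position); the
  transition law depends only on the signed jump width between successive
  source positions, bucketed at ±`max_jump` (default 5).  Emissions are
  initialised from the Model 1 table and refined by Baum–Welch.

Training is staged — `m1_iters` then `hmm_iters` (defaults 2 + 2) — and
*joint*: at every E-step the two directional link posteriors are
multiplied elementwise (the transposed reverse matrix against the forward
one) and renormalised per row before expected counts are collected in
both models.  The NULL column keeps the forward direction's mass, since
it has no reverse counterpart.  This agreement heuristic suppresses links
only one direction believes in; the exact joint-likelihood variant is out
of scope.

Decoding is posterior thresholding: every (word, region) cell of the
combined posterior matrix at or above δ (default 0.1) becomes a link, so
one-to-many and many-to-one mappings are allowed.  Image-level output
pools the per-observer links as a set, keeping each pair's maximum
posterior.

### Numerical and structural choices

- **Deficient transition parameterisation.**  Transition rows of the
  per-pair lattice are *not* renormalised over the positions that exist in
  the sentence; jumps that would leave the sentence simply keep their
  probability mass (as in the IBM fertility models).  With this choice the
  normalised-count update is the exact M-step for the tied jump buckets,
  so the Baum–Welch corpus log-likelihood is non-decreasing by
  construction — with per-row renormalisation the count update is only
  approximate and measurable likelihood drops occur on small corpora.
  Posteriors are unaffected because forward–backward conditions on the
  observed pair.
- **Decode-time transition smoothing** (`jump_smooth`, default 0.5).  The
  jump law is learned mostly from short windowed pairs whose sides have
  equal length, so its mass concentrates near +1; decoded full sequences
  have roughly twice as many visual as linguistic tokens, so their true
  jumps are larger.  Left unsmoothed, the spiky transition prior can
  overrule a several-fold lexical preference and chain misalignments.  At
  read-out (only), the jump law is interpolated with a uniform law over
  reachable positions.  Order correspondence between gaze and speech is
  far weaker than between two languages — regions are revisited and often
  left unnamed — so weighting lexical evidence over positional evidence at
  decode time is the scientifically conservative choice.  Training
  lattices are untouched, keeping EM exact.
- **NULL rate** `p_null` is fixed at 0.2 rather than re-estimated, keeping
  the jump M-step exact and the model identifiable on small corpora.
- Expected counts receive add-ε smoothing (ε = 1e-12) to avoid zero rows
  for rare tokens.
- Model 1 E-step posteriors, and HMM posteriors via scaled
  forward–backward, are tested against brute-force enumeration of all
  alignment functions / state paths (≤ 1e-10 and ≤ 1e-8 respectively).

## Corpus construction

Windows `[w, w + T)` advance by `stride` (default 0.5 s) while `w` is
below the latest unit end time; a unit belongs to a window iff its onset
lies in the half-open interval, and windows with an empty side are
dropped.  Within each window, contiguous identical visual units merge
(first onset, summed duration) and the longest-duration units are kept
until |visual| = max(1, round(β·|linguistic|)), rounding half away from
zero; ties prefer the earlier onset and original order is preserved.
Alternative selection rules (`earliest`, seeded `random`) implement the
selection-method axis.  The stride default is chosen so that ~22 s trials
from 30 observers yield on the order of 1000 pairs per image.

The full-sequence pair is merged but **not** β-balanced (configurable via
`full_pair_balance`).  Two reasons: the full pair is the decoding input,
and truncating it removes alignment candidates — a word whose region token
was dropped gets forced onto a neighbouring region with high confidence;
and including the untruncated pair during training exposes the HMM to the
jump geometry it will face at decode time.  Windowed pairs are balanced
exactly as described above.

## Region models

- **Mean-shift fixation clustering** (flat kernel, via scikit-learn) on
  fixation coordinates pooled over observers; the cluster count is
  data-driven.  The bandwidth is not dictated by the underlying method;
  the default is 2° of visual angle at 44 px/°, i.e. 88 px, from the
  1680×1050 @ 38°×22° display geometry — a foveal-scale grouping radius.
  Clusters whose centroid falls outside the image (blinks, track losses)
  are discarded together with their fixations.
- **k-means segmentation** on (R, G, B, w·x, w·y) per-pixel features, each
  channel standardised before the spatial weight (default 1) is applied;
  Lloyd iterations capped at 300, tol 1e-4, seeded k-means++.  `k` is
  typically taken from the mean-shift cluster count of the same image.
  Degenerate inputs (fewer distinct feature vectors than k) reduce k with
  a warning.
- **External label maps** are accepted as integer matrices.

Fixation-log parsing collapses consecutive fixation samples within 1 px
into one fixation whose duration is the spanned time; a single-sample
fixation gets one sample period (4 ms at 250 Hz).  When both eyes report a
fixation their positions are averaged, otherwise the valid eye is used.
Observer quality control keeps observers whose mean calibration error is
within k·SD (default 2, sample SD) of the group mean in both axes; with
zero spread everyone passes.

## Linguistic filtering

POS whitelist: JJ/JJR/JJS, NN/NNS, NNP/NNPS, VBG, FW (Penn tags; any
tagger may produce them — tagging itself is an input contract).  Stopword
removal uses an editable list shipped with the package plus task words
(default {"next"}).  Singleton removal counts surface forms per image
*after* the other filters.  Unit timestamps anchor at token onset,
matching fixation onsets.

## Evaluation

P\* = S ∪ P is enforced internally (sure links always count as possible),
otherwise the printed precision formula would penalise correct sure
links.  Baselines are scored exactly like the framework: a pooled set of
(word, region) pairs per image.  In fixation gaps a word links to the
most recent preceding fixation (config `gap_rule="strict"` disables
this); words before the first fixation stay unaligned.  Reference regions
project onto model labels by strict majority: an MSFC cluster maps to the
region containing > 50% of its fixations; a segment maps to the region
with maximal pixel overlap if that overlap exceeds half the segment.
Exact 50/50 ties map to nothing and the region is reported uncovered.

Annotation ranks each region's linked words by utterance frequency
(descending by default, with an ascending switch since display
conventions differ), ties by maximum posterior then lexicographically.

## The simulator

`simulate_trial` emulates the regularities of free image description:
lognormal fixation durations with mean 250 ms; region visits sampled from
a salience-weighted chain without immediate self-transitions (revisits
allowed), about four fixations per visit; ~22 s trials; speech at 2.5
words/s beginning after a 0.58 s silent preview; an eye–voice lag drawn
per naming from N(0.9 s, 0.3 s), truncated at zero, from the visit onset
to the word onset.  A region is named on its first visit and with
probability 0.25 on revisits — speakers fixate an object about when they
first mention it rather than re-naming it on every glance — which yields
roughly 11 content words per narrative, matching the token statistics of
real description corpora.  Region salience is heavy-tailed (lognormal,
σ = 0.9): a few primary objects draw most visits while background regions
are inspected and named rarely; each observer additionally perturbs the
salience by a lognormal factor (σ = 0.6) to model idiosyncratic
attention.  Filler words come from the stopword vocabulary so the
linguistic filter is exercised; names are tagged NN, fillers UH/DT, and a
final task word "next" closes each narrative.

Scenes are abstract: regions are Gaussian fixation sources (σ = 40 px) on
a jittered grid over a 1680×1050 canvas with dominant names drawn from a
noun bank and optional synonyms (used with probability 0.2).  Ground
truth references put each region's dominant name in S and its synonyms in
P, as pixel discs of radius 3σ; `simulate_dataset` clusters the pooled
simulated fixations and projects these references so that simulated
ground truth and pipeline output share one label space.  Default scenes
have 10 regions, consistent with the ~11 fixation clusters per image that
mean-shift clustering finds on real scenes.

**What the simulator does not capture:** real images with shared visual
features across objects (so k-means/segment label collisions do not
arise), ASR transcription errors, multi-word referring expressions,
abstract or relational language,
and lags correlated with word frequency or scene complexity.  Passing the
simulated checks therefore demonstrates the machinery is correct and the
method's advantage over temporal baselines under controlled lag
variability — not that real-data accuracy will match the simulated
numbers.

One consequence is worth stating plainly: with ten observers pooled into
a single link set, the 1-second-delay baseline catches most sure pairs at
least once (each dominant name is uttered several times per image and
each utterance matches temporally with probability ≈ 0.4), so pooled
baseline *recall* saturates near 1.0 and the framework's recall advantage
appears on only part of the images, even though its AER and precision
advantages are large and systematic.  On real data, where reference
vocabularies are broad and lags far more variable, baselines miss much
more.

## Problem sizes

The bundled study runs 20 simulated images × 10 observers (~450 training
pairs per image) for the framework-vs-baseline comparison and lexicon
recovery; the zero-noise control uses 4 images × 10 observers; oracle
checks enumerate pairs up to 5×5 tokens; EM monotonicity is checked on
100 random toy corpora.  These sizes make the whole suite reproducible on
a single CPU in a few minutes while keeping per-image corpus statistics
(pair counts, unit densities) close to the real-study regime.
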