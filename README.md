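# gazealign

Annotate image regions with words by fusing two streams people produce
naturally when they inspect a picture: where they look (eye-movement
fixations) and what they say (a spoken description).  Because speakers do
not name an object at the instant they fixate it — the eye–voice lag is
positive, variable, and typically sub-second — purely temporal matching is
unreliable.  `gazealign` instead treats the two streams as a *bitext*:
the fixation sequence, encoded as region labels, is one "language" and the
content words of the narrative are the other, and an unsupervised word
aligner discovers which words translate which regions.

The package is aimed at researchers in visual cognition, psycholinguistics
and multimodal HCI who have co-captured gaze and speech (or want to
prototype against the bundled simulator) and want per-region word labels
plus a quantitative evaluation against human reference alignments.

## Method

1. **Visual units.** Fixations pooled over observers are grouped into
   regions by mean-shift clustering of their (x, y) coordinates (no preset
   cluster count), by k-means segmentation of the raster on RGB + spatial
   features, or by an external label map.  Each observer's fixation
   sequence becomes an ordered sequence of region labels.
2. **Linguistic units.** From the word-level, time-stamped, POS-tagged
   transcript, adjectives, nouns, proper nouns, gerunds and foreign words
   are kept; stopwords, task words, and word forms uttered only once for
   an image are removed.  Order and onsets are preserved.
3. **Parallel corpus.** A sliding window of `T` seconds (default 5 s,
   stride 0.5 s) over each trial yields bitext "sentence" pairs; within
   each window contiguous identical region labels are merged and the
   longest-duration units are kept so that |visual| ≈ β·|linguistic|
   (defaults β = 1, α = longest).  The full-sequence pair is included too.
4. **Alignment.** Two iterations of IBM Model 1 EM followed by two of an
   HMM aligner (Baum–Welch), trained in both directions with agreement
   (directional posteriors multiplied and renormalised at every E-step).
   Posterior decoding keeps every link with combined posterior ≥ δ = 0.1,
   so one word may label several regions and vice versa.
5. **Evaluation.** Against references with *sure* (S) and *possible* (P)
   links, with P\* = S ∪ P:

   precision = |A∩P\*|/|A|,  recall = |A∩S|/|S|,
   AER = 1 − (|A∩S| + |A∩P\*|)/(|A| + |S|)

   and two temporal baselines: *simultaneous* (word ↔ region fixated at
   the word's onset) and a fixed *1-second delay*.

A simulator (`gazealign.simulate`) generates co-registered scanpaths and
narratives with known word–region ground truth (250 ms mean fixations,
~22 s narratives at 2.5 words/s, lag ~ N(0.9 s, 0.3 s)), emitting the same
file formats the production readers consume.

## Worked example

```python
from gazealign.pipeline import run_experiment

exp = run_experiment(n_images=2, n_observers=8, seed=7)
print(exp.summary.round(2).to_string())
hit, total = exp.lexicon_recovery()
print(f"lexicon recovery: {hit}/{total}")
```

prints

```
              n_images  precision  recall   aer  n_fw_better_precision  n_fw_better_recall  n_fw_better_aer
method
delayed              2       0.22     1.0  0.64                    2.0                 0.0              2.0
framework            2       0.90     1.0  0.06                    NaN                 NaN              NaN
simultaneous         2       0.28     1.0  0.58                    2.0                 0.0              2.0
```

The framework's alignment error rate (0.06) is far below both temporal
baselines (0.58–0.64) on both simulated images, and the learned
translation table names all 20 regions correctly (`lexicon recovery:
20/20`).  Per-region annotations are available on each image result, e.g.
`exp.results[0].annotations["cluster1"].top() == ['cake']`.

The same pipeline runs from the shell with checkpointed stages:

```bash
gazealign run-all --run out/demo --images 2 --observers 8 --seed 7
# or stage by stage: simulate, cluster, extract, corpus, align, evaluate, annotate
cat out/demo/summary.tsv
```

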