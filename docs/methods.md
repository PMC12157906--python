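# Methods

This note records the modeling assumptions, numerical conventions and
deliberate design decisions behind the package, in enough detail to
re-derive or challenge any number the code produces.

## 1. Signal model and preprocessing

An **instance** is a trace of 180 consecutive accelerometer-magnitude
samples at 256 Hz (≈ 0.7 s). Tri-axial input is reduced to magnitude
`sqrt(ax² + ay² + az²)` at load time.

Preprocessing per instance:

1. Split into 3 contiguous segments of 60 samples. Segmentation happens
   **before** filtering by default (each segment is filtered
   independently); `filter_full_trace=True` filters first and segments
   after, for sensitivity analysis.
2. Order-4 Butterworth low-pass at 30 Hz, applied zero-phase
   (forward–backward, `scipy.signal.filtfilt`) with odd-reflection
   padding, `padlen = 3·(2·order + 1) = 27`. Segments must therefore be
   longer than 27 samples; shorter input is a hard error naming the
   minimum.
3. Per-segment min–max normalization to [0, 1]. A constant segment maps
   to all zeros (documented convention, not an error).
4. Ten features per segment, in fixed order: mean, std, min, max,
   peak-to-peak, RMS, skewness, kurtosis, dominant frequency, low-band
   energy ratio. Defaults use population moments (`ddof=0`, biased
   g1/Fisher g2); an `unbiased` switch is provided. Dominant frequency
   is the frequency of the largest non-DC rFFT bin; low-band energy is
   the fraction of non-DC spectral energy at or below 10 Hz. A
   zero/constant segment yields 0 for both spectral features.

The result is a 30-dimensional feature vector (3 × 10, segment-major).

### Numerical caveat: filtfilt edge transients

Pad-based zero-phase filtering is exactly zero-phase only in the limit;
with 60-sample segments the odd-padding scheme leaves ~1e-4 relative
transients within ~27 samples of each segment edge (the interior is
symmetric to ~1e-7). `method="gust"` would be exact but the padding
scheme is part of the pipeline definition, so tests assert the
zero-phase property on segment interiors only.

## 2. Candidate selection and relevance scoring

For a query, the labeled pool (same user, query excluded) is reduced to
the `distance_k` nearest candidates by plain Euclidean distance on the
30-dim vectors. Ties break deterministically by (distance, user_id,
instance_id).

Each surviving candidate is scored in [0, 1] for contextual relevance.
Two interchangeable scorer backends:

* **API backend** — an OpenAI-compatible chat endpoint (default model
  `gpt-4o-mini`, temperature 0.3) called with a structured prompt that
  embeds both feature summaries and the domain-knowledge rules, and must
  answer `SCORE:` / `REASON:` lines. Implemented with the standard
  library (`urllib`) only; the key comes exclusively from an environment
  variable.
* **Heuristic backend** — a deterministic offline emulation:
  `score = w1·exp(−distance/τ) + w2·synergy`, with τ the median
  candidate distance of the current batch (fallback 1.0), weights
  0.5/0.5 normalized, and synergy 1 / 0 / 0.5 when the candidate's label
  matches / contradicts / is indeterminate against the rule-implied
  label of the query.

Score replies are parsed totally: a regex extracts the number, values
outside [0, 1] are clamped (status `clamped`), unparsable replies fall
back to 0.5 (status `fallback`). One retry per candidate, then a
backend error; every exchange can be logged to a JSONL transcript.

### Domain-knowledge rules

Two explicit threshold rules over normalized segment features:

* RMS > 0.5 in **both** segments 2 and 3 ⇒ fatigue;
* mean < 0.31 in **any** segment ⇒ fatigue.

When multiple rules fire, the majority of fired implications decides
the implied label; no rule firing means "indeterminate". Rules can be
disabled wholesale for ablations (`--dk off`), which makes the
heuristic scorer a pure distance kernel.

## 3. Shot selection, prompting, prediction

Scored candidates are re-ranked by (score ↓, distance ↑, identifiers)
and the `top_k` kept. From those, the 2-shot pair is the best-scored
example of each class when both classes are present, otherwise the two
best overall; the higher-scored shot renders first. Presets:
`paramA = (distance_k 5, top_k 3)`, `paramB = (10, 5)`.

The classification prompt shows each shot's per-segment numbers (4
decimals), its relevance score and reason, and an explicit label
conclusion, then the query's numbers and a single-word answer
instruction. Reply parsing is total: exact tokens map directly;
otherwise non-overlapping "non-fatigue" mentions are counted and
consumed before counting "fatigue" (avoiding substring double-counts);
ties — including empty replies — resolve to the higher-scored shot's
label. Every prediction records which fallback path produced it.

For offline end-to-end experiments the classification backend is a
**nearest-shot mock**: it answers with the label of whichever shot is
closer to the query in feature space. This makes prediction quality a
direct function of shot quality, which is exactly the property the
selection pipeline is supposed to improve, giving a closed loop that
needs no network access.

## 4. Evaluation protocol

Strictly per-user. For each user: a seeded shuffle picks the first
fatigue and first non-fatigue instance as the ML baseline's training
pair; all remaining instances are the shared test set. For every test
instance the prompt methods may select shots from all of the user's
other instances — never the test instance itself, which is asserted on
every prediction. Methods: `ml` (Random Forest, 100 trees,
`random_state=42`, trained on the 2-example pair), `random` (2 uniform
shots without replacement), `distance` (2 nearest shots), and
`hedlm_paramA` / `hedlm_paramB`. Metric: macro F1 over the two classes
(`zero_division=0`), reported as percentages.

## 5. Comparison statistics

All hand-implemented with scipy used as a cross-check oracle in tests:

* **Friedman** chi-square with the tie-correction term; **Iman–
  Davenport** F transform alongside. The headline "54.55" statistic on
  the bundled benchmark is the chi-square form (n=19, k=5).
* **Nemenyi post hoc**: `p = Q.sf(|ΔR̄| / sqrt(k(k+1)/(12n)), k, ∞)`
  with Q the studentized range. Note this is **without** the extra √2
  of some textbook presentations; this convention (the one used by
  common post-hoc libraries) is the one that reproduces the reference
  values bundled with the package to all printed digits.
* **Cliff's delta** via vectorized pair counting (brute-force
  double-loop equivalence is part of the acceptance suite).
* **Paired t** (two-sided) and **Wilcoxon signed-rank** — exact
  distribution for n ≤ 25 with zero-difference pairs dropped
  (`wilcox` rule), normal approximation with continuity correction
  above. All-zero differences return p = 1 with a warning.
* Summaries report sample SD (n−1) as primary and population SD
  alongside, since the convention behind the reference table's "± SD"
  is not stated.

A 19-user × 5-method benchmark table of per-user macro-F1 percentages
ships at `hedlm/data/benchmark_macro_f1.csv`; the acceptance suite
recomputes every summary statistic from it at printed precision.

## 6. Synthetic data generator

A seeded gait-proxy generator emulates the data shape (180 samples,
256 Hz, per-user instances, binary labels) with class structure aligned
to the domain-knowledge rules: after per-segment [0,1] normalization,
`rms² = mean² + var`, so "lower mean **and** higher RMS" forces the
fatigue class to be strongly bimodal. Concretely:

* **non-fatigue**: mid-level plateau with narrow two-sided excursions
  (sharp up-spikes and unloading dips) — mid mean, moderate RMS;
* **fatigue**: saturated, flat-topped impact pulses at the step
  frequency (2 × stride frequency, default stride 2.5 Hz) over a low
  baseline, with a linear late-trace drift — low mean, high late RMS.

An `overlap ∈ [0, 1]` dial linearly interpolates both classes' parameter
sets toward their midpoint: at 0 a nearest-centroid classifier on the
30-dim features exceeds 0.9 macro F1 (200 instances), at 1 it falls
below 0.7. Per-user RNG streams come from `SeedSequence(seed,
spawn_key=(user_index,))`, so user k's data is bit-identical regardless
of `n_users`; per-user scale and amplitude jitters are lognormal. Any
user drawn single-class by the Bernoulli labeling has one instance
flipped so the protocol is always runnable.

**Limitations**: this is a statistical proxy, not a biomechanical
simulation. It targets only the feature-level structure the selection
pipeline is sensitive to; it does not reproduce stride-segmentation
statistics, inter-axis structure, or any real dataset's absolute F1
levels.

## 7. Reproducibility

Everything offline is deterministic given explicit seeds: generator
(`SeedSequence` spawns), user splits, random baseline, Random Forest
(`random_state=42`). `run_pipeline` writes a manifest with the full
config, a config hash and library versions; transcripts capture every
prompt/reply. `scripts/acceptance.py --seed N --out report.json`
recomputes all headline quantities in one shot.
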