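# Methods

## Problem and model

`pathmeta` performs pathway-centric meta-analysis of heterogeneous untargeted
LC-MS metabolomics studies. Individual studies arrive as tsv/csv peak lists —
one row per metabolic feature with m/z, an optional retention time and
intensity, and a p-value from that study's own pairwise comparison. Feature
identities are unknown (putative annotation by mass only), so the unit of
inference is the metabolic pathway, not the metabolite: a pathway whose
compounds are hit by significantly dysregulated features far beyond chance is
predicted active, and evidence is combined across studies at the compound
level before the pathway test.

The pipeline, per study and then merged:

1. **Partition.** Features passing the study's intensity floor form the
   *reference* list; the subset with `p < p_cutoff` (strict) is *significant*.
   Features with no intensity value pass only when the floor is 0; features
   with no p-value are never significant. Each study carries its own
   `p_cutoff`, ppm tolerance and intensity floor, because archived studies
   differ in platform and power.
2. **Putative annotation.** For every feature and every mode-appropriate
   adduct rule, the candidate neutral mass is `M = (mz·|z| − Δ) / n` (shift Δ,
   charge z, molecular multiplicity n). A model compound with monoisotopic
   mass `M_c` matches when `|M − M_c| / M_c × 10⁶ ≤ ppm tolerance`; the ppm
   error is computed against the compound mass (the standard convention).
   A compound hit by several features or adducts is one compound in the
   compound sets, keeping the smallest feature p-value; all contributing
   (feature, adduct, source file) triples are retained for filtering and
   tracing.
3. **Merge.** Across studies, the universe is the union of per-study matched
   reference compounds. A compound significant in several studies is merged
   into one record with the best (smallest) per-study p-value. Enrichment
   runs on the union of per-study significant compounds by default
   (`merge_mode="union"`); `"shared"` mode restricts it to compounds
   significant in ≥ `min_studies` studies. The shared-compound count is
   reported for every pathway in both modes, since the reporting rule
   (below) is phrased in terms of shared metabolites.
4. **Pathway score.** With universe size `N`, significant compound count
   `n_sig`, pathway compounds in the universe `m` and significant pathway
   compounds `k`, the score is the EASE variant of the one-sided Fisher's
   exact test: the right hypergeometric tail at `max(k−1, 1)`,
   `p = P(X ≥ k−1)`, `X ~ Hypergeom(N, m, n_sig)`, with `p = 1` whenever
   `k ≤ 1`. The one-hit decrement is deliberately conservative for pathways
   supported by a single putative annotation. The tail is an exact integer
   sum (`math.comb`), so it is correct to the last floating-point digit.
5. **Permutation validation.** Mass-based annotation is many-to-many: the
   same ion can annotate several compounds (a glucose [M+H]⁺ is also a
   lactate [2M+H]⁺), and abundant compounds attract many features. Raw
   hypergeometric p-values are therefore biased in structure-dependent ways.
   The null redraws, per study, a pseudo-significant feature list of the
   observed size uniformly without replacement from that study's reference
   features, re-derives compound sets through the stored annotation, merges
   across studies exactly as the observed statistic was merged, and scores
   every pathway; the scores are pooled over permutations and pathways.
6. **Adjustment.** The default empirical adjustment is the add-one tail
   frequency with mid-rank tie handling:
   `p_adj = (1 + #{v < p} + #{v = p}/2) / (1 + n_null)`.
   The pathway score is discrete, so the observed score frequently equals
   null scores exactly; counting ties with weight ½ centers the adjusted
   p-value and keeps it calibrated (approximately uniform under the null),
   where counting ties fully (`#{v ≤ p}`) would be systematically
   conservative and leave a large atom at 1. For a tie-free null the two
   rules coincide. A gamma alternative fits a gamma distribution to the
   −log10 null scores and reports its upper tail; it is useful when
   permutations are few, and falls back to the empirical rule (with a
   warning) on degenerate nulls.
7. **Reporting.** The pathway table is sorted by merged raw p-value; the
   standing reporting filter keeps pathways with at least `min_shared = 10`
   shared dysregulated metabolites. Post-hoc adduct/study filters prune
   compound provenance and recompute displayed counts but never recompute
   p-values. Confirmed metabolites (already identified by name in archived
   studies) bypass mass matching, join the reference set always and the
   significant set when their p-value beats the cutoff or is absent
   (configurable via `confirmed_as`).
8. **Omics overlay.** Pre-thresholded dysregulated gene lists (symbols,
   upper-cased) and protein lists (UniProt accessions, isoform suffixes
   stripped; gene symbols accepted as fallback) are intersected with each
   pathway's annotations. The overlay is annotation-only: no joint
   metabolite-omics statistic is computed, because the two evidence types
   are not exchangeable and a principled combined test would require
   per-identifier statistics that the uploaded lists no longer carry.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `p_cutoff` | 0.05 | per-study feature significance threshold (strict `<`) |
| `mz_tolerance_ppm` | 10 | relative mass window for compound matching |
| `intensity_cutoff` | 0 | reference-list intensity floor (0 keeps intensity-less features) |
| `permutations` | 100 | resampling depth of the null |
| `seed` | 42 | permutation/generator seed (always explicit in configs) |
| `merge_mode` | union | merged significant set used for enrichment |
| `min_shared` | 10 | shared-metabolite reporting threshold |

The default adduct table covers the common electrospray species
(positive: M+H, M+Na, M+K, M+NH4, M+H−H2O, 2M+H; negative: M−H, M+Cl,
M−H−H2O, 2M−H) and is user-replaceable via a tsv file, since instrument
setups differ in which adducts dominate.

## Built-in model

`builtin_toy_model()` holds 78 real human metabolites across 13 overlapping
pathways (glycolysis, TCA, amino-acid, polyamine/urea, purine/pyrimidine,
bile-acid, taurine, carnitine, neurotransmitter and glycerophospholipid
chemistry). Masses are computed from elemental monoisotopic masses, so e.g.
glucose is 180.063388 Da. Near-isobaric pairs indistinguishable by mass
(leucine/isoleucine, citrate/isocitrate) are represented once. Pathway sizes
span 4–12 compounds on purpose: the null pathway score is discrete, and
heterogeneous sizes give the pooled null a rich support, which the
calibration experiment (below) relies on. The model is deliberately small
and pluggable — users substitute a full organism model (e.g. an export of a
genome-scale metabolic network) through the JSON or TSV-pair format; nothing
in the statistics assumes the built-in model.

## Synthetic-study generator

`generate_study` emulates a processed peak list: one feature per compound of
each designated enriched pathway (random mode-appropriate adduct, Gaussian
m/z jitter of 2 ppm SD against the default 10 ppm tolerance, p ~ Beta(a, 1)
with a = 0.05 so ~86% of enriched features pass p < 0.05), 100 background
features on random non-enriched compounds with uniform p-values, and 20%
decoy features with m/z uniform over the model's mass range. Decoys are
uniform rather than mass-shifted from real compounds so that the false-match
rate is purely tolerance-driven. `generate_meta_set` derives per-study seeds
(`base_seed + i`) under a shared truth, emulating independent studies of the
same biology.

What the generator does **not** emulate: retention-time structure, isotope
envelopes, in-source fragments, correlated noise between studies,
batch/platform effects, and missing-value patterns. Passing the synthetic
benchmarks therefore demonstrates the correctness and calibration of the
statistical machinery, not robustness to real-data artifacts — on archived
data the annotation ambiguity is harsher and the permutation null is doing
correspondingly more work.

## Validation experiments

Two standing experiments live in `pathmeta.validation` and are exercised by
the test suite and `scripts/acceptance.py`:

* **Null calibration** — 200 replicates of a two-study null-mode
  meta-analysis (no spiked pathways), 100 permutations each, pooling all
  adjusted pathway p-values. The fraction below 0.05 must sit within
  binomial noise of 0.05, and the pooled values must be consistent with
  uniformity (Kolmogorov–Smirnov, α = 0.01). Null-mode studies use 500
  background features (~6.5 features per model compound) so the significant
  compound set is a sizeable fraction of the universe; in sparser regimes
  the pathway statistic collapses onto a handful of values (mostly exactly
  1) and a uniformity test is uninformative by construction. Residual
  discreteness still leaves a small systematic KS distance (~0.03 at n =
  2600), so the test sits above but not far above the α = 0.01 boundary;
  this is a property of any discrete test statistic, not an implementation
  artifact.
* **Spike-in recovery** — 50 replicates of a two-study meta-set with one
  enriched pathway (effect a = 0.05, 2 ppm jitter, 10 ppm tolerance); the
  enriched pathway must rank first by merged raw p-value in ≥ 90% of
  replicates. Under the defaults it wins essentially always.

Problem sizes (feature counts in the hundreds, 78-compound model, 100
permutations, 50–200 replicates) were chosen so the full suite runs in well
under a minute while keeping every count in the regime where the binomial /
KS tolerances above are meaningful.

## Numerical and design notes

* The EASE tail uses exact integer arithmetic; `scipy.stats.hypergeom` is
  used only as an independent oracle in tests.
* Pathway ranking ties (equal raw p) break by descending hit count, then
  pathway id, making output order total and deterministic.
* Matching uses a sorted mass array with bisection; the window
  `[M/(1+t), M/(1−t)]` is exact for the relative-error criterion, and a
  brute-force (feature × rule × compound) scan is kept as a test oracle.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; CLI outputs are byte-identical across reruns of the same
  config + seed.
* Degenerate inputs fail loudly with typed exceptions: empty models, empty
  universes ("no compounds matched"), significant lists larger than the
  reference, shared-mode merges with no shared compounds.
* The union/shared ambiguity in how studies should be combined is resolved
  by implementing both, defaulting to union for the enrichment statistic
  while always reporting the shared count that drives the `min_shared`
  reporting rule.

## Known limitations

* Mass-only annotation cannot separate isobars or in-source fragments;
  confidence lives at the pathway level only.
* Confirmed metabolites without statistics default to "significant", which
  overweights studies that report identifications without p-values; set
  `confirmed_as="ref"` to keep them as background only.
* Locus-style gene identifiers are matched as opaque upper-cased strings;
  no locus→symbol mapping is attempted.
* The permutation null conditions on the observed significant-list size; it
  does not model uncertainty in the significance threshold itself.
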