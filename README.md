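# pathmeta

Pathway-centric meta-analysis of heterogeneous untargeted metabolomics
studies, with superimposition of transcriptomic and proteomic hit lists.

Archived untargeted LC-MS studies are abundant (XCMS Online, Metabolomics
Workbench, MetaboLights, GNPS, ...) but hard to compare directly: each study
was processed with its own platform, thresholds and annotation pipeline, and
the physical samples are usually gone, so feature identities cannot be
confirmed by fragmentation. `pathmeta` is for researchers who want to ask a
*pathway-level* question across several such studies anyway: it takes each
study's peak list (m/z, retention time, p-value, intensity, fold change),
putatively annotates features by adduct-aware neutral-mass matching against a
metabolic model, merges compound hits across studies keeping the best
p-value, scores pathways with a permutation-validated enrichment test, and
overlays user-supplied dysregulated gene/protein lists for a systems-level
reading.

## The statistic

For a pathway with `m` compounds inside the matched universe of `N`
compounds, of which `k` are significant among `n_sig` significant compounds
overall, the pathway score is the EASE-adjusted one-sided Fisher's exact
test — the right hypergeometric tail with the hit count decremented by one:

```
p = P(X ≥ max(k−1, 1)),   X ~ Hypergeom(N, m, n_sig),   p = 1 if k ≤ 1
```

computed as an exact integer tail sum. Because mass-only annotation is
many-to-many, raw scores are validated by permutation: pseudo-significant
feature lists of the observed size are redrawn from each study's reference
features, pushed through the same annotation and merging, and the pooled
null scores calibrate the observed ones
(`p_adj = (1 + #{v < p} + #{v = p}/2) / (1 + n_null)`, or an optional gamma
fit to the −log10 null). Compounds seen in several studies are merged with
best-p selection, and pathways are reported with their count of *shared*
dysregulated metabolites (significant in ≥ k studies), with a default
reporting filter of ≥ 10. See `docs/methods.md` for the full model,
defaults and limitations.

## Worked example

Two synthetic studies sharing dysregulation of the polyamine/urea and
bile-acid pathways (`examples/03_meta_analysis.py`; all examples run
offline against the built-in 78-compound model):

```python
import pathmeta as pm

model = pm.builtin_toy_model()
truth = pm.SyntheticTruth(enriched_pathway_ids={"P5", "P8"}, effect=0.02)
studies = pm.generate_meta_set(model, truth, n_studies=2, base_seed=5)
analysis = pm.meta_analyze(studies, model, config=pm.MetaConfig(permutations=100, seed=5))
```

prints

```
pathway                                 k1  k2 shared merged     p_raw     p_adj
Urea cycle and polyamine metabolism      9  11      9     11   0.00013  0.000769
Bile acid biosynthesis                   7   8      7      8   0.00348  0.000769
Aspartate and asparagine metabolism      7   7      6      8    0.0551  0.000769
Taurine and hypotaurine metabolism       3   2      2      3      0.48     0.113
...
top pathway: Urea cycle and polyamine metabolism
  spermine               seen in 2 studies, best p = 6.02e-62, adducts: M+H, M+K
  urea                   seen in 2 studies, best p = 2.36e-57, adducts: M+H-H2O, M+Na
```

`k1`/`k2` are each study's significant pathway compounds; `shared` counts
compounds significant in *both* studies (the reporting criterion); `merged`
counts compounds significant in at least one (the enrichment input); `p_raw`
is the EASE tail on the merged sets and `p_adj` its empirical tail
probability in the permutation null. The two spiked pathways lead the
ranking, and the aspartate/asparagine pathway follows because it shares
polyamine compounds with the spiked urea-cycle pathway — overlap is a
feature of real pathway databases, not an artifact.

The same pipeline runs from the shell (`examples/05_cli_pipeline.sh`):

```
pathmeta synth --out work --seed 31 --enrich P3
pathmeta run --config work/run.yaml --out work/out
```

writing `pathway_results.tsv`, `metabolite_results.tsv` and a
`run_manifest.json`; reruns with the same config and seed are
byte-identical. `pathmeta validate-model` checks a user-supplied model file
(JSON or a compounds.tsv/pathways.tsv pair) before use.

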