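# pdxmeta

Metabolic-fidelity analysis of patient tumours and patient-derived
xenografts (PDXs): a tested, reusable pipeline covering

- **preprocessing** — detection filtering, median-of-ratios total-signal
  normalization, log10 transform, minimum-based imputation;
- **differential analysis** — per-metabolite moderated linear models
  (empirical-Bayes variance shrinkage, Benjamini–Hochberg adjustment),
  multivariate models, REML variance partitioning, and mixed-effects
  selection of species-agnostic metabolites (host fixed effect, random
  intercept per origin);
- **fingerprint matching** — z-transform, pairwise Euclidean distances
  between PDX and patient samples, minimal-distance origin assignment, and
  per-metabolite squared-distance decomposition (Δd_k);
- **fidelity/stability** — origin-explained variance, per-line passage
  slopes, P0–P6 Pearson correlation, characteristic-metabolite
  classification;
- **isotope tracing** — natural-abundance correction of mass isotopomer
  distributions (convolution matrix + nonnegative least squares), total
  labelling, glucose M+6 enrichment normalization, citrate M+2 / pyruvate
  M+3 ratio;
- **set enrichment** — hypergeometric over-representation against GMT
  metabolite-set collections with the detected metabolome as background;
- **synthetic cohorts** — a generator planting origin fingerprints, host
  shifts, passage drift, per-sample scale factors and threshold-censored
  missingness, returning the ground truth for recovery tests.

## Command-line usage

All stages are exposed under one entry point; tables are TSV/CSV text.

```sh
pdxmeta simulate   --seed 1 --out-dir sim/
pdxmeta preprocess --intensity sim/intensity.tsv --out-dir prep/
pdxmeta diff       --normalized prep/normalized.tsv --annotation sim/annotation.tsv \
                   --factor host --out host_diff.tsv
pdxmeta diff       --normalized prep/normalized.tsv --annotation sim/annotation.tsv \
                   --mixed-origin --out agnostic.tsv
pdxmeta match      --normalized prep/normalized.tsv --annotation sim/annotation.tsv \
                   --out-dir match/
pdxmeta fidelity   --normalized prep/normalized.tsv --annotation sim/annotation.tsv \
                   --out fidelity.tsv
pdxmeta isotope    --mids mids.tsv --compositions comps.tsv --out corrected.tsv
pdxmeta enrich     --query hits.txt --sets sets.gmt --background detected.txt \
                   --out enrichment.tsv
```

`pdxmeta <subcommand> --help` documents every option (thresholds, reference
windows, z-score conventions, tracer purity, …).

## Data formats

- **Intensity tables**: delimited text, metabolites as rows, one header row,
  one identifier column; empty cells / `NA` / `NaN` are missing.
- **Sample annotation**: one row per sample with `origin`, `host`
  (`human`/`mouse`), `passage` (0 for patient tumours), plus optional
  `pigmentation`, `braf`, `sex`, `site_class`, `batch`.
- **Metabolite sets**: GMT (TAB-separated name, description, members).
- **MID tables**: fragment id then `M+0 … M+n` columns; compositions as
  fragment id, elemental formula (e.g. `C9H20NO3Si2`), tracer-carbon count.

## Notes and assumptions

- The detection filter defaults to "exclude metabolites missing in >90% of
  samples"; the stricter reading ("detected in <90%") is available via
  `--max-missing 0.1`.
- Missingness in the synthetic generator is left-censoring at a detection
  threshold, consistent with minimum-based imputation; real data may differ.
- The z-transform uses the sample SD over patients and PDXs pooled;
  conventions are configurable.
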