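# poised-omics

Integrated proteome–transcriptome analysis of mouse B-cell maturation.

During peripheral maturation, transitional (T1, T2) and mature (marginal
zone, follicular) B cells acquire the ability to exit quiescence within
hours of antigen encounter. Part of that readiness is post-transcriptional:
some abundant, full-length protein-coding mRNAs are carried *without any
detectable protein* — a "poised" state that could enable rapid translation
on activation. Telling a genuinely poised mRNA from a transcript whose
protein mass spectrometry simply missed requires quantitative care, and
that care is what this package implements:

1. **Copy numbers per cell** from label-free MS intensities via the histone
   proteomic ruler: `copies = (I / ΣI_histones) · m_DNA · N_A / MW`, using
   the summed histone signal as an internal standard for cellular DNA mass
   (≈ 5.58 pg for a diploid mouse cell).
2. **Differential proteome** across the four subsets: sum-normalization,
   per-protein one-way ANOVA with Benjamini–Hochberg control (FDR < 0.05),
   six-cluster partitioning of log2 deviation profiles, subset-presence
   Venn counts, Welch two-group comparisons, and complex stoichiometry
   ratios (e.g. eIF4A1:PDCD4).
3. **Gene-level integration** of mean copies and mean TPM (first-accession
   mapping), with Pearson/Spearman correlations on log10 scales, dynamic
   ranges, and a density-contour trend line per subset.
4. **Detection calibration**: the probability of detecting a protein as a
   function of binned mRNA abundance — 10 TPM gives ≈ 50% detection — which
   sets the abundance threshold for poised candidates.
5. **Poised classification** with an expression-matched resampling null:
   each gene-set member is matched to its 100 nearest-expression
   protein-coding genes; 100 random control sets give a 5th–95th percentile
   envelope of expected protein detections against which the observed count
   is judged (depleted / within-envelope / enriched).

A first-class synthetic-data generator (`poised_omics.synthetic_data`)
produces the full input bundle — MaxQuant-style protein groups, TPM table,
design, gene sets, id mapping — with planted ground truth, so every stage is
testable end to end without downloads.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic bundle (8000 genes, seed 1) and write their tables under
`results/`:

```bash
python analysis/01_simulate.py
python analysis/02_copy_numbers.py
python analysis/03_differential_proteome.py
python analysis/04_integrate_transcriptome.py
python analysis/05_poised_signature.py
```

Selected output (verbatim):

```
m_DNA per cell: 5.584 pg (mouse diploid genome)
protein groups: 5647 raw -> 5557 after artifact filter -> 4714 after presence filter
confidence classes: {'medium': 3486, 'high': 711, 'low': 517}

tested 3519 proteins; 1070 differential at FDR < 0.05 (30%), 2449 unchanged (70%)
cluster sizes (1..6, ordered by peak subset): {1.0: 59, 2.0: 122, 3.0: 43, 4.0: 123, 5.0: 56, 6.0: 65}

joined 4562 genes (96.8% of detected proteins, 57.0% of transcribed genes)
  T1: Pearson r = 0.46, Spearman rho = 0.44 (n = 2981); mRNA spans 4.1 orders, protein 8.3; trend line R^2 = 0.951

  T1: bin containing 10 TPM -> 48.0% detected; 50% crossing at ~12.1 TPM

  early_activation  T1   observed  85 vs [114, 124, 131] -> depleted (-31%)
  pb_related        T1   observed 125 vs [117, 124, 131] -> within-envelope (+1%)
```

Reading this: the ruler recovers per-cell copy numbers (~170–190 pg total
protein per cell); 30% of the tested proteome is differential across
maturation; protein and mRNA correlate moderately (r ≈ 0.46) while protein
abundance spans ~4 more orders of magnitude; detection probability crosses
50% near 10 TPM; and the gene set carrying planted poised mRNAs shows ~30%
fewer detected proteins than its expression-matched controls (depleted),
while the control set without planted effect stays inside the null envelope.

The same stages are scriptable through the CLI:

```bash
poised-omics simulate --outdir bundle --seed 1
poised-omics run-all --config cfg.yaml         # or: ruler, de, integrate, calibrate, poised
```

## Layout

```
src/poised_omics/     library: io_tables, synthetic_data, ruler,
                      differential, integration, poised, pipeline, cli
analysis/             numbered drivers reproducing the study on synthetic data
scripts/acceptance.py headline-quantity reproduction
tests/                pytest suite (unit, property and acceptance tests)
docs/methods.md       models, parameters, conventions, limitations
```
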