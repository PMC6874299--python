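# duplinoise

Quantitative analytics for a pair of duplicated stress-response
transcription factors (Msn2/Msn4 in budding yeast): how two promoters split
the trade-off between expression noise and environmental responsiveness.
The package implements the measurement pipelines such a study needs —
single-cell mRNA count statistics, nuclear-translocation trace scoring,
UMI-based stress-response quantification, flow-cytometry noise estimation,
binding-signal k-mer preference, and growth/competition fitness — together
with seeded synthetic-data generators that carry analytic ground truth, so
every stage can be validated end to end.

It is intended for computational biologists who want tested, reusable
implementations of these procedures, or a harness for benchmarking their
own variants against known generative parameters.

## The statistics at the core

* **Count noise.** For per-cell mRNA counts \(x_i\): Fano factor
  \(F = \sigma^2/\mu\) and Poisson-normalized skewness
  \(\tilde\gamma = \gamma\,\sqrt{\mu}\) (a Poisson law has skewness
  \(\mu^{-1/2}\)), with a \(\chi^2\) goodness-of-fit test against the
  Poisson MLE \(\hat\lambda = \bar x\). Bursty (telegraph-limit)
  transcription follows the negative-binomial stationary law with
  \(F = 1 + b\) for burst size \(b\).
* **Nuclear localization.** Each cell's masked frame is filtered with a
  disk of radius 3 px; the maximal response defines a hypothetical nucleus,
  and the trace is mean(nucleus)/mean(cytoplasm), min-normalized per cell
  and z-scored for cross-channel correlation.
* **RNA-seq response.** Reads collapse to molecules by (position, UMI);
  molecules are counted in each gene's 3′ window (−400/+200 bp around the
  3′ end) with multimappers split by the unique-molecule ratio; the
  response is the integrated log2 change \( \mathrm{AUC} = \int \log_2
  \frac{x(t)+p}{x(0)+p}\,dt \), and the dependency score is the mean
  WT/double-deletion AUC ratio.
* **Cytometry noise.** G1 gating at the FSC-W density valley, reciprocal
  scatter-regression outlier removal, background regression on
  (FSC-W, SSC-W, density), then \(\mathrm{CV}^2 = \sigma^2/\mu^2\).
* **Fitness.** Time to growth = time of maximal OD slope (the logistic
  inflection \(t^* = \mathrm{lag} + \ln(K/x_0 - 1)/r\)); competition
  fitness = \(100\,(1 + \text{slope of } \log_2 \text{mutant/WT odds vs
  generations})\), with generations \(g = \log_2(\text{dilution factor})\).
* **Binding preference.** Read 5′ ends form a signal track normalized to
  \(10^7\); each 7-mer is scored by its mean ±10 bp windowed signal across
  promoter occurrences (promoter = ≤700 bp upstream of the TSS, truncated
  at the upstream transcript), z-scored across 7-mers; TATA boxes match
  `TATA[AT]A[AT]`.

## Worked example

Simulate a bursty gene and measure its noise:

```python
from duplinoise import synthetic, smfish

cv, truth = synthetic.simulate_mrna_counts(
    10_000, "bursty", seed=1, burst_rate=1.0, burst_size=5.0)
stats = smfish.count_stats(cv)
print(f"mean={stats.mean:.2f} fano={stats.fano:.2f} "
      f"skew_norm={stats.skew_norm:.2f} gof_p={stats.gof_p:.3g}")
```

prints

```
mean=4.99 fano=5.91 skew_norm=4.37 gof_p=0
```

The mean matches the generative burst_rate × burst_size = 5; the Fano
factor sits at the analytic 1 + burst_size = 6 rather than the Poisson 1;
the normalized skewness ≫ 1 and the vanishing goodness-of-fit p-value both
reject the Poisson null — the signature of bursty transcription that
distinguishes a noisy, flexible promoter from a stable one.

The same round-trip works from the shell:

```bash
duplinoise simulate chec --seed 7 --out sim/
duplinoise chec kmers --genome sim/genome.fa --annotation sim/annotation.tsv \
    --alignments sim/alignments.tsv --out kmers.csv
# -> top kmer: GATCGAT   (the planted binding motif, or its reverse complement)
```

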