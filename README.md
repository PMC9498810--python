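# polwave

Quantitative analysis of RNA polymerase II (RNAPII) transcription dynamics
from DRB/4sU nascent-RNA time courses, with companion tools for
spike-in-normalized RNAPII occupancy, pausing indices, and m6A quantification
on chromatin-associated RNA.

## Who this is for

Labs measuring transcription elongation with DRB-release TT-seq designs
(reversible inhibition of the initiation-to-elongation transition, 4sU pulse
labeling of nascent RNA, sequencing at time points after washout), and anyone
comparing RNAPII behaviour between conditions where global occupancy shifts
(e.g. linker-histone-depleted cells), which requires exogenous spike-in
normalization.

## The model

After DRB washout, polymerases released from promoter-proximal positions move
synchronously into gene bodies, so the nascent-RNA coverage of a gene at time
*t* forms a wave whose front sits at distance *v·t* from the TSS, where *v* is
the elongation rate (kb/min). Per gene:

1. coverage is binned from the TSS in transcription direction and
   depth-normalized (`bin_coverage`);
2. the 0-min control is subtracted, exonic bins (contaminated by mature mRNA)
   are imputed from neighbors, and the signal is smoothed (`wave_signal`);
3. the wave front is the two-segment least-squares changepoint *c\**
   minimizing Σ<sub>i&lt;c</sub>(s<sub>i</sub>−μ<sub>L</sub>)² +
   Σ<sub>i≥c</sub>(s<sub>i</sub>−μ<sub>R</sub>)² subject to
   μ<sub>L</sub> &gt; μ<sub>R</sub>, gated on a 2× contrast
   (`detect_boundary`);
4. the rate is the through-origin least-squares slope of boundary vs. time,
   *v* = Σt<sub>i</sub>b<sub>i</sub> / Σt<sub>i</sub>² (`estimate_rate`);
5. QC removes genes shorter than 20 kb, with &lt; 0.7 reads per million over
   the first 20 kb, with rates ≤ 0.5 kb/min, or absent from the companion
   condition (`apply_rate_filters`), and survivors are split into
   slow/medium/fast classes at the 1/3 and 2/3 quantiles
   (`assign_speed_groups`).

Companion quantifications:

* **Spike-in correction** (`chip`): with human chromatin added to mouse
  samples before IP, the corrected signal for the knockout condition is the
  reads-normalized RPKM multiplied by
  *factor* = (mouse<sub>WT</sub>/human<sub>WT</sub>) /
  (mouse<sub>TKO</sub>/human<sub>TKO</sub>).
  The **pausing index** is promoter (TSS±500 bp) over gene-body
  (TSS+500..TTS) occupancy.
* **m6A level** (`m6a`): depth-normalized MeRIP IP / chromatin-RNA input read
  ratio over [TSS−2 kb, TTS+2 kb), replicate-mean after dropping genes
  missing in either replicate; cross-condition log2 ratios, H1-occupancy
  quartile analysis (one-sample Wilcoxon vs. 0), and TSS/TTS ±2 kb peak
  window classification.
* **Group statistics** (`stats`): two-sided Mann-Whitney / Wilcoxon
  signed-rank tests, Spearman/Pearson correlations, per-class summaries.

A bundled generator (`simulate`) produces annotations, wave fragment tables,
bedGraphs, count tables, and spike-in ledgers with known ground truth, so the
entire chain is testable without any sequencing download.

## Worked example

Simulate a 30-gene cohort transcribed at a constant 3 kb/min and re-estimate
the rates from the fragment tables:

```bash
polwave simulate --outdir demo --seed 4 --n-genes 30 --preset constant --rate 3.0
polwave rates --annotation demo/genes.bed \
    --fragments 0=demo/fragments_t0.tsv --fragments 5=demo/fragments_t5.tsv \
    --out demo/rates.tsv
```

prints

```
wrote synthetic cohort of 30 genes to demo
30/30 genes retained; median rate 3.00 kb/min
```

and `demo/rates.tsv` starts

```
gene_id  boundary_bp  rate_kb_min  coverage_20kb  qc_flags  speed_class
g0000    15000.0      3.0          33384.97       ...
```

Each gene's wave front after 5 minutes sits near 15 000 bp from the TSS
(boundaries are quantized to the 200-bp bin), giving 15 000 bp / 5 min =
3.0 kb/min; `coverage_20kb` is the reads-per-million coverage entering the
low-coverage filter, and `speed_class` stays `unassigned` here because a
constant-rate cohort has degenerate speed quantiles. The same library calls
are available in Python (`polwave.estimate_rates_pipeline`,
`polwave.pausing_table`, `polwave.m6a_table`, ...).

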