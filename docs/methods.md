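# Methods

## Elongation-rate estimation

**Model.** DRB reversibly blocks the transition from initiation to
elongation; on washout, polymerases leave promoter-proximal positions
together, so nascent-RNA coverage forms a wave advancing at the gene's
elongation rate *v*. A 4sU pulse of length *w* minutes before harvest labels
only RNA polymerized during that window, so the labeled coverage at time *t*
occupies the trailing wave segment [max(0, v·(t−w)), v·t] kb from the TSS.
With the default 0/5-minute design and a 10-minute pulse the whole wave is
labeled, and the front position alone carries the rate.

**Coverage and signal.** Fragments are binned by their 5′-most position in
transcription direction (bin 0 at the TSS, default bin size 200 bp — the
20-bp bin used for metagene profiles is too fine for per-gene changepoints at
realistic depth; both are configurable). Bin values are raw counts divided by
the sample's total aligned reads. The wave signal is
max(0, release-time − 0-min control) per bin. Subtraction removes shared
structure, but because the 0-min library contains only mature-mRNA background
its depth normalization differs, so exonic residue can survive; exonic bins
are therefore imputed from the mean of non-exonic neighbors within 5 bins
(0 if none), preventing mature-RNA spikes from faking a distal front. A
centered running mean over 5 bins (edges use the available bins) suppresses
Poisson noise without moving a step edge by more than ~2 bins.

**Boundary.** The front is the changepoint c\* minimizing the two-segment
squared error with the constraint mean_left > mean_right, ties broken toward
the larger c. A detection is accepted only if mean_left > 2 × mean_right at
c\*; otherwise the gene has no boundary (flat or empty signal). The 2×
contrast gate and the least-squares criterion were chosen to make the
detector fully specifiable and checkable against an exhaustive-search oracle
(the tests compare the vectorized cumulative-sum implementation with an
independent naive implementation on 1000 random signals); the original
Matlab boundary-calling protocol is not published in algorithmic detail, so
per-gene equality with it is not claimed — only the observable (wave-front
position) is shared.

**Rate.** Through-origin least squares of boundary versus time,
v = Σtᵢbᵢ/Σtᵢ², in kb/min. The origin anchor is physical: DRB synchronizes
polymerases at the TSS at t = 0. An intercept fit is available but off by
default.

**QC filters** (all thresholds configurable): gene length ≥ 20 kb; coverage
over the first 20 kb ≥ 0.7 reads per million total aligned reads (the
published threshold's units are unstated; reads-per-million is the natural
reading of "normalized by total read number" and is what the generator's
depths make comparable); rate > 0.5 kb/min (exactly 0.5 is excluded); gene
must have a rate in the companion condition when one is supplied. Flags are
independent, so a gene can carry several.

**Speed classes.** Retained genes are split at the 1/3 and 2/3 empirical
quantiles (linear/type-7 interpolation) into slow/medium/fast; ties at a
boundary go to the lower class. Degenerate cohorts (a class would be empty)
are fatal in `assign_speed_groups`; the end-to-end pipeline degrades to
`unassigned` instead, since constant-rate simulations are legitimate inputs.

## Spike-in normalization and pausing

Occupancies are RPKM-like: count / (region length in kb) / (total aligned
reads in millions), with the knockout condition additionally multiplied by
factor = (mouseWT/humanWT)/(mouseTKO/humanTKO) computed per replicate from
the ledger of dual-genome read totals. Promoter = TSS±500 bp, body =
TSS+500..TTS. Occupancies are averaged across replicates first and the
pausing index is the ratio of the replicate means (mean-then-ratio is more
stable than ratio-then-mean for low body signals; the original order is
unstated). Genes with zero body signal get an undefined (NaN) index and are
excluded from rank tests — infinities would poison them. MNase fragment
preprocessing keeps same-chromosome pairs with span < 250 bp (span read as
outer fragment length), trims 25 bp at both ends, and drops fragments whose
trimmed length is ≤ 0.

## m6A quantification

Level = (IP reads / IP total) / (input reads / input total) per replicate
over the extended transcript [TSS−2 kb, TTS+2 kb) (the modification
concentrates near the TTS, hence the extension), averaged across replicates
after excluding genes missing in either replicate. Cross-condition effect =
log2(TKO level / WT level), undefined when either level is 0 or missing. The
H1-quartile analysis splits genes into four quantiles of promoter-proximal
H1 occupancy (TSS±2 kb window, matching the promoter-occupancy convention
used elsewhere; the exact window is an open choice) and tests each
quartile's log2 ratios against 0 with the one-sample Wilcoxon signed-rank
test, reporting p = 1 for all-zero quartiles. Peak window classification
uses the peak midpoint (any-overlap would double-count long peaks): TSS
class if within TSS±2 kb, TTS class if within TTS±2 kb, both where the
windows overlap (genes < 4 kb), else neither.

## Group statistics

Mann-Whitney U (unpaired) and Wilcoxon signed-rank (paired, or one-sample
against 0) via scipy, two-sided throughout (sidedness is otherwise
unstated; two-sided is conservative); exact small-sample p-values where
scipy's policy allows, normal approximation with tie correction otherwise.
Identical samples are degenerate and report p = 1 by convention. Raw
p-values are reported; a Benjamini-Hochberg helper exists but is off by
default. Correlations (Spearman/Pearson) use pairwise-complete observations
and flag zero-variance input rather than erroring.

## Synthetic-data generator

The generator emulates: a sharp-front wave with uniform occupancy behind it
(the simplest model consistent with synchronous release; real waves have a
sloped front from initiation heterogeneity), Poisson fragment counts at
2000 expected labeled fragments per gene per time point, an exon-restricted
background of 100 expected fragments per gene emulating mature-mRNA
contamination, two replicates, and two conditions whose ledger mouse totals
are scaled by the inverse spike-in factor. Genes (default 300, 30-60 kb,
matching the length range where the 20-kb filter and a 5-min front of
~15 kb both sit comfortably inside the body) carry 2-10 exons of 150-400 bp,
placed one per equal segment; 50 genes per synthetic chromosome with 10-kb
gaps. The default rate model is a lognormal mixture with modes at 2.0 and
3.5 kb/min and weights 1/3 and 2/3, mirroring the observed bimodal mixture
of a slow (< 2 kb/min) minority and a fast (~3.5 kb/min) majority; m6A
truths cycle through {0.5, 1, 2, 4}. Everything is deterministic given the
seed (independent substreams per time point/replicate/condition).

What the generator does **not** emulate: read-level errors and mappability,
overdispersion beyond Poisson, antisense or intergenic transcription,
multiple TSSs, wave-front broadening, replicate batch effects. Passing
recovery tests therefore demonstrates correctness of the estimation chain
under the stated generative model, not robustness to every artifact of real
libraries — the QC filters carry that burden on real data.

## Numerical choices and limitations

Changepoint ties: broken toward the larger changepoint (the more distal
front); the tie tolerance is a relative 1e-15 on the SSE. Boundary positions
are quantized to the bin size, so estimated rates are quantized to
bin/(t·1000) kb/min (0.04 kb/min at defaults); medians over cohorts inherit
a bias of at most half that. Genes whose wave front passes the TTS before
the release time (v·t > length) lose rate information and typically return
no boundary. The acceptance script uses 300-gene cohorts (200 for the slow
cohort), the package's standard desk-scale design, which bounds the median's
Monte-Carlo error well below the stated ±0.15 kb/min tolerance.
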