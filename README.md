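# nucbubble

Tools for quantifying nucleosome occupancy on reconstituted promoter
DNA from single-molecule psoralen-crosslink electron microscopy, with
companion modules for MNase fragment occupancy profiling around
transcription start sites and for global fitting of fluorescence-
polarization binding titrations.

## The problem

Psoralen crosslinks protein-free duplex DNA under UV light. After
protein digestion and denaturing spreading, regions that were protected
by a nucleosome cannot re-anneal and appear in electron micrographs as
single-stranded "bubbles" along each traced molecule. Counting
nucleosome-sized bubbles per molecule therefore measures nucleosome
occupancy molecule by molecule — for example on a reconstituted 461-bp
cell-cycle-gene promoter, with and without a chromatin-binding factor.

The pipeline implemented here:

1. **Geometry** — each molecule is traced as two ordered strand
   polylines in pixels. The strands are co-oriented by endpoint
   matching, base positions are assigned along each strand by arc
   length using the known template length *L* (scale = arc length / *L*,
   base *k* at arc (*k* + ½)·scale), and the per-base-pair inter-strand
   distance is the closest point-to-segment distance to the opposite
   strand.
2. **Bubble calling** — a base pair is single-stranded iff its
   inter-strand distance strictly exceeds an empirically calibrated
   threshold (two-class Otsu split of the pooled distance histogram by
   default). Maximal single-stranded runs are bubbles; a bubble is
   scored as a nucleosome iff its length is strictly > 90 bp; fused
   bubbles (> 240 bp) are flagged but count as one nucleosome.
3. **Statistics** — per-condition count histograms are fit by a Poisson
   distribution (λ̂ = sample mean, the MLE), with a 10,000-resample
   percentile bootstrap 95% CI on λ, and conditions are compared with
   the exact-Poisson test: conditional on the total count
   *K*ₐ + *K*ᵦ, *K*ₐ ~ Binomial(*K*ₐ + *K*ᵦ, *n*ₐ/(*n*ₐ + *n*ᵦ)) under
   equal rates; two-sided p by tail doubling.

The **MNase module** filters paired-end fragments to mononucleosome
size (120–180 bp), builds 1-bp-resolution occupancy tracks and
TSS-centered, transcription-oriented matrices, aggregates normalized
per-gene profiles (locating e.g. a sharply positioned +1 nucleosome),
flags genes above a fold-enrichment threshold (default 4.7) of IP over
control, and bootstraps occupancy differences in TSS-relative windows.

The **binding module** fits FP titrations globally across replicates
with the exact single-site (ligand-depletion) model
f = (R + L + K_d − √((R + L + K_d)² − 4RL)) / 2L, reporting K_d with
Jacobian standard errors and a "no binding detected" flag for flat or
out-of-range curves.

A **synthetic-data module** generates ground-truth-annotated inputs for
every stage (traced molecules with planted bubbles, fragment
populations with a planted +1 nucleosome, titrations from a known Kd),
so the whole pipeline is verifiable end to end.

## Worked example

```bash
python examples/01_trace_to_counts.py
```

```
calibrated single-stranded threshold: 5.69 px
molecules analyzed: 150 (0 ambiguous excluded)
mean nucleosomes per molecule: called 1.187, planted 1.187
exact per-molecule agreement: 100.0%
```

The threshold (5.69 px) falls between the simulated duplex (2 px) and
open (10 px) strand separations; every molecule's nucleosome count was
recovered from raw strand coordinates alone. Comparing two conditions
(`examples/02_condition_comparison.py`):

```
octamer alone: lambda = 0.23 [0.17, 0.31] (n = 150)
octamer + factor: lambda = 0.97 [0.85, 1.11] (n = 150)
exact-Poisson test, octamer alone vs octamer + factor: p = 2.56e-17
```

λ is the mean number of nucleosome-sized bubbles per molecule with its
bootstrap 95% CI; the exact test rejects equal occupancy decisively.
`examples/03_mnase_tss_profile.py` and `examples/04_fp_global_fit.py`
demonstrate the MNase and binding layers the same way.

A thin CLI mirrors the stages
(`nucbubble simulate-traces | profile | callbubbles | run | mnase ... | fpfit`);
run `nucbubble --help`.

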