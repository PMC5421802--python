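# ctcflow

Circulating tumor cells (CTCs) are tumor-derived cells shed into peripheral
blood, typically one per ~10⁷ white blood cells.  After label-free
microfluidic enrichment the output is still dominated by leukocytes, which
leaves two downstream problems that this package addresses as one tested
workflow:

1. **Enumeration** — identify and count CTCs on three-channel
   immunofluorescence images (DAPI for nuclei, a combined CK/EpCAM channel
   for epithelial tumor cells, CD45 for leukocytes) and estimate **CTC
   purity** = CTC count / total cell count.
2. **Mutation profiling** — detect low-frequency somatic variants in
   amplicon deep-sequencing of the enrichment output, using that purity to
   adjust the variant-frequency threshold of a one-tailed Fisher's exact
   test on tumor/normal read counts, with consensus calling across
   technical replicates.

It is aimed at labs building CTC pipelines who want the image-analysis and
variant-calling halves reproducible, scriptable and testable without
microscope or sequencer in the loop: both halves come with synthetic data
generators (ground-truth slides; spike-in pileup series) that drive the
test suite and the benchmarks.

## The core procedures

**Enumeration** (re-implemented image pipeline): a single global threshold
(Otsu by default) segments nuclei on the DAPI channel; objects touching the
border are discarded; nuclei are kept if their area-equivalent diameter
*d* = 2√(A/π)·pixel_size lies in the closed window [9, 36] µm and their
ellipse-fit **eccentricity** e = (between-foci distance)/(major axis) — 0
for a circle — is ≤ 0.80 (lobed, irregular leukocyte nuclei fail this);
each nucleus is expanded by 3 px into a secondary object in which mean
CK/EpCAM and CD45 intensities are measured; gates set from staining
controls (isotype mean + 3·SD) classify each cell:

| CK/EpCAM | CD45 | class |
|---|---|---|
| + | − | CTC |
| + | + | dual-positive |
| − | + | WBC |
| − | − | negative |

**Somatic calling**: for each locus with tumor counts (ref_t, var_t) and
normal counts (ref_n, var_n), the somatic p value is the exact
hypergeometric upper tail P(X ≥ var_t) of the 2×2 table (computed in log
space, stable at coverage ~4×10⁵).  A variant is called when
p < 0.05, tumor VF ≥ 0.20·purity (floored at 10⁻⁴), and normal VF ≤ 1%
(germline guard).  A **consensus somatic mutation** is one called with
p < 0.05 in *every* technical replicate.

Supporting statistics: ROC/AUC of CTC counts as a cancer biomarker
(Mann–Whitney rank form, exact under ties), sensitivity/specificity at a
count cutoff, inter-run CV%, percent CTC reduction under treatment,
dilution-series linearity fits, and PPV/FDR/sensitivity evaluation against
simulated truth.  The amplicon module models the 2-step PCR construct with
the 10-bp random **diversifier** that restores base diversity in the first
five sequencing cycles, plus adapter/diversifier trimming back to the
insert.

## Worked example

```bash
ctc run-demo --seed 7 --out demo/
```

renders a synthetic enrichment-output slide (8 CTCs, 40 WBCs, 2
dual-positives, 2 negatives), enumerates it, and feeds the measured purity
into the simulated sequencing stage.  The report (`demo/report.json`)
contains:

```
"counts": {"CTC": 8, "DUAL_POSITIVE": 2, "NEGATIVE": 2, "WBC": 40}
"ctc_purity": 0.15384615384615385
"somatic_calling": {"purity_used": 0.15384615384615385,
                    "consensus_calls": ["EGFR:chr7:55259524"], ...}
```

All 52 cells were recovered and classified correctly (purity 8/52 ≈ 15.4%);
with that purity the caller's effective VF threshold drops to
0.20 × 0.154 ≈ 3.1%, and the one spiked EGFR L861Q variant is recovered as
a consensus call in both technical replicates while the five
variant-free panel loci stay quiet.  Library-level benchmarks:

```bash
ctc benchmark-linearity --seed 1
# {"slope": 0.9945, "intercept": 0.000168, "r_squared": 0.99997, ...}
ctc benchmark-consensus --seed 1 --n-samples 5
# consensus duplicates: tp=5, fp=0, fn=0 → sensitivity 1.0
```

i.e. detected VF tracks expected VF essentially 1:1 across the
0.08%–8% spike-in series at coverage 4×10⁵, and duplicate-consensus
calling detects every 0.8%-VF truth variant.

Other entry points: `ctc simulate-images`, `ctc count`,
`ctc calibrate-gates`, `ctc roc`, `ctc repro`, `ctc build-library`,
`ctc trim`, `ctc diversity`, `ctc simulate-dilution`, `ctc call-somatic`,
`ctc config --show-defaults`.

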