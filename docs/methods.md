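# Methods

## Synthetic slide model

A slide is a field of non-overlapping cells on a uniform background.  Each
cell is specified by its nuclear diameter (µm), lobe count, mean CK/EpCAM
and CD45 levels and a true class label.  A round nucleus is a rasterized
disk; a k-lobed nucleus (k ≥ 2) is a union of k equal disks spaced 0.6
diameters apart along one axis, which produces an elongated footprint with
controllable ellipse eccentricity (~0.9 at k = 3) without attempting real
granulocyte morphology.  All three channels paint the cell's value over the
nuclear footprint; the DAPI level is a config parameter (`dna_intensity`,
default 200) since marker semantics attach only to CK/EpCAM and CD45.
Background is constant (default 10) plus optional additive Gaussian noise
(σ = `noise_sd`), clipped at zero.  Pixel size defaults to 0.5 µm/px and is
explicit in every measurement call — no hidden unit conversions.

Auto-placed cells are positioned by rejection sampling (≤ 1000 retries)
with a bounding-circle clearance of `min_gap_px` (default 8 px) between
nuclei.  The clearance, not mere footprint disjointness, is what makes
"well-separated" true operationally: footprints one pixel apart would fuse
into a single 4-connected component after thresholding, and an 8 px gap
also keeps 3 px secondary expansions from annexing a neighbor's pixels.
Cells with fixed centers are honored exactly and raise on any footprint
overlap.

What the generator does **not** emulate: point-spread blur, illumination
gradients, autofluorescence, cell doublets/clumps, staining heterogeneity
within a cell.  Passing the end-to-end recovery test therefore shows the
pipeline's logic is correct on resolvable, gateable cells; it does not
certify performance on crowded or low-contrast real slides, where
threshold choice and clump splitting dominate.

## Enumeration pipeline

Segmentation uses one global threshold over the DAPI image — Otsu's
criterion by default, with `fixed` and `quantile` strategies available —
then hole filling, 4-connected labeling, and removal of border-touching
objects (cells cut by the field of view are unmeasurable).  A constant
image yields zero objects rather than an error.

Shape: equivalent diameter 2√(A/π)·pixel_size; eccentricity from the
second-central-moment ellipse (scikit-image `regionprops`), guaranteed in
[0, 1] and exactly 0 for pixel-symmetric disks.  The diameter window
[9, 36] µm is closed at both ends.  The eccentricity ceiling has no
published canonical value; the default 0.80 is an explicit configuration
choice reported in output metadata.

Secondary objects are distance-limited expansions (default 3 px) of the
filtered nuclei with contested pixels assigned to the nearest object —
there is no membrane stain in this panel, so watershed on a membrane
channel is not an option.  Mean intensities are arithmetic means under the
expanded labels.

Gate calibration follows negative-control gating practice: threshold =
isotype-control mean + k·SD per channel (k = 3 default, sample SD).  A
positive control with < 90% of cells above the CK/EpCAM gate triggers a
`CalibrationWarning`.  Classification is strict at the threshold (a cell
exactly at the gate is negative for that marker), making classes a
partition.  Purity is CTC/total; with zero cells it is reported as
undefined (flag), never as 0.

## Count statistics

AUC is computed as the Mann–Whitney probability P(score_cancer >
score_healthy) + ½P(tie) via ranks, which is exact under the heavy ties of
small integer counts; operating points are evaluated at half-integer
cutoffs with "count > cutoff" positive, matching the convention of a 3.5
cutoff on integer counts.  CV% uses the n−1 SD and is flagged undefined at
zero mean.  Percent reduction is 100·(pre − post)/pre and requires pre > 0.

## Amplicon construct and diversity

Constructs are modeled as exact segment maps (0-based half-open, reverse
elements stored as top-strand reverse complements):
`p5 | diversifier | fwd-primer | insert | rev-primer(rc) | diversifier |
p7(rc)`.  The first PCR instantiates both 10-nt diversifiers i.i.d.
uniform over ACGT; the second PCR extends partial adapters (suffixes of
the full adapters) to full P5/P7 and leaves the interior bit-identical.
Default adapter sequences are the generic Illumina P5/P7 flowcell
adapters (29/24 nt); panel-specific primers come from config.  The
diversifier is placed on both ends (symmetric construct), controllable by
setting `diversifier_length`.

Trimming matches the adapter as a prefix with ≤ 2 substitutions (no
indels — synthetic reads carry none), drops the diversifier by length,
verifies and removes the forward primer, and cuts at the reverse-primer
reverse-complement if found (≥ 8 bases of a truncated occurrence suffice);
unmatched reads are flagged untrimmed and excluded downstream.  Per-cycle
diversity is the Shannon entropy (bits, max 2) of the base composition at
each of the first n cycles (default 5) of the reads as sequenced, i.e.
starting at the diversifier.

## Pileup simulator

Sequencing is simulated at the pileup-count level: per-locus
variant-supporting reads are Binomial(coverage, q) with
q = VF + e·(1 − VF) in the tumor and q = e in the matched normal, where
VF is the expected variant frequency of the mixture (tumor fraction for a
homozygous variant, half for heterozygous) and e is the per-base
probability of the specific substitution (default 10⁻⁴,
post-filter Illumina-like).  Alignment is deliberately not simulated —
amplicon positions are known by construction — and indels, strand bias,
UMI consensus and GC effects are out of scope.  Default coverage is
4×10⁵ reads/locus, the magnitude observed in deep amplicon runs of this
kind.  The spike-in cell line's EGFR L861Q is treated as homozygous, so
spike fraction equals expected VF — the only mapping consistent with the
0%, 0.08%, 0.8%, 2.68%, 8% series.  All randomness flows from a master
seed through `SeedSequence.spawn`, so series and replicates are
reproducible end to end.

## Somatic caller

The somatic p value is the one-tailed Fisher's exact upper tail for tumor
enrichment, summed in log space via log-gamma (log-sum-exp), exact to
double precision at 4×10⁵-scale margins (verified against integer
combinatorics at small margins and against an independent implementation
at large ones).  One-tailed because somatic calling is directional.

The purity adjustment is multiplicative: effective minimum tumor VF =
`base_min_vf` (0.20) × purity, floored at 10⁻⁴.  The upstream tool this
mirrors documents the *intent* of purity adjustment but not its formula;
multiplicative scaling is the natural reading (a clonal variant's VF in
the mixture scales with purity) and is an explicit, overridable choice.
The `max_normal_vf` guard (1%) exists because at deep coverage Fisher
significance alone would call germline heterozygous sites somatic.

Consensus requires the call (p < 0.05 and both VF guards) in **all**
replicates; the consensus record retains per-replicate p values.
Evaluation reports PPV = TP/(TP+FP), FDR = FP/(TP+FP) (complements by
construction) and sensitivity = TP/(TP+FN), with PPV/FDR undefined when no
calls exist.  Linearity is an OLS fit of detected on expected VF with
R² = 1 − SS_res/SS_tot.

## Benchmark problem sizes

The dilution benchmark draws 10 points round-robin over the four nonzero
VF levels at coverage 4×10⁵ and fits the nonzero levels (the blank level
belongs to the assay but contributes nothing to slope).  The consensus
benchmark simulates 5 samples × 6 panel loci × k replicates, one true
mutation per sample at 0.8% VF, caller purity set to the spike fraction,
and pools calls over samples.  The repeated-run properties (100 fixtures,
100 seeded benchmark repetitions) use these sizes; they complete in
seconds to tens of seconds on a single CPU.

## Known limitations

- Image half: no real-data validation artifacts ship with the package;
  thresholds (eccentricity 0.80, gate k = 3) are defaults to be tuned per
  staining protocol.
- The error model gives every locus the same substitution rate; real
  amplicon error is sequence-context dependent and can exceed 10⁻⁴ at
  specific motifs, which would raise the false-discovery pressure the
  consensus rule is designed to absorb.
- The caller handles SNVs only, one alt allele per locus, no multi-sample
  joint modeling.
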