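# Methods

This note documents the models, defaults and design choices behind
`notimeth`, and what the synthetic-data validation does and does not show.

## Array signal model and calling

A NotI microarray interrogates genomic clones flanking NotI sites; because
NotI cuts only unmethylated `GCGGCCGC`, the tumor/normal hybridization
ratio of a clone reports methylation and copy number jointly. The caller
treats the two causes as one event class (MD); they are not separable from
the array alone, which is exactly why the bisulfite concordance module
exists.

Per pair, the chain is:

1. **Net intensity** per spot: `max(foreground − background, 0)`.
2. **Replicate aggregation**: median of the unflagged replicate nets per
   clone and channel; a channel yields data only with ≥ `min_valid`
   (default 4 of 6) unflagged spots. The median with a 4-of-6 quorum is
   robust to single bad spots on the six-replicate layout.
3. **Log-ratio** `log2(net_tumor/net_normal)`, undefined (no data) when a
   channel lacks a quorum or the normal net is zero; −∞ (a certain MD)
   when only the tumor net is zero.
4. **Normalization**: subtract the median of the finite log-ratios,
   excluding the non-human negative-control clones. This absorbs global
   channel imbalance and assumes the majority of sites are unaltered —
   true here, where a typical sample carries on the order of 10–20 events
   over 180 sites. When *most* sites are altered the centre is no longer
   identifiable (a genome-wide alteration looks exactly like a dye
   imbalance); for such data `call_pair(..., normalize=False)` skips
   centering, and the pipeline's scale-invariance guarantees are given up.
5. **Thresholding**: MD at log-ratio ≤ −0.58, AD at ≥ +0.58
   (1.5-fold), retention between; boundary equality calls the event state
   (a single deterministic tie rule). The original analysis software's
   internal cutoffs are not published; ±0.58 is this package's default,
   chosen as a conservative margin for the 2-fold signal expected from
   hemizygous loss or full monoallelic methylation, and every threshold is
   configuration-exposed.

A consequence worth knowing: at the default spot noise the conservative
threshold slightly *under*-calls true 2-fold events (≈ 1–2% of planted MD
events are missed, and median centering adds a small shift in the same
direction), so a site planted at 56.5% MD is recovered at ≈ 55–56% over
5000 pairs. The reproduction suite asserts recovery within ±2 percentage
points of the planted frequency.

## Synthetic array generator

`ArraySimConfig` defaults emulate the study design: 180 sites × 6
replicate spots, 6 E. coli control clones carrying no human signal, 23
pairs per cohort. Latent per-site states are drawn independently (MD with
the site's event probability, AD with 0.01 — events of this class were
single cases in the study and are excluded from frequency statistics —
else retention). Signals are lognormal: per-site baseline 2^N(10, 1),
spot noise 2^N(0, 0.25) on the signal, multiplicative background around
100, 2% of spots flagged bad. MD multiplies the tumor signal by 0.5 and
AD by 2.0, the simplest copy-ratio reading of the assay. The replicate
noise and intensity scale are not published; these values are stated
config, not claims about the original data.

Sites are independent by default because the study publishes only
marginal frequencies. The observed co-occurrence structure (a minority of
samples carrying many events at once) is injectable through an optional
per-sample *hypermethylator* latent factor (`hyper_prob`, off by
default), which raises a sample's event probabilities to
`p + (1−p)·hyper_gain`. Dye bias, print-tip and spatial effects are not
simulated. Passing tests therefore demonstrate correctness of the
estimators under this error model, not robustness to array artifacts the
model omits.

## Reference fixtures and the synthetic cohort matrix

The packaged fixtures carry the study's printed tables: the 19
high-frequency NotI sites with genes, cytobands and MD counts (out of 23),
the 23+12 sample annotations (stage I/II/III with their TNM strings), and
the six-marker panel with its 2-of-6 rule. Two printed-table conventions
matter: percentages round half-up (13/23 → 57, 8/23 → 35), and the
"more than 17%" selection is operationalized as a *count* filter
(≥ 4 of 23), since sites at 4/23 = 17.4% are included in the printed list.
The clone spanning the shared *RBSP3*/*CTDSPL* locus is stored under the
official symbol CTDSPL (one gene), which is what makes the distinct-gene
count across the 19 sites equal 22.

The per-sample call matrix behind the burden and panel numbers is not
published. `datasets.reference_call_matrix()` is a **synthetic
reconstruction**, built deterministically to satisfy every published
marginal simultaneously: the 19 per-site MD counts; exactly five samples
(#8, 11, 16, 17, 22) with MD in more than 9 of the 19 sites; 18 of 23
samples positive under the 2-of-6 panel rule (78% sensitivity); and MD in
the sample/gene cells validated by bisulfite sequencing. Cell-level
detail beyond those constraints is arbitrary, so conclusions that depend
on unpublished joint structure (e.g. exact per-sample panel scores of
unflagged samples) should not be read off this matrix.

## Marker panel

A sample's score is its number of MD markers; no-data and AD markers
count zero, because a biopsy assay cannot treat a failed marker as
positive. Classification is score ≥ k (default 2 of 6). Sensitivity,
specificity and accuracy follow from the confusion counts; the Gini
coefficient is 2·AUC − 1 with a midrank AUC on the integer score, which
is well defined under heavy ties. Subset search enumerates all
candidate subsets of the requested size (deterministically ranked by
accuracy, then sensitivity, then lexicographic clone order), replacing the
original support-vector selection heuristic with an exactly reproducible
procedure over the same published decision rule; a forward-selection
fallback covers candidate lists too large to enumerate.

The study does not define the negative cohort behind its specificity and
accuracy figures. Specificity here is therefore *conditional on an
explicit negative model* — an idealized all-retention cohort, or
normal/normal self-hybridizations simulated with a configurable per-site
false-positive rate — while sensitivity is computed from the tumor matrix
alone.

## qPCR quantification

Relative mRNA level uses fractional amplification efficiencies
(one cycle multiplies template by 1+E; all assays are expected above 0.9
and the estimator warns below): per reference gene,
`R_ref = 2^[(log2(1+E_tar)·C̄t_tar − log2(1+E_ref)·C̄t_ref)_normal −
(…)_tumor]`, with arithmetic-mean replicate averaging of Ct and no outlier
dropping. The combination rule across the two reference genes is not
published; the geometric mean of per-reference R is used, the standard
multi-reference practice. With all efficiencies at 1 the estimator reduces
exactly to 2^(−ΔΔCt), and swapping the tissue labels maps R to 1/R; both
are asserted in the suite. Changes are significant at 2-fold (boundary
counts as changed), cohort summaries report half-up-rounded percentages,
and the median change is printed as 1 ("typically unchanged") whenever the
median |log2 R| is below one — the convention of the study's expression
table. The generative qPCR simulator is the exact inverse of the
estimator (a fold change f shifts the tumor target Ct by
−log2 f / log2(1+E_tar)), making planted-fold recovery a closed-loop test.

Stage association compares log2 R between stages I+II and stage III with a
two-sided Mann-Whitney test; which test produced each reported p is always
recorded in the result's method note, since the original report is
ambiguous on this point.

## Bisulfite concordance

A clone set is a clones × CpGs boolean matrix (default layout 7 clones ×
24 CpGs, matching the validation amplicon; the two CpGs flagged as the
NotI recognition site default to positions 13–14, a synthetic placement).
The site-level verdict requires *every* NotI-site CpG methylated in
strictly more than half the clones (threshold configurable): NotI cleavage
is blocked only by methylation of its own recognition CpGs, so partial
site methylation should not count as the assay-positive state. The
concordance table interprets MD-without-methylation as a likely deletion —
the mechanism the study inferred for *NKIRAS1* and *VHL* discordant cases.

## Statistical tests

All tests delegate to scipy.stats behind a thin contract layer: the
rank-sum test enumerates exactly for total n ≤ 12 without ties and
otherwise uses the tie-corrected normal approximation; the signed-rank
test drops zero differences and records how many; the chi-square test uses
no continuity correction and warns when an expected cell is below 5; every
result carries a method note naming the branch taken. Significance
conventions are α = 0.05, relaxed to 0.06 for very small samplings, and no
multiple-testing correction is applied (matching the source analysis; a
Benjamini-Hochberg helper is deliberately not wired into reports).

Calibration: the validation suite measures each test's attained size at
α = 0.05 at study-scale group sizes, by seeded Monte Carlo for the rank
tests and by exact enumeration over a binomial null for the count tests.
Discreteness matters at these sizes: Fisher's exact test is inherently
conservative (its attained size peaks at ≈ 0.035 at 7 vs 8 and is ≈ 0.02
at 12 vs 12), so its calibration is asserted at 7 vs 8 — the configuration
within the study's group-size range where calibration is attainable —
and the chi-square test is asserted at 12 vs 12 (attained size ≈ 0.064).

## Problem sizes and determinism

The reproduction script and suite run at desk scale: 5000 simulated pairs
for the planted-frequency recovery, 200 replicates for fold-change
recovery, 2000 Monte-Carlo replicates per rank-test calibration, and
exact enumeration wherever the instance is small enough. Every stochastic
component consumes a `numpy` `SeedSequence` derived from an explicit seed;
identical (config, seed) pairs reproduce every output byte for byte, and
the pipeline manifest records config, seed, package version and a SHA-256
digest of each written file.
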