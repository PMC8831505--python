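# Methods

## The screen being modeled

A pooled knockout screen in TCR-transgenic CD4 T cells: Cas9⁺ cells are
transduced in culture with a retroviral sgRNA library, expanded,
adoptively transferred into wild-type hosts, and challenged with an
acute viral infection. Six days later the responding cells have split
into Th1 and Tfh (pre-Tfh and germinal-center Tfh) populations, which
are sorted and deep-sequenced along with the plasmid library and the
pre-transfer culture. A guide whose knockout impairs Tfh
differentiation is depleted from the Tfh sorts relative to Th1; the
analysis turns per-sample guide counts into gene-level calls of that
depletion.

## Simulator

The generative chain and its distributions:

1. **Plasmid pool.** Relative guide abundance is log-normal with
   log-sd `plasmid_sigma` (default 0.5), normalized to sum 1. Pooled
   cloning yields roughly 2-fold interquartile skew at this value;
   σ = 0 gives an exactly uniform pool.
2. **Culture.** Expected cells per guide ∝
   abundance × 2^(d_c·(1+f_vitro)) with `culture_doublings` d_c
   (default 6) and per-gene in vitro fitness f_vitro (0 = neutral,
   −1 = no net growth); counts are Poisson around the expectation.
3. **Transfer.** A multinomial draw of `transfer_pool_size` cells
   (default 10⁶, the upper limit of antigen-specific cells that still
   allows a normal response) by culture composition.
4. **Engraftment.** Independent binomial thinning at
   `engraftment_rate` = 0.10: adoptive transfer loses ~90% of cells.
   No homing heterogeneity is modeled — the simplest mechanism
   matching the stated loss.
5. **In vivo expansion.** Deterministic exponential expectation
   2^(d_v·(1+f_vivo)) with Poisson realization per guide, rather than a
   per-cell birth–death process: same first two moments at screen-scale
   counts, far cheaper. `invivo_doublings` defaults to 6 (one division
   per day over d0→d6, typical of acutely activated CD4 T cells); no
   measured value exists for this setting, so it is an explicit
   configuration choice.
6. **Fate.** Each cell is Tfh with probability
   logistic(`baseline_tfh_logit` + Δ_gene), else Th1; Tfh cells are GC
   Tfh with probability `gc_tfh_fraction` (default 0.4) and pre-Tfh
   otherwise. The fixed GC split reflects the observation that
   pre-Tfh-vs-Th1 and GC-Tfh-vs-Th1 screen readouts are highly
   similar; Δ is the single per-gene differentiation parameter.
   Baseline logit 0 (a 50:50 split) is used because no canonical split
   exists across infections and days.
7. **Sorting.** Per gate, min(available, `sort_coverage` × n_guides)
   cells are drawn proportionally to the gate's per-guide composition
   (with replacement — indistinguishable from hypergeometric sampling
   at screen-scale counts). With probability 1 − `sort_purity`
   (default 0.95) a sorted cell comes from the complementary gate
   (Th1 ↔ Tfh); impurity is symmetric since only the purity bound, not
   its direction, is known.
8. **Sequencing.** `seq_depth` × n_guides reads (default 300×) drawn
   multinomially on gamma-weighted cell counts; the gamma weights
   (shape `pcr_shape` = 10, mean 1) model per-guide PCR amplification
   jitter, and reads converge to cell fractions as the shape → ∞.

One screen is 1 shared plasmid sample, 1 culture per experiment, and
either per-mouse or pooled Th1/preTfh/GCTfh sorts (individual sorting
of 2 experiments × 5 mice gives 33 samples). Everything is driven by
one `numpy` Generator seeded from the config, so identical
config + truth + seed gives bit-identical tables.

**FASTQ emission** writes one read per count: the 60-nt
flank–spacer–flank cassette placed at a random offset in random
padding, with per-base substitution errors and constant Phred+33
qualities. Reads are sense-strand; the counter can search both strands
behind a flag.

**Spike-in cohorts** put a target gene's guides at a chosen total
frequency in an otherwise neutral pool (the in-silico analogue of
spiking transduced cells into mock-transduced carriers) and run the
same mouse chain.

### What the simulator does not emulate

Viral titer and infection kinetics, homing heterogeneity, regulatory
T cells, germinal-center spatial structure, guide-level (as opposed to
gene-level) effect variation, cutting toxicity, and flow-cytometry
measurement noise. Passing tests therefore demonstrate that the
analysis chain is correct and calibrated *under this generative model*,
not that any particular biological screen will behave this way.

## Quantification

For a closed library of known 20-mers, alignment reduces to anchored
matching: find the 3′ 9-mer of the upstream flank (`CCTTGTTTG`), read
the next 20 nt, and require the 5′ 6-mer of the tracr flank
(`GTTTTA`) to follow. Extraction scans past chance anchor hits whose
grammar does not check out, which makes the zero-error round trip
(emit → count) exact. Spacers map by exact match first; a 1-mismatch
rescue applies only when the Hamming-1 neighbour is unique in the
library — ambiguous reads stay unmapped. The accounting identity
mapped + unmapped = total holds per sample. Normalization is counts
per million mapped reads (CPM); a median-of-controls alternative is
provided for count tables whose depth differences are control-driven.

## Statistics

**Per-guide fold change.** L2FC = log₂((CPM₁+c)/(CPM₂+c)) with
pseudocount c = 0.5, which bounds dropout guides. Ratios are computed
within mouse when sorts are individual (Tfh and Th1 from the same
animal share its engraftment history) and against the experiment-level
culture or shared plasmid sample otherwise. Guides with zero counts on
both sides of a pair are excluded from that replicate. The combined
"Tfh" population is the per-mouse sum of the preTfh and GCTfh gates.

**Hierarchy.** Replicates average as mean over mice within experiment,
then unweighted mean over experiments, so experiments with unequal
mouse counts weight equally. Gene mean ± SEM is over its guides'
overall means (n−1 sd; SEM undefined for a single guide).

**Z-scores.** Genes are standardized against control pseudo-genes —
consecutive groups of `guides_per_gene` non-targeting controls —
z = (m − mean(ctrl))/sd(ctrl). Applied to the controls themselves this
gives sample mean 0 and sd 1 exactly (no leave-one-out correction).
With few controls (e.g. 20 controls → 4 pseudo-genes) the reference
mean and sd are noisy, so z behaves like a scaled t statistic with few
degrees of freedom: its scale is unstable screen-to-screen, and the
FDR, not a |z| cutoff, should decide calls. All-gene standardization
is available via `zscore_reference="all"`.

**α-RRA.** Guides are ranked by L2FC in the tested direction (missing
values take the worst rank); normalized rank r = rank/N. A gene with
sorted guide ranks r₍₁₎ ≤ … ≤ r₍ₖ₎ scores
min{ P(Beta(j, k−j+1) ≤ r₍ⱼ₎) : r₍ⱼ₎ < α }, with score 1 when no guide
ranks inside the top-α fraction (α = 0.25, mirroring the FDR display
threshold). Significance comes from size-matched pseudo-genes drawn
from a rank pool, p = (1 + #{null ≤ obs})/(1 + n_perm) with
n_perm = 10 000 by default, and Benjamini–Hochberg FDR over genes.
Two-sided results take per gene the smaller of the depleted/enriched
p-values, doubled and capped at 1.

*Null-pool choice.* Drawing pseudo-genes only from non-targeting
controls is attractive (controls are null by construction) but
unstable when the pool is small: with 20 control guides every gene's
p-value rises and falls with that one 20-rank draw, and BH then
rejects en masse in unlucky screens. The default (`null_pool="auto"`)
therefore uses controls only when at least 10 pseudo-genes' worth are
available, falling back to the all-guide pool, which is exact under
exchangeability and mildly conservative when many true hits occupy the
extreme ranks. Both pools remain selectable. A related structural
fact: the score distribution has an atom at 1 (a fraction ≈ (1−α)^k of
null genes have no guide inside α), so permutation p-values are
uniform only below that atom — calibration checks should target the
lower region that drives FDR.

**Classification.** In the (Tfh/culture, Th1/culture) plane with
thresholds ±1 L2FC (drawn, as in practice, as quadrants around the
controls): both depleted → required for expansion; both enriched →
inhibits expansion; only Tfh depleted → required for Tfh; only Th1
depleted → required for Th1; else neutral.

## Power analysis

Monte-Carlo only. Each grid cell (spike frequency × effect × coverage)
simulates `n_reps` cohorts; detection is |z| ≥ 2 for the spiked gene's
Tfh-vs-Th1 mean against the background-gene distribution — a modeling
translation of the original flow-cytometry readout into count space.
Target and background are both gene-level means, so the null z is
approximately standard normal and the rule's nominal size ≈ 4.6%.
Detection rates carry binomial SE = √(p(1−p)/n); the minimum
detectable frequency is the smallest tested frequency reaching the
target power (default 0.8). Reported detection limits are conditional
on the assumed effect size (default logit shift −3, a strong
knockout); no effect size is asserted for any real gene.

## Numerical and scale choices

Spacer generation rejects duplicates and homopolymer runs ≥ 6; spacer
sequence content is otherwise irrelevant to the pipeline. Seeds fan
out from one master seed through a counter-based `SeedSequence`
scheme, so stages rerun reproducibly in isolation. Test and
acceptance runs use design-scale screens (400–420 guides, 2 × 5 mice,
750× sort coverage, 300× depth) with 10–20 Monte-Carlo replicates and
n_perm = 2000 inside replicate loops (p-value resolution 1/2001,
ample for FDR-at-0.25 checks); single-run analyses default to
n_perm = 10 000. Degenerate inputs are defined rather than left to
chance: σ = 0 plasmid pools are exactly uniform, empty engrafted mice
warn and return empty samples, all-zero sequencing columns warn and
return zeros, and zero-mapped samples are a hard error naming the
sample.

## Known limitations

Gene effects are uniform across a gene's guides (no per-guide efficacy
model), the null simulator has no overdispersion beyond PCR gamma
jitter, the extraction stage does not model indels or quality decay,
and the permutation FDR — like any rank-aggregation FDR on a small
control pool — should be read alongside effect size, never alone.
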