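# Methods

## The assay and its count model

Methyl-sensitive cut counting (MSCC) measures CpG methylation at CCGG
sites, the common recognition motif of the isoschizomers HpaII and MspI.
Two tag libraries are built per sample: a methylation-*sensitive* library
(HpaII cuts only unmethylated sites, so its tags arise from unmethylated
molecules; per-site count `U`) and an inverse methylation-*insensitive*
library (MspI cuts regardless, constructed so its tags arise from
methylated molecules; per-site count `M`). The per-site methylation
fraction is estimated as the library-size-normalized share of
methylated-library signal:

    m̂ = (M / N_M) / (M / N_M + U / N_U)

where `N_U`, `N_M` are the two libraries' total mapped tag counts. The
estimator reduces to `M / (M + U)` when the totals are equal, is invariant
to scaling both libraries' counts and totals by a common constant, and is
exactly the quantity the four internal spike-in standards (0%, 33%, 67%
and 100% methylated control DNA) can calibrate.

**Bias and normalizers.** `m̂` is unbiased (up to the usual O(1/depth)
ratio bias) precisely when `N_U / N_M` equals the true ratio of the two
libraries' per-molecule sequencing depths. When no library metadata is
supplied the totals default to the column sums of the counts table; those
sums depend on the genome's average methylation, so on data whose mean
methylation is far from 0.5 the estimates are a monotone distortion of the
truth — direction calls and rank order are preserved, absolute levels are
not. Supplying `LibraryInfo` with depth-proportional totals (or applying
the spike-in calibration) removes the distortion. The synthetic generator
therefore emits totals equal to each library's sequencing *capacity*
(`depth × n_sites` plus the spike-in share), mirroring the real assay in
which both libraries are sequenced to a fixed throughput regardless of
methylation content.

**Undefined sites.** `U = M = 0` yields no estimate (NaN), never a 0/0;
such sites are removed by the coverage filter.

**Coverage filter.** A site is kept when it has at least 30 combined tags
(`U + M ≥ 30`) *in each condition*; the threshold is a parameter because
the region summaries are also reported at 60 and 100. Reading the filter
per condition (rather than pooled across conditions) is a deliberate
choice: every retained site needs a usable estimate in both samples.

**Calibration.** A least-squares line maps raw `m̂` at the four standards
to their known fractions; per-standard raw values are averaged across the
two conditions so that a single line applies identically to both samples,
and calibrated values are clamped to [0, 1]. Calibration is off by
default — the assay description defines the standards but no correction
procedure, so the correction is optional and reported rather than silently
applied. With fewer than four measurable standards the fit is unavailable
and raw values are used with a warning.

## Annotation model

Coordinates are 0-based and half-open throughout; BED input is native and
GTF-dialect input (1-based, closed) is converted on read.

* **Promoter window**: 1500 bp upstream to 500 bp downstream of the TSS,
  strand-aware — `[tss−1500, tss+500)` on the plus strand,
  `[tss−500, tss+1500)` on the minus strand — clipped at the chromosome
  boundaries. Upstream/downstream must be directional because genes lie on
  both strands. One subtlety of the half-open convention: on the minus
  strand, window membership corresponds to signed distances in
  `(−1500, 500]` rather than `[−1500, 500)`; the two definitions differ at
  exactly the two boundary bases and we keep the interval form above so
  every window has width 2000.
* **Island membership** is a union test over possibly-overlapping island
  intervals (backed by an interval tree).
* **Nearest TSS**: the gene minimizing `|pos − tss|` on the site's
  chromosome; the signed distance is negative when the site is upstream in
  the gene's reading direction. Equidistant ties break toward the gene the
  site is upstream of, then lexicographically by gene id — an arbitrary but
  deterministic rule. Sites on chromosomes without genes are flagged and
  excluded from TSS profiles (they remain in genome-wide tallies).
* **Promoter assignment** when windows overlap: the site goes to the gene
  with the nearest TSS only, keeping region strata disjoint. (The
  per-gene promoter profile used in integration counts all sites inside
  that gene's window, independent of this single assignment.)

## Change profile

`delta = m̂_hypoxic − m̂_control` on the absolute fraction scale. Direction
is `hyper` for positive, `hypo` for negative; exact zeros are reported as
`none` rather than forced into either tally. The "substantial change"
cutoff is `|delta| ≥ 0.20` in absolute percentage points (the scatter the
study stratifies is on absolute fraction axes, so a relative reading would
be wrong). Summaries count hyper/hypo sites per stratum — genome,
promoters, islands, and island sites within 1500 bp of a TSS — at coverage
thresholds {30, 60, 100} and cutoffs {0, 0.2}.

## Expression filter and integration

The DE table (gene, fold change, p-value) comes from an upstream
differential-expression tool and is treated as input; testing is not
re-implemented. Filters are strict inequalities: `p < 0.05` and
`FC > 1.5` or `FC < 1/1.5` (the symmetric ratio-scale reading of
"absolute fold change greater than 1.5" — the published down-regulated
genes all lie below 2/3). No multiple-testing correction is applied,
mirroring the upstream convention; this is a faithfulness choice, not an
endorsement.

For each filtered DE gene, the measured sites inside its promoter window
are profiled; genes with fewer than two measured sites are excluded as
noise-prone. The promoter statistic is

    pct_hyper = 100 · n_hyper / n_sites

with zero-change sites in the denominator only, reported to 4 decimal
places. Concordance classes at threshold `T = 90`:

| expression | pct_hyper ≤ 100−T | pct_hyper ≥ T | otherwise |
|------------|-------------------|---------------|-----------|
| up         | concordant_up     | discordant_up | unclassified |
| down       | discordant_down   | concordant_down | unclassified |

Bounds are inclusive (`≤ 10`, `≥ 90`): the published table's note ("no
more than 10% of sites differing") and its contents (a retained gene at
9.6774%) are consistent with the inclusive reading, and no published row
falls strictly between 90 and 100 to distinguish the alternatives. By
default any nonzero site delta counts toward a direction
(`--site-change-cutoff` exposes the stricter option; whether the original
analysis imposed the 20% cutoff here is not stated).

## Synthetic study generator

The generator emulates the statistical structure the pipeline assumes, not
sequence-level reality: no reads, no mapping ambiguity, no bisulfite
chemistry, no PCR duplicates. What it does emulate, with defaults chosen
to be realistic for a mammalian neuronal methylome:

* **Genome**: `n_chrom=2` chromosomes of 5 Mb; 300 genes with unique TSS
  and random strands; 150 islands of 0.5–2 kb, each centred on a random
  promoter's TSS with probability 0.6 (most mammalian CpG islands overlap
  promoters); CCGG density 5× higher inside islands.
* **Methylome**: control fractions are Beta-distributed with concentration
  10 around mean 0.10 inside islands (islands are hypomethylated) and
  0.75 outside (typical somatic CpG methylation). A fraction (default
  0.10) of genes are `promoter_shifted`: every site in their promoter
  window moves by `shift_size` (default −0.40, i.e. treatment-induced
  promoter hypomethylation) in the treated condition, clamped to [0, 1].
  All other sites get clipped Gaussian noise (sd 0.02), producing the
  near-diagonal cloud of a control-vs-treated scatter without washing out
  effects.
* **Counts**: per site and condition, `U ~ Poisson(d_U (1−m))`,
  `M ~ Poisson(d_M m)` with `d_U = 50` tags/site/library and
  `d_M = d_U × depth_ratio` (`depth_ratio` deliberately exercises the
  normalization). A Poisson-per-library model rather than a multinomial
  over sites keeps sites independent and the estimator analysis simple.
  Spike-ins are drawn identically at depth 1000 on the reserved contig
  `spikein`.
* **DE truth**: 2% of genes are DE (about the rate the study observed over
  the genome-wide annotation), 61% of them up. Up genes receive
  `FC = 1.5 · 1.5^{|z|}` with `z ~ N(0, lfc_scale)` and `p ~ U(0, 0.05)`;
  down genes the reciprocal; null genes sit near FC 1 with uniform p.
  Labels are retained so recovery can be scored exactly.

Everything derives from a single `numpy` generator seeded by
`SimulationConfig.seed`; two runs with the same config are identical, and
dataset writers emit deterministically ordered TSV/BED so pipeline reruns
are byte-identical.

Because the generator shares none of the real data's hard parts (mapping
error, fragment-length bias, strand effects, biological replicate
variance), passing tests demonstrate that the *computations* are correct
and self-consistent — not that the pipeline would reproduce the original
study's genome-scale counts, which require the deposited raw reads and are
out of scope here.

## Problem sizes and numerical choices

Tests and the analysis scripts run at desk scale: simulated studies of
2–12 thousand sites, a few hundred genes, depths 20–1000. Calibration
recovery uses 200 replicates at depth 1000, where the standard error of
the mean estimate is ≈ 0.1 percentage points against a ±2-point check.
Estimator consistency is checked as mean absolute error at `m = 0.5`
decreasing across depths 20/100/500 (at `m = 0.5` the estimator is
symmetric, so signed bias is ~0 at every depth and MAE is the informative
quantity). The end-to-end recovery experiment uses deliberately strong
effects — shift −0.5, depth 100, five guaranteed sites per promoter — so
that failures indicate logic errors rather than sampling noise.

Degenerate inputs are handled explicitly: zero-coverage sites are flagged
undefined, empty strata report zero counts, genes on unknown chromosomes
are skipped in integration, and an incomplete spike-in set disables
calibration rather than extrapolating from fewer points.

## Known limitations

* The count model ignores overdispersion; real tag counts are noisier than
  Poisson, so real-data coverage filters are doing more work than the
  simulation suggests.
* A single TSS per gene; alternative promoters and transcript isoforms are
  not modelled.
* The column-sum default for library totals is a convenience, not a
  recommendation — see the normalizer discussion above.
* Per-site differential methylation is thresholded, not tested; no
  uncertainty is propagated into the concordance classes.
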