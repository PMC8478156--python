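# Methods

## Scope and data model

`gilandscape` analyzes targeted-panel sequencing results for GI cancer
cohorts. Its inputs are per-patient tables, not reads: a MAF-like somatic/
germline variant TSV, a standard 6-column SEG file of copy-number segments
(1-based inclusive on disk, converted to 0-based half-open in memory), a
long-format TSV of read-length histograms at panel-embedded mononucleotide
microsatellites, a clinical TSV, and a YAML panel configuration. Upstream
read processing (alignment, variant calling, segmentation) is out of scope.

The bundled default panel (`data/default_panel_synthetic.yaml`) is a
synthetic stand-in for a proprietary 416-gene clinical panel: it keeps the
genes that matter to the analysis (drivers, the six MMR and three POL
genes, nine signaling pathways, co-located gene pairs such as WRN/NAT1 and
CDKN2A/B) and pads the list to 416 with clearly marked filler symbols on a
simplified 22-autosome coordinate model. Analyses that depend only on gene
membership, interval overlap and target size are unaffected by the
simplification.

## Variant retention

A somatic call is retained when VAF ≥ 1.0% **and** it has ≥ 3 supporting
reads on each strand. Both thresholds are inclusive and configurable
(`filter_variants(min_vaf, min_reads_per_strand)`); germline records pass
through untouched. The filter is idempotent and order-preserving.

## TMB and hyper-mutation

TMB counts somatic, in-target substitutions and small indels (missense,
nonsense, stop-gain, splice-site, frameshift and in-frame indels) divided
by the panel target size in Mb (default 1.2). Fusions, "other" class
records and germline variants never count. Hyper-mutation is TMB strictly
greater than 20 mut/Mb; the boundary itself is not hyper-mutated.

## MSI calling

Per locus, the method needs a baseline length distribution from
microsatellite-stable samples. Because matched normals are not part of the
input, the stable pool is self-selected: a sample joins the pool when its
modal repeat length equals the panel reference length at ≥ 80% of loci
(unstable tumors shift the mode at a large fraction of loci and are
excluded). Pooled read counts per locus are normalized and the **support
set** is every length holding ≥ 1% of pooled mass — with the default
stutter noise this is {ref, ref−1, ref−2}.

A locus of a test sample is *unqualified* below 20 reads, otherwise
*unstable* when ≥ 20% of its reads lie outside the support set. A sample
is MSI when strictly more than 45% of its qualified loci are unstable, and
not evaluable with fewer than 10 qualified loci. The out-of-support
read-mass rule was chosen over a per-locus distribution test (KS or
chi-square) for determinism and interpretability; both the mass cutoff and
the depth floor are keyword arguments.

## CIN scoring and grouping

The CIN score is the length-weighted fraction of covered genome in
segments with |log2 ratio| > 0.2 ("proportion of the genome altered"); a
patient with no segments is not evaluable rather than scored 0. The score
is invariant under splitting segments, and values at exactly ±0.2 are
neutral.

High/low CIN groups are pooled-cohort quartiles with a nearest-rank
definition: with n evaluable tumors the extreme groups hold ⌊n/4⌋ patients
each; the k-th smallest and k-th largest scores are the cutoffs, and a
score tied at both cutoffs (degenerate, e.g. a constant cohort) is mid.
This reproduces exact 25/25 splits on distinct scores and resolves ties
deterministically. Quartiles are pooled across cancer types, not computed
per type.

## Gene-level CNV calls

Per patient and gene, overlapping segments contribute their log2 ratio
weighted by overlap length; the mean is a gain above +0.2, a loss below
−0.2, and the call is neutral when less than half of the gene interval is
covered. This deterministic threshold rule replaces recurrence-based
methods (GISTIC-style q-values are out of scope). Genes inside one deleted
segment necessarily receive concurrent calls, which is the behavior the
co-located WRN/NAT1 pair models.

## Statistics

- `fisher_exact_2x2` — two-sided Fisher exact test by summation of
  hypergeometric table probabilities ≤ the observed table's probability
  (delegates to `scipy.stats.fisher_exact`; verified in the test suite
  against exhaustive integer enumeration of every 2×2 table with N ≤ 30).
  A table with a zero margin returns p = 1.
- `bh_fdr` — Benjamini–Hochberg step-up q-values (statsmodels
  `multipletests`; cross-checked against the direct step-up recursion).
- `pairwise_group_test` — Fisher tests of every feature between every
  unordered group pair. The FDR family is the tested features within one
  group pair (configurable to a single global family); features altered in
  no patient of a pair are reported untested and consume no FDR slots.
- `kruskal_wallis` — tie-corrected H with the chi-square approximation
  (scipy).
- `dunn_posthoc` — hand-implemented rank-based pairwise z tests with the
  standard tie correction
  `z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j))`,
  two-sided normal p-values, BH-adjusted across pairs by default
  (Bonferroni switchable). With two groups it reproduces the continuity-
  uncorrected normal approximation of the rank-sum test.
- `compare_to_reference` — per-gene Fisher tests of (mutated, unmutated)
  between the cohort and an external counts table, BH-corrected over the
  shared gene set.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, at
defaults chosen to match the study conditions of a 414-patient GI cohort:

| parameter | default | meaning |
|---|---|---|
| `n_per_type` | CORE 207, GAST 144, PAAD 27, GABI 14, GIST 22 | cohort composition |
| `gene_freq` | e.g. TP53 0.82 / APC 0.60 / KRAS 0.50 in CORE; KIT 0.73 in GIST | per-type driver alteration probabilities |
| `msi_h_fraction` | CORE 11/207, GAST 5/124 | planted MSI-H rate |
| `hyper_fraction` | CORE 0.09, GAST 0.03 | planted hyper-mutation rate |
| `tmb_median` (mut/Mb) | 6 / 5 / 4 / 4 / 2.5 (CORE/GAST/PAAD/GABI/GIST) | log-normal background TMB, σ = 0.65 |
| `cin_median` | 0.31 / 0.27 / 0.11 / 0.18 / 0.40 | per-type Beta CIN targets (concentration 10, exact median inversion) |
| `msi_h_cin_median` | 0.10 | scarce CNVs in MSI-H tumors |
| `msi_noise` | stutter 0.12 / decay 0.75, depth 400, shift fraction 0.6, min shift 3 bp, 30% residual normal allele | repeat-histogram model |

Construction guarantees, not just expectations: non-hyper TMB draws are
capped at 18 mut/Mb and hyper draws start at 25, so threshold recovery is
exact by design; MSI-H tumors have at least ⌈0.6·52⌉ shifted loci (the
Bernoulli draws are topped up when short); segments realize the CIN target
to integer-bp rounding (a tiled genome is greedily assigned aberrant
log2 values until the target length is met, splitting one segment at the
exact boundary). MSI-H tumors carry ≥ 1 MMR-gene lesion with probability
0.95 and draw 45% of background variants as frameshift indels.

Two calibration rates are set by prevalence arithmetic rather than taken
directly from a printed number: the planted MMR/POL lesion probability in
low-mutation tumors is 0.15 because background mutations falling in the
nine MMR/POL genes (~14% of patients at median TMB) and the CORE POLE
driver frequency (0.09) already contribute, making total carrier
prevalence ~30%; hyper-mutated tumors draw 1 + Poisson(1) planted lesions
so that total burden (planted + background) has median ~3.

Stutter noise was fixed so the pooled support set is {ref, ref−1, ref−2}:
mass at ref−3 sits at ~0.6%, safely below the 1% support floor, which a
legitimate 3-bp somatic shift must clear for the out-of-support rule to
fire.

All randomness derives from a single seed through per-patient
`SeedSequence(entropy=seed, spawn_key=(family, type, index))` substreams —
one stream family per output (clinical/variants/segments/MSI) — so
enlarging one cancer type never perturbs existing patients' draws and
outputs are byte-reproducible.

### What the generator does not emulate

Real panel data have locus-specific stutter profiles, purity- and
FFPE-driven VAF distortion, correlated driver co-occurrence and mutual
exclusivity, signature-structured substitution spectra, and focal
amplifications superimposed on arm-level events. Passing closed-loop tests
therefore demonstrates that the *metrics and statistics* behave as
specified under the planted structure — not that the MSI caller or CIN
score would reach the same operating point on clinical data. The published
per-type medians serve as calibration targets and qualitative direction
checks (e.g. MSI-H tumors score lower CIN than MSS tumors) only.

## Stratification

Colorectal: cecum, ascending colon, hepatic flexure and the proximal
transverse colon are right-sided; the distal transverse colon, splenic
flexure, descending colon, sigmoid and rectum are left-sided; an
unqualified "transverse colon" is ambiguous and maps to unknown. Gastric:
cardia; fundus and body; pylorus and duodenum — "antrum" and "pylorus" go
to the pylorus/duodenum group, "body" to fundus/body. Both synonym tables
are module-level constants a user can extend. MSI status is assigned
first; an MSI tumor never carries a side/region stratum. TNM stage is
carried through the clinical table but used descriptively only.

## Numerical conventions

Display percentages round half away from zero to integers. Internal
coordinates are 0-based half-open everywhere; SEG and variant positions are
converted at I/O. Fewer than 4 evaluable CIN scores, fewer than 10
qualified MSI loci, or an empty segment list yield explicit
`not_evaluable` states instead of numeric sentinels. Problem sizes used by
the test suite (a 414-patient default cohort, a 200-patient recovery
cohort, 1000-rep null simulations, exhaustive Fisher enumeration to
N = 30) keep the full suite around half a minute on one core.
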