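# Methods

## The Ratio method and its denominator

TMB is estimated as the ratio of callable somatic mutations to
callable megabases.  The denominator is constructed by interval
algebra on BED-defined region sets: definitions are merged into
non-overlapping intervals (book-ended intervals coalesce, matching
`bedtools merge` defaults) and assembly gaps — supplied as an
arbitrary user BED, since no assembly parsing is done — are
subtracted.  All interval arithmetic is half-open 0-based internally;
1-based VCF positions are converted at the membership test
(`pos − 1`).  A mutation counts toward a definition iff its converted
position lies inside the merged, gap-subtracted set.  The panel
denominator is always the *measured* span of the supplied panel BED,
not a nominal kit size, so the ratio stays self-consistent with the
membership test.

Three nested definitions are modelled after common practice: a
"canonical" exon set, a clinical capture-kit subset (~88% of
canonical, mirroring 67.3/76.3 Mb), and an older, smaller subset
(~57% of that, mirroring 38/67.3 Mb).  Because each definition
interrogates a different region set, raw TMB values are compared
across definitions after per-definition z-score standardisation
(sample SD, n−1) across samples.  Standardising across samples within
a definition — rather than across definitions within a sample — is
the assumed orientation; `zscore_standardise` is orientation-agnostic
so the alternative is a one-line change.  Zero spread raises instead
of silently emitting zeros.

## Filter regimes

Two regimes, both operating on caller-PASS records (non-PASS records
are dropped at ingest; a flag retains them):

* **WGS quality + germline**: keep SNVs with depth ≥ 15 and
  VAF ≥ 0.05 (values exactly at a threshold are kept, the literal
  complement of removing "depth < 15" / "VAF < 0.05"); then remove
  known SNPs (exact chrom/pos/ref/alt match against a germline
  resource — positional matching alone would over-filter somatic hits
  at polymorphic sites) and calls with population AF strictly above
  1e-4.  Unannotated population AF counts as 0.  Indels are excluded
  by default (symmetric with the panel regime); `include_indels`
  admits them.  Membership filtering and the AF cut-off are
  independently switchable, since either convention is defensible for
  a dbSNP-style resource.
* **Panel (Oncomine-style)**: SNVs only, consequence ∈ {exonic,
  splice_site, intronic}, depth ≥ 60, VAF ≥ 0.05, plus the germline
  rule above.  When a VCF carries no consequence annotation every
  call defaults to "exonic" and the consequence predicate is a no-op;
  the synthetic generator writes a `CONSEQUENCE` INFO tag so the
  predicate is exercised.  No synonymous/nonsynonymous distinction is
  applied.

Removal tallies use first-failing-predicate attribution in the order
written above, so kept + removed always equals the input count; the
pipeline additionally logs every removed variant with its reason
code.

Depth/VAF recovery from VCFs prefers the named (or sole) sample's
FORMAT AD/DP, falling back to INFO DP with AD/AF-like keys; the
source used is recorded per file.  Multi-allelic records split into
one call per alternate allele with per-allele AD over DP.  Records
with no recoverable depth are kept with depth 0 — they fail every
quality filter — and tallied.

## Paired concordance

Each patient contributes two sites (site 1 = primary or first
sampled site, site 2 = metastatic/nodal); free-text site labels are
carried through from the sample table.  A pair is discordant iff the
two sites' high/low classes differ at the cut-off.  The cut-off
defaults to 10 mut/Mb with "high" at TMB ≥ 10; both the value and the
strictness of the boundary are configuration options, since ">10" and
"cut-off of 10" both circulate.  Patients missing a site are excluded
pairwise (never imputed) and listed in the report.  Cohort summaries
give medians with IQR and SD side by side, Spearman correlation and
the two-sided paired Wilcoxon test at α = 0.05.

Small cohorts need exact inference:

* Wilcoxon signed-rank drops zero differences (Wilcoxon convention,
  the common package default) and uses the exact null when the
  effective n ≤ 25 with no tied absolute differences, else a normal
  approximation with continuity correction.  All-zero differences
  yield a flagged degenerate result (p = 1), not an error.
* Spearman uses average-rank ties; the p-value is an exact
  full-permutation enumeration for n ≤ 9, a t-approximation above,
  with an optional seeded Monte-Carlo permutation mode (default 1e5
  draws).  Constant vectors are reported as undefined rather than
  NaN-propagated.

KRAS status is positive at mutant-allele fraction ≥ 0.002.  MAF can
be ingested directly or computed from ddPCR droplet counts with
Poisson correction (λ = −ln(N_neg/N_total) per channel,
maf = λ_mut/(λ_mut+λ_wt)); the raw-fraction alternative is a switch.
PD-L1 copy number is ingested as a value; a convenience utility
computes CN = 2·2^(−ΔΔCt) from Ct tables against a two-copy
calibrator.  PD-L1 has no established cut-off, so its report carries
correlation and paired-difference statistics only.

## The synthetic cohort generator

The generator emulates the paired design on a toy genome of two
10 Mb contigs.  What it models:

* nested region definitions drawn as random 2 kb segments (canonical
  ⊃ capture-kit-like ⊃ older-kit-like; panel ⊂ canonical, default
  1.7 Mb; gaps drawn over the whole genome so they genuinely overlap
  the definitions);
* per patient, trunk mutations ~ Poisson(trunk_rate × callable Mb)
  shared by both sites — including a shared true clonal VAF per
  mutation — plus independent per-site private mutations;
* read sampling per site: depth ~ Poisson(mean_depth), alt reads ~
  Binomial(depth, VAF) with clonal VAF ~ Beta(α, β); calls with zero
  sampled alt reads are not emitted (a caller would not report them)
  and are marked unemitted in the truth table;
* germline contaminants (shared genotype across sites, het:hom 2:1)
  whose population AFs follow a stated mixture — 80% common,
  AF ~ U(0.01, 0.5); 20% rare, AF ~ 10^U(−5,−3) — and which appear in
  the emitted germline-resource VCF, so `annotate_known` can find
  exactly them;
* sub-threshold artefacts, split 50/50 between depth-violating
  (depth ~ U{1..14}) and VAF-violating (measured VAF < 0.05), to
  exercise both quality predicates;
* orthogonal assays: an exact number of KRAS-positive patients
  (round(fraction × n); positives MAF ~ Beta(2, 8), negatives below
  the 0.2% cut-off; site 2 correlated via log-normal noise), ddPCR
  droplet counts consistent with those MAFs at 20 000 droplets, and
  log-normally distributed PD-L1 copy numbers correlated across
  sites; per-site tumour cellularity ~ U(18, 80)% so the 20% QC flag
  is occasionally exercised.

Default study conditions, chosen once to emulate an advanced-NSCLC
paired cohort sitting near the clinical cut-off: trunk 8/Mb, private
0.5/Mb (site 1) and 1.0/Mb (site 2, metastatic sites accrue more
private events), depth 60x (WGS) or 500x (panel mode), clonal VAF
Beta(3.5, 6.5) (mean 0.35 — purity is modelled only through this
distribution), germline 2/Mb, artefacts 2/Mb, 30% KRAS-positive,
10 patients.  Note the asymmetric private rates create a genuine,
consistent site effect: at n ≥ 10 the paired Wilcoxon will often call
the between-site difference significant even though every pair may
remain concordant at the cut-off — a deliberate illustration that
"statistically different" and "clinically discordant" are different
questions.

Reference alleles are arbitrary bases (no computation here depends on
sequence context) and placement is uniform within the callable
region; real mutational spectra, signatures, clonal phylogenies
beyond trunk+private, and read-level artefact structure are *not*
modelled, so passing recovery tests demonstrate estimator
correctness, not robustness to spectrum- or alignment-driven biases
in real data.

Reproducibility: one root seed; every consumer (regions, cohort
assignment, each patient) uses a named substream derived by stable
CRC32 hashing, so identical configs give byte-identical output
bundles and adding a patient never perturbs earlier patients.  The
output manifest records the config hash and per-file SHA-256s.

## Calibration experiments

`tmbpair.calibration` measures the statistical behaviour of the
pipeline on generator output (sizes chosen to make each experiment a
well-powered but quick check):

* **Density recovery** — planted λ ∈ {1, 5, 10, 20}/Mb on a 10 Mb
  callable exome, 200 replicates each, run in a high-detection regime
  (depth 200, VAF ~ Beta(20, 30), SNVs only, no nuisance signals).
  The regime matters: with the default noisy VAF distribution about
  0.3–0.8% of true variants fall below the 5% LOD (computed from the
  Beta/Binomial model), which is a property of detection, not of the
  estimator under test.  Mean recovered TMB is within 3 SE of λ.
* **Panel calibration** — the same uniformly placed mutations scored
  on a 17 Mb exome and a nested 1.7 Mb panel, 1000 replicates: the
  mean TMBs agree within 2% and the SD ratio is within 20% of
  √10, the square root of the area ratio — the panel is unbiased but
  noisier exactly as Poisson sampling predicts.
* **Wilcoxon null size** — 1000 simulated 10-patient cohorts with no
  site effect (shared trunk, zero private rates; between-site
  differences arise only from independent read sampling through the
  filters): rejection at nominal α = 0.05 stays ≤ 7% (measured ≈ 2%,
  reflecting exact-test conservatism at small n).
* **Discordance vs private rate** — with zero private mutations and
  high depth, 50 cohorts × 10 patients give exactly zero discordant
  pairs: shared trunk mutations are detected identically at both
  sites.  Across a private-rate grid at trunk 9/Mb the discordance
  rate is *not* monotone: it rises steeply as soon as private
  mutations exist, peaks where the expected site burden straddles the
  cut-off (around 1–2 private/Mb; measured means ≈ 0, 0.13, 0.12,
  0.007, 0 at 0, 1, 2, 4, 8/Mb), and collapses again once both sites
  are almost surely above the cut-off.  Discordance is a
  boundary phenomenon — it measures proximity of the cohort's burden
  to the cut-off as much as biological divergence — which is why
  cut-off-based classification can disagree between sites even when
  the sites' TMB values are strongly correlated.

## Numerical and degenerate-input choices

* 1 Mb = 1e6 bp exactly; TMB is kept at full precision internally and
  rounded to 2 decimals only in output tables (z-scores to 4).
* A zero or negative callable denominator raises
  (`DegenerateDenominatorError`) — never a silent 0 or infinity.
* Chromosome names are compared verbatim; an explicit option strips
  or adds the "chr" prefix on ingest, because silent harmonisation
  hides real mismatches.
* Calls outside every definition are simply not counted; the run log
  records the in-region fraction per sample.
* Region membership uses binary search over merged per-chromosome
  interval arrays (vectorised for bulk queries).
* Pipeline outputs contain no timestamps and serialise with sorted
  keys, so identical config + seed reproduce reports byte for byte.

## Known limitations

No tumour-purity or cellularity correction of TMB (cellularity is
recorded and QC-flagged at < 20%, never used to adjust scores); no
cross-platform panel calibration beyond z-scores; no variant calling,
realignment or manual review — the pipeline starts at somatic VCFs;
no liftover or capture-kit manifest retrieval; read-level simulation
(FASTQ/BAM) is out of scope for the generator.
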