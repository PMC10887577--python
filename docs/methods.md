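# Methods

This note documents the models, algorithms, parameter conventions and design
choices behind `rohscan`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Genotype model and QC

Genotypes are stored as a dense site × sample matrix of four codes
(`HOM_REF`, `HET`, `HOM_ALT`, `MISSING`). Only biallelic SNPs are kept;
multi-allelic records are dropped at VCF read time and counted. Half-calls
(`./1`) are coded `MISSING` — the conservative choice for homozygosity
calling, since treating them as homozygous would inflate ROH. Phase
separators are ignored. Internal coordinates are 1-based inclusive
everywhere; BED's 0-based half-open convention is converted only at file
boundaries. Chromosome names are matched exactly (no `chr` stripping):
silent renaming corrupts overlap joins, so mismatched sources must be
reconciled explicitly by the user.

Site filters follow the GATK `VariantFiltration` convention with strict
inequalities: a site is removed iff QD < 4.0 **or** FS > 60.0 **or**
MQ < 40.0 (each criterion evaluated only where the annotation is present —
a filter that cannot be evaluated cannot fail, and the pass-through count is
reported for audit). Genotypes with GQ < 20 are set missing. Boundary values
(QD = 4.0, GQ = 20) are retained, matching the quoted filter expressions.
Site filtering and genotype masking commute (site removal is
genotype-independent), which a test asserts; both are idempotent.

## ROH detection

The scan reproduces the classic SNP-array windowed algorithm:

1. Slide a window of `window_snp` = 50 consecutive SNPs along each
   chromosome of each individual. A window is a *hit* iff it contains at
   most `window_het_max` = 1 heterozygous and `window_missing_max` = 5
   missing calls (tolerating genotyping error inside true autozygous
   tracts).
2. Score each SNP by the fraction of containing windows that are hits; SNPs
   near chromosome ends sit in fewer windows, and chromosomes shorter than
   one window yield no calls at all.
3. Maximal stretches of SNPs with fraction ≥ `window_hit_threshold` = 0.05
   are candidate runs, split wherever adjacent SNPs are more than
   `max_gap_kb` = 1000 apart.
4. A candidate is emitted iff it has ≥ `min_snp` = 50 SNPs, spans
   ≥ `min_length_kb` = 100, and meets the density cap.

Segment coordinates are the first/last SNP positions of the run (the `.hom`
output convention), not window boundaries.

Parameter provenance: window composition (1 het + 5 missing), the 50-SNP
minimum, the 100-kb minimum and the density setting of 1000 are the
protocol's four named criteria for medium-density livestock data; the 5%
window-hit threshold and the 1000-kb gap are the underlying tool's
documented defaults, kept configurable. The density criterion is ambiguous
as usually quoted ("minimum SNP density … 1000 bp"): read literally it would
demand one SNP per kb and suppress nearly every run at a realistic 2–5 kb
SNP spacing, so the default interpretation is the tool's density option — at
most `max_density` = 1000 **kb per SNP** inside a run — with the literal
bp-per-SNP reading selectable via `density_units = "bp_per_snp"`. No
per-segment heterozygote cap is applied (window-level allowances only, as in
the 1.x tool).

`oracle_call_roh` re-implements the same contract by literal enumeration —
every window counted with explicit loops, every SNP's fraction tallied by
revisiting its windows — and shares no code with the vectorized scanner.
Equivalence is asserted segment-for-segment on randomized instances with
randomized parameters (regime-switching genotypes so that real runs, gap
splits and density rejections all occur).

## Length summaries

ROH lengths in Mb are (end − start + 1)/10⁶, binned into <1, 1–2, 2–3, 3–4,
4–5, >5 Mb and classed as short (<1 Mb), medium (1–5 Mb inclusive) and long
(>5 Mb strictly). Bins are left-closed except at the 5-Mb boundary: exactly
5 Mb falls in 4–5 so that the classes remain exact unions of bins. The
per-individual mean keeps zero-ROH individuals in the denominator — an
animal without ROH is an observation, not missing data. The length-SD uses
the sample (ddof = 1) convention.

## Inbreeding coefficients

* **F_ROH** = Σ segment lengths (bp) on autosomes / L_AUTO, where L_AUTO is
  the summed length of autosomal contigs from the VCF `##contig` headers or
  a chrom-sizes file. Detected segments are used as-is (no re-thresholding),
  preserving the pipeline's order of operations.
* **F_PED** (path counting): F = Σ (1/2)^(n₁+n₂+1)(1+F_A) over common
  ancestors A and path pairs from sire and dam that share no individual
  besides A (Wright's rule, enforced by explicit path enumeration with a
  per-pair membership check). Paths are truncated `max_generations` = 5
  parent steps above the individual, emulating pedigrees recorded to a fixed
  depth; ancestors beyond the horizon are treated as non-inbred founders.
  F_A of a common ancestor is computed the same way with the horizon
  re-anchored at that ancestor — a genuinely open choice (one could also
  count A's remaining depth against the proband's horizon); re-anchoring was
  chosen because it makes F_A independent of which descendant is being
  evaluated. An individual with any unknown parent has F = 0 (unrecorded
  ancestry treated as unrelated). Founder inbreeding values default to 0 and
  may be overridden.
* **`f_ped_recursive`** is the tabular kinship recurrence
  (kinship(a,a) = (1+F(a))/2, expansion through the deeper individual's
  parents) over the untruncated pedigree; it serves as the independent
  oracle for the path method.
* The **Pearson correlation** between coefficient vectors reports r, the
  exact t statistic t = r√((n−2)/(1−r²)) and the two-sided p from Student's
  t with n−2 df; degenerate inputs (n < 3, zero variance) raise rather than
  returning NaN.

## ROH islands

Per-SNP incidence counts *individuals* (not segments) whose ROH cover the
position, over the QC-surviving SNP universe. The high-frequency threshold
is the nearest-rank top-1% value — the incidence of the ⌈0.01·N⌉-th largest
SNP, ties included — chosen because "top 1%" admits many quantile dialects
and nearest-rank is exact and reproducible. Above-threshold SNPs are grouped
into islands per chromosome, splitting at gaps > 500 kb between consecutive
high-frequency SNPs and discarding groups of fewer than 2 SNPs; both island
parameters are artifact defaults (the grouping rule is rarely stated in
published analyses) and are echoed in output metadata.

## Annotation

Feature overlap requires ≥1 shared bp, with no reciprocal-fraction
requirement. QTL trait text maps to four categories (reproduction, growth,
meat_and_carcass, health) through an editable TSV seeded with
AnimalQTLdb-style trait classes and common pig trait names; unmapped traits
are counted in an explicit `unclassified` bucket so category totals always
reconcile with the overlap count.

## Synthetic data

The simulator emulates the target study design: ~12 genotyped animals from a
5-generation pedigree with inbreeding loops, 18 autosomes, SNPs every few
kb, genotyping error and missingness.

* **Pedigree**: generation 0 founders of alternating sex, random mating
  within the previous generation (re-drawing a few times to avoid incidental
  full-sib pairs, so close inbreeding comes from explicit loop directives);
  `loop_spec` forces full-sib (F = 1/4), half-sib (1/8) or first-cousin
  (1/16) matings at chosen generations, building the required relatives.
* **Gene drop**: founders carry two uniquely labeled haplotypes; each
  meiosis draws Poisson(rate × length) crossovers placed uniformly with no
  interference — the simplest model that produces the 1–10 Mb tract-length
  structure arising 2–5 generations after a loop at the default ~1 cM/Mb
  (0.01 crossovers/Mb). An individual is autozygous exactly where its two
  labels coincide; these intervals are the TruthSet, re-derivable from the
  stored labels at any time. `implant_tracts` additionally forces
  autozygosity over chosen intervals by copying the paternal label track,
  for controlled recall and island experiments.
* **Genotypes**: founder-haplotype alleles are drawn per SNP from a
  Beta(0.8, 0.8) allele-frequency distribution (U-shaped, SNP-array-like);
  SNP positions have exponential spacing with mean 3 kb (mimicking ~532k
  SNPs over a 2.5-Gb genome at full scale); error flips a call to a random
  different code at rate 10⁻³ and missingness masks at 10⁻². All outputs are
  bit-reproducible from (config, seed).

What the generator does **not** model: linkage disequilibrium among founder
haplotypes, crossover interference, mutation, selection, and
non-IBD homozygosity runs caused by allele-frequency structure. Passing
recovery tests therefore demonstrates that the detector finds genuine
IBD tracts under realistic noise, not that every ROH in real data is
autozygous.

## Problem sizes and numerical choices

Validation experiments run at a deliberate desk scale chosen to exercise
every code path while staying fast: 18 chromosomes of 10 Mb (a ~7%-scale
genome) with 1 SNP / 3 kb for recovery experiments; ≤2,000-SNP instances for
oracle equivalence (the oracle is quadratic by design); 1,000 replicates for
the full-sib Monte-Carlo check, compared at 3 standard errors. Recovery of
implanted tracts ≥2 Mb is asserted at ≥95% with boundary errors within one
window span (50 SNPs × 3 kb), the intrinsic resolution of a windowed scan.
Ties in the island threshold are included on the high side; the
worked-example cohort is engineered (homozygous blocks of 60 SNPs between
heterozygous spacers) so the detector provably emits one run per block.

## Known limitations

* The scan approximates PLINK `--homozyg` semantics as specified above; it
  is not a byte-level re-implementation of any particular PLINK version's
  corner cases (e.g. `.hom` end-of-chromosome window handling).
* F_PED truncation conventions differ across the literature; results at
  small `max_generations` depend on the re-anchoring choice documented
  above.
* Island counts depend on the gap/min-SNP grouping rule; comparisons across
  datasets should fix these parameters explicitly.
* The annotation step matches trait text exactly (case-insensitive); fuzzy
  or ontology-based trait mapping is out of scope.
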