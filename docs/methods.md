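# Methods

## The problem

The lager yeast *Saccharomyces pastorianus* is an allopolyploid hybrid of
*S. cerevisiae* and *S. eubayanus*. Its *S. eubayanus* subgenome belongs to
the Holarctic clade, for which several candidate source populations exist
(Tibetan, North Carolinian, and Irish isolates). Because recombination and
incomplete lineage sorting mean no single isolate is the direct ancestor,
the subgenome is best described as a mosaic: different chromosomal segments
share ancestry with different present-day populations. `lagerpaint`
implements the full procedure for quantifying that mosaic from a joint
multi-sample VCF: variant filtering, per-site assignment by uniquely shared
alleles, block calling, midpoint expansion, and per-population length
summaries, plus the random-repeated-haplotype-sampling (RRHS) alignment
generator used for phylogenetics.

## Site classification by uniquely shared alleles

Let Q be the set of alleles carried by the query (hybrid) strain at a
filtered biallelic SNP. The site is *assigned* to candidate population P iff
some allele a ∈ Q is carried by at least one of P's assignment
representatives and by none of the exclusion representatives of any other
population. Exactly one qualifying population gives an assignment; two or
more give `UNASSIGNED(shared_by_multiple)`; none gives
`UNASSIGNED(shared_by_none)`. A missing query genotype is
`UNASSIGNED(query_missing)`, and a population whose representatives are all
missing at the site is `UNASSIGNED(reps_missing)`.

Two deliberate choices:

* **Allele symmetry.** "Carries the variant" is interpreted as "carries a
  shared allele", REF or ALT. Variants are called against a single
  reference assembly, so the REF allele at a site is simply the allele that
  assembly happens to carry; a REF allele unique to one population is as
  diagnostic as a unique ALT. The literal ALT-only reading is available via
  `alt_presence_only=True` (CLI `--alt-presence-only`).
* **Partial missingness.** An exclusion representative with a missing
  genotype carries no observable allele and therefore cannot veto an
  assignment; only a population whose representatives are *all* missing
  voids the site. This keeps the rule monotone in observed data.

## Blocks and midpoint expansion

Runs of ≥ `min_support` (default 2) *consecutive* sites assigned to the same
population seed raw blocks. "Consecutive" counts population-assigned sites
only: unassigned sites are transparent and do not break a run, but a single
site assigned to a *different* population does break it (isolated discordant
sites interrupt runs; the alternative is exposed as
`unassigned_breaks_runs`). Singletons form no block.

Raw blocks are expanded outwards to tile each chromosome. The border between
adjacent blocks is `floor((left_last + right_first) / 2)` in 1-based
coordinates — the midpoint between the outermost supporting sites — with the
boundary base going to the left block. The first and last blocks extend to
the chromosome ends. This is provably identical to assigning every base to
the block whose nearest outermost supporting site is closest (ties to the
left block); a brute-force per-base oracle in the test suite asserts that
equivalence on a thousand randomized chromosomes.

One refinement prevents painting across data deserts: a run of at least
`missing_run_cap` (default 10) consecutive query-missing sites breaks runs
and becomes an explicit UNASSIGNED block with its own outermost sites, so
expansion of its neighbours stops at the midpoints into the desert rather
than bridging it. This is what lets total assigned bp fall short of the
genome length in low-coverage regions. The cap is configurable; `None`
disables it.

All block arithmetic is 0-based half-open (BED convention); VCF positions
stay 1-based up to the block boundary conversion `[f..l] → [f−1, l)`.

## Summaries

Per-population assigned bp is the sum of expanded block lengths per label.
Percentages divide by **total assigned bp**, not genome length — unassigned
regions carry no evidence and are excluded from the denominator; they are
reported separately, and assigned + unassigned always equals genome length
(tiling is asserted exactly). Strain-averaged contributions are unweighted
means of per-strain percentages.

## Filter cascade

Order is pinned: (1) genotype-level masking of calls with DP < 15 or
GQ < 40 (strict inequalities; genotypes lacking the annotation are left
alone, matching GATK VariantFiltration's treatment of absent annotations);
(2) removal of every SNP inside any window of ≤ 20 bp (inclusive span)
containing ≥ 5 SNPs — indels neither count nor are removed; (3) removal of
multiallelic sites; (4) removal of sites with > 30% missing genotypes
(strict; exactly 30% survives), evaluated *after* masking so quality failures
feed into missingness; (5) removal of non-SNP sites. The report's counts
satisfy input − site removals = output by construction, and the cascade is
idempotent. Quality filtering as site-level deletion instead of genotype
masking is available (`site_level_quality_filter`).

## RRHS

Each iteration resolves every diploid genotype to a single base: homozygous
calls emit their allele, heterozygous calls emit either allele with
probability 1/2 independently per sample per site (no within-chromosome
phasing), and missing genotypes emit `N`. Iteration k draws from an RNG
substream seeded by (seed, k), so any single alignment can be regenerated
byte-identically without replaying the rest. The default 1000 iterations
match standard practice for downstream tree building; tree search itself
(RAxML or similar) is out of scope — the package stops at alignment files
(relaxed PHYLIP or FASTA). One pseudo-haplotype row is emitted per strain.

## Synthetic cohorts

The generator emulates the statistical shape of the real panel, not its
genealogy: SNPs are placed by a Poisson process (default density 1 per
200 bp over two 250-kb chromosomes — a scaled-down stand-in for a 12-Mb
genome, chosen to keep dozens of sites per ancestry tract while tests run in
seconds), and each site is, with probability `private_allele_fraction`
(default 0.8), diagnostic: exactly one population's strains carry the ALT
allele. Non-diagnostic sites carry alleles shared by ≥ 2 populations or
population-internal heterozygosity (`het_rate`, default 0.02). Three
populations × two strains plus one hybrid query mirror the real scheme
(assignment via one strain per population, exclusion via both). The query is
a mosaic: within each truth tract it copies the genotype of one randomly
chosen strain of the source population. Noise is applied per genotype across
all samples: `missing_rate` masks calls, `genotype_error_rate` flips one
allele. DP/GQ are constants above the filter thresholds unless `degrade`
injects sub-threshold values to exercise the cascade.

What the generator does **not** model: linkage disequilibrium and coalescent
ancestry within populations, indel/multiallelic abundance matching real
callers, read-level error structure, reference bias, and polyploidy (the
hybrid is emitted as a diploid, as joint diploid calling would). Passing
recovery tests therefore demonstrate the correctness of the assignment and
interval arithmetic under the stated signal model, not robustness to every
artefact of real short-read data.

## Numerical and degenerate-input conventions

* Midpoint borders use integer floor; the boundary base goes left. The
  per-base oracle uses leftmost-wins ties; the two agree exactly.
* A chromosome with no qualifying blocks becomes a single UNASSIGNED block.
* Empty filtered tables are allowed but flagged; RRHS refuses zero-site
  tables (an empty alignment is meaningless downstream).
* All randomness flows from explicit integer seeds through
  `numpy.random.Generator`; simulator VCF output is byte-stable.

## Parameter recovery

On a 10-tract mosaic over 500 kb with default signal parameters and no
noise, painted per-population bp agrees with truth within a fraction of a
percentage point of the genome (the residual is junction quantization — about
half an inter-site gap per tract boundary). With 1% genotype error and 5%
missingness the error stays well inside a few points: isolated erroneous
assignments cannot seed blocks (they fail `min_support`) and cannot survive
inside a discordant run, so the procedure is strongly noise-damped. These
runs are what `scripts/acceptance.py` and the acceptance tests recompute.
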