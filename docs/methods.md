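# Methods

This note documents the models and procedures implemented in
`hapfeatures`, the choices made where the design was genuinely open,
and what the synthetic data can and cannot show.

## The demographic model

`simdata.build_colonization_model()` encodes a neutral Wright–Fisher
history for an admixed, colonization-bottlenecked population on a
single 10 Mb chromosome:

| parameter | value | units |
|---|---|---|
| ancestral Ne | 10,000 | diploids |
| out-of-Africa reduction | 2,000 at 50 kya, recovery to 10,000 at 5 kya | diploids, years ago |
| colonization bottleneck | 100, from 500 to 90 ya | diploids, years ago |
| admixture pulse | 70% from a European-like lineage, at 500 ya | fraction of parent draws |
| inbreeding window | selfing probability 0.70, 500–90 ya | per offspring |
| mutation rate μ | 1.5e-8 | /bp/generation |
| recombination rate r | 1e-8 | /bp/generation |
| generation time g | 30 | years |

Two lineages are maintained after the out-of-Africa event: the focal
(colonized) lineage and a European-like source that follows the same
size trajectory but skips the colonization bottleneck. This is the
minimal population structure that makes a one-generation admixture
pulse executable within a single forward simulation. "Inbreeding
probability" is implemented as selfing (the offspring's two gametes
come from one parent); sib-mating or other mechanisms would need a
pedigree layer and are out of scope, but the reproduction step is
pluggable.

Offspring chromosomes are crossover mosaics of one parent's two
chromosomes (Poisson crossover count, mean r·L; uniform breakpoints);
new mutations arrive as Poisson(μ·L) per gamete at unique continuous
positions (infinite sites), converted to unique integer bp on export.
Output marker sets keep sites with sampled derived frequency in
(0.05, 1.0) — segregating, above the study's MAF floor — except where a
caller asks for the unfiltered panel (`maf=0.0`), which the diversity
calibration needs because the 4·Ne·μ expectation refers to all
segregating sites.

### Rescaling

`rescale(model, q)` divides all Ne and all times by q and multiplies μ
and r by q, preserving θ = 4Neμ and ρ = 4Ner. The package's desk
preset is q = 20, which runs one replicate in seconds–tens of seconds
on one CPU. Genetic maps for simulated data use the model's own
(rescaled) recombination rate (cM/Mb = r·1e8): coalescent-scale
genetic lengths are only preserved if the map reflects the rescaled
rate.

Rescaling has a known, unavoidable cost: epochs shorter than one scaled
generation are rounded to whole generations (the 500–90 ya bottleneck
becomes a single generation at Ne 100/q), so statistics tied to
specific recent coalescence times are distorted. Two consequences
matter here:

- The IBD length band of 3–20 cM corresponds to coalescence roughly
  2.5–17 generations ago. At q = 20 that window compresses below one
  scaled generation, so the bottleneck's excess sharing partly lands in
  segments longer than 20 cM. The directional contrast (bottleneck >
  control in the banded score) still holds in ≥ 9/10 seeded replicate
  pairs, but the margin is smaller than the unscaled model would give.
- A large fraction of markers is skipped in the iHS scan because EHH
  never decays to 0.05 before the chromosome end: the one-generation
  bottleneck leaves only ~2Ne/q founder chromosomes, putting a floor
  under haplotype homozygosity. The skip rule is applied faithfully;
  skipped markers carry a reason and are excluded from test counts.

### Burn-in

Mutation–drift equilibrium at the start of the forward phase is
obtained by default from a coalescent sample (msprime) of the ancestral
population — the same stationary distribution a long forward burn-in
converges to, at a fraction of the cost. A forward burn-in of 10·Ne
generations is available (`burn_in="forward"`) and is checked against
the coalescent seeding in the tests at small scale. The constant-size
control model spans 12,000 years (400 generations) of forward
simulation; since it starts at equilibrium, this span only decorrelates
the sample from the seed.

### What the generator does not emulate

Array ascertainment (the study's marker sets are genotyping-array
panels with ~14.5 kb spacing; simulated panels are sequence-dense),
genotyping or phasing error, multiple chromosomes, variable
recombination maps, and selection. Tests passing on this generator
validate the statistics' behavior under the stated demography, not
robustness to array artifacts.

## Haplotype statistics

**EHH** at a core allele is Σ_h C(c_h,2)/C(n_c,2) over extended
haplotype classes among the n_c carriers, evaluated at marker positions
and non-increasing outward by construction. **iHS** integrates each
allele's EHH curve over genetic distance (trapezoid, with one
interpolated point at the exact EHH = 0.05 crossing); markers whose
curves fail to reach 0.05 before the chromosome end are skipped, as are
cores with derived frequency outside [0.05, 0.95]. uiHS =
ln(iHH_ancestral/iHH_derived) is standardized to mean 0, SD 1
(denominator n) within derived-allele-frequency bins of width 0.02.
There is no gap penalty and no maximum-extension cap; inter-marker gaps
above 200 kb are logged. The scan precomputes fully-extended haplotype
classes per side; because EHH is monotone, a core whose class-level
floor exceeds the cutoff can be skipped without scanning — this is an
exact shortcut, not an approximation.

**LD decay** is the squared Pearson correlation of per-individual
dosage vectors (0/1/2) for all marker pairs within 100 kb, averaged in
1 kb bins; zero-variance markers are excluded from pairing rather than
assigned r² = 0. Under independence the finite-sample expectation of r²
is 1/(n−1) for n individuals, which the tests use as the free-
recombination reference.

**Diversity**: Nei's haplotype diversity H = n/(n−1)(1 − Σp_i²) over
non-overlapping 10-marker windows (the window convention is a choice;
overlapping windows would change only the averaging), and per-site
expected heterozygosity 2p(1−p).

## IBD detection and score

Seed-and-extend matching in the GERMLINE style: 64-marker slices,
exact-match hash seeds, merging across adjacent slices while per-
segment mismatch allowances hold (1 mismatch where both individuals are
homozygous, 1 otherwise — classified on genotype context), then
marker-by-marker extension to the first mismatching marker. Detection
reports segments ≥ 2 cM; the score band [3, 20] cM is applied at
scoring time. Within-individual haplotype pairs are excluded (that
signal is ROH). The score normalizes total in-band genetic length by
C(2n,2) − n, the number of between-haplotype pairs among n diploids
excluding within-individual pairs. Standard errors use a Busing-type
weighted delete-one-block jackknife over 10 Mb blocks (weights
proportional to block length; midpoint block assignment); 95% CI =
score ± 1.96·SE. With equal blocks this reduces to the textbook
delete-one jackknife, which the tests verify directly.

## ROH calling

PLINK-style sliding windows: 50-SNP windows, a window is homozygous
with ≤ `window_het` heterozygous (0 for array-like data, 3 for
WGS-like) and ≤ 5 missing calls; a SNP qualifies when ≥ 5% of its
overlapping windows are homozygous (end-truncated windows count with
reduced coverage); maximal qualifying runs are split at gaps > 1 Mb and
kept if ≥ 50 SNPs, ≥ 1 Mb, and ≤ 50 kb/SNP average density (the
density default and the absence of heterozygote end-trimming are
documented constants). An explicit window-enumeration oracle checks the
caller on randomized instances in the tests.

## Selection cutoffs and the null calibration

Empirical iHS significance cutoffs come from neutral simulation scores
pooled across groups of 80 diploids: the lower/upper cutoff is the mean
minimum/maximum over B = 1000 without-replacement draws of the
population's test count from the pool (expected extremes at the matched
test count). This choice makes smaller test counts yield less extreme
cutoffs and is deterministic under a seed; a per-tail α = 1/n_tests
quantile alternative is available behind `method="tail_quantile"`.
Cutoff comparisons are strict inequalities; scores exactly at a cutoff
are not candidates.

The end-to-end null calibration simulates independent neutral
replicates, pools standardized scores from eight replicates (two groups
of 80 each), derives cutoffs matched to the usable test count of four
further independent replicates, and filters those scores. Usable tests
are markers with a finite standardized score; the naive comparison rate
is the |iHS| > 2 fraction of the same set. The surviving fraction falls
at least an order of magnitude below the naive rate at these problem
sizes. Problem sizes (replicate counts, 160 sampled diploids per
replicate, q = 20) are the package's desk-scale defaults.

## TMRCA dating

Under a star phylogeny with a recombination clock, the probability that
two carrier chromosomes remain identical at genetic distance r Morgans
from the core after T generations is e^(−2rT). The estimator locates
the interpolated EHH = 0.25 crossings of the favored allele (derived if
iHS > 0, ancestral otherwise) on both sides, takes r as half the
genetic span between the crossings (symmetric-decay assumption), and
returns T = ln(4)/(2r) generations, converted to years at 30
years/generation. Spans over 1.1 cM are skipped — such an allele would
be implausibly young for a neutral-ish sweep — and cores whose EHH
never reaches 0.25 inside the panel are reported as unresolved rather
than dropped. On engineered panels where carriers share a founder
haplotype of known age τ, the estimator recovers τ within a factor of 2
for τ in [100, 2000] generations (tests); by construction it
underestimates ages when the true genealogy is not star-shaped.

## Numerical conventions

Physical positions are 1-based bp; genetic distances are cM at API
surfaces and Morgans inside the TMRCA clock. Floats in result tables
are written at 6 significant digits. All stochastic procedures take
explicit integer seeds; identical inputs and seeds reproduce outputs
byte-for-byte. Ties and degenerate inputs: empty marker sets are legal
panels; zero-variance LD pairs are excluded; DAF bins with fewer than
two records leave scores undefined with a warning; jackknife with a
single block is an error.
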