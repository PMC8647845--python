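# Methods

`centel` re-implements, as one tested pipeline, the analysis style used to
characterize recently evolved, retrotransposon-dominated centromeres in a
chromosome-level plant assembly (the worked reference case is the yellowhorn
"JGXP" genome: 15 chromosomes, 470 Mb, centromeres totalling 23 Mb): joint
centromere localization from Hi-C, TE-density boundary refinement and
arm-ratio karyotyping, centromeric-vs-arm compartment statistics, K2P
insertion dating, TE similarity networks, and solo/intact/truncated LTR-RT
demography. Every stage runs end-to-end on synthetic genomes produced by the
package's own generator, so the whole analysis is exercisable with no
downloads.

## Synthetic-genome generator (`simgenome`)

The generator emulates the statistical structure the analysis assumes, not
real sequence:

- **TE landscape.** Each chromosome carries one centromeric interval of
  configurable width (default 0.5 Mb on 3–10 Mb toy chromosomes). Element
  counts per compartment are Poisson with mean density × compartment span;
  defaults put LINE1 at 60/Mb inside vs 4/Mb outside and Gypsy at 40 vs
  12/Mb, genes depleted inside (2 vs 20/Mb), mirroring the order-of-magnitude
  contrast of centromeric TE landscapes. Compartment membership of an element
  is decided by its midpoint throughout the package, which counts straddlers
  exactly once.
- **Sequences.** Each family has a random consensus; LINE1 and Gypsy
  additionally have a centromere-specific subfamily consensus (diverged 0.20
  and 0.15 from the family consensus, GC-shifted 0.36 → 0.44) from which
  centromeric copies derive. This is what makes centromeric LINE1/Gypsy form
  their own similarity-network modules while Copia (no subfamily) does not.
  Element and LTR sequences evolve by a per-site independent
  Kimura two-parameter substitution process with transition:transversion
  rate ratio κ = α/2β (default 2; κ = 0.5 is Jukes–Cantor). There are no
  indels: dating uses substitutions only, and the generator is not meant to
  exercise alignment gaps.
- **Hi-C.** Expected cis counts decay as d^(−α) (default α = 1, 100 counts
  at one bin) plus a uniform floor; expected trans counts are a uniform
  background (0.5) plus a Gaussian bump (amplitude 10, σ = 1.5 bins) centred
  on the centromere-bin pair, emulating Rabl-style centromere clustering.
  Observed counts are Poisson and symmetrized. The bump-to-background ratio
  of 20:1 reflects the strong trans enrichment that makes Hi-C centromere
  calling work in practice.
- **LTR-RT loci.** Loci are intact/solo/truncated in configurable
  proportions; the default (0.13, 0.21, 0.66) follows the I:S:T balance
  reported for the reference genome (6,749 : 10,771 : 33,692). Intact loci
  carry a complete ordered Gag-Pol domain hit; truncated loci carry one
  qualifying one-sided hit; solo loci carry a single LTR and no hits. The 5′
  and 3′ LTRs of paired loci evolve independently for the locus age T at
  r = 1.3 × 10⁻⁸ substitutions/site/year, so their expected K2P divergence is
  2rT. Ages implying expected pair identity ≤ 80% (the usual LTR-pair
  detection envelope) trigger a warning and a per-locus flag.

All outputs are deterministic given the config seed; the three generator
operations draw from independent streams spawned from it.

## Centromere calling from Hi-C (`cenhic`)

Centromeres cluster in the nucleus, concentrating inter-chromosomal contact
mass at centromere–centromere bin pairs. The caller is a transparent
re-derivation of that colocalization principle, not a port of any published
tool (whose parameters and normalization are not public): after per-pair
trans normalization (each chromosome pair scaled to unit mean over its
nonzero trans bins), it maximizes

  S(c₁…cₙ) = Σ_{A<B} Σ_{i∈A, j∈B} exp(−(i−c_A)²/2h²) · exp(−(j−c_B)²/2h²) · count(i, j)

over one bin per chromosome, with Gaussian bandwidth h = 2 bins by default.
Cis counts are excluded: cis decay mass would otherwise dominate the
objective. Optimization is coordinate ascent (monotone in the objective)
from the max-trans-coverage initialization plus 9 random restarts, ties
toward the lowest bin index; the reported point is the winning bin's
midpoint, since sub-bin precision is not defensible from binned counts.
Exhaustive grid search over all placements is provided for small maps and is
used in tests as the argmax oracle.

## Boundaries, karyotype, composition (`cenbound`)

Density tracks use non-overlapping 100-kb windows and the midpoint rule.
Boundary refinement automates what is usually drawn by eye: background b is
the genome-wide median of nonzero LINE1 window densities, and the centromeric
region is the maximal run of windows ≥ k·b (default k = 4) containing — or
within g windows of — the Hi-C point, tolerating up to g = 2 consecutive
sub-threshold windows. A rule with exposed parameters was chosen over manual
curation because reproducibility requires one; k = 4 sits well inside the
order-of-magnitude contrast the generator (and real centromeric LINE1
density) provides. Regions snap to window edges (start ≡ 1, end ≡ 0 modulo
the window size, unless clipped at the chromosome end).

Arm ratio r = long arm / short arm is measured from the refined region's
midpoint (regions, not points, are the reported unit). Karyotype classes are
closed on the left class: m for r ≤ 1.7, sm for r ≤ 3, st for r ≤ 7, t
above — the published boundary case r = 1.70 = m fixes the inclusivity. The
karyotype formula "2n = … = …m + …sm + …st" doubles haploid counts and omits
zero classes.

The tandem-repeat screen is intentionally simple (satellite discovery is not
the goal; the reference case is notable for *lacking* centromeric
satellites): windowed self-match autocorrelation picks the smallest period
with ≥ 90% self-identity, arrays extend to their maximal matching run,
monomers cluster greedily at > 90% identity, and region enrichment is a
one-sided binomial test against the length expectation. Absence of
candidates is a valid result.

## Intactness, dating, compartment statistics (`teevo`)

ORFs are start-to-stop, six frames, ≥ 800 nt (the getorf "-find 1 -minsize
800" convention), with N-containing codons breaking the scan; a LINE1 is
intact iff a qualifying ORF carries a reverse-transcriptase domain label and
one (possibly the same) carries an endonuclease label — the minimal rule
consistent with the ORF-size convention and cited practice. Domain hits are
consumed from a table; profile-HMM search itself is out of scope.

K2P divergence uses K = −½ ln(1−2P−Q) − ¼ ln(1−2Q) over columns where both
sequences have unambiguous bases; gap/N columns leave the denominator. Pairs
with a non-positive log argument are reported as *censored* ("saturated"),
never clamped, which prevents silent age deflation. Insertion age is
T = K/(2r), r = 1.3 × 10⁻⁸/site/yr by default. LTR pairs (and best-hit
partners) are aligned with an exact global edit-distance DP before the K2P
count — a numerical choice that keeps dating thousands of kb-scale pairs
fast; with the generator's indel-free sequences it is exact, and on real
data it is a reasonable stand-in for a full affine-gap global aligner.

The rank-sum test reports Mann-Whitney U from midranks. For groups of ≤ 8
observations it enumerates the tie-aware exact permutation distribution;
above that it uses the tie-corrected normal approximation with a 0.5
continuity correction. Tests are two-sided by default, with an
`alternative` flag for directional questions; no multiple-testing adjustment
is applied across families (none is prescribed for this analysis style).
Compartment reports flag families with fewer than two elements on either
side instead of testing them.

## Similarity networks (`tenet`)

Edges are affine-gap local-alignment scores (match +1, mismatch −2, gap of
length L costs 5 + 2L; a gap of length L costs open + L·extend), optionally
converted to bitscores S′ = (λS − ln κ)/ln 2 with λ = 1.28, κ = 0.46.
Pruning follows display practice for repeat networks: optionally remove each
node's weakest incident edge — an edge is dropped only when it is the
weakest edge of *both* endpoints, so an edge that is some node's best
remaining link survives (the any-endpoint variant is available) — then keep
the globally strongest ⌈q·E⌉ edges. Modules default to connected components
(with greedy-modularity refinement available); "module" is a display-level
notion here, and components are the least-interpreted reading of it.
Centromere specificity of the module structure is the maximum over modules
(size ≥ 2) of n_cen × (n_cen/size) — centromeric count weighted by purity,
which ignores trivial singletons — against a compartment-label permutation
null with p = (1 + #{null ≥ obs})/(B + 1).

## LTR-RT demography (`ltrdem`)

Classification: intact (I) iff the internal evidence contains the five
Gag-Pol domains GAG, PR, RT, RH, INT as an ordered subsequence; else
truncated (T) iff any one-sided hit has coverage ≥ 0.50 of a Gag-Pol
reference, E-value < 10⁻⁸ and identity > 30%; else solo (S). Coverage is
inclusive ("at least 50%"), E-value and identity strict. Counts are reported
raw and after dropping loci on scaffolds < 1 Mb (fragmented scaffolds bias
the three classes differently; the 1-Mb default is exposed in config and
echoed in the report header). S:I, T:I and (S+T):I are reported to two
decimals alongside the birth-rate proxy I+S+T.

LTR clustering is single-linkage over pairs meeting both coverage ≥ 0.70 (of
the shorter sequence, on the best local alignment) and identity ≥ 0.60; both
LTRs of intact loci contribute to linkage and a locus inherits its 5′ LTR's
cluster. A shared-12-mer screen (≥ 3 exact 12-mers) gates the alignment — a
seed-and-extend heuristic; pairs at these thresholds share many exact
12-mers with overwhelming probability. Clusters with S:I above the death
threshold (default 3) are high-death; clusters with I = 0 but S > 0 count as
high-death (infinite ratio) rather than being dropped, which would bias the
high-death fraction downward; clusters with neither I nor S are excluded
from the denominator.

## What the synthetic experiments do and do not show

The generator produces compartment contrasts, Hi-C bumps, LTR-pair
divergences and I/S/T mixtures with known truth, so the tests are
parameter-recovery experiments: caller accuracy within ±1 bin, dating
medians within 15% at the 0.7-MYA regime and order preservation across
0.5/1/2 MYA, null-calibrated p-values, exact classifier rules. They do not
show performance on real genomes: real TE landscapes have nested/fragmented
insertions, indels, non-stationary base composition and assembly artifacts
that the generator deliberately omits.

For the same reason, the genome-scale figures of the reference case — e.g.
3,312 centromeric LINE1 (15.0%), filtered S:I = 1.53, 18.66% high-death
families, centromeric insertion-time medians of 0.67/0.66/1.36 MYA — depend
on that specific 470-Mb assembly and its annotations and are **not
reproduced** by this package's desk-scale simulations; they are covered
instead by the property-based recovery experiments above, which check the
estimators that produced such figures rather than the figures themselves.
The published per-chromosome centromere table *is* shipped as a regression
fixture: spans, the 23-Mb total, the 4.9% genome fraction, all 15 karyotype
terms and the formula 2n = 30 = 22m + 4sm + 4st are recomputed exactly.

One published inconsistency is handled explicitly: the reported filtered
ratios 1.53 (S:I) and 4.98 (T:I) cannot sum to the reported 5.50 for
(S+T):I under any single filter. The package always reports the
componentwise-consistent (S+T):I and leaves variant filters to the caller.

## Numerical choices and degenerate inputs

- Coordinates are 1-based inclusive in memory; only the BED writer/reader
  converts to 0-based half-open.
- Coordinate-ascent ties break toward the lowest bin index; pruning ties
  toward the lexicographically smallest node pair; cluster ids are numbered
  by smallest member key — all outputs are deterministic given seeds.
- Maps with a chromosome pair lacking trans contacts warn and skip
  normalization for that pair; calling requires at least two chromosomes.
- A uniform density track (no enrichment anywhere near the point) yields a
  flagged empty region, which downstream stages carry as "NA" rather than
  inventing boundaries.
- Degenerate rank-sum inputs (all values identical) return p = 1 with a
  degenerate flag.

## Default problem sizes

The shipped demo and test configurations use 3–5 chromosomes of 2–5 Mb at
100-kb bins, 40–300 LTR loci, and networks of ≤ 60 nodes — sizes chosen so
each stage completes in seconds while leaving every estimator's statistical
behavior measurable. All are plain config parameters; nothing in the code
assumes the toy scale.
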