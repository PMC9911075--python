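# Methods

## The model

Two members a, b of a pedigree are observed at two autosomal loci L1, L2
with recombination fraction ρ ∈ [0, 1/2], assumed equal in the two sexes.
Alleles are *identical by descent* (IBD) when they descend from one
ancestral allele within the pedigree.  The quantities computed are joint
distributions of IBD configurations at the two loci:

* **φ₁₁(ρ)** — the two-locus kinship: the probability that a random gamete
  from a and a random gamete from b carry IBD alleles at both loci.  It
  obeys φ₁₁(0) = φ and φ₁₁(1/2) = φ², where φ is the single-locus kinship.
* **K(ρ) = (κᵢⱼ)** — for a pair in which neither individual is inbred, the
  3×3 matrix of probabilities of sharing exactly i alleles IBD at L1 and j
  at L2.  Row and column sums are the single-locus κ = (κ₀, κ₁, κ₂); K(0)
  is diagonal and K(1/2) is the outer product κκᵀ.
* **Phased components** — κ₁₁ splits into cis/cis, cis/trans, trans/cis and
  trans/trans parts according to whether the IBD alleles at the two loci lie
  on the same haplotype within a and within b; κ₂₁, κ₁₂ and κ₂₂ each split
  into a haplotype-preserving (h) and a recombinant (r) part.  Relationships
  with identical K can differ in phase (parent–offspring versus half sibs
  with a completely inbred shared parent), which is what makes them
  distinguishable through a common child.
* **D(ρ) = (Δᵢⱼ)** — for arbitrary (possibly inbred) pairs, the 9×9 matrix
  of joint probabilities over Jacquard's condensed identity states S1..S9.
  Row and column sums are the single-locus Δ; D(0) is diagonal, D(1/2) an
  outer product.

## The recursion

Everything reduces to *generalized two-locus kinship coefficients*
Φ(G1 ⋈ G2): the probability that sampled gametes realize a prescribed IBD
partition (blocks) at each locus.  Gametes are identified by labels scoped
to the emitting individual; a label appearing at both loci means "the same
emitted gamete observed twice", which is where ρ enters.

The evaluator pivots on the youngest nonfounder present and replaces each of
its gametes by parental-origin gametes: a gamete observed at both loci stays
on one parental haplotype with probability (1−ρ)/2 per haplotype and
switches haplotypes (recombines) with probability ρ/2 per ordered choice; a
gamete observed at one locus picks either haplotype with probability 1/2.
All gametes of the pivot draw on the same two parental gametes — the pivot's
own haplotypes — which are two distinct gametes even under selfing.  A
subtle and essential point: a pattern may refer to "the gamete x received
from its father" *before* x is eliminated (this happens for every direct
relationship, where one target individual is a parent of gametes in the
pattern).  Such constitutive references carry semantic labels and unify with
the gametes introduced when x is pivoted; treating them as independent
meioses produces wrong answers precisely for direct relationships.

At the founder boundary each remaining gamete resolves into one of the
founder's two haplotypes with the same branching (founders recombine like
everyone else), after which blocks are constraints on fixed ancestral
alleles.  Since a block spanning two distinct founders is already screened
out as a structural zero, the boundary probability factorizes over founders,
which keeps deep pedigrees cheap.  A completely inbred founder (f = 1)
carries a single allele class.  Partial founder inbreeding (0 < f < 1) is
honored at a single locus as IBD/non-IBD factors f and 1−f, but makes joint
two-locus probabilities ill-defined; every two-locus entry point rejects it
with a dedicated error.

Memoization keys are canonical forms invariant under block order,
within-block order and consistent renaming of free gamete labels (semantic
labels are kept verbatim).  Canonicalization sorts labels by an
isomorphism-invariant signature and resolves ties by minimizing over the
residual permutations, so key equality coincides exactly with pattern
isomorphism.  The memo is per (pedigree, ρ); sweeping ρ (as the quadrature
does) builds one small cache per node.

Arithmetic is generic: passing ρ as `fractions.Fraction` evaluates every
coefficient as an exact rational, which the polynomial-recovery utility uses
to reconstruct closed forms by interpolation (Newton form, exact
verification at two extra nodes).

## Assembly of the user-facing matrices

* Unilineal pairs (κ₂ = 0): κ₁₁ comes from the balanced pattern
  H* = {[a¹,a²,b¹,b²]} ⋈ {[a¹,b¹],[a²],[b²]}, whose probability equals
  (ρ̄²ρ²/16)·κ₁₁ under every phase, and K follows from the marginal
  constraints.  ρ = 0 is handled by the closed form κ₁₁(0) = κ₁.
* Bilineal pairs: the 7×7 grid Φ(J_r ⋈ J_s) over the parental-gamete
  patterns of the noninbred detailed states (r, s ∈ {9..15}), summed over
  the index sets B₀ = {15}, B₁ = {10,11,13,14}, B₂ = {9,12}; the same grid
  refines into the ten phased components.
* General pairs: the full grid over J₁..J₁₅ aggregated by the condensed
  index sets C₁..C₉.  Cells in row 8 and column 8 of D — the most expensive
  ones, with |C₈| = 4 — are recovered from the single-locus row/column sums
  instead: first Δᵢ₈ = Δᵢ − Σ_{j≠8} Δᵢⱼ for i ≠ 8, then Δ₈ⱼ by column sums.
  This leaves 121 of the 225 grid terms for recursive evaluation.
  Founder targets are first given two fresh unrelated parents, which leaves
  all existing coefficients unchanged; a completely inbred founder cannot be
  extended this way and is rejected as an identity target.

Locus-exchange symmetry Φ(J_r ⋈ J_s) = Φ(J_s ⋈ J_r) and the symmetries
κᵢⱼ = κⱼᵢ, κ₁₂• = κ₂₁• are used to compute each unordered pair once.

## Applications

* **Expected likelihood ratio.**  For two markers with n₁ and n₂ equally
  frequent alleles, E[LR] under hypothesized matrix K and true matrix K′ is
  the bilinear form Σ κᵢⱼ κ′ᵢ′ⱼ′ M⁽¹⁾ᵢᵢ′ M⁽²⁾ⱼⱼ′ with the single-marker
  kernel M having first row/column 1, M₁₁ = (n+3)/4, M₁₂ = (n+1)/2,
  M₂₂ = n(n+1)/2.  It equals 1 when the true relationship is "unrelated"
  and factorizes into single-marker products at ρ = 1/2.
* **Realized relatedness.**  With kⱼ the realized genome fraction in IBD
  state j on a chromosome of length L Morgan, Var(kⱼ) =
  (2/L²)∫₀ᴸ (L−d)·κⱼⱼ(ρ(d)) dd − κⱼ², with ρ(d) = (1−e^{−2d})/2 (Haldane,
  no interference).  The integral uses fixed-order Gauss–Legendre
  quadrature, 64 nodes by default (doubling changes the half-sib value by
  < 1e−15; the convergence test asserts < 1e−6), with κⱼⱼ cached per node.
  Chromosomes combine with squared length weights; cross-chromosome
  covariance vanishes because κⱼⱼ(1/2) = κⱼ².  Only noninbred pairs are
  exposed; the analogous variance over S1..S9 for inbred pairs is a
  documented extension point.
* **IBD correlation.**  The correlation of the allele-sharing proportions
  at the two loci: with π = κ₁/2 + κ₂,
  corr = (Σ (i/2)(j/2) κᵢⱼ − π²) / (Σ (i/2)² κᵢ − π²).  It is 1 at ρ = 0,
  0 at ρ = 1/2, and undefined for zero-variance relationships such as
  parent–offspring (explicit error).  This convention does not attempt to
  reproduce the integer-coefficient tables of the older path-counting
  literature, whose normalization differs; only the qualitative behaviour
  is asserted in tests.

## The gene-drop oracle

The simulator realizes the defining probability model with no code shared
with the recursion: founders get unique ancestral allele labels (one class
when completely inbred), each meiosis picks a haplotype at L1 uniformly and
switches at L2 with probability ρ, and the pair's detailed/condensed states
are tallied per replicate.  It emulates exactly the two-point, no-
interference meiosis model under which the coefficients are defined — it
does not model crossover interference, mutation, genotyping error or
sex-specific maps, so agreement says nothing about those aspects of real
data.  Test assertions use 200 000 replicates with fixed seeds and a
4-standard-error band (binomial SE per cell; exact-zero cells must be hit
exactly).  A separate continuous-genome simulator realizes half-sib sharing
fractions along a chromosome as a rate-2 telegraph process (the union of two
Poisson crossover processes) and validates the realized-relatedness
variance; 50 000 chromosomes, moment-based SE of the sample variance.

## Fixture conventions

The half-sib pedigree uses ids 1..5 with shared parent 2 and children 4, 5.
Other fixtures follow field conventions where a convention exists: quadruple
half first cousins have four founders and four parents forming four half-sib
links; "HS + HSC" makes the pair half sibs whose unshared parents are half
first cousins; double second cousins (type A) make both the fathers and the
mothers first cousins through two unrelated families.  `cousins(p, q,
half)` descends p and q generations from a (half-)sib pair, covering
uncle–nephew (0, 1), great-uncle (0, 2) and ordinary cousins.  Internal ids
of these constructions are this package's own convention.  The pair of the
"full sibs of half-sib parents" fixture is itself inbred (f = 1/16), so κ
matrices are undefined for it and tests exercise it through φ₁₁ and D.

## Numerical choices and limitations

Probabilities are computed in double precision by default; all headline
identities hold to ≤ 1e−10 on the fixture suite, and the exact-rational mode
removes rounding entirely where closed forms are recovered.  Entries of D
that come out as tiny negatives from the row/column-8 recovery (below 1e−14)
are clamped to zero.  Degenerate inputs are defined rather than accidental:
a = b gives κ₂₂ ≡ 1 (and is rejected by the identity-matrix routine, which
addresses four distinct parental gametes); unconnected pairs reduce to the
unrelated case; selfing is supported throughout (the two gametes forming a
selfed individual are distinct).  X-chromosomal coefficients, more than two
loci, and sex-specific recombination are out of scope.  Test problem sizes
(pedigrees up to 18 members, one generation of sib mating for the inbred
9×9 case) were chosen so the full suite exercises every code path in well
under a minute of engine time; the recursion itself handles deeper
pedigrees, with cost growing with the number of inbreeding loops rather
than pedigree size.
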