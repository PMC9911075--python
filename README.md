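# ibd2loc

Exact two-locus identity-by-descent (IBD) coefficients in arbitrary
pedigrees — including inbred, selfed and founder-inbred ones — plus the
forensic and realized-relatedness applications built on them.

## The problem

Two relatives share alleles *identical by descent* at a locus according to
well-known single-locus coefficients: the kinship φ, the IBD triple
κ = (κ₀, κ₁, κ₂) of a noninbred pair, and Jacquard's nine condensed identity
coefficients Δ₁..Δ₉ for general pairs.  At **two linked loci** with
recombination fraction ρ, the joint distribution of IBD states is what
matters for linkage analysis, forensic kinship testing with linked markers,
and the variance of realized relatedness — but closed forms exist only for a
handful of simple relationships, obtained historically by laborious path
counting.

`ibd2loc` computes these joint distributions exactly in any pedigree:

* the two-locus kinship φ₁₁(ρ) = P(random gametes from a and b carry IBD
  alleles at both loci), with φ₁₁(0) = φ and φ₁₁(1/2) = φ²;
* the 3×3 matrix K(ρ) = (κᵢⱼ(ρ)) for noninbred pairs, with its full phased
  refinement (cis/trans components of κ₁₁, haplotype/recombinant components
  of κ₂₁, κ₁₂, κ₂₂);
* the 9×9 matrix D(ρ) = (Δᵢⱼ(ρ)) over condensed identity states for
  arbitrary pairs.

The engine is a memoized recursion over *generalized two-locus kinship
coefficients* Φ(G1 ⋈ G2) — probabilities of prescribed IBD partitions of
sampled gametes at the two loci — which peels the youngest nonfounder off
the pattern with recombination-aware transmission probabilities until only
founder alleles remain.  Coefficient matrices are assembled from these via
parental-gamete patterns; see `docs/methods.md` for the model, the
recursion, and every numerical choice.  All of it can run in exact rational
arithmetic, so printed closed-form polynomials in ρ are recovered digit for
digit by interpolation.

## Worked example

Half siblings (ids 4 and 5, shared parent 2) at ρ = 0.25:

```sh
$ ibd2loc ibd2 --fixture half_sibs --rho 0.25
        ibd0    ibd1    ibd2
ibd0    0.3125  0.1875  0
ibd1    0.1875  0.3125  0
ibd2    0       0       0
```

κ₁₁ = 0.3125 is the probability of sharing one allele IBD at *both* loci —
the matrix realizes the closed form κ₁₁ = (ρ² + ρ̄²)/2 with marginals
(0.5, 0.5, 0).  Now make the shared parent completely inbred
(`founderInbreeding`-style annotation):

```sh
$ ibd2loc phi11 --fixture half_sibs --founder-inbreeding 2=1.0 --rho 0.25
0.140625
$ ibd2loc ibd2 --fixture half_sibs --founder-inbreeding 2=1.0 --rho 0.25 --phased
k11cc   1
k11ct   0
...
```

The two-locus kinship 0.140625 = ρ̄²/4, and the phased decomposition shows
*why* this relationship differs from parent–offspring even though both have
the constant matrix κ₁₁ ≡ 1: here the IBD alleles are always in cis
(κ₁₁ᶜᶜ = 1), whereas parent–offspring gives (κ₁₁ᶜᶜ, κ₁₁ᵗᶜ) = (ρ̄, ρ).

Exact closed-form recovery — φ₁₁(ρ) for two full siblings whose parents are
half siblings, a relationship beyond pairwise-ancestor methods:

```sh
$ ibd2loc polyfit --fixture sibs_of_halfsib_parents --degree 6
(5/16) + (-5/4)*rho^1 + (177/64)*rho^2 + (-97/32)*rho^3 + (59/32)*rho^4 + (-5/8)*rho^5 + (1/8)*rho^6
```

i.e. 64·φ₁₁ = 8ρ⁶ − 40ρ⁵ + 118ρ⁴ − 194ρ³ + 177ρ² − 80ρ + 20, with constant
term 64·φ = 20.  The same machinery yields the full 9×9 identity matrix for
inbred pairs (`ibd2loc identity2 --fixture sib_mating_sibs --rho 0.25`),
expected likelihood ratios for linked forensic markers (`ibd2loc elr`), and
realized-relatedness variances (`ibd2loc varibd`).

From Python:

```python
import ibd2loc as ib

ped, (a, b) = ib.make_fixture("quad_half_first_cousins")
K = ib.two_locus_ibd(ped, a, b, rho=0.1)          # 3x3 kappa matrix
var = ib.var_realized_k(ped, a, b, j=1, genome=2.5)  # 2.5-Morgan chromosome
sim = ib.gene_drop(ped, a, b, rho=0.1, n=200_000, seed=7)  # MC cross-check
```

Pedigrees also load from PLINK-style text (`id father mother [sex]`, 0 or *
for missing) via `ib.load_pedigree`.

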