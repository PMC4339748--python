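# Methods

`parclipper` identifies RNA-binding-protein (RBP) interaction sites in
PAR-CLIP sequencing data. PAR-CLIP cultures cells with a photoreactive
ribonucleoside (4-thiouridine, 4SU, or 6-thioguanosine, 6SG); UV crosslinking
at sites of protein contact leaves a diagnostic imprint in the sequenced
cDNA — T→C transitions for 4SU, G→A for 6SG. The analytical problem is that
observed transitions also arise from SNPs, sequencing errors and RNA
contaminants, and that the read coverage around true binding sites is noisy
enough that naive peak calling either merges adjacent sites or drops weak
ones. The package addresses both problems with (i) a Bayesian mixture model
over relative substitution frequencies, (ii) a rank-based boundary search
(Mini-Rank Norm, MRN), and (iii) empirical FDR bounds from matched RNA-Seq.

## Transition model

At a genomic position covered by `z` aligned reads with `y` reads showing the
expected transition, the relative substitution frequency (RSF) is `x = y/z`.
The generative model is a three-variable chain (Θ, X, Y):

* Θ ∈ {1, 2} is the transition source — non-experimental (Θ=1, prior
  probability λ) or crosslink-induced (Θ=2);
* X | Θ=θ ~ f_θ, a component density on (0, 1];
* Y | X=x ~ Binomial(z, x).

The joint factorizes as p(Y, X, Θ) = p(Y|X) p(X|Θ) p(Θ), so the source
posterior marginalizes the unobserved RSF out:

    p(Θ=θ | Y) ∝ p(θ) ∫ Binom(Y; z, x) f_θ(x) dx

Each transition is scored with the log-odds log(p(Θ=2|Y)/p(Θ=1|Y)); a cluster
is scored with the *relative log-odds*: the sum of member log-odds divided by
the number of crosslinkable bases (T in transcript orientation) in the
cluster sequence, so that T-poor and T-rich sites are comparable.

### Density estimation and mixing weight

The component densities are non-parametric: histograms of observed RSFs on a
fixed grid over (0, 1] (default step 0.001), smoothed with a
boundary-reflected Gaussian kernel. The non-experimental component f1 is
estimated from the substitutions of every type *other* than the expected one
(11 ordered base pairs, pooled) — none of these can be crosslink-induced, and
under the error/SNP processes their RSF distribution is exchangeable with the
non-experimental part of the expected-transition RSFs.

The default kernel bandwidth is 0.02. Observed RSFs live on the lattice
{1/z, 2/z, …}; at the default coverage cutoff the lattice spacing is up to
0.05, and a bandwidth below the typical spacing (~0.02–0.04 at 25–55×
coverage) leaves the estimated densities as disjoint spike combs whose
pointwise ratio is dominated by which lattice a site happens to sit on. The
bandwidth is exposed as a parameter for data at very different coverage.

The mixing weight is the largest value keeping the experimental component
non-negative, λ = min fhat(x)/f1(x) with fhat the density of
expected-transition RSFs and f2 = (fhat − λ f1)/(1 − λ) (clamped at zero and
renormalized). The minimum is taken over f1's *data-supported* region: grid
points inside the observed background RSF range with f1 ≥ 0.1·max(f1).
Outside that region both numerator and denominator are kernel tails carrying
no information, and the raw minimum collapses toward zero; the 0.1 floor is
a numerical safeguard, not a tuning knob (the estimate is insensitive to it
within roughly a factor of three either way).

### Classification and scoring

The x-conditional responsibility p(Θ=2|x) = (1−λ)f2(x) / (λf1(x)+(1−λ)f2(x))
is evaluated on the grid; grid points where both densities vanish carry no
data and are excluded. For a posterior cutoff δ ∈ (0.5, 1) the RSF support
[a, b] is the smallest interval containing all grid points with
p(Θ=2|x) ≥ δ. High-confidence transitions (hcTs) are the observed sites with
coverage ≥ c (default c = 20, the same cutoff used for model fitting) and
RSF inside [a, b]. Classification uses the x-conditional posterior (it is
what the support interval means); ranking uses the Y-marginalized posterior
and log-odds, which integrate coverage information — a 3/10 site and a
30/100 site share an RSF but not a weight of evidence.

Numerical choices: posteriors are computed through the odds ratio
((1−λ)/λ)·(f2/f1 or I2/I1) so that identical densities return exactly the
prior; integrals use the trapezoidal rule on the model grid (the marginal
posterior changes by <1e−6 when the step is halved, and approaches the
conditional posterior as z→∞); infinite log-odds (one integral numerically
zero) are capped at ±700 by default.

## Mini-Rank Norm boundary search

Let C(i) be strand-specific coverage and S(i)/E(i) the number of alignments
whose first/last covered base is i (the positive/negative coverage
differences). The expected coverage of an RBP binding site is a sharply
peaked rectangle: most reads start just 5' and end just 3' of the protected
footprint. For each hcT:

1. **Window.** The largest window of consecutive non-zero coverage
   containing the hcT.
2. **Noise threshold.** A sample of N hcTs (default 1000; all of them when
   fewer exist) contributes windows of ±n positions (default 25). Within
   each window all S and E values are divided by the single window maximum
   over both tracks; the pooled non-zero ratios D⁺ are fitted with a
   two-component unequal-variance Gaussian mixture by EM (initialized at the
   25th/75th percentiles, tolerance 1e−8, ≤500 iterations, variance floor
   1e−6). The crossover coefficient c is the smallest observed ratio whose
   responsibility favours the sharp-jump component. Per window the
   side-specific thresholds are δ_s = max(1, ⌈c·max S(w)⌉) and
   δ_e = max(1, ⌈c·max E(w)⌉) — the combination of c with the window maxima
   is a design choice; scaling each side by its own dynamic range keeps the
   filter meaningful when start and end signals differ. A fit is rejected as
   degenerate when the component means are closer than the larger standard
   deviation. Alternatively a global threshold ⌊0.1·max(m1, m2)⌋ (m1 =
   coverage cutoff, m2 = modal coverage at hcTs; clamped to ≥1) can be used.
3. **Candidates.** Every suprathreshold start at or 5' of the hcT crossed
   with every suprathreshold end at or 3' of it; if a side has no
   suprathreshold position the window edge is used, so every hcT yields at
   least one candidate (no hcT is ever silently dropped).
4. **Rank vectors.** Candidates are mapped to (r_s, r_e, r_w): start
   positions ranked by decreasing S (ties toward 5'), end positions by
   decreasing E (ties toward 3'), widths ranked increasing with ties sharing
   the minimum rank. All ranks are 0-based, so the ideal rectangle is
   O = (0, 0, 0).
5. **Selection.** The candidate minimizing ‖r‖₂ wins; ties go to the
   shortest candidate, remaining ties to the smallest genomic start
   (determinism). Tie directions are applied in genomic coordinates on both
   strands; a strand-reflected convention would only permute exact ties.

hcTs whose searches resolve to the identical interval merge into one
cluster; overlapping-but-distinct intervals are reported separately — that
separation is precisely what resolves adjacent binding sites. Clusters are
ranked by decreasing relative log-odds; a cluster whose sequence contains no
crosslinkable base keeps an undefined score and sorts last.

## FDR from matched RNA-Seq

Total RNA-Seq from the same cells shares SNPs and recurrent sequencing
artifacts with the PAR-CLIP library but carries no crosslink-induced
transitions, so transitions that recur in RNA-Seq indicate false positives.

*Site level.* Over positions covered ≥ c in both data sets and showing ≥1
expected-type transition in PAR-CLIP, the RSF interval (0, 1] is split into
ten equal bins by PAR-CLIP RSF. The upper bound counts as FP every position
with ≥1 RNA-Seq transition of the expected type regardless of its RSF; the
lower bound only positions whose RNA-Seq RSF falls in the same bin. Bins
without members are reported as missing.

*Cluster level.* Clusters are ranked by relative log-odds; for each top-n
cut, the conservative FDR is the fraction of clusters with ≥1 member hcT
whose RNA-Seq RSF lies inside the model support [a, b]; the relaxed FDR
requires every member with RNA-Seq evidence to lie inside. An hcT without
RNA-Seq coverage (default: ≥1 read, configurable) contributes no evidence
and never creates an FP. Unstranded RNA-Seq libraries can be pooled across
strands per position.

## miRNA seed enrichment

For Argonaute-type data, each cluster set is scanned for the reverse
complement of every miRNA seed (positions 2–8, a 7-mer). The observed count
(per kb of cluster sequence) is compared with the mean count obtained from
dinucleotide-shuffled copies of the miRNA (default 10⁴ shuffles). The
shuffle is an Altschul–Erickson Eulerian-path permutation and preserves the
dinucleotide multiset exactly, controlling the background for seed length
and composition. Per-kb normalization cancels in the ratio but keeps the
observed and background columns individually interpretable.

## Synthetic data generator

The generator emulates the features of PAR-CLIP data the method is built
around, with defaults chosen to be realistic at desk scale:

* 200 binding sites (width 30) centred in 150-nt transcripts laid out with
  ≥100-nt gaps on a 150-kb random genome (GC 0.45); per-site crosslink
  conversion probability Uniform(0.25, 0.6) applied per read to every
  transcript-orientation T in the site; rectangular pile-ups of 50 reads of
  length 36, each fully containing the site.
* Low-level PAR-CLIP background (3×) over site transcripts, plus 30 abundant
  background transcripts (300 nt, 25×) representing non-specific RNA in the
  immunoprecipitate.
* 20 SNPs (fixed alternate allele, ref→alt uniform over the 12 ordered
  pairs) and sequencing errors: i.i.d. per-base errors at 0.002 plus error
  hotspots at 1% of transcript positions (per-read probability
  Uniform(0.02, 0.10) toward a fixed alternate base). SNPs and hotspots are
  shared with the matched RNA-Seq simulation (uniform 30× over all
  transcripts, no crosslink conversions); i.i.d. errors are drawn
  independently per experiment.

Reads are emitted pre-aligned at their true coordinates (alignment is
upstream of this package's scope), coordinate-sorted and indexed. Everything
is driven by a single seed.

What the generator does **not** emulate: mappability and alignment error,
PCR duplicates, fragment-length and RNA-structure effects, coverage
heterogeneity within a transcript, dominant single crosslink positions
within a site, and contaminant transcripts absent from RNA-Seq. Passing the
test suite therefore demonstrates correctness of the algorithms under the
stated data model, not end-to-end performance on a real library.

## Problem sizes used in tests and the reproduction script

The default simulation (200 sites, ~50k reads total across both libraries)
runs the full pipeline in a few seconds. The boundary-search oracle check
uses 600 random windows of length ≤60; the shuffle invariance check 1000
random sequences; seed enrichment uses a 1.6-Mb synthetic cluster corpus
with 1000 shuffles (the library default is 10⁴). These sizes give stable
statistics while keeping the whole suite near ten seconds.

## Known limitations

* λ is identified by a minimum statistic and inherits a small downward bias
  from density-estimation noise; on the default simulation λ̂ tracks the
  planted value within ~0.01 (both are a few percent).
* The exchangeability assumption behind f1 is imperfect wherever coverage
  classes and base composition interact (e.g. every T inside a true binding
  site is signal, so the expected-transition background lacks mass exactly
  where other-type substitutions in peaks contribute to f1); the effect is a
  conservative (slightly low) λ.
* The RSF support is an interval by construction; a genuinely multimodal
  experimental component would be bracketed, not resolved.
* Cluster-level FDR treats member hcTs independently and ignores linkage
  between nearby positions on the same reads.
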