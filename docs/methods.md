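# Methods

## Problem and data model

A pooled scRNA-seq run mixes cells from k genetically distinct donors.
At V known biallelic SNPs, a counting tool (vartrix / cellSNP) reports
per barcode the reference and alternate read counts, giving two sparse
cells × variants matrices.  Real matrices are ~5% dense: a cell covers
only the variants its expressed transcripts happen to span, at a mean
depth of only a few reads.

Each donor is characterized by its vector of alt-allele dosages
g_v ∈ {0, 1, 2}; a cell from that donor draws its alt reads at a
covered site as

    a_v | n_v ~ Binomial(n_v, p_v),   p_v = g_v / 2  (up to error),

and a cross-donor doublet as the equal mixture p_v = (g_v + g'_v)/4 of
its two donors.  A cluster center is a vector of allele fractions
p ∈ [floor, 1−floor]^V; the log likelihood of a cell against a center
is the sum of the per-site binomial terms over the cell's covered
sites (a beta-binomial family with concentration `dispersion` is
available for overdispersed data).  The clustering distance is the
negated log likelihood plus `distance_epsilon` (default 1e−6), keeping
distances strictly positive so the K-harmonic-means objective — which
divides by powers of distances — is always defined.

Fractions are clamped into [`fraction_floor`, 1−`fraction_floor`]
(default 0.01) everywhere: a center may never assign probability zero
to an allele some cell carries.

## Pipeline

`demultiplex` runs five stages, all deterministic given the seed:

1. **10× merge initialization.**  Ten preliminary centers per expected
   donor, each seeded from a distinct uniformly sampled cell:
   add-one-smoothed fractions (a+1)/(n+2) at the cell's covered sites,
   the dataset-wide smoothed allele fraction elsewhere (that fill value
   is the natural answer to "what is a center's value in dimensions
   where the seeding cell has no data").  The closest pair under the
   coverage-weighted squared difference Σ_v w_v (a_v − b_v)², with w_v
   the total read count at variant v, is merged to its per-variant
   mean, repeatedly, until k centers remain.  Ties break to the lowest
   index pair, so the procedure is fully deterministic.

2. **Annealed K-harmonic-means.**  KHM minimizes Σ_i k / Σ_j d_ij^−p
   with soft memberships m_ij ∝ d_ij^−(p+2) and per-cell weights
   w_i = Σ_j d_ij^−(p+2) / (Σ_j d_ij^−p)², exponent p = 3 (see the
   next section for the baselining applied to the distances these
   forms are fed).  The temperature schedule starts at `t_start` = 5, decays by
   0.8 per step to 1, with 3 sweeps per temperature, then iterates at
   T = 1 until the relative loss change drops below 1e−6 (cap 200
   sweeps).

3. **Donor discovery by leave-one-out reassignment.**  Sequential
   iterated-conditional-modes on the binomial mixture: each cluster
   keeps per-variant summed alt/total reads; its profile is the
   posterior mean under a Beta prior of strength 2 pseudo-reads
   anchored at the pooled per-variant allele fraction.  Cells are
   visited in seeded random order; the visited cell is removed from
   its cluster's sufficient statistics, scored against all k cluster
   profiles, and moved to the argmax.  Sweeps stop when a full pass
   moves no cell (cap 50).  The stage starts from the hard assignment
   of stage 2.

4. **Polish and refinement.**  The discovered profiles are polished by
   a second annealed KHM fit, then refined: clusters are scored by
   size and mean member distance (robust z-scores using median and
   MAD·1.4826); flagged high-loss clusters that still hold many cells
   (the signature of two donors sharing a center) are split two ways
   by a leave-one-out reassignment restricted to their members, the
   halves replacing the source and a flagged starved slot; flagged
   slots with no split partner are reseeded by the 10× merge strategy
   from the worst-fit quartile of cells (ten preliminary centers per
   slot, merged down).  Half of the healthy clusters (random,
   resampled each round) are locked — their fraction rows pass through
   the refit bit-identical — and KHM is rerun.  A round is accepted
   only if the total best-cluster distance improves; otherwise the
   previous state is restored and refinement stops.  At most 10
   rounds.

5. **Calling.**  For every cell the best singlet log likelihood L_s
   over k clusters competes with the best doublet log likelihood L_d
   over all k(k−1)/2 pair centers (p_a + p_b)/2 through
   P(singlet) = (1−π) e^{L_s} / [(1−π) e^{L_s} + π e^{L_d}], computed
   in log space, with doublet prior π (default 0.08).  Cells covering
   fewer than `min_coverage` = 10 variants are reported unassigned.
   Before scoring, centers are snapped to diploid genotype levels
   {e, 0.5, 1−e} (e = 0.02; thresholds 0.2 / 0.8, the same used for
   the cluster-genotype VCF): donors are diploid, and fitted fractions
   are slightly shrunk toward the middle by smoothing and
   soft-membership mixing, which flatters the singlet model exactly
   when scoring doublets.  On a 4-donor mixture with 10% doublets at
   2,000 variants, discretized calling recovers doublets with
   recall and specificity 1.00 at ≥ 20 covered sites, versus ~0.82
   recall with continuous centers.

## Why the KHM sweeps baseline their distances

The textbook KHM forms act on distance *ratios*: memberships
m_ij ∝ d'_ij^−(p+2), weights w_i = Σ_j d'_ij^−(p+2) / (Σ_j d'_ij^−p)²,
annealed as d' = d^{1/T}.  Log-likelihood distances, however, are sums
over a cell's ~100 covered sites, so the genotype evidence lives in
their *differences* (a few to tens of nats) while their ratios stay
within a couple of percent of 1.  Fed raw distances, the memberships
are nearly uniform at any realistic k, every center is pulled to the
pooled marginal, and the symmetric collapsed state is stable — in our
experiments a planted perfect 64-cluster solution decays to noise
within ~10 sweeps, and w_i ∝ d^(p−2) additionally hands the update to
the deepest, worst-fit cells.

`anneal_fit` therefore feeds the membership operation per-cell excess
distances d_ij − min_j d_ij + c·T with offset c = `baseline_offset`
(default 1.0 nat), and uses uniform cell weights at magnitude k.
Since (1 + Δ/c)^−(p+2) ≈ exp(−(p+2)Δ/c) for Δ ≲ c, the power-law
membership then behaves like an exponential posterior with temperature
c·T/(p+2), the annealing temperature scales the softness, and a
perfect high-k solution is a stable fixed point.  The weight magnitude
k keeps the add-one smoothing in the center update honest: with
unit-scale soft weights the effective evidence per cluster-variant can
drop to a few reads and the +1/+2 prior drags every center toward 0.5.
Setting `baseline_offset=None` restores the textbook composition,
which remains adequate for small k.

Even baselined, center sweeps only *preserve* structure; they do not
*find* it from a weak start, because a cell inside a cluster
dominates that cluster's profile at exactly the sites the cell covers
(a self-fit advantage of roughly 0.2 nats per covered site, ~20 nats
per cell) and is anchored wherever it happens to sit.  The
leave-one-out stage removes that anchor: scored against profiles built
from *other* cells only, two or three same-donor cells that land in
the same cluster by chance already out-pull every alternative for the
rest of their donor (measured critical nucleus 2–3 cells at 64-donor
scale), and a random or collapsed partition self-organizes into donor
clusters within tens of sweeps.  This stage is what carries the
pipeline from ~16 donors to 64.

## Synthetic mixtures

The simulator draws population alt-allele frequencies
f_v ~ Beta(1, 3) (rare-skewed), donor dosages Binomial(2, f_v)
(Hardy–Weinberg), uniform donor proportions unless specified, doublet
barcodes at the configured rate with a second distinct donor, coverage
as independent Bernoulli(0.05) per cell-variant pair, total reads
1 + Poisson(depth_mean − 1) with depth_mean = 2, and alt reads
binomial at the dosage-implied fraction perturbed by a symmetric 0.5%
base miscall rate.  Defaults emulate the sparse, low-depth regime of
real SNP count matrices (~5% density).

Not modeled: gene-expression structure in coverage (real coverage is
concentrated in highly expressed genes and correlated across cells),
ambient RNA, UMI duplication, unequal RNA contribution within a
doublet, and genotyping errors in the input VCF.  Passing tests
therefore demonstrate correctness of the algorithms under the stated
statistical model, not performance on any particular real dataset;
coverage correlation in real data reduces the effective number of
informative sites per cell pair relative to the independence
assumption.

## Evaluation metrics

Adjusted Rand Index in the Hubert–Arabie form, computed on true
singlets (optionally intersected with cells the pipeline also called
singlet); the degenerate case where expected and maximum index
coincide is reported as 1.0 with a warning.  Incorrectly merged
clusters: map each true donor to the predicted cluster holding the
plurality of its cells (ties to the lowest id) and count predicted
clusters that are modal for two or more donors.  A secondary
diagnostic counts split donors — donors with under 60% of their cells
in their modal cluster — and doublet precision/recall complete the
report.

## Problem sizes and determinism

The shipped test and acceptance configurations use 64 donors × 50
cells at 2,000 variants (the high-donor benchmark), 18 donors × 2,400
cells at 1,500 variants with a 0.84% minority donor (unbalanced
benchmark), and 4–8 donors for unit-level checks; a 64-donor run
completes in well under a minute on one core.  Every stochastic step —
cell seeding, lock sampling, visit order, simulation — derives from
explicit integer seeds through numpy Generators, so rerunning any
entry point with the same inputs and seed reproduces outputs
byte-for-byte.

## Known limitations

* k is an input; the pipeline does not estimate the donor count.
* Ambient RNA is not modeled; heavily contaminated data will shrink
  observed allele fractions toward the pool mean and erode doublet
  margins.
* The doublet model assumes equal RNA contribution from both cells.
* Same-donor doublets are indistinguishable by genotype and are not
  modeled.
* The leave-one-out discovery stage visits cells sequentially; its
  runtime is linear in cells × sweeps but is implemented in Python
  loops over numpy slices, so very large runs (≫10⁵ cells) would
  benefit from a compiled inner loop.
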