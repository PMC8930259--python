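# Methods

## The optimization model

Both segmenters are instances of clonal selection: a population of
fixed-length bitstring *antibodies* evolves against a single *antigen*, the
segmentation objective. Each antibody encodes one or more gray values, 8 bits
per value, most-significant bit first, so the search space is exactly the
8-bit intensity scale the images live on.

Per generation the engine:

1. evaluates the antigen affinity of every antibody;
2. updates the *memory cell* — the best antibody ever evaluated — making the
   reported best monotone by construction;
3. (clusterer only) locally refines the memory cell and re-injects it if
   improved;
4. computes each antibody's *concentration* D_i = #{j : A(i,j) > λ}/N, the
   fraction of the population (self included) whose pairwise affinity with it
   exceeds the affinity constant λ, so D_i ∈ [1/N, 1];
5. forms the diversity-corrected fitness `affinity · exp(k·D_i)`, k < 0 —
   crowded antibodies are demoted, but antibodies of equal concentration keep
   their affinity ranking;
6. sorts by fitness (stable, ties by original index), keeps the top
   m = ⌈N/2⌉, and clones rank r (1-based) `max(1, round_half_up(Mc/r))`
   times;
7. crosses each clone, with probability Qc, with a freshly drawn random
   antibody: single-point crossover at a uniform cut in {0,…,L−1}, the clone
   taking the partner's suffix (cut 0 is a full replacement);
8. mutates each antibody with probability Qm by flipping exactly one
   uniformly chosen bit — never more, so mutants stay within Hamming
   distance 1;
9. re-evaluates the varied group and lets its champion update the memory
   cell;
10. builds the next population: the memory cell in slot 0, then the varied
    group with **duplicates suppressed** (first occurrence kept), the last
    N//5 slots renewed with fresh random antibodies, and any shortfall
    padded randomly.

Step 10 is the one place the engine goes beyond the minimal loop, and it is
deliberate. A plain truncation of the varied group fills the population with
copies of the top clone; single-bit mutation then cannot cross Hamming
cliffs of the binary code (127 ↔ 128 differ in all 8 bits), and the search
stalls on near-optimal plateaus. Duplicate suppression is the survivor-side
counterpart of the concentration penalty, and the random newcomer influx is
the standard birth step of clonal-selection algorithms; together they keep
exploration pressure up at no cost to the elitist guarantee, since the
memory cell is never discarded.

All randomness flows through one `numpy.random.Generator` seeded from
`ImmuneParams.seed`; every entry point is bit-exact reproducible.

### Pairwise affinities

* Thresholder: A(i,j) = 1/(1 + Hamming(i,j)). With the default λ = 0.95 only
  identical antibodies exceed λ, so concentration degenerates to a duplicate
  count — which is precisely the crowding signal wanted on an 8-bit space.
* Clusterer: A(i,j) = 1/(1 + s) with s the squared Euclidean distance
  between the decoded center vectors, position-wise. Again only identical
  decodings pass λ = 0.95.

## The two objectives

**Otsu thresholder.** Class 0 is intensity ≤ t, class 1 is > t (the target:
lesions are hyperintense on the FLAIR/DWI sequences this models). Affinity
is the raw between-class variance σ²_b(t) = V₀(w₀−V)² + V₁(w₁−V)², with an
empty class contributing 0 (its mean is defined as 0 and its proportion
vanishes). The variance is not rescaled to [0,1]: the exponential
concentration correction is multiplicative, hence scale-covariant, and
ranking is all that matters. Internally σ²_b is precomputed for all 256
thresholds from histogram cumulative sums — an exact lookup, identical
arithmetic to the scalar definition up to float reassociation. The same
table drives `exhaustive_otsu`, the brute-force oracle, which breaks
variance ties toward the smallest t; the immune run reports whatever code it
converged to, which on tied plateaus (e.g. a two-level image) may be any
maximizer.

**Immune/K-means clusterer.** J is the within-cluster sum of squared
intensity differences under nearest-center assignment, ties to the lowest
center index. Because the feature is scalar intensity, J and the Lloyd
updates are computed on the 256-bin histogram; this is exact, not an
approximation, and makes objective evaluation O(256·K). Lloyd's center
update is the rounded (half-up) mean of the assigned pixels; an empty
cluster keeps its previous center. Integer rounding means J can rise by at
most 1/4 per center per iteration, which is the K·0.25 slack the descent
property is asserted with. The hybrid step refines the elite every
generation (decode → Lloyd to convergence → re-encode, accepted only on
improvement), so the elite's J is monotone non-increasing.

## Termination

* Thresholder: stop when the memory-cell affinity has not changed for
  `stall_gens` consecutive generations (default 20), or at `maxgen`.
* Clusterer: J1 is recorded as the objective of the best antibody of the
  initial population, before any refinement. The run stops when the
  improvement |J1 − J*| (J* the current elite objective) has reached
  `j_tol_rel · J1` (default 10⁻³) **and** the elite objective has been flat
  for `stall_gens` generations, or at `maxgen`. Reading the improvement
  threshold alone literally ("stop once |J1 − J*| is small") would fire at
  generation 0, where J* = J1; conditioning it on a stabilized elite turns
  it into a usable convergence rule while keeping J1 as the reference point.
  When J1 = 0 the initial elite is already perfect and the stall clause
  alone ends the run.

## Parameter defaults

| parameter | thresholder | clusterer | meaning |
|---|---|---|---|
| popsize | 20 | 30 | antibodies per generation |
| maxgen | 200 | 300 | generation cap |
| Qc | 0.6 | 0.6 | crossover probability per clone |
| Qm | 0.06 | 0.06 | mutation probability per antibody |
| λ | 0.95 | 0.95 | concentration affinity constant (admissible range [0.9, 1]) |
| k | −0.8 | −0.8 | concentration penalty exponent |
| Mc | 10 | 10 | clone-count constant (rank r gets ≈ Mc/r clones) |
| stall_gens | 20 | 20 | flat-elite window for stopping |
| j_tol_rel | — | 10⁻³ | improvement threshold relative to J1 |

Qc/Qm defaults follow the parameter-declaration convention (0.6/0.06); an
alternative pairing (0.8/0.05) circulates for the same loop, and both are
reachable through `ImmuneParams`. λ sits mid-interval of its admissible
range; at any admissible value its effect here is the duplicate count, so
results are insensitive within [0.9, 1). K (number of clusters) defaults
to 4 — background, CSF-like, parenchyma-like and lesion-like classes of the
default phantom — and is a user parameter, bounded to [2, 16].

## Image conventions

Images are 2-D uint8 arrays, row-major, 0-based (row, col). Color inputs
collapse to BT.709 luminance (0.2126R + 0.7152G + 0.0722B). Inputs already
on the 8-bit scale keep their values exactly; 16-bit and float inputs are
min–max rescaled to [0,255] with half-up rounding. A strict min–max
`normalize_quantize` is exposed separately; it maps a constant image to
constant 0 rather than raising, keeping pipelines total on degenerate
fixtures. Quantization and all center rounding use round-half-up, fixed and
tested. Label images are written as 8-bit PNGs with values 0..K−1. Cluster
labels are the encoded center indices; for comparison against truth they
are relabeled by ascending center intensity (phantom class means are
strictly increasing), with greedy maximum-overlap matching available when
the predicted and truth class counts differ.

## The phantom generator

Phantoms stand in for clinical slices: nested concentric ellipses (slightly
wider than tall) assign classes 1..K−1 over a class-0 background, an
optional lesion disc is painted last, and pixel intensity is the class mean
plus zero-mean Gaussian noise, clipped to [0,255] and rounded. The default
study condition is 30/90/150/220 class means with σ = 8 gray levels —
well-separated tissue peaks (gap/σ = 7.5) of the kind a T2/FLAIR slice with
distinct CSF/parenchyma/lesion intensities presents.

What this emulates: multi-modal intensity histograms with known class
geometry, so thresholding, clustering and the volume-fraction metrics can
be validated against exact ground truth. What it does not: Rician magnitude
noise (Gaussian is used; at moderate SNR the two are close, and Gaussian
keeps the recovery analysis transparent), bias fields, partial-volume
voxels, anatomy, or 3-D structure. Passing the recovery tests therefore
demonstrates correctness of the optimizers and metrics on well-posed
intensity mixtures — not clinical performance.

The noiseless two-level fixture (`generate_bilevel`, exactly half the
pixels at 10 and half at 200) makes the Otsu objective hand-checkable:
σ²_b = 0.5·(10−105)² + 0.5·(200−105)² = 9025 at any threshold between the
levels.

## Problem sizes

The validation experiments use 64×64 images for the thresholder (50 random
images against the exhaustive oracle) and 32×32 four-class phantoms for the
clusterer (20 runs against the best of 50 seeded Lloyd restarts; 10 runs
for center/TPVF recovery). These sizes give every intensity class hundreds
of pixels — enough for stable class statistics — while keeping the full
suite fast enough to run on every change.

## Known limitations

* Both optimizers see only the intensity histogram; spatial context,
  multi-channel features and 3-D volumes are out of scope by design.
* The thresholder is strictly binary (no multilevel Otsu).
* On variance-tied plateaus the thresholder's reported t is
  seed-dependent (the attained variance is not).
* The stochastic guarantees are rates over seeded runs, not certificates;
  the exhaustive oracle exists precisely so the thresholder's gap can
  always be measured.
* The benchmark's "plain scan" arm is the deterministic exhaustive Otsu
  baseline, as a conventional non-iterative reference.
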