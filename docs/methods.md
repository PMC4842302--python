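# Methods

## Model

SEA treats the comparison of two ligand sets as a sequence-search-style
significance problem. The raw score `RS(A, B)` sums all cross-pair
Tanimoto coefficients at or above a cutoff TS; pairs below TS contribute
exactly zero. Against random sets, RS has mean `F_mean(s) = μs` and
standard deviation `F_sd(s) = φs^η` in the set-size product
`s = |A|·|B|`; the standardised score `z = (RS − μs)/(φs^η)` is referred
to the standard (zero-mean, unit-variance) Gumbel extreme-value
distribution, whose upper tail is

    p(z) = 1 − exp(x(z)),   x(z) = −exp(−(zπ/√6 + γ)),  γ = 0.577215665.

For z > 28 the direct form is numerically void (`x` underflows against
1), so the three-term Taylor expansion `−x − x²/2 − x³/6` is used; the
branches agree to better than 1e−6 relative at the switch, and in
practice to machine precision. `log10_p_value` evaluates the tail in log
space, so significance thresholds far below the smallest double (the
1e−80 regime used for target networks) remain exact; for z > 28 the
log-tail is linear in z with slope −π/(√6·ln 10).

The model is deliberately assumption-light: it does not require the
Gumbel to be the true law of RS for arbitrary fingerprints — TS is
*selected* as the threshold where the empirical background is closest to
Gumbel, which is what makes the P-values meaningful.

## Background fitting

Random background pairs are drawn as two **disjoint** subsets of the
fingerprint universe for every unordered pair of distinct sizes on the
grid (10–1000 step 10 by default: C(100,2) = 4950 pairs per repetition;
the printed pair count implies distinct sizes only, so same-size pairs
are excluded). Each pair's similarity matrix is reduced to raw scores at
every TS of the 0.00–0.99 grid in one pass (bin each TC by the highest
threshold not exceeding it, then a reversed cumulative sum). Repetitions
are pooled, not averaged, before fitting: pooling keeps every sample's
information and the grouped fit is insensitive to the distinction under
balanced designs.

Per TS, raw scores are grouped by s; μ is the least-squares slope
through the origin of group means on s (groups need ≥ 2 samples), and
(φ, η) come from OLS of log(group sd) on log(s) with zero-sd groups
excluded. A TS where fewer than two groups have positive spread is
unusable and recorded as such. Goodness of fit uses a chi-square
statistic over equal-probability bins of the standard Gumbel (20 bins by
default, reduced so each expects ≥ 5 observations); the minimal
statistic selects TS, ties breaking to the lowest TS. The zero-mean,
unit-variance Gumbel parameterisation (scale √6/π, location −γ√6/π) is
used so the same standardisation serves the chi-square and the
P-value tail.

Singleton queries give s = n_B, usually below the smallest fitted
product; the power laws extrapolate smoothly and the extrapolation is
noted in debug logs rather than blocked.

## Representations

Binary fingerprints are kept as exact sparse on-bit sets (no folding),
so Tanimoto counts are exact. Providers: Morgan (radius 2 by default,
the common ECFP4-equivalent convention; the radius is exposed), atom
pair, topological torsion, MACCS keys, and Gobbi 2D pharmacophore
fingerprints with configurable point counts ({2} or {2,3}) and distance
bins (default (2,3),(3,4),(4,5),(5,6),(6,7),(7,20); bins are half-open
[lo, hi)). Tanimoto of two empty fingerprints is defined as 0 —
featureless molecules should not appear maximally similar. Fingerprints
carry a provider key (name + parameters), and any cross-provider
comparison is an error rather than a silent mismatch.

SHED descriptors are computed in-package on the Gobbi feature types
(donor, acceptor, hydrophobic, aromatic): for each of the 10 unordered
type pairs, the topological distances between feature atoms (capped at
20 bonds, one bin per bond) give a Shannon entropy H, and the descriptor
value is e^H ∈ [0, 20] (0 when no such pair exists). Similarity is
1 − d/(20√10) with d the Euclidean distance, so each component's range
bounds the normaliser.

## Curation

Structures are standardised to their largest fragment (heavy-atom count,
then molecular weight, as tie-break) and canonicalised; molecules above
1000 Da are dropped, and unparseable rows are counted and skipped, never
fatal. Identical structures under different identifiers collapse onto
one identifier, and repeated activities of a (molecule, target) pair are
combined by the geometric mean in concentration space — the arithmetic
mean of pChEMBL values. Aggregation happens **before** the activity
threshold, so a molecule with activities straddling the cutoff is judged
by its mean. Thresholds of pChEMBL 5/6/7 (10/1/0.1 μM) then apply,
targets with < 5 ligands are dropped, and targets above 3000 ligands are
capped by seeded max-min (farthest-point) picking on Tanimoto distance.
Filtering is monotone in the threshold by construction. Target-type
filtering (e.g. to single proteins) is treated as upstream of the input
table.

## Voting ensemble

Each model's P-value for a pair is a vote when p ≤ α (ties count, the
same convention as "p ≤ 0.05" significance; a k-vote scheme therefore
reads "at least k", the only reading under which a 3-vote scheme needs
three votes). Missing P-values — a pair not scored by some model — are
non-votes. Nesting in k (union at k = 1, intersection at k = n) is
structural and tested.

## Evaluation

Metrics are always computed from integer confusion counts, never from
pre-rounded rates, and reported to 3 decimals; undefined denominators
yield "undefined" (None), not 0, because silent zeros corrupt model
comparisons. F_β weights precision 1/β² times as much as sensitivity;
F₀.₅ and F₀.₂₅ are the defaults, matching the precision-oriented regime
where negatives are under-verified and the false-positive rate is
underestimated.

## Synthetic data

The generator works at the fingerprint level (no structures), so the
core statistics are testable without chemistry: background molecules
draw each of 2048 bits independently at density 0.03 (~60 on-bits, the
order of a Morgan fingerprint on a drug-like molecule; mean null
Tanimoto d/(2−d) ≈ 0.015), and each planted family shares a random core
pattern plus per-molecule noise bits outside the core, giving expected
within-family Tanimoto ≈ core/(core + 2·noise). Default family settings
for end-to-end checks are 25 members, 60 core + 10 noise bits (expected
TC 0.75). The generator emits the same activity-table and fingerprint
sidecar formats the real pipeline consumes, with uniform pChEMBL in
[5.5, 9] and an equal number of background-molecule negative test pairs.

What it does not emulate: realistic chemical-space topology, correlated
bit distributions, activity cliffs, or inter-family relatedness. Passing
tests therefore demonstrate the statistics and the pipeline, not
real-data headline performance.

## Problem sizes in the test suite

The suite and the acceptance script run the background protocol at
reduced scale — universe of 400 molecules, size grid 10–100 step 10 (45
distinct-size pairs), 60 repetitions (2700 pooled samples) — which is
ample for a stable TS selection and tail calibration on the synthetic
null, as the calibration checks confirm; null calibration uses 45 fresh
repetitions (2025 comparisons ≥ the 2000 required). Parameter-recovery
checks simulate directly from the mean/sd laws on the full 10–1000 grid
with 60 repetitions, where μ, φ and η refit to within a few percent.
Reference-scale defaults (10–1000, 100 repetitions) remain the
estimator defaults.

## Known limitations

* The background chi-square compares thresholds to each other; it is not
  an absolute goodness-of-fit test, and a universe whose raw scores are
  far from EVD-like at every TS will still select some TS (diagnostics
  are retained per TS for inspection).
* Background subsets are drawn disjoint; ligand sets sharing molecules
  are mildly anti-conservative against this null.
* Binary fingerprints only; count-based variants and 3D conformers are
  out of scope.
* Significance is per-comparison, with no multiple-testing correction,
  matching standard SEA usage; large target libraries imply the usual
  family-wise caveats.
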