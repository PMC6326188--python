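# Methods

## From stability changes to preference profiles

The central object is the site-specific amino acid preference (SSAP)
profile π, an L×20 row-stochastic matrix giving, for each protein site,
the normalized propensity of each amino acid to occupy it. The package
derives π from a matrix of folding free-energy changes ΔΔG_{r,a}
(kcal/mol; positive = destabilizing; the wildtype self-substitution is
identically 0 and is forced to 0 on input with a warning if a file says
otherwise). Three stability-to-fitness maps convert ΔΔG to a folding
probability P_f:

| model     | P_f                                | interpretation                          |
|-----------|------------------------------------|-----------------------------------------|
| threshold | e^(−ΔG/kT) / (1 + e^(−ΔG/kT)), ΔG = ΔΔG + ΔG_wt | marginal stability; sigmoid around a stability threshold |
| maximum   | α·e^(−λ·ΔΔG)                       | strong monotone selection for stability |
| optimum   | α·e^(−λ·ΔΔG²)                      | fitness optimum at wildtype stability   |

and π_{r,a} = P_f(ΔΔG_{r,a}) / Σ_j P_f(ΔΔG_{r,j}).

Parameter choices. kT defaults to 0.593 kcal/mol (≈298 K), matching
kcal/mol energy inputs; it is configurable. λ defaults to 1.0 for the
power models — under row normalization, structural-data fits in the
literature justify λ = 1 — and the threshold model keeps 1/kT inside its
sigmoid. λ for the optimum (n = 2) model is likewise 1.0 by assumption;
nothing in our sources pins it, and it is exposed as a parameter. α > 0
cancels under normalization (asserted by test). ΔG_wt defaults to 0 (the
usual marginal-stability approximation) but is a real parameter so the
sensitivity of conclusions to it can be probed; the sigmoid midpoint sits
exactly at ΔΔG = −ΔG_wt.

Numerics. All normalization happens in log space (log-sum-exp /
softmax over log P_f), so a row with one +800 kcal/mol outlier yields a
clean simplex row instead of 0/0. The threshold model uses
−logaddexp(0, x/kT); +50 kcal/mol gives P_f ≈ 10⁻³⁷ without overflow.

## Replicate simulation and σ calibration

Structures are rarely solved twice, so replicate "measurements" of a
predicted profile are simulated: per site, a multinomial sample of size
n = 100 centered at the profile row is converted to fractions, Gaussian
noise of scale σ is added per amino acid, negatives are clamped at 0, and
the row is renormalized over the site's 20 amino acids. (The printed form
of this recipe in our source material indexes the denominator ambiguously;
per-site normalization over amino acids is the only reading consistent
with a row-stochastic output and is what we implement.) A site whose
clamped row sums to zero has its noise redrawn (bounded retries).

Replicate quality is summarized by the Pearson correlation between the
flattened L×20 replicate and source matrices — the global convention used
when mutagenesis replicate correlations are reported. `calibrate_sigma`
inverts the monotone σ→correlation relation by bisection to a tolerance of
0.01 on the mean correlation over 20 probe replicates. The probe draws use
common random numbers (fixed multinomial samples and standard-normal noise
scaled by σ), which makes the objective a deterministic, monotone function
of σ — bisection then converges cleanly, and fresh-seed replicates
reproduce the target to ±0.02 (tested).

Two caveats worth knowing. First, the multinomial resampling alone bounds
the achievable correlation: a high-entropy (near-uniform) profile has a
σ = 0 ceiling around 0.85–0.90 at n = 100, so very high targets can be
unreachable for flat profiles; the calibrator reports the achievable range
in that case. Second, "target correlation" here means replicate-to-source,
averaged over replicates; replicate-to-replicate correlation is slightly
lower and is not the calibrated quantity.

## Per-site significance: JS metric, RMSD_corrected, permutation, FDR

The distance between two preference rows is the Jensen–Shannon metric,
√JSD with base-2 logarithms — a true metric on the simplex (symmetry,
identity, triangle inequality; all tested), 0 iff the rows are equal and
exactly 1 for disjoint support. Given n replicates of profile a and m of
profile b, per equivalent site:

- RMSD_within: root mean square of JS distances over within-set replicate
  pairs, pooled from both sets (C(n,2)+C(m,2) pairs). An alternative
  "averaged" mode (mean of the two per-set RMSDs) is available; pooling is
  the default reading of a single within-set RMSD per site.
- RMSD_between: RMS over the n×m cross-set pairs.
- RMSD_corrected = RMSD_between − RMSD_within.

The null distribution comes from an exact permutation test: every
relabeling of the pooled n+m replicates into groups of sizes n and m
(all C(n+m, n) when that count fits the budget, otherwise a uniform random
subsample that always contains the identity). Ties count as ≥ observed
(conservative), so p ≥ 1/#relabelings, and with n = m the whole-group swap
reproduces the observed statistic exactly, making the smallest attainable
p equal to 2/C(2n, n). Benjamini–Hochberg step-up (via statsmodels)
controls the FDR across the sites of one pairwise comparison; the scope is
per comparison because each homolog pair is reported separately.

Replicate count. The group-swap tie is why the default is six replicates
per profile: with five, min p = 2/252 ≈ 0.0079, which sits above the BH
threshold k·α/m needed to recover ten planted sites among one hundred at
α = 0.05 (10·0.05/100 = 0.005) — perfect signal would still be
undetectable. Six replicates give 924 relabelings and min p ≈ 0.0022,
restoring usable granularity. The minimal two-replicate scheme (6
relabelings, min p = 1/6) remains available via `n_replicates=2` for
strict compatibility with two-replicate designs; how such a design could
ever certify p < 0.05 per site is left as an open question rather than
resolved.

## Structural analysis

Superposition is iterative Kabsch (scipy's `align_vectors` for the rigid
fit): fit on the current Cα pairing, re-pair by mutual nearest neighbors
within 3.5 Å, repeat until stable. It is a pragmatic equivalent-site
mapper, not a full structural aligner — externally produced alignment maps
are first-class inputs everywhere. Equivalence threshold: Cα within 3.5 Å
after superposition. Structural deviation (sRMSD) is the arithmetic mean
of paired Cα distances; despite the conventional name it is a mean, not a
root mean square, and is implemented exactly as defined.

Contacts: two residues are in contact when any atom pair under the
dialect's filter is within 3.5 Å — `sidechain_3p5` uses side-chain atoms
only (backbone N, Cα, C, O and OXT excluded; glycine contributes none),
`allatom_3p5` all heavy atoms. Hydrogens are excluded at parse time
(crystal structures generally lack them). Sequential |i−j| = 1 neighbors
are included by default (no exclusion is part of the contact definition);
a configurable exclusion is offered since many contact-map conventions
drop them. Ensemble networks average edge indicators over a model
ensemble into a contact frequency E ∈ (0, 1].

Rewiring: per aligned site, neighbor sets of the two homologs are mapped
into a common index space; conserved/gained/lost sets give
f_r = (|G|+|L|)/(|G|+|L|+|C|) = 1 − Jaccard. Contacts to unaligned sites
have no image in the other homolog and are counted as lost/gained by
default (switchable to "ignore"). f_r is symmetric under swapping which
homolog is "a" (G and L exchange; their sum does not).

Network proximity: the observed statistic is the mean over query sites of
the shortest-path distance (Dijkstra via networkx; unweighted hops by
default, 1−E weights optionally) to the nearest anchor; the null redraws
equally sized site sets uniformly from non-anchor nodes, and
p = (#null ≤ observed + 1)/(n_random + 1).

Binned summaries use percentile bootstrap (2.5/97.5) of the per-bin mean;
bins default to width 0.1 over divergence [0, 1]; empty bins are reported
as missing, singleton bins get a degenerate CI. Per-site entropy is
base-2 Shannon entropy of a preference row (0·log 0 = 0; range
[0, log₂20]).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes,
not physics. ΔΔG entries are drawn as scale·(Gamma(1.5) − 0.3) — right
skewed, mostly destabilizing with a mild stabilizing tail — with a larger
scale at buried sites (defaults 2.0 vs 0.5 kcal/mol, burial fraction
0.35), so buried sites get lower-entropy preferences and typical rows land
in the 1.5–4.3 bit band: non-uniform but not degenerate. Toy structures
use ideal helix geometry (rise 1.5 Å, 100°/residue, radius 2.3 Å; Cα–Cα
≈ 3.83 Å) with approximate backbone N/C/O placement and a single outward
CB pseudo-side-chain per non-glycine residue; the default fold is a
two-helix bundle with facing side chains near the contact cutoff, so both
contact dialects produce non-trivial networks. Homolog pairs displace each
residue rigidly by per-residue Gaussian noise (per-axis σ =
`coordinate_noise`, default 0.5 Å), substitute an exact
`divergence_target` fraction of sites, and perturb the homolog's ΔΔG with
noise proportional to the local substituted fraction over the contact
shell (`epistasis_scale`, default 1 kcal/mol) — a deliberately crude
epistasis surrogate. Planted sites are forced into the substituted set and
given rows concentrated on each homolog's own wildtype, yielding
near-disjoint point-mass preferences (point JS ≈ 1) with exact truth
labels.

None of this captures real force-field error structure, rotamer packing,
backbone plasticity, indels, or functional selection. Passing tests
therefore demonstrate that the statistical machinery behaves correctly
under its stated assumptions (calibrated error rates under the null,
recovery of planted signal, monotone responses to divergence and
coordinate noise) — not that stability predictions on real structures are
accurate.

## Pipeline conventions and problem sizes

`run_pair` chains profile prediction, σ calibration, replicate simulation,
per-site testing and (when structures are given) contact rewiring, and is
fully determined by its seed. `run_cohort` derives each pair's seed from
its pair id (so cohort order is irrelevant), skips pairs whose alignment
covers less than 95% of either structure (configurable), continues past
individual failures, and reports divergence-binned summaries plus a
substituted-vs-conserved rank-sum contrast of f_r (scipy's test, reported
not reimplemented).

Default problem sizes in the tests and the acceptance script — 56-site
profiles (the size of a small well-studied mutagenesis target), 100-site
planted-recovery runs, cohorts of tens of sites per pair, 100-repetition
null calibrations, bootstrap at 200–10,000 resamples — were chosen as the
smallest sizes at which the statistical assertions are stable across
seeds.

## Known limitations

- The superposition utility assumes mostly rigid homologs; large
  conformational changes should use an external aligner's map.
- The JS metric ignores physicochemical similarity between amino acids;
  distances between chemically similar substitutions are not discounted.
- σ calibration targets replicate-to-source correlation; designs that
  report replicate-to-replicate correlation need a small offset.
- FoldX run aggregation is the arithmetic mean across runs; best-energy
  aggregation is not implemented.
- PDB writing is minimal (single chain, ATOM records) and round-trips at
  the format's 3-decimal precision only.
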