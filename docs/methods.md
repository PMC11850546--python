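# Methods

`hlacompat` implements four molecular HLA compatibility metrics, the
imputation layer that lets them run on low-resolution typings, and the
survival harness used to calibrate and compare them. This note records
the models, the numerical choices, and what the synthetic fixtures do
and do not demonstrate.

## Exposure maps (Snowflake / Snowball)

**Surface.** Solvent-accessible surface area is computed per atom by
the rolling-ball (Shrake–Rupley) construction: of `n_points` (default
960) quasi-uniform sphere points at radius r_vdw + 1.4 Å, the fraction
not inside any neighbour's expanded sphere, times the expanded-sphere
area. The point set is a deterministic golden-spiral lattice so results
are bit-reproducible; the price is that the quadrature grid is
orientation-fixed, so rigid *rotations* perturb per-atom SASA by
O(1/n_points) (~0.3% at 960 points) while translations are exact. Van
der Waals radii are the Bondi set; per-residue SASA is normalised by
the residue type's theoretical Gly-X-Gly maximum (Tien-style values)
and clipped to [0, 1] — without this normalisation accessibility is
underestimated for small residues (glycine) and overestimated for large
ones (tryptophan). Both tables ship as editable CSVs.

**Protrusion.** Every atom serves once as a neighbourhood centre; the
atoms within 15 Å are fitted with a moment ellipsoid (PCA axes,
semi-axes = per-axis standard deviation, floored at 0.5 Å so planar or
collinear clouds never degenerate). Each member atom's normalised
ellipsoidal radius is min–max mapped to a rank in [0, 1] — the furthest
atom 1.0, the innermost 0.0, ties shared. An atom's protrusion is the
median of its ranks over all neighbourhoods containing it; a residue's
rank is the maximum over its atoms. Neighbourhoods with fewer than 10
atoms are skipped with a warning.

A max-|projection| semi-axis fit was considered and rejected: it pins
one principal axis to whichever single atom is most extreme, so that
atom's normalised radius is exactly 1 while atoms at the other axis
extremes score sqrt(1 + cross-terms) > 1 — a genuinely protruding spike
can then rank *below* ordinary boundary atoms. The standard-deviation
fit preserves the intended endpoints (sphere-plus-centre fixture:
centre 0.00, shell > 0.97) and makes an outlier spike the strict
maximum.

Note the rank-endpoint interpretation presumes the neighbourhood spans
the local cluster; hollow shells larger than the neighbourhood radius
produce cap-shaped neighbourhoods whose ellipsoids are not informative
about global protrusion. Test fixtures therefore keep cluster diameters
below 15 Å (or pass a larger neighbourhood radius explicitly).

**Sequence extrapolation.** A small MLP regressor maps a one-hot
sequence window (default 9 residues) plus normalised position to the
(surface, protrusion) pair, clipped to [0, 1], so that proteins without
a solved structure still get allele-specific exposure maps. Stopping is
loss-based rather than validation-R² based because R² is undefined on
constant targets.

## Mismatch metrics

*Amino acid*: donor (group, position, residue) configurations absent
from the recipient, with HLA-A/B/C pooled into one interlocus class I
position space and class II counted per locus. Set semantics make
homozygous contributions count once.

*Eplet*: registry entries (name, locus group, residue requirements,
antibody-verified flag); an allele carries an eplet iff every
requirement matches; the mismatch count is |donor set − recipient set|,
optionally restricted to antibody-verified entries (always ≤ the
unrestricted count).

*Snow*: the amino-acid mismatch restricted to positions whose
surface score and protrusion rank both *strictly* exceed the
Snowflake/Snowball thresholds on at least one donor allele carrying the
residue. Because "surpass" is strict, Snow(0.00/0.00) equals the
amino-acid mismatch count only when all exposure values are strictly
positive; the synthetic exposure generator draws from U(0.02, 1) for
exactly this reason. Donor-side exposure maps are used: the donor
protein is the antibody target.

## Binding predictor and PIRCHE-II

Peptide–HLA-DRB1 binding is predicted by an ensemble of small
feed-forward networks (two hidden ReLU layers, default 64/32, Adam)
over BLOSUM-62 encoded features: 9 core positions plus the presenting
allele's 25 binding-groove residues → (9+25)×20 = 680 inputs. Training
targets are IC50 values transformed by 1 − log(IC50)/log(50000),
clipped to [0, 1]. A pool of `pool_size` networks (protocol default
512) each gets its own random initialisation and 80/20 split; the
`keep` best (default 128) by held-out MSE form the ensemble.

Core registers are latent. Binders (IC50 < 500 nM) train on a single
assigned register that is re-derived from the network's own predictions
every `reassign_every` iterations; non-binders contribute **all seven
registers** as negatives, since any register of a non-binder is a
non-binding core. Initial registers are uniform-random per network.
A hydropathy anchor-propensity initialiser is available
(`anchor_offsets`) but deliberately not used for training: when the
true anchors are hydrophilic the propensity prior starts every register
away from the motif and the self-consistent re-assignment converges to
a wrong fixpoint (measured: planted-core accuracy 1–3%, AUC ≈ 0.67,
versus 0.98 / 1.00 with random starts).

At prediction each network votes its best register; the modal register
wins (ties → lowest offset); affinity is the mean over agreeing
networks; each agreeing network's permille rank against a shared
10,000-peptide proteome background (tie convention ≥, floor 1000/n) is
combined by geometric mean. The geometric mean of imperfectly
correlated uniform ranks is not itself uniform (measured: 55–57% of
background peptides fell below 500‰, and longer training does not
close the gap), so the reported final rank maps the raw geometric mean
through the background's empirical distribution of that same statistic
— a monotone recalibration computed once per presenter — restoring the
permille semantics: r‰ means r/1000 of random human 15-mers score at
least as well.

PIRCHE-II enumerates donor 15-mers over HLA-A/B/C/DRB1/DQB1, takes
their 9-mer substrings as candidate cores, discards cores occurring in
any recipient protein (target ∪ presenting loci), and counts, per
recipient DRB1 presenter, allo cores whose best containing 15-mer
reaches the rank threshold (v4 mode) or predicted IC50 < 1000 nM (v3
mode — computed with the in-package predictor, so published v3 scores
are not implied). The score sums over presenters, homozygous
contributions counted once; the promiscuity-corrected variant divides
each presenter's count by its background binding fraction.

## Imputation

Haplotype pairs compatible with a low-resolution typing (first-field
allele-code matching per locus) are weighted by Hardy–Weinberg
probabilities 2f₁f₂ (f² for identical haplotypes), normalised per
subject, filtered at a normalised weight of 1%, renormalised, and
merged into genotype distributions. Compatibility scores aggregate over
the recipient × donor genotype cross product by weighted summation.

## Survival harness

Cox PH models (lifelines) are fitted on random 70/30 splits. AIC = 2k −
2logL; BIC = k·ln(n_events) − 2logL (events, not subjects, as is usual
for partial likelihood; switchable by recomputation from the stored
log-likelihood). Discrimination is the IPCW (Uno) dynamic AUC
(scikit-survival) at the 25th/50th/75th percentiles of pooled
follow-up, summarised as their unweighted mean (iAUC); with three
points a trapezoid over percentile spacing reduces to a weighted mean
and the unweighted mean is the documented choice. Censoring weights are
estimated on the evaluation split itself — a training-split censoring
curve cannot extrapolate past its own last follow-up. Evaluation times
are clipped strictly inside the test follow-up range. Mismatch loads
enter as ln(score+1). Repeated comparison scales BIC per split by
subtracting the split minimum and ranks specs by median scaled BIC.

Threshold optimisation scans the Snowflake grid {0.00…1.00 step 0.10}
∪ {0.20…0.70 step 0.02}, the Snowball grid {0.00…1.00 step 0.10} ∪
{0.30…0.80 step 0.02} and the permille rank list [5, 10, 15, 20, 30,
40, 50, 75, 100, 150, 200, 250, 300, 400, 500], fitting one Cox model
per triple (log-Snow, log-PIRCHE, companions) and returning the AIC
argmin with the full surface. Score ingredients are cached per
genotype pair, so a grid point costs one array reduction plus one fit.

Cutpoints use maximally selected rank statistics: the standardised
two-sample log-rank statistic maximised over candidate cuts inside the
score's 10–90% quantile range (at most 100 quantile-thinned
candidates); the "three consecutive analyses" are realised recursively
(one cut on the full cohort, then one in each resulting subgroup, → 4
intervals), with subgroups under 50 events left unsplit. No p-value
adjustment is applied; cutpoints are descriptive. A bootstrap stability
fraction (re-estimates within 10% of the score range) is reported so
null scores are flagged (< 0.5).

The XGBoost AFT grid is trees {16, 32, 64, 128, 256, 512} × depth
{2…12}, normal AFT loss, ≤ 512 feature bins, early stopping after
0.5×max-trees non-improving rounds monitored on a fifth of the training
split (kept separate from the 30% evaluation split to avoid leakage).
Top-5 models by iAUC form an averaged ensemble; gain importances are
reported next to an injected uniform-random control covariate.

## Synthetic fixtures

The generators emulate the shape of the restricted inputs, not their
content: allele stores (8 alleles per locus, 100 alignment columns, 20
polymorphic positions per locus — the scale of common-allele HLA
variation; class I loci share a consensus since their positions pool
interlocus), toy structures (isolated 11-atom core+shell clusters with
known buried/exposed labels, spaced 80 Å so neither the rolling ball
nor 15 Å neighbourhoods couple them), motif-driven binding data
(binders carry K at core P1 and Y at P9; IC50 lognormal around 100 nM
vs 20,000 nM, σ = 0.4; each groove alanine multiplies IC50 by 0.85 so
alanine-rich grooves are measurably more promiscuous), Dirichlet
haplotype pools (12 haplotypes), and Weibull proportional-hazards
cohorts (shape 1.2, baseline scale 20 y, administrative cutoff 15 y,
exponential dropout solved by bisection to a target censored fraction,
default 80% — the event fraction of large registry cohorts). Cohort
truth records carry the generative coefficients and the expected event
rate.

Passing tests on these fixtures demonstrates algorithmic correctness
and statistical calibration — not clinical performance: the fixtures
have no linkage disequilibrium beyond the haplotype pool, no
locus-specific immunogenicity, exposure values independent across
positions, and a binding rule far cleaner than IEDB data.

## Problem sizes in tests

The default test run trains a reduced ensemble (pool 32, keep 8, 200
iterations, 2000 examples) for motif recovery and rank calibration,
uses n = 3000 cohorts for threshold-recovery and null-calibration
checks, n = 5000 for effect-size and cutpoint recovery, and a coarse
0.10-step threshold grid; these sizes give stable pass/fail behaviour
at desk scale. `scripts/acceptance.py` recomputes the same quantities
from scratch at the same sizes.

## Known limitations

- v3-mode PIRCHE uses the in-package predictor, not the published
  netMHCIIpan pipeline; numbers are not comparable to published v3
  scores.
- The groove position list is a documented default, derivable from any
  peptide-bound structure via the 4 Å heavy-atom contact helper, not a
  curated truth.
- Exposure prediction from sequence interpolates training structures;
  it does not model conformational change.
- DQ heterodimer pairing (DQA1/DQB1) and DRB3/4/5 are out of scope;
  only HLA-A, -B, -C, -DRB1, -DQB1 are first-class.
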