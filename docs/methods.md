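# Methods

This note documents the models and procedures implemented in `af2conf`, the
parameter choices that matter, what the synthetic benchmarks do and do not
show, and the numerical decisions taken where the underlying procedures are
conventionally under-specified.

## Confidence model

Per-residue pLDDT (0–100) is read from the Cα atom's B-factor; other atoms'
B-factors are ignored for confidence, since AlphaFold-style files repeat
the per-residue value on every atom while experimental files carry thermal
factors there.  B-factors outside [0, 100] are accepted but flagged as
likely experimental.  Residues are indexed 0-based internally; author
residue numbers are preserved as labels, which keeps PAE-matrix alignment
unambiguous.  Multi-model files use the first model; first altloc wins.

## Segmentation

The pLDDT trace is smoothed per chain with a discrete Gaussian filter,
σ = 5 residues, kernel truncated at 4σ.  The boundary is reflective: a
symmetric extension avoids the artificial terminal decay that zero-padding
would produce, which would otherwise truncate terminal domains.  Chains
never share a smoothing window.  High-confidence segments are maximal runs
with smoothed pLDDT strictly above 70; runs shorter than 50 residues are
discarded.  The strict inequality is deliberate and is asserted at the
boundary in tests; note that the enzyme-candidate filter (below) uses an
inclusive ≥ 70 on the *mean* — the two thresholds serve different rules and
are implemented independently.

Domain-like region detection reports contiguous uncovered runs of 100–500
residues whose median **raw** pLDDT exceeds 70.  Whether the median should
be taken over smoothed scores is genuinely open; raw is the default and a
`use_smoothed` flag exposes the alternative.

## Disorder scores

Four per-residue metrics, all oriented so higher = more disordered:
`plddt` = 1 − pLDDT/100, `rsa` = relative SASA, and 20-residue
moving-average variants of each.  The moving average uses a centered window
whose radius shrinks symmetrically at chain termini (window 1 = identity);
normalization precedes smoothing for the SASA variant.

Relative SASA divides each residue's absolute SASA (Shrake–Rupley, 1.4 Å
probe, 960 sphere points, via biotite for full-atom models) by the
residue's maximum exposure in an extended Gly-X-Gly context.  The
normalization table is the standard theoretical maximum-ASA table of Tien
et al. (2013); computing an in-house table from built Gly-Gly-X-Gly-Gly
peptides would require an all-atom side-chain builder that adds nothing to
the downstream statistics, since the ROC evaluation is invariant to any
per-residue-type monotone rescaling.  Values may slightly exceed 1; an
*isolated* residue systematically exceeds 1 (measured 1.3–1.9×) because it
exposes the surface its chain context occludes.  Cα-only models fall back
to a coarse sphere-exposure estimate (3.0 Å residue spheres, Fibonacci
points, normalized so an isolated residue scores exactly 1); the fallback
is flagged with a warning and is suitable for ranking, not absolute
accessibility.

ROC curves are computed per residue; AUC is the rank statistic
(Mann–Whitney U scaled to [0, 1], ties counting ½), so it is invariant
under any strictly monotone transform of the scores — the choice of
orientation function is therefore immaterial to the benchmark.

## Shape-mers and topics

Fragments are 16-residue sliding k-mers and 10 Å Cα-radius neighborhoods;
fragments never cross chain or high-confidence-segment boundaries.  Each
fragment is summarized by four rigid-motion invariants of its Cα cloud —
the trace (O3), second elementary symmetric function (O4) and determinant
(O5) of the second-order central moment tensor, and the norm of the
third-order moment tensor (F), with central moments taken as sums over
points.  Each invariant m is log-binned as
round(resolution · sign(m) · ln(1+|m|)), resolution 4 for k-mers and 6 for
radius fragments; the (kind, 4-integer) tuple is the shape-mer id.  These
closed forms are declared normative for this package and guarded by
rotation-invariance, degeneracy and monotonicity tests rather than by
equality with any external tool.  Radius fragments are not size-normalized
by default (larger neighborhoods carry larger raw moments);
`normalize_by_count` divides the moments by the member count for users who
want size robustness.

TFIDF uses raw counts as tf with the smoothed idf
ln((1+n)/(1+df)) + 1, so a shape-mer present in every protein keeps its
counts unweighted; the same convention as scikit-learn's transformer, which
serves as an independent cross-check in the tests.

NMF minimizes the Frobenius objective with hierarchical alternating least
squares (columnwise coordinate descent projected to the non-negative
orthant) from a deterministic NNDSVDa initialization.  HALS was chosen over
multiplicative updates because the latter's linear convergence is too slow
to reach the exact factorizations that exist in the rank-deficient and
full-rank limits; HALS reaches relative reconstruction error < 1e-6 on
rank-1 problems and < 1e-3 at p = min(n, m), and its objective trace is
recorded and asserted non-increasing.  p defaults to 250 for corpus-scale
work; desk-scale tests use p ≤ 10.

Topic membership uses knee detection on each topic's sorted weight column:
coordinates are normalized to [0, 1], the knee is the point of maximum
perpendicular distance to the chord from first to last point, and proteins
strictly above the knee weight are assigned.  Topics whose maximum chord
distance falls below 1e-9 of the maximum weight (uniform or all-zero
columns) assign nothing.  Residue topic scores multiply each fragment's
topic weight H[t, s] by an RBF kernel of the residue–fragment-center Cα
distance, σ = 5 Å (roughly the radius of a fragment), summed over
fragments.  Protein matching uses cosine similarity of the sparse count
vectors; ties rank the lower corpus index first.

## PAE rigid domains

The asymmetric PAE is symmetrized with the pairwise **minimum**: a residue
pair belongs to a rigid unit if either direction is confidently placed.
Edges exist below 5 Å symmetrized error with weight (1/e)^1, e floored at
0.2 Å to avoid infinite weights; cutoff, power, resolution and minimum
community size (10) are all exposed as flags since no canonical values
exist.  Community detection is greedy modularity agglomeration
(networkx CNM, deterministic), validated by planted-block recovery (ARI 1.0
for intra ≤ 3 Å / inter ≥ 15 Å / blocks ≥ 30 residues over 20 seeds) rather
than equality with any particular external implementation.  The
molecular-replacement core keeps the largest community, trims residues with
pLDDT ≤ 50, and sets every B-factor to a constant 50 — a neutral value for
search-model weighting.

## Adaptive restraints

Cα pairs with sequence separation ≥ 3 are restrained when their distance is
within 8 Å in *either* model (the union rule keeps pair selection symmetric
under swapping working and reference; the target is always the reference
distance d₀).  The distance-dependent parameters scale linearly with d₀
relative to d_ref_scale = 3 Å: wellHalfWidth = 0.3·(d₀/3) Å, tolerance =
0.075·(d₀/3) Å, fallOff = 2·(d₀/3); base kappa = 10 energy units.  These
coefficients are declared defaults exposed in `RestraintConfig`; the tests
assert the qualitative contract (all three increase with d₀) rather than
the coefficients.  With confidence weighting, p = the pair's minimum pLDDT:
kappa ×= clip((p−50)/50, 0, 1) (0 at 50, 1 at 100), tolerance and fallOff
×= 1 + (100−p)/50; pairs with p < 50 are disabled outright.

The top-out energy is E(x) = κ(1 − exp(−x²/(2c²(1+f·x/c)))) with
x = max(0, |r−target|−tolerance) and c = wellHalfWidth: exactly zero inside
the flat bottom, quadratic (harmonic) near it, force peaking near x ≈ c and
decaying to zero at large x for f > 0 (measured tail force at x = 10c,
f = 1: 1.8 % of peak).  The analytic force is verified against numerical
differentiation.

Torsion restraints cover φ, ψ and χ1 (standard atom quadruples) measured
on the reference by the signed dihedral formula; degenerate (collinear)
quadruples are skipped with a warning.  Torsions on residues with pLDDT
< 50 are disabled; no graded confidence weighting is applied to torsions —
the graded scheme is defined for distances only, and extending it to
torsions is left open.

## Oligomer state scans

The N-copy MSA is built by copy/pad/concatenate: block j carries the
original aligned rows in columns [jL, (j+1)L) and gaps elsewhere, plus one
full-length query row repeating the query in every block so the target
sequence covers all copies.  State calling aggregates each state's
per-model pTM scores with the minimum (worst-of-models; mean is available)
and takes the argmax, ties broken toward the smaller copy number
(parsimony).  A scan against an annotation succeeds when the call matches,
or when the state one above the annotated one scores ≥ 0.1 below the
annotated state's aggregate — read as "the annotated state is still a
sharp local peak"; the comparison is against the annotated state's score
(not the global peak's), a deliberate reading of an ambiguous rule, with
the margin exposed as a parameter.  Heterodimer single-chain preparation
renumbers chain B to start at len_a + 200 + 1, leaving a 200-residue gap.

## Pockets

Pocket points map to residues with any atom within 4.5 Å (heavy-atom
contact convention; Cα-only models fall back to 8 Å, flagged).  Pocket
confidence is the mean pLDDT of associated residues, high quality iff
strictly above 90.  Overlap metrics are residue-level F-score and MCC over
an explicit confusion matrix with zero-denominator → 0.  The
enzyme-candidate filter keeps models with mean pLDDT ≥ 70 (inclusive) and
100–500 residues, ranked by top pocket score, with an optional drop of
low-confidence pockets.

## Synthetic data: what it emulates, and what passing tests show

Generators are pure functions of (spec, seed).  Helix segments use ideal
α-helix Cα geometry (rise 1.5 Å, radius 2.3 Å, 100°/residue), strands are
near-extended 3.8 Å steps with a ±0.5 Å pleat, disordered segments are
3.8 Å-step self-avoiding random walks (2.5 Å clash radius, 1,000 retries
per step before failing); consecutive Cα distances stay within
[3.5, 4.1] Å.  pLDDT is Normal(mean, sd) per segment clipped to [0, 100],
i.i.d. by default with an optional AR(1) autocorrelation (ρ = 0.5 in the
disorder benchmark) because the smoothing operations are only informative
with correlated noise.  The disorder benchmark draws ordered residues from
N(90, 5) and disordered from N(40, 8) over ≥ 500 residues — under these
conditions the pLDDT metric reaches AUC ≥ 0.95.  PAE matrices are
block-constant plus Gaussian noise with the diagonal at intra/2; oligomer
scans place state s at base − gap·|s − true| with Gaussian noise; planted
binding sites grow a spatially contiguous core and define the known site
through the same pocket→residue mapping used downstream, so the truth is
consistent with the contact convention.

These benchmarks validate the *mechanics* — segmentation against the
smoothing oracle, clustering against planted blocks, metrics against brute
force — not performance on real proteins: real pLDDT profiles have
structured, non-Gaussian error modes, real PAE matrices are not
block-constant, and real disorder is not a clean two-Gaussian mixture.
Passing tests show the procedures compute what they claim under known
ground truth; published benchmark figures on real databases are out of
scope here.

## Problem sizes and determinism

Desk-scale defaults keep the full suite around ten seconds and the
acceptance script a few seconds on one CPU: 16-point fragments × 50 rigid
motions, 300-residue smoothing traces, 525-residue disorder benchmarks,
120-residue three-block PAE matrices × 20 seeds, 50×80 NMF problems, 400
oligomer scans, 200-residue pocket models.  Every stochastic quantity
derives from an explicit integer seed; the acceptance script threads its
`--seed` through every generator.

## Known limitations

- PDB output only (no mmCIF writing); residue numbers above 9999 are
  rejected with advice to renumber.
- Cα-only SASA is a coarse exposure proxy, not a calibrated accessibility.
- Torsion restraints cover φ/ψ/χ1, not the full χ ladder.
- The 2-D embedding of W for topic-map visualization is a plotting
  convenience, not a tested contract (stochastic by nature).
- Database-scale corpus statistics (hundreds of thousands of proteins,
  250 topics) are supported by the algorithms but not exercised by the
  desk-scale tests.
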