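# Methods

## Consensus-panel classification

The metal-binding site of canonical PHP domains is described as an
ordered panel of nine positions with consensus residue sets
(H, H, D/H, H, E, H, C/H, D/N, H), anchored to *E. coli* Pol III
residue numbers 10, 12, 19, 44, 69, 83, 134, 201, 203. Observed
residues are read off alignment columns found by counting non-gap
characters in the reference row; all residue numbers and columns are
1-based at every interface.

Two matching modes exist because the literature is ambiguous about
degenerate positions: *permissive* (default) accepts any member of a
site's consensus set, *strict* accepts only the primary (first-listed)
residue. The *G. kaustophilus* D→N substitution at site 8 is the
motivating case — inside the consensus set, yet described as a
replacement; reports can show both modes. A gap at an anchored site
always counts as a deviation: an absent residue cannot coordinate a
metal. A sequence is *canonical* iff its deviation count is zero,
otherwise *variant*.

Substitution spectra count observed residues per site over a cohort;
modal replacements are computed over deviating sequences only, with
ties reported as unordered sets rather than broken silently.

Loop absence at site 7 is declared when the gap fraction of a sequence
over ±5 alignment columns around the anchored site-7 column exceeds
0.8. No window size is canonical for this; ±5 columns captures a
deleted loop while ignoring isolated single-column gaps.

Conservation is scored per column as `1 − H/log2(20)`, where `H` is the
Shannon entropy of the non-gap residue frequencies. An invariant column
scores 1, a column uniform over the twenty residues scores 0; columns
with more than 50% gaps are flagged. Property-based conservation scores
(physicochemical set methods) are a possible alternative; the entropy
score was chosen because it is fully specified and directly testable.

## ε-exonuclease detection

DEDD-superfamily exonucleases are recognized through their four acidic
anchor residues distributed over three motifs. The default patterns
encode the classical arrangement — ExoI `D-x-E`, ExoII `D`, ExoIII a
fifth residue (His → DEDDh, Tyr → DEDDy) followed by the final `D`
five positions later — with inter-motif spacing bounds (20–150
residues) bracketing the *E. coli* DnaQ anchor geometry
(D12/E14/D103/D167, catalytic H162). The patterns and bounds are
configuration, not constants: the family definition fixes only the four
acidic residues and the fifth H/Y, so different pattern choices are
legitimate. When several complete arrangements exist, the leftmost
(lexicographically smallest anchor tuple) wins and all candidates are
retained.

The α-binding tail is detected as a His followed by a Trp, 10–25
residues apart, within the final 60 residues (the *E. coli* pair
His 225 / Trp 241 is 16 apart). A *bona fide* ε call is the
conjunction: DEDD found ∧ subtype DEDDh ∧ tail found. This is a
pattern-based surrogate for homology-based retrieval: it cannot be
expected to reproduce any particular published sequence set, and it is
not a profile-HMM search.

## Phylogenetics

Distances default to the p-distance (mismatch fraction over mutually
ungapped columns); a Poisson correction `−ln(1−p)` is available.
Full empirical-matrix (e.g. WAG) maximum-likelihood distances are a
documented limitation, not implemented.

Neighbor joining follows Saitou–Nei: at each step the pair minimizing
`Q(i,j) = (m−2)d(i,j) − r_i − r_j` is joined, branch lengths follow the
standard formulas, and the matrix is reduced by
`d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2`. Ties in Q are broken by the
lexicographically smallest label pair (merged clusters inherit the
smaller child label), so results are reproducible across platforms.
Negative branch lengths are clamped to zero and counted on the tree
(`n_clamped_branches`). NJ is exact on additive matrices — this is
tested both on a constructed example and against an exhaustive
least-squares topology search on perturbed matrices up to six taxa.

Bootstrap supports resample alignment columns with replacement; the
support of an internal edge is the fraction of replicate NJ trees
containing its bipartition. The resampling RNG is seeded and the
procedure is deterministic given the seed. Trees are unrooted
internally (the NJ seed node is the final trifurcation); midpoint
rooting is offered for display only.

## Coevolution statistic

The association between the two binary species traits — variant PHP
domain and ε presence — is quantified as the *leaf agreement*: the
fraction of leaves at which the traits coincide. Significance comes
from permuting the ε trait over leaves (`n_perm` default 999, seeded),
with the +1-corrected p-value `(1+#{S′≥S})/(1+n_perm)`, which can never
be zero. The permutation null ignores phylogenetic autocorrelation — a
trait-simulation (Mk) null is a known extension point, not implemented —
so the p-value should be read as "association given the leaves", not as
a correlated-evolution likelihood test.

Supplementary descriptors: minimum state-change counts for each trait
and for their XOR (zero iff the traits are identical), computed by
unit-cost dynamic programming over node states (exact for any node
degree, rooting-independent), and a monophyly check of the variant leaf
set in the unrooted sense (the set or its complement is a bipartition
side; sets of size ≤ 1, or missing at most one leaf, are trivially
monophyletic). A single clade-restricted co-loss therefore reads:
agreement 1, one change per trait, zero XOR changes, monophyletic.

These statistics are defined by this package to make a claim that is
usually argued by visual tree comparison testable; reports label them
as such.

## Biophysical models

All fits use `scipy.optimize.least_squares` with tight tolerances
(1e-12) and report a convergence flag instead of raising; temperatures
are Celsius at interfaces and kelvin internally, R = 8.314 J·mol⁻¹·K⁻¹,
energies in kJ/mol.

**Thermal melts** use the two-state van't Hoff model with linear
baselines and ΔCp = 0:

    y(T) = [(a_N + b_N·T) + (a_U + b_U·T)·K(T)] / (1 + K(T)),
    K(T) = exp[−ΔH_vH (1 − T/T_m) / (R T)]

Initialization: T_m from the steepest finite-difference slope,
baselines from linear fits to the first/last 20% of points, ΔH_vH
300 kJ/mol. A trace whose signal range does not exceed ten times a
robust noise floor (second-difference MAD) is flagged non-converged
without fitting ("no resolvable transition").

**Chemical denaturation** uses the Santoro–Bolen linear-extrapolation
model at 298.15 K, `K(c) = exp[−(ΔG_H₂O − m·c)/(RT)]`, with the same
baseline treatment; the midpoint is `C_m = ΔG_H₂O/m`. Points at or
above a configurable denaturant concentration (default 3.0 M) are
removed before fitting and their count reported — the standard practice
of discarding the highest-concentration samples whose baseline
behaviour is unreliable. These specific functional forms (and ΔCp = 0)
are this package's fixed choices of the standard two-state equations.

**Kinetics** are single-exponential, `A(t) = A∞ + (A0−A∞)e^{−kt}`,
suitable for first-order label-release assays and polymerization
progress curves; a constant trace yields k = 0 exactly. Repeated plate
reads are reduced to the mean of the last n (default 5 of 9) reads.
Relative rates divide each construct's k by a reference construct's k.

**Spectral reduction.** Emission scans are reduced to their centre of
mass Σ(λI)/Σ(I); CD signals are normalized to mean residue ellipticity
θ/(10·l·c·n).

## Structural geometry

PDB files are parsed with gemmi, keeping the first model and, for
alternate conformations, the highest-occupancy location per
(chain, residue, atom) key; element assignment falls back to atom-name
parsing when the element column is blank. Superposition pairs Cα atoms
by identical chain + residue number (appropriate for a mutant vs its
parent structure) or by an explicit pairing table for cross-species
comparisons, then applies the closed-form Kabsch SVD solution with the
determinant correction enforcing a proper rotation. Metal contacts list
all non-water, non-metal atoms within a closed-interval cutoff
(default 2.6 Å; coordination bonds to Zn/Mn/Mg sit near 2.0–2.1 Å) of
each metal in the default set Zn, Mn, Mg, Ni, Co, Cu.

## Synthetic data: what it emulates and what it does not

The generator is first-class, tested code. Its defaults are the study
conditions of the analysis, chosen once:

* **Tree**: Yule process, birth rate 1, 30 taxa, tips extended to the
  present (clock-like). The expected total branch length is (n−1)/λ,
  which the test suite checks across replicates.
* **Alignment**: 250 columns (covering the panel span to residue 203),
  indel-free so that columns equal residue numbers and no aligner is
  needed; per-site substitution probability `1 − e^{−0.05·branch}` with
  uniform replacement residues. Panel sites are held at consensus
  except in the implant clade, so classification ground truth is exact.
* **Variant clade**: the internal edge closest to 40% of taxa; sites
  1, 4, 9 (the three histidines most often lost in real variant
  domains) substituted, arginine with probability 0.8 and glutamine 0.2
  (arginine being the most frequent replacement observed in nature).
  Twenty marker columns carry a shared derived state in the clade,
  giving the tree stage clean, homoplasy-free clade signal.
* **Loop deletions**: 20% of taxa (the observed ballpark for loop
  absence), drawn from the variant clade so that canonical/variant
  ground truth stays exact, never the reference taxon; an 11-column gap
  block around the site-7 column.
* **ε cohort**: clade taxa receive a DEDDh + tail sequence with
  probability `epsilon_concordance` (default 1.0); non-clade taxa
  receive DEDDy decoys with probability 0.5. The background alphabet
  excludes D/E/H/W/Y so implanted motifs are provably unique and anchor
  positions are exact ground truth.
* **Curves**: melts on a 20–70 °C, 1 °C grid with T_m 46.0 / 44.0 /
  42.0 / 39.4 °C across the wild-type-to-quintuple-mutant series (the
  endpoints are the observed values; the intermediates are interpolated),
  ΔH_vH 300 kJ/mol; denaturation on 0–3.0 M in 0.2 M steps (so the 3 M
  exclusion rule is exercised) with ΔG_H₂O 20 kJ/mol, m 10 kJ/mol/M;
  kinetics with rates 0.010/0.005/0.005/0.0025 s⁻¹ (mutants at roughly
  half the wild-type rate); Gaussian noise σ = 2% of signal range.
  Spectra are equal-area two-Gaussian mixtures (native 330 nm, unfolded
  350 nm) so the centre of mass is exactly linear in the unfolded
  fraction.

Real data differ in ways the generator deliberately ignores: empirical
substitution matrices and rate heterogeneity, indel evolution beyond
the single loop block, paralogy and incomplete genomes in the ε search,
ΔCp ≠ 0 and instrument drift in the biophysics. Passing tests therefore
demonstrate correctness of the algorithms under their stated models,
not performance on any particular biological dataset.

## Problem sizes and numerical choices

Test and acceptance workloads are sized for quick, deterministic runs:
NJ optimality is enumerated up to 6 taxa (105 topologies), parsimony up
to 8 leaves, melt-bias Monte Carlo at 200 replicates, permutation tests
at 999 permutations, orientation-oracle checks on 10-point clouds.
Fitting tolerances are 1e-12; NJ Q-ties use a 1e-12 comparison band;
p-values carry the +1 correction; report rounding is fixed (supports
3 d.p., agreement 4 d.p.) so reruns are byte-identical.

## Known limitations

* No ML/WAG distances; trees are distance-based NJ only.
* The permutation null is not a phylogenetic null model.
* The ε scanner is pattern-based, not homology-based; sensitivity and
  specificity on real proteomes are uncharacterized.
* Cross-species superposition requires a user-supplied pairing; no
  structure-based alignment is computed.
* No mmCIF parsing; no dose–response (metal titration) modelling; no
  ΔCp-dependent stability curves; no global multi-probe fits.
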