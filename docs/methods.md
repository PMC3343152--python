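# Methods

This note documents the statistical models and numerical choices behind
`qensemble`, the assumptions they rest on, and what the synthetic-data
validation does and does not demonstrate.

## Ensemble representation

An ensemble is a set of conformations of one peptide chain.  The core
representation is per-residue backbone dihedrals in degrees within
(−180, +180]: φ(i) = C(i−1)–N(i)–Cα(i)–C(i), ψ(i) = N(i)–Cα(i)–C(i)–N(i+1)
and ω(i) = Cα(i)–C(i)–N(i+1)–Cα(i+1), the peptide-bond torsion *following*
residue i (so the bond preceding a proline at position j is ω(j−1)).
φ of the first residue and ψ, ω of the last are undefined; they are
stored as NaN, surfaced as "NA" in files, and excluded from every
population denominator.  Torsion signs follow the standard IUPAC
convention (an ideal right-handed α-helix reports φ ≈ −57°), verified
against biotite's independent rotation-based implementation.  All
user-facing residue indices are 1-based.

PDB coordinate fields carry three decimals, which bounds the accuracy of
dihedrals recomputed after a PDB round trip at roughly 0.05–0.1°; the
in-memory dihedral→backbone→dihedral round trip is exact to < 1e-4°, and
TSV round trips (4-decimal angles) to < 1e-3°.

## Ramachandran regions

Four regions partition the (φ, ψ) torus: α_R, α_L, PPII and β.  Default
boundaries are axis-aligned rectangles (half-open, ψ-intervals may wrap
across ±180°):

| region | φ | ψ |
|---|---|---|
| α_R | [−180, 0) | [−120, +50) |
| α_L | [0, +180) | [−50, +120) |
| PPII | [−110, 0) | [+50, +180) ∪ [−180, −120) |
| β | [−180, −110) | [+50, +180) ∪ [−180, −120) |

Points in the leftover torus area take the region of the nearest
canonical center — α_R (−63, −43), α_L (57, 47), PPII (−75, 150),
β (−140, 150) — under wrapped Euclidean distance, so the assignment is a
full partition and region percentages always sum to 100.  Boundaries and
centers are configuration-overridable.

Because real per-residue populations overlap at region borders, the
default assignment mode is clustering: each residue's defined (φ, ψ)
points are histogrammed on a 5° torus grid and clustered by wrapped
k-means (k = 4, seeded at the canonical centers, ≤ 100 iterations,
deterministic given the data).  Final clusters are re-identified by
their nearest canonical center; if two clusters collapse onto one
center, that residue falls back to hard assignment (logged).  Ensembles
with fewer than 100 defined pairs fall back entirely.  On well-separated
blobs the two modes agree on ≥ 95% of points; clustering only wins when
a population's density gap is displaced from the rectangle border.

An **α̃ repeat** marks a residue in α_R with an adjacent residue in α_L
or vice versa, either order; terminal residues use their single
neighbor and undefined neighbors never match.  Residues preceding a
proline receive no special treatment — the data decide.

Prolines are excluded from all population statistics (the default
residue filter is glutamine).

## Secondary structure and motifs

The DSSP subset is re-implemented rather than wrapped so that synthetic
and dihedral-only ensembles (with ideal-geometry oxygens rebuilt when
absent) run through exactly the same code path.  Amide hydrogens sit
1.0 Å from N opposite the preceding C=O direction; prolines and the
first residue carry none.  A hydrogen bond exists when the
Kabsch–Sander energy E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)
is below −0.5 kcal/mol and |donor − acceptor| ≥ 2; distances are floored
at 0.5 Å and floored pairs never bond.  n-turns (i→i+3,4,5) give G/H/I
by the two-consecutive-turn rule, remaining turn spans T, Cα-direction
changes above 70° over i±2 give bends S, and the standard parallel /
antiparallel bridge patterns give B (isolated) or E (ladder).  Code
priority is H > E > I > G > B > T > S > C; G/I remnants truncated below
their minimum run length by that priority are demoted to turn so the
run-length invariants (H ≥ 4, G ≥ 3, I ≥ 5) hold.  π-helix beyond the
I code, chirality flags and solvent accessibility are omitted.

Motifs defined on top of labels + H-bonds:

- **Strand**: a maximal run of ≥ 3 (variant: ≥ 4) residues with a
  constant region label (β, PPII) or strict α_R/α_L alternation (α̃,
  either phase).  *Isolated* strands have no residue participating in
  any backbone H-bond (side chains are out of scope, so "any H-bond"
  reads backbone–backbone).
- **Hairpin**: two same-kind strand runs (each ≥ 3 residues) separated
  only by a connector of 1–8 residues containing at least one
  turn/bend-coded residue, with ≥ 1 H-bond linking region-labelled
  residues of the two strands.  The connector cap (`max_loop = 8`,
  configurable to ∞) prevents distant strand pairs in collapsed
  globules from registering as hairpins; both H-bonded turns and plain
  bends are accepted in the connector.
- **Turn typing**: an i→i+3 H-bond is a β-turn, typed I-β when both
  middle residues are α_R, else "other β"; an i→i+2 bond is a γ-turn;
  S-coded residues without a turn H-bond count as bends.

Motif prevalence is the percentage of conformations with ≥ 1 instance
inside the polyQ portion of the chain.

## Odds-ratio correlation

For binary residue properties X, Y the odds ratio
OR = (p00·p11)/(p01·p10) equals 1 under independence.  Writing the cell
probabilities as free energies turns ln OR into a double free-energy
difference; the association score is ΔΔG = k_B·T·ln OR (k_B =
0.0019872 kcal/mol/K, default T = 300 K, so k_B·T = 0.5962 kcal/mol),
with positive score = positive association, and asymptotic standard
error k_B·T·√(Σ 1/n_xy).  Zero cells take the Haldane–Anscombe +0.5
correction (flagged) or, with correction disabled, raise / propagate
±∞ explicitly.

Profiles against sequence separation r pool one 2×2 table over all
eligible pairs (i, i+r) and conformations (default; a per-pair
inverse-variance average is available as a sensitivity check).
Eligible residues are glutamines at least `trim` positions from each
end — 5 for chains of ≥ 30 residues, 2 otherwise — because end residues
have systematically different populations.  Conformations are treated
as independent samples in the SE; an effective-sample-size correction
is deliberately not applied (ensembles are assumed subsampled to
near-independence upstream).

Derived diagnostics:

- **Dominant period**: linear detrend of the profile, then a 4×
  zero-padded periodogram restricted to periods in [3, span/2]; the
  power fraction sums the main lobe (one fundamental-resolution width
  around the peak).  Exact-zero residuals report fraction 0.
- **Long-range flag**: true when the mean profile value over r ≥ 10
  exceeds twice the mean standard error over that tail — i.e. the
  profile oscillates around a significantly positive level rather than
  decaying to zero.
- **Profile similarity**: Pearson correlation of two profiles over
  their shared r grid (≥ 3 finite points).

The linear cross-check is the Pearson correlation of ψ′ = wrap(ψ + 100°)
between residues at separation r.  The +100° shift moves the circular
wrap seam into the sparsely populated ψ band between the α_L and PPII
basins, making the linear statistic meaningful for data concentrated in
the α_R (ψ ≈ −43°) and PPII/β (ψ ≈ 150°) bands.

## Radius of gyration

Rg is the root-mean-square distance of the glutamine Cα atoms from
their centroid — prolines excluded so that Q_N and Q_N–P_6 chains are
compared on equal footing.  Histograms use left-closed 0.5 Å bins
aligned to zero.  The distribution is decomposed into k Gaussians by
least squares on the bin densities (Levenberg–Marquardt; trust-region
with a σ floor of window/2 on the flagged refit path).  The model
integrates each Gaussian over the bin (CDF differences) rather than
evaluating at bin centers, removing mid-bin bias at σ comparable to the
window.  Initialization: quantile-spaced means, pooled σ/√k, equal
weights; weights are renormalized to sum to 1; components are sorted by
mean.  The reduced χ² uses per-bin Poisson variance max(count, 1) in
density units with dof = nonempty bins − (3k − 1); an unweighted
variant (uniform variance from the mean bin count) is reported
alongside because the weighting convention of histogram fits is not
standardized.

A caveat established during validation: for overlapping components the
weight split is statistically ill-conditioned — at n = 50,000 the worst
direction has sd ≈ 0.016 for the 0.25/0.45/0.30 reference mixture, and
a converged EM/MLE fit shows the same spread.  Validation therefore
averages fitted parameters over five independent ensembles; single fits
are asserted at the honest single-fit tolerance.

The compaction exponent assumes Rg ∝ N^ν: pairwise estimates
ν_ij = ln(Rg_i/Rg_j)/ln(N_i/N_j) plus a pooled log-log least-squares
slope with its standard error.

Prolyl bonds are cis when |ω| < 90° (the boundary |ω| = 90° goes to
trans — symmetric between the ~0° and ~180° basins); the ensemble splits
into all-trans and cis-containing sub-ensembles for separate Rg
analysis.

## Synthetic ensembles

The generator is the validation substrate, standing in for sampled MD
ensembles that cannot be regenerated at desk scale.  Its defaults are
the study conditions used throughout the tests.

Region labels come from a latent Gaussian copula: per conformation, a
stationary Gaussian process over residue index with covariance

    k(d) = a·exp(−d/λ)·[(1−c)·cos(2πd/P) + c] + (1−a)·[d = 0]

(amplitude a ∈ [0, 1), decay length λ, period P, baseline c = 0.5;
positive semidefinite as a sum of Bochner kernels) is mapped through
the standard-normal CDF and per-residue cumulative marginals ordered
(β, PPII, α_L, α_R).  The copula gives direct, independent control of
the two properties the correlation statistics must recover — decay
length and period.  The cosine term alone cannot reproduce a profile
oscillating around a *positive* level: the log-odds response is
superlinear in the latent correlation and cos(2πr/7) sampled at integer
lags is skewed toward large negative values, so a pure damped cosine
yields a slightly negative tail.  The baseline term supplies the
positive long-range component that a genuinely long-range-correlated
chain exhibits; with λ = 50 on a 40-mer the β-region profile oscillates
around ≈ +0.6 kcal/mol, with λ = 3 it decays to zero.  No claim is made
that this kernel is the physical mechanism.

(φ, ψ) scatter within a region is an independent wrapped Gaussian
around the canonical center (sd 15°, chosen so hard assignment recovers
generated labels ≥ 98% of the time while the borders still see
traffic).  ω is 180° except before prolines, where it is 180° with
probability `omega_trans_prob` (default 0.85 for the Q40-P6 emulation)
else 0°, plus 5° wrapped jitter.  Reference compositions: `q40_like` is
40 glutamines with marginals α_R/α_L/PPII/β = 0.80/0.05/0.07/0.08;
`q40p6_like` appends six prolines.

Backbones are reconstructed by sequential natural-extension (NeRF)
placement with fixed ideal geometry (N–Cα 1.458, Cα–C 1.525, C–N 1.329,
C=O 1.231 Å; N–Cα–C 111.0°, Cα–C–N 116.6°, C–N–Cα 121.7°); carbonyl
oxygens sit in the Cα–C–N(i+1) plane opposite the bisector.  Terminal
undefined angles are replaced by 180° for placement only.  The chain is
not energy-minimized and has no side chains or excluded volume: it is
adequate for hydrogen-bond pattern tests on engineered fixtures
(ideal helix, extended chain, PPII helix, α̃ strand, β-hairpin with a
tuned 3-residue loop, type-I β-turn) and for relative Rg statistics,
but free generation can produce sterically impossible chains.
Consequently, passing tests demonstrate the correctness of the
statistics and detectors, not the physical realism of the ensembles;
absolute motif prevalences of synthetic ensembles should not be read as
predictions for real peptides.

## Reported sizes and determinism

Validation uses 10,000-conformation ensembles for correlation recovery
(20 replicate pairs), 1,000 replicates of n = 2,000 for the
independence-null coverage of the SE formula, and five n = 50,000
ensembles for mixture recovery — sizes at which the targeted effects
sit well clear of their sampling noise.  Every random draw flows from
an explicit integer seed through `numpy.random.default_rng`; identical
seed + configuration reproduce byte-identical outputs, and every CLI
run writes a provenance block (version, seed, config echo, input hash).

## Known limitations

- The DSSP subset omits π-helix chirality details and accessibility;
  bridge detection requires |i − j| ≥ 3.
- Odds-ratio profiles assume exchangeable conformations; correlated
  trajectories will understate the SE unless subsampled upstream.
- The histogram mixture fit is bin-width sensitive at σ ≲ window; the
  CDF-integrated model removes the leading bias but the window remains
  a user choice.
- The generator's within-region scatter is uncorrelated between φ and
  ψ and between residues; only region membership carries the injected
  inter-residue correlation, so ψ-based Pearson profiles on synthetic
  data are attenuated relative to the odds-ratio profiles (they remain
  strongly rank-correlated, ≳ 0.99 profile similarity at these sizes).
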