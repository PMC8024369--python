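# Methods

`bundlestab` models the rational thermostabilisation workflow for a de novo
four-helix-bundle dimer: find buried hydrophilic residues, enumerate and
rank substitutions at those sites, quantify stability gains from thermal
denaturation curves, and characterise oligomeric state by SEC–MALS mass
assignment and small-angle X-ray scattering. This document states the
models, the numerical choices, and their known limits. All reference
datasets shipped with the package are synthetic and generated by
`bundlestab.synthetic_data`; every generator records its parameters and
seed so ground truth is exact.

## Solvent accessibility and the buried-hydrophilic screen

Per-atom solvent-accessible surface area (SASA) uses the Shrake–Rupley
method: a deterministic Fibonacci lattice of 960 points per atom on the
solvent-extended sphere (van der Waals radius + 1.4 Å probe; radii C 1.70,
N 1.55, O 1.52, S 1.80 Å), counting points not enclosed by any
neighbour's extended sphere. Properties and limits:

- Exact for an isolated atom (quadrature weight is uniform).
- Translation-exact: the lattice is atom-centred, so rigid translations
  reproduce areas bitwise.
- Rotation-invariant only to lattice resolution: the lattice is
  axis-aligned, so rotations perturb per-atom areas by ≲2% of a
  single-atom area and totals by ≲0.1% at 960 points.
- Agrees with an independent implementation (biotite, same radii and
  probe) to <0.1% in total on a test bundle, and with a 50 000-point
  Monte-Carlo oracle to <2%.
- The method detects only contact-range occlusion. Enclosure by atoms
  beyond contact distance of the probe-extended sphere does not reduce
  SASA; burial in a protein core is a statement about packed neighbours,
  not about topological enclosure.

Relative accessibility divides each residue's SASA by the same residue's
SASA in an extended Gly-X-Gly tripeptide built from idealised backbone
geometry. A residue is *buried* when its ratio is ≤ 0.11; the screen
reports hydrophilic residues (R, K, H, D, E, N, Q, S, T, Y) buried in
both chains of the dimer. On the synthetic C2-symmetric stand-in bundle
the screen recovers exactly the five designed buried-polar positions
{26, 74, 78, 79, 86} with the exposed polar decoys rejected.

## Mutant construction and ranking

Saturation mutagenesis enumerates all 19 substitutions per site (wild
type included once as reference). Mutant structures keep the backbone
bitwise unchanged and rebuild the side chain from ideal internal
coordinates (NeRF chain extension from fixed bond lengths, angles and
template dihedrals); this is a naive placer — no rotamer search, no
clash relief — sufficient for topology-level screening, not for
energetics.

Constructs are scored by unfolding propensity: replicate trajectories per
construct, endpoint Cα RMSD after Kabsch superposition (proper rotations
only; reflections are excluded by the determinant correction), aggregated
as mean ± SD over replicates. Ranking is by ascending mean RMSD with SD
as tie-breaker; post-scan filters flag (not delete) glycine substitutions
at helical sites and constructs whose replicate SD exceeds twice the
per-site median. Two trajectory sources exist deliberately: a
Metropolis Monte-Carlo surrogate unfolder (Gō-like native-contact
energy, temperature factor controlling drift) and a seeded Gaussian
diffusion generator whose drift scale is tied to each construct's
assigned stability. Both are synthetic stand-ins for molecular dynamics;
they let the pipeline's statistics be validated against known ground
truth (the surrogate's mean endpoint RMSD is monotone in temperature and
reproduces the initial structure exactly at T = 0).

## Two-state melt fitting

Thermal denaturation follows the two-state, ΔCp = 0 model:
ΔG(T) = ΔH·(1 − T/Tm), f_folded = 1/(1 + e^(−ΔG/RT)) evaluated in
log-space (no overflow for any argument; f(Tm) = 1/2 exactly). The
observable is f·(θN + mN·T) + (1−f)·(θD + mD·T) with linear folded and
denatured baselines (slopes per Kelvin). Fitting is 6-parameter nonlinear
least squares (scipy `least_squares`), initialised from the steepest
finite-difference slope and baseline fits to the terminal 15% of points,
with up to three jittered restarts. A curve whose total signal span is
within 5× the point-to-point noise estimate is flagged non-converged
rather than fit.

Parameter uncertainty uses the delete-one jackknife with warm-started
refits; the SE is flagged unreliable when >10% of refits fail. Against a
Monte-Carlo ensemble of 50 independent noise realisations the jackknife
Tm SE agrees within a factor of 2.

Noiseless recovery is exact to ~1e-13 relative; at 2% (of signal)
Gaussian noise the Tm error is ≲0.1 °C on a 100-point curve. ΔTm tables
are referenced to a named parent; double mutants are classified
synergistic / additive / antagonistic by comparing their ΔTm with the sum
of the constituent singles at a 0.5 °C tolerance.

## Oligomer assignment

Monomer mass is the residue-mass sum minus one water per peptide bond.
A280 extinction coefficients use ε(Trp) = 5559, ε(Tyr) = 1197,
ε(Phe) = 0.7 M⁻¹cm⁻¹; sequences without Trp/Tyr are flagged as not
quantifiable at 280 nm. SEC–MALS peaks are assigned the nearest integer
multiple of the monomer mass (minimum 1, ties round up); the residual in
monomer units is reported so off-lattice masses are visible, and mass
fractions that do not total 100 ± 1% produce a warning.

## Small-angle scattering

**Guinier analysis.** Weighted linear fit of ln I vs q² on a
self-consistent window: trim until q·Rg ≤ 1.3 at the upper edge, then
refine the edge by a curvature test (drop points while an added q⁴ term
is significant at 3σ against the observed residual level). A
non-negative low-q slope (aggregation upturn) raises
`NoGuinierRegimeError` instead of returning a number. Known bias: on a
sphere form factor the qRg ≤ 1.3 window overestimates Rg by up to ~2%
(the curve is already convex there); this is inherent to the Guinier
approximation at that window, not a fitting artefact, and the tests pin
it at <2% rather than masking it. The fit is scale-equivariant exactly
in exact arithmetic (floating point leaves ~1e-14). Molecular mass
follows from I(0)/c ratioed to a reference standard of known mass
(default 44.3 kDa), valid for dilute samples of similar scattering
density with S(q) ≈ 1.

**Form factors.** Homogeneous sphere (analytic) and orientation-averaged
homogeneous cylinder (Gauss–Legendre quadrature, 256 nodes). In the rod
limit the cross-section Rg = R/√2 is approached with a finite-length bias
that decays as ~1/(2Lq³); tests assert the convergence trend rather than
an unreachable exact value.

**Indirect Fourier transform.** p(r) on [0, Dmax] as a histogram with
pinned zero endpoints, Tikhonov second-difference regularisation, and the
coefficient chosen at the L-curve corner; negative excursions are
suppressed by an iterated soft penalty and *reported* (never silently
clamped). An undersized Dmax manifests as reduced χ² > 2. On a noiseless
3-nm sphere the recovered p(r) matches the analytic distribution within
2% of peak and Rg within 1%.

**Dmax scan.** Each candidate Dmax is scored by reduced χ², negativity
and the terminal slope of p(r); the smallest Dmax within 5% of the best
score wins. Limitation: for elongated particles this is only reliable at
very low noise (≲1e-4 relative). At percent-level noise χ² keeps
improving with oversized Dmax and the estimate saturates high —
operator judgement (as used by standard IFT software) is not fully
automatable; the tests pin the length-monotonicity property at 1e-4
relative noise and this caveat is the documented reason.

## Pipeline and statistics

The study pipeline chains sasa → scan → melt → correlation from a single
master seed; every stochastic stage derives its seed deterministically,
so two runs with the same config produce byte-identical reports.
Stability–unfolding association uses Pearson r with a two-sided t-test
(n − 2 df) and, as a distribution-free cross-check, a label-permutation
p-value (20 000 permutations, add-one estimator); at n = 7–8 the two
agree to ~1 percentage point for moderate r.

## Open questions / scope limits

- With 8 constructs the correlation p-value treats constructs as
  independent observations; per-replicate correlation would mix
  within- and between-construct variance. The package reports the
  construct-level statistic only.
- RMSD uses Cα selection by default; heavy-atom RMSD is available but
  couples side-chain placement noise into the unfolding signal.
- Ellipticity is fit on the raw scale; normalising to fraction folded
  first changes the noise model and is deliberately not done.
- The synthetic stand-in structure reproduces the buried-polar pattern
  of a natural-like bundle; it is not the crystal structure of any real
  protein and absolute SASA values on real structures will differ by the
  ~2% method spread between SASA implementations.
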