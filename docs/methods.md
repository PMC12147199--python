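# Methods

`gqstack` models the stacking–unstacking equilibrium of multimeric
G-quadruplexes (GQs) formed on long human telomeric overhangs
((TTAGGG)-repeat single strands folding into 2–4 consecutive GQ units).
It combines three layers: an extremely coarse-grained (ECG) Monte Carlo
model of the multimer, a small-angle X-ray scattering (SAXS) forward model
that connects the simulated ensembles to solution scattering, and an exact
two-state transfer-matrix (Zimm–Bragg-like) description that extrapolates
the simulated stacking statistics to arbitrarily long chains.

## 1. The coarse-grained model

Each GQ unit is a hard cylinder (HC) of radius R = 1.48 nm and height
H = 2.21 nm, the dimensions obtained from SAXS-constrained fits of
telomeric 1–4-mers. Three interactions define the model:

- **Hard core.** No two cylinders may interpenetrate. Overlap is decided
  by GJK boolean intersection built on the exact support map of a
  flat-capped cylinder. GJK is exact for convex bodies up to its iteration
  tolerance (~1e-12 here); if the 64-iteration cap is ever reached without
  a verdict the move is conservatively treated as overlapping (a
  measure-zero event). The test suite referees this routine against a
  brute-force Monte Carlo point-membership oracle.
- **Tether.** Consecutive units are joined by the TTA linker, modelled as
  an infinite square well acting between the *rims* of the two facing
  bases: the minimum distance between the two rim circles must not exceed
  L_max. The linker is chemically attached, so the facing-base pair is
  chosen once at chain construction (the pair minimizing base-center
  distance) and never changes during a run. Default L_max = 1.5 nm,
  comparable to an extended three-nucleotide linker.
- **Stacking.** A finite square well of depth u0 acting between the facing
  *base centers*: a junction is bonded (stacked) when that distance is at
  most delta. Both square-well boundaries are inclusive; the convention is
  fixed purely for determinism. The well depth enters only through the
  dimensionless effective temperature T* = kB·T/u0; T* = +inf disables
  the attraction entirely and produces the beads-on-a-string reference
  ensemble.

### Calibration of the stacking range

Neither delta nor L_max is fixed by the cylinder dimensions; with L_max
frozen at 1.5 nm, delta is pinned by a chance-bonding anchor. For a
square-well dimer the equilibrium stacked fraction obeys exactly

    f2 / (1 - f2) = p0 / (1 - p0) * exp(1/T*),

where p0 is the probability that a *free* dimer (attraction off) visits a
bond-satisfying geometry by chance. The reference values f2 = 31.5 ± 0.1%
at T* = 0.190 therefore imply p0 = 0.2376% (consistent with the ~0.2%
chance-bonding rate reported for this class of models). `calibrate_delta`
samples the free dimer and returns the p0-quantile of the facing
base-center distance distribution; running it at p0 = 0.2376% with ten
independent seeds (52 million sweeps in total) gives delta = 1.292 ±
0.002 nm, which ships as `DEFAULT_DELTA`. The anchor was chosen over the
rounder "0.2%" because the stacked-fraction anchor is quoted with ~100x
higher precision and the two are linked by the identity above; the shipped
geometry consequently reproduces a chance-bonding rate of ≈0.23–0.24%.

delta = 1.292 nm is large compared to an atomistic stacking distance: it
is an *effective* range that absorbs the orientational freedom of the
coarse unit, and with the rim tether at 1.5 nm it makes bonded junctions
a ~0.24% sliver of the free-dimer configuration space.

## 2. Monte Carlo sampling

Metropolis sampling with single-unit trial moves: a uniform translation in
a cube of half-width 0.3 nm combined with a rotation of the unit axis by a
uniform angle within ±20° about a random direction (both step sizes
config-exposed; they give 60–85% acceptance across the T* range of
interest here, higher than the 30–50% one would tune for in a denser
system because most of the configuration space is an open tether volume).
Moves violating the hard core (any pair involving the moved unit) or a
tether constraint are rejected outright; otherwise the square-well energy
difference dE (in units of u0, i.e. the change in bonded-junction count
times -1) is accepted with probability min(1, exp(-dE/T*)). At T* = +inf
every constraint-respecting move is accepted, which samples the uniform
measure on the allowed configuration space.

Randomness comes from the NumPy legacy MT19937 generator seeded inside the
compiled kernel, making every run bit-reproducible from its integer seed.
Ensemble averages carry block-averaged standard errors (10 contiguous
blocks of the snapshot series), which absorbs the autocorrelation of the
Metropolis chain at the measured block sizes. No cluster or crankshaft
moves are implemented: with n <= 10 units the single-particle dynamics
equilibrates in well under the default budgets.

Default production budgets (chosen as a compromise between statistical
error and minutes-scale runtimes on a single core; all config-exposed): 10^6 sweeps for the
dimer and several 10^5 for the longer chains give bonded-fraction standard
errors of roughly 0.7–1.2 percentage points.

## 3. Ensemble observables

- **Bonded fraction** f_n: the bond indicator averaged over all junctions
  and snapshots.
- **Junction angle beta**: the angle between consecutive unit axes,
  histogrammed in 2° bins (resolving the ~15° peak of the stacked
  component without starving bins). Because the stacking well is square,
  the conditional beta distributions inside and outside the well are
  exactly temperature-independent; the mid-T* distribution is therefore an
  almost exact two-component mixture of a "very low T*" basis (taken at
  T* = 0.050, where the dimer is essentially always stacked) and a
  "T* = +inf" basis. `mixture_weight` solves the one-parameter
  least-squares mixture in closed form (uniform bin weights; per-bin
  error weighting would change the estimate by less than its Monte Carlo
  scatter) and the recovered weight p estimates the bonded fraction.
- **Chance-bonding rate**: the bond-geometry rate in a T* = +inf ensemble
  (see calibration above).
- **U-turn bending**: a snapshot counts as bent when the best-fit circle
  through the unit centers (PCA plane + Kasa fit) has a radius within
  ±25% of the target arc radius, the centers advance monotonically in
  angle around the fitted center, the subtended angle is >= 160°, and the
  rms radial scatter is <= 8% of the fitted radius. All four thresholds
  are parameters. The measured fraction depends strongly on the chosen
  arc radius: for the 4-mer at T* = 0.190 it is below 2% for tight arcs
  commensurate with the unit height (r ≈ H), but grows to several percent
  for wider, looser arcs. Any quantitative statement about bending must
  therefore cite the criterion used.

## 4. SAXS forward model and fitting

The scattering amplitude of a flat-capped cylinder at angle alpha between
its axis and the scattering vector is A(q, alpha) =
[2 J1(qR sin a)/(qR sin a)]·sinc(qH cos a/2) (volume-normalized, uniform
contrast). A configuration scatters coherently:
I(q) = <|sum_i V_i A_i exp(i q·r_i)|^2>, with the orientational average
taken over a spherical Fibonacci quadrature (default 300 directions; the
single-cylinder curve agrees with 1-D adaptive quadrature to better than
1e-4 relative, and doubling the direction count moves multimer curves by
well under 0.5%). Ensemble curves average up to 200 evenly spaced
snapshots and report the snapshot standard error.

Model-experiment comparison profiles out an intensity scale and a constant
background in closed form (weighted linear least squares; unweighted when
the data carry no error column), after log-linear interpolation of the
model curve onto the data grid. The structural parameters (R, H, T*) are
fitted by an exhaustive, seeded grid search — Monte Carlo noise makes the
chi-square landscape non-smooth, so gradient-free exhaustive search over a
small grid mirrors how such coarse models are actually matched to data.
Experimental curves are read from ATSAS-style 2- or 3-column text files,
with an explicit flag declaring the q unit (nm^-1 or A^-1).

No experimental curves ship with the package; the synthetic generator
(below) stands in for them, which means the SAXS stage is validated by
parameter recovery, not against measured telomeric profiles.

## 5. Transfer-matrix (helix-coil) model

Units are stacked (B) or unstacked (U); the first unit is U by convention;
a unit is B when its junction with the predecessor is engaged. Conditional
weights: q(B|U) = q(B|B) = s, q(U|B) = 1, q(U|U) = sigma, with the second
unit contributing 1 (U) or s (B). Here sigma is *not* the Zimm–Bragg
nucleation constant: it is an excluded-volume correction penalizing two
consecutive unstacked junctions, whose neighbours would otherwise be free
to collide. The transfer matrix G = [[sigma, 1], [s, s]] has eigenvalues
lam_{0,1} = (s + sigma ± sqrt((s-sigma)^2 + 4s))/2 (the discriminant is
strictly positive for s > 0, so the pair never degenerates), and the
partition function has the closed form

    Q_n = [(lam0^n - lam1^n) + (1 - sigma)(lam0^(n-1) - lam1^(n-1))]
          / (lam0 - lam1).

The stacked fraction follows by analytic differentiation,
f_n = s/(n-1) d ln Q_n/ds, and the stacking free energy is
dG_s(n) = -kB·T·(n-1)·ln(f_n/(1-f_n)) (natural logarithm; this makes the
identity s = exp(-dG_s(2)/kB·T) exact, because Q_2 = 1 + s). Free-energy
conversions default to T = 293 K with kB = 1.9872e-3 kcal/(mol·K); this
temperature reproduces the reference free-energy table from the reference
fractions to their quoted precision and is config-exposed. An exhaustive
enumeration over all 2^(n-1) states (exact arithmetic for rational inputs,
guarded at n <= 20) serves as the independent oracle for both Q_n and f_n;
closed form and enumeration agree to better than 1e-12 relative across a
wide (s, sigma) grid.

Fitting (s, sigma) to a stacked-fraction series uses bounded nonlinear
least squares (bounds (0, 10]^2, five fixed starting points, deterministic;
the Jacobian is taken by finite differences — the 2-parameter problem is
well-conditioned and the multistart guards the only realistic failure
mode). Parameter uncertainties come from the Jacobian at the optimum,
scaled by the residual variance when the series carries no error bars.
Fitting the reference fractions (0.315, 0.350, 0.369 at n = 2, 3, 4)
yields s = 0.458 ± 0.010, sigma = 0.762 ± 0.027.

**Unstacked multiplets.** The default reading of "the fraction of m
consecutive unstacked units in an n-chain" is the Boltzmann expectation of
the fraction of the n-m+1 length-m windows that are entirely unstacked
(the density of binding sites for ligands spanning m units). The
alternative reading — the probability that at least one such run exists —
is available via `mode="any_run"`. Both are computed by enumeration.

**Specific heat (optional).** The square-well model fixes only the
dimensionless weights, so C(T) requires an explicit user-supplied mapping
s(T), sigma(T); the curve is then obtained from U = kB·T^2·d ln Q/dT by
central differences on the user grid and is exactly zero for constant
mappings. The result is flagged as assumption-dependent: no particular
thermal calibration ships with the package.

## 6. Synthetic data

`gqstack.synthetic` generates every pipeline input from known ground
truth: SAXS curves (simulate at (R, H, T*), add Gaussian noise — default
2% relative, typical of a well-exposed synchrotron curve at mid q; the
sigma column records the applied noise), stacked-fraction series from
(s, sigma), and junction-angle histograms from planted two-component
mixtures. Noise-free outputs are exactly the forward models, and all
generators are bit-reproducible from their seeds.

What the generators do *not* emulate: instrument smearing, buffer
subtraction residuals, inter-particle structure factors, GQ topology
mixtures (hybrid-1/hybrid-2), or concentration effects. Passing recovery
tests therefore demonstrates the internal consistency of the pipeline on
idealized data, not robustness to every artifact of measured curves.

## 7. Known limitations

- The tether length L_max is not experimentally pinned here; the shipped
  1.5 nm is a physically motivated default. The emergent second-neighbour
  penalty depends on it: with this geometry the simulated 3- and 4-mer
  stacked fractions at T* = 0.190 come out around 33–34%, i.e. an
  effective sigma ≈ 0.95 rather than the reference 0.76 (a 5–9% relative
  difference in f_3, f_4). A shorter tether would deepen the
  excluded-volume penalty; we deliberately do not tune it.
- The bending ("U-turn") fraction is criterion-dependent (see §3).
- The SAXS stage is validated by synthetic parameter recovery only.
- delta and L_max enter as sharp square wells; all conclusions inherit the
  square-well idealization (no soft shoulders, no electrostatics).
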