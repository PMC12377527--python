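# Methods

`mlpforge` is a desk-scale implementation of the concurrent-learning
workflow used to assemble training sets for machine-learned interatomic
potentials of small organic (drug-like) molecules, together with the
benchmark suite such potentials are judged by: torsion-profile metrics,
relaxed-geometry comparison and finite-temperature MD error statistics.
Every stage runs in seconds on one CPU because the expensive components of
a production pipeline — the quantum-chemical labeler and the deep
potential ensemble — are replaced by an analytic force field and a
committee of closed-form surrogate regressors.  The *logic* of the loop
(deviation-based selection, curriculum, stopping rule, accounting) is the
object of study and is implemented in full.

Units are fixed package-wide: kcal/mol, Angstrom, femtoseconds, Kelvin;
k_B = 0.0019872041 kcal/mol/K.  The 70 kJ/mol bias cap converts to
16.73 kcal/mol; committee-deviation thresholds quoted in eV/A convert by
1 eV/A = 23.0605 kcal/mol/A.

## The labeling oracle

The reference method is a classical force field with harmonic bonds
`k_b (r - r0)^2`, harmonic angles `k_a (theta - theta0)^2`, Fourier
torsions `sum_n V_n (1 + cos(n phi - gamma_n))`, Lennard-Jones and Coulomb
nonbonded terms (1-2/1-3 excluded, 1-4 scaled by 0.5 / 1/1.2,
Lorentz-Berthelot combination, no cutoff — molecules are small and the
oracle stays exactly smooth).  Forces are the exact analytic negative
gradient; finite-difference agreement is asserted to 1e-5 relative in the
test suite.  Omitted torsion entries contribute zero (the usual force-field
convention); bond and angle terms must cover the topology and a missing
term is rejected by name.

`perturb_params` produces "degraded oracles" — every continuous constant
jittered by `c -> c (1 + scale * g)`, g ~ N(0,1), clipped non-negative —
which play the role of cheaper, less accurate comparator methods in the
benchmark demonstrations.

## Fixture molecules

Four families of parameterized toys emulate the structural motifs of
drug-like sets: plain carbon chains, six-rings with a two-atom tail,
biaryl-like ring pairs joined by one rotatable bond, and multi-torsion
chains.  Element labels matter only for masses and descriptor channels.
Bond and angle reference values are read off the ideal geometry, so every
enumerated term is parameterized and the ideal geometry is the oracle
minimum.  Each rotatable bond carries one two-fold Fourier term with
V2 = barrier/2; because fixtures default to bonded terms only, a
constrained scan reproduces the declared barrier essentially exactly
(the 5% realization check in the tests is far exceeded).  Force constants
(k_b = 300 kcal/mol/A^2, k_a = 60 kcal/mol/rad^2, r0 = 1.53/1.40 A,
theta0 = 111/120 degrees) are typical organic single-bond values.

What the fixtures do *not* emulate: hydrogen atoms and their fast modes,
electrostatics and conformational polarization, aromatic pi systems, and
chemical diversity at scale.  Tests passing on these fixtures show the
workflow's machinery is correct, not that the surrogate family would
reach any particular accuracy on real molecules.

## Torsion collective variables

A bond is a torsion CV when it is single, both endpoints have further
neighbors, and it lies on no cycle.  The no-cycle condition is our
tightening of the usual coordination-number rule: rigidly rotating a ring
bond is geometrically invalid, and rotatable-bond datasets mean exocyclic
single bonds.  One representative dihedral per CV bond is formed from the
lowest-index neighbor on each side — a deterministic convention; any
dihedral about the bond differs only by a constant offset for rigid
substituents.  Dihedrals follow the IUPAC sign convention, range
(-180, 180]; collinear geometries raise an explicit degenerate-geometry
error rather than returning NaN.  Note that torsion angles are invariant
under atom-order reversal (A,B,C,D) -> (D,C,B,A); they change sign under
mirror reflection.

## The committee surrogate

Each committee member maps per-atom environment descriptors to a per-atom
energy; the molecular energy is the sum, so the model is extensive and its
forces are analytic.  Descriptors are per-element-channel radial sums
`F_cm = sum_{j in c} g_m(r_ij)` with Gaussians g_m on 10 centers between
0.8 and 5.2 A under a smooth cosine cutoff at 6 A, plus a rotation-invariant
vector moment `A_cm = |sum_j g_m(r_ij) u_ij|^2` that carries three-body
(angular) information.  A member's readout is

    e_i = b_e + w_e . z_i + v_e . tanh(W z_i + c),

element-resolved, where z is the normalized descriptor vector and (W, c)
is an *untrained* random feature layer drawn from the member's seed.  The
readout (b, w, v) is linear in the parameters, so training is a joint
energy+force ridge least-squares solve — deterministic, bitwise
reproducible, with a recorded non-increasing loss.  Committee diversity
comes entirely from the seed-dependent feature layers; warm starts reuse
the previous readout as the loss-history origin and inherit the
normalization statistics, which are frozen after the first fit.

Two design points matter for the loop's health and were chosen for cause:

* the **linear channel** keeps forces (and committee disagreement) alive
  outside the training distribution, where tanh units saturate; without
  it an exploded geometry beyond the cutoff yields zero features, zero
  forces from every member, and a deviation of exactly zero — the worst
  possible signal;
* the **ridge default of 1.0** stabilizes member-driven dynamics when the
  dataset is small (tens of frames); with thousands of force equations the
  relative regularization becomes negligible.

Defaults (10 centers, width factor 0.6, 64 hidden units) were fixed by a
held-out force-RMSE sweep on chain and biaryl fixtures during development.
The representational ceiling of this family on the fixture oracles is a
held-out force RMSE of roughly 2-3 kcal/mol/A (forces of scale ~20): good
enough for the loop to function and improve, far from the near-DFT
accuracy of production deep potentials — a deliberate trade for
closed-form, seconds-scale training.

## Dynamics, biasing, relaxation, scans

Langevin NVT uses the BAOAB splitting (friction default 0.05 1/fs,
timestep 0.5 fs), which reduces exactly to velocity Verlet at zero
friction; a 10,000-step NVE run conserves total energy to ~1e-3 kcal/mol.
Velocities are drawn from the Maxwell-Boltzmann distribution at the run
temperature with the run seed; the center of mass is not projected out
(immaterial for these observables).  Non-finite energies abort with the
step index, or truncate the trajectory when an immature surrogate drives
exploration.

The dihedral bias is an adaptive kernel bias on one torsion CV with a
bounded total, in the spirit of on-the-fly probability enhanced sampling:
periodic Gaussians (width 25 degrees, height 1.5 kcal/mol, deposited
every 25 steps, well-tempered attenuation factor 10) accumulate into a
sum S, deposition stops where the bias has reached 95% of the cap, and
the applied bias is the smooth soft minimum
`V = -a ln(exp(-S/a) + exp(-cap/a))` (a = 1 kcal/mol), which equals S
below the cap and is strictly below the cap (default 16.73 kcal/mol =
70 kJ/mol) everywhere.  The transform being the identity below the cap is
essential: a transform that flattens the interior of a filled basin parks
the walker at the basin edges, where continued deposition builds walls on
the surrounding slopes and can *raise* the effective barrier instead of
removing it.  With these defaults a 750 K, 20,000-step run crosses a
15 kcal/mol torsional barrier for every seed tried (1-20) while the
matched unbiased 300 K run never leaves its starting well.  No
reweighting or free-energy estimate is attempted — the loop only needs
barrier crossing.

Relaxation wraps L-BFGS with analytic forces, restarting through
line-search stalls, and terminates on a max-per-atom-force criterion; the
accepted (energy-decreasing) path is retained so nonequilibrium frames can
be harvested.  Constrained torsion scans hold the CV with a stiff harmonic
restraint in the wrapped angle (k = 1000 kcal/mol/rad^2), relax everything
else, and report energies *without* the restraint term.  The restrained
optimum sits where restraint and torsion gradients balance, about
slope/k radians (under one degree) off the nominal target; profile
energies correspond to the measured, not nominal, angles.  The successive
protocol seeds each angle from the previous optimum, ascending from the
starting conformation's measured dihedral; the per-angle-seeded protocol
takes supplied starts.  Non-converged points are flagged, never dropped.
The 2D scan applies both restraints over the full outer grid
((360/increment)^2 points), seeding each row from the previous row's first
point.

## The concurrent-learning loop

The committee disagreement signal is the maximal per-atom force standard
deviation, sigma = max_i sqrt((1/N_m) sum_a |F_i^a - mean_i|^2), with
population normalization, N_m = 4 members by default.  Selection
discards frames with sigma above an upper bound sigma_u (nonphysical
regime), takes the ceil(r_candi * kept) largest-deviation frames as
candidates (ties broken by input order; r_candi default 0.12), reports
sigma_l as the smallest candidate deviation, and labels a uniform
without-replacement subsample (desk default 50-200 per iteration).  A band
mode (lower < sigma <= upper) supports molecule screening.  The stopping
rule declares convergence when the trailing window (default 8 iterations)
of the sigma_l trace has range below a tolerance (default 0.01);
"fluctuation" is read as max - min.  Deviation thresholds are quoted in
the conventional eV/A of the deep-potential ecosystem and converted to
kcal/mol/A internally: sigma_u = 0.5 eV/A = 11.53 kcal/mol/A, band
(0.15, 0.45) eV/A, tolerance 0.01 eV/A.

Each curriculum stage admits molecules up to a heavy-atom bound and ramps
exploration temperature and run length linearly across its iterations
(e.g. 300 -> 750 K, 300 -> 600 steps), so early iterations probe gently
near trusted data.  Molecules entering a stage contribute their
relaxation-path frames before exploration starts, and the initial dataset
is the stage-0 relaxation paths plus 15 labeled jittered copies (0.05 A)
of each optimized endpoint — one descent path alone carries no curvature
information and the first committee would otherwise be unusable.
Exploration is driven by member 0, as in query-by-committee practice;
frames whose bonded distances leave [0.5, 1.8] x r0 are screened out as
nonphysical before deviation ranking (this physicality screen does the job
the upper bound does in production loops; our committee's
out-of-distribution failure mode is force collapse rather than explosion,
so sigma alone cannot flag exploded geometries).  All randomness is
threaded from explicit seeds through `numpy.random.SeedSequence`; reruns
are bitwise identical.

At desk scale the sigma_l trace behaves qualitatively as in production —
it declines as the dataset grows — but its iteration-to-iteration
fluctuation (~0.1-0.3 eV/A) sits far above the 0.01 eV/A stopping
tolerance: sigma_l is an order statistic of a handful of candidates drawn
from exploration pools of ~10^2 frames, versus ~10^5 frames and candidate
sets of thousands in production, so its sampling noise alone exceeds the
tolerance.  The stopping rule is therefore exercised with looser
tolerances in the demos, and the strict tolerance is reported as measured.

The manifest tracks per-category molecule and configuration counts by
source (relaxation-path, md, scan) in exact integer arithmetic; the
published training-set manifest ships as a CSV resource and its totals
(1,363,587 configurations over 97,213 molecules) are recomputed, not
stored.

## Benchmark metrics

Torsion-profile MAE and RMSE operate on relative energies (reference
point: first scan point, profile minimum, or first trajectory frame,
chosen per protocol) and average per-molecule bin statistics over
molecules; the RMSE takes the root of the per-molecule bin-mean square
*before* the molecule average — the nesting is implemented exactly as
conventionally printed, not as a pooled RMSE.  The barrier of a profile is
max - min; MAEB is the mean absolute barrier error and NABH counts
profiles with error strictly greater than 1 kcal/mol (chemical accuracy).
Geometry comparison reports Kabsch RMSD (proper rotations, all atoms by
default, optional mask; the residual is recomputed from the optimal
rotation for full precision near zero) and bond/angle/torsion MAEs with
the circular metric for torsions (179 vs -179 degrees is 2 degrees);
degenerate torsions are skipped and counted.  Trajectory error statistics
report relative-energy MAE/RMSE (each method referenced to its own first
frame, so constant offsets cancel), force-component MAE/RMSE over all 3N
components, and the per-frame aggregate force-error magnitude
`||dF|| = sqrt((1/N) sum_i |dF_i|^2)` with its own MAE/RMSE.

## Reproducibility and problem sizes

The test suite and the acceptance script use fixed seeds throughout and
desk-scale problem sizes chosen as the package's own study conditions:
4-12 heavy-atom fixtures, 5-iteration loops with 100-frame exploration
pools and up to 100 labels per iteration, 10-20 ps sampling runs, 200
short trajectories for the subsampling protocol, and a full 36 x 36
constrained 2D scan.  File outputs are written atomically (temporary file
plus rename), so interrupted runs never leave truncated artifacts.

## Known limitations

* The surrogate family's accuracy ceiling (see above) bounds how sharply
  the committee can converge; sigma_l stabilizes in the 0.1-0.5 eV/A
  range on fixtures rather than collapsing toward zero.
* Barrier crossing under the capped bias is stochastic; at the default
  schedule a 20,000-step 750 K run crosses a 15 kcal/mol barrier for the
  large majority of seeds, but no finite run guarantees it.
* No hydrogens, charges, or periodic boundaries; no SMILES or 3D
  embedding — fixtures carry their own coordinates.
* The loop explores with a single member and one bias CV per molecule per
  iteration; production pipelines parallelize both.
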