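# Methods

## Forward model

The volume conductor is a set of concentric spherical shells with piecewise
constant conductivity under the quasi-static approximation.  For a point
current source on the scalp surface the potential in every shell is a
Legendre series `V = Σ_l (A_l r^l + B_l r^-(l+1)) P_l(cos γ)`; the
coefficients follow from continuity of potential and radial current density
at each interface and from the injected surface current density at the scalp.
The degree-0 term of a lone source does not conserve current and is dropped —
it cancels exactly in the source/reference pair from which every lead-field
column is built.  All per-degree systems are solved in radii scaled to the
scalp radius so the powers stay O(1) at any series order (naive conversion to
unscaled powers underflows beyond degree ≈ 300).

Defaults: four shells of radii 92/86/80/78 mm with conductivities
0.465 (scalp), 0.010 (skull), 1.654 (CSF), 0.276 (gray matter) S/m; white
matter (0.126 S/m) is available as an optional fifth shell.  Units are fixed
throughout: mm, mA, S/m, V/m.  Electrodes are point sources on the scalp
sphere — the optimization consumes only the lead-field matrix, and point
sources keep the model closed-form; a physical contact model would only
smooth the very shallow field.  The 69-electrode default layout is a
deterministic Fibonacci covering restricted to the upper three quarters of
the sphere, standing in for a dense EEG-style cap; the optimizers are
layout-agnostic, so exact 10-10 coordinates are not reproduced.

The series is truncated at `series_order` (default 120).  The truncation
error is monitored as the magnitude of the last accumulated term relative to
the accumulated field; when it exceeds 1e-6 a `SeriesTruncationWarning`
carrying that estimate is raised.  With cortex nodes at ≤ 70 mm and the 78 mm
inner interface, order 120 leaves a relative tail below 1e-6; nodes close to
an interface need a higher order.

Correctness anchor: with all shells set to one conductivity the series must
reduce to the homogeneous sphere, for which the sum has a closed form via the
Legendre generating function
(`Σ x^l P_l = (1−2xc+x²)^{-1/2} − 1`, `Σ x^l P_l / l = log 2/(1−xc+s)`).
The equal-conductivity check against this independent closed form (potential
and its analytic radial derivative) holds to ~1e-14 relative; the acceptance
suite asserts 1e-6.

## Cortex node clouds and targets

Two node samplings are provided.  A single-radius Fibonacci sphere (default
70 mm) is the plain "cortical surface".  For depth studies this is useless:
an anchor moved toward the centre keeps the same nearest surface cap, so
depth would have no effect.  The depth and multi-target studies therefore
default to a volumetric shell — quasi-uniform directions with seeded radii
filling 0.35–1.0 of the cortex radius (volume-uniform in r³) — emulating the
fact that real cortical folds reach depth.  Node normals are radial, the
sphere's stand-in for the cortical-surface normal that pyramidal neurons are
sensitive to.

A depth target with index i ∈ 1..5 is the k = 50 nodes nearest an anchor at
radius (1 − 0.12·i)·r_c along a fixed meridian, preserving the monotone
shallow-to-deep ordering the depth study needs.  Multi-target anchors are
four fixed, well-separated directions (two anterior, two posterior, on
opposite left/right sides) at 0.70–0.75 of the cortex radius; each target
pair is evaluated per region inside an explicit half-space partition (the
splitting plane is a study parameter, never inferred, because anterior pairs
cannot be separated by an anterior/posterior plane).

## Random lead-field fixture

`generate_random_leadfield` draws each column as a random-Fourier-feature
approximation of a squared-exponential Gaussian process over node
coordinates (length scale `smoothness_length`, default 25 mm), multiplied by
`exp(−depth_decay · d)` with `d` the node-to-electrode distance in mm
(default 0.02/mm).  This reproduces the two features of real lead fields the
optimizers interact with — spatial smoothness and shallow bias — and nothing
else: no tissue boundaries, no current conservation across columns, no
anatomical asymmetry.  Tests passing on it show optimizer correctness, not
physiological validity.

## Modulation, metrics and loss

The beat envelope is `2·min(|a|,|b|)`; the algebraically equal (on
sign-agreeing nodes) signed form `|a+b| − |a−b|` is retained as an option.
All *reported* metrics use the non-negative envelope.  The mis-stimulation
count uses a strict inequality (ties at exactly the target mean do not
count), and region areas are node counts — both simple, documented choices.
PR, CR and exact MR are invariant under positive rescaling of the
modulation; the smoothed MR is not, which is why the sigmoid slope (default
1 in this unit system) is exposed.

**Training form (a deliberate deviation).**  Training against the *signed*
difference form makes the loss `MR/(PR·CR)` unbounded below: signed
modulation can drive the total (hence CR) or the non-target peak negative,
and gradient descent then diverges to sign-cancelling montages (measured:
"best" loss −32.6 whose true envelope PR was 0.53).  The default training
form is therefore the envelope, which keeps every ratio non-negative and the
loss bounded below by zero; the signed form remains selectable for
experimentation.

## Safety normalization

Per frequency channel, raw currents are scaled so max |I| = 2 mA exactly,
then rescaled to Σ|I| = 8 mA if the absolute sum exceeds 8 mA.  Exactly one
of the two limits is binding (to 1e-9) for any non-degenerate input, zero net
current is preserved, and the map is idempotent.  Limits are applied per
channel by default — matching two independent stimulators — with a joint
(concatenated-channel) mode available, since hardware could share a current
budget.  Inside the training graph the same map is used with subgradients at
the max/branch points; the branch set has measure zero along a trajectory.

## Generator network and training

The generator is a constant-input MLP: scalar 1 → hidden layers (linear →
ReLU → layer normalization; default three layers of width 64) → linear
output of (M−1) currents per frequency channel (two channels for tTIS, one
for tACS).  The reference electrode's current is the negative sum of the
others, so Kirchhoff's law holds by construction at every step rather than
being learned.  Everything downstream of the generator — normalization,
field superposition, envelope, ratio loss — has fixed, non-trainable
weights.  Training uses Adam (lr 1e-3, default moment decays) for a fixed
number of epochs (default 1000 single-target, 2000 multi-target); the
*best-loss* iterate's currents are returned, since the last iterate of a
non-monotone stochastic-free gradient run is not guaranteed best.  A
non-finite loss aborts with a diagnostic; an all-zero initial output
re-initializes once with seed+1.  With no installed autodiff framework in
the dependency set, gradients come from a minimal in-package reverse-mode
engine (`tistim._autograd`) covering exactly the primitives the pipeline
uses; it is verified against central finite differences through a replica of
the full training graph.

Small instances can still trap gradient descent in local minima (measured on
random 3-electrode/4-node instances: most seeds reach the global optimum
found by dense grid search, some stall at 1.2–3×), so quality claims are
made for a small number of seeded restarts, and the study drivers replicate
over seeds.

## Genetic-algorithm baselines

Two chromosome kinds: `two_pair` (anode index, cathode index, magnitude per
frequency — magnitudes are largely absorbed by per-channel normalization)
and `hd` (all 2·(M−1) free currents).  Operators: tournament selection of
size 2, uniform crossover (rate 0.9), Gaussian mutation on current genes
(scale 0.4 mA, i.e. 0.2 of the ±2 mA range) and random reassignment on index
genes (rate 0.1), elite conservation.  These are conventional defaults, all
exposed in the config; elitism makes the best-loss history non-increasing,
which the tests assert.  The GA minimizes the identical loss as the
generator network so budget-matched comparisons are fair: a gradient run
costs one loss evaluation per epoch, a GA costs population × generations.

## Study problem sizes

The bundled studies and the acceptance script run at desk scale, chosen so a
full suite completes in minutes on one CPU while leaving the qualitative
contrasts (interference vs single-frequency depth robustness, gradient vs
evolutionary search at matched budgets) clearly resolved: 400–800 cortex
nodes, 69 electrodes, 25–50-node targets, 1000 epochs, five seeds.
Replication over seeds on one synthetic geometry stands in for replication
over subjects; it captures optimizer variability only, not anatomical
variability.

## Known limitations

* The sphere has no tissue anisotropy, no cortical folding geometry, and
  radial-only normals; absolute field magnitudes are indicative, not
  subject-specific.
* Neural response is reduced to the beat-envelope amplitude along the normal;
  orientation-free (vector) envelope maximization and physiological transfer
  functions are out of scope.
* The smoothed mis-stimulation area is unit-sensitive through its slope.
* Single-instance optimization only: nothing is learned that transfers across
  head models.
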