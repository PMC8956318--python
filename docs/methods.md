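# Methods

`fentanyltwin` simulates transdermal fentanyl therapy as one coupled
initial-value problem per therapy: a one-dimensional diffusion PDE for the
patch and skin, a five-compartment physiologically based pharmacokinetic
(PBPK) ODE system, and two effect-compartment pharmacodynamic (PD) states.
This note records the model, its assumptions, the numerical choices, and the
design decisions taken where the underlying physiology or literature leaves
the formulation open.

## Drug transport through patch and skin

The domain is a stack of four homogeneous slabs: the patch
(drug-in-matrix, 50.8 um, D = 6.91e-16 m2/s), the stratum corneum
(age-dependent thickness, D = 3.0e-14 m2/s), the viable epidermis
(36.5 um, same D), and an *equivalent dermis*.  Fentanyl moves by Fickian
diffusion; at layer interfaces it partitions with coefficient
K_i/j = K_i/K_j, where K_i is the layer's dimensionless drug capacity
(patch 1, epidermis and dermis 3.4).  Solving for the drug potential
psi = c/K makes the field continuous across interfaces; the governing
equation per layer is the capacity-weighted diffusion equation
K dpsi/dt = d/dz(D K dpsi/dz).

The real dermis clears drug by capillary advection, not pure diffusion.  The
model replaces it by a reduced, purely diffusive thickness calibrated so the
membrane lag time t_D = d^2/(6 D) reproduces the observed 1.5 h delay
between patch application and detectable plasma fentanyl.  Two conventions
coexist for a 20-year-old: the tabulated 320 um (used for the base case) and
the age relation d_Edm = -2.25*Age + 354.5 um, which gives 309.5 um (used
for age sweeps so all ages are treated consistently).  The temperature
dependence of the dermis diffusivity is kept only as a parameterized hook
(`dermis_diffusivity`); its Arrhenius constants must be supplied by the
caller, and without them the constant 3.82e-11 m2/s is used.

Boundary conditions: zero flux at the outer patch surface and at all
peripheral boundaries (hence 1-D); at the dermis base the potential tracks
the plasma concentration computed by the PBPK block (a pure-sink variant is
a configuration switch; at therapeutic plasma levels, ~1e-6 kg/m3 against
skin potentials of order 1, the difference is negligible).  The patch starts
with a uniform concentration equal to load/(area*thickness); the 12.6 mg /
30 cm2 / 50.8 um reference patch gives 82.7 kg/m3.  We anchor on the 12.6 mg
load rather than the rounded 80 kg/m3 sometimes quoted for this patch,
because the mass-bookkeeping outputs (residual ~9 mg after 72 h) are
consistent with 12.6 mg.

### Patch replacement and application sites

Clinical practice puts each replacement patch on a fresh skin site.  The
default `"multi"` mode therefore spawns an independent transport problem per
application: the vacated site keeps its skin depot, gets a zero-flux top
boundary, and keeps releasing stored drug into the blood; the total dermal
flux is the sum over sites.  Sites whose depot has decayed below 1e-4 of a
patch load are retired from the state vector.  A `"reset"` mode (single
site, skin field zeroed at each change) is provided because the original
analysis does not state which bookkeeping was used; the first wear period is
identical in both modes.

## Pharmacokinetics

Five well-mixed compartments: central (plasma + lungs, Vc = 23.8 L), rapidly
equilibrating (24.5 L), slowly equilibrating (muscle/fat, 808 L),
gastrointestinal (17.3 L, draining to the liver) and hepatic (20.4 L, CYP
metabolism at k_met = 4.2e-3 1/s, the dominant elimination route; renal
clearance k_re = 3e-5 1/s removes drug from the central compartment).  The
input term is (dermal flux x area)/Vc.

How the unbound plasma fraction fu = 0.22 enters the transfer terms is
genuinely under-determined in the source literature, and the choice is
consequential: with these rate constants, applying fu only to the pooled
outbound central terms (the "literal" transcription) makes the system
dynamically unstable — the slow-compartment return k_sc*(k_cs/k_sc) = 1.5e-3
1/s exceeds the fu-scaled central loss 7.4e-4 1/s, so every trajectory
diverges.  The package exposes four readings (`fu_mode`); the default,
`"distribution"`, applies fu to the permeability-limited exchange with the
two equilibrating tissues while the clearance pathways (hepatic artery +
portal route, renal filtration) act on total plasma concentration, their
rate constants having been calibrated as clearances over total
concentration.  This is the only stable reading whose whole-body clearance
(~0.7 L/min at quasi-steady state) falls in the clinically reported range
for fentanyl (0.6-1 L/min); the alternatives (`"unbound-all"`, `"none"`,
`"literal"`) are retained for sensitivity studies.  The rate-constant set
itself is not flow-balanced in concentration form, so global
amount-conservation across compartments is not asserted; the input-term
bookkeeping (central amount grows exactly by the delivered mass when all
transfers are off) is.

## Pharmacodynamics

Each effect has a hypothetical effect compartment, dce/dt = ke*(cp - ce),
and a sigmoid-Emax (Hill) relation E = E0 - Emax*ce^g/(EC50^g + ce^g).

* Pain: visual analog scale (VAS), baseline 7 (severe, assumed constant
  cause throughout therapy), Emax 7, EC50 1.35 ng/ml at age 20, gamma 2.7,
  ke 2e-3 1/s.  VAS is continuous internally; only patient reports are
  integers.
* Ventilation: baseline 20 L/min, Emax 12*0.91 L/min, EC50 1.14 ng/ml,
  gamma 2.68, ke 7e-4 1/s.  Hypoventilation duration is reported against a
  configurable threshold (default 12 L/min, an assumption — no standard
  value exists); every output carries the threshold used.

`fit_emax` calibrates Hill parameters from a concentration-effect table by
bounded nonlinear least squares with a deterministic multistart (gamma in
{1,2,4} x EC50 at the data quartiles), because Hill fits are multimodal.

## Aging

Only three parameters depend on age (20-80 y): stratum-corneum thickness
(+0.125 um/y), equivalent dermis length (-2.25 um/y) and the analgesic EC50.
For the latter, the EEG-potency-derived relation EC50 = -1.148e-2*Age + 1.96
ng/ml evaluates to 1.73 ng/ml at age 20, while the calibrated value is
1.35 ng/ml; these cannot be reconciled from the sources.  The default
`"anchored"` mode rescales the relation to pass through 1.35 at age 20 while
preserving its normalized slope; the literal `"equation"` mode remains
available.  PK and ventilation-PD parameters are held age-independent (the
data to model their age dependence are insufficient).

## Therapy policies

* Conventional: n patches (default 3), each worn a fixed interval
  (default 72 h), horizon 216 h.
* Precalibrated twin: at every output step (0.1 h) the patch is replaced iff
  model VAS > 3, dVAS/dt > 1e-3 /h, and the current patch has been worn at
  least `min_wear_h`.  The wear guard defaults to 3 h: fentanyl needs ~1.5 h
  to reach plasma plus further effect-compartment lag, so decisions sooner
  than ~3 h after an application carry no information about the new patch
  and the controller double-fires.  A livelock diagnostic rejects >24
  changes within any 24 h.
* Real-time twin: every 24 h the virtual patient reports an integer VAS
  (model VAS rounded plus an integer deviation in [-2, 2], clamped to
  [0, 10]).  The difference between report and rounded model score persists
  as an additive correction to the controller's working VAS until the next
  report, so a zero deviation leaves the controller exactly on the
  precalibrated trajectory.
* Population: deviations are drawn i.i.d. uniform on {-2,...,2} (the
  maximum-entropy choice under the stated bound) from a single seeded
  generator; 8 moments per patient over 9 days.

## Numerics

Cell-centred finite volumes on 110 cells (30/20/20/40 per layer) with
geometric refinement (ratio 1.3) toward both faces of every layer; interface
fluxes use series resistances (dz/2)/(D K) per side, which realizes the
partition condition exactly at faces.  Doubling the resolution changes the
peak dermal flux by <0.1%, comfortably inside the 0.5% verification gate.
Time integration is SciPy's BDF with rtol 1e-8 / atol 1e-12 (SI
concentration units) and an analytic sparsity pattern (tridiagonal per site
plus an arrow through cp); each segment restarts at local time zero because
a fresh-patch discontinuity at t ~ 2e5 s would otherwise demand steps below
machine spacing.  Dense output is resampled every 0.1 h; controller
decisions, mass bookkeeping and all reported metrics live on that grid.
Masses are audited two ways (initial load = patch + skin + cumulative flux
to blood), closing to ~2e-5 relative on the base case.

"Time without pain" accumulates intervals with VAS strictly below the
target, interpolating threshold crossings linearly.  The sensitivity index
is the central-difference elasticity (dU/dx)*(x/U) at +-1% perturbation,
computed by rebuilding the patient and re-running a single-patch simulation
per evaluation.

## What the synthetic inputs do and do not emulate

The virtual population varies only in its reported-pain deviations; skin,
PK and PD parameters are identical across patients.  Passing population
tests therefore demonstrates controller behaviour under reporting noise,
not inter-individual pharmacokinetic variability, organ impairment, tolerance
development, or skin-site heterogeneity — all outside scope.  The Emax
calibration fixtures are sampled from the package's own pain model (plus
optional Gaussian noise), so recovery tests verify the optimizer, not the
clinical validity of the parameters.

## Problem sizes used in the shipped tests

Test runs use the default 110-cell grid and 0.1 h output step throughout;
the base case is 216 h with three patches, age sweeps use ages 20-80 in
10-year steps, the controller comparison runs the four (site mode x EC50
mode) configurations, and the feedback population uses 100 seeded virtual
patients — the full study size.

## Known limitations

* The skin-depot dynamics are faster than in reference finite-element
  solutions of the same configuration: our dermal flux peaks near 11 h
  (vs reported ~19 h) and retains less drug in the skin at 72 h.  The
  reference base-case values are themselves internally inconsistent at the
  ~20% level (the average-flux/residual/skin-mass triple violates mass
  balance), so exact agreement is not attainable from the tabulated
  parameter set; the derived timing quantities (plasma peak time,
  therapeutic-band entry time) inherit the shift.
* No single fu reading reproduces both the reported plasma curve and the
  reported peripheral-compartment peaks; the slow-compartment peak of
  ~14 ng/ml would require 11 mg stored in that compartment when only ~3 mg
  has entered the body.  The default reading favours a clinically plausible
  plasma clearance.
* Plasma peaks near 1.3-1.5 ng/ml in the base case, so conventional therapy
  yields little time below VAS 3 and the controller's relative gain in
  time-without-pain is much larger than the reported +314%.
* 1-D layered skin; no follicular pathways, adhesion physics, dose-strength
  adaptation, drug-drug interactions, or naloxone reversal.
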