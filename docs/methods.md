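# Methods

## Model

The chromatin fibre is a discrete twistable worm-like chain. Each bead
represents one 10-nm fibre segment (σ = 10 nm ≈ 400 bp); each bond carries
a unit material-frame vector perpendicular to its tangent. The twist angle
at a joint is the rotation from the parallel-transported frame of the
incoming bond to the frame of the outgoing bond, measured about the
outgoing tangent and unwrapped continuously in time. Because frames are
convected by the minimal rotation between successive tangents, the sum of
all joint angles plus the exact polygon writhe is the linking number of
the embedded ribbon; conservation of Tw + Wr on a closed fibre is a
*measured* property of the integrator (drift ~1e-11 turns over 1e5 steps
in the test suite), not an imposed constraint.

Energy terms (reduced units: lengths in σ, energies in kT):

| term | form | default |
|---|---|---|
| bond | FENE centred at l0, diverging at r_max | l0 = 1, k = 100 kT/σ², r_max = 1.5 |
| bending | ½ k_bend θ² per joint | k_bend ≈ 4.82 kT (see below) |
| twist | C/(2 l0) (φ − φ0)² per joint | C = kT·Lt, Lt = 75 nm |
| excluded volume | WCA, cutoff at the sum of bead radii | ε = 1 kT |
| handcuff rigidity | body-frame shape restraint | k = 300 kT/σ² |
| CTCF attachment / anchors | harmonic bonds | k = 50 kT/σ² |

The bending stiffness is calibrated by inverting the exact discrete
relation ⟨cos θ⟩_k = exp(−l0/Lp) for the Boltzmann average over
exp(−kθ²/2) sin θ, so that the *fitted* tangent-correlation persistence
length of the simulated chain equals the nominal Lp = 50 nm. The naive
continuum ratio kT·Lp/l0 (5 kT) under-recovers Lp by about half a bond
length (~10%), which matters because the persistence length is verified by
fitting, exactly as it would be measured.

The FENE stiffness is higher than the classic Kremer–Grest value because
the potential here is centred at the 1 σ equilibrium bond length rather
than at zero: at k = 30 the re-centred bond is five times floppier than a
Kremer–Grest bond and violates the model's own contract that the mean bond
length stays within 2% of 1 σ (the r² Jacobian biases soft bonds long).
k = 100 restores comparable tightness.

## Machinery

**Active swivel (RNA polymerase + TOP1).** The motor advances the rest
angle φ0 of its joint by −sign·2π·ω per unit time; `injected_R`
accumulates ω·dt exactly. The measured twist observable counts the
*elastic deviation* (φ − φ0) at motor joints — the rest angle itself is
the motor's rotation, not fibre twist — which makes
Δ(Tw + Wr) = sign·injected_R an exact identity on a closed fibre. With
sign = −1 the flanking fibre acquires negative twist and, past the
buckling threshold, negative writhe (right-handed interwound plectonemes,
detected with negative Gauss-kernel crossing signs).

**Barrier motors** (continuously transcribing polymerase): the motor joint
becomes torsionally free (no twist exchanged between the flanks) and the
injection is applied by rotating the upstream bond's material frame
directly, so the full dose lands in one flank.

**Passive swivels** are joints with zero twist stiffness; their freely
accumulating angle is excluded from Tw and reported separately. They are
the torsional sinks at TAD borders; the `lk_deficit` ledger
(Tw + Wr − Lk0 − sign·injected_R) measures exactly how many turns have
been dissipated through them (or passed through phantom regions, which
appear as ±2 jumps).

**Threading detector.** Every few steps each ring's centre and best-fit
plane are recomputed; the threaded bead is the nearest fibre bead within
the 1.25 σ aperture radius and within ±1 σ of the ring plane (ties to the
lowest index). Threaded beads carry a 10× multiplier on translational and
rotational drag, all cohesin beads 2×, restored on exit.

**CTCF rule.** A ring is eligible to interact with a CTCF obstacle only
once it has *arrived* at the site along the chromatin (threaded bead
within 10 beads of the attachment bead) — the orientation-specific
C-terminal contact is made by the arriving ring, not by one drifting past
in space. An eligible ring centre within 3 σ of a convergent obstacle
(ring pressing against the 1.75 σ-radius bead) anchors via three harmonic
bonds to its nearest ring beads; at a divergent obstacle a dwell clock
runs from first contact (surviving thermal bounces out to twice the
contact distance) and after 10 τ the whole handcuff dissociates
(restraints, excluded volume and drag couplings removed, beads frozen).

Handcuff rigidity is a harmonic restraint toward the Kabsch-fitted
reference figure-eight (stiffness 300 kT/σ² per bead). A pure
distance-spring network was rejected after measurement: the reference
shape is planar, so its out-of-plane bending modes change pair distances
only at second order and their thermal amplitude scales as k^(-1/4) —
the 0.2 σ rigidity contract was unreachable at any stable pair stiffness.
Fitting the reference to the instantaneous beads before applying the
springs keeps the restraint conservative (envelope theorem) with zero net
force and torque, and every internal mode gets the same first-order
stiffness, far below the integrator stability limit.

## Dynamics

Overdamped Langevin (Brownian) dynamics with the Leimkuhler–Matthews
update (noise averaged over successive steps), which removes the leading
configurational sampling bias of plain Euler–Maruyama at no extra force
evaluation. First-order Euler proved insufficient only in one respect
worth recording: neither scheme was the cause of an apparent softening of
long-wavelength bending statistics — that was traced to starting linear
fibres from a straight rod, whose slow modes need ~1e3 τ to thermalise.
Linear fibres are therefore initialised from the exact ideal-chain
equilibrium ensemble (Boltzmann joint angles by rejection sampling) and
only re-equilibrated locally.

Numerical choices:

* dt = 2e-3 τ (τ = γσ²/kT, γ the drag of one fibre bead), validated by
  the conservation, ledger and persistence-length checks. At 5e-3 the
  thermal kick per step (~0.24 σ between bonded beads) jumps FENE bonds
  past their extensibility limit.
* Force-driven displacement capped at 0.1 σ per bead per step (equivalent
  to sub-stepping steep WCA/FENE walls); thermal noise is never modified.
  The near-wall FENE force is evaluated with its argument clipped at 98%
  of the extensibility range; a bond ever stretching 1.5× past the limit
  aborts the run with a time-step diagnostic.
* Excluded-volume pairs come from a KD-tree neighbour list with a 1 σ
  skin, rebuilt every 8 steps.
* Rotational friction of a bond about its axis: γ_r = 0.1 kT·τ. This puts
  twist transport through plain fibre well above the default injection
  rate (free borders dissipate, as in the border-relaxation experiment)
  while the 10× threaded-bead drag makes the handcuff the dominant
  barrier, so supercoiling accumulates only between the rings.
* Writhe is the exact Gauss double sum over straight segment pairs
  (solid-angle form); coplanar pairs contribute zero analytically.

## Scenarios and scaling

The canonical system is the 300-bead (120 kb) circular fibre; the circle
represents one TAD with its two borders glued at bead 0 (passive swivels
flanked by 3-bead phantom regions sit a few beads either side; CTCF
obstacles, where present, just inside them). The motor sits at bead 150
(fig1–fig3 family) or at bead 75, a quarter TAD from the near border
(fig4/fig5 family), with handcuff arms of 10 and 40 beads in the
asymmetric geometry. Handcuffed scenarios are built in a deterministic
"stadium" conformation that presents the two threading beads one
ring-spacing apart with parallel tangents; the planar start is torsionally
relaxed (Wr = 0, Lk0 = 0).

Desk-scale runs (80–100 beads) keep the injected turns per bead per unit
time fixed by scaling the motor rate as ω = 0.05·(300/n) turns/τ, and
enforce a minimum asymmetric-loop size of 30 beads (a pushing plectoneme
needs ~5 enclosed turns to fill the loop and engage the rings). The test
suite runs: persistence-length recovery on 100-bead linear fibres
(20–40 short replicas, frames pooled, correlation fitted to
s = 8 bonds ≈ 1.5 Lp); the closed-loop injection experiment at
n = 100; border-relaxation and localisation at n = 100 to ~10–12 injected
turns; symmetric extrusion at n = 80 for 450 τ; the asymmetric-arrival
experiment at n = 80 with the near ring a dozen beads from its border; and
the CTCF-orientation comparison at n = 80 from a fully extruded starting
loop (both rings at their border stations), where the anchor/dissociate
outcome and its effect on border-border contacts is reached quickly.

Replica pooling in the persistence-length experiment is essential: one
run of a few hundred τ contains only a handful of independent large-scale
conformations, and single-run fits scatter between ~40 and ~85 nm. The
desk-scale extrusion ratchet is similarly stochastic: individual seeds
reach 70–95% of the TAD within the same horizon, so the extrusion test
pins one reference run rather than asserting an ensemble property.

## What the generator does and does not emulate

The synthetic scenarios reproduce the *mechanistic* conditions of the
modelled system — a torsionally live fibre, count-exact supercoil
injection, border relaxation sinks, geometric ring blocking — on clean,
monodisperse fibres with a single motor and a single handcuff. They do
not emulate nucleosome-scale structure, sequence heterogeneity,
polymerase traffic, cohesin loading/unloading kinetics beyond the border
event rule, or hydrodynamic coupling between distant beads. Passing the
desk-scale property tests shows the mechanism operates in this model
class; it does not by itself quantify real chromatin.

## Known limitations

* The rotational block of a cohesin ring is realised purely as the 10×
  drag on the single threaded bead. Twist therefore *leaks* through rings
  at a finite rate, and the enclosed supercoiling reflects a balance
  between injection and leak. Symmetric loops accumulate and extrude
  robustly; strongly asymmetric loops whose short arm sits close to a
  border sink accumulate much more slowly at desk scale, because the
  compressed outside arm acts as a low-resistance shunt that does not
  exist at full scale.
* Extrusion at desk scale begins with a brief loop-shrinkage phase while
  the plectoneme grows to fill the loop (fibre slides outward through the
  rings until the two-stranded plectoneme abuts them); the monotone-growth
  property is asserted on the smoothed series for this reason.
* The hemi-plectoneme regime of a continuously transcribing (barrier)
  motor requires flank stress to outrun the border sinks; at 60-80-bead
  desk scale the drained flank asymmetry is weak, so only the barrier's
  exact transport contract is tested, not the emergent morphology.
* Overdamped beads without hydrodynamic interactions: time is meaningful
  only in units of the single-bead diffusion time.
* The open-chain "writhe" is the standard Gauss sum without closure and
  is reported as a diagnostic only.
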