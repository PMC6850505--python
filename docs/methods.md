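# Methods

`trackchem` simulates the three early stages of ionizing-radiation action
on liquid water: discrete physical transport, physicochemical dissociation
of activated water, and the diffusion–reaction chemistry of the radiolysis
species between 1 ps and 1 μs. This note documents the models, the
parameters that matter, the numerical choices, what the synthetic-data
generator does and does not emulate, and the known limitations.

Internal units are nm, ps and eV everywhere. SI-configured inputs
(diffusion coefficients in m²/s, rate constants in dm³ mol⁻¹ s⁻¹) are
converted exactly once when the registry is built (1 m²/s = 10⁶ nm²/ps);
this keeps all quantities near unity at the nanometer/picosecond scales
the simulation lives on.

## Physical stage

Charged particles (electrons, protons, hydrogen, the three helium charge
states, generic ions) are transported step by step: for each process that
covers the particle's kind and energy an exponential free path is drawn
from the tabulated total cross section, the shortest step wins, and the
winning interaction is applied at the endpoint. No condensed-history
grouping is performed, so the nanometer structure of the track is
preserved. Interactions are: elastic scattering, electronic excitation
(level-tagged), ionization, vibrational excitation, dissociative
attachment, and charge exchange (increase for He⁰/He⁺ and H, decrease for
He⁺⁺/He⁺ and protons). Energy is conserved exactly per interaction:
primary energy loss = local deposit + secondary kinetic energy + stored
channel potential.

Tracking stops at the per-particle cuts (electrons 7.4 eV, protons and
hydrogen 100 eV, helium 1 keV, ions 0.5 MeV/u), where the residual kinetic
energy is deposited locally, or when the particle leaves the box.
Electrons are special: between the 7.4 eV hard cut and the 8.22 eV lowest
electronic excitation of liquid water they leave the loop as *solvation
candidates* — they can no longer excite electronically and will
thermalize into hydrated electrons. An electron already below 7.4 eV is
simply deposited. Particles are processed LIFO (a track stack, secondaries
pushed at creation), which makes an event bit-reproducible for a fixed
seed.

Cross sections are consumed as data: log-log-interpolated totals plus
small declarative samplers (fixed values, uniform ranges, inverse-CDF
tables) for energy loss and secondary energies. The bundled `toy_tables()`
set — constant and power-law totals with simple loss spectra — is *not* a
physical model of water; it exists so the entire pipeline can run and be
tested end to end without external high-fidelity tables. Conclusions that
depend on real stopping powers or spectra must use externally supplied
tables in the same schema. Density enters only through the molecule number
density (interaction probability per unit length); the chemistry tables
are fixed to liquid water at 1 g/cm³.

Scoring: radial dose is accumulated in 100 logarithmic cylindrical shells
between 1 and 250 nm around the beam axis over a 10 μm height
(configurable), normalized per incident particle, with dose = energy /
(ρ · shell volume). LET is the mean per-event energy deposit in the target
divided by the traversed path length (eV/nm, numerically equal to keV/μm);
zero-deposit events count in the mean.

## Physicochemical stage

Activated water decays on femtosecond timescales according to the
branching table: the ionized molecule always gives H₃O⁺ + ·OH (proton
transfer); the A¹B₁ excitation dissociates to ·OH + H· (65%) or relaxes
(35%); the B¹A₁ excitation auto-ionizes to H₃O⁺ + ·OH + e⁻aq (55%),
dissociates to 2·OH + H₂ (15%) or relaxes (30%); the Rydberg/diffuse bands
auto-ionize (50%) or relax (50%); dissociative attachment always gives
·OH + OH⁻ + H₂. Relaxation releases the excess energy locally and yields
no species. Fractions must sum to exactly 100 per parent state and are
validated at load.

The branching table carries no geometry, so placement is a model choice:

* fragments are placed back to back along a random axis at a configurable
  separation, default **0.24 nm** — the scale of a bond length plus a
  water diameter. This knob directly controls geminate recombination
  (e.g. the early ·OH + H· loss) and is deliberately exposed.
* hydrated electrons (solvation candidates and auto-ionization products)
  receive an isotropic 3D Gaussian displacement whose Maxwell-distributed
  magnitude has a configurable mean, default **10 nm**. The scale follows
  the thermalization distances of sub-excitation electrons in liquid
  water (order 10 nm, Meesungnoen-type penetration ranges). The Gaussian
  (random-flight endpoint) form is used rather than an exponential
  magnitude because a physical endpoint density vanishes ∝ r² at the
  origin; an exponential magnitude overweights r ≈ 0, solvates a few
  percent of electrons inside their parent radical cluster and produces a
  spurious sub-picosecond OH⁻ spike-and-collapse that no reference
  time-profile shows.

## Chemical stage

The population evolves from 1 ps to 1 μs through four kernels per
iteration:

1. **Pair search + contact reactions.** All alive pairs whose species
   appear in the reaction table are candidates. Each reaction's contact
   radius comes from the Smoluchowski relation R = k/(4π N_A D_sum); the
   nine tabulated rate constants give radii from 0.067 nm (e⁻aq + e⁻aq)
   to 1.35 nm (H₃O⁺ + OH⁻). Every pair with distance d < R reacts.
   Conflicts (one molecule wanted twice) are resolved greedily by
   increasing distance with a stable index tie-break; one reaction per
   molecule per iteration. Products are placed at the midpoint (one
   product), at the parent positions assigned in reactant order (two), or
   parent/parent/midpoint (three, the two-electron channel). Reactions
   whose only product is water leave nothing behind.
2. **Dynamic time step.** Δt = (d − R)²/(8(√D_A + √D_B)²), minimized over
   candidate pairs, clamped from below at Δt_min = 1 ps (flagged), and
   capped so the stepper lands exactly on the next output sample time.
   The minimum is taken over per-pair Δt rather than evaluated only for
   the minimal-distance pair: with contact radii spanning a factor 13,
   the closest pair is not always the most urgent one, and the per-pair
   minimum is the reading that actually guarantees (statistically) that
   no pair penetrates its reaction radius during the step. With no
   candidate pairs the step runs to the next sample time.
3. **Diffusion.** Every molecule takes an isotropic Gaussian step with
   per-axis σ = √(2DΔt) (MSD = 6DΔt). Molecules leaving the box are
   removed permanently. Over the full 1 μs window the 1D rms displacement
   spans ≈ 53–134 nm across the diffusion-coefficient table, small
   compared to the validation geometries, so losses are minor.
4. **Brownian-bridge check** (clamped steps only). A surviving candidate
   pair may have met *during* the step even though both endpoints are
   outside R; the encounter probability is
   p = exp(−(d_i − R)(d_f − R)/(D_sum Δt)), clipped to [0,1], with p = 1
   at contact of either endpoint — the level-crossing probability of the
   1D Brownian bridge of the pair separation. Accepted events share the
   contact-step conflict rule; products are anchored at the average of
   each parent's pre- and post-step positions. Probabilities below 10⁻¹²
   are ignored (at the 1 ps clamp that cutoff corresponds to pairs
   within ~0.7 nm of contact, so nothing physical is lost).

The pair search is exact: a brute-force O(N²) reference and a k-d-tree
search (scipy `cKDTree`) that provably returns the identical pair set;
the production loop uses the tree within an adaptive working radius and
expands it until the in-radius minimum time step is authoritative (pairs
beyond the radius cannot demand a smaller step than the analytic bound
for their distance). Verification: the single-pair reaction probability
against the closed-form absorbing-sphere result
(R/d₀)·erfc((d₀−R)/√(4D′T)) agrees to a few percent (slightly
conservative, because unclamped steps skip the bridge check by design),
and a well-mixed box recovers the tabulated e⁻aq + ·OH rate constant
within ~7% once the textbook time-dependent Smoluchowski transient
k(t) = k∞(1 + R/√(πD′t)) is carried by the rate-equation oracle.

Identical-reactant channels use the tabulated k unmodified (no statistical
factor of 2); the two-electron channel is stored as an ordinary
bimolecular pair with three products, water being implicit solvent.

RNG: every event gets an independent `numpy` SeedSequence substream, so
ensembles are reproducible and order-independent; a fixed (config, seed)
pair gives bit-identical outputs.

## Synthetic 1 ps track generator

The chemical stage needs a 1 ps molecular population with realistic
*yields* and *clustering*. The generator lays energy down in **spurs**
along a straight track: spur spacing ~ Exp(E_spur/LET), spur energy ~
truncated Exp on [6, 100] eV with mean **50 eV** (the classical spur
band), so doubling LET halves the spacing at fixed deposit. Each spur
spawns Poisson(Σf·e/100) dissociation sites displaced isotropically from
the spur center with an exponential radius of mean **1 nm** (the spur
radius scale); each site draws a product bundle with probability
proportional to its calibrated frequency and places fragments by the
physicochemical rules above. Attachment bundles are additionally
displaced by the thermalization law, because attachment happens at the
end of a slowing electron's path, not in the spur core.

**Calibration** solves the per-100 eV bundle frequencies from target 1 ps
yields: attachment from OH⁻, auto-ionization from e⁻aq, the ion pair from
H₃O⁺ − e⁻aq, ·OH + H· from H·, 2·OH + H₂ from the remaining H₂/·OH
budget, plus residual singleton channels that absorb the overdetermined
remainder exactly. Negative frequencies raise an infeasibility error.
Bundled presets: `e750keV` (LET 0.2 eV/nm), `p20MeV` (2.7 eV/nm),
`p5MeV` (8.0 eV/nm); proton LET values come from standard liquid-water
stopping-power tables (log-log interpolated between 0.5 and 100 MeV), and
the 5 MeV preset reuses the 20 MeV 1 ps yields since 1 ps yields are
nearly LET-independent.

What the generator does *not* emulate: delta-ray branches (all energy is
on one axis), the joint spatial correlations between specific channel
products beyond spur co-location, LET-dependence of the 1 ps yields, and
any sub-picosecond kinetics. The spur geometry (mean energy, spread) and
the thermalization displacement are therefore the declared source of
residual disagreement in 1 μs yields: with the defaults above the
electron-irradiation yields at 1 μs land within ~10% of the reference
values, while the proton-track hydrated-electron population decays too
slowly (the diffuse ~10 nm e⁻aq halo around a dense ion column
under-recombines relative to the reference chemistry, whose 1 ps spatial
correlations are not published). Passing tests show the chemistry solver
is unbiased; they do not certify the generator's spatial model for dense
tracks.

## Problem sizes

The validation ensembles use the natural per-primary deposits of the
reference geometries — ≈4 keV for a 750 keV electron crossing the 20 μm
cube (LET ≈ 0.2 eV/nm) and ≈2.7 keV for a 20 MeV proton crossing the 1 μm
cube — with 12–16 events per ensemble. Per-100 eV yields are invariant to
how a low-LET deposit is split across independent events; splitting keeps
the globally-coupled dynamic time step (one near-contact pair anywhere
clamps the whole system to 1 ps) tractable, since the number of clamped
steps grows with the number of molecules sharing a clock. A 4 keV electron
event takes a few thousand kernel iterations and a few seconds on one
core.

## Numerical choices and degenerate inputs

* Sample times default to 10 points per decade over [1 ps, 1 μs]; the
  stepper lands on each exactly, so recorded counts are not interpolated.
* Δt = 0 at contact (d ≤ R) clamps to 1 ps; empty populations jump
  directly between sample times; a zero-duration diffusion call is a
  no-op.
* Dead molecules are compacted out of the arrays when they outnumber the
  living; indices are never reused within an iteration.
* Registry validation rejects non-positive k or D, duplicate species or
  reactant pairs, unknown species references, and branching fractions
  that do not sum to 100 (tolerance 10⁻⁹).
* Serialization round-trips the registry bit-exactly through a plain
  dict/JSON form.

## Known limitations

* No independent-reaction-times acceleration; no periodic boundaries; no
  bulk scavengers; no temperature or pH dependence of k or D.
* Photons, positrons, magnetic fields, non-water materials and atomic
  deexcitation (Auger/fluorescence) are out of scope; ionization deposits
  the binding-energy remainder locally.
* The bundled cross-section tables are toys; the physics stage is
  quantitative only with externally supplied tables.
* H· yields show a pronounced early dip (geminate ·OH + H· recombination
  at the 0.24 nm fragment separation) that recovers via e⁻aq + H₃O⁺; the
  reference profiles are flatter. H· is excluded from the monotone-trend
  guarantees for this reason.
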