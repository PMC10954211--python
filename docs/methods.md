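# Methods

This note records the models behind `traptamer`, the conventions and
calibration constants that are the package's own choices, and what the
synthetic fixtures do and do not establish about real data.

## Ideal-geometry model

The trap is built as three parallel, coplanar A-form helices (axes along
x, tile in the xy-plane, Å units, right-handed frames):

* **Helix parameters.** 11 bp per turn (twist 360/11 ≈ 32.727°/bp), rise
  2.9 Å/bp, helix radius 11.5 Å, 3 Å surface-to-surface gap between
  neighbouring helices (axis spacing 26 Å). Only the twist and rise carry
  scientific weight here; radius and gap set absolute separations but do
  not affect any twist quantity.
* **Architecture.** The middle helix spans L + n_apt + R base-pair steps
  between its two crossover seams; the outer helices are 25 bp. The top
  helix is anchored to the middle helix's left end, the bottom helix to
  its right end, and each seam transfers the helical register with a
  half-turn flip. The two lock hairpins sit at bp 1 and bp 23 of each
  outer helix — exactly two full turns apart, so both locks experience
  the same register mismatch.
* **Coarse resolution.** One node per base pair along the duplex helices
  (a single-pass phosphate-trace cartoon) and one node per nucleotide in
  the lock hairpins (5-bp stem out, 6-nt loop, stem back) and seam
  spacers. The PDB writer emits one P pseudo-atom per node, one chain,
  1-based numbering; "residue count" means model nodes.
* **Seam spacers.** Rigid ideally-placed helices cannot satisfy both
  crossover seams for an arbitrary middle-helix length — that residual
  register mismatch *is* the strain the method measures. The chain is
  kept continuous by a 6-nt single-stranded spacer at each seam, routed
  along a circular arc whose bulge grows until every bond clears the
  bonded-distance window. All consecutive-node bonds, spacers included,
  then lie in 3.0–8.0 Å (a generous bracket around the ~5.9 Å A-form
  backbone spacing; intra-helix bonds are ≈7.1 Å at these parameters).

**Closing twist.** The lock anchors face each other when the top anchor
points at 180° and the bottom at 0° (about the helix axes); the signed
sum of the two deviations is the twist the middle helix must supply to
close both locks. Because the seams propagate register rigidly, this
reduces to the closed form

    τ = wrap( (L + n_apt + R − 1)·ω + δ_apt + 180° ),  ω = 360/11,

with positive τ = overtwist. The model-measured anchor mismatch and the
closed form agree to machine precision (tested). τ is periodic under
+11 bp and gains exactly ω per inserted bp; the middle helix's axial
end-to-end length gains exactly 2.9 Å per inserted bp.

**Aptamer insert.** The folded aptamer's effective helical parameters
inside the middle helix are not measurable from a blueprint, so the
insert is treated as a rigid pseudo-helical segment with configurable
(effective bp, intrinsic twist offset, intrinsic length). The defaults
— **n_apt = 14 effective bp, zero offset, 40.6 Å** — are a calibration
constant of this package, chosen once so that design 14-14 falls in the
overtwist-above-60° regime and 11-11 in the undertwist-below-−90° regime,
the behaviour those designs are expected to show. No other geometry
result depends on this choice beyond a constant rotation of the whole τ
series.

**Limitations.** Separations are measured between loop-tip reference
points of the *relaxed* model; even at perfect register the tips sit
~11 Å apart transversally (kissing requires slight inward bending), and
absolute separations depend on the coarse hairpin conventions. The model
does not predict multimerisation; designs known to multimerise are
flagged with a caveat by the screen classifier, not predicted.

## Strain → regime classification

Thresholds: undertwist cut −90°, overtwist cut +60° (both configurable).
τ below the undertwist cut → `untrapped`; above the overtwist cut →
`trapped_responsive`; otherwise `variable`. The intermediate band has
also been described with bounds (60° to −80°); the defaults take the
conservative union anchored on the two firmer regime statements and
expose both cuts as parameters. Classification is a pure function of
(τ, thresholds).

## Sequence design

A blueprint is a linear layout with a symmetric partial involution of
pairing targets (helix stems, lock stems, kissing pseudoknot pairs
between cognate lock loops) and fixed bases (5′ GGA transcription start,
aptamer block, lock hairpins, 3′ primer site). The bundled motif
sequences are synthetic stand-ins chosen for internal consistency —
palindromic kissing loops so cognate loops are mutually complementary,
and a GC-richer stem for lock B than lock A (−12.46 vs −11.03 kcal/mol
by the bundled nearest-neighbour table), which propagates into the
kinetics as lock B's slower invasion.

The solver randomises free positions, repairs every designed pair to a
Watson–Crick complement, then applies single-position mutations with
immediate partner repair, accepting moves that do not increase the
violation score (unsatisfied pairs + spurious windows). The spurious
screen forbids perfect complementary windows ≥ 8 nt between regions not
designed to pair (runs through designed pairs are broken before length
counting, so the intended key-invasion pathway is not flagged). G·U
wobbles are accepted at unconstrained paired positions except the 2 bp
flanking each seam. The search is seeded and deterministic; thermodynamic
folding prediction is out of scope.

Keys are the reverse complement of a lock's invasion path (outgoing stem
+ loop), optionally extended with a toehold (default 6 nt; a 5-nt
variant is a parameter away) on the 5′ (t-key) or 3′ (key-t) side;
anti-keys are full reverse complements of their keys.

## Machine-cycle kinetics

State lattice: {closed, loop, open} per lock × {unfolded, folded} ×
{dye-free, dye-bound} (36 states), plus free keys, anti-keys, dye and
key:anti-key duplexes in nM. Mass action throughout; key/anti-key/dye
binding are second order, everything else first order. Conventions worth
recording:

* Exit from the loop state combines stem invasion (step 2, rate
  `k_branch·exp(+ΔG_stem/RT)`, capped at 10⁴/min) and kissing disruption
  (step 3, `k_open`) as two sequential barriers (series rates). Invasion
  is treated as nearly irreversible (`k_close` = 10⁻³/min); this is what
  lets slow locks reach full opening rather than a partial equilibrium.
* Anti-key displacement is single step: an open lock returns to closed,
  the key leaving as an inert duplex. Free keys and free anti-keys also
  annihilate at the same second-order constant — without this, re-added
  keys would see a standing pool of anti-key and the reactivation leg of
  the cycle would not close.
* Folding gate: AND coupling folds at full rate only with both locks
  open, with a leak factor 0.22 when one lock is open (observed single-key
  activation is partial, not zero); OR coupling folds with either lock
  open. Unfolding runs only while the gate is off (mechanical unfolding
  by the re-engaged trap) and ejects a bound dye in the same step.
* Fluorescence = baseline + scale × (dye-bound fraction). "Percent
  activation" of a simulated trace is measured against its own plateau;
  the a.u.→U scale is a single shipped constant. Instrument units are
  arbitrary, so absolute rates are meaningful only relative to that
  constant.
* Integration: LSODA, rtol 10⁻⁸ / atol 10⁻¹⁰, restarted at each timed
  addition; output on a 0.5–1 min grid. Lattice probability is conserved
  to <10⁻⁶ and dye/key mass balances close to <10⁻⁴ nM (tested).
* K⁺ dependence is reduced to an optional multiplier on the folding rate;
  no quantitative claim is attached to it.

**Calibration.** `calibrate()` runs derivative-free least squares in
log-parameter space against observables computed by full simulation
(activation at a time point, sliding-window max rate, turn-off time,
time-to-90%-of-plateau). The shipped defaults are the frozen output of
calibrating (`k_toehold_on`, `k_branch`, the two toehold penalties, the
signal scale) against the activation level at 30 min with 5× keys, the
three toehold-placement maximum rates, and the anti-key turn-off window,
with the deactivation chain (`k_antikey`, `k_unfold`) tuned to a ~9 min
1/e decay. With these defaults the simulator gives 81.9% activation at
30 min, maximum rates 840/543/444 a.u./min for plain/key-t/t-key, return
to within 5% of baseline 23.5 min after 2× anti-keys, 90% of plateau at
74 min, and a re-activation peak within ~10% of the first peak — each of
which the test suite and the acceptance script recompute by simulation.
The toehold penalties act on loop binding (key-t) and stem invasion
(t-key) respectively, reflecting that internal toeholds slow strand
displacement.

## Synthetic fixtures

The screening generator emits tidy plate-reader-like traces: a flat
No-KL control (normalised reference), and per design × condition a
pre-addition plateau followed by an exponential rise (τ = 12 min, keys
at 30 min) scaled to hit the configured fold-change/activation values
exactly at the 50-min evaluation time. Noise is multiplicative Gaussian
(CV 2% default, 3 replicates, seeded); noise-free runs recover every
configured parameter to 10⁻⁹ (tested), and a 20-seed recovery suite
checks the noisy round trip to 3×SEM.

The shipped means table transcribes only stated screening numbers (0.52 /
0.16 single-key activation and 22-fold for 14-14; ~0.90 / ~0.50 for the
OR-class designs); backgrounds are chosen inside their stated class bands
(<0.2 for trapped designs). The `14-14v2` entry carries the
later-experiment regime (0.25 / 0.10) in which the 30% AND-gate
threshold applies — in the screening-series regime key A alone exceeds
the threshold and the honest gate call is `none`. The generator does not
model instrument drift, photobleaching, or plate-removal artifacts, so
passing tests show statistic-recovery correctness, not robustness to
those real-world effects.

## Trace statistics

Plateaus are means of the last 3 pre-addition points (robust to
single-point noise); fold change is the replicate-mean ratio to the
no-keys sample at addition + 50 min (linear interpolation inside the
grid only); percent activation is referenced to the both-keys endpoint
(an alternative No-KL-referenced mode follows from `normalize_to_control`);
the maximum rate is the best least-squares slope over sliding 3-point
windows (window 2 reduces to the max finite difference); replicates
aggregate as mean ± SD. All statistics are invariant to uniform
rescaling (percent activation to affine transforms) — property-tested.
Gate rule: AND if both single-key activations < θ and both-keys ≥ 1−θ;
OR if any single key ≥ 1−θ; else none; θ = 0.30 with symmetric high/low
cuts (only the 30% number is anchored; the symmetry is this package's
choice).

## Problem sizes

Default test and acceptance runs use ideal models up to ~45 bp middle
helices (≈170 nodes), 270-nt blueprints, and ODE integrations over
200–300 simulated minutes on ~0.5–1 min grids; the full suite and the
acceptance script each complete in seconds on one CPU.
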