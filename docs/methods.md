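# Methods

This note documents the models and numerical choices behind switchmd's
activation battery: what each metric computes, the conventions and
defaults, what the synthetic generator does and does not emulate, and the
known limitations.

## Coordinate model and conventions

A trajectory is an ordered set of frames over a fixed atom table
(identical atom count and ordering in every frame). Residue identity is
`(chain_id, residue_id)` with 1-based numbering preserved from the source
file; no renumbering ever happens. Units are Ångström and nanoseconds;
angles are degrees in (−180°, 180°]. Waters are recognised by residue
name (HOH, TIP3, SOL, WAT) and represented downstream by their oxygen
only. For altloc groups the highest-occupancy conformer is kept (ties:
first encountered) — deterministic and the common practice. Insertion
codes are rejected rather than silently renumbered.

Coordinates are assumed pre-imaged (whole molecules, no periodic-box
wrapping); no PBC correction is applied to any distance.

## Ballesteros–Weinstein mapping

Within a helix, position `p` maps to `anchor_id + (p − 50)` where the
anchor is the x.50 residue. Anchors come from an explicit YAML config —
auditable, and robust to isoform numbering differences — with sequence
motifs (DRY → R3.50; CWxP → anchor 6.50 two residues after the W6.48;
NPxxY → anchor 7.50 three residues before the Y7.53) available as ranked
*suggestions* that a user must confirm. Helix spans bound resolution;
when a config omits them the default is anchor ± 25 clipped to the chain.
Spans only affect out-of-range validation, not any metric value.
Intracellular-loop residues (e.g. the ICL3 arginine R233) have no BW
label and are addressed directly as `(chain, residue_id)` through the
config's `special` table.

## Geometry kernels

* **Dihedral**: atan2 form of the two-plane-normal construction, IUPAC
  sign (clockwise positive viewed from the second to the third point).
  Collinear or coincident defining points raise a geometry error rather
  than returning an arbitrary angle.
* **χ1**: dihedral over N–Cα–Cβ–γ with the γ atom by residue type (CG;
  CG1 for Ile/Val; OG for Ser; OG1 for Thr; SG for Cys). Gly/Ala are
  rejected as unsupported rather than reported as 0°.
* **Centroids**: unweighted geometric means of the stated atom
  selections. The coupling probes are Cα-only, where mass weighting is a
  no-op; side-chain centroids (interface distances) are kept unweighted
  too, for reproducibility without mass tables.
* **Superposition**: Kabsch least squares with a proper rotation
  (det = +1) enforced; requires ≥ 3 non-collinear fit atoms. RMSF uses a
  two-pass fit (to frame 0, then to the time average) and reports the
  per-atom RMS deviation about the mean position.
* **Residue contact maps**: minimum heavy-atom distance per residue pair
  (hydrogens are often absent from PDB dumps), contact at ≤ 3.0 Å.
  Time-averaged maps average the per-frame minimum distances over the
  window and then threshold, so a contact is a pair whose mean closest
  approach stays within the cutoff.
* **Helix axis / TM6 kink**: the axis is the largest-variance principal
  direction of a Cα run (≥ 5 residues), oriented first → last residue.
  The kink is the angle between the 6.30–6.47 and 6.49–6.60 sub-axes
  (clipped to the mapped span), splitting at the toggle tryptophan where
  activation bends TM6. Short helical segments carry an intrinsic
  principal-axis tilt of a few degrees (the winding does not average out
  over a fraction of a turn), so a perfectly straight helix reads ≈ 2–5°
  rather than 0°; a planted 30° bend is recovered within 3°. The
  "bent" call therefore uses a threshold (default 15°, configurable)
  comfortably above the straight-limit bias.

## Coupling trend

The receptor–Gα approach is summarised by the OLS line through the
per-frame distance between the two Cα probe centroids (receptor
{Y7.53, L2.46, I3.46, T5.54, V6.40}; Gα: the C-terminal five α5
residues, config-supplied since Gα numbering differs between subtypes).
Classification is by slope sign against a threshold, default
5·10⁻⁴ Å/ns — i.e. 0.5 Å of net drift over a microsecond — to avoid
labelling noise as a trend; the fit window defaults to all frames with a
late-window option. The OLS standard error is reported with the slope.

## Water channel

Channel waters are oxygens inside a cylinder (radius 8 Å) around the
segment joining the 3.32 and 7.53 Cα positions, within the endpoints
± 3 Å axially. The channel is *open* in a frame when the graph on those
waters (edges at O–O ≤ 3.5 Å, the hydrogen-bond heavy-atom distance)
connects a water within 4 Å of the top reference to one within 4 Å of
the bottom reference. Barrier hydration counts waters within 4 Å of any
heavy atom of L2.42/I2.43/L3.43/I3.46/M6.36. These numeric criteria are
this package's operational definition of calls that are usually made by
visual inspection; they are exposed on `ChannelSpec` and stamped into
output metadata. H-bond checks elsewhere use the same heavy-atom-only
3.5 Å criterion with no angular term, since hydrogens are routinely
absent.

## PCA and covariance overlap

Frames are superposed twice (to frame 0, then to the resulting average;
the final fitting target is stored so projections of any frame are
computed in exactly the covariance's coordinate system). The 3N×3N
covariance of the analysis Cα coordinates is accumulated non-mass-
weighted, normalised by the frame count. Eigendecomposition is the
symmetric `eigh`; eigenvalues below 0 (roundoff) are clipped at −10⁻⁸
tolerance. Default analysis selections: TM6 Cα for the main projection,
with fit on all receptor helix Cα; TM5/TM7 sub-spans (x.50 ± 8) around
Y5.58/Y7.53 are the configurable alternative. Simulations are compared
by the normalized covariance overlap
Ω(A,B) = 1 − √( tr((A^½ − B^½)²) / (tr A + tr B) ), computed via PSD
square roots from the eigendecomposition; Ω is symmetric, 1 iff A = B
and 0 for disjoint support, and is clipped into [0, 1] against roundoff.
When several trajectories are analysed together an overlap matrix with
unit diagonal is written.

## Synthetic trajectories

The generator builds a toy 7-helix Cα bundle (ideal helices: 1.5 Å rise,
100°/residue, helix centers on a 14 Å circle, per-helix axial offsets
aligning the intracellular ends the way a receptor bundle sits), with
residue ids `1000·helix + position` so the BW arithmetic is transparent,
the DRY/CWxP/NPxxY motifs planted, and every battery residue present.
Planted, exactly recoverable truths:

* χ1 of the four switch residues via internal-coordinate (NeRF)
  construction, evolving as a two-state Markov chain
  (per-frame flip probability, state pair in degrees);
* TM6 bend at 6.48 by rigid rotation of the upper segment;
* an exact linear α5-approach: the whole Gα chain translates along the
  probe-to-probe line so the coupling distance is d₀ + slope·t before
  noise;
* an R3.50/E6.30 charged-group pair with an exact minimum distance;
* a water wire along the 3.32 → 7.53 axis (≤ 3 Å spacing) that is
  continuous, blocked at mid-channel, or alternating per frame; waters
  of a closed frame are relocated to a bulk site so the atom count never
  changes;
* optional exact Y5.58–Y7.53 Cα distance (used for the synthetic
  inactive-state reference fixture, a constructed stand-in carrying the
  19.4 Å / 3.0 Å inactive hallmark values — not deposited coordinates).

I.i.d. Gaussian noise (σ per axis) is added last, so the noiseless
geometry is the ground truth and recovery tolerances scale with σ√3.
One `numpy.random.default_rng(seed)` stream with a fixed draw order
(rotamer flips in label order, then the noise block) makes equal seeds
byte-identical.

Default σ is 0.5 Å — the regime used for the trend-recovery Monte-Carlo
(±0.003 Å/ns slopes at 1000 frames are recovered within 20% and
classified correctly in ≥ 95% of seeded runs). The four presets
(`active-coupled`, `inactive-decoupled`, `blocked-barrier`,
`alternating-channel`) plant σ = 0.1 Å: the water-wire link margin is
0.5 Å, and larger jitter (≈ 0.87 Å relative O–O at σ = 0.5) would destroy
the per-frame open/closed truth the presets exist to encode. σ = 0.1
emulates imaged, well-equilibrated frames where hydrogen-bond geometry
is intact.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no force field, membrane, solvent dynamics or
physical kinetics; no correlated motions (noise is i.i.d., so PCA on
presets has a flat spectrum unless a mode is planted); side chains are
minimal (only the atoms the battery reads); waters have no residence
dynamics. The generator validates the *measurement* pipeline, not any
biology.

## Problem sizes used in the validation suite

Monte-Carlo trend recovery runs 100 seeds per slope sign at 1000 frames;
preset discrimination uses 1000-frame presets; PCA sanity checks use
1000-frame planted motions; oracle-equivalence suites use 100 random
fixtures per kernel. These sizes give the stochastic checks comfortable
statistical margins at desk scale.

## Known limitations

* Binary trajectory formats (XTC/DCD) are not read; the adapter surface
  is a single function returning the in-memory trajectory, so a reader
  can be added without touching analyses.
* The channel call is geometric, not energetic; a wire of crystallographic
  waters at odd angles would still count as open.
* RMSD/RMSF and PCA assume the fit selection is rigid enough to define a
  frame; fitting on mobile atoms biases fluctuations downward.
* The trend classifier fits one line per trajectory; replicas are
  analysed independently and never pooled into a joint fit.
* Helix-axis bias in the straight limit (above) means kink values below
  ~5° are indistinguishable from straight.
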