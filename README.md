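# switchmd

Residue-level activation and G-protein-coupling analysis for class-A GPCR
molecular-dynamics trajectories — with a ground-truth synthetic trajectory
generator so every stage of the battery can be validated without MD data.

## Who this is for

Groups running MD simulations of receptor–G-protein complexes (e.g. the
dopamine D2 receptor short/long isoforms against Gαi subtypes) who want the
standard activation-hallmark battery as one reproducible, tested pipeline
instead of a pile of ad-hoc scripts:

* **χ1 microswitches** — side-chain torsion χ1 = ∠(N, Cα, Cβ, γ) of the
  toggle tryptophan W6.48, the transmission switch F6.44, H6.55 and the
  NPxxY tyrosine Y7.53, binned into rotamers (gauche⁻ (−120°, 0],
  gauche⁺ (0°, 120°], trans otherwise);
* **ionic lock** — minimum R3.50 guanidinium-N to E6.30 carboxylate-O
  distance (≈3 Å when formed in the inactive state);
* **TM5–TM7 distance** — Cα(Y5.58)–Cα(Y7.53), large when TM6 is straight;
* **TM6 kink** — angle between the principal axes of the 6.30–6.47 and
  6.49–6.60 Cα segments, bending at the CWxP motif on activation;
* **coupling trend** — the ordinary-least-squares line through the
  centroid distance d(t) between five intracellular receptor Cα probes
  {Y7.53, L2.46, I3.46, T5.54, V6.40} and the C-terminal five α5 residues
  of Gα, classified *approaching* / *flat* / *receding* by the sign of the
  slope against a noise threshold (default 5·10⁻⁴ Å/ns);
* **internal water channel** — graph continuity of water oxygens (O–O
  link ≤ 3.5 Å) inside a cylinder along the 3.32 → 7.53 axis, plus
  hydration counts of the hydrophobic barrier L2.42/I2.43/L3.43/I3.46/M6.36;
* **Cα PCA** — non-mass-weighted essential dynamics of helix subsets, and
  the normalized covariance overlap
  `Ω(A,B) = 1 − √( tr((A^½ − B^½)²) / (tr A + tr B) )`
  (1 for identical matrices, 0 for orthogonal subspaces) to compare
  simulations.

All residues are addressed by Ballesteros–Weinstein labels (`h.p`,
position relative to the helix's most conserved residue `h.50`), resolved
through an explicit, auditable mapping config; the conserved DRY / CWxP /
NPxxY motifs can propose anchors from sequence.

## Worked example

Generate a synthetic "active, coupled" receptor (known ground truth:
drift −0.003 Å/ns, TM6 bent 30°, channel open, lock broken at 12 Å) and
run the battery on it:

```bash
switchmd simulate --preset active-coupled --seed 42 --frames 400 --out demo/sim
switchmd analyze --traj demo/sim/trajectory.pdb \
                 --map demo/sim/residue_map.yaml --out demo/report
```

```
Activation battery trajectory (400 frames)
==========================================
coupling slope (A/ns)            -0.002986 +/- 0.000027  approaching
ionic lock R3.50-E6.30 (A)               12.01 +/- 0.14
Y5.58-Y7.53 CA (A)                       22.03 +/- 0.14
TM6 kink (deg)                                     30.8  bent
chi1(6.48) (deg)                                  -59.5  gauche-
chi1(6.44) (deg)                                 +179.7  trans
chi1(6.55) (deg)                                 -179.5  trans
chi1(7.53) (deg)                                  -59.6  gauche-
water channel open fraction                       1.000
PCA PC1/PC2 variance fraction             0.023 / 0.023
```

Every planted value is recovered: the fitted slope −0.002986 ± 0.000027
Å/ns matches the generated −0.003 and is classified *approaching* (the
G protein closes in on the receptor core); the 30° planted kink reads
30.8° ("bent"); the broken ionic lock sits at the planted 12 Å; W6.48 and
Y7.53 hold their gauche⁻ rotamers near −60°; the water wire is continuous
in every frame. The flat PC1/PC2 fractions are correct for this preset:
its internal motion is isotropic noise, so no essential mode dominates.

The same battery runs on real data: point `--traj` at your multi-model
PDB (repeatable for replicas — an overlap matrix across simulations is
written when PCA is enabled) and `--map` at a YAML config naming the x.50
anchor residue of each helix, the receptor/Gα chains, the α5 probe
residues and any loop residues of interest.

From Python, the same thing is two objects:

```python
import switchmd as sm

traj = sm.read_structure("trajectory.pdb")
rmap = sm.ResidueMap.from_config("residue_map.yaml")
results = sm.ActivationModel(traj, rmap).fit()
print(results.summary())
results.write("report/")
```

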