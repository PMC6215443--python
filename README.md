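# trajpose

Reverse-trajectorial posture recovery for bipedal hindlimb models.

Cancellous bone aligns its strut architecture with habitual principal
stress directions.  Running that logic backwards, the habitual ("characteristic")
limb posture of a biped can be inferred by searching for the joint-angle
configuration whose predicted principal stress axes best match a measured
cancellous-fabric direction field.  `trajpose` implements that pipeline at
desk scale:

1. **`trajpose.synthetic_limb`** — parameterized limb templates at three
   species scales (large-tyrannosaurid, troodontid, chicken), plus synthetic
   fabric fields with a known generating posture: unit axes drawn from a
   bipolar Watson distribution around the forward model's compressive
   (or tensile) stress axes on a capsule lattice.
2. **`trajpose.musculoskeletal`** — quasi-static single-limb kinematics
   (3-DOF hip, hinge knee/ankle/MTP, fixed pelvis), tendon-excursion moment
   arms, virtual-work inverse statics under a vertical 1-body-weight ground
   reaction force, and static optimization of muscle activations
   (min sum of squared activations, 2-body-weight force caps, an activity
   mask, and a mass-proportional MTP reserve actuator).
3. **`trajpose.bone_stress`** — a beam-theory surrogate for the original
   finite-element stage: internal loads along each bone, hollow-ellipse
   section stresses, mid-shaft metrics (principal stress inclination,
   shear/bending ratio, neutral-axis angle), least-squares cylinder fit of
   the local long axis, and principal stress axis fields on a lattice
   (epiphyses use a documented joint-resultant surrogate).
4. **`trajpose.fabric_correspondence`** — axial directional statistics:
   orientation-tensor mean axes, sign-free angular deviations, per-ROI
   scoring, regular-grid downsampling and equal-angle stereonet projection.
5. **`trajpose.posture_search`** — greedy coordinate-descent posture
   refinement ("propose, evaluate, accept the best improving candidate,
   stop when nothing improves"), plus the medial hip-articulation variant.
6. **`trajpose.report_cli`** — cross-species parameter extraction
   (normalized muscle moments `M* = a·Fmax·r/(m·g·h)`, degree of crouch,
   monotonic-trend checks) and the command line.

## Command line

```bash
# write a synthetic dataset (model spec, fabric table, ROIs, manifest)
trajpose fixtures --template troodontid-scale --seed 3 --kappa 50 --out data/

# evaluate a single posture end to end
trajpose simulate --model data/model.json --posture data/true_posture.txt \
    --fabric data/fabric.tsv --rois data/rois.tsv --out run/

# run the posture search against a fabric field
trajpose search --model data/model.json --fabric data/fabric.tsv \
    --rois data/rois.tsv --base-posture data/true_posture.txt --out run/

# cross-species records + trend table
trajpose report \
    --species large:data/large.json:large_posture.txt \
    --species troodontid:data/troodontid.json:troodontid_posture.txt \
    --species chicken:data/chicken.json:chicken_posture.txt \
    --out report/
```

All outputs are plain-text tables (whitespace/tab delimited) and JSON
manifests recording the seed, configuration hash and package version; runs
are bit-for-bit reproducible given (config, seed).

## Conventions

* Global frame: x anterior, y mediolateral (left positive), z up; right
  hindlimb; pelvis fixed.  Angles in degrees at every interface, radians
  internally.  Hip extension is measured from the horizontal (90 =
  vertical femur); positive abduction/LAR are abduction/external rotation.
* Axial (sign-free) quantities throughout the fabric machinery; all
  deviations fold into [0, 90] degrees.
* The degree-of-crouch index is operationalized as
  `1 − hip_height / fully_extended_limb_length` and recorded as such in
  output metadata.
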