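# Methods

## Measurement model

`cranioangle` quantifies how far a head deviates from neutral posture using
ten sticker-type anatomical landmarks digitized per frame of a 3D surface
scan: sellion, promentale, subnasale, left/right ectocanthus, left/right
tragion, left/right acromion, and (optionally) left/right infraorbitale.
Coordinates are millimetres in a right-handed frame with +x the subject's
right, +y up, +z anterior; the scanner vertical is assumed to coincide with
gravity.

**Body alignment.** Each frame is rotated about the world vertical axis until
the horizontal projection of the acromion line (right − left) points along
+x, then translated so the acromion midpoint is the origin. The shoulder
line determines only this transverse rotation, so no full Procrustes fit is
attempted; tilting of the scanner relative to gravity is not modelled.
Degenerate configurations are rejected: acromia closer than 1 mm, or a
shoulder line within 5° of vertical.

**Direction vectors.** Three unit vectors describe the head:

* `roll_dir` = unit(sellion − promentale), the head's vertical;
* `yaw_dir` = unit(subnasale − tragion midpoint), the facing direction;
* `pitch_dir_raw` = unit(ectocanthus midpoint − tragion midpoint), the
  ear-eye line.

Each is orientation-normalized (up-ish / forward-ish) so that sticker
mislabeling cannot silently flip a sign. The neutral head carries its
ear-eye line 15° above horizontal, so a neutral-corrected anterior vector
`pitch_dir_neutral` is produced by rotating `pitch_dir_raw` down by the
neutral offset about the head's own lateral axis, realized as
unit(roll_dir × pitch_dir_raw). That axis co-rotates rigidly with the head,
which makes the correction commute with any head rotation; in particular a
purely rolled head keeps its anterior vector unchanged, which is what gives
the composite angle its clean closed forms (below). An alternative
realization — rotating about vertical × (horizontal projection of the
ear-eye line) — fails that commutation and was rejected.

**Angles.** With references vertical = (0,1,0), anterior = (0,0,1) and
diagonal = unit(0,1,1):

* roll = atan2(roll_dir·x, roll_dir·y) — frontal-plane tilt, right positive;
* in the default `projected` mode, `yaw_dir` and `pitch_dir_raw` are first
  de-rolled about the anterior axis by the measured roll, then
  yaw = atan2(yaw_dir·x, yaw_dir·z) (transverse azimuth, right positive) and
  pitch = asin(pitch_dir_raw·vertical) − 15° (elevation above the neutral
  carrying angle, up positive);
* the composite **3D angle** = angle between unit(roll_dir +
  pitch_dir_neutral) and the diagonal reference — 0 for a neutral head,
  non-negative, ≤ 180°. It is computed as atan2(‖u×v‖, u·v) rather than
  arccos(u·v) to retain precision near 0°.

The de-roll step exists because the raw projected formulas leak a pure
lateral tilt into yaw and pitch (the subnasale sits below, and the ear-eye
line above, the tragion plane, so rolling the head moves both projections
laterally — about 0.5°/0.24° of spurious yaw/pitch at 10° of roll). With the
de-roll, every single-axis rotation of the neutral template is recovered
exactly (numerically: to well below 1e-6°) with zero leakage into the other
two angles, and the closed forms hold on the full tested grid:

* pure pitch θ → 3D angle |θ|;
* pure yaw or pure roll θ → 3D angle arccos((1 + cos θ)/2).

A literal dot-product `dot` mode is kept behind a flag: each of yaw/roll is
the plain arccos against its reference, signed by the lateral component. It
conflates axes by construction (a 20° pitch with a trace of roll reads as
~20° of roll) and exists only for fidelity comparisons.

**Combined rotations.** Synthetic poses compose extrinsically as
R = Ry(yaw)·Rx(pitch)·Rz(roll). Per-vector extraction cannot invert a
general composition: the error is quadratic, roughly
sin θ₁·sin θ₂ for the two largest magnitudes (≈0.4° when both are 5°, ≈3.9°
when both are 15°). The property tests therefore assert exact recovery for
single-axis poses, 0.5° for mild (≤5°) combined poses, and a quadratic
envelope 1.6·θ₁·θ₂ over the ±15° box. Clinical torticollis postures are
dominated by one axis, where the method is exact.

**Modal aggregation.** A capture is 10 fps for 20 s (200 frames). Each
angle's sequence is reduced to its most frequent value: values fall into
half-open bins [k·b, (k+1)·b) with b = 0.1° by default; the mean of the most
populated bin is reported. Ties go to the bin whose mean is closest to the
overall median, then to the lower bin index. Binning is required because the
mode of a continuous quantity is otherwise undefined; 0.1° is well below
clinical resolution and well above the noise floor of the simulated
digitization.

## Statistics

* **ICC(3,1)** — two-way mixed, single measure, consistency:
  (MSR − MSE)/(MSR + (k−1)·MSE) from the ANOVA decomposition; 95% CI from
  the F bounds on MSR/MSE, p from the F test (null: no subject effect).
  The absolute-agreement ICC(2,1) is available behind a flag; note the
  clinical literature often labels ICC(3,1) "absolute agreement" although it
  is a consistency coefficient. Zero-variance input is defined as ICC = 1
  with a degenerate CI.
* **Pearson r** with the two-sided t-test p-value (scipy).
* **Mann–Whitney U** — reported as min(U₁, U₂) with midranks for ties. For
  n₁+n₂ ≤ 12 the two-sided p is exact: all C(n₁+n₂, n₁) labelings are
  enumerated and p = P(min-U ≤ observed). Larger samples use the normal
  approximation with tie correction and 0.5 continuity correction.
* **ROC** — thresholds are the distinct scores plus a sentinel above the
  maximum; positive means score ≥ threshold; AUC by pair counting with ties
  worth 0.5 (identically U/(n₁n₂)). The diagnostic cut-off is the point
  where the sensitivity and specificity curves cross, found by linear
  interpolation between adjacent thresholds, so sensitivity = specificity
  at the cut-off by construction.
* **Sample size** — smallest per-group n at which a two-sample t test with
  noncentrality d·√(n/2) and df = 2n−2 reaches the requested power,
  iterated upward with the noncentral t distribution. One-tailed by default
  (the between-group hypothesis is directional: patients deviate more).
  At d = 0.5, α = 0.05, power 0.80 this gives 51 per group (64 two-tailed).
* All cohort comparisons run on absolute values: signed clinical angles
  point left or right depending on the affected side, so magnitudes are the
  comparable quantity.

## Synthetic data

**Pose/sequence generator.** Rigid rotations of a neutral template head
about the tragion midpoint, plus translation and isotropic Gaussian landmark
noise (default experiments use 0.5 mm, about sticker-digitization scale).
Acromions translate but do not rotate with the head, keeping body alignment
and head pose independent. Sequences default to the capture protocol —
10 fps, 20 s — with Gaussian per-frame jitter of 0.3° SD on each angle, a
plausible placeholder for involuntary head motion (per-frame variability
during capture is not reported anywhere to estimate from). All randomness
hangs off one integer seed per call.

The template head satisfies the neutral constraints exactly (vertical
sellion–promentale, midsagittal subnasale, ear-eye line at exactly 15°
elevation, lateral acromion line), with adult-scale dimensions.

**Cohort generator.** Per-subject measurement magnitudes are drawn to match
published group absolute-value moments (control vs torticollis, 52 per
group, seven measurement columns). The default family is the folded normal —
the distribution of |X| for a signed normal deviation, the minimal family
consistent with "absolute value of a signed angle" — with underlying (μ, σ)
solved from the closed-form folded-normal moments by root-finding. A folded
normal cannot have sd/mean above the half-normal ratio √(π/2 − 1) ≈ 0.7555;
five of the fourteen published group×column moment pairs (e.g. torticollis
goniometer 6.67 ± 7.45) exceed it, so the bundled preset uses
`family="auto"`, which falls back to a moment-matched gamma for exactly
those columns; `family="folded_normal"` raises on them instead. Columns of
one subject share a latent severity factor through a Gaussian copula
(loading 0.8 → pairwise Spearman ≈ 0.62), and all signed columns of a
subject share one random sign (deviation direction is a subject property);
the 3D-angle column is always non-negative.

**What the generator does and does not emulate.** It reproduces group-level
magnitude moments, within-subject coupling between methods, rigid-pose
geometry and frame jitter. It does not model soft-tissue deformation,
sticker placement bias, digitization error structure, age effects, or the
true shape of the clinical severity distribution — only its first two
absolute moments. Consequently, passing tests demonstrate the correctness
of the measurement and statistics machinery under controlled conditions,
not clinical performance: with folded-normal magnitudes at the published
moments, the expected AUC of the 3D angle is 0.8146 (by integration), below
what the clinical data showed, because the real severity distribution is
evidently less overlapping than a folded normal with the same moments.
For the same reason the distribution-dependent clinical numbers (specific
ICC values, r = 0.72, AUC = 0.872, cut-off 4.950°) are not reproduction
targets of the simulation.

## Numerical choices and degeneracies

* Direction-defining landmark pairs closer than 1 mm (sticker size) are
  rejected as degenerate rather than normalized.
* Angle-between-vectors is always atan2(‖u×v‖, u·v).
* Modal bins are half-open with floor(v/b) indexing; the tie-break is
  median-then-lower-bin.
* Folded-normal matching root-finds the ratio equation on θ = μ/σ ∈ [0, 60]
  with xtol 1e-13; the inverse reproduces target moments to 1e-6.
* Frames with non-increasing timestamps are an error, never reordered.
* CSV/JSON round-trips write full float precision (shortest-repr), lossless
  to the bit.

## Problem sizes

Default test and validation runs use the protocol-sized sequence (200
frames), cohorts of 52 + 52, 100-seed sweeps for concordance checks, and
exact Mann–Whitney enumeration up to 12 pooled observations; everything
completes in about a minute on a single CPU.
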