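"""Study-design numbers: minimum sample size and the neutral-posture pitch convention.

Two quantities follow analytically from the measurement conventions:
the per-group n for a one-sided two-sample t test at d = 0.5 / alpha = 0.05 /
power 0.80, and the |pitch| assigned to a head whose ear-eye line lies in the
horizontal plane (15 deg below the neutral carrying angle).
"""

from cranioangle import PoseSpec, apply_pose, frame_angles, sample_size_t, template_head

n = sample_size_t(effect_size_d=0.5, alpha=0.05, power=0.80, tails=1)
print(f"minimum n per group (d=0.5, alpha=0.05, power=0.80, one-sided): {n}")

frame = apply_pose(template_head(), PoseSpec(pitch_deg=-15.0))
a = frame_angles(frame)
print(f"|pitch| of a horizontal ear-eye line: {abs(a.pitch_deg):.3f} deg")
# 51 subjects per group; 15 deg — the neutral head carries its ear-eye line
# 15 deg above horizontal, so a horizontal line is a 15 deg flexion deviation.
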