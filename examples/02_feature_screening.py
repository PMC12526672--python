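"""Screen features with one-way ANOVA (alert vs fatigue, p < 0.01).

A feature survives when it differs significantly in enough band × channel
combinations. Amplitude-sensitive features (ENE, VAR, RMS, PSD) rack up
significant combinations; purely spectral-shape features (MEA, CF, FV, MSF)
do not respond to the generator's amplitude-only fatigue effect.
"""

from asft.features import extract_study_features
from asft.select import anova_screen
from asft.synthetic import SimConfig, simulate_study

table = extract_study_features(simulate_study(
    SimConfig(n_subjects=6, duration_s=30.0, seed=1)))

result = anova_screen(table, alpha=0.01, min_combos=16)
print(f"significant-combination count per feature "
      f"(out of {result.n_combos} band × channel combos):")
for feature, count in sorted(result.combo_counts.items(),
                             key=lambda kv: -kv[1]):
    mark = "retained" if feature in result.retained_features else "dropped"
    print(f"  {feature:4s} {count:3d}  {mark}")
# at full scale (38,336 samples) the retention threshold is 40 of 64; here it
# is 16, scaled to the study's statistical power.
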