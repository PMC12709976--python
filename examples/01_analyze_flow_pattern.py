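"""Analyze a single flow-pattern image: Flow Index, Agglomeration Ratio, class.

Builds a backlit synthetic scene with known ground truth (30% powder
coverage, 40% of it agglomerated), runs the full analysis pipeline on the
rendered image, and compares the measured metrics with the truth labels.
"""

from powderflow import SceneParams, analyze_image, classify_flow, generate_scene

scene = generate_scene(
    SceneParams(target_coverage=0.30, agglomerate_fraction=0.40, seed=42)
)
m = analyze_image(scene.image, polarity="backlight")

print(f"ground truth   : FI {scene.truth_fi:6.2f} %   AG {scene.truth_ag:.3f}")
print(f"measured       : FI {m.fi_percent:6.2f} %   AG {m.ag_ratio:.3f}")
print(f"flow class     : {classify_flow(m.fi_percent).label}")
print(f"thresholds     : powder<= {m.powder_threshold}, agglomerate<= {m.agglomerate_threshold}")
print(f"bimodal pattern: {m.bimodality_flag}")
# FI is the % of the illuminated field the powder covers (higher = better
# flow); AG is the darker-pixel share of the pattern (higher = more cohesive
# lumping). The measured values should sit within 2 FI points / 0.05 AG of
# the generator's ground truth.
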