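"""Classify replicate FI/AG measurements and rank materials.

Feeds the reported unmilled/milled replicate-level magnitudes through the
aggregation and classification stages: mean +/- sample sd per material, the
flow class of the mean FI, ranked best flow first.
"""

from powderflow import classify_flow, rank_report

samples = {
    "Palbociclib unmilled": {"fi": [27.55, 28.30, 29.20], "ag": [0.04, 0.05, 0.06]},
    "Palbociclib milled": {"fi": [13.60, 15.60, 17.36], "ag": [0.39, 0.42, 0.45]},
}
report = rank_report(samples)
print(report.to_string(index=False))
for fi in (55.0, 35.0, 15.0, 5.0):
    print(f"FI {fi:5.1f} % -> {classify_flow(fi).label}")
# Both materials fall in the Acceptable band (FI 10-30); milling lowers FI
# (worse flow) and raises AG (more cohesive lumping).
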