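"""Write a small grid of synthetic fixtures (TIFF + JSON ground truth).

Each cell of the coverage x agglomerate-fraction grid becomes one seeded
scene on disk; the manifest lists every fixture with its seed, so the whole
suite can be regenerated byte-identically.
"""

import pandas as pd

from powderflow import make_fixture_suite

manifest = make_fixture_suite(
    "scratch/fixtures",
    coverages=[0.15, 0.30],
    agglomerate_fractions=[0.05, 0.40],
    noise_sds=[5.0],
    seeds=[1],
)
print(f"manifest: {manifest}")
print(pd.read_csv(manifest)[["image", "truth_fi", "truth_ag"]].to_string(index=False))
# truth_fi / truth_ag are exact pixel counts over the generator's label map,
# available for scoring any analysis run on the written images.
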