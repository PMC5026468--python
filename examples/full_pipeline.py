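"""End-to-end demo: cohorts -> per-image metrics -> retinal means -> stats.

Simulates a mosaically spaced wild-type cohort against a clustered mutant
cohort (6 retinas x 3 images each), computes packing factor, Voronoi VMR
and NNRI ratio per image, averages to retinal means, and compares the
genotypes.  Small p-values on the spacing metrics show the pipeline
separating the regimes; every output (plus a manifest with seeds and
digests) lands in ./mosaic_demo_out.
"""

import pandas as pd

import retmosaic as rm

manifest = rm.run_pipeline(rm.DEMO_CONFIG, "mosaic_demo_out")
print(f"analyzed {manifest['n_images']} images "
      f"(seed {manifest['seed']}, v{manifest['version']})\n")

stats = pd.read_csv("mosaic_demo_out/stats_report.csv")
cols = ["metric", "test_name", "groups", "statistic", "p_raw"]
print(stats[cols].to_string(index=False))
print("\np_raw < 0.05 on a metric means the wild-type and mutant cohorts "
      "are distinguishable on that spacing statistic.")
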