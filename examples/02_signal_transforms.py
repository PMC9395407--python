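"""From raw X/Y allele intensities to theta, BAF and LRR.

theta = arctan(Y/X)/(pi/2) places a sample between the AA (theta ~ 0) and
BB (theta ~ 1) canonical clusters; BAF rescales theta so the clusters land
at 0 / 0.5 / 1; LRR = log2(R_obs/R_exp) measures total copy number.
"""

import numpy as np

from ovinecnv import signal

# canonical clusters for one SNP, as estimated from reference samples
clusters = signal.CanonicalClusters(
    theta_aa=[0.05], theta_ab=[0.50], theta_bb=[0.95],
    r_aa=[2.0], r_ab=[2.1], r_bb=[2.0],
)

for label, x, y in [
    ("homozygous AA", 2.0, 0.16),
    ("heterozygous AB", 1.05, 1.05),
    ("homozygous BB", 0.16, 2.0),
    ("AB after one-copy loss", 0.7, 0.7),  # total intensity down ~2/3
]:
    theta = signal.compute_theta(x, y)
    baf = signal.compute_baf(np.array([theta]), clusters)[0]
    r_exp = signal.expected_r(np.array([theta]), clusters)[0]
    lrr = signal.compute_lrr(x + y, r_exp)
    print(f"{label:24s} X={x:4.2f} Y={y:4.2f} -> theta={theta:.3f} "
          f"BAF={baf:.2f} LRR={float(lrr):+.2f}")

print("\nBAF near 0/0.5/1 with LRR ~ 0 is a normal diploid marker; a "
      "negative LRR flags fewer copies, positive flags more.")
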