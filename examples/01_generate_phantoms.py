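"""Generate a small cohort of synthetic planar-scan phantoms.

Each phantom mimics the anterior view of a radioiodine post-ablation scan:
a dim body silhouette, a bright thyroid-remnant focus (label 2), optional
metastatic-lymph-node foci (label 1), a physiological oral-cavity focus
(label 0, like all background), camera blur and Poisson count noise.
"""

import numpy as np

from scintiseg import PhantomSpec, generate_cohort

spec = PhantomSpec()
cohort = generate_cohort(spec, n=20, seed=7)

n_with_mln = sum((lab == 1).any() for _, lab in cohort)
rem_px = [int((lab == 2).sum()) for _, lab in cohort]
mln_px = [int((lab == 1).sum()) for _, lab in cohort]

print(f"cohort size:          {len(cohort)} phantoms of "
      f"{spec.image_height}x{spec.image_width} px")
print(f"phantoms with mLN:    {n_with_mln}/20 "
      f"(target presence probability {spec.mln_presence_prob})")
print(f"remnant area (px):    median {int(np.median(rem_px))}, "
      f"range {min(rem_px)}-{max(rem_px)}")
print(f"mLN area (px):        median {int(np.median(mln_px))}, "
      f"range {min(mln_px)}-{max(mln_px)}")
scan0 = cohort[0][0]
print(f"intensity range:      {scan0.min()}-{scan0.max()} (8-bit)")

# The remnant is drawn brighter on average than the mLN foci, but their
# noisy intensity distributions overlap — position priors, not gray value
# alone, are what lets the classifier tell them apart.
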