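"""Generate a synthetic H&E / fluorescence phantom pair with ground truth.

The phantom carries everything a real validation sample would: the two H&E
exports (with and without the drawn tumor outline), the raw fluorescence
image related to them by a hidden degree-2 warp, the exact landmark pairs,
and the true tumor/tissue masks in both coordinate frames.
"""

import musetransfer as mt

sample = mt.generate_phantom(seed=42, shape=(600, 600))

print(f"H&E canvas:          {sample.clean_he.shape[:2]}")
print(f"raw MUSE canvas:     {sample.raw_muse.shape[:2]}")
print(f"tissue area:         {int(sample.true_tissue_mask.sum())} px")
print(f"tumor area (fixed):  {int(sample.true_tumor_mask_fixed.sum())} px")
print(f"landmark pairs:      {len(sample.control_points)}")
print(f"hidden warp a:       {sample.true_transform.a.round(4)}")
print(f"hidden warp b:       {sample.true_transform.b.round(4)}")

# The landmark pairs satisfy the hidden warp exactly, so a fresh fit must
# reproduce its twelve coefficients to numerical precision.
fit = mt.fit_transform(sample.control_points)
err = max(abs(fit.a - sample.true_transform.a).max(),
          abs(fit.b - sample.true_transform.b).max())
print(f"fit vs truth, max coefficient error: {err:.2e}  (exact landmark pairs)")
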