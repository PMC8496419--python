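"""Fit normative limits on control phantoms and detect a deep defect.

Eight control eyes define, for every superpixel of every analysed SMAS
slab, kernel-density-estimated 1st/5th/10th/50th percentiles and a
region-of-interest mask (superpixels without visible bundles in controls
are censored).  A glaucomatous phantom with an arcuate defect confined to
depth pixels 14-20 is then classified slab by slab, and the per-depth
deviation maps are combined: a superpixel is abnormal if it falls below
the 1st percentile at any analysed depth.
"""

from smas.normative import Category
from smas.phantom import generate_cohort
from smas.pipeline import RunConfig, detect, fit_normative, process_phantom_eye

config = RunConfig()
eyes = generate_cohort(n_controls=12, n_glaucoma=1, seed=7)
controls = [process_phantom_eye(e, config) for e in eyes if e.group == "control"]
glaucoma_eye = next(e for e in eyes if e.group == "glaucoma")

models = fit_normative(controls, config)
model = models["SMAS"]
print("ROI superpixels per analysed slab:", [int(r.sum()) for r in model.roi])

features = process_phantom_eye(glaucoma_eye, config)
result = detect(features, model)
for m in result.maps:
    n_abn = int((m.categories == int(Category.BELOW1)).sum())
    n_tested = int((m.categories != int(Category.UNTESTED)).sum())
    print(f"slab {m.slab_index}: {n_abn:3d} abnormal of {n_tested:3d} tested")
print(f"combined map: proportion abnormal = {result.proportion_abnormal:.3f}, "
      f"median distance from ONH = {result.median_onh_distance:.1f} superpixels")

# The defect sits at 50-77 um below the ILM, so the abnormal counts peak
# in slabs 3-5 (the depths the defect spans).  The smaller counts in the
# other slabs are the held-out noise floor of percentile limits fitted
# from a modest number of controls; the combined map aggregates every
# slab into one summary of reflectance loss.
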