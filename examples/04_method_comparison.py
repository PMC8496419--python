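"""Compare the six slab-construction schemes on a phantom cohort.

Runs the full study (controls fit the normative models; glaucomatous
eyes carry arcuate defects confined to depth pixels 14-20 near the ONH)
and summarises per-scheme detection: proportion of abnormal superpixels
per eye, surrogate false-positive rate in controls, and paired
differences against the multi-slab reference.
"""

from smas.evaluation import paired_differences
from smas.phantom import generate_cohort
from smas.pipeline import RunConfig, run_study

eyes = generate_cohort(n_controls=10, n_glaucoma=6, seed=3)
study = run_study(eyes, RunConfig())

print("surrogate false-positive rate (training controls, 1% level):")
for scheme, rate in study.fp_rates.items():
    print(f"  {scheme:10s} {rate:.4f}")

wide = study.proportions.pivot(index="eye", columns="method", values="y")
print("\nproportion of abnormal superpixels per eye:")
print(wide.round(3).to_string())

diffs = paired_differences(study.proportions, reference="SMAS", seed=0)
print("\npaired differences vs SMAS (bootstrap 95% CI):")
print(diffs.round(4).to_string(index=False))

# Defects confined to 50-77 um are invisible to the shallow single-slab
# schemes (Hood, Ashimatey, BestVis average pixels above depth 13), so
# their proportions stay near the false-positive floor while the
# multi-slab scheme and the deep slab capture the loss; negative mean
# differences reproduce the direction of effect seen on clinical data.
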