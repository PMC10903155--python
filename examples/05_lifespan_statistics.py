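"""Recover the planted lifespan effect from a synthetic cohort.

Generates a 98-subject cohort whose target volume grows 15% per decade with
a positive male offset and realistic inter-subject scatter, fits
volume ~ age + sex + TIV, and reports the percent-per-decade estimate and
McFadden R2.
"""

from plexseg import lifespan_model, make_cohort

_, table = make_cohort(98, age_range=(21, 89), sequences=["t1"], seed=9,
                       grid_shape=(48, 48, 48), ventricle_base_volume_cm3=2.0,
                       base_plexus_volume_cm3=0.45, male_volume_offset_cm3=0.15,
                       noise_sd=0.0, volume_scatter_cm3=0.3)

res = lifespan_model(table, sequence="t1like")
reg = res.regression
print(f"n = {reg.n}")
print(f"age coefficient: {reg.params['age']:+.4f} cm^3/yr "
      f"(p = {reg.pvalues['age']:.2e})")
print(f"male offset: {reg.params['sex_male']:+.3f} cm^3 "
      f"(p = {reg.pvalues['sex_male']:.2e})")
print(f"percent per decade: {res.percent_per_decade:.1f}% (planted: 15%)")
print(f"McFadden R2: {reg.mcfadden_r2:.3f}")
# The age slope is reported relative to the cohort mean volume; recovering
# ~15%/decade confirms the volumetric ageing signal survives rasterization
# and the regression pipeline.
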