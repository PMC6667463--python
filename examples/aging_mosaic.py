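"""The aging-mosaic analysis on a cohort with planted effects.

Simulates 23 young and 18 old subjects; four aging markers per region
(the MTsat derivative, MTV, R2*, volume).  Different regions get different
planted dominant markers — the mosaic pattern — which the effect-size
profile should recover.
"""

from mdmtv import default_cohort_spec, effect_profile, run_group_comparisons, simulate_cohort

regions = ("thalamus", "pallidum", "frontal-wm", "parietal-wm", "hippocampus", "putamen")
planted = {
    ("thalamus", "dMTsat/dMTV"): 2.0,   # very large chemophysical effect
    ("pallidum", "R2star"): 1.2,        # iron accumulation
    ("frontal-wm", "MTV"): -1.0,        # water-related change
    ("hippocampus", "volume"): -1.2,    # atrophy
}
spec = default_cohort_spec(regions=regions, planted_d=planted)
cohort = simulate_cohort(spec, seed=20)

comparisons = run_group_comparisons(cohort)
print("significant (q < 0.05) group differences:")
sig = comparisons[comparisons["q"] < 0.05]
print(sig[["region", "marker", "t", "q", "d", "stars"]].round(3).to_string(index=False))

profile = effect_profile(cohort)
print()
print("effect-size mosaic (Cohen's d, old - young):")
table = profile.d.round(2)
table["dominant"] = profile.dominant
table["below_d=0.2"] = profile.below_floor
print(table.to_string())

print()
print("Each region's dominant marker identifies the biological source of")
print("its strongest age effect; regions without a planted effect fall")
print("at or below the small-effect floor (d = 0.2) up to sampling noise.")
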