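# Demonstration run: simulate a 20 000-person cohort and push it through
# QC, stratified Cox fits (all-cause + vascular), mediation and projection.
seed: 1
output_dir: out
simulate_n: 20000
simulate_effects: default
causes: [all, vascular]
age_min: 35.0
age_max: 75.0
mediators: [smoking, alcohol, activity, weight, height, waist, hip, diabetes_cat, sbp]
contrast: [none, tertiary]
projection_start: 35.0
projection_end: 70.0
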