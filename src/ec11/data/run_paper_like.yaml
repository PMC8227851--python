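# Full pipeline at the study's cohort sizes: a 757-sample discovery-style
# cohort for variant ranking and a 523-sample Norwegian-model-style cohort
# for LOOCV prediction and reporting.  Runtime is dominated by the 100
# resampling splits of the ranking stage; lower rank_reps for a quick look.
outdir: ec11_run
seed: 17
n_discovery: 757
n_model: 523
rank_reps: 100
cutoff: 0.003
panels: [ec11, irisplex6, rs12913832]
systems: [quantitative, two_category, three_category]
two_category_thresholds: [pmax, "0.7"]
three_category_thresholds: [pmax, "0.5", "0.7"]
lr_rsid: rs12913832
lr_smoothing: false
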