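# Demo configuration: full synthetic cohort through quantification,
# statistics and context-specific flux simulation.

[run]
seed = 7
outdir = "nmrflux_demo"

[simulate]
cell_lines = ["LN18", "A172", "U118", "NHA"]
sources = ["cell", "EV", "media"]
replicates_per_group = 3
noise_sd = 0.0005
shift_jitter_sd = 0.0005
baseline_amp = 0.0005
biological_cv = 0.1
grid_points = 32768
base_concentration = 1.0

# planted group effects (multiplicative factors on the group mean)
[[simulate.effect]]
cell_lines = ["LN18", "A172", "U118", "NHA"]
sources = ["cell"]
metabolites = ["methionine"]
factor = 3.0

[[simulate.effect]]
cell_lines = ["LN18", "A172"]
sources = ["EV"]
metabolites = ["glycerol", "tryptophan", "carnitine", "gssg"]
factor = 3.0

[[simulate.effect]]
cell_lines = ["U118"]
sources = ["EV", "media"]
metabolites = ["5-oxoproline"]
factor = 3.0

[[simulate.effect]]
cell_lines = ["LN18"]
sources = ["EV"]
metabolites = ["glycine", "threonine", "homoserine"]
factor = 2.5

[preprocess]
region = [-0.5, 10.0]
exclude_water = [4.5, 5.0]
align_intervals = [[1.2, 1.6], [1.8, 3.1], [3.15, 4.45]]
align_target = "median"
max_shift = 50

[quantify]
pls_components = 10

[stats]
anova_by = "source"
anova_threshold = 5.0
scaling = "per_metabolite"
pca_components = 2
corr_diff_line_a = "U118"
corr_diff_line_b = "LN18"
corr_diff_sources = ["EV", "media"]

[[flux.context]]
name = "LN18"
network = "mini_tca"
present_genes = ["g_acont", "g_icdh", "g_akgd", "g_sucd", "g_fum"]
expr_cutoff = 50.0
objective_fraction = 0.9

[[flux.context]]
name = "U118"
network = "mini_tca"
present_genes = ["g_acont", "g_icdh", "g_akgd"]
expr_cutoff = 50.0
objective_fraction = 0.9

[[flux.context]]
name = "LN18"
network = "glutathione"
present_genes = ["g_gpx", "g_ggt"]
expr_cutoff = 50.0
objective_fraction = 0.4

[[flux.context]]
name = "U118"
network = "glutathione"
present_genes = ["g_oplah", "g_oxct"]
expr_cutoff = 50.0
objective_fraction = 0.4
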