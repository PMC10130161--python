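# Example pipeline configuration.
# Generate matching input tables first, e.g.:
#   spatialtme simulate --n-subjects 50 --seed 1 --out example_data
cell_table: example_data/cells.tsv
clinical_table: example_data/clinical.tsv
out_dir: example_results
window_spec: [circle, 1000.0]   # or convex_hull for real, possibly partial cores
edge_correction: border
density_threshold: 2.0          # cells/mm2, cohort-median filter
min_reference: 5
min_target: 5
anchor_phenotype: CD3+
dichotomize_by_histology: false
seed: 1
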