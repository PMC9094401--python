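# Reduced demo configuration for `voxeldecode run-all`.
# A paper-scale run (25 voxels x 32 bands, 200 epochs, 10 repetitions) is
# supported but takes days on one CPU; this demo decodes three bands of one
# simulated voxel in about a minute.

[run]
bands = [0, 8, 10]
include_original = true
test_fraction = 0.25
split_mode = "sample"
auc_threshold = 0.61

[sim]
n_subjects = 12
n_timepoints = 128
effect_band_hz = 0.103
effect_ratio = 2.0

[hyper]
epochs = 15
n_repetitions = 2
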