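W: 2.0
activities:
- standing
- walking
- vacuuming
- running
band_hz:
- 0.6
- 1.2
- 2.0
- 2.8
- 4.0
epochs: 80
folds: 4
fps: 6.0
frame_shape:
- 48
- 64
gmm_K: 8
gmm_max_iter: 100
gmm_ridge: 0.05
gmm_tol: 0.0001
hidden_size: 32
interval_s: 4.0
lr: 0.01
n_recordings: 8
noise_preset: noisy
novelty1_filter: true
novelty2_graphs: true
overlap: 0.5
sample_rate: 50.0
seed: 0
use_ambient: true
use_motion: true
use_vision: true
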