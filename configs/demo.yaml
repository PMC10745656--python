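W: 2.0
activities:
- lying
- standing
- walking
- running
band_hz:
- 0.6
- 1.2
- 2.0
- 2.8
- 4.0
epochs: 150
folds: 10
fps: 8.0
frame_shape:
- 48
- 64
gmm_K: 8
gmm_max_iter: 100
gmm_ridge: 0.05
gmm_tol: 0.0001
hidden_size: 64
interval_s: 5.0
lr: 0.01
n_recordings: 10
noise_preset: default
novelty1_filter: true
novelty2_graphs: true
overlap: 0.5
sample_rate: 50.0
seed: 0
use_ambient: true
use_motion: true
use_vision: true
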