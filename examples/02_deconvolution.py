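"""From BOLD to neural series by Wiener deconvolution.

Simulates a noise-free neural trajectory from a ground-truth model, observes
it through the hemodynamic response at a 50:1 SNR, deconvolves, and reports
how well the underlying neural states are recovered.
"""

import numpy as np

import mindyx as mx
from mindyx.synthetic import task_labels

cfg = mx.SynthConfig(seed=1)
rng = np.random.default_rng(1)
gt = mx.make_ground_truth(cfg, rng)

design = mx.build_design(task_labels(cfg), cfg.conditions)
traj = mx.simulate_noise_driven(gt, design, mx.NoiseSpec(process_sd=0.0),
                                warmup=50, rng=rng, x0=0.1 * np.ones(gt.n))
hrf = mx.canonical_hrf(cfg.tr)
bold = mx.generate_bold(traj, hrf, mx.NoiseSpec(obs_snr=50.0), rng=rng)
neural = mx.wiener_deconvolve(bold, hrf, snr=50)

sl = slice(60, -20)  # interior volumes (run onset carries an edge artifact)
rs = [np.corrcoef(neural.data[i, sl], traj.states[i, sl])[0, 1]
      for i in range(gt.n)]
print(f"HRF kernel: {hrf.h.size} taps at TR = {cfg.tr} s, "
      f"peak at {np.argmax(hrf.h) * cfg.tr:.2f} s")
print(f"per-parcel correlation with the true neural states: "
      f"min {min(rs):.3f}, mean {np.mean(rs):.3f}")
# Correlations near 1 mean the inverse filter restores the neural series
# inside the HRF passband; what is lost is broadband content the
# hemodynamic blur never transmitted.
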