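"""Generate synthetic motor-imagery trials and run the preprocessing stage.

Shows the sample-size arithmetic, windowing, band-pass filter bank, CSP
spatial filtering, channel selection and time-domain-parameter features.
"""

import numpy as np

from matrixmi import (
    FilterBankSpec,
    SyntheticSpec,
    allocate_samples,
    bandpass_filterbank,
    compute_sample_size,
    csp_fit,
    csp_transform,
    gen_trials,
    segment_signal,
    select_channels,
    tdp_features,
)

# How many samples does a proportion estimate need at 99% confidence with a
# 1% margin of error?  With a finite recording of 4097 samples the correction
# brings the requirement down.
spec = compute_sample_size(p=0.5, Z=2.58, e=0.01)
corrected = compute_sample_size(p=0.5, Z=2.58, e=0.01, N=4097)
print(f"uncorrected sample size n0 = {spec.n0:.0f}")
print(f"finite-population corrected n = {corrected.n}")

# Cut the 4097-sample recording into 4 near-equal stationary windows and
# allocate a measurement budget by window size x variance weight.
lengths = segment_signal(4097, 4)
print(f"window lengths: {lengths.tolist()} (sum {lengths.sum()})")
plan = allocate_samples(lengths, np.ones((4, 10)), budget=1000)
print(f"budget allocation across windows: {plan.counts.tolist()}")

# Two-class synthetic session: 10 channels, 250 Hz, class-swapped spatial
# covariance blocks plus mu/beta rhythms and 10% outlier trials.
ts, meta = gen_trials(SyntheticSpec(seed=0))
print(f"\ngenerated {ts.n_trials} trials "
      f"({int(meta['outlier_flags'].sum())} outliers), "
      f"shape {ts.n_channels} channels x {ts.n_samples} samples")

# Band-pass filter bank (9 x 4 Hz bands, 4-40 Hz), then CSP on the mu band.
bands = bandpass_filterbank(ts, FilterBankSpec())
mu_band = bands[1]  # 8-12 Hz
csp = csp_fit(mu_band, (0, 1))
print(f"CSP eigenvalues (class-0 variance share): "
      f"{np.round(csp.eigenvalues, 3).tolist()}")
print(f"dominant channels: {select_channels(csp, 3).tolist()} "
      "(high-variance blocks of the two classes)")

# Log-variance CSP features and Hjorth-style TDP features.
csp_feats = csp_transform(csp, mu_band, m=2)
tdp = tdp_features(ts, K=2)
print(f"CSP feature matrices: {csp_feats.matrix_shape} per trial")
print(f"TDP feature matrices: {tdp.matrix_shape} per trial "
      "(channels x derivative order)")
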