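"""Band-pass filtering and multidimensional feature extraction.

Filters epochs to the 8-30 Hz sensorimotor band (Butterworth order 4,
zero-phase), then extracts time-domain AR coefficients, spatial-domain
CSP variances and time-frequency DWT subband energies, and fuses them
into one 24-column feature matrix.
"""

import eegfuse as ef

cfg = ef.SyntheticConfig(n_trials_per_class=40, fs=128.0, seed=7)
epochs = ef.generate_mi_epochs(cfg)

spec = ef.design_bandpass(8, 30, order=4, fs=epochs.fs)
filtered = ef.apply_filter(ef.select_channels(epochs, ("C3", "Cz", "C4")), spec)

ar = ef.ar_features(filtered, ef.ARConfig(order=6))          # 6 coeffs x 3 ch
csp_filter = ef.csp_fit(filtered)
csp = ef.csp_features(filtered, csp_filter)                  # 3 variances
dwt = ef.dwt_features(filtered, ef.WaveletSpec())            # 3 subband energies
fused = ef.fuse_features([ar, csp, dwt], standardize=True)

print(f"AR features:  {ar.values.shape}")
print(f"CSP features: {csp.values.shape}")
print(f"DWT features: {dwt.values.shape}")
print(f"fused matrix: {fused.values.shape}")
print("CSP eigenvalue pairs (class share of variance; each pair sums to 1):")
for k in range(csp_filter.n_filters):
    print(f"  filter {k + 1}: lambda1={csp_filter.eigenvalues_class1[k]:.3f}  "
          f"lambda2={csp_filter.eigenvalues_class2[k]:.3f}")

# lambda1 far from 0.5 marks a spatial filter whose variance discriminates
# the classes; the fused matrix concatenates all three feature families
# with provenance, e.g.:
print("first/last columns:", fused.column_names()[0], "...", fused.column_names()[-1])
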