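"""Generate two-class synthetic EEG and extract windowed CD features.

Each channel mixes a chaotic Hénon component with AR(1) colored noise; the
"alcoholic-like" class uses a higher chaotic weight, which lowers its
windowed correlation dimension. Non-overlapping 10-sample windows reduce
every channel 10:1 (2560 samples -> 256 CD values; 64 channels -> 16384
features per record). Here a smaller 16-channel, 640-sample configuration
keeps the example quick.
"""

import warnings

from cdboost import SyntheticSpec, extract_cd_features, generate_eeg_dataset, moment_summary

spec = SyntheticSpec(
    n_records_per_class=5, n_channels=16, n_samples=640,
    chaos_mix_class0=0.2, chaos_mix_class1=0.8, seed=1,
)
records = generate_eeg_dataset(spec)
with warnings.catch_warnings():
    warnings.simplefilter("ignore", RuntimeWarning)
    cd = extract_cd_features(records)

print(f"{len(records)} records -> CD feature matrix {cd.values.shape}")
print(f"({cd.n_channels} channels x {cd.n_windows} windows per record)")

for label, name in [(0, "low-chaos class "), (1, "high-chaos class")]:
    vals = cd.values[cd.labels == label].ravel()
    s = moment_summary(vals)
    print(
        f"{name}: mean CD {s.mean:.3f}, variance {s.variance:.3f}, "
        f"skewness {s.skewness:.3f}"
    )
print("the higher chaotic mixing weight lowers the mean windowed CD —")
print("that level difference is the class signal the classifiers recover")
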