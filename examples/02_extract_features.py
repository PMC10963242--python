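"""Extract the 48-slot feature vector from one preprocessed record.

Runs a single record through normalization, 7th-order Butterworth
filtering, best-cycle selection and fiducial detection, then prints the
feature vector grouped by origin (PPG waveform, first/second derivative,
spectrum, demographics).
"""

import warnings

from ppg2bp.features import FEATURE_GROUPS, extract_features
from ppg2bp.ingest import SubjectRecord
from ppg2bp.preprocess import preprocess_record
from ppg2bp.synthetic import DEFAULT_NOISE, generate_record

record, _ = generate_record(noise_config=DEFAULT_NOISE, seed=3)
subject = SubjectRecord("S0001", age=57.0, gender="male", sbp_ref=127.0, dbp_ref=71.0)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    fv = extract_features(preprocess_record(record), subject)

series = fv.as_series()
labels = {"ppg": "PPG waveform", "d1": "first derivative", "d2": "second derivative",
          "fft": "spectrum", "demographic": "demographics"}
for group, names in FEATURE_GROUPS.items():
    print(f"\n-- {labels[group]} ({len(names)} features)")
    for name in names:
        print(f"   {name:>14s} = {series[name]: .4f}")

print("\nTimes are seconds from the cycle onset; amplitudes are on the [0,1] "
      "normalized scale; slot ratios follow the canonical definitions "
      "(e.g. y/x is the augmentation index, a vascular-stiffness proxy).")
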