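"""Add calibrated noise to a record and round-trip it through files.

White Gaussian noise is scaled against the clean signal's AC power (mean
removed), so the requested SNR is well-defined despite the waveform's
positive baseline.  Records are saved as a CSV plus a JSON annotation
sidecar; the pair is lossless and self-describing.
"""

import tempfile
from pathlib import Path

import numpy as np

from ppgsynth import NoiseSpec, SynthesisConfig, read_record, run_synthesis

clean_cfg = SynthesisConfig(signal_type="regular", length=10.0, rr_sd=0.0, seed=5)
noisy_cfg = SynthesisConfig(
    signal_type="regular", length=10.0, rr_sd=0.0, seed=5,
    noise=NoiseSpec(snr_db=20.0, components=((0.05, 8.0),)),
)

clean = run_synthesis(clean_cfg)
noisy = run_synthesis(noisy_cfg)
residual = noisy.samples - clean.samples
snr_emp = 10 * np.log10(np.var(clean.samples) / np.mean(residual**2))
print(f"requested white-noise SNR : 20.0 dB (+ one 8 Hz sinusoid, A = 0.05)")
print(f"empirical SNR of residual : {snr_emp:.2f} dB")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "record.csv"
    run_synthesis(noisy_cfg, out=path)
    back = read_record(path)
    print(f"round-trip exact          : {np.array_equal(back.samples, noisy.samples)}")
    print(f"annotations preserved     : {back.beat_labels == noisy.beat_labels}")
# The empirical SNR sits near the request (the sinusoid adds a little
# extra power); the CSV + sidecar pair reproduces the record bit-exactly.
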