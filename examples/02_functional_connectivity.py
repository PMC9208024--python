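"""Corrected amplitude envelope correlation (AECc) on synthetic signals.

Shows the two defining behaviours of the leakage-corrected envelope
correlation: a scaled copy of a signal (pure leakage) yields AECc near
zero, while genuinely shared envelope dynamics yield a positive AECc
that grows with the planted correlation.
"""

import numpy as np

from scfc import CohortConfig, THETA, aecc_pair
from scfc.synth import generate_envelope_correlated_series

FS = 1250.0
rng = np.random.default_rng(0)

# leakage: y is just a scaled copy of x plus 1% noise
T = 2**17
x = rng.standard_normal(T)
noise = rng.standard_normal(T)
y = 3.0 * x + 0.01 * np.linalg.norm(3.0 * x) / np.linalg.norm(noise) * noise
print(f"AECc of a scaled copy (pure leakage): {aecc_pair(x, y, THETA, FS):+.4f}")
print("  -> near 0: orthogonalization removed the zero-lag shared component\n")

# shared envelopes: planted correlation raises the estimate monotonically
cfg = CohortConfig(n_nodes=2, n_epochs=4, epoch_samples=16384)
for planted in (0.0, 0.3, 0.6, 0.9):
    c = np.array([[1.0, planted], [planted, 1.0]])
    ts = generate_envelope_correlated_series(c, THETA, cfg, rng)
    est = aecc_pair(ts.data[0], ts.data[1], THETA, FS)
    print(f"planted envelope correlation {planted:.1f} -> estimated AECc {est:+.3f}")
print(
    "\nEstimates are attenuated relative to the planted values (rectification"
    "\nand orthogonalization both shrink them) but strictly increasing."
)
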