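"""Why imaginary coherence: insensitivity to instantaneous mixing.

Two *independent* sources are mixed instantaneously (each channel sees
60% of the other), emulating volume conduction.  Ordinary magnitude-
squared coherence reports strong spurious connectivity; imaginary
coherence stays at the independent-noise floor (the Monte-Carlo 95th
percentile at the same epoch count), because zero-lag mixing produces a
purely real coherency.
"""

import numpy as np

from hemianet import (
    GroundTruth,
    MixingSpec,
    epoch_spectra,
    icoh_null_quantile,
    imaginary_coherence,
    magnitude_squared_coherence,
    segment,
    simulate_subject,
)

mix = MixingSpec(np.array([[1.0, 0.6], [0.6, 1.0]]))
truth = GroundTruth(couplings=[], mixing=mix, seed=0, snr=4.0)
rec = simulate_subject(["a", "b"], truth, duration_s=300.0, fs=250.0)
spectra = epoch_spectra(segment(rec))

msc = magnitude_squared_coherence(spectra, "Alpha1").pair("a", "b")
ic = imaginary_coherence(spectra, "Alpha1").pair("a", "b")
null95 = icoh_null_quantile(n_epochs=spectra.n_epochs, band="Alpha1",
                            n_reps=200, seed=1)

print(f"independent sources, instantaneous mixing, {spectra.n_epochs} epochs")
print(f"ordinary coherence |coh|^2 : {msc:.3f}   (spurious connectivity)")
print(f"imaginary coherence       : {ic:.3f}")
print(f"independent-noise null 95%: {null95:.3f}   (icoh stays below)")
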