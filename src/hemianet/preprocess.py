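"""Signal conditioning and epoch segmentation.

The conditioning chain mirrors standard resting-state EEG practice: a
1-145 Hz band-pass, a 50 Hz notch for line noise, polyphase downsampling
to 250 Hz, then common-average re-referencing.  All filters are applied
zero-phase (forward-backward), since phase distortion would bias the
coherence estimates downstream.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Callable

import numpy as np
from scipy import signal

from .recording import EpochSet, RegionRecording

#: No-op artifact-removal hook; real data can plug an ICA-based cleaner in
#: here.  Synthetic recordings carry no blink/cardiac components.
ArtifactCleaner = Callable[[RegionRecording], RegionRecording]


def condition(
    rec: RegionRecording,
    band: tuple[float, float] = (1.0, 145.0),
    notch_hz: float = 50.0,
    target_fs: float = 250.0,
    notch_q: float = 30.0,
    artifact_cleaner: ArtifactCleaner | None = None,
) -> RegionRecording:
    """Band-pass, notch, downsample and common-average reference a recording.

    Parameters
    ----------
    rec : RegionRecording
        Raw recording; its sampling rate must be at least twice the upper
        band edge.
    band : (lo, hi)
        Band-pass edges in Hz (order-4 Butterworth, zero-phase).
    notch_hz : float
        Line-noise notch frequency (IIR notch of quality factor ``notch_q``,
        zero-phase).
    target_fs : float
        Output sampling rate; resampling is polyphase with anti-aliasing.
    artifact_cleaner : callable, optional
        Hook applied after filtering, before re-referencing.

    Returns
    -------
    RegionRecording
        Conditioned recording at ``target_fs`` with zero channel-mean at
        every sample (common average reference).
    """
    nyq = rec.fs / 2.0
    if band[1] >= nyq:
        raise ValueError(
            f"band edge {band[1]} Hz at or above Nyquist ({nyq} Hz); "
            f"need fs >= {2 * band[1]} Hz"
        )
    x = rec.data

    sos = signal.butter(4, band, btype="bandpass", fs=rec.fs, output="sos")
    x = signal.sosfiltfilt(sos, x, axis=1)

    if notch_hz is not None and notch_hz < nyq:
        b, a = signal.iirnotch(notch_hz, notch_q, fs=rec.fs)
        x = signal.filtfilt(b, a, x, axis=1)

    if target_fs != rec.fs:
        frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator, axis=1)

    out = RegionRecording(
        data=x, fs=target_fs, labels=list(rec.labels),
        lesion_side=rec.lesion_side, meta=dict(rec.meta),
    )
    if artifact_cleaner is not None:
        out = artifact_cleaner(out)

    # common average reference: subtract the instantaneous channel mean
    out.data = out.data - out.data.mean(axis=0, keepdims=True)
    return out


def segment(
    rec: RegionRecording,
    length_s: float = 2.0,
    overlap_s: float = 0.5,
) -> EpochSet:
    """Cut a recording into fixed-length overlapping epochs.

    Epoch k covers ``[k*step, k*step + length_s)`` with
    ``step = length_s - overlap_s`` (0.5 s of shared signal between
    consecutive 2-s epochs at the defaults).  Only epochs fully inside the
    recording are kept; no padding is applied, so 300 s at the defaults
    yields ``floor((300 - 2) / 1.5) + 1 = 199`` epochs.
    """
    if not 0 <= overlap_s < length_s:
        raise ValueError("need 0 <= overlap_s < length_s")
    n_len = int(round(length_s * rec.fs))
    step = int(round((length_s - overlap_s) * rec.fs))
    if rec.n_samples < n_len:
        raise ValueError(
            f"recording of {rec.duration_s:.3f} s shorter than one "
            f"{length_s} s epoch"
        )
    n_epochs = (rec.n_samples - n_len) // step + 1
    starts = np.arange(n_epochs) * step
    epochs = np.stack([rec.data[:, s : s + n_len] for s in starts])
    return EpochSet(
        epochs=epochs, fs=rec.fs, labels=list(rec.labels),
        epoch_length_s=length_s, overlap_s=overlap_s,
        lesion_side=rec.lesion_side,
    )
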