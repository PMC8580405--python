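"""Canonical EEG frequency bands.

Seven bands are used throughout: six disjoint narrow bands (note the gaps
between Delta/Theta and Theta/Alpha1) plus the whole alpha band (8-13 Hz),
which overlaps Alpha1 and Alpha2.  Band edges are inclusive on both sides.
"""

from __future__ import annotations

#: Band name -> (lower edge, upper edge) in Hz, both edges inclusive.
BANDS: dict[str, tuple[float, float]] = {
    "Delta": (1.0, 3.0),
    "Theta": (4.0, 7.0),
    "Alpha1": (8.0, 10.0),
    "Alpha2": (11.0, 13.0),
    "Beta1": (14.0, 21.0),
    "Beta2": (22.0, 30.0),
    "Alpha": (8.0, 13.0),
}


def band_table() -> dict[str, tuple[float, float]]:
    """Return the seven-band table as ``{name: (lo_hz, hi_hz)}`` (a copy)."""
    return dict(BANDS)


def band_range(name: str) -> tuple[float, float]:
    """Look up a band's (lo, hi) edges in Hz.

    Raises
    ------
    KeyError
        If ``name`` is not one of the seven defined bands.
    """
    try:
        return BANDS[name]
    except KeyError:
        raise KeyError(
            f"unknown band {name!r}; valid bands: {sorted(BANDS)}"
        ) from None


def bands_containing(freq_hz: float) -> list[str]:
    """All band names whose closed interval [lo, hi] contains ``freq_hz``.

    May return several names (the whole-alpha band overlaps Alpha1/Alpha2)
    or none (frequencies in the gaps between the narrow bands).
    """
    return [name for name, (lo, hi) in BANDS.items() if lo <= freq_hz <= hi]
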