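"""Atlas topology: region -> lobe/hemisphere mapping and lobe coherence.

The full montage is the 90-region automated-anatomical-labeling scheme
(45 regions per hemisphere), shipped as a packaged CSV that is the single
point of truth for lobe membership.  Cingulate, insular and subcortical
regions are mapped to the "Other" lobe and excluded from the four-lobe
(Frontal/Temporal/Parietal/Occipital) coherence profile.  A reduced
10-region montage (2 hemispheres x 5 lobes) is provided for desk-scale
simulation work.

Lesion-frame relabeling maps anatomical hemispheres {L, R} to
{LH (lesioned), IH (intact)} according to each patient's lesion side, so
that group analyses align homologous regions across patients with left-
and right-sided strokes.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .connectivity import CoherenceMatrix

LOBES = ("Frontal", "Temporal", "Parietal", "Occipital", "Other")
_HEMI_CODES = ("L", "R", "LH", "IH")


def load_atlas(montage: str = "aal90") -> pd.DataFrame:
    """Atlas table with columns (index, label, hemisphere, lobe).

    ``montage`` is ``"aal90"`` (90 regions) or ``"reduced"`` (10 regions,
    one per lobe per hemisphere, labelled e.g. ``Occipital_L``).
    """
    if montage == "aal90":
        with resources.files("hemianet.data").joinpath("aal90.csv").open() as f:
            return pd.read_csv(f)
    if montage == "reduced":
        rows = []
        i = 1
        for lobe in LOBES:
            for hemi in ("L", "R"):
                rows.append((i, f"{lobe}_{hemi}", hemi, lobe))
                i += 1
        return pd.DataFrame(rows, columns=["index", "label", "hemisphere", "lobe"])
    raise ValueError(f"unknown montage {montage!r}")


def split_label(label: str) -> tuple[str, str]:
    """Split ``Occipital_Sup_LH`` into (``Occipital_Sup``, ``LH``)."""
    base, _, hemi = label.rpartition("_")
    if hemi not in _HEMI_CODES:
        raise ValueError(f"label {label!r} has no hemisphere suffix")
    return base, hemi


_BASE_LOBE: dict[str, str] | None = None


def region_lobe(label: str) -> str:
    """Lobe of a region label, in either anatomical or lesion frame."""
    global _BASE_LOBE
    if _BASE_LOBE is None:
        table = load_atlas("aal90")
        _BASE_LOBE = {
            split_label(row.label)[0]: row.lobe for row in table.itertuples()
        }
        _BASE_LOBE.update({lobe: lobe for lobe in LOBES})  # reduced montage
    base, _ = split_label(label)
    try:
        return _BASE_LOBE[base]
    except KeyError:
        raise KeyError(f"region {label!r} not in the atlas") from None


def relabel(matrix: CoherenceMatrix, lesion_side: str) -> CoherenceMatrix:
    """Swap a matrix between the anatomical (L/R) and lesion (LH/IH) frames.

    With ``lesion_side="left"``, L <-> LH and R <-> IH; with
    ``lesion_side="right"``, R <-> LH and L <-> IH.  The mapping is an
    involution: relabeling twice with the same side restores the original
    labels.  Region order (and hence the value layout) is unchanged; only
    the frame of the labels changes.
    """
    if lesion_side not in ("left", "right"):
        raise ValueError(
            "lesion_side must be 'left' or 'right' for lesion-frame analysis"
        )
    if lesion_side == "left":
        fwd = {"L": "LH", "R": "IH"}
    else:
        fwd = {"R": "LH", "L": "IH"}
    mapping = dict(fwd)
    mapping.update({v: k for k, v in fwd.items()})
    new_labels = []
    for label in matrix.labels:
        base, hemi = split_label(label)
        if hemi not in mapping:
            raise ValueError(f"label {label!r} not in a single consistent frame")
        new_labels.append(f"{base}_{mapping[hemi]}")
    return CoherenceMatrix(
        values=matrix.values.copy(), labels=new_labels, band=matrix.band,
        n_epochs=matrix.n_epochs, lesion_side=lesion_side,
    )


def _members(labels: list[str], lobe: str, hemisphere: str) -> np.ndarray:
    idx = [
        i for i, lab in enumerate(labels)
        if split_label(lab)[1] == hemisphere and region_lobe(lab) == lobe
    ]
    return np.array(idx, dtype=int)


def local_coherence(matrix: CoherenceMatrix, lobe: str, hemisphere: str) -> float:
    """Mean coherence over unordered region pairs within one lobe."""
    idx = _members(matrix.labels, lobe, hemisphere)
    if len(idx) < 2:
        raise ValueError(
            f"lobe {lobe}_{hemisphere} has {len(idx)} region(s); need >= 2"
        )
    sub = matrix.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), 1)
    return float(sub[iu].mean())


def long_coherence(
    matrix: CoherenceMatrix,
    seed: tuple[str, str],
    targets: list[tuple[str, str]] | None = None,
) -> float:
    """Mean coherence between a seed lobe and target lobes.

    ``seed`` is (lobe, hemisphere), e.g. ``("Occipital", "LH")``.  With
    ``targets=None`` the target set is the full long-range profile: every
    other (lobe, hemisphere) block among the four cortical lobes —
    for an occipital seed, the contralateral occipital lobe plus the
    frontal/temporal/parietal lobes of both hemispheres.  Passing an
    explicit list (e.g. ``[("Temporal", "IH")]``) averages only that block.
    """
    seed_lobe, seed_hemi = seed
    seed_idx = _members(matrix.labels, seed_lobe, seed_hemi)
    if len(seed_idx) == 0:
        raise ValueError(f"seed lobe {seed_lobe}_{seed_hemi} has no regions")
    if targets is None:
        hemis = sorted({split_label(lab)[1] for lab in matrix.labels})
        targets = [
            (lobe, hemi)
            for lobe in ("Frontal", "Temporal", "Parietal", "Occipital")
            for hemi in hemis
            if (lobe, hemi) != (seed_lobe, seed_hemi)
        ]
    tgt_idx = np.concatenate(
        [_members(matrix.labels, lobe, hemi) for lobe, hemi in targets]
        or [np.array([], dtype=int)]
    )
    tgt_idx = np.array(sorted(set(tgt_idx) - set(seed_idx)), dtype=int)
    if len(tgt_idx) == 0:
        raise ValueError("empty target set for long-range coherence")
    block = matrix.values[np.ix_(seed_idx, tgt_idx)]
    return float(block.mean())
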