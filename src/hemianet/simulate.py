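"""Synthetic oscillatory cohort generator with known ground truth.

Because raw patient EEG is not deposited, every downstream stage of the
pipeline is exercised on simulated region-level recordings whose coupling
structure is known exactly.  The generative model:

* Each region's signal is a sum of band-limited Gaussian oscillations
  (white noise band-passed to each canonical band with a zero-phase
  order-4 Butterworth filter) plus broadband white noise.  The SNR is the
  ratio of total band-limited signal variance to broadband noise variance.
* Phase-lagged coupling: a coupled pair shares a band-limited source; the
  receiving region sees it delayed by ``lag_s`` (default: a quarter cycle
  of the band center, which maximizes the imaginary part of coherency)
  and scaled by ``strength``; the receiver's independent component is
  attenuated to keep unit band variance, so the coherency magnitude of
  the pair approximates ``strength``.
* Instantaneous ("volume-conduction") mixing is applied last as a K x K
  matrix multiplication; it produces zero-lag crosstalk that ordinary
  coherence sees but imaginary coherence is designed to reject.
* Cohort-level effects: a latent recovery score per subject and time point
  drives (a) long-range "shortcut" couplings whose strength lowers the
  characteristic path length of the thresholded alpha-band graph and (b)
  the behavioral FOV percentage change, yielding the injected negative
  FOV <-> CPL association; separate switches inject the stimulation-group
  effects (alpha coupling into the superior-occipital region of the
  lesioned hemisphere at follow-up, a Post decrease of delta-band
  interhemispheric occipital coupling, a Post increase of low-beta
  coupling between intact occipital and intact temporal regions).

Everything is driven by one integer seed; identical (config, seed) pairs
give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as _sig

from .atlas import load_atlas, split_label
from .bands import BANDS, band_range
from .recording import RegionRecording

#: Relative amplitude of each background band component (unitless); a
#: crude 1/f-like profile so lower bands carry more power, as in resting
#: EEG.
BACKGROUND_AMPLITUDES: dict[str, float] = {
    "Delta": 1.0,
    "Theta": 0.7,
    "Alpha1": 1.0,
    "Alpha2": 0.7,
    "Beta1": 0.5,
    "Beta2": 0.35,
}


@dataclass(frozen=True)
class OscillatorSpec:
    """A band-limited noise oscillator: center frequency and bandwidth."""

    band_name: str
    center_hz: float
    bandwidth_hz: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = band_range(self.band_name)
        if not lo <= self.center_hz <= hi:
            raise ValueError(
                f"center {self.center_hz} Hz outside {self.band_name} "
                f"[{lo}, {hi}] Hz"
            )
        if self.bandwidth_hz <= 0:
            raise ValueError("bandwidth must be positive")

    @classmethod
    def for_band(cls, band_name: str, amplitude: float = 1.0) -> "OscillatorSpec":
        lo, hi = band_range(band_name)
        return cls(band_name=band_name, center_hz=(lo + hi) / 2.0,
                   bandwidth_hz=hi - lo, amplitude=amplitude)

    @property
    def edges(self) -> tuple[float, float]:
        half = self.bandwidth_hz / 2.0
        return max(self.center_hz - half, 0.05), self.center_hz + half


def quarter_cycle_lag(center_hz: float) -> float:
    """Lag (s) of a quarter cycle at ``center_hz`` - the icoh-optimal lag."""
    return 1.0 / (4.0 * center_hz)


@dataclass(frozen=True)
class CouplingSpec:
    """Directed phase-lagged coupling of one band between two regions."""

    region_i: str
    region_j: str
    band_name: str
    strength: float
    lag_s: float

    def __post_init__(self) -> None:
        if self.region_i == self.region_j:
            raise ValueError("coupling requires two distinct regions")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("coupling strength must be in [0, 1]")
        if self.lag_s == 0:
            raise ValueError(
                "zero-lag coupling is volume conduction; express it through "
                "MixingSpec, not CouplingSpec"
            )


@dataclass(frozen=True)
class MixingSpec:
    """Instantaneous K x K mixing applied after signal synthesis."""

    matrix: np.ndarray

    @classmethod
    def identity(cls, k: int) -> "MixingSpec":
        return cls(matrix=np.eye(k))

    @classmethod
    def uniform_leakage(cls, k: int, leak: float) -> "MixingSpec":
        """Each region leaks a fraction ``leak`` of its signal, shared
        equally among the other regions (rows sum to 1)."""
        if not 0 <= leak < 1:
            raise ValueError("leak fraction must be in [0, 1)")
        m = np.full((k, k), leak / (k - 1)) if k > 1 else np.eye(1)
        if k > 1:
            np.fill_diagonal(m, 1.0 - leak)
        return cls(matrix=m)

    @property
    def is_identity(self) -> bool:
        return np.array_equal(self.matrix, np.eye(self.matrix.shape[0]))

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("mixing matrix must be square")
        object.__setattr__(self, "matrix", m)


@dataclass
class GroundTruth:
    """Everything injected into one simulated recording."""

    couplings: list[CouplingSpec]
    mixing: MixingSpec
    seed: int
    snr: float
    background_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(BACKGROUND_AMPLITUDES)
    )
    behavioral_effects: dict = field(default_factory=dict)


def _band_noise(rng: np.random.Generator, osc: OscillatorSpec,
                n: int, fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed to the oscillator band."""
    lo, hi = osc.edges
    if hi >= fs / 2.0:
        raise ValueError(
            f"band edge {hi} Hz requires fs > {2 * hi} Hz (got {fs} Hz)"
        )
    sos = _sig.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    x = _sig.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def make_coupled_pair(
    spec: OscillatorSpec,
    coupling: CouplingSpec,
    snr: float = 10.0,
    duration_s: float = 60.0,
    fs: float = 250.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Two signals sharing one delayed band-limited component.

    ``y`` contains ``x``'s band component delayed by ``coupling.lag_s`` and
    scaled by ``coupling.strength``; its independent component is scaled to
    keep unit band variance.  Broadband white noise is added to both at
    the stated SNR (``snr=np.inf`` for noiseless signals).
    """
    lo, hi = spec.edges
    if fs < 2.0 * hi:
        raise ValueError(f"fs = {fs} Hz below Nyquist for band edge {hi} Hz")
    if duration_s < 4.0:
        raise ValueError("need at least two 2-s epochs of signal")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    d = int(round(abs(coupling.lag_s) * fs))
    if d == 0:
        raise ValueError(f"lag {coupling.lag_s} s rounds to 0 samples at {fs} Hz")
    shared = _band_noise(rng, spec, n + d, fs)
    x = shared[d:] * spec.amplitude
    s = coupling.strength
    own = _band_noise(rng, spec, n, fs)
    y = (s * shared[:n] + np.sqrt(max(0.0, 1.0 - s**2)) * own) * spec.amplitude
    if np.isfinite(snr):
        noise_sd = spec.amplitude / np.sqrt(snr)
        x = x + noise_sd * rng.standard_normal(n)
        y = y + noise_sd * rng.standard_normal(n)
    truth = GroundTruth(
        couplings=[coupling], mixing=MixingSpec.identity(2),
        seed=seed, snr=snr,
        background_amplitudes={spec.band_name: spec.amplitude},
    )
    return x, y, truth


def simulate_subject(
    regions: list[str],
    truth: GroundTruth,
    duration_s: float = 60.0,
    fs: float = 250.0,
    background_bands: tuple[str, ...] = tuple(BACKGROUND_AMPLITUDES),
    lesion_side: str = "none",
) -> RegionRecording:
    """Synthesize one region-level recording from a ground-truth spec.

    Uncoupled regions are mutually independent before mixing; the mixing
    matrix is applied last.
    """
    if len(set(regions)) != len(regions):
        raise ValueError("duplicate region labels")
    for c in truth.couplings:
        for r in (c.region_i, c.region_j):
            if r not in regions:
                raise ValueError(f"coupling names unknown region {r!r}")
    if truth.mixing.matrix.shape[0] != len(regions):
        raise ValueError("mixing matrix size does not match region count")
    rng = np.random.default_rng(truth.seed)
    n = int(round(duration_s * fs))
    delays = [int(round(abs(c.lag_s) * fs)) for c in truth.couplings]
    if any(d == 0 for d in delays):
        bad = truth.couplings[delays.index(0)]
        raise ValueError(f"lag {bad.lag_s} s rounds to 0 samples at {fs} Hz")
    dmax = max(delays, default=0)

    amps = dict(truth.background_amplitudes)
    bands = list(dict.fromkeys(
        [b for b in background_bands if amps.get(b, 0) > 0]
        + [c.band_name for c in truth.couplings]
    ))
    # independent unit-variance base component per region per band
    base: dict[tuple[str, str], np.ndarray] = {}
    for region in regions:
        for band in bands:
            osc = OscillatorSpec.for_band(band)
            base[(region, band)] = _band_noise(rng, osc, n + dmax, fs)
    own_weight = {key: 1.0 for key in base}
    received: dict[tuple[str, str], np.ndarray] = {}
    for c, d in zip(truth.couplings, delays):
        src = base[(c.region_i, c.band_name)]
        key = (c.region_j, c.band_name)
        received[key] = received.get(key, 0.0) + c.strength * src[dmax - d : dmax - d + n]
        own_weight[key] = np.sqrt(max(0.0, own_weight[key] ** 2 - c.strength**2))

    sig_var = sum(amps.get(b, 1.0) ** 2 for b in bands)
    noise_sd = np.sqrt(sig_var / truth.snr) if np.isfinite(truth.snr) else 0.0
    data = np.zeros((len(regions), n))
    for i, region in enumerate(regions):
        for band in bands:
            key = (region, band)
            comp = own_weight[key] * base[key][dmax:]
            if key in received:
                comp = comp + received[key]
            data[i] += amps.get(band, 1.0) * comp
        if noise_sd > 0:
            data[i] += noise_sd * rng.standard_normal(n)
    data = truth.mixing.matrix @ data
    return RegionRecording(
        data=data, fs=fs, labels=list(regions), lesion_side=lesion_side,
        meta={"seed": truth.seed, "snr": truth.snr},
    )


# ---------------------------------------------------------------------------
# cohort-level simulation
# ---------------------------------------------------------------------------

GROUP_CODES = {"Sham": 0, "AC": 1, "ACDC": 2}
TIMEPOINTS = ("pre", "post", "fu")


@dataclass(frozen=True)
class CohortEffects:
    """Injected group x time effects, all zero for a null cohort.

    Units: coupling-strength deltas are on the [0, 1] coupling scale;
    ``strength_effect_sd`` is in units of the within-subject SD of the
    latent node-strength metric; FOV changes are percentages.
    """

    #: mean latent recovery score for ACDC at (post, fu); other groups 0
    acdc_recovery: tuple[float, float] = (0.0, 0.0)
    #: FOV percentage-change gain per unit latent recovery
    fov_gain_pct: float = 0.0
    #: shortcut (long-range) alpha coupling strength gained per unit recovery;
    #: this is what couples FOV change negatively to the alpha-band CPL
    cpl_chord_slope: float = 0.0
    #: fade rate of the redundant short-range couplings per unit recovery;
    #: recovery trades local redundancy for long-range shortcuts, so the
    #: thresholded graph of a recovered subject has shorter paths
    cpl_local_fade: float = 0.0
    #: ACDC increase of the alpha coupling into the superior-occipital region
    #: of the lesioned hemisphere at (post, fu)
    acdc_alpha_occ: tuple[float, float] = (0.0, 0.0)
    #: ACDC change of delta-band interhemispheric occipital coupling at
    #: (post, fu); negative = the coupling declines after treatment
    acdc_delta_interhemi: tuple[float, float] = (0.0, 0.0)
    #: ACDC change of low-beta coupling between intact occipital and intact
    #: temporal regions at (post, fu)
    acdc_beta_occ_temp: tuple[float, float] = (0.0, 0.0)
    #: injected effect on the latent strength metric for ACDC at (post, fu),
    #: in within-subject SDs (drives power studies without rendering EEG)
    strength_effect_sd: tuple[float, float] = (0.0, 0.0)


#: Effects emulating the study's reported direction and rough magnitude of
#: findings: alpha-band strength gains and a delta-band interhemispheric
#: decline after combined stimulation, a low-beta occipito-temporal increase
#: after treatment, and a strong negative FOV <-> CPL association.
DEFAULT_EFFECTS = CohortEffects(
    acdc_recovery=(0.7, 0.9),
    fov_gain_pct=6.0,
    cpl_chord_slope=0.45,
    cpl_local_fade=0.22,
    acdc_alpha_occ=(0.25, 0.35),
    acdc_delta_interhemi=(-0.20, -0.15),
    acdc_beta_occ_temp=(0.20, 0.10),
    strength_effect_sd=(1.0, 1.5),
)


@dataclass(frozen=True)
class CohortDesign:
    """Study design for a simulated cohort.

    The defaults mirror the study conditions: three stimulation groups of
    8 patients, three time points (baseline, post-treatment, two-month
    follow-up), 5-minute recordings at 500 Hz.  ``montage="reduced"`` uses
    the 10-region (2 hemispheres x 5 lobes) atlas; ``"aal90"`` the full
    90-region one.
    """

    n_per_group: int = 8
    groups: tuple[str, ...] = ("Sham", "AC", "ACDC")
    timepoints: tuple[str, ...] = TIMEPOINTS
    montage: str = "reduced"
    duration_s: float = 300.0
    fs: float = 500.0
    snr: float = 4.0
    mixing_leak: float = 0.05
    effects: CohortEffects = field(default_factory=CohortEffects)
    #: latent-recovery between-subject SD and FOV pct-change noise
    recovery_sd: float = 0.2
    fov_noise_pct: float = 1.0
    #: backbone (path) alpha coupling strength, long-range chord baseline,
    #: and redundant short-range coupling baseline
    backbone_strength: float = 0.6
    chord_base: float = 0.1
    local_base: float = 0.35

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("need >= 2 subjects per group for statistics")
        if len(self.timepoints) < 2:
            raise ValueError("need >= 2 time points")


@dataclass
class CohortTruth:
    """Ground truth for a whole simulated cohort."""

    design: CohortDesign
    seed: int
    subject_truths: dict = field(default_factory=dict)   # (sid, time) -> GroundTruth
    latent_recovery: pd.DataFrame | None = None          # sid x time score
    effects: CohortEffects | None = None


@dataclass
class CohortResult:
    behavior: pd.DataFrame               # patient-table schema
    metrics: pd.DataFrame                # subject, timepoint, latent metrics
    truth: CohortTruth
    recordings: dict | None = None       # (sid, time) -> RegionRecording


def _cohort_regions(design: CohortDesign) -> list[str]:
    return list(load_atlas(design.montage)["label"])


def _lesion_map(lesion_side: str) -> dict[str, str]:
    return {"LH": "L", "IH": "R"} if lesion_side == "left" else {"LH": "R", "IH": "L"}


def _resolve(frame_label: str, lesion_side: str, regions: list[str]) -> str:
    """Map a lesion-frame label like 'Occipital_LH' to an atlas label."""
    base, hemi = split_label(frame_label)
    out = f"{base}_{_lesion_map(lesion_side)[hemi]}"
    if out not in regions:
        raise ValueError(f"region {out!r} not in montage")
    return out


def _subject_couplings(
    design: CohortDesign,
    regions: list[str],
    lesion_side: str,
    group: str,
    timepoint: str,
    recovery: float,
) -> list[CouplingSpec]:
    """Coupling set for one subject at one time point.

    An alpha-band path backbone over the montage keeps the thresholded
    graph connected with a long characteristic path; diametral "chord"
    couplings shorten it in proportion to the latent recovery score.
    Group x time effects modulate the occipital couplings on top.
    """
    eff = design.effects
    k = len(regions)
    alpha_lag = quarter_cycle_lag(OscillatorSpec.for_band("Alpha1").center_hz)
    coup: list[CouplingSpec] = []
    for i in range(k - 1):
        coup.append(CouplingSpec(regions[i], regions[i + 1], "Alpha1",
                                 design.backbone_strength, alpha_lag))
    half = k // 2
    chord_s = float(np.clip(
        design.chord_base + eff.cpl_chord_slope * recovery, 0.0, 0.95
    ))
    local_s = float(np.clip(
        design.local_base - eff.cpl_local_fade * recovery, 0.0, 0.95
    ))
    for i in range(half):
        coup.append(CouplingSpec(regions[i], regions[(i + half) % k],
                                 "Alpha1", chord_s, alpha_lag))
    for i in range(min(half, k - 2)):
        coup.append(CouplingSpec(regions[i], regions[i + 2],
                                 "Alpha1", local_s, alpha_lag))

    t_idx = {"post": 0, "fu": 1}.get(timepoint)
    is_acdc = group == "ACDC"

    def tp(pair: tuple[float, float]) -> float:
        return pair[t_idx] if (is_acdc and t_idx is not None) else 0.0

    occ = "Occipital_Sup" if design.montage == "aal90" else "Occipital"
    tmp = "Temporal_Mid" if design.montage == "aal90" else "Temporal"
    occ_lh = _resolve(f"{occ}_LH", lesion_side, regions)
    occ_ih = _resolve(f"{occ}_IH", lesion_side, regions)
    tmp_ih = _resolve(f"{tmp}_IH", lesion_side, regions)

    # alpha coupling into the lesioned superior occipital region
    s_alpha = float(np.clip(0.15 + tp(eff.acdc_alpha_occ), 0.0, 0.95))
    coup.append(CouplingSpec(occ_ih, occ_lh, "Alpha2", s_alpha, alpha_lag))
    # delta interhemispheric occipital coupling (declines under treatment)
    delta_lag = quarter_cycle_lag(OscillatorSpec.for_band("Delta").center_hz)
    s_delta = float(np.clip(0.35 + tp(eff.acdc_delta_interhemi), 0.0, 0.95))
    coup.append(CouplingSpec(occ_lh, occ_ih, "Delta", s_delta, delta_lag))
    # low-beta intact occipital <-> intact temporal coupling
    beta_lag = quarter_cycle_lag(OscillatorSpec.for_band("Beta1").center_hz)
    s_beta = float(np.clip(0.15 + tp(eff.acdc_beta_occ_temp), 0.0, 0.95))
    coup.append(CouplingSpec(occ_ih, tmp_ih, "Beta1", s_beta, beta_lag))
    return coup


def simulate_cohort(
    design: CohortDesign | None = None,
    seed: int = 0,
    render_eeg: bool = True,
) -> CohortResult:
    """Simulate a full cohort: recordings, behavioral table, ground truth.

    With ``render_eeg=False`` only the behavioral table and the latent
    metric table are generated (cheap; used for statistical power and
    type-I-error studies).  The behavioral table follows the patient-table
    column schema, so it feeds directly into the behavior module.
    """
    design = design or CohortDesign()
    rng = np.random.default_rng(seed)
    regions = _cohort_regions(design)
    eff = design.effects
    t_index = {"post": 0, "fu": 1}

    subjects = []
    sid = 0
    for group in design.groups:
        for _ in range(design.n_per_group):
            sid += 1
            subjects.append((sid, group))

    # latent recovery scores: 0 at baseline; group mean + subject trait after
    recovery = {}
    traits = {s: rng.normal(0.0, design.recovery_sd) for s, _ in subjects}
    for s, group in subjects:
        for t in design.timepoints:
            if t == "pre":
                recovery[(s, t)] = 0.0
            else:
                mu = eff.acdc_recovery[t_index[t]] if group == "ACDC" else 0.0
                recovery[(s, t)] = mu + traits[s]

    # behavioral table in the patient-table schema
    rows = []
    sides = {}
    for s, group in subjects:
        sides[s] = "left" if rng.random() < 0.5 else "right"
        fov_pre = float(np.clip(np.round(rng.normal(25.4, 2.2)), 18, 32))
        hrp_black = float(np.clip(rng.normal(164, 52), 10, 350))
        hrp_gray = float(np.clip(rng.normal(44, 36), 2, 150))
        hrp_white = float(np.clip(rng.normal(233, 55), 50, 400))
        rt_gray = float(np.clip(rng.normal(0.52, 0.05), 0.3, 0.9))
        rt_white = float(np.clip(rng.normal(0.43, 0.07), 0.25, 0.9))
        row = dict(
            id=s, group=GROUP_CODES[group],
            lesion_age_months=float(np.clip(rng.lognormal(3.3, 0.9), 6, 200)),
            gender="M" if rng.random() < 0.75 else "F",
            age_years=float(np.clip(np.round(rng.normal(57.4, 10.5)), 18, 75)),
        )
        for t in design.timepoints:
            e = recovery[(s, t)]
            if t == "pre":
                fov = fov_pre
            else:
                pct = eff.fov_gain_pct * e + rng.normal(0.0, design.fov_noise_pct)
                fov = np.round(fov_pre * (1.0 + pct / 100.0))
            row[f"fov_{t}"] = float(fov)
            # HRP: recovery converts black (blind) to white (intact) positions
            shift = 12.0 * e
            row[f"hrp_black_{t}"] = float(max(hrp_black - shift + rng.normal(0, 5), 0))
            row[f"hrp_gray_{t}"] = float(max(hrp_gray + rng.normal(0, 5), 0))
            row[f"hrp_white_{t}"] = float(max(hrp_white + shift + rng.normal(0, 5), 0))
            row[f"rt_gray_{t}"] = float(np.clip(
                rt_gray - 0.03 * e + rng.normal(0, 0.01), 0.2, 1.0))
            row[f"rt_white_{t}"] = float(np.clip(
                rt_white - 0.03 * e + rng.normal(0, 0.01), 0.2, 1.0))
        rows.append(row)
    behavior = pd.DataFrame(rows)

    # latent node-strength metric (within-subject SD = 1 by construction)
    mrows = []
    for s, group in subjects:
        intercept = rng.normal(0.0, 1.0)
        for t in design.timepoints:
            shift = 0.0
            if group == "ACDC" and t in t_index:
                shift = eff.strength_effect_sd[t_index[t]]
            mrows.append(dict(
                subject=s, group=group, timepoint=t,
                occ_strength=5.0 + intercept + shift + rng.normal(0.0, 1.0),
            ))
    metrics = pd.DataFrame(mrows)

    truth = CohortTruth(
        design=design, seed=seed, effects=eff,
        latent_recovery=pd.DataFrame(
            [{"subject": s, "timepoint": t, "recovery": recovery[(s, t)],
              "group": g} for (s, g) in subjects for t in design.timepoints]
        ),
    )
    recordings = None
    if render_eeg:
        recordings = {}
        mixing = (
            MixingSpec.identity(len(regions)) if design.mixing_leak == 0
            else MixingSpec.uniform_leakage(len(regions), design.mixing_leak)
        )
        for s, group in subjects:
            for t in design.timepoints:
                couplings = _subject_couplings(
                    design, regions, sides[s], group, t, recovery[(s, t)]
                )
                sub_seed = int(rng.integers(0, 2**31 - 1))
                st = GroundTruth(
                    couplings=couplings, mixing=mixing, seed=sub_seed,
                    snr=design.snr,
                    behavioral_effects={"recovery": recovery[(s, t)]},
                )
                truth.subject_truths[(s, t)] = st
                rec = simulate_subject(
                    regions, st, duration_s=design.duration_s, fs=design.fs,
                    lesion_side=sides[s],
                )
                rec.meta.update({"subject": s, "timepoint": t, "group": group})
                recordings[(s, t)] = rec
    return CohortResult(
        behavior=behavior, metrics=metrics, truth=truth, recordings=recordings
    )


def null_design(**overrides) -> CohortDesign:
    """A cohort design with every injected effect set to zero."""
    return CohortDesign(effects=CohortEffects(), **overrides)


def interaction_type_one_error(
    n_cohorts: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    n_per_group: int = 8,
) -> float:
    """Empirical size of the mixed-ANOVA group x time interaction test.

    Simulates null cohorts (no injected effects) of the study design
    (3 groups x 3 time points, n per group), runs the mixed-design ANOVA
    on the latent strength metric and returns the fraction of cohorts
    whose interaction p falls below ``alpha``.  Should sit near ``alpha``.
    """
    from .stats import mixed_anova

    rng = np.random.default_rng(seed)
    design = CohortDesign(n_per_group=n_per_group, effects=CohortEffects())
    hits = 0
    for _ in range(n_cohorts):
        res = simulate_cohort(design, seed=int(rng.integers(2**31 - 1)),
                              render_eeg=False)
        aov = mixed_anova(res.metrics, dv="occ_strength", within="timepoint",
                          subject="subject", between="group")
        p = next(r for r in aov if r.effect == "interaction").p_report
        hits += p < alpha
    return hits / n_cohorts


def time_effect_detection_rate(
    n_cohorts: int = 100,
    effects: CohortEffects | None = None,
    group: str = "ACDC",
    alpha: float = 0.05,
    seed: int = 0,
    n_per_group: int = 8,
) -> float:
    """Detection rate of the within-group time effect on node strength.

    Simulates cohorts carrying the injected strength effect (default: the
    standard effect set, 1.5 within-subject SD at follow-up in the treated
    group), runs the repeated-measures ANOVA within ``group`` and returns
    the fraction of cohorts with time-effect p < ``alpha``.
    """
    from .stats import rm_anova

    effects = effects if effects is not None else DEFAULT_EFFECTS
    rng = np.random.default_rng(seed)
    design = CohortDesign(n_per_group=n_per_group, effects=effects)
    hits = 0
    for _ in range(n_cohorts):
        res = simulate_cohort(design, seed=int(rng.integers(2**31 - 1)),
                              render_eeg=False)
        sub = res.metrics[res.metrics["group"] == group]
        r = rm_anova(sub, dv="occ_strength", within="timepoint",
                     subject="subject")
        hits += r.p_report < alpha
    return hits / n_cohorts


def icoh_null_quantile(
    n_epochs: int = 199,
    band: str = "Alpha1",
    fs: float = 250.0,
    epoch_length_s: float = 2.0,
    n_reps: int = 1000,
    q: float = 0.95,
    seed: int = 0,
) -> float:
    """Monte-Carlo null quantile of band icoh for independent white noise.

    Simulates ``n_reps`` pairs of independent white-noise epoch sets and
    returns the ``q`` quantile of the band icoh values - the finite-epoch
    noise floor (of order 1/sqrt(N)) against which estimated connectivity
    should be judged.
    """
    rng = np.random.default_rng(seed)
    n = int(round(epoch_length_s * fs))
    win = np.hanning(n)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    lo, hi = band_range(band)
    mask = (freqs >= lo) & (freqs <= hi)
    vals = np.empty(n_reps)
    chunk = max(1, int(2e7 // (2 * n_epochs * n)))
    done = 0
    while done < n_reps:
        m = min(chunk, n_reps - done)
        x = rng.standard_normal((m, 2, n_epochs, n)) * win
        spec = np.fft.rfft(x, axis=3)[..., mask]
        cross = np.sum(spec[:, 0] * np.conj(spec[:, 1]), axis=1)
        p1 = np.sum(np.abs(spec[:, 0]) ** 2, axis=1)
        p2 = np.sum(np.abs(spec[:, 1]) ** 2, axis=1)
        coh = cross / np.sqrt(p1 * p2)
        vals[done : done + m] = np.abs(coh.imag).mean(axis=1)
        done += m
    return float(np.quantile(vals, q))
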