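"""Seeded simulator of motor-imagery EEG sessions with ground truth.

The generator emulates the kind of session the rest-to-task method is built
for: dipolar mu+beta sources over left and right sensorimotor cortex with
strong resting power, a contralateral event-related desynchronization (and
weaker ipsilateral synchronization) during the imagery window, an occipital
alpha confound, a frontal low-frequency artifact, and white sensor noise —
all mixed through the analytic single-sphere forward model so the mixing
matrix is known exactly.

Source time courses are narrowband processes (band-pass-filtered Gaussian
noise) rather than sinusoids, so their spectra look EEG-like.  Each carrier
is additionally multiplied by a slow log-normal amplitude modulation that
emulates the waxing and waning of real cortical rhythms; a band-limited
Gaussian process is itself Gaussian and thus unidentifiable for ICA, and it
is exactly this burstiness that makes EEG rhythms super-Gaussian and
separable.  Task modulation is applied on top as a deterministic envelope:
``base_amplitude`` in the rest window, ``base_amplitude * (1 +
erd_depth[class])`` in the imagery window, with 0.25-s linear transitions.
An ``erd_depth`` of -0.5 therefore scales imagery-window band power by 0.25.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .forward import default_montage, forward_gain
from .io import STATE_WINDOWS, EventTable, Recording, TrialSet, bandpass_array, epoch

CLASSES = ("left", "right")

#: canonical motor dipole eccentricity (fraction of head radius under the scalp)
MOTOR_DEPTH = 0.7


def motor_dipole_location(montage_labels: list[str], montage: np.ndarray, side: str) -> np.ndarray:
    """Canonical hand-area dipole: under C3 (left hemisphere) or C4 (right)."""
    ch = {"left": "C3", "right": "C4"}[side]
    idx = [c.lower() for c in montage_labels].index(ch.lower())
    return MOTOR_DEPTH * montage[idx] / np.linalg.norm(montage[idx])


@dataclass
class SourceSpec:
    """One simulated cortical source.

    ``erd`` maps class label to the fractional amplitude change applied in
    the imagery window (negative = ERD, positive = ERS); classes not listed
    are unmodulated.
    """

    name: str
    location: np.ndarray
    orientation: np.ndarray
    bands: list[tuple[float, float]]
    base_amplitude: float
    erd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.location = np.asarray(self.location, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if np.linalg.norm(self.location) >= 1:
            raise ValueError(f"source '{self.name}' not inside the unit sphere")
        for v in self.erd.values():
            if not -1.0 <= v <= 1.0:
                raise ValueError("erd_depth must lie in [-1, 1]")


@dataclass
class SimConfig:
    sources: list[SourceSpec]
    n_trials_per_class: int = 120
    fs: float = 256.0
    trial_len: float = 8.0
    windows: dict[str, tuple[float, float]] = field(default_factory=lambda: dict(STATE_WINDOWS))
    transition: float = 0.25
    sensor_noise_sd: float = 1.0
    burst_strength: float | None = None  # None -> BURST_STRENGTH
    seed: int = 0
    montage_labels: list[str] = field(default_factory=list)
    montage: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_trials_per_class < 1:
            raise ValueError("need at least one trial per class")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.montage_labels:
            self.montage_labels, self.montage = default_montage()


@dataclass
class SimTruth:
    """Ground truth of a simulated session: the oracle for recovery tests."""

    mixing: np.ndarray           # (n_channels, n_sources), unit-norm columns
    source_names: list[str]
    locations: np.ndarray        # (n_sources, 3)
    envelopes: np.ndarray        # (n_sources, n_samples) amplitude envelopes
    seed: int

    def column(self, name: str) -> np.ndarray:
        return self.mixing[:, self.source_names.index(name)]


def default_scene(
    erd_contra: float = -0.5,
    erd_ipsi: float = 0.15,
    motor_amplitude: float = 6.0,
    right_motor_amplitude: float | None = None,
    alpha_amplitude: float = 25.0,
    artifact_amplitude: float = 4.0,
    location_jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[SourceSpec]:
    """The minimal cast that makes motor-IC identification nontrivial.

    Left/right motor mu (10-12 Hz) + beta (20-22 Hz) sources under C3/C4,
    an unmodulated occipital alpha source, and a frontal low-frequency
    artifact.  The left hemisphere controls the right hand, so the left
    motor source carries ``erd_contra`` for right-hand imagery and
    ``erd_ipsi`` for left-hand imagery, mirrored on the other side.
    ``location_jitter`` adds an isotropic Gaussian offset to each source
    location (used to simulate anatomical variation across a cohort).
    """
    labels, pos = default_montage()
    loc_l = motor_dipole_location(labels, pos, "left")
    loc_r = motor_dipole_location(labels, pos, "right")
    # posterior alpha is strong, widespread and lateralized; a deep left
    # parietal generator leaks asymmetrically into C3/C4 and so obscures mu
    # at the motor electrodes without being linearly cancellable
    idx_p3 = [c.lower() for c in labels].index("p3")
    loc_o = 0.4 * pos[idx_p3] / np.linalg.norm(pos[idx_p3])
    idx_fp = [c.lower() for c in labels].index("fp1")
    loc_f = 0.75 * (pos[idx_fp] + pos[[c.lower() for c in labels].index("fp2")]) / 2
    locs = [loc_l, loc_r, loc_o, loc_f]
    if location_jitter > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        locs = [l + rng.normal(scale=location_jitter, size=3) for l in locs]
    amp_r = motor_amplitude if right_motor_amplitude is None else right_motor_amplitude
    return [
        SourceSpec("motor_left", locs[0], locs[0], [(10, 12), (20, 22)],
                   motor_amplitude, {"right": erd_contra, "left": erd_ipsi}),
        SourceSpec("motor_right", locs[1], locs[1], [(10, 12), (20, 22)],
                   amp_r, {"left": erd_contra, "right": erd_ipsi}),
        SourceSpec("occipital_alpha", locs[2], locs[2], [(9, 11)], alpha_amplitude),
        SourceSpec("frontal_artifact", locs[3], locs[3], [(2, 5)], artifact_amplitude),
    ]


#: strength of the log-normal burst modulation (0 = stationary Gaussian,
#: ICA-blind; 0.6 gives an excess-kurtosis clearly super-Gaussian rhythm)
BURST_STRENGTH = 0.6


def _narrowband_noise(rng: np.random.Generator, n: int, fs: float,
                      bands: list[tuple[float, float]],
                      burst: float = BURST_STRENGTH) -> np.ndarray:
    """Unit-variance bursty narrowband process.

    Sum of band-pass-filtered Gaussian noise carriers — the first band at
    full amplitude, further bands (beta companions of a mu rhythm) at half
    amplitude, matching the mu-dominant spectra of sensorimotor components —
    multiplied by a slow (~0.5-s timescale) log-normal amplitude modulation
    normalized to unit mean square, so the waxing/waning changes the
    marginal distribution but not the average band power.
    """
    out = np.zeros(n)
    for i, (lo, hi) in enumerate(bands):
        comp = bandpass_array(rng.standard_normal(n), fs, lo, hi)
        out += (1.0 if i == 0 else 0.5) * comp / comp.std()
    out /= out.std()
    if burst > 0:
        from scipy.ndimage import gaussian_filter1d

        # circular smoothing has no edge transient, unlike an IIR low-pass
        z = gaussian_filter1d(rng.standard_normal(n), sigma=0.5 * fs, mode="wrap")
        z /= z.std()
        m = np.exp(burst * z)
        out *= m / np.sqrt(np.mean(m**2))
    return out / out.std()


def _trial_envelope(cfg: SimConfig, depth: float) -> np.ndarray:
    """Per-trial modulation profile: 1 outside imagery, 1+depth inside,
    with linear ``cfg.transition``-second ramps centred on the window edges."""
    n = int(round(cfg.trial_len * cfg.fs))
    t = np.arange(n) / cfg.fs
    lo, hi = cfg.windows["imagery"]
    h = cfg.transition / 2
    knots_t = [0.0, lo - h, lo + h, hi - h, hi + h, cfg.trial_len]
    knots_v = [0.0, 0.0, 1.0, 1.0, 0.0, 0.0]
    return 1.0 + depth * np.interp(t, knots_t, knots_v)


def simulate_recording(cfg: SimConfig) -> tuple[Recording, EventTable, SimTruth]:
    """Generate a continuous session: trials back-to-back, balanced classes
    in seeded random order.  Reproducible: same (config, seed) -> identical
    output."""
    rng = np.random.default_rng(cfg.seed)
    n_trial = int(round(cfg.trial_len * cfg.fs))
    labels_seq = np.array(
        [CLASSES[0]] * cfg.n_trials_per_class + [CLASSES[1]] * cfg.n_trials_per_class
    )
    rng.shuffle(labels_seq)
    n_total = n_trial * len(labels_seq)
    onsets = np.arange(len(labels_seq)) * n_trial

    mixing = np.zeros((len(cfg.montage_labels), len(cfg.sources)))
    envelopes = np.zeros((len(cfg.sources), n_total))
    data = np.zeros((len(cfg.montage_labels), n_total))
    for j, src in enumerate(cfg.sources):
        g = forward_gain(src.location, src.orientation, cfg.montage)
        g = g / np.linalg.norm(g)
        mixing[:, j] = g
        burst = BURST_STRENGTH if cfg.burst_strength is None else cfg.burst_strength
        carrier = _narrowband_noise(rng, n_total, cfg.fs, src.bands, burst=burst)
        env = np.empty(n_total)
        for k, lab in enumerate(labels_seq):
            env[k * n_trial : (k + 1) * n_trial] = _trial_envelope(
                cfg, src.erd.get(lab, 0.0)
            )
        env *= src.base_amplitude
        envelopes[j] = env
        data += np.outer(g, carrier * env)
    data += cfg.sensor_noise_sd * rng.standard_normal(data.shape)

    rec = Recording(data, cfg.fs, list(cfg.montage_labels), montage=cfg.montage)
    events = EventTable(onsets, list(labels_seq))
    truth = SimTruth(mixing, [s.name for s in cfg.sources],
                     np.array([s.location for s in cfg.sources]), envelopes, cfg.seed)
    return rec, events, truth


def simulate_session(cfg: SimConfig) -> tuple[TrialSet, SimTruth]:
    """Epoched view of :func:`simulate_recording` (same ground truth)."""
    rec, events, truth = simulate_recording(cfg)
    ts = epoch(rec, events, cfg.trial_len)
    ts = replace(ts, windows=dict(cfg.windows))
    return ts, truth


def jittered_montage(montage: np.ndarray, angle_deg: float,
                     rng: np.random.Generator,
                     electrode_sd_deg: float = 1.0) -> np.ndarray:
    """Electrode-misalignment model for session-to-session simulations.

    The whole cap is rotated rigidly by ``angle_deg`` about a random axis —
    a re-seated cap shifts coherently, which is what damages a fixed
    spatial filter — plus a small independent per-electrode wobble
    (``electrode_sd_deg``).  Positions stay on the unit sphere.
    """
    from scipy.spatial.transform import Rotation

    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()
    out = montage @ R.T
    if electrode_sd_deg > 0:
        out = out + np.tan(np.deg2rad(electrode_sd_deg)) * rng.standard_normal(out.shape)
    return out / np.linalg.norm(out, axis=1, keepdims=True)
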