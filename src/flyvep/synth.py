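"""Synthetic SSVEP cohort generator.

Generates seeded, ground-truth-known per-trial voltage time series with the
statistical structure the downstream analysis assumes:

* an 11-second trial per (spatial, temporal) frequency condition, repeated
  10 times per animal in randomized order, 20 animals per genotype;
* a stimulus-phase-locked response concentrated at the second harmonic (2F)
  of the reversal frequency, with a first-harmonic (1F) admixture that is
  strong only at very low spatial frequency (photoreceptor 1F energy shifts
  to 2F once different photoreceptors see opposite grating phases);
* genotype-dependent tuning surfaces: temporal bandpass (log-Gaussian,
  peaking near 6 Hz for wild types), spatial low-pass (logistic, falling
  above ~0.88 cpd), and for early-onset-PD-like genotypes a multiplicative
  gain elevation at the two lowest spatial frequencies plus a slight drop at
  the lowest temporal frequency;
* additive 1/f^alpha noise with phase drawn independently per trial (so it
  cancels under coherent averaging) and log-normal between-animal gain
  variability.

Trials are synthesized lazily and deterministically from per-trial seed
streams: a :class:`Cohort` stores only its design, per-fly gains and seeds,
and regenerates bit-identical sample vectors on demand.

All preset parameter values are free (non-measured) parameters chosen to
give realistic effect sizes; they are not estimates from any recording.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Dict, Iterator, List, Optional, Sequence

import numpy as np

from .design import (
    SPATIAL_FREQS_CPD,
    TEMPORAL_FREQS_HZ,
    StimulusCondition,
    design_grid,
)
from .exceptions import (
    ConfigurationError,
    InvalidDesignError,
    InvalidSpecError,
)

#: default sampling rate: every analysis frequency (2F up to 72 Hz) falls on
#: an exact 1-Hz bin of a 1-s window, so there is no leakage by construction.
DEFAULT_FS_HZ = 1000
DEFAULT_TRIAL_S = 11

# spatial frequency (cpd) at which 1F and 2F photoreceptor energy are equal
F1_HALF_CPD = 0.05
F1_STEEPNESS = 4.0

# stimulus-locked phase of the 2F component (radians); arbitrary but fixed,
# and identical across genotypes (the analysis uses amplitude only)
DEFAULT_PHASE_2F = np.pi / 4

#: noise components are synthesized up to this frequency; the 1/f^alpha
#: amplitude spectrum is negligible far above the highest analysis
#: frequency (72 Hz), so the band cap changes nothing the pipeline sees
NOISE_MAX_HZ = 150.0

# independent sub-streams of the root seed
_GAIN_STREAM = 1
_TRIAL_STREAM = 2
_ORDER_STREAM = 3

CLASS_LABELS = ("control", "early_PD", "late_PD", "neurodegeneration")


@dataclass(frozen=True)
class GenotypeSpec:
    """Phenomenological description of one genotype's visual response.

    Parameters
    ----------
    name : str
        Genotype label.
    class_label : str
        One of ``control``, ``early_PD``, ``late_PD``, ``neurodegeneration``.
    gain : float
        Overall response scale (µV) of the tuning surface peak region.
    tf_peak_hz : float
        Center of the temporal bandpass, in [1, 36] Hz.
    tf_bandwidth_oct : float
        SD of the log-Gaussian temporal bandpass, in octaves.
    sf_cutoff_cpd : float
        Half-height point of the spatial low-pass (cycles/degree).
    low_sf_boost : float
        Multiplicative elevation applied at the two lowest spatial
        frequencies (>1 for early-onset-PD-like genotypes).
    fly_cv : float
        Between-animal gain coefficient of variation (log-normal).
    noise_amp : float
        Scale of the additive 1/f^alpha noise amplitude spectrum (µV per
        trial-level frequency component).
    noise_alpha : float
        Spectral exponent of the noise.
    low_tf_drop : float
        Multiplicative attenuation at the lowest temporal frequency
        (slightly < 1 for early-onset-PD-like genotypes), default 1.
    """

    name: str
    class_label: str = "control"
    gain: float = 6.0
    tf_peak_hz: float = 6.0
    tf_bandwidth_oct: float = 1.5
    sf_cutoff_cpd: float = 0.88
    low_sf_boost: float = 1.0
    fly_cv: float = 0.2
    noise_amp: float = 5.0
    noise_alpha: float = 1.0
    low_tf_drop: float = 1.0

    def __post_init__(self):
        if self.class_label not in CLASS_LABELS:
            raise InvalidSpecError(
                f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}"
            )
        # gain == 0 is permitted (degenerate all-zero surface); negative is not
        if self.gain < 0:
            raise InvalidSpecError(f"gain must be >= 0, got {self.gain}")
        if self.fly_cv < 0:
            raise InvalidSpecError(f"fly_cv must be >= 0, got {self.fly_cv}")
        if self.noise_amp < 0:
            raise InvalidSpecError(f"noise_amp must be >= 0, got {self.noise_amp}")
        if not (1.0 <= self.tf_peak_hz <= 36.0):
            raise InvalidSpecError(
                f"tf_peak_hz must lie in [1, 36] Hz, got {self.tf_peak_hz}"
            )
        if self.tf_bandwidth_oct <= 0:
            raise InvalidSpecError("tf_bandwidth_oct must be > 0")
        if self.sf_cutoff_cpd <= 0:
            raise InvalidSpecError("sf_cutoff_cpd must be > 0")
        if self.low_sf_boost < 0 or self.low_tf_drop < 0:
            raise InvalidSpecError("low_sf_boost and low_tf_drop must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GenotypeSpec":
        return cls(**d)


def default_f1_weight(sf_cpd: float) -> float:
    """Relative 1F amplitude as a function of spatial frequency.

    A descending logistic in log spatial frequency with half point
    ``F1_HALF_CPD``: near 1 at the lowest spatial frequencies (the whole
    display has one polarity, photoreceptors track the reversal frequency)
    and ~0 at high spatial frequencies (pooled photoreceptor energy shifts
    to 2F).
    """
    return 1.0 / (1.0 + (np.asarray(sf_cpd, dtype=float) / F1_HALF_CPD) ** F1_STEEPNESS)


@dataclass
class TuningSurface:
    """Deterministic 8x8 response-amplitude surface for one genotype.

    ``amplitude[s, t]`` is the 2F response amplitude (µV) at spatial
    frequency index ``s`` (ascending) and temporal frequency index ``t``
    (ascending), before per-fly gain scaling.
    """

    amplitude: np.ndarray
    phase_2f: float = DEFAULT_PHASE_2F
    f1_weight: Callable[[float], float] = default_f1_weight

    def __post_init__(self):
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.amplitude.shape != (8, 8):
            raise InvalidSpecError(
                f"amplitude must be 8x8, got {self.amplitude.shape}"
            )
        if np.any(self.amplitude < 0):
            raise InvalidSpecError("amplitude entries must be >= 0")

    def amplitude_at(self, condition: StimulusCondition) -> float:
        s = SPATIAL_FREQS_CPD.index(condition.spatial_freq_cpd)
        t = TEMPORAL_FREQS_HZ.index(condition.temporal_freq_hz)
        return float(self.amplitude[s, t])


def tuning_surface(spec: GenotypeSpec) -> TuningSurface:
    """Build the deterministic tuning surface of a genotype.

    The surface is separable: ``gain * T(tf) * S(sf) * B(sf) * D(tf)`` where
    ``T`` is a log-Gaussian bandpass centered at ``tf_peak_hz`` with SD
    ``tf_bandwidth_oct`` octaves, ``S`` a logistic low-pass with half height
    at ``sf_cutoff_cpd``, ``B`` equals ``low_sf_boost`` at the two lowest
    spatial frequencies (1 elsewhere), and ``D`` equals ``low_tf_drop`` at
    the lowest temporal frequency (1 elsewhere).
    """
    if spec.gain < 0:
        raise InvalidSpecError(f"gain must be >= 0, got {spec.gain}")
    tf = np.asarray(TEMPORAL_FREQS_HZ, dtype=float)
    sf = np.asarray(SPATIAL_FREQS_CPD, dtype=float)

    T = np.exp(-0.5 * (np.log2(tf / spec.tf_peak_hz) / spec.tf_bandwidth_oct) ** 2)
    S = 1.0 / (1.0 + (sf / spec.sf_cutoff_cpd) ** 3)
    B = np.ones_like(sf)
    B[:2] = spec.low_sf_boost
    D = np.ones_like(tf)
    D[0] = spec.low_tf_drop

    amplitude = spec.gain * np.outer(S * B, T * D)
    return TuningSurface(amplitude=amplitude)


def _noise_trace(
    n_samples: int,
    fs_hz: float,
    noise_amp: float,
    noise_alpha: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Additive noise with amplitude spectrum ~ noise_amp / f^alpha.

    Built in the frequency domain as a sum of cosines with independent
    uniform random phases (so the noise has random phase per trial and
    cancels under coherent averaging). Gaussian-like in the time domain by
    the central limit theorem.
    """
    if noise_amp == 0:
        return np.zeros(n_samples)
    mags = _noise_mags(n_samples, fs_hz, noise_amp, noise_alpha)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=mags.shape)
    # coefficient c_k = (N/2) * m_k * e^{i phi}  =>  x(t) = sum m_k cos(w_k t + phi_k)
    coeffs = np.empty(mags.shape, dtype=complex)
    coeffs.real = np.cos(phases)
    coeffs.imag = np.sin(phases)
    coeffs *= (n_samples / 2.0) * mags
    return np.fft.irfft(coeffs, n=n_samples)


def _noise_mags(
    n_samples: int, fs_hz: float, noise_amp: float, noise_alpha: float
) -> np.ndarray:
    """Amplitude per trial-level frequency component, band-limited to
    ``NOISE_MAX_HZ`` (the spectrum is truncated where it is negligible)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    n_keep = int(np.searchsorted(freqs, min(NOISE_MAX_HZ, fs_hz / 2), side="right"))
    mags = np.zeros(n_keep)
    mags[1:] = noise_amp / freqs[1:n_keep] ** noise_alpha
    return mags


@dataclass
class TrialRecording:
    """An 11-s voltage trace for one animal x one condition x one repetition."""

    samples: np.ndarray
    fs_hz: int
    condition: StimulusCondition
    fly_id: str
    genotype: str
    repetition: int

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz != int(self.fs_hz):
            raise ConfigurationError("fs_hz x 1 s must contain whole samples")
        if len(self.samples) % int(self.fs_hz) != 0:
            raise ConfigurationError(
                "trial length must be an integer number of seconds"
            )

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs_hz


def simulate_trial(
    surface: TuningSurface,
    spec: GenotypeSpec,
    condition: StimulusCondition,
    fly_gain: float,
    fs_hz: int = DEFAULT_FS_HZ,
    rng: Optional[np.random.Generator] = None,
    *,
    trial_s: float = DEFAULT_TRIAL_S,
    fly_id: str = "fly",
    repetition: int = 0,
) -> TrialRecording:
    """Synthesize one trial.

    The phase-locked part is ``fly_gain * [A2 cos(2pi*2F*t + phase) +
    A1 cos(2pi*F*t + phase/2)]`` with ``A2`` the surface amplitude at the
    condition and ``A1 = f1_weight(sf) * A2``; 1/f^alpha noise with random
    per-trial phase is added on top. Because every temporal frequency divides
    the 1-s analysis bins exactly, the locked components have identical phase
    in every bin.
    """
    F = condition.temporal_freq_hz
    if fs_hz < 2 * (2 * max(TEMPORAL_FREQS_HZ)):
        raise ConfigurationError(
            f"fs_hz={fs_hz} violates Nyquist for the highest 2F "
            f"({2 * max(TEMPORAL_FREQS_HZ)} Hz); need fs_hz >= "
            f"{4 * max(TEMPORAL_FREQS_HZ)}"
        )
    if fs_hz != int(fs_hz):
        raise ConfigurationError("fs_hz x 1 s must contain whole samples")
    if fly_gain <= 0:
        raise InvalidSpecError(f"fly_gain must be > 0, got {fly_gain}")
    fs_hz = int(fs_hz)
    n = int(round(fs_hz * trial_s))
    t = np.arange(n) / fs_hz

    a2 = surface.amplitude_at(condition)
    a1 = float(surface.f1_weight(condition.spatial_freq_cpd)) * a2
    phase = surface.phase_2f
    samples = fly_gain * (
        a2 * np.cos(2 * np.pi * (2 * F) * t + phase)
        + a1 * np.cos(2 * np.pi * F * t + phase / 2)
    )
    if spec.noise_amp > 0:
        if rng is None:
            raise ConfigurationError("rng is required when noise_amp > 0")
        samples = samples + _noise_trace(n, fs_hz, spec.noise_amp, spec.noise_alpha, rng)
    return TrialRecording(
        samples=samples,
        fs_hz=fs_hz,
        condition=condition,
        fly_id=fly_id,
        genotype=spec.name,
        repetition=repetition,
    )


@dataclass
class Cohort:
    """A lazily-synthesized cohort of per-trial SSVEP recordings.

    Stores the design, per-fly gains and the root seed; every trial is
    regenerated on demand from a per-trial seed stream, so iteration is
    memory-light and bit-reproducible.
    """

    specs: Dict[str, GenotypeSpec]
    n_flies_per_genotype: int
    n_reps: int
    fs_hz: int
    seed: int
    trial_s: float = DEFAULT_TRIAL_S
    design: List[StimulusCondition] = field(default_factory=design_grid)
    fly_gains: Dict[str, float] = field(default_factory=dict)
    fly_genotype: Dict[str, str] = field(default_factory=dict)

    _surfaces: Dict[str, TuningSurface] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._surfaces:
            self._surfaces = {g: tuning_surface(s) for g, s in self.specs.items()}

    # -- bookkeeping -------------------------------------------------------
    @property
    def genotypes(self) -> List[str]:
        return list(self.specs)

    @property
    def fly_ids(self) -> List[str]:
        return list(self.fly_gains)

    @property
    def n_trials(self) -> int:
        return len(self.fly_gains) * len(self.design) * self.n_reps

    def surface(self, genotype: str) -> TuningSurface:
        return self._surfaces[genotype]

    # -- deterministic per-trial synthesis ---------------------------------
    def _trial_rng(self, fly_index: int, cond_index: int, rep: int):
        ss = np.random.SeedSequence(
            entropy=self.seed, spawn_key=(_TRIAL_STREAM, fly_index, cond_index, rep)
        )
        return np.random.default_rng(ss)

    def get_trial(
        self, fly_id: str, condition: StimulusCondition, repetition: int
    ) -> TrialRecording:
        if fly_id not in self.fly_gains:
            raise InvalidDesignError(f"unknown fly_id {fly_id!r}")
        fly_index = self.fly_ids.index(fly_id)
        cond_index = self.design.index(condition)
        genotype = self.fly_genotype[fly_id]
        return simulate_trial(
            self._surfaces[genotype],
            self.specs[genotype],
            condition,
            self.fly_gains[fly_id],
            self.fs_hz,
            self._trial_rng(fly_index, cond_index, repetition),
            trial_s=self.trial_s,
            fly_id=fly_id,
            repetition=repetition,
        )

    def trials_for(
        self, fly_id: str, condition: StimulusCondition
    ) -> List[TrialRecording]:
        """All repetitions of one (fly, condition): batched synthesis.

        Bit-identical to repeated :meth:`get_trial` calls (same per-trial
        seed streams) but shares the phase-locked signal across repetitions
        and batches the noise inverse FFT.
        """
        if fly_id not in self.fly_gains:
            raise InvalidDesignError(f"unknown fly_id {fly_id!r}")
        fly_index = self.fly_ids.index(fly_id)
        cond_index = self.design.index(condition)
        genotype = self.fly_genotype[fly_id]
        spec = self.specs[genotype]
        surface = self._surfaces[genotype]
        fs = int(self.fs_hz)
        n = int(round(fs * self.trial_s))
        t = np.arange(n) / fs

        F = condition.temporal_freq_hz
        a2 = surface.amplitude_at(condition)
        a1 = float(surface.f1_weight(condition.spatial_freq_cpd)) * a2
        phase = surface.phase_2f
        signal = self.fly_gains[fly_id] * (
            a2 * np.cos(2 * np.pi * (2 * F) * t + phase)
            + a1 * np.cos(2 * np.pi * F * t + phase / 2)
        )

        if spec.noise_amp > 0:
            mags = _noise_mags(n, fs, spec.noise_amp, spec.noise_alpha)
            phases = np.stack([
                self._trial_rng(fly_index, cond_index, rep)
                .uniform(0.0, 2.0 * np.pi, size=mags.shape)
                for rep in range(self.n_reps)
            ])
            coeffs = np.empty(phases.shape, dtype=complex)
            coeffs.real = np.cos(phases)
            coeffs.imag = np.sin(phases)
            coeffs *= (n / 2.0) * mags
            noise = np.fft.irfft(coeffs, n=n, axis=1)
            samples = signal + noise
        else:
            samples = np.broadcast_to(signal, (self.n_reps, n))
        return [
            TrialRecording(
                samples=samples[rep].copy(),
                fs_hz=fs,
                condition=condition,
                fly_id=fly_id,
                genotype=genotype,
                repetition=rep,
            )
            for rep in range(self.n_reps)
        ]

    def iter_trials(self, fly_id: Optional[str] = None) -> Iterator[TrialRecording]:
        flies = [fly_id] if fly_id is not None else self.fly_ids
        for f in flies:
            for cond in self.design:
                yield from self.trials_for(f, cond)

    @property
    def recordings(self) -> Iterator[TrialRecording]:
        return self.iter_trials()

    def trial_order(self, fly_id: str) -> np.ndarray:
        """Randomized presentation order: (n_reps, 64) condition indices."""
        fly_index = self.fly_ids.index(fly_id)
        ss = np.random.SeedSequence(
            entropy=self.seed, spawn_key=(_ORDER_STREAM, fly_index)
        )
        rng = np.random.default_rng(ss)
        return np.vstack(
            [rng.permutation(len(self.design)) for _ in range(self.n_reps)]
        )

    # -- export -------------------------------------------------------------
    def export(self, out_dir) -> Path:
        """Write manifest.json + per-trial two-column CSV time series."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "seed": self.seed,
            "fs_hz": self.fs_hz,
            "trial_s": self.trial_s,
            "n_flies_per_genotype": self.n_flies_per_genotype,
            "n_reps": self.n_reps,
            "design": [
                {"temporal_freq_hz": c.temporal_freq_hz, "spatial_freq_cpd": c.spatial_freq_cpd}
                for c in self.design
            ],
            "specs": {g: s.to_dict() for g, s in self.specs.items()},
            "fly_gains": self.fly_gains,
            "fly_genotype": self.fly_genotype,
            "trial_orders": {f: self.trial_order(f).tolist() for f in self.fly_ids},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        for trial in self.iter_trials():
            c = trial.condition
            fname = (
                f"fly_{trial.fly_id}_cond_{c.temporal_freq_hz:g}Hz_"
                f"{c.spatial_freq_cpd:g}cpd_rep{trial.repetition}.csv"
            )
            t = np.arange(len(trial.samples)) / trial.fs_hz
            np.savetxt(
                out / fname,
                np.column_stack([t, trial.samples]),
                delimiter=",",
                header="time_s,microvolts",
                comments="",
            )
        return out


def simulate_cohort(
    specs: Sequence[GenotypeSpec],
    n_flies: int = 20,
    n_reps: int = 10,
    fs_hz: int = DEFAULT_FS_HZ,
    seed: int = 0,
    trial_s: float = DEFAULT_TRIAL_S,
) -> Cohort:
    """Simulate a full cohort: ``n_flies`` animals per genotype, ``n_reps``
    repetitions of every one of the 64 conditions per animal.

    Per-fly gains are log-normal with mean 1 and coefficient of variation
    ``fly_cv``; all randomness derives from ``seed`` via independent
    sub-streams, so identical seeds reproduce the cohort exactly.
    """
    specs = list(specs)
    if not specs:
        raise InvalidDesignError("specs must be non-empty")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise InvalidDesignError(f"duplicate genotype names in design: {names}")
    if n_flies < 1 or n_reps < 1:
        raise InvalidDesignError("n_flies and n_reps must be >= 1")

    fly_gains: Dict[str, float] = {}
    fly_genotype: Dict[str, str] = {}
    for g_idx, spec in enumerate(specs):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(_GAIN_STREAM, g_idx))
        rng = np.random.default_rng(ss)
        cv = spec.fly_cv
        if cv > 0:
            sigma2 = np.log1p(cv**2)
            # mean-1 log-normal: mu = -sigma^2/2
            gains = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n_flies)
        else:
            gains = np.ones(n_flies)
        for f_idx in range(n_flies):
            fid = f"{spec.name}_f{f_idx:02d}"
            fly_gains[fid] = float(gains[f_idx])
            fly_genotype[fid] = spec.name
    return Cohort(
        specs={s.name: s for s in specs},
        n_flies_per_genotype=n_flies,
        n_reps=n_reps,
        fs_hz=int(fs_hz),
        seed=seed,
        trial_s=trial_s,
        fly_gains=fly_gains,
        fly_genotype=fly_genotype,
    )


# ---------------------------------------------------------------------------
# Genotype presets
# ---------------------------------------------------------------------------

def default_presets() -> Dict[str, GenotypeSpec]:
    """Ten genotype presets: 4 control-like white-eyed strains, 4 early-onset
    PD-like mutants (DJ-1/PINK1-like: elevated gain at low spatial frequency,
    slight drop at the lowest temporal frequency), 1 late-onset PD-like
    (dLRRK-like: shifted temporal peak) and 1 general-neurodegeneration-like
    (eggroll-like: broadened tuning).

    All numbers are free parameters of the generator chosen for realistic
    effect sizes, not measured values.
    """
    mk = GenotypeSpec
    presets = [
        # controls: small idiosyncratic differences between lab strains
        mk("w1118", "control", gain=6.0, tf_peak_hz=6.0, sf_cutoff_cpd=0.88),
        mk("w1", "control", gain=5.7, tf_peak_hz=6.0, sf_cutoff_cpd=0.92),
        mk("wDah", "control", gain=5.8, tf_peak_hz=6.0, sf_cutoff_cpd=0.90),
        mk("wTu", "control", gain=6.2, tf_peak_hz=6.0, sf_cutoff_cpd=0.84),
        # early-onset PD-like: elevated low-SF gain, mild low-TF drop
        mk("DJ1a", "early_PD", gain=7.0, tf_peak_hz=6.0, sf_cutoff_cpd=0.80,
           low_sf_boost=2.0, low_tf_drop=0.8),
        mk("DJ1b", "early_PD", gain=7.2, tf_peak_hz=6.0, sf_cutoff_cpd=0.85,
           low_sf_boost=1.8, low_tf_drop=0.8),
        mk("PINK1_B9", "early_PD", gain=7.5, tf_peak_hz=6.0, sf_cutoff_cpd=0.95,
           low_sf_boost=2.2, low_tf_drop=0.75),
        mk("PINK1_5", "early_PD", gain=7.8, tf_peak_hz=6.0, sf_cutoff_cpd=0.90,
           low_sf_boost=2.4, low_tf_drop=0.75),
        # late-onset PD-like: control-level gain, distinct temporal tuning
        mk("dLRRK", "late_PD", gain=6.0, tf_peak_hz=3.5, tf_bandwidth_oct=1.2,
           sf_cutoff_cpd=0.60),
        # general neurodegeneration: control-level gain, broadened/shifted
        mk("eggroll", "neurodegeneration", gain=6.0, tf_peak_hz=9.0,
           tf_bandwidth_oct=2.0, sf_cutoff_cpd=1.2),
    ]
    return {p.name: p for p in presets}


def save_presets(presets: Dict[str, GenotypeSpec], path) -> None:
    """Write a preset file: JSON mapping genotype name -> spec fields."""
    payload = {name: spec.to_dict() for name, spec in presets.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_presets(path) -> Dict[str, GenotypeSpec]:
    payload = json.loads(Path(path).read_text())
    return {name: GenotypeSpec.from_dict(d) for name, d in payload.items()}
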