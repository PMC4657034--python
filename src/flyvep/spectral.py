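"""Second-harmonic feature extraction by coherent frequency-domain averaging.

Each 11-s trial is cut into 1-s bins (the first bin is discarded to drop
the stimulus-onset transient), each bin is Fourier transformed, and the
*complex* coefficients of all bins of all repetitions of a condition are
averaged before any modulus is taken. Stimulus-locked components share the
same phase in every bin (every reversal frequency divides the 1-s bin
exactly) and therefore add; non-locked noise has random phase and cancels
as 1/sqrt(N).

The feature of interest is the modulus at the second harmonic (2F) of the
reversal frequency: for 1, 2 and 4 Hz inputs the analysis frequencies are
2, 4 and 8 Hz respectively, up to 72 Hz for the 36 Hz input. The 64 per-fly
2F amplitudes, in canonical condition order, form the classifier's feature
vector.

Amplitude convention: a cosine of amplitude A at an exact bin frequency
yields a modulus of exactly A (one-sided scaling). No taper is applied:
bins contain integer cycle counts, so rectangular windows are leakage-free
at the analysis frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Union

import numpy as np
import pandas as pd

from .design import StimulusCondition, canonical_columns, design_grid
from .exceptions import (
    EmptyTableError,
    FrequencyGridError,
    IncompleteFlyError,
    InsufficientDataError,
    ShapeError,
)
from .synth import Cohort, TrialRecording


@dataclass
class SpectralEstimate:
    """One-sided complex spectrum on an integer-Hz bin grid.

    ``complex_amps[k]`` is the coefficient at ``k / bin_duration_s`` Hz,
    scaled so a unit-amplitude cosine yields modulus 1.
    """

    complex_amps: np.ndarray
    fs_hz: float
    bin_duration_s: float = 1.0

    @property
    def freq_resolution_hz(self) -> float:
        return 1.0 / self.bin_duration_s

    @property
    def freqs_hz(self) -> np.ndarray:
        return np.arange(len(self.complex_amps)) * self.freq_resolution_hz

    def amplitude(self) -> np.ndarray:
        return np.abs(self.complex_amps)


def segment_bins(
    trial: TrialRecording,
    bin_s: float = 1.0,
    discard_lead_bins: int = 1,
) -> List[np.ndarray]:
    """Cut a trial into consecutive non-overlapping ``bin_s`` windows,
    dropping the first ``discard_lead_bins`` (onset transient).

    For an 11-s trial with defaults this yields exactly 10 windows.
    """
    n_per_bin = bin_s * trial.fs_hz
    if n_per_bin != int(n_per_bin) or n_per_bin <= 0:
        raise ShapeError(f"bin_s x fs_hz must be a positive integer, got {n_per_bin}")
    n_per_bin = int(n_per_bin)
    n = len(trial.samples)
    if n % n_per_bin != 0:
        raise ShapeError(
            f"trial length {n} is not an integer multiple of the bin length {n_per_bin}"
        )
    n_bins = n // n_per_bin
    if n_bins < discard_lead_bins + 1:
        raise InsufficientDataError(
            f"trial has {n_bins} bin(s); need at least {discard_lead_bins + 1} "
            f"to discard {discard_lead_bins} and keep one"
        )
    windows = trial.samples.reshape(n_bins, n_per_bin)
    return list(windows[discard_lead_bins:])


def _window_stack(windows: Union[Sequence[np.ndarray], np.ndarray]) -> np.ndarray:
    if isinstance(windows, np.ndarray) and windows.ndim == 2:
        return windows
    windows = list(windows)
    if len(windows) == 0:
        raise InsufficientDataError("need at least one window")
    lengths = {len(np.asarray(w)) for w in windows}
    if len(lengths) != 1:
        raise ShapeError(f"windows have unequal lengths: {sorted(lengths)}")
    return np.vstack([np.asarray(w, dtype=float) for w in windows])


def coherent_spectrum(
    windows: Union[Sequence[np.ndarray], np.ndarray],
    fs_hz: float,
) -> SpectralEstimate:
    """Average the complex spectra of the windows (coherent, phase-sensitive).

    Phase-locked signal is unchanged by the averaging; random-phase noise
    shrinks as 1/sqrt(N windows).
    """
    stack = _window_stack(windows)
    if stack.shape[0] == 0:
        raise InsufficientDataError("need at least one window")
    n = stack.shape[1]
    coeffs = np.fft.rfft(stack, axis=1).mean(axis=0) / n
    # one-sided scaling: cosine amplitude A -> modulus A
    coeffs[1:] *= 2.0
    if n % 2 == 0:
        coeffs[-1] /= 2.0  # Nyquist bin is not duplicated
    return SpectralEstimate(
        complex_amps=coeffs, fs_hz=fs_hz, bin_duration_s=n / fs_hz
    )


def harmonic_amplitude(
    spectrum: SpectralEstimate,
    input_freq_hz: float,
    harmonic: int = 2,
) -> float:
    """Modulus at ``harmonic x input_freq_hz``; never interpolates."""
    target = harmonic * input_freq_hz
    idx = target * spectrum.bin_duration_s
    if abs(idx - round(idx)) > 1e-9:
        raise FrequencyGridError(
            f"{target} Hz is not on the {spectrum.freq_resolution_hz} Hz bin grid"
        )
    idx = int(round(idx))
    if idx >= len(spectrum.complex_amps):
        raise FrequencyGridError(
            f"{target} Hz exceeds the Nyquist frequency "
            f"{spectrum.fs_hz / 2:g} Hz of the spectrum"
        )
    return float(np.abs(spectrum.complex_amps[idx]))


# ---------------------------------------------------------------------------
# Per-fly feature vectors
# ---------------------------------------------------------------------------

CohortLike = Union[Cohort, Iterable[TrialRecording]]


def _trials_by_condition(
    cohort: CohortLike, fly_id: str
) -> Dict[StimulusCondition, List[TrialRecording]]:
    grouped: Dict[StimulusCondition, List[TrialRecording]] = {}
    if isinstance(cohort, Cohort):
        it = cohort.iter_trials(fly_id)
    else:
        it = (t for t in cohort if t.fly_id == fly_id)
    for trial in it:
        grouped.setdefault(trial.condition, []).append(trial)
    return grouped


def build_feature_vector(
    cohort: CohortLike,
    fly_id: str,
    bin_s: float = 1.0,
    discard_lead_bins: int = 1,
) -> pd.Series:
    """Coherently-averaged 2F amplitude at each of the 64 conditions.

    All post-discard bins of all repetitions of a condition enter one flat
    complex mean (equal weights); the modulus at 2F is taken last. Returns
    a Series indexed by the canonical column labels, with ``fly_id`` and
    ``genotype`` attached via ``attrs``.
    """
    grouped = _trials_by_condition(cohort, fly_id)
    conditions = design_grid()
    missing = [c.label() for c in conditions if c not in grouped]
    if missing:
        raise IncompleteFlyError(fly_id, missing)

    amps = np.empty(len(conditions))
    genotype = None
    for i, cond in enumerate(conditions):
        trials = grouped[cond]
        genotype = trials[0].genotype
        windows = np.vstack(
            [segment_bins(t, bin_s=bin_s, discard_lead_bins=discard_lead_bins)
             for t in trials]
        )
        spectrum = coherent_spectrum(windows, trials[0].fs_hz)
        amps[i] = harmonic_amplitude(spectrum, cond.temporal_freq_hz, harmonic=2)

    out = pd.Series(amps, index=canonical_columns(), name=fly_id)
    out.attrs["fly_id"] = fly_id
    out.attrs["genotype"] = genotype
    return out


def feature_matrix(
    cohort: CohortLike,
    bin_s: float = 1.0,
    discard_lead_bins: int = 1,
) -> pd.DataFrame:
    """Feature table: one row per fly, ``fly_id`` and ``genotype`` columns
    followed by the 64 amplitude columns in canonical order."""
    if isinstance(cohort, Cohort):
        fly_ids = cohort.fly_ids
        genotypes = cohort.fly_genotype
        source: CohortLike = cohort
    else:
        trials = list(cohort)
        fly_ids = list(dict.fromkeys(t.fly_id for t in trials))
        genotypes = {t.fly_id: t.genotype for t in trials}
        source = trials
    if not fly_ids:
        raise EmptyTableError("cohort contains no flies")

    rows = []
    for fid in fly_ids:
        vec = build_feature_vector(
            source, fid, bin_s=bin_s, discard_lead_bins=discard_lead_bins
        )
        rows.append([fid, genotypes[fid], *vec.to_numpy()])
    return pd.DataFrame(rows, columns=["fly_id", "genotype", *canonical_columns()])
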