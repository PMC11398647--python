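"""Frozen-noise stimulus synthesis for the noise repetition-detection (NRD) task.

Four stimulus classes are used throughout:

``N``
    1 s of fresh Gaussian white noise, drawn anew for every trial.
``RN``
    repeated noise: a fresh 0.5 s token concatenated twice, so the second
    half of the waveform is a bit-exact copy of the first.
``RefN`` / ``RefRN``
    "referenced" variants of N and RN whose realization is frozen, i.e. the
    same time series re-occurs across all trials of a session.

Stimuli are generated at 44 kHz, passed through an A-weighting filter (the
standard first-order approximation to human loudness sensitivity, peaking
near 3 kHz), and resampled to 2 kHz.  The processed waveform at its natural
pipeline scale (RMS ≈ 0.14 for unit-variance raw noise) is what the
reservoir sees; an optional unit-RMS normalization is available for
sensitivity analyses.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "KINDS",
    "REPEATED_KINDS",
    "REFERENCED_KINDS",
    "Waveform",
    "Stimulus",
    "StimulusSession",
    "TestSet",
    "generate_white_noise",
    "make_raw_stimulus",
    "a_weighting",
    "resample",
    "make_stimulus",
    "build_session",
    "build_test_set",
]

#: Stimulus classes of the NRD task.
KINDS = ("N", "RN", "RefN", "RefRN")
#: Kinds whose raw waveform is a 0.5 s token repeated twice.
REPEATED_KINDS = frozenset({"RN", "RefRN"})
#: Kinds whose realization is frozen across trials.
REFERENCED_KINDS = frozenset({"RefN", "RefRN"})

#: Native sampling rate of raw stimuli (Hz).
RAW_FS = 44_000.0
#: Sampling rate after resampling (Hz).
PROCESSED_FS = 2_000.0
#: Stimulus duration (s).
DURATION = 1.0

_SEED_MAX = 2**31  # keep all derived seeds in int32 range


@dataclass(frozen=True)
class Waveform:
    """A sampled signal: dimensionless amplitudes at a fixed rate."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1:
            raise ValueError("waveform samples must be one-dimensional")
        if samples.size and not np.all(np.isfinite(samples)):
            raise ValueError("waveform contains non-finite samples")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.samples.size / self.fs

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))


@dataclass(frozen=True)
class Stimulus:
    """One NRD stimulus: raw 44 kHz waveform plus its processed 2 kHz form.

    ``raw`` may be ``None`` for bulk test material where only the processed
    waveform is needed (the raw array is 22x larger).
    """

    kind: str
    processed: Waveform
    realization_seed: int
    raw: Waveform | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown stimulus kind {self.kind!r}")


def _check_kind(kind: str) -> None:
    if kind not in KINDS:
        raise ValueError(f"unknown stimulus kind {kind!r}; expected one of {KINDS}")


def generate_white_noise(n_samples: int, seed: int, fs: float = RAW_FS) -> Waveform:
    """Draw i.i.d. zero-mean unit-variance Gaussian white noise.

    Reproducible: the same seed always yields the same samples.
    """
    if n_samples < 0:
        raise ValueError(f"n_samples must be non-negative, got {n_samples}")
    rng = np.random.default_rng(seed)
    return Waveform(rng.standard_normal(n_samples), fs)


def make_raw_stimulus(kind: str, seed: int) -> Waveform:
    """Build the 1 s raw waveform (44,000 samples) for one stimulus.

    For the repeated kinds (RN, RefRN) a 22,000-sample token is drawn and
    concatenated twice, so the two halves are bit-identical; for N and RefN
    a single fresh 44,000-sample realization is drawn.
    """
    _check_kind(kind)
    n_total = int(round(DURATION * RAW_FS))
    if kind in REPEATED_KINDS:
        half = generate_white_noise(n_total // 2, seed)
        samples = np.concatenate([half.samples, half.samples])
        return Waveform(samples, RAW_FS)
    return generate_white_noise(n_total, seed)


# IEC 61672 analog A-weighting: four zeros at DC and real poles at these
# corner frequencies (Hz); gain normalized to 0 dB at 1 kHz.
_A_WEIGHT_POLE_FREQS = (20.598997, 20.598997, 107.65265, 737.86223,
                        12194.217, 12194.217)
_A_WEIGHT_GAIN_DB = 1.9997  # makes the response exactly unity at 1 kHz


@lru_cache(maxsize=8)
def _a_weighting_sos(fs: float) -> np.ndarray:
    zeros = [0.0] * 4
    poles = [-2.0 * np.pi * f for f in _A_WEIGHT_POLE_FREQS]
    gain = (2.0 * np.pi * 12194.217) ** 2 * 10.0 ** (_A_WEIGHT_GAIN_DB / 20.0)
    zd, pd, kd = signal.bilinear_zpk(zeros, poles, gain, fs)
    return signal.zpk2sos(zd, pd, kd)


def a_weighting(w: Waveform) -> Waveform:
    """Apply the standard A-weighting filter (0 dB at 1 kHz).

    The analog IEC 61672 pole/zero prototype is discretized by the bilinear
    transform at the waveform's own rate, which must be at least 8 kHz for
    the transform to be well conditioned around the 12.2 kHz pole pair.
    """
    if w.fs < 8_000:
        raise ValueError(
            f"A-weighting requires fs >= 8 kHz, got {w.fs} Hz"
        )
    sos = _a_weighting_sos(w.fs)
    return Waveform(signal.sosfilt(sos, w.samples), w.fs)


@lru_cache(maxsize=8)
def _decimation_fir(up: int, down: int, fs: float, fs_out: float) -> np.ndarray:
    # sharp Kaiser low-pass: flat to 0.95 of the new Nyquist, >=60 dB
    # stopband from the new Nyquist upward
    nyq_in = fs * up / 2.0
    nyq_out = fs_out / 2.0
    width = 0.05 * nyq_out / nyq_in
    numtaps, beta = signal.kaiserord(60.0, width)
    numtaps |= 1  # odd length, linear phase type I
    return signal.firwin(numtaps, 0.975 * nyq_out / nyq_in,
                         window=("kaiser", beta)) * up


def resample(w: Waveform, fs_out: float) -> Waveform:
    """Anti-aliased polyphase downsampling to ``fs_out``.

    A Kaiser-windowed FIR low-pass holds the passband flat to 0.95 of the
    new Nyquist rate and attenuates everything above it by >= 60 dB before
    decimation.  Upsampling is not supported.
    """
    if fs_out >= w.fs:
        raise ValueError(
            f"resample only downsamples: fs_out={fs_out} >= fs={w.fs}"
        )
    ratio = Fraction(fs_out / w.fs).limit_denominator(10_000)
    fir = _decimation_fir(ratio.numerator, ratio.denominator, w.fs, fs_out)
    out = signal.resample_poly(w.samples, ratio.numerator, ratio.denominator,
                               window=fir)
    n_expected = int(round(len(w) * fs_out / w.fs))
    return Waveform(out[:n_expected], fs_out)


def make_stimulus(
    kind: str,
    seed: int,
    normalize: bool = False,
    keep_raw: bool = True,
) -> Stimulus:
    """Run the full pipeline: raw noise -> A-weighting -> 2 kHz resample.

    With ``normalize=True`` the processed waveform is rescaled to unit RMS;
    by default it keeps its natural pipeline scale.
    """
    raw = make_raw_stimulus(kind, seed)
    processed = resample(a_weighting(raw), PROCESSED_FS)
    if normalize:
        processed = Waveform(processed.samples / processed.rms(), processed.fs)
    return Stimulus(
        kind=kind,
        processed=processed,
        realization_seed=int(seed),
        raw=raw if keep_raw else None,
    )


@dataclass
class StimulusSession:
    """The 20-stimulus training session: 5 realizations per kind.

    All RefRN entries share one frozen realization (``ref_rn_seed``),
    likewise RefN (``ref_n_seed``).  The presentation order is a seeded
    uniform shuffle constrained so the final stimulus is an N.
    """

    stimuli: list[Stimulus]
    ref_rn_seed: int
    ref_n_seed: int
    order_seed: int
    fresh_seeds: tuple[int, ...] = field(default_factory=tuple)
    normalize: bool = False

    def kinds(self) -> list[str]:
        return [s.kind for s in self.stimuli]

    def realization_seeds(self, kind: str) -> set[int]:
        return {s.realization_seed for s in self.stimuli if s.kind == kind}

    def reference(self, kind: str) -> Stimulus:
        """The frozen RefN or RefRN stimulus of this session."""
        if kind not in REFERENCED_KINDS:
            raise ValueError(f"{kind!r} has no frozen session-wide realization")
        return next(s for s in self.stimuli if s.kind == kind)


def _draw_fresh_seeds(rng: np.random.Generator, n: int,
                      forbidden: set[int]) -> list[int]:
    seeds: list[int] = []
    taken = set(forbidden)
    while len(seeds) < n:
        s = int(rng.integers(0, _SEED_MAX))
        if s not in taken:
            seeds.append(s)
            taken.add(s)
    return seeds


def build_session(
    ref_rn_seed: int,
    ref_n_seed: int,
    order_seed: int,
    fresh_seeds: int | Sequence[int],
    normalize: bool = False,
) -> StimulusSession:
    """Assemble the 20-trial training session (5 stimuli per kind).

    ``fresh_seeds`` either lists the ten realization seeds for the fresh
    N and RN trials or is a single integer from which they are drawn.
    The order is a seeded permutation with the last trial forced to be N
    (so the session never ends on a RefRN).
    """
    if ref_rn_seed == ref_n_seed:
        raise ValueError("RefRN and RefN must use distinct realizations")
    if isinstance(fresh_seeds, (int, np.integer)):
        rng = np.random.default_rng(fresh_seeds)
        fresh = _draw_fresh_seeds(rng, 10, {int(ref_rn_seed), int(ref_n_seed)})
    else:
        fresh = [int(s) for s in fresh_seeds]
        if len(fresh) != 10:
            raise ValueError("need 10 fresh seeds: 5 for N and 5 for RN")
        if len(set(fresh) | {int(ref_rn_seed), int(ref_n_seed)}) != 12:
            raise ValueError("fresh seeds collide with each other or the references")

    entries: list[tuple[str, int]] = []
    entries += [("N", s) for s in fresh[:5]]
    entries += [("RN", s) for s in fresh[5:]]
    entries += [("RefN", int(ref_n_seed))] * 5
    entries += [("RefRN", int(ref_rn_seed))] * 5

    order = list(np.random.default_rng(order_seed).permutation(len(entries)))
    # force the final presentation to be an N trial
    if entries[order[-1]][0] != "N":
        last_n_pos = max(i for i, idx in enumerate(order)
                         if entries[idx][0] == "N")
        order[last_n_pos], order[-1] = order[-1], order[last_n_pos]

    cache: dict[tuple[str, int], Stimulus] = {}
    stimuli = []
    for idx in order:
        kind, seed = entries[idx]
        key = (kind, seed)
        if key not in cache:
            cache[key] = make_stimulus(kind, seed, normalize=normalize)
        stimuli.append(cache[key])
    return StimulusSession(
        stimuli=stimuli,
        ref_rn_seed=int(ref_rn_seed),
        ref_n_seed=int(ref_n_seed),
        order_seed=int(order_seed),
        fresh_seeds=tuple(fresh),
        normalize=normalize,
    )


@dataclass
class TestSet:
    """Per-kind test material for the evaluation runs.

    N and RN entries are fresh realizations disjoint from the training
    session; RefN and RefRN re-use the session's frozen time series for
    every run.
    """

    stimuli: dict[str, list[Stimulus]]
    n_runs: int
    seed: int

    def processed_matrix(self, kind: str) -> np.ndarray:
        """Stack processed waveforms for one kind into an (n_runs, K) array."""
        return np.stack([s.processed.samples for s in self.stimuli[kind]])


def build_test_set(
    session: StimulusSession,
    n_runs: int = 200,
    seed: int = 0,
    kinds: Sequence[str] = KINDS,
) -> TestSet:
    """Build ``n_runs`` test stimuli per kind.

    Fresh kinds get realization seeds disjoint from every training seed;
    referenced kinds reuse the identical session stimulus object in every
    run.  Raw waveforms are dropped to keep bulk material small.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    for kind in kinds:
        _check_kind(kind)
    rng = np.random.default_rng(seed)
    training_seeds = {s.realization_seed for s in session.stimuli}
    stimuli: dict[str, list[Stimulus]] = {}
    for kind in kinds:
        if kind in REFERENCED_KINDS:
            ref = session.reference(kind)
            stimuli[kind] = [ref] * n_runs
        else:
            fresh = _draw_fresh_seeds(rng, n_runs, training_seeds)
            stimuli[kind] = [
                make_stimulus(kind, s, normalize=session.normalize,
                              keep_raw=False)
                for s in fresh
            ]
    return TestSet(stimuli=stimuli, n_runs=n_runs, seed=int(seed))


# ---------------------------------------------------------------------------
# inspection / export helpers


def _checksum(samples: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(samples).tobytes()).hexdigest()[:16]


def session_manifest(session: StimulusSession) -> dict:
    """JSON-serializable description of a session: seeds, order, checksums."""
    return {
        "ref_rn_seed": session.ref_rn_seed,
        "ref_n_seed": session.ref_n_seed,
        "order_seed": session.order_seed,
        "fresh_seeds": list(session.fresh_seeds),
        "normalize": session.normalize,
        "trials": [
            {
                "index": i,
                "kind": s.kind,
                "realization_seed": s.realization_seed,
                "processed_sha256_16": _checksum(s.processed.samples),
            }
            for i, s in enumerate(session.stimuli)
        ],
    }


def export_session(session: StimulusSession, out_dir: str | Path,
                   wav: bool = False) -> Path:
    """Write the session manifest (and optionally WAV files) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = session_manifest(session)
    (out / "session.json").write_text(json.dumps(manifest, indent=2))
    if wav:
        from scipy.io import wavfile

        for i, s in enumerate(session.stimuli):
            if s.raw is not None:
                wavfile.write(out / f"trial{i:02d}_{s.kind}_raw.wav",
                              int(s.raw.fs), s.raw.samples.astype(np.float32))
            wavfile.write(out / f"trial{i:02d}_{s.kind}_2khz.wav",
                          int(s.processed.fs),
                          s.processed.samples.astype(np.float32))
    return out
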