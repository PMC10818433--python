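"""Audio and annotation I/O for auscultation recordings.

Reads WAV recordings and per-recording annotation text files (one row per
respiratory cycle: start s, end s, crackle 0/1, wheeze 0/1), resamples to the
working rate, and cuts recordings into fixed-duration labelled respiratory
cycles.  The unit of classification downstream is a single respiratory cycle,
zero-padded or truncated to a fixed duration (default 6 s at 4 kHz).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import InputFormatError, ParameterError

logger = logging.getLogger(__name__)

#: canonical 4-class label order used everywhere in the package
LABELS4 = ("normal", "crackle", "wheeze", "both")


def label_from_flags(crackle: bool, wheeze: bool) -> str:
    """Map the (crackle, wheeze) flag pair to the 4-class label.

    The taxonomy is total and exclusive: both flags false -> ``normal``,
    both true -> ``both``, otherwise the single present sound.
    """
    if crackle and wheeze:
        return "both"
    if crackle:
        return "crackle"
    if wheeze:
        return "wheeze"
    return "normal"


def flags_from_label(label4: str) -> tuple[bool, bool]:
    """Inverse of :func:`label_from_flags`; returns (crackle, wheeze)."""
    try:
        idx = LABELS4.index(label4)
    except ValueError:
        raise ParameterError(f"unknown 4-class label {label4!r}") from None
    return idx in (1, 3), idx in (2, 3)


@dataclass
class AudioRecording:
    """A mono auscultation recording.

    samples are dimensionless amplitudes, nominally in [-1, 1]; rate is the
    sampling frequency in Hz.  patient_id / record_id are opaque strings used
    only for patient-wise grouping.
    """

    samples: np.ndarray
    rate: float
    patient_id: str = ""
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.rate <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.rate}")
        if self.samples.size < 1:
            raise ParameterError("recording must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("recording contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass(frozen=True)
class CycleAnnotation:
    """One annotated respiratory cycle: [start, end) seconds plus event flags."""

    start: float
    end: float
    crackle: bool
    wheeze: bool

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ParameterError(
                f"annotation requires 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def label4(self) -> str:
        return label_from_flags(self.crackle, self.wheeze)


@dataclass
class RespiratoryCycle:
    """A fixed-length labelled segment: exactly round(rate * duration) samples."""

    samples: np.ndarray
    rate: float
    duration: float
    patient_id: str
    crackle: bool
    wheeze: bool
    label4: str = field(default="")
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        expected = round(self.rate * self.duration)
        if self.samples.size != expected:
            raise ParameterError(
                f"cycle has {self.samples.size} samples, expected "
                f"round({self.rate} * {self.duration}) = {expected}"
            )
        derived = label_from_flags(self.crackle, self.wheeze)
        if not self.label4:
            self.label4 = derived
        elif self.label4 != derived:
            raise ParameterError(
                f"label4 {self.label4!r} inconsistent with flags "
                f"(crackle={self.crackle}, wheeze={self.wheeze})"
            )


def read_wav(path: str | Path) -> AudioRecording:
    """Read a WAV file as a mono float recording in [-1, 1].

    Multichannel files are reduced to channel 0 (auscultation recordings are
    mono in practice).  Integer PCM is scaled by the type's full scale; float
    WAVs are passed through.  patient_id follows the common auscultation-corpus
    filename convention ``<patient>_<...>.wav`` when the stem contains an
    underscore, else it is left empty.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises ValueError on malformed RIFF
        raise InputFormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        # divide by the positive full scale (matches the 16-bit write path)
        samples = data.astype(np.float64) / float(np.iinfo(data.dtype).max)
    else:
        samples = data.astype(np.float64)
    stem = path.stem
    patient = stem.split("_")[0] if "_" in stem else ""
    return AudioRecording(samples=samples, rate=float(rate), patient_id=patient, record_id=stem)


def write_wav(path: str | Path, rec: AudioRecording) -> None:
    """Write a recording as 16-bit PCM WAV (clipping amplitudes to [-1, 1])."""
    clipped = np.clip(rec.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(str(path), int(round(rec.rate)), pcm)


def resample(rec: AudioRecording, target_rate: float) -> AudioRecording:
    """Resample to ``target_rate`` with an anti-aliased polyphase FIR.

    Output length is round(len * target_rate / rate).  An identity request
    returns a copy.
    """
    if target_rate <= 0:
        raise ParameterError(f"target_rate must be positive, got {target_rate}")
    if target_rate == rec.rate:
        return AudioRecording(rec.samples.copy(), rec.rate, rec.patient_id, rec.record_id)
    frac = Fraction(target_rate / rec.rate).limit_denominator(10000)
    out = resample_poly(rec.samples, frac.numerator, frac.denominator)
    n_out = round(rec.samples.size * target_rate / rec.rate)
    if out.size > n_out:
        out = out[:n_out]
    elif out.size < n_out:
        out = np.pad(out, (0, n_out - out.size))
    return AudioRecording(out, float(target_rate), rec.patient_id, rec.record_id)


def parse_annotations(path: str | Path) -> list[CycleAnnotation]:
    """Parse a 4-column whitespace-separated annotation file.

    Columns: start s, end s, crackle flag (0/1), wheeze flag (0/1); one
    respiratory cycle per row, returned in file order.  Malformed rows raise
    :class:`InputFormatError` naming the offending line.
    """
    anns: list[CycleAnnotation] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            cols = line.split()
            if len(cols) < 4:
                raise InputFormatError(
                    f"{path}: line {lineno}: expected 4 columns, got {len(cols)}"
                )
            try:
                start, end = float(cols[0]), float(cols[1])
                crackle, wheeze = bool(int(cols[2])), bool(int(cols[3]))
            except ValueError as exc:
                raise InputFormatError(f"{path}: line {lineno}: {exc}") from exc
            anns.append(CycleAnnotation(start, end, crackle, wheeze))
    return anns


def write_annotations(path: str | Path, anns: list[CycleAnnotation]) -> None:
    """Write annotations in the same 4-column dialect read by parse_annotations."""
    with open(path, "w") as fh:
        for a in anns:
            fh.write(f"{a.start:.3f}\t{a.end:.3f}\t{int(a.crackle)}\t{int(a.wheeze)}\n")


def extract_cycles(
    rec: AudioRecording,
    anns: list[CycleAnnotation],
    duration: float = 6.0,
) -> list[RespiratoryCycle]:
    """Cut a recording into fixed-duration labelled cycles.

    Seconds map to samples via floor(t * rate) with half-open [start, end)
    indexing, so adjacent annotated cycles never overlap.  Segments shorter
    than the target are zero-padded at the end (preserving onset timing);
    longer segments are truncated.  Annotations extending beyond the recording
    are clipped to the recording end with a logged warning.
    """
    if duration <= 0:
        raise ParameterError(f"duration must be positive, got {duration}")
    n_target = round(rec.rate * duration)
    cycles: list[RespiratoryCycle] = []
    for ann in anns:
        i0 = math.floor(ann.start * rec.rate)
        i1 = math.floor(ann.end * rec.rate)
        if i1 > rec.samples.size:
            logger.warning(
                "annotation [%.3f, %.3f) extends beyond recording %s (%.3f s); clipping",
                ann.start, ann.end, rec.record_id or "<unnamed>", rec.duration,
            )
            i1 = rec.samples.size
        i0 = min(i0, rec.samples.size)
        seg = rec.samples[i0:i1]
        if seg.size < n_target:
            seg = np.pad(seg, (0, n_target - seg.size))
        else:
            seg = seg[:n_target].copy()
        cycles.append(
            RespiratoryCycle(
                samples=seg,
                rate=rec.rate,
                duration=duration,
                patient_id=rec.patient_id,
                crackle=ann.crackle,
                wheeze=ann.wheeze,
                record_id=rec.record_id,
            )
        )
    return cycles
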