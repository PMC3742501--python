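"""Audio I/O, spectra and per-call acoustic feature extraction.

Calls are described by eight variables derived either from the averaged
magnitude spectrum of the entire call or from nine short measurement
windows spaced regularly within the call:

==========  =======================================================
pf          peak frequency (Hz): bin with the highest amplitude
q50         median frequency (Hz): splits spectral energy in half
ent         Wiener entropy scaled to the call's bandwidth (see below)
q50start    q50 in the first retained measurement window (Hz)
q50end      q50 in the last retained measurement window (Hz)
q50min      minimum q50 over the nine windows (Hz)
dur         call duration (s)
q50maxloc   index (1..9) of the window with the maximum q50
==========  =======================================================

Spectrograms use a Hamming window, 1024-point FFT and 87.5 % overlap at a
44100 Hz sampling rate, giving a ~43 Hz frequency grid and ~3 ms hop; the
analysis window is ~23 ms. Eleven measurement positions are placed at the
call start and then every dur/10; the first and last are discarded and the
remaining nine (indexed 1..9) are retained, each analysed as a single FFT
frame centred on its position.

Wiener entropy (geometric / arithmetic mean of the spectrum) grows with
bandwidth, so the reported ``ent`` is computed on the spectrum truncated at
twice the call's q50; the raw full-band value is kept alongside it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .study import SITUATION_CODES

logger = logging.getLogger(__name__)

#: canonical column order of the 8-variable feature table
FEATURE_NAMES = ["pf", "q50", "ent", "q50start", "q50end", "q50min", "dur", "q50maxloc"]

#: metadata columns carried alongside features
META_NAMES = ["call_id", "situation", "piglet", "litter"]

ANNOTATION_COLUMNS = ["call_id", "file", "start_s", "end_s", "situation", "piglet", "litter"]


@dataclass(frozen=True)
class SpectrogramParams:
    """Short-time analysis settings."""

    sample_rate: float = 44100.0
    fft_length: int = 1024
    overlap: float = 0.875
    window: str = "hamming"

    def __post_init__(self) -> None:
        if self.fft_length <= 0 or (self.fft_length & (self.fft_length - 1)) != 0:
            raise ValueError(f"fft_length must be a power of two, got {self.fft_length}")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError(f"overlap must be in [0, 1), got {self.overlap}")

    @property
    def hop(self) -> int:
        return max(1, int(round(self.fft_length * (1.0 - self.overlap))))

    @property
    def bin_width(self) -> float:
        """Frequency grid resolution in Hz (≈43 Hz at 44100/1024)."""
        return self.sample_rate / self.fft_length

    @property
    def window_duration(self) -> float:
        """Analysis window length in seconds (≈23 ms at the defaults)."""
        return self.fft_length / self.sample_rate

    def taper(self) -> np.ndarray:
        from scipy.signal import get_window

        return get_window(self.window, self.fft_length, fftbins=True)


@dataclass(frozen=True)
class CallSegment:
    """One annotated call: a half-open interval [start_s, end_s) in a file."""

    call_id: str
    file: str
    start_s: float
    end_s: float
    situation: str
    piglet: str
    litter: str

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"call {self.call_id}: end_s ({self.end_s}) must exceed start_s ({self.start_s})"
            )

    @property
    def dur(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class AcousticFeatures:
    pf: float
    q50: float
    ent: float
    q50start: float
    q50end: float
    q50min: float
    dur: float
    q50maxloc: int
    ent_raw: float = np.nan

    def as_series(self) -> pd.Series:
        return pd.Series({name: getattr(self, name) for name in FEATURE_NAMES})


# ---------------------------------------------------------------------------
# audio and annotation I/O


def read_audio(path: str | Path, channel: int | None = None) -> tuple[np.ndarray, float]:
    """Read a WAV file as float samples in [-1, 1] plus its sample rate.

    Multi-channel files require an explicit ``channel`` selection.
    """
    try:
        sample_rate, data = wavfile.read(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with context
        raise ValueError(f"could not read WAV file {path!r}: {exc}") from exc
    if data.ndim == 2:
        if channel is None:
            raise ValueError(
                f"{path!r} has {data.shape[1]} channels; pass channel= to select one"
            )
        data = data[:, channel]
    if np.issubdtype(data.dtype, np.integer):
        scale = float(max(abs(np.iinfo(data.dtype).min), np.iinfo(data.dtype).max))
        samples = data.astype(np.float64) / scale
    else:
        samples = data.astype(np.float64)
    return samples, float(sample_rate)


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: float) -> None:
    """Write a mono waveform in [-1, 1] as 16-bit PCM."""
    clipped = np.clip(np.asarray(waveform, dtype=np.float64), -1.0, 1.0)
    scaled = np.clip(np.round(clipped * 32768.0), -32768, 32767)
    wavfile.write(str(path), int(sample_rate), scaled.astype(np.int16))


def load_annotations(
    path: str | Path, valid_situations: tuple[str, ...] = SITUATION_CODES
) -> list[CallSegment]:
    """Load a delimited call-annotation table into validated segments.

    Rows with ``end_s <= start_s`` are rejected with their row number;
    unknown situation codes raise an error listing the valid codes.
    Segments are returned ordered by file then start time. Overlapping
    segments within a file are accepted (calls may abut) but logged.
    """
    table = pd.read_csv(path, sep=None, engine="python")
    if table.empty:
        warnings.warn(f"annotation file {path!r} contains no calls", stacklevel=2)
        return []
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"annotation file {path!r} lacks columns: {missing}")

    segments: list[CallSegment] = []
    for row_number, row in enumerate(table.itertuples(index=False), start=1):
        if not row.end_s > row.start_s:
            raise ValueError(
                f"annotation row {row_number}: end_s ({row.end_s}) <= start_s ({row.start_s})"
            )
        if row.situation not in valid_situations:
            raise ValueError(
                f"annotation row {row_number}: unknown situation code {row.situation!r}; "
                f"valid codes: {sorted(valid_situations)}"
            )
        segments.append(
            CallSegment(
                call_id=str(row.call_id),
                file=str(row.file),
                start_s=float(row.start_s),
                end_s=float(row.end_s),
                situation=str(row.situation),
                piglet=str(row.piglet),
                litter=str(row.litter),
            )
        )
    segments.sort(key=lambda s: (s.file, s.start_s))
    for prev, cur in zip(segments, segments[1:]):
        if cur.file == prev.file and cur.start_s < prev.end_s:
            logger.info("overlapping segments %s and %s in %s", prev.call_id, cur.call_id, cur.file)
    return segments


# ---------------------------------------------------------------------------
# spectra


def _frame_spectrum(waveform: np.ndarray, center: int, params: SpectrogramParams) -> np.ndarray:
    """Magnitude spectrum of the single analysis frame centred at a sample."""
    n = params.fft_length
    start = center - n // 2
    frame = np.zeros(n)
    lo, hi = max(start, 0), min(start + n, waveform.size)
    if hi > lo:
        frame[lo - start : hi - start] = waveform[lo:hi]
    return np.abs(np.fft.rfft(frame * params.taper()))


def call_spectrum(
    waveform: np.ndarray, segment: CallSegment, params: SpectrogramParams
) -> np.ndarray:
    """Average magnitude spectrum over all analysis frames inside the call.

    Frames of ``fft_length`` samples advance by the hop implied by the
    overlap; every frame fully inside [start_s, end_s) contributes. The
    returned vector has ``fft_length/2 + 1`` bins; bin k sits at
    ``k * sample_rate / fft_length`` Hz.
    """
    sr = params.sample_rate
    start = int(round(segment.start_s * sr))
    end = int(round(segment.end_s * sr))
    if start < 0 or end > waveform.size:
        raise ValueError(f"call {segment.call_id} exceeds file bounds")
    n, hop = params.fft_length, params.hop
    if end - start < n:
        raise ValueError(
            f"call {segment.call_id} ({segment.dur:.4f} s) is shorter than one "
            f"analysis window ({params.window_duration:.4f} s)"
        )
    taper = params.taper()
    frames = []
    for frame_start in range(start, end - n + 1, hop):
        frames.append(np.abs(np.fft.rfft(waveform[frame_start : frame_start + n] * taper)))
    return np.mean(frames, axis=0)


def _check_positive(spectrum: np.ndarray) -> np.ndarray:
    spectrum = np.asarray(spectrum, dtype=np.float64)
    if spectrum.ndim != 1 or spectrum.size == 0:
        raise ValueError("spectrum must be a non-empty 1-D array")
    if np.any(spectrum < 0):
        raise ValueError("spectrum amplitudes must be non-negative")
    if not np.any(spectrum > 0):
        raise ValueError("spectrum has zero total energy")
    return spectrum


def q50_of_spectrum(spectrum: np.ndarray, bin_width: float) -> float:
    """Median frequency: centre of the lowest bin at which cumulative
    energy (amplitude squared) first reaches half the total."""
    spectrum = _check_positive(spectrum)
    energy = spectrum**2
    cumulative = np.cumsum(energy)
    k = int(np.searchsorted(cumulative, 0.5 * cumulative[-1]))
    return k * bin_width


def peak_frequency(spectrum: np.ndarray, bin_width: float) -> float:
    """Frequency of the maximum-amplitude bin; ties go to the lowest bin."""
    spectrum = _check_positive(spectrum)
    return int(np.argmax(spectrum)) * bin_width


def wiener_entropy(
    spectrum: np.ndarray, scale_to_q50: bool = False, bin_width: float = 1.0
) -> float:
    """Ratio of the geometric to the arithmetic mean of the spectrum.

    0 for a single-component spectrum, 1 for a flat one. With
    ``scale_to_q50`` the spectrum is first truncated at twice its q50,
    which removes the intrinsic bandwidth dependence of the raw value
    using only in-call quantities.
    """
    spectrum = _check_positive(spectrum)
    if scale_to_q50:
        q50 = q50_of_spectrum(spectrum, bin_width)
        upper_bin = int(round(2.0 * q50 / bin_width))
        spectrum = spectrum[: max(upper_bin + 1, 2)]
    arithmetic = float(np.mean(spectrum))
    if np.any(spectrum == 0):
        return 0.0
    geometric = float(np.exp(np.mean(np.log(spectrum))))
    return geometric / arithmetic


def measurement_windows(segment: CallSegment, params: SpectrogramParams) -> np.ndarray:
    """Absolute times (s) of the nine retained measurement windows.

    Eleven positions sit at the call start and then every dur/10; the
    first and last are discarded, leaving windows indexed 1..9 centred
    at ``start_s + k * dur / 10`` for k = 1..9.
    """
    if segment.dur < params.window_duration:
        logger.info(
            "call %s is not longer than one analysis window; measurement "
            "windows are degenerate",
            segment.call_id,
        )
    offsets = segment.start_s + np.arange(11) * segment.dur / 10.0
    return offsets[1:10]


def extract_features(
    waveform: np.ndarray, segment: CallSegment, params: SpectrogramParams
) -> AcousticFeatures:
    """Compute the 8-variable description of one call."""
    spectrum = call_spectrum(waveform, segment, params)
    bw = params.bin_width
    pf = peak_frequency(spectrum, bw)
    q50 = q50_of_spectrum(spectrum, bw)
    ent = wiener_entropy(spectrum, scale_to_q50=True, bin_width=bw)
    ent_raw = wiener_entropy(spectrum)

    window_q50 = []
    for t in measurement_windows(segment, params):
        frame = _frame_spectrum(waveform, int(round(t * params.sample_rate)), params)
        window_q50.append(q50_of_spectrum(frame, bw))
    window_q50 = np.asarray(window_q50)
    return AcousticFeatures(
        pf=pf,
        q50=q50,
        ent=ent,
        q50start=float(window_q50[0]),
        q50end=float(window_q50[-1]),
        q50min=float(window_q50.min()),
        dur=segment.dur,
        q50maxloc=int(np.argmax(window_q50)) + 1,  # ties break to the earliest window
        ent_raw=ent_raw,
    )


def extract_feature_table(
    audio: dict[str, tuple[np.ndarray, float]] | str | Path,
    segments: list[CallSegment],
    params: SpectrogramParams | None = None,
) -> pd.DataFrame:
    """Extract features for every annotated call.

    ``audio`` is either a directory of WAV files or a preloaded mapping
    ``file -> (waveform, sample_rate)``. Returns a table with the metadata
    columns followed by the eight feature columns.
    """
    params = params or SpectrogramParams()
    cache: dict[str, tuple[np.ndarray, float]] = {}
    rows = []
    for segment in segments:
        if isinstance(audio, (str, Path)):
            if segment.file not in cache:
                cache[segment.file] = read_audio(Path(audio) / segment.file)
            waveform, sr = cache[segment.file]
        else:
            waveform, sr = audio[segment.file]
        if abs(sr - params.sample_rate) > 1e-6:
            raise ValueError(
                f"{segment.file}: sample rate {sr} differs from analysis rate {params.sample_rate}"
            )
        features = extract_features(waveform, segment, params)
        rows.append(
            {
                "call_id": segment.call_id,
                "situation": segment.situation,
                "piglet": segment.piglet,
                "litter": segment.litter,
                **features.as_series().to_dict(),
            }
        )
    return pd.DataFrame(rows, columns=META_NAMES + FEATURE_NAMES)


# ---------------------------------------------------------------------------
# standardization and variable screening


@dataclass
class Standardizer:
    """Column-wise z-scoring with stored means and sample SDs (ddof=1)."""

    means: pd.Series
    sds: pd.Series

    @classmethod
    def fit(cls, table: pd.DataFrame) -> "Standardizer":
        if len(table) < 2:
            raise ValueError("standardization needs at least 2 calls")
        sds = table.std(ddof=1)
        zero = sds[sds == 0]
        if len(zero):
            raise ValueError(f"zero-variance column(s): {list(zero.index)}")
        return cls(means=table.mean(), sds=sds)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return (table[self.means.index] - self.means) / self.sds

    def inverse(self, table: pd.DataFrame) -> pd.DataFrame:
        return table[self.means.index] * self.sds + self.means


def standardize(table: pd.DataFrame) -> tuple[pd.DataFrame, Standardizer]:
    """Z-score each column (mean 0, variance 1) and keep the transform."""
    scaler = Standardizer.fit(table)
    return scaler.transform(table), scaler


def screen_variables(
    table: pd.DataFrame, corr_threshold: float = 0.9
) -> tuple[list[str], list[tuple[str, str, float]]]:
    """Drop the later-listed member of every highly correlated pair.

    Greedy: while any retained pair has |r| above the threshold, the
    later column is removed. Returns the retained column list and the
    dropped (kept, dropped, r) pairs.
    """
    retained = list(table.columns)
    dropped: list[tuple[str, str, float]] = []
    changed = True
    while changed:
        changed = False
        corr = table[retained].corr()
        for i, a in enumerate(retained):
            for b in retained[i + 1 :]:
                r = corr.loc[a, b]
                if abs(r) > corr_threshold:
                    retained.remove(b)
                    dropped.append((a, b, float(r)))
                    changed = True
                    break
            if changed:
                break
    return retained, dropped
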