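"""Reading and writing the audio and tabular formats the pipeline touches.

The instrument is a piezo contact microphone sampled through a consumer
audio interface, so recordings arrive as mono WAV files — 32-bit float at
44,100 Hz in the reference setup — with amplitudes on a relative scale in
[-1, 1] (1 being the maximum measurable intensity).  Insertion depths,
measured with a caliper after each hammer blow, travel as small CSV tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import AudioFormatError, EmptyInputError, SchemaError

__all__ = ["Recording", "read_wav", "write_wav", "read_depth_table", "write_depth_table"]

# full-scale divisors for integer PCM encodings
_PCM_SCALE = {
    np.dtype(np.int16): 32768.0,
    np.dtype(np.int32): 2147483648.0,
    np.dtype(np.uint8): 128.0,  # offset binary: subtract 128 first
}


@dataclass(frozen=True)
class Recording:
    """A mono audio recording on a relative amplitude scale.

    Attributes
    ----------
    samples
        Amplitude series, float64, nominally within [-1, 1].
    sample_rate
        Sampling rate in Hz (positive integer).
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise AudioFormatError("Recording samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise AudioFormatError("Recording contains non-finite samples")
        if self.sample_rate <= 0:
            raise AudioFormatError("sample_rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Length in seconds: number of samples / sample rate."""
        return len(self.samples) / self.sample_rate

    def __len__(self) -> int:
        return len(self.samples)


def read_wav(path) -> Recording:
    """Read a PCM or float WAV file as a mono :class:`Recording`.

    Multi-channel input is reduced to the first channel (the instrument is
    a single contact microphone).  Integer PCM is rescaled to [-1, 1] by
    dividing by the dtype's full-scale value; float data is taken as-is.

    Raises
    ------
    AudioFormatError
        If the file cannot be parsed as WAV.
    EmptyInputError
        If the file holds zero audio samples.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises bare ValueError on bad headers
        raise AudioFormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise EmptyInputError(f"WAV file {path} contains no audio samples")
    if data.ndim > 1:
        data = data[:, 0]
    dtype = data.dtype
    if dtype in _PCM_SCALE:
        if dtype == np.dtype(np.uint8):
            samples = (data.astype(np.float64) - 128.0) / _PCM_SCALE[dtype]
        else:
            samples = data.astype(np.float64) / _PCM_SCALE[dtype]
    elif np.issubdtype(dtype, np.floating):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported WAV sample format {dtype} in {path}")
    return Recording(samples=samples, sample_rate=int(rate))


def write_wav(rec: Recording, path) -> None:
    """Write a :class:`Recording` as a 32-bit float mono WAV file."""
    if len(rec) == 0:
        raise EmptyInputError("refusing to write an empty Recording")
    wavfile.write(Path(path), rec.sample_rate, rec.samples.astype(np.float32))


def read_depth_table(path) -> pd.DataFrame:
    """Read a per-blow insertion-depth table.

    The expected CSV schema is a header with columns ``blow_index``
    (1-based, strictly increasing) and ``depth_mm`` (non-negative, the
    caliper reading taken after each hammer blow).

    Returns a DataFrame with exactly those two columns.
    """
    table = pd.read_csv(path)
    missing = {"blow_index", "depth_mm"} - set(table.columns)
    if missing:
        raise SchemaError(f"depth table {path} is missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise EmptyInputError(f"depth table {path} has no rows")
    idx = table["blow_index"].to_numpy()
    if not np.all(np.diff(idx) > 0):
        raise SchemaError(f"blow_index in {path} must be strictly increasing")
    depths = table["depth_mm"].to_numpy(dtype=float)
    if np.any(depths < 0) or not np.all(np.isfinite(depths)):
        raise SchemaError(f"depth_mm in {path} must be finite and non-negative")
    return table[["blow_index", "depth_mm"]].reset_index(drop=True)


def write_depth_table(table: pd.DataFrame, path) -> None:
    """Write a blow-index/depth table to CSV (inverse of :func:`read_depth_table`)."""
    table[["blow_index", "depth_mm"]].to_csv(path, index=False)
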