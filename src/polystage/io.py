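"""Reading and writing polysomnography signals and hypnogram annotations.

The staging pipeline works on a fixed five-channel montage — two referential
EEG derivations (C3/A2, C4/A1), left and right EOG, and one EMG channel —
sampled nominally at 200 Hz, with expert stage labels in 30-s epochs over the
five-stage alphabet W, N1, N2, N3, R.

Signals travel as EDF (European Data Format); hypnograms as one-label-per-line
UTF-8 text or as an EDF+ annotation track (read only).  All amplitudes are
held in microvolts internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

#: Canonical stage order used everywhere (indices 0..4).
STAGES: tuple[str, ...] = ("W", "N1", "N2", "N3", "R")
STAGE_INDEX: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: Canonical channel-role order of the staging montage.
ROLES: tuple[str, ...] = ("EEG_C3A2", "EEG_C4A1", "EOG_L", "EOG_R", "EMG")

#: Default alias table for hypnogram labels found in the wild.  "N4" folds
#: into N3 (the pre-2007 four-NREM convention), "REM"/"R" are synonymous.
DEFAULT_STAGE_ALIASES: dict[str, str] = {
    "W": "W", "WAKE": "W", "N1": "N1", "S1": "N1", "N2": "N2", "S2": "N2",
    "N3": "N3", "S3": "N3", "S4": "N3", "N4": "N3", "R": "R", "REM": "R",
}

EPOCH_S_DEFAULT = 30.0


class MontageError(ValueError):
    """A required staging channel role is missing or duplicated."""


class FormatError(ValueError):
    """A signal or annotation file could not be parsed."""


class AlignmentError(ValueError):
    """Paired signal/label structures disagree in length."""


@dataclass
class Channel:
    name: str
    role: str
    samples: np.ndarray  # µV
    rate: float  # Hz

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.role not in ROLES:
            raise MontageError(f"unknown channel role {self.role!r}")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")


@dataclass
class PSGRecord:
    """Multi-channel PSG signal with per-channel rate and role.

    Channels are kept in the canonical role order
    ``EEG_C3A2, EEG_C4A1, EOG_L, EOG_R, EMG``.
    """

    channels: list[Channel]
    duration_s: float

    def __post_init__(self) -> None:
        roles = [c.role for c in self.channels]
        for role in ROLES:
            if roles.count(role) > 1:
                raise MontageError(f"duplicate channel for role {role}")
        # canonical role order, extras (none expected) dropped at read time
        self.channels.sort(key=lambda c: ROLES.index(c.role))
        for c in self.channels:
            n_expected = int(round(c.rate * self.duration_s))
            if len(c.samples) != n_expected:
                raise ValueError(
                    f"channel {c.name}: {len(c.samples)} samples, expected "
                    f"{n_expected} for {self.duration_s} s at {c.rate} Hz"
                )

    @property
    def roles(self) -> list[str]:
        return [c.role for c in self.channels]

    def channel(self, role: str) -> Channel:
        for c in self.channels:
            if c.role == role:
                return c
        raise MontageError(f"record has no channel with role {role}")

    def n_epochs(self, epoch_s: float = EPOCH_S_DEFAULT) -> int:
        return int(np.floor(self.duration_s / epoch_s))

    def trim_to_epochs(self, epoch_s: float = EPOCH_S_DEFAULT) -> "PSGRecord":
        """Trim (never pad) to a whole number of scoring epochs."""
        n_ep = self.n_epochs(epoch_s)
        if n_ep < 1:
            raise ValueError("record shorter than one epoch")
        dur = n_ep * epoch_s
        chans = [
            Channel(c.name, c.role, c.samples[: int(round(c.rate * dur))], c.rate)
            for c in self.channels
        ]
        return PSGRecord(chans, dur)

    def as_array(self) -> np.ndarray:
        """Stack channels into a (5, n_samples) array; requires a common rate."""
        rates = {c.rate for c in self.channels}
        if len(rates) != 1:
            raise ValueError("channels have differing rates; resample first")
        return np.stack([c.samples for c in self.channels])


@dataclass
class Hypnogram:
    """Sequence of 30-s epoch stage labels."""

    labels: list[str]
    epoch_s: float = EPOCH_S_DEFAULT

    def __post_init__(self) -> None:
        if len(self.labels) == 0:
            raise ValueError("hypnogram must contain at least one epoch")
        if self.epoch_s <= 0:
            raise ValueError("epoch_s must be positive")
        bad = sorted({l for l in self.labels if l not in STAGE_INDEX})
        if bad:
            raise ValueError(f"labels outside the 5-stage alphabet: {bad}")

    def __len__(self) -> int:
        return len(self.labels)

    def indices(self) -> np.ndarray:
        return np.array([STAGE_INDEX[l] for l in self.labels], dtype=np.int64)

    @classmethod
    def from_indices(cls, idx: Sequence[int], epoch_s: float = EPOCH_S_DEFAULT) -> "Hypnogram":
        return cls([STAGES[int(i)] for i in idx], epoch_s)


@dataclass
class RecordMetadata:
    subject_id: str
    ahi: float | None = None
    arousal_count: int | None = None

    def __post_init__(self) -> None:
        if self.ahi is not None and self.ahi < 0:
            raise ValueError("AHI must be non-negative")
        if self.arousal_count is not None and self.arousal_count < 0:
            raise ValueError("arousal count must be non-negative")


# ---------------------------------------------------------------------------
# EDF signal I/O
# ---------------------------------------------------------------------------

def _edf_ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        # shorten numerics rather than truncating digits blindly
        if isinstance(value, float):
            s = f"{value:.{max(0, width - 8)}g}"[:width]
        else:
            s = s[:width]
    return s.ljust(width).encode("ascii")


def write_psg(record: PSGRecord, path: str | Path) -> None:
    """Write a PSGRecord as plain EDF (16-bit, 1-s data records).

    The physical range per channel is chosen from the data (symmetric), so
    quantization error is at most range/2^16 per sample.  Requires integer
    sampling rates and an integer duration in seconds.
    """
    path = Path(path)
    n_sig = len(record.channels)
    dur = record.duration_s
    if abs(dur - round(dur)) > 1e-9:
        raise ValueError("EDF export needs an integer duration in seconds")
    n_records = int(round(dur))
    rates = []
    for c in record.channels:
        if abs(c.rate - round(c.rate)) > 1e-9:
            raise ValueError("EDF export needs integer per-channel rates")
        rates.append(int(round(c.rate)))

    phys = []
    digital = []
    for c in record.channels:
        lim = float(np.max(np.abs(c.samples))) if c.samples.size else 0.0
        lim = max(lim * 1.0001, 1e-3)
        # exact inverse of the EDF affine decode:
        # x = pmin + (d - dmin) * (pmax - pmin) / (dmax - dmin)
        gain = 2 * lim / 65535.0
        d = np.clip(np.round((c.samples + lim) / gain) - 32768, -32768, 32767)
        phys.append(lim)
        digital.append(d.astype("<i2"))

    header = bytearray()
    header += _edf_ascii("0", 8)
    header += _edf_ascii("X X X X", 80)                      # patient id
    header += _edf_ascii("Startdate X X X X", 80)            # recording id
    header += _edf_ascii("01.01.00", 8)
    header += _edf_ascii("00.00.00", 8)
    header += _edf_ascii(256 * (1 + n_sig), 8)
    header += _edf_ascii("", 44)
    header += _edf_ascii(n_records, 8)
    header += _edf_ascii(1, 8)                               # record duration s
    header += _edf_ascii(n_sig, 4)
    for c in record.channels:
        header += _edf_ascii(c.name, 16)
    for _ in record.channels:
        header += _edf_ascii("", 80)                         # transducer
    for _ in record.channels:
        header += _edf_ascii("uV", 8)
    for lim in phys:
        header += _edf_ascii(f"{-lim:.6g}", 8)
    for lim in phys:
        header += _edf_ascii(f"{lim:.6g}", 8)
    for _ in record.channels:
        header += _edf_ascii(-32768, 8)
    for _ in record.channels:
        header += _edf_ascii(32767, 8)
    for _ in record.channels:
        header += _edf_ascii("", 80)                         # prefilter
    for r in rates:
        header += _edf_ascii(r, 8)                           # samples/record
    for _ in record.channels:
        header += _edf_ascii("", 32)

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        for rec in range(n_records):
            for d, r in zip(digital, rates):
                fh.write(d[rec * r : (rec + 1) * r].tobytes())


def read_psg(path: str | Path, montage_map: Mapping[str, str]) -> PSGRecord:
    """Read an EDF file and select/order the five staging channels.

    Parameters
    ----------
    path : EDF file.
    montage_map : file channel name -> role; must cover all five roles
        (``EEG_C3A2, EEG_C4A1, EOG_L, EOG_R, EMG``).

    Returns
    -------
    PSGRecord with channels in canonical role order and amplitudes in µV,
    trimmed to a whole number of 30-s epochs.
    """
    import mne

    path = Path(path)
    for role in ROLES:
        if role not in montage_map.values():
            raise MontageError(f"montage map does not assign role {role}")
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises a mix of OSError/ValueError
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc

    present = set(raw.ch_names)
    name_by_role: dict[str, str] = {}
    for name, role in montage_map.items():
        if name in present:
            if role in name_by_role:
                raise MontageError(f"two channels map to role {role}")
            name_by_role[role] = name
    missing = [r for r in ROLES if r not in name_by_role]
    if missing:
        raise MontageError(f"record lacks channel(s) for role(s): {missing}")

    raw.set_channel_types({name_by_role[r]: "eeg" for r in ROLES}, verbose="error")
    rate = float(raw.info["sfreq"])
    data = raw.get_data(picks=[name_by_role[r] for r in ROLES], units="uV")
    duration = data.shape[1] / rate
    chans = [
        Channel(name_by_role[role], role, data[i], rate)
        for i, role in enumerate(ROLES)
    ]
    return PSGRecord(chans, duration).trim_to_epochs()


# ---------------------------------------------------------------------------
# Hypnogram I/O
# ---------------------------------------------------------------------------

def write_hypnogram(h: Hypnogram, path: str | Path) -> None:
    """One label per line; the epoch length rides in a header comment."""
    path = Path(path)
    lines = [f"# epoch_s={h.epoch_s:g}"]
    lines.extend(h.labels)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_hypnogram(
    path: str | Path,
    aliases: Mapping[str, str] | None = None,
    epoch_s: float = EPOCH_S_DEFAULT,
) -> Hypnogram:
    """Read a hypnogram from text (one label per line) or an EDF+ annotation track.

    Unknown labels without an alias raise :class:`FormatError` with the
    offending line number.
    """
    path = Path(path)
    table = dict(DEFAULT_STAGE_ALIASES)
    if aliases:
        table.update({k.upper(): v for k, v in aliases.items()})

    if path.suffix.lower() == ".edf":
        return _read_hypnogram_edf(path, table)

    labels: list[str] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "epoch_s=" in line:
                epoch_s = float(line.split("epoch_s=")[1])
            continue
        key = line.upper()
        if key not in table:
            raise FormatError(f"{path}:{lineno}: unknown stage label {line!r}")
        labels.append(table[key])
    if not labels:
        raise FormatError(f"{path}: no stage labels found")
    return Hypnogram(labels, epoch_s)


def _read_hypnogram_edf(path: Path, table: Mapping[str, str]) -> Hypnogram:
    import mne

    try:
        ann = mne.read_annotations(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read annotations from {path}: {exc}") from exc
    labels: list[str] = []
    epoch_s = EPOCH_S_DEFAULT
    for i, (desc, dur) in enumerate(zip(ann.description, ann.duration), 1):
        key = str(desc).strip().upper()
        # tolerate "Sleep stage N2"-style descriptions
        key = key.replace("SLEEP STAGE", "").strip()
        if key not in table:
            raise FormatError(f"{path}: annotation {i}: unknown stage {desc!r}")
        n_rep = max(1, int(round(dur / EPOCH_S_DEFAULT))) if dur else 1
        labels.extend([table[key]] * n_rep)
    if not labels:
        raise FormatError(f"{path}: no stage annotations found")
    return Hypnogram(labels, epoch_s)


def check_alignment(record: PSGRecord, hypnogram: Hypnogram) -> int:
    """Return the shared epoch count or raise :class:`AlignmentError`."""
    n_rec = record.n_epochs(hypnogram.epoch_s)
    if n_rec != len(hypnogram):
        raise AlignmentError(
            f"record holds {n_rec} epochs but hypnogram holds {len(hypnogram)}"
        )
    return n_rec
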