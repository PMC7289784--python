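"""Per-epoch, per-channel-group signal-falloff detection.

Electrode shedding and amplifier faults produce epochs whose staging models
emit garbage; the ensemble zeroes those models' weights.  Three transparent
per-epoch statistics cover the failure modes:

* **flatline** — epoch standard deviation below a µV floor (lost contact);
* **saturation** — too many samples pinned at the amplifier rails;
* **hf_noise** — too large a fraction of epoch power above 25 Hz.

Detection runs on the source-rate record, *before* the anti-alias
decimation: the 33 Hz low-pass deliberately destroys the broadband evidence
the hf detector needs, so running it afterwards would blind that detector.
The EMG channel is exempt from the hf detector — physiological EMG is
intrinsically broadband, so its above-25 Hz fraction is high even when clean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import PSGRecord

REASONS = ("flatline", "saturation", "hf_noise")


@dataclass
class NoiseConfig:
    flatline_std_uv: float = 0.5
    saturation_fraction: float = 0.2
    rail_uv: float = 250.0
    rail_tolerance_uv: float = 1.0
    hf_power_ratio: float = 0.5      # power above hf_cutoff / total
    hf_cutoff_hz: float = 25.0
    hf_exempt_roles: tuple[str, ...] = ("EMG",)
    epoch_s: float = 30.0

    def __post_init__(self) -> None:
        if self.flatline_std_uv <= 0 or self.rail_uv <= 0 or self.hf_cutoff_hz <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.saturation_fraction < 1) or not (0 < self.hf_power_ratio < 1):
            raise ValueError("fractions must lie in (0, 1)")


@dataclass
class NoiseMask:
    """epoch × group boolean flags plus the reason for each flag."""

    flags: np.ndarray                 # (n_epochs, n_groups) bool
    reasons: dict[tuple[int, int], str] = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return self.flags.shape[0]

    def to_frame(self):
        """Long-format (epoch, group, reason) table for CSV export."""
        import pandas as pd

        rows = [
            {"epoch": e, "group": g, "reason": r}
            for (e, g), r in sorted(self.reasons.items())
        ]
        return pd.DataFrame(rows, columns=["epoch", "group", "reason"])


def _channel_epoch_flags(
    x: np.ndarray, rate: float, role: str, cfg: NoiseConfig
) -> list[str | None]:
    """Reason per epoch for one channel (None = clean).

    Flags depend only on the epoch's own samples (locality), so adding an
    artifact to one epoch can never unflag another.
    """
    spe = int(round(cfg.epoch_s * rate))
    n_ep = len(x) // spe
    epochs = x[: n_ep * spe].reshape(n_ep, spe)

    out: list[str | None] = [None] * n_ep
    stds = epochs.std(axis=1)
    at_rail = np.mean(np.abs(np.abs(epochs) - cfg.rail_uv) <= cfg.rail_tolerance_uv, axis=1)

    check_hf = role not in cfg.hf_exempt_roles
    if check_hf:
        spec = np.abs(np.fft.rfft(epochs - epochs.mean(axis=1, keepdims=True), axis=1)) ** 2
        freqs = np.fft.rfftfreq(spe, d=1.0 / rate)
        total = spec.sum(axis=1)
        hf = spec[:, freqs >= cfg.hf_cutoff_hz].sum(axis=1)
        hf_ratio = np.divide(hf, total, out=np.zeros(n_ep), where=total > 0)

    for e in range(n_ep):
        if stds[e] < cfg.flatline_std_uv:
            out[e] = "flatline"
        elif at_rail[e] >= cfg.saturation_fraction:
            out[e] = "saturation"
        elif check_hf and hf_ratio[e] >= cfg.hf_power_ratio:
            out[e] = "hf_noise"
    return out


def detect_noise(
    record: PSGRecord,
    groups: list[list[str]] | None = None,
    cfg: NoiseConfig | None = None,
) -> NoiseMask:
    """Flag each (epoch, channel group) where any member channel trips a detector.

    ``groups`` is a list of role lists (default: the five staging groups —
    four singletons plus the all-channel group).  A group is flagged in an
    epoch iff any member channel is flagged there, so one bad channel
    silences exactly the models that consume it.
    """
    from .network import default_groups

    cfg = cfg or NoiseConfig()
    if groups is None:
        groups = default_groups()

    per_channel: dict[str, list[str | None]] = {}
    for c in record.channels:
        per_channel[c.role] = _channel_epoch_flags(c.samples, c.rate, c.role, cfg)

    n_ep = min(len(v) for v in per_channel.values())
    flags = np.zeros((n_ep, len(groups)), dtype=bool)
    reasons: dict[tuple[int, int], str] = {}
    for g, roles in enumerate(groups):
        for role in roles:
            ch = per_channel[role]
            for e in range(n_ep):
                if ch[e] is not None and not flags[e, g]:
                    flags[e, g] = True
                    reasons[(e, g)] = ch[e]
    return NoiseMask(flags=flags, reasons=reasons)
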