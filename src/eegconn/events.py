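"""Interval events: detected or planted spindles, SWDs and artifacts."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

EVENT_KINDS = ("spindle", "swd", "artifact")


@dataclass
class IntervalEvent:
    """A time interval on (or aggregated across) a channel.

    ``properties`` carries per-kind attributes such as ``fundamental_hz``,
    ``amplitude_uv``, ``peak_freq_hz``, ``band_power`` and ``duration_s``.
    """

    kind: str
    channel: int | None
    start_s: float
    end_s: float
    properties: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if not self.end_s > self.start_s:
            raise ValueError(
                f"event end ({self.end_s}) must exceed start ({self.start_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlaps(self, other: "IntervalEvent") -> bool:
        """True when the two intervals share any positive-length time."""
        return self.start_s < other.end_s and other.start_s < self.end_s


def events_to_frame(events: list[IntervalEvent]) -> pd.DataFrame:
    """Tabulate events (one row each) with property columns expanded."""
    rows = []
    for ev in events:
        row = {
            "kind": ev.kind,
            "channel": ev.channel,
            "start_s": ev.start_s,
            "end_s": ev.end_s,
        }
        row.update(ev.properties)
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["kind", "channel", "start_s", "end_s"])
    return pd.DataFrame(rows)


def frame_to_events(frame: pd.DataFrame) -> list[IntervalEvent]:
    core = {"kind", "channel", "start_s", "end_s"}
    out = []
    for _, row in frame.iterrows():
        props = {
            k: row[k] for k in frame.columns if k not in core and pd.notna(row[k])
        }
        chan = None if pd.isna(row["channel"]) else int(row["channel"])
        out.append(
            IntervalEvent(row["kind"], chan, float(row["start_s"]),
                          float(row["end_s"]), props)
        )
    return out


def write_events_csv(events: list[IntervalEvent], path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events_csv(path) -> list[IntervalEvent]:
    return frame_to_events(pd.read_csv(path))
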