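"""Rule-based activity monitoring and alerting.

The decision layer watches the time-ordered stream of per-window activity
predictions and notifies registered contacts (a gynaecologist, a
care-taker) when an activity they proscribed — prolonged standing is the
canonical example — has been sustained continuously for a configurable
duration.  The cellular text-message hardware of a deployed system is
abstracted behind a message-sink interface; this package ships logging,
list and file sinks.

Which activities are proscribed is a clinical judgement that varies by
patient and trimester, so the default policy proscribes nothing: the
rule set belongs in configuration, not code.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence

import yaml

__all__ = [
    "MonitorPolicy",
    "AlertEvent",
    "MessageSink",
    "ListSink",
    "LoggingSink",
    "FileSink",
    "monitor_stream",
    "smooth_predictions",
    "load_policy",
    "save_policy",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MonitorPolicy:
    """What to alert on, and how often.

    proscribed
        Activity labels that should trigger alerts.
    sustain_seconds
        Minimum continuous duration of a proscribed activity before the
        first alert (default 60 s — transient misclassifications and
        brief postures should not page a clinician).
    cooldown_seconds
        Minimum gap before re-alerting for the same continuing episode
        (default 600 s).
    recipients
        Opaque contact identifiers passed through to the sink.
    """

    proscribed: frozenset[str] = frozenset()
    sustain_seconds: float = 60.0
    cooldown_seconds: float = 600.0
    recipients: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "proscribed", frozenset(self.proscribed))
        object.__setattr__(self, "recipients", tuple(self.recipients))
        if self.sustain_seconds <= 0:
            raise ValueError("sustain_seconds must be positive")
        if self.cooldown_seconds < 0:
            raise ValueError("cooldown_seconds must be non-negative")


@dataclass(frozen=True)
class AlertEvent:
    """One emitted alert: which activity, since when, for how long."""

    activity: str
    onset_time: float
    emit_time: float
    sustained_seconds: float
    recipients: tuple[str, ...] = ()

    def message(self) -> str:
        return (
            f"ALERT: activity {self.activity} sustained for "
            f"{self.sustained_seconds:.0f} s (since t={self.onset_time:.0f} s)"
        )


class MessageSink(Protocol):
    """Destination for alert messages (stand-in for a cellular modem)."""

    def send(self, event: AlertEvent) -> None: ...


class ListSink:
    """Collects alerts in memory."""

    def __init__(self) -> None:
        self.events: list[AlertEvent] = []

    def send(self, event: AlertEvent) -> None:
        self.events.append(event)


class LoggingSink:
    """Writes alerts to the module logger."""

    def send(self, event: AlertEvent) -> None:
        logger.warning("%s -> %s", event.message(), ", ".join(event.recipients) or "-")


class FileSink:
    """Appends alerts to a delimited text file."""

    HEADER = "emit_time,activity,onset_time,sustained_seconds,recipients\n"

    def __init__(self, path: str | os.PathLike) -> None:
        self.path = os.fspath(path)
        if not os.path.exists(self.path) or os.path.getsize(self.path) == 0:
            with open(self.path, "w", encoding="utf-8") as fh:
                fh.write(self.HEADER)

    def send(self, event: AlertEvent) -> None:
        with open(self.path, "a", encoding="utf-8") as fh:
            fh.write(
                f"{event.emit_time:.3f},{event.activity},{event.onset_time:.3f},"
                f"{event.sustained_seconds:.3f},{';'.join(event.recipients)}\n"
            )


def _infer_window_seconds(times: Sequence[float]) -> float:
    if len(times) < 2:
        return 1.0
    import numpy as np

    return float(np.median(np.diff(np.asarray(times, dtype=float))))


def monitor_stream(
    predictions: Iterable[tuple[float, str]],
    policy: MonitorPolicy,
    sink: MessageSink | None = None,
    window_seconds: float | None = None,
) -> list[AlertEvent]:
    """Scan a prediction stream and emit alerts per the policy.

    ``predictions`` is a time-ordered sequence of ``(start_time, label)``
    pairs, one per window; each prediction covers ``window_seconds`` of
    wall time (inferred from the median spacing when not given).  An
    alert fires at the first moment a proscribed label has been predicted
    continuously for at least ``policy.sustain_seconds``; the same
    continuing episode re-alerts only after ``policy.cooldown_seconds``.
    An episode ends as soon as a different label appears.

    Returns all emitted events; they are also pushed to ``sink``.
    """
    preds = [(float(t), str(lab)) for t, lab in predictions]
    times = [t for t, _ in preds]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("prediction timestamps must be strictly increasing")
    if window_seconds is None:
        window_seconds = _infer_window_seconds(times)

    events: list[AlertEvent] = []
    run_label: str | None = None
    run_onset = 0.0
    last_emit: float | None = None  # emission time of the episode's last alert

    for t, label in preds:
        if label != run_label:
            run_label = label
            run_onset = t
            last_emit = None
        if label not in policy.proscribed:
            continue
        covered_until = t + window_seconds
        sustained = covered_until - run_onset
        if sustained < policy.sustain_seconds:
            continue
        if last_emit is None:
            emit_time = run_onset + policy.sustain_seconds
        elif covered_until - last_emit >= policy.cooldown_seconds:
            emit_time = covered_until
        else:
            continue
        event = AlertEvent(
            activity=label,
            onset_time=run_onset,
            emit_time=emit_time,
            sustained_seconds=sustained,
            recipients=policy.recipients,
        )
        events.append(event)
        last_emit = emit_time
        if sink is not None:
            sink.send(event)
    return events


def smooth_predictions(
    predictions: Sequence[tuple[float, str]], vote_width: int = 3
) -> list[tuple[float, str]]:
    """Majority-vote smoothing of a prediction stream.

    Each label is replaced by the majority label of the centred block of
    ``vote_width`` predictions (truncated at the edges); ties keep the
    centre label.  Width 1 is the identity.  Damps single-window flicker
    before the sustain rule is applied.
    """
    if vote_width < 1 or vote_width % 2 == 0:
        raise ValueError(f"vote_width must be odd and >= 1, got {vote_width}")
    preds = list(predictions)
    if vote_width == 1:
        return [(float(t), str(lab)) for t, lab in preds]
    half = vote_width // 2
    out: list[tuple[float, str]] = []
    labels = [lab for _, lab in preds]
    for i, (t, centre) in enumerate(preds):
        block = labels[max(0, i - half) : i + half + 1]
        counts: dict[str, int] = {}
        for lab in block:
            counts[lab] = counts.get(lab, 0) + 1
        best = max(counts.values())
        winners = [lab for lab, c in counts.items() if c == best]
        out.append((float(t), centre if centre in winners or len(winners) > 1
                    else winners[0]))
    return out


def load_policy(path: str | os.PathLike) -> MonitorPolicy:
    """Read a policy from a YAML key-value document."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    return MonitorPolicy(
        proscribed=frozenset(doc.get("proscribed", ())),
        sustain_seconds=float(doc.get("sustain_seconds", 60.0)),
        cooldown_seconds=float(doc.get("cooldown_seconds", 600.0)),
        recipients=tuple(doc.get("recipients", ())),
    )


def save_policy(policy: MonitorPolicy, path: str | os.PathLike) -> str:
    """Write a policy as a YAML key-value document; returns the path."""
    doc = {
        "proscribed": sorted(policy.proscribed),
        "sustain_seconds": policy.sustain_seconds,
        "cooldown_seconds": policy.cooldown_seconds,
        "recipients": list(policy.recipients),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return os.fspath(path)
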