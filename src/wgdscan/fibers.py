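"""DNA-combing (molecular combing) fiber analytics.

A fiber carries ordered labeled segments from two sequential analog pulses:
CldU first, then IdU, each of duration ``pulse_minutes`` (default 30 min).
A fork is an adjacent CldU→IdU segment pair.  Measured lengths are in µm on
the combed fiber; the stretch factor (kb/µm, default 2.0 — the standard
constant-stretching value for molecular combing) converts to kb.

Readouts:

* fork speed  = stretch × (len_CldU + len_IdU) / (2 × pulse_minutes), i.e.
  the combined labeled track length over the total labeling time, in kb/min;
* fork asymmetry = len_CldU / len_IdU in pulse order (a stalled or collapsed
  fork slows during the second pulse, pushing the ratio above 1);
* inter-origin distance (IOD) = distance in kb between consecutive origins
  on the same fiber.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._errors import InvalidArgumentError

__all__ = [
    "FiberSegment",
    "FiberTrack",
    "FiberSet",
    "ForkMetrics",
    "fork_speed",
    "asymmetry_ratio",
    "inter_origin_distances",
    "analyze_forks",
    "summarize_forks",
    "DEFAULT_PULSE_MINUTES",
    "DEFAULT_STRETCH_KB_PER_UM",
]

DEFAULT_PULSE_MINUTES = 30.0
DEFAULT_STRETCH_KB_PER_UM = 2.0

CLDU = "CldU"
IDU = "IdU"
UNLABELED = "unlabeled"
_LABELS = {CLDU, IDU, UNLABELED}


@dataclass(frozen=True)
class FiberSegment:
    label: str
    length_um: float

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise InvalidArgumentError(f"unknown segment label {self.label!r}")
        if not self.length_um > 0:
            raise InvalidArgumentError("segment lengths must be > 0")


@dataclass
class FiberTrack:
    """One fiber: an ordered list of labeled segments."""

    fiber_id: str
    segments: list[FiberSegment]

    def forks(self) -> list[tuple[FiberSegment, FiberSegment]]:
        """Adjacent CldU→IdU pairs, in order along the fiber.

        CldU precedes IdU in time, so only that orientation forms a fork;
        an isolated label (e.g. a CldU track whose IdU partner ran off the
        fiber) contributes nothing.
        """
        pairs = []
        for a, b in zip(self.segments, self.segments[1:]):
            if a.label == CLDU and b.label == IDU:
                pairs.append((a, b))
        return pairs


@dataclass
class ForkMetrics:
    fork_id: str
    speed_kb_per_min: float
    asymmetry: float
    cldu_kb: float
    idu_kb: float


@dataclass
class FiberSet:
    """A collection of fiber tracks plus acquisition parameters.

    ``origins`` maps fiber id to sorted origin positions in kb along the
    fiber.  ``ground_truth`` (optional) records simulator parameters for
    recovery tests.
    """

    tracks: list[FiberTrack]
    origins: dict[str, list[float]] = field(default_factory=dict)
    pulse_minutes: float = DEFAULT_PULSE_MINUTES
    stretch_kb_per_um: float = DEFAULT_STRETCH_KB_PER_UM
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        if not self.pulse_minutes > 0:
            raise InvalidArgumentError("pulse_minutes must be > 0")
        if not self.stretch_kb_per_um > 0:
            raise InvalidArgumentError("stretch factor must be > 0")
        for positions in self.origins.values():
            if any(b < a for a, b in zip(positions, positions[1:])):
                raise InvalidArgumentError("origin positions must be sorted per fiber")

    # ---------------------------------------------------------- CSV round trip
    def to_csv(self, path: str | Path) -> None:
        """Write a mixed-record CSV: one row per segment and one per origin."""
        rows = []
        for track in self.tracks:
            for i, seg in enumerate(track.segments):
                rows.append(
                    {
                        "fiber_id": track.fiber_id,
                        "record": "segment",
                        "index": i,
                        "label": seg.label,
                        "length_um": seg.length_um,
                        "position_kb": "",
                    }
                )
        for fiber_id, positions in self.origins.items():
            for i, pos in enumerate(positions):
                rows.append(
                    {
                        "fiber_id": fiber_id,
                        "record": "origin",
                        "index": i,
                        "label": "",
                        "length_um": "",
                        "position_kb": pos,
                    }
                )
        frame = pd.DataFrame(
            rows, columns=["fiber_id", "record", "index", "label", "length_um", "position_kb"]
        )
        header = json.dumps(
            {"pulse_minutes": self.pulse_minutes, "stretch_kb_per_um": self.stretch_kb_per_um}
        )
        with open(path, "w") as fh:
            fh.write(f"# wgdscan-fibers {header}\n")
            frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FiberSet":
        with open(path) as fh:
            first = fh.readline()
            params = {}
            if first.startswith("# wgdscan-fibers"):
                params = json.loads(first.split(" ", 2)[2])
            else:
                fh.seek(0)
            frame = pd.read_csv(fh, keep_default_na=False)
        tracks: dict[str, list[tuple[int, FiberSegment]]] = {}
        origins: dict[str, list[float]] = {}
        for row in frame.itertuples(index=False):
            fiber_id = str(row.fiber_id)
            if row.record == "segment":
                tracks.setdefault(fiber_id, []).append(
                    (int(row.index), FiberSegment(row.label, float(row.length_um)))
                )
            elif row.record == "origin":
                origins.setdefault(fiber_id, []).append(float(row.position_kb))
            else:
                raise InvalidArgumentError(f"unknown record type {row.record!r}")
        track_list = [
            FiberTrack(fid, [seg for _, seg in sorted(items)]) for fid, items in tracks.items()
        ]
        return cls(
            tracks=track_list,
            origins={fid: sorted(v) for fid, v in origins.items()},
            pulse_minutes=float(params.get("pulse_minutes", DEFAULT_PULSE_MINUTES)),
            stretch_kb_per_um=float(params.get("stretch_kb_per_um", DEFAULT_STRETCH_KB_PER_UM)),
        )


def fork_speed(
    cldu: FiberSegment,
    idu: FiberSegment,
    pulse_minutes: float = DEFAULT_PULSE_MINUTES,
    stretch_kb_per_um: float = DEFAULT_STRETCH_KB_PER_UM,
) -> float:
    """Fork speed in kb/min from the combined CldU+IdU track length.

    The combined labeled length is laid down over two pulses, hence the
    division by 2 × pulse_minutes.
    """
    if cldu is None or idu is None:
        raise InvalidArgumentError("fork speed requires both a CldU and an IdU segment")
    total_kb = stretch_kb_per_um * (cldu.length_um + idu.length_um)
    return total_kb / (2.0 * pulse_minutes)


def asymmetry_ratio(cldu: FiberSegment, idu: FiberSegment) -> float:
    """CldU/IdU length ratio in pulse order (first track over second track)."""
    if not (cldu.length_um > 0 and idu.length_um > 0):
        raise InvalidArgumentError("asymmetry requires both track lengths > 0")
    return cldu.length_um / idu.length_um


def max_min_asymmetry(cldu: FiberSegment, idu: FiberSegment) -> float:
    """Orientation-free asymmetry variant: longer track over shorter track."""
    r = asymmetry_ratio(cldu, idu)
    return max(r, 1.0 / r)


def inter_origin_distances(fibers: FiberSet) -> list[float]:
    """Distances (kb) between consecutive origins on the same fiber.

    Fibers with fewer than two origins contribute nothing.
    """
    out: list[float] = []
    for positions in fibers.origins.values():
        if len(positions) >= 2:
            out.extend(float(b - a) for a, b in zip(positions, positions[1:]))
    return out


def analyze_forks(fibers: FiberSet) -> tuple[list[ForkMetrics], list[str]]:
    """Per-fork speed and asymmetry for every CldU→IdU pair in the set.

    Returns the metrics plus a log of fibers skipped for having no complete
    fork (excluded with a reason, never silently dropped).
    """
    metrics: list[ForkMetrics] = []
    skipped: list[str] = []
    for track in fibers.tracks:
        pairs = track.forks()
        if not pairs:
            skipped.append(f"{track.fiber_id}: no adjacent CldU->IdU pair")
            continue
        for j, (cldu, idu) in enumerate(pairs):
            metrics.append(
                ForkMetrics(
                    fork_id=f"{track.fiber_id}/fork{j}",
                    speed_kb_per_min=fork_speed(
                        cldu, idu, fibers.pulse_minutes, fibers.stretch_kb_per_um
                    ),
                    asymmetry=asymmetry_ratio(cldu, idu),
                    cldu_kb=cldu.length_um * fibers.stretch_kb_per_um,
                    idu_kb=idu.length_um * fibers.stretch_kb_per_um,
                )
            )
    return metrics, skipped


def summarize_forks(metrics: list[ForkMetrics]) -> dict:
    """Median/mean speed, median asymmetry and n (midpoint median for even n)."""
    if not metrics:
        raise InvalidArgumentError("cannot summarize an empty fork list")
    speeds = np.array([m.speed_kb_per_min for m in metrics])
    ratios = np.array([m.asymmetry for m in metrics])
    return {
        "n_forks": len(metrics),
        "median_speed_kb_per_min": float(np.median(speeds)),
        "mean_speed_kb_per_min": float(np.mean(speeds)),
        "median_asymmetry": float(np.median(ratios)),
    }
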