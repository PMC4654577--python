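"""Speaking-turn construction from an utterance track.

A speaking turn is a fairly consistent utterance by one person lasting
more than four seconds; short pauses (and brief interjections by
others) inside it do not break it. Turns drive both the status
components (floor seconds, turn counts) and the speaking/listening
normalisation of the physiological measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import intervals as iv

__all__ = [
    "Utterance",
    "UtteranceTrack",
    "Turn",
    "TurnTrack",
    "build_turns",
    "speaking_listening_sets",
    "turn_statistics",
    "read_label_track",
    "write_label_track",
]


@dataclass(frozen=True)
class Utterance:
    speaker_id: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"utterance end must exceed start ({self.speaker_id})")


@dataclass
class UtteranceTrack:
    """Raw diarised utterances over the conversation extent."""

    utterances: List[Utterance]
    extent: Tuple[float, float]
    speakers: Optional[List[str]] = None

    def __post_init__(self) -> None:
        if self.speakers is None:
            self.speakers = sorted({u.speaker_id for u in self.utterances})
        by = {}
        for u in self.utterances:
            by.setdefault(u.speaker_id, []).append((u.start_s, u.end_s))
        for spk, ivs in by.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping utterances for speaker {spk}")


@dataclass(frozen=True)
class Turn:
    speaker_id: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class TurnTrack:
    turns: List[Turn]
    extent: Tuple[float, float]
    speakers: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.speakers:
            self.speakers = sorted({t.speaker_id for t in self.turns})
        self.turns = sorted(self.turns, key=lambda t: (t.start_s, t.speaker_id))

    def for_speaker(self, speaker_id: str) -> List[Tuple[float, float]]:
        return [(t.start_s, t.end_s) for t in self.turns if t.speaker_id == speaker_id]


def build_turns(track: UtteranceTrack, min_turn_s: float = 4.0,
                merge_gap_s: float = 2.0) -> TurnTrack:
    """Merge same-speaker utterances into turns and apply the duration rule.

    Consecutive utterances by one speaker separated by a gap of at most
    ``merge_gap_s`` seconds are merged into a single span (interjections
    by others during the gap do not block merging). Merged spans with
    duration strictly greater than ``min_turn_s`` become turns; shorter
    spans are discarded.
    """
    turns: List[Turn] = []
    for spk in track.speakers:
        ivs = sorted((u.start_s, u.end_s) for u in track.utterances
                     if u.speaker_id == spk)
        merged: List[Tuple[float, float]] = []
        for s, e in ivs:
            if merged and s - merged[-1][1] <= merge_gap_s:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        turns.extend(Turn(spk, s, e) for s, e in merged if e - s > min_turn_s)
    return TurnTrack(turns, track.extent, speakers=list(track.speakers))


def speaking_listening_sets(turns: TurnTrack, subject_id: str):
    """Speaking and listening interval sets for one subject.

    Speaking is the union of the subject's own turns. Listening is the
    union of the other members' turns minus any overlap with the
    subject's own turns (overlap counts as speaking: stress attribution
    follows own vocal effort). Silence — no one holding a turn — is in
    neither set.
    """
    if subject_id not in turns.speakers:
        raise KeyError(f"unknown subject {subject_id!r}; roster: {turns.speakers}")
    own = iv.normalize(turns.for_speaker(subject_id))
    others: List[Tuple[float, float]] = []
    for spk in turns.speakers:
        if spk != subject_id:
            others.extend(turns.for_speaker(spk))
    listen = iv.subtract(iv.normalize(others), own)
    return own, listen


def turn_statistics(turns: TurnTrack,
                    topic_counts: Optional[Dict[str, int]] = None) -> pd.DataFrame:
    """Per-speaker turn count and floor seconds, with a pass-through slot
    for topics introduced (annotated from video, not computed here)."""
    rows = []
    for spk in turns.speakers:
        ivs = turns.for_speaker(spk)
        rows.append(
            {
                "speaker_id": spk,
                "turn_count": len(ivs),
                "floor_seconds": iv.total_length(ivs),
                "topics": (topic_counts or {}).get(spk, 0),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# label-file I/O (Audacity label dialect: start<TAB>end<TAB>speaker)
# ---------------------------------------------------------------------------

def write_label_track(track: UtteranceTrack, path) -> None:
    with open(path, "w") as fh:
        for u in sorted(track.utterances, key=lambda u: u.start_s):
            fh.write(f"{u.start_s:.3f}\t{u.end_s:.3f}\t{u.speaker_id}\n")


def read_label_track(path, extent: Optional[Tuple[float, float]] = None,
                     speakers: Optional[Sequence[str]] = None) -> UtteranceTrack:
    utts: List[Utterance] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected start<TAB>end<TAB>speaker")
            s, e, spk = float(parts[0]), float(parts[1]), parts[2]
            utts.append(Utterance(spk, s, e))
    if extent is None:
        extent = (
            min((u.start_s for u in utts), default=0.0),
            max((u.end_s for u in utts), default=0.0),
        )
    return UtteranceTrack(utts, extent,
                          speakers=list(speakers) if speakers else None)
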