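"""Proteome screening for wholly disordered proteins (WDPs).

A WDP is operationally a protein of at least ``min_length`` residues
(default 50) whose disordered regions cover at least ``min_fraction``
of the chain (default 0.90, i.e. "90–100% disordered"). Both
boundaries are inclusive. Disorder evidence comes from interval tracks
(UniProt-style features) or per-residue score tracks (e.g. exported
pLDDT, where scores below 50 are conventionally read as disorder).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .io import DisorderTrack, ProteinRecord, scores_to_intervals


@dataclass(frozen=True)
class ScreenConfig:
    min_fraction: float = 0.90
    min_length: int = 50
    score_threshold: float = 50.0
    score_direction: Literal["below", "above"] = "below"
    prefer_intervals: bool = True  # when a protein has both track kinds

    def __post_init__(self) -> None:
        if not (0 < self.min_fraction <= 1):
            raise ValueError("min_fraction must be in (0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass(frozen=True)
class ScreenResult:
    protein_id: str
    length: int
    disordered_residues: int
    disorder_fraction: float
    passes: bool
    reason: Literal["ok", "too_short", "below_fraction", "no_track"]


def union_size(intervals: Sequence[tuple[int, int]]) -> int:
    """Number of residues covered by the union of 1-based inclusive intervals."""
    covered = 0
    last_end = 0
    for start, end in sorted(intervals):
        start = max(start, last_end + 1)
        if end >= start:
            covered += end - start + 1
            last_end = end
        else:
            last_end = max(last_end, end)
    return covered


def disorder_fraction(track: DisorderTrack, length: int) -> tuple[int, float]:
    """(covered residue count, covered fraction) for one interval track.

    Overlapping intervals are not double-counted; intervals are assumed
    clamped to [1, length] at load.
    """
    if length <= 0:
        raise ValueError("protein length must be positive")
    if track.intervals is None:
        raise ValueError(f"{track.protein_id}: track has no intervals")
    count = union_size([(s, min(e, length)) for s, e in track.intervals
                        if s <= length])
    return count, count / length


def is_wdp(record: ProteinRecord, track: DisorderTrack | None,
           config: ScreenConfig = ScreenConfig()) -> ScreenResult:
    """Screen one protein against the WDP definition."""
    length = len(record)
    if track is None:
        return ScreenResult(record.id, length, 0, 0.0, False, "no_track")
    if track.scores is not None:
        track = scores_to_intervals(track, config.score_threshold,
                                    config.score_direction)
    count, fraction = disorder_fraction(track, length)
    if length < config.min_length:
        return ScreenResult(record.id, length, count, fraction, False, "too_short")
    if fraction < config.min_fraction:
        return ScreenResult(record.id, length, count, fraction, False,
                            "below_fraction")
    return ScreenResult(record.id, length, count, fraction, True, "ok")


def screen_proteome(records: Sequence[ProteinRecord],
                    tracks: Iterable[DisorderTrack],
                    config: ScreenConfig = ScreenConfig()
                    ) -> tuple[list[ScreenResult], list[ProteinRecord]]:
    """Screen every record; returns (results in input order, passing records).

    When a protein has both an interval track and a score track, the
    config's ``prefer_intervals`` picks which one is used.
    """
    by_protein: dict[str, dict[str, DisorderTrack]] = {}
    for track in tracks:
        by_protein.setdefault(track.protein_id, {})[track.kind] = track

    results: list[ScreenResult] = []
    passing: list[ProteinRecord] = []
    for rec in records:
        available = by_protein.get(rec.id, {})
        order = (("intervals", "scores") if config.prefer_intervals
                 else ("scores", "intervals"))
        track = next((available[k] for k in order if k in available), None)
        result = is_wdp(rec, track, config)
        results.append(result)
        if result.passes:
            passing.append(rec)
    return results, passing


def results_table(results: Sequence[ScreenResult]) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [r.protein_id for r in results],
            "length": [r.length for r in results],
            "disordered_residues": [r.disordered_residues for r in results],
            "disorder_fraction": [r.disorder_fraction for r in results],
            "passes": [r.passes for r in results],
            "reason": [r.reason for r in results],
        }
    )
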