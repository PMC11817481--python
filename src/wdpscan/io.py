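"""Reading and writing the formats the pipeline touches.

Sequences travel as :class:`ProteinRecord`; disorder evidence as
:class:`DisorderTrack`, which carries either 1-based inclusive residue
intervals (the UniProt feature convention) or one real-valued score per
residue (e.g. an exported AlphaFold pLDDT or MobiDB consensus track).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .constants import CANONICAL_AA

#: Residues tolerated in lenient mode on top of the 20 canonical ones.
AMBIGUOUS_AA = "XBZUJO"

TrackSource = Literal["annotation", "plddt", "consensus"]


class FastaError(ValueError):
    """Raised on malformed or contract-violating FASTA input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its accession and free-text description."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DisorderTrack:
    """Per-protein disorder evidence: intervals or per-residue scores.

    ``intervals`` are 1-based inclusive ``(start, end)`` residue
    coordinates. ``scores`` is one value per residue, in residue order.
    Exactly one of the two is populated.
    """

    protein_id: str
    intervals: list[tuple[int, int]] | None = None
    scores: list[float] | None = None
    source: TrackSource = "annotation"

    def __post_init__(self) -> None:
        if (self.intervals is None) == (self.scores is None):
            raise ValueError("track must carry intervals or scores, not both")
        if self.intervals is not None:
            for start, end in self.intervals:
                if not (1 <= start <= end):
                    raise ValueError(
                        f"{self.protein_id}: bad interval ({start}, {end}); "
                        "need 1 <= start <= end"
                    )

    @property
    def kind(self) -> str:
        return "intervals" if self.intervals is not None else "scores"


def _validate_sequence(seq: str, rec_id: str, strict: bool) -> str:
    seq = seq.upper()
    allowed = set(CANONICAL_AA) | (set() if strict else set(AMBIGUOUS_AA))
    bad = sorted(set(seq) - allowed)
    if bad:
        if strict:
            raise FastaError(
                f"record {rec_id!r}: non-canonical residue(s) {''.join(bad)} "
                "(use lenient mode to keep them)"
            )
        warnings.warn(f"record {rec_id!r}: unusual residue(s) {''.join(bad)} kept")
    elif not strict and set(seq) & set(AMBIGUOUS_AA):
        warnings.warn(
            f"record {rec_id!r}: ambiguous residue(s) "
            f"{''.join(sorted(set(seq) & set(AMBIGUOUS_AA)))} kept"
        )
    return seq


def read_fasta(path: str | Path, strict: bool = True) -> list[ProteinRecord]:
    """Read a multi-record FASTA into :class:`ProteinRecord` objects.

    Record order is preserved and sequences are upper-cased. Duplicate
    ids and (in strict mode) non-amino-acid characters are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _validate_sequence(str(rec.seq), rec.id, strict)
        if not seq:
            raise FastaError(f"record {rec.id!r} in {path} has an empty sequence")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(id=rec.id, sequence=seq, description=desc))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records as FASTA, preserving order; 60-column wrapping."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def dedup_exact(records: Sequence[ProteinRecord]) -> tuple[list[ProteinRecord], list[str]]:
    """Drop records whose sequence is byte-identical to an earlier one.

    The first occurrence (input order) is kept; the relative order of
    kept records is unchanged. Returns ``(kept, removed_ids)``.
    """
    seen: dict[str, str] = {}
    kept: list[ProteinRecord] = []
    removed: list[str] = []
    for rec in records:
        if rec.sequence in seen:
            removed.append(rec.id)
        else:
            seen[rec.sequence] = rec.id
            kept.append(rec)
    return kept, removed


def read_disorder(path: str | Path, kind: Literal["intervals", "scores"],
                  proteome: Sequence[ProteinRecord] | None = None,
                  source: TrackSource = "annotation") -> list[DisorderTrack]:
    """Read disorder tracks from a headered TSV.

    ``intervals`` files carry columns ``protein_id, start, end`` with
    1-based inclusive coordinates; one row per disordered region.
    ``scores`` files carry ``protein_id, score`` rows in residue order
    (or ``protein_id, position, score``; the position column is checked
    for contiguity and otherwise ignored).

    When ``proteome`` is given, intervals extending beyond the protein
    are clamped to its length with a warning, and a score track whose
    length disagrees with the protein length is an error. Tracks for
    ids absent from the proteome are kept with a warning.
    """
    path = Path(path)
    lengths = {r.id: len(r) for r in proteome} if proteome is not None else None

    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(f"{path}: empty file")
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]

    tracks: list[DisorderTrack] = []
    if kind == "intervals":
        per_protein: dict[str, list[tuple[int, int]]] = {}
        order: list[str] = []
        for row in rows:
            pid, start, end = row[0], int(row[1]), int(row[2])
            if start > end:
                raise ValueError(f"{path}: interval start {start} > end {end} for {pid}")
            if start < 1:
                raise ValueError(f"{path}: interval start {start} < 1 for {pid}")
            if lengths is not None:
                if pid not in lengths:
                    warnings.warn(f"{path}: track for unknown protein {pid!r} retained")
                elif end > lengths[pid]:
                    warnings.warn(
                        f"{path}: interval ({start}, {end}) on {pid} clamped to "
                        f"({start}, {lengths[pid]})"
                    )
                    end = lengths[pid]
                    if start > end:
                        continue
            per_protein.setdefault(pid, []).append((start, end))
            if pid not in order:
                order.append(pid)
        tracks = [DisorderTrack(pid, intervals=per_protein[pid], source=source)
                  for pid in order]
    elif kind == "scores":
        per_scores: dict[str, list[float]] = {}
        order = []
        for row in rows:
            pid = row[0]
            score = float(row[-1])  # 2- or 3-column dialect
            if len(row) >= 3:
                pos = int(row[1])
                expected = len(per_scores.get(pid, [])) + 1
                if pos != expected:
                    raise ValueError(
                        f"{path}: scores for {pid} not contiguous at position {pos}"
                    )
            per_scores.setdefault(pid, []).append(score)
            if pid not in order:
                order.append(pid)
        for pid in order:
            if lengths is not None:
                if pid not in lengths:
                    warnings.warn(f"{path}: track for unknown protein {pid!r} retained")
                elif len(per_scores[pid]) != lengths[pid]:
                    raise ValueError(
                        f"{path}: {len(per_scores[pid])} scores for {pid} but the "
                        f"protein has {lengths[pid]} residues"
                    )
            tracks.append(DisorderTrack(pid, scores=per_scores[pid], source=source))
    else:
        raise ValueError(f"unknown track kind {kind!r}")
    return tracks


def scores_to_intervals(track: DisorderTrack, threshold: float,
                        direction: Literal["below", "above"] = "below") -> DisorderTrack:
    """Convert a score track to intervals by thresholding.

    Maximal runs of residues with score < threshold (``below``, the
    pLDDT convention: low confidence reads as disorder) or score >=
    threshold (``above``) become 1-based inclusive intervals.
    """
    if track.scores is None:
        raise ValueError("track does not carry scores")
    if direction == "below":
        mask = [s < threshold for s in track.scores]
    elif direction == "above":
        mask = [s >= threshold for s in track.scores]
    else:
        raise ValueError(f"unknown direction {direction!r}")

    intervals: list[tuple[int, int]] = []
    start = None
    for i, hit in enumerate(mask, start=1):
        if hit and start is None:
            start = i
        elif not hit and start is not None:
            intervals.append((start, i - 1))
            start = None
    if start is not None:
        intervals.append((start, len(mask)))
    return DisorderTrack(track.protein_id, intervals=intervals, source=track.source)


def write_intervals(tracks: Iterable[DisorderTrack], path: str | Path) -> None:
    """Write interval tracks as a headered TSV (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("protein_id\tstart\tend\n")
        for track in tracks:
            if track.intervals is None:
                raise ValueError(f"{track.protein_id}: track has no intervals")
            for start, end in track.intervals:
                fh.write(f"{track.protein_id}\t{start}\t{end}\n")
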