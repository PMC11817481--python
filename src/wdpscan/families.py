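"""Homology family grouping from a pairwise hit table.

Hits come in the standard 12-column BLAST tabular layout (outfmt 6):
qseqid sseqid pident length mismatch gapopen qstart qend sstart send
evalue bitscore. Hits passing the E-value cutoff (default 1e-4) and
the per-query hit cap (default 20, by descending bitscore) become
undirected edges; families are the connected components of that graph
(single linkage). Proteins with no qualifying hit are singleton
families. The family label is the lexicographically smallest member
accession, so output is deterministic and diff-friendly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

BLAST6_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch",
                  "gapopen", "qstart", "qend", "sstart", "send",
                  "evalue", "bitscore")


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    bitscore: float
    extras: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")


@dataclass(frozen=True)
class FamilyConfig:
    max_evalue: float = 1e-4
    max_hits_per_query: int = 20
    include_self_hits: bool = False
    min_identity: float | None = None   # optional extra edge filter, %
    min_coverage: float | None = None   # optional, alignment_length / query not tracked here

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be > 0")


@dataclass
class FamilyAssignment:
    """protein_id → family_id; family_id is the smallest member id."""

    assignments: dict[str, str]

    def families(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pid, fid in self.assignments.items():
            out.setdefault(fid, []).append(pid)
        return {fid: sorted(members) for fid, members in sorted(out.items())}

    @property
    def n_families(self) -> int:
        return len(set(self.assignments.values()))


def read_hit_table(path: str | Path, strict: bool = True) -> list[HitRecord]:
    """Parse a 12-column BLAST tabular file; extra columns kept opaquely."""
    path = Path(path)
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                msg = (f"{path}:{lineno}: expected >= 12 tab-separated columns, "
                       f"got {len(fields)}")
                if strict:
                    raise ValueError(msg)
                warnings.warn(msg + " (row skipped)")
                continue
            hits.append(HitRecord(
                query_id=fields[0],
                subject_id=fields[1],
                percent_identity=float(fields[2]),
                evalue=float(fields[10]),
                bitscore=float(fields[11]),
                extras=tuple(fields[3:10]) + tuple(fields[12:]),
            ))
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            extras = h.extras or ("0",) * 7
            mid = "\t".join(extras[:7])
            tail = "\t".join(extras[7:])
            row = (f"{h.query_id}\t{h.subject_id}\t{h.percent_identity}\t{mid}"
                   f"\t{h.evalue:g}\t{h.bitscore:g}")
            fh.write(row + ("\t" + tail if tail else "") + "\n")


def filter_hits(hits: Sequence[HitRecord],
                config: FamilyConfig = FamilyConfig()) -> list[HitRecord]:
    """E-value cutoff, optional identity filter, per-query top-k by bitscore.

    Selection is independent of input order: per query, hits sort by
    (descending bitscore, ascending evalue, subject id) before the cap.
    """
    kept = [h for h in hits if h.evalue <= config.max_evalue]
    if config.min_identity is not None:
        kept = [h for h in kept if h.percent_identity >= config.min_identity]
    if not config.include_self_hits:
        kept = [h for h in kept if h.query_id != h.subject_id]
    by_query: dict[str, list[HitRecord]] = {}
    for h in kept:
        by_query.setdefault(h.query_id, []).append(h)
    out: list[HitRecord] = []
    for qid in sorted(by_query):
        ranked = sorted(by_query[qid],
                        key=lambda h: (-h.bitscore, h.evalue, h.subject_id))
        out.extend(ranked[: config.max_hits_per_query])
    return out


def cluster_families(protein_ids: Sequence[str], hits: Sequence[HitRecord],
                     config: FamilyConfig = FamilyConfig()) -> FamilyAssignment:
    """Single-linkage families = connected components of the filtered graph.

    Hits naming a protein outside ``protein_ids`` raise a warning and
    contribute no edge. Asymmetric hits still connect (edges are
    undirected).
    """
    known = set(protein_ids)
    graph = nx.Graph()
    graph.add_nodes_from(protein_ids)
    for h in filter_hits(hits, config):
        if h.query_id not in known or h.subject_id not in known:
            missing = {h.query_id, h.subject_id} - known
            warnings.warn(
                f"hit {h.query_id}->{h.subject_id} references unknown "
                f"protein(s) {sorted(missing)}; edge ignored"
            )
            continue
        if h.query_id != h.subject_id:
            graph.add_edge(h.query_id, h.subject_id)
    assignments = {}
    for component in nx.connected_components(graph):
        label = min(component)
        for pid in component:
            assignments[pid] = label
    return FamilyAssignment(assignments)


def families_table(assignment: FamilyAssignment) -> "pandas.DataFrame":  # noqa: F821
    import pandas as pd

    rows = sorted(assignment.assignments.items())
    return pd.DataFrame({"id": [pid for pid, _ in rows],
                         "family_id": [fid for _, fid in rows]})
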