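"""Synthetic proteomes with known ground truth.

The generator emulates the statistical structure of a real screen
without any download: a minority class of "WDP-like" sequences —
hydrophilic, charge-enriched, 99–442 residues, with disorder tracks
covering at least 90% of the chain — mixed into a background of
ordinary sequences (100–600 residues, low charge, mostly sub-60%
disorder coverage), plus a BLAST-style hit table with planted family
structure. Every draw flows through one explicit NumPy generator
seeded from a single integer, so a spec is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .families import HitRecord, write_hit_table
from .io import DisorderTrack, ProteinRecord, write_fasta, write_intervals

NON_CHARGED_AA = "ACFGHILMNPQSTVWY"  # the 16 residues outside {K,R,D,E}
POLAR_POOL = "SGNQTP"  # hydrophilic, disorder-promoting pool


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic proteome.

    Lengths are drawn uniformly per class; charge fractions per
    protein are drawn uniformly from the class ranges. ``wdp_fraction``
    of the proteins get >= 90% disorder coverage, the rest get 0–60%.
    ``n_families`` families of ``family_size`` are planted among the
    WDP-class proteins; everything else is a singleton.
    """

    n_proteins: int = 100
    wdp_fraction: float = 0.10
    seed: int = 0

    wdp_length: tuple[int, int] = (99, 442)
    background_length: tuple[int, int] = (100, 600)

    wdp_f_plus: tuple[float, float] = (0.02, 0.28)
    wdp_f_minus: tuple[float, float] = (0.02, 0.28)
    background_f_plus: tuple[float, float] = (0.02, 0.10)
    background_f_minus: tuple[float, float] = (0.02, 0.10)

    wdp_hydrophilic_bias: float = 0.8
    background_hydrophilic_bias: float = 0.15

    wdp_coverage: tuple[float, float] = (0.90, 1.0)
    background_coverage: tuple[float, float] = (0.0, 0.60)

    n_families: int = 0
    family_size: int = 4

    def __post_init__(self) -> None:
        if not (0 <= self.wdp_fraction <= 1):
            raise ValueError("wdp_fraction must be in [0, 1]")
        for lo, hi in (self.wdp_f_plus, self.wdp_f_minus,
                       self.background_f_plus, self.background_f_minus):
            if lo < 0 or hi > 1:
                raise ValueError("charge fraction ranges must lie in [0, 1]")
        if self.wdp_f_plus[1] + self.wdp_f_minus[1] > 1:
            raise ValueError("requested charge fractions infeasible (f+ + f- > 1)")


@dataclass
class ProteomeFixture:
    """In-memory synthetic proteome plus its ground truth."""

    records: list[ProteinRecord]
    tracks: list[DisorderTrack]
    hits: list[HitRecord]
    truth: pd.DataFrame
    spec: SyntheticSpec

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit FASTA + intervals TSV + hits TSV + truth TSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "proteome.fasta",
            "intervals": outdir / "disorder.tsv",
            "hits": outdir / "hits.tsv",
            "truth": outdir / "truth.tsv",
        }
        write_fasta(self.records, paths["fasta"])
        write_intervals(self.tracks, paths["intervals"])
        write_hit_table(self.hits, paths["hits"])
        with open(paths["truth"], "w") as fh:
            fh.write(f"# seed={self.spec.seed} n_proteins={self.spec.n_proteins} "
                     f"wdp_fraction={self.spec.wdp_fraction}\n")
            fh.write(f"# polar_pool={POLAR_POOL} (uniform weights), "
                     f"wdp_bias={self.spec.wdp_hydrophilic_bias}, "
                     f"background_bias={self.spec.background_hydrophilic_bias}\n")
            self.truth.to_csv(fh, sep="\t", index=False)
        return paths


def gen_sequence(length: int, f_plus: float, f_minus: float,
                 hydropathy_bias: float, rng: np.random.Generator) -> str:
    """One sequence with exact charge composition.

    Exactly ``round(length * f_plus)`` residues come from {K, R} (split
    evenly) and ``round(length * f_minus)`` from {D, E}; the remainder
    is drawn from the non-charged pool, interpolated between uniform
    (bias 0) and the polar disorder-promoting pool (bias 1). Residue
    positions are shuffled by ``rng``.
    """
    n_plus = int(round(length * f_plus))
    n_minus = int(round(length * f_minus))
    if n_plus + n_minus > length:
        raise ValueError(
            f"infeasible composition: {n_plus} + {n_minus} charged residues "
            f"for length {length}"
        )
    if not (0 <= hydropathy_bias <= 1):
        raise ValueError("hydropathy_bias must be in [0, 1]")

    residues = (["K"] * (n_plus // 2) + ["R"] * (n_plus - n_plus // 2)
                + ["D"] * (n_minus // 2) + ["E"] * (n_minus - n_minus // 2))

    pool = list(NON_CHARGED_AA)
    weights = np.full(len(pool), (1.0 - hydropathy_bias) / len(pool))
    polar_idx = [pool.index(aa) for aa in POLAR_POOL]
    weights[polar_idx] += hydropathy_bias / len(POLAR_POOL)
    weights /= weights.sum()

    n_rest = length - n_plus - n_minus
    residues.extend(rng.choice(pool, size=n_rest, p=weights).tolist())
    arr = np.array(residues)
    rng.shuffle(arr)
    return "".join(arr)


def _gen_track(pid: str, length: int, coverage: float, guarantee_min: float | None,
               rng: np.random.Generator) -> tuple[DisorderTrack, float]:
    """One contiguous disorder interval realizing ``coverage`` of the chain.

    With ``guarantee_min`` set, the covered residue count rounds up so
    the realized fraction never drops below the drawn coverage.
    """
    if guarantee_min is not None:
        k = int(np.ceil(coverage * length))
    else:
        k = int(round(coverage * length))
    k = min(k, length)
    if k == 0:
        return DisorderTrack(pid, intervals=[], source="consensus"), 0.0
    offset = int(rng.integers(0, length - k + 1))
    track = DisorderTrack(pid, intervals=[(offset + 1, offset + k)],
                          source="consensus")
    return track, k / length


def gen_proteome_fixture(spec: SyntheticSpec) -> ProteomeFixture:
    """Generate the full fixture: records, tracks, hits, truth table."""
    rng = np.random.default_rng(spec.seed)
    n_wdp = int(round(spec.n_proteins * spec.wdp_fraction))
    if spec.n_families * spec.family_size > max(n_wdp, 0) and spec.n_families:
        raise ValueError(
            f"cannot plant {spec.n_families} families of {spec.family_size} "
            f"among {n_wdp} WDP-class proteins"
        )

    width = len(str(spec.n_proteins))
    records: list[ProteinRecord] = []
    tracks: list[DisorderTrack] = []
    rows = []
    for i in range(spec.n_proteins):
        is_wdp_class = i < n_wdp
        pid = f"SYN{i + 1:0{width}d}"
        if is_wdp_class:
            lo, hi = spec.wdp_length
            fp = rng.uniform(*spec.wdp_f_plus)
            fm = rng.uniform(*spec.wdp_f_minus)
            bias = spec.wdp_hydrophilic_bias
            cov = rng.uniform(*spec.wdp_coverage)
            guarantee = spec.wdp_coverage[0]
        else:
            lo, hi = spec.background_length
            fp = rng.uniform(*spec.background_f_plus)
            fm = rng.uniform(*spec.background_f_minus)
            bias = spec.background_hydrophilic_bias
            cov = rng.uniform(*spec.background_coverage)
            guarantee = None
        length = int(rng.integers(lo, hi + 1))
        seq = gen_sequence(length, fp, fm, bias, rng)
        track, realized = _gen_track(pid, length, cov, guarantee, rng)
        records.append(ProteinRecord(
            pid, seq, description="wdp-like" if is_wdp_class else "background"))
        if track.intervals:
            tracks.append(track)
        rows.append({
            "protein_id": pid,
            "class": "wdp" if is_wdp_class else "background",
            "length": length,
            "f_plus": round(fp, 4),
            "f_minus": round(fm, 4),
            "disorder_fraction": round(realized, 6),
            "family_id": pid,  # overwritten below for planted families
        })
    truth = pd.DataFrame(rows)

    # Plant families among the WDP-class proteins.
    family_of: dict[str, str] = {}
    for fam in range(spec.n_families):
        members = [records[fam * spec.family_size + j].id
                   for j in range(spec.family_size)]
        label = min(members)
        for pid in members:
            family_of[pid] = label
    truth["family_id"] = [family_of.get(pid, pid) for pid in truth["protein_id"]]

    hits = gen_hit_table(truth, rng)
    return ProteomeFixture(records=records, tracks=tracks, hits=hits,
                           truth=truth, spec=spec)


def gen_hit_table(truth: pd.DataFrame, rng: np.random.Generator,
                  noise: int = 0) -> list[HitRecord]:
    """Hit table realizing the truth table's family structure.

    Within-family ordered pairs get strongly passing E-values
    (<= 1e-10); ``noise`` adds that many cross-family hits with
    E-values >= 1e-2, which must not survive the 1e-4 cutoff.
    """
    hits: list[HitRecord] = []
    fam_members: dict[str, list[str]] = {}
    for pid, fid in zip(truth["protein_id"], truth["family_id"]):
        fam_members.setdefault(fid, []).append(pid)

    def _mk(q: str, s: str, evalue: float) -> HitRecord:
        return HitRecord(
            query_id=q, subject_id=s,
            percent_identity=float(np.round(rng.uniform(60, 99), 1)),
            evalue=evalue,
            bitscore=float(np.round(rng.uniform(80, 500), 1)),
            extras=("100", "5", "1", "1", "100", "1", "100"),
        )

    for members in fam_members.values():
        if len(members) < 2:
            continue
        for q in members:
            for s in members:
                if q != s:
                    hits.append(_mk(q, s, 10.0 ** -rng.uniform(10, 50)))

    all_ids = list(truth["protein_id"])
    fam_of = dict(zip(truth["protein_id"], truth["family_id"]))
    added = 0
    while added < noise and len(all_ids) >= 2:
        q, s = rng.choice(all_ids, size=2, replace=False)
        if fam_of[q] == fam_of[s]:
            continue
        hits.append(_mk(str(q), str(s), 10.0 ** -rng.uniform(0, 2)))
        added += 1
    return hits
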