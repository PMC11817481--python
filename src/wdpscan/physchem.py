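"""Sequence-derived physicochemical indices.

Four indices classically used to contrast disordered with structured
proteins:

* GRAVY — grand average of hydropathicity, the mean Kyte–Doolittle
  value over the chain; negative means hydrophilic.
* Instability index (II) — Guruprasad's dipeptide-weight statistic,
  ``II = (10/N) * sum_i DIWV(res_i, res_{i+1})``; II > 40 classes the
  protein as unstable in vivo.
* Aliphatic index (AI) — ``X(Ala) + 2.9*X(Val) + 3.9*(X(Ile)+X(Leu))``
  with X in mole percent; a proxy for thermostability.
* Theoretical isoelectric point (pI) — the pH at which the
  Henderson–Hasselbalch net charge over D, E, C, Y, H, K, R side
  chains plus both termini vanishes, found by bisection.

Non-canonical residues (lenient-mode input) contribute zero to the
hydropathy and aliphatic sums, the default DIWV weight, and no
ionizable group; they still count toward N.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import constants as C
from .io import ProteinRecord

INSTABILITY_THRESHOLD = 40.0  # II above this ⇒ predicted unstable in vivo


@dataclass(frozen=True)
class PhyschemProfile:
    """The four indices for one protein, plus the II stability call."""

    protein_id: str
    length: int
    pi: float
    gravy: float
    ii: float
    ai: float

    @property
    def stability_class(self) -> str:
        return "unstable" if self.ii > INSTABILITY_THRESHOLD else "stable"


def gravy(sequence: str) -> float:
    """Mean Kyte–Doolittle hydropathy; unknown residues contribute 0."""
    if not sequence:
        raise ValueError("empty sequence")
    return sum(C.KYTE_DOOLITTLE.get(aa, 0.0) for aa in sequence) / len(sequence)


def instability_index(sequence: str) -> float:
    """Guruprasad instability index from dipeptide weights."""
    if len(sequence) < 2:
        raise ValueError("instability index needs at least 2 residues")
    total = sum(C.diwv(sequence[i], sequence[i + 1])
                for i in range(len(sequence) - 1))
    return 10.0 / len(sequence) * total


def aliphatic_index(sequence: str) -> float:
    """Ikai aliphatic index from Ala/Val/Ile/Leu mole percents."""
    if not sequence:
        raise ValueError("empty sequence")
    n = len(sequence)
    x_ala = 100.0 * sequence.count("A") / n
    x_val = 100.0 * sequence.count("V") / n
    x_il = 100.0 * (sequence.count("I") + sequence.count("L")) / n
    return x_ala + C.AI_COEFF_VAL * x_val + C.AI_COEFF_ILE_LEU * x_il


def net_charge(sequence: str, ph: float) -> float:
    """Henderson–Hasselbalch net charge of the chain at the given pH.

    Positive groups (N-terminus, K, R, H) contribute
    ``1 / (1 + 10**(ph - pKa))``; negative groups (C-terminus, D, E,
    C, Y) contribute ``-1 / (1 + 10**(pKa - ph))``. Terminal pKas are
    residue-specific where the Bjellqvist set lists them.
    """
    if not sequence:
        raise ValueError("empty sequence")
    pos = 0.0
    neg = 0.0

    nterm_pka = C.PKA_NTERM_BY_RESIDUE.get(sequence[0], C.PKA_POSITIVE["Nterm"])
    pos += 1.0 / (1.0 + 10.0 ** (ph - nterm_pka))
    cterm_pka = C.PKA_CTERM_BY_RESIDUE.get(sequence[-1], C.PKA_NEGATIVE["Cterm"])
    neg += 1.0 / (1.0 + 10.0 ** (cterm_pka - ph))

    for aa, pka in C.PKA_POSITIVE.items():
        if aa == "Nterm":
            continue
        count = sequence.count(aa)
        if count:
            pos += count / (1.0 + 10.0 ** (ph - pka))
    for aa, pka in C.PKA_NEGATIVE.items():
        if aa == "Cterm":
            continue
        count = sequence.count(aa)
        if count:
            neg += count / (1.0 + 10.0 ** (pka - ph))
    return pos - neg


def isoelectric_point(sequence: str, tol: float = 1e-4) -> float:
    """pH of zero net charge, by bisection on [0, 14].

    The net charge is strictly decreasing in pH and changes sign on the
    interval, so the root exists and is unique; bisection runs until
    ``|net_charge| < tol``.
    """
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(sequence, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def physchem_profile(record: ProteinRecord) -> PhyschemProfile:
    """All four indices for one record; equals the standalone functions."""
    seq = record.sequence
    return PhyschemProfile(
        protein_id=record.id,
        length=len(seq),
        pi=isoelectric_point(seq),
        gravy=gravy(seq),
        ii=instability_index(seq),
        ai=aliphatic_index(seq),
    )


def profile_table(records) -> "pandas.DataFrame":  # noqa: F821
    """Profiles for a collection of records as a tidy DataFrame."""
    import pandas as pd

    profiles = [physchem_profile(r) for r in records]
    return pd.DataFrame(
        {
            "id": [p.protein_id for p in profiles],
            "length": [p.length for p in profiles],
            "pi": [p.pi for p in profiles],
            "gravy": [p.gravy for p in profiles],
            "ii": [p.ii for p in profiles],
            "ai": [p.ai for p in profiles],
            "stability_class": [p.stability_class for p in profiles],
        }
    )
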