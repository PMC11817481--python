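"""Charge fractions and the diagram-of-states classification.

For a sequence of N residues with N+ lysines/arginines and N− aspartates/
glutamates (histidine is not counted as charged):

    f+ = N+/N    f− = N−/N    FCR = f+ + f−    NCPR = |f+ − f−|

The (FCR, NCPR) pair places each protein in one of the Das–Pappu
diagram-of-states regions:

    R1: FCR < 0.25                     — weak polyampholytes/polyelectrolytes
                                         (globule or tadpole conformations)
    R2: 0.25 ≤ FCR ≤ 0.35              — boundary ("Janus") sequences
    R3: FCR > 0.35 and NCPR ≤ 0.35     — strong polyampholytes (coil/hairpin)
    R4/R5: FCR > 0.35 and NCPR > 0.35  — strong polyelectrolytes, split by
                                         the sign of the net charge

Because NCPR ≤ FCR always holds, the R1 and R2 membership depends on
FCR alone; the NCPR clauses sometimes quoted for them (NCPR < 0.25,
NCPR ≤ 0.35) are vacuous and kept only in this comment.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Literal

from .io import ProteinRecord

POSITIVE_AA = frozenset("KR")
NEGATIVE_AA = frozenset("DE")

R4SignConvention = Literal["negative_is_R4", "positive_is_R4"]


@dataclass(frozen=True)
class RegionScheme:
    """Boundary thresholds of the diagram of states.

    Defaults reproduce the standard scheme above. ``r4_sign_convention``
    picks which net-charge sign the R4 label gets; ``negative_is_R4``
    is the Das–Pappu orientation (R4 = negatively charged strong
    polyelectrolytes, R5 = positively charged).
    """

    r1_fcr_max: Fraction = Fraction(1, 4)      # FCR strictly below ⇒ R1
    r2_fcr_max: Fraction = Fraction(7, 20)     # FCR ≤ this (and ≥ r1_fcr_max) ⇒ R2
    r34_ncpr_split: Fraction = Fraction(7, 20)  # above r2_fcr_max: NCPR ≤ this ⇒ R3
    r4_sign_convention: R4SignConvention = "negative_is_R4"

    def __post_init__(self) -> None:
        # Thresholds are exact rationals so boundary ties (a protein with
        # FCR of exactly 7/20) resolve by the printed inequalities, never
        # by binary float rounding. Decimal strings/floats are accepted.
        for name in ("r1_fcr_max", "r2_fcr_max", "r34_ncpr_split"):
            value = getattr(self, name)
            if not isinstance(value, Fraction):
                object.__setattr__(self, name, Fraction(str(value)))


DEFAULT_SCHEME = RegionScheme()


@dataclass(frozen=True)
class ChargeProfile:
    """Charge composition of one sequence; fractions are exact rationals."""

    protein_id: str
    n: int
    n_plus: int
    n_minus: int
    region: str | None = None

    @property
    def f_plus(self) -> Fraction:
        return Fraction(self.n_plus, self.n)

    @property
    def f_minus(self) -> Fraction:
        return Fraction(self.n_minus, self.n)

    @property
    def fcr(self) -> Fraction:
        return self.f_plus + self.f_minus

    @property
    def ncpr(self) -> Fraction:
        return abs(self.f_plus - self.f_minus)

    @property
    def ncpr_signed(self) -> Fraction:
        return self.f_plus - self.f_minus


def charge_fractions(sequence: str, protein_id: str = "") -> ChargeProfile:
    """Count charged residues and form the (f+, f−, FCR, NCPR) profile."""
    if not sequence:
        raise ValueError("empty sequence")
    n_plus = sum(1 for aa in sequence if aa in POSITIVE_AA)
    n_minus = sum(1 for aa in sequence if aa in NEGATIVE_AA)
    return ChargeProfile(protein_id=protein_id, n=len(sequence),
                         n_plus=n_plus, n_minus=n_minus)


def classify_region(profile: ChargeProfile,
                    scheme: RegionScheme = DEFAULT_SCHEME) -> str:
    """Assign the diagram-of-states region for one charge profile."""
    fcr, ncpr = profile.fcr, profile.ncpr
    if fcr < scheme.r1_fcr_max:
        return "R1"
    if fcr <= scheme.r2_fcr_max:
        return "R2"
    if ncpr <= scheme.r34_ncpr_split:
        return "R3"
    negative = profile.ncpr_signed < 0
    if scheme.r4_sign_convention == "negative_is_R4":
        return "R4" if negative else "R5"
    return "R5" if negative else "R4"


def charge_profile(record: ProteinRecord,
                   scheme: RegionScheme = DEFAULT_SCHEME) -> ChargeProfile:
    """Charge fractions plus region for one record."""
    profile = charge_fractions(record.sequence, record.id)
    from dataclasses import replace
    return replace(profile, region=classify_region(profile, scheme))


def charge_table(records: Iterable[ProteinRecord],
                 scheme: RegionScheme = DEFAULT_SCHEME) -> "pandas.DataFrame":  # noqa: F821
    """Charge profiles for a collection of records as a DataFrame."""
    import pandas as pd

    profiles = [charge_profile(r, scheme) for r in records]
    return pd.DataFrame(
        {
            "id": [p.protein_id for p in profiles],
            "n": [p.n for p in profiles],
            "f_plus": [float(p.f_plus) for p in profiles],
            "f_minus": [float(p.f_minus) for p in profiles],
            "fcr": [float(p.fcr) for p in profiles],
            "ncpr": [float(p.ncpr) for p in profiles],
            "region": [p.region for p in profiles],
        }
    )


def region_histogram(profiles_or_table) -> dict[str, int]:
    """Counts per region label R1..R5 (zero-filled)."""
    counts = {f"R{i}": 0 for i in range(1, 6)}
    regions = (profiles_or_table["region"]
               if hasattr(profiles_or_table, "columns")
               else [p.region for p in profiles_or_table])
    for region in regions:
        counts[region] += 1
    return counts
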