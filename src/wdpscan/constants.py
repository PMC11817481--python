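"""Pinned physicochemical constant tables.

All tables are published reference data:

* ``KYTE_DOOLITTLE`` — the hydropathy scale of Kyte & Doolittle (1982),
  the scale that defines GRAVY.
* ``DIWV`` — the dipeptide instability weight values of Guruprasad,
  Reddy & Pandit (1990), the basis of the instability index. Pairs the
  original publication leaves unlisted carry the default weight 1.0.
* ``AI_COEFF_*`` — the side-chain volume coefficients of Ikai (1980)
  for the aliphatic index.
* ``PKA_*`` — the Bjellqvist ionizable-group pKa set used by
  ExPASy ProtParam for the theoretical isoelectric point, including
  residue-specific terminal pKas.

The tables are module-level data on purpose: they are part of the
package contract (``wdpscan physchem --show-constants`` dumps them) and
swapping a table swaps the definition of the index.
"""

from __future__ import annotations

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

TABLES_VERSION = "kd1982/guruprasad1990/ikai1980/bjellqvist1993"

# Kyte & Doolittle (1982) hydropathy.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

DIWV_DEFAULT = 1.0

# Guruprasad et al. (1990) dipeptide instability weight values,
# DIWV[first][second]; unlisted pairs default to 1.0.
DIWV: dict[str, dict[str, float]] = {
    "A": {"C": 44.94, "D": -7.49, "H": -7.49, "P": 20.26},
    "C": {"D": 20.26, "H": 33.60, "L": 20.26, "M": 33.60, "P": 20.26,
          "Q": -6.54, "T": 33.60, "V": -6.54, "W": 24.68},
    "D": {"F": -6.54, "K": -7.49, "R": -6.54, "S": 20.26, "T": -14.03},
    "E": {"C": 44.94, "D": 20.26, "E": 33.60, "H": -6.54, "I": 20.26,
          "P": 20.26, "Q": 20.26, "S": 20.26, "W": -14.03},
    "F": {"D": 13.34, "K": -14.03, "P": 20.26, "Y": 33.601},
    "G": {"A": -7.49, "E": -6.54, "G": 13.34, "I": -7.49, "K": -7.49,
          "N": -7.49, "T": -7.49, "W": 13.34, "Y": -7.49},
    "H": {"F": -9.37, "G": -9.37, "I": 44.94, "K": 24.68, "N": 24.68,
          "P": -1.88, "T": -6.54, "W": -1.88, "Y": 44.94},
    "I": {"E": 44.94, "H": 13.34, "K": -7.49, "L": 20.26, "P": -1.88,
          "V": -7.49},
    "K": {"G": -7.49, "I": -7.49, "L": -7.49, "M": 33.60, "P": -6.54,
          "Q": 24.64, "R": 33.60, "V": -7.49},
    "L": {"K": -7.49, "P": 20.26, "Q": 33.60, "R": 20.26, "W": 24.68},
    "M": {"A": 13.34, "H": 58.28, "M": -1.88, "P": 44.94, "Q": -6.54,
          "R": -6.54, "S": 44.94, "T": -1.88, "Y": 24.68},
    "N": {"C": -1.88, "F": -14.03, "G": -14.03, "I": 44.94, "K": 24.68,
          "P": -1.88, "Q": -6.54, "T": -7.49, "W": -9.37},
    "P": {"A": 20.26, "C": -6.54, "D": -6.54, "E": 18.38, "F": 20.26,
          "M": -6.54, "P": 20.26, "Q": 20.26, "R": -6.54, "S": 20.26,
          "V": 20.26, "W": -1.88},
    "Q": {"C": -6.54, "D": 20.26, "E": 20.26, "F": -6.54, "P": 20.26,
          "Q": 20.26, "S": 44.94, "V": -6.54, "Y": -6.54},
    "R": {"G": -7.49, "H": 20.26, "N": 13.34, "P": 20.26, "Q": 20.26,
          "R": 58.28, "S": 44.94, "W": 58.28, "Y": -6.54},
    "S": {"C": 33.60, "E": 20.26, "P": 44.94, "Q": 20.26, "R": 20.26,
          "S": 20.26},
    "T": {"E": 20.26, "F": 13.34, "G": -7.49, "N": -14.03, "Q": -6.54,
          "W": -14.03},
    "V": {"D": -14.03, "G": -7.49, "K": -1.88, "P": 20.26, "T": -7.49,
          "Y": -6.54},
    "W": {"A": -14.03, "G": -9.37, "H": 24.68, "L": 13.34, "M": 24.68,
          "N": 13.34, "T": -14.03, "V": -7.49},
    "Y": {"A": 24.68, "D": 24.68, "E": -6.54, "G": -7.49, "H": 13.34,
          "M": 44.94, "P": 13.34, "R": -15.91, "T": -7.49, "W": -9.37,
          "Y": 13.34},
}

# Aliphatic index coefficients (Ikai 1980): relative volumes of the
# Val and Ile/Leu side chains against Ala.
AI_COEFF_VAL = 2.9
AI_COEFF_ILE_LEU = 3.9

# Bjellqvist pKa set (as used by ExPASy ProtParam).
PKA_POSITIVE: dict[str, float] = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
PKA_NEGATIVE: dict[str, float] = {"Cterm": 3.55, "D": 4.05, "E": 4.45,
                                  "C": 9.0, "Y": 10.0}
# Residue-specific terminal pKas override the generic terminus value.
PKA_NTERM_BY_RESIDUE: dict[str, float] = {"A": 7.59, "M": 7.0, "S": 6.93,
                                          "P": 8.36, "T": 6.82, "V": 7.44,
                                          "E": 7.7}
PKA_CTERM_BY_RESIDUE: dict[str, float] = {"D": 4.55, "E": 4.75}


def diwv(first: str, second: str) -> float:
    """Dipeptide instability weight for the ordered pair ``first+second``."""
    return DIWV.get(first, {}).get(second, DIWV_DEFAULT)


def format_constants() -> str:
    """Human-readable dump of every table, for ``--show-constants``."""
    lines = [f"tables_version\t{TABLES_VERSION}", "", "# Kyte-Doolittle hydropathy"]
    for aa in CANONICAL_AA:
        lines.append(f"{aa}\t{KYTE_DOOLITTLE[aa]}")
    lines.append("")
    lines.append(f"# DIWV dipeptide weights (default {DIWV_DEFAULT} for unlisted pairs)")
    for a in CANONICAL_AA:
        for b in CANONICAL_AA:
            w = diwv(a, b)
            if w != DIWV_DEFAULT:
                lines.append(f"{a}{b}\t{w}")
    lines.append("")
    lines.append(f"# Aliphatic index coefficients: a={AI_COEFF_VAL} (Val), "
                 f"b={AI_COEFF_ILE_LEU} (Ile/Leu)")
    lines.append("")
    lines.append("# Bjellqvist pKa set")
    for name, table in [("positive", PKA_POSITIVE), ("negative", PKA_NEGATIVE),
                        ("nterm_by_residue", PKA_NTERM_BY_RESIDUE),
                        ("cterm_by_residue", PKA_CTERM_BY_RESIDUE)]:
        for k, v in table.items():
            lines.append(f"pka.{name}.{k}\t{v}")
    return "\n".join(lines)
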