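"""Reference accession lists and a fetch helper.

``ARABIDOPSIS_WDP_ACCESSIONS`` is the published set of 56 UniProt
accessions of wholly disordered Arabidopsis thaliana proteins (UniProt
proteome UP000006548). Sequences are not bundled; fetch them with
:func:`fetch_uniprot_fasta` (requires network access) and feed the
resulting FASTA to the charge/physchem stages to reproduce the
reference characterization.
"""

from __future__ import annotations

import urllib.request
from pathlib import Path
from typing import Iterable, Sequence

ARABIDOPSIS_WDP_ACCESSIONS: tuple[str, ...] = (
    "F4I179", "Q9M3G8", "O82760", "Q8VXY1", "Q9FRL0", "Q9LUC7", "Q9C7W1",
    "Q8L9A7", "Q681J0", "Q9SCK5", "Q9LU05", "A0A1P8ASG6", "Q9SXE9", "Q8L7Z6",
    "Q5XV49", "Q84WZ5", "Q9SWI1", "Q9M9T4", "Q8GXS8", "Q9FYE2", "Q9XI29",
    "Q9SSC1", "Q3E9A8", "Q9LZM9", "Q9STG0", "Q9FGU5", "Q1G3N4", "Q9LSN1",
    "Q9C7Y9", "O04254", "Q8GYJ0", "Q9FKA5", "Q9LJV8", "Q9FM74", "Q9LF22",
    "B3H4F1", "Q9LE54", "Q9SJW3", "Q8LGD1", "Q9S7P8", "Q9FL02", "P30185",
    "P42758", "Q9M2Q5", "O48526", "B6IDH8", "Q67YG7", "Q9CA45", "F4J6N7",
    "Q9FKQ9", "Q8L9K4", "Q9LEZ1", "Q9FH00", "Q9LPW6", "F4I7D8", "O22729",
)

UNIPROT_FASTA_URL = "https://rest.uniprot.org/uniprotkb/{accession}.fasta"


def fetch_uniprot_fasta(accessions: Sequence[str] | Iterable[str],
                        out_path: str | Path,
                        timeout: float = 30.0) -> Path:
    """Download UniProt sequences into one FASTA file (needs network)."""
    out_path = Path(out_path)
    with open(out_path, "w") as fh:
        for acc in accessions:
            url = UNIPROT_FASTA_URL.format(accession=acc)
            with urllib.request.urlopen(url, timeout=timeout) as resp:
                fh.write(resp.read().decode())
    return out_path
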