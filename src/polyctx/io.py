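"""Reading and writing proteomes and annotation tables.

Proteins are plain upper-case amino-acid strings over the 20 standard
letters plus the ambiguity letters X, B, Z, U, O.  Ambiguity letters are
legal in sequences but are excluded from every composition numerator and
denominator, so frequency vectors are always over exactly 20 letters.

All coordinates in this package are 1-based and inclusive on both ends.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"
AMBIGUOUS_AA: str = "XBZUO"
VALID_AA = frozenset(STANDARD_AA) | frozenset(AMBIGUOUS_AA)

#: Closed vocabulary of subcellular location labels.
LOCATION_LABELS = ("Nucleus", "Cytoplasm", "Mitochondrion", "Secreted", "Other/Mixed")
#: Closed vocabulary of N-terminal targeting-peptide calls (TargetP-style).
PEPTIDE_CALLS = ("mTP", "SP", "other")

_UNIPROT_HEADER = re.compile(r"^(?:sp|tr)\|([^|\s]+)\|")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with a stable identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        object.__setattr__(self, "sequence", self.sequence.upper())
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in VALID_AA:
                raise ValueError(
                    f"invalid residue {ch!r} at position {pos} in protein {self.id!r}"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BackgroundComposition:
    """Amino-acid frequencies over the 20 standard letters of a proteome."""

    freq: Mapping[str, float]
    total_residues: int

    def __getitem__(self, letter: str) -> float:
        return self.freq[letter]

    def as_series(self) -> pd.Series:
        return pd.Series({aa: self.freq[aa] for aa in STANDARD_AA}, name="background")


@dataclass(frozen=True)
class AnnotationRow:
    location: str | None = None
    peptide_call: str | None = None


@dataclass
class AnnotationTable:
    """Per-protein subcellular location labels and targeting-peptide calls."""

    rows: dict[str, AnnotationRow] = field(default_factory=dict)

    def location(self, protein_id: str) -> str | None:
        row = self.rows.get(protein_id)
        return row.location if row else None

    def peptide_call(self, protein_id: str) -> str | None:
        row = self.rows.get(protein_id)
        return row.peptide_call if row else None

    def __len__(self) -> int:
        return len(self.rows)


def _extract_id(header_token: str) -> str:
    """Accession from a FASTA id token; UniProt ``sp|ACC|NAME`` yields ACC."""
    m = _UNIPROT_HEADER.match(header_token)
    return m.group(1) if m else header_token


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Records come back in file order.  The id is the header token before the
    first whitespace; UniProt-style ``sp|ACC|NAME`` headers are reduced to
    the accession.  Duplicate ids, empty files and non-amino-acid characters
    are hard errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        pid = _extract_id(entry.id)
        if pid in seen:
            raise ValueError(f"duplicate protein id {pid!r} in {path}")
        seen.add(pid)
        records.append(ProteinRecord(pid, str(entry.seq).strip()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    entries = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    SeqIO.write(entries, str(path), "fasta")


def as_mapping(proteome) -> dict[str, ProteinRecord]:
    """Normalise a proteome (sequence of records or id-keyed mapping) to a dict."""
    if isinstance(proteome, Mapping):
        return dict(proteome)
    return {r.id: r for r in proteome}


def read_annotations(path) -> AnnotationTable:
    """Read a TSV annotation table with columns ``id``, ``location``, ``peptide``.

    Either of the last two columns may be empty per row.  Labels outside the
    closed vocabularies and duplicate ids are hard errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"id", "location", "peptide"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation table must have columns {sorted(required)}")
    table = AnnotationTable()
    for _, row in df.iterrows():
        pid = row["id"]
        if pid in table.rows:
            raise ValueError(f"duplicate protein id {pid!r} in annotation table")
        loc = row["location"] or None
        pep = row["peptide"] or None
        if loc is not None and loc not in LOCATION_LABELS:
            raise ValueError(f"unknown location label {loc!r} for {pid!r}")
        if pep is not None and pep not in PEPTIDE_CALLS:
            raise ValueError(f"unknown peptide call {pep!r} for {pid!r}")
        table.rows[pid] = AnnotationRow(location=loc, peptide_call=pep)
    return table


def write_annotations(table: AnnotationTable, path) -> None:
    df = pd.DataFrame(
        {
            "id": list(table.rows),
            "location": [r.location or "" for r in table.rows.values()],
            "peptide": [r.peptide_call or "" for r in table.rows.values()],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def background_composition(proteome) -> BackgroundComposition:
    """Frequency of each standard amino acid over the whole proteome.

    Ambiguity letters are excluded from both numerator and denominator.
    """
    counts: Counter[str] = Counter()
    for rec in as_mapping(proteome).values():
        counts.update(rec.sequence)
    total = sum(counts[aa] for aa in STANDARD_AA)
    if total == 0:
        raise ValueError("proteome contains no standard residues")
    freq = {aa: counts[aa] / total for aa in STANDARD_AA}
    return BackgroundComposition(freq=freq, total_residues=total)
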