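"""FASTA input/output and sequence normalization.

Sequences are kept as plain upper-case strings over {A,C,G,T,N}; any
character outside ACGT is masked to N and every downstream k-window that
touches an N is skipped rather than guessed at.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

_NORMALIZE_TABLE = str.maketrans(
    {c: "N" for c in "BDEFHIJKLMOPQRSUVWXYZ"}
)


class FastaFormatError(ValueError):
    """Raised when an input file is not parseable FASTA."""


@dataclass
class SequenceDataset:
    """An ordered collection of named DNA sequences.

    Attributes
    ----------
    records : list of (identifier, sequence) pairs. Sequences are strings
        over {A,C,G,T,N}.
    """

    records: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def widths(self) -> list[int]:
        return [len(s) for _, s in self.records]

    @property
    def sequences(self) -> list[str]:
        return [s for _, s in self.records]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _clean(seq: str) -> str:
    return seq.upper().translate(_NORMALIZE_TABLE)


def read_fasta(path: str | Path) -> SequenceDataset:
    """Read a FASTA file into a :class:`SequenceDataset`.

    Sequences are upper-cased and non-ACGT characters masked to N.
    Record order is preserved. Raises :class:`FastaFormatError` on an
    empty file or text that does not start with a header line.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FastaFormatError(f"{path}: empty FASTA file")
    first = next(ln for ln in text.splitlines() if ln.strip())
    if not first.startswith(">"):
        raise FastaFormatError(
            f"{path}: line 1: expected FASTA header starting with '>'"
        )
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        records.append((rec.id, _clean(str(rec.seq))))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return SequenceDataset(records)


def write_fasta(dataset: SequenceDataset, path: str | Path, width: int = 70) -> None:
    """Write a dataset to FASTA, wrapping lines at ``width`` columns."""
    recs = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in dataset.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def normalize(dataset: SequenceDataset, width_policy: str = "none") -> SequenceDataset:
    """Character-normalize a dataset, optionally standardizing widths.

    ``width_policy``:

    * ``"none"`` — sequences unchanged apart from upper-casing and masking
      of ambiguous characters to N.
    * ``"center_trim"`` — all sequences symmetrically trimmed to the
      minimum width in the dataset (the extra symbol on odd trims is taken
      from the right), matching summit-centered peak extraction.
    """
    if dataset.n == 0:
        raise ValueError("cannot normalize an empty dataset")
    if width_policy not in ("none", "center_trim"):
        raise ValueError(f"unknown width_policy {width_policy!r}")
    cleaned = [(name, _clean(seq)) for name, seq in dataset.records]
    if width_policy == "center_trim":
        target = min(len(s) for _, s in cleaned)
        if target < 1:
            raise ValueError("sequence shorter than 1 after trimming")
        trimmed = []
        for name, seq in cleaned:
            extra = len(seq) - target
            left = extra // 2
            trimmed.append((name, seq[left:left + target]))
        cleaned = trimmed
    return SequenceDataset(cleaned)


def encode(seq: str) -> "list[int]":
    """Encode a sequence as integer codes A=0, C=1, G=2, T=3; N and any
    other symbol become -1."""
    return [BASE_INDEX.get(c, -1) for c in seq]


def decode(codes) -> str:
    return "".join(ALPHABET[c] if 0 <= c <= 3 else "N" for c in codes)
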