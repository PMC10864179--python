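"""Reading, writing and integer encoding of multiple sequence alignments.

Two text dialects are supported:

* **A3M** (HH-suite flavour): the first record is the query; uppercase
  letters and ``-`` occupy query match columns, lowercase letters are
  insertions relative to the query and carry no match-column index.
* **Aligned FASTA**: the degenerate A3M case in which no row contains
  lowercase letters and every row has the same physical length.

Alignments are mapped onto a fixed 22-state integer alphabet: the 20
canonical amino acids in alphabetical one-letter order (states 0-19), one
unknown/nonstandard state (20, covering X, B, Z, J, U, O and anything else
unrecognised), and the gap state (21).  This canonical ordering keeps
coupling-parameter indices reproducible across runs.

Species annotations are pulled from UniProt-style headers (``OX=`` numeric
taxon identifiers take precedence over ``OS=`` organism names); sequences
without an annotation — typically metagenomic hits — simply have no species
key and are never linked across chains.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from io import StringIO
from typing import IO, Iterable, Optional

import numpy as np
from Bio import SeqIO

from .errors import MsaFormatError

#: Canonical amino acids, alphabetical by one-letter code.
AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: Integer state for nonstandard / unknown residues (X, B, Z, J, U, O, ...).
UNKNOWN_STATE = 20
#: Integer state for an alignment gap.
GAP_STATE = 21
#: Total number of states: 20 amino acids + unknown + gap.
NUM_STATES = 22

_LOWER_AND_DOTS = str.maketrans("", "", "abcdefghijklmnopqrstuvwxyz.")

_OX_RE = re.compile(r"\bOX=(\d+)\b")
_OS_RE = re.compile(r"\bOS=(.+?)(?=\s+[A-Za-z0-9]{2,3}=|\s*$)")


@dataclass(frozen=True)
class Alphabet22:
    """Fixed 22-state symbol-to-integer mapping.

    ``symbols[state]`` is the canonical symbol for each state; every other
    uppercase character encodes to the unknown state so that the mapping is
    total over printable input.
    """

    symbols: tuple = tuple(AA20) + ("X", "-")

    def __post_init__(self) -> None:
        if len(self.symbols) != NUM_STATES:
            raise ValueError(f"alphabet must have {NUM_STATES} symbols")

    def lookup_table(self) -> np.ndarray:
        """Return a 256-entry byte-to-state table (unknown for unmapped)."""
        lut = np.full(256, UNKNOWN_STATE, dtype=np.uint8)
        for state, sym in enumerate(self.symbols):
            lut[ord(sym)] = state
        return lut


DEFAULT_ALPHABET = Alphabet22()


def parse_species(header: str, mode: str = "auto") -> Optional[str]:
    """Extract a species key from a UniProt-style FASTA header.

    In ``auto`` mode the numeric ``OX=`` taxon identifier wins when present,
    falling back to the ``OS=`` organism name; ``taxid`` and ``name``
    restrict the search to one field.  Absence is a value (``None``), not an
    error: unannotated sequences are legitimate but unlinkable.
    """
    if mode not in ("taxid", "name", "auto"):
        raise ValueError(f"unknown species parse mode: {mode!r}")
    if mode in ("taxid", "auto"):
        m = _OX_RE.search(header)
        if m:
            return m.group(1).strip()
        if mode == "taxid":
            return None
    m = _OS_RE.search(header)
    if m:
        value = m.group(1).strip()
        return value or None
    return None


@dataclass(frozen=True)
class SeqRecord:
    """One aligned row: uppercase/'-' are match columns, lowercase insertions."""

    id: str
    aligned_seq: str
    description: str = ""
    species_key: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise MsaFormatError("sequence record with empty id")
        if not self.aligned_seq:
            raise MsaFormatError(f"record {self.id!r} has an empty sequence")

    @property
    def match_columns(self) -> str:
        """The row restricted to query match columns (insertions dropped)."""
        return self.aligned_seq.translate(_LOWER_AND_DOTS)

    @property
    def n_match_columns(self) -> int:
        return len(self.match_columns)

    def header(self) -> str:
        return f"{self.id} {self.description}".rstrip()


@dataclass
class Msa:
    """An alignment over a fixed query coordinate system.

    ``records[0]`` is the query; it must be gap-free and defines the length
    ``L`` of the coordinate system.  Every row must present exactly ``L``
    match columns.
    """

    records: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise MsaFormatError("an MSA needs at least the query row")
        query = self.records[0]
        if "-" in query.match_columns:
            raise MsaFormatError(
                f"query record {query.id!r} contains gaps; the query defines "
                "the match-column coordinate system and must be gap-free"
            )
        L = query.n_match_columns
        for rec in self.records[1:]:
            if rec.n_match_columns != L:
                raise MsaFormatError(
                    f"record {rec.id!r} has {rec.n_match_columns} match "
                    f"columns, expected {L} (ragged alignment)"
                )

    @property
    def query(self) -> SeqRecord:
        return self.records[0]

    @property
    def L(self) -> int:
        """Query length in residues (number of match columns)."""
        return self.query.n_match_columns

    @property
    def N(self) -> int:
        """Number of rows, query included."""
        return len(self.records)

    @property
    def homologs(self) -> list:
        return self.records[1:]


def _records_from_stream(handle: IO[str]) -> Iterable[SeqRecord]:
    for rec in SeqIO.parse(handle, "fasta"):
        desc = rec.description
        rest = desc[len(rec.id):].strip() if desc.startswith(rec.id) else desc
        yield SeqRecord(
            id=rec.id,
            aligned_seq=str(rec.seq),
            description=rest,
            species_key=parse_species(desc),
        )


def read_a3m(source) -> Msa:
    """Parse an A3M (or aligned FASTA) stream or string into an :class:`Msa`.

    The first record is taken as the query.  Ragged match-column counts
    raise :class:`MsaFormatError` naming the offending record; an empty
    stream is also a format error.
    """
    handle = StringIO(source) if isinstance(source, str) else source
    records = list(_records_from_stream(handle))
    if not records:
        raise MsaFormatError("empty alignment input")
    return Msa(records)


def write_a3m(msa: Msa) -> str:
    """Serialise an :class:`Msa` as A3M text; round-trips through read_a3m."""
    lines = []
    for rec in msa.records:
        lines.append(f">{rec.header()}")
        lines.append(rec.aligned_seq)
    return "\n".join(lines) + "\n"


def write_afa(msa: Msa) -> str:
    """Serialise as aligned FASTA: insertions are dropped, match columns kept."""
    lines = []
    for rec in msa.records:
        lines.append(f">{rec.header()}")
        lines.append(rec.match_columns)
    return "\n".join(lines) + "\n"


def to_match_matrix(msa: Msa, alphabet: Alphabet22 = DEFAULT_ALPHABET) -> np.ndarray:
    """Encode the alignment as an ``N x L`` uint8 matrix of states 0..21.

    Insertions are dropped; gaps map to the gap state; any unrecognised
    character (nonstandard residues such as B, Z, J, U, O) maps to the
    unknown state, so the encoding is total.
    """
    lut = alphabet.lookup_table()
    rows = np.empty((msa.N, msa.L), dtype=np.uint8)
    for n, rec in enumerate(msa.records):
        raw = np.frombuffer(rec.match_columns.encode("latin-1", "replace"), dtype=np.uint8)
        rows[n] = lut[raw]
    return rows


def query_only_msa(query_id: str, sequence: str, description: str = "") -> Msa:
    """Build a single-row MSA holding just the query sequence."""
    return Msa([SeqRecord(id=query_id, aligned_seq=sequence.upper(), description=description)])
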