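"""Reading per-taxon multi-FASTA proteome files.

Each input file holds every protein sequence of one taxon.  Residues are
mapped onto the 20-letter amino-acid alphabet; everything else (B, J, O, U,
X, Z, stop/gap symbols, ...) is kept in place but flagged ambiguous, so
sequence coordinates are stable.  Windows containing an ambiguous residue
are later excluded from spaced-word extraction.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = ["AMINO_ACIDS", "AMBIGUOUS_CODE", "Proteome", "read_proteome", "write_proteome", "encode_sequence"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: integer code marking a non-canonical (ambiguous) residue
AMBIGUOUS_CODE = -1

_CODE_TABLE = np.full(256, AMBIGUOUS_CODE, dtype=np.int8)
for _i, _aa in enumerate(AMINO_ACIDS):
    _CODE_TABLE[ord(_aa)] = _i
    _CODE_TABLE[ord(_aa.lower())] = _i

_NAME_SANITIZE_RE = re.compile(r"[\s:;(),'\"\[\]]+")


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a residue string as int8 codes 0..19, ambiguous = -1."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    return _CODE_TABLE[raw]


def sanitize_taxon_name(name: str) -> str:
    """Replace characters that break PHYLIP/Newick files with underscores."""
    return _NAME_SANITIZE_RE.sub("_", name.strip())


@dataclass
class Proteome:
    """All protein sequences of one taxon."""

    taxon_name: str
    record_ids: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.taxon_name:
            raise ValueError("taxon_name must be nonempty")
        if len(self.record_ids) != len(self.sequences):
            raise ValueError("record_ids and sequences must have equal length")
        for rid, s in zip(self.record_ids, self.sequences):
            if not s:
                raise ValueError(f"record {rid!r} has an empty sequence")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    def encoded(self) -> list[np.ndarray]:
        """Per-sequence int8 code arrays (0..19 canonical, -1 ambiguous)."""
        return [encode_sequence(s) for s in self.sequences]

    def ambiguous_mask(self, seq_index: int) -> np.ndarray:
        return encode_sequence(self.sequences[seq_index]) == AMBIGUOUS_CODE


def _open_maybe_gzip(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_proteome(path: str | Path, name: str | None = None) -> Proteome:
    """Read one taxon's proteome from a (possibly gzipped) multi-FASTA file.

    Sequences are uppercased; record order is preserved.  The taxon name
    defaults to the file basename without extensions, sanitized for
    PHYLIP/Newick output.
    """
    path = Path(path)
    if name is None:
        name = path.name
        for ext in (".gz", ".fasta", ".fa", ".faa", ".fas", ".pep"):
            if name.endswith(ext):
                name = name[: -len(ext)]
    name = sanitize_taxon_name(name)

    ids: list[str] = []
    seqs: list[str] = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if not seq:
                raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
            ids.append(rec.id)
            seqs.append(seq)
    if not ids:
        raise ValueError(f"no FASTA records found in {path}")
    return Proteome(taxon_name=name, record_ids=tuple(ids), sequences=tuple(seqs))


def write_proteome(prot: Proteome, path: str | Path) -> None:
    """Write a proteome back to plain FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for rid, seq in zip(prot.record_ids, prot.sequences):
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_proteomes(paths: Iterable[str | Path], names: Sequence[str] | None = None) -> list[Proteome]:
    """Read several proteome files; taxon names must come out unique."""
    paths = list(paths)
    if names is not None and len(names) != len(paths):
        raise ValueError("one name per path required")
    prots = [read_proteome(p, None if names is None else names[i]) for i, p in enumerate(paths)]
    seen: dict[str, int] = {}
    for pr in prots:
        if pr.taxon_name in seen:
            raise ValueError(f"duplicate taxon name {pr.taxon_name!r}")
        seen[pr.taxon_name] = 1
    return prots
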