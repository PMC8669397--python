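"""Circular genome container and FASTA I/O.

A bacterial chromosome is circular; motif scans and skew profiles must wrap
across the sequence origin. The ``circular`` flag is carried in the FASTA
header as a ``circular=true|false`` token so that files round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from muklock.errors import DataError

_DNA = set("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class CircularGenome:
    """A DNA sequence with explicit topology.

    Parameters
    ----------
    name : str
        Record identifier.
    seq : str
        Upper-case sequence over {A, C, G, T}. Ambiguity codes are
        rejected: downstream edit-distance arithmetic is defined on the
        concrete alphabet only.
    circular : bool
        Whether coordinate arithmetic wraps at the origin.
    """

    name: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise DataError("genome sequence must be non-empty")
        bad = [i for i, c in enumerate(self.seq) if c not in _DNA]
        if bad:
            shown = ", ".join(str(i + 1) for i in bad[:10])
            raise DataError(
                f"genome '{self.name}' contains non-ACGT characters at "
                f"position(s) {shown} (1-based)"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, length: int) -> str:
        """Substring of given length starting at ``start``, wrapping if circular."""
        n = len(self.seq)
        start %= n
        if start + length <= n:
            return self.seq[start:start + length]
        if not self.circular:
            raise DataError("window extends past the end of a linear genome")
        return (self.seq * 2)[start:start + length]

    def reverse_complement(self) -> "CircularGenome":
        return CircularGenome(self.name, self.seq.translate(_COMPLEMENT)[::-1],
                              self.circular)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path) -> CircularGenome:
    """Read a single-record FASTA file into a :class:`CircularGenome`.

    Lowercase is normalized to uppercase. A ``circular=true`` token anywhere
    in the header line marks the molecule as circular (default linear).
    Multi-record files are rejected so that coordinates are unambiguous.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise DataError(f"{path}: no FASTA records found")
    if len(records) > 1:
        raise DataError(
            f"{path}: expected a single record, found {len(records)}"
        )
    rec = records[0]
    header = rec.description
    circular = "circular=true" in header.lower().split()
    return CircularGenome(rec.id, str(rec.seq).upper(), circular)


def write_fasta(genome: CircularGenome, path: str | Path, width: int = 70) -> None:
    """Write a genome as FASTA, recording topology in the header."""
    token = "circular=true" if genome.circular else "circular=false"
    rec = SeqRecord(Seq(genome.seq), id=genome.name, description=token)
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")
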