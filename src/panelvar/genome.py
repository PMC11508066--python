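"""In-memory genome container with 1-based inclusive coordinate accessors.

Sequences are held as upper-case bytearrays so that the simulator can edit
them in place without copying whole chromosomes. All public coordinates are
1-based inclusive (the convention of the variant notation ``chr2:122881444:G > T``);
interval arithmetic elsewhere in the package is 0-based half-open with
conversion at I/O boundaries.
"""

from __future__ import annotations

import textwrap
from typing import Dict, Iterator, Mapping

import pyfaidx

from .errors import ConfigurationError, CoordinateError

COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.encode()[::-1].translate(COMPLEMENT).decode()


class Genome:
    """A set of named chromosome sequences."""

    def __init__(self, seqs: Mapping[str, str]):
        for name, s in seqs.items():
            if len(s) < 1:
                raise ConfigurationError(f"chromosome {name!r} has length 0; must be >= 1")
        self._seqs: Dict[str, bytearray] = {
            name: bytearray(s.upper().encode()) for name, s in seqs.items()
        }

    # -- accessors ---------------------------------------------------------

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {name: len(s) for name, s in self._seqs.items()}

    def chroms(self) -> Iterator[str]:
        return iter(self._seqs)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    def sequence(self, chrom: str) -> str:
        self._check_chrom(chrom)
        return self._seqs[chrom].decode()

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of ``chrom`` from ``start`` to ``end``, 1-based inclusive."""
        self._check_chrom(chrom)
        n = len(self._seqs[chrom])
        if not (1 <= start <= end <= n):
            raise CoordinateError(f"{chrom}:{start}-{end} outside 1..{n}")
        return self._seqs[chrom][start - 1 : end].decode()

    def base(self, chrom: str, pos: int) -> str:
        return self.fetch(chrom, pos, pos)

    # -- edits -------------------------------------------------------------

    def replace(self, chrom: str, start: int, seq: str) -> None:
        """Overwrite bases starting at 1-based ``start`` with ``seq``."""
        self._check_chrom(chrom)
        n = len(self._seqs[chrom])
        end = start + len(seq) - 1
        if not (1 <= start <= end <= n):
            raise CoordinateError(f"replacement {chrom}:{start}-{end} outside 1..{n}")
        self._seqs[chrom][start - 1 : end] = seq.upper().encode()

    def set_base(self, chrom: str, pos: int, base: str) -> None:
        self.replace(chrom, pos, base)

    # -- I/O ---------------------------------------------------------------

    def to_fasta(self, path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name in self._seqs:
                fh.write(f">{name}\n")
                for line in textwrap.wrap(self.sequence(name), width):
                    fh.write(line + "\n")

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        fa = pyfaidx.Fasta(str(path), rebuild=True)
        genome = cls({name: str(fa[name][:]) for name in fa.keys()})
        fa.close()
        return genome

    def _check_chrom(self, chrom: str) -> None:
        if chrom not in self._seqs:
            raise CoordinateError(f"unknown chromosome {chrom!r}")
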