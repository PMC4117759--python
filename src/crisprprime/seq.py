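"""Circular DNA sequences and strand arithmetic.

All plasmid coordinates in this package are 0-based half-open on the +
strand.  Intervals that cross the origin of a circular replicon are encoded
with ``end > length`` and reduced modulo the length when extracting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CircularSequence:
    """A replicon (typically a plasmid) with modular coordinate access.

    Parameters
    ----------
    id : str
        Record identifier.
    seq : str
        Uppercase DNA over {A, C, G, T}.
    circular : bool
        Whether coordinate arithmetic wraps around the origin.  All plasmid
        fixtures in this package are circular; ``circular=False`` restricts
        extraction and motif scanning to the linear sequence.
    """

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.seq) == 0:
            raise ValueError("empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def length(self) -> int:
        return len(self.seq)

    def fetch(self, start: int, end: int, strand: str = "+") -> str:
        """Extract ``[start, end)`` on the requested strand.

        On a circular sequence the coordinates may be negative or exceed the
        length (multi-wrap extraction is supported so that flanks remain
        defined on very short test replicons).  On a linear sequence the
        interval must lie within ``[0, length]``.
        """
        if end < start:
            raise ValueError(f"end < start: [{start}, {end})")
        L = len(self.seq)
        if not self.circular:
            if start < 0 or end > L:
                raise ValueError(
                    f"interval [{start}, {end}) outside linear sequence of length {L}"
                )
            out = self.seq[start:end]
        else:
            span = end - start
            start %= L
            reps = span // L + 2
            out = (self.seq * reps)[start : start + span]
        if strand == "+":
            return out
        if strand == "-":
            return revcomp(out)
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")

    def reverse_complement(self, new_id: str | None = None) -> "CircularSequence":
        """The same replicon viewed from the opposite strand.

        + coordinate ``x`` maps to ``length - 1 - x``; an interval
        ``[s, e)`` maps to ``[L - e, L - s)`` with strands exchanged.
        """
        return CircularSequence(
            id=new_id or f"{self.id}|rc", seq=revcomp(self.seq), circular=self.circular
        )
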