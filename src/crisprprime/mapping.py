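"""Mapping spacers to a circular plasmid and calling PAMs.

PAM nomenclature
----------------
Flank positions are counted *away from the protospacer into the 3' flank*:
position -1 is the base immediately 3' of the protospacer on its own strand,
-2 the next one, and so on; +1 denotes the protospacer's last base.  The
Type I-F consensus is 5'-protospacer-GG-3', i.e. G at -1 and -2.  Note this
is the reverse of some community conventions that count the PAM 5'-to-3'
from the protospacer-distal side.

A "slipped" PAM is a GG register shifted by one base: GG at +1/-1
(slip_plus1, the protospacer ends one base too late) or at -2/-3
(slip_minus1, one base too early).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seq import CircularSequence, revcomp

FLANK_LEN = 8
SPACER_LENGTHS = (31, 32, 33, 34)

PAM_CONSENSUS = "consensus"
SLIP_PLUS1 = "slip_plus1"
SLIP_MINUS1 = "slip_minus1"
SLIP_BOTH = "both"
PAM_NONE = "none"

#: annotation attached to 33-nt hits whose GG sits at +1/-1: the protospacer
#: is 32 nt when measured from the shifted (correct-register) PAM.
NOTE_33NT_PLUS1 = "32 nt from the -1/-2 PAM register"


@dataclass
class ProtospacerHit:
    """A spacer placement on the plasmid.

    ``start``/``end`` are 0-based half-open + strand coordinates; ``end`` may
    exceed the plasmid length to encode an origin-spanning interval.  ``seq``
    is read 5'->3' on ``strand`` and equals the spacer for an exact hit.
    ``flank3[0]`` is the -1 base; ``pam`` is ``flank3[:2]`` (positions -1, -2).
    """

    plasmid_id: str
    strand: str
    start: int
    end: int
    seq: str
    flank5: str
    flank3: str
    pam: str = ""
    pam_class: str = ""
    mismatches: int = 0
    ambiguous: bool = False
    hit_id: str = ""
    note: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def hit_from_interval(
    plasmid: CircularSequence,
    strand: str,
    start: int,
    length: int,
    mismatches: int = 0,
    hit_id: str = "",
) -> ProtospacerHit:
    """Build a fully annotated hit from a + strand interval ``[start, start+length)``."""
    end = start + length
    if strand == "+":
        seq = plasmid.fetch(start, end)
        flank5 = plasmid.fetch(start - FLANK_LEN, start)
        flank3 = plasmid.fetch(end, end + FLANK_LEN)
    elif strand == "-":
        seq = plasmid.fetch(start, end, "-")
        # on the - strand the 3' flank sits at lower + coordinates
        flank3 = plasmid.fetch(start - FLANK_LEN, start, "-")
        flank5 = plasmid.fetch(end, end + FLANK_LEN, "-")
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    hit = ProtospacerHit(
        plasmid_id=plasmid.id,
        strand=strand,
        start=start % len(plasmid),
        end=start % len(plasmid) + length,
        seq=seq,
        flank5=flank5,
        flank3=flank3,
        mismatches=mismatches,
        hit_id=hit_id,
    )
    return call_pam(hit)


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def map_spacer(
    spacer: str, plasmid: CircularSequence, max_mismatch: int = 0
) -> list[ProtospacerHit]:
    """All placements of ``spacer`` on either strand of the plasmid.

    Placements within Hamming distance ``max_mismatch`` are returned, across
    the circular junction.  When more than one placement attains the minimal
    distance, those placements are flagged ``ambiguous=True``.  An unmapped
    spacer yields an empty list.
    """
    spacer = spacer.upper()
    k = len(spacer)
    if not 20 <= k <= 50:
        raise ValueError(f"spacer length {k} outside [20, 50]")
    L = len(plasmid)
    if k > L:
        return []
    n_offsets = L if plasmid.circular else L - k + 1
    doubled = _encode(plasmid.seq * 2 if plasmid.circular else plasmid.seq)
    windows = np.lib.stride_tricks.sliding_window_view(doubled, k)[:n_offsets]

    hits: list[ProtospacerHit] = []
    for strand, query in (("+", spacer), ("-", revcomp(spacer))):
        mism = (windows != _encode(query)).sum(axis=1)
        for off in np.flatnonzero(mism <= max_mismatch):
            hits.append(
                hit_from_interval(plasmid, strand, int(off), k, mismatches=int(mism[off]))
            )
    if hits:
        best = min(h.mismatches for h in hits)
        minimal = [h for h in hits if h.mismatches == best]
        if len(minimal) > 1:
            for h in minimal:
                h.ambiguous = True
    return hits


def call_pam(hit: ProtospacerHit) -> ProtospacerHit:
    """Set ``pam``, ``pam_class`` (and slippage note) on a hit, in place.

    ``pam`` is read at flank positions -1/-2.  Non-consensus PAMs are passed
    to :func:`classify_slippage`.
    """
    if len(hit.flank3) < 3:
        raise RuntimeError("3' flank shorter than 3 nt; flanks must be extracted circularly")
    if not hit.seq:
        raise ValueError("empty protospacer sequence")
    hit.pam = hit.flank3[:2]
    if hit.pam == "GG":
        hit.pam_class = PAM_CONSENSUS
        hit.note = ""
    else:
        hit.pam_class, hit.note = classify_slippage(hit)
    return hit


def classify_slippage(hit: ProtospacerHit) -> tuple[str, str]:
    """Classify a non-consensus PAM by +/-1 register shift.

    Returns ``(category, note)`` with category in {slip_plus1, slip_minus1,
    both, none}.  slip_plus1: GG at +1/-1 (protospacer last base + flank -1);
    slip_minus1: GG at -2/-3.  33-nt slip_plus1 hits carry a note that they
    are 32 nt when measured from the shifted GG register.
    """
    if hit.flank3[:2] == "GG":
        raise ValueError("classify_slippage called on a consensus-PAM hit")
    plus1 = (hit.seq[-1] + hit.flank3[0]) == "GG"
    minus1 = hit.flank3[1:3] == "GG"
    if plus1 and minus1:
        category = SLIP_BOTH
    elif plus1:
        category = SLIP_PLUS1
    elif minus1:
        category = SLIP_MINUS1
    else:
        category = PAM_NONE
    note = ""
    if plus1 and hit.length == 33:
        note = NOTE_33NT_PLUS1
    return category, note


def length_distribution(hits: list[ProtospacerHit]):
    """Counts and rounded percentages of hit lengths, split by PAM consensus.

    Returns a pandas DataFrame indexed by length (31..34 plus any other
    observed length) with count/percent columns for all hits, consensus-PAM
    hits and non-consensus hits.
    """
    import pandas as pd

    lengths = sorted(set(SPACER_LENGTHS) | {h.length for h in hits})
    groups = {
        "all": hits,
        "consensus": [h for h in hits if h.pam_class == PAM_CONSENSUS],
        "nonconsensus": [h for h in hits if h.pam_class != PAM_CONSENSUS],
    }
    data = {}
    for name, grp in groups.items():
        counts = [sum(1 for h in grp if h.length == ln) for ln in lengths]
        total = sum(counts)
        data[f"count_{name}"] = counts
        data[f"pct_{name}"] = [
            int(round(100.0 * c / total)) if total else 0 for c in counts
        ]
    return pd.DataFrame(data, index=pd.Index(lengths, name="length"))
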