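"""Stochastic simulator of primed spacer acquisition on a circular plasmid.

The model: a crRNA-guided surveillance complex sits at a primed protospacer
whose PAM is degenerate (e.g. TG instead of the GG consensus), forming an
R-loop that displaces the non-target strand (NTS).  An adaptation complex
(Cas1:Cas2-3) loads on the displaced NTS and translocates 3'->5' along it
with a memoryless per-bp fall-off (geometric travel distance, mean
``proc_mean``).  Every GG dinucleotide it reads on the NTS is excised into a
new spacer with probability ``p_capture``; the protospacer is the 32 nt
(occasionally 31/33/34) immediately 5' of the GG on that strand.  The
unwound region exposes the target strand (TS) 3' of the primed protospacer
as ssDNA; a Poisson(``lambda_ts``) number of additional complexes load at
uniform positions within that exposed span and translocate 3'->5' along the
TS with the same fall-off/capture rules, which lets them run past the primed
site and produce TS hits on both sides of it.  Rarely (``p_slip``) the
excision register slips by one base, shifting protospacer and PAM together;
rarely (``p_bg``) a cell acquires one background spacer at a PAM drawn
uniformly from the whole plasmid.  Each acquisition is routed to one of the
three CRISPR arrays with fixed weights and inserted at the leader-proximal
end, duplicating the first repeat.

Geometry on + strand coordinates: 3'->5' on the + strand is decreasing
coordinate; 3'->5' on the - strand is increasing coordinate.  With the
primed protospacer on the - strand (as in the reference configuration), the
NTS is the + strand, so NTS-leg hits accumulate at decreasing + coordinates
(5' of the site on the + strand); everything mirrors exactly when the primed
strand is flipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .mapping import ProtospacerHit, hit_from_interval
from .seq import CircularSequence, revcomp
from .stats import scan_pams

ARRAYS = ("CRISPR1", "CRISPR2", "CRISPR3")
LEG_NTS = "NTS_leg"
LEG_TS = "TS_leg"
LEG_BG = "background"

_MAX_ROUNDS = 25
# minimum priming rounds pooled per cell before subsampling to the per-cell
# event target: retaining a prefix of a single round's events over-selects the
# lower-variance NTS leg (the TS leg count is Poisson-dispersed), so retained
# events are drawn uniformly from a pool covering several rounds
_MIN_ROUNDS = 3


@dataclass
class PrimedSite:
    """The primed protospacer: target of the pre-existing priming spacer."""

    protospacer: ProtospacerHit
    pam_variant: str
    priming_spacer_seq: str
    plasmid_length: int = 0

    def __post_init__(self) -> None:
        if self.pam_variant == "GG":
            raise ValueError("a primed site must carry a non-consensus PAM variant")
        if self.priming_spacer_seq != self.protospacer.seq:
            raise ValueError("priming spacer must equal the protospacer sequence on its strand")


@dataclass
class SimParams:
    """Parameters of the bi-directional translocation model.

    All probabilities are per the docstring of this module; ``array_weights``
    default to the observed per-array acquisition shares (0.65, 0.32, 0.03).
    ``events_per_cell`` is a truncated geometric on 1..``max_events_per_cell``
    with success probability ``event_geom_p``; it sets the per-cell target
    number of retained acquisitions (clones carry 1-9 new spacers).
    """

    p_capture: float = 0.05
    proc_mean: float = 500.0
    lambda_ts: float = 1.0
    p_bg: float = 0.05
    p_len33: float = 0.12
    p_len_other: float = 0.01
    p_slip: float = 0.08
    array_weights: tuple[float, float, float] = (0.65, 0.32, 0.03)
    event_geom_p: float = 0.4
    max_events_per_cell: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_capture", "p_bg", "p_len33", "p_len_other", "p_slip", "event_geom_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} not in [0, 1]")
        if self.proc_mean <= 0:
            raise ValueError("proc_mean must be positive")
        if self.lambda_ts < 0:
            raise ValueError("lambda_ts must be non-negative")
        w = np.asarray(self.array_weights, dtype=float)
        if w.size != 3 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("array_weights must be three non-negative values summing to 1")
        if self.p_len33 + self.p_len_other > 1.0:
            raise ValueError("length probabilities exceed 1")


@dataclass
class AcquisitionEvent:
    """Simulator ground truth for one acquired spacer."""

    cell_id: str
    leg: str
    hit: ProtospacerHit
    dest_array: str
    order_index: int


# ---------------------------------------------------------------------------


def generate_plasmid(length: int, gc: float = 0.5, seed: int = 0, id: str = "plasmid") -> CircularSequence:
    """A random circular plasmid with the requested G+C fraction in expectation."""
    if length < 200:
        raise ValueError("plasmid length must be >= 200")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(rng.choice(list("ACGT"), size=length, p=p))
    return CircularSequence(id=id, seq=seq, circular=True)


def plant_primed_protospacer(
    plasmid: CircularSequence,
    spacer: str,
    strand: str,
    start: int,
    pam_variant: str = "TG",
) -> tuple[CircularSequence, PrimedSite]:
    """Write a protospacer + non-consensus PAM into the plasmid.

    The spacer is placed verbatim on ``strand`` at + interval
    ``[start, start + len(spacer))`` with ``pam_variant`` immediately 3' of it
    on that strand.  Returns the edited plasmid and the matching PrimedSite.
    """
    spacer = spacer.upper()
    k = len(spacer)
    if not 31 <= k <= 34:
        raise ValueError(f"spacer length {k} outside [31, 34]")
    if pam_variant == "GG":
        raise ValueError("primed PAM must be a non-consensus variant")
    L = len(plasmid)
    if k + 2 > L:
        raise ValueError("planting would wrap more than once around the plasmid")
    seq = list(plasmid.seq)
    if strand == "+":
        plus_payload = spacer + pam_variant
        origin = start
    elif strand == "-":
        # the PAM sits 3' of the spacer on the - strand = lower + coordinates
        plus_payload = revcomp(spacer + pam_variant)
        origin = start - 2
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    for i, base in enumerate(plus_payload):
        seq[(origin + i) % L] = base
    edited = CircularSequence(id=plasmid.id, seq="".join(seq), circular=plasmid.circular)
    hit = hit_from_interval(edited, strand, start % L, k, hit_id="primed")
    site = PrimedSite(
        protospacer=hit, pam_variant=pam_variant, priming_spacer_seq=hit.seq, plasmid_length=L
    )
    return edited, site


# ---------------------------------------------------------------------------


def _draw_length(rng: np.random.Generator, params: SimParams) -> int:
    u = rng.random()
    if u < params.p_len33:
        return 33
    if u < params.p_len33 + params.p_len_other:
        return 31 if rng.random() < 0.5 else 34
    return 32


def _capture_hit(
    plasmid: CircularSequence,
    strand: str,
    pam_pos: int,
    rng: np.random.Generator,
    params: SimParams,
) -> ProtospacerHit:
    """Excise a protospacer at a PAM (-1 base at ``pam_pos``), with slippage."""
    k = _draw_length(rng, params)
    p = pam_pos
    if rng.random() < params.p_slip:
        p = (p + (1 if rng.random() < 0.5 else -1)) % len(plasmid)
    if strand == "+":
        start = p - k
    else:
        start = p + 1
    return hit_from_interval(plasmid, strand, start % len(plasmid), k)


def _walk_captures(
    pool: np.ndarray,
    x: int,
    dirsign: int,
    travel: int,
    L: int,
    rng: np.random.Generator,
    p_capture: float,
) -> list[int]:
    """PAM -1 positions captured by a machine at ``x`` walking ``dirsign``.

    ``pool`` holds the PAM -1 positions readable on the ridden strand; the
    walk covers offsets 1..min(travel, L) from ``x`` in + direction
    ``dirsign`` (at most one full turn around the circle).
    """
    if pool.size == 0:
        return []
    off = ((pool - x) * dirsign) % L
    reach = min(travel, L)
    in_span = (off >= 1) & (off <= reach)
    cand = pool[in_span]
    order = np.argsort(off[in_span])
    cand = cand[order]
    taken = rng.random(cand.size) < p_capture
    return [int(c) for c in cand[taken]]


def simulate_priming(
    plasmid: CircularSequence,
    site: PrimedSite,
    params: SimParams,
    n_cells: int = 100,
) -> list[list[AcquisitionEvent]]:
    """Simulate priming in ``n_cells`` independent cells.

    Returns one list of :class:`AcquisitionEvent` per cell, each event
    annotated with its mechanism leg and destination array.  Per-cell RNG
    streams are derived from ``params.seed`` and the cell index, so results
    do not depend on iteration order and are reproducible bit-for-bit.
    """
    L = len(plasmid)
    pams = scan_pams(plasmid, "GG")
    if pams["+"].size == 0 and pams["-"].size == 0:
        warnings.warn("no GG PAM anywhere on the plasmid; cells acquire nothing", stacklevel=2)

    ts = site.protospacer.strand
    nts = "-" if ts == "+" else "+"
    if ts == "-":
        nts_start = site.protospacer.start  # walk 3'->5' on + = decreasing coords
        nts_dir = -1
    else:
        nts_start = site.protospacer.end % L  # walk 3'->5' on - = increasing coords
        nts_dir = +1
    ts_dir = -nts_dir  # TS machines run 3'->5' on the TS, opposite + direction

    cells: list[list[AcquisitionEvent]] = []
    for c in range(n_cells):
        rng = np.random.default_rng([params.seed, c])
        target = min(rng.geometric(params.event_geom_p), params.max_events_per_cell)
        raw: list[tuple[str, ProtospacerHit]] = []
        rounds = 0
        while (len(raw) < target or rounds < _MIN_ROUNDS) and rounds < _MAX_ROUNDS:
            rounds += 1
            round_events: list[tuple[str, ProtospacerHit]] = []
            # leg 1: one machine on the displaced non-target strand
            t1 = int(rng.geometric(1.0 / params.proc_mean))
            for p in _walk_captures(pams[nts], nts_start, nts_dir, t1, L, rng, params.p_capture):
                round_events.append((LEG_NTS, _capture_hit(plasmid, nts, p, rng, params)))
            # leg 2: machines loading on the exposed target-strand span
            span = min(t1, L)
            for _ in range(rng.poisson(params.lambda_ts)):
                u = (nts_start + nts_dir * int(rng.integers(1, span + 1))) % L
                t2 = int(rng.geometric(1.0 / params.proc_mean))
                for p in _walk_captures(pams[ts], u, ts_dir, t2, L, rng, params.p_capture):
                    round_events.append((LEG_TS, _capture_hit(plasmid, ts, p, rng, params)))
            raw.extend(round_events)
        # background: one off-pathway capture at a uniform PAM, either strand
        if rng.random() < params.p_bg:
            all_pams = [("+", int(p)) for p in pams["+"]] + [("-", int(p)) for p in pams["-"]]
            if all_pams:
                s, p = all_pams[int(rng.integers(len(all_pams)))]
                raw.append((LEG_BG, _capture_hit(plasmid, s, p, rng, params)))
        order = rng.permutation(len(raw))[:target]
        raw = [raw[i] for i in order]
        events = []
        for i, (leg, hit) in enumerate(raw):
            hit.hit_id = f"PIM{c:03d}.{i}"
            dest = ARRAYS[int(rng.choice(3, p=np.asarray(params.array_weights, float)))]
            events.append(
                AcquisitionEvent(cell_id=f"PIM{c:03d}", leg=leg, hit=hit, dest_array=dest, order_index=i)
            )
        cells.append(events)
    return cells


# ---------------------------------------------------------------------------
# Rendering clone arrays


@dataclass
class CRISPRArrayModel:
    """Wild-type model of one array: repeat consensus + ordered spacers."""

    array_id: str
    repeat_consensus: str
    wt_spacers: list[str]

    def __post_init__(self) -> None:
        if self.array_id not in ARRAYS:
            raise ValueError(f"unknown array {self.array_id!r}")
        if len(self.repeat_consensus) < 20:
            raise ValueError("repeat consensus shorter than 20 nt")


# Type I-F repeat (28 nt); CRISPR3 repeats differ slightly from CRISPR1/2.
REPEAT_IF = "GTTCACTGCCGTATAGGCAGCTAAGAAA"
REPEAT_IF_VARIANT = "GTTCACTGCCGCATAGGCAGCTAAGAAA"

WT_SPACER_COUNTS = {"CRISPR1": 28, "CRISPR2": 10, "CRISPR3": 3}


def default_array_models(seed: int = 7) -> dict[str, CRISPRArrayModel]:
    """Wild-type three-array models with 28/10/3 random 32-nt spacers."""
    rng = np.random.default_rng(seed)
    models = {}
    for aid, n in WT_SPACER_COUNTS.items():
        spacers = ["".join(rng.choice(list("ACGT"), size=32)) for _ in range(n)]
        repeat = REPEAT_IF_VARIANT if aid == "CRISPR3" else REPEAT_IF
        models[aid] = CRISPRArrayModel(array_id=aid, repeat_consensus=repeat, wt_spacers=spacers)
    return models


def render_amplicon(repeat: str, spacers: list[str]) -> str:
    """Leader-to-trailer array amplicon: repeat + (spacer + repeat)*."""
    return repeat + "".join(s + repeat for s in spacers)


def build_pim_arrays(
    cells: list[list[AcquisitionEvent]],
    array_models: dict[str, CRISPRArrayModel],
    seed: int = 0,
):
    """Render per-clone array amplicons and the matching truth table.

    New spacers are inserted at the leader-proximal end in acquisition order,
    so the most recent acquisition is closest to the leader.  Returns
    ``(genotypes, amplicons, truth)`` where ``amplicons`` is a list of
    Bio.SeqRecord (ids ``PIM<k>|CRISPR<a>``, one per clone per array) and
    ``truth`` a pandas DataFrame of all events.  ``seed`` is accepted for
    interface symmetry; rendering itself is deterministic.
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    from .arrays import PIMGenotype

    genotypes: list[PIMGenotype] = []
    amplicons: list[SeqRecord] = []
    truth_rows = []
    for idx, events in enumerate(cells):
        cell_id = events[0].cell_id if events else f"PIM{idx:03d}"
        new_by_array: dict[str, list[str]] = {a: [] for a in ARRAYS}
        for ev in sorted(events, key=lambda e: e.order_index):
            if ev.dest_array not in ARRAYS:
                raise ValueError(f"unknown destination array {ev.dest_array!r}")
            # leader-proximal insertion: newest first
            new_by_array[ev.dest_array].insert(0, ev.hit.seq)
            truth_rows.append(
                {
                    "cell_id": ev.cell_id,
                    "order_index": ev.order_index,
                    "leg": ev.leg,
                    "strand": ev.hit.strand,
                    "start": ev.hit.start,
                    "end": ev.hit.end,
                    "pam": ev.hit.pam,
                    "pam_class": ev.hit.pam_class,
                    "dest_array": ev.dest_array,
                    "spacer_seq": ev.hit.seq,
                }
            )
        arrays = {
            a: new_by_array[a] + list(array_models[a].wt_spacers) for a in ARRAYS
        }
        genotypes.append(
            PIMGenotype(
                pim_id=cell_id,
                replicate_id="",
                arrays=arrays,
                new_spacers={a: list(new_by_array[a]) for a in ARRAYS},
            )
        )
        for a in ARRAYS:
            amp = render_amplicon(array_models[a].repeat_consensus, arrays[a])
            amplicons.append(
                SeqRecord(Seq(amp), id=f"{cell_id}|{a}", description="")
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "cell_id", "order_index", "leg", "strand", "start", "end",
            "pam", "pam_class", "dest_array", "spacer_seq",
        ],
    )
    return genotypes, amplicons, truth


def params_to_dict(params: SimParams) -> dict:
    d = asdict(params)
    d["array_weights"] = list(d["array_weights"])
    return d
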