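"""Parsing CRISPR array amplicons and counting acquisitions.

An amplicon, oriented leader->trailer, is a run of near-identical direct
repeats separated by spacers.  Newly acquired spacers form a leader-proximal
prefix absent from the wild-type array; everything below them must match the
wild-type spacer order exactly, otherwise the amplicon is misassembled or was
matched against the wrong array model.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .seq import revcomp

ARRAYS = ("CRISPR1", "CRISPR2", "CRISPR3")

MIN_SPACER_GAP = 20
MAX_SPACER_GAP = 50


class NoArrayError(ValueError):
    """No repeats were found in the amplicon."""


class ArrayMismatchError(ValueError):
    """The observed spacers below the new prefix do not match the WT model."""


@dataclass
class SpacerCall:
    seq: str
    start: int
    end: int
    anomalous: bool = False


@dataclass
class PIMGenotype:
    """One clone's three-array spacer state (unit of independence counting)."""

    pim_id: str
    replicate_id: str
    arrays: dict[str, list[str]]
    new_spacers: dict[str, list[str]]


# ---------------------------------------------------------------------------


def find_repeats(
    amplicon: str, repeat_consensus: str, max_mismatch: int = 3
) -> list[tuple[int, int]]:
    """Greedy left-to-right scan for direct repeats.

    Returns non-overlapping ``(start, end)`` intervals, each within Hamming
    distance ``max_mismatch`` of the consensus.  An amplicon without repeats
    yields an empty list ("no-array").
    """
    rl = len(repeat_consensus)
    if rl < 20:
        raise ValueError("repeat consensus shorter than 20 nt")
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    amplicon = amplicon.upper()
    if len(amplicon) < rl:
        return []
    arr = np.frombuffer(amplicon.encode(), np.uint8)
    win = np.lib.stride_tricks.sliding_window_view(arr, rl)
    mism = (win != np.frombuffer(repeat_consensus.encode(), np.uint8)).sum(axis=1)
    candidates = np.flatnonzero(mism <= max_mismatch)
    intervals: list[tuple[int, int]] = []
    cursor = 0
    for pos in candidates:
        if pos >= cursor:
            intervals.append((int(pos), int(pos) + rl))
            cursor = int(pos) + rl
    return intervals


def extract_spacers(amplicon: str, repeat_intervals: list[tuple[int, int]]) -> list[SpacerCall]:
    """Inter-repeat segments, in leader->trailer order.

    Flanks outside the first/last repeat are discarded.  Gaps shorter than
    20 bp or longer than 50 bp are retained but flagged anomalous.
    """
    if len(repeat_intervals) < 2:
        raise ValueError("need at least 2 repeat intervals to extract spacers")
    spacers = []
    for (_, e1), (s2, _) in zip(repeat_intervals, repeat_intervals[1:]):
        gap = s2 - e1
        spacers.append(
            SpacerCall(
                seq=amplicon[e1:s2],
                start=e1,
                end=s2,
                anomalous=not MIN_SPACER_GAP <= gap <= MAX_SPACER_GAP,
            )
        )
    return spacers


def identify_new_spacers(observed: list[str], model) -> list[str]:
    """Leader-proximal spacers absent from the wild-type array.

    Finds the shortest prefix of ``observed`` whose removal leaves a
    non-empty list exactly matching the leader-proximal wild-type spacers
    covered by the amplicon.  Raises :class:`NoArrayError` on empty input and
    :class:`ArrayMismatchError` when no suffix anchors to the model (wrong
    model, or a mutated WT spacer — exact matching is deliberate).
    """
    if not observed:
        raise NoArrayError("no spacers observed")
    wt = list(model.wt_spacers)
    n = len(observed)
    for k in range(n):  # suffix must be non-empty: the amplicon reaches into WT
        tail = observed[k:]
        if len(tail) <= len(wt) and tail == wt[: len(tail)]:
            return list(observed[:k])
    raise ArrayMismatchError(
        f"observed spacers do not terminate in a wild-type prefix of {model.array_id}"
    )


def parse_amplicons(
    records,
    array_models: dict,
    max_mismatch: int = 3,
    auto_orient: bool = True,
) -> tuple[list[PIMGenotype], list[dict]]:
    """Parse amplicon FASTA records (ids ``<pim>|<array>``) into genotypes.

    Per-record failures (no-array, array-mismatch, anomalous spacers) are
    collected and reported, not fatal.  Returns ``(genotypes, problems)``.
    """
    by_pim: dict[str, dict[str, list[str]]] = {}
    problems: list[dict] = []
    for rec in records:
        rid = rec.id
        try:
            pim_id, array_id = rid.split("|", 1)
        except ValueError:
            problems.append({"record": rid, "error": "malformed id (expected PIM|ARRAY)"})
            continue
        if array_id not in array_models:
            problems.append({"record": rid, "error": f"unknown array {array_id!r}"})
            continue
        model = array_models[array_id]
        seq = str(rec.seq).upper()
        reps = find_repeats(seq, model.repeat_consensus, max_mismatch)
        if not reps and auto_orient:
            seq = revcomp(seq)
            reps = find_repeats(seq, model.repeat_consensus, max_mismatch)
        if not reps:
            problems.append({"record": rid, "error": "no-array"})
            continue
        if len(reps) < 2:
            problems.append({"record": rid, "error": "single repeat; no spacers"})
            continue
        calls = extract_spacers(seq, reps)
        for c in calls:
            if c.anomalous:
                problems.append(
                    {"record": rid, "error": f"anomalous-spacer ({len(c.seq)} bp at {c.start})"}
                )
        spacers = [c.seq for c in calls]
        by_pim.setdefault(pim_id, {})[array_id] = spacers

    genotypes = []
    for pim_id in sorted(by_pim):
        arrays: dict[str, list[str]] = {}
        new: dict[str, list[str]] = {}
        for array_id, model in array_models.items():
            observed = by_pim[pim_id].get(array_id, [])
            if not observed:
                arrays[array_id] = []
                new[array_id] = []
                continue
            try:
                new_sp = identify_new_spacers(observed, model)
            except ArrayMismatchError as exc:
                problems.append({"record": f"{pim_id}|{array_id}", "error": str(exc)})
                continue
            arrays[array_id] = observed
            new[array_id] = new_sp
        genotypes.append(
            PIMGenotype(pim_id=pim_id, replicate_id="", arrays=arrays, new_spacers=new)
        )
    return genotypes, problems


# ---------------------------------------------------------------------------
# Activity summaries


def summarize_array_activity(genotypes: list[PIMGenotype]) -> dict[str, pd.DataFrame]:
    """Acquisition-activity tables across a set of clones.

    * ``per_array`` — total new spacers per array and integer percentages.
    * ``arrays_with_k`` — number of arrays containing k >= 1 new spacers.
    * ``pims_with_total`` — number of clones with a given total of new spacers.
    * ``combinations`` — percentage of clones by which arrays were expanded.
    """
    if not genotypes:
        raise ValueError("need at least one genotype")
    per_array = {a: 0 for a in ARRAYS}
    k_counter: Counter[int] = Counter()
    total_counter: Counter[int] = Counter()
    combo_counter: Counter[str] = Counter()
    for g in genotypes:
        total = 0
        expanded = []
        for a in ARRAYS:
            n = len(g.new_spacers.get(a, []))
            per_array[a] += n
            total += n
            if n >= 1:
                k_counter[n] += 1
                expanded.append(a)
        total_counter[total] += 1
        combo_counter["+".join(expanded) if expanded else "none"] += 1

    grand = sum(per_array.values())
    per_array_df = pd.DataFrame(
        {
            "new_spacers": [per_array[a] for a in ARRAYS],
            "percent": [
                int(round(100.0 * per_array[a] / grand)) if grand else 0 for a in ARRAYS
            ],
        },
        index=pd.Index(ARRAYS, name="array"),
    )
    arrays_with_k = pd.DataFrame(
        sorted(k_counter.items()), columns=["new_spacers_in_array", "n_arrays"]
    )
    pims_with_total = pd.DataFrame(
        sorted(total_counter.items()), columns=["total_new_spacers", "n_pims"]
    )
    combos = pd.DataFrame(
        sorted(combo_counter.items()), columns=["arrays_expanded", "n_pims"]
    )
    combos["percent"] = [
        int(round(100.0 * n / len(genotypes))) for n in combos["n_pims"]
    ]
    return {
        "per_array": per_array_df,
        "arrays_with_k": arrays_with_k,
        "pims_with_total": pims_with_total,
        "combinations": combos,
    }


def count_independent_events(genotypes: list[PIMGenotype]) -> int:
    """Lower bound on independent incorporation events.

    An event is identified by the triple (array, spacer sequence, ordered
    list of spacers below it at insertion time).  Identical triples across
    clones could be ancestors or siblings and are counted once, so the count
    of distinct triples is a lower bound on independent acquisitions.
    """
    triples = set()
    for g in genotypes:
        for a, new in g.new_spacers.items():
            arr = g.arrays.get(a, [])
            n_new = len(new)
            for i in range(n_new):
                triples.add((a, arr[i], tuple(arr[i + 1 :])))
    return len(triples)
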