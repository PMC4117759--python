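"""Protospacer distribution statistics on a circular replicon.

Conventions that matter here:

* Signed distance ``d`` is midpoint-to-midpoint, reduced to the circular
  range ``(-L/2, L/2]``, positive in the direction of increasing + strand
  coordinate.
* TS (target strand) is the strand carrying the primed protospacer; NTS is
  its complement.  A hit is labelled TS when it lies on the same strand as
  the primed protospacer.
* 5'/3' is evaluated on the *hit's own strand*: a hit at lower + coordinate
  than the primed site is 5' of it when the hit is on the + strand, but 3'
  of it when the hit is on the - strand.  This follows the convention that
  the two strands run in opposite directions, and it is the single most
  error-prone convention in this analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mapping import PAM_CONSENSUS, ProtospacerHit
from .seq import CircularSequence, revcomp

TS = "TS"
NTS = "NTS"
FIVE_PRIME = "5prime"
THREE_PRIME = "3prime"

BASES = ("A", "C", "G", "T")


# ---------------------------------------------------------------------------
# PAM landscape


def scan_pams(plasmid: CircularSequence, motif: str = "GG") -> dict[str, np.ndarray]:
    """All occurrences of a PAM motif on each strand.

    The motif is read 5'->3' on each strand, so its first base is the -1
    position; reported positions are the + strand coordinate of that -1 base.
    Overlapping occurrences count separately; occurrences spanning the
    circular junction are included iff the plasmid is circular.
    """
    m = len(motif)
    L = len(plasmid)
    n_offsets = L if plasmid.circular else max(L - m + 1, 0)

    def _scan(text: str) -> np.ndarray:
        arr = np.frombuffer((text * 2 if plasmid.circular else text).encode(), np.uint8)
        if len(arr) < m:
            return np.empty(0, dtype=int)
        win = np.lib.stride_tricks.sliding_window_view(arr, m)[:n_offsets]
        q = np.frombuffer(motif.encode(), np.uint8)
        return np.flatnonzero((win == q).all(axis=1))

    plus = _scan(plasmid.seq)
    # - strand: offset r in the reverse complement puts the -1 base at L-1-r
    minus_rc = _scan(revcomp(plasmid.seq))
    minus = np.sort((L - 1 - minus_rc) % L) if minus_rc.size else minus_rc
    return {"+": np.sort(plus), "-": minus}


# ---------------------------------------------------------------------------
# Signed circular distances


@dataclass
class DistanceRecord:
    """Displacement of one hit from the primed protospacer."""

    hit_id: str
    d: float
    hit_strand: str
    ts_label: str
    dir_label: str


def circular_signed_diff(a: float, b: float, L: int) -> float:
    """Signed displacement a - b on a circle of length L, in (-L/2, L/2]."""
    d = (a - b) % L
    if d > L / 2:
        d -= L
    return d


def signed_distance(hit: ProtospacerHit, site, L: int | None = None) -> DistanceRecord:
    """Distance record of ``hit`` relative to a primed site.

    ``site`` is a :class:`~crisprprime.simulate.PrimedSite` (anything with a
    ``.protospacer`` hit).  Ambiguously placed hits are rejected: distance
    statistics need a unique locus.
    """
    if hit.ambiguous:
        raise ValueError(f"hit {hit.hit_id or hit.seq[:8]} is ambiguous; no unique distance")
    pps = site.protospacer
    if L is None:
        raise ValueError("plasmid length L is required")
    d = circular_signed_diff(hit.midpoint % L, pps.midpoint % L, L)
    ts_label = TS if hit.strand == pps.strand else NTS
    if d == 0:
        dir_label = ""  # reserved for the primed site itself
    elif (hit.strand == "+") == (d < 0):
        dir_label = FIVE_PRIME
    else:
        dir_label = THREE_PRIME
    return DistanceRecord(
        hit_id=hit.hit_id, d=d, hit_strand=hit.strand, ts_label=ts_label, dir_label=dir_label
    )


def strand_direction_summary(records: list[DistanceRecord]) -> dict[str, pd.DataFrame]:
    """TS/NTS x 5'/3' contingency table with percentages and marginals.

    Returns ``{"counts": ..., "percent": ...}``; percentages are of all
    records, so the four cells sum to 100 (up to rounding) and the ``total``
    column holds the TS/NTS marginals.  Empty input yields NaN percentages.
    """
    counts = pd.DataFrame(
        0, index=pd.Index([TS, NTS], name="strand"), columns=[FIVE_PRIME, THREE_PRIME]
    )
    for r in records:
        if r.dir_label:
            counts.loc[r.ts_label, r.dir_label] += 1
    counts["total"] = counts.sum(axis=1)
    n = counts["total"].sum()
    percent = 100.0 * counts / n if n else counts * np.nan
    return {"counts": counts, "percent": percent}


def summarize_experiments(record_sets: list[list[DistanceRecord]]) -> dict[str, pd.DataFrame]:
    """Mean and standard deviation of the percentage table across experiments."""
    tables = [strand_direction_summary(rs)["percent"] for rs in record_sets]
    stacked = pd.concat(tables, keys=range(len(tables)))
    grouped = stacked.groupby(level=1, sort=False)
    return {"mean": grouped.mean(), "sd": grouped.std(ddof=1)}


# ---------------------------------------------------------------------------
# Shifting-window densities


def window_density(
    hits: list[ProtospacerHit],
    pam_positions: dict[str, np.ndarray],
    L: int,
    site=None,
    window_frac: float = 0.05,
    step_frac: float = 0.01,
) -> pd.DataFrame:
    """PAM-normalized protospacer density in circular shifting windows.

    Windows of ``round(window_frac * L)`` bp slide by ``round(step_frac * L)``
    bp around the plasmid.  Each row reports the window center, its signed
    displacement from the primed site (when given), per-strand and total PAM
    counts, the number of protospacer midpoints, and the ratio
    protospacers/PAMs (NaN, not zero, where the window has no PAM).
    """
    if not 0 < window_frac <= 0.5:
        raise ValueError("window_frac must be in (0, 0.5]")
    if step_frac > window_frac:
        raise ValueError("step_frac must not exceed window_frac")
    w = max(1, round(window_frac * L))
    step = max(1, round(step_frac * L))
    origin = site.protospacer.midpoint % L if site is not None else 0.0
    centers = (origin + np.arange(0, L, step)) % L

    mids = np.array([h.midpoint % L for h in hits], dtype=float)
    rows = []
    for c in centers:
        lo = c - w / 2.0

        def _in(pos: np.ndarray) -> int:
            return int(((pos - lo) % L < w).sum()) if len(pos) else 0

        pam_p = _in(pam_positions["+"])
        pam_m = _in(pam_positions["-"])
        ps = _in(mids)
        pam_t = pam_p + pam_m
        rows.append(
            {
                "center": c,
                "displacement": circular_signed_diff(c, origin, L),
                "window_bp": w,
                "pam_plus": pam_p,
                "pam_minus": pam_m,
                "pam_count": pam_t,
                "ps_count": ps,
                "ratio": ps / pam_t if pam_t else np.nan,
            }
        )
    return pd.DataFrame(rows).sort_values("displacement").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Clustering permutation test


def clustering_test(
    records: list[DistanceRecord],
    pam_positions: dict[str, np.ndarray],
    site,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test of protospacer clustering near the primed site.

    The statistic is the mean |d| over records.  The null draws the same
    number of positions per strand uniformly *without replacement* from the
    GG PAM landscape and recomputes the statistic; the p-value is
    ``(1 + #{null <= observed}) / (n_perm + 1)`` (small mean |d| = clustered).
    """
    if len(records) < 5:
        raise ValueError("need at least 5 unambiguous records")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    L = len(pam_positions["+"]) + len(pam_positions["-"])  # only for error msg
    per_strand = {s: sum(1 for r in records if r.hit_strand == s) for s in ("+", "-")}
    for s, need in per_strand.items():
        if need > len(pam_positions[s]):
            raise ValueError(
                f"{need} records on strand {s} but only {len(pam_positions[s])} PAMs "
                f"({L} total): null is not samplable without replacement"
            )
    observed = float(np.mean([abs(r.d) for r in records]))

    rng = np.random.default_rng(seed)
    origin = site.protospacer.midpoint
    null_means = np.empty(n_perm)
    Lrep = getattr(site, "plasmid_length", None)
    if Lrep is None:
        raise ValueError("site must carry plasmid_length for the permutation null")
    # absolute circular distances from the site for the whole landscape, once
    abs_d = {}
    for s in ("+", "-"):
        pos = np.asarray(pam_positions[s], dtype=float)
        d = (pos - origin) % Lrep
        d = np.where(d > Lrep / 2, d - Lrep, d)
        abs_d[s] = np.abs(d)
    for i in range(n_perm):
        draws = []
        for s in ("+", "-"):
            if per_strand[s]:
                idx = rng.choice(len(abs_d[s]), size=per_strand[s], replace=False)
                draws.append(abs_d[s][idx])
        null_means[i] = np.mean(np.concatenate(draws))
    p = (1.0 + np.sum(null_means <= observed)) / (n_perm + 1.0)
    return observed, float(p)


# ---------------------------------------------------------------------------
# Flank sequence logos


@dataclass
class LogoMatrix:
    """Position frequency matrix over the 8-nt 5' and 3' protospacer flanks.

    ``freq`` is a 16 x 4 DataFrame (rows ``5:-8`` .. ``5:-1`` then ``3:-1``
    .. ``3:-8``; ``3:-1`` is the PAM -1 position).  ``info_bits`` is the
    per-position information content 2 - H (Shannon, uniform background, no
    small-sample correction), in [0, 2].
    """

    freq: pd.DataFrame
    info_bits: pd.Series
    n: int


LOGO_POSITIONS = [f"5:-{i}" for i in range(8, 0, -1)] + [f"3:-{i}" for i in range(1, 9)]


def flank_logo(hits: list[ProtospacerHit]) -> LogoMatrix:
    """Frequency matrix and information content of the 16 flank positions."""
    if not hits:
        raise ValueError("no hits to build a logo from")
    cols = []
    for h in hits:
        if len(h.flank5) < 8 or len(h.flank3) < 8:
            raise ValueError("flanks must be complete 8-mers")
        cols.append(h.flank5 + h.flank3)
    mat = np.array([list(c) for c in cols])
    freq = pd.DataFrame(
        [[np.mean(mat[:, j] == b) for b in BASES] for j in range(16)],
        index=pd.Index(LOGO_POSITIONS, name="position"),
        columns=list(BASES),
    )
    p = freq.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    info = pd.Series(2.0 + plogp.sum(axis=1), index=freq.index, name="info_bits")
    return LogoMatrix(freq=freq, info_bits=info, n=len(hits))


def flank_logos_by_length(hits: list[ProtospacerHit]) -> dict[int, LogoMatrix]:
    """Logos of consensus-PAM hits grouped by protospacer length."""
    groups: dict[int, list[ProtospacerHit]] = {}
    for h in hits:
        if h.pam_class == PAM_CONSENSUS:
            groups.setdefault(h.length, []).append(h)
    return {ln: flank_logo(grp) for ln, grp in sorted(groups.items())}


# ---------------------------------------------------------------------------
# Processivity recovery


@dataclass
class ProcessivityFit:
    mean_bp: float
    ci_low: float
    ci_high: float
    n: int
    small_sample: bool


def fit_processivity(
    nts_distances, n_boot: int = 200, seed: int = 0, min_n: int = 30
) -> ProcessivityFit:
    """ML mean of a geometric travel model fitted to NTS-leg capture distances.

    Under a memoryless per-bp fall-off the capture distances are geometric on
    {1, 2, ...}; the maximum-likelihood success probability is 1/mean, so the
    fitted mean travel is the sample mean.  A percentile bootstrap interval
    is attached; with fewer than ``min_n`` distances the fit carries a
    small-sample flag because the interval is unreliable.
    """
    d = np.asarray(list(nts_distances), dtype=float)
    if d.size == 0:
        raise ValueError("no distances supplied")
    if (d <= 0).any():
        raise ValueError("distances must be positive")
    est = float(d.mean())
    rng = np.random.default_rng(seed)
    boots = np.array([d[rng.integers(0, d.size, d.size)].mean() for _ in range(n_boot)])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    small = d.size < min_n
    if small:
        warnings.warn(
            f"processivity fitted from only {d.size} distances; interval is unreliable",
            stacklevel=2,
        )
    return ProcessivityFit(est, float(lo), float(hi), int(d.size), small)
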