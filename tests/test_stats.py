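"""Distance, window, logo, clustering and processivity statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import crisprprime as cp
from crisprprime.mapping import ProtospacerHit
from crisprprime.seq import CircularSequence, revcomp
from crisprprime.stats import DistanceRecord, circular_signed_diff


def doubled_string_pam_count(seq, motif="GG"):
    """Oracle: occurrences in the doubled sequence, offsets below L."""
    L = len(seq)
    dbl = seq * 2
    plus = [i for i in range(L) if dbl[i : i + len(motif)] == motif]
    rc = revcomp(seq) * 2
    minus = [(L - 1 - r) % L for r in range(L) if rc[r : r + len(motif)] == motif]
    return sorted(plus), sorted(minus)


def test_scan_pams_linear_overlaps():
    pl = CircularSequence("x", "GGGG", circular=False)
    pams = cp.scan_pams(pl)
    assert list(pams["+"]) == [0, 1, 2]
    assert len(pams["-"]) == 0  # the - strand reads CCCC


def test_scan_pams_junction_spanning():
    pl = CircularSequence("x", "GAAAAG", circular=True)
    pams = cp.scan_pams(pl)
    assert list(pams["+"]) == [5]  # GG across the origin, -1 base at 5
    assert list(pams["-"]) == []


def test_scan_pams_minus_strand_position_is_minus1_base():
    # + strand CC at [10,12) is GG on -, read from + position 11 downward
    seq = ["A"] * 40
    seq[10:12] = "CC"
    pl = CircularSequence("x", "".join(seq))
    pams = cp.scan_pams(pl)
    assert list(pams["-"]) == [11]


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_scan_pams_matches_doubled_string_oracle(seed):
    pl = cp.generate_plasmid(int(np.random.default_rng(seed).integers(200, 2000)), 0.5, seed=seed)
    got = cp.scan_pams(pl)
    plus, minus = doubled_string_pam_count(pl.seq)
    assert list(got["+"]) == plus
    assert sorted(got["-"]) == minus


# ---------------------------------------------------------------------------
# Signed distances


def _point_hit(mid, strand="+", hid="h"):
    # a degenerate 0-length interval places the midpoint exactly at `mid`
    return ProtospacerHit(
        plasmid_id="p", strand=strand, start=mid, end=mid, seq="A",
        flank5="A" * 8, flank3="A" * 8, hit_id=hid,
    )


class _Site:
    def __init__(self, mid, strand, L):
        self.protospacer = _point_hit(mid, strand)
        self.plasmid_length = L


def test_signed_distance_plain_and_wrapped():
    site = _Site(500, "-", 1000)
    r = cp.signed_distance(_point_hit(600), site, 1000)
    assert r.d == 100 and r.ts_label == "NTS" and r.dir_label == "3prime"
    site2 = _Site(50, "-", 1000)
    r2 = cp.signed_distance(_point_hit(980), site2, 1000)
    assert r2.d == -70  # wraps the origin


def test_signed_distance_rejects_ambiguous_hits():
    h = _point_hit(10)
    h.ambiguous = True
    with pytest.raises(ValueError):
        cp.signed_distance(h, _Site(0, "+", 100), 100)


def test_signed_distance_antisymmetry_exhaustive_modulo_L():
    L = 40
    for a in range(L):
        for b in range(L):
            d1 = circular_signed_diff(a, b, L)
            d2 = circular_signed_diff(b, a, L)
            assert (d1 + d2) % L == 0
            if abs(d1) != L / 2:
                assert d1 == -d2


def test_direction_label_depends_on_hit_strand():
    site = _Site(500, "-", 1000)
    assert cp.signed_distance(_point_hit(400, "+"), site, 1000).dir_label == "5prime"
    assert cp.signed_distance(_point_hit(400, "-"), site, 1000).dir_label == "3prime"
    assert cp.signed_distance(_point_hit(600, "-"), site, 1000).dir_label == "5prime"


def test_strand_direction_summary_cells():
    recs = [
        DistanceRecord("a", -10, "+", "NTS", "5prime"),
        DistanceRecord("b", -20, "+", "NTS", "5prime"),
    ]
    out = cp.strand_direction_summary(recs)
    assert out["percent"].loc["NTS", "5prime"] == 100.0
    recs = [
        DistanceRecord("a", 10, "-", "TS", "5prime"),
        DistanceRecord("b", 20, "-", "TS", "5prime"),
        DistanceRecord("c", -10, "-", "TS", "3prime"),
        DistanceRecord("d", -20, "-", "TS", "3prime"),
    ]
    out = cp.strand_direction_summary(recs)
    assert out["percent"].loc["TS", "5prime"] == 50.0
    assert out["percent"].loc["TS", "3prime"] == 50.0
    assert out["counts"].to_numpy().sum() == 2 * len(recs)  # cells + marginal


def test_summary_conservation(sim_records):
    out = cp.strand_direction_summary(sim_records)
    assert out["counts"]["total"].sum() == len(sim_records)


def test_nts_5prime_dominates_under_the_model(sim_records):
    out = cp.strand_direction_summary(sim_records)["percent"]
    assert out.loc["NTS", "5prime"] > out.loc["NTS", "3prime"]


def test_multi_experiment_mean_sd(sim_records):
    half = len(sim_records) // 2
    out = cp.summarize_experiments([sim_records[:half], sim_records[half:]])
    assert out["mean"].shape == out["sd"].shape
    assert (out["mean"]["total"] >= 0).all()


# ---------------------------------------------------------------------------
# Shifting windows


def test_window_density_zero_hits():
    pl = cp.generate_plasmid(1000, 0.5, seed=1)
    pams = cp.scan_pams(pl)
    df = cp.window_density([], pams, 1000, site=_Site(0, "+", 1000))
    assert (df.loc[df["pam_count"] > 0, "ratio"] == 0).all()
    assert df.loc[df["pam_count"] == 0, "ratio"].isna().all()


def test_window_density_single_hit_ratio():
    # non-overlapping tiling, hit in exactly one window with p PAMs
    pl = cp.generate_plasmid(1000, 0.5, seed=2)
    pams = cp.scan_pams(pl)
    site = _Site(0, "+", 1000)
    df = cp.window_density(
        [_point_hit(125)], pams, 1000, site=site, window_frac=0.1, step_frac=0.1
    )
    row = df[df["ps_count"] == 1]
    assert len(row) == 1
    p = row["pam_count"].iloc[0]
    assert row["ratio"].iloc[0] == pytest.approx(1.0 / p)


def test_window_tiling_conserves_pam_total():
    pl = cp.generate_plasmid(1000, 0.5, seed=3)
    pams = cp.scan_pams(pl)
    df = cp.window_density([], pams, 1000, site=_Site(0, "+", 1000), window_frac=0.1, step_frac=0.1)
    assert df["pam_count"].sum() == len(pams["+"]) + len(pams["-"])
    assert df["pam_plus"].sum() == len(pams["+"])


def test_window_ratio_invariant_under_rotation():
    pl = cp.generate_plasmid(1000, 0.5, seed=4)
    pams = cp.scan_pams(pl)
    hits = [_point_hit(m) for m in (100, 220, 760)]
    a = cp.window_density(hits, pams, 1000, site=_Site(100, "+", 1000))
    # rotate the origin by 300: all positions shift, the site too
    shift = 300
    pams_r = {s: np.sort((p + shift) % 1000) for s, p in pams.items()}
    hits_r = [_point_hit((m + shift) % 1000) for m in (100, 220, 760)]
    b = cp.window_density(hits_r, pams_r, 1000, site=_Site((100 + shift) % 1000, "+", 1000))
    assert np.allclose(a["ratio"].fillna(-1), b["ratio"].fillna(-1))
    assert np.allclose(a["displacement"], b["displacement"])


# ---------------------------------------------------------------------------
# Clustering test


def test_clustering_statistic_is_mean_abs_distance():
    site = _Site(0, "+", 1000)
    recs = [
        DistanceRecord("a", -30, "+", "NTS", "5prime"),
        DistanceRecord("b", 50, "+", "NTS", "3prime"),
        DistanceRecord("c", 100, "-", "TS", "5prime"),
        DistanceRecord("d", -10, "+", "NTS", "5prime"),
        DistanceRecord("e", 60, "-", "TS", "5prime"),
    ]
    pams = {"+": np.arange(0, 1000, 10), "-": np.arange(5, 1000, 10)}
    stat, _ = cp.clustering_test(recs, pams, site, n_perm=99, seed=1)
    assert stat == pytest.approx(np.mean([30, 50, 100, 10, 60]))


def test_clustering_extreme_case_minimal_p():
    # records at the PAMs nearest the site: no null draw can beat them
    L = 1000
    site = _Site(0, "+", L)
    pams = {"+": np.sort(np.arange(1, 500, 7)), "-": np.empty(0, dtype=int)}
    nearest = np.sort(pams["+"])[:5]
    recs = [
        DistanceRecord(f"r{i}", circular_signed_diff(p, 0, L), "+", "NTS", "5prime")
        for i, p in enumerate(nearest)
    ]
    n_perm = 199
    stat, p = cp.clustering_test(recs, pams, site, n_perm=n_perm, seed=0)
    assert p == pytest.approx(1.0 / (n_perm + 1))


def test_clustering_requires_enough_pams():
    site = _Site(0, "+", 100)
    recs = [DistanceRecord(f"r{i}", i + 1, "+", "NTS", "3prime") for i in range(5)]
    with pytest.raises(ValueError):
        cp.clustering_test(recs, {"+": np.array([1, 2]), "-": np.array([])}, site, n_perm=99)


# ---------------------------------------------------------------------------
# Logos


def _logo_hit(flank5, flank3):
    return ProtospacerHit(
        plasmid_id="p", strand="+", start=0, end=32, seq="A" * 32,
        flank5=flank5, flank3=flank3, pam_class="consensus",
    )


def test_logo_consensus_gg_positions_reach_two_bits():
    rng = np.random.default_rng(0)
    hits = [
        _logo_hit(
            "".join(rng.choice(list("ACGT"), 8)),
            "GG" + "".join(rng.choice(list("ACGT"), 6)),
        )
        for _ in range(64)
    ]
    logo = cp.flank_logo(hits)
    assert logo.freq.loc["3:-1", "G"] == 1.0
    assert logo.freq.loc["3:-2", "G"] == 1.0
    assert logo.info_bits["3:-1"] == pytest.approx(2.0)
    assert logo.info_bits["3:-2"] == pytest.approx(2.0)
    assert (logo.freq.sum(axis=1) - 1.0).abs().max() < 1e-12


def test_logo_uniform_column_zero_bits_all_A_two_bits():
    hits = [_logo_hit(b * 8, "A" * 8) for b in "ACGT"]
    logo = cp.flank_logo(hits)
    assert logo.info_bits["5:-1"] == pytest.approx(0.0)
    assert logo.info_bits["3:-1"] == pytest.approx(2.0)
    assert logo.info_bits.between(0, 2).all()


def test_logo_invariant_under_hit_order(sim_records, sim_cells):
    hits = [e.hit for c in sim_cells for e in c][:200]
    a = cp.flank_logo(hits)
    rng = np.random.default_rng(1)
    shuffled = list(hits)
    rng.shuffle(shuffled)
    b = cp.flank_logo(shuffled)
    assert np.allclose(a.info_bits, b.info_bits)
    assert np.allclose(a.freq, b.freq)


# ---------------------------------------------------------------------------
# Processivity


def test_processivity_constant_distances():
    fit = cp.fit_processivity([400] * 100)
    assert fit.mean_bp == pytest.approx(400.0)
    assert not fit.small_sample


def test_processivity_recovers_geometric_mean():
    rng = np.random.default_rng(0)
    d = rng.geometric(1 / 500.0, size=5000)
    fit = cp.fit_processivity(d, seed=1)
    assert abs(fit.mean_bp - 500.0) / 500.0 < 0.2
    assert fit.ci_low < fit.mean_bp < fit.ci_high


def test_processivity_small_sample_warns():
    with pytest.warns(UserWarning):
        fit = cp.fit_processivity([10, 20, 30, 40, 50])
    assert fit.small_sample


def test_processivity_rejects_bad_input():
    with pytest.raises(ValueError):
        cp.fit_processivity([])
    with pytest.raises(ValueError):
        cp.fit_processivity([5, -1, 3])
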