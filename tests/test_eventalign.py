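"""Signal preprocessing: parsing, event collapsing, normalization, bagging."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nanomil as nm
from nanomil.eventalign import (DataInconsistencyError, EventalignFormatError,
                                NormalizationError)

HEADER = ("contig\tposition\treference_kmer\tread_index\tstrand\tevent_index\t"
          "event_level_mean\tevent_stdv\tevent_length\tmodel_kmer\n")


def tsv(rows):
    return io.StringIO(HEADER + "".join(rows))


def test_parse_single_row_passthrough():
    recs = list(nm.parse_eventalign(tsv(
        ["tx1\t7\tGGACT\tr1\tt\t0\t108.9\t2.5\t0.00166\tGGACT\n"])))
    assert len(recs) == 1
    r = recs[0]
    assert (r.transcript_id, r.position, r.read_id) == ("tx1", 7, "r1")
    assert r.event_mean == pytest.approx(108.9)
    assert r.event_dwell == pytest.approx(0.00166)


def test_parse_drops_unknown_model_kmer_sentinel():
    rows = [f"tx1\t{i}\tGGACT\tr1\tt\t{i}\t100\t2\t0.01\tNNNNN\n"
            for i in range(3)]
    assert list(nm.parse_eventalign(tsv(rows))) == []


def test_parse_canonicalizes_u_to_t():
    recs = list(nm.parse_eventalign(tsv(
        ["tx1\t7\tGGACU\tr1\tt\t0\t100\t2\t0.01\tggacu\n"])))
    assert recs[0].reference_fivemer == "GGACT"
    assert recs[0].model_fivemer == "GGACT"


def test_parse_missing_column_names_it():
    buf = io.StringIO("contig\tposition\n" "tx1\t3\n")
    with pytest.raises(EventalignFormatError, match="reference_kmer"):
        list(nm.parse_eventalign(buf))


def test_parse_bad_numeric_reports_line_number():
    rows = ["tx1\t7\tGGACT\tr1\tt\t0\t100\t2\t0.01\tGGACT\n",
            "tx1\t8\tGACTC\tr1\tt\t1\toops\t2\t0.01\tGACTC\n"]
    with pytest.raises(EventalignFormatError, match="line 3"):
        list(nm.parse_eventalign(tsv(rows)))


def test_parse_roundtrips_generator_output(tmp_path, small_sim):
    paths = small_sim.write(tmp_path)
    parsed = pd.DataFrame([r.__dict__ for r in
                           nm.parse_eventalign(paths["eventalign"])])
    assert len(parsed) == len(small_sim.events)
    np.testing.assert_allclose(parsed["event_mean"],
                               small_sim.events["event_level_mean"], rtol=1e-6)
    assert (parsed["reference_fivemer"]
            == small_sim.events["reference_kmer"]).all()


# ---------------------------------------------------------------------------
# collapsing


def rec(mean, sd, dwell, pos=7, fivemer="GGACT", read="r1"):
    return nm.EventRecord("tx1", pos, fivemer, read, mean, sd, dwell, fivemer)


def test_collapse_single_event_is_identity():
    obs = nm.collapse_events([rec(100.0, 2.0, 0.01)])
    assert (obs.mean, obs.sd, obs.dwell) == (100.0, 2.0, 0.01)
    assert obs.fivemer == "GGACT"


def test_collapse_weighted_mean_hand_computed():
    obs = nm.collapse_events([rec(90.0, 1.0, 0.01), rec(110.0, 1.0, 0.03)])
    assert obs.mean == pytest.approx((90 * 0.01 + 110 * 0.03) / 0.04)
    assert obs.dwell == pytest.approx(0.04)


def test_collapse_equal_dwells_is_arithmetic_mean():
    obs = nm.collapse_events([rec(m, 1.0, 0.02) for m in (90.0, 100.0, 110.0)])
    assert obs.mean == pytest.approx(100.0)


@settings(deadline=None, max_examples=50)
@given(mean=st.floats(50, 150), sd=st.floats(0.1, 5), dwell=st.floats(1e-4, 0.1),
       fracs=st.lists(st.floats(0.05, 1.0), min_size=1, max_size=5))
def test_collapse_split_invariance(mean, sd, dwell, fracs):
    """Subdividing an event while conserving stats and total dwell is a no-op."""
    whole = nm.collapse_events([rec(mean, sd, dwell)])
    w = np.array(fracs) / np.sum(fracs)
    parts = [rec(mean, sd, dwell * f) for f in w]
    split = nm.collapse_events(parts)
    assert split.mean == pytest.approx(whole.mean, rel=1e-9)
    assert split.sd == pytest.approx(whole.sd, rel=1e-9)
    assert split.dwell == pytest.approx(whole.dwell, rel=1e-9)


def test_collapse_conflicting_fivemers_raise():
    with pytest.raises(DataInconsistencyError):
        nm.collapse_events([rec(100, 2, 0.01),
                            rec(100, 2, 0.01, fivemer="GGACA")])


def test_filter_mismatches_predicate():
    assert nm.filter_mismatches("GGACT", "GGACT")
    assert not nm.filter_mismatches("GGACT", "GGATT")


def test_collapse_table_drops_exactly_injected_mismatches(small_sim, small_obs):
    events = small_sim.events
    groups = events.groupby(
        ["contig", "position", "read_index"], sort=False).ngroups
    dropped = groups - len(small_obs)
    assert dropped == len(small_sim.mismatch_truth)
    kept = set(map(tuple, small_obs[["transcript_id", "position", "read_id"]]
                   .itertuples(index=False)))
    for row in small_sim.mismatch_truth.itertuples(index=False):
        assert (row.transcript_id, row.position, row.read_id) not in kept


# ---------------------------------------------------------------------------
# normalization


def obs_frame(fivemer, means, sds=None, dwells=None):
    n = len(means)
    return pd.DataFrame({
        "transcript_id": "tx1", "position": np.arange(n), "fivemer": fivemer,
        "read_id": [f"r{i}" for i in range(n)], "mean": means,
        "sd": sds if sds is not None else np.ones(n),
        "dwell": dwells if dwells is not None else np.full(n, 0.01)})


def test_fit_normalization_flags_degenerate_variance():
    table = nm.fit_normalization(obs_frame("GGACT", [100.0] * 5,
                                           [2.0] * 5, [0.01] * 5))
    row = table.table.loc["GGACT"]
    assert row["mean_mu"] == pytest.approx(100.0)
    assert row["mean_sigma"] == 0.0
    assert not row["usable"]
    with pytest.raises(NormalizationError, match="GGACT"):
        table.entry("GGACT")


def test_fit_normalization_recovers_distribution_parameters():
    rng = np.random.default_rng(11)
    df = obs_frame("GGACT", rng.normal(105.0, 3.0, 10_000),
                   rng.normal(2.0, 0.3, 10_000),
                   rng.lognormal(-4.5, 0.3, 10_000))
    table = nm.fit_normalization(df)
    row = table.table.loc["GGACT"]
    assert row["mean_mu"] == pytest.approx(105.0, abs=0.1)
    assert row["mean_sigma"] == pytest.approx(3.0, abs=0.1)


def test_fit_normalization_groups_are_independent():
    rng = np.random.default_rng(12)
    a = obs_frame("GGACT", rng.normal(100, 2, 500))
    b = obs_frame("TGACC", rng.normal(120, 5, 500))
    table = nm.fit_normalization(pd.concat([a, b], ignore_index=True))
    for df, f in ((a, "GGACT"), (b, "TGACC")):
        assert table.table.loc[f, "mean_mu"] == pytest.approx(df["mean"].mean())
        assert table.table.loc[f, "mean_sigma"] == pytest.approx(
            df["mean"].std(ddof=1))


def test_znormalize_trivial_points():
    rng = np.random.default_rng(13)
    table = nm.fit_normalization(obs_frame("GGACT", rng.normal(100, 2, 50)))
    mu = table.table.loc["GGACT", "mean_mu"]
    sigma = table.table.loc["GGACT", "mean_sigma"]
    o = nm.ReadObservation("tx1", 0, "GGACT", "r1", mu, 1.0, 0.01)
    # sd/dwell table entries come from constant columns -> unusable; rebuild
    df = obs_frame("GGACT", rng.normal(100, 2, 50), rng.normal(2, .2, 50),
                   rng.lognormal(-4.5, .2, 50))
    table = nm.fit_normalization(df)
    mu = table.table.loc["GGACT", "mean_mu"]
    sigma = table.table.loc["GGACT", "mean_sigma"]
    z0 = nm.znormalize(nm.ReadObservation("tx1", 0, "GGACT", "r1", mu,
                                          df["sd"].mean(), 0.01), table)
    assert z0.mean == pytest.approx(0.0, abs=1e-12)
    z1 = nm.znormalize(nm.ReadObservation("tx1", 0, "GGACT", "r1", mu + sigma,
                                          df["sd"].mean(), 0.01), table)
    assert z1.mean == pytest.approx(1.0, abs=1e-12)


def test_full_dataset_normalization_is_exactly_standardizing(small_obs):
    table = nm.fit_normalization(small_obs)
    normed = nm.normalize_observations(small_obs, table)
    for f in ("mean", "sd", "dwell"):
        g = normed.groupby("fivemer")[f]
        assert np.abs(g.mean()).max() < 1e-9
        assert np.abs(g.std(ddof=1) - 1.0).max() < 1e-9


# ---------------------------------------------------------------------------
# bag assembly


def window_obs(reads_positions, center=10):
    """Observations for a GGACT site planted at positions 8..12 of a toy
    transcript; reads_positions maps read id -> positions carrying data."""
    seq = "CCCCCCCCGGACTCCCCCCCC"
    rows = []
    for rid, positions in reads_positions.items():
        for p in positions:
            rows.append({"transcript_id": "tx1", "position": p,
                         "fivemer": seq[p:p + 5], "read_id": rid,
                         "mean": 0.1, "sd": 0.2, "dwell": 0.3})
    return pd.DataFrame(rows), {"tx1": seq}


def test_incomplete_reads_are_excluded_from_bags():
    obs, seqs = window_obs({"r1": [7, 8, 9], "r2": [7, 8]})
    bags = nm.build_site_bags(obs, seqs, flank_width=1, min_reads=1)
    assert bags.n_sites == 1
    assert bags.index["n_reads"].iloc[0] == 1
    assert list(bags.read_ids) == ["r1"]
    assert bags.index["position"].iloc[0] == 10  # central A of GGACT
    assert bags.index["kmer"].iloc[0] == seqs["tx1"][7:14]


def test_flank_zero_bags_have_minimal_width():
    obs, seqs = window_obs({"r1": [8], "r2": [8]})
    bags = nm.build_site_bags(obs, seqs, flank_width=0, min_reads=1)
    assert bags.signals.shape == (2, 3)
    assert bags.kmer_idx.shape == (2, 1)


def test_site_near_transcript_end_is_skipped():
    seq = "GGACTCCC"  # center at 2; window at w=1 starts at position -1
    obs = pd.DataFrame([{"transcript_id": "tx1", "position": 0,
                         "fivemer": "GGACT", "read_id": "r1",
                         "mean": 0.0, "sd": 0.0, "dwell": 0.0}])
    bags = nm.build_site_bags(obs, {"tx1": seq}, flank_width=1, min_reads=1)
    assert bags.n_sites == 0


def test_bag_count_matches_generator_truth(small_sim, small_obs, small_bags):
    # truth: planted DRACH centers whose window is fully covered by >= 20 reads
    table = nm.fit_normalization(small_obs)
    normed = nm.normalize_observations(small_obs, table)
    expected = 0
    for site in small_sim.site_truth.itertuples(index=False):
        sub = normed[(normed["transcript_id"] == site.transcript_id) &
                     normed["position"].isin(
                         [site.position - 3, site.position - 2,
                          site.position - 1])]
        complete = sub.groupby("read_id").size() == 3
        expected += int(complete.sum() >= 20)
    assert small_bags.n_sites == expected
    got = set(map(tuple, small_bags.index[["transcript_id", "position"]]
                  .itertuples(index=False)))
    truth = set(map(tuple, small_sim.site_truth[["transcript_id", "position"]]
                    .itertuples(index=False)))
    assert got <= truth


def test_bags_only_contain_vocabulary_indices(small_bags):
    assert small_bags.kmer_idx.min() >= 0
    assert small_bags.kmer_idx.max() < len(small_bags.vocabulary)


def test_bag_dataset_roundtrip(tmp_path, small_bags):
    prefix = tmp_path / "bags"
    small_bags.save(prefix)
    loaded = nm.BagDataset.load(prefix)
    assert loaded.flank_width == small_bags.flank_width
    assert loaded.vocabulary == small_bags.vocabulary
    np.testing.assert_array_equal(loaded.signals, small_bags.signals)
    np.testing.assert_array_equal(loaded.kmer_idx, small_bags.kmer_idx)
    pd.testing.assert_frame_equal(loaded.index, small_bags.index)
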