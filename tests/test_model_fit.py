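"""Training, model selection, prediction and read-representation export."""

import numpy as np
import pandas as pd
import pytest

import nanomil as nm
from nanomil import network
from nanomil.model import ModelParameters

from conftest import split_bags


def read_truth_auc(results, bags, sim):
    reads = results.predict_reads(bags)
    truth = sim.read_truth.rename(columns={"position": "transcript_position"})
    merged = reads.merge(truth, on=["transcript_id", "transcript_position",
                                    "read_id"])
    roc, _, _ = nm.roc_pr_metrics(merged["probability_modified"],
                                  merged["modified"])
    return roc


def test_separable_data_reaches_high_validation_auc(trained):
    best = trained["results"].history["val_roc_auc"].max()
    assert best >= 0.95


def test_read_level_recovery_from_site_labels_only(trained):
    """Read probabilities discriminate hidden read labels the model never saw."""
    assert read_truth_auc(trained["results"], trained["bags"],
                          trained["sim"]) >= 0.9


def test_no_signal_training_stays_at_chance():
    cfg = nm.GeneratorConfig(n_transcripts=100, sites_per_transcript=3,
                             coverage=25, delta=(0.0, 0.0, 0.0), seed=4)
    sim = nm.simulate_dataset(cfg)
    obs = nm.collapse_table(sim.events)
    bags = nm.build_site_bags(nm.normalize_observations(
        obs, nm.fit_normalization(obs)), sim.sequences)
    train, val = split_bags(bags, sim.site_truth)
    results = nm.MILSiteModel(train, sim.site_truth, val, sim.site_truth,
                              nm.TrainingConfig(epochs=5, seed=5)).fit()
    final = results.history["val_roc_auc"].iloc[-1]
    assert 0.4 <= final <= 0.6


def test_same_config_and_seed_reproduce_training_bitwise(trained):
    model = nm.MILSiteModel(trained["train"], trained["sim"].site_truth,
                            trained["val"], trained["sim"].site_truth,
                            nm.TrainingConfig(epochs=3, seed=3))
    a = model.fit()
    b = nm.MILSiteModel(trained["train"], trained["sim"].site_truth,
                        trained["val"], trained["sim"].site_truth,
                        nm.TrainingConfig(epochs=3, seed=3)).fit()
    for key in a.params.weights:
        np.testing.assert_array_equal(a.params.weights[key],
                                      b.params.weights[key])
    pd.testing.assert_frame_equal(a.history, b.history)


def test_training_requires_modified_sites_and_validation():
    cfg = nm.GeneratorConfig(n_transcripts=6, coverage=25,
                             modified_fraction=0.0, seed=6)
    sim = nm.simulate_dataset(cfg)
    obs = nm.collapse_table(sim.events)
    bags = nm.build_site_bags(nm.normalize_observations(
        obs, nm.fit_normalization(obs)), sim.sequences)
    train, val = split_bags(bags, sim.site_truth)
    with pytest.raises(ValueError, match="modified"):
        nm.MILSiteModel(train, sim.site_truth, val, sim.site_truth)


# ---------------------------------------------------------------------------
# prediction


def test_prediction_invariants_on_exact_size_bags(trained):
    """Bags holding exactly reads_per_run reads make sampling degenerate."""
    bags = trained["bags"]
    n = int(bags.index["n_reads"].iloc[0])
    exact = [i for i in range(bags.n_sites)
             if bags.index["n_reads"].iloc[i] == n]
    assert exact, "fixture should contain equal-coverage bags"
    sub = bags.subset(exact)
    one = trained["results"].predict(sub, n_runs=1, reads_per_run=n, seed=0)
    five = trained["results"].predict(sub, n_runs=5, reads_per_run=n, seed=123)
    for a, b in zip(one, five):
        assert a.probability == b.probability
        # pooled probability matches the noisy-OR of the per-read values
        assert a.probability == pytest.approx(
            nm.noisy_or_pool(a.read_probabilities), abs=1e-12)
        assert a.probability >= a.read_probabilities.max()


def test_constant_read_probability_model_pools_in_closed_form(trained):
    p0 = 0.07
    params = trained["results"].params
    weights = {k: v.copy() for k, v in params.weights.items()}
    weights["W3"][:] = 0.0
    weights["b3"][:] = np.log(p0 / (1 - p0))
    const = nm.MILResults(
        ModelParameters(weights, params.flank_width, params.vocabulary,
                        params.hidden, params.embedding_dim),
        pd.DataFrame(), 0)
    preds = const.predict(trained["bags"], n_runs=1, seed=0)
    for p in preds:
        assert p.probability == pytest.approx(1 - (1 - p0) ** 20, rel=1e-9)


def test_prediction_is_deterministic_given_seed(trained):
    a = trained["results"].predict(trained["bags"], seed=11).site_frame()
    b = trained["results"].predict(trained["bags"], seed=11).site_frame()
    pd.testing.assert_frame_equal(a, b)


def test_small_bags_are_skipped_with_warning(trained):
    preds = trained["results"].predict(trained["bags"], min_reads=10_000)
    assert len(preds) == 0
    assert preds.skipped == trained["bags"].n_sites


def test_flank_width_mismatch_is_a_contract_error(trained, small_obs, small_sim):
    table = nm.fit_normalization(small_obs)
    normed = nm.normalize_observations(small_obs, table)
    w0 = nm.build_site_bags(normed, small_sim.sequences, flank_width=0,
                            min_reads=1)
    with pytest.raises(ValueError, match="flank width"):
        trained["results"].predict(w0)


# ---------------------------------------------------------------------------
# read representation export


def test_read_representation_shape_and_determinism(trained):
    table, h = trained["results"].read_representation(trained["bags"])
    assert h.shape == (trained["bags"].signals.shape[0],
                       trained["results"].params.hidden[1])
    assert len(table) == h.shape[0]
    # identical reads map to identical vectors
    bags = trained["bags"]
    dup_sig = np.vstack([bags.signals[:1], bags.signals[:1]])
    dup_kid = np.vstack([bags.kmer_idx[:1], bags.kmer_idx[:1]])
    _, h2 = network.read_probability(trained["results"].params.weights,
                                     dup_sig, dup_kid, return_hidden=True)
    np.testing.assert_array_equal(h2[0], h2[1])


def test_representation_separates_modified_reads_linearly(trained):
    from sklearn.decomposition import PCA
    from sklearn.metrics import silhouette_score

    table, h = trained["results"].read_representation(trained["bags"])
    truth = trained["sim"].read_truth.rename(
        columns={"position": "transcript_position"})
    merged = table.reset_index(drop=True).reset_index().merge(
        truth, on=["transcript_id", "transcript_position", "read_id"])
    labels = merged["modified"].to_numpy()
    proj = PCA(n_components=2, random_state=0).fit_transform(
        h[merged["index"].to_numpy()])
    assert silhouette_score(proj, labels) > 0


# ---------------------------------------------------------------------------
# checkpointing


def test_checkpoint_roundtrip_is_bit_exact(tmp_path, trained):
    path = tmp_path / "model.npz"
    trained["results"].params.read_threshold = 0.0333
    trained["results"].save(path)
    loaded = nm.MILResults.load(path)
    for key, val in trained["results"].params.weights.items():
        np.testing.assert_array_equal(loaded.params.weights[key], val)
    assert loaded.params.vocabulary == trained["results"].params.vocabulary
    assert loaded.params.read_threshold == 0.0333
    assert loaded.best_epoch == trained["results"].best_epoch
    a = trained["results"].predict(trained["bags"], seed=3).site_frame()
    b = loaded.predict(trained["bags"], seed=3).site_frame()
    pd.testing.assert_frame_equal(a, b)


def test_summary_reports_architecture(trained):
    text = trained["results"].summary()
    assert "150, 32" in text
    assert "66" in text
    assert "noisy-OR" in text
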