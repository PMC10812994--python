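import numpy as np
import pandas as pd
import pytest

from neurotx.synthetic import make_mask
from neurotx.transcriptome import (ExpressionSampleSet, GeneBySampleMatrix,
                                   aggregate_and_stabilize,
                                   differential_stability, handle_missing,
                                   intensity_filter, match_samples_to_mask,
                                   normalize, reannotate_probes,
                                   select_probes)


def _sample_set(intensity, background, annotations, coords=None, donors=None):
    n = intensity.shape[1]
    sample_ids = [f"S{i}" for i in range(n)]
    intensity = pd.DataFrame(intensity,
                             index=annotations["probe_id"][:intensity.shape[0]]
                             if len(annotations) >= intensity.shape[0]
                             else None, columns=sample_ids)
    coords = coords if coords is not None else np.zeros((n, 3))
    donors = donors if donors is not None else ["d1"] * n
    samples = pd.DataFrame({"sample_id": sample_ids, "donor": donors,
                            "x": coords[:, 0], "y": coords[:, 1],
                            "z": coords[:, 2], "structure": "syn"})
    return ExpressionSampleSet(samples, intensity,
                               pd.Series(background, index=intensity.index),
                               annotations)


class TestReannotate:
    def test_stale_symbol_revised_and_missing_dropped(self):
        ann = pd.DataFrame({"probe_id": ["p1", "p2", "p3"],
                            "gene_symbol": ["OLD_A", "B", "C"]})
        out = reannotate_probes(ann, {"p1": "A", "p2": "B"})
        assert list(out["probe_id"]) == ["p1", "p2"]
        assert list(out["gene_symbol"]) == ["A", "B"]

    def test_identity_map_keeps_everything(self):
        ann = pd.DataFrame({"probe_id": ["p1", "p2"],
                            "gene_symbol": ["A", "B"]})
        out = reannotate_probes(ann, {"p1": "A", "p2": "B"})
        assert list(out["gene_symbol"]) == ["A", "B"]

    def test_empty_result_rejected(self):
        ann = pd.DataFrame({"probe_id": ["p1"], "gene_symbol": ["A"]})
        with pytest.raises(ValueError):
            reannotate_probes(ann, {})


class TestIntensityFilter:
    def _set(self):
        ann = pd.DataFrame({"probe_id": ["p1", "p2", "p3"],
                            "gene_symbol": ["A", "B", "C"]})
        inten = np.array([
            [9.0] * 10,                      # always above background
            [9.0] * 4 + [1.0] * 6,           # above in 40% of samples
            [1.0] * 10,                      # never above
        ])
        return _sample_set(inten, [5.0, 5.0, 5.0], ann)

    def test_threshold_semantics(self):
        out = intensity_filter(self._set(), min_fraction=0.5)
        assert list(out.intensity.index) == ["p1"]

    def test_planted_low_probes_exactly_dropped(self):
        rng = np.random.default_rng(0)
        n_probes, n_samp = 50, 40
        low = rng.random(n_probes) < 0.1
        inten = np.where(low[:, None], 4.0, 9.0) \
            + 0.1 * rng.normal(size=(n_probes, n_samp))
        ann = pd.DataFrame({"probe_id": [f"p{i:02d}" for i in range(n_probes)],
                            "gene_symbol": [f"G{i:02d}" for i in range(n_probes)]})
        out = intensity_filter(_sample_set(inten, [6.0] * n_probes, ann))
        kept = set(out.intensity.index)
        expected = {f"p{i:02d}" for i in range(n_probes) if not low[i]}
        assert kept == expected

    def test_everything_filtered_raises(self):
        ann = pd.DataFrame({"probe_id": ["p1"], "gene_symbol": ["A"]})
        s = _sample_set(np.full((1, 5), 1.0), [9.0], ann)
        with pytest.raises(ValueError):
            intensity_filter(s)


class TestSelectProbes:
    def _multi_donor_set(self, seed=0):
        rng = np.random.default_rng(seed)
        n = 90
        coords = rng.uniform(-30, 30, size=(n, 3))
        donors = [f"d{1 + i % 3}" for i in range(n)]
        pattern = np.sin(coords[:, 0] / 8.0) + coords[:, 1] / 30.0
        signal = pattern + 0.1 * rng.normal(size=n)
        noise = rng.normal(size=n)
        ann = pd.DataFrame({"probe_id": ["pA_sig", "pA_noise"],
                            "gene_symbol": ["A", "A"]})
        inten = np.vstack([8 + signal, 8 + noise])
        return _sample_set(inten, [5.0, 5.0], ann, coords, donors)

    def test_single_probe_gene_kept(self):
        ann = pd.DataFrame({"probe_id": ["p1"], "gene_symbol": ["A"]})
        s = _sample_set(np.full((1, 6), 8.0), [5.0], ann)
        out = select_probes(s)
        assert list(out["probe_id"]) == ["p1"]

    def test_signal_probe_beats_noise_probe(self):
        hits = 0
        for seed in range(10):
            s = self._multi_donor_set(seed)
            out = select_probes(s)
            hits += (out.loc[out["gene_symbol"] == "A", "probe_id"].iloc[0]
                     == "pA_sig")
        assert hits >= 9

    def test_exact_tie_breaks_to_smaller_probe_id(self):
        ann = pd.DataFrame({"probe_id": ["pB", "pA"],
                            "gene_symbol": ["G", "G"]})
        inten = np.vstack([np.arange(6.0), np.arange(6.0)])  # identical
        s = _sample_set(inten, [0.0, 0.0], ann)
        out = select_probes(s, method="max_intensity")
        assert out["probe_id"].iloc[0] == "pA"


class TestMatchSamples:
    def test_exact_center_distance_zero_and_tolerance(self):
        mask = make_mask(shape=(10, 10, 10), seed=3)
        vox = mask.voxel_indices()[5]
        center = mask.grid.voxel_to_world(vox)[0]
        far = center + np.array([0.0, 0.0, 40.0])
        samples = pd.DataFrame({
            "sample_id": ["a", "b"], "donor": ["d1", "d1"],
            "x": [center[0], far[0]], "y": [center[1], far[1]],
            "z": [center[2], far[2]], "structure": "syn"})
        out = match_samples_to_mask(samples, mask, max_distance_mm=2.0)
        assert list(out["sample_id"]) == ["a"]
        assert out["distance_mm"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_array_equal(out[["i", "j", "k"]].iloc[0], vox)

    def test_hemisphere_filter_keeps_left_half(self):
        mask = make_mask(shape=(12, 12, 12), seed=4)
        xs = np.array([-9.0, -3.0, 3.0, 9.0])
        samples = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(4)], "donor": "d1",
            "x": xs, "y": 0.0, "z": 0.0, "structure": "syn"})
        out = match_samples_to_mask(samples, mask, max_distance_mm=3.0,
                                    left_only=True)
        assert set(out["sample_id"]) == {"s0", "s1"}


class TestHandleMissing:
    def test_no_missing_unchanged(self):
        m = pd.DataFrame({"A": [1.0, 2.0], "B": [3.0, 4.0]},
                         index=["s1", "s2"])
        donors = pd.Series(["d1", "d1"], index=m.index)
        pd.testing.assert_frame_equal(handle_missing(m, donors), m)

    def test_single_missing_imputed_with_donor_median(self):
        m = pd.DataFrame({"A": [1.0, np.nan, 5.0, 10.0]},
                         index=["s1", "s2", "s3", "s4"])
        donors = pd.Series(["d1", "d1", "d1", "d2"], index=m.index)
        out = handle_missing(m, donors)
        assert out.loc["s2", "A"] == pytest.approx(3.0)  # median of 1, 5

    def test_gene_over_threshold_dropped(self):
        m = pd.DataFrame({"A": [np.nan, np.nan, np.nan, 1.0, 2.0],
                          "B": [1.0, 2.0, 3.0, 4.0, 5.0]})
        donors = pd.Series(["d1"] * 5, index=m.index)
        out = handle_missing(m, donors, max_missing_fraction=0.5)
        assert list(out.columns) == ["B"]


class TestNormalize:
    def _matrix(self, seed=0, n=40, g=6):
        rng = np.random.default_rng(seed)
        m = pd.DataFrame(rng.normal(8, 2, size=(n, g)),
                         index=[f"s{i}" for i in range(n)],
                         columns=[f"G{j}" for j in range(g)])
        donors = pd.Series(["d1"] * (n // 2) + ["d2"] * (n - n // 2),
                           index=m.index)
        return m, donors

    def test_output_bounded_in_unit_interval(self):
        m, donors = self._matrix()
        out = normalize(m, donors)
        assert (out.to_numpy() >= 0).all() and (out.to_numpy() <= 1).all()

    def test_within_donor_ranking_preserved_per_gene(self):
        # when every sample holds a permutation of the same values, the
        # sample-wise step applies one and the same monotone map to each
        # sample, so the per-gene sample ranking must survive both steps
        rng = np.random.default_rng(1)
        base = np.linspace(2.0, 12.0, 8)
        rows = [rng.permutation(base) for _ in range(20)]
        m = pd.DataFrame(rows, index=[f"s{i}" for i in range(20)],
                         columns=[f"G{j}" for j in range(8)])
        donors = pd.Series(["d1"] * 10 + ["d2"] * 10, index=m.index)
        out = normalize(m, donors)
        for donor in ("d1", "d2"):
            idx = donors[donors == donor].index
            pd.testing.assert_frame_equal(m.loc[idx].rank(axis=0),
                                          out.loc[idx].rank(axis=0))

    def test_affine_rescaling_of_donor_is_invisible(self):
        m, donors = self._matrix(2)
        scaled = m.copy()
        idx = donors[donors == "d1"].index
        scaled.loc[idx] = 3.5 * scaled.loc[idx] + 11.0
        out1 = normalize(m, donors)
        out2 = normalize(scaled, donors)
        np.testing.assert_allclose(out1.to_numpy(), out2.to_numpy(),
                                   atol=1e-10)

    def test_constant_gene_set_to_half(self):
        m = pd.DataFrame({"A": [5.0, 5.0, 5.0, 5.0],
                          "B": [1.0, 2.0, 3.0, 4.0]})
        donors = pd.Series(["d1"] * 4, index=m.index)
        out = normalize(m, donors)
        np.testing.assert_allclose(out["A"], 0.5)


class TestAggregateStabilize:
    def _assignment(self, coords, donors):
        n = len(coords)
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "donor": donors,
            "i": coords[:, 0], "j": coords[:, 1], "k": coords[:, 2],
            "voxel_x": coords[:, 0] * 3.0, "voxel_y": coords[:, 1] * 3.0,
            "voxel_z": coords[:, 2] * 3.0,
            "distance_mm": 0.0,
        })

    def test_colocated_samples_averaged(self):
        coords = np.array([[1, 1, 1], [1, 1, 1], [2, 2, 2]])
        assignment = self._assignment(coords, ["d1"] * 3)
        m = pd.DataFrame({"A": [0.0, 1.0, 0.4]},
                         index=["s0", "s1", "s2"])
        out = aggregate_and_stabilize(m, assignment, stability_threshold=0.2)
        assert len(out.values) == 2
        assert sorted(out.values["A"]) == pytest.approx([0.4, 0.5])

    def test_planted_stable_gene_retained_noise_gene_dropped(self):
        rng = np.random.default_rng(5)
        n = 120
        coords = rng.integers(0, 20, size=(n, 3))
        donors = [f"d{1 + i % 3}" for i in range(n)]
        pattern = np.sin(coords[:, 0] / 3.0) + coords[:, 2] / 10.0
        m = pd.DataFrame({
            "STABLE": pattern + 0.05 * rng.normal(size=n),
            "NOISE": rng.normal(size=n),
        }, index=[f"s{i}" for i in range(n)])
        assignment = self._assignment(coords, donors)
        out = aggregate_and_stabilize(m, assignment, stability_threshold=0.2)
        assert "STABLE" in out.values.columns
        assert "NOISE" not in out.values.columns


class TestEndToEndPrep:
    def test_true_genes_survive_and_output_clean(self, screen_run):
        matrix = screen_run["matrix"]
        truth = screen_run["truth"]
        kept = set(matrix.genes)
        survival = len(kept & set(truth.true_gene_ids)) \
            / len(truth.true_gene_ids)
        assert survival >= 0.9
        assert not matrix.values.isna().any().any()
        assert matrix.values.columns.is_unique

    def test_step_counts_non_increasing_and_ordered(self, screen_run):
        prov = screen_run["matrix"].provenance
        steps = list(prov)
        assert steps == ["reannotate_probes", "intensity_filter",
                         "select_probes", "match_samples_to_mask",
                         "handle_missing", "normalize",
                         "aggregate_and_stabilize"]
        assert prov["intensity_filter"]["probes"] <= \
            prov["reannotate_probes"]["probes"]
        assert prov["aggregate_and_stabilize"]["genes_kept"] <= \
            prov["handle_missing"]["genes"]

    def test_unstable_genes_mostly_dropped(self, screen_run):
        # the generator plants donor-independent (unstable) genes; the
        # stability filter should remove the vast majority of them while
        # keeping most genes overall
        expr = screen_run["expr"]
        kept = set(screen_run["matrix"].genes)
        unstable = set(expr.unstable_gene_ids)
        assert unstable
        dropped_frac = len(unstable - kept) / len(unstable)
        assert dropped_frac >= 0.9
        assert len(kept) > 0.8 * expr.truth.n_genes
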