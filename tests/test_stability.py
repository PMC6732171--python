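import numpy as np
import pytest
import scipy.sparse as sp

from cellstab import (
    ClustererSpec,
    CountMatrix,
    Partition,
    PermutationRun,
    StabilityAnalysis,
    cell_stability_score,
    cluster_stability,
    css_sweep,
    permute_and_cluster,
    silhouette_from_embedding,
    violin_export,
)


# ---------------------------------------------------------------------------
# independent brute-force oracle: raw python set arithmetic, no contingency
# tables
# ---------------------------------------------------------------------------


def css_bruteforce(ref_cells, ref_labels, runs):
    """runs: list of (retained_cells, labels) pairs."""
    ref_cluster = {c: l for c, l in zip(ref_cells, ref_labels)}
    out = {}
    for cell in ref_cells:
        jaccards = []
        for retained, labels in runs:
            run_cluster = {c: l for c, l in zip(retained, labels)}
            if cell not in run_cluster:
                continue
            retained_set = set(retained)
            a = {
                c
                for c in ref_cells
                if ref_cluster[c] == ref_cluster[cell] and c in retained_set
            }
            b = {c for c in retained if run_cluster[c] == run_cluster[cell]}
            jaccards.append(len(a & b) / len(a | b))
        out[cell] = float(np.mean(jaccards)) if jaccards else np.nan
    return out


def _runs_from_tuples(tuples):
    runs = []
    for i, (retained, labels) in enumerate(tuples, start=1):
        retained = np.array(retained, dtype=object)
        runs.append(
            PermutationRun(i, i, retained, Partition(retained, list(labels)))
        )
    return runs


class TestCSSWorkedExample:
    """Hand-computed 6-cell example: reference {a,b,c} {d,e,f}; one run
    retains {a,b,c,d,e} split as {a,b} {c,d,e}."""

    ref = Partition(np.array(list("abcdef"), dtype=object), [1, 1, 1, 2, 2, 2])
    runs = _runs_from_tuples([(list("abcde"), [1, 1, 2, 2, 2])])

    def test_hand_values(self):
        css, n_ret = cell_stability_score(self.ref, self.runs)
        expected = {
            "a": 2 / 3,
            "b": 2 / 3,
            "c": 1 / 5,
            "d": 2 / 3,
            "e": 2 / 3,
        }
        for cell, value in expected.items():
            i = list(self.ref.cell_ids).index(cell)
            assert css[i] == pytest.approx(value, abs=1e-15)
        # f was removed: undefined, flagged
        assert np.isnan(css[5])
        assert n_ret.tolist() == [1, 1, 1, 1, 1, 0]

    def test_matches_bruteforce(self):
        css, _ = cell_stability_score(self.ref, self.runs)
        oracle = css_bruteforce(
            list("abcdef"), [1, 1, 1, 2, 2, 2], [(list("abcde"), [1, 1, 2, 2, 2])]
        )
        for i, cell in enumerate("abcde"):
            assert css[i] == pytest.approx(oracle[cell], abs=1e-15)

    def test_cluster_stability_follows_max_jaccard(self):
        # gamma(C1) = max(|{a,b,c}∩{a,b}|/|{a,b,c}∪{a,b}|, ...) = max(2/3, 1/5)
        stab = cluster_stability(self.ref, self.runs)
        assert stab[1] == pytest.approx(2 / 3)
        # C2 ∩ retained = {d,e}; best match {c,d,e}: 2/3
        assert stab[2] == pytest.approx(2 / 3)


class TestCSSProperties:
    def test_perfect_stability(self):
        cells = np.array([f"c{i}" for i in range(12)], dtype=object)
        labels = [1] * 4 + [2] * 4 + [3] * 4
        ref = Partition(cells, labels)
        rng = np.random.default_rng(0)
        tuples = []
        for _ in range(5):
            keep = np.sort(rng.choice(12, size=10, replace=False))
            tuples.append((cells[keep], np.array(labels)[keep]))
        runs = _runs_from_tuples(tuples)
        css, n_ret = cell_stability_score(ref, runs)
        assert np.allclose(css[n_ret > 0], 1.0)
        stab = cluster_stability(ref, runs)
        assert np.allclose(stab, 1.0)

    def test_singleton_dissolution_closed_form(self):
        # reference cluster {a,b,c}; run keeps all but splits into singletons
        cells = np.array(list("abc"), dtype=object)
        ref = Partition(cells, [1, 1, 1])
        runs = _runs_from_tuples([(cells, [1, 2, 3])])
        css, _ = cell_stability_score(ref, runs)
        assert np.allclose(css, 1 / 3)
        stab = cluster_stability(ref, runs)
        assert stab[1] == pytest.approx(1 / 3)

    def test_oracle_equivalence_random_small(self):
        rng = np.random.default_rng(42)
        for trial in range(20):
            n = int(rng.integers(4, 9))
            cells = np.array([f"c{i}" for i in range(n)], dtype=object)
            ref_labels = rng.integers(1, 4, size=n)
            ref = Partition(cells, ref_labels)
            tuples = []
            for _ in range(int(rng.integers(1, 4))):
                keep = np.sort(
                    rng.choice(n, size=int(rng.integers(2, n + 1)), replace=False)
                )
                tuples.append((cells[keep], rng.integers(1, 4, size=len(keep))))
            runs = _runs_from_tuples(tuples)
            css, _ = cell_stability_score(ref, runs)
            oracle = css_bruteforce(
                list(cells),
                list(ref.labels),
                [(list(r), list(Partition(np.array(r, dtype=object), l).labels))
                 for r, l in tuples],
            )
            for i, cell in enumerate(cells):
                expected = oracle[cell]
                if np.isnan(expected):
                    assert np.isnan(css[i])
                else:
                    assert css[i] == pytest.approx(expected, abs=1e-12)

    def test_relabel_invariance(self):
        cells = np.array([f"c{i}" for i in range(8)], dtype=object)
        ref_a = Partition(cells, [1, 1, 2, 2, 3, 3, 3, 1])
        ref_b = Partition(cells, [3, 3, 1, 1, 2, 2, 2, 3])  # same co-membership
        keep = cells[[0, 1, 2, 3, 4, 6, 7]]
        runs_a = _runs_from_tuples([(keep, [2, 2, 1, 1, 5, 5, 2])])
        runs_b = _runs_from_tuples([(keep, [9, 9, 4, 4, 7, 7, 9])])
        css_a, _ = cell_stability_score(ref_a, runs_a)
        css_b, _ = cell_stability_score(ref_b, runs_b)
        assert np.allclose(css_a, css_b, equal_nan=True)

    def test_label_noise_degrades_css_monotonically(self):
        rng = np.random.default_rng(7)
        n = 60
        cells = np.array([f"c{i}" for i in range(n)], dtype=object)
        base = np.repeat([1, 2, 3], n // 3)
        ref = Partition(cells, base)
        means = []
        for q in (0.0, 0.2, 0.5):
            noise_rng = np.random.default_rng(123)
            tuples = []
            for _ in range(20):
                labels = base.copy()
                flip = noise_rng.random(n) < q
                labels[flip] = noise_rng.integers(1, 4, size=int(flip.sum()))
                tuples.append((cells, labels))
            css, _ = cell_stability_score(ref, _runs_from_tuples(tuples))
            means.append(np.nanmean(css))
        assert means[0] >= means[1] >= means[2]
        assert means[0] == pytest.approx(1.0)

    def test_inconsistent_run_rejected(self):
        ref = Partition(np.array(list("abc"), dtype=object), [1, 1, 2])
        alien = np.array(["x"], dtype=object)
        runs = [PermutationRun(1, 1, alien, Partition(alien, [1]))]
        with pytest.raises(ValueError, match="unknown cell"):
            cell_stability_score(ref, runs)


class TestPermuteAndCluster:
    def test_retained_sizes_and_determinism(self, easy2):
        m, _ = easy2  # 100 cells
        spec = ClustererSpec(engine="kmeans_log", k=2)
        runs = permute_and_cluster(m, spec, B=5, f=0.1, master_seed=3)
        assert len(runs) == 5
        for run in runs:
            assert len(run.retained_cell_ids) == 90
            assert run.seed == 3 + run.run_index
        rerun = permute_and_cluster(m, spec, B=5, f=0.1, master_seed=3)
        for r1, r2 in zip(runs, rerun):
            assert list(r1.retained_cell_ids) == list(r2.retained_cell_ids)
            assert np.array_equal(r1.partition.labels, r2.partition.labels)

    def test_tiny_f_keeps_all_cells(self, easy2):
        m, _ = easy2
        runs = permute_and_cluster(
            m, ClustererSpec(engine="kmeans_log", k=2), B=2, f=0.001, master_seed=0
        )
        assert all(len(r.retained_cell_ids) == m.n_cells for r in runs)

    def test_f_out_of_range(self, easy2):
        m, _ = easy2
        spec = ClustererSpec(engine="kmeans_log", k=2)
        for bad in (0.0, 1.0, 1.5, -0.1):
            with pytest.raises(ValueError, match="f"):
                permute_and_cluster(m, spec, B=1, f=bad)

    def test_retained_below_minimum_rejected_upfront(self):
        counts = np.random.default_rng(0).poisson(5, size=(20, 10))
        m = CountMatrix(
            gene_ids=np.array([f"g{i}" for i in range(20)], dtype=object),
            cell_ids=np.array([f"c{i}" for i in range(10)], dtype=object),
            counts=sp.csr_matrix(counts),
        )
        with pytest.raises(ValueError, match="minimum"):
            permute_and_cluster(
                m, ClustererSpec(engine="kmeans_log", k=8), B=1, f=0.5
            )


class TestSilhouette:
    def test_one_dimensional_closed_form(self):
        emb = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array([1, 1, 2, 2])
        s = silhouette_from_embedding(emb, labels)
        assert s[0] == pytest.approx(9.5 / 10.5, abs=1e-12)

    def test_identical_points_convention_zero(self):
        emb = np.zeros((6, 2))
        s = silhouette_from_embedding(emb, np.array([1, 1, 1, 2, 2, 2]))
        assert np.allclose(s, 0.0)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="silhouette"):
            silhouette_from_embedding(np.zeros((4, 2)), np.array([1, 1, 1, 1]))

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(11)
        emb = rng.normal(size=(200, 5))
        labels = rng.integers(1, 4, size=200)
        s = silhouette_from_embedding(emb, labels)
        assert abs(s.mean()) < 0.1


class TestStabilityAnalysis:
    def test_reproducible_and_summary(self, easy2):
        m, _ = easy2
        analysis = StabilityAnalysis(m, ClustererSpec(k=2), B=10, f=0.1)
        r1 = analysis.fit(master_seed=5)
        r2 = analysis.fit(master_seed=5)
        assert np.allclose(r1.css, r2.css, equal_nan=True)
        assert np.array_equal(r1.reference.labels, r2.reference.labels)
        assert np.allclose(r1.silhouette, r2.silhouette)
        text = r1.summary()
        assert "mean CSS" in text and "cluster" in text

    def test_css_positive_where_retained(self, easy2):
        m, _ = easy2
        res = StabilityAnalysis(m, ClustererSpec(k=3), B=15, f=0.2).fit(1)
        defined = res.n_retained > 0
        assert (res.css[defined] > 0).all()
        assert (res.css[defined] <= 1).all()

    def test_save_artifacts(self, tmp_path, easy2):
        m, _ = easy2
        res = StabilityAnalysis(m, ClustererSpec(k=2), B=5, f=0.1).fit(0)
        out = res.save(tmp_path / "run")
        for name in (
            "reference_labels.csv",
            "cell_scores.csv",
            "cluster_stability.csv",
            "violin_table.csv",
            "params.json",
        ):
            assert (out / name).exists()


class TestSweepAndViolin:
    def test_sweep_single_k_equals_plain_run(self, easy2):
        m, _ = easy2
        spec = ClustererSpec(k=2)
        sweep = css_sweep(m, spec, [2], B=10, f=0.1, master_seed=4)
        plain = StabilityAnalysis(m, spec, B=10, f=0.1).fit(master_seed=4)
        assert sweep.best_k == 2
        assert sweep.table.loc[0, "mean_css"] == pytest.approx(plain.mean_css)

    def test_sweep_requires_k_engine(self, easy2):
        m, _ = easy2
        with pytest.raises(ValueError, match="k"):
            css_sweep(m, ClustererSpec(engine="graph_community"), [2, 3], B=2)

    def test_violin_table_contract(self, easy2):
        m, _ = easy2
        res = StabilityAnalysis(m, ClustererSpec(k=2), B=5, f=0.1).fit(0)
        table = violin_export(res)
        n_css = (table["metric"] == "css").sum()
        assert n_css == int(np.sum(~np.isnan(res.css)))
        assert set(table.columns) == {"cell_id", "metric", "value", "k"}
        assert (table.loc[table["metric"] == "css", "value"] > 0).all()
        assert table.attrs["n_omitted"] == int(
            np.isnan(res.css).sum() + np.isnan(res.silhouette).sum()
        )
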