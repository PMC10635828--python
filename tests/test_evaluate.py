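import numpy as np
import pytest

import spotalign as sa
from spotalign.evaluate import (
    partition_by_tumor_distance,
    rank_genes_by_fold_change,
    retention_index,
    subsample_per_type,
)
from spotalign.preprocess import intersect_genes, log_normalize

from conftest import random_expression


def mk_mapping(assignments, types=None, provenance=None):
    rows = []
    for k, (cid, sid) in enumerate(assignments):
        rows.append(
            sa.MappingRow(
                cid, sid, k,
                (types or {}).get(cid, "T"),
                (provenance or {}).get(cid, "original"),
            )
        )
    return sa.MappingTable(rows)


class TestPrecision:
    def test_formula(self):
        mapping = mk_mapping(
            [("c1", "s1"), ("c2", "s2"), ("c3", "s9"), ("c4", "s4")]
        )
        truth = {"c1": "s1", "c2": "s2", "c3": "s3", "c4": "s4"}
        rep = sa.precision(mapping, truth)
        assert rep.overall == 0.75 and rep.tp == 3 and rep.denominator == 4

    def test_duplicated_cell_counts_once(self):
        # c1 mapped twice, one copy correct: one TP out of one unique cell
        mapping = mk_mapping(
            [("c1", "s1"), ("c1", "s5")],
            provenance={"c1": "duplicated"},
        )
        rep = sa.precision(mapping, {"c1": "s1"})
        assert rep.overall == 1.0 and rep.denominator == 1

    def test_generated_cells_excluded(self):
        mapping = mk_mapping(
            [("c1", "s1"), ("gen0", "s2")],
            provenance={"gen0": "generated"},
        )
        rep = sa.precision(mapping, {"c1": "s1"})
        assert rep.denominator == 1 and rep.overall == 1.0

    def test_all_generated_is_error(self):
        mapping = mk_mapping([("g1", "s1")], provenance={"g1": "generated"})
        with pytest.raises(ValueError, match="no mapped cells"):
            sa.precision(mapping, {})

    def test_per_type_breakdown(self):
        mapping = mk_mapping(
            [("c1", "s1"), ("c2", "s2")], types={"c1": "T", "c2": "B"}
        )
        rep = sa.precision(mapping, {"c1": "s1", "c2": "sX"})
        assert rep.per_type == {"B": 0.0, "T": 1.0}


class TestConcordances:
    def test_identity_and_reversal(self):
        f = sa.CellTypeFractions({"a": 1 / 6, "b": 2 / 6, "c": 3 / 6})
        assert sa.fraction_concordance(f, f).r == pytest.approx(1.0)
        rev = sa.CellTypeFractions({"a": 3 / 6, "b": 2 / 6, "c": 1 / 6})
        assert sa.fraction_concordance(rev, f).r == pytest.approx(-1.0)

    def test_constant_estimate_degenerate_flag(self):
        est = sa.CellTypeFractions({"a": 1 / 3, "b": 1 / 3, "c": 1 / 3})
        true = sa.CellTypeFractions({"a": 0.2, "b": 0.3, "c": 0.5})
        out = sa.fraction_concordance(est, true)
        assert out.r == 0.0 and out.degenerate

    def test_too_few_types_rejected(self):
        f2 = sa.CellTypeFractions({"a": 0.5, "b": 0.5})
        with pytest.raises(ValueError, match="3"):
            sa.fraction_concordance(f2, f2)

    def test_cells_per_spot_affine_invariance(self):
        sm = sa.SpotModel([f"s{i}" for i in range(5)],
                          {f"s{i}": i + 1 for i in range(5)})
        true = {f"s{i}": 10 + 3 * (i + 1) for i in range(5)}
        assert sa.cells_per_spot_concordance(sm, true).r == pytest.approx(1.0)

    def test_shuffled_truth_uncorrelated(self):
        rng = np.random.default_rng(0)
        n = 1000
        counts = rng.integers(1, 20, n)
        sm = sa.SpotModel([f"s{i}" for i in range(n)],
                          {f"s{i}": int(c) for i, c in enumerate(counts)})
        shuffled = rng.permutation(counts)
        true = {f"s{i}": int(c) for i, c in enumerate(shuffled)}
        assert abs(sa.cells_per_spot_concordance(sm, true).r) < 0.1


class TestFindMarkers:
    def _exclusive_gene_data(self, seed=0):
        rng = np.random.default_rng(seed)
        n_per = 30
        vals = rng.poisson(5.0, size=(40, 2 * n_per)).astype(float)
        vals[0, :n_per] += 50.0   # gene g0 exclusively high in T
        vals[0, n_per:] = 0.0
        expr = sa.ExpressionMatrix(
            vals, [f"g{i}" for i in range(40)],
            [f"c{i}" for i in range(2 * n_per)], "raw",
        )
        ann = sa.CellAnnotation(
            {f"c{i}": ("T" if i < n_per else "B") for i in range(2 * n_per)}
        )
        return log_normalize(expr), ann

    def test_exclusive_gene_ranked_first(self):
        expr, ann = self._exclusive_gene_data()
        markers = sa.find_markers(expr, ann)
        assert markers["T"]["gene"].iloc[0] == "g0"

    def test_marker_minimum_enforced(self, caplog):
        rng = np.random.default_rng(1)
        # pure noise: no type reaches five significant markers
        vals = rng.poisson(5.0, size=(30, 40)).astype(float)
        expr = log_normalize(sa.ExpressionMatrix(
            vals, [f"g{i}" for i in range(30)],
            [f"c{i}" for i in range(40)], "raw",
        ))
        ann = sa.CellAnnotation(
            {f"c{i}": ("T" if i < 20 else "B") for i in range(40)}
        )
        with caplog.at_level("WARNING"):
            markers = sa.find_markers(expr, ann, min_markers=5)
        skipped = [r for r in caplog.records if "skipped" in r.getMessage()]
        assert (not markers) == bool(skipped) or len(markers) < 2

    def test_bh_adjustment_monotone(self):
        expr, ann = self._exclusive_gene_data(seed=2)
        markers = sa.find_markers(expr, ann)
        for df in markers.values():
            assert np.all(df["padj"].to_numpy() >= df["pval"].to_numpy() - 1e-15)

    def test_gene_order_invariance(self):
        expr, ann = self._exclusive_gene_data(seed=3)
        perm = np.random.default_rng(4).permutation(expr.n_genes)
        shuffled = sa.ExpressionMatrix(
            expr.values[perm], [expr.gene_ids[i] for i in perm],
            list(expr.column_ids), expr.layer,
        )
        m1 = sa.find_markers(expr, ann)
        m2 = sa.find_markers(shuffled, ann)
        for t in m1:
            assert m1[t]["gene"].tolist() == m2[t]["gene"].tolist()

    def test_single_type_rejected(self):
        expr, _ = self._exclusive_gene_data()
        ann = sa.CellAnnotation({c: "T" for c in expr.column_ids})
        with pytest.raises(ValueError, match="2 cell types"):
            sa.find_markers(expr, ann)


class TestConfidenceScores:
    def test_half_plane_contrast(self):
        """A type confined to one half of a blocks tissue scores higher
        inside its territory than outside."""
        tissue = sa.simulate_tissue(
            n_types=2, n_genes=200, cells_per_type=60,
            layout="blocks", target_mean_cells_per_spot=5, seed=31,
        )
        mapping = sa.truth_mapping(tissue)
        sc_g, st_g, _ = intersect_genes(
            log_normalize(tissue.query), log_normalize(tissue.spot_counts)
        )
        rep = sa.confidence_scores(mapping, sc_g, st_g, tissue.annotation, seed=1)
        t = tissue.annotation.cell_types()[0]
        spots_with = {r.assigned_spot_id for r in mapping.rows if r.cell_type == t}
        inside = [v for s, v in rep.spot_scores[t].items() if s in spots_with]
        outside = [v for s, v in rep.spot_scores[t].items() if s not in spots_with]
        assert np.median(inside) > 0.5 > np.median(outside)

    def test_planted_errors_score_lower(self):
        from sklearn.metrics import roc_auc_score

        tissue = sa.simulate_tissue(
            n_types=4, n_genes=200, cells_per_type=50,
            layout="blocks", target_mean_cells_per_spot=5, seed=32,
        )
        corrupted, planted = sa.plant_swapped_errors(
            sa.truth_mapping(tissue), tissue.spot_geometry,
            tissue.annotation, fraction=0.10, seed=5,
        )
        sc_g, st_g, _ = intersect_genes(
            log_normalize(tissue.query), log_normalize(tissue.spot_counts)
        )
        rep = sa.confidence_scores(corrupted, sc_g, st_g, tissue.annotation, seed=2)
        idx = {r.sub_spot_index: r.query_cell_id for r in corrupted.rows}
        y = [0 if idx[k] in planted else 1 for k in rep.cell_scores]
        s = list(rep.cell_scores.values())
        assert roc_auc_score(y, s) > 0.5

    def test_shuffled_training_labels_no_signal(self):
        """The confidence classifier trained on label-shuffled
        pseudo-bulks discriminates held-out groups at chance level."""
        from sklearn.metrics import roc_auc_score
        from spotalign.evaluate import train_spot_classifier

        aucs = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            # two genuinely separable pseudo-bulk groups ...
            pos = rng.normal(1.0, 1.0, size=(50, 20))
            neg = rng.normal(-1.0, 1.0, size=(50, 20))
            X = np.concatenate([pos, neg])
            y_true = np.array([1] * 50 + [0] * 50)
            # ... but the training labels are shuffled
            y_shuf = rng.permutation(y_true)
            clf = train_spot_classifier(X, y_shuf)
            test = np.concatenate(
                [rng.normal(1.0, 1.0, size=(30, 20)),
                 rng.normal(-1.0, 1.0, size=(30, 20))]
            )
            y_test = np.array([1] * 30 + [0] * 30)
            probs = clf.predict_proba(test)[:, list(clf.classes_).index(1)]
            aucs.append(roc_auc_score(y_test, probs))
        assert abs(np.mean(aucs) - 0.5) < 0.15


class TestPartition:
    def _geom(self, coords):
        return sa.SpotGeometry(coords)

    def test_median_split_hand_case(self):
        coords = {"o": (0.0, 0.0)}
        coords.update({f"s{i}": (float(i), 0.0) for i in (1, 2, 3, 4)})
        rows = [sa.MappingRow(f"tum{i}", "o", i, "Tumor", "original")
                for i in range(5)]
        rows += [
            sa.MappingRow(f"c{i}", f"s{i}", 10 + i, "Tcell", "original")
            for i in (1, 2, 3, 4)
        ]
        part = partition_by_tumor_distance(
            sa.MappingTable(rows), self._geom(coords), "Tumor", k=5
        )
        groups = {rows[5 + j].query_cell_id: part[10 + j + 1] for j in range(4)}
        assert groups == {"c1": "close", "c2": "close", "c3": "far", "c4": "far"}

    def test_k_one_uses_single_nearest(self):
        coords = {"t1": (0.0, 0.0), "t2": (10.0, 0.0), "x": (1.0, 0.0),
                  "y": (9.0, 0.0)}
        rows = [
            sa.MappingRow("tumA", "t1", 0, "Tumor", "original"),
            sa.MappingRow("tumB", "t2", 1, "Tumor", "original"),
            sa.MappingRow("cx", "x", 2, "Tcell", "original"),
            sa.MappingRow("cy", "y", 3, "Tcell", "original"),
        ]
        part = partition_by_tumor_distance(
            sa.MappingTable(rows), self._geom(coords), "Tumor", k=1
        )
        assert part[2] == "close" and part[3] in ("close", "far")

    def test_group_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(5)
        coords = {"o": (0.0, 0.0)}
        rows = [sa.MappingRow(f"tum{i}", "o", i, "Tumor", "original")
                for i in range(5)]
        for i in range(17):
            coords[f"s{i}"] = (float(rng.uniform(0, 5)), float(rng.uniform(0, 5)))
            rows.append(
                sa.MappingRow(f"c{i}", f"s{i}", 100 + i, "Tcell", "original")
            )
        part = partition_by_tumor_distance(
            sa.MappingTable(rows), self._geom(coords), "Tumor", k=5
        )
        close = sum(1 for g in part.values() if g == "close")
        far = sum(1 for g in part.values() if g == "far")
        assert abs(close - far) <= 1

    def test_too_few_tumor_cells_rejected(self):
        coords = {"o": (0.0, 0.0), "s": (1.0, 0.0)}
        rows = [
            sa.MappingRow("tum", "o", 0, "Tumor", "original"),
            sa.MappingRow("c", "s", 1, "Tcell", "original"),
        ]
        with pytest.raises(ValueError, match="fewer than"):
            partition_by_tumor_distance(
                sa.MappingTable(rows), self._geom(coords), "Tumor", k=5
            )

    def test_tumor_region_distance_zero(self):
        coords = {"o": (0.0, 0.0), "far_s": (100.0, 0.0), "near_s": (1.0, 0.0)}
        rows = [sa.MappingRow(f"tum{i}", "o", i, "Tumor", "original")
                for i in range(5)]
        rows += [
            sa.MappingRow("inside", "far_s", 10, "Tcell", "original"),
            sa.MappingRow("nearby", "near_s", 11, "Tcell", "original"),
        ]
        part = partition_by_tumor_distance(
            sa.MappingTable(rows), self._geom(coords), "Tumor", k=5,
            tumor_region_spots={"far_s"},
        )
        assert part[10] == "close"  # distance forced to zero inside the region


class TestFoldChangeRanking:
    def _expr(self, close_vals, far_vals):
        n_close, n_far = 10, 10
        vals = np.concatenate(
            [np.tile(close_vals[:, None], n_close),
             np.tile(far_vals[:, None], n_far)], axis=1,
        )
        cols = [f"c{i}" for i in range(n_close + n_far)]
        groups = {c: ("close" if i < n_close else "far")
                  for i, c in enumerate(cols)}
        expr = sa.ExpressionMatrix(
            vals, [f"g{i}" for i in range(len(close_vals))], cols, "raw"
        )
        return expr, groups

    def test_doubling_gives_log2fc_one(self):
        expr, groups = self._expr(
            np.array([199.0, 9.0]), np.array([99.0, 9.0])
        )
        df = rank_genes_by_fold_change(expr, groups)
        assert df.set_index("gene").loc["g0", "log2fc"] == pytest.approx(1.0)

    def test_identical_groups_all_zero(self):
        expr, groups = self._expr(np.array([5.0, 7.0]), np.array([5.0, 7.0]))
        df = rank_genes_by_fold_change(expr, groups)
        np.testing.assert_allclose(df["log2fc"], 0.0)

    def test_label_swap_antisymmetry(self):
        expr, groups = self._expr(np.array([20.0, 3.0]), np.array([5.0, 9.0]))
        swapped = {c: ("far" if g == "close" else "close")
                   for c, g in groups.items()}
        a = rank_genes_by_fold_change(expr, groups).set_index("gene")["log2fc"]
        b = rank_genes_by_fold_change(expr, swapped).set_index("gene")["log2fc"]
        np.testing.assert_allclose(a.sort_index(), -b.sort_index())

    def test_small_group_rejected(self):
        expr, groups = self._expr(np.array([5.0]), np.array([5.0]))
        few = dict(list(groups.items())[:12])  # only 2 far cells remain
        with pytest.raises(ValueError, match=">= 10"):
            rank_genes_by_fold_change(expr, few)


class TestRetentionIndex:
    def test_self_identity(self):
        rng = np.random.default_rng(6)
        q = random_expression(rng, 50, 10, "c")
        assert retention_index(q, q) == pytest.approx(1.0, abs=1e-12)

    def test_permuted_reference_near_zero(self):
        rng = np.random.default_rng(7)
        vals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            q = random_expression(r, 60, 12, "c")
            perm = r.permutation(12)
            ref = sa.ExpressionMatrix(
                q.values[:, perm], list(q.gene_ids),
                list(q.column_ids), "raw",
            )
            vals.append(retention_index(q, ref))
        assert abs(np.mean(vals)) < 0.1

    def test_monotone_in_noise(self):
        rng = np.random.default_rng(8)
        q = random_expression(rng, 80, 15, "c")
        prev = 1.0
        for scale in (0.1, 1.0, 5.0):
            noisy = sa.ExpressionMatrix(
                q.values + rng.normal(0, scale, q.values.shape) ** 2,
                list(q.gene_ids), list(q.column_ids), "raw",
            )
            idx = retention_index(noisy, q)
            assert idx <= prev + 0.05
            prev = idx
        assert prev < 1.0

    def test_too_few_cells_rejected(self):
        rng = np.random.default_rng(9)
        q = random_expression(rng, 20, 2, "c")
        with pytest.raises(ValueError, match="3 cells"):
            retention_index(q, q)

    def test_subsample_per_type_equal_sizes(self):
        ann = sa.CellAnnotation(
            {f"c{i}": ("T" if i < 20 else "B") for i in range(50)}
        )
        picked = subsample_per_type(ann, list(ann.types), n=15, seed=1)
        census = {}
        for c in picked:
            census[ann[c]] = census.get(ann[c], 0) + 1
        assert census == {"T": 15, "B": 15}
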