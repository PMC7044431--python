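"""Patterning scores, promoter classification, CGI calls and clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from nucpatterns import patterning as pat
from nucpatterns import synthetic as syn
from nucpatterns.occupancy import PromoterMatrix


def matrix_from_rows(rows, ids=None):
    rows = np.asarray(rows, dtype=float)
    ids = ids or [f"p{i}" for i in range(len(rows))]
    rel = np.arange(-1000, 1010, 10)[: rows.shape[1]]
    return PromoterMatrix(promoter_ids=list(ids), relative_positions=rel, values=rows)


class TestMeanTemplate:
    def test_identical_rows(self):
        m = matrix_from_rows([[1, 2, 3], [1, 2, 3]])
        assert np.allclose(pat.mean_template(m, m.promoter_ids), [1, 2, 3])

    def test_row_order_irrelevant(self):
        m = matrix_from_rows([[1, 0, 2], [3, 1, 0], [0, 0, 1]])
        a = pat.mean_template(m, ["p0", "p1", "p2"])
        b = pat.mean_template(m, ["p2", "p0", "p1"])
        assert np.allclose(a, b)

    def test_requires_two_promoters(self):
        m = matrix_from_rows([[1, 2, 3]])
        with pytest.raises(ValueError):
            pat.mean_template(m, ["p0"])

    def test_synthetic_template_shows_ndr_and_array(self, arch192, matrices192):
        matA, _ = matrices192
        labels = {a.promoter_id: a.class_label for a in arch192}
        active = [p for p in matA.promoter_ids if labels[p] == "active_patterned"]
        tmpl = pat.mean_template(matA, active)
        rel = matA.relative_positions
        assert tmpl[(rel >= -140) & (rel < -10)].mean() < tmpl[(rel >= 50) & (rel <= 150)].mean()


class TestPatterningScore:
    def test_constant_profile_scores_zero(self):
        t = np.array([0.1, 0.5, 0.2, 0.9])
        assert pat.patterning_score(np.full(4, 3.0), t) == pytest.approx(0.0)

    def test_template_against_itself_is_n_times_variance(self):
        rng = np.random.default_rng(0)
        t = rng.random(201)
        expected = len(t) * t.var()
        assert pat.patterning_score(t, t) == pytest.approx(expected)

    def test_mean_reflection_flips_sign(self):
        rng = np.random.default_rng(1)
        t = rng.random(50)
        reflected = 2 * t.mean() - t
        assert pat.patterning_score(reflected, t) == pytest.approx(
            -pat.patterning_score(t, t)
        )

    def test_invariant_to_additive_shift(self):
        rng = np.random.default_rng(2)
        p, t = rng.random(30), rng.random(30)
        assert pat.patterning_score(p + 7.3, t) == pytest.approx(
            pat.patterning_score(p, t)
        )
        assert pat.patterning_score(p, t - 2.5) == pytest.approx(
            pat.patterning_score(p, t)
        )

    def test_bilinear_after_centering(self):
        rng = np.random.default_rng(3)
        p, t = rng.random(30), rng.random(30)
        assert pat.patterning_score(4.0 * p, t) == pytest.approx(
            4.0 * pat.patterning_score(p, t)
        )
        assert pat.patterning_score(p, 0.5 * t) == pytest.approx(
            0.5 * pat.patterning_score(p, t)
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pat.patterning_score(np.ones(5), np.ones(6))

    def test_score_matrix_matches_scalar_route(self):
        rng = np.random.default_rng(4)
        m = matrix_from_rows(rng.random((5, 20)))
        t = rng.random(20)
        series = pat.score_matrix(m, t)
        for i, pid in enumerate(m.promoter_ids):
            assert series[pid] == pytest.approx(pat.patterning_score(m.values[i], t))

    def test_planted_patterned_separate_from_unpatterned(self, arch192, matrices192):
        """AUROC >= 0.9 for patterned vs unpatterned at default conditions."""
        matA, _ = matrices192
        labels = {a.promoter_id: a.class_label for a in arch192}
        active = [p for p in matA.promoter_ids if labels[p] == "active_patterned"]
        tmpl = pat.mean_template(matA, active)
        scores = pat.score_matrix(matA, tmpl)
        pos = scores[[p for p in scores.index if labels[p] in syn.PATTERNED_CLASSES]]
        neg = scores[[p for p in scores.index if labels[p] not in syn.PATTERNED_CLASSES]]
        auroc = np.mean([(pos.to_numpy()[:, None] > neg.to_numpy()[None, :])])
        assert auroc >= 0.9


class TestSplitByPatterning:
    def test_median_split(self):
        scores = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        groups = pat.split_by_patterning(scores, ["a", "b", "c", "d"])
        assert groups[groups == "high"].index.tolist() == ["c", "d"]

    def test_all_equal_scores_all_low(self):
        scores = pd.Series({"a": 2.0, "b": 2.0, "c": 2.0})
        groups = pat.split_by_patterning(scores, ["a", "b", "c"])
        assert (groups == "low").all()

    def test_recovers_planted_patterning_groups(self, arch192, matrices192):
        matA, _ = matrices192
        labels = {a.promoter_id: a.class_label for a in arch192}
        active = [p for p in matA.promoter_ids if labels[p] == "active_patterned"]
        inducible = [p for p in matA.promoter_ids if labels[p].startswith("inducible")]
        tmpl = pat.mean_template(matA, active)
        scores = pat.score_matrix(matA, tmpl)
        groups = pat.split_by_patterning(scores, inducible)
        correct = sum(
            (groups[p] == "high") == (labels[p] == "inducible_patterned")
            for p in inducible
        )
        assert correct / len(inducible) >= 0.9


class TestClassifyPromoters:
    def make_table(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene", "nonstim_level", "induction_diff",
                     "nonstim_rep1", "nonstim_rep2", "nonstim_rep3",
                     "stim_rep1", "stim_rep2", "stim_rep3", "baf_diff"],
        )

    def test_rule_applications(self):
        table = self.make_table([
            ("silent", 0.0, 0.0, 5, 5.1, 4.9, 5, 5.05, 4.95, 0.0),
            ("induced", 0.1, 1.2, 5, 5.1, 4.9, 6.2, 6.3, 6.1, -0.5),
            ("busy", 8.0, 0.0, 5, 5.1, 4.9, 5, 5.05, 4.95, 0.4),
        ])
        out = pat.classify_promoters(table).set_index("gene")
        assert out.loc["silent", "class_label"] == "inactive"
        assert out.loc["induced", "class_label"] == "inducible"
        assert out.loc["busy", "class_label"] == "active"
        assert bool(out.loc["induced", "baf_dependent"])
        assert bool(out.loc["busy", "baf_inhibited"])

    def test_large_difference_without_significance_not_inducible(self):
        table = self.make_table([
            ("noisy", 0.5, 2.0, 2, 8, 5, 4, 10, 7, 0.0),
            ("ref", 5.0, 0.0, 5.0, 5.1, 4.9, 5.0, 5.1, 4.9, 0.0),
        ])
        out = pat.classify_promoters(table).set_index("gene")
        assert out.loc["noisy", "class_label"] != "inducible"

    def test_labels_partition(self, aux192):
        out = pat.classify_promoters(aux192.expression)
        assert set(out["class_label"]) <= {"active", "inactive", "inducible", "unclassified"}
        assert out["class_label"].notna().all()

    def test_round_trip_recovers_planted_labels(self, arch192, aux192):
        out = pat.classify_promoters(aux192.expression).set_index("gene")
        planted = {
            "active_patterned": "active",
            "inactive": "inactive",
            "inducible_patterned": "inducible",
            "inducible_nonpatterned": "inducible",
        }
        for a in arch192:
            assert out.loc[a.promoter_id, "class_label"] == planted[a.class_label]

    def test_missing_replicates_flagged(self):
        table = pd.DataFrame({"gene": ["g"], "nonstim_level": [1.0],
                              "induction_diff": [2.0]})
        with pytest.raises(ValueError, match="replicate"):
            pat.classify_promoters(table)


def oracle_cgi(seq):
    seq = seq.upper().replace("N", "")
    if not seq:
        return None
    c = sum(1 for ch in seq if ch == "C")
    g = sum(1 for ch in seq if ch == "G")
    gc = (c + g) / len(seq)
    cg = sum(1 for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G")
    if c == 0 or g == 0:
        return False
    return gc > 0.5 and cg * len(seq) / (c * g) > 0.6


class TestDetectCGI:
    def test_cg_repeat_is_island(self):
        assert pat.detect_cgi("CG" * 200) is True

    def test_at_repeat_is_not(self):
        assert pat.detect_cgi("AT" * 200) is False

    def test_gc_repeat_follows_formula(self):
        seq = "GC" * 200  # CpGs only at GC|GC junctions: 199 of them
        expected = oracle_cgi(seq)
        assert pat.detect_cgi(seq) is expected

    def test_mostly_n_undetermined(self):
        assert pat.detect_cgi("N" * 300 + "CG" * 50) is None

    def test_matches_oracle_on_random_sequences(self):
        rng = np.random.default_rng(11)
        alphabet = np.array(list("ACGT"))
        for _ in range(1000):
            # GC-probability near the decision boundary to exercise both sides
            p_gc = rng.uniform(0.35, 0.65) / 2
            probs = [0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc]
            seq = "".join(rng.choice(alphabet, size=400, p=probs))
            assert pat.detect_cgi(seq) == oracle_cgi(seq)


class TestClusterSamples:
    def test_duplicate_sample_distance_zero(self):
        rng = np.random.default_rng(0)
        m = matrix_from_rows(rng.random((4, 30)))
        d = pat.cluster_samples({"a": m, "b": m}, mode="mean")
        assert d.linkage[0, 2] == pytest.approx(0.0)

    def test_replicates_pair_before_cell_types(self):
        """Two spacings x two replicates: replicates merge first."""
        from nucpatterns import occupancy

        mats = {}
        for ct, spacing, seed in (("f", 192.0, 51), ("d", 183.0, 52)):
            arch = syn.build_architectures(10, spacing=spacing, jitter_sd=15.0,
                                           footprint=147, seed=seed)
            proms = arch.promoter_table()
            for rep, s in (("1", 1), ("2", 2)):
                frags = syn.sample_fragments(arch, 0.08, seed=s + seed)
                mat = occupancy.promoter_matrix(frags, proms)
                mat.promoter_ids = [f"p{i}" for i in range(len(mat.promoter_ids))]
                mats[f"{ct}{rep}"] = mat
        for mode in ("mean", "individual"):
            dend = pat.cluster_samples(mats, mode=mode)
            first_pairs = []
            n = len(dend.labels)
            merged = {i: {dend.labels[i]} for i in range(n)}
            for row in dend.linkage:
                a, b = int(row[0]), int(row[1])
                merged[len(merged)] = merged[a] | merged[b]
            # the first two merges must be the replicate pairs
            assert merged[n] in ({"f1", "f2"}, {"d1", "d2"})
            assert merged[n + 1] in ({"f1", "f2"}, {"d1", "d2"})

    def test_mismatched_universe_rejected(self):
        m1 = matrix_from_rows(np.ones((2, 10)), ids=["a", "b"])
        m2 = matrix_from_rows(np.ones((2, 10)), ids=["a", "c"])
        with pytest.raises(ValueError):
            pat.cluster_samples({"x": m1, "y": m2})


class TestClusterPromoterClasses:
    def test_identical_classes_equal_inter_and_intra_distance(self):
        rng = np.random.default_rng(1)
        rows = rng.random((10, 30))
        m = matrix_from_rows(np.vstack([rows, rows]),
                             ids=[f"a{i}" for i in range(10)] + [f"b{i}" for i in range(10)])
        labels = pd.Series(["A"] * 10 + ["B"] * 10,
                           index=m.promoter_ids)
        dend = pat.cluster_promoter_classes(m, labels, sample_size=10, seed=0)
        # the two duplicated classes are at the mean pairwise distance of the
        # class with itself: reconstruct it directly
        x = np.sqrt(rows)
        diff = x[:, None, :] - x[None, :, :]
        intra = np.linalg.norm(diff, axis=2).mean()
        assert dend.linkage[0, 2] == pytest.approx(intra, rel=1e-6)

    def test_seed_determinism(self, arch192, matrices192):
        matA, _ = matrices192
        labels = pd.Series({a.promoter_id: a.class_label for a in arch192})
        d1 = pat.cluster_promoter_classes(matA, labels, sample_size=20, seed=5)
        d2 = pat.cluster_promoter_classes(matA, labels, sample_size=20, seed=5)
        assert np.allclose(d1.linkage, d2.linkage)

    def test_patterned_inducible_joins_active_before_inactive(self, arch192, matrices192):
        matA, _ = matrices192
        labels = pd.Series({a.promoter_id: a.class_label for a in arch192})
        keep = labels[labels.isin(["active_patterned", "inactive", "inducible_patterned"])]
        dend = pat.cluster_promoter_classes(matA, keep, sample_size=25, seed=2)
        first = {dend.labels[int(dend.linkage[0, 0])], dend.labels[int(dend.linkage[0, 1])]}
        assert first == {"active_patterned", "inducible_patterned"}


class TestClusterInducible:
    def test_identical_rows_merge_at_zero(self):
        m = matrix_from_rows(np.vstack([np.ones(20), np.ones(20), np.zeros(20) + 4]))
        dend, _ = pat.cluster_inducible(m, k=2)
        assert dend.linkage[0, 2] == pytest.approx(0.0)

    def test_ward_heights_non_decreasing(self, matrices192):
        matA, _ = matrices192
        dend, _ = pat.cluster_inducible(matA, k=3)
        heights = dend.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-9)

    def test_trichotomy_recovered(self):
        """NDR-in-both / NDR-in-one / NDR-in-neither resolve as the 3 top clusters."""
        rng = np.random.default_rng(9)
        rel = np.arange(-1000, 1010, 10)
        ndr = np.where((rel >= -150) & (rel < 0), 0.002, 0.012)
        flat = np.full(rel.size, 0.012)
        rows, truth, ids = [], [], []
        for group, (p1, p2) in enumerate([(ndr, ndr), (ndr, flat), (flat, flat)]):
            for i in range(30):
                noise = rng.normal(0, 0.0012, size=2 * rel.size)
                rows.append(np.concatenate([p1, p2]) + noise)
                truth.append(group)
                ids.append(f"g{group}_{i}")
        m = PromoterMatrix(promoter_ids=ids,
                           relative_positions=np.arange(2 * rel.size),
                           values=np.clip(np.array(rows), 0, None))
        _, assign = pat.cluster_inducible(m, k=3)
        # cluster labels are arbitrary: majority-map them onto the truth
        df = pd.DataFrame({"cluster": assign.to_numpy(), "truth": truth})
        correct = sum(
            (grp["truth"] == grp["truth"].mode()[0]).sum()
            for _, grp in df.groupby("cluster")
        )
        assert correct / len(df) >= 0.9

    def test_weights_hook(self):
        rng = np.random.default_rng(10)
        m = matrix_from_rows(rng.random((4, 20)))
        w = np.zeros(20)
        w[:10] = 1.0
        dend, _ = pat.cluster_inducible(m, k=2, weights=w)
        assert dend.linkage.shape == (3, 4)
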