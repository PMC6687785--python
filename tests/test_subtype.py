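"""Nearest-template workflow: splits, templates, filters, calls, gates."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tumormatch.fidelity import CorrelationMatrix
from tumormatch.pipeline import normalize_counts, run_subtype_workflow
from tumormatch.simulate import SyntheticConfig, generate_cohort
from tumormatch.subtype import (
    SubtypeTemplateSet,
    build_templates,
    evaluate_accuracy,
    filter_templates_for_cell_lines,
    ntp_classify,
    split_train_test,
    subtype_proportion_test,
    subtype_specific_ranks,
)


class TestSplit:
    def test_balanced_two_subtype_allocation(self):
        ids = [f"s{i}" for i in range(100)]
        labels = pd.Series(["A"] * 50 + ["B"] * 50, index=ids)
        train, test = split_train_test(ids, labels, train_frac=0.8, seed=0)
        assert len(train) == 80 and len(test) == 20
        for sub in "AB":
            assert sum(labels[s] == sub for s in train) == 40
            assert sum(labels[s] == sub for s in test) == 10

    def test_five_by_ten_allocation(self):
        ids = [f"s{i}" for i in range(50)]
        labels = pd.Series(sum(([c] * 10 for c in "ABCDE"), []), index=ids)
        train, test = split_train_test(ids, labels, seed=1)
        for c in "ABCDE":
            assert sum(labels[s] == c for s in train) == 8
            assert sum(labels[s] == c for s in test) == 2

    def test_deterministic_and_disjoint(self):
        ids = [f"s{i}" for i in range(30)]
        labels = pd.Series(["A"] * 15 + ["B"] * 15, index=ids)
        t1 = split_train_test(ids, labels, seed=5)
        t2 = split_train_test(ids, labels, seed=5)
        assert t1 == t2
        assert not set(t1[0]) & set(t1[1])
        assert set(t1[0]) | set(t1[1]) == set(ids)

    def test_singleton_subtype_named(self):
        ids = ["a", "b", "c"]
        labels = pd.Series({"a": "X", "b": "X", "c": "LONER"})
        with pytest.raises(ValueError, match="LONER"):
            split_train_test(ids, labels)


class TestTemplates:
    def test_planted_markers_recovered(self, small_cohort):
        counts, meta, truth = small_cohort
        tumors = list(truth.purity.index)
        labels = meta.loc[tumors, "subtype"]
        templates = build_templates(counts[tumors], labels)
        for s in truth.subtype_names:
            planted = set(truth.marker_genes(s))
            got = set(templates.templates[s])
            assert len(planted & got) / len(planted) >= 0.9

    def test_identical_subtypes_yield_no_templates(self, rng):
        counts = pd.DataFrame(
            rng.poisson(100, (200, 30)),
            index=[f"g{i}" for i in range(200)],
            columns=[f"s{i}" for i in range(30)],
        )
        labels = pd.Series(["A"] * 15 + ["B"] * 15, index=counts.columns)
        with pytest.raises(ValueError, match="no template genes"):
            build_templates(counts, labels)

    def test_shared_gene_goes_to_larger_lfc_subtype(self, rng):
        """A gene elevated in A and more in B lands only in B's template."""
        G, per = 1500, 12
        base = rng.poisson(200, (G, 3 * per)).astype(float)
        counts = pd.DataFrame(
            base, index=[f"g{i}" for i in range(G)],
            columns=[f"s{i}" for i in range(3 * per)],
        )
        labels = pd.Series(["A"] * per + ["B"] * per + ["C"] * per,
                           index=counts.columns)
        shared = "g0"
        counts.loc[shared, labels == "A"] *= 6.0
        counts.loc[shared, labels == "B"] *= 24.0
        # give every subtype some private markers so templates are non-empty
        for i, sub in enumerate("ABC"):
            for g in [f"g{j}" for j in range(1 + 10 * i, 1 + 10 * i + 8)]:
                counts.loc[g, labels == sub] *= 8.0
        templates = build_templates(counts, labels)
        assert shared in templates.templates["B"]
        assert shared not in templates.templates["A"]


class TestTemplateFilter:
    @staticmethod
    def _setup(rng):
        templates = SubtypeTemplateSet(
            templates={"A": ["g1", "g2", "g3"], "B": ["g4", "g5"]},
            provenance=pd.DataFrame(),
        )
        de = pd.DataFrame({"lfc": [3.0, 0.1, -0.5, 0.2, 0.0]},
                          index=["g1", "g2", "g3", "g4", "g5"])
        cell_x = pd.DataFrame(
            rng.normal(5, 1, (10, 6)),
            index=[f"g{i}" for i in range(1, 11)],
            columns=[f"cl{i}" for i in range(6)],
        )
        return templates, de, cell_x

    def test_tumor_cl_de_gene_dropped(self, rng):
        templates, de, cell_x = self._setup(rng)
        cell_x.loc[:, :] = 5.0
        cell_x.loc["g2"] = 9.0
        cell_x.loc["g3"] = 9.0
        cell_x.loc["g4"] = 9.0
        cell_x.loc["g5"] = 9.0
        out = filter_templates_for_cell_lines(templates, de, cell_x)
        prov = out.provenance.set_index("gene")["status"]
        assert prov["g1"] == "dropped_tumor_cl_de"
        assert "g1" not in out.templates["A"]

    def test_low_expression_boundary_two_lines(self, rng):
        templates, de, cell_x = self._setup(rng)
        # g2 above the per-sample median in exactly two cell lines -> kept;
        # g3 above in only one -> dropped
        cell_x.loc[:, :] = rng.normal(5, 0.1, cell_x.shape)
        cell_x.loc["g2"] = [9.0, 9.0, 0.0, 0.0, 0.0, 0.0]
        cell_x.loc["g3"] = [9.0, 0.0, 0.0, 0.0, 0.0, 0.0]
        out = filter_templates_for_cell_lines(templates, de, cell_x)
        prov = out.provenance.set_index("gene")["status"]
        assert "g2" in out.templates["A"]
        assert prov["g3"] == "dropped_low_expression"

    def test_immune_template_gene_removed_on_synthetic_truth(self, small_cohort):
        """An immune-role gene planted into a template is caught by one of
        the two cell-line relevance rules (absent from pure cultures)."""
        from tumormatch.diffexp import build_design, run_voom_limma

        counts, meta, truth = small_cohort
        tumors = list(truth.purity.index)
        labels = meta.loc[tumors, "subtype"]
        templates = build_templates(counts[tumors], labels)
        immune_gene = truth.genes_with_role("immune")[0]
        sub0 = truth.subtype_names[0]
        templates.templates[sub0] = sorted(templates.templates[sub0] + [immune_gene])
        de = run_voom_limma(counts, build_design(meta))
        logged = normalize_counts(counts, meta, batch_correct=False)
        cells = meta.index[meta["cohort"] == "cell_line"]
        out = filter_templates_for_cell_lines(templates, de, logged[cells])
        assert immune_gene not in out.templates[sub0]
        status = out.provenance.set_index(["gene", "subtype"])["status"]
        assert status[(immune_gene, sub0)].startswith("dropped")


class TestNtp:
    @staticmethod
    def _templates():
        return SubtypeTemplateSet(
            templates={"A": [f"a{i}" for i in range(8)],
                       "B": [f"b{i}" for i in range(8)]},
            provenance=pd.DataFrame(), n_resample=500, seed=0,
        )

    @staticmethod
    def _matrix(rng, n_samples=30, signal=None):
        genes = ([f"a{i}" for i in range(8)] + [f"b{i}" for i in range(8)]
                 + [f"n{i}" for i in range(60)])
        x = pd.DataFrame(rng.normal(0, 1, (len(genes), n_samples)),
                         index=genes, columns=[f"s{i}" for i in range(n_samples)])
        if signal:
            for j in range(n_samples):
                which = "a" if j % 2 == 0 else "b"
                x.loc[[f"{which}{i}" for i in range(8)], f"s{j}"] += signal
        return x

    def test_strong_match_gets_floor_p(self, rng):
        x = self._matrix(rng, signal=6.0)
        calls = ntp_classify(x, self._templates())
        assert (calls.loc[[f"s{j}" for j in range(0, 30, 2)], "subtype"] == "A").all()
        assert (calls.loc[[f"s{j}" for j in range(1, 30, 2)], "subtype"] == "B").all()
        assert calls["p"].min() == pytest.approx(1 / 501)
        assert calls["assigned"].all()

    def test_noise_only_rarely_assigned(self, rng):
        x = self._matrix(rng, signal=None)
        calls = ntp_classify(x, self._templates())
        assert calls["assigned"].mean() <= 0.1
        assert (calls["p"] > 0).all() and (calls["p"] <= 1).all()

    def test_tie_breaks_by_subtype_name(self, rng):
        templates = self._templates()
        x = self._matrix(rng)
        # mirror the B block onto the A block: every sample's standardized
        # profile is identical on both templates, so distances tie exactly
        # and the name-order tiebreak picks "A" every time
        x.loc[[f"b{i}" for i in range(8)]] = x.loc[[f"a{i}" for i in range(8)]].to_numpy()
        calls = ntp_classify(x, templates)
        assert (calls["subtype"] == "A").all()

    def test_affine_rescaling_invariance(self, rng):
        x = self._matrix(rng, signal=2.0)
        c1 = ntp_classify(x, self._templates())
        c2 = ntp_classify(x * 3.0 + 11.0, self._templates())
        pd.testing.assert_frame_equal(c1, c2)

    def test_single_sample_cohort_rejected(self, rng):
        x = self._matrix(rng)[["s0"]]
        with pytest.raises(ValueError, match="single-sample"):
            ntp_classify(x, self._templates())

    def test_missing_template_genes_rejected(self, rng):
        x = self._matrix(rng).drop(index=[f"a{i}" for i in range(6)])
        with pytest.raises(ValueError, match="fewer than"):
            ntp_classify(x, self._templates())


class TestAccuracyGate:
    def test_boundary_eighty_percent(self):
        calls = pd.DataFrame(
            {"subtype": ["A"] * 8 + ["B"] * 2, "assigned": [True] * 10},
            index=[f"s{i}" for i in range(10)],
        )
        truth = pd.Series(["A"] * 8 + ["A"] * 2, index=calls.index)
        res = evaluate_accuracy(calls, truth)
        assert res["accuracy"] == pytest.approx(0.8)
        assert res["gate_passed"]

    def test_unassigned_count_as_errors(self):
        calls = pd.DataFrame(
            {"subtype": ["A"] * 10, "assigned": [False] * 10},
            index=[f"s{i}" for i in range(10)],
        )
        truth = pd.Series(["A"] * 10, index=calls.index)
        res = evaluate_accuracy(calls, truth)
        assert res["accuracy"] == 0.0
        assert not res["gate_passed"]


class TestProportions:
    def test_two_by_two_closed_form(self):
        """(30,10)/(10,30): X^2 = 20 by the standard 2x2 formula."""
        tumor = pd.Series(["A"] * 30 + ["B"] * 10, index=[f"t{i}" for i in range(40)])
        calls = pd.DataFrame(
            {"subtype": ["A"] * 10 + ["B"] * 30, "assigned": True},
            index=[f"c{i}" for i in range(40)],
        )
        p, table = subtype_proportion_test(tumor, calls)
        a, b, c, d = 30, 10, 10, 30
        n = a + b + c + d
        x2 = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert x2 == pytest.approx(20.0)
        assert p == pytest.approx(float(stats.chi2.sf(x2, df=1)), abs=1e-12)

    def test_identical_proportions_not_significant(self):
        tumor = pd.Series(["A"] * 60 + ["B"] * 40, index=[f"t{i}" for i in range(100)])
        calls = pd.DataFrame(
            {"subtype": ["A"] * 30 + ["B"] * 20, "assigned": True},
            index=[f"c{i}" for i in range(50)],
        )
        p, _ = subtype_proportion_test(tumor, calls)
        assert p > 0.05

    def test_empty_calls_rejected(self):
        tumor = pd.Series(["A", "B"], index=["t1", "t2"])
        calls = pd.DataFrame({"subtype": ["A"], "assigned": [False]}, index=["c1"])
        with pytest.raises(ValueError, match="no assigned"):
            subtype_proportion_test(tumor, calls)


class TestSubtypeRanks:
    def test_single_subtype_equals_global_summary(self, rng):
        from tumormatch.fidelity import summarize_cell_lines

        rho = pd.DataFrame(rng.uniform(0, 1, (4, 10)),
                           index=[f"cl{i}" for i in range(4)],
                           columns=[f"t{i}" for i in range(10)])
        cm = CorrelationMatrix(rho=rho)
        labels = pd.Series("ONLY", index=rho.columns)
        out = subtype_specific_ranks(cm, labels)
        pd.testing.assert_frame_equal(out["ONLY"], summarize_cell_lines(cm))

    def test_pooled_median_invariant_to_label_shuffle(self, rng):
        rho = pd.DataFrame(rng.uniform(0, 1, (3, 12)),
                           index=[f"cl{i}" for i in range(3)],
                           columns=[f"t{i}" for i in range(12)])
        cm = CorrelationMatrix(rho=rho)
        labels = pd.Series(["X"] * 6 + ["Y"] * 6, index=rho.columns)
        shuffled = pd.Series(rng.permutation(labels), index=rho.columns)
        for lab in (labels, shuffled):
            out = subtype_specific_ranks(cm, lab)
            pooled = pd.concat([cm.rho[lab.index[lab == s]] for s in out], axis=1)
            assert pooled.shape == cm.rho.shape


def test_end_to_end_recovery_and_null(default_cohort):
    """At the default effect size the full workflow passes the gate and
    recovers cell-line subtypes; templates come from the training tumors."""
    counts, meta, truth = default_cohort
    res = run_subtype_workflow(counts, meta, seed=1)
    assert res.test_accuracy["gate_passed"]
    assert res.test_accuracy["accuracy"] >= 0.9
    calls = res.cell_line_calls
    assigned = calls[calls["assigned"]]
    agree = (assigned["subtype"] == truth.subtype.loc[assigned.index]).mean()
    assert agree >= 0.9
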