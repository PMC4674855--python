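import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import bh_stepup
from conftest import make_study
from reposnet import diffexpr
from reposnet.diffexpr import (
    collapse_probes,
    combine_disease_datasets,
    combine_drug_timepoints,
    differential_expression,
    trigamma_inverse,
)
from reposnet.io_formats import FormatError, ProbeAnnotation


class TestCollapseProbes:
    def test_mean_of_probes_sharing_symbol(self):
        study = make_study({"p1": [1, 3], "p2": [3, 5]}, n_ref=1, n_cond=1)
        ann = ProbeAnnotation({"p1": "GENE", "p2": "GENE"})
        out = collapse_probes(study, ann)
        assert list(out.matrix.index) == ["GENE"]
        assert out.matrix.loc["GENE"].tolist() == [2.0, 4.0]

    def test_unmapped_probe_removed(self):
        study = make_study({"p1": [1, 1], "p2": [2, 2]}, n_ref=1, n_cond=1)
        out = collapse_probes(study, ProbeAnnotation({"p1": "A", "p2": None}))
        assert list(out.matrix.index) == ["A"]

    def test_one_to_one_mapping_only_renames(self):
        study = make_study({"p1": [1, 2], "p2": [3, 4]}, n_ref=1, n_cond=1)
        out = collapse_probes(study, ProbeAnnotation({"p1": "B", "p2": "A"}))
        assert out.matrix.loc["B"].tolist() == [1.0, 2.0]
        assert out.matrix.loc["A"].tolist() == [3.0, 4.0]

    def test_nothing_mapped_is_error(self):
        study = make_study({"p1": [1, 2]}, n_ref=1, n_cond=1)
        with pytest.raises(FormatError, match="no probe"):
            collapse_probes(study, ProbeAnnotation({"p1": None}))


class TestDifferentialExpression:
    def _planted_study(self, seed=0, n_genes=50, n_planted=5, effect=2.0, sd=0.3, n=5):
        rng = np.random.default_rng(seed)
        genes = [f"g{i:02d}" for i in range(n_genes)]
        base = rng.normal(7, 1, n_genes)
        ref = base[:, None] + rng.normal(0, sd, (n_genes, n))
        cond = base[:, None] + rng.normal(0, sd, (n_genes, n))
        cond[:n_planted] += effect
        samples = [f"r{i}" for i in range(n)] + [f"c{i}" for i in range(n)]
        matrix = pd.DataFrame(np.hstack([ref, cond]), index=genes, columns=samples)
        groups = {s: ("reference" if s.startswith("r") else "condition") for s in samples}
        from reposnet.io_formats import ExpressionStudy

        return ExpressionStudy(matrix=matrix, groups=groups, study_id="planted"), genes[:n_planted]

    @pytest.mark.parametrize("method", ["moderated", "welch"])
    def test_planted_genes_have_smallest_q_and_direction_up(self, method):
        study, planted = self._planted_study()
        res = differential_expression(study, q_threshold=0.01, method=method)
        top5 = res.table.nsmallest(5, "q_value")
        assert set(top5.gene) == set(planted)
        assert (top5.direction == "up").all()
        assert top5.significant.all()

    def test_significant_iff_q_below_threshold(self):
        study, _ = self._planted_study()
        res = differential_expression(study, q_threshold=0.01)
        assert (res.table.significant == (res.table.q_value < 0.01)).all()

    def test_identical_groups_yield_no_signal(self):
        matrix = {f"g{i}": [1.0, 2.0, 1.0, 2.0] for i in range(10)}
        study = make_study(matrix, n_ref=2, n_cond=2)
        res = differential_expression(study, q_threshold=0.05)
        assert not res.table.significant.any()
        assert (res.table.log2fc == 0).all()
        assert res.significant_directions() == {}
        assert res.table.direction.isna().all()

    def test_group_smaller_than_two_rejected(self):
        study = make_study({"g1": [1.0, 2.0, 3.0]}, n_ref=1, n_cond=2)
        with pytest.raises(ValueError, match="at least 2"):
            differential_expression(study)

    def test_gene_order_permutation_invariance(self):
        study, _ = self._planted_study(seed=3)
        res1 = differential_expression(study, q_threshold=0.01)
        perm = study.matrix.sample(frac=1, random_state=11)
        from reposnet.io_formats import ExpressionStudy

        shuffled = ExpressionStudy(matrix=perm, groups=study.groups, study_id="s")
        res2 = differential_expression(shuffled, q_threshold=0.01)
        merged = res1.table.set_index("gene").join(res2.table.set_index("gene"), rsuffix="_p")
        assert np.allclose(merged.q_value, merged.q_value_p)
        assert (merged.significant == merged.significant_p).all()

    def test_zero_variance_gene_does_not_produce_nan(self):
        matrix = {"flat": [1.0, 1.0, 2.0, 2.0], "noisy": [1.0, 1.2, 1.1, 0.9]}
        study = make_study(matrix, n_ref=2, n_cond=2)
        res = differential_expression(study, q_threshold=0.05)
        assert np.isfinite(res.table.p_value).all()

    def test_moderated_matches_limma_ebayes(self, tmp_path):
        """The empirical-Bayes moderated t must reproduce R limma's p-values."""
        study, _ = self._planted_study(seed=5, n_genes=80)
        mfile = tmp_path / "m.tsv"
        study.matrix.to_csv(mfile, sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(limma))
                x <- as.matrix(read.table("{mfile}", header=TRUE, row.names=1, sep="\\t"))
                group <- factor(ifelse(grepl("^r", colnames(x)), "reference", "condition"),
                                levels=c("reference", "condition"))
                design <- model.matrix(~group)
                fit <- eBayes(lmFit(x, design))
                out <- data.frame(gene=rownames(x), p=fit$p.value[,2], df_prior=fit$df.prior)
                write.table(out, "{tmp_path / 'limma_out.tsv'}", sep="\\t",
                            row.names=FALSE, quote=FALSE)
                """
            )
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        limma = pd.read_csv(tmp_path / "limma_out.tsv", sep="\t").set_index("gene")
        res = differential_expression(study, q_threshold=0.01, method="moderated")
        mine = res.table.set_index("gene")
        assert np.allclose(mine.p_value, limma.loc[mine.index].p, rtol=1e-4)


class TestBenjaminiHochberg:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_q_values_match_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 1000))
        p = rng.uniform(size=n)
        assert np.allclose(diffexpr.bh_qvalues(p), bh_stepup(p), atol=1e-12)

    def test_q_at_least_p_and_monotone_in_p_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=300)
        q = diffexpr.bh_qvalues(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


def test_trigamma_inverse_round_trips():
    from scipy import special

    x = np.array([0.1, 0.5, 1.0, 5.0, 50.0])
    y = special.polygamma(1, x)
    assert np.allclose(trigamma_inverse(y), x, rtol=1e-8)


def _contrast(study_id, sig: dict[str, str], q=0.01):
    rows = [
        {"gene": g, "log2fc": 1.0 if d == "up" else -1.0, "p_value": 1e-6,
         "q_value": 1e-5, "direction": d, "significant": True}
        for g, d in sig.items()
    ]
    rows.append({"gene": "null_gene_" + study_id, "log2fc": 0.1, "p_value": 0.9,
                 "q_value": 0.9, "direction": "up", "significant": False})
    return diffexpr.ContrastResult(study_id=study_id, table=pd.DataFrame(rows), q_threshold=q)


class TestCombination:
    def test_disease_union_keeps_single_dataset_gene(self):
        sig = combine_disease_datasets(
            [_contrast("d1", {"A": "up"}), _contrast("d2", {"B": "down"})]
        )
        assert sig.directions == {"A": "up", "B": "down"}
        assert sig.provenance["A"] == ["d1"]

    def test_disease_conflicting_direction_excluded(self):
        sig = combine_disease_datasets(
            [_contrast("d1", {"A": "up", "B": "up"}), _contrast("d2", {"A": "down"})]
        )
        assert "A" not in sig.directions
        assert sig.conflicting == {"A"}
        assert sig.directions == {"B": "up"}

    def test_disease_disjoint_sets_union_size(self):
        sig = combine_disease_datasets(
            [
                _contrast("d1", {"A": "up", "B": "up", "C": "down"}),
                _contrast("d2", {"D": "up", "E": "down", "F": "up", "G": "down"}),
            ]
        )
        assert len(sig.directions) == 7

    def test_drug_timepoints_intersection(self):
        tps = [
            _contrast("12h", {"A": "up", "B": "down"}),
            _contrast("24h", {"A": "up", "C": "up"}),
            _contrast("48h", {"A": "up", "B": "down"}),
        ]
        sig = combine_drug_timepoints(tps)
        assert sig.directions == {"A": "up"}

    def test_drug_timepoint_direction_conflict_excluded(self):
        tps = [_contrast("12h", {"A": "up"}), _contrast("24h", {"A": "down"})]
        sig = combine_drug_timepoints(tps)
        assert sig.directions == {}
        assert sig.conflicting == {"A"}

    def test_single_timepoint_is_identity(self):
        sig = combine_drug_timepoints([_contrast("only", {"A": "up", "B": "down"})])
        assert sig.directions == {"A": "up", "B": "down"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            combine_disease_datasets([])
        with pytest.raises(ValueError):
            combine_drug_timepoints([])
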