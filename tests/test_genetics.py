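"""Cell-set polygenic scores, partial correlation, and subtype validation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from corticell.containers import GenotypeBundle
from corticell.errors import InputError, NumericalError
from corticell.genetics import (
    cell_prs,
    genomewide_prs,
    membership_sweep,
    partial_corr,
    snps_for_cell_type,
    subtype_score,
    validate_subtypes,
)
from corticell.containers import GeneSetCollection


def toy_bundle(dosages, weights, annotation=None, gene_spans=None):
    dosages = pd.DataFrame(dosages)
    dosages.index = [f"s{i}" for i in range(len(dosages))]
    dosages.columns = [f"rs{j}" for j in range(dosages.shape[1])]
    if annotation is None:
        annotation = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": 100 * (np.arange(dosages.shape[1]) + 1),
                "gene_id": [f"g{j}" for j in range(dosages.shape[1])],
            },
            index=dosages.columns,
        )
    wdf = pd.DataFrame(
        {"effect_allele": "A", "beta": weights}, index=dosages.columns
    )
    rel = pd.Series(0.0, index=dosages.index)
    return GenotypeBundle(dosages, annotation, wdf, rel, gene_spans)


class TestSnpSelection:
    def test_gene_membership_enumeration(self):
        bundle = toy_bundle(np.zeros((3, 5)) + 1, [0.1] * 5)
        bundle.annotation["gene_id"] = ["gA", "gA", "gB", "gB", "gB"]
        sets = GeneSetCollection({"neuron": ("gA",), "glia": ("gB",)})
        assert snps_for_cell_type(bundle, sets, "neuron") == ["rs0", "rs1"]
        assert snps_for_cell_type(bundle, sets, "glia") == ["rs2", "rs3", "rs4"]

    def test_positional_boundary_is_closed_interval(self):
        spans = pd.DataFrame(
            {"chrom": ["chr1"], "start": [300], "end": [400]},
            index=pd.Index(["gA"], name="gene_id"),
        )
        bundle = toy_bundle(np.ones((3, 5)), [0.1] * 5, gene_spans=spans)
        # positions are 100, 200, 300, 400, 500
        sets = GeneSetCollection({"neuron": ("gA",)})
        assert snps_for_cell_type(bundle, sets, "neuron", boundary_kb=0) == ["rs2", "rs3"]
        assert snps_for_cell_type(bundle, sets, "neuron", boundary_kb=0.1) == [
            "rs1", "rs2", "rs3", "rs4",
        ]

    def test_disjoint_sets_give_disjoint_snp_lists(self, default_bundle):
        lists = {
            ct: set(snps_for_cell_type(default_bundle.genotypes,
                                       default_bundle.gene_sets, ct))
            for ct in default_bundle.gene_sets.names
        }
        names = list(lists)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert not lists[a] & lists[b]

    def test_empty_selection_names_cell_type(self):
        bundle = toy_bundle(np.ones((3, 2)), [0.1, 0.2])
        sets = GeneSetCollection({"ghost": ("not_a_gene",)})
        with pytest.raises(InputError, match="ghost"):
            snps_for_cell_type(bundle, sets, "ghost")


class TestCellPrs:
    def test_hand_computed_standardized_scores(self):
        bundle = toy_bundle([[0, 1, 2], [2, 1, 0]], [0.1, 0.2, -0.1])
        score = cell_prs(bundle, ["rs0", "rs1", "rs2"])
        np.testing.assert_allclose(
            score.to_numpy(), [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12
        )

    def test_zero_weights_degenerate(self):
        bundle = toy_bundle([[0, 1], [2, 1], [1, 0]], [0.0, 0.0])
        with pytest.raises(NumericalError, match="degenerate"):
            cell_prs(bundle, ["rs0", "rs1"])

    def test_invariant_to_weight_rescaling(self):
        rng = np.random.default_rng(0)
        d = rng.integers(0, 3, (20, 6)).astype(float)
        w = rng.normal(0, 0.1, 6)
        a = cell_prs(toy_bundle(d, w), [f"rs{j}" for j in range(6)])
        b = cell_prs(toy_bundle(d, 2 * w), [f"rs{j}" for j in range(6)])
        pd.testing.assert_series_equal(a, b)


class TestSubtypeScore:
    def test_single_cell_type_passthrough(self):
        scores = pd.DataFrame(
            {"a": [1.0, -1.0, 0.5, -0.5], "b": [0.1, 0.2, -0.1, -0.2]}
        )
        agg = subtype_score(scores, ["a"])
        expected = (scores["a"] - scores["a"].mean()) / scores["a"].std(ddof=1)
        np.testing.assert_allclose(agg, expected, atol=1e-12)

    def test_mean_of_uncorrelated_scores_has_half_variance(self):
        rng = np.random.default_rng(1)
        scores = pd.DataFrame(rng.standard_normal((4000, 2)), columns=["a", "b"])
        scores = (scores - scores.mean()) / scores.std(ddof=1)
        raw_var = scores[["a", "b"]].mean(axis=1).var(ddof=1)
        assert raw_var == pytest.approx(0.5, abs=0.05)
        agg = subtype_score(scores, ["a", "b"])
        assert agg.std(ddof=1) == pytest.approx(1.0)

    def test_signature_order_irrelevant(self):
        rng = np.random.default_rng(2)
        scores = pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc"))
        pd.testing.assert_series_equal(
            subtype_score(scores, ["a", "b", "c"]),
            subtype_score(scores, ["c", "a", "b"]),
        )

    def test_empty_signature_rejected(self):
        with pytest.raises(InputError, match="signature"):
            subtype_score(pd.DataFrame({"a": [1.0, 2.0]}), [])


class TestPartialCorr:
    def test_no_covariates_equals_pearson(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        r, p = partial_corr(x, y)
        r_ref, p_ref = stats.pearsonr(x, y)
        assert r == pytest.approx(r_ref)
        assert p == pytest.approx(p_ref, rel=1e-6)

    def test_covariate_equal_to_x_degenerate(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(30)
        y = rng.standard_normal(30)
        with pytest.raises(NumericalError, match="covariates"):
            partial_corr(x, y, x[:, None])

    @pytest.mark.parametrize("trial", range(8))
    def test_matches_precision_matrix_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n, q = 20, 2
        z = rng.standard_normal((n, q))
        x = z @ rng.standard_normal(q) + rng.standard_normal(n)
        y = z @ rng.standard_normal(q) + rng.standard_normal(n)
        r, _ = partial_corr(x, y, z)
        # oracle: partial correlation from the inverse correlation matrix
        m = np.corrcoef(np.column_stack([x, y, z]), rowvar=False)
        prec = np.linalg.inv(m)
        oracle = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        assert r == pytest.approx(oracle, abs=1e-10)

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_pingouin(self, trial):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(200 + trial)
        n = 30
        frame = pd.DataFrame(
            rng.standard_normal((n, 4)), columns=["x", "y", "c1", "c2"]
        )
        r, p = partial_corr(
            frame["x"], frame["y"], frame[["c1", "c2"]].to_numpy()
        )
        ref = pingouin.partial_corr(frame, x="x", y="y", covar=["c1", "c2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        p_col = next(c for c in ("p-val", "p_val", "p-unc") if c in ref.columns)
        assert p == pytest.approx(float(ref[p_col].iloc[0]), abs=1e-8)

    def test_type_one_error_near_alpha_with_prs_covariates(self, default_bundle):
        # null generator: outcome independent of every score; the partial
        # correlation with sex/genome-wide/relatedness covariates must reject
        # at ~alpha
        bundle = default_bundle.genotypes
        score = genomewide_prs(bundle)
        sex = default_bundle.patients.demographics["sex"]
        rng = np.random.default_rng(17)
        rejections = 0
        n_rep = 400
        cov = np.column_stack([sex, bundle.relatedness])
        for _ in range(n_rep):
            y = rng.standard_normal(len(score))
            _, p = partial_corr(score.to_numpy(), y, cov)
            rejections += p < 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.03)


class TestValidateSubtypes:
    @pytest.fixture(scope="class")
    def truth_validation(self, default_bundle, default_coupling, default_deviations):
        """Validation run against the planted (truth) subtype labels."""
        from corticell.subtypes import soft_membership, subtype_profiles

        labels = default_bundle.truth.labels
        coupling = default_coupling.loc[labels.index]
        prof = subtype_profiles(coupling, default_deviations.delta_z, labels)

        class TruthSolution:
            hard_labels = labels
            memberships = soft_membership(
                coupling, labels
            )

        result = validate_subtypes(
            default_deviations.delta_z, TruthSolution(), default_bundle.genotypes,
            default_bundle.gene_sets, prof,
            sex=default_bundle.patients.demographics["sex"],
        )
        return result

    def test_matched_partial_correlations_negative(self, truth_validation):
        assert (truth_validation.primary["partial_r"] < 0).all()
        assert len(truth_validation.primary) == 3

    def test_matched_effects_significant(self, truth_validation):
        # planted burden -> severity link must be recoverable at FDR < 0.05
        # for the majority of subtypes in the canonical study
        assert (truth_validation.primary["fdr_p"] < 0.05).sum() >= 2

    def test_specificity_of_disjoint_planted_signatures(self, default_bundle,
                                                        default_deviations):
        # subtype I (neuronal/endothelial) and III (astrocyte/OPC) share no
        # marker sets and effect weights are independent, so the crossed
        # score-vs-members correlations carry no planted signal; pooled over
        # replicates they are overwhelmingly non-significant
        import warnings

        from corticell import deviation_scores, fit_normative_model
        from corticell.simulate import SimConfig, gen_fixture_bundle

        planted = {"I": ["excitatory", "inhibitory", "endothelial"],
                   "III": ["astrocyte", "OPC"]}
        crossed_p = []
        for seed, bundle, deviations in [
            (None, default_bundle, default_deviations),
            (301, None, None),
            (302, None, None),
        ]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if bundle is None:
                    bundle = gen_fixture_bundle(SimConfig(seed=seed))
                    model = fit_normative_model(bundle.healthy)
                    deviations = deviation_scores(model, bundle.patients)
            severity = deviations.delta_z.mean(axis=1)
            labels = bundle.truth.labels
            scores = pd.DataFrame(
                {
                    ct: cell_prs(
                        bundle.genotypes,
                        snps_for_cell_type(bundle.genotypes, bundle.gene_sets, ct),
                    )
                    for ct in bundle.gene_sets.names
                }
            )
            gw = genomewide_prs(bundle.genotypes)
            sex = bundle.patients.demographics["sex"]
            for score_of, tested_in in (("I", "III"), ("III", "I")):
                members = labels.index[labels == tested_in]
                score = subtype_score(scores, planted[score_of])
                cov = np.column_stack(
                    [sex.loc[members], gw.loc[members],
                     bundle.genotypes.relatedness.loc[members]]
                )
                _, p = partial_corr(
                    score.loc[members].to_numpy(), severity.loc[members].to_numpy(),
                    cov,
                )
                crossed_p.append(p)
        assert np.mean(np.array(crossed_p) > 0.05) >= 0.75

    def test_sweep_threshold_zero_reproduces_primary(self, truth_validation):
        base = truth_validation.primary.set_index("subtype")["partial_r"]
        sweep0 = truth_validation.sweep[truth_validation.sweep["threshold"] == 0.0]
        for _, row in sweep0.iterrows():
            assert row["partial_r"] == pytest.approx(base[row["subtype"]])

    def test_sign_recovery_across_replicates(self):
        # planted slope (+0.3) with negative mean shifts must yield negative
        # matched partial correlations in (nearly) every replicate
        import warnings

        from corticell import (
            build_cell_map,
            compute_coupling,
            deviation_scores,
            fit_normative_model,
        )
        from corticell.simulate import SimConfig, gen_fixture_bundle
        from corticell.subtypes import soft_membership, subtype_profiles

        signs = []
        for seed in (301, 302, 303):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                b = gen_fixture_bundle(SimConfig(seed=seed))
                model = fit_normative_model(b.healthy)
                dev = deviation_scores(model, b.patients)
                cmap = build_cell_map(b.expression, b.gene_sets)
                coupling = compute_coupling(dev.delta_z, cmap)
                prof = subtype_profiles(coupling, dev.delta_z, b.truth.labels)

                class TruthSolution:
                    hard_labels = b.truth.labels
                    memberships = soft_membership(coupling, b.truth.labels)

                result = validate_subtypes(
                    dev.delta_z, TruthSolution(), b.genotypes, b.gene_sets, prof,
                    sex=b.patients.demographics["sex"],
                )
            signs.extend((result.primary["partial_r"] < 0).tolist())
        assert np.mean(signs) >= 0.95


class TestMembershipSweep:
    def test_contract_thresholds_and_missing_rows(self, default_bundle,
                                                  default_coupling,
                                                  default_deviations):
        from corticell.subtypes import soft_membership

        labels = default_bundle.truth.labels

        class TruthSolution:
            hard_labels = labels
            memberships = soft_membership(default_coupling.loc[labels.index], labels)

        score = genomewide_prs(default_bundle.genotypes)
        severity = default_deviations.delta_z.mean(axis=1)
        table = membership_sweep(
            TruthSolution(), score, severity, None, "I",
            thresholds=(0.0, 0.3, 0.99),
        )
        assert list(table["threshold"]) == [0.0, 0.3, 0.99]
        assert table.iloc[0]["n"] == (labels == "I").sum()
        assert np.isnan(table.iloc[-1]["partial_r"])  # nearly everyone excluded

    def test_unsorted_thresholds_rejected(self, default_bundle, default_coupling):
        from corticell.subtypes import soft_membership

        labels = default_bundle.truth.labels

        class TruthSolution:
            hard_labels = labels
            memberships = soft_membership(default_coupling.loc[labels.index], labels)

        score = genomewide_prs(default_bundle.genotypes)
        with pytest.raises(InputError):
            membership_sweep(
                TruthSolution(), score, score, None, "I", thresholds=(0.5, 0.2)
            )
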