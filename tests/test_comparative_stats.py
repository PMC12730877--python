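"""Group comparisons, trait correlations, independent contrasts, clustering, enrichment."""

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from scipy.special import comb

import cubtools as ct


class TestGroupCompare:
    def test_disjoint_supports_reject_strongly(self):
        values = {f"a{i}": float(i) for i in range(10)}
        values.update({f"b{i}": 100.0 + i for i in range(10)})
        groups = {k: k[0] for k in values}
        comparison = ct.group_compare(values, groups, trait="enc")
        assert comparison.pairwise.p_adj.item() < 0.001
        assert comparison.kw_p < 0.001

    def test_identical_group_duplicated_shows_no_signal(self):
        base = [1.0, 2.0, 3.0, 4.0, 5.0]
        values = {f"a{i}": v for i, v in enumerate(base)}
        values.update({f"b{i}": v for i, v in enumerate(base)})
        groups = {k: k[0] for k in values}
        comparison = ct.group_compare(values, groups)
        assert comparison.pairwise.p_adj.item() == pytest.approx(1.0)

    def test_small_groups_excluded_with_remaining_compared(self):
        values = {"a1": 1.0, "a2": 2.0, "b1": 10.0, "b2": 11.0, "solo": 5.0}
        groups = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "solo": "C"}
        comparison = ct.group_compare(values, groups)
        assert comparison.excluded_groups == ("C",)
        assert set(comparison.pairwise.group1) | set(comparison.pairwise.group2) == {"A", "B"}

    def test_fewer_than_two_usable_groups_errors(self):
        with pytest.raises(ValueError):
            ct.group_compare({"a1": 1.0, "a2": 2.0, "b1": 3.0}, {"a1": "A", "a2": "A", "b1": "B"})

    def test_bonferroni_never_decreases_and_caps_at_one(self):
        rng = np.random.default_rng(0)
        values, groups = {}, {}
        for g in "ABCD":
            for i in range(5):
                gid = f"{g}{i}"
                values[gid] = float(rng.normal())
                groups[gid] = g
        comparison = ct.group_compare(values, groups)
        assert comparison.n_comparisons == 6
        assert (comparison.pairwise.p_adj >= comparison.pairwise.p_raw - 1e-15).all()
        assert (comparison.pairwise.p_adj <= 1.0).all()

    def test_type_one_error_controlled_under_null(self):
        rejections = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            values = {f"a{i}": float(v) for i, v in enumerate(rng.normal(size=10))}
            values.update({f"b{i}": float(v) for i, v in enumerate(rng.normal(size=10))})
            groups = {k: k[0] for k in values}
            comparison = ct.group_compare(values, groups)
            if comparison.pairwise.p_adj.item() < 0.05:
                rejections += 1
        assert rejections / n_seeds <= 0.06  # >= 94% of seeds accept

    def test_pretest_normality_reports_both_tests(self):
        rng = np.random.default_rng(1)
        values = {f"g{i}": float(v) for i, v in enumerate(rng.normal(size=12))}
        groups = {f"g{i}": "A" if i < 6 else "B" for i in range(12)}
        table = ct.pretest_normality(values, groups)
        assert set(table.test) == {"shapiro", "bartlett"}


class TestSpearman:
    def test_monotone_transform_gives_one(self):
        x = {f"g{i}": float(i) for i in range(8)}
        y = {k: math.exp(v) for k, v in x.items()}
        rho, _ = ct.spearman_corr(x, y)
        assert rho == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = {f"g{i}": float(i) for i in range(8)}
        y = {k: -v for k, v in x.items()}
        rho, _ = ct.spearman_corr(x, y)
        assert rho == pytest.approx(-1.0)

    def test_six_point_hand_value(self):
        # ranks of y: one adjacent swap; rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 12/210
        x = {f"g{i}": float(i) for i in range(6)}
        y = {"g0": 0.0, "g1": 1.0, "g2": 3.0, "g3": 2.0, "g4": 4.0, "g5": 5.0}
        rho, _ = ct.spearman_corr(x, y)
        assert rho == pytest.approx(1 - 12 / 210)

    def test_too_few_shared_genomes_errors(self):
        with pytest.raises(ValueError):
            ct.spearman_corr({"a": 1.0, "b": 2.0, "c": 3.0}, {"a": 1.0, "b": 2.0, "c": 3.0})


class TestPicContrasts:
    def test_two_tip_hand_value(self):
        contrasts = ct.pic_contrasts("(A:1,B:1);", {"A": 3.0, "B": 1.0})
        assert abs(contrasts.item()) == pytest.approx(2 / math.sqrt(2))

    def test_identical_tip_values_give_zero_contrasts(self):
        nwk = "((A:1,B:2):0.5,(C:1,D:1):0.5);"
        contrasts = ct.pic_contrasts(nwk, {t: 7.0 for t in "ABCD"})
        assert np.allclose(contrasts, 0.0)

    def test_zero_length_resolved_star_reproduces_scaled_differences(self):
        # a star resolved into zero-length bifurcations: hand-evaluated recursion
        nwk = "(((A:1,B:1):0,C:1):0,D:1);"
        values = {"A": 1.0, "B": 5.0, "C": 2.0, "D": 2.0}
        contrasts = ct.pic_contrasts(nwk, values)
        expected = [
            4 / math.sqrt(2),            # (A,B) cherry
            1 / math.sqrt(1.5),          # mean(A,B)=3 vs C over 0.5+1
            (8 / 3 - 2) / math.sqrt(4 / 3),  # weighted node 8/3 vs D
        ]
        assert np.allclose(sorted(np.abs(contrasts)), sorted(expected))

    def test_missing_tip_value_errors(self):
        with pytest.raises(ValueError, match="without trait values"):
            ct.pic_contrasts("(A:1,B:1);", {"A": 1.0})

    def test_zero_length_sibling_pair_errors(self):
        with pytest.raises(ValueError, match="zero-length"):
            ct.pic_contrasts("(A:0,B:0);", {"A": 1.0, "B": 2.0})

    def test_matches_ape_pic_oracle(self, tmp_path):
        """Cross-check against the reference implementation in R's ape package."""
        rscript = shutil.which("Rscript")
        assert rscript is not None, "Rscript expected on PATH"
        nwk = "((A:1,B:2):0.5,((C:0.7,D:1.3):0.6,(E:1.2,F:0.3):0.4):1.1);"
        values = {"A": 1.0, "B": 3.5, "C": -2.0, "D": 0.7, "E": 4.2, "F": 0.1}
        script = tmp_path / "pic.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(ape))
                tree <- read.tree(text="{nwk}")
                x <- c(A=1.0, B=3.5, C=-2.0, D=0.7, E=4.2, F=0.1)
                cat(sprintf("%.12f\\n", pic(x[tree$tip.label], tree)))
                """
            )
        )
        out = subprocess.run(
            [rscript, str(script)], capture_output=True, text=True, check=True
        )
        expected = sorted(abs(float(line)) for line in out.stdout.split())
        ours = sorted(np.abs(ct.pic_contrasts(nwk, values)))
        assert np.allclose(ours, expected, atol=1e-9)


class TestCorrelateContrasts:
    def test_proportional_contrasts_give_one(self):
        cx = np.array([1.0, -2.0, 0.5, 3.0])
        rho, p = ct.correlate_contrasts(cx, 2 * cx)
        assert rho == pytest.approx(1.0)
        assert p < 1e-6

    def test_constructed_orthogonal_vectors_give_zero(self):
        cx = np.array([1.0, 1.0, -1.0, -1.0])
        cy = np.array([1.0, -1.0, 1.0, -1.0])
        rho, p = ct.correlate_contrasts(cx, cy)
        assert rho == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            ct.correlate_contrasts([1.0, 2.0], [1.0])

    def test_brownian_motion_recovery(self):
        rhos = []
        for seed in range(10):
            nwk, traits = ct.simulate_tree_and_traits(
                ct.TreeSimSpec(n_tips=64, bm_correlation=0.8, seed=seed)
            )
            table = traits.set_index("genome_id")
            cx = ct.pic_contrasts(nwk, table.trait1.to_dict())
            cy = ct.pic_contrasts(nwk, table.trait2.to_dict())
            rhos.append(ct.correlate_contrasts(cx, cy)[0])
        assert abs(np.median(rhos) - 0.8) < 0.15

    def test_null_rejection_rate_near_alpha(self):
        rejections = []
        for seed in range(60):
            nwk, traits = ct.simulate_tree_and_traits(
                ct.TreeSimSpec(n_tips=32, bm_correlation=0.0, seed=seed)
            )
            table = traits.set_index("genome_id")
            cx = ct.pic_contrasts(nwk, table.trait1.to_dict())
            cy = ct.pic_contrasts(nwk, table.trait2.to_dict())
            rejections.append(ct.correlate_contrasts(cx, cy)[1] < 0.05)
        assert 0.0 <= np.mean(rejections) <= 0.15


class TestClusterGenomes:
    def test_identical_profiles_merge_at_zero(self):
        z, order = ct.cluster_genomes({"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [5.0, 5.0]})
        assert z[0, 2] == pytest.approx(0.0)
        assert set(order) == {"a", "b", "c"}

    def test_close_pair_merges_first(self):
        profiles = {"a": [0.0], "b": [1.0], "c": [11.0]}
        z, order = ct.cluster_genomes(profiles)
        assert z[0, 2] == pytest.approx(1.0)  # a-b merge
        assert order.index("c") in (0, 2)  # outlier on an edge of the dendrogram

    def test_input_order_invariance_of_heights(self):
        rng = np.random.default_rng(5)
        profiles = {f"g{i}": rng.normal(size=6).tolist() for i in range(8)}
        z1, _ = ct.cluster_genomes(profiles)
        shuffled = {k: profiles[k] for k in reversed(list(profiles))}
        z2, _ = ct.cluster_genomes(shuffled)
        assert np.allclose(sorted(z1[:, 2]), sorted(z2[:, 2]))

    def test_unequal_vector_lengths_error(self):
        with pytest.raises(ValueError):
            ct.cluster_genomes({"a": [1.0, 2.0], "b": [1.0]})

    def test_missing_values_rejected_until_imputed(self):
        import pandas as pd

        matrix = pd.DataFrame({"x": [1.0, np.nan], "y": [0.5, 0.5]}, index=["a", "b"])
        with pytest.raises(ValueError):
            ct.cluster_genomes(matrix)
        z, _ = ct.cluster_genomes(ct.impute_rscu(matrix))
        assert z.shape == (1, 4)


class TestTermEnrichment:
    def test_study_equal_to_population_gives_p_one(self):
        population = {f"g{i}" for i in range(20)}
        annotations = {g: {"T1"} for g in population}
        rows = ct.term_enrichment(population, population, annotations)
        assert rows.p_raw.item() == pytest.approx(1.0)

    def test_extreme_enrichment_hypergeometric_tail(self):
        population = {f"g{i}" for i in range(100)}
        carriers = {f"g{i}" for i in range(10)}
        annotations = {g: {"T1"} for g in carriers}
        rows = ct.term_enrichment(carriers, population, annotations)
        assert rows.p_raw.item() == pytest.approx(1 / comb(100, 10), rel=1e-9)

    def test_terms_absent_from_study_not_tested(self):
        population = {"a", "b", "c", "d"}
        annotations = {"a": {"T1"}, "b": {"T2"}, "c": {"T2"}}
        rows = ct.term_enrichment({"b", "c"}, population, annotations)
        assert set(rows.term) == {"T2"}

    def test_bonferroni_uses_number_of_tested_terms(self):
        population = {f"g{i}" for i in range(30)}
        annotations = {f"g{i}": {f"T{i % 3}"} for i in range(30)}
        study = {f"g{i}" for i in range(6)}
        rows = ct.term_enrichment(study, population, annotations)
        assert np.allclose(
            rows.p_bonferroni, np.minimum(1.0, rows.p_raw * len(rows))
        )

    def test_empty_study_errors(self):
        with pytest.raises(ValueError):
            ct.term_enrichment(set(), {"a"}, {})

    def test_study_not_subset_errors(self):
        with pytest.raises(ValueError):
            ct.term_enrichment({"x"}, {"a"}, {})


def test_group_separation_on_simulated_cohort(small_cohort):
    """Genome-wide GC3 differs between cohorts generated at GC3 0.58 vs 0.72."""
    profiles = {
        g.spec.genome_id: ct.genome_profile(g.genes, group=g.spec.group)
        for g in small_cohort["genomes"]
    }
    values = {gid: p.gc3_genomewide for gid, p in profiles.items()}
    groups = {gid: p.group for gid, p in profiles.items()}
    comparison = ct.group_compare(values, groups, trait="gc3")
    assert comparison.pairwise.p_adj.item() < 0.05
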