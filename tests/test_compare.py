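import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polskit.compare import compare_behaviour_smr, compare_lht_means
from polskit.simulate import SimulationConfig, generate_trait_panel

from conftest import univariate_config


def two_pop_config(direct_shift=0.0, size_shift=0.0, n=40, seed=0, smr_size_corr=0.0):
    """SMR + size panel where the populations may differ in size, in SMR
    directly, or in SMR only through their size difference."""
    c = smr_size_corr
    si = np.array([[0.25, c * 0.25], [c * 0.25, 0.25]])
    sr = np.eye(2) * 0.25
    beta = {
        "SG": {"smr": {"intercept": direct_shift / 2}, "standard_size": {"intercept": size_shift / 2}},
        "FG": {"smr": {"intercept": -direct_shift / 2}, "standard_size": {"intercept": -size_shift / 2}},
    }
    return SimulationConfig(
        n_individuals_per_population=n,
        trait_names=["smr", "standard_size"],
        populations=("SG", "FG"),
        sigma_ind={p: si for p in ("SG", "FG")},
        sigma_res={p: sr for p in ("SG", "FG")},
        beta=beta,
        measurement_schedule={"smr": 1, "standard_size": 1},
        missing_rate={},
        seed=seed,
    )


class TestLhtComparison:
    def test_detects_one_sd_size_difference(self):
        hits = 0
        for s in range(20):
            cfg = two_pop_config(size_shift=1.0, n=40, seed=s)
            panel = generate_trait_panel(cfg)
            cmp_ = compare_lht_means(panel, "standard_size")
            hits += cmp_.p_value < 0.01
        assert hits >= 19  # >=95% power expected at this effect size

    def test_null_p_values_are_uniform(self):
        ps = []
        for s in range(200):
            cfg = univariate_config(
                0.0, 1.0, n=100, per_stage=1, seed=s, populations=("SG", "FG")
            )
            panel = generate_trait_panel(cfg)
            panel = panel[panel.age_stage < 0]  # one measure per individual
            ps.append(compare_lht_means(panel, "x").p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_full_mediation_zeroes_population_coefficient(self):
        # trait difference produced entirely through the covariate: the
        # adjusted population effect must vanish
        rng = np.random.default_rng(5)
        n = 400
        pop = np.array(["SG"] * n + ["FG"] * n)
        size = rng.normal(0, 1, 2 * n) + np.where(pop == "SG", 1.0, -1.0)
        y = 0.8 * size + rng.normal(0, 0.1, 2 * n)
        rows = []
        for i in range(2 * n):
            rows.append((f"i{i}", pop[i], 0.0, -0.5, 0, "y", y[i]))
            rows.append((f"i{i}", pop[i], 0.0, -0.5, 0, "size", size[i]))
        panel = pd.DataFrame(
            rows,
            columns=["individual_id", "population", "sex", "age_stage", "trial", "trait", "value"],
        )
        adj = compare_lht_means(panel, "y", adjust_for="size")
        unadj = compare_lht_means(panel, "y")
        assert abs(unadj.difference) > 1.0
        assert adj.difference == pytest.approx(0.0, abs=3 * adj.difference_se)


class TestBehaviourSmrComparison:
    def test_marginal_difference_equals_population_coefficient(self, study_panel):
        cmp_ = compare_behaviour_smr(study_panel, "hiding_time")
        fit = cmp_.fit
        i = fit.fixed_names[""].index("population")
        assert cmp_.difference == pytest.approx(fit.beta[""][i], rel=1e-10)
        assert cmp_.means[1] - cmp_.means[0] == pytest.approx(cmp_.difference, rel=1e-10)

    @staticmethod
    def _mediated_panel(direct=0.5, size_shift=1.0, slope=0.8, n=60, seed=0):
        """SMR depends structurally on size; populations differ in size and
        carry an additional direct SMR shift."""
        rng = np.random.default_rng(seed)
        rows = []
        for g, (pop, code) in enumerate((("SG", 0.5), ("FG", -0.5))):
            u_size = rng.normal(0, 0.5, n)
            u_smr = rng.normal(0, 0.5, n)
            sexes = rng.choice([-0.5, 0.5], n)
            for i in range(n):
                for stage in (-0.5, 0.5):
                    size = size_shift * code + u_size[i] + rng.normal(0, 0.3)
                    smr = direct * code + slope * size + u_smr[i] + rng.normal(0, 0.3)
                    rows.append((f"{pop}{i}", pop, sexes[i], stage, 0, "standard_size", size))
                    rows.append((f"{pop}{i}", pop, sexes[i], stage, 0, "smr", smr))
        return pd.DataFrame(
            rows,
            columns=["individual_id", "population", "sex", "age_stage", "trial",
                     "trait", "value"],
        )

    def test_adjustment_recovers_direct_shift_under_size_confounding(self):
        # population SMR shift of 0.5 SD rides on a 1 SD size shift that
        # feeds SMR through a within-individual slope: the size-adjusted
        # comparison must isolate the direct shift, the unadjusted one
        # absorbs the mediated part (direct + slope * size_shift)
        diffs_adj, diffs_raw = [], []
        for s in range(15):
            panel = self._mediated_panel(seed=s)
            adj = compare_behaviour_smr(panel, "smr", covariates=("standard_size",))
            raw = compare_behaviour_smr(panel, "smr", covariates=())
            diffs_adj.append(adj.difference)  # SG - FG (SG coded +0.5)
            diffs_raw.append(raw.difference)
        for diffs, target in ((diffs_adj, 0.5), (diffs_raw, 0.5 + 0.8 * 1.0)):
            mcse = np.std(diffs, ddof=1) / np.sqrt(len(diffs))
            assert abs(np.mean(diffs) - target) < 3 * mcse

    def test_adjusted_and_unadjusted_agree_without_covariate_effects(self):
        cfg = two_pop_config(direct_shift=0.6, size_shift=0.0, n=80, seed=4)
        panel = generate_trait_panel(cfg)
        adj = compare_behaviour_smr(panel, "smr", covariates=("standard_size",))
        unadj = compare_behaviour_smr(panel, "smr", covariates=())
        assert adj.difference == pytest.approx(unadj.difference, abs=0.1)

    def test_marginal_means_invariant_to_population_relabeling(self, study_panel):
        cmp1 = compare_behaviour_smr(study_panel, "smr")
        flipped = study_panel.assign(
            population=study_panel.population.map({"SG": "A_SG", "FG": "Z_FG"})
        )
        cmp2 = compare_behaviour_smr(flipped, "smr")
        # label order flips the coding; the per-population means must not move
        m1 = dict(zip(cmp1.populations, cmp1.means))
        m2 = dict(zip(cmp2.populations, cmp2.means))
        assert m1["SG"] == pytest.approx(m2["A_SG"], abs=1e-6)
        assert m1["FG"] == pytest.approx(m2["Z_FG"], abs=1e-6)

    def test_missing_covariates_are_dropped_gracefully(self, study_panel):
        cmp_ = compare_behaviour_smr(study_panel, "distance_moved")
        # panel has no fulton_k trait: adjustment reports what was used
        assert cmp_.covariate_adjustment == "standard_size"

    def test_type_one_error_for_population_term(self):
        rej, reps = 0, 200
        for s in range(reps):
            cfg = two_pop_config(direct_shift=0.0, size_shift=0.0, n=40, seed=1000 + s)
            panel = generate_trait_panel(cfg)
            cmp_ = compare_behaviour_smr(panel, "smr", covariates=())
            rej += cmp_.p_value < 0.05
        tol = 3 * np.sqrt(0.05 * 0.95 / reps)
        assert abs(rej / reps - 0.05) < tol
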