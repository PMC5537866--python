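"""Probe QC, batch adjustment and surrogate-variable estimation."""

import subprocess
import tempfile

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dietmeth.batch import combat_adjust
from dietmeth.config import EffectConfig
from dietmeth.preprocess import compute_beta, filter_probes
from dietmeth.simulate import generate_methylation, generate_phenotypes
from dietmeth.sva import (estimate_surrogate_variables,
                          pca_covariate_association)
from dietmeth.transform import beta_to_m


class TestComputeBeta:
    @pytest.mark.parametrize("m, u, offset, expected", [
        (300, 700, 0, 0.30),
        (300, 700, 100, 300 / 1100),
        (0, 5, 0, 0.0),
    ])
    def test_fraction_of_methylated_signal(self, m, u, offset, expected):
        assert compute_beta(m, u, offset) == pytest.approx(expected)

    def test_zero_total_signal_is_missing(self):
        assert np.isnan(compute_beta(0, 0, 0))

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            compute_beta(-1, 5)


def _qc_fixture(rng, n_samples=20, n_probes=100):
    probes = [f"cg{i:04d}" for i in range(n_probes)]
    beta = pd.DataFrame(rng.uniform(0.1, 0.9, (n_samples, n_probes)),
                        columns=probes)
    detp = pd.DataFrame(np.zeros((n_samples, n_probes)), columns=probes)
    ann = pd.DataFrame({"probe_id": probes,
                        "chrom": ["chr1"] * n_probes,
                        "pos": np.arange(n_probes) * 1000 + 1,
                        "sex_chromosome": False, "multimap": False,
                        "snp_overlap": False})
    return beta, detp, ann


class TestFilterProbes:
    def test_sex_probes_removed(self, rng):
        beta, detp, ann = _qc_fixture(rng)
        ann.loc[:9, "sex_chromosome"] = True
        kept, report = filter_probes(beta, detp, ann)
        assert report.n_retained == 90 and kept.shape[1] == 90
        assert report.n_removed_sex == 10

    def test_detection_boundary_is_inclusive_at_fail_fraction(self, rng):
        beta, detp, ann = _qc_fixture(rng, n_samples=100)
        detp.iloc[:74, 0] = 0.5   # fails in 74% of samples -> retained
        detp.iloc[:75, 1] = 0.5   # fails in 75% of samples -> removed
        kept, report = filter_probes(beta, detp, ann)
        assert "cg0000" in kept.columns and "cg0001" not in kept.columns
        assert report.n_removed_detection == 1

    def test_overlapping_flags_counted_once_with_precedence(self, rng):
        beta, detp, ann = _qc_fixture(rng, n_samples=8)
        ann.loc[0:4, "sex_chromosome"] = True
        ann.loc[3:8, "multimap"] = True            # 3,4 overlap with sex
        ann.loc[7:12, "snp_overlap"] = True        # 7,8 overlap with multimap
        detp.iloc[:, 10:14] = 0.5
        ann.loc[12, "snp_overlap"] = True
        kept, report = filter_probes(beta, detp, ann)
        # independent per-probe re-scan under the stated precedence
        expected = {"sex": 0, "det": 0, "multi": 0, "snp": 0}
        for i in range(len(ann)):
            if ann.loc[i, "sex_chromosome"]:
                expected["sex"] += 1
            elif (detp.iloc[:, i] > 0.001).mean() >= 0.75:
                expected["det"] += 1
            elif ann.loc[i, "multimap"]:
                expected["multi"] += 1
            elif ann.loc[i, "snp_overlap"]:
                expected["snp"] += 1
        assert report.n_removed_sex == expected["sex"]
        assert report.n_removed_detection == expected["det"]
        assert report.n_removed_multimap == expected["multi"]
        assert report.n_removed_snp == expected["snp"]
        assert (report.n_input - report.n_retained
                == sum(expected.values()))

    def test_missing_annotation_names_probes(self, rng):
        beta, detp, ann = _qc_fixture(rng)
        with pytest.raises(ValueError, match="cg0099"):
            filter_probes(beta, detp, ann.iloc[:-1])


class TestCombat:
    def test_single_batch_is_identity(self, rng):
        beta = pd.DataFrame(rng.uniform(0.2, 0.8, (20, 30)))
        out = combat_adjust(beta, ["b1"] * 20)
        assert np.abs(out.to_numpy() - beta.to_numpy()).max() < 1e-8

    def test_singleton_batch_rejected_by_name(self, rng):
        beta = pd.DataFrame(rng.uniform(0.2, 0.8, (5, 10)))
        with pytest.raises(ValueError, match="lonely"):
            combat_adjust(beta, ["a", "a", "a", "a", "lonely"])

    def test_batch_shift_removed(self):
        """Planted chip effects leave no detectable batch signal behind."""
        fracs = []
        for seed in (0, 1, 2):
            cfg = EffectConfig(n_probes_total=300, seed=seed, batch_sd=0.5,
                               latent_loading_sd=0.0, effect_size=0.0)
            ph = generate_phenotypes(120, cfg)
            beta, _, _ = generate_methylation(ph, cfg)
            prot = ph[["fruit_servings", "juice_servings"]].set_axis(beta.index)
            adj = combat_adjust(beta, ph["chip"], prot)
            m = beta_to_m(adj.to_numpy())
            chips = ph["chip"].to_numpy()
            levels = np.unique(chips)
            pvals = np.array([
                stats.f_oneway(*(m[chips == c, j] for c in levels)).pvalue
                for j in range(m.shape[1])])
            fracs.append((pvals > 0.05).mean())
        assert min(fracs) >= 0.95

    def test_protected_exposure_slope_preserved(self):
        """Exposure slopes on planted probes survive adjustment (<10% shift)."""
        from dietmeth.ewas import energy_adjust, run_ewas
        cfg = EffectConfig(seed=3, n_probes_total=500, batch_sd=0.2,
                           latent_loading_sd=0.0, effect_size=0.08,
                           noise_sd=0.25)
        ph = generate_phenotypes(400, cfg)
        beta, _, truth = generate_methylation(ph, cfg)
        prot = ph[["fruit_servings", "juice_servings"]].set_axis(beta.index)
        adj = combat_adjust(beta, ph["chip"], prot)
        planted = truth.loc[truth["slope_a"] != 0, "probe_id"]
        x = energy_adjust(ph["fruit_servings"], ph["total_energy"])
        pre = run_ewas(beta, x, moderation=False).loc[planted, "slope"]
        post = run_ewas(adj, x, moderation=False).loc[planted, "slope"]
        rel = ((post - pre) / pre).abs()
        assert rel.median() < 0.10

    def test_second_pass_changes_little(self, rng):
        """Re-adjusting adjusted data moves it an order of magnitude less
        than the first pass (residual batch means are noise-level and get
        shrunk toward zero, so exact idempotency is not expected)."""
        cfg = EffectConfig(n_probes_total=300, seed=9, batch_sd=0.4,
                           latent_loading_sd=0.0, effect_size=0.0)
        ph = generate_phenotypes(200, cfg)
        beta, _, _ = generate_methylation(ph, cfg)
        once = combat_adjust(beta, ph["chip"])
        twice = combat_adjust(once, ph["chip"])
        d1 = np.abs(once.to_numpy() - beta.to_numpy()).max()
        d2 = np.abs(twice.to_numpy() - once.to_numpy()).max()
        assert d2 < 0.15 * d1

    def test_matches_reference_empirical_bayes_implementation(self, rng):
        """Cross-check against the R sva::ComBat oracle on a small Gaussian
        fixture (identity scale)."""
        n, g = 30, 40
        batch = np.repeat(["A", "B", "C"], 10)
        x = rng.normal(size=n)
        dat = (rng.normal(size=(n, g))
               + np.outer((batch == "B") * 1.0, rng.normal(0.8, 0.3, g))
               + np.outer(x, rng.normal(0, 0.2, g)))
        df = pd.DataFrame(dat, columns=[f"p{i}" for i in range(g)])
        mine = combat_adjust(df, batch, pd.DataFrame({"x": x}),
                             scale="identity")
        with tempfile.TemporaryDirectory() as d:
            pd.DataFrame(dat.T).to_csv(f"{d}/dat.csv", index=False)
            pd.DataFrame({"batch": batch, "x": x}).to_csv(f"{d}/ph.csv",
                                                          index=False)
            script = f"""
            suppressMessages(library(sva))
            dat <- as.matrix(read.csv("{d}/dat.csv"))
            ph <- read.csv("{d}/ph.csv")
            out <- ComBat(dat=dat, batch=ph$batch,
                          mod=model.matrix(~x, data=ph), par.prior=TRUE)
            write.csv(out, "{d}/out.csv", row.names=FALSE)
            """
            subprocess.run(["Rscript", "-e", script], check=True,
                           capture_output=True)
            theirs = pd.read_csv(f"{d}/out.csv").to_numpy().T
        assert np.abs(mine.to_numpy() - theirs).max() < 1e-4


class TestSurrogateVariables:
    def test_pure_noise_yields_rank_zero(self, rng):
        zeros = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            noise = pd.DataFrame(r.normal(size=(60, 150)))
            sv = estimate_surrogate_variables(noise, None, max_k=5, seed=seed)
            zeros += sv.k == 0
        assert zeros >= 9

    def test_planted_factor_recovered(self):
        cfg = EffectConfig(seed=5, n_probes_total=400, batch_sd=0.0,
                           latent_loading_sd=0.9, noise_sd=0.3, n_latent=1,
                           loading_sparsity=1.0, effect_size=0.0)
        ph = generate_phenotypes(200, cfg)
        beta, _, _ = generate_methylation(ph, cfg)
        m = pd.DataFrame(beta_to_m(beta.to_numpy()), index=beta.index,
                         columns=beta.columns)
        sv = estimate_surrogate_variables(
            m, ph[["fruit_servings"]], max_k=5, seed=0)
        assert sv.k >= 1
        r = np.corrcoef(sv.matrix[:, 0], ph["latent_1"])[0, 1]
        assert abs(r) > 0.9

    def test_zero_residual_yields_rank_zero(self, rng):
        x = rng.normal(size=50)
        data = pd.DataFrame(np.outer(x, rng.normal(size=40))
                            + rng.normal(size=(1, 40)))
        sv = estimate_surrogate_variables(data, pd.DataFrame({"x": x}),
                                          max_k=5, seed=0)
        assert sv.k == 0

    def test_columns_orthonormal(self):
        cfg = EffectConfig(seed=5, n_probes_total=200, latent_loading_sd=0.9,
                           n_latent=2, loading_sparsity=1.0, effect_size=0.0)
        ph = generate_phenotypes(100, cfg)
        beta, _, _ = generate_methylation(ph, cfg)
        sv = estimate_surrogate_variables(beta, None, max_k=4, seed=0)
        if sv.k:
            gram = sv.matrix.T @ sv.matrix
            assert np.allclose(gram, np.eye(sv.k), atol=1e-10)

    def test_invariant_to_sample_reordering_up_to_sign(self, rng):
        cfg = EffectConfig(seed=6, n_probes_total=200, latent_loading_sd=1.2,
                           n_latent=1, loading_sparsity=1.0, effect_size=0.0,
                           batch_sd=0.0)
        ph = generate_phenotypes(80, cfg)
        beta, _, _ = generate_methylation(ph, cfg)
        perm = rng.permutation(len(beta))
        sv1 = estimate_surrogate_variables(beta, None, max_k=2, seed=0)
        sv2 = estimate_surrogate_variables(beta.iloc[perm], None, max_k=2,
                                           seed=0)
        assert sv1.k == sv2.k >= 1
        aligned = sv2.matrix[np.argsort(perm), 0]
        r = np.corrcoef(sv1.matrix[:, 0], aligned)[0, 1]
        assert abs(abs(r) - 1) < 1e-6

    def test_max_k_must_be_below_sample_count(self, rng):
        data = pd.DataFrame(rng.normal(size=(10, 20)))
        with pytest.raises(ValueError):
            estimate_surrogate_variables(data, None, max_k=10)


class TestPcaCovariateAssociation:
    def test_dominant_chip_effect_tops_pc1(self):
        cfg = EffectConfig(seed=8, n_probes_total=300, batch_sd=1.5,
                           latent_loading_sd=0.0, effect_size=0.0,
                           noise_sd=0.2)
        ph = generate_phenotypes(120, cfg)
        beta, _, _ = generate_methylation(ph, cfg)
        cov = ph[["chip", "age", "sex"]]
        table = pca_covariate_association(beta, cov, n_pc=3)
        pc1 = table[table["pc"] == 1].iloc[0]
        assert pc1["covariate"] == "chip"

    def test_rank_one_matrix_explains_everything(self, rng):
        x = rng.normal(size=30)
        data = pd.DataFrame(np.outer(x, rng.normal(size=25)))
        table = pca_covariate_association(data, pd.DataFrame({"x": x}),
                                          n_pc=1)
        assert table["variance_explained"].iloc[0] > 0.999

    def test_constant_covariate_flagged_not_tested(self, rng):
        data = pd.DataFrame(rng.normal(size=(40, 30)))
        cov = pd.DataFrame({"const": np.ones(40), "x": rng.normal(size=40)})
        table = pca_covariate_association(data, cov, n_pc=2)
        const_rows = table[table["covariate"] == "const"]
        assert (const_rows["test"] == "constant").all()
        assert const_rows["p_value"].isna().all()
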