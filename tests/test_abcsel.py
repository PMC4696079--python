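import itertools
import math

import numpy as np
import pytest

from coalabc import abcsel, scenarios, sumstats
from coalabc.abcsel import (
    STAT_NAMES,
    AbcSettings,
    ReferenceTable,
    compute_sumstats,
    cross_validate,
    estimate_parameters,
    model_select,
    simulate_reference_table,
)
from coalabc.alignment import Alignment


def _three_region_alignment(seed=0, n_per=5):
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    ids, seqs, dm = [], [], {}
    for r in ("MEX", "SAL", "PER"):
        anchor = rng.integers(0, 4, size=30)
        for i in range(n_per):
            row = anchor.copy()
            flips = rng.integers(0, 30, size=2)
            row[flips] = rng.integers(0, 4, size=2)
            sid = f"{r}_{i}"
            ids.append(sid)
            seqs.append("".join(bases[row]))
            dm[sid] = r
    return Alignment(ids, seqs, dm)


def brute_force_vector(a):
    """All 15 statistics by direct enumeration (the independent oracle)."""
    out = []
    regions = ["MEX", "SAL", "PER"]
    m = a.matrix()
    labels = np.array(a.deme_labels)
    for r in regions:
        sub = m[labels == r]
        n = sub.shape[0]
        diffs = [
            (sub[i] != sub[j]).sum()
            for i, j in itertools.combinations(range(n), 2)
        ]
        k = float(np.mean(diffs))
        S = sum(1 for col in sub.T if len(set(col)) > 1)
        haps: dict = {}
        for row in sub:
            haps[tuple(row)] = haps.get(tuple(row), 0) + 1
        p = np.array(list(haps.values())) / n
        H = n / (n - 1) * (1 - (p**2).sum())
        D = sumstats.tajimas_d(n, S, k)
        out += [k / a.L, H, S, 0.0 if math.isnan(D) else D]
    for r1, r2 in (("MEX", "SAL"), ("MEX", "PER"), ("SAL", "PER")):
        idx = np.where((labels == r1) | (labels == r2))[0]
        sub = m[idx]
        z = labels[idx] == r1
        N = idx.size
        n1 = int(z.sum())
        n2 = N - n1
        d2 = np.array(
            [[(sub[i] != sub[j]).sum() for j in range(N)] for i in range(N)],
            dtype=float,
        )
        ss_t = d2.sum() / (2 * N)
        ss_w = (
            d2[np.ix_(z, z)].sum() / (2 * n1)
            + d2[np.ix_(~z, ~z)].sum() / (2 * n2)
        )
        sigma_c = ss_w / (N - 2)
        n_coef = N - (n1**2 + n2**2) / N
        sigma_b = (ss_t - ss_w - sigma_c) / n_coef
        out.append(sigma_b / (sigma_b + sigma_c))
    return np.array(out)


class TestComputeSumstats:
    def test_matches_brute_force_enumeration(self):
        a = _three_region_alignment(seed=3)
        np.testing.assert_allclose(
            compute_sumstats(a), brute_force_vector(a), rtol=1e-10
        )

    def test_identical_regions_all_zero(self):
        ids = [f"{r}_{i}" for r in ("MEX", "SAL", "PER") for i in range(4)]
        a = Alignment(
            ids, ["ACGT" * 5] * 12, {sid: sid.split("_")[0] for sid in ids}
        )
        v = compute_sumstats(a)
        np.testing.assert_allclose(v, 0.0)

    def test_deterministic_idempotent(self):
        a = _three_region_alignment(seed=9)
        v1, v2 = compute_sumstats(a), compute_sumstats(a)
        assert np.array_equal(v1, v2)

    def test_region_count_enforced(self, two_deme_alignment):
        with pytest.raises(ValueError, match="3 regions"):
            compute_sumstats(two_deme_alignment)

    def test_vector_length_and_names(self):
        assert len(STAT_NAMES) == 15
        a = _three_region_alignment()
        assert compute_sumstats(a).shape == (15,)


class TestReferenceTable:
    def test_single_row_reproducible(self):
        sizes = {"MEX": 6, "SAL": 6, "PER": 6}
        pri = scenarios.default_priors()
        t1 = simulate_reference_table("TOEMS", pri, 1, sizes, 77)
        t2 = simulate_reference_table("TOEMS", pri, 1, sizes, 77)
        np.testing.assert_array_equal(t1.stats, t2.stats)
        assert t1.params.equals(t2.params)

    def test_chunked_concatenation_deterministic(self):
        """Same seed -> identical rows regardless of other chunks."""
        sizes = {"MEX": 6, "SAL": 6, "PER": 6}
        pri = scenarios.default_priors()
        t5 = simulate_reference_table("NOSS", pri, 5, sizes, 123)
        t2 = simulate_reference_table("NOSS", pri, 2, sizes, 123)
        np.testing.assert_array_equal(t5.stats[:2], t2.stats)

    def test_prior_coverage_of_drawn_times(self, small_tables):
        t = small_tables[0]
        assert t.params["t1"].min() >= 150e3
        assert t.params["t1"].max() <= 300e3
        assert (t.params["t0"] < t.params["t1"]).all()

    def test_round_trip_tsv(self, tmp_path, small_tables):
        p = tmp_path / "table.tsv"
        small_tables[0].to_tsv(p)
        back = ReferenceTable.from_tsv(p)
        assert back.model_id == small_tables[0].model_id
        np.testing.assert_allclose(back.stats, small_tables[0].stats)

    def test_models_discriminable_in_tropical_diversity(self, small_tables):
        """TOEMS and NOSS tables differ in distribution (the signal the
        ABC uses)."""
        from scipy import stats as sps

        toems = small_tables[0]
        noss = small_tables[2]
        j = STAT_NAMES.index("SAL_pi")
        p = sps.ks_2samp(toems.stats[:, j], noss.stats[:, j]).pvalue
        assert p < 0.01


class TestModelSelect:
    def test_rejection_with_full_tolerance_recovers_prior(self, small_tables):
        """delta = 1 accepts everything: PP equals table-size frequencies."""
        obs = small_tables[0].stats[0]
        res = model_select(
            obs, small_tables, AbcSettings(tolerances=(1.0,), method="rejection")
        )
        for m, pp in res.posterior[1.0].items():
            assert pp == pytest.approx(0.25)

    def test_self_match_favours_true_model(self, small_tables):
        obs = small_tables[0].stats[5]
        res = model_select(
            obs, small_tables,
            AbcSettings(tolerances=(0.02,), method="rejection"),
        )
        assert res.best(0.02) == "TOEMS"

    def test_posteriors_sum_to_one(self, small_tables):
        obs = small_tables[1].stats[3]
        res = model_select(
            obs, small_tables,
            AbcSettings(tolerances=(0.05, 0.2), method="neuralnet",
                        n_restarts=1),
            rng_seed=5,
        )
        for d in (0.05, 0.2):
            assert sum(res.posterior[d].values()) == pytest.approx(1.0, abs=1e-9)

    def test_accepted_count_is_delta_fraction(self, small_tables):
        obs = small_tables[0].stats[0]
        res = model_select(
            obs, small_tables, AbcSettings(tolerances=(0.01,), method="rejection")
        )
        assert res.n_accepted[0.01] == round(0.01 * 4 * 800)

    def test_affine_rescaling_invariance(self, small_tables):
        """MAD standardisation makes PP invariant to rescaling a statistic."""
        obs = small_tables[2].stats[10].copy()
        res1 = model_select(
            obs, small_tables, AbcSettings(tolerances=(0.02,), method="rejection")
        )
        scaled = []
        for t in small_tables:
            s = t.stats.copy()
            s[:, 0] = s[:, 0] * 1000.0 + 5.0
            scaled.append(ReferenceTable(t.model_id, t.params, s))
        obs2 = obs.copy()
        obs2[0] = obs2[0] * 1000.0 + 5.0
        res2 = model_select(
            obs2, scaled, AbcSettings(tolerances=(0.02,), method="rejection")
        )
        assert res1.posterior == res2.posterior

    def test_bayes_factors_consistent_with_pp(self, small_tables):
        obs = small_tables[0].stats[2]
        res = model_select(
            obs, small_tables, AbcSettings(tolerances=(0.05,), method="rejection")
        )
        pp = res.posterior[0.05]
        bf = res.bayes_factors[0.05]
        if pp["TOEPS"] > 0:
            assert bf[("TOEMS", "TOEPS")] == pytest.approx(
                pp["TOEMS"] / pp["TOEPS"]
            )


class TestEstimateParameters:
    def test_rejection_median_of_duplicated_row(self):
        """Observed equal to a duplicated table row: median lands there."""
        rng = np.random.default_rng(0)
        stats_ = rng.normal(size=(100, 15))
        stats_[:10] = stats_[0]
        params = {
            "t0": np.full(100, 60e3), "t1": np.full(100, 300e3),
            "anc0": np.full(100, 2.0), "anc1": np.full(100, 3.0),
            "bot0": np.nan, "bot1": np.nan,
        }
        import pandas as pd

        params["t0"][:10] = 77e3
        tbl = ReferenceTable("TOEMS", pd.DataFrame(params), stats_)
        res = estimate_parameters(
            stats_[0], tbl,
            AbcSettings(tolerances=(0.1,), method="rejection"),
        )
        assert res.estimates[0.1]["t0"]["median"] == pytest.approx(77e3)

    def test_zero_iteration_network_equals_rejection(self, small_tables):
        obs = small_tables[0].stats[1]
        s_rej = AbcSettings(tolerances=(0.05,), method="rejection")
        s_net0 = AbcSettings(tolerances=(0.05,), method="neuralnet", max_iter=0)
        r1 = estimate_parameters(obs, small_tables[0], s_rej, rng_seed=1)
        r2 = estimate_parameters(obs, small_tables[0], s_net0, rng_seed=1)
        for p in r1.estimates[0.05]:
            assert r1.estimates[0.05][p]["median"] == pytest.approx(
                r2.estimates[0.05][p]["median"]
            )

    def test_posterior_median_within_sample_range(self, small_tables):
        obs = small_tables[0].stats[4]
        res = estimate_parameters(
            obs, small_tables[0],
            AbcSettings(tolerances=(0.05,), method="neuralnet", n_restarts=1,
                        max_iter=100),
            rng_seed=2,
        )
        for p, est in res.estimates[0.05].items():
            samp = res.samples[0.05][p]
            assert samp.min() <= est["median"] <= samp.max()
            assert (res.samples[0.05]["weight"] >= 0).all()
            assert res.samples[0.05]["weight"].sum() == pytest.approx(1.0)


class TestCrossValidate:
    def test_identical_generators_give_chance_level(self):
        """Two tables from the same generator: ~50% correct."""
        rng = np.random.default_rng(3)
        import pandas as pd

        mk = lambda m, seed: ReferenceTable(
            m,
            pd.DataFrame({"t0": np.full(600, 1.0), "t1": np.full(600, 2.0),
                          "anc0": 1.0, "anc1": 1.0}),
            np.random.default_rng(seed).normal(size=(600, 15)),
        )
        tables = [mk("A", 1), mk("B", 2)]
        res = cross_validate(
            tables,
            AbcSettings(tolerances=(0.1,), method="rejection"),
            cv_steps=60,
            rng_seed=4,
        )
        pcts = list(res.pct_correct[0.1].values())
        se = 100 * math.sqrt(0.25 / 60)
        assert abs(np.mean(pcts) - 50.0) < 3 * se

    def test_confusion_rows_sum_to_cv_steps(self, small_tables):
        res = cross_validate(
            small_tables,
            AbcSettings(tolerances=(0.05,), method="rejection"),
            cv_steps=20,
            rng_seed=0,
        )
        conf = res.confusion[0.05]
        assert (conf.sum(axis=1) == 20).all()

    def test_cv_steps_exceeding_table_rejected(self, small_tables):
        with pytest.raises(ValueError, match="exceeds"):
            cross_validate(small_tables, cv_steps=10_000)

    def test_true_model_recovered_above_chance(self, small_tables):
        """End-to-end recovery beats the 25% chance level (binomial)."""
        from scipy import stats as sps

        res = cross_validate(
            small_tables,
            AbcSettings(tolerances=(0.05,), method="rejection"),
            cv_steps=40,
            rng_seed=8,
        )
        correct = sum(res.confusion[0.05].loc[m, m] for m in res.models)
        total = 4 * 40
        assert sps.binomtest(int(correct), total, 0.25, "greater").pvalue < 0.01


class TestRecoveryCoverage:
    def test_rejection_credible_interval_coverage(self, small_tables):
        """90% intervals from rejection ABC cover the truth ~90% of the
        time when pseudo-observations come from the same generator."""
        table = small_tables[0]  # TOEMS, 800 rows
        pri = scenarios.default_priors()
        sizes = {"MEX": 70, "SAL": 71, "PER": 47}
        pseudo = simulate_reference_table("TOEMS", pri, 100, sizes, 9_999)
        settings = AbcSettings(tolerances=(0.25,), method="rejection")
        covered = 0
        for i in range(100):
            res = estimate_parameters(pseudo.stats[i], table, settings)
            samp = res.samples[0.25]
            w = samp["weight"].to_numpy()
            x = samp["t1"].to_numpy()
            order = np.argsort(x)
            cw = np.cumsum(w[order])
            lo = x[order][np.searchsorted(cw, 0.05)]
            hi = x[order][min(np.searchsorted(cw, 0.95), x.size - 1)]
            if lo <= pseudo.params["t1"][i] <= hi:
                covered += 1
        assert 85 <= covered <= 95
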