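"""Clumping, scoring, candidate selection and PRS characterisation."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_genotypes, stats_for
from pdrisk import prs as prs_mod
from pdrisk.prs import CTGrid, PRSModel, clump, score


def brute_force_clump(stats, reference, r2_threshold, window_kb):
    """Literal restatement of the greedy clumping definition, O(n^2)."""
    d = reference.dosages.astype(float)
    idx = reference.variant_index()
    rows = stats[stats["SNP"].isin(idx)]
    order = sorted(
        rows.itertuples(), key=lambda r: (r.P, r.BP, r.SNP)
    )
    claimed, retained = set(), []
    for r in order:
        if r.SNP in claimed:
            continue
        retained.append(r.SNP)
        claimed.add(r.SNP)
        for other in order:
            if other.SNP in claimed or other.CHR != r.CHR:
                continue
            if abs(other.BP - r.BP) > window_kb * 1000:
                continue
            a, b = d[:, idx[r.SNP]], d[:, idx[other.SNP]]
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < 2 or a[ok].std() == 0 or b[ok].std() == 0:
                continue
            if np.corrcoef(a[ok], b[ok])[0, 1] ** 2 >= r2_threshold:
                claimed.add(other.SNP)
    return retained


def random_instance(rng, n_var=None):
    n_var = n_var or rng.integers(3, 26)
    n = 60
    base = rng.integers(0, 3, size=(n, n_var)).astype(float)
    # induce correlation between random column pairs
    for _ in range(n_var // 2):
        i, j = rng.choice(n_var, 2, replace=False)
        mask = rng.random(n) < 0.8
        base[mask, j] = base[mask, i]
    miss = rng.random(base.shape) < 0.05
    base[miss] = np.nan
    chrom = rng.integers(1, 3, size=n_var)
    pos = rng.integers(1, 500_000, size=n_var)
    g = make_genotypes(
        [f"rs{i}" for i in range(n_var)], base, chrom=chrom, pos=pos,
        maf=[0.3] * n_var,
    )
    stats = stats_for(g, beta=rng.normal(0, 0.1, n_var), p=rng.random(n_var))
    return g, stats


class TestClump:
    def test_single_variant_retained(self):
        g = make_genotypes(["rs1"], np.array([[0.0], [1.0], [2.0]]), maf=[0.3])
        assert clump(stats_for(g), g, 0.5) == ["rs1"]

    def test_correlated_trio_keeps_best_p(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 3, size=(200, 1)).astype(float)
        noise = lambda: np.where(rng.random((200, 1)) < 0.02, rng.integers(0, 3, (200, 1)), col)
        dosages = np.hstack([col, noise(), noise()])
        g = make_genotypes(["rsA", "rsB", "rsC"], dosages,
                           pos=[10_000, 30_000, 50_000], maf=[0.3] * 3)
        stats = stats_for(g, p=[1e-8, 1e-6, 1e-4])
        assert clump(stats, g, 0.5, window_kb=250) == ["rsA"]

    def test_window_limits_claiming(self):
        col = np.random.default_rng(1).integers(0, 3, size=(100, 1)).astype(float)
        g = make_genotypes(["rs1", "rs2"], np.hstack([col, col]),
                           pos=[100_000, 400_000], maf=[0.3] * 2)
        stats = stats_for(g, p=[1e-8, 1e-4])
        kept = clump(stats, g, 0.5, window_kb=250)
        assert set(kept) == {"rs1", "rs2"}  # 300 kb apart: both survive

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            g, stats = random_instance(rng)
            r2 = rng.choice([0.1, 0.4, 0.8])
            w = rng.choice([50, 250])
            assert clump(stats, g, r2, w) == brute_force_clump(stats, g, r2, w)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(11)
        g, stats = random_instance(rng, n_var=15)
        kept = clump(stats, g, 0.4, 250)
        shuffled = stats.sample(frac=1, random_state=5).reset_index(drop=True)
        assert clump(shuffled, g, 0.4, 250) == kept

    def test_absent_variant_warns_not_errors(self):
        g = make_genotypes(["rs1"], np.array([[0.0], [1.0], [2.0]]), maf=[0.3])
        stats = pd.concat([stats_for(g), stats_for(g).assign(SNP="rs_missing")])
        with pytest.warns(UserWarning, match="absent from the reference"):
            kept = clump(stats, g, 0.5)
        assert kept == ["rs1"]


class TestBuildCandidates:
    def test_grid_produces_fifty_models(self, bundle):
        grid = CTGrid()
        models = prs_mod.build_candidates(
            bundle.summary_stats, bundle.genotypes, grid, bundle.genotypes
        )
        assert len(models) == 50

    def test_loose_threshold_contains_all_variants(self, bundle):
        grid = CTGrid(p_thresholds=(1.0,), r2_thresholds=(1.0,))
        models = prs_mod.build_candidates(
            bundle.summary_stats, bundle.genotypes, grid, bundle.genotypes
        )
        # r2 threshold 1.0: only perfectly correlated pairs are claimed
        assert models[0].n_snps >= bundle.genotypes.n_variants * 0.95

    def test_n_snps_monotone_in_p_threshold(self, bundle):
        grid = CTGrid()
        models = prs_mod.build_candidates(
            bundle.summary_stats, bundle.genotypes, grid, bundle.genotypes
        )
        by_r2 = {}
        for m in models:
            by_r2.setdefault(m.r2_threshold, []).append((m.p_threshold, m.n_snps))
        for pairs in by_r2.values():
            pairs.sort()
            sizes = [s for _, s in pairs]
            assert sizes == sorted(sizes)


def _toy_model_and_panel():
    """3-person panel, 2 loci, betas (0.2, -0.1) - the worked scoring example."""
    dosages = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
    g = make_genotypes(["rs1", "rs2"], dosages, a1=["A", "C"], a2=["G", "T"],
                       maf=[0.3, 0.3])
    betas = np.array([0.2, -0.1])
    s = dosages * betas
    mean, sd = s.mean(axis=0), s.std(axis=0)
    model = PRSModel(
        rsids=np.array(["rs1", "rs2"]),
        chroms=np.array([1, 1]),
        positions=np.array([1000, 2000]),
        effect_alleles=np.array(["A", "C"]),
        other_alleles=np.array(["G", "T"]),
        weights=betas,
        locus_mean=mean,
        locus_sd=sd,
        p_threshold=1.0,
        r2_threshold=0.5,
    )
    return g, model, s, mean, sd


class TestScore:
    def test_hand_computed_standardised_sum(self):
        g, model, s, mean, sd = _toy_model_and_panel()
        expected = ((s - mean) / sd).sum(axis=1)
        result = score(g, model)
        np.testing.assert_allclose(result.raw, expected, atol=1e-12)
        # person with dosages (2, 1): ((0.4-0.2)/sd1 + (-0.1+0.1)/sd2)
        assert result.raw[2] == pytest.approx((0.4 - mean[0]) / sd[0] + (0.0 - mean[1]) / sd[1])

    def test_all_missing_scores_zero(self):
        g, model, *_ = _toy_model_and_panel()
        dosages = np.full((1, 2), np.nan)
        g1 = make_genotypes(["rs1", "rs2"], dosages, a1=["A", "C"], a2=["G", "T"])
        assert score(g1, model).raw[0] == 0.0

    def test_allele_flip_invariance(self):
        g, model, *_ = _toy_model_and_panel()
        flipped = make_genotypes(
            ["rs1", "rs2"], 2.0 - g.dosages,
            a1=["G", "T"], a2=["A", "C"], maf=[0.3, 0.3],
        )
        np.testing.assert_allclose(score(flipped, model).raw, score(g, model).raw,
                                   atol=1e-12)

    def test_linearity_before_standardisation(self):
        rng = np.random.default_rng(2)
        dosages = rng.integers(0, 3, size=(20, 5)).astype(float)
        g = make_genotypes([f"rs{i}" for i in range(5)], dosages, maf=[0.3] * 5)
        def unit_model(w):
            return PRSModel(
                rsids=g.variants["rsid"].to_numpy(),
                chroms=g.variants["chrom"].to_numpy(),
                positions=g.variants["pos"].to_numpy(),
                effect_alleles=g.variants["a1"].to_numpy(),
                other_alleles=g.variants["a2"].to_numpy(),
                weights=np.asarray(w, dtype=float),
                locus_mean=np.zeros(5),
                locus_sd=np.ones(5),
                p_threshold=1.0, r2_threshold=0.5,
            )
        w1, w2 = rng.normal(size=5), rng.normal(size=5)
        np.testing.assert_allclose(
            score(g, unit_model(w1 + w2)).raw,
            score(g, unit_model(w1)).raw + score(g, unit_model(w2)).raw,
            atol=1e-10,
        )

    def test_majority_absent_errors(self):
        _, model, *_ = _toy_model_and_panel()
        g1 = make_genotypes(["rs_other"], np.array([[1.0]]))
        with pytest.raises(ValueError, match="absent"):
            score(g1, model)

    def test_transformed_score_standard_normalish(self, bundle):
        grid = CTGrid(p_thresholds=(1.0,), r2_thresholds=(0.4,))
        models = prs_mod.build_candidates(
            bundle.summary_stats, bundle.genotypes, grid, bundle.genotypes
        )
        res = score(bundle.genotypes, models[0])
        assert abs(res.transformed.mean()) < 0.01
        assert abs(res.transformed.std() - 1) < 0.02
        counts = np.bincount(res.decile)[1:]
        assert counts.max() - counts.min() <= 1  # near-equal decile bins


class TestSelectBest:
    def test_identical_candidates_tie_broken_by_snp_count(self, bundle):
        grid = CTGrid(p_thresholds=(0.05,), r2_thresholds=(0.4,))
        [model] = prs_mod.build_candidates(
            bundle.summary_stats, bundle.genotypes, grid, bundle.genotypes
        )
        # clone with an extra zero-weight variant: identical scores, more SNPs
        extra_snp = next(
            s for s in bundle.genotypes.variants["rsid"] if s not in set(model.rsids)
        )
        row = bundle.genotypes.variants.set_index("rsid").loc[extra_snp]
        clone = PRSModel(
            rsids=np.append(model.rsids, extra_snp),
            chroms=np.append(model.chroms, row["chrom"]),
            positions=np.append(model.positions, row["pos"]),
            effect_alleles=np.append(model.effect_alleles, row["a1"]),
            other_alleles=np.append(model.other_alleles, row["a2"]),
            weights=np.append(model.weights, 0.0),
            locus_mean=np.append(model.locus_mean, 0.0),
            locus_sd=np.append(model.locus_sd, 1.0),
            p_threshold=model.p_threshold,
            r2_threshold=model.r2_threshold,
        )
        scores = [score(bundle.genotypes, m) for m in (clone, model)]
        np.testing.assert_allclose(scores[0].raw, scores[1].raw, atol=1e-12)
        best, table = prs_mod.select_best(
            [clone, model], bundle.cohort, scores, n_boot=0
        )
        assert best.n_snps == model.n_snps
        assert table["r2"].nunique() == 1

    def test_empty_candidates_skipped(self, bundle):
        stats = bundle.summary_stats.copy()
        stats["P"] = stats["P"].clip(lower=0.01)  # no variant below 0.005
        grid = CTGrid(p_thresholds=(0.005, 0.05), r2_thresholds=(0.4,))
        models = prs_mod.build_candidates(
            stats, bundle.genotypes, grid, bundle.genotypes
        )
        assert models[0].empty
        scores = [None if m.empty else score(bundle.genotypes, m) for m in models]
        best, table = prs_mod.select_best(models, bundle.cohort, scores, n_boot=0)
        assert not best.empty
        assert table.loc[0, "n_snps"] == 0


class TestDecileAnalysis:
    def test_or_matches_cross_product_oracle(self):
        # constructed 2x10 table, no covariates
        rng = np.random.default_rng(4)
        n_per = 200
        case_rates = np.linspace(0.05, 0.30, 10)
        rows = []
        for d in range(10):
            for i in range(n_per):
                rows.append({"id": f"D{d}_{i}", "pd_status": int(rng.random() < case_rates[d])})
        cohort = pd.DataFrame(rows)
        raw = np.repeat(np.arange(10), n_per) + rng.random(10 * n_per) * 0.5
        result = prs_mod.PRSResult(
            ids=list(cohort["id"]), raw=raw, transformed=raw,
            decile=np.repeat(np.arange(1, 11), n_per),
        )
        table = prs_mod.decile_analysis(result, cohort, covariates=())
        counts = cohort.assign(decile=result.decile).groupby("decile")["pd_status"]
        a1, n1 = counts.sum()[1], counts.count()[1]
        for d in range(2, 11):
            ad, nd = counts.sum()[d], counts.count()[d]
            oracle = (ad * (n1 - a1)) / ((nd - ad) * a1)
            assert table.loc[table["decile"] == d, "or_"].iloc[0] == pytest.approx(
                oracle, rel=1e-4
            )

    def test_null_prs_deciles_cover_one(self):
        rng = np.random.default_rng(8)
        n = 4000
        cohort = pd.DataFrame(
            {"id": [f"I{i}" for i in range(n)],
             "pd_status": rng.integers(0, 2, n)}
        )
        raw = rng.normal(size=n)
        ranks = pd.Series(raw).rank(method="first")
        result = prs_mod.PRSResult(
            ids=list(cohort["id"]), raw=raw, transformed=raw,
            decile=np.ceil(ranks * 10 / n).astype(int).to_numpy(),
        )
        table = prs_mod.decile_analysis(result, cohort, covariates=())
        covered = ((table["ci_low"] <= 1) & (table["ci_high"] >= 1))[1:]
        assert covered.sum() >= 8


class TestOnsetModel:
    def test_refuses_small_samples(self):
        cohort = pd.DataFrame(
            {"id": [f"I{i}" for i in range(10)], "age": 60.0, "sex": "male",
             "age_at_diagnosis": 65.0,
             **{f"pc{k}": 0.0 for k in range(1, 5)}}
        )
        res = prs_mod.PRSResult(list(cohort["id"]), np.zeros(10), np.zeros(10),
                                np.ones(10, dtype=int))
        with pytest.raises(ValueError, match="insufficient cases"):
            prs_mod.onset_model(res, cohort)

    def test_null_slope_ci_covers_zero_and_duplication_shrinks_p(self):
        rng = np.random.default_rng(9)
        n = 500
        prs = rng.normal(size=n)
        cohort = pd.DataFrame(
            {"id": [f"I{i}" for i in range(n)],
             "age": rng.integers(40, 70, n).astype(float),
             "sex": rng.choice(["male", "female"], n),
             "age_at_diagnosis": 65 + rng.normal(0, 5, n),
             **{f"pc{k}": rng.normal(0, 0.05, n) for k in range(1, 5)}}
        )
        res = prs_mod.PRSResult(list(cohort["id"]), prs, prs, np.ones(n, dtype=int))
        out = prs_mod.onset_model(res, cohort)
        assert out["ci_low"] <= 0 <= out["ci_high"]
        doubled = pd.concat([cohort, cohort.assign(id=cohort["id"] + "b")],
                            ignore_index=True)
        res2 = prs_mod.PRSResult(list(doubled["id"]), np.tile(prs, 2),
                                 np.tile(prs, 2), np.ones(2 * n, dtype=int))
        out2 = prs_mod.onset_model(res2, doubled)
        assert out2["slope"] == pytest.approx(out["slope"], abs=1e-10)
        assert out2["p"] <= out["p"]

    def test_recovers_negative_onset_slope(self, bundle):
        # generator draws onset = 65 - 0.5*g + noise; cases only
        cases = bundle.cohort[bundle.cohort["pd_status"] == 1]
        g = bundle.cohort.set_index("id")["true_genetic_score"]
        res = prs_mod.PRSResult(
            ids=list(bundle.cohort["id"]),
            raw=g.to_numpy(),
            transformed=g.to_numpy(),
            decile=np.ones(len(bundle.cohort), dtype=int),
        )
        if len(cases) >= 30:
            out = prs_mod.onset_model(res, cases)
            assert out["slope"] < 0.5  # point estimate not strongly positive


class TestExcludeKnownLoci:
    def _model(self):
        m = 5
        g = make_genotypes(
            [f"rs{i}" for i in range(m)],
            np.random.default_rng(0).integers(0, 3, (30, m)).astype(float),
            chrom=[1] * m,
            pos=[4_100_000, 5_000_000, 5_900_000, 6_000_001, 8_000_000],
            maf=[0.3] * m,
        )
        stats = stats_for(g, p=1e-6)
        grid = CTGrid(p_thresholds=(1.0,), r2_thresholds=(1.0,))
        [model] = prs_mod.build_candidates(stats, g, grid, g)
        return g, model

    def test_inclusive_one_mb_removal(self):
        g, model = self._model()
        out = prs_mod.exclude_known_loci(model, [(1, 5_000_000)], g)
        # rs0 (4.1 Mb) and rs2 (5.9 Mb) are within 1 Mb inclusive; rs3 at
        # 6,000,001 is 1,000,001 bp away -> retained (strict beyond 1 Mb)
        assert set(out.rsids) == {"rs3", "rs4"}

    def test_empty_lead_list_is_identity(self):
        g, model = self._model()
        out = prs_mod.exclude_known_loci(model, [], g)
        assert out is model

    def test_standardisation_refit(self):
        g, model = self._model()
        out = prs_mod.exclude_known_loci(model, [(1, 5_000_000)], g)
        keep = np.isin(model.rsids, out.rsids)
        np.testing.assert_allclose(out.locus_mean, model.locus_mean[keep])
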