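"""RUST enrichment, offset calibration, occupancy and tRNA tables."""

import numpy as np
import pandas as pd
import pytest

from ribodyn import codon, simulate as sim
from ribodyn.io import PipelineError, SampleTable, TrnaMeasurement


class TestKlDivergence:
    def test_identical_distributions_are_zero(self):
        p = np.array([0.2, 0.3, 0.5])
        assert codon.kl_divergence(p, p) == 0.0

    def test_hand_computed_value(self):
        # sum p log2(p/q) for p=(.5,.5), q=(.25,.75)
        got = codon.kl_divergence(np.array([0.5, 0.5]),
                                  np.array([0.25, 0.75]))
        assert got == pytest.approx(0.2075, abs=2e-4)

    def test_nonnegative_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.dirichlet(np.ones(10))
            q = rng.dirichlet(np.ones(10))
            assert codon.kl_divergence(p, q) >= 0


class TestRustAndOffsets:
    def test_uniform_dwell_gives_flat_enrichment(self, tiny_annotation):
        cfg = sim.SimulationConfig(read_lengths=(30,), true_offsets={30: 15},
                                   footprint_reads=150_000, seed=2,
                                   stages=("E12.5",), stage_hours=(0.0,),
                                   te_shift_stage=0,
                                   dwell_params=sim.uniform_dwell())
        profiles, _ = sim.simulate_footprints(cfg, tiny_annotation)
        rust = codon.compute_rust(profiles, tiny_annotation, 30, "E12.5",
                                  trim_codons=5)
        enr = rust.enrichment[15].dropna()
        assert enr.std() < 0.25 * enr.mean()

    def test_offsets_recovered_under_cut_bias(self, footprint_sim):
        cfg, ann, profiles, truth = footprint_sim
        pool = type(profiles)(profiles.tx_lengths, {"all": "all"})
        for (s, t, rl) in list(profiles.keys()):
            pool.add("all", t, rl, profiles.get(s, t, rl))
        rusts = {rl: codon.compute_rust(pool, ann, rl, "all")
                 for rl in profiles.read_lengths}
        offsets, diag = codon.select_offsets(rusts)
        assert offsets.offsets == truth.offsets
        assert not offsets.uncalibrated

    def test_flat_profile_flagged_uncalibrated(self, tiny_annotation):
        # uniform dwell and deep coverage: no codon signal anywhere
        cfg = sim.SimulationConfig(read_lengths=(30,), true_offsets={30: 15},
                                   footprint_reads=400_000, seed=3,
                                   stages=("E12.5",), stage_hours=(0.0,),
                                   te_shift_stage=0,
                                   dwell_params=sim.uniform_dwell())
        profiles, _ = sim.simulate_footprints(cfg, tiny_annotation)
        rust = codon.compute_rust(profiles, tiny_annotation, 30, "E12.5",
                                  trim_codons=5)
        offsets, _ = codon.select_offsets({30: rust}, flatness_ratio=2.0)
        assert 30 in offsets.uncalibrated


class TestSiteOccupancy:
    def test_p_site_is_a_site_shifted_three(self, footprint_sim):
        cfg, ann, profiles, truth = footprint_sim
        from ribodyn.io import OffsetTable
        pooled = profiles.pooled_by_stage()
        rust = {st: {30: codon.compute_rust(pooled, ann, 30, st)}
                for st in ("E12.5",)}
        a_off = OffsetTable({30: truth.offsets[30]})
        p_off = OffsetTable({30: truth.offsets[30] - 3})
        occ_a, _ = codon.site_occupancy(rust, a_off)
        occ_b, _ = codon.site_occupancy(rust, p_off)
        a_sites = occ_b[occ_b["site"] == "A"].set_index("codon")["occupancy"]
        p_sites = occ_a[occ_a["site"] == "P"].set_index("codon")["occupancy"]
        common = a_sites.index.intersection(p_sites.index)
        assert np.allclose(a_sites[common], p_sites[common])

    def test_bimodal_dwell_separates_groups(self, footprint_sim):
        cfg, ann, profiles, truth = footprint_sim
        pool = type(profiles)(profiles.tx_lengths, {"all": "all"})
        for (s, t, rl) in list(profiles.keys()):
            pool.add("all", t, rl, profiles.get(s, t, rl))
        rusts = {rl: codon.compute_rust(pool, ann, rl, "all")
                 for rl in profiles.read_lengths}
        offsets, _ = codon.select_offsets(rusts)
        occ, _ = codon.site_occupancy({"all": rusts}, offsets)
        a = occ[occ["site"] == "A"].set_index("codon")["occupancy"]
        dwell = truth.dwell["E12.5"]
        slow = a[a.index.isin(dwell[dwell > 1].index)]
        fast = a[a.index.isin(dwell[dwell < 1].index)]
        # slow codons occupy more than fast ones, cleanly separated
        assert slow.mean() > 1.5 * fast.mean()
        assert slow.min() > fast.max() - 0.1


def _toy_trna(ct_rows: dict, anticodons: dict, stages=("E12.5",)):
    samples = SampleTable.build(stages, "tRNA", 1, all_stages=stages)
    cols = samples.df["sample"]
    ct = pd.DataFrame({c: ct_rows for c in cols}).T.reset_index(drop=True).T
    ct.columns = cols
    return TrnaMeasurement(ct, pd.Series(anticodons), samples)


class TestTrnaTable:
    def test_neg_delta_ct_arithmetic(self, tiny_annotation):
        meas = _toy_trna(
            {"iso1": 25.0, "rRNA_5S": 15.0, "rRNA_18S": 17.0},
            {"iso1": codon.anticodon_for("GAA")})
        table = codon.trna_codon_table(meas, tiny_annotation)
        assert table.isodecoder_abundance.loc["iso1"].iloc[0] == \
            pytest.approx(-9.0)
        assert table.codon_abundance.loc["GAA"].iloc[0] == pytest.approx(-9.0)

    def test_availability_residuals_sum_to_zero(self, tiny_annotation):
        cfg = sim.SimulationConfig(seed=4)
        meas, _ = sim.simulate_trna(cfg)
        table = codon.trna_codon_table(meas, tiny_annotation)
        for st in table.availability.columns:
            resid = table.availability[st].dropna()
            assert abs(resid.sum()) < 1e-8

    def test_availability_matches_ols_oracle(self, tiny_annotation):
        """3-codon toy vs the normal-equations solution."""
        usage = np.array([0.5, 0.3, 0.2])
        abund = np.array([2.0, 1.0, 1.0])
        X = np.vstack([np.ones(3), abund]).T
        beta = np.linalg.solve(X.T @ X, X.T @ usage)
        expect = usage - X @ beta
        # run through the module on a crafted measurement
        meas = _toy_trna(
            {"i1": 16.0 - abund[0], "i2": 16.0 - abund[1],
             "i3": 16.0 - abund[2], "rRNA_5S": 15.0, "rRNA_18S": 17.0},
            {"i1": codon.anticodon_for("GCT"),
             "i2": codon.anticodon_for("GGT"),
             "i3": codon.anticodon_for("CCT")})
        table = codon.trna_codon_table(meas, tiny_annotation)
        sub = table.usage.iloc[:, 0].loc[["GCT", "GGT", "CCT"]]
        # reproduce the module's own usage values in the oracle
        X2 = np.vstack([np.ones(3),
                        table.codon_abundance.iloc[:, 0]
                        .loc[["GCT", "GGT", "CCT"]]]).T
        beta2 = np.linalg.solve(X2.T @ X2, X2.T @ sub.to_numpy())
        expect2 = sub.to_numpy() - X2 @ beta2
        got = table.availability.iloc[:, 0].loc[["GCT", "GGT", "CCT"]]
        assert np.allclose(got.to_numpy(dtype=float), expect2)

    def test_missing_reference_rejected(self, tiny_annotation):
        with pytest.raises(Exception):
            _toy_trna({"iso1": 25.0}, {"iso1": "TTC"})


class TestVariancePartition:
    def test_constant_occupancy_explains_nothing(self, tiny_annotation):
        rows = [{"codon": c, "stage": "E12.5", "site": "A",
                 "occupancy": 1.0, "amino_acid": codon.GENETIC_CODE[c]}
                for c in codon.SENSE_CODONS]
        rows += [{"codon": c, "stage": "E14", "site": "A",
                  "occupancy": 1.0, "amino_acid": codon.GENETIC_CODE[c]}
                 for c in codon.SENSE_CODONS]
        occ = pd.DataFrame(rows)
        cfg = sim.SimulationConfig(seed=5, stages=("E12.5", "E14"),
                                   stage_hours=(0.0, 36.0),
                                   te_shift_stage=0)
        meas, _ = sim.simulate_trna(cfg)
        table = codon.trna_codon_table(meas, tiny_annotation)
        part = codon.dwell_variance_partition(occ, table, interaction=False)
        assert part["anova"]["sum_sq"].drop("Residual").sum() < 1e-12

    def test_null_abundance_fraction_small(self, footprint_sim):
        """tRNA abundances drawn independently of dwell explain no
        systematic occupancy variance.

        A single draw can correlate with the 61 codon values by chance
        (the per-stage observations replicate the same codon pattern,
        so nominal p-values overstate certainty); the median fraction
        over independent abundance draws is the stable null quantity.
        """
        cfg, ann, profiles, truth = footprint_sim
        pooled = profiles.pooled_by_stage()
        from ribodyn.io import OffsetTable
        offsets = OffsetTable(dict(truth.offsets))
        rusts = {st: {rl: codon.compute_rust(pooled, ann, rl, st)
                      for rl in profiles.read_lengths}
                 for st in pooled.samples}
        occ, _ = codon.site_occupancy(rusts, offsets)
        import dataclasses
        fractions = []
        for s in range(5):
            meas, _ = sim.simulate_trna(dataclasses.replace(cfg, seed=50 + s))
            table = codon.trna_codon_table(meas, ann)
            part = codon.dwell_variance_partition(occ, table,
                                                  interaction=False)
            fractions.append(part["fraction"]["trna"])
        assert float(np.median(fractions)) < 0.05


class TestSiteCorrelation:
    def _occ(self, a_vals, p_vals, stage="E12.5"):
        rows = []
        for c, a, p in zip(codon.SENSE_CODONS, a_vals, p_vals):
            rows.append({"codon": c, "stage": stage, "site": "A",
                         "occupancy": a,
                         "amino_acid": codon.GENETIC_CODE[c]})
            rows.append({"codon": c, "stage": stage, "site": "P",
                         "occupancy": p,
                         "amino_acid": codon.GENETIC_CODE[c]})
        return pd.DataFrame(rows)

    def test_identity_gives_unit_slope(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(0, 0.3, len(codon.SENSE_CODONS))
        out = codon.site_correlation(self._occ(vals, vals))
        assert out["slope"].iloc[0] == pytest.approx(1.0)

    def test_permuted_p_site_slope_ci_covers_zero(self):
        rng = np.random.default_rng(2)
        a = rng.lognormal(0, 0.3, len(codon.SENSE_CODONS))
        p = rng.permutation(a)
        out = codon.site_correlation(self._occ(a, p))
        assert out["ci_low"].iloc[0] < 0 < out["ci_high"].iloc[0]
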