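"""Metagene profiles, 15-bin scheme, UTR density, and PQS scanning."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ribodyn import positional, simulate as sim
from ribodyn.io import (
    FootprintProfiles,
    OffsetTable,
    Transcript,
    Transcriptome,
)


def _tx(n_codons, u5=30, u3=30, tx_id="tx0", gene="g0", seed=0):
    rng = np.random.default_rng(seed)
    sense = [c for c in sim.SENSE_CODONS if c != "ATG"]
    body = "ATG" + "".join(rng.choice(sense, n_codons - 2)) + "TAA"
    utr5 = "".join(rng.choice(list("ACT"), u5))   # G-free UTRs
    utr3 = "".join(rng.choice(list("ACT"), u3))
    return Transcript(tx_id, gene, utr5 + body + utr3, u5, u5 + len(body))


class TestBinScheme:
    def test_bins_tile_cds(self):
        for n in (57, 80, 200):
            t = _tx(n)
            scheme = positional.bin_scheme(t)
            assert sum(scheme.widths) == n
            # no overlap and full coverage
            covered = sorted(itertools.chain.from_iterable(
                range(a, b) for a, b in scheme.bounds))
            assert covered == list(range(n))

    def test_too_short_cds_excluded(self):
        assert positional.bin_scheme(_tx(56)) is None
        assert positional.bin_scheme(_tx(57)) is not None


class TestBestTranscripts:
    def test_min_cds_length_applied(self):
        # 63 codons = 189 nt < 192: excluded; 64 codons = 192: kept
        short = _tx(63, tx_id="s", gene="gs")
        ok = _tx(64, tx_id="k", gene="gk")
        ann = Transcriptome([short, ok])
        prof = FootprintProfiles({t.tx_id: t.length for t in ann},
                                 {"s1": "E12.5"})
        for t in ann:
            vec = np.zeros(t.length, dtype=np.int64)
            vec[t.cds_start] = 5
            prof.add("s1", t.tx_id, 30, vec)
        best = positional.select_best_transcripts(prof, ann)
        assert best == ["k"]

    def test_highest_median_coverage_wins(self):
        a = _tx(80, tx_id="a", gene="g")
        b = _tx(80, tx_id="b", gene="g", seed=1)
        ann = Transcriptome([a, b])
        prof = FootprintProfiles({t.tx_id: t.length for t in ann},
                                 {"s1": "E12.5"})
        va = np.zeros(a.length, dtype=np.int64); va[a.cds_start] = 100
        vb = np.zeros(b.length, dtype=np.int64); vb[b.cds_start] = 5
        prof.add("s1", "a", 30, va)
        prof.add("s1", "b", 30, vb)
        assert positional.select_best_transcripts(prof, ann) == ["a"]


class TestMetagene:
    def test_spike_at_start_codon(self):
        t = _tx(80)
        ann = Transcriptome([t])
        prof = FootprintProfiles({t.tx_id: t.length}, {"s1": "E12.5"})
        vec = np.zeros(t.length, dtype=np.int64)
        vec[t.cds_start - 12] = 50  # P-site lands on the start codon
        prof.add("s1", t.tx_id, 30, vec)
        offsets = OffsetTable({30: 15})
        mg = positional.metagene(prof, ann, offsets, "start",
                                 transcripts=[t.tx_id])
        assert mg["E12.5"].idxmax() == 0

    def test_uniform_profile_is_flat_and_scale_invariant(self):
        t = _tx(100)
        ann = Transcriptome([t])
        offsets = OffsetTable({30: 15})
        out = []
        for scale in (1, 17):
            prof = FootprintProfiles({t.tx_id: t.length}, {"s1": "E12.5"})
            vec = np.zeros(t.length, dtype=np.int64)
            vec[t.cds_start - 12: t.cds_end - 12] = scale
            prof.add("s1", t.tx_id, 30, vec)
            mg = positional.metagene(prof, ann, offsets, "start",
                                     flank=(0, 60), transcripts=[t.tx_id])
            out.append(mg["E12.5"])
        assert np.allclose(out[0], 1.0)
        assert np.allclose(out[0], out[1])  # per-transcript normalization


class TestBinPositionalFc:
    def _profiles(self, counts_by_stage, t):
        prof = FootprintProfiles({t.tx_id: t.length},
                                 {st: st for st in counts_by_stage})
        for st, vec in counts_by_stage.items():
            prof.add(st, t.tx_id, 30, vec)
        return prof

    def test_identical_stages_not_significant(self):
        t = _tx(100)
        rng = np.random.default_rng(3)
        vec = np.zeros(t.length, dtype=np.int64)
        vec[t.cds_start - 12: t.cds_end - 12] = rng.integers(
            5, 30, t.cds_length)
        prof = self._profiles({"E12.5": vec, "E14": vec.copy()}, t)
        out = positional.bin_positional_fc(prof, Transcriptome([t]),
                                           OffsetTable({30: 15}),
                                           "E12.5", "E14",
                                           transcripts=[t.tx_id])
        assert np.allclose(out.filter(like="log2fc"), 0.0)
        assert not out["significant"].any()

    def test_start_bin_inflation_detected(self):
        t = _tx(100)
        rng = np.random.default_rng(4)
        base = np.zeros(t.length, dtype=np.int64)
        base[t.cds_start - 12: t.cds_end - 12] = 20
        inflated = base.copy()
        # 4x more footprints in the first four codons in stage B
        sl = slice(t.cds_start - 12, t.cds_start - 12 + 12)
        inflated[sl] = base[sl] * 4
        prof = self._profiles({"E12.5": base, "E14": inflated}, t)
        out = positional.bin_positional_fc(prof, Transcriptome([t]),
                                           OffsetTable({30: 15}),
                                           "E12.5", "E14",
                                           transcripts=[t.tx_id])
        row = out.iloc[0]
        lib_shift = np.log2(inflated.sum() / base.sum())
        assert row["bin01_log2fc"] == pytest.approx(2.0 - lib_shift, abs=0.1)
        assert abs(row["bin08_log2fc"]) < 0.4
        assert row["significant"]


class TestUtr5Density:
    def _setup(self, utr_counts, tpm, n_codons=80, u5=60):
        t = _tx(n_codons, u5=u5)
        ann = Transcriptome([t])
        prof = FootprintProfiles({t.tx_id: t.length},
                                 {"E12.5": "E12.5", "E15.5": "E15.5"})
        for st, c in utr_counts.items():
            vec = np.zeros(t.length, dtype=np.int64)
            # P-site at UTR position 10 (well outside the 15-nt window)
            vec[10 - 12 + 15] = c  # 5' end placing P-site at 10... use offset 15
            vec = np.zeros(t.length, dtype=np.int64)
            vec[0] = c  # P-site at 0 + 15 - 3 = 12 < cds_start - 15
            prof.add(st, t.tx_id, 30, vec)
        rna = pd.DataFrame({"E12.5": [tpm], "E15.5": [tpm]}, index=["g0"])
        return t, ann, prof, rna

    def test_density_arithmetic(self):
        t, ann, prof, rna = self._setup({"E12.5": 20, "E15.5": 20}, 10.0)
        records, _ = positional.utr5_density_fc(
            prof, ann, OffsetTable({30: 15}), rna,
            pd.Series(dtype=object), stage_pair=("E12.5", "E15.5"))
        assert records["density_a"].iloc[0] == pytest.approx(2.0)

    def test_low_tpm_excluded(self):
        t, ann, prof, rna = self._setup({"E12.5": 20, "E15.5": 20}, 0.05)
        records, _ = positional.utr5_density_fc(
            prof, ann, OffsetTable({30: 15}), rna,
            pd.Series(dtype=object), stage_pair=("E12.5", "E15.5"))
        assert records.empty

    def test_exclusion_window_not_counted(self):
        t = _tx(80, u5=60)
        ann = Transcriptome([t])
        prof = FootprintProfiles({t.tx_id: t.length},
                                 {"E12.5": "E12.5", "E15.5": "E15.5"})
        vec = np.zeros(t.length, dtype=np.int64)
        # P-site lands 5 nt upstream of the start codon: inside the
        # 15-nt exclusion window
        p_site = t.cds_start - 5
        vec[p_site - 12] = 30
        prof.add("E12.5", t.tx_id, 30, vec)
        prof.add("E15.5", t.tx_id, 30, vec)
        rna = pd.DataFrame({"E12.5": [5.0], "E15.5": [5.0]}, index=["g0"])
        records, _ = positional.utr5_density_fc(
            prof, ann, OffsetTable({30: 15}), rna,
            pd.Series(dtype=object), stage_pair=("E12.5", "E15.5"))
        assert records.empty or (records["utr_count_a"] == 0).all()


PQS = positional.pqs_count


def brute_pqs_count(seq: str) -> int:
    """Exhaustive decomposition enumeration, independent of the scanner."""
    n = len(seq)

    def longest_end(i):
        best = None
        for g1 in range(3, n - i + 1):
            if seq[i:i + g1] != "G" * g1:
                break
            stack = [(i + g1, 1)]
            seen = {}
            while stack:
                p, runs = stack.pop()
                if runs == 4:
                    if best is None or p > best:
                        best = p
                    continue
                if (p, runs) in seen:
                    continue
                seen[(p, runs)] = True
                for loop in range(1, 8):
                    q = p + loop
                    for g in range(3, n - q + 1):
                        if q + g <= n and seq[q:q + g] == "G" * g:
                            stack.append((q + g, runs + 1))
                        else:
                            break
        return best

    count, i = 0, 0
    while i <= n - 15:
        e = longest_end(i)
        if e:
            count += 1
            i = e
        else:
            i += 1
    return count


class TestPqs:
    @pytest.mark.parametrize("seq,expect", [
        ("GGGAGGGAGGGAGGG", 1),            # canonical minimal G4
        ("A" * 40, 0),                     # no G runs
        ("GGGAGGGAGGGAGG", 0),             # fourth run too short
        ("G" * 30, 1),                     # one long run hosts one PQS
        ("GGGAGGGAGGGAGGG" + "ACTACTAC" + "GGGTGGGTGGGTGGG", 2),
    ])
    def test_known_counts(self, seq, expect):
        assert PQS(seq) == expect

    def test_exhaustive_short_sequences_all_zero(self):
        # nothing under 15 nt can host four G3 runs with three loops
        for bits in itertools.product("AG", repeat=12):
            assert PQS("".join(bits)) == 0

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGG", min_size=15, max_size=40))
    def test_matches_brute_force_oracle(self, seq):
        assert PQS(seq) == brute_pqs_count(seq)

    def test_density_table(self):
        t1 = Transcript("t1", "g1", "GGGAGGGAGGGAGGG" + "ATG" + "GCA" * 60
                        + "TAA", 15, 15 + 186)
        t2 = Transcript("t2", "g2", "ACT" * 3 + "ATG" + "GCA" * 60 + "TAA",
                        9, 9 + 186)  # UTR shorter than 15 nt
        out = positional.pqs_density(Transcriptome([t1, t2]))
        assert out.loc["t1", "pqs_count"] == 1
        assert out.loc["t1", "pqs_density"] == pytest.approx(1 / 15)
        assert np.isnan(out.loc["t2", "pqs_density"])
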