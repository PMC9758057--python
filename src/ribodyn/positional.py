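"""Positional ribosome-density analyses.

Works on P-site-aligned footprint counts (5'-end position + calibrated
A-site offset - 3). Includes metagene profiles around the start and stop
codons, the 15-bin positional fold-change scheme (seven 4-codon bins at
each CDS end plus a variable 'mid' bin), 5'-UTR ribosome density with a
15-nt start-proximal exclusion window, and a scanner for potential
G-quadruplex-forming sequences (PQS) in 5' UTRs.
"""

from __future__ import annotations

import functools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import (
    FootprintProfiles,
    OffsetTable,
    PipelineError,
    Transcript,
    Transcriptome,
)

log = logging.getLogger("ribodyn")

#: Minimum CDS length (nt) for metagene/positional analyses.
MIN_CDS_NT = 192

#: nt immediately upstream of the start codon excluded from 5'-UTR
#: counting, to keep initiation-complex blur out of the UTR signal.
UTR5_EXCLUSION_NT = 15

N_BINS = 15
_EDGE_BINS = 7
_BIN_CODONS = 4
#: Smallest CDS (codons) that fits 14 four-codon bins plus a nonempty mid.
MIN_CODONS_FOR_BINS = 2 * _EDGE_BINS * _BIN_CODONS + 1


def psite_vector(profiles: FootprintProfiles, offsets: OffsetTable,
                 sample: str, tx_id: str) -> np.ndarray:
    """P-site counts per transcript nucleotide, pooling calibrated read
    lengths. The P site of a footprint lies (offset - 3) nt 3' of its
    5' end."""
    L = profiles.tx_lengths[tx_id]
    out = np.zeros(L, dtype=np.int64)
    for rl in offsets.calibrated_lengths:
        counts = profiles.get(sample, tx_id, rl)
        shift = offsets[rl] - 3
        if shift >= 0:
            out[shift:] += counts[: L - shift]
        else:
            out[: L + shift] += counts[-shift:]
    return out


def select_best_transcripts(profiles: FootprintProfiles,
                            annotation: Transcriptome,
                            min_cds_nt: int = MIN_CDS_NT) -> list[str]:
    """One transcript per gene: the one with the highest median
    footprint coverage across samples (ties go to the smaller id),
    restricted to CDS length >= ``min_cds_nt``."""
    samples = profiles.samples
    best: dict[str, tuple[float, str]] = {}
    for gene, txs in annotation.by_gene().items():
        for t in sorted(txs, key=lambda t: t.tx_id):
            if t.cds_length < min_cds_nt:
                continue
            cov = float(np.median([
                sum(profiles.get(s, t.tx_id, rl).sum()
                    for rl in profiles.read_lengths) / t.length
                for s in samples])) if samples else 0.0
            if gene not in best or cov > best[gene][0]:
                best[gene] = (cov, t.tx_id)
            elif cov == best[gene][0] and t.tx_id < best[gene][1]:
                log.info("tie on median coverage for %s; %s wins "
                         "lexicographically", gene, t.tx_id)
                best[gene] = (cov, t.tx_id)
    return sorted(tx for _, tx in best.values())


def metagene(profiles: FootprintProfiles, annotation: Transcriptome,
             offsets: OffsetTable, anchor: str = "start",
             flank: tuple[int, int] = (-30, 90),
             transcripts: list[str] | None = None) -> pd.DataFrame:
    """Mean normalized P-site occupancy around the start or stop codon.

    Per transcript the P-site vector is divided by its mean CDS density
    (making the profile invariant to expression level), then averaged
    over transcripts per stage. Position 0 is the first nucleotide of
    the anchor codon. Returns positions x stages.
    """
    if anchor not in ("start", "stop"):
        raise PipelineError("anchor must be 'start' or 'stop'")
    if transcripts is None:
        transcripts = select_best_transcripts(profiles, annotation)
    if not transcripts:
        raise PipelineError("empty transcript set for metagene")
    lo, hi = flank
    positions = np.arange(lo, hi)
    stages = sorted(set(profiles.sample_stage.values()))
    pooled = profiles.pooled_by_stage()
    out = {}
    for st in stages:
        acc = np.zeros(len(positions))
        n = np.zeros(len(positions))
        for tx_id in transcripts:
            t = annotation[tx_id]
            vec = psite_vector(pooled, offsets, st, tx_id).astype(float)
            cds_mean = vec[t.cds_start: t.cds_end].mean()
            if cds_mean == 0:
                continue
            vec = vec / cds_mean
            origin = t.cds_start if anchor == "start" else t.cds_end - 3
            idx = origin + positions
            ok = (idx >= 0) & (idx < t.length)
            acc[ok] += vec[idx[ok]]
            n[ok] += 1
        with np.errstate(invalid="ignore"):
            out[st] = np.where(n > 0, acc / np.maximum(n, 1), np.nan)
    return pd.DataFrame(out, index=positions)


# ---------------------------------------------------------------------------
# 15-bin positional scheme
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinScheme:
    """Codon-coordinate bins for one transcript: seven 4-codon bins
    anchored at the start, a variable mid bin, seven anchored at the
    stop. Bins tile the CDS without overlap."""

    tx_id: str
    bounds: tuple[tuple[int, int], ...]  # (start_codon, end_codon) half-open

    @property
    def widths(self) -> list[int]:
        return [b - a for a, b in self.bounds]


def bin_scheme(t: Transcript) -> BinScheme | None:
    """The 15-bin layout, or None when the CDS is too short to host
    14 x 4 codons plus a nonempty mid bin."""
    n = t.n_codons
    if n < MIN_CODONS_FOR_BINS:
        return None
    bounds = [(i * _BIN_CODONS, (i + 1) * _BIN_CODONS)
              for i in range(_EDGE_BINS)]
    bounds.append((_EDGE_BINS * _BIN_CODONS, n - _EDGE_BINS * _BIN_CODONS))
    tail0 = n - _EDGE_BINS * _BIN_CODONS
    bounds += [(tail0 + i * _BIN_CODONS, tail0 + (i + 1) * _BIN_CODONS)
               for i in range(_EDGE_BINS)]
    return BinScheme(t.tx_id, tuple(bounds))


def _bin_counts(vec: np.ndarray, t: Transcript, scheme: BinScheme
                ) -> np.ndarray:
    cds = vec[t.cds_start: t.cds_end]
    per_codon = cds.reshape(-1, 3).sum(axis=1)
    return np.array([per_codon[a:b].sum() for a, b in scheme.bounds])


def bin_positional_fc(profiles: FootprintProfiles,
                      annotation: Transcriptome, offsets: OffsetTable,
                      stage_a: str, stage_b: str,
                      transcripts: list[str] | None = None,
                      min_total: int = 64,
                      pseudocount: float = 0.5,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene 15-bin log2 fold changes between two stages with a
    chi-square test on the bin contingency table.

    Bin counts are library-size normalized before the fold change
    (pseudocount on normalized counts); significance is a chi-square
    test of homogeneity on the raw 2 x 15 table, BH-adjusted across
    genes. Genes under ``min_total`` total counts are untested.
    """
    if transcripts is None:
        transcripts = select_best_transcripts(profiles, annotation)
    pooled = profiles.pooled_by_stage()
    rows = []
    lib = {st: max(pooled.total_counts(st), 1) for st in (stage_a, stage_b)}
    scale = 1e6
    for tx_id in transcripts:
        t = annotation[tx_id]
        scheme = bin_scheme(t)
        if scheme is None:
            continue
        ca = _bin_counts(psite_vector(pooled, offsets, stage_a, tx_id),
                         t, scheme)
        cb = _bin_counts(psite_vector(pooled, offsets, stage_b, tx_id),
                         t, scheme)
        row = {"gene": t.gene_id, "transcript": tx_id,
               "total": int(ca.sum() + cb.sum())}
        na = ca / lib[stage_a] * scale + pseudocount
        nb = cb / lib[stage_b] * scale + pseudocount
        lfc = np.log2(nb / na)
        for i in range(N_BINS):
            row[f"bin{i + 1:02d}_log2fc"] = lfc[i]
        if row["total"] >= min_total:
            table = np.vstack([ca, cb])
            keep = table.sum(axis=0) > 0
            try:
                row["p"] = stats.chi2_contingency(table[:, keep])[1]
            except ValueError:
                row["p"] = np.nan
        else:
            row["p"] = np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["padj"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "padj"] = multipletests(out.loc[tested, "p"],
                                                method="fdr_bh")[1]
    out["significant"] = out["padj"] < alpha
    return out


# ---------------------------------------------------------------------------
# 5' UTR ribosome density
# ---------------------------------------------------------------------------

def utr5_density_fc(profiles: FootprintProfiles, annotation: Transcriptome,
                    offsets: OffsetTable, rna_tpm: pd.DataFrame,
                    dte_groups: pd.Series,
                    stage_pair: tuple[str, str] | None = None,
                    min_tpm: float = 0.1, min_psite: int = 10,
                    exclusion_nt: int = UTR5_EXCLUSION_NT
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """5'-UTR ribosome density fold change by dTE group.

    Density = (UTR P-site count, the last ``exclusion_nt`` nt before the
    start codon excluded) / RNA TPM. Fold change runs from the first to
    the middle stage by default. Transcripts need >= ``min_tpm`` TPM at
    both stages and >= ``min_psite`` UTR P-site counts summed over the
    pair. Rank-sum (Wilcoxon) tests compare down/none/up groups.
    """
    pooled = profiles.pooled_by_stage()
    stages = sorted(set(pooled.sample_stage.values()))
    if stage_pair is None:
        order = [st for st in rna_tpm.columns if st in stages]
        stage_pair = (order[0], order[len(order) // 2])
    st_a, st_b = stage_pair
    rows, n_excluded = [], 0
    for tx_id in pooled.transcripts():
        t = annotation[tx_id]
        utr_end = max(t.cds_start - exclusion_nt, 0)
        dens = {}
        counts = {}
        for st in (st_a, st_b):
            vec = psite_vector(pooled, offsets, st, tx_id)
            counts[st] = int(vec[:utr_end].sum())
            tpm = float(rna_tpm.at[t.gene_id, st]) \
                if t.gene_id in rna_tpm.index else 0.0
            dens[st] = counts[st] / tpm if tpm > 0 else np.nan
        tpm_a = rna_tpm.at[t.gene_id, st_a] if t.gene_id in rna_tpm.index else 0
        tpm_b = rna_tpm.at[t.gene_id, st_b] if t.gene_id in rna_tpm.index else 0
        if (tpm_a < min_tpm or tpm_b < min_tpm
                or counts[st_a] + counts[st_b] < min_psite):
            n_excluded += 1
            continue
        lfc = np.log2((dens[st_b] + 1e-9) / (dens[st_a] + 1e-9))
        rows.append({
            "transcript": tx_id, "gene": t.gene_id,
            "utr_count_a": counts[st_a], "utr_count_b": counts[st_b],
            "density_a": dens[st_a], "density_b": dens[st_b],
            "log2fc": lfc,
            "dte": dte_groups.get(t.gene_id, "none"),
        })
    log.info("utr5_density_fc: %d transcripts excluded by thresholds",
             n_excluded)
    records = pd.DataFrame(rows)
    tests = []
    if not records.empty:
        groups = {g: records.loc[records["dte"] == g, "log2fc"]
                  for g in ("down", "none", "up")}
        for g1, g2 in (("up", "none"), ("down", "none"), ("up", "down")):
            a, b = groups[g1], groups[g2]
            if len(a) >= 2 and len(b) >= 2:
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                tests.append({"group1": g1, "group2": g2, "n1": len(a),
                              "n2": len(b), "U": stat, "p": p})
    return records, pd.DataFrame(tests)


# ---------------------------------------------------------------------------
# Potential G-quadruplex sequences
# ---------------------------------------------------------------------------

_MIN_PQS_NT = 4 * 3 + 3  # four G3 runs, three 1-nt loops


def _pqs_match_end(seq: str, i: int) -> int | None:
    """Longest end index of a PQS starting exactly at ``i``:
    G{3,} (N{1,7} G{3,}){3}. None if no match starts there."""
    n = len(seq)

    @functools.lru_cache(maxsize=None)
    def run_len(p: int) -> int:
        q = p
        while q < n and seq[q] == "G":
            q += 1
        return q - p

    best: dict[tuple[int, int], int | None] = {}

    def explore(p: int, runs_done: int) -> int | None:
        # p: next unread position after finishing `runs_done` G-runs
        key = (p, runs_done)
        if key in best:
            return best[key]
        if runs_done == 4:
            best[key] = p
            return p
        res = None
        for loop in range(1, 8):
            q = p + loop
            if q + 3 > n:
                break
            r = run_len(q)
            if r >= 3:
                for g in range(3, r + 1):
                    sub = explore(q + g, runs_done + 1)
                    if sub is not None and (res is None or sub > res):
                        res = sub
        best[key] = res
        return res

    r0 = run_len(i)
    if r0 < 3:
        return None
    out = None
    for g in range(3, r0 + 1):
        sub = explore(i + g, 1)
        if sub is not None and (out is None or sub > out):
            out = sub
    return out


def pqs_count(seq: str) -> int:
    """Non-overlapping PQS matches, scanning left to right and taking
    the longest match at each leftmost start."""
    seq = seq.upper()
    count, i = 0, 0
    n = len(seq)
    while i <= n - _MIN_PQS_NT:
        end = _pqs_match_end(seq, i)
        if end is not None:
            count += 1
            i = end
        else:
            i += 1
    return count


def pqs_density(annotation: Transcriptome,
                min_utr_len: int = 15) -> pd.DataFrame:
    """PQS count per 5'-UTR nucleotide per transcript; NaN where the
    UTR is shorter than ``min_utr_len``."""
    rows = []
    for t in annotation:
        utr = t.utr5_seq
        if len(utr) < min_utr_len:
            dens, cnt = np.nan, np.nan
        else:
            cnt = pqs_count(utr)
            dens = cnt / len(utr)
        rows.append({"transcript": t.tx_id, "gene": t.gene_id,
                     "utr5_length": len(utr), "pqs_count": cnt,
                     "pqs_density": dens})
    return pd.DataFrame(rows).set_index("transcript")
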