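"""Codon-resolution ribosome occupancy and tRNA availability.

The core estimator is the RUST transform: per transcript, footprint
5'-end counts are binarized (1 where above the transcript mean) so the
codon-level enrichment of high-count positions is robust to library
depth and per-transcript coverage differences. Plotting the
between-codon variance (and the KL divergence of the observed codon
distribution from its background) as a function of distance from the
read 5' end reveals a single narrow peak a consistent distance from the
codon: that distance is the 5'-end-to-A-site offset for that read
length. This data-driven calibration is what makes dwell-time analysis
possible on libraries with strong nuclease cut-site bias, where
start/stop-peak methods pick implausible offsets.

A-site occupancy for a codon is the RUST enrichment at the calibrated
offset; the P site sits 3 nt closer to the 5' end, the E site 6 nt.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io import (
    GENETIC_CODE,
    SENSE_CODONS,
    FootprintProfiles,
    OffsetTable,
    PipelineError,
    Transcriptome,
    TrnaMeasurement,
    anticodon_for,
    DEFAULT_OFFSET_WINDOW,
)

log = logging.getLogger("ribodyn")

#: Codons excluded from each CDS end before RUST, to keep start/stop
#: peaks and terminal ramp effects out of the dwell estimates.
DEFAULT_TRIM_CODONS = 20

_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


@dataclass
class RustProfile:
    """RUST enrichment (observed/expected) per codon at each distance
    from the read 5' end, for one sample and read length."""

    sample: str
    read_length: int
    enrichment: pd.DataFrame          # codons x distances (nt from 5' end)
    expected_codon_freq: pd.Series    # background codon distribution
    mean_binarized: float
    n_reads: int


def compute_rust(profiles: FootprintProfiles, annotation: Transcriptome,
                 read_length: int, sample: str,
                 trim_codons: int = DEFAULT_TRIM_CODONS,
                 expected: str = "footprint") -> RustProfile:
    """RUST enrichment profile for one sample and read length.

    Per transcript, the 5'-end count vector over the trimmed CDS is
    binarized at the transcript mean. The observed value for codon c at
    distance d is the mean binarized count over all positions lying d nt
    5' of an occurrence of c; expected is the global mean binarized
    value. ``expected`` chooses the codon background for the KL
    diagnostics: footprint-weighted codon frequency (default) or
    uniform. Transcripts with no footprints are skipped.
    """
    n_codons_t = len(SENSE_CODONS)
    n_d = read_length - 2  # distances 0 .. read_length-3
    sum_b = np.zeros((n_codons_t, n_d))
    cnt = np.zeros((n_codons_t, n_d))
    freq_w = np.zeros(n_codons_t)
    total_b, total_pos, total_reads = 0.0, 0, 0

    for tx_id in profiles.transcripts(sample):
        t = annotation[tx_id]
        counts = profiles.get(sample, tx_id, read_length)
        region_start = t.cds_start + 3 * trim_codons
        region_end = t.cds_end - 3 * trim_codons
        if region_end - region_start < 3:
            continue
        region = counts[region_start:region_end]
        n_reads_tx = int(region.sum())
        if n_reads_tx == 0:
            continue
        b = (region > region.mean()).astype(float)
        total_b += b.sum()
        total_pos += b.size
        total_reads += n_reads_tx

        codons = t.codons()
        codon_idx = np.array(
            [_CODON_INDEX.get(codons[ci], -1)
             for ci in range(trim_codons, t.n_codons - trim_codons)])
        starts = (np.arange(trim_codons, t.n_codons - trim_codons) * 3
                  + t.cds_start - region_start)  # codon start in region coords
        valid_codon = codon_idx >= 0
        codon_idx = codon_idx[valid_codon]
        starts = starts[valid_codon]
        freq = np.bincount(codon_idx, minlength=n_codons_t).astype(float)
        freq_w += freq * n_reads_tx
        for d in range(n_d):
            pos = starts - d
            ok = pos >= 0
            if not ok.any():
                continue
            np.add.at(sum_b[:, d], codon_idx[ok], b[pos[ok]])
            np.add.at(cnt[:, d], codon_idx[ok], 1.0)

    if total_pos == 0:
        raise PipelineError(
            f"no usable footprints for sample {sample!r} length {read_length}")
    expected_mean = total_b / total_pos
    with np.errstate(invalid="ignore", divide="ignore"):
        obs = np.where(cnt > 0, sum_b / np.maximum(cnt, 1), np.nan)
        enr = obs / expected_mean if expected_mean > 0 else obs * np.nan
    enrichment = pd.DataFrame(enr, index=list(SENSE_CODONS),
                              columns=np.arange(n_d))
    if expected == "uniform":
        q = pd.Series(1.0 / n_codons_t, index=list(SENSE_CODONS))
    else:
        q = pd.Series(freq_w / freq_w.sum(), index=list(SENSE_CODONS))
    return RustProfile(sample, read_length, enrichment, q,
                       expected_mean, total_reads)


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) in bits; terms with p = 0 contribute 0."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def select_offsets(rusts: dict[int, RustProfile],
                   window: tuple[int, int] = DEFAULT_OFFSET_WINDOW,
                   flatness_ratio: float = 1.05
                   ) -> tuple[OffsetTable, pd.DataFrame]:
    """Choose the 5'-end -> A-site offset per read length.

    For each distance d the between-codon variance of RUST enrichment
    and the KL divergence (bits) of the observed codon distribution at d
    from the background are computed; the offset is the variance argmax
    within the plausible ``window``. A flat variance curve
    (max/median < ``flatness_ratio``) flags the length uncalibrated
    rather than defaulting silently. Diagnostics include the full curves
    and the secondary (P-site) value 3 nt 5' of the chosen offset.
    """
    offsets: dict[int, int] = {}
    uncalibrated: set[int] = set()
    rows = []
    lo, hi = window
    for rl, rust in sorted(rusts.items()):
        enr = rust.enrichment
        q = rust.expected_codon_freq
        var_curve, kl_curve = {}, {}
        for d in enr.columns:
            col = enr[d].dropna()
            if len(col) < 2:
                continue
            var_curve[d] = float(col.var(ddof=1))
            obs = col * q.reindex(col.index)
            p = (obs / obs.sum()).to_numpy()
            kl_curve[d] = kl_divergence(p, (q.reindex(col.index)
                                            / q.reindex(col.index).sum()
                                            ).to_numpy())
        in_win = {d: v for d, v in var_curve.items() if lo <= d <= hi}
        if not in_win:
            uncalibrated.add(rl)
            chosen = None
        else:
            chosen = max(in_win, key=in_win.get)
            # median over informative distances only: with a single read
            # length all 5' ends share a frame, so two of every three
            # distances are structurally empty (variance exactly 0)
            positive = [v for v in var_curve.values() if v > 0]
            med = float(np.median(positive)) if positive else 0.0
            if med <= 0 or in_win[chosen] / med < flatness_ratio:
                uncalibrated.add(rl)
                chosen = None
        for d in sorted(var_curve):
            rows.append({
                "read_length": rl, "distance": d,
                "var_between_codons": var_curve[d],
                "kl_bits": kl_curve.get(d, np.nan),
                "chosen": chosen is not None and d == chosen,
                "secondary_p_site": chosen is not None and d == chosen - 3,
            })
        if chosen is not None:
            offsets[rl] = int(chosen)
    return (OffsetTable(offsets, uncalibrated, window=window),
            pd.DataFrame(rows))


def site_occupancy(rusts_by_stage: dict[str, dict[int, RustProfile]],
                   offsets: OffsetTable
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A/P/E-site occupancy per codon and stage.

    The A site sits at the calibrated offset, the P site 3 nt and the E
    site 6 nt closer to the 5' end. Read lengths are combined by
    footprint-count-weighted mean. Returns (combined, per-length) tidy
    tables with columns codon, stage, site, occupancy[, read_length].
    """
    site_shift = {"A": 0, "P": -3, "E": -6}
    per_len_rows = []
    for stage, rusts in rusts_by_stage.items():
        for rl, rust in rusts.items():
            if rl not in offsets.offsets:
                continue
            off = offsets[rl]
            for site, shift in site_shift.items():
                d = off + shift
                if d < 0:
                    warnings.warn(
                        f"{site}-site distance negative for length {rl}; "
                        "site omitted")
                    continue
                col = rust.enrichment[d]
                for codon, val in col.items():
                    if np.isfinite(val):
                        per_len_rows.append({
                            "codon": codon, "stage": stage, "site": site,
                            "read_length": rl, "occupancy": val,
                            "weight": rust.n_reads,
                            "amino_acid": GENETIC_CODE[codon],
                        })
    per_len = pd.DataFrame(per_len_rows)
    if per_len.empty:
        raise PipelineError("no calibrated read length with occupancy data")

    def wmean(g: pd.DataFrame) -> float:
        return float(np.average(g["occupancy"], weights=g["weight"]))

    combined = (per_len.groupby(["codon", "stage", "site"])
                .apply(wmean, include_groups=False)
                .rename("occupancy").reset_index())
    combined["amino_acid"] = combined["codon"].map(GENETIC_CODE)
    return combined, per_len.drop(columns="weight")


# ---------------------------------------------------------------------------
# tRNA abundance, usage, availability
# ---------------------------------------------------------------------------

#: Codon third positions readable through wobble by each anticodon first
#: (position-34) base, beyond the Watson-Crick partner.
_WOBBLE_EXTRA = {"G": ["T"], "T": ["G"]}


@dataclass
class TrnaTable:
    isodecoder_abundance: pd.DataFrame  # isodecoder x stage, -dCt scale
    codon_abundance: pd.DataFrame       # codon x stage
    usage: pd.DataFrame                 # codon x stage, sums to 1
    availability: pd.DataFrame          # codon x stage, OLS residuals


def _decoding_map(anticodons: pd.Series, wobble: bool) -> dict[str, list[str]]:
    """codon -> isodecoder ids able to decode it."""
    out: dict[str, list[str]] = {c: [] for c in SENSE_CODONS}
    for iso, ac in anticodons.items():
        codon = anticodon_for(ac)  # exact Watson-Crick partner
        if codon in out:
            out[codon].append(iso)
        if wobble:
            for third in _WOBBLE_EXTRA.get(ac[0], []):
                wob = codon[:2] + third
                if wob in out:
                    out[wob].append(iso)
    return out


def trna_codon_table(ct: TrnaMeasurement, annotation: Transcriptome,
                     rna_density: pd.DataFrame | None = None,
                     wobble: bool = False) -> TrnaTable:
    """Abundance, usage and availability per codon and stage.

    Abundance is -(Ct_tRNA - mean(Ct_5S, Ct_18S)) averaged over
    replicates; per-codon abundance sums decoding isodecoders (exact
    anticodon match; set ``wobble`` to add G:U pairs). Usage counts each
    codon in every CDS weighted by the transcript's RNA density for that
    stage (uniform weights if none given), normalized to sum 1.
    Availability is the residual of usage regressed on abundance, per
    stage; positive values mean demand exceeds supply.
    """
    ref = ct.ct.loc[list(ct.reference_ids)].mean(axis=0)
    neg_dct = -(ct.ct.loc[ct.isodecoders] - ref)
    stage_of = {r.sample: r.stage for r in ct.samples.df.itertuples()}
    abundance = neg_dct.T.groupby(
        neg_dct.columns.map(stage_of)).mean().T
    stages = [st for st in ct.samples.stages if st in abundance.columns]
    abundance = abundance[stages]

    decode = _decoding_map(ct.anticodon, wobble)
    codon_ab = pd.DataFrame(
        {st: {c: (abundance.loc[ids, st].sum() if ids else np.nan)
              for c, ids in decode.items()} for st in stages})

    counts = pd.DataFrame(
        {t.tx_id: pd.Series(t.codons()).value_counts() for t in annotation}
    ).reindex(list(SENSE_CODONS)).fillna(0.0)
    usage = {}
    for st in stages:
        if rna_density is None:
            w = pd.Series(1.0, index=counts.columns)
        else:
            gene_w = rna_density[st]
            w = pd.Series({t.tx_id: gene_w.get(t.gene_id, 0.0)
                           for t in annotation})
        u = counts.mul(w, axis=1).sum(axis=1)
        usage[st] = u / u.sum()
    usage = pd.DataFrame(usage)

    availability = pd.DataFrame(index=usage.index, columns=stages,
                                dtype=float)
    for st in stages:
        df = pd.DataFrame({"usage": usage[st], "ab": codon_ab[st]}).dropna()
        X = sm.add_constant(df["ab"])
        fit = sm.OLS(df["usage"], X).fit()
        availability.loc[df.index, st] = fit.resid.astype(float)
    return TrnaTable(abundance, codon_ab, usage, availability)


# ---------------------------------------------------------------------------
# Dwell-time variance partition and site correlation
# ---------------------------------------------------------------------------

def dwell_variance_partition(occupancy: pd.DataFrame, trna: TrnaTable,
                             trna_term: str = "abundance",
                             interaction: bool = True) -> dict:
    """Linear partition of A-site occupancy variance.

    Model: occupancy ~ stage + amino acid + tRNA abundance (or
    availability) [+ stage x amino acid]. One observation per quantified
    codon per stage. Returns the ANOVA table, the fraction of total sum
    of squares per term, and the coefficient table.
    """
    a = occupancy[occupancy["site"] == "A"].copy()
    if a.empty:
        raise PipelineError("no A-site occupancy rows")
    src = trna.codon_abundance if trna_term == "abundance" \
        else trna.availability
    a["trna"] = [src.at[r.codon, r.stage]
                 if r.codon in src.index and r.stage in src.columns
                 else np.nan
                 for r in a.itertuples()]
    a = a.dropna(subset=["occupancy", "trna"])
    formula = "occupancy ~ C(stage) + C(amino_acid) + trna"
    if interaction:
        formula += " + C(stage):C(amino_acid)"
    fit = smf.ols(formula, data=a).fit()
    exog = fit.model.exog
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        # name the aliased columns via the QR diagonal
        _, r = np.linalg.qr(exog)
        diag = np.abs(np.diag(r))
        aliased = [n for n, d in zip(fit.model.exog_names, diag)
                   if d < 1e-8 * diag.max()]
        raise PipelineError(f"rank-deficient design; aliased terms: {aliased}")
    anova = sm.stats.anova_lm(fit, typ=2)
    total_ss = float(anova["sum_sq"].sum())
    fraction = anova["sum_sq"] / total_ss if total_ss > 0 \
        else anova["sum_sq"] * 0.0
    return {"anova": anova, "fraction": fraction, "coef": fit.params,
            "pvalues": fit.pvalues, "n_obs": int(a.shape[0]),
            "r2": float(fit.rsquared)}


def site_correlation(occupancy: pd.DataFrame) -> pd.DataFrame:
    """Per-stage OLS slope of A-site on P-site occupancy with 95% CI."""
    a = occupancy[occupancy["site"] == "A"].set_index(["codon", "stage"])
    p = occupancy[occupancy["site"] == "P"].set_index(["codon", "stage"])
    joined = a[["occupancy"]].join(p[["occupancy"]], lsuffix="_A",
                                   rsuffix="_P").dropna().reset_index()
    rows = []
    for stage, grp in joined.groupby("stage", sort=False):
        X = sm.add_constant(grp["occupancy_P"])
        fit = sm.OLS(grp["occupancy_A"], X).fit()
        ci = fit.conf_int().loc["occupancy_P"]
        rows.append({"stage": stage, "slope": fit.params["occupancy_P"],
                     "ci_low": ci[0], "ci_high": ci[1],
                     "n_codons": len(grp)})
    return pd.DataFrame(rows)
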