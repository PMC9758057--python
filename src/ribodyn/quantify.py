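"""Translation-efficiency quantification and differential calling.

Translation efficiency (TE) is the ratio of ribosome-footprint density
over a gene's coding sequence to the mRNA's abundance; a TE change is a
shift in ribosome loading not explained by the transcriptional change.
The differential machinery here is a transparent stand-in for the
moderated-t / bivariate-posterior tools used on the original data: a
log-scale z-test with simple variance shrinkage, and a
difference-of-log-fold-changes statistic for TE. Calls use the
conventional >= 1.25-fold and BH-adjusted p < 0.05 thresholds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneMatrix, PipelineError

#: A gene counts as translated with at least this many footprints
#: (summed over replicates) in at least one stage.
TRANSLATED_FOOTPRINT_MIN = 32

FC_THRESHOLD = 1.25
ALPHA = 0.05
DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_SHRINKAGE = 0.5


def density_normalize(counts: GeneMatrix, lengths: pd.Series) -> GeneMatrix:
    """TPM-style length and depth normalisation.

    rate = count / length(kb); density = rate / sum(rate) * 1e6, per
    sample. ``lengths`` are nucleotides per gene (CDS length for
    footprints, transcript length for RNA).
    """
    lengths = lengths.reindex(counts.genes)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])[:5]
        raise PipelineError(f"no length for genes: {missing}")
    rate = counts.values.div(lengths / 1000.0, axis=0)
    colsum = rate.sum(axis=0)
    if (colsum <= 0).any():
        bad = list(colsum.index[colsum <= 0])
        raise PipelineError(f"zero library size in samples: {bad}")
    dens = rate.div(colsum, axis=1) * 1e6
    return GeneMatrix(dens, "density", counts.samples)


def filter_translated(rpf_counts: GeneMatrix,
                      threshold: int = TRANSLATED_FOOTPRINT_MIN) -> set[str]:
    """Genes whose per-stage footprint sum reaches ``threshold`` in at
    least one stage."""
    sums = rpf_counts.stage_sums()
    keep = sums.max(axis=1) >= threshold
    return set(sums.index[keep])


def _contrast_pairs(stages: tuple[str, ...], contrasts: str
                    ) -> list[tuple[str, str]]:
    if contrasts == "stepwise":
        return list(zip(stages[:-1], stages[1:]))
    if contrasts == "vs-first":
        return [(stages[0], st) for st in stages[1:]]
    raise PipelineError(f"unknown contrast scheme {contrasts!r}")


def assay_fold_changes(matrix: GeneMatrix, contrasts: str = "stepwise",
                       assay: str | None = None,
                       pseudocount: float = DEFAULT_PSEUDOCOUNT,
                       shrinkage: float = DEFAULT_SHRINKAGE,
                       fc_threshold: float = FC_THRESHOLD,
                       alpha: float = ALPHA) -> pd.DataFrame:
    """Per-gene log2 fold changes with shrunken-variance z-tests.

    For each stage the per-gene replicate variance of log2(value +
    pseudocount) is shrunk toward the across-gene mean variance of that
    stage (weight ``shrinkage`` on the global mean); the z statistic is
    log2FC over the quadrature SE of the two stage means. BH adjustment
    is applied within each contrast. Genes with fewer than two usable
    replicates in either stage are flagged untestable and never called.
    """
    means, variances, ns = matrix.log2_stage_stats(pseudocount)
    grand_var = variances.mean(axis=0)  # per stage, across genes
    shrunk = (1 - shrinkage) * variances + shrinkage * grand_var
    if assay is None:
        assay = matrix.samples.df["assay"].iloc[0]
    out = []
    for st_a, st_b in _contrast_pairs(matrix.stages, contrasts):
        lfc = means[st_b] - means[st_a]
        se = np.sqrt(shrunk[st_b] / ns[st_b].clip(lower=1)
                     + shrunk[st_a] / ns[st_a].clip(lower=1))
        testable = (ns[st_a] >= 2) & (ns[st_b] >= 2)
        z = lfc.where(testable) / se.where(testable & (se > 0))
        p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=lfc.index)
        # zero-variance data: the z-test degenerates; p is 1 with no
        # change and 0 with any change
        degenerate = testable & (se == 0)
        p[degenerate] = np.where(lfc[degenerate] == 0, 1.0, 0.0)
        padj = pd.Series(np.nan, index=lfc.index)
        mask = p.notna()
        if mask.any():
            padj[mask] = multipletests(p[mask], method="fdr_bh")[1]
        call = _make_calls(lfc, padj, testable, fc_threshold, alpha)
        out.append(pd.DataFrame({
            "gene": lfc.index, "contrast": f"{st_b}_vs_{st_a}",
            "assay": assay, "log2fc": lfc.to_numpy(), "se": se.to_numpy(),
            "p": p.to_numpy(), "padj": padj.to_numpy(),
            "testable": testable.to_numpy(), "call": call,
        }))
    return pd.concat(out, ignore_index=True)


def _make_calls(lfc: pd.Series, padj: pd.Series, testable: pd.Series,
                fc_threshold: float, alpha: float) -> np.ndarray:
    thr = np.log2(fc_threshold)
    sig = testable & (padj < alpha)
    call = np.where(sig & (lfc >= thr), "up",
                    np.where(sig & (lfc <= -thr), "down", "none"))
    call = np.where(testable, call, "untestable")
    return call


def compute_te(rna_density: GeneMatrix, rpf_density: GeneMatrix,
               translated: set[str] | None = None,
               pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Gene x stage translation efficiency on per-stage replicate means.

    TE = (RPF + pc) / (RNA + pc). Entries are NaN (undefined, not zero)
    where RNA density is 0 or the gene is outside the translated set.
    """
    if list(rna_density.genes) != list(rpf_density.genes) or \
            rna_density.stages != rpf_density.stages:
        raise PipelineError("RNA and RPF matrices must share genes and stages")
    rna_m = rna_density.stage_means()
    rpf_m = rpf_density.stage_means()
    te = (rpf_m + pseudocount) / (rna_m + pseudocount)
    te = te.where(rna_m > 0)
    if translated is not None:
        te.loc[~te.index.isin(translated)] = np.nan
    te.attrs["pseudocount"] = pseudocount
    return te


def dte_call(rna_counts: GeneMatrix, rpf_counts: GeneMatrix,
             contrasts: str = "vs-first",
             pseudocount: float = DEFAULT_PSEUDOCOUNT,
             shrinkage: float = DEFAULT_SHRINKAGE,
             footprint_min: int = TRANSLATED_FOOTPRINT_MIN,
             fc_threshold: float = FC_THRESHOLD,
             alpha: float = ALPHA) -> pd.DataFrame:
    """Differential translation efficiency with transcription controlled.

    statistic = log2FC(RPF) - log2FC(RNA); its SE is the quadrature sum
    of the two assay SEs, so a transcriptional change shared by both
    assays cancels exactly. Calls at >= ``fc_threshold``-fold TE change
    and BH-adjusted p < ``alpha``, restricted to genes passing the
    footprint filter. Swapping the two inputs flips up and down calls.
    """
    keep = sorted(filter_translated(rpf_counts, footprint_min))
    rna_fc = assay_fold_changes(rna_counts, contrasts, "RNA",
                                pseudocount, shrinkage)
    rpf_fc = assay_fold_changes(rpf_counts, contrasts, "RPF",
                                pseudocount, shrinkage)
    key = ["gene", "contrast"]
    merged = rpf_fc.merge(rna_fc, on=key, suffixes=("_rpf", "_rna"))
    merged = merged[merged["gene"].isin(keep)].copy()
    lfc = merged["log2fc_rpf"] - merged["log2fc_rna"]
    se = np.sqrt(merged["se_rpf"] ** 2 + merged["se_rna"] ** 2)
    testable = merged["testable_rpf"] & merged["testable_rna"]
    z = lfc.where(testable) / se.where(testable & (se > 0))
    p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=merged.index)
    degenerate = testable & (se == 0)
    p[degenerate] = np.where(lfc[degenerate] == 0, 1.0, 0.0)
    out_rows = []
    for contrast, grp in merged.assign(lfc=lfc, se=se, p=p,
                                       testable=testable
                                       ).groupby("contrast", sort=False):
        padj = pd.Series(np.nan, index=grp.index)
        mask = grp["p"].notna()
        if mask.any():
            padj[mask] = multipletests(grp.loc[mask, "p"],
                                       method="fdr_bh")[1]
        call = _make_calls(grp["lfc"], padj, grp["testable"],
                           fc_threshold, alpha)
        out_rows.append(pd.DataFrame({
            "gene": grp["gene"], "contrast": contrast, "assay": "TE",
            "log2fc": grp["lfc"].to_numpy(), "se": grp["se"].to_numpy(),
            "p": grp["p"].to_numpy(), "padj": padj.to_numpy(),
            "testable": grp["testable"].to_numpy(), "call": call,
        }))
    return pd.concat(out_rows, ignore_index=True)


def dte_gene_groups(te_table: pd.DataFrame) -> pd.Series:
    """Collapse per-contrast TE calls to one label per gene: 'up' if any
    contrast is called up (mirror for down), 'both' if both occur,
    otherwise 'none'."""
    def collapse(calls: pd.Series) -> str:
        has_up = (calls == "up").any()
        has_down = (calls == "down").any()
        if has_up and has_down:
            return "both"
        if has_up:
            return "up"
        if has_down:
            return "down"
        return "none"
    return te_table.groupby("gene")["call"].apply(collapse)


# ---------------------------------------------------------------------------
# Arithmetic summaries
# ---------------------------------------------------------------------------

def percent_te_changing(n_up: int, n_down: int, n_quantified: int) -> float:
    """Percentage of quantified transcripts with a TE change."""
    if n_quantified <= 0:
        raise PipelineError("n_quantified must be positive")
    return 100.0 * (n_up + n_down) / n_quantified


def te_fold_change(rpf_fold: float, rna_fold: float) -> float:
    """TE fold change implied by footprint and mRNA fold changes."""
    if rna_fold <= 0:
        raise PipelineError("RNA fold change must be positive")
    return rpf_fold / rna_fold
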