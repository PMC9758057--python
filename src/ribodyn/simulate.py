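"""Synthetic multi-omics generator with known ground truth.

Emulates the study design every downstream stage expects: five
developmental stages, RNA-seq and Ribo-seq in duplicate, mass
spectrometry in triplicate, a tRNA qPCR array of 151 isodecoders, and
ribosome footprints whose 5'-end positions are driven by codon-specific
A-site dwell times with length-specific offsets and RNase cut-site bias.

Counts are negative-binomial around stage-specific means; a subset of
genes carries a translation-efficiency shift concentrated at the middle
stage (footprint means scale by ``te_effect`` from ``te_shift_stage``
onward with RNA unchanged). Protein trajectories follow the
synthesis-degradation ODE in :mod:`ribodyn.kinetics` with per-gene rates,
multiplicative log-normal noise and missing-at-random dropout.

Setting ``nb_dispersion`` to 0 switches count noise off entirely
(realized counts equal their expected means); this degenerate mode
exists for exactness tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import kinetics
from .io import (
    DEFAULT_STAGE_HOURS,
    DEFAULT_STAGES,
    GENETIC_CODE,
    SENSE_CODONS,
    ConfigError,
    FootprintProfiles,
    GeneMatrix,
    SampleTable,
    Transcript,
    Transcriptome,
    TrnaMeasurement,
    anticodon_for,
)

KINETIC_CATEGORIES = ("stationary", "linear", "degradation", "production",
                      "MSdev")

#: Per-length 5'-end -> A-site offsets used by the generator by default;
#: the calibration algorithm must recover these.
DEFAULT_TRUE_OFFSETS = {25: 12, 26: 13, 27: 13, 28: 14, 29: 14, 30: 15, 31: 15}


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    stages: tuple[str, ...] = DEFAULT_STAGES
    stage_hours: tuple[float, ...] = DEFAULT_STAGE_HOURS
    reps_rna: int = 2
    reps_rpf: int = 2
    reps_ms: int = 3
    reps_trna: int = 2
    nb_dispersion: float = 0.01
    frac_te_up: float = 0.1
    frac_te_down: float = 0.1
    te_shift_stage: int = 2
    te_effect: float = 2.0
    mean_log10_expr: float = 2.3        # median gene ~200 counts
    sd_log10_expr: float = 0.6
    stage_walk_sd: float = 0.25         # per-stage log-normal drift of means
    baseline_te_sd: float = 0.15
    category_fracs: dict[str, float] = field(default_factory=lambda: {
        c: 0.2 for c in KINETIC_CATEGORIES})
    log_ks_range: tuple[float, float] = (-1.0, 1.0)      # log10, per h
    log_kd_range: tuple[float, float] = (-2.46, -1.15)   # log10 of 1/h,
    # i.e. half-lives between ~10 h and ~200 h, typical for proteins
    p0_deviation_sd: float = 0.8        # log-scale start-off-equilibrium
    msdev_jump_sd: float = 0.7
    ms_noise_sd: float = 0.1
    ms_dropout_rate: float = 0.1
    n_transcripts: int = 40
    cds_codons_range: tuple[int, int] = (150, 400)
    utr5_range: tuple[int, int] = (30, 200)
    utr3_range: tuple[int, int] = (30, 150)
    footprint_reads: int = 200_000
    read_lengths: tuple[int, ...] = tuple(range(25, 32))
    true_offsets: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_OFFSETS))
    dwell_params: dict | None = None    # codon->weight or stage->codon->
    # weight; None = amino-acid-structured default (see _stage_dwell)
    cutbias_params: dict | None = None  # {"five": {nt: w}, "three": {nt: w}}
    trna_ct_ref: float = 16.0
    trna_ct_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if not (0 <= self.frac_te_up <= 1 and 0 <= self.frac_te_down <= 1):
            raise ConfigError("TE fractions must be proportions")
        if self.frac_te_up + self.frac_te_down > 1:
            raise ConfigError("frac_te_up + frac_te_down must be <= 1")
        if not 0 <= self.te_shift_stage < len(self.stages):
            raise ConfigError("te_shift_stage outside stage range")
        if self.te_effect <= 1:
            raise ConfigError("te_effect must exceed 1")
        bad = [rl for rl in self.read_lengths if not 25 <= rl <= 31]
        if bad:
            raise ConfigError(f"read lengths outside [25, 31]: {bad}")
        missing = [rl for rl in self.read_lengths if rl not in self.true_offsets]
        if missing:
            raise ConfigError(f"read lengths without a true offset: {missing}")
        if self.dwell_params is not None:
            flat = self.dwell_params
            if flat and isinstance(next(iter(flat.values())), dict):
                flat = {c: w for d in flat.values() for c, w in d.items()}
            if any(w <= 0 for w in flat.values()):
                raise ConfigError("dwell weights must be strictly positive")
        if not np.isclose(sum(self.category_fracs.values()), 1.0):
            raise ConfigError("category fractions must sum to 1")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]


def load_config(path: str | Path) -> SimulationConfig:
    """Build a SimulationConfig from a YAML file (flat or nested one
    level; nested sections are merged)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    flat: dict = {}
    for key, value in raw.items():
        if isinstance(value, dict) and key not in (
                "true_offsets", "dwell_params", "cutbias_params",
                "category_fracs"):
            flat.update(value)
        else:
            flat[key] = value
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(flat) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for k in ("true_offsets",):
        if k in flat and isinstance(flat[k], dict):
            flat[k] = {int(a): int(b) for a, b in flat[k].items()}
    for k in ("stages", "stage_hours", "read_lengths", "cds_codons_range",
              "utr5_range", "utr3_range", "log_ks_range", "log_kd_range"):
        if k in flat and isinstance(flat[k], list):
            flat[k] = tuple(flat[k])
    return SimulationConfig(**flat)


@dataclass
class GroundTruth:
    """Per-gene/per-feature generating values, for recovery tests."""
    te_label: pd.Series | None = None          # gene -> up/down/none
    te_trajectory: pd.DataFrame | None = None  # gene x stage true TE
    kinetic: pd.DataFrame | None = None        # gene -> category, Ks, Kd, P0
    protein_truth: pd.DataFrame | None = None  # gene x stage noiseless P
    dwell: dict[str, pd.Series] | None = None  # stage -> codon weight
    offsets: dict[int, int] | None = None
    tx_abundance: pd.Series | None = None
    isodecoder_abundance: pd.Series | None = None


# ---------------------------------------------------------------------------
# Expression counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB counts with Var = mu + dispersion * mu^2; dispersion 0 is the
    deterministic noise-off mode (counts = rounded means)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return np.round(mean).astype(np.int64)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(np.int64)


def simulate_expression(config: SimulationConfig
                        ) -> tuple[GeneMatrix, GeneMatrix, GroundTruth]:
    """RNA and RPF count matrices plus the generating truth.

    dTE-up genes have their footprint means multiplied by ``te_effect``
    from ``te_shift_stage`` onward with RNA means unchanged; dTE-down is
    the mirror image.
    """
    rng = np.random.default_rng(config.seed)
    n, T = config.n_genes, len(config.stages)
    genes = config.gene_ids

    base = 10 ** rng.normal(config.mean_log10_expr, config.sd_log10_expr, n)
    walk = np.cumsum(rng.normal(0, config.stage_walk_sd, (n, T)), axis=1)
    walk -= walk[:, [0]]
    rna_mean = base[:, None] * np.exp(walk)

    te0 = np.exp(rng.normal(0, config.baseline_te_sd, n))
    te = np.tile(te0[:, None], (1, T))

    n_up = int(round(config.frac_te_up * n))
    n_down = int(round(config.frac_te_down * n))
    order = rng.permutation(n)
    up_idx, down_idx = order[:n_up], order[n_up:n_up + n_down]
    label = pd.Series("none", index=genes, name="dte")
    label.iloc[up_idx] = "up"
    label.iloc[down_idx] = "down"
    shift = config.te_shift_stage
    te[up_idx, shift:] *= config.te_effect
    te[down_idx, shift:] /= config.te_effect

    rpf_mean = rna_mean * te

    rna_samples = SampleTable.build(config.stages, "RNA", config.reps_rna)
    rpf_samples = SampleTable.build(config.stages, "RPF", config.reps_rpf)
    rna_vals = {}
    for j, st in enumerate(config.stages):
        for s in rna_samples.samples("RNA", st):
            rna_vals[s] = _nb_draw(rng, rna_mean[:, j], config.nb_dispersion)
    rpf_vals = {}
    for j, st in enumerate(config.stages):
        for s in rpf_samples.samples("RPF", st):
            rpf_vals[s] = _nb_draw(rng, rpf_mean[:, j], config.nb_dispersion)

    rna = GeneMatrix(pd.DataFrame(rna_vals, index=genes), "count", rna_samples)
    rpf = GeneMatrix(pd.DataFrame(rpf_vals, index=genes), "count", rpf_samples)

    truth = GroundTruth(
        te_label=label,
        te_trajectory=pd.DataFrame(te, index=genes, columns=config.stages),
    )
    _draw_kinetic_truth(config, truth, rng)
    return rna, rpf, truth


def _draw_kinetic_truth(config: SimulationConfig, truth: GroundTruth,
                        rng: np.random.Generator) -> None:
    n = config.n_genes
    cats = list(config.category_fracs)
    probs = np.array([config.category_fracs[c] for c in cats])
    counts = np.floor(probs * n).astype(int)
    counts[0] += n - counts.sum()
    assignment = np.repeat(cats, counts)
    rng.shuffle(assignment)
    ks = 10 ** rng.uniform(*config.log_ks_range, n)
    kd = 10 ** rng.uniform(*config.log_kd_range, n)
    truth.kinetic = pd.DataFrame({
        "category": assignment, "Ks": ks, "Kd": kd,
        "P0_factor": np.exp(rng.normal(0, config.p0_deviation_sd, n)),
    }, index=config.gene_ids)


# ---------------------------------------------------------------------------
# Protein trajectories
# ---------------------------------------------------------------------------

def noiseless_protein(config: SimulationConfig, truth: GroundTruth,
                      rpf: GeneMatrix,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Noise-free protein trajectory per gene at the stage times, by the
    generating category. MSdev deviations are drawn from ``rng``."""
    times = np.asarray(config.stage_hours, dtype=float)
    R_all = rpf.stage_means()
    rows = {}
    kin = truth.kinetic
    for gene in rpf.genes:
        R = R_all.loc[gene].to_numpy(dtype=float)
        R = np.clip(R, 1e-6, None)
        row = kin.loc[gene]
        ks, kd = float(row.Ks), float(row.Kd)
        eq0 = ks * R[0] / kd
        p0 = eq0 * float(row.P0_factor)
        cat = row.category
        if cat == "stationary":
            traj = np.full_like(times, p0)
        elif cat == "linear":
            traj = (ks / kd) * R
        elif cat == "degradation":
            traj = p0 * np.exp(-kd * times)
        else:  # production or MSdev
            traj = kinetics.piecewise_solution(p0, ks, kd, R, times, times)
            if cat == "MSdev":
                if rng is None:
                    rng = np.random.default_rng(config.seed + 1)
                jumps = np.concatenate(
                    [[0.0], rng.normal(0, config.msdev_jump_sd,
                                       len(times) - 1)])
                traj = traj * np.exp(jumps)
        rows[gene] = traj
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(config.stages))


def simulate_protein(config: SimulationConfig, truth: GroundTruth,
                     rpf: GeneMatrix) -> GeneMatrix:
    """MS abundance matrix: noiseless kinetic trajectory x log-normal
    noise, with entries removed missing-at-random at ``ms_dropout_rate``."""
    missing = set(config.stages) - set(rpf.stages)
    if missing:
        raise ConfigError(f"rpf matrix lacks stages: {sorted(missing)}")
    rng = np.random.default_rng(config.seed + 1)
    traj = noiseless_protein(config, truth, rpf, rng)
    truth.protein_truth = traj
    samples = SampleTable.build(config.stages, "MS", config.reps_ms)
    vals = {}
    for j, st in enumerate(config.stages):
        for s in samples.samples("MS", st):
            noise = np.exp(rng.normal(0, config.ms_noise_sd, len(traj)))
            col = traj.iloc[:, j].to_numpy() * noise
            drop = rng.random(len(col)) < config.ms_dropout_rate
            col = np.where(drop, np.nan, col)
            vals[s] = col
    return GeneMatrix(pd.DataFrame(vals, index=traj.index), "abundance",
                      samples)


def random_gene_lengths(config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> pd.DataFrame:
    """Nominal transcript and CDS lengths (nt) for every expression
    gene, for TPM-style normalisation. Drawn once per seed; CDS is ~60%
    of the transcript, rounded to whole codons."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 6)
    tx_len = np.round(10 ** rng.normal(3.2, 0.25, config.n_genes)
                      ).astype(int)
    tx_len = np.clip(tx_len, 300, None)
    cds_len = (np.round(0.6 * tx_len / 3).astype(int) * 3).clip(150)
    return pd.DataFrame({"tx_length": tx_len, "cds_length": cds_len},
                        index=config.gene_ids).rename_axis("gene")


# ---------------------------------------------------------------------------
# Transcriptome and footprints
# ---------------------------------------------------------------------------

def random_transcriptome(config: SimulationConfig,
                         rng: np.random.Generator | None = None
                         ) -> Transcriptome:
    """Random spliced transcripts: ATG + uniform sense codons + stop,
    flanked by random UTRs. One transcript per gene, ids tx00000...."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    records = []
    sense = [c for c in SENSE_CODONS if c != "ATG"]
    for i in range(config.n_transcripts):
        n_codons = int(rng.integers(*config.cds_codons_range))
        body = "".join(rng.choice(sense, n_codons - 1))
        cds = "ATG" + body + "TAA"
        utr5 = "".join(rng.choice(list("ACGT"), int(rng.integers(*config.utr5_range))))
        utr3 = "".join(rng.choice(list("ACGT"), int(rng.integers(*config.utr3_range))))
        seq = utr5 + cds + utr3
        records.append(Transcript(f"tx{i:05d}", f"g{i:05d}", seq,
                                  len(utr5), len(utr5) + len(cds)))
    return Transcriptome(records)


def uniform_dwell() -> dict[str, float]:
    return {c: 1.0 for c in SENSE_CODONS}


def single_codon_dwell(codon: str, factor: float) -> dict[str, float]:
    w = uniform_dwell()
    w[codon] = factor
    return w


def bimodal_dwell(slow: float = 2.0, fast: float = 0.5,
                  rng: np.random.Generator | None = None) -> dict[str, float]:
    """Half the codons slow, half fast (the early-development bimodal
    occupancy regime)."""
    if rng is None:
        rng = np.random.default_rng(7)
    order = rng.permutation(len(SENSE_CODONS))
    return {c: (slow if rank < len(SENSE_CODONS) // 2 else fast)
            for c, rank in zip(SENSE_CODONS, order)}


def amino_acid_dwell(aa_variance_fraction: float = 0.34,
                     total_log_sd: float = 0.25,
                     rng: np.random.Generator | None = None
                     ) -> dict[str, float]:
    """Log-dwell = amino-acid effect + codon residual, with the
    amino-acid term contributing ``aa_variance_fraction`` of the total
    between-codon log variance."""
    if rng is None:
        rng = np.random.default_rng(11)
    codons = list(SENSE_CODONS)
    aa_of = np.array([GENETIC_CODE[c] for c in codons])
    aas = sorted(set(aa_of))
    # codon-level amino-acid effect, centred and scaled over codons
    raw_aa = dict(zip(aas, rng.normal(0, 1, len(aas))))
    a = np.array([raw_aa[x] for x in aa_of])
    a = (a - a.mean()) / a.std(ddof=0)
    a *= total_log_sd * np.sqrt(aa_variance_fraction)
    # residuals centred within each amino-acid group, so they are
    # orthogonal to the group-mean (amino-acid) term by construction
    r = rng.normal(0, 1, len(codons))
    for x in aas:
        sel = aa_of == x
        r[sel] -= r[sel].mean()
    r = r / r.std(ddof=0) * total_log_sd * np.sqrt(1 - aa_variance_fraction)
    return {c: float(np.exp(ai + ri))
            for c, ai, ri in zip(codons, a, r)}


def _stage_dwell(config: SimulationConfig) -> dict[str, dict[str, float]]:
    # real ribosome-profiling libraries always carry codon-specific
    # dwell variation; the default emulates the amino-acid-structured
    # regime (aa identity ~34% of between-codon log variance)
    dp = config.dwell_params
    if dp is None:
        dp = amino_acid_dwell()
        return {st: dict(dp) for st in config.stages}
    if isinstance(next(iter(dp.values())), dict):
        return {st: dict(dp[st]) for st in config.stages}
    return {st: dict(dp) for st in config.stages}


def simulate_footprints(config: SimulationConfig, annotation: Transcriptome
                        ) -> tuple[FootprintProfiles, GroundTruth]:
    """Footprint 5'-end profiles per stage.

    A-site codons are sampled proportionally to transcript abundance x
    codon dwell weight; read length is drawn from ``read_lengths`` and
    the 5' end placed at (codon first nt) - true_offset[length].
    Cut-site bias multiplies the sampling weight by nucleotide
    preferences at the two read termini. Transcripts with CDS < 60
    codons are skipped with a warning.
    """
    import warnings

    rng = np.random.default_rng(config.seed + 3)
    stage_dwell = _stage_dwell(config)
    bias5 = (config.cutbias_params or {}).get("five", {})
    bias3 = (config.cutbias_params or {}).get("three", {})
    lengths = np.array(sorted(config.read_lengths))
    n_len = len(lengths)
    len_probs = np.full(n_len, 1.0 / n_len)

    usable = []
    for t in annotation:
        if t.n_codons < 60:
            warnings.warn(f"{t.tx_id}: CDS shorter than 60 codons, skipped")
            continue
        usable.append(t)
    if not usable:
        raise ConfigError("no transcript with CDS >= 60 codons")

    abund = pd.Series(
        np.exp(np.random.default_rng(config.seed + 4).normal(
            0, 1, len(usable))),
        index=[t.tx_id for t in usable])

    # enumerate sampling categories (transcript, codon index, length)
    cat_tx, cat_p5, cat_codon, cat_len_idx, base_w = [], [], [], [], []
    nt_w5 = {nt: bias5.get(nt, 1.0) for nt in "ACGTN"}
    nt_w3 = {nt: bias3.get(nt, 1.0) for nt in "ACGTN"}
    for ti, t in enumerate(usable):
        codons = t.codons()
        seq = t.seq
        L = t.length
        for ci, codon in enumerate(codons):
            codon_start = t.cds_start + 3 * ci
            for li, rl in enumerate(lengths):
                p5 = codon_start - config.true_offsets[int(rl)]
                p3 = p5 + int(rl) - 1
                if p5 < 0 or p3 >= L:
                    continue
                cat_tx.append(ti)
                cat_p5.append(p5)
                cat_codon.append(codon)
                cat_len_idx.append(li)
                base_w.append(abund.iloc[ti] * nt_w5[seq[p5]] * nt_w3[seq[p3]])
    cat_tx = np.array(cat_tx)
    cat_p5 = np.array(cat_p5)
    cat_len_idx = np.array(cat_len_idx)
    base_w = np.array(base_w) * len_probs[cat_len_idx]
    codon_arr = np.array(cat_codon)

    tx_lengths = {t.tx_id: t.length for t in annotation}
    profiles = FootprintProfiles(tx_lengths,
                                 {st: st for st in config.stages})
    for st in config.stages:
        # stop codons (and any codon without a dwell weight) are not
        # sampled as A-site positions
        w = base_w * np.array([stage_dwell[st].get(c, 0.0)
                               for c in codon_arr])
        p = w / w.sum()
        counts = rng.multinomial(config.footprint_reads, p)
        nz = np.nonzero(counts)[0]
        per_key: dict[tuple[int, int], np.ndarray] = {}
        for k in nz:
            key = (cat_tx[k], cat_len_idx[k])
            if key not in per_key:
                per_key[key] = np.zeros(usable[cat_tx[k]].length,
                                        dtype=np.int64)
            per_key[key][cat_p5[k]] += counts[k]
        for (ti, li), vec in per_key.items():
            profiles.add(st, usable[ti].tx_id, int(lengths[li]), vec)

    truth = GroundTruth(
        dwell={st: pd.Series(stage_dwell[st]) for st in config.stages},
        offsets=dict(config.true_offsets),
        tx_abundance=abund,
    )
    return profiles, truth


def coupled_protein_r(n_genes: int = 2000, explained: float = 0.6,
                      b: float = 1.0, sd_r_signal: float = 1.0,
                      sd_meas_p: float = 0.2, sd_meas_r: float = 0.15,
                      seed: int = 0
                      ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Synthetic (P, R) gene vectors for the variance decomposition.

    Protein = b * R_true + independent protein signal + measurement
    noise; observed R = R_true + measurement noise. The independent
    signal variance is set so R explains exactly ``explained`` of the
    systematic protein variance. Returns (P, R, s2_P, s2_R) with the
    true per-gene measurement-error variances.
    """
    rng = np.random.default_rng(seed)
    r_true = rng.normal(0, sd_r_signal, n_genes)
    var_signal = (b * sd_r_signal) ** 2
    var_pdt = var_signal * (1.0 - explained) / explained
    pdt = rng.normal(0, np.sqrt(var_pdt), n_genes)
    P = b * r_true + pdt + rng.normal(0, sd_meas_p, n_genes)
    R = r_true + rng.normal(0, sd_meas_r, n_genes)
    return P, R, sd_meas_p ** 2, sd_meas_r ** 2


# ---------------------------------------------------------------------------
# tRNA qPCR array
# ---------------------------------------------------------------------------

def default_isodecoder_table() -> pd.DataFrame:
    """Synthetic 151-isodecoder panel: two isodecoders per sense-codon
    anticodon plus a third for the first 29 anticodons (alphabetical).
    A stand-in for the commercial qPCR panel, which is not public."""
    anticodons = sorted({anticodon_for(c) for c in SENSE_CODONS})
    rows = []
    for i, ac in enumerate(anticodons):
        n_copies = 3 if i < 151 - 2 * len(anticodons) else 2
        aa = GENETIC_CODE[anticodon_for(ac)]
        for k in range(n_copies):
            rows.append({"isodecoder": f"tRNA-{aa}-{ac}-{k + 1}",
                         "anticodon": ac})
    return pd.DataFrame(rows).set_index("isodecoder")


def simulate_trna(config: SimulationConfig,
                  isodecoders: pd.DataFrame | None = None
                  ) -> tuple[TrnaMeasurement, GroundTruth]:
    """qPCR Ct table: Ct = ct_ref - log2(true abundance) + noise, with 5S
    and 18S reference rows centered so mean(ref) = ct_ref."""
    if isodecoders is None:
        isodecoders = default_isodecoder_table()
    rng = np.random.default_rng(config.seed + 5)
    abundance = pd.Series(
        np.exp(rng.normal(0, 1, len(isodecoders))),
        index=isodecoders.index, name="abundance")
    samples = SampleTable.build(config.stages, "tRNA", config.reps_trna)
    ct = {}
    for s in samples.df["sample"]:
        noise = rng.normal(0, config.trna_ct_noise_sd, len(abundance))
        ct[s] = config.trna_ct_ref - np.log2(abundance.to_numpy()) + noise
    df = pd.DataFrame(ct, index=isodecoders.index)
    # references one cycle either side of ct_ref; their mean is ct_ref
    df.loc["rRNA_5S"] = config.trna_ct_ref - 1.0
    df.loc["rRNA_18S"] = config.trna_ct_ref + 1.0
    meas = TrnaMeasurement(df, isodecoders["anticodon"], samples)
    return meas, GroundTruth(isodecoder_abundance=abundance)
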