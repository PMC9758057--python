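"""Domain containers and on-disk formats for the translatome pipeline.

Everything downstream operates on four containers: a sample sheet
(:class:`SampleTable`), gene-by-sample matrices (:class:`GeneMatrix`),
spliced transcript models with CDS bounds (:class:`Transcriptome`), and
per-read-length footprint 5'-end profiles (:class:`FootprintProfiles`).
All coordinates are 0-based half-open internally; external dialects are
converted at the boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("ribodyn")

#: Default developmental stages, embryonic day 12.5 through postnatal day 0.
DEFAULT_STAGES: tuple[str, ...] = ("E12.5", "E14", "E15.5", "E17", "P0")

#: Stage positions on a real-time axis, in hours from the first stage.
#: The inter-stage spacing is a convention (the study design gives none);
#: it is recorded in output metadata wherever rates in 1/h are reported.
DEFAULT_STAGE_HOURS: tuple[float, ...] = (0.0, 36.0, 72.0, 108.0, 132.0)

ASSAYS = ("RNA", "RPF", "MS", "tRNA")

#: Ribosome-protected fragments are retained at these lengths only.
MIN_READ_LENGTH = 25
MAX_READ_LENGTH = 31

_BASES = "TCAG"
_AA = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"

#: Standard genetic code, codon -> one-letter amino acid ('*' = stop).
GENETIC_CODE: dict[str, str] = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}
STOP_CODONS = tuple(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa != "*"))


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def anticodon_for(codon: str) -> str:
    """Anticodon (5'->3') exactly complementary to a codon."""
    return reverse_complement(codon)


class PipelineError(Exception):
    """Base class for user-facing pipeline errors."""


class ParseError(PipelineError):
    pass


class ConfigError(PipelineError):
    pass


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

@dataclass
class SampleTable:
    """Sample metadata: one row per (stage, assay, replicate).

    The stage column is ordered; all per-stage summaries in the pipeline
    follow this order.
    """

    df: pd.DataFrame
    stages: tuple[str, ...] = DEFAULT_STAGES

    def __post_init__(self) -> None:
        required = {"sample", "stage", "assay", "replicate"}
        missing = required - set(self.df.columns)
        if missing:
            raise ParseError(f"sample table missing columns: {sorted(missing)}")
        bad_assay = set(self.df["assay"]) - set(ASSAYS)
        if bad_assay:
            raise ParseError(f"unknown assays in sample table: {sorted(bad_assay)}")
        bad_stage = set(self.df["stage"]) - set(self.stages)
        if bad_stage:
            raise ParseError(f"unknown stages in sample table: {sorted(bad_stage)}")
        key = self.df[["stage", "assay", "replicate"]]
        if key.duplicated().any():
            raise ParseError("duplicate (stage, assay, replicate) in sample table")
        if self.df["sample"].duplicated().any():
            raise ParseError("duplicate sample ids in sample table")

    def samples(self, assay: str, stage: str | None = None) -> list[str]:
        m = self.df["assay"] == assay
        if stage is not None:
            m &= self.df["stage"] == stage
        return list(self.df.loc[m, "sample"])

    def stage_of(self, sample: str) -> str:
        row = self.df.loc[self.df["sample"] == sample]
        if row.empty:
            raise KeyError(f"unknown sample id: {sample}")
        return row["stage"].iloc[0]

    def subset(self, assay: str) -> "SampleTable":
        return SampleTable(self.df[self.df["assay"] == assay].reset_index(drop=True),
                           stages=self.stages)

    @staticmethod
    def build(stages: Iterable[str], assay: str, n_reps: int,
              all_stages: tuple[str, ...] | None = None) -> "SampleTable":
        stages = tuple(stages)
        rows = [
            {"sample": f"{assay}_{st}_r{r + 1}", "stage": st, "assay": assay,
             "replicate": r + 1}
            for st in stages for r in range(n_reps)
        ]
        return SampleTable(pd.DataFrame(rows), stages=all_stages or stages)


def read_sample_table(path: str | Path,
                      stages: tuple[str, ...] = DEFAULT_STAGES) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t"), stages=stages)


def write_sample_table(table: SampleTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Gene matrices
# ---------------------------------------------------------------------------

VALUE_KINDS = ("count", "density", "abundance")


@dataclass
class GeneMatrix:
    """Genes x samples numeric table with its sample sheet.

    ``kind`` distinguishes raw counts, length/depth-normalised densities
    (TPM-like), and mass-spectrometry abundances. Missing values (NaN) are
    permitted only for MS samples, where label-free quantification drops
    low-intensity peptides.
    """

    values: pd.DataFrame
    kind: str
    samples: SampleTable

    def __post_init__(self) -> None:
        if self.kind not in VALUE_KINDS:
            raise ConfigError(f"unknown value kind {self.kind!r}")
        unknown = set(self.values.columns) - set(self.samples.df["sample"])
        if unknown:
            raise ParseError(
                f"matrix columns absent from sample table: {sorted(unknown)}")
        assay_of = self.samples.df.set_index("sample")["assay"]
        nan_cols = self.values.columns[self.values.isna().any()]
        for c in nan_cols:
            if assay_of[c] != "MS":
                raise ParseError(f"missing values in non-MS column {c!r}")
        arr = self.values.to_numpy(dtype=float)
        finite = arr[np.isfinite(arr)]
        if (finite < 0).any():
            raise ParseError("negative values in gene matrix")
        if self.kind == "count" and not np.allclose(finite, np.round(finite)):
            raise ParseError("non-integer values in count matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def stages(self) -> tuple[str, ...]:
        return self.samples.stages

    def stage_columns(self, stage: str) -> list[str]:
        cols = [c for c in self.values.columns
                if self.samples.stage_of(c) == stage]
        return cols

    def stage_sums(self) -> pd.DataFrame:
        """Per-stage sums over replicates (genes x stages)."""
        out = {st: self.values[self.stage_columns(st)].sum(axis=1)
               for st in self.stages}
        return pd.DataFrame(out)

    def stage_means(self) -> pd.DataFrame:
        """Per-stage replicate means, ignoring missing entries."""
        out = {st: self.values[self.stage_columns(st)].mean(axis=1)
               for st in self.stages}
        return pd.DataFrame(out)

    def log2_stage_stats(self, pseudocount: float = 0.5
                         ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        """Mean, variance and n of log2(value + pseudocount) per stage."""
        means, variances, ns = {}, {}, {}
        for st in self.stages:
            block = np.log2(self.values[self.stage_columns(st)] + pseudocount)
            means[st] = block.mean(axis=1)
            variances[st] = block.var(axis=1, ddof=1)
            ns[st] = block.notna().sum(axis=1)
        return pd.DataFrame(means), pd.DataFrame(variances), pd.DataFrame(ns)


def read_gene_matrix(path: str | Path, sample_table: SampleTable,
                     kind: str) -> GeneMatrix:
    """Read a TSV gene matrix (first column gene ids, header sample ids).

    "NA" cells become missing entries; the GeneMatrix validator rejects
    them outside MS columns and rejects negative or ragged input.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                         keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    unknown = set(df.columns) - set(sample_table.df["sample"])
    if unknown:
        raise ParseError(
            f"{path}: columns not in sample table: {sorted(unknown)}")
    return GeneMatrix(df, kind=kind, samples=sample_table)


def write_gene_matrix(matrix: GeneMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene", na_rep="NA")


# ---------------------------------------------------------------------------
# Transcript annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Transcript:
    tx_id: str
    gene_id: str
    seq: str
    cds_start: int  # 0-based, inclusive
    cds_end: int    # 0-based, exclusive

    def __post_init__(self) -> None:
        if not 0 <= self.cds_start < self.cds_end <= len(self.seq):
            raise ParseError(f"{self.tx_id}: CDS outside sequence bounds")
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ParseError(f"{self.tx_id}: CDS length not divisible by 3")
        if set(self.seq) - set("ACGTN"):
            raise ParseError(f"{self.tx_id}: sequence alphabet outside ACGTN")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def cds_length(self) -> int:
        return self.cds_end - self.cds_start

    @property
    def n_codons(self) -> int:
        return self.cds_length // 3

    @property
    def utr5(self) -> tuple[int, int]:
        return (0, self.cds_start)

    @property
    def utr3(self) -> tuple[int, int]:
        return (self.cds_end, len(self.seq))

    @property
    def utr5_seq(self) -> str:
        return self.seq[: self.cds_start]

    @property
    def cds_seq(self) -> str:
        return self.seq[self.cds_start: self.cds_end]

    def codons(self) -> list[str]:
        cds = self.cds_seq
        return [cds[i: i + 3] for i in range(0, len(cds), 3)]


class Transcriptome:
    """Collection of transcripts keyed by transcript id."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self._tx: dict[str, Transcript] = {}
        for t in transcripts:
            if t.tx_id in self._tx:
                raise ParseError(f"duplicate transcript id {t.tx_id}")
            self._tx[t.tx_id] = t

    def __getitem__(self, tx_id: str) -> Transcript:
        return self._tx[tx_id]

    def __contains__(self, tx_id: str) -> bool:
        return tx_id in self._tx

    def __iter__(self):
        return iter(self._tx.values())

    def __len__(self) -> int:
        return len(self._tx)

    @property
    def ids(self) -> list[str]:
        return list(self._tx)

    def by_gene(self) -> dict[str, list[Transcript]]:
        out: dict[str, list[Transcript]] = {}
        for t in self:
            out.setdefault(t.gene_id, []).append(t)
        return out


def read_annotation(fasta_path: str | Path, bed_path: str | Path) -> Transcriptome:
    """Join spliced transcript FASTA with a BED-like CDS table.

    The BED-like TSV has columns (transcript id, CDS start, CDS end,
    gene id), 0-based half-open, with a header row.
    """
    seqs = {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(fasta_path), "fasta")}
    bed = pd.read_csv(bed_path, sep="\t")
    expect = ["transcript", "cds_start", "cds_end", "gene"]
    if list(bed.columns[:4]) != expect:
        raise ParseError(f"{bed_path}: expected columns {expect}")
    missing = set(bed["transcript"]) - set(seqs)
    if missing:
        raise ParseError(f"transcripts in BED absent from FASTA: {sorted(missing)[:5]}")
    extra = set(seqs) - set(bed["transcript"])
    if extra:
        raise ParseError(f"FASTA ids absent from BED: {sorted(extra)[:5]}")
    records = [
        Transcript(row.transcript, row.gene, seqs[row.transcript],
                   int(row.cds_start), int(row.cds_end))
        for row in bed.itertuples(index=False)
    ]
    return Transcriptome(records)


def write_annotation(tx: Transcriptome, fasta_path: str | Path,
                     bed_path: str | Path) -> None:
    recs = [SeqRecord(Seq(t.seq), id=t.tx_id, description="") for t in tx]
    SeqIO.write(recs, str(fasta_path), "fasta")
    pd.DataFrame(
        [(t.tx_id, t.cds_start, t.cds_end, t.gene_id) for t in tx],
        columns=["transcript", "cds_start", "cds_end", "gene"],
    ).to_csv(bed_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Footprint profiles
# ---------------------------------------------------------------------------

class FootprintProfiles:
    """Footprint 5'-end count vectors per (sample, transcript, read length).

    Vectors are dense, one entry per transcript nucleotide. Read lengths
    outside [25, 31] are rejected at construction.
    """

    def __init__(self, tx_lengths: Mapping[str, int],
                 sample_stage: Mapping[str, str]):
        self.tx_lengths = dict(tx_lengths)
        self.sample_stage = dict(sample_stage)
        self._data: dict[tuple[str, str, int], np.ndarray] = {}

    def add(self, sample: str, tx_id: str, read_length: int,
            counts: np.ndarray) -> None:
        if not MIN_READ_LENGTH <= read_length <= MAX_READ_LENGTH:
            raise ParseError(
                f"read length {read_length} outside "
                f"[{MIN_READ_LENGTH}, {MAX_READ_LENGTH}]")
        counts = np.asarray(counts)
        if counts.shape != (self.tx_lengths[tx_id],):
            raise ParseError(
                f"profile length {counts.shape} != transcript length "
                f"{self.tx_lengths[tx_id]} for {tx_id}")
        if (counts < 0).any():
            raise ParseError("negative footprint counts")
        key = (sample, tx_id, read_length)
        if key in self._data:
            self._data[key] = self._data[key] + counts
        else:
            self._data[key] = counts.astype(np.int64)

    def get(self, sample: str, tx_id: str, read_length: int) -> np.ndarray:
        key = (sample, tx_id, read_length)
        if key in self._data:
            return self._data[key]
        return np.zeros(self.tx_lengths[tx_id], dtype=np.int64)

    def keys(self):
        return self._data.keys()

    @property
    def samples(self) -> list[str]:
        return sorted({s for s, _, _ in self._data})

    @property
    def read_lengths(self) -> list[int]:
        return sorted({rl for _, _, rl in self._data})

    def transcripts(self, sample: str | None = None) -> list[str]:
        return sorted({t for s, t, _ in self._data
                       if sample is None or s == sample})

    def pooled_by_stage(self) -> "FootprintProfiles":
        """Sum counts over samples of the same stage (stage becomes the
        sample id)."""
        pooled = FootprintProfiles(
            self.tx_lengths,
            {st: st for st in set(self.sample_stage.values())})
        for (s, t, rl), v in self._data.items():
            pooled.add(self.sample_stage[s], t, rl, v)
        return pooled

    def total_counts(self, sample: str | None = None) -> int:
        return int(sum(v.sum() for (s, _, _), v in self._data.items()
                       if sample is None or s == sample))


def read_footprint_profiles(path: str | Path, tx_lengths: Mapping[str, int],
                            sample_stage: Mapping[str, str]) -> FootprintProfiles:
    """Read the sparse profile TSV: sample, transcript, read_length,
    position (0-based), count. Absent positions are zero; duplicate rows
    are summed with a warning."""
    df = pd.read_csv(path, sep="\t")
    expect = {"sample", "transcript", "read_length", "position", "count"}
    if not expect <= set(df.columns):
        raise ParseError(f"{path}: expected columns {sorted(expect)}")
    if df.duplicated(["sample", "transcript", "read_length", "position"]).any():
        log.warning("%s: duplicate (sample, transcript, length, position) "
                    "rows summed", path)
    profiles = FootprintProfiles(tx_lengths, sample_stage)
    grouped = df.groupby(["sample", "transcript", "read_length"], sort=False)
    for (sample, tx_id, rl), grp in grouped:
        if tx_id not in tx_lengths:
            raise ParseError(f"{path}: unknown transcript {tx_id}")
        L = tx_lengths[tx_id]
        pos = grp["position"].to_numpy()
        if (pos >= L).any() or (pos < 0).any():
            raise ParseError(f"{path}: position outside transcript {tx_id}")
        vec = np.zeros(L, dtype=np.int64)
        np.add.at(vec, pos, grp["count"].to_numpy())
        profiles.add(sample, tx_id, int(rl), vec)
    return profiles


def write_footprint_profiles(profiles: FootprintProfiles,
                             path: str | Path) -> None:
    rows = []
    for (sample, tx_id, rl), vec in sorted(profiles._data.items()):
        nz = np.nonzero(vec)[0]
        for p in nz:
            rows.append((sample, tx_id, rl, int(p), int(vec[p])))
    pd.DataFrame(rows, columns=["sample", "transcript", "read_length",
                                "position", "count"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Offsets
# ---------------------------------------------------------------------------

#: Biochemically plausible window for the 5'-end -> A-site offset, in nt.
DEFAULT_OFFSET_WINDOW = (10, 18)


@dataclass
class OffsetTable:
    """Read length -> distance (nt) from the 5' end to the first
    nucleotide of the A-site codon. Lengths that failed calibration carry
    an ``uncalibrated`` flag instead of a silent default."""

    offsets: dict[int, int] = field(default_factory=dict)
    uncalibrated: set[int] = field(default_factory=set)
    window: tuple[int, int] = DEFAULT_OFFSET_WINDOW

    def __post_init__(self) -> None:
        lo, hi = self.window
        for rl, off in self.offsets.items():
            if not lo <= off <= hi:
                raise ConfigError(
                    f"offset {off} for length {rl} outside window [{lo},{hi}]")

    def __getitem__(self, read_length: int) -> int:
        return self.offsets[read_length]

    @property
    def calibrated_lengths(self) -> list[int]:
        return sorted(self.offsets)


def read_offsets(path: str | Path) -> OffsetTable:
    df = pd.read_csv(path, sep="\t")
    offsets = {int(r.read_length): int(r.offset)
               for r in df.itertuples() if r.status == "ok"}
    uncal = {int(r.read_length) for r in df.itertuples() if r.status != "ok"}
    return OffsetTable(offsets, uncal)


def write_offsets(table: OffsetTable, path: str | Path) -> None:
    rows = [(rl, off, "ok") for rl, off in sorted(table.offsets.items())]
    rows += [(rl, -1, "uncalibrated") for rl in sorted(table.uncalibrated)]
    pd.DataFrame(rows, columns=["read_length", "offset", "status"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# tRNA measurements
# ---------------------------------------------------------------------------

@dataclass
class TrnaMeasurement:
    """qPCR Ct table: rows are isodecoders plus the 5S/18S rRNA
    references, columns are samples."""

    ct: pd.DataFrame                       # rows: feature ids, cols: samples
    anticodon: pd.Series                   # isodecoder id -> anticodon
    samples: SampleTable
    reference_ids: tuple[str, str] = ("rRNA_5S", "rRNA_18S")

    def __post_init__(self) -> None:
        for ref in self.reference_ids:
            if ref not in self.ct.index:
                raise ParseError(f"reference row {ref!r} missing from Ct table")

    @property
    def isodecoders(self) -> pd.Index:
        return self.ct.index.drop(list(self.reference_ids))


def read_trna_table(path: str | Path, samples: SampleTable) -> TrnaMeasurement:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "anticodon" not in df.columns:
        raise ParseError(f"{path}: expected an 'anticodon' column")
    anticodon = df["anticodon"].drop(["rRNA_5S", "rRNA_18S"], errors="ignore")
    ct = df.drop(columns=["anticodon"]).astype(float)
    return TrnaMeasurement(ct, anticodon, samples)


def write_trna_table(m: TrnaMeasurement, path: str | Path) -> None:
    out = m.ct.copy()
    out.insert(0, "anticodon", m.anticodon.reindex(out.index).fillna("-"))
    out.to_csv(path, sep="\t", index_label="feature")
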