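"""Shared fixtures: small synthetic datasets reused across test modules.

Everything is generated programmatically from fixed seeds; session-scoped
fixtures cache the more expensive simulations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ribodyn import simulate as sim
from ribodyn.io import SampleTable, Transcript, Transcriptome


@pytest.fixture(scope="session")
def tiny_annotation() -> Transcriptome:
    """Three hand-built transcripts with known UTR/CDS structure."""
    rng = np.random.default_rng(42)

    def cds(n_codons: int) -> str:
        sense = [c for c in sim.SENSE_CODONS if c != "ATG"]
        return "ATG" + "".join(rng.choice(sense, n_codons - 2)) + "TAA"

    def utr(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), n))

    records = []
    for i, (u5, nc, u3) in enumerate([(50, 120, 40), (35, 90, 60),
                                      (60, 200, 30)]):
        s5, body, s3 = utr(u5), cds(nc), utr(u3)
        records.append(Transcript(f"tx{i}", f"gene{i}", s5 + body + s3,
                                  u5, u5 + len(body)))
    return Transcriptome(records)


@pytest.fixture(scope="session")
def expression_sim():
    """Small expression simulation with dTE genes (seeded)."""
    cfg = sim.SimulationConfig(n_genes=400, seed=101)
    rna, rpf, truth = sim.simulate_expression(cfg)
    return cfg, rna, rpf, truth


@pytest.fixture(scope="session")
def footprint_sim():
    """Footprints from a bimodal dwell generator with cut-site bias."""
    cfg = sim.SimulationConfig(
        n_transcripts=30, footprint_reads=120_000, seed=7,
        dwell_params=sim.bimodal_dwell(),
        cutbias_params={"five": {"A": 1.0, "C": 0.5, "G": 2.0, "T": 0.8},
                        "three": {"A": 0.6, "C": 1.4, "G": 1.0, "T": 1.2}})
    annotation = sim.random_transcriptome(cfg)
    profiles, truth = sim.simulate_footprints(cfg, annotation)
    return cfg, annotation, profiles, truth


@pytest.fixture()
def small_sample_table() -> SampleTable:
    return SampleTable.build(("E12.5", "E14"), "RNA", 2)


def make_matrix(values: dict[str, list], genes: list[str],
                assay: str = "RNA", stages=("E12.5", "E14"),
                kind: str = "count"):
    """Helper to build a GeneMatrix from literal columns."""
    from ribodyn.io import GeneMatrix
    n_reps = len(values) // len(stages)
    table = SampleTable.build(stages, assay, n_reps)
    df = pd.DataFrame(values, index=genes)
    return GeneMatrix(df, kind, table)
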