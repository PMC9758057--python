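"""Calibrate A-site offsets from footprint 5'-end profiles.

Simulates footprints whose 5' ends sit a known, length-specific distance
from the A-site codon, with strong RNase cut-site bias at the read
termini, and recovers the offsets from the between-codon variance of
RUST enrichment.
"""

from ribodyn import codon, simulate as sim

cfg = sim.SimulationConfig(
    n_transcripts=40, footprint_reads=200_000, seed=42,
    dwell_params=sim.bimodal_dwell(),
    cutbias_params={"five": {"A": 1.0, "C": 0.4, "G": 2.5, "T": 0.7},
                    "three": {"A": 0.5, "C": 1.6, "G": 1.0, "T": 1.3}})
annotation = sim.random_transcriptome(cfg)
profiles, truth = sim.simulate_footprints(cfg, annotation)

pool = type(profiles)(profiles.tx_lengths, {"all": "all"})
for (s, t, rl) in list(profiles.keys()):
    pool.add("all", t, rl, profiles.get(s, t, rl))
rusts = {rl: codon.compute_rust(pool, annotation, rl, "all")
         for rl in profiles.read_lengths}
offsets, diagnostics = codon.select_offsets(rusts)

print("read length : calibrated offset (true offset)")
for rl in sorted(truth.offsets):
    got = offsets.offsets.get(rl, "uncalibrated")
    print(f"  {rl} nt     : {got} ({truth.offsets[rl]})")
peak = diagnostics[diagnostics["chosen"]]
print("\nchosen positions sit at the between-codon variance maximum; the")
print("terminus-proximal cut-bias artifacts fall outside the [10, 18] nt")
print("plausibility window and do not mislead the calibration.")
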