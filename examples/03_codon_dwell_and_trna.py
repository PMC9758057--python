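"""Codon dwell times, tRNA availability, and the variance partition.

Dwell weights are generated so the amino acid coded for explains 34% of
the between-codon variance (with tRNA abundance independent of dwell);
the A-site occupancy ANOVA recovers that structure.
"""

from ribodyn import codon, simulate as sim

dwell = sim.amino_acid_dwell(aa_variance_fraction=0.34, total_log_sd=0.25)
cfg = sim.SimulationConfig(n_transcripts=80, footprint_reads=400_000,
                           seed=42, dwell_params=dwell)
annotation = sim.random_transcriptome(cfg)
profiles, truth = sim.simulate_footprints(cfg, annotation)

pool = type(profiles)(profiles.tx_lengths, {"all": "all"})
for (s, t, rl) in list(profiles.keys()):
    pool.add("all", t, rl, profiles.get(s, t, rl))
offsets, _ = codon.select_offsets(
    {rl: codon.compute_rust(pool, annotation, rl, "all")
     for rl in profiles.read_lengths})

pooled = profiles.pooled_by_stage()
rusts = {st: {rl: codon.compute_rust(pooled, annotation, rl, st)
              for rl in profiles.read_lengths}
         for st in pooled.samples}
occupancy, _ = codon.site_occupancy(rusts, offsets)

trna, _ = sim.simulate_trna(cfg)
table = codon.trna_codon_table(trna, annotation)
part = codon.dwell_variance_partition(occupancy, table)

print(f"observations (codon x stage): {part['n_obs']}")
for term in ("C(amino_acid)", "C(stage)", "trna"):
    print(f"  {term:16s} explains {100 * part['fraction'][term]:5.1f}% "
          "of occupancy variance")
print("\nthe amino-acid term dominates (engineered at 34%); tRNA")
print("abundance, drawn independently of dwell, explains ~nothing --")
print("mirroring the finding that amino-acid identity, not tRNA supply,")
print("sets A-site dwell time.")

corr = codon.site_correlation(occupancy)
print("\nper-stage slope of A-site on P-site occupancy:")
print(corr.to_string(index=False))
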