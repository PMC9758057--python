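# ribodyn

Analysis toolkit for multi-omic time courses of mRNA translation:
paired RNA-seq and ribosome profiling (Ribo-seq), label-free mass
spectrometry, and tRNA qPCR arrays measured across an ordered series of
developmental stages. The package was built around the design of a
five-stage mouse neocortex neurogenesis course (E12.5, E14, E15.5, E17,
P0; RNA/Ribo-seq in duplicate, MS in triplicate, a 151-isodecoder tRNA
panel) but every dimension is configurable.

It answers four families of questions:

1. **Which genes change translation efficiency (TE), and when?**
   TE is the ratio of ribosome-footprint density on a coding sequence to
   the mRNA's overall abundance. A gene whose footprints rise faster
   than its mRNA is translationally upregulated. The TE-change statistic
   is a difference of log fold changes, Δ = log2FC(RPF) − log2FC(RNA),
   tested with shrunken-variance z-tests and BH correction, called at
   ≥ 1.25-fold and adjusted p < 0.05, on genes with ≥ 32 footprints in
   at least one stage.

2. **Where on the mRNA do ribosomes sit, codon by codon?**
   Footprint 5′-end profiles are binarized per transcript (RUST) and the
   enrichment of high-count positions is traced as a function of
   distance from the read 5′ end. The between-codon variance of that
   enrichment peaks a fixed distance from the A-site codon — that
   distance, selected inside a biochemically plausible 10–18 nt window,
   is the per-read-length A-site offset (P site 3 nt closer to the 5′
   end, E site 6 nt). This data-driven calibration survives strong
   RNase cut-site bias that defeats start-peak-based methods. On top of
   it sit per-codon dwell scores, metagene profiles, a 15-bin positional
   change test, 5′-UTR ribosome density, G-quadruplex scanning, tRNA
   abundance (−ΔCt against 5S/18S rRNA), codon usage, availability
   (usage-on-abundance residuals), and a variance partition of dwell
   into stage, amino-acid, and tRNA terms.

3. **Do protein trajectories follow synthesis?** Protein is modeled as
   dP/dt = K_s·R(t) − K_d·P(t), with R(t) the piecewise-linear
   footprint density and an exact closed-form solution. Five model
   categories per gene (stationary, linear, degradation, production,
   MSdev) compete by BIC with a χ² residual-normality gate; a shared
   K_s then gives half-lives π½ = ln2/K_d for every protein.

4. **How much protein variance does transcription vs translation
   explain?** An error-corrected variance decomposition splits measured
   protein variance into measurement error, R-explained, and
   R-independent systematic parts; Ward clustering of joint
   mRNA/protein fold-change trajectories with Fisher tests locates the
   dTE genes among trajectory shapes.

A synthetic-data generator (`ribodyn.simulate`) produces every input
with known ground truth — negative-binomial counts with planted TE
shifts, ODE-generated proteins with log-normal noise and dropout,
footprints driven by codon dwell weights with known offsets and
cut-site bias, and tRNA Ct tables — so every stage of the pipeline is
testable without any external download.

## Worked example

```python
from ribodyn import quantify, simulate as sim

cfg = sim.SimulationConfig(n_genes=1000, seed=42)
rna, rpf, truth = sim.simulate_expression(cfg)
dte = quantify.dte_call(rna, rpf, contrasts="vs-first")
groups = quantify.dte_gene_groups(dte)
```

Running `python examples/01_translation_efficiency.py` (the same code)
prints:

```
genes passing the 32-footprint filter: 978
called TE-up: 99, TE-down: 96 (19.9% of quantified genes change TE)
sensitivity: up 0.87, down 0.93 (fraction of true dTE genes recovered)
false-call rate on unchanged genes: 0.027
```

The generator planted a 2-fold TE shift in 100 + 100 of 1,000 genes at
the middle stage; the caller recovers ~90% of them while mislabeling
2.7% of unchanged genes. The other scripts in `examples/` walk through
offset calibration, dwell/tRNA analysis, kinetic fitting, variance
decomposition, clustering, and positional density the same way.

## Command line

`ribodyn` exposes each stage as a subcommand over TSV/FASTA files:

```bash
ribodyn simulate --outdir sim --seed 3
ribodyn quantify --rna sim/rna_counts.tsv --rpf sim/rpf_counts.tsv \
    --ms sim/ms_abundance.tsv --samples sim/samples.tsv \
    --lengths sim/gene_lengths.tsv --outdir quant
ribodyn codon --profiles sim/footprint_profiles.tsv \
    --fasta sim/transcripts.fasta --bed sim/transcripts_cds.tsv \
    --trna sim/trna_ct.tsv --samples sim/samples.tsv \
    --rna-density quant/rna_density_stage.tsv --outdir codon
# ... positional, kinetics, vardecomp, cluster
```

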