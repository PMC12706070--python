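# combiscreen

Simulation and analysis of **combinatorial CRISPRa activation-domain
sort-seq screens**.

In this screening design, a library of activation domains (ADs) and inert
protein folders (PFs) — each tagged with a unique 8-bp DNA barcode — is
combinatorially fused into ordered one-, two- and three-part activators
recruited to a dCas9 scaffold (25 parts expand to 25 single-domain, 625
bipartite and 15,625 tripartite constructs). Cells carrying the library are
FACS-sorted into four extreme target-expression bins (two low, two high,
12.5% of the population each) and the barcode/UMI amplicons of every bin,
the unsorted population and the plasmid pool are sequenced. `combiscreen`
provides the full computational side of such a screen, for people who run
or want to model one:

- a **synthetic screen generator** with known ground truth (low-MOI Poisson
  transduction, toxicity-driven clonal depletion over passages, extreme-bin
  sorting, multinomial sequencing with PCR-jackpot UMIs and spiked
  barcoded controls),
- **read extraction**: scar-anchored parsing of barcode/UMI blocks with
  typed rejections, optional single-mismatch barcode correction, and
  control-barcode removal,
- **screen scoring**: outlier-UMI filtering, UMI-prefix grouping (64 or 16
  groups per construct), per-condition normalization to a mean of 100
  reads, and the two scores

  ```
  activation(group)  =  Σ_{bin=1..4}  normalized_reads_bin × MFI_bin
  toxicity           =  −log2( (reads_cells + 1) / (reads_plasmid + 1) )
  ```

  where MFI is each bin's mean fluorescence intensity and the toxicity
  ratio compares unsorted transduced cells to the plasmid pool (higher =
  more toxic),
- **combinatorial analyses**: forward/reverse order effects, positional
  effects, copy-number effects padded with inert PFs, and additivity of
  single-domain scores,
- **AD sequence features**: net charge per residue, Kyte–Doolittle
  hydropathy, disorder-promoting fraction, the blob-patterning statistics
  kappa (K/R vs D/E) and omega (W/F/Y/L vs D/E, lower = better mixed),
  native-protein position profiles over 20 protein sections, two-fold hit
  calling, hit/miss t-tests and predictor sensitivity/precision.

## Worked example

```python
from combiscreen import SimConfig, FilterConfig, simulate_screen
from combiscreen.scoring import (filter_outlier_umis, group_and_normalize,
                                 score_activation_screen, score_toxicity_screen)
from combiscreen.simulate import drop_controls

cfg = SimConfig(arity=2, n_cells=200_000, read_depth=300_000, seed=42)
sim = simulate_screen(cfg)                      # 625 bipartite constructs

flt = FilterConfig()                            # 64 UMI groups, mean-100 norm
table = drop_controls(sim.counts)
grouped = group_and_normalize(filter_outlier_umis(table, flt), flt)
activation = (score_activation_screen(grouped, sim.mfi, flt)
              .groupby("construct_id")["activation_score"].mean())
toxicity = score_toxicity_screen(table, FilterConfig(umi_prefix_length=0))
```

Printing the three strongest recovered activators and the agreement with
the simulator's latent ground truth:

```
strongest activators (score = sum of bin reads x bin MFI):
construct_id
A07-A09    1078.1
A19-A19     864.6
A16-A09     864.5
rank agreement with latent strength: rho = 0.90
rank agreement with latent fitness cost: rho = 0.94
```

A construct's activation score is the mean over its UMI groups of the
bin-weighted read profile — read mass concentrated in the high-expression
bins earns a high score — and Spearman's ρ against the latent per-part
strengths and fitness costs shows how faithfully the full
simulate→sequence→score chain recovers the generative truth.

The same stages are available as a CLI for file-based runs
(`combiscreen simulate | extract | score | toxicity | analyze | features |
report`); every stage writes TSV artifacts plus a `manifest.json` recording
all thresholds, the seed and the package version, and manifest-identical
reruns are byte-identical.

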