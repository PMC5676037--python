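# hupmap

Analysis toolkit for the chromosome-scale binding behaviour of an abundant
bacterial nucleoid-associated protein (NAP) — the mycobacterial HU
homologue HupB being the motivating case.  The package quantifies, from
tabular microscopy and sequencing-derived inputs:

* **where the protein binds on the circular chromosome** — replicate-confirmed
  ChIP-seq peak sets, their spacing and density, and a permutation test for
  the characteristic decline of binding-site density from the replication
  origin (*oriC*) toward the terminus (*ter*);
* **how individual molecules move** — single-particle (PALM-style) track
  linking, mean squared displacement, the apparent diffusion coefficient
  `D* = MSD / (4 Δt)`, and classification into immobile (DNA-bound) versus
  diffusing particles with positions mapped into a normalized rod-cell frame;
* **how the nucleoid is organised** — long-axis fluorescence profiles,
  nucleoid condensation as a percentage of cell length, two-channel
  colocalization, and time-lapse condensation summaries;
* **how much protein there is** — densitometry standard-curve calibration to
  molecules per cell, and the implied genome-wide binding interval
  `L / n_units` bp.

A fully seeded synthetic-data module generates every input the pipeline
consumes (peak replicates with an ori-biased intensity gradient, two-population
particle tracks inside spherocylindrical cells, plateau-shaped nucleoid
profiles, calibration tables), so the entire analysis is testable without
any external data.

## Core statistics

For `n` confirmed peaks on a circular chromosome of length `L`, the mean
midpoint-to-midpoint spacing is exactly `L / n` (the circular gaps sum to
`L`).  The ori→ter bias statistic is the Spearman rank correlation between
per-bin peak counts (default 100 kb bins) and each bin's circular distance
from *oriC*; its null distribution is obtained by re-placing the `n` peak
midpoints uniformly on the circle (two-sided permutation p-value).

For a 2D track with frame interval `Δt`, the per-track MSD is the mean of
the first four single-frame squared displacements and
`D* = MSD / (4 Δt)`.  An immobile emitter localized with error `σ` per
frame has the noise floor `E[D*] = σ² / Δt`; tracks with `D*` below a
threshold (default 0.1 µm²/s) are labelled immobile.

Nucleoid condensation is the fraction of cell length between the outermost
positions where the background-subtracted profile reaches 20% of its
maximum (background = median intensity near the poles).

## Worked example

```python
from hupmap.genome_io import GenomeContext
from hupmap.chip_spatial import mean_interpeak_spacing, ori_ter_bias, confirm_peaks
from hupmap.abundance import expected_binding_interval
from hupmap.synthetic_data import PeakSimConfig, simulate_peaks, DEFAULT_GENOME

genome = GenomeContext("chr", 7_000_000)          # ~7 Mbp circular chromosome
print(expected_binding_interval(30_000, genome))  # 233.33  bp per dimer

sim = simulate_peaks(PeakSimConfig(), DEFAULT_GENOME, seed=7)
confirmed = confirm_peaks(sim.rep1, sim.rep2, sim.control)
spacing, _ = mean_interpeak_spacing(confirmed, DEFAULT_GENOME)
bias = ori_ter_bias(confirmed, DEFAULT_GENOME, n_perm=1000, seed=7)
print(confirmed.n_confirmed, round(spacing), round(bias.statistic, 3), bias.p_value)
# 549 12750 -0.526 0.000999000999000999
```

549 of 600 simulated binding sites survive replicate confirmation and
control subtraction; they sit ~12.7 kb apart on average, and the negative
rank correlation with origin distance (p ≈ 0.001 at 1,000 permutations)
detects the built-in decline of binding density toward *ter*.

The same analyses run from the shell:

```bash
hupmap --seed 7 --outdir out all       # simulate + chip + spt + profiles + abundance
cat out/chip/summary.tsv out/spt/summary.tsv
```

Every run writes `manifest.json` digesting the configuration, seed, inputs
and outputs; reruns with the same seed reproduce it byte for byte.

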