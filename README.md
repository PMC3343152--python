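# qensemble

Statistical analysis of conformational ensembles of polyglutamine (polyQ)
peptides — the monomeric species whose rare extended conformations are
thought to seed the aggregates behind Huntington's disease and the other
CAG-repeat disorders.  The package is aimed at people who have an ensemble
of single-chain peptide conformations (from enhanced-sampling MD or any
other source) and want to quantify its secondary-structure propensities and
inter-residue correlations.

Given an ensemble of backbone conformations of one peptide — either a
multi-model PDB file or a plain table of backbone dihedrals (φ, ψ, ω) —
`qensemble` computes:

- **Ramachandran-region assignment.** Every defined (φ, ψ) pair is
  assigned to one of four regions of the Ramachandran torus — α_R
  (right-handed helical), α_L (left-handed helical), PPII
  (polyproline II) and β (extended) — either by hard rectangular
  boundaries or by per-residue wrapped k-means clustering that tolerates
  population overlap at region borders.  Per-residue and ensemble-mean
  region populations are reported, along with the population of α̃
  repeats: adjacent residues alternating between α_R and α_L, the
  building block of an α-sheet.
- **Secondary-structure motifs.**  A re-implemented DSSP subset (backbone
  amide hydrogens placed geometrically; Kabsch–Sander hydrogen-bond
  energy `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` kcal/mol
  with the standard −0.5 kcal/mol cutoff; n-turns, helices, bridges,
  ladders, turns and bends) plus bespoke motif detectors for isolated
  β / α̃ / PPII strands, β- and α̃-hairpins, helix segments and typed
  turns (I-β, other β, γ), with per-conformation prevalence statistics.
- **Odds-ratio correlation profiles.**  For a binary residue property X
  (e.g. "residue is in the β region"), the association of residues at
  sequence separation r is measured by the odds ratio
  `OR = (p00·p11)/(p01·p10)` of the pooled 2×2 table, mapped to free-energy
  units as `ΔΔG = k_B T · ln OR` with asymptotic standard error
  `k_B T · √(1/n00 + 1/n01 + 1/n10 + 1/n11)`.  Profiles against r (with
  end-residue trimming) expose the correlation range, its oscillation
  period and a long-range diagnostic; a Pearson correlation profile of
  shifted ψ angles provides a clustering-free cross-check.
- **Radius of gyration.**  Rg over the glutamine Cα atoms, histograms,
  Gaussian-mixture decomposition by Levenberg–Marquardt least squares,
  the chain-compaction exponent ν in `Rg ∝ N^ν`, and prolyl-bond
  cis/trans sub-ensemble splitting for Q_N–P_6 peptides.
- **Synthetic ensembles.**  A latent-Gaussian-copula generator with
  controllable region marginals, correlation decay length and
  oscillation period, plus an ideal-geometry backbone builder (NeRF), so
  that every statistic can be validated against known ground truth.

## Worked example

```python
import numpy as np
from qensemble import (q40_like, generate_ensemble, mean_region_populations,
                       region_mask, or_profile, dominant_period, long_range_flag)

# Q40-like ensemble: 40 glutamines, alphaR-dominant marginals,
# correlation kernel with decay length 50 residues and period 7
spec = q40_like(10000, seed=1, kernel=(0.8, 50.0, 7.0))
labels, ens = generate_ensemble(spec)

pops = mean_region_populations(labels)
print({k: round(v, 1) for k, v in pops.items()})
# {'alphaR': 80.0, 'alphaL': 5.0, 'PPII': 7.0, 'beta': 7.9, 'alpha_tilde': 12.4}

profile = or_profile(region_mask(labels, "beta"), trim=5)
period, power = dominant_period(profile)
flag, tail_mean, threshold = long_range_flag(profile)
print(round(period, 1), round(tail_mean, 2), flag)
# 6.8 0.61 True
```

The region populations recover the generator's marginals (80/5/7/8 %);
the β-region odds-ratio profile oscillates with the injected ~7-residue
period, and its tail mean of ≈0.6 kcal/mol beyond r = 10 exceeds twice
the mean standard error, so the long-range-correlation flag fires.  With
a short decay length (`kernel=(0.8, 3.0, 7.0)`) the same pipeline
reports `flag = False` — the Q40-vs-short-peptide contrast.

The same analyses are available from the shell:

```sh
qensemble simulate --spec spec.json --seed 1 --out ens.tsv --pdb ens.pdb
qensemble summary ens.tsv --seed 1 --out-dir run1
qensemble correlate ens.tsv --statistic beta --out beta_profile.tsv
qensemble rg ens.pdb --components 3 --split-prolyl --out rg.json
```

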