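# agodyn

Quantitative analysis of AGO2–miRNA targeting dynamics.

Argonaute-2 (AGO2) loaded with a guide miRNA silences messenger RNAs it
recognizes mainly through the guide's **seed** (nucleotides g2–g8 from the
guide 5′ end).  Disease-associated AGO2 missense variants can leave the
protein folded and loaded yet change *how* it engages targets: binding and
release kinetics, discrimination between seed-matched and mismatched RNAs,
strand selection, and the isomiR complement carried by the silencing
complex.  `agodyn` is a Python library for the measurements that expose
those changes:

- **Seed-site taxonomy** — classify target windows as 8mer / 7mer-m8 /
  7mer-A1 / 6mer / none against a guide, and enumerate degenerate
  RNA Bind-n-Seq (RBNS) libraries such as the 256-member `RYRYYYYR` pool.
- **RBNS enrichment** — demultiplex, adapter-trim and length-filter raw
  reads, count exact library-member matches, compute read fractions, fold
  enrichments (bound fraction / input fraction) and seed-fidelity
  summaries.
- **Binding kinetics** — fit the ligand-depletion equilibrium isotherm

  F = B·((E_T + S_T + K_D) − √((E_T + S_T + K_D)² − 4·E_T·S_T)) / (2·S_T),

  two-phase dissociation F(t) = A_f·e^(−k_fast·t) + A_s·e^(−k_slow·t) (+
  plateau) with a single-exponential fallback when the phases are not
  separable, one-phase association F(t) = F_max·(1 − e^(−k_obs·t)), the
  k_obs = k_on·[E] + k_off line, and K_D = k_off / k_on.
- **Small-RNA profiling** — isomiR assignment and categorization (5′/3′
  trimming, extension, nucleotide exchange, mixed), condition-exclusivity
  calls, 3p/5p arm ratios with a two-group Welch test, Benjamini–Hochberg
  FDR, differential-expression threshold rules, and miRAP
  ΔCt = Ct(IP) − Ct(IN).
- **Network / GSEA** — CWCS confidence tiers (high < −0.4, moderate
  −0.4…−0.2), anti-correlation miRNA→mRNA edge filtering, and preranked
  GSEA with a permutation p-value.
- **Synthetic data** — `agodyn.simulate` generates every input the pipeline
  consumes with known ground truth (titrations, decay/association time
  courses, barcoded RBNS reads under a class-weight occupancy model,
  replicate small-RNA count tables with planted effects, prediction/DE
  tables with planted edges), so every stage is testable end to end.

## Worked example

```sh
python examples/seed_site_classification.py
```

```
guide miR-122, seed g2-g8 = GGAGUGU
library size: 256
      none: 252 member(s)
      8mer: 1 member(s)
   7mer-m8: 1 member(s)
   7mer-A1: 1 member(s)
      6mer: 1 member(s)
the perfect 8mer target: ACACUCCA
```

The degenerate pool contains exactly one perfect seed match (the 8mer
`ACACUCCA`, i.e. the reverse complement of the miR-122 seed plus a 3′ A)
and one member in each weaker canonical class; the remaining 252 members
carry no seed match.  Fitting synthetic kinetic data
(`python examples/binding_kinetics_fits.py`) prints

```
K_D fit: 0.0370 nM (truth 0.05 nM), B_max 0.971
release: k_fast 1.052 min^-1, k_slow 0.0487 min^-1 (truth 1.0, 0.05), A_fast 0.49
k_on: 0.0362 nM^-1 s^-1 (truth 0.04), intercept 0.0110 s^-1
K_D from rates: 0.250 nM
```

— sub-nanomolar affinity recovered through ligand-depletion-aware fitting,
a 20-fold-separated slow release phase, and an association slope (k_on)
whose intercept estimates k_off.  The other examples
(`rbns_fidelity.py`, `isomir_profiles.py`, `network_and_gsea.py`) walk the
RBNS fidelity comparison, the isomiR/arm-ratio analyses, and the
network/GSEA integration the same way.

A thin CLI mirrors the library (`agodyn synth`, `agodyn rbns`,
`agodyn kinetics`, `agodyn smallrna`, `agodyn network`); run
`agodyn --help` for the commands.

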