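# volscale

Whole-cell model of gene expression in which all genes compete for a
limiting pool of RNA polymerases (and all mRNAs for ribosomes) through
Michaelis–Menten promoter binding. Promoters with heterogeneous
recruitment abilities (1/K_n per gene) split the transcriptome into
scaling classes as the cell grows: genes recruiting **below** the
proteome-weighted average K spontaneously scale **superlinearly** with
cell volume, genes **above** it **sublinearly**, and the bulk stays
linear. The package

- generates synthetic genomes with the model's statistical structure
  (lognormal recruitment constants and mRNA lifetimes, a coarse-grained
  RNAP gene and a 5-copy ribosome gene) and calibrates initiation rates
  so the genome-wide RNAP capacity `n_c = Σ g_i (1 + Λ_n,i)` hits its
  target exactly,
- solves the self-consistent free-RNAP / free-ribosome fractions at
  every instant and integrates the coupled mRNA/protein ODEs, including
  a concentration-ratio-triggered cell-division cycle,
- evaluates the closed-form nonlinear scaling degrees (`β` for mRNA,
  `α` for nondegradable protein) from recruitment constants, and
- fits those degrees from expression-vs-volume data (simulated or
  external tables) and summarizes their correlation with mRNA
  production rates.

## Library quick start

```python
import volscale as vs

gl = vs.GlobalParams()                              # minutes, um^3, codons
genome = vs.make_genome(2000, K_cv=0.5, seed=1)     # lognormal recruitment
traj = vs.run_experiment(genome, gl)                # calibrate + integrate
pred = vs.predict_scaling(genome=traj.genome,
                          phi=traj.meta["phi0"],
                          n0_over_nc=traj.meta["n0_over_nc"])
fits = vs.fit_trajectory_betas(traj)                # measured degrees
```

`run_experiment` calibrates the genome (attempted ribosome mass
fraction `φ_r = μ0 L_r / v_r`, RNAP provisioned at 10% of ribosome
copies), integrates until the protein mass exceeds 9× its initial
value, discards a 20-minute burn-in, and re-bases all normalizations
there.

## CLI

```sh
volscale generate-genome --n-genes 2000 --k-cv 0.5 --seed 1 --out genes.tsv
volscale calibrate --genome genes.tsv --out calibrated.tsv
volscale simulate  --genome genes.tsv --out traj.tsv
volscale theory    --genome genes.tsv --out predictions.tsv
volscale fit --expression expr.tsv --volumes volumes.tsv \
             [--lifetimes lifetimes.tsv] --out betas.tsv
volscale run --config cfg.yaml --out-dir out/
```

`volscale run` drives one of four scenarios (`homogeneous`,
`two_special`, `lognormal_ensemble`, `cell_cycle`) from a YAML config:

```yaml
seed: 1
genome: {n_genes: 2000, K_cv: 0.5}
experiment: {scenario: lognormal_ensemble, t_end: 900, stop_mass_multiple: 6}
```

All tabular artifacts are tab-separated text with `# key=value` headers
carrying the config hash, seed and package version; infinite protein
lifetimes are written as `inf`.

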