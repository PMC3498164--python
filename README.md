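# bondfluct

Coarse-grained Monte Carlo simulation of a protein chain on a cubic
lattice — the bond-fluctuation model with knowledge-based residue–residue
contact potentials — together with the analysis suite used to characterize
the thermal random-coil ⇌ globule transition of the 136-residue histone
H3.1.

**Who it is for.**  Researchers in structural bioinformatics / polymer
biophysics who want a fast, reproducible lattice model of how a specific
amino-acid sequence responds to temperature when residue specificity enters
only through a 20×20 contact-energy table (Miyazawa–Jernigan,
Betancourt–Thirumalai, Bastolla-type matrices, or synthetic surrogates).

## Model

* Each residue is a unit cube (8 lattice sites) with excluded volume;
  consecutive residues are tethered by bonds from the classic 3-D
  bond-fluctuation vector set (squared lengths {4, 5, 6, 9, 10}, i.e.
  lengths 2 … √10, excluding √8 so chains can never cross).
* Residues i, j within the cutoff r_c = √8 interact through a generalized
  Lennard-Jones contact potential

      U_ij(r) = |ε_ij| (σ/r)¹² + ε_ij (σ/r)⁶ ,   r ≤ r_c ,  σ = 1,

  where ε_ij is the contact-matrix entry for their amino-acid types,
  indexed in the hydropathy ordering I V L F C M A G T S W Y P H Q N D E K R.
* Metropolis dynamics: a random residue attempts a hop to one of the six
  nearest lattice sites; geometrically valid moves are accepted with
  probability min(1, exp(−ΔE/T)), T in reduced units (k_B = 1).  One Monte
  Carlo step (MCS) = N attempts.
* Observables: radius of gyration R_g; RMS center-of-mass displacement
  R_c ∝ t^k (k = 1/2 diffusive, k → 0 frozen); spherically averaged
  structure factor S(q) ∝ q^(−1/ν) whose effective dimension D_e ≈ 1/ν
  distinguishes rod (≈1), random coil (≈2) and compact globule (≈3);
  residue–residue contact maps; per-residue energy and mobility profiles.
* Temperature sweeps over independent seeds, with detectors for the
  transition range (thresholded dR_g/dT) and for anomalous intervals where
  R_g *decreases* with rising T.

The published MJ/BT/BFKV energy tables are **not** redistributed here;
they load from user-transcribed text files (20×20 labeled table or 210-row
upper-triangle listing).  Synthetic matrices (zero, uniform, random
symmetric) make every code path testable without them.

## Worked example

Simulate the bundled H3.1 sequence with a uniform attractive surrogate
matrix (ε ≡ −1) at T = 0.02, then recompute observables from the stored
trajectory:

```bash
bondfluct simulate -T 0.02 --mcs 20000 --seed 7 \
    --matrix uniform_attract --record-every 500 -o h3_T0.02.traj
# wrote h3_T0.02.traj: 41 records, final Rg 16.025

bondfluct analyze h3_T0.02.traj --out-prefix h3_T0.02
# {"k": 0.20895..., "k_stderr": 0.036..., "frozen": false,
#  "De": 2.14497..., "De_stderr": 0.0251..., "nu": 0.46620...}
```

Reading the numbers: at this intermediate temperature the uniformly
attractive 136-mer is a fluctuating coil (final R_g ≈ 16 lattice units,
effective dimension D_e ≈ 2.1 from the S(q) fit over q ∈ [0.35, 0.75])
with sub-diffusive center-of-mass motion (k ≈ 0.21, between the frozen
k → 0 and diffusive k = 1/2 limits).  The run also writes CSV files with
R_g(t), R_c(t), S(q), per-residue profiles and the final contact map.

The same library API:

```python
import bondfluct as bf

seq = bf.h3_1_sequence()                      # 136 residues
mat = bf.make_matrix("uniform", value=-1.0)   # surrogate contact table
cfg = bf.SimulationConfig(T=0.02, mcs_total=20_000, record_every=500, seed=7)
traj = bf.run_simulation(cfg, seq, mat)
print(traj.rg()[-1])                          # 16.025...
```

Temperature sweeps (`bondfluct sweep`) aggregate many seeds per
temperature, cache per-run summaries by config hash, and report the
detected transition range.

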