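# mlpforge

Desk-scale concurrent learning for machine-learned interatomic potentials
of small drug-like molecules — the full train / explore / select / label
loop, its enhanced-sampling exploration engines, and the benchmark suite
such potentials are judged by, all runnable in seconds on one CPU.

Training sets for neural-network potentials are not collected, they are
*grown*: an ensemble (committee) of potentials is trained on the data so
far, molecular dynamics explores new conformations, and the frames on
which the committee disagrees most are labeled by a reference method and
added.  The disagreement signal is the **force model deviation**

    sigma = max_i sqrt( (1/N_m) * sum_alpha || F_i^alpha - F_i^mean ||^2 )

— the maximal per-atom standard deviation of forces over the N_m committee
members.  Frames with sigma above an upper bound sigma_u are discarded as
nonphysical; of the rest, the fraction r_candi with the largest deviation
become candidates, sigma_l is the smallest candidate deviation, and a
random subsample is labeled.  Iterations stop when sigma_l stops moving
(max - min below a tolerance over a trailing window).  A curriculum grows
molecule size while exploration temperature and run length ramp upward,
and high torsional barriers are reached by dihedral-biased sampling with
a capped adaptive bias.

`mlpforge` implements this workflow with two substitutions that make it
desk-scale: the quantum-chemical labeler is replaced by an analytic force
field (the *oracle* — exact energies and forces, no electronic structure),
and the deep-potential committee by seeded random-feature regressors over
smooth atomic-environment descriptors, trained in closed form.  The loop
logic, selection rules, sampling engines, accounting and benchmark
metrics are implemented in full:

* torsion-profile **MAE/RMSE** over relative energies (per-molecule bin
  averages, then the molecule average; the RMSE roots per molecule before
  averaging), **MAEB** (mean absolute barrier-height error, barrier =
  max - min of a profile) and **NABH** (profiles with barrier error
  > 1 kcal/mol);
* relaxed-structure comparison: Kabsch RMSD and bond/angle/torsion MAEs
  (circular metric for torsions);
* MD trajectory errors: relative-energy and force-component MAE/RMSE and
  the per-frame force-error magnitude ||dF|| = sqrt((1/N) sum_i |dF_i|^2).

Audience: method developers and students who want the *mechanics* of
concurrent learning — selection thresholds, stopping rules, curriculum
and biasing — observable and testable without GPUs, DFT or downloads.

## Worked example

```bash
python examples/05_active_learning_loop.py
```

```
iteration 1: explored  60 frames, discarded   7, labeled   4, sigma_l 0.270 eV/A, held-out force RMSE 3.47 kcal/mol/A
iteration 2: explored  75 frames, discarded   2, labeled   7, sigma_l 0.181 eV/A, held-out force RMSE 3.28 kcal/mol/A
iteration 3: explored  90 frames, discarded   2, labeled   2, sigma_l 0.182 eV/A, held-out force RMSE 2.91 kcal/mol/A
iteration 4: explored 105 frames, discarded   2, labeled   3, sigma_l 0.089 eV/A, held-out force RMSE 2.90 kcal/mol/A
iteration 5: explored 120 frames, discarded  84, labeled   1, sigma_l 0.369 eV/A, held-out force RMSE 2.89 kcal/mol/A
final held-out force RMSE: 2.91 kcal/mol/A
training set: 52 configurations
```

Each line is one concurrent-learning iteration on a butane-like fixture:
MD exploration frames (the exploration temperature ramps 300 to 750 K
across iterations, which is why the last iteration discards many frames)
are ranked by committee force deviation, frames above sigma_u are
discarded, and the top-deviation candidates are labeled by the oracle and
appended.  The held-out force RMSE of the committee mean falls from 3.47
to 2.91 kcal/mol/A as selected data accumulates; sigma_l is the smallest
committee disagreement among the frames chosen for labeling.

The other examples each demonstrate one capability: topology and
rotatable-bond selection (`01`), oracle labeling and degraded comparator
methods (`02`), Langevin NVT dynamics and biased barrier crossing (`03`),
constrained torsion scans with the profile metrics (`04`), and
relaxed-geometry plus MD-trajectory benchmarking (`06`).

A thin CLI wraps the same library calls:

```bash
forge fixtures make --family chain --size 4 --barrier 3.0 --out fx
forge scan --fixture fx --increment 10 --out scan-out   # 36-row profile CSV
forge run --config run.json --seed 1                    # the full loop
forge manifest check manifest.csv                       # accounting audit
```

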