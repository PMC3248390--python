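# replikinetics

Quantitative analysis of human DNA replication kinetics, combining three
views of the same process:

* **single molecules** — DNA combing fibers carrying IdU/CldU pulse labels,
  from which fork velocities, origin positions, fork-to-fork distances and
  fork clustering are measured;
* **cell populations** — Repli-seq style replication timing profiles
  (S50/TR50) built from binned nascent-DNA tag densities of FACS-sorted
  S-phase fractions, with an optional cytometry-model calibration of the
  DNA-content → time map;
* **the genome** — multiscale maps of the *apparent replication speed* and a
  segmentation into constant timing regions (CTRs) and timing transition
  regions (TTRs), with chromatin-feature gradients measured along TTRs.

The package also contains a stochastic origin-firing simulator (independent
and domino activation models) that generates every input kind synthetically,
so the whole pipeline is testable without any external data.

## The model

In a single cell with origins at positions `x_i` firing at times `T_i` and
forks moving at velocity `v`, every locus is replicated by the first
arriving fork:

```
t(x) = min_i ( T_i + |x - x_i| / v )
```

Averaged over a population, the timing-profile slope obeys

```
dt/dx = (R - L) / v
```

where `R` and `L` are the fractions of cells in which the locus is
replicated by a rightward or leftward moving fork (`R + L = 1`).  The
**apparent replication speed** is the inverse slope, `v / (R - L)`: it
equals the single-fork velocity only where all forks move one way, and
diverges where forks move equally in both directions.  Measured at a chosen
scale with a derivative-of-Gaussian kernel, this quantity segments the
genome into CTRs (|speed| > 10 kb/min) and TTRs (≤ 10 kb/min).  A TTR of
length `Dx` crossed in time `Dt` has mean speed `Dx/Dt`; sequential firing
of origins spaced `d` apart at intervals `τ` produces `Dx/Dt = d/τ`, which
is how timing gradients can replicate several-fold faster than any single
fork moves.

## Worked example

Fork densities of 2.64, 3.88, 4.55 and 5.40 forks/Mb in the four S-phase
compartments, fork velocities of 0.64–0.72 kb/min, and the fractions of the
genome replicated in each compartment give the genome duplication time:

```python
>>> import numpy as np
>>> from replikinetics import combing as cb
>>> inputs = cb.DuplicationTimeInputs(
...     p_si=[0.15, 0.19, 0.22, 0.20],
...     density=[2.64, 3.88, 4.55, 5.40],
...     velocity=[0.64, 0.68, 0.67, 0.72])
>>> print(np.round(inputs.t_si, 1))          # minutes per compartment
[88.8 72.  72.2 51.4]
>>> print(round(cb.genome_duplication_time(inputs)))
374
```

374 minutes ≈ 6 ¼ hours to duplicate the genome — consistent with the
independent estimate from the 22 h doubling time and the one-third S-phase
cell fraction (22 h × 1/3 = 7 h 20 min).  The reciprocal of the S1 fork
density is the global fork-to-fork distance:

```python
>>> density, ftfd = cb.fork_density_and_ftfd(82, 31.03)   # forks, Mb
>>> print(round(density, 2), round(ftfd))
2.64 379
```

379 kb between forks genome-wide, versus a ~19 kb *local* fork-to-fork
distance on fork-containing fibers — the signature of clustered origin
firing.

A full synthetic pipeline runs from the shell:

```bash
replikinetics simulate  --config config.yaml   # fibers, fractions, FACS
replikinetics timing    --config config.yaml   # S50 / TR50 profile
replikinetics speedmap  --config config.yaml   # per-scale speed bedGraphs
replikinetics segment   --config config.yaml   # CTR/TTR BED
replikinetics ttr-stats --config config.yaml   # per-TTR Dx, Dt, speeds
```

with a YAML config carrying an explicit seed (see `tests/test_cli.py` for a
complete example).

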