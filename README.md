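# escdyn

Stochastic epigenetic dynamics of the mouse embryonic stem cell (ESC) core
gene network.

ESC cultures show striking cell-to-cell variation in Nanog — a bimodal
copy-number distribution — while Oct4 and Sox2 stay single-peaked, and
individual cells shuttle between the high- and low-Nanog states over days.
`escdyn` implements a mechanistic explanation: each allele of the six core
genes (*Sox2*, *Oct4*, *Nanog*, *Cdx2*, *Gata6*, *Gcnf*) carries a
hierarchy of switching layers,

* transcription-factor binding/unbinding (fast, adiabatic:
  `f_unbind / k_deg = 100`),
* formation and dissolution of the transcription apparatus (TA), a
  three-level variable `ta ∈ {0, 1/2, 1}`,
* a bistable histone code `h ∈ {0, 1}` (slow, non-adiabatic:
  `r_off / k_deg = 0.05`),

coupled to bursty protein synthesis (`ta = 1` at rate `g`, `ta = 1/2` at
`g/γ`, Poisson burst size `b̄`) and first-order degradation.  Nanog acts
on chromatin only through its dimer (`d = K m²`, fast equilibrium) and is
degraded through its monomer.  The whole reaction system is simulated
exactly with the Gillespie algorithm (numba-compiled inner loop).

When the TA of the *Nanog* locus switches on the cell-cycle timescale
(dissolution rate 1.16e-5 /s, adiabaticity ≈ 0.1) the simulated culture
reproduces the observed phenotype; when it switches as fast as the other
loci, Nanog collapses to a single peak.  On top of the simulator the
package provides

* a nine-feature score of the Sox2/Oct4/Nanog distributions and massive
  two-parameter scans (how the slow-switching regime is located),
* coarse-graining of trajectories into discrete cell states with
  dwell-time-derived transition rates `W_ij = 1/τ_ij`,
* an epigenetic-landscape fit `W_ij = k0·exp(−(F‡_ij − F_i))` with one
  non-equilibrium curl flux per independent loop of the transition
  diagram, and a 2-D projection onto trophectoderm/endoderm closeness.

## Worked example

```python
import escdyn
from escdyn import DAY

cfg = escdyn.load_config()                 # shipped slow-Nanog defaults
ens = escdyn.run_ensemble(cfg.network, cfg.params,
                          n_cells=200, duration=3 * DAY,
                          base_seed=1, burn_in=10 * DAY)   # ~6 min

hists = {g: escdyn.expression_histogram(ens, g)
         for g in ("Sox2", "Oct4", "Nanog")}
rep = escdyn.score(hists)
pk = escdyn.detect_peaks(hists["Nanog"])
print("score S =", rep.total, "/", rep.s_max)
print("Nanog peaks at", pk.locations.round(0),
      "zero fraction %.3f%%" % (100 * hists["Nanog"].zero_fraction))
```

prints (seed 1):

```
score S = 9.0 / 9.0
Nanog peaks at [ 330. 7947.] zero fraction 0.625%
```

i.e. the simulated ESC culture is bimodal in Nanog with the low mode near
330 copies (the partial-TA branch, `g·b̄/(γ·k_deg)` plus its dimer pool)
and the high mode near 8000 copies (complete TA, mostly dimeric), the
high peak higher, and essentially no cells at exactly zero Nanog — the
experimentally observed fingerprint, worth the full score of 9.

The same objects drive the downstream analyses:

```python
dia = escdyn.build_diagram(ens, escdyn.default_scheme(),
                           occ_threshold=0.01, link_count_threshold=600)
sol = escdyn.solve_landscape(dia)          # depths, saddles, curl fluxes
```

A command-line interface mirrors the library
(`escdyn simulate | score | scan | diagram | landscape | fixture`); every
run writes its resolved configuration next to its outputs.

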