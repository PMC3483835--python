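# turnoverkit

Tools for simulating and critically appraising protein-degradation
experiments.

Half-lives reported for cellular proteins depend heavily on how they were
measured. A cycloheximide chase, a Tet-off shutoff, an siRNA knockdown, a
radioactive pulse-chase and a SILAC medium switch all probe different
combinations of mRNA decay, translation, protein degradation and growth
dilution — and several of them systematically overestimate protein
stability whenever the mRNA, not the protein, is the slow species.
`turnoverkit` gives cell biologists and proteomics researchers a small
quantitative model to simulate these designs, estimators to fit
half-lives back from (noisy) time courses, a bias grid that quantifies
how far a shutoff design inflates the apparent half-life, and a
deterministic checklist engine that grades what a declared design can
conclude about degradation.

## The model

One protein species per average cell, with mRNA pool *M* and protein
pool *P*:

    dM/dt = T − k_M · M
    dP/dt = R · M − (D + V) · P

where *T* is transcription (balancing decay at baseline), *k_M* =
ln2 / mRNA half-life, *R* is the translation rate (proteins per mRNA per
hour), *D* = ln2 / protein half-life the degradation rate and
*V* = ln2 / doubling time the dilution rate from growth (0 for
non-dividing cells). At steady state

    P₀ = M₀ · R / (D + V).

Experimental designs are ordered, instantaneous multiplier steps on
synthesis, transcription or degradation, plus an isotope label switch;
trajectories are propagated analytically across each piecewise-constant
segment (single- and two-exponential closed forms), and an independent
high-order numeric integrator cross-checks every solution. Key closed
forms: a total synthesis block decays as exp(−k_P t) with
k_P = D + V; a transcription shutoff decays as the slower
two-exponential [k_P e^(−k_M t) − k_M e^(−k_P t)] / (k_P − k_M), which is
why the "apparent" half-life read from a Tet-off or knockdown experiment
is an overestimate unless k_M ≫ k_P.

## Worked example

```python
from turnoverkit import TurnoverParams, apparent_vs_true_grid

template = TurnoverParams(mrna_copies=10, translation_rate=2.0,
                          mrna_half_life=1.0, protein_half_life=1.0)
grid = apparent_vs_true_grid("tet_off",
                             mrna_half_lives=[0.01, 0.1, 0.5, 1.0, 2.0, 5.0],
                             protein_half_lives=[1.0],
                             params_template=template)
```

prints (see `examples/tet_off_apparent_half_life.py`):

```
mRNA t1/2 (h)   apparent/true half-life
        0.01      1.014
        0.10      1.152
        0.50      1.772
        1.00      2.421
        2.00      3.543
        5.00      6.572
```

Each row is the ratio of the half-life read off the simulated Tet-off
decline (50% crossing) to the protein's true effective removal half-life
ln2/(D+V). With a fast-decaying mRNA the design is nearly unbiased
(ratio 1.014); when mRNA and protein half-lives are equal the readout
overestimates stability 2.42-fold, and a stable mRNA makes the protein
look arbitrarily long-lived.

The other capabilities each have a short narrative script under
`examples/`: steady state plus a noisy chase fit, the
degradation-inhibitor fold-change decomposition (a complete block on a
40 h half-life protein yields at most a 1.14-fold rise in 8 h, so a
3-fold rise implies a 2.6-fold synthesis effect), pulse-chase and SILAC
labeled pools, and checklist appraisal.

A thin CLI mirrors the library: `turnoverkit simulate --config run.yaml
--out out/`, `turnoverkit fit table.csv --method nonlinear_1exp`,
`turnoverkit grid ...`, `turnoverkit appraise --ticks 1,4,8`.

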