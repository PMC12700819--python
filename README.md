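# chromodyn

Chromosomes exiting mitosis rebuild their 3D architecture: A/B compartments,
TADs and CTCF loops form gradually through G1, while *microcompartments* —
nested grids of focal contacts between kilobase-scale cis-regulatory
elements (CREs) — are already present in prometaphase, peak in strength
around anaphase/telophase, and then weaken.  `chromodyn` is a package for
studying that behavior in silico: a coupled 1D loop-extrusion / 3D
block-copolymer chromosome simulator with a time-varying mitosis-to-G1
protocol, plus the contact-map statistics and the transcriptional-spiking
classifier needed to quantify the results, exercisable end to end on
seeded synthetic inputs.

## The model in brief

**Loop extrusion.** Two-legged extruders (condensin I, condensin II,
cohesin) live on a lattice of σ = 0.5-kb sites.  Each leg steps outward with
probability p per τ₀ = 0.5 s, giving loop growth v = 2pσ/τ₀ (1 kb/s at
p = 0.5); extruders unload at rate 1/τ_res and reload to a target abundance
N = Lσ/d.  Cohesin stalls at convergently oriented CTCF sites with
probability q = 0.5.

**Polymer.** One monomer per lattice site (a = 25 nm ≈ 0.5 kb), harmonic
chain and bridge bonds, and a smooth square-well pair potential: soft
repulsive core E_repel = 3 k_BT and homotypic attraction of depth ε on
a ≤ r ≤ 1.5a, with ε_A = 0, ε_B = 0.05, ε_C = 0.9 k_BT.  C-type blocks
(1.5 kb) are the microcompartment anchors; microcompartments form by block
copolymer microphase separation.  The chain is confined to a sphere or a
4:1 cylinder at volumetric density ρ_chr; dynamics are underdamped BAOAB
Langevin.

**M-to-G1 protocol.** Condensins extrude in a dense cylinder (ρ = 0.65)
during prometaphase; condensin I is removed by 20 min, the cylinder shortens
to ρ = 0.45 during anaphase/telophase, and at 30 min condensin II is
removed, CTCF and A/B affinities switch on, cohesin starts loading linearly
to d = 100 kb, and confinement crosses over to a sphere at ρ = 0.25 (a
2.6-fold density decrease).  Contact maps are collected in five windows:
PM, AT, EG1, MG1, LG1.

**Analysis.** ICE balancing, P(s) and its log-log derivative, 21×21-window
background-subtracted and observed/expected loop strengths, 6-kb simulation
window strengths, APA pileups, promoter/enhancer/CTCF anchor classification
(inclusive and exclusive), compartment eigenvectors, and a PCA classifier
that labels genes whose Pol II signal transiently exceeds its G1 level
("spiking", PC1 > 0).

See `docs/methods.md` for the full model description, parameter defaults and
reduced-scale conventions.

## Worked example

A steady-state affinity sweep at reduced scale — does switching on the
microcompartment affinity create focal C–C enrichment?

```python
from chromodyn.protocol import SweepSpec, run_steady_state
from chromodyn.synth import gen_monomer_typing

typing = gen_monomer_typing(locus_monomers=400, spacer_monomers=0, copies=1, seed=0)
spec = SweepSpec(grid={"eps_c": [0.0, 0.9]}, replicates=2,
                 equil_1d_steps=500, equil_blocks=400, collect_blocks=400,
                 steps_per_block=50, sample_stride=5)
table = run_steady_state(spec, typing, seeds=[1, 2])
print(table.groupby("eps_c")["cc_strength"].mean())
```

```
eps_c
0.0    0.863917
0.9    1.294557
Name: cc_strength, dtype: float64
```

`cc_strength` is the mean distance-normalized contact frequency in 6-kb
windows centered on pairs of C-type anchors: ≈ 1 means no enrichment over
the distance-decay background (ε_C = 0), while values above 1 show focal
microcompartment contacts (ε_C = 0.9 k_BT).  Longer equilibration and higher
density push the enriched value up further.

The spiking classifier on synthetic Pol II profiles:

```python
from chromodyn.synth import gen_polII_series
from chromodyn.spiking import SpikingModel

matrix, manifest = gen_polII_series(n_genes=100, spiking_fraction=0.4, seed=5)
result = SpikingModel(matrix).fit()
print(result.summary())
```

```
Transcriptional spiking PCA
========================================
genes analyzed        100
spiking (PC1 > 0)     39 (39.0%)
PC1 variance explained 86.8%
PC1 loadings: PM=-0.02  AT=+0.92  EG1=+0.32  MG1=-0.16  LG1=-0.16
```

PC1 loads on the AT time point: genes with positive scores are the planted
spiking subpopulation (39 called vs 40 planted).

There is also a CLI (`chromodyn synth | sim1d | transition | sweep | loops |
compartments | spiking | report`); every subcommand writes a manifest with
the resolved configuration and seed.

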