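# acudyn

Analysis toolkit for the conformational dynamics of **AcuB**, the
adenine-nucleotide energy sensor of the bacterial *acu* operon, and for
the biophysical assays that characterise its regulation of the
deacetylase **AcuC**.

AcuB is a scissor-shaped dimer: each monomer carries an N-terminal
Bateman domain (two CBS modules, together binding two adenine
nucleotides) and a C-terminal ACT domain that forms the AcuC-binding
effector surface.  AMP-loaded AcuB binds and inhibits AcuC; ADP/ATP
loading releases it.  This package implements the computational side of
that story:

- **Conformational landscapes** (`acudyn.landscape`).  Two per-frame
  order parameters summarise an MD ensemble of the dimer — the *opening*
  distance ‖COM(res 1–82, monomer A) − COM(res 1–82, monomer B)‖ and the
  *jacking* distance ‖COM(ACT, res 135–214) − COM(Bateman, res 1–134)‖.
  Their joint histogram is Boltzmann-inverted into a free-energy surface
  ΔG = −RT·ln(P/Pmax), and conformational basins (closed/compact,
  open/compact, extended) are extracted with OPTICS density clustering.
- **Binding stability** (`acudyn.stability`).  RMSD of bound AcuC after
  alignment on the non-hydrogen atoms of the AcuB chains, decorrelated
  through the integrated autocorrelation time
  τ = 1 + 2·Σρ(t) and compared across nucleotide-loading conditions with
  one-way ANOVA + Tukey HSD.
- **Structure toolbox** (`acudyn.structio`, `acudyn.geometry`).
  Multi-model PDB/XYZ I/O, deterministic residue/chain selections,
  Kabsch superposition, per-residue displacement tables, ligand
  B-factor summaries and nucleotide-site classification.
- **Assay calculations** (`acudyn.assays`).  Nucleotide loading from
  denatured-sample absorbances, HPLC peak-area ratios, IC50 dose-response
  fits (Hill slope fixed at −1), nanoDSF melting temperatures
  (Tm = extremum of d(Em350/Em330)/dT) with a derivative non-additivity
  interaction test, and SEC calibration
  (Kav = (Ve−V0)/(Vc−V0), log-linear in MW) with integer stoichiometry
  inference.
- **Synthetic data** (`acudyn.synthio`).  Seeded generators producing
  trajectories and assay tables with exact ground truth, so every stage
  is testable end to end.

## Worked example

Generate a three-state dimer ensemble (populations 0.6/0.3/0.1), compute
the order parameters and recover the basins:

```python
from acudyn import synthio, landscape

spec = synthio.DimerSpec(n_frames=5000, seed=7)
traj, truth = synthio.gen_dimer_trajectory(spec)
ops = landscape.compute_order_parameters(traj)
fes = landscape.free_energy_surface(ops.opening, ops.jacking)
basins = landscape.optics_cluster(ops.points(), min_samples=50,
                                  extraction="eps-cut", eps=0.6)
table = landscape.categorize_and_populate(basins)
print(table[["category", "population", "centroid_opening_A", "centroid_jacking_A"]]
      .to_string(index=False))
print(f"FES: RT = {fes.rt:.4f} kcal/mol")
```

prints

```
      category  population  centroid_opening_A  centroid_jacking_A
closed/compact      0.6096           19.986191           13.948691
  open/compact      0.2918           32.031908           13.939211
      extended      0.0986           22.200792           26.007264
FES: RT = 0.6160 kcal/mol
```

The three basins recover the planted state populations to within a
percentage point; centroids sit on the planted (opening, jacking) means,
and RT = 0.6160 kcal/mol corresponds to the 310 K simulation base
temperature.

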