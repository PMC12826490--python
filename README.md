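# eggchamber

Dynamics of Gurken/EGFR signaling on the growing *Drosophila* egg chamber.

During mid-oogenesis (stages S7–S10A, modeled as 3–19.5 h), the TGF-α-like
ligand Gurken (GRK) is secreted around the oocyte nucleus into the
perivitelline space, diffuses over that thin curved gap, and activates EGFR
in the overlying follicle cells (FCs), read out as dpERK. Three
morphological movements shape where the signal ends up: the nucleus
migrates from the posterior pole to the dorsal anterior; the chamber grows
~4-fold along AP and ~3-fold along DV; and the follicular epithelium
compacts toward the posterior as cells turn columnar. This package
implements a dynamic transport–reaction–diffusion model of that system for
people who want to simulate and perturb the morphology *in silico* —
perturbations (stopping growth, nuclear migration, or the FC shift) that
are lethal or unreachable genetically.

## Model

On the time-varying prolate spheroid surface (semi-axes `L_AP(t)`,
`L_DV(t)` from staged measurements), with Δ_t the Laplace–Beltrami
operator of the surface at time t, v the growth velocity field and w the
tangential FC-shift field:

    ∂L/∂t  + ∇·(vL)           = D Δ_t L + V(t,x) − (1/H) k̄_on R L + k_off C
    ∂C/∂t  + ∇·(vC) + ∇·(wC)  = (1/H) k̄_on R L − k_off C − k_ec C + α_rec k_rec Ci
    ∂Ci/∂t + ∇·(vCi)+ ∇·(wCi) = k_ec C − α_deg k_deg Ci − α_rec k_rec Ci
    ∂R/∂t  + ∇·(vR) + ∇·(wR)  = −(1/H) k̄_on R L + k_off C − k_er R + Q_r
    ∂S/∂t  + ∇·(vS) + ∇·(wS)  = k̄_s Ci − k_d S

with negative feedback through Kekkon1 and Sprouty,

    k̄_on = k_on / (1 + γ_KEK1 KEK1 / K),     k̄_s = k_s / (1 + γ_STY STY / K′),
    ∂STY/∂t  + … = k_STY S − k_dSTY STY,      ∂KEK1/∂t + … = k_KEK1 S − k_dKEK1 KEK1.

L is the free ligand, R free EGFR, C/Ci surface/internalized complexes, S
the dpERK signal. V(t,x) is a T-shaped secretion source tracking the
nucleus with total flux proportional to the oocyte surface area. The
surface is discretized by a cubed-spheroid mesh (no polar degeneracy), the
Laplace–Beltrami operator by conservative linear finite elements, advection
by conservative upwinding, and time by operator-split forward Euler. See
`docs/methods.md` for assumptions, parameter provenance and numerics.

## Worked example

```python
from eggchamber import EggChamberModel
from eggchamber.analysis import elongation, max_signal, extract_ap_profile

model = EggChamberModel.from_defaults(n=32)

wt = model.simulate()                      # wild type, 3 h -> 19.5 h
ns = model.simulate(preset="no-fc-shift")  # epithelium compaction removed

wt_max = max_signal(wt, 19.5)
print(f"WT S10A elongation       : {elongation(wt, 19.5, 0.6):.1f} um")
print(f"no-shift S10A elongation : "
      f"{elongation(ns, 19.5, 0.6, reference_max=wt_max):.1f} um")
print(f"no-shift max dpERK       : {100*max_signal(ns,19.5)/wt_max:.1f} % of WT")
```

prints

```
WT S10A elongation       : 344.1 um
no-shift S10A elongation : 349.1 um
no-shift max dpERK       : 97.5 % of WT
```

Elongation is the arc-length of the closed AP meridian ring where dpERK
exceeds 0.6 of the wild-type maximum at that stage — the spatial-extent
metric of the perturbation experiments. Removing the FC shift leaves the
signal maximum essentially unchanged but lets the pattern spread further
anteriorly; stopping growth at late S8 (preset `growth-stop`) shrinks both
the source (oocyte area frozen) and the pattern.

The same experiments are available from the shell:

```bash
eggchamber preset no-fc-shift --out out/          # metrics table + snapshots
eggchamber simulate --config my.yaml --out out/   # custom configuration
eggchamber calibrate --grid-sty 5e3,5e4,5e5 --grid-kek 1e2,1e3,1e4 \
    --reference 1.0=wt.csv --reference 0.5=half.csv --reference 2.0=double.csv
```

Calibration of the inhibitor strengths (γ_STY, γ_KEK1) grid-searches the
summed L1 relative error between simulated and reference AP/DV intensity
profiles across three *grk* dosages; `EggChamberModel.fit` returns the
estimates with the full error surface and a `summary()` table. A seeded
synthetic-reference generator (`eggchamber.analysis.synth_reference_curves`)
makes the calibration pipeline testable without experimental data.

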