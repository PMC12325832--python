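# nanotherm

Simulation of **nanoparticle-mediated magnetic hyperthermia** in a
vascularised tumour microenvironment, for computational-oncology and
thermal-therapy modellers. Iron-oxide nanoparticles are infused into the
bloodstream, extravasate through the leaky tumour endothelium, and heat
the tissue when excited by an alternating magnetic field (AMF); the
therapeutic window (mild hyperthermia at 39-44 °C versus ablation above
50 °C) depends sensitively on how many particles accumulate, on their
specific absorption rate (SAR), and on how strongly blood perfusion
cools the tissue.

The package solves, on 2D bilinear-quadrilateral FEM grids with backward
Euler in time:

* **Nanoparticle transport** in the interstitial fluid (IF):
  storage ∂ₜ(ρ ε Sₗ ωₗ), Darcy advection, diffusion, Starling-type
  transvascular exchange
  (convective drag `Lp·(pv − pl − σΔπ)` plus one-way wall permeation
  `Pv·(ωv − ωl)₊`), and lymphatic drainage impaired above a collapse
  pressure;
* **Bioheat transfer** under local thermal equilibrium:
  `(cpρ)_eff ∂ₜT − ∇·(κ_eff ∇T) = Qp − Qbl` with the SAR source
  `Qp = (ρv εv ωv + ρl ε Sl ωl)·SAR` and either the lumped **Pennes**
  perfusion sink `ρ cp w (T − T_b)` or a **discrete** embedded vessel
  sink `2πR β_T (T − T_b) δ_Λ` on the centrelines of a resolved 1D
  microvascular network (Hagen–Poiseuille flow, 1D advection–diffusion,
  Murray-law synthetic trees, tumour-induced vessel collapse);
* **Synthetic microenvironments** standing in for a multiphase
  tumour-growth model: spherical or elliptical tumours with elevated
  interstitial pressure, an avascular core, and configurable phase
  saturations.

See `docs/methods.md` for the model equations, parameter defaults with
units, and the design rationale.

## Worked example

Idealised spherical tumour (0.5 × 0.5 mm quarter domain, 120×120
elements), 60-minute protocol — nanoparticle infusion at vascular mass
fraction 2×10⁻³ for 40 min, AMF from minute 20 at SAR = 2 MW/kg —
without and with the Pennes perfusion sink:

```python
import nanotherm as nt

hot = nt.run_idealised(omega_inj=2e-3, SAR=2000.0, w=0.0)     # SAR in W/g
cool = nt.run_idealised(omega_inj=2e-3, SAR=2000.0, w=0.036)  # perfused
print(nt.summarise(hot, reference=cool, spread_time=2400.0))
```

prints (values in °C; negative deltas mean the reference runs cooler):

```
{'peak_avg_C': 52.0508, 't_peak_s': 2400.0, 'peak_point_C': 52.0801,
 'spread_C': 0.1609, 'spread_time_s': 2400.0,
 'delta_peak_avg_C': -9.1699, 'delta_peak_point_C': -9.1785,
 'max_pointwise_cooling_C': -4.3562}
```

The domain-average temperature peaks at 52.1 °C exactly when the
infusion ends (t = 2400 s) — ablation range — while the field is nearly
homogeneous (spread 0.16 °C): the surrounding host tissue is heated
almost as much as the tumour. Turning on a perfusion rate of
w = 0.036 s⁻¹ lowers the peak by 9.2 °C, out of the ablation range.

The same protocol with an explicitly resolved capillary network instead
of the lumped sink:

```python
ref  = nt.run_discrete(perfusion_model="none", network_seed=0)
line = nt.run_discrete(2e-5, "discrete", network_seed=0)
x, T_ref = ref.profiles["T_y1.8"]; _, T_line = line.profiles["T_y1.8"]
print(float((T_ref - T_line).max()))   # -> 0.054 °C
```

the capillary line sink at the literature wall coefficient
β_T = 2×10⁻⁵ W/(mm²·K) cools by only ~0.05 °C — an order of magnitude
less than the Pennes sink under the same conditions, which is the
central comparison the package is built to make.

A CLI wraps the three scenarios and writes CSV time series, legacy-VTK
fields, and JSON summaries:

```bash
nanotherm idealised --omega-inj 2e-3 --sar 2000 --w 0.036 --out runs/a
nanotherm discrete --beta-t 2e-5 --perfusion-model discrete --out runs/b
nanotherm mouse --distribution clustered --out runs/c
nanotherm batch --out runs/grid      # full dose x SAR x perfusion grid
```

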