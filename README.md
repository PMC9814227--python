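# pipnano

Analysis of cation-induced PI(4,5)P₂ nanodomains in coarse-grained lipid
bilayers, with the companion fluorescence-spectroscopy computations.

PI(4,5)P₂ is a polyanionic inner-leaflet phospholipid whose headgroup
phosphates are crosslinked by divalent cations (Ca²⁺, Mg²⁺) into
nanometre-scale clusters. Characterizing those nanodomains in
coarse-grained molecular-dynamics snapshots — how large they are, how
ordered their acyl chains become, whether they pack into gel-like
hexagonal lattices, whether they register across the two leaflets, and
what membrane curvature they generate — requires a stack of bespoke
analyses that are usually written as one-off scripts. `pipnano` packages
those analyses as a tested library and CLI for membrane biophysicists,
together with the fluorescence computations used to probe the same
phenomena in vitro (steady-state anisotropy, TCSPC lifetime fitting,
melting-midpoint extraction), and synthetic generators that plant known
ground truth so every stage is verifiable without running MD or owning a
spectrometer.

## What it computes

| Quantity | Definition |
|---|---|
| Cluster partition | connected components of lipid–lipid contact (any selected-bead pair within a cutoff, periodic minimum image, in-plane) |
| Average cluster size | number-weighted (Σs)/n and mass-weighted (Σs²)/(Σs), monomers included |
| S-value order parameter | S = (3⟨cos²θ⟩ − 1)/2 per chain bond, θ against the bilayer normal |
| Distance-resolved order | probe-lipid first-bond S binned by in-plane distance to the nearest PI(4,5)P₂ molecule |
| Hexagonality | chains whose six nearest in-plane neighbours sit 60° ± tolerance apart within a cutoff (gel hallmark) |
| Height / thickness fields | gridded periodic leaflet surfaces from PO4 beads; upper − lower thickness |
| Mean curvature H | local quadratic Monge-patch fit, H = (a(1+e²) + b(1+d²) − cde)/(1+d²+e²)^{3/2}; crests (bumps toward +z) negative |
| Registration | Pearson correlation of per-leaflet species-occupancy grids (+1 registered, 0 independent, <0 anti-registered) |
| Anisotropy | ⟨r⟩ = (I_VV − G·I_VH)/(I_VV + 2G·I_VH), G = I_HV/I_HH |
| Lifetimes | i(t) = Σᵢ αᵢ exp(−t/τᵢ) by Poisson-weighted multistart Levenberg–Marquardt; τ̄ = Σᵢ αᵢτᵢ; reduced-χ² and residual-autocorrelation diagnostics |
| Melting midpoint Tm | logistic fit of anisotropy vs temperature, with no-transition detection |

See `docs/methods.md` for assumptions, defaults, and numerical choices.

## Worked example

```python
import numpy as np
import pipnano as pn
from pipnano import synthetic_data as sd

# a 900-lipid POPC bilayer with 10% PI(4,5)P2, clusters planted
frame, truth = sd.build_fluid_bilayer(n_lipids=900, pip2_fraction=0.1, seed=42)
frame, truth = sd.plant_clusters(frame, [30, 25, 20, 15], seed=43)

part = pn.detect_clusters(frame, species="PIP2", cutoff=0.6)
print(sorted(part.sizes.tolist(), reverse=True))
print(pn.average_cluster_size(part, "number"))
print(pn.average_cluster_size(part, "mass"))

prof = pn.order_profile(frame, "PIP2", chain=0)
print(np.round(prof.s_values, 3))

hist, _ = sd.simulate_decay([0.6, 0.4], [1.0, 10.0], n_photons=1e6, seed=42)
model, diag = pn.fit_decay(hist, n_components=2, seed=42)
print(np.round(model.amplitudes, 3), np.round(model.lifetimes, 3))
print(round(model.mean_lifetime, 3), round(diag.chi2_reduced, 3))
```

prints

```
[30, 25, 20, 15]
22.5
23.88888888888889
[0.338 0.393 0.364]
[0.597 0.403] [0.974 9.868]
4.56 1.023
```

The detector recovers the four planted clusters exactly (number-weighted
mean 22.5 lipids; the mass-weighted mean is higher because large clusters
dominate it). The sn-1 chain of PI(4,5)P₂ shows fluid-like bond order
S ≈ 0.35–0.4 at the generator's default disorder. The two-exponential fit
recovers the planted amplitudes (0.6, 0.4) and lifetimes (1, 10 ns) to a
few percent, with amplitude-weighted mean lifetime τ̄ = Σαᵢτᵢ ≈ 4.56 ns
and reduced χ² ≈ 1.02, inside the conventional ≤ 1.3 acceptance band.

The same operations are available from a shell, e.g.

```sh
pipnano synth clusters --sizes 30,25,20,15 --seed 42 --out bilayer.gro
pipnano cluster bilayer.gro --species PIP2 --cutoff 0.6 --out sizes.tsv
pipnano info bilayer.gro
pipnano lifetime decay.tsv --components 2
```

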