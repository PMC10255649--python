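# toothmc

Voxel-based Monte Carlo photon transport for diffuse optical spectroscopy
(DOS) of human teeth.

DOS probes tissue by injecting light at one point on the surface and
collecting the multiply scattered light at another; the source–detector
separation (SDS) controls how deeply the detected photons have travelled.
`toothmc` simulates this measurement on a three-compartment tooth crown —
enamel, dentin, and pulp — at 633 nm and 1310 nm, in both **reflectance**
(source and detector on the occlusal face) and **transmittance** (detector on
the opposite face) geometries, with Fresnel surface reflection at
refractive-index-mismatched boundaries either enabled (WSR) or disabled
(W/OSR). It is written for researchers designing optical probes for dental
imaging who need pathlength, fluence, scattering, and sensitivity estimates
per tissue compartment.

## Model

Photon packets of initial weight *w* = 1 are launched from a Gaussian beam
(200 µm 1/e² diameter) and propagated through a labeled voxel grid by exact
face-to-face ray stepping. Free paths are exponential in the local total
interaction coefficient µ_t = µ_a + µ_s; at each interaction the packet
deposits *w*·µ_a/µ_t (implicit capture), survives with *w*·µ_s/µ_t, and
deflects by a Henyey–Greenstein angle,

    cos θ = [1 + g² − ((1 − g²)/(1 − g + 2gδ))²] / (2g),   δ ~ U(0,1),

with the isotropic limit cos θ = 2δ − 1 at g = 0. Under WSR, unpolarized
Fresnel reflection/refraction is applied at every voxel face where the
refractive index changes. Packets are tracked for 1 ns in ten 0.1 ns gates;
Russian roulette (threshold 10⁻⁴, survival 0.1) terminates low weights
unbiasedly. Detected packets record exit weight W_j, exit time, and
per-tissue partial pathlengths PP_j and scattering counts.

From detected packets, the mean partial pathlength per voxel (or tissue) and
its companion quantities are

    MPP(V_i, T) = Σ_{j∈T} W_j PP_j(V_i) / Σ_{j} W_j,       MTP = Σ_i MPP_i,
    J_µa(V_i, T) = −MPP(V_i, T),
    J_µs(V_i, T) = N̄_sc(V_i, T)/µ_s(V_i) − MPP(V_i, T),

computed by **photon replay**: every detected packet's counter-based random
stream is replayed so the identical path re-accumulates voxelwise statistics
(perturbation Monte Carlo), without storing paths.

Because no segmented molar mesh is distributed, `toothmc` generates a
parametric voxelized crown: nested superellipsoid surfaces calibrated by
bisection so the enamel/dentin/pulp volume fractions hit 0.44/0.52/0.04, a
6 mm crown with flat occlusal and root-side faces, and a pulp chamber with a
root-canal stem fully enclosed by dentin. At the default 0.05 mm pitch the
model exceeds 2 million tissue voxels. The tooth is embedded in a
high-absorption, high-scattering bounding medium (µ_a = µ_s = 10 mm⁻¹) that
terminates escaped photons.

## Worked example

```python
from toothmc import *
from toothmc.analysis import summarize_pathlengths
from toothmc.replay import contribution_table, jacobian_mu_a, replay_detected

tooth = generate_tooth_model(GeometryParams(pitch_mm=0.15))
grid = embed_in_bounding_box(tooth, pad_voxels=6)
media = load_media(633)
src, dets = auto_probes(grid, "transmittance", sds_mm=(7.0,), radius_mm=1.0)
cfg = SimulationConfig(n_photons=200_000, seed=1, wsr=True)
res = run_simulation(grid, media, cfg, src, dets)

s = summarize_pathlengths(res.records)
ct = contribution_table(res.records)
mpp, nsc, wdp = replay_detected(res)
```

Output (printed by the snippet above with the shown settings):

```
tooth voxels: 135624   fractions: enamel 0.442  dentin 0.518  pulp 0.040
detected packets: 761   detected weight: 24.785
batch error rate: 0.243
MPP (mm): {'enamel': 7.27, 'dentin': 6.61, 'pulp': 1.354}   MTP: 15.23 mm
pulp contribution: 8.89 %
MPP map sum (= MTP): 15.23 mm   J_mu_a min: -0.110
```

Reading this: of the light crossing the 6 mm crown to a detector 7 mm away,
the average detected photon travelled 15.2 mm inside the tooth (multiple
scattering more than doubles the geometric path), spending most of it in
enamel and dentin; pulp — only 4 % of the volume — carries ~9 % of the
detected signal in transmittance at this scale. The voxelwise MPP map sums
exactly to the MTP, and the absorption Jacobian is its pointwise negation:
raising µ_a by δ in a region changes the log detected signal by −δ·MPP of
that region. The batch error rate (sd/mean over 5 batches) shrinks as
1/√N_photons.

A CLI mirrors the library:

```
toothmc geometry --pitch 0.05 --crown 6.0 --out tooth.nrrd
toothmc run --config run.json --geometry tooth.nrrd --out results/
toothmc replay --run results/ --out maps/
toothmc analyze --run results/ --out report/
```

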