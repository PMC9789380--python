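# ciliaxis

Quantitative image and signal analysis for **axo-ciliary synapses** — the
contacts formed between serotonergic axonal varicosities and the primary
cilia of hippocampal pyramidal neurons. The package reimplements, as a
tested pipeline, the measurements that establish and characterize these
synapses:

- **3D contact mapping** — nuclei, cilia (ADCY3) and serotonergic axons
  (SERT) are Otsu-segmented from multichannel volumes resampled to an
  isotropic grid; cilia and axons are reduced to one-voxel central axes,
  and the Euclidean distance transform of the axon skeleton is sampled
  along each cilium axis. A cilium is *axon-contacting* when its minimum
  axis-to-axis distance is ≤ 2 µm (the upper end of the 1–3 µm varicosity
  scale); synaptophysin puncta within 1 µm of an axon axis are
  axon-associated.
- **Puncta detection** — scale-normalized 3D Laplacian-of-Gaussian filtering
  with 26-neighborhood maxima, plus radial counts (1–8 µm shells) around
  distance-transform-split nucleus centers.
- **Ciliary receptor fraction** — integrated receptor signal inside the
  1-voxel-dilated cilia mask over the total supra-threshold signal
  (20-photon-count cutoff).
- **Biosensor trace analytics** — ΔF/F₀ = (F − F₀)/F₀ with background
  subtraction, hard-cutoff Fourier low-pass filtering, peak/mean response
  metrics, Hill dose–response fits (EC₅₀), single-exponential on/off
  kinetics.
- **FRET / FLIM** — FRET ratio time series (rolling-ball background
  flattening, Otsu masking, acellular background subtraction); fixed
  two-lifetime decay fits (1.3 ns quenched / 2.7 ns unquenched donor);
  per-cilium lifetime summaries as the analytic mode of a maximum-likelihood
  three-parameter alpha distribution over ≥ 50-count voxels,
  mode = loc + scale · (√(a² + 8) − a)/4.
- **Ratiometric chromatin readouts** — per-voxel marker/DNA ratios
  (H4K5ac-, H3K27ac-, ATAC-see-to-Hoechst) with a per-z-plane flat-field
  correction vector, a 90th-percentile-restricted Otsu gate on the DNA
  channel, and Gaussian-KDE mode summaries.
- **Estimation statistics** — mean differences as 5000-sample bootstrap
  distributions with percentile 95% CIs, and two-sided permutation tests.

The microscopy data behind these measurements are not publicly deposited,
so the package ships a first-class **synthetic-scene generator**
(`ciliaxis.synth`) that plants every quantity the pipeline measures:
a band of nuclei with tubular cilia, axons with varicosities and known
minimum axis distances, diffraction-limited puncta, ciliary receptor
enrichment, lifetime fields with closed-form modes, depth-attenuated
ratiometric stainings, and stimulus-locked sensor traces. All tests and
demos run against this ground truth.

## Worked example

Generate a contact scene and run the full mapping pipeline:

```python
from ciliaxis import synth, contacts as ct, segmentation as sg

mc, truth = synth.make_contact_scene(seed=1)        # 5 channels, 0.189 um iso

cil = sg.close_and_filter(sg.otsu_mask(mc["cilia"]), 0.4, 0.05)
axn = sg.close_and_filter(sg.otsu_mask(mc["axon"]), 0.4, 0.05)
nuc = sg.close_and_filter(sg.otsu_mask(mc["nuclei"]), 0.4, 0.5)

table = ct.build_cilium_table(
    ct.skeletonize_instances(cil), ct.skeletonize_instances(axn),
    sg.select_layer(nuc, 1.5), sg.nucleus_centers(nuc), cilia_mask=cil,
)
active = table[~table.excluded]
print(len(active), "cilia,",
      f"{ct.percent_of(int(active.contacting.sum()), len(active))}% contacting,",
      f"median length {active.length.median():.2f} um")
print("ciliary receptor fraction:",
      round(ct.ciliary_fraction(mc["receptor"], cil), 3))
```

```
20 cilia, 35% contacting, median length 7.24 um
ciliary receptor fraction: 0.936
```

35% of cilia are axon-contacting because the generator plants that contact
rate by default; the measured minimum axis distances agree with the planted
ones to within one voxel diagonal, and the receptor fraction recovers the
planted 94% ciliary enrichment. The same scenes are available from the
shell: `ciliaxis simulate --preset contact --seed 1 --out scene/`, followed
by `ciliaxis segment ...` and `ciliaxis contacts ...` (see `ciliaxis
--help` for all subcommands: resample, unmix, flim-split, segment, orient,
contacts, puncta, radial-counts, trace, fret, flim-mode, ratio, stats).

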