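# nucdeform

Nucleosome dyad and occupancy prediction from the deformation energy of DNA.

About 147 bp of DNA wrap ~1.7 turns around the histone octamer in a
left-handed superhelix. Where nucleosomes sit along a genome — and which base
pair ends up at the dyad, the central pseudo-twofold axis — is encoded in part
in the sequence-dependent mechanics of the double helix. `nucdeform` models
nucleosome formation as *forced* bending and shearing of an elastic rod with
dinucleotide-dependent stiffness, and turns the resulting energy landscape
into dyad probabilities and occupancy tracks. It is aimed at chromatin and
regulatory-genomics researchers who want a physically interpretable,
training-free baseline for nucleosome positioning.

## The model

Each base-pair step *i* is described by six rigid-body parameters (shift,
slide, rise, tilt, roll, twist). A candidate window of odd length *L* centred
on a putative dyad must satisfy two global superhelix constraints:

* **Bend** — the phase-projected sum of roll and tilt over the window equals
  the superhelical curvature α (579° for the central 129 bp, 600° for 147 bp):
  Σᵢ [ρ(i)·cos Ωᵢ + τ(i)·sin Ωᵢ] = α, where Ωᵢ is the cumulative helical
  twist at the centre of step *i* counted from the dyad.
* **Shear** — slide and shift likewise realise the displacement *S* = 41.96 Å
  of the DNA along the superhelix screw axis.

Steps respond harmonically and independently to a uniform bending torque F_b
(and shearing force F_s): Δρ(i) = F_b·cos Ωᵢ / k_roll(i), etc. Solving each
constraint gives closed forms

    E_bend = (α − A₀)² / 2C,   A₀ = Σ (ρ₀ cos Ω + τ₀ sin Ω),
                               C  = Σ (cos²Ω/k_roll + sin²Ω/k_tilt),

and analogously E_shear with (S, slide, shift). Sequences whose intrinsically
bent steps (high positive equilibrium roll) recur every ~10 bp in phase with
cos Ω need less torque and score low bending energy — the classic rotational-
positioning signal. Equilibrium values and force constants per dinucleotide
are estimated from base-pair-step observations in protein–DNA crystal
structures: equilibria are class means (tilt/shift antisymmetrized between
complementary dinucleotides, zero for self-complementary ones) and force
constants are diagonal entries of the inverted 6×6 step covariance, with each
physical step counted exactly once.

Energies feed two thermodynamic layers: a **grand-canonical hard-rod model**
(nucleosomes as non-overlapping 147-bp rods at fugacity τ, inverse
temperature β; exact start probabilities via forward/backward dynamic
programming in log space) and a simpler **Boltzmann model** without steric
exclusion. Occupancy at a position is the footprint-window sum of start
probabilities; dyad probability is the start probability re-centred.

## Worked example

The package ships a synthetic benchmark of ten in-vitro-style sequences with
twenty planted nucleosome positions (plus a synthetic default parameter
table; see `docs/methods.md` for what these fixtures do and do not emulate).

```python
import numpy as np
from nucdeform import (packaged_benchmark, occupancy_track, energy_profile,
                       EnergyModelConfig, ThermoConfig, call_extrema, match_dyads)

sequences, dyads, table = packaged_benchmark()
ecfg = EnergyModelConfig()                      # L=129, alpha=579, S=41.96
tcfg = ThermoConfig(tau=0.35, beta=35, footprint=147, energy_channel="bend")

name = "pGUB_synth"
occ = occupancy_track(sequences[name], table, ecfg, tcfg,
                      model="grand_canonical", sequence_id=name)
calls = call_extrema(occ.dyad_prob, mode="maxima")
ref = dyads.loc[dyads.chrom == name, "start"].to_numpy()
report = match_dyads(calls, ref, tolerance=2)
print("reference dyads:", report.reference.astype(int).tolist())
print("nearest calls:  ", report.matched.astype(int).tolist())
print("within 2 bp:    ", report.n_within, "of", len(ref))

prof = energy_profile(sequences[name], table, ecfg, sequence_id=name)
k = ref[0] - prof.start_offset
print(f"bend energy at dyad {ref[0]}: {prof.bend[k]:.4f} kT/step "
      f"(profile mean {np.nanmean(prof.bend):.4f})")
```

prints

```
reference dyads: [95, 285]
nearest calls:   [95, 286]
within 2 bp:     2 of 2
bend energy at dyad 95: 0.3406 kT/step (profile mean 0.4562)
```

Both planted dyads on this two-nucleosome sequence are recovered by local
maxima of the bend-channel dyad probability (one exactly, one 1 bp off), and
the bending energy at the dyad sits well below the profile average — the
energetic signature the dyad caller exploits. The same CLI pipeline
(`nucdeform occupancy … | dyads call | dyads match`) reports 20/20 dyads
within 2 bp at a mean absolute offset of 0.2 bp over the whole benchmark.

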