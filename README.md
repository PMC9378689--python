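# putec

Quantitative structural and biochemical analysis of **put**RNA-modified RNA
polymerase elongation complexes (ECs).

The phage HK022 *put* element is a nascent-RNA *cis*-element: the folded putRNA
binds the β′ zinc-binding domain (ZBD) at the RNA exit channel of the *E. coli*
RNAP elongation complex and suppresses transcriptional pausing by holding the
enzyme in its non-swiveled, catalytically poised conformation. Characterising
that mechanism requires a set of measurements that this package implements as a
tested, reusable library for structural biologists and RNA biochemists:

- **Swivel angle** between two EC models: both structures are superposed on the
  *core module*, then the residual rigid rotation that maps the *swivel module*
  (clamp, shelf, jaw, SI3, β′ C-terminal region) of one onto the other is
  extracted; its angle θ = arccos((tr **R** − 1)/2) is the swivel angle, and its
  axis is compared with the bridge-helix axis. Per-domain Cα RMSDs and probe-atom
  displacements (e.g. the βSI2 tip) come from the same alignment.
- **Interfaces and contacts**: Shrake–Rupley solvent-accessible surface area with
  a deterministic golden-spiral point set; buried surface area in the PISA
  convention, BSA = (SASA(A) + SASA(B) − SASA(A∪B))/2; heavy-atom hydrogen
  bonds, salt bridges and cation-π contacts; in-silico base substitution with
  hydrogen-bond recounting against a binding pocket.
- **Base-pair inventory**: geometric pair detection (C1′–C1′ window, coplanarity,
  inter-base hydrogen bonds), Saenger classification (XIX/XX canonical, XXVIII
  wobble, VIII and XI A·G families), triplex flagging, RNA–DNA hybrid length and
  translocation register, helix-axis kink angles.
- **Anti-pausing assay statistic**: cytosine-calibrated paused fraction
  P = (I_p/n_C,p) / (I_p/n_C,p + I_r/n_C,r) and the relative anti-pausing
  activity of a mutant x, `1 − (P_x − P_WT)/(P_put− − P_WT)`, with SEM over
  replicates and classification (inactivating < 20 %, inert > 90 %).
- **Conservation scores**: per-reference-residue identity counts over a multiple
  sequence alignment of put sequences.
- **Transcript masses**: average/monoisotopic RNA masses from elemental
  composition (5′-triphosphate/monophosphate/OH termini) and a charge-series
  consistency deconvolution that recovers neutral masses from native-MS peak
  series.
- **Synthetic fixtures** with known ground truth for all of the above
  (`putec.synth_data`), so the whole pipeline is testable without downloads.

## Worked example

```python
import putec

fx = putec.make_two_module_model(angle=2.5, noise_sigma=0.1, seed=7)
report = putec.swivel_angle(fx.reference, fx.target, fx.domain_set)
print(f"{report.angle_deg:.3f} deg, axis vs bridge helix "
      f"{report.bridge_helix_axis_angle:.2f} deg")
```

prints

```
2.491 deg, axis vs bridge helix 0.19 deg
```

— the measured swivel angle recovers the applied 2.5° rotation to ~0.01° under
0.1 Å coordinate noise, and the rotation axis is parallel to the bridge helix,
which is the geometric signature of swiveling. The `examples/` directory holds
one short narrative script per capability (swivel measurement, base-pair
inventory, interface/contacts, assay quantification, transcript masses, and the
deposited-model reproduction); each prints its numbers with a line on what they
mean.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computations end to end from synthetic ground truth
— swivel-angle parameter recovery across angles and noise levels, surface-area
checks against the analytic sphere, duplex/triplex/hybrid inventories, the
assay round-trip, and the mass round-trip — logging a summary to stderr and
writing the result JSON to `--out`.
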