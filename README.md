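# gpcrvar

Variant characterization for heterodimeric G-protein-coupled receptors —
in particular the GABA_B receptor (GB1/GB2 heterodimer) — from molecular
dynamics trajectories and functional assay data.

When exome sequencing turns up a missense variant of unknown significance
in a receptor gene, the clinical question is not just "is it pathogenic?"
but "does it cause a gain or a loss of function?". This package implements
the analysis side of an MD-plus-pharmacology answer to that question:

1. **Segment distance profiling** — divide each subunit into named segments
   (the LB1/LB2 lobes of the Venus-fly-trap domain, individual TM helices),
   extract per-frame centre-of-mass (COM) coordinates, Gaussian-filter them
   over time, and measure inter-segment Euclidean distances
   (`gpcrvar.geometry`).
2. **Interaction occupancy** — detect per-frame side-chain salt bridges,
   hydrogen bonds and contacts of a focal residue and assemble a
   partner × frame occurrence matrix with per-partner occupancies
   (`gpcrvar.interactions`).
3. **Activation-state classification** — compare WT and variant distance
   series against each other and against the open (~41.5 Å) / closed
   (~34.5 Å) VFTD references, and call GAIN_OF_FUNCTION /
   LOSS_OF_FUNCTION / INDETERMINATE. TM helix distances take precedence:
   a gain call needs the TM6 pair significantly closer *and* the TM5 pair
   significantly further apart (the inactive→active interface switch);
   VFTD evidence is reported and flagged when discordant, never decisive
   (`gpcrvar.classify`).
4. **Dose–response pharmacology** — fit the three-parameter log-logistic
   model
   `R(c) = basal + (top − basal) / (1 + 10^(logEC50 − log10 c))`
   (Hill slope fixed at 1) to concentration–response tables, extract
   constitutive activity (basal), Emax (top) and EC50, and model 1:1
   WT/variant co-expression as a weighted curve mixture
   (`gpcrvar.pharm`).
5. **Synthetic data** — generators for trajectories with controllable
   segment separations, scripted interaction patterns, and replicate
   dose–response curves at the packaged assay parameter sets, all with
   bookkeeping ground truth, so every stage is testable without external
   downloads (`gpcrvar.synthetic`).

Structures and multi-model trajectories are read and written as PDB/mmCIF
via biotite; any adapter that yields (atom metadata, per-frame coordinates)
can feed the same pipeline.

## Worked example

`examples/01_distance_profile.py` measures the VFTD lobe distance on a
packaged synthetic trajectory (two Cα lobes generated at a 37.5 Å mean
separation, 0.5 Å rigid-body jitter, 250 frames):

```
frames analysed:        250
raw mean distance:      37.49 Å
filtered mean distance: 37.48 ± 0.20 Å
closure index:          0.57
```

The closure index places the measured separation between the inactive
(41.5 Å → 0) and active (34.5 Å → 1) references: 0.57 means the lobes sit
closer to the closed, active-like conformation — the geometric signature
of increased constitutive activity.

`examples/03_classify_variant.py` runs the classifier on synthetic WT and
variant TM trajectories with the gain-of-function geometry:

```
GB1_TM4-GB2_TM4: WT 28.12 Å → variant 30.13 Å, Δ = +2.02 Å (significant)
GB1_TM5-GB2_TM5: WT 30.08 Å → variant 32.13 Å, Δ = +2.05 Å (significant)
GB1_TM6-GB2_TM6: WT 31.97 Å → variant 29.95 Å, Δ = -2.02 Å (significant)

call: GAIN_OF_FUNCTION
```

`examples/02_interaction_occupancy.py` and `examples/04_dose_response.py`
cover the occurrence matrix and the pharmacology fits; each script prints
a line explaining what its numbers mean.

## Command line

A thin CLI wraps the pipeline for shell use:

```sh
gpcrvar simulate R212Q-inactive-VFTD --out-dir out          # synthetic PDB + bookkeeping
gpcrvar profile-distances --config config.yaml              # distance CSVs + JSON summaries
gpcrvar classify --config config.yaml                       # StateCall JSON report
gpcrvar fit-pharm curves.csv --out-dir out                  # per-replicate fits + group summary
gpcrvar profile-interactions --config config.yaml --structure t.pdb --chain B --residue 212
```

Every output embeds the configuration hash, package version and seed.

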