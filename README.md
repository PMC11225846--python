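# hilipid

Class-resolved phospholipid profiling from HILIC-ESI-FTMS data, as used to
compare mitochondrial membranes across cell lines: from centroided full-scan +
all-ion-fragmentation (AIF) runs to annotated lipid species with
isotope-corrected intensities, internal-standard concentrations, class ratios
and chemometric group comparison. A forward instrument model generates
realistic synthetic runs, so every stage can be validated against known ground
truth.

## The analysis

Hydrophilic interaction chromatography separates glycerophospholipids by head
group, so all species of one class (PC, PE, PI, CL, plus the ether subclasses
PC O and PE O) co-elute in one chromatographic band. The pipeline:

1. **Band detection** — extracted-ion chromatograms of class-diagnostic AIF
   fragments (phosphocholine *m/z* 184.0733 for PC; *m/z* 196.0380 for PE;
   241.0119 for PI; 152.9958 for CL) locate each class band; MS1 scans inside
   the band are averaged into one class spectrum.
2. **Annotation** — averaged peaks are matched, within 0.05 *m/z*, against a
   generated target list of sum compositions C:D (total side-chain carbons :
   double bonds), ionized as [M+H]⁺ (PC), [M−H]⁻ (PE, PI) or [M−2H]²⁻ (CL).
   Species below 1% of the endogenous base peak are discarded.
3. **Isotopic corrections** — co-eluting species of one class that differ by
   one C=C bond are 2 Da apart, so the M+2 isotopologue of the more
   unsaturated species overlaps the monoisotopic (M+0) peak of its ΔD = 1
   neighbour. Processing each (subclass, C) group in descending D, the
   *type-II* correction subtracts `corrected_M0(D) · f₂(D)/f₀(D)` from the
   M+0 of the D−1 member; the *type-I* correction then rescales each clean
   M+0 to the whole isotope pattern by dividing by the monoisotopic fraction
   f₀ computed from the species' elemental formula.
4. **Quantification** — one deuterated internal standard per class, spiked at
   3 μg/ml, converts corrected intensities to concentrations:
   `conc = total(species)/total(IS) × 3 μg/ml`. Class totals yield the five
   comparison ratios PE/PC, PI/PC, CL/PC, PC O/PC and PE O/PE (diacyl
   denominators).
5. **Statistics** — per-class relative abundance profiles are filtered at 20%
   RSD across extraction replicates, autoscaled, and summarized by PCA (with
   95% confidence ellipses per cell line) and UPGMA hierarchical clustering on
   Euclidean distances; class ratios are compared across lines with a post hoc
   Tukey HSD test (stars at P < 0.01 / 0.005 / 0.001).

The synthetic-data module plants known group effects (reduced ether-lipid
incidence and increased unsaturation in fusion-deficient lines, loss of
72-carbon cardiolipins outside WT) and renders them into centroided scans with
isotope patterns, band profiles, coelution-driven M+0/M+2 interference, ppm
mass error and intensity noise.

## Worked example

```python
import hilipid as hp

cfg = hp.PipelineConfig(outdir="demo_out", seed=1)   # 3 lines x 3 bio x 3 extracts
result = hp.run_pipeline(cfg)

print(result.quant.ratios.groupby("cell_line")[
    ["PE/PC", "PI/PC", "CL/PC", "PC O/PC", "PE O/PE"]].mean().round(3))
```

```
           PE/PC  PI/PC  CL/PC  PC O/PC  PE O/PE
cell_line
MFN12_KO   0.780  0.146  0.231    0.242    0.339
OPA1_KO    0.808  0.153  0.280    0.401    0.599
WT         0.811  0.150  0.317    0.514    0.915
```

The recovered ratios sit within a few percent of the planted ground truth
(WT CL/PC planted at 0.30, recovered 0.317 on this seed; the PE O/PE gradient
0.90 → 0.60 → 0.35 is recovered as 0.92 → 0.60 → 0.34). The Tukey table flags
every pairwise PE O/PE difference at P < 0.001:

```
  ratio  group_a group_b  mean_difference  p_value stars
PE O/PE MFN12_KO OPA1_KO        -0.259722 0.000002   ***
PE O/PE MFN12_KO      WT        -0.576459 0.000000   ***
PE O/PE  OPA1_KO      WT        -0.316737 0.000001   ***
```

and the per-class PCA explains 80–86% of variance in the first two
components, with the three lines forming separate clusters for PC, PE and PI
profiles (the two knockouts overlap for CL, whose discriminating feature —
72-carbon species — is exclusive to WT).

The same pipeline is exposed as a CLI with isolated, re-runnable stages:

```bash
hilipid all -o demo_out --seed 1          # simulate -> detect -> annotate -> quantify -> stats
hilipid stats -o demo_out                 # re-run one stage from the previous stage's files
```

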