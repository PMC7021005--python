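# mlctip

An in-silico study of how the multileaf-collimator (MLC) **leaf-tip model** in
a treatment planning system (TPS) perturbs IMRT/VMAT dose, and whether
patient-specific QA — gamma analysis on a diode array — can detect such
modeling errors.

## Who this is for

Medical physicists and QA researchers who want a fully synthetic, reproducible
sandbox for the question: *if the TPS's MLC leaf-tip parameters are wrong, how
much does the calculated dose move, and would routine IMRT QA catch it?*
Everything is generated in-package — plans, phantom, dose, measurements — so
the sensitivity and detectability analyses run anywhere in minutes, with no
commercial TPS or hardware.

## The model

The leaf end is a **double step** in transmission.  With leaf-tip offset
δ (mm), leaf-tip width w (mm) and intraleaf transmission T, a leaf whose
nominal tip sits at position x₀ transmits, along the leaf-travel axis x:

```
           1      in the open field        (x beyond the effective tip)
  t(x) =   τ      for the tip region of width w under the leaf end
           T      deeper under the leaf
```

where the effective tip is the nominal tip retracted outward by δ (so a
positive δ enlarges the effective field; each bank retracts, so +1 mm of δ
widens a gap by 2 mm), and τ = √T by default (a true double step with
T < τ < 1; τ = T is available via `tip_rule="intraleaf"`).  A leaf pair
combines as the pointwise minimum of its two single-leaf profiles.

Around this core:

* a two-Gaussian convolution dose engine (sharp primary + broad scatter)
  with exponential depth attenuation in a cylindrical phantom;
* a synthetic nine-plan suite — five step-and-shoot IMRT plans (7/7/7/9/9
  beams) and four arc plans (2/2/2/3 full arcs), total MU 1469–2114 —
  conformal to two PTVs with the posterior spinal cord blocked, plus seeded
  random modulation;
* four TLD-like ROIs (PTV1 center, PTV1 periphery, PTV2, spinal cord), the
  latter two pairs sitting in low- and high-dose-gradient regions;
* a virtual planar diode array (10 mm pitch, 0.5 % Gaussian noise) with a
  full global-gamma implementation (γ via dose difference ΔD % of the
  reference maximum, distance-to-agreement Δd, 10 % low-dose threshold) and
  a brute-force oracle;
* tie-aware trapezoidal ROC/AUC over gamma pass rates, where comparisons
  against the clinical model (δ = −0.5 mm, w = 4.5 mm) are negatives and
  comparisons against perturbed models are positives.

The default study recalculates all nine plans on a grid of 27 beam models
(offsets −2.0 … +2.0 mm in 0.5 mm steps × widths 2.5/4.5/6.0 mm).  A second
published width triple (2.0/4.5/6.5 mm) appears in some summaries of this
design; the Methods values (2.5/4.5/6.0) are the default here and the other
triple is available through `StudyConfig(widths_mm=(2.0, 4.5, 6.5))`.

## Worked example

```python
>>> from mlctip import BeamModelParams, LeafPairAperture, effective_edges
>>> clinical = BeamModelParams(leaf_tip_offset_mm=-0.5, leaf_tip_width_mm=4.5)
>>> pair = LeafPairAperture(0, -2.5, 2.5, left_pos_mm=-10.0, right_pos_mm=10.0)
>>> effective_edges(pair, clinical)          # each tip retracts by delta
(-9.5, 9.5)
>>> clinical.tip_transmission                # tau = sqrt(T), T = 0.005
0.07071067811865475
```

The analysis itself is a sequence of thin drivers:

```bash
python analysis/01_generate_plans.py     # writes results/plans/
python analysis/02_sensitivity.py        # 9 plans x 27 models -> results/sensitivity.csv
python analysis/03_qa_detectability.py   # virtual QA + ROC -> results/roc_summary.csv
python analysis/04_report.py             # figures
```

On the default seed, `02_sensitivity.py` prints:

```
Max |%dD| over the offset sweep (clinical width):
SpinalCord       99.6
PTV1_periphery   28.6
PTV1_center       7.7
PTV2              5.4

Open-field central-axis sensitivity: 0.0169 %/mm of offset, vs 28.76 %/mm for
the spinal-cord ROI (1703x larger) — leaf-tip model errors hide in open-field checks.
```

i.e. a ±2 mm offset error moves the spinal-cord TLD dose by up to ~100 %
while an open field barely notices, and the high-gradient ROIs (cord, PTV1
periphery) dominate the low-gradient ones.  `03_qa_detectability.py` prints:

```
AUC by offset deviation from the clinical model:
criteria             2%/2mm  3%/3mm
 0.5                  0.551   0.501
 1.0                  0.825   0.503
 1.5                  1.000   0.801
 2.0                  1.000   0.997
```

AUC near 0.5 means the gamma pass rate carries almost no information: a
0.5 mm leaf-tip offset error — already worth several percent of TLD dose —
is essentially invisible to array QA at either criterion.

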