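# ftirdeconv

FTIR band deconvolution for bread model systems: protein secondary
structure from the amide I band, starch order from the fingerprint region,
and the replicate statistics that compare treatments.

## The problem

Bread staling and dough quality are governed by the conformations of the
two major wheat biopolymers. In gluten, the balance of α-helices, β-turns
and β-sheets sets the viscoelasticity of the network; in starch,
retrogradation (re-crystallization of gelatinized starch during storage)
firms the crumb. Both can be followed by infrared spectroscopy:

* The **amide I band** (1600–1700 cm⁻¹, mainly backbone C=O stretching) is
  a sum of heavily overlapping sub-bands, one per secondary-structure
  class. Deconvolving it yields the **relative peak area** (RPA) of each
  class — a band's fitted area as a percentage of the total fitted area.
  Window assignments on the wavenumber axis: intermolecular β-sheet
  [1620, 1640), α-helix [1650, 1660), β-turn [1660, 1680), intramolecular
  β-sheet [1680, 1695); centers in the gaps count as unassigned
  (random coil / side chains).
* The **1047/1022 cm⁻¹ height ratio** of the starch fingerprint compares
  ordered (crystalline) to amorphous starch and rises as starch
  retrogrades.

This package implements the full analysis chain for model systems of
inulin + gluten + starch + polyols (glycerol, sorbitol, propylene glycol),
plus a synthetic-spectrum generator with exact ground truth so every
inference stage can be validated without measured data.

## The model

Each sub-band is an additive pseudo-Voigt (Gaussian–Lorentzian mix)

```
f(ν) = h · [ η·L(ν; ν₀, w) + (1−η)·G(ν; ν₀, w) ]
area  = h · w · [ η·π/2 + (1−η)·(1/2)·√(π/ln 2) ]
```

with center ν₀, height h, common FWHM w and Lorentzian fraction
η ∈ [0, 1]. The number and positions of bands are initialized from the
minima of the vector-normalized Savitzky–Golay second derivative
(resolution enhancement); the band set is then refined by bounded
trust-region least squares, adding one band at the largest positive
residual while each addition still materially reduces the residual sum of
squares. Preprocessing follows the conventional conditioning chain:
replicate averaging → resampling to a uniform 1 cm⁻¹ grid → least-squares
component subtraction → multipoint linear baseline correction.

Treatment groups (n = 3 replicates, completely randomized design) are
compared by one-way ANOVA followed by Duncan's multiple range test with a
compact letter display; the pooled SEM is √(MSE/n).

## Worked example

```python
import ftirdeconv as fd

# a noise-free amide I composite with known class fractions (percent of
# total band area, in band order 1627/1645/1654/1670/1685 cm-1)
spec, truth = fd.generate_amide_i([36.58, 3.01, 19.56, 31.30, 9.55])
fit, profile = fd.analyze_amide(spec, anchors=None)
print(fit.summary())
print(profile.as_dict())

# a starch fingerprint with a prescribed 1047/1022 order ratio
fp, _ = fd.generate_fingerprint(1.109)
print(fd.analyze_starch(fp))
```

prints (abridged):

```
Gaussian-Lorentzian band fit
  region: 1600-1700 cm-1   bands: 7
  R^2: 1.000000   RMSE: 6.790e-13 AU   converged: True

 center_cm-1  height_au  fwhm_cm-1    eta   area
   1627.0000     0.1388    20.0000 0.5000 3.6580
   1645.0000     0.0114    20.0000 0.5000 0.3010
   ...
{'intermolecular_beta_sheet_pct': 36.58, 'alpha_helix_pct': 19.56,
 'beta_turn_pct': 31.30, 'intramolecular_beta_sheet_pct': 9.55,
 'unassigned_pct': 3.01}
StarchOrderResult(h1047=0.5545, h1022=0.5, ratio=1.109)
```

The fit recovers every class fraction the generator prescribed
(the two zero-height bands the iteration proposed and discarded carry no
area), and the fingerprint ratio is reproduced exactly.

A full directory-of-spectra run is driven by the CLI:

```
ftirdeconv synth fingerprint --ratio 1.109 --out control_d0_r1.csv
ftirdeconv run --config run.yaml       # manifest CSV + YAML over defaults
```

which writes per-sample fitted band tables, the ratio and RPA tables, and
per-day Duncan letter tables.

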