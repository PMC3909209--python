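# copetrend

Decadal and seasonal change in two Northeast U.S. shelf copepods —
*Calanus finmarchicus* and *Centropages typicus* — analysed as a tested,
reusable pipeline.  Bi-monthly abundance series per sub-region (Gulf of
Maine, Georges Bank, Southern New England, Mid-Atlantic Bight) are
decomposed into a Kalman-filtered local trend and a deterministic
trigonometric seasonal cycle; annual peak abundance and peak timing are
read from the fitted series; an altimetry-style alongshore-transport index
and a PCA-weighted Gulf Stream North Wall Index (GSNWI) are constructed;
and the biological and physical series are related by ordinary
least-squares regression.  A synthetic-data module with known ground truth
stands in for the survey and altimetry downloads, so every stage is
verifiable at desk scale.

## The model

For each species × region series \(y_t\) (one value per two-month bin,
six bins per year):

```
y_t   = mu_t + gamma_t + eps_t,        eps_t ~ N(0, sigma_eps^2)
mu_t  = phi * mu_{t-1} + eta_t,        eta_t ~ N(0, sigma_eta^2),  phi in (0, 1]
gamma_t = sum_{j=1,2} [ a_j cos(2 pi j t / 6) + b_j sin(2 pi j t / 6) ]
          + a_3 cos(pi t)
```

`phi = 1` recovers a random-walk trend.  The likelihood is evaluated by a
Kalman filter that skips missing bins, the five seasonal coefficients are
concentrated out by GLS on the filter innovations, and
`(phi, sigma_eta^2, sigma_eps^2)` are maximised numerically from several
starts; smoothed components come from the fixed-interval smoother.  The
transport index is the mean northward velocity over four 1/3° cells at
39.3°N (six cells within 2° of the coast, the two nearest the coast
discarded); the GSNWI is the first-principal-component-weighted average of
the six standardized north-wall latitude series (79, 75, 72, 70, 67,
65°W).

## Worked example

Run the numbered analysis scripts in order (they share `scratch/data/` and
write their tables under `results/`):

```
python analysis/01_simulate.py        # synthetic world, seed 1
python analysis/02_bin_series.py      # bi-monthly series per species x region
python analysis/03_fit_decomposition.py
python analysis/04_phenology.py
python analysis/05_forcing.py
python analysis/06_associations.py
python analysis/07_verification.py
```

`04_phenology.py` prints the era cross-tabulation of annual peak timing
(bins 1-6 are Jan-Feb ... Nov-Dec):

```
modal peak bin by era (split at 1985 ):
  CFIN GB: early mode bin 3, late mode bin 3
  CFIN GOM: early mode bin 3, late mode bin 3
  ...
  CTYP MAB: early mode bin 6, late mode bin 1
  CTYP SNE: early mode bin 6, late mode bin 6
```

*C. finmarchicus* peaks in May-June (bin 3) everywhere; the Mid-Atlantic
Bight *Cen. typicus* peak moves from Nov-Dec to Jan-Feb after 1985 — the
phenology shift that the generator builds in and the fitted series
recover.  `06_associations.py` prints the GSNWI ~ alongshore-velocity
regression at both timescales:

```
timescale   n   slope       r     p
bimonthly 108 -0.2772 -0.7025 0.000
   annual  18 -0.2761 -0.7090 0.001
```

The negative slope reflects the generator's negative coupling between the
north-wall position and the alongshore flow: a southward-displaced Gulf
Stream goes with stronger southward shelf transport.

The same pipeline runs from a single command and config:

```
copetrend run-all --seed 1 --outdir out/
```

or stage by stage (`copetrend simulate|bin|fit|peaks|forcing|associate`).
Supplying `samples_path` / `northwall_path` / `velocity_path` in a YAML
config replaces the simulated inputs with real tables in the same layout.

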