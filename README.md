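# pulsepore

Analysis tools for pulsed-electric-field (PEF) electroporation and
electrofusion experiments, and for the membrane configurations that explain
them.

When cells are exposed to electric pulses, nanometre-scale aqueous pores open
in the plasma membrane. Small pores admit the dye YO-PRO-1 (YP); only larger
pores admit propidium iodide (PI); and two adjacent electroporated cells can
merge (electrofusion). `pulsepore` answers two questions about such data:

1. **Which kind of pore drives fusion?** A partial least squares (PLS)
   regression relates the YP-positive and PI-positive cell fractions
   (predictors X) to the measured cell fusion rate (response y) across pulse
   conditions, with repeated-split and Y-scrambling validation to show the
   model is not a chance correlation.
2. **What do the membranes look like?** For particle configurations of a
   hydrated bilayer (positions, charges, species labels, periodic box), the
   package computes the charge-density profile ρ(z) along the membrane
   normal, the electrostatic potential φ(z) by double integration of the
   Poisson equation, the transmembrane potential Δφ, the inter-leaflet water
   volume, and the number and size of pores via periodic connected-component
   labeling.

A synthetic-data module generates every input with known ground truth —
idealized bilayers with planted cylindrical pores, charged-slab frames with a
closed-form potential, and a generative PEF→(YP, PI)→fusion dataset — so the
whole pipeline is testable by parameter recovery.

## The model

PLS decomposes the autoscaled predictor and response blocks into shared
latent components,

    X = T P′ + E,    Y = U C′ + G,    Y = T C′ + F,

where T, P are the X scores and loadings, U, C the Y scores and weights, and
E, G, F residuals. Components are extracted by NIPALS with deflation; for a
single response the first weight vector is w = X′y / ‖X′y‖. Model quality is
summarised by R² on training rows, both held-out R² definitions
(1 − SSres/SStot and the squared Pearson correlation), and the leave-one-out
Q² = 1 − PRESS/SStot.

The electrostatic potential along the membrane normal follows from the
charge-per-slice density by

    φ(z) = −(1/ε₀) ∬₀^z ρ(z″) dz″ dz′,

in reduced units (ε₀ = 1, charge in e, length in nm) with the gauge
φ(0) = 0 at the lower box edge.

## Worked example

The package ships a 12-sample reference table (8 training / 4 test rows)
spanning pulse widths 200 ns – 40 µs and strengths 0 – 2.4 kV/cm:

```python
>>> import pulsepore as pp
>>> table = pp.load_reference_table()
>>> model = pp.fit_table(table, n_components=1)
>>> model.W[:, 0]           # first-component weights (YP, PI)
array([0.51643301, 0.85632759])
>>> pp.predict(model, table.select_ids(["W_40us_E_2.4_"]))
array([13.48955969])
>>> stats = pp.fit_stats(model, table)
>>> round(stats.r2_train, 3), round(stats.r2_test_corr, 3)
(0.672, 0.749)
```

The PI weight (0.86) exceeding the YP weight (0.52) says that large-pore
formation contributes more to fusion than small-pore formation. The sample
with the strongest, longest pulse (YP = 90 %, PI = 82 %) is predicted to fuse
at 13.49 %; the one-component model explains 67 % of the training variance.

Validation from the shell:

```bash
$ pulsepore validate --out out/ --n-repeats 500 --n-perm 500 --seed 0
mean r2_train=0.707 ± 0.064
```

Membrane metrics on a synthetic frame with one planted 1 nm pore:

```python
>>> frame, truth = pp.make_bilayer_frame(pp.BilayerSpec(pores=[((4, 4), 1.0)], seed=12))
>>> bounds = pp.leaflet_bounds(frame)      # ≈ (4.0, 7.0) nm
>>> pp.interleaflet_water_volume(frame, bounds)
(314, 9.42)
>>> pp.count_pores(frame, bounds).n_pores
1
```

314 water molecules sit between the leaflets, i.e. a pore volume of 9.42 nm³
— the analytic cylinder volume π·1.0²·3.0 ≈ 9.42 nm³.

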