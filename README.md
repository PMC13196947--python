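# contourdensity

Structural monitoring of agricultural landscapes from single-band satellite
reflectance. When fields are abandoned — through depopulation, conflict, or
economic collapse — their spectral signature can stay deceptively stable
while the *structure* of the landscape decays: field boundaries blur,
roads and shelterbelts disappear, the managed mosaic dissolves into a
homogeneous succession landscape. This package quantifies that decay
directly from the density and contrast of object contours in imagery such
as Sentinel-2 L2A band 4 at 10 m, without training data or field masks,
which makes it usable where ground access is impossible (war zones,
disaster areas, occupied territories).

## Method

1. **Gradient-preserving contour extraction.** A Canny chain — Gaussian
   smoothing (σ = 1 px), Sobel gradient, non-maximum suppression, thinning,
   hysteresis (levels 0.9/0.5) — is applied to the contrast-stretched band,
   but the final binarization is replaced by retention of the gradient
   amplitude `G[i,j]` at accepted edge pixels (zero elsewhere). The
   amplitude carries the *contrast* of each boundary, which is exactly what
   fades under abandonment.
2. **Contour Density Indicator.** The CDI is the sliding-window mean of `G`
   over a centered M × N window (2 × 2 km for regional maps, 200 × 200 m
   for detail):

   `CDI[i,j] = (1 / MN) · Σ_m Σ_n G[i+m, j+n]`

3. **Cross-date normalization.** Acquisition conditions shift CDI levels
   between dates. Stable areas — pixels where two dates' CDI maps are
   locally Pearson-correlated above r = 0.95 — yield a correction factor
   `k = CDI_avg(1) / CDI_avg(2)` that rescales the later map before any
   comparison.
4. **Change analysis.** Change maps `ΔCDI = CDI_t2 − CDI_t1`, per-zone
   histogram modes, and the normalized mode change
   `dmCDI = (CDI_mode(t2) − CDI_mode(ref)) / CDI_mode(ref)` (negative =
   degradation, positive = recultivation), plus a random-point experiment
   correlating CDI loss with distance to a frontline.

A synthetic-scene generator (Voronoi field mosaic, shelterbelt/road grid,
settlements, boundary-blurring degradation operator, radiometric gain and
noise) makes the whole pipeline testable end to end without downloads.

## Worked example

Generate a synthetic 3-date series (a 5.12 km scene whose "frontline" band
degrades over time while global gain drifts), then run the pipeline:

```sh
cdi fixtures --out demo --seed 1
cdi cdi    --config demo/config.yaml
cdi change --config demo/config.yaml
```

which prints (per date: recovered correction factor and scene mode, then
the per-zone table):

```
2020: k=1.0000 mode=0.10650
2022: k=1.2310 mode=0.08650
2024: k=1.4217 mode=0.09250
      zone year   mode     dmcdi      n
    Area 1 2020 0.1005       NaN  98304
    Area 1 2022 0.0915 -0.089552  98304
    Area 1 2024 0.0895 -0.109453  98304
    Area 2 2020 0.1075       NaN  65536
    Area 2 2022 0.0795 -0.260465  65536
    Area 2 2024 0.0575 -0.465116  65536
    Area 3 2020 0.0845       NaN  98304
    Area 3 2022 0.0865  0.023669  98304
    Area 3 2024 0.0925  0.094675  98304
Study Area 2020 0.1065       NaN 262144
Study Area 2022 0.0865 -0.187793 262144
Study Area 2024 0.0925 -0.131455 262144
```

The 2024 scene was rendered with a global gain of 0.9 on top of the 2022
drift; the k values recover that drift. Area 2 — the synthetic frontline
buffer, where boundary blurring is strongest — shows the deepest mode
decline (dmCDI = −0.47 by 2024), while the flanking zones move an order of
magnitude less: the indicator attributes the structural loss to the right
zone. `cdi proximity --config demo/config.yaml --year 2024` then reports
the distance/ΔCDI correlation of 1000 random points (r = 0.957 under the
signed ΔCDI convention, i.e. loss shrinking with distance from the line).

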