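# hemianet

EEG functional-connectivity network analysis for hemianopia after
occipital stroke — band-limited **imaginary coherence** between atlas
regions, **graph-theoretic network measures** under proportional
thresholding, lobe-level coherence profiles in a lesioned/intact-
hemisphere frame, behavioral **responder classification**, the
accompanying statistics (mixed-design ANOVA with Greenhouse–Geisser
correction, Tukey–Kramer post-hoc, Pearson, Mann–Whitney z), and a
**synthetic oscillatory cohort simulator** with known ground truth so
that every estimation stage has a parameter-recovery test.

It is written for researchers who analyze resting-state EEG of stroke
or low-vision cohorts and want a reproducible, testable version of this
analysis chain, from region-level time series to statistical tables.

## The method in brief

Connectivity between regions i and j is the band-averaged magnitude of
the imaginary part of the epoch-accumulated coherency,

    icoh_ij(band) = mean_{f in band} | Im( Σ_n S_in(f) S*_jn(f)
                    / sqrt(Σ_n |S_in(f)|² · Σ_n |S_jn(f)|²) ) |

with Hann-tapered spectra of 2-s epochs (0.5 s overlap). Zero-lag
mixing of sources — volume conduction — yields a purely real coherency,
so icoh rejects spurious instantaneous connectivity by construction.
On each K × K band matrix the pipeline computes node strength (weighted)
and, after keeping the top 30 % of edges, the clustering coefficient
C = (1/n) Σᵢ 2tᵢ/(Kᵢ(Kᵢ−1)), the characteristic path length L (node mean
of average shortest-path distances), and betweenness centrality.
Patients are classified as responders when their visual-field (FOV)
percentage change from baseline is positive.

## Worked example

Inject a known alpha-band coupling at increasing strength and recover
it (`examples/coupled_pair_recovery.py`):

```text
alpha-band oscillator at 9.0 Hz, lag 27.8 ms
 injected  estimated icoh
      0.0           0.117
      0.2           0.309
      0.4           0.488
      0.6           0.658
      0.8           0.822
      1.0           0.989
```

The estimate tracks the injected strength almost linearly; the value at
strength 0 is the finite-epoch noise floor (order 1/√N). The
volume-conduction contrast (`examples/volume_conduction.py`) shows why
the imaginary part matters — two *independent* but instantaneously
mixed sources:

```text
independent sources, instantaneous mixing, 199 epochs
ordinary coherence |coh|^2 : 0.778   (spurious connectivity)
imaginary coherence       : 0.024
independent-noise null 95%: 0.064   (icoh stays below)
```

The behavioral module reproduces the packaged 24-patient table
(`examples/behavioral_table.py`):

```text
cohort of 24 patients; selected summary means:
  lesion_age_months     40.95 (SD 39.21)
  hrp_black_pre        163.70 (SD 51.68)
  fov_pre               25.41 (SD 2.22)
  fov_post              26.08 (SD 2.18)
  age_years             57.37 (SD 10.56)

responders (FOV % change post vs pre > 0): 10
non-responders:                            14
```

`examples/graph_metrics.py` walks one simulated subject from recording
to thresholded-graph measures, and `examples/full_pipeline.py` runs the
whole chain (simulate → condition → connectivity → graph/lobe metrics →
responders → statistics) on a desk-scale cohort, printing among other
things the correlation between FOV change and alpha-band characteristic
path length — negative under the default injected effects, i.e. larger
visual-field gains go with a shorter-path (more efficient) network.

The same stages are exposed as a thin CLI:

```bash
hemianet behavior summarize
hemianet behavior responders
hemianet simulate --out sim --seed 3 --n-per-group 2 --duration 60 --fs 250
hemianet connectivity sim/s01_pre.csv --band Alpha1 --out m.csv
hemianet graph m.csv --threshold 0.30 --out metrics.csv
hemianet topology m.csv --lesion-side left --out lobes.csv
hemianet run --out out/run1 --seed 0
```

## Layout

```
src/hemianet/     bands, recording, io, preprocess, connectivity, graph,
                  atlas, behavior, stats, simulate, pipeline, cli
src/hemianet/data AAL-90 lobe table, packaged patient table
examples/         one narrative script per capability
tests/            unit + property tests, brute-force graph oracles,
                  Monte-Carlo calibration, acceptance suite
docs/methods.md   model, assumptions, parameter choices, limitations
```
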