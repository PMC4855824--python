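# eitzones

Bedside electrical impedance tomography (EIT) monitors regional lung
aeration as a stream of reconstructed relative-impedance images (here
32×32 pixels at 40 frames/s). During an incremental PEEP trial in injured
lungs, the clinically important question is *where* the lung is
overdistending, *where* alveoli are cyclically collapsing and reopening
with each breath, and *where* previously airless tissue has been
recruited. `eitzones` answers this with a pixel classification built from
two thresholded images per PEEP step, for intensivists and researchers
analysing EIT PEEP titrations.

## Method

For each PEEP step the final five breaths are located on the global
impedance waveform; the five end-inspiratory and five end-expiratory
frames are averaged, and the **tidal image** is their difference:

```
tidal = end_insp − end_exp
```

Two lung regions follow from thresholds relative to each image's own
maximum (strict inequality; the end-expiratory threshold is 5 % higher
because end-expiratory images are noisier than difference images):

```
lung_EE(p)    ⇔  end_exp(p)  >  0.25 · max(end_exp)     (aerated lung)
lung_TIDAL(p) ⇔  tidal(p)    >  0.20 · max(tidal)       (ventilated lung)
```

The functional categories are pure set algebra:

| category | definition | meaning |
|---|---|---|
| overinflated | `lung_EE \ lung_TIDAL` | holds air at end-expiration but no air moves in or out |
| cyclic (tidally recruited/derecruited) | `lung_TIDAL \ lung_EE` | ventilated but airless at end-expiration: collapses and reopens each breath |
| recruited | `lung_EE \ lung_EE(reference)` | aerated now but not at the reference PEEP (default 6 cmH2O) |

Counts are reported as percentages of the **total lung pixels** — the
size of `lung_EE` at the highest PEEP step — and steps from 9 cmH2O
upward form the primary result table. A labelled synthetic phantom
(tidal oscillations on PEEP-dependent aeration, with overdistending,
recruitable, cyclically collapsing and non-lung pixel archetypes plus
Gaussian sensor noise) exercises every stage end to end with known
ground truth.

## Worked example

```python
import eitzones as ez

config = ez.PhantomConfig(noise_sd=0.05, seed=1)      # 10 % sensor noise
sequences, truth = ez.generate(config)
result = ez.analyze_trial(sequences)

print(ez.percentages(result).to_string(index=False, float_format=lambda v: f"{v:5.1f}"))
print("total lung pixels (highest PEEP):", result.total_lung_pixels)
```

prints

```
 peep_cmH2O  overinflated_pct  cyclic_pct  recruited_pct
        9.0               0.4        20.1           10.4
       12.0               2.6        14.6           19.9
       15.0               5.7         9.7           24.7
       18.0               9.7         4.9           33.6
       21.0              13.7         4.9           36.6
       24.0              18.5         4.9           38.9
       27.0              18.5         4.9           38.9
       30.0              18.5         4.9           39.3
total lung pixels (highest PEEP): 453
```

Reading the table: as PEEP climbs from 9 to 30 cmH2O the overinflated
fraction of the lung grows from 0.4 % to 18.5 % (the non-dependent
archetype bands successively stop ventilating), recruitment rises to
39 % of the lung (dependent rows open above their graded opening
pressures), and tidal collapse/reopening falls from 20 % to a residual
4.9 % band that cycles throughout the studied range.
`ez.save_map(result.step(9.0), "map_09.png")` renders the step in the
conventional display — overinflated white, cyclic red, recruited blue,
lung outline yellow — with the percentages printed beneath the map.

The same pipeline is scriptable from a shell:

```sh
eitzones simulate --noise-sd 0.05 --seed 1 --out sim/
eitzones analyze --steps sim/ --reference-peep 6 --out out/
eitzones render --trial out/trial.json --peep 9 --out map_09.png
eitzones stats --trial out/trial.json --ancillary physiology.csv \
               --category recruited --variable pao2_fio2
```

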