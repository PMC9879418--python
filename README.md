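# paleodraught

Quantitative osteology for identifying **draught cattle** in
zooarchaeological assemblages. The package is written for
zooarchaeologists and archaeology data scientists working with tabular
bone-specimen records (one row per specimen, von den Driesch measurement
codes) who want the standard traction-detection toolkit as tested,
scriptable code rather than spreadsheet arithmetic.

## What it computes

**Pathological index on first phalanges.** Five draught-related foot-bone
features are scored per phalanx: proximal exostosis (*pex*), distal
exostosis (*dex*) and proximal lipping (*plip*) on an ordinal 1–4 scale
(1 = no pathology), and osteoarthritis on the proximal and distal
articular surfaces (present/absent, coded 1/2). The pathological index is
the normalised sum

$$\mathrm{PI} = \frac{\sum_f (s_f - 1)}{\sum_f (\max_f - 1)} \in [0, 1],$$

and the modified index (MPI) omits *dex*, which tracks age rather than
workload. Because draught work loads the hindlimb preferentially, the
posterior-minus-anterior contrast of mean MPI (with a seeded percentile
bootstrap interval) is the herd-level traction signal.

**Metapodial traction index.** e/D1, the remodelling/extension ratio of
the distal medial condyle; values **≥ 0.75** (inclusive) are consistent
with traction.

**Osteometric sexing and withers height.** Distal-breadth thresholds
(Bd < 63 mm cow, > 65 mm bull, between ambiguous) and the gracility index
SD/GL × 100 read jointly with greatest length (gracility < 17 cow, 17–20
bull; GL > 215 mm with gracility 15–17.5 flags an early-castrated male —
an ox, the classic draught animal). Withers height is GL × an element- and
sex-specific factor / 10 (cm).

**Kill-off profile.** Grant mandible-wear stages map through an editable
age-class scheme; per-class MNI uses max(left, right) with unknown-side
overflow, and the profile is the distribution of class MNIs.

**Synthetic assemblages.** A generative herd model (cumulative-logit
ordinal pathology, dimorphic measurements, beta-scaled e/D1 signal,
taphonomic censoring) produces assemblages with known ground truth, so
every stage — and the full pipeline — is testable without excavated
material.

## Worked example

```python
from paleodraught import (HerdConfig, TaphonomyConfig, generate_assemblage,
                          TractionAnalysis)

cfg = HerdConfig(n_individuals=58, seed=0)     # 30% of adult males worked
assemblage, truth = generate_assemblage(cfg, TaphonomyConfig())
results = TractionAnalysis(assemblage).fit(seed=0)
print(results.summary())
```

```
Draught-cattle osteological analysis
====================================================================
Site: synthetic-herd                 Specimens: 968
Seed: 0   Config hash: 44f0fdf8320d768a   paleodraught 0.1.0

Pathological index on first phalanges
--------------------------------------------------------------------
limb            n     mean PI    mean MPI
anterior       58       0.085       0.073
posterior      58       0.122       0.103
Hindlimb MPI bias (post - ant): +0.0302  95% CI [-0.0194, +0.0797] (includes 0; 2000 bootstrap replicates)

Traction index e/D1 on 155 fused metapodials: 19 at or above threshold
Sexing (gracility method): {'female': 82, 'male': 46, 'castrate_candidate': 20, 'ambiguous': 7}
Withers height range: 103.8-140.4 cm

Kill-off profile (mandible MNI = 32; element-based MNI = 48)
--------------------------------------------------------------------
0-1 m           1      3.1%
1-8 m           1      3.1%
8-18 m          4     12.5%
18-34 m         3      9.4%
34-43 m        17     53.1%
3.4-6.5 y       2      6.2%
6-11 y          3      9.4%
7-20 y          1      3.1%
```

Reading it: both limbs contribute 58 scored phalanges; the posterior mean
MPI (0.103) exceeds the anterior (0.073) — the direction expected when
part of the herd works — but at 58 individuals the bootstrap interval
still includes zero (at 200 individuals it does not; see the tests).
19 of 155 fused metapodials carry a condyle ratio at or above 0.75, the
sexing resolves cows/bulls plus castrate candidates, and the kill-off
concentrates at the 34–43-month meat optimum with a minority kept into
adulthood. `results.to_json()`, `results.save(outdir)` and the per-section
DataFrames (`results.synthesis_table`, `results.killoff.to_frame()`, …)
expose everything programmatically.

The same pipeline runs from a shell:

```sh
paleodraught simulate --out sim --seed 21
paleodraught analyze --input sim/assemblage.csv --out analysis --seed 3
paleodraught validate --input sim/assemblage.csv
```

Real data enter through `TractionAnalysis.from_csv("specimens.csv")` (see
the canonical column set in `paleodraught.io.COLUMNS`; a `column_map`
renames other layouts). Thresholds, withers factors, the index variant and
the age-class scheme are all editable YAML (`src/paleodraught/data/`).

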