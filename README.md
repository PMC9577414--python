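# migraseed

Data-driven simulation of propagule dispersal by migratory herbivores.

Seasonal animal migration moves more than animals: herbivores that eat fruit
in one seasonal range and defecate days later, far downslope, are long-range
seed dispersal vectors. `migraseed` is a modelling toolkit for quantifying
that process for a partially migratory population — the motivating system is
a giant-tortoise population carrying invasive guava seeds from highland
farmland into a protected lowland — and for predicting where seeds land
("seed rain") and where they can establish ("seed fate").

The pipeline chains five calibratable stages:

1. **Seasonal ranges** — per-individual 95% kernel utilization distributions
   from GPS tracks, population convex hulls, converted to presence/absence on
   an equal-area hexagonal grid (~1.18 km² cells).
2. **Migratory connectivity** — an optimal-redistribution model: NDVI-derived
   energy distributions H (highland) and L (lowland), each rescaled to the
   population size N, connected by the minimum-cost flow

       min Σᵢⱼ cᵢⱼ fᵢⱼ   s.t.  fᵢⱼ ≥ 0,  Σⱼ fᵢⱼ ≤ k_hᵢ,  Σᵢ fᵢⱼ ≤ k_lⱼ,
                               Σᵢⱼ fᵢⱼ = min(Σ k_h, Σ k_l)

   with cᵢⱼ the centroid distance — i.e. the Earth Mover's Distance plan
   between the seasonal energy surfaces, solved exactly as an LP, then
   integerised into per-individual origin→destination assignments.
3. **Trajectories** — an empirical random trajectory generator: fixed-length
   conditional random walks between assigned endpoints whose step-length /
   turning-angle geometry (including lag-1 autocorrelation and step–turn
   covariance) is resampled from empirical template tracks, with a
   feasibility "pull" toward the destination.
4. **Gut retention and deposition** — daily foraging and excretion along each
   trajectory. Retention follows a right-skewed normal (mean 12 d, sd 8 d,
   skewness 2, truncated at 28 d); the excretion probability is
   P_g = Σ R_d F_d / Σ R_d over the binary feeding history F of the last 28
   days, and each excretion deposits a truncated-normal seed count
   (μ = 1443, σ = 2057). Population totals over stochastic repeats give the
   seed-rain map; a binary suitability mask turns it into seed fate.
5. **Validation** — two-sample Kolmogorov–Smirnov comparison of simulated vs
   observed dung-pile elevations, plus landcover/zone/elevation summaries and
   a stop-frequency (1/2/4 stops per day) sensitivity analysis.

A fully synthetic island generator (`migraseed.synthetic`) produces every
input the pipeline needs — grid layers, phase-labelled tracks, observed-style
dung piles — so the whole framework runs and is tested without any download.

## Worked example

Run the full pipeline on the synthetic island, scaled to 200 migrants and
5 stochastic repeats:

```python
import json
from migraseed import PipelineConfig, run_pipeline

cfg = PipelineConfig(outdir="runs/demo", population_size=200, repeats=5, rng_seed=7)
out = run_pipeline(cfg)
print(json.dumps(json.loads((out / "validation.json").read_text()), indent=1))
```

which prints

```json
{
 "n_events": 2989,
 "total_seeds": 6933384,
 "germinable_seeds": 4670782,
 "ks_observed_vs_simulated": {
  "D": 0.0992165718746515,
  "p": 0.19423505693832702,
  "n_obs": 120,
  "n_sim": 2989
 }
}
```

Reading this: the 200 simulated migrants × 5 repeats produced 2,989 excretion
events carrying ~6.9 M seeds in total, of which ~4.7 M landed in cells where
the establishment mask predicts germination success. The KS comparison of the
elevation distribution of simulated events against the island's "observed"
dung-pile dataset gives D = 0.099 with p = 0.19 — no detectable mismatch, so
the simulated deposition pattern is statistically consistent with the
observations. The run directory also contains the seasonal ranges, the flow
matrix (`flows.csv`), one repeat of simulated trajectories, the per-cell
seed-rain and seed-fate tables, deposition summaries, and a `manifest.json`
hashing every artifact (runs are bit-reproducible for a fixed seed).

The same run from a shell:

```sh
migraseed all --synthetic --seed 7 --population 200 --repeats 5 --out runs/demo
```

Stage subcommands (`ranges`, `connectivity`, `trajectories`, `dispersal`),
`validate` for stand-alone KS comparisons, and `synth` for writing the
synthetic input bundle are also available; see `migraseed --help`.

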