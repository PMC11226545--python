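# oscflux

Alpha-oscillation burst analysis and directed connectivity for epoched EEG,
built around the question of how rhythmic alpha activity and the direction
of its propagation change between task conditions during semantic
association (e.g. free vs. goal-directed word association), together with a
synthetic-data module that makes every stage testable against a known
ground truth.

The package is aimed at cognitive-electrophysiology researchers who want a
reproducible, scriptable version of this analysis chain:

1. **Semantic distance** — responses are scored as `1 − cos(v_w, v_prev)`
   from a local word-embedding table (consecutive-response or forward-flow
   convention), median-split per participant and condition into lower /
   higher distance, and filtered by the protocol's inclusion rules
   (thinking time ≥ 1 s, ≤ 20 % artefact samples at ±80 µV, ≥ 10 valid
   responses with ≥ 5 per condition, group-level 3 SD outlier removal).
2. **Oscillation bursts over a 1/f background** — 3-cycle Morlet wavelet
   power from 4–40 Hz; the aperiodic background is modelled as
   `P(f) = 10^offset / (knee + f^χ)` with a peak-robust fit; a frequency is
   "bursting" when power exceeds the 95th percentile of the χ²(2)
   distribution anchored at the model (≈ 3.0 × model power) for more than
   3 cycles.  The individual alpha frequency (IAF) is the 8–13 Hz
   frequency with the longest summed burst duration, and each epoch is
   summarised by burst power, burst time proportion and mean burst
   duration at the IAF.
3. **Phase Slope Index (PSI)** — directed connectivity per channel pair
   over the alpha band,
   `Ψ̃_ij = Im Σ_{f∈F} C*_ij(f) C_ij(f+δf)` with `C` the complex coherency,
   standardised by its leave-one-epoch-out jackknife standard deviation.
   Positive Ψ means the first channel leads (drives); zero-lag volume
   conduction cancels because only the imaginary part enters.
4. **Cluster permutation test** — per-edge paired t contrasts between
   conditions, p ≤ .05 edges assigned to the condition with the larger
   |mean PSI|, oriented by the PSI sign and grouped into strongly connected
   components; cluster statistic = sum of edge t values; the null
   distribution of per-iteration maximum |cluster statistic| comes from
   5000 random within-participant label flips.

## Worked example

Simulate a 12-participant two-condition study in which condition B carries
six planted left→right alpha-band couplings (20 ms lag), then run the full
pipeline and summarise:

```bash
oscflux simulate --seed 7 --out demo --n-participants 12 --n-epochs 10 --planted-edges 6
```

```python
from oscflux import RunConfig, run_pipeline, report

cfg = RunConfig(epochs_path="demo/eeg.npz", responses_path="demo/responses.csv",
                vectors_path="demo/vectors.txt", output_dir="demo_out",
                n_perm=500, seed=7)
run_pipeline(cfg)
report("demo_out")
```

prints (abridged):

```json
{
 "distance_mean": 0.7007345852551125,
 "distance_sd": 0.10102630206607775,
 "n_responses": 575,
 "significant_clusters": [
  {
   "cluster_stat": 7.497545410935592,
   "condition_membership": "B",
   "edges": [["C3", "C4"]],
   "p_value": 0.001996007984031936,
   "significant": true
  }
 ],
 "t_critical": 4.453568824660743,
 "thinking_time_median": 5.013820414995943,
 "topography_max_abs_t_channel": "T8"
}
```

Reading this: the synthetic association sequences realise their target
semantic-distance distribution (mean ≈ 0.70, SD ≈ 0.10); the permutation
null at α = .05 two-tailed puts the critical cluster statistic at 4.45; the
analysis recovers a significant condition-B cluster on a planted
left→right edge (C3→C4, cluster t = 7.50, p = .002) and the channel with
the strongest burst-measure contrast is T8, the right temporal electrode
receiving most planted couplings.  The output directory also contains the
scored responses, the exclusion report, per-epoch burst events and alpha
measures, the long-format PSI edge table, the full cluster JSON and a
manifest with a content hash of every file.

The same stages are available individually as `oscflux semdist`, `oscflux
detect`, `oscflux psi`, `oscflux cluster` and `oscflux report`.

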