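# tvdfc

Dynamic functional connectivity of temporally localized emotional events
in EEG.

When a person watches an emotionally engaging video and marks the moment
of a felt emotion with a click, the 7 s of EEG around that click (6 s
before to 1 s after) carry the network dynamics of the experience. This
package implements the full analysis chain for such data, for
researchers in affective and network neuroscience:

1. **Phase-locking networks.** Per frequency band (δ 1–4, θ 4–8, α 8–12,
   lower β 12–20, upper β 20–30, γ 30–40 Hz) and per 1-s sliding segment
   (250 samples, 175-sample step → nine segments per epoch), the
   phase-locking value between every electrode pair:
   `PLV = |1/N Σ_t exp(i(φ_a(t) − φ_b(t)))|`, phases from the analytic
   signal of the full 7-s band-limited epoch.
2. **Max-statistic permutation significance.** Each emotion group's
   event PLVs are contrasted with baseline-epoch PLVs by pooled-variance
   t statistics; family-wise error over all pairs is controlled by the
   single-threshold method (within-subject label exchange, null
   distribution of the maximum |t|, critical value = the (c+1)th largest
   maximum with c = ⌊αN⌋, α = 0.01).
3. **Band selection.** Significant connections form weighted multi-hot
   connectivity vectors; Euclidean distances between the 8 emotion
   groups, pooled over segments, are tested per band against the global
   mean distance **Gcst** (one-sample t, df = 27 for 28 group pairs,
   Bonferroni over bands).
4. **Temporal variability (tvDFC).** Per event, the mean Euclidean
   distance between consecutive segment networks on the selected band.
5. **Mixed-model regression.** `scale ~ tv + (1|subject)` by REML for
   each self-assessment scale (valence, arousal, dominance, liking,
   familiarity, relevance), standardized slopes with Wald inference,
   plus a mixed-logistic arousal × dominance interaction check.
6. **Hubs.** Eigenvector centrality on the pooled significant network,
   tested against 10,000 Erdős–Rényi graphs of matched density.

A synthetic-data generator (`tvdfc.synthdata`) emulates the whole study
design — band-limited oscillations with controllable von Mises phase
coupling, click events, a 24-label emotion vocabulary in 8
valence–arousal groups, and ratings with a known linear dependence on
the injected connectivity variability — so every stage is testable with
known ground truth. See `docs/methods.md` for the model details and
design choices.

## Worked example

Simulate a small study in which each emotion group phase-locks its own
electrode pair in the upper beta band only, then run the pipeline:

```python
import json
from tvdfc import PipelineConfig, SimConfig, run_all
from tvdfc.synthdata import group_discriminative_coupling

sim = SimConfig(
    n_subjects=6, n_channels=8, n_events_per_subject=16, seed=42,
    band_coupling=group_discriminative_coupling(8, "upper_beta", kappa=0.9),
)
cfg = PipelineConfig(out_dir="example-out", simulate=sim,
                     n_perm=200, n_random_graphs=2000, seed=42)
run_all(cfg)

s = json.load(open("example-out/summary.json"))
print("Gcst:", round(s["gcst"], 3))
print("selected band:", s["selected_band"])
ub = s["band_tests"]["upper_beta"]
print(f"upper beta: t({ub['df']}) = {ub['t']:.2f}, p = {ub['p']:.2g}, d = {ub['cohens_d']:.2f}")
ar = s["regressions"]["arousal"]
print(f"arousal ~ tv: beta = {ar['beta']:.3f} (se {ar['se']:.3f}), p = {ar['p']:.2g}")
print("hub channels:", s["hubs"])
```

Output:

```
Gcst: 0.219
selected band: upper_beta
upper beta: t(27) = 25.40, p = 6.6e-20, d = 4.80
arousal ~ tv: beta = 0.521 (se 0.087), p = 2.1e-09
hub channels: ['Fp1']
```

The pipeline finds the band that actually carries the
group-discriminative coupling (upper beta: its 28 inter-group network
distances far exceed the all-band mean Gcst = 0.219, while the other
bands fall below it or show no significant connections at all), recovers
a positive standardized arousal slope close to the generator's
`tv_slope = 0.5` (events whose injected coupling fluctuates more between
segments received higher arousal ratings), and flags the channel that
serves as coupling source for most groups (`Fp1`) as the network hub.
Distances here are desk-scale synthetic magnitudes; a 40-subject,
128-channel study produces distances on the order of 8.

The same run is available from the shell:

```sh
tvdfc run-all --config cfg.json --seed 42 --out example-out
tvdfc simulate --out dataset/ --seed 1 --n-subjects 4
```

Per-stage outputs are written as TSV/JSON (`emotion_groups.tsv`,
`permtest/edges_<band>_seg<k>_group<g>.tsv`, `distances.tsv`,
`tv_records.tsv`, `hubs.tsv`, `summary.json`, `manifest.json`), and
identical configs reproduce byte-identical outputs.

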