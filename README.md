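# dyadom

Temporal analysis of how pairs of animals form dominant–subordinate
relationships from timestamped behavioral event logs. The package covers the
full chain:

1. **events_io** — tidy event-log model (one row per behavior bout:
   `dyad_id, day, subject_id, behavior, onset_s, offset_s`), a 19-behavior
   ethogram with seven behavioral states, validation, onset-series and
   no-repeat sequence derivation.
2. **bursts** — from-scratch two-parameter burst automaton
   (gamma = 0.3, rate ratio s = 2 by default) on pooled agonistic onset
   series; second-order burst extraction and descriptive statistics.
3. **resolution** — per-burst 2×2 agonistic matrices, the phi-coefficient
   criterion (phi > 0, chi-square p < 0.1 from a burst onward, bursts with
   fewer than 6 events excluded) and the difference criterion
   ((a−c) ≥ (b−d) onward); eventual-role assignment from the last two
   bursts; pre/middle/post phase segmentation and paired Wilcoxon
   comparisons of phase-wise behavior proportions.
4. **markov** — within-individual first-order transition matrices with
   structural-zero diagonals, quasi-independence expected counts via
   iterative proportional fitting, G² tests with adjusted df, no-repeat
   permutation nulls (1000 draws, strict ">" convention), group medians
   (significant: median p ≤ 0.01; meaningful: median probability ≥ 0.075),
   and kinetogram export (GraphML + DOT).
5. **fsttc** — directional forward spike-time tiling coefficient between
   one subject's behavior and the partner's response within Δt = 2 s,
   per phase and direction, with paired direction comparisons.
6. **synthetic_data** — dyad generator with planted bursts, a planted
   resolution burst, role-specific behavior, and tunable forward
   contingency (theta), so every stage has a ground-truth recovery test.
7. **pipeline** / **cli** — end-to-end orchestration with per-stage CSV
   outputs and a JSON run manifest.

## CLI

```sh
# synthetic cohort with ground truth
dyadom simulate --seed 42 --out events.csv --truth truth.json

# stage by stage
dyadom bursts --input events.csv --gamma 0.3 --s 2 --level 2 --out bursts.csv
dyadom burst-summary --input events.csv --bursts bursts.csv --out burst_summary.csv
dyadom resolve --input events.csv --bursts bursts.csv --alpha 0.1 --min-events 6 --out resolution.csv
dyadom fsttc --input events.csv --phases out/phases.csv --roles out/roles.csv --dt 2 --out fsttc.csv

# everything from one YAML config
dyadom run --config pipeline.yaml
```

A minimal `pipeline.yaml`:

```yaml
input: events.csv
out_dir: out
n_perm: 1000
seed: 7
```

The pipeline writes `bursts.csv`, `burst_summary.csv`, `resolution.csv`,
`phases.csv`, `roles.csv`, `phase_proportions.csv`, `phase_stats.csv`,
`markov/` (per-individual and group transition tables plus kinetograms),
`fsttc.csv`, `fsttc_tests.csv`, and `manifest.json`.

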