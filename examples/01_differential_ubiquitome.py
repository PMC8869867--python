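"""Differential ubiquitome analysis on synthetic TUBE pull-down counts.

Generates a two-condition, three-replicate spectral-count experiment
with matched resin controls and a planted 4-fold regulated subset,
runs the subtract -> floor -> log2 -> quantile-normalize chain, applies
the reproducible two-fold filter and scores it against the plant.
"""

import proteaphagy as pp
from proteaphagy import differential as diff
from proteaphagy import quant

cfg = pp.SynthCountConfig(n_proteins=1000, frac_up=0.05, frac_down=0.05, seed=1)
raw, truth = pp.generate_tube_counts(cfg)
print(f"raw matrix: {raw.data.shape[0]} proteins x {raw.data.shape[1]} samples "
      f"({len(raw.control_columns)} GST controls)")

subtracted = quant.subtract_background(raw)          # mean control per protein
normalized = quant.quantile_normalize(quant.log2_with_floor(subtracted))

detected = quant.call_detected_proteins(subtracted, min_value=1.0)
print("detected (>=1 count above background in all replicates):", detected.sizes)

fc = diff.replicate_fold_changes(normalized)          # B - A per replicate
result = diff.reproducible_differential(fc, log2_threshold=1.0)
print("differential summary:", result.summary())

report = diff.recovery_report(result, truth)
print(f"vs planted truth: sensitivity={report['sensitivity']:.3f}, "
      f"FDP={report['false_discovery_proportion']:.3f}")
# sensitivity ~0.98: nearly every planted 4-fold protein survives the
# "more than two-fold in every replicate" rule; FDP ~0: the rule admits
# essentially no unplanted protein at this count depth.
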