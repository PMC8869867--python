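# proteaphagy

Quantitative analysis of a proteasome-to-autophagy degradation shift in
drug-resistant cancer cells, packaged as a tested, reusable Python
pipeline. Proteasome-inhibitor–resistant cell lines (e.g. bortezomib-
resistant mantle cell lymphoma clones) reroute the disposal of
ubiquitylated proteins from the 26S proteasome to the
autophagy–lysosome system; demonstrating this requires four distinct
quantitative readouts, all implemented here:

1. **Differential ubiquitome quantification** — label-free spectral
   counts from TUBE (tandem ubiquitin-binding entity) pull-downs of two
   conditions × replicates with matched GST (resin-only) controls.
   Counts are summed per protein, the control background is subtracted,
   values below one are floored to one, log2-transformed and quantile-
   normalized across samples. A protein is called regulated when
   |log2(B/A)| > 1 (more than two-fold) **in every replicate pair** — a
   reproducibility criterion, not a p-value test.
2. **Functional-category summaries and enrichment** — per-category
   means ("means of all single values") over proteasome subcomplexes
   (20S α/β rings, 19S base/lid) and autophagy stages (early signaling,
   autophagosome formation, lysosome fusion), plus two-sided Fisher's
   exact tests for category enrichment in the differential set.
3. **ROI-restricted co-localization** — puncta detection in the
   autophagy-marker channel (LC3B/p62), thresholded Manders
   coefficients computed inside those puncta
   (M1 = Σ ref·[partner > T] / Σ ref), and normalized line profiles.
4. **Drug-combination analysis** — annexin-V gating of flow-cytometry
   events, median-effect fits fa/(1−fa) = (D/Dm)^m, and the
   Chou–Talalay combination index at a constant dose ratio,
   CI = dA/DxA + dB/DxB, with CI < 1 indicating cooperativity.

Every stage is exercisable on synthetic data with known ground truth:
negative-binomial spectral counts with planted fold changes, Gaussian
puncta with a planted channel-overlap fraction, median-effect dose
series with a planted Loewe interaction, and two-component flow-event
mixtures. The generators are first-class, tested code — they define
the conditions under which the pipeline's guarantees are verified.

## Worked example

```python
import proteaphagy as pp
from proteaphagy import quant, differential as diff

cfg = pp.SynthCountConfig(n_proteins=1000, frac_up=0.05, frac_down=0.05, seed=1)
raw, truth = pp.generate_tube_counts(cfg)
m = quant.quantile_normalize(quant.log2_with_floor(quant.subtract_background(raw)))
result = diff.reproducible_differential(diff.replicate_fold_changes(m))
print(result.summary())
print(diff.recovery_report(result, truth))
```

prints

```
{'n_enriched': 50, 'n_reduced': 50, 'n_total_differential': 100}
{'n_planted': 100, 'n_called': 100, 'sensitivity': 1.0, 'specificity': 1.0,
 'false_discovery_proportion': 0.0}
```

— all 50 planted 4-fold-up and 50 planted 4-fold-down proteins survive
the "more than two-fold in every replicate" rule, and no unplanted
protein sneaks in. The drug-combination side, on a series with a
planted synergistic interaction (α = 0.7):

```
A    : m=1.54  Dm(IC50)=9.70  r=0.9935
B    : m=1.95  Dm(IC50)=5.38  r=0.9919
fa=0.50: CI = 0.68 +/- 0.03  (cooperative)
```

One narrative script per capability lives in `examples/`; the
`proteaphagy` command exposes the same stages as CLI subcommands
(`simulate | quantify | differential | annotate | coloc | ci | run`),
and `proteaphagy run` writes a seed-reproducible JSON report.

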