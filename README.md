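# p3fscreen

Analysis pipeline for discovering and characterizing small-molecule
inhibitors of an oncogenic fusion transcription factor (PAX3-FOXO1, the
driver of fusion-positive rhabdomyosarcoma). The package re-implements,
as tested and reusable Python, the five computational stages such a
campaign runs after the wet lab:

1. **Dual-reporter screen triage** (`reporter_screen`) — per-plate
   percent-of-control normalization of three channels (an *ALK*
   super-enhancer luciferase reporting fusion-driven transcription, a CMV
   promoter luciferase reporting general transcription, and XTT
   viability), the weighted triage score

   *score* = (4·ALK + 2·CMV + XTT) / 7,

   hit selection, and classification into three mechanistic groups:
   **strong** (both reporters < 10% of control), **HDACi-like** (ALK
   down, CMV up) and **ALK-selective** (ALK down, CMV unchanged).
2. **Dose-response QC and potency** (`dose_response`) — four-parameter
   logistic (4PL) fits, response = bottom + (top − bottom)/(1 +
   (d/EC50)^h), on the follow-up dilution series (five 10-fold steps,
   20 µM → 2 nM), plus a Spearman monotonicity criterion for "ALK signal
   falls as dose rises".
3. **Tiled-CRISPR depletion mapping** (`crispr_tiling`) — per-guide
   log2 fold change against the plasmid pool (median-ratio normalization,
   pseudocount 0.5), a trailing walking average of 4 guides, the
   \>4-fold depleted fraction, and hotspot-interval calls with an
   empirical p from the non-targeting guides.
4. **Spike-in-normalized differential chromatin analysis**
   (`spikein_chip`) — per-sample scaling by 1e6 / spike-in mapped reads
   (which preserves genome-wide shifts that library-size scaling
   erases), a per-region t-test on log2 scaled counts with
   Benjamini–Hochberg adjustment at padj ≤ 0.05 and |FC| ≥ 1.5,
   nearest-gene annotation, anchored (TSS / binding-site) metaprofiles
   and chromatin-state signal aggregation.
5. **Preranked gene-set enrichment** (`gsea_lite`) — weighted
   running-sum enrichment score, gene-set-permutation NES / p / FDR,
   leading-edge extraction, and construction of UP/DOWN signature sets
   from the top-k differential genes.

Every input the pipeline consumes can be generated by `synthetic_data`
with planted ground truth (compound classes, a depleted sgRNA hotspot,
differential regions, an enriched gene set), so the whole pipeline is
exercisable and testable end to end without any external data.

## Worked example

Simulate a 2,000-compound screen with 5% multiplicative plate noise,
score and classify it, and check the planted classes are recovered:

```python
from p3fscreen import synthetic_data as sd
from p3fscreen.reporter_screen import score_screen, select_primary_hits

wells, truth = sd.simulate_screen(sd.ScreenSimSpec(n_compounds=2000, seed=1))
scores = score_screen(wells)
print(scores["class_label"].value_counts().to_dict())
merged = scores.merge(truth, on="compound_id", suffixes=("_called", "_planted"))
acc = (merged["class_label_called"]
       == merged["class_label_planted"].replace({"inactive": "unclassified"})).mean()
print(f"planted-class recovery: {100 * acc:.1f}%")
print(f"hits at weighted score <= 50: {len(select_primary_hits(scores, 50))}")
```

prints

```
{'unclassified': 1760, 'alk_selective': 100, 'hdaci_like': 100, 'strong': 40}
planted-class recovery: 100.0%
hits at weighted score <= 50: 40
```

i.e. the 100 HDACi-like, 100 ALK-selective and 40 strong planted
inhibitors are all recovered at this noise level, and only the strong
class (weighted score (4·5 + 2·5 + 40)/7 = 10) clears the 50% triage
cutoff. The same objects are reachable from the shell via the `p3fscreen`
command (`simulate`, `screen-score`, `dose-qc`, `tiling`, `chip-diff`,
`chip-profile`, `chip-states`, `gsea`, `make-sets`).

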