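# concord

Multi-observer contour-agreement analysis for radiotherapy target volumes.

When several radiation oncologists delineate the same clinical target volume
(CTV) on one planning CT, their contours disagree — and quantifying that
disagreement is the first step toward consensus guidelines. `concord` takes
a panel of co-registered binary masks (one per observer, NIfTI) and
computes, per case:

- **volume statistics** — min / max / mean / SD, union and intersection (cm³);
- **chance-corrected agreement** — generalized (Fleiss) kappa over an
  explicit analysis region, κ = (P̄ − P̄ₑ)/(1 − P̄ₑ), with apparent
  agreement P̄, shared-marginal chance agreement P̄ₑ, a large-sample z test,
  and the conventional interpretive label (0.41–0.6 = moderate, …);
- **generalized conformity index** —
  CI_gen = Σ_{i<j}|Aᵢ∩Aⱼ| / Σ_{i<j}|Aᵢ∪Aⱼ|, an observer-count-unbiased
  overlap measure (< 0.5 weak, ≥ 0.7 suitable);
- **STAPLE consensus** — expectation-maximization estimation of the latent
  "true" structure together with every rater's sensitivity pⱼ and
  specificity qⱼ, thresholded at a confidence level (CTV80 at CL = 80%);
- **border discrepancies** — signed, outward-positive distances (mm) between
  each observer's contour and the consensus in the six patient directions
  (left/right, anterior/posterior, superior/inferior), with per-direction
  spread ranking;
- **synthetic panels** — ground-truth ellipsoids with iid
  (sensitivity/specificity) or smooth boundary-perturbation observer models,
  fully deterministic under a seed, so every statistic above is testable
  against a known truth.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
from concord import format_table2, make_paper_like_case, run_observer_set

obs = make_paper_like_case("distal", seed=1)   # 9 synthetic observers, ~120 cm3
report, consensus, posterior = run_observer_set(obs)
print(format_table2([report]).to_string())
```

prints

```
                                    distal-synthetic-seed1
Parameters
Volume minimum (cm3)                                108.08
Volume maximum (cm3)                                157.53
Volume mean (cm3)                                   131.31
SD (cm3)                                             14.14
Volume union (cm3)                                  181.51
Volume intersection (cm3)                            89.67
Volume of consensus at CL 80% (cm3)                 136.66
Overall kappa                            0.842 (excellent)
Mean sensitivity                                     0.894
SD of sensitivity                                    0.062
Mean specificity                                     0.986
SD of specificity                                    0.012
p-value                                            <1e-300
CI_gen                                    0.770 (suitable)
```

Reading it: the nine synthetic observers' volumes average 131 cm³ with the
consensus (STAPLE posterior ≥ 0.8) at 137 cm³, between the 90 cm³
intersection and the 182 cm³ union. Kappa 0.842 means agreement far beyond
chance over the analysis region (union bounding box + 10 mm); CI_gen 0.770
means 77% pairwise overlap. Smooth synthetic boundary noise agrees much more
than real expert panels do — these numbers characterize the generator, not
clinicians. Per-rater sensitivity/specificity are measured against the
STAPLE estimate of the true structure.

The scripts in `examples/` each demonstrate one capability (agreement
statistics, STAPLE parameter recovery, border-discrepancy ranking, the full
multi-case report) and print what the numbers mean.

## Command line

```bash
concord simulate --config sim.json --out panel/      # synthetic panel + manifest
concord run --manifest panel/manifest.json --cl 0.8 --out report/
concord table --reports report/*_report.json
```

A case manifest is JSON: `{"case_id": ..., "observers": [{"label": ...,
"path": ...}]}` with NIfTI mask paths relative to the manifest.

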