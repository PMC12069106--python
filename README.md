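# fccmap

Evidence mapping of food contact chemicals (FCCs) in humans.

Thousands of chemicals are known to be used in, or to migrate from, food
packaging and other food contact articles, but whether humans actually carry
them has never been assessed systematically at inventory scale. `fccmap`
implements that assessment as a reusable, tested pipeline for exposure
scientists and regulators:

1. **Step 1 — database matching.** A registry of known FCCs (with CAS
   Registry Numbers, InChIKeys, and SMILES) is matched against analyte lists
   from five human biomonitoring programs (NHANES, CHMS, HBM4EU, KoNEHS,
   Biomonitoring California) and three metabolome/exposome databases (HMDB,
   Blood Exposome Database, Exposome Explorer). Analytes that are metabolites
   are expanded along their metabolite→parent links, so an FCC counts as
   monitored whether the program measured the parent compound or a
   metabolite. Each FCC receives one status: *detected*, *monitored but not
   detected*, or *no evidence*.
2. **Step 2 — systematic evidence map.** FCCs absent from every step-1
   source are prioritized when the FCM migration/extraction database
   (FCCmigex-style) reports their detection in at least five entries.
   Post-screening literature extraction records (study × FCC × sample type ×
   method × analyte form × detected) then classify each prioritized FCC's
   human-evidence status and are aggregated by sample type, analytical
   method, and analyte form.
3. **Hazard tiering.** Pooled GHS classification records assign each
   hazard-mapped FCC a concern tier: *high* (CMR category 1A/1B or STOT RE
   category 1), *medium* (category 2), *other concern*, *not classified*, or
   *no hazard data*.

Everything consolidates into one per-FCC table plus summary exports
(headline counts, group summaries, Sankey flow tables). Because the upstream
databases are proprietary or living resources, the package ships a seeded
synthetic-universe generator (`fccmap.synthetic`) whose quotas are
constructed, not sampled — a spec of marginal counts and overlaps is
reproduced exactly by the pipeline, which makes every stage testable offline.

## Worked example

```python
from fccmap import generate_universe, paper_marginals, run_pipeline_on_bundle

bundle = generate_universe(paper_marginals(seed=1))
result = run_pipeline_on_bundle(bundle)
s = result.summary
print(f"{s.n_evidence} of {s.n_universe} FCCs ({s.pct_evidence}%) with evidence")
print(f"step-1 detected: {result.partition.n_detected}, "
      f"monitored only: {result.partition.monitored_not_detected}")
print(f"step-2: {result.step2_summary.n_detected} of "
      f"{len(result.prioritized)} prioritized FCCs detected")
print(f"high concern: {result.biomonitored_tiers.counts['high'] + result.prioritized_tiers.counts['high']}")
```

prints

```
3601 of 14402 FCCs (25%) with evidence
step-1 detected: 3538, monitored only: 10
step-2: 63 of 175 prioritized FCCs detected
high concern: 105
```

meaning: of 14,402 known FCCs, 3601 (25%) have evidence of presence in
humans — 3538 from biomonitoring detections and metabolome/exposome listings
in step 1 and 63 more from the literature in step 2; only 10 FCCs were
monitored in step 1 without ever being detected or listed; and 105 of the
410 hazard-mapped FCCs carry high-concern GHS classifications.

The same run is available from the shell:

```bash
fccmap generate --preset paper --seed 1 --out-dir fixtures/
fccmap step1 --registry fixtures/registry.csv --biomon fixtures/biomonitoring.csv \
             --metabolome fixtures/metabolome.csv --out step1.csv
fccmap report --src-dir fixtures/ --out-dir out/   # fcchumon.csv, summary.json,
                                                   # group_summary.csv, sankey.csv
```

## Scope

The package covers identifier reconciliation, matching, status resolution,
prioritization, evidence classification, hazard tiering, and reporting. It
does not download or parse the native formats of the upstream services, does
not perform bibliographic search or screening (inputs are post-screening
extraction records), does not predict metabolites, and does not compute
chemical groups (group labels are curated inputs). See `docs/methods.md` for
the model, parameter, and design details.
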