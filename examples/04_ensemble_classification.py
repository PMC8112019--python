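"""Classify a planted structural effect with a small CNN ensemble.

Generates the reference synthetic cohort (16 regions, a distributional
shift planted in regions 1 and 2 of cases), trains a few ensemble members on
scrambled-rectangle encodings of the structural similarity matrices, and
aggregates their test predictions into an ensemble AUROC.  A functional-only
ensemble on the same subjects has no planted signal and should hover near
chance.  Takes a couple of minutes on one CPU.
"""

import wassconn as w

cfg = w.SyntheticConfig(seed=42)
cohort = w.generate_cohort(cfg)
instances = w.cohort_instances(cohort, include=("structural", "functional"))
print(f"cohort: {len(cohort.records)} subjects, planted regions "
      f"{cfg.planted_regions}, struct effect {cfg.struct_effect} pooled s.d.")

for channels in (("structural",), ("functional",)):
    result = w.run_ensemble(
        cohort.records, instances, n_models=5, spec=w.ModelSpec(),
        match_cfg=w.MatchConfig(), seed=42, channels=channels,
    )
    auroc = w.aggregate_auroc(result.predictions, result.labels)
    covered = result.predictions["instance_id"].nunique()
    print(f"{'/'.join(channels):12s} ensemble AUROC = {auroc:.3f} "
          f"({covered} instances covered, leakage-free = "
          f"{w.audit_leakage(result)})")
print("— the structural channel carries the planted effect, so its AUROC "
      "should be far above the functional channel's (which is near 0.5).")
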