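"""Find which regions the classifier used: Grad-CAM, betweenness, hubs.

Trains a small structural-only ensemble on the planted-effect cohort,
averages guided Grad-CAM saliency over all instances and members into a
class activation map (CAM), concentrates it with edge betweenness
centrality, partitions the betweenness graph by modularity maximization,
and ranks regions by within-community CAM strength.  The planted regions
should surface among the top hubs.  Takes a few minutes on one CPU.
"""

import wassconn as w

cfg = w.SyntheticConfig(seed=42)
cohort = w.generate_cohort(cfg)
instances = w.cohort_instances(cohort, include=("structural",))
result = w.run_ensemble(cohort.records, instances, n_models=10,
                        spec=w.ModelSpec(), match_cfg=w.MatchConfig(),
                        seed=42, channels=("structural",))
print(f"ensemble AUROC = "
      f"{w.aggregate_auroc(result.predictions, result.labels):.3f}")

cam = w.ensemble_cam(result, instances, channels=("structural",))
print(f"CAM averaged over {cam.n_contributions} (instance, model) maps")

bw = w.edge_betweenness_matrix(cam)
part = w.communities_by_modularity(bw, seed=42)
print(f"{len(set(part.assignment.values()))} communities, Q = {part.modularity:.3f}")

report = w.hub_report(part, cam, k=3)
print("top-3 hubs (region index, total incident CAM strength):")
for region, strength in report.top_hubs:
    marker = " <- planted" if region + 1 in cfg.planted_regions else ""
    print(f"  region {region + 1:2d}  strength {strength:.4f}{marker}")
print("— regions whose grey-matter distributions were shifted in cases "
      "should dominate the classifier's saliency hubs.")
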