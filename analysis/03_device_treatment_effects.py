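#!/usr/bin/env python
"""Flow-modulating device effects: velocity drop vs BB signal gain.

Simulates all five aneurysm models untreated and with their fifteen
devices (five flow-diverter stents on the ICA model, ten intrasaccular
devices on the bifurcation models), quantifies median intra-aneurysmal
velocity and normalized BB signal in registered VOIs, and evaluates:

* per-device treatment effects delta_velocity and delta_BB and their
  medians (aneurysm sac vs parent vessel);
* two-sided Wilcoxon signed-rank tests of the effects against zero;
* Spearman correlation between delta_velocity and delta_BB;
* Kruskal-Wallis + Dunn/Benjamini-Hochberg comparison of the voxel-level
  BB distributions of the untreated ICA model against two of its devices
  (statistical unit: voxel, so p-values are at the voxel scale).

Writes results/device_effects.csv, results/device_stats.json and
results/ica_bb_posthoc.csv.
"""

import json
import shutil
from pathlib import Path

import pandas as pd

from bbflow import phantom, pipeline, stats

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 19


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = pipeline.RunConfig(
        seed=SEED,
        models=pipeline.default_models(),
        devices=pipeline.default_device_set(),
        spacing=0.6,
        n_phases=8,
        output_dir=str(OUT / "device_run"),
    )
    res = pipeline.run_experiment(cfg)
    shutil.copy(OUT / "device_run" / "effects.csv", OUT / "device_effects.csv")
    report = res["report"]
    with open(OUT / "device_stats.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    print("aneurysm sac:")
    print(f"  median delta_velocity = {report['aneurysm_delta_velocity_median']:+.2f} "
          f"(Wilcoxon p = {report['aneurysm_wilcoxon_p_delta_velocity']:.2e})")
    print(f"  median delta_BB       = {report['aneurysm_delta_bb_median']:+.2f} "
          f"(Wilcoxon p = {report['aneurysm_wilcoxon_p_delta_bb']:.2e})")
    print(f"  rho(delta_velocity, delta_BB) = "
          f"{report['aneurysm_rho_delta_velocity_delta_bb']:+.2f} "
          f"(p = {report['aneurysm_rho_p']:.2e}, n = {report['aneurysm_rho_n']})")
    print("parent vessel:")
    print(f"  median delta_velocity = {report['vessel_delta_velocity_median']:+.3f}, "
          f"median delta_BB = {report['vessel_delta_bb_median']:+.3f}")

    # voxel-level BB distributions: untreated ICA vs a strong and a weak device
    ica = pipeline.default_models()[0]
    groups, labels = [], []
    for i, (label, k) in enumerate((("untreated", 1.0), ("FD1", 0.05), ("FD2", 0.92))):
        flow = phantom.FlowSpec(mean_flow_rate=ica.mean_flow_rate, treatment_factor=k)
        scene = phantom.make_scene(
            ica.geometry, flow, spacing=0.7, n_phases=6, seed=SEED * 100 + i,
        )
        q = pipeline.quantify_scene(scene, sac_plane_spacing=ica.sac_plane_spacing)
        groups.append(q.bb_values[("BB_perp", "aneurysm")])
        labels.append(label)
    kw = stats.kruskal_wallis(groups)
    dunn = stats.dunn_bh_posthoc(groups)
    rows = [
        {"group_a": labels[i], "group_b": labels[j], "z": z, "p_raw": p, "p_adj": pa}
        for (i, j), (z, p, pa) in dunn.pairwise.items()
    ]
    pd.DataFrame(rows).to_csv(OUT / "ica_bb_posthoc.csv", index=False)
    print(f"\nvoxel-level BB_perp distributions (ICA sac): Kruskal-Wallis "
          f"H = {kw.statistic:.1f}, p = {kw.p_value:.2e}")
    for row in rows:
        print(f"  {row['group_a']:>9s} vs {row['group_b']:<9s} "
              f"adjusted p = {row['p_adj']:.2e}")
    print(f"\nwrote {OUT / 'device_effects.csv'}, {OUT / 'device_stats.json'}, "
          f"{OUT / 'ica_bb_posthoc.csv'}")
    print("finding: effective devices cut intra-aneurysmal velocity while the "
          "parent vessel is unchanged; the failed flow suppression raises the "
          "BB signal, inversely correlated with the velocity change.")


if __name__ == "__main__":
    main()
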