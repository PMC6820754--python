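#!/usr/bin/env python
"""Extract significant networks: within-group and patients-vs-controls.

Within each group, a one-sample sign-flip permutation test asks which edges
carry consistently above-average flow; between groups, a label-permutation
t-test finds edges with stronger flow in patients.  Both are thresholded
edge-wise with Benjamini-Hochberg FDR at q = 0.001, and the surviving
networks are written as edge lists with JSON summaries alongside the
group-level densities.
"""

import json
from pathlib import Path

from ptenet.graphs import network_density
from ptenet.io import read_connectome, write_network
from ptenet.pipeline import PipelineConfig
from ptenet.stats import (
    edgewise_one_sample_test,
    edgewise_two_sample_test,
    extract_significant_network,
    fdr_threshold,
)

HERE = Path(__file__).resolve().parent


def main() -> None:
    cfg = PipelineConfig.from_yaml(HERE / "config.yaml")
    out = Path(cfg.out_dir)
    conn_dir = out / "connectomes"
    groups = json.loads((conn_dir / "groups.json").read_text())
    conns = {
        g: [read_connectome(conn_dir / f"{sid}.txt") for sid in sids]
        for g, sids in groups.items()
    }
    n_total = conns["control"][0].n_nodes
    densities = {}
    for gi, (group, mats) in enumerate(conns.items()):
        stats = edgewise_one_sample_test(
            mats, n_permutations=cfg.n_permutations, seed=cfg.seed + 101 + gi
        )
        mask = fdr_threshold(stats.p, cfg.fdr_q)
        net = extract_significant_network(stats, mask, alpha_q=cfg.fdr_q)
        densities[group] = network_density(n_total, net.n_edges) if net.n_edges else 0.0
        write_network(net, stats, out / f"network_{group}.tsv")
        print(
            f"{group} network: {len(net.nodes)} nodes, {net.n_edges} edges, "
            f"density {densities[group]:.4f}"
        )
    diff = edgewise_two_sample_test(
        conns["patient"], conns["control"],
        n_permutations=cfg.n_permutations, seed=cfg.seed + 103,
    )
    mask = fdr_threshold(diff.p, cfg.fdr_q)
    net_pos = extract_significant_network(diff, mask & (diff.t > 0), alpha_q=cfg.fdr_q)
    net_neg = extract_significant_network(diff, mask & (diff.t < 0), alpha_q=cfg.fdr_q)
    write_network(net_pos, diff, out / "network_patient_gt_control.tsv")
    write_network(net_neg, diff, out / "network_control_gt_patient.tsv")
    (out / "densities.json").write_text(json.dumps(densities, indent=2))
    print(f"patients > controls: {len(net_pos.nodes)} nodes, {net_pos.n_edges} edges")
    print(f"controls > patients: {len(net_neg.nodes)} nodes, {net_neg.n_edges} edges")


if __name__ == "__main__":
    main()
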