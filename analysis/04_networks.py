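#!/usr/bin/env python
"""Build space-sharing networks and compute their metrics.

For each season: the weighted sharing network (same-site-same-night
co-occurrence, Jaccard weights), the related-pairs-only filtered network
(r >= 0.25), the co-roosting matrix, and density / normalized degree /
clustering / weighted degree.  Writes edge lists, GraphML and node metrics
under results/tables/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from oasisnet import spacenet as sn


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results/tables"))
    ap.add_argument("--threshold", type=float, default=0.25)
    args = ap.parse_args()

    rel = pd.read_csv(args.out / "relatedness_matrix.csv", index_col=0)
    summary = {}
    for season in ("winter", "spring"):
        visits = pd.read_csv(args.out / f"visits_{season}.csv")
        net = sn.build_sharing_network(visits)
        net.write(args.out / f"edges_{season}.csv", args.out / f"network_{season}.graphml")
        filt = sn.filter_by_relatedness(net, rel, threshold=args.threshold)
        filt.write(args.out / f"edges_filtered_{season}.csv")
        roosting = pd.read_csv(args.data / season / "day_roosts.csv")
        coroost = sn.build_coroost_matrix(roosting, nodes=list(net.nodes))
        coroost.to_csv(args.out / f"coroost_{season}.csv")
        m = sn.network_metrics(net)
        m.node_metrics.to_csv(args.out / f"node_metrics_{season}.csv", index=False)
        summary[season] = {
            "n": len(net.nodes),
            "density": round(m.density, 4),
            "mean_degree_norm": round(m.mean_degree_norm, 4),
            "mean_clustering": round(m.mean_clustering, 4),
            "mean_strength": round(m.mean_strength, 4),
            "filtered_density": round(sn.network_metrics(filt).density, 4),
        }
        print(f"{season}: " + ", ".join(f"{k}={v}" for k, v in summary[season].items()))
    (args.out / "network_summary.json").write_text(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
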