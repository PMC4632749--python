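"""Graph-theory property table for the two correlation networks.

Per variety: node/edge counts, common-edge share, diameter, transitivity,
and modularity under the fixed biochemical partition plus walk-trap and
Girvan-Newman community detection — the property-table layout of the study.
Computed for both the full filtered networks and the unique-edge networks
(the study does not state which variant its table used). Reads
results/cohort/ and results/networks/; writes results/graph_stats.json.
"""

import argparse
import json
from pathlib import Path

from vinemet import graphstats, network
from vinemet.io import read_abundance_table, read_class_annotation

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--out", type=Path, default=Path("results/graph_stats.json"))
parser.add_argument("--threshold", type=float, default=0.5)
parser.add_argument("--alpha", type=float, default=0.05)
args = parser.parse_args()

table = read_abundance_table(args.cohort / "abundance.tsv")
annotation = read_class_annotation(args.cohort / "annotation.tsv")

nets = {
    v: network.build_network(
        network.ratio_to_control(table, v), annotation,
        threshold=args.threshold, alpha=args.alpha,
    )
    for v in ("Cs", "Sh")
}
cmp = network.compare_networks(nets["Cs"], nets["Sh"])

payload = {}
header = (f"{'variety':8} {'nodes':>5} {'edges':>5} {'common':>6} {'diam':>4} "
          f"{'trans':>6}  bio Q    walk-trap   edge-betw")
print(header)
for variety, net in nets.items():
    full = graphstats.graph_stats(net, annotation, cmp)
    uniq = graphstats.graph_stats(
        network.unique_edge_network(net, cmp), annotation
    )
    payload[variety] = {"full": full.to_dict(),
                        "unique_edges_only": uniq.to_dict()}
    c = full.communities
    print(
        f"{variety:8} {full.n_nodes:>5} {full.n_edges:>5} "
        f"{full.n_common_edges:>3} ({full.percent_common:.0f}%) "
        f"{full.diameter:>4} {full.transitivity:>6.2f}  "
        f"{c['biochemical']['n_communities']} ({c['biochemical']['modularity']:.2f})  "
        f"{c['walk_trap']['n_communities']} ({c['walk_trap']['modularity']:.2f})  "
        f"{c['edge_betweenness']['n_communities']} "
        f"({c['edge_betweenness']['modularity']:.2f})"
    )

args.out.parent.mkdir(parents=True, exist_ok=True)
args.out.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
print(f"wrote {args.out}")
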