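"""Build the per-variety correlation networks and compare their edge sets.

For each variety the 35 degC profiles are divided by the variety's own 25 degC
control means, all metabolite pairs are scored by Spearman correlation, and
edges are kept at |rho| >= 0.5, p < 0.05, positive sign. The two networks are
then intersected into common vs variety-unique edges. Reads results/cohort/
(run 01 first); writes GraphML/SIF/TSV networks and a comparison JSON under
results/networks/.
"""

import argparse
import json
from pathlib import Path

from vinemet import network
from vinemet.io import read_abundance_table, read_class_annotation, write_network

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--outdir", type=Path, default=Path("results/networks"))
parser.add_argument("--threshold", type=float, default=0.5)
parser.add_argument("--alpha", type=float, default=0.05)
parser.add_argument("--sign", choices=["positive_only", "both"],
                    default="positive_only")
args = parser.parse_args()

table = read_abundance_table(args.cohort / "abundance.tsv")
annotation = read_class_annotation(args.cohort / "annotation.tsv")
args.outdir.mkdir(parents=True, exist_ok=True)

nets = {}
for variety in ("Cs", "Sh"):
    ratio = network.ratio_to_control(table, variety)
    net = network.build_network(
        ratio, annotation, threshold=args.threshold, alpha=args.alpha,
        sign_policy=args.sign,
    )
    nets[variety] = net
    for fmt in ("graphml", "sif", "tsv"):
        write_network(net, args.outdir / f"network_{variety}.{fmt}", fmt)
    print(f"{variety}: {net.n_nodes} nodes, {net.n_edges} edges")

cmp = network.compare_networks(nets["Cs"], nets["Sh"])
payload = {
    "n_common": len(cmp.common),
    "common_edges": [list(p) for p in sorted(cmp.common)],
    "n_unique": {v: len(u) for v, u in cmp.unique.items()},
    "percent_common": {v: round(p) for v, p in cmp.percent_common.items()},
}
(args.outdir / "comparison.json").write_text(json.dumps(payload, indent=2) + "\n")
for variety in ("Cs", "Sh"):
    print(
        f"{variety}: {payload['n_unique'][variety]} unique edges, "
        f"{payload['n_common']} common ({payload['percent_common'][variety]}% of "
        f"its {nets[variety].n_edges})"
    )
print(f"wrote networks and comparison.json under {args.outdir}/")
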