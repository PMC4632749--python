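"""Temperature and cultivar fold-change reports on the simulated cohort.

For each cultivar: 35/25 degC fold change, equal-variance t p-value and the
significant-metabolite summary (count and mean |change|). For each
temperature: the Cs/Sh cultivar contrast. Mirrors the published fold-change
tables' layout. Reads results/cohort/ (run 01 first) and writes
results/differential/.
"""

import argparse
from pathlib import Path

from vinemet import diffabund
from vinemet.io import read_abundance_table, read_class_annotation

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--outdir", type=Path, default=Path("results/differential"))
parser.add_argument("--alpha", type=float, default=0.05)
args = parser.parse_args()

table = read_abundance_table(args.cohort / "abundance.tsv")
annotation = read_class_annotation(args.cohort / "annotation.tsv")
args.outdir.mkdir(parents=True, exist_ok=True)

for cultivar in ("Cs", "Sh"):
    frame, summary = diffabund.diff_report(
        table,
        {"cultivar": cultivar, "temperature": "35"},
        {"cultivar": cultivar, "temperature": "25"},
        alpha=args.alpha,
    )
    frame.insert(1, "class", [annotation[m] for m in frame.metabolite])
    frame.to_csv(args.outdir / f"temperature_{cultivar}.tsv", sep="\t",
                 index=False, float_format="%.4g")
    print(
        f"{cultivar} 35 vs 25 degC: {summary.n_significant} significant "
        f"metabolites, mean |change| {summary.mean_abs_percent_change:.0f}%"
    )

for temperature in ("25", "35"):
    frame, summary = diffabund.diff_report(
        table,
        {"cultivar": "Cs", "temperature": temperature},
        {"cultivar": "Sh", "temperature": temperature},
        alpha=args.alpha,
    )
    frame.insert(1, "class", [annotation[m] for m in frame.metabolite])
    frame.to_csv(args.outdir / f"cultivar_{temperature}C.tsv", sep="\t",
                 index=False, float_format="%.4g")
    print(
        f"Cs vs Sh at {temperature} degC: {summary.n_significant} significant "
        f"metabolites"
    )
print(f"wrote reports under {args.outdir}/")
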