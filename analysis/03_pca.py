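"""PCA of the log10-normalized cohort: explained variance and leading loadings.

The planted design should reproduce the qualitative ordination of the study:
cultivars separating along PC1 (the quinate-block offsets dominate) and
growth temperatures along PC2. Writes scores/loadings TSVs under results/pca/.
"""

import argparse
from pathlib import Path

from sklearn.metrics import silhouette_score

from vinemet import multivariate
from vinemet.io import read_abundance_table

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--outdir", type=Path, default=Path("results/pca"))
parser.add_argument("-k", type=int, default=2)
args = parser.parse_args()

table = read_abundance_table(args.cohort / "abundance.tsv")
args.outdir.mkdir(parents=True, exist_ok=True)

res = multivariate.pca(table, k=args.k)
scores = res.scores.copy()
scores.insert(0, "cultivar", table.samples["cultivar"])
scores.insert(1, "temperature", table.samples["temperature"])
scores.to_csv(args.outdir / "scores.tsv", sep="\t", index=False, float_format="%.6g")
res.loadings.to_csv(args.outdir / "loadings.tsv", sep="\t",
                    index_label="metabolite", float_format="%.6g")

for i, frac in enumerate(res.explained_variance_fraction, start=1):
    print(f"PC{i}: {100 * frac:.1f}% of variance; "
          f"top loadings {multivariate.top_loadings(res, i, 4)}")
sil_cult = silhouette_score(res.scores[["PC1"]], table.samples["cultivar"])
sil_temp = silhouette_score(res.scores[["PC2"]], table.samples["temperature"])
print(f"PC1 separates cultivars (silhouette {sil_cult:.2f}); "
      f"PC2 separates temperatures (silhouette {sil_temp:.2f})")
print(f"wrote {args.outdir}/scores.tsv and loadings.tsv")
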