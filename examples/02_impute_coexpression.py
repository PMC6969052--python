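"""Recover co-expression of a population-restricted gene pair by diffusion.

Dropout hides per-cell co-expression of sparse population markers
(think Cspg4/Foxl1 in pericyte-like stromal cells). MAGIC-style
diffusion (k=10, alpha=15) shares counts among similar cells; the
mean-value cutoff then calls each gene expressed/not per cell.
"""

from gutniche import imputation as im
from gutniche import preprocess as pp
from gutniche.simulate import SimConfig, simulate_two_tissue

cfg = SimConfig(
    n_genes=600, shared_types=4, specific_types_per_tissue=(1, 1),
    cells_per_type=150, markers_per_type=15, seed=2,
)
cm, _, truth = simulate_two_tissue(cfg)
filt = pp.filter_counts(cm, pp.QCParams.for_tissue("stomach", min_genes_per_cell=30))
expr = pp.normalize_cpm_log(filt)["log_cpm"]
keep = [cm.cell_ids.index(c) for c in filt.cell_ids]
cell_type = truth.cell_type["stomach"][keep]

scores, n_pcs = pp.pca_elbow(pp.scale_genes(expr, pp.select_hvg(expr, 400)))
params = im.ImputationParams()  # knn=10, decay_alpha=15, t=3
M = im.build_markov(scores, params)
imputed = im.impute(expr, M, params.t_diffusion)

gx, gy = truth.coexpr_pair
is_target = cell_type == truth.coexpr_type
for name, layer in (("raw", expr), ("imputed", imputed)):
    mask, n_co = im.coexpression_call(layer, gx, gy)
    precision = is_target[mask].mean() if n_co else float("nan")
    print(f"{name:8s}: {n_co:4d} cells call {gx}+{gy} co-expressed; "
          f"precision vs planted type = {precision:.3f}")
# The planted pair is expressed only in one shared type; diffusion
# removes per-cell dropout noise, so the co-expressing set tightens
# around that population (higher precision at full recall).
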