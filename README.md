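# spexkit

Headless spatial-omics analysis for multiplexed tissue imaging and spatial
transcriptomics: image preprocessing and watershed cell segmentation,
per-cell feature extraction, proteomics/transcriptomics clustering
recipes, colocation-quotient (CLQ) spatial statistics with permutation
significance, neighborhood-composition niche detection, and spatially
informed differential expression and pathway scoring — as a Python library
and a `spexkit` command-line tool, fully testable end-to-end on synthetic
data with known ground truth.

It is aimed at computational biologists working with IMC / MIBI / MERFISH
style data who want the analytical core of a spatial pipeline without a
web GUI: every stage is a plain function over an `AnnData` cell table
(coordinates in `obsm["spatial"]`, batch in `obs["image_id"]`) or a small
image dataclass.

## The colocation quotient

For an ordered cell-type pair A → B, each type-A cell *i* gets a local
quotient comparing the proportion of type-B cells in its radius
neighborhood against the proportion expected under no spatial structure:

    LCLQ(A_i → B) = ( Σ_j w_ij δ_ij / Σ_j w_ij ) / ( N_b′ / (N − 1) )

with δ_ij indicating a type-B neighbor, w_ij a uniform or Gaussian
distance-decay weight, N the total cell count, and N_b′ the candidate
target count (N_b, or N_b − 1 for the self pair). The global CLQ(A → B)
is the mean over A cells; 1 means no spatial relationship, above 1
attraction, below 1 avoidance. Significance comes from a label
permutation test with coordinates fixed: with n_perm permutations the
observed value joins the null (999 + 1 = 1,000 values at defaults) and

    P_attractive = (#{CLQ_perm ≥ CLQ_obs} + 1) / (n_perm + 1)

and symmetrically for avoidance. See `docs/methods.md` for the full
model notes, defaults, and numerical choices.

## Worked example

Simulate a tissue in which T cells cluster around tumor cells, then test
every cell-type pair for spatial attraction or avoidance:

```python
from spexkit.synthetic_data import PatternSpec, gen_labeled_pattern
from spexkit.spatial_stats import build_neighbor_graph, clq_significance

spec = PatternSpec(
    mode="attraction",
    n_cells_per_type={"tumor": 150, "tcell": 100},
    field_size_um=(400.0, 400.0),
    interaction_radius_um=20.0,
    strength=4.0,
    seed=7,
)
cells = gen_labeled_pattern(spec)
graph = build_neighbor_graph(cells, radius_um=25.0, kernel="uniform")
result = clq_significance(graph, cells, n_perm=999, alpha=0.05, seed=0)
print(result.to_tidy().to_string(index=False))
```

which prints

```
type_a type_b      clq  p_attractive  p_avoidant       call
 tcell  tcell 0.730773         0.997       0.004   avoidant
 tcell  tumor 1.177690         0.004       0.997 attractive
 tumor  tcell 1.275956         0.001       1.000 attractive
 tumor  tumor 0.814795         1.000       0.001   avoidant
```

Read: T cells sit near tumor cells about 18–28% more often than a random
arrangement of the same labels would allow (CLQ 1.18 and 1.28 for the two
directions, both significant at the 1/1,000 permutation floor), and each
type correspondingly avoids its own kind — exactly the structure the
generator planted. `result.local_clq[("tcell", "tumor")]` holds the
per-cell map for visualizing *where* the attraction happens.

The same chain runs from the shell:

```sh
spexkit simulate --mode attraction --counts tumor=150,tcell=100 \
    --field 400 --radius 20 --strength 4 --seed 7 --out cells.h5ad
spexkit clq cells.h5ad --radius 25 --n-perm 999 --out clq.csv
```

Other subcommands cover the rest of the pipeline: `preprocess`, `segment`,
`features` (image → cell table), `cluster` (proteomics / transcriptomics
recipes), `cooccur` (population-level interaction test), `niche`, `de`,
`pathway`, and `pipeline` (a YAML-configured stage chain with a run
manifest; same config + seed ⇒ identical outputs).

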