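# foldmatch

Longitudinal cortical-folding analysis via joint spectral surface
matching.

Between roughly 30 and 40 weeks equivalent gestational age (EGA) the
white–grey matter boundary of the human brain nearly doubles its surface
area and develops most of its secondary and tertiary folds. Measuring
*where* this folding happens in an individual infant requires a
point-wise correspondence between two surfaces that are far from rigidly
related — exactly the regime where conventional nonlinear registration
fails. `foldmatch` is written for researchers in developmental
neuroimaging and morphometry who need that correspondence and the folding
measures built on it.

The method:

1. **Spectral embedding.** A surface mesh S = {V, E} becomes a weighted
   graph with w_ij = 1/‖x_i − x_j‖ on mesh edges; the general Laplacian
   L = D⁻¹(D − W) is diagonalized and each vertex gets the first k
   non-null eigenvector components (U₁…U_k) as coordinates. Near-isometric
   surfaces — the same cortex at two folding stages — have nearly
   identical embeddings.
2. **Joint spectral matching (JSM), CPD-initialized.** A rigid/similarity
   Coherent Point Drift registration gives an initial correspondence; the
   two meshes then form the layers of a dual-layered graph connected by
   correspondence links, and the joint Laplacian's shared eigenmodes put
   both surfaces into one spectral space where nearest neighbors define
   the final map.
3. **Folding change.** Principal curvatures k₁, k₂ per vertex give mean
   curvature M = (k₁+k₂)/2 (gyri positive, sulci negative), Gaussian
   curvature G = k₁k₂, and total curvature T = k₁²+k₂². Curvatures are
   normalized by the cube-root enclosed-volume ratio so pure growth
   cancels; the bending-energy change tracks ∂/∂t ∫(k₁²+k₂²)dA per
   vertex. All change maps live on the early mesh.
4. **Group statistics.** Subjects are mapped onto a reference surface,
   mean shapes are built per time point, and each vertex's two groups of
   3-D coordinates are compared with the two-sample Hotelling T² (exact
   F-transform p-values).

Because no infant meshes are publicly deposited, the package ships a
synthetic-surface generator (`foldmatch.synthetic`) producing cohorts of
growing, progressively folding genus-0 surfaces with exact ground-truth
correspondence, on which every claim of the pipeline is tested.

## Worked example

```python
import numpy as np
import foldmatch as fm
from foldmatch import curvature as curv
from foldmatch.matching import MatchConfig
from foldmatch.mesh import enclosed_volume, surface_area

# one synthetic subject: early/late surfaces with ground truth
spec = fm.FoldingSpec(seed=0)
early, late, truth, patch = fm.generate_longitudinal_pair(spec, subdivision=3)
print(surface_area(early) / 100, surface_area(late) / 100)  # cm²

corr = fm.match_pipeline(early, late, MatchConfig(seed=0))
err = np.linalg.norm(late.vertices[corr.map] - late.vertices[truth.map], axis=1)
print(np.median(err))                                        # mm

fe, fl = fm.principal_curvatures(early), fm.principal_curvatures(late)
dm, dg = curv.curvature_change(fe, fl, corr,
                               enclosed_volume(early), enclosed_volume(late))
de = curv.bending_energy_change(fe, fl, corr,
                                curv.local_area_change(early, late, corr), early)
inside = patch >= 0
print(round(np.abs(dm[inside]).mean(), 4), round(np.abs(dm[~inside]).mean(), 4))
print(round(de[inside].sum(), 3), round(de[~inside].sum(), 3))
```

prints (values from this exact script):

```
113.20912637484896 201.50198425818724
0.0
0.007 0.0014
0.815 -0.084
```

Reading: the subject grows from 113 to 202 cm²; the matching recovers the
ground-truth correspondence exactly (median error 0 mm); the
volume-normalized mean-curvature change |ΔM| is ~5× larger inside the
patches where late-only folds were injected than outside; and the
bending-energy change sums to a clearly positive value inside the patches
(folding work done) against a near-zero remainder elsewhere.

The same chain is available from the shell:

```bash
foldmatch simulate --seed 0 --out run          # synthetic cohort + metadata
foldmatch all --seed 0 --out run               # match + morphometry + group + summary
```

## Layout

- `src/foldmatch/mesh.py` — mesh model, I/O, areas/volumes, components,
  subject metadata
- `src/foldmatch/spectral.py` — weighted graph, general Laplacian,
  spectral embedding, mode alignment
- `src/foldmatch/cpd.py` — rigid/similarity CPD, subsampling
- `src/foldmatch/matching.py` — joint graph, JSM, full matching pipeline,
  consistency maps
- `src/foldmatch/curvature.py` — principal curvatures, volume
  normalization, ΔM/ΔG, local area change, bending-energy change
- `src/foldmatch/groupstats.py` — group mapping, mean shapes,
  Hotelling T²
- `src/foldmatch/synthetic.py` — folding-surface generator, cohorts,
  analytic fixtures
- `src/foldmatch/pipeline.py`, `cli.py` — orchestration and the
  `foldmatch` command

`docs/methods.md` documents the model, parameter choices, numerical
details, and what the synthetic data does and does not emulate.
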