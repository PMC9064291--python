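# centriomig

Quantification pipeline for **centriole-group migration in olfactory sensory
neurons (OSNs)**.

In the olfactory epithelium, each sensory neuron grows dozens of cilia from a
dendritic knob at the apical surface. The centrioles that template those cilia
are born in progenitor cells near the basal lamina, 50–100 µm away, and must
migrate apically through the dendrite — in groups, and slowly (≤ ~0.2 µm/min).
`centriomig` implements the measurements this biology calls for, end to end:

- **3D detection** of centrioles as diffraction-limited puncta
  (scale-normalised Laplacian-of-Gaussian, anisotropic PSF) and of cilia as
  filaments (matched smoothing → threshold → 3D skeleton → path tracing),
  plus one-to-one centriole–cilium **association** by optimal assignment
  within a capture radius.
- **Group clustering** (single linkage at a physical cutoff, with singleton
  handling) and the **lag** of a leading group behind its dendrite tip.
- **Time-lapse tracking** with fiducial drift correction. Rates follow the
  field's convention, (last − first observed position)/elapsed time, with a
  regression slope reported alongside; net direction is classified
  apical/basal/none against a displacement threshold. **Kymographs** are
  built by bilinear sampling along a line over time.
- **Epithelial compartment scoring**: side-view positions are classified
  into the subapical compartment (apical surface → bottom of sustentacular
  nuclei) or the middle/basal compartment (→ basal lamina), and counts are
  normalised per 100 µm of basal-lamina arc length.
- **Statistics**: mean/SD/SEM summaries (SEM = SD/√n, sample SD), fold
  changes of normalised densities, traversal-time arithmetic, and a **paired
  permutation test**: for matched drug/control pairs the statistic is the
  mean paired difference of length-normalised counts, and its null
  distribution is built by independently sign-flipping each pair (exhaustive
  enumeration when 2^n fits the resampling budget, Monte-Carlo with an
  add-one-corrected p-value otherwise).
- A first-class **synthetic-data module** that simulates all of the above
  with known ground truth — knob scenes with docked centrioles and fanned
  cilia, 4D migration movies with a static fiducial, and paired count tables
  with configurable drug enrichment — so every stage is testable without any
  image download.

## Worked example

```sh
centriomig run --demo --seed 1 --out demo_run
```

simulates a dendritic knob bearing 36 centrioles and 31 cilia, detects and
associates them, clusters groups, scores a synthetic epithelium section, and
runs the paired permutation test on a simulated paclitaxel-vs-control count
table. It prints:

```json
{
 "n_spots_detected": 36,
 "n_cilia_detected": 32,
 "fraction_associated": 0.8333333333333334,
 "n_groups": 8,
 "n_singletons": 13,
 "permutation_p_value": 0.0026997300269973002,
 "observed_stat": 2.402866480897699,
 "exact": false
}
```

Reading: all 36 simulated centrioles were recovered; 32 filament traces were
found and 30 of 36 centrioles (83.3%) matched a cilium base — the regime of
a mature knob, where ~85% of centrioles carry a cilium. The drug arm of the
simulated table was enriched 2.58× in the subapical compartment, and the
permutation test rejects the no-effect null (observed mean paired difference
2.40 groups per 100 µm, p ≈ 0.003, Monte-Carlo with 10,000 sign-flip
resamples over 16 animal × timepoint × compartment pairs).

The same stages are available as a library:

```python
from centriomig import (SceneConfig, generate_knob_scene,
                        detect_spots, detect_cilia, associate)
import numpy as np

grid, truth = generate_knob_scene(SceneConfig(seed=1))
spots = detect_spots(grid, channel="centrin")
cloud = np.array([s.position_um for s in spots])
cilia = detect_cilia(grid, channel="cilia", base_reference_um=cloud)
result = associate(spots, cilia, capture_radius_um=1.4, base_segment_um=2.0)
print(len(spots), len(cilia), result.fraction_associated)
```

and as individual subcommands (`simulate`, `detect`, `cilia`, `associate`,
`group`, `track`, `kymo`, `score`, `test`) exchanging CSV/JSON/TIFF files;
see `centriomig --help`.

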