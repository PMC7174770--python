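# repdiv

Single-cell TCR repertoire analysis for paired-chain (TRA/TRB) droplet
data: barcode quality control, clonotype assignment, Hill-diversity
evenness profiles, CDR3β specificity annotation, and conserved cluster
markers. Built for studies that compare clonal structure between T cell
populations — for example regulatory T cells from cord blood versus adult
peripheral blood — where the question is not just *how many* clones a
repertoire holds but *how evenly* cells are spread across them.

## What it computes

**Barcode QC.** Four filters decide which droplet barcodes are cells:
a Monte-Carlo test of each barcode against the ambient-RNA profile
(estimated from droplets with ≤ 100 UMIs, retention at BH-FDR < 0.01), a
knee-point threshold on the log-log barcode-rank curve, 3-MAD outlier
removal on library size, genes detected and mitochondrial fraction, and
exclusion of presumed doublets carrying > 1 unique TRB or > 2 unique TRA
chains.

**Clonotypes.** Cells with exactly one α and one β chain get a clonotype
keyed by (TRAV, CDR3α, TRAJ, TRBV, CDR3β, TRBJ); everything else is
reported with a reason, never silently dropped.

**Evenness profiles.** For clone frequencies f, Hill diversity
D_α(f) = (Σᵢ fᵢ^α)^(1/(1−α)) (richness at α = 0, exp of Shannon entropy
at α = 1) is evaluated on the grid α = 0, 0.2, …, 10 and normalised as
E_α = D_α / D₁, giving a 51-dimensional profile per sample and per
cluster. A flat profile at 1 is a perfectly even repertoire; the faster
E_α falls with α, the stronger the clonal expansion.

**Specificity.** Exact CDR3β matching against a McPAS-style catalog of
pathology-associated sequences, counted per category by clone or by cell.

**Markers.** Per-sample Wilcoxon rank-sum tests of each cluster versus
the pooled rest (p, AUC, logFC), combined across k samples with
Wilkinson's minimum-p rule P = 1 − (1 − min p)^k and ranked.

**Synthetic data.** Generators for contig tables (uniform / geometric /
power-law clonal distributions, chain-set doublets, catalog spikes),
raw count matrices (negative-binomial cells, ambient background, planted
markers and dying cells) and mock catalogs — all seeded, all with ground
truth, all using a reserved `SYN` name prefix.

## Worked example

Two synthetic repertoires of 4,000 cells over 50 clones — one with
uniform clone frequencies, one geometrically expanded (ratio 0.9):

```python
import numpy as np
from repdiv import (RepertoireSpec, simulate_repertoire, assign_clonotypes,
                    frequency_vector, evenness_profile, compare_profiles)

profiles = {}
for name, dist in (("even", "uniform"), ("expanded", "geometric")):
    spec = RepertoireSpec(n_clones=50, n_cells=4000, distribution=dist,
                          ratio=0.9, seed=11)
    contigs, _ = simulate_repertoire(spec)
    res = assign_clonotypes(contigs)
    profiles[name] = evenness_profile(frequency_vector(res.table),
                                      sample_id=name)

cmp = compare_profiles(profiles["even"], profiles["expanded"])
alphas = profiles["even"].grid.alphas
for a in (0.0, 1.0, 2.0, 5.0, 10.0):
    i = int(np.flatnonzero(np.isclose(alphas, a))[0])
    print(f"alpha={a:>4}: E_even={profiles['even'].evenness[i]:.3f}  "
          f"E_expanded={profiles['expanded'].evenness[i]:.3f}")
print("dominant profile:", cmp.dominant)
```

```
alpha= 0.0: E_even=1.007  E_expanded=2.010
alpha= 1.0: E_even=1.000  E_expanded=1.000
alpha= 2.0: E_even=0.994  E_expanded=0.764
alpha= 5.0: E_even=0.975  E_expanded=0.587
alpha=10.0: E_even=0.946  E_expanded=0.517
```

Both profiles are pinned to 1 at α = 1 by construction. The even
repertoire stays near 1 across the whole grid; the expanded one rises
above 1 at α = 0 (richness exceeds the entropy-effective clone number)
and falls steeply as α up-weights the dominant clones — at α = 10 its
evenness is roughly half the even repertoire's. `compare_profiles`
reports the even profile as dominant: its evenness is higher at every
α > 1, the signature of weaker clonal expansion.

The same operations are available from a shell:

```bash
repdiv simulate counts --seed 4 --out sim/
repdiv simulate repertoire --seed 4 --out sim/
repdiv qc --matrix sim/matrix.mtx --features sim/features.tsv \
          --barcodes sim/barcodes.tsv --contigs sim/contigs.csv \
          --seed 4 --out qc/
repdiv clonotype --contigs sim/contigs.csv --keep qc/kept_barcodes.tsv --out clono/
repdiv diversity --clonotypes clono/clonotypes.tsv --out profile.tsv
```

## Limitations

The ambient test is a simplified multinomial goodness-of-fit, not a full
emptyDrops reimplementation; expression input to the marker module must
already be normalised; clonotyping is amino-acid level; no fuzzy CDR3
matching. See `docs/methods.md` for the models, parameter defaults and
the synthetic generator's known simplifications.
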