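# cgrfractal

Multifractal characterization of shotgun metagenomes via chaos game
representation (CGR).

A whole-genome-shotgun read set is mapped into the unit square by the
chaos game — each nucleotide pulls the current point halfway toward its
corner (A=(0,0), C=(0,1), G=(1,0), T=(1,1)), restarting from the center
for every read — box-counted on dyadic grids, and summarized by its
generalized (Rényi) dimension spectrum

    D(q) = slope of ln Σᵢ Mᵢ^q vs ln ε, divided by (q − 1),

with the information-dimension branch Σ (Mᵢ/M₀) ln(Mᵢ/M₀) at q = 1.
Here Mᵢ is the CGR point count in grid cell i at box side ε = 2^−ℓ and
M₀ the total. D(0) is the box dimension, D(1) the information
dimension, D(2) the correlation dimension; D(q) is non-increasing in q.

The spectrum is an alignment-free, assembly-free signature of a
microbial community: across simulated communities, D(0) tracks species
richness, D(1) the Shannon index, and D(2)–D(5) the Simpson index, so
the classical alpha-diversity indices appear as slices of one
multifractal curve. The package targets microbiome researchers who want
this signature (and the surrounding simulation/statistics workflow)
without taxonomic profiling: it bundles the CGR/box-counting core, a
metagenome read simulator, alpha-diversity indices, the
correlation-sweep and t-test analyses, and LDA classification of
samples by their spectra.

## Worked example

```python
import numpy as np
from cgrfractal import (
    CGRMultifractal, SimulationConfig, AbundanceProfile,
    simulate_reads, diversity_indices,
)
from cgrfractal.experiments import synthetic_genome_pool

genomes = synthetic_genome_pool(n_species=10, genome_length=50_000, seed=0)
profile = AbundanceProfile(
    [label for label, _ in genomes],
    np.array([0.016928832, 0.30559462, 0.120814049, 0.0, 0.07959993,
              0.00894306, 0.03682631, 0.37768779, 0.00570905, 0.04789635]),
)
idx = diversity_indices(profile)
print(f"richness={idx.richness} shannon={idx.shannon:.4f} simpson={idx.simpson:.4f}")

reads = simulate_reads(SimulationConfig(
    genomes=genomes, profile=profile, n_reads=10_000, read_length=200, seed=1,
))
est = CGRMultifractal().fit()          # q = 0..15 step 0.2, ε = 2^-6..2^-13
spec = est.spectrum(reads)
for q in (0.0, 1.0, 2.0):
    print(f"D({q:g}) = {spec.dimension_at(q):.4f}")
```

prints

```
richness=9 shannon=1.5947 simpson=0.7390
D(0) = 0.8953
D(1) = 0.8015
D(2) = 0.7505
```

Nine of ten species are present but abundance is concentrated in two of
them, so the entropy (1.59 nats of a possible ln 9 ≈ 2.20) and
Gini–Simpson (0.74) are well below their uniform maxima — and the
spectrum decreases steeply in q as the dense species dominate the
high-order moments. A uniform community of the same richness gives a
flatter, higher curve.

The same workflows are available from the shell:

```bash
cgrfractal simulate --genomes genomes.fasta --abundance-table ab.tsv \
    --output-dir sim/ --n-reads 10000 --read-length 200 --seed 1
cgrfractal spectrum --input sim/reads.fasta --output-dir out/
cgrfractal replicate-sim --output-dir rep/ --seed 1   # 50-community study
```

Every command writes its resolved configuration as JSON next to its
outputs; identical configuration and seed give byte-identical results.

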