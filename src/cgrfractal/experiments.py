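"""Desk-scale replications of the simulation studies.

These workflows reproduce the structure of the full-scale experiments —
communities of up to 10 species, shotgun sampling, D(q) spectra, and the
correlation of D(q) with alpha-diversity — at sizes that run in minutes
on one CPU. Synthetic i.i.d. genomes (default 50 kb) stand in for
reference bacterial genomes: reads remain much shorter than genomes and
the k-mer space covered by a community still grows with its richness,
which is the mechanism the correlation experiment probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .diversity import DiversityIndices, diversity_indices
from .estimators import CGRMultifractal
from .io import AbundanceProfile
from .multifractal import MultifractalSpectrum
from .simulate import SimulationConfig, generate_random_genome, sample_abundance_profile, simulate_reads

__all__ = [
    "CohortResult",
    "synthetic_genome_pool",
    "richness_gradient_cohort",
    "sampled_profile_cohort",
]

DEFAULT_GENOME_LENGTH = 50_000


@dataclass
class CohortResult:
    """Spectra, profiles and diversity indices of one simulated cohort."""

    q_values: np.ndarray
    spectra: np.ndarray  # (n_samples, n_q) D(q) matrix
    profiles: list[AbundanceProfile]
    indices: list[DiversityIndices]
    full_spectra: list[MultifractalSpectrum]


def synthetic_genome_pool(
    n_species: int, genome_length: int, seed: int
) -> list[tuple[str, str]]:
    """Independent i.i.d.-uniform genomes, one per species."""
    rng = np.random.default_rng(seed)
    return [
        (
            f"species_{i}",
            generate_random_genome(genome_length, seed=int(rng.integers(2**31))),
        )
        for i in range(n_species)
    ]


def _cohort(
    profiles: list[AbundanceProfile],
    genomes: list[tuple[str, str]],
    n_reads: int,
    read_length: int,
    read_seeds: list[int],
    transformer: CGRMultifractal | None,
) -> CohortResult:
    est = (transformer or CGRMultifractal()).fit()
    full = []
    for profile, rs in zip(profiles, read_seeds):
        config = SimulationConfig(
            genomes=genomes,
            profile=profile,
            n_reads=n_reads,
            read_length=read_length,
            seed=rs,
        )
        full.append(est.spectrum(simulate_reads(config)))
    return CohortResult(
        q_values=est.q_values_,
        spectra=np.vstack([s.dimensions for s in full]),
        profiles=profiles,
        indices=[diversity_indices(p) for p in profiles],
        full_spectra=full,
    )


def richness_gradient_cohort(
    n_communities: int = 50,
    richness_min: int = 2,
    richness_max: int = 10,
    n_reads: int = 10_000,
    read_length: int = 200,
    genome_length: int = DEFAULT_GENOME_LENGTH,
    seed: int = 0,
    transformer: CGRMultifractal | None = None,
) -> CohortResult:
    """Communities of varying richness with uniform abundance profiles.

    Richness cycles over ``richness_min..richness_max``; each community
    draws that many species uniformly (without replacement) from a
    shared pool and gives them equal abundance. This is the cohort used
    to locate where the correlation between D(q) and each diversity
    index peaks.
    """
    rng = np.random.default_rng(seed)
    pool = synthetic_genome_pool(richness_max, genome_length, int(rng.integers(2**31)))
    labels = [label for label, _ in pool]
    richness_values = [
        richness_min + i % (richness_max - richness_min + 1) for i in range(n_communities)
    ]
    profiles = []
    for r in richness_values:
        chosen = rng.choice(richness_max, size=r, replace=False)
        ab = np.zeros(richness_max)
        ab[chosen] = 1.0 / r
        profiles.append(AbundanceProfile(labels, ab))
    read_seeds = [int(rng.integers(2**31)) for _ in range(n_communities)]
    return _cohort(profiles, pool, n_reads, read_length, read_seeds, transformer)


def sampled_profile_cohort(
    n_samples: int = 20,
    n_species: int = 10,
    n_reads: int = 5_000,
    read_length: int = 200,
    genome_length: int = DEFAULT_GENOME_LENGTH,
    concentration: float = 1.0,
    zero_probability: float = 0.1,
    seed: int = 0,
    transformer: CGRMultifractal | None = None,
) -> CohortResult:
    """Cohort with Dirichlet-sampled abundance profiles (zeros allowed).

    Emulates repeated simple random sampling of metagenomes from
    communities with heterogeneous abundances; used for spectrum-shape
    checks such as the monotonicity of D(q).
    """
    rng = np.random.default_rng(seed)
    pool = synthetic_genome_pool(n_species, genome_length, int(rng.integers(2**31)))
    profiles = [
        sample_abundance_profile(
            n_species,
            concentration=concentration,
            zero_probability=zero_probability,
            seed=int(rng.integers(2**31)),
            labels=[label for label, _ in pool],
        )
        for _ in range(n_samples)
    ]
    read_seeds = [int(rng.integers(2**31)) for _ in range(n_samples)]
    return _cohort(profiles, pool, n_reads, read_length, read_seeds, transformer)
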