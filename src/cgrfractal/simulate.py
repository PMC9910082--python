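"""Synthetic communities and shotgun read sets.

Emulates the simulation design used throughout the analyses: a community
of ~10 species with a fixed relative-abundance profile (zeros allowed),
from which each metagenome is a simple random sample of reads — a
species is drawn per read according to its abundance, then an error-free
read of fixed length is cut from a uniform start position on that
species' genome (linear, forward strand). Defaults are 100,000 reads of
1,000 bp per metagenome. Synthetic genomes stand in for reference
genomes so the whole pipeline runs without downloads; an optional
uniform substitution-error rate supports robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AbundanceProfile, ReadSet

__all__ = [
    "SimulationConfig",
    "generate_random_genome",
    "sample_abundance_profile",
    "simulate_reads",
    "source_species",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_N_READS = 100_000
DEFAULT_READ_LENGTH = 1_000


@dataclass
class SimulationConfig:
    """Genomes, a matching abundance profile, and sampling parameters."""

    genomes: list[tuple[str, str]]
    profile: AbundanceProfile
    n_reads: int = DEFAULT_N_READS
    read_length: int = DEFAULT_READ_LENGTH
    seed: int = 0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_reads <= 0 or self.read_length <= 0:
            raise ValueError("n_reads and read_length must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        genome_labels = [label for label, _ in self.genomes]
        if genome_labels != list(self.profile.labels):
            raise ValueError("genome labels and profile labels must match 1:1, in order")
        for (label, seq), ab in zip(self.genomes, self.profile.abundances):
            if ab > 0 and len(seq) < self.read_length:
                raise ValueError(
                    f"genome {label!r} (length {len(seq)}) is shorter than the "
                    f"read length {self.read_length} but has positive abundance"
                )


def generate_random_genome(
    length: int,
    composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    order: int = 0,
    seed: int = 0,
    persistence: float = 0.3,
) -> str:
    """Random nucleotide sequence with a target base composition.

    ``order=0`` draws bases i.i.d. from ``composition`` (A, C, G, T).
    ``order=1`` draws from a first-order Markov chain whose rows mix the
    composition with self-persistence: T[a, b] = (1 - persistence) *
    composition[b] + persistence * [a == b], so the stationary
    distribution is the composition itself. Deterministic given ``seed``.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    comp = np.asarray(composition, dtype=float)
    if comp.size != 4 or np.any(comp < 0) or abs(comp.sum() - 1.0) > 1e-9:
        raise ValueError("composition must be 4 non-negative reals summing to 1")
    if order not in (0, 1):
        raise ValueError("order must be 0 or 1")
    rng = np.random.default_rng(seed)
    if order == 0:
        codes = rng.choice(4, size=length, p=comp)
    else:
        if not 0 <= persistence < 1:
            raise ValueError("persistence must be in [0, 1)")
        trans = (1 - persistence) * np.tile(comp, (4, 1)) + persistence * np.eye(4)
        codes = np.empty(length, dtype=np.int64)
        codes[0] = rng.choice(4, p=comp)
        # cumulative inverse-CDF sampling, one uniform per step
        cum = np.cumsum(trans, axis=1)
        u = rng.random(length)
        for i in range(1, length):
            codes[i] = np.searchsorted(cum[codes[i - 1]], u[i])
    return _BASES[codes].tobytes().decode("ascii")


def sample_abundance_profile(
    n_species: int,
    concentration: float = 1.0,
    zero_probability: float = 0.1,
    seed: int = 0,
    labels: list[str] | None = None,
) -> AbundanceProfile:
    """Random relative-abundance profile with sparse zeros.

    Each species is independently absent with ``zero_probability`` (at
    least one survivor is forced); present species receive symmetric
    Dirichlet weights with the given ``concentration``. The result sums
    to 1 exactly.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if not 0 <= zero_probability < 1:
        raise ValueError("zero_probability must be in [0, 1)")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    present = rng.random(n_species) >= zero_probability
    if not present.any():
        present[rng.integers(n_species)] = True
    weights = np.zeros(n_species)
    weights[present] = rng.dirichlet(np.full(int(present.sum()), concentration))
    if labels is None:
        labels = [f"species_{i}" for i in range(n_species)]
    return AbundanceProfile(labels, weights)


def simulate_reads(config: SimulationConfig) -> ReadSet:
    """Draw an error-free shotgun read set from a community.

    Read identifiers encode the true source as ``read_<i>|species=<label>``
    so downstream evaluations can recover the ground truth. Deterministic
    given ``config.seed``.
    """
    probs = config.profile.abundances
    if probs.sum() == 0:
        raise ValueError("all abundances are zero")
    rng = np.random.default_rng(config.seed)
    species_idx = rng.choice(len(probs), size=config.n_reads, p=probs)

    genome_arrays = [
        np.frombuffer(seq.encode("ascii"), dtype=np.uint8) for _, seq in config.genomes
    ]
    # start positions drawn before any error draws, so the sampled
    # fragments do not depend on whether an error model is active
    n_starts = np.array([len(g) - config.read_length + 1 for g in genome_arrays])
    starts = (rng.random(config.n_reads) * n_starts[species_idx]).astype(np.int64)

    labels = config.profile.labels
    reads: list[tuple[str, str]] = []
    for i, (s, start) in enumerate(zip(species_idx, starts)):
        fragment = genome_arrays[s][start : start + config.read_length]
        if config.error_rate > 0:
            fragment = fragment.copy()
            hit = np.nonzero(rng.random(config.read_length) < config.error_rate)[0]
            if hit.size:
                # substitute with a uniformly random different base
                old = np.searchsorted(_BASES, fragment[hit])
                fragment[hit] = _BASES[(old + rng.integers(1, 4, size=hit.size)) % 4]
        reads.append((f"read_{i}|species={labels[s]}", fragment.tobytes().decode("ascii")))
    return ReadSet(reads)


def source_species(readset: ReadSet) -> list[str]:
    """Recover the true source labels encoded in simulated identifiers."""
    out = []
    for rid, _ in readset:
        if "|species=" not in rid:
            raise ValueError(f"identifier {rid!r} does not encode a source species")
        out.append(rid.rsplit("|species=", 1)[1])
    return out
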