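"""Classical alpha-diversity indices of a relative-abundance profile.

Richness counts the species present; Shannon is the entropy
-sum p ln p (natural log); Simpson is reported in the Gini-Simpson
orientation 1 - sum p^2 so that larger always means more diverse,
matching the orientation of the Rényi dimensions D(1) and D(2) it is
compared against. The inverse form 1 / sum p^2 is available by flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AbundanceProfile

__all__ = ["DiversityIndices", "diversity_indices"]


@dataclass(frozen=True)
class DiversityIndices:
    richness: int
    shannon: float
    simpson: float

    def __post_init__(self) -> None:
        if self.richness > 0 and self.shannon > np.log(self.richness) + 1e-12:
            raise ValueError("shannon exceeds ln(richness)")


def diversity_indices(
    profile: AbundanceProfile, simpson_variant: str = "gini"
) -> DiversityIndices:
    """Richness, Shannon and Simpson indices of one profile.

    Parameters
    ----------
    profile:
        Relative abundances summing to 1; zeros mark absent species and
        contribute to no index.
    simpson_variant:
        ``"gini"`` for 1 - sum p^2 (default) or ``"inverse"`` for
        1 / sum p^2.
    """
    p = profile.abundances[profile.abundances > 0]
    richness = int(p.size)
    shannon = float(-np.sum(p * np.log(p))) if richness else 0.0
    shannon = max(shannon, 0.0)  # guard -0.0 from a single-species profile
    ssq = float(np.sum(p**2))
    if simpson_variant == "gini":
        simpson = 1.0 - ssq
    elif simpson_variant == "inverse":
        simpson = 1.0 / ssq
    else:
        raise ValueError(f"unknown simpson_variant {simpson_variant!r}")
    return DiversityIndices(richness=richness, shannon=shannon, simpson=simpson)
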