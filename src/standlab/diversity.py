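"""Plot-level tree-diversity indices from a species-abundance vector.

Eight indices are computed: species richness S; two richness-standardised
indices (Margalef, Menhinick); two information indices (Shannon-Wiener with
natural logs, Brillouin); and three dominance/evenness indices (Simpson in
reciprocal form, McIntosh, Berger-Parker in reciprocal form).  Reciprocal
forms are used for Simpson and Berger-Parker so that larger values mean more
diversity, matching the magnitudes (Si ~ 3, B-P ~ 2) typical of ~10-species
stands with two dominants.  Stand density is customarily reported alongside
them as an abundance-based companion measure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln

__all__ = ["AbundanceVector", "DiversityProfile", "diversity_profile", "INDEX_NAMES"]

INDEX_NAMES = ("S", "Mg", "Mn", "SW", "Br", "Si", "Mc", "BP")


class AbundanceVector:
    """Species -> positive integer count; the input to every index."""

    def __init__(self, counts: Mapping[str, int] | Sequence[int]):
        if not isinstance(counts, Mapping):
            counts = {f"sp{i}": int(c) for i, c in enumerate(counts)}
        if len(counts) == 0:
            raise ValueError("abundance vector must contain at least one species")
        for sp, c in counts.items():
            if int(c) != c or c < 1:
                raise ValueError(f"count for {sp!r} must be a positive integer, got {c}")
        self.counts = {str(sp): int(c) for sp, c in counts.items()}

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def s(self) -> int:
        return len(self.counts)

    def ranked(self) -> np.ndarray:
        """Abundances sorted in decreasing order (rank 1 first)."""
        return np.sort(np.fromiter(self.counts.values(), dtype=float))[::-1]


@dataclass(frozen=True)
class DiversityProfile:
    S: int
    Mg: float  # Margalef (S-1)/ln N
    Mn: float  # Menhinick S/sqrt(N)
    SW: float  # Shannon-Wiener, nats
    Br: float  # Brillouin
    Si: float  # Simpson, reciprocal finite-sample form
    Mc: float  # McIntosh
    BP: float  # Berger-Parker, reciprocal form

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in INDEX_NAMES}


def diversity_profile(v: AbundanceVector) -> DiversityProfile:
    """Compute all indices for one abundance vector.

    Simpson uses the finite-sample concentration sum(n_i (n_i - 1)) /
    (N (N - 1)); an all-singletons vector has zero concentration and Si is
    returned as +inf (undefined dominance).
    """
    counts = v.ranked()
    n, s = float(v.n), v.s
    p = counts / n

    mg = (s - 1) / math.log(n) if n > 1 else 0.0
    mn = s / math.sqrt(n)
    sw = float(-(p * np.log(p)).sum())
    br = float((gammaln(n + 1) - gammaln(counts + 1).sum()) / n)
    conc = float((counts * (counts - 1)).sum()) / (n * (n - 1)) if n > 1 else 1.0
    si = 1.0 / conc if conc > 0 else math.inf
    mc = (n - math.sqrt(float((counts**2).sum()))) / (n - math.sqrt(n)) if n > 1 else 0.0
    bp = n / float(counts[0])
    return DiversityProfile(S=s, Mg=mg, Mn=mn, SW=sw, Br=br, Si=si, Mc=mc, BP=bp)
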