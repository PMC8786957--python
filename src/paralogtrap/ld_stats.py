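"""Linkage-disequilibrium statistics computed from phased haplotype panels.

For two biallelic sites with alt-allele frequencies p_A and p_B and joint
alt-haplotype frequency p_AB, the disequilibrium coefficient is

    D = p_AB - p_A * p_B

D' normalises D by its maximum attainable magnitude given the marginals
(D_max = min(p_A(1-p_B), (1-p_A)p_B) for D > 0, else
min(p_A p_B, (1-p_A)(1-p_B))), and r^2 = D^2 / (p_A(1-p_A) p_B(1-p_B)) is
the squared allelic correlation.  Everything is exact tabulation over phased
haplotypes; there is no EM estimation from unphased genotypes here.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import LDError

SiteRef = Union[int, str]


@dataclass(frozen=True)
class HaplotypePanel:
    """Phased haplotypes over biallelic sites: 0 = ref allele, 1 = alt."""

    site_ids: tuple[str, ...]
    matrix: np.ndarray  # shape (n_haplotypes, n_sites), entries {0, 1}

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=np.int8)
        object.__setattr__(self, "matrix", matrix)
        if matrix.ndim != 2:
            raise LDError("haplotype matrix must be 2-dimensional")
        if matrix.shape[0] < 2:
            raise LDError("panel needs at least 2 haplotypes")
        if matrix.shape[1] != len(self.site_ids):
            raise LDError("matrix width does not match the number of site ids")
        if not np.isin(matrix, (0, 1)).all():
            raise LDError("haplotype entries must be 0 (ref) or 1 (alt)")

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def site_index(self, site: SiteRef) -> int:
        if isinstance(site, str):
            try:
                return self.site_ids.index(site)
            except ValueError as exc:
                raise LDError(f"unknown site {site!r}") from exc
        if not 0 <= site < self.n_sites:
            raise LDError(f"site index {site} out of range")
        return site

    def alt_frequency(self, site: SiteRef) -> float:
        return float(self.matrix[:, self.site_index(site)].mean())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, columns=list(self.site_ids)).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HaplotypePanel":
        frame = pd.read_csv(path, sep="\t")
        return cls(tuple(frame.columns), frame.to_numpy(dtype=np.int8))


@dataclass(frozen=True)
class LDResult:
    site_i: str
    site_j: str
    p_a: float
    p_b: float
    p_ab: float
    d: float
    d_prime: float
    r2: float


def pair_ld(panel: HaplotypePanel, site_i: SiteRef, site_j: SiteRef) -> LDResult:
    """Exact D, D' and r^2 for one site pair from the haplotype panel.

    Both sites must be polymorphic (0 < p < 1); a monomorphic site raises
    :class:`LDError` naming the site.
    """
    i, j = panel.site_index(site_i), panel.site_index(site_j)
    col_i = panel.matrix[:, i]
    col_j = panel.matrix[:, j]
    n = panel.n_haplotypes
    n_a, n_b = int(col_i.sum()), int(col_j.sum())
    for count, idx in ((n_a, i), (n_b, j)):
        if count in (0, n):
            raise LDError(
                f"site {panel.site_ids[idx]!r} is monomorphic "
                f"({count}/{n} alt haplotypes)"
            )
    n_ab = int((col_i & col_j).sum())
    # exact rational arithmetic so that hard identities (D' = 1 in perfect
    # coupling, D = 0 under independence) come out exact, not within epsilon
    p_a, p_b, p_ab = Fraction(n_a, n), Fraction(n_b, n), Fraction(n_ab, n)
    d = p_ab - p_a * p_b
    if d > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = Fraction(0) if d == 0 else abs(d) / d_max
    r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    return LDResult(
        site_i=panel.site_ids[i],
        site_j=panel.site_ids[j],
        p_a=float(p_a),
        p_b=float(p_b),
        p_ab=float(p_ab),
        d=float(d),
        d_prime=float(d_prime),
        r2=float(r2),
    )


def all_pairs_ld(
    panel: HaplotypePanel, sites: Optional[Sequence[SiteRef]] = None
) -> list[LDResult]:
    """One LDResult per unordered site pair, C(n, 2) results in a fixed order."""
    if sites is None:
        indices = list(range(panel.n_sites))
    else:
        indices = [panel.site_index(s) for s in sites]
    if len(indices) < 2:
        raise LDError("need at least two sites for pairwise LD")
    return [pair_ld(panel, i, j) for i, j in combinations(indices, 2)]


@dataclass(frozen=True)
class CooccurrenceVerdict:
    cooccur: bool
    results: tuple[LDResult, ...]
    failing_pairs: tuple[tuple[str, str], ...]


def triplet_cooccurrence(
    panel: HaplotypePanel,
    sites: Optional[Sequence[SiteRef]] = None,
    dprime_min: float = 0.99,
    r2_min: float = 0.94,
) -> CooccurrenceVerdict:
    """Do the sites travel together as one haplotype?

    True iff every pairwise D' >= ``dprime_min`` and every r^2 >= ``r2_min``.
    The default thresholds encode near-perfect co-occurrence (D' of 1 and
    r^2 above ~0.94) with a little slack for floating point.
    """
    results = all_pairs_ld(panel, sites)
    failing = tuple(
        (res.site_i, res.site_j)
        for res in results
        if res.d_prime < dprime_min or res.r2 < r2_min
    )
    return CooccurrenceVerdict(
        cooccur=not failing, results=tuple(results), failing_pairs=failing
    )


def ld_table(results: Sequence[LDResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_i": r.site_i, "site_j": r.site_j,
                "p_a": r.p_a, "p_b": r.p_b, "p_ab": r.p_ab,
                "D": r.d, "D_prime": r.d_prime, "r2": r.r2,
            }
            for r in results
        ]
    )
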