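"""Background-relative fold enrichment of a category in a hit list.

Fold enrichment is (fraction of hits in the category) / (fraction of the
platform background in the category).  Fractions are kept as exact rationals
until final rendering, and the percentage rounding convention (hit percent to
0 decimals, background percent to 1 decimal, half-up) matches how such
numbers are conventionally printed — e.g. 117/341 -> 34%, 2044/54613 -> 3.7%,
a 9.2-fold enrichment.

A hypergeometric upper-tail p-value is attached as optional plumbing; it
never gates output.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Mapping

from scipy import stats

from .core_data import CategoryUniverse


def percent_half_up(numerator: int, denominator: int, decimals: int = 0) -> float:
    """Percentage with decimal half-up rounding (so 34.5 -> 35, not 34)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class EnrichmentResult:
    """Hit/background category counts, fractions, and fold enrichment."""

    category: str
    hits_in_category: int
    hits_total: int
    background_in_category: int
    background_total: int
    hit_level: str = "gene"
    background_level: str = "gene"
    hypergeom_p: float | None = None

    def __post_init__(self) -> None:
        if self.hits_total < 1:
            raise ValueError("hits_total must be >= 1")
        if self.background_in_category < 1:
            raise ValueError("background_in_category must be >= 1")
        if not 0 <= self.hits_in_category <= self.hits_total:
            raise ValueError("need 0 <= hits_in_category <= hits_total")
        if self.background_in_category > self.background_total:
            raise ValueError("background_in_category exceeds background_total")

    @property
    def hit_fraction_exact(self) -> Fraction:
        return Fraction(self.hits_in_category, self.hits_total)

    @property
    def background_fraction_exact(self) -> Fraction:
        return Fraction(self.background_in_category, self.background_total)

    @property
    def fold_exact(self) -> Fraction:
        return self.hit_fraction_exact / self.background_fraction_exact

    @property
    def hit_fraction(self) -> float:
        return float(self.hit_fraction_exact)

    @property
    def background_fraction(self) -> float:
        return float(self.background_fraction_exact)

    @property
    def fold(self) -> float:
        return float(self.fold_exact)

    @property
    def hit_percent(self) -> float:
        """Hit percentage rendered at 0 decimals, half-up."""
        return percent_half_up(self.hits_in_category, self.hits_total, 0)

    @property
    def background_percent(self) -> float:
        """Background percentage rendered at 1 decimal, half-up."""
        return percent_half_up(self.background_in_category, self.background_total, 1)

    def to_dict(self) -> dict:
        return {
            "category": self.category,
            "hits_in_category": self.hits_in_category,
            "hits_total": self.hits_total,
            "background_in_category": self.background_in_category,
            "background_total": self.background_total,
            "hit_fraction": self.hit_fraction,
            "background_fraction": self.background_fraction,
            "hit_percent": self.hit_percent,
            "background_percent": self.background_percent,
            "fold": self.fold,
            "hit_level": self.hit_level,
            "background_level": self.background_level,
            "hypergeom_p": self.hypergeom_p,
        }


def fold_enrichment(
    k: int,
    m: int,
    K: int,
    N: int,
    category: str = "",
    hit_level: str = "gene",
    background_level: str = "gene",
    with_p: bool = True,
) -> EnrichmentResult:
    """Fold enrichment of k/m hits against a K/N background.

    Parameters follow the 2x2 over-representation convention: ``k`` hits
    annotated to the category out of ``m`` total hits, against ``K`` annotated
    identifiers on a platform of ``N``.  The optional p-value is the
    hypergeometric upper tail P(X >= k) for X ~ Hypergeom(N, K, m).
    """
    res = EnrichmentResult(
        category=category,
        hits_in_category=k,
        hits_total=m,
        background_in_category=K,
        background_total=N,
        hit_level=hit_level,
        background_level=background_level,
    )
    if with_p and k <= K and m <= N:
        res.hypergeom_p = float(stats.hypergeom.sf(k - 1, N, K, m))
    return res


def enrich_screen_hits(
    hit_ids,
    universe: CategoryUniverse,
    category: str,
    hit_level: str = "probe",
    bridge: Mapping[str, str] | None = None,
) -> EnrichmentResult:
    """Enrichment of a category among screen hits against the platform universe.

    ``hit_ids`` must be at the universe's declared level, or a ``bridge``
    (e.g. probe → gene symbol) must be supplied to translate them; a level
    mismatch without a bridge is a hard error.
    """
    members = universe.members(category)
    ids = list(hit_ids)
    if hit_level != universe.level:
        if bridge is None:
            raise ValueError(
                f"hit level {hit_level!r} does not match universe level "
                f"{universe.level!r} and no bridge was supplied"
            )
        ids = [bridge[h] for h in ids if h in bridge]
    ids = list(dict.fromkeys(ids))  # dedupe, order-preserving
    if not ids:
        raise ValueError("no hits to enrich")
    k = sum(1 for h in ids if h in members)
    return fold_enrichment(
        k,
        len(ids),
        len(members),
        universe.universe_size,
        category=category,
        hit_level=universe.level,
        background_level=universe.level,
    )
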