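"""Pool set algebra and the per-category summary of group-specific variants.

Variant identity for the cross-pool Venn logic is the normalized
(contig, pos, ref, alt) key; per-pool frequencies or p-values do not enter
identity.  Percentages are rounded half-up to one decimal.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Iterable, List, Set, Tuple, Union

import pandas as pd

from .dtypes import (
    AA_CHANGING_CLASSES,
    AnnotatedVariant,
    NEAR_GENE_CLASSES,
    NONCODING_CLASSES,
    CODING_CLASSES,
    REGION_CLASSES,
    VariantCall,
)

Key = Tuple[str, int, str, str]
KeyLike = Union[VariantCall, Key]


def pct(numer: int, denom: int) -> float:
    """100*numer/denom rounded half-up to one decimal; 0.0 for denom 0."""
    if denom == 0:
        return 0.0
    q = (Decimal(100) * Decimal(numer) / Decimal(denom)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP
    )
    return float(q)


def _keys(calls: Iterable[KeyLike], pool_name: str) -> Set[Key]:
    out: Set[Key] = set()
    for c in calls:
        key = c.key if isinstance(c, VariantCall) else tuple(c)
        if key in out:
            raise ValueError(
                f"duplicate variant key {key} in pool {pool_name!r}; "
                "normalize calls upstream"
            )
        out.add(key)
    return out


@dataclass(frozen=True)
class ComparisonResult:
    """Shared and group-specific variant keys of the two pools."""

    shared: Set[Key]
    specific_low: Set[Key]
    specific_high: Set[Key]
    fraction_low: float  # shared as % of pool L, 1 decimal
    fraction_high: float  # shared as % of pool H, 1 decimal

    @property
    def n_low(self) -> int:
        return len(self.shared) + len(self.specific_low)

    @property
    def n_high(self) -> int:
        return len(self.shared) + len(self.specific_high)


def compare_pools(
    calls_low: Iterable[KeyLike], calls_high: Iterable[KeyLike]
) -> ComparisonResult:
    """Exact set intersection/differences of the two pools' variant keys."""
    low = _keys(calls_low, "low")
    high = _keys(calls_high, "high")
    shared = low & high
    return ComparisonResult(
        shared=shared,
        specific_low=low - shared,
        specific_high=high - shared,
        fraction_low=pct(len(shared), len(low)),
        fraction_high=pct(len(shared), len(high)),
    )


@dataclass
class CategorySummary:
    """Per-pool category counts with the standard roll-ups."""

    counts: Dict[str, Counter] = field(default_factory=dict)

    def count(self, pool: str, category: str) -> int:
        return self.counts[pool][category]

    def noncoding_total(self, pool: str) -> int:
        return sum(self.counts[pool][c] for c in NONCODING_CLASSES)

    def coding_total(self, pool: str) -> int:
        return sum(self.counts[pool][c] for c in CODING_CLASSES)

    def aa_changing_total(self, pool: str) -> int:
        return sum(self.counts[pool][c] for c in AA_CHANGING_CLASSES)

    def near_gene_total(self, pool: str) -> int:
        return sum(self.counts[pool][c] for c in NEAR_GENE_CLASSES)

    def grand_total(self, pool: str) -> int:
        return sum(self.counts[pool].values())

    def aa_changing_pct(self, pool: str) -> float:
        return pct(self.aa_changing_total(pool), self.grand_total(pool))

    def to_frame(self) -> pd.DataFrame:
        pools = list(self.counts)
        rows = []
        rows.append(
            ["non-coding region"] + [self.noncoding_total(p) for p in pools]
        )
        for c in NONCODING_CLASSES:
            rows.append([c] + [self.counts[p][c] for p in pools])
        rows.append(
            ["coding region"] + [self.coding_total(p) for p in pools]
        )
        for c in CODING_CLASSES:
            rows.append([c] + [self.counts[p][c] for p in pools])
        rows.append(["Total"] + [self.grand_total(p) for p in pools])
        return pd.DataFrame(rows, columns=["category"] + pools)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _labels(variants: Iterable[Union[AnnotatedVariant, str]]) -> List[str]:
    out = []
    for v in variants:
        label = v if isinstance(v, str) else v.region_class
        if label not in REGION_CLASSES:
            raise ValueError(f"unknown category label {label!r}")
        out.append(label)
    return out


def summarize_categories(
    annotated_low_specific: Iterable[Union[AnnotatedVariant, str]],
    annotated_high_specific: Iterable[Union[AnnotatedVariant, str]],
    pool_low: str = "low-specific",
    pool_high: str = "high-specific",
) -> CategorySummary:
    """Tabulate group-specific variants per category for both pools.

    Inputs are annotated variants (or bare category labels); they must
    already be restricted to the group-specific sets.
    """
    return CategorySummary(
        counts={
            pool_low: Counter(_labels(annotated_low_specific)),
            pool_high: Counter(_labels(annotated_high_specific)),
        }
    )


def affected_genes(
    annotated_low_specific: Iterable[AnnotatedVariant],
    annotated_high_specific: Iterable[AnnotatedVariant],
) -> Set[str]:
    """Genes hit by an amino-acid-changing variant in either group."""
    genes: Set[str] = set()
    for group in (annotated_low_specific, annotated_high_specific):
        for a in group:
            if a.region_class in AA_CHANGING_CLASSES:
                genes.update(a.gene_ids)
    return genes
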