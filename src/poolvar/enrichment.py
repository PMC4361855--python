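"""Fisher-exact over-representation of functional categories.

For each category the one-sided (enrichment-only) hypergeometric upper
tail is computed over a gene universe of N background genes, of which K
carry the category, with n study genes and k category hits; p-values are
Benjamini-Hochberg adjusted across all tested categories.  Genes may
carry several category labels and count once per label; N counts genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Set, Union

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["EnrichmentResult", "fisher_enrichment"]


@dataclass(frozen=True)
class EnrichmentResult:
    category_label: str
    k: int  # category hits in the study set
    n: int  # study set size
    K: int  # category size in the background
    N: int  # background size
    p_value: float
    fdr: float
    significant: bool


def _label_sets(
    background: Mapping[str, Union[str, Iterable[str]]]
) -> Dict[str, Set[str]]:
    out: Dict[str, Set[str]] = {}
    for gene, labels in background.items():
        if labels is None:
            out[gene] = set()
        elif isinstance(labels, str):
            out[gene] = {labels} if labels else set()
        else:
            out[gene] = set(labels)
    return out


def fisher_enrichment(
    study: Iterable[str],
    background: Mapping[str, Union[str, Iterable[str]]],
    cutoff: float = 0.01,
    cutoff_on: str = "fdr",
) -> List[EnrichmentResult]:
    """One-sided Fisher/hypergeometric enrichment with BH FDR control.

    ``background`` maps every gene in the universe to its category
    label(s) (possibly none).  ``cutoff_on`` selects whether the
    significance flag is gated on the adjusted ("fdr") or raw ("p") value.
    Results are sorted by p-value.
    """
    if cutoff_on not in ("fdr", "p"):
        raise ValueError("cutoff_on must be 'fdr' or 'p'")
    labels_by_gene = _label_sets(background)
    study_set = set(study)
    missing = sorted(study_set - set(labels_by_gene))
    if missing:
        raise ValueError(
            f"study gene(s) absent from background: {', '.join(missing)}"
        )
    N = len(labels_by_gene)
    n = len(study_set)
    categories = sorted({c for s in labels_by_gene.values() for c in s})
    if not categories:
        raise ValueError("background defines no categories")

    rows = []
    for cat in categories:
        K = sum(1 for s in labels_by_gene.values() if cat in s)
        k = sum(1 for g in study_set if cat in labels_by_gene[g])
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((cat, k, K, min(p, 1.0)))

    pvals = [r[3] for r in rows]
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        EnrichmentResult(
            category_label=cat,
            k=k,
            n=n,
            K=K,
            N=N,
            p_value=p,
            fdr=float(fdr),
            significant=(fdr if cutoff_on == "fdr" else p) <= cutoff,
        )
        for (cat, k, K, p), fdr in zip(rows, fdrs)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.category_label))


def enrichment_frame(results: List[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.category_label, r.k, r.n, r.K, r.N, r.p_value, r.fdr,
             r.significant)
            for r in results
        ],
        columns=["category", "k", "n", "K", "N", "p_value", "fdr",
                 "significant"],
    )
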