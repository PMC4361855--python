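"""Protein family clustering and core/dispensable/specific analysis.

Families are single-linkage connected components over pairwise similarity
edges that pass identity (>50%), coverage (>70%) and significance gates —
the minimal reading of threshold-based clustering of all-vs-all protein
hits.  A family present in every species of the panel is *core*, in
exactly one *specific*, otherwise *dispensable*.  The built-in aligner is
Smith-Waterman (BLOSUM62, BLAST-style affine gaps 11 open / 1 extend); it
reports a raw score rather than an E-value, so built-in edges are gated
on a score floor instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import pearsonr

__all__ = [
    "ProteinRecord",
    "SimilarityEdge",
    "ProteinFamily",
    "PanGenomeSummary",
    "pairwise_similarity",
    "build_similarity_edges",
    "cluster_families",
    "classify_and_summarize",
    "density_profile",
]

_AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein of one species; positions are optional and only used
    for chromosomal density profiles."""

    protein_id: str
    species_id: str
    sequence: str
    chrom_pos: Optional[int] = None  # genomic midpoint, 1-based
    chrom_length: Optional[int] = None

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _AA20 - {"X"}
        if bad:
            raise ValueError(
                f"protein {self.protein_id!r}: invalid residue(s) "
                f"{''.join(sorted(bad))}"
            )


@dataclass(frozen=True)
class SimilarityEdge:
    query_id: str
    subject_id: str
    pct_identity: float  # percent over aligned columns
    cov_query: float  # aligned fraction of the query sequence
    cov_subject: float
    evalue: Optional[float] = None  # ingested BLAST hits
    score: Optional[float] = None  # built-in alignment


@dataclass
class ProteinFamily:
    family_id: str  # lexicographically smallest member id
    member_ids: Tuple[str, ...]
    member_species: Tuple[str, ...]
    family_class: Optional[str] = None  # core | dispensable | specific

    @property
    def species_presence(self) -> frozenset:
        return frozenset(self.member_species)


def _default_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST gap cost 11 + 1*L; Biopython charges open on the first residue
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _default_aligner()


def pairwise_similarity(
    a: ProteinRecord,
    b: ProteinRecord,
    aligner: Optional[Align.PairwiseAligner] = None,
) -> SimilarityEdge:
    """Local alignment of two proteins into a similarity edge.

    Identity is matches over aligned columns (gap columns included, X
    excluded from the numerator); coverage is each sequence's aligned
    span over its length.  Deterministic: the aligner's first optimal
    alignment is used.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align an empty sequence")
    aligner = aligner or _ALIGNER
    aln = aligner.align(a.sequence, b.sequence)[0]
    blocks_a, blocks_b = aln.aligned
    matched_cols = 0
    matches = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        matched_cols += a1 - a0
        for x, y in zip(a.sequence[a0:a1], b.sequence[b0:b1]):
            if x == y and x != "X":
                matches += 1
    span_a = int(blocks_a[-1][1] - blocks_a[0][0]) if len(blocks_a) else 0
    span_b = int(blocks_b[-1][1] - blocks_b[0][0]) if len(blocks_b) else 0
    columns = span_a + span_b - matched_cols
    identity = 100.0 * matches / columns if columns else 0.0
    return SimilarityEdge(
        query_id=a.protein_id,
        subject_id=b.protein_id,
        pct_identity=identity,
        cov_query=span_a / len(a.sequence),
        cov_subject=span_b / len(b.sequence),
        evalue=None,
        score=float(aln.score),
    )


def build_similarity_edges(
    proteins: Sequence[ProteinRecord],
    aligner: Optional[Align.PairwiseAligner] = None,
) -> List[SimilarityEdge]:
    """All-vs-all (i < j) built-in similarity edges."""
    return [
        pairwise_similarity(a, b, aligner)
        for a, b in itertools.combinations(proteins, 2)
    ]


def _edge_passes(
    e: SimilarityEdge,
    min_identity: float,
    min_coverage: float,
    max_evalue: float,
    min_score: float,
    coverage_mode: str,
) -> bool:
    if e.pct_identity <= min_identity:
        return False
    cov = {
        "min": min(e.cov_query, e.cov_subject),
        "query": e.cov_query,
        "subject": e.cov_subject,
    }[coverage_mode]
    if cov <= min_coverage:
        return False
    if e.evalue is not None:
        return e.evalue <= max_evalue
    if e.score is not None:
        return e.score >= min_score
    return True


def cluster_families(
    proteins: Sequence[ProteinRecord],
    edges: Iterable[SimilarityEdge],
    min_identity: float = 50.0,
    min_coverage: float = 0.70,
    max_evalue: float = 1e-5,
    min_score: float = 50.0,
    coverage_mode: str = "min",
) -> List[ProteinFamily]:
    """Single-linkage protein families over qualifying edges.

    An edge qualifies when identity > ``min_identity``, coverage >
    ``min_coverage`` (``coverage_mode`` selects min/query/subject) and its
    significance passes (E <= ``max_evalue`` for ingested hits, raw score
    >= ``min_score`` for built-in alignments).  Unconnected proteins form
    singleton families; family ids are the lexicographically smallest
    member id.
    """
    if coverage_mode not in ("min", "query", "subject"):
        raise ValueError("coverage_mode must be min, query or subject")
    species_of = {p.protein_id: p.species_id for p in proteins}
    if len(species_of) != len(proteins):
        raise ValueError("duplicate protein ids")
    graph = nx.Graph()
    graph.add_nodes_from(species_of)
    for e in edges:
        for pid in (e.query_id, e.subject_id):
            if pid not in species_of:
                raise ValueError(f"edge references unknown protein {pid!r}")
        if e.query_id != e.subject_id and _edge_passes(
            e, min_identity, min_coverage, max_evalue, min_score,
            coverage_mode,
        ):
            graph.add_edge(e.query_id, e.subject_id)
    families = []
    for comp in nx.connected_components(graph):
        members = tuple(sorted(comp))
        families.append(
            ProteinFamily(
                family_id=members[0],
                member_ids=members,
                member_species=tuple(species_of[m] for m in members),
            )
        )
    return sorted(families, key=lambda f: f.family_id)


@dataclass
class PanGenomeSummary:
    """Per-species and global pan-genome statistics."""

    per_species: pd.DataFrame
    family_counts: Dict[str, int]
    correlations: Dict[str, Tuple[float, float]]  # class -> (R^2, p)


def classify_and_summarize(
    families: Sequence[ProteinFamily],
    species_meta: Mapping[str, Optional[float]],
) -> PanGenomeSummary:
    """Classify families and compute the per-species statistics.

    ``species_meta`` maps every species of the panel to its genome size
    (bp), or None when sizes are unknown (correlations are then skipped).
    The expansion rate of a species is its core-gene count divided by the
    number of core families (mean paralog load of the core, 2 decimals);
    the specific/core ratio is per-species (3 decimals).
    """
    all_species = set(species_meta)
    if len(all_species) < 2:
        raise ValueError("pan-genome classes need at least two species")
    for fam in families:
        extra = fam.species_presence - all_species
        if extra:
            raise ValueError(
                f"family {fam.family_id!r} has unknown species {extra}"
            )
        if fam.species_presence == all_species:
            fam.family_class = "core"
        elif len(fam.species_presence) == 1:
            fam.family_class = "specific"
        else:
            fam.family_class = "dispensable"

    n_core_families = sum(1 for f in families if f.family_class == "core")
    counts = {
        sp: {"core": 0, "dispensable": 0, "specific": 0}
        for sp in sorted(all_species)
    }
    for fam in families:
        for sp in fam.member_species:
            counts[sp][fam.family_class] += 1

    rows = []
    for sp in sorted(all_species):
        c = counts[sp]
        total = c["core"] + c["dispensable"] + c["specific"]
        # truncated (not rounded) to 2 decimals, the convention used when
        # quoting expansion rates next to their gene/family fractions
        expansion = (
            int(c["core"] / n_core_families * 100) / 100
            if n_core_families
            else float("nan")
        )
        ratio = (
            round(c["specific"] / c["core"], 3) if c["core"] else float("nan")
        )
        rows.append(
            (sp, total, c["core"], c["dispensable"], c["specific"],
             expansion, ratio)
        )
    per_species = pd.DataFrame(
        rows,
        columns=[
            "species", "total_genes", "core_genes", "dispensable_genes",
            "specific_genes", "expansion_rate", "specific_core_ratio",
        ],
    ).set_index("species")
    assert (
        per_species["total_genes"]
        == per_species[["core_genes", "dispensable_genes", "specific_genes"]].sum(axis=1)
    ).all(), "per-species class counts must sum to totals"

    family_counts = {
        "core": n_core_families,
        "dispensable": sum(1 for f in families if f.family_class == "dispensable"),
        "specific": sum(1 for f in families if f.family_class == "specific"),
        "total": len(families),
    }
    assert (
        family_counts["core"] + family_counts["dispensable"]
        + family_counts["specific"] == family_counts["total"]
    )

    correlations: Dict[str, Tuple[float, float]] = {}
    sizes = [species_meta[sp] for sp in per_species.index]
    if all(s is not None for s in sizes) and len(sizes) >= 3:
        for cls in ("core", "dispensable", "specific"):
            x = np.asarray(sizes, dtype=float)
            y = per_species[f"{cls}_genes"].to_numpy(dtype=float)
            if np.ptp(x) > 0 and np.ptp(y) > 0:
                r, p = pearsonr(x, y)
                correlations[cls] = (r * r, p)
    return PanGenomeSummary(
        per_species=per_species,
        family_counts=family_counts,
        correlations=correlations,
    )


def density_profile(
    proteins: Sequence[ProteinRecord],
    families: Sequence[ProteinFamily],
    bin_bp: int = 400_000,
) -> pd.DataFrame:
    """Per-class gene-density histograms along each species' chromosome.

    Bins are fixed ``bin_bp`` windows; per (species, class) the proportion
    of that species' class genes falling in each bin is reported, with
    bin starts expressed as percent of chromosome length.  Proportions of
    each (species, class) sum to 1.
    """
    class_of_protein: Dict[str, str] = {}
    for fam in families:
        if fam.family_class is None:
            raise ValueError("families must be classified first")
        for pid in fam.member_ids:
            class_of_protein[pid] = fam.family_class
    missing = [
        p.protein_id
        for p in proteins
        if p.protein_id in class_of_protein
        and (p.chrom_pos is None or p.chrom_length is None)
    ]
    if missing:
        raise ValueError(
            "missing chromosome positions for: " + ", ".join(sorted(missing))
        )

    rows = []
    by_group: Dict[Tuple[str, str], List[ProteinRecord]] = {}
    for p in proteins:
        if p.protein_id in class_of_protein:
            key = (p.species_id, class_of_protein[p.protein_id])
            by_group.setdefault(key, []).append(p)
    for (sp, cls), members in sorted(by_group.items()):
        chrom_len = members[0].chrom_length
        n_bins = max(1, -(-chrom_len // bin_bp))  # ceil
        hist = np.zeros(n_bins)
        for p in members:
            b = min((p.chrom_pos - 1) // bin_bp, n_bins - 1)
            hist[b] += 1
        props = hist / hist.sum()
        for b in range(n_bins):
            rows.append(
                (sp, cls, b, 100.0 * (b * bin_bp) / chrom_len, props[b])
            )
    return pd.DataFrame(
        rows,
        columns=["species", "family_class", "bin", "bin_start_pct",
                 "proportion"],
    )
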