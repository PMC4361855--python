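"""Functional classification of variant calls against gene models.

Each variant receives exactly one category from a fixed vocabulary:
coding variants are classified by their protein-level effect (bacterial
genetic code, translation table 11), and non-coding variants by their
position relative to near-gene windows (default 300 bp) on the
strand-aware 5'/3' sides of neighbouring genes.  A variant upstream of
one gene and downstream of another gets the combined class
"upstream;downstream".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from Bio.Data import CodonTable

from .dtypes import (
    AnnotatedVariant,
    GeneModel,
    GenomeSequence,
    VariantCall,
    reverse_complement,
)

__all__ = ["AnnotatedVariant", "classify_variant", "annotate_set"]

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: most-severe-first order used when a variant hits several CDSs
_SEVERITY = (
    "stopgain SNV",
    "frameshift insertion",
    "frameshift deletion",
    "stoploss SNV",
    "nonsynonymous SNV",
    "nonframeshift insertion",
    "nonframeshift deletion",
    "synonymous SNV",
)


def translate_codon(codon: str) -> str:
    """One-letter residue for a codon under table 11; '*' for a stop."""
    if codon in _TABLE11.stop_codons:
        return "*"
    return _TABLE11.forward_table[codon]


def _genome_lookup(
    genome: Union[GenomeSequence, Dict[str, GenomeSequence]], contig: str
) -> GenomeSequence:
    if isinstance(genome, GenomeSequence):
        if genome.contig_id != contig:
            raise ValueError(f"no sequence for contig {contig!r}")
        return genome
    return genome[contig]


@dataclass(frozen=True)
class _CodingEffect:
    region_class: str
    gene_id: str
    aa_change: Optional[str]
    cds_change: Optional[str]


def _snv_effect(
    call: VariantCall, gene: GeneModel, seq: str
) -> _CodingEffect:
    cds = seq[gene.start - 1 : gene.end]
    if gene.strand == "-":
        cds = reverse_complement(cds)
        off = gene.end - call.pos
        alt_base = call.alt.translate(_COMPLEMENT)
    else:
        off = call.pos - gene.start
        alt_base = call.alt
    ci, co = divmod(off, 3)
    codon = cds[3 * ci : 3 * ci + 3]
    alt_codon = codon[:co] + alt_base + codon[co + 1 :]
    ref_aa = translate_codon(codon)
    alt_aa = translate_codon(alt_codon)
    if ref_aa == alt_aa:
        cls = "synonymous SNV"
    elif alt_aa == "*":
        cls = "stopgain SNV"
    elif ref_aa == "*":
        cls = "stoploss SNV"
    else:
        cls = "nonsynonymous SNV"
    return _CodingEffect(
        region_class=cls,
        gene_id=gene.gene_id,
        aa_change=f"{ref_aa}{ci + 1}{alt_aa}",
        cds_change=None,
    )


def _indel_effect(call: VariantCall, gene: GeneModel) -> _CodingEffect:
    if call.vtype == "insertion":
        ins = call.alt[1:]
        shift = len(ins) % 3 != 0
        cls = "frameshift insertion" if shift else "nonframeshift insertion"
        if gene.strand == "+":
            c1 = call.pos - gene.start + 1
            change = f"{c1}_{c1 + 1}ins{ins}"
        else:
            c1 = gene.end - call.pos
            change = f"{c1}_{c1 + 1}ins{reverse_complement(ins)}"
    else:
        dlen = len(call.ref) - 1
        shift = dlen % 3 != 0
        cls = "frameshift deletion" if shift else "nonframeshift deletion"
        g_lo, g_hi = call.pos + 1, call.pos + dlen
        if gene.strand == "+":
            a, b = g_lo - gene.start + 1, g_hi - gene.start + 1
        else:
            a, b = gene.end - g_hi + 1, gene.end - g_lo + 1
        change = f"{a}_{b}del"
    return _CodingEffect(
        region_class=cls,
        gene_id=gene.gene_id,
        aa_change=None,
        cds_change=change,
    )


def _coding_genes(
    call: VariantCall, models: Sequence[GeneModel]
) -> List[GeneModel]:
    """CDS genes whose bases are touched by the variant."""
    hits = []
    for g in models:
        if not g.is_cds or g.contig_id != call.contig_id:
            continue
        if call.vtype == "SNV":
            inside = g.start <= call.pos <= g.end
        elif call.vtype == "insertion":
            # inserted between pos and pos+1: both neighbours must be coding
            inside = g.start <= call.pos < g.end
        else:
            d_lo, d_hi = call.pos + 1, call.pos + len(call.ref) - 1
            inside = not (d_hi < g.start or d_lo > g.end)
        if inside:
            hits.append(g)
    return hits


def _flank_hits(
    call: VariantCall,
    models: Sequence[GeneModel],
    window_bp: int,
    strand_aware: bool,
) -> Tuple[List[Tuple[int, str]], List[Tuple[int, str]]]:
    """(distance, gene_id) lists for 5'-side and 3'-side window membership."""
    up: List[Tuple[int, str]] = []
    down: List[Tuple[int, str]] = []
    pos = call.pos
    for g in models:
        if g.contig_id != call.contig_id:
            continue
        before = g.start - window_bp <= pos <= g.start - 1  # left of gene
        after = g.end + 1 <= pos <= g.end + window_bp  # right of gene
        strand = g.strand if strand_aware else "+"
        if before:
            (up if strand == "+" else down).append((g.start - pos, g.gene_id))
        if after:
            (down if strand == "+" else up).append((pos - g.end, g.gene_id))
    return sorted(up), sorted(down)


def classify_variant(
    call: VariantCall,
    models: Sequence[GeneModel],
    genome: Union[GenomeSequence, Dict[str, GenomeSequence]],
    window_bp: int = 300,
    strand_aware: bool = True,
    severity_resolution: bool = True,
) -> AnnotatedVariant:
    """Assign the variant exactly one functional category.

    Precedence: CDS overlap -> coding effect; else membership of the 5'
    and/or 3' near-gene windows -> upstream / downstream /
    "upstream;downstream"; else intergenic.  When several CDSs overlap, the
    most severe effect wins if ``severity_resolution`` (all gene ids are
    retained); otherwise the first gene in model order is used.
    """
    seq_rec = _genome_lookup(genome, call.contig_id)
    if not (1 <= call.pos <= len(seq_rec)):
        raise ValueError(
            f"variant {call.contig_id}:{call.pos} outside contig bounds"
        )
    seq = seq_rec.sequence

    coding = _coding_genes(call, models)
    if coding:
        effects = [
            _snv_effect(call, g, seq)
            if call.vtype == "SNV"
            else _indel_effect(call, g)
            for g in coding
        ]
        if severity_resolution:
            chosen = min(effects, key=lambda e: _SEVERITY.index(e.region_class))
        else:
            chosen = effects[0]
        return AnnotatedVariant(
            call=call,
            region_class=chosen.region_class,
            gene_ids=tuple(sorted(g.gene_id for g in coding)),
            aa_change=chosen.aa_change,
            cds_change=chosen.cds_change,
            window_bp=window_bp,
        )

    up, down = _flank_hits(call, models, window_bp, strand_aware)
    if up and down:
        cls = "upstream;downstream"
        genes = tuple(sorted({g for _, g in up} | {g for _, g in down}))
    elif up:
        cls, genes = "upstream", tuple(g for _, g in up)
    elif down:
        cls, genes = "downstream", tuple(g for _, g in down)
    else:
        cls, genes = "intergenic", ()
    return AnnotatedVariant(
        call=call,
        region_class=cls,
        gene_ids=genes,
        aa_change=None,
        cds_change=None,
        window_bp=window_bp,
    )


def annotate_set(
    calls: Iterable[VariantCall],
    models: Sequence[GeneModel],
    genome: Union[GenomeSequence, Dict[str, GenomeSequence]],
    window_bp: int = 300,
    strand_aware: bool = True,
    severity_resolution: bool = True,
) -> List[AnnotatedVariant]:
    """Elementwise :func:`classify_variant`, preserving input order."""
    return [
        classify_variant(
            c, models, genome, window_bp, strand_aware, severity_resolution
        )
        for c in calls
    ]


def write_annotated_tsv(annotated: Sequence[AnnotatedVariant], path) -> None:
    """TSV report; the category column uses the vocabulary verbatim."""
    import pandas as pd

    rows = [
        {
            "contig": a.call.contig_id,
            "pos": a.call.pos,
            "ref": a.call.ref,
            "alt": a.call.alt,
            "pool": a.call.pool_id,
            "var_freq": a.call.var_freq,
            "region_class": a.region_class,
            "gene_ids": ",".join(a.gene_ids),
            "aa_change": a.aa_change or "",
            "cds_change": a.cds_change or "",
            "window_bp": a.window_bp,
        }
        for a in annotated
    ]
    pd.DataFrame(
        rows,
        columns=[
            "contig",
            "pos",
            "ref",
            "alt",
            "pool",
            "var_freq",
            "region_class",
            "gene_ids",
            "aa_change",
            "cds_change",
            "window_bp",
        ],
    ).to_csv(path, sep="\t", index=False)
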