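"""Core value types shared across the pipeline stages.

All genomic coordinates are 1-based and inclusive, matching GFF3 and the
samtools pileup dialect; any half-open arithmetic is confined to the code
that needs it and never leaks through these types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N self-pairs)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A single replicon: one chromosome or plasmid sequence."""

    contig_id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for contig {self.contig_id!r}")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"contig {self.contig_id!r} contains non-ACGTN character(s): "
                f"{''.join(sorted(bad))}"
            )
        if self.topology not in ("linear", "circular"):
            raise ValueError(f"unknown topology {self.topology!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene (optionally a CDS) on a contig.

    ``category_label`` is a COG-style single-letter functional class used by
    the enrichment stage; ``product`` is free text.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    is_cds: bool = True
    category_label: Optional[str] = None
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        if self.is_cds and (self.end - self.start + 1) % 3 != 0:
            raise ValueError(
                f"CDS {self.gene_id!r}: length {self.end - self.start + 1} "
                "not divisible by 3"
            )
        if self.category_label is not None and (
            len(self.category_label) != 1 or not self.category_label.isupper()
        ):
            raise ValueError(
                f"gene {self.gene_id!r}: category_label must be A..Z"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class PileupSite:
    """Per-position, per-strand allele counts for one pooled library.

    ``allele_counts`` maps an allele to (forward, reverse) read counts.  An
    allele is a single base, an insertion spelled ``+SEQ`` or a deletion
    spelled ``-SEQ``.  A read that carries an indel supports the indel
    allele (not the reference), so ``depth`` always equals the sum of all
    counts over alleles and strands.
    """

    contig_id: str
    pos: int
    ref_base: str
    depth: int
    allele_counts: Dict[str, Tuple[int, int]]
    mean_baseq: float

    def __post_init__(self) -> None:
        total = sum(f + r for f, r in self.allele_counts.values())
        if total != self.depth:
            raise ValueError(
                f"{self.contig_id}:{self.pos}: depth {self.depth} != "
                f"summed allele counts {total}"
            )
        if any(f < 0 or r < 0 for f, r in self.allele_counts.values()):
            raise ValueError(f"{self.contig_id}:{self.pos}: negative count")


@dataclass(frozen=True)
class VariantCall:
    """A normalized, anchored variant call from one pool.

    ``pos``/``ref``/``alt`` follow the VCF anchoring convention: SNVs are a
    single base each; indels carry the anchor base so that
    (contig, pos, ref, alt) keys are comparable across pools.
    """

    contig_id: str
    pos: int
    ref: str
    alt: str
    vtype: str  # SNV | insertion | deletion
    depth: int
    alt_count: int
    var_freq: float
    alt_fwd: int
    alt_rev: int
    p_value: float
    pool_id: str

    def __post_init__(self) -> None:
        if self.vtype not in ("SNV", "insertion", "deletion"):
            raise ValueError(f"unknown vtype {self.vtype!r}")
        if self.alt_fwd + self.alt_rev != self.alt_count:
            raise ValueError("alt_count must equal alt_fwd + alt_rev")
        if not (0 < self.var_freq <= 1):
            raise ValueError("var_freq must lie in (0, 1]")

    @property
    def key(self) -> Tuple[str, int, str, str]:
        """Identity used for cross-pool set algebra."""
        return (self.contig_id, self.pos, self.ref, self.alt)


#: The full functional-category vocabulary, one label per variant.
NONCODING_CLASSES = (
    "intergenic",
    "upstream",
    "downstream",
    "upstream;downstream",
)
CODING_CLASSES = (
    "synonymous SNV",
    "nonsynonymous SNV",
    "frameshift deletion",
    "frameshift insertion",
    "nonframeshift deletion",
    "nonframeshift insertion",
    "stopgain SNV",
    "stoploss SNV",
)
REGION_CLASSES = NONCODING_CLASSES + CODING_CLASSES

#: Classes whose variants alter the protein sequence.
AA_CHANGING_CLASSES = frozenset(
    c for c in CODING_CLASSES if c != "synonymous SNV"
)
#: Near-gene regulatory-candidate classes.
NEAR_GENE_CLASSES = frozenset(
    ("upstream", "downstream", "upstream;downstream")
)


@dataclass(frozen=True)
class AnnotatedVariant:
    """A variant call plus exactly one functional category."""

    call: VariantCall
    region_class: str
    gene_ids: Tuple[str, ...] = field(default_factory=tuple)
    aa_change: Optional[str] = None
    cds_change: Optional[str] = None
    window_bp: int = 300

    def __post_init__(self) -> None:
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        aa_bearing = self.region_class in (
            "synonymous SNV",
            "nonsynonymous SNV",
            "stopgain SNV",
            "stoploss SNV",
        )
        if (self.aa_change is not None) != aa_bearing:
            raise ValueError(
                f"aa_change must be present iff the class carries an amino "
                f"acid change (class {self.region_class!r})"
            )
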