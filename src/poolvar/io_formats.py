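"""Readers and writers for the standard formats the pipeline touches.

FASTA is read through Biopython, GFF3 through gffutils and VCF through
pysam; the samtools text-pileup base string is decoded here because its
per-read semantics (strand case, ``^``/``$`` markers, attached indels) are
what the pooled caller consumes.
"""

from __future__ import annotations

import logging
import os
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Tuple, Union

import pysam
from Bio import SeqIO

from .dtypes import (
    DNA_ALPHABET,
    GeneModel,
    GenomeSequence,
    PileupSite,
    VariantCall,
)

logger = logging.getLogger(__name__)

PathOrLines = Union[str, os.PathLike, Iterable[str]]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, os.PathLike]) -> List[GenomeSequence]:
    """Read a FASTA file into :class:`GenomeSequence` records.

    Sequences are upper-cased and U is normalized to T; any character
    outside ACGTN is rejected.  Duplicate record ids are an error.
    """
    records: List[GenomeSequence] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {rec.id!r} contains invalid character(s): "
                f"{''.join(sorted(bad))}"
            )
        records.append(GenomeSequence(contig_id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    records: Sequence[GenomeSequence],
    path: Union[str, os.PathLike],
    width: int = 70,
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.contig_id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: Union[str, os.PathLike]) -> List[GeneModel]:
    """Read gene models from GFF3.

    Only ``gene`` and ``CDS`` features carrying an ``ID`` attribute are
    consumed; other feature types are ignored with a logged count.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: List[GeneModel] = []
    skipped = 0
    for feat in db.all_features(order_by=("seqid", "start")):
        if feat.featuretype not in ("gene", "CDS") or "ID" not in feat.attributes:
            skipped += 1
            continue
        category = feat.attributes.get("category_label", [None])[0]
        product = feat.attributes.get("product", [None])[0]
        models.append(
            GeneModel(
                gene_id=feat.attributes["ID"][0],
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                is_cds=(feat.featuretype == "CDS"),
                category_label=category,
                product=product,
            )
        )
    if skipped:
        logger.info("read_gff3: ignored %d non-gene/CDS features", skipped)
    return models


def write_gff3(
    models: Sequence[GeneModel], path: Union[str, os.PathLike]
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            attrs = [f"ID={m.gene_id}"]
            if m.category_label:
                attrs.append(f"category_label={m.category_label}")
            if m.product:
                attrs.append(f"product={m.product}")
            ftype = "CDS" if m.is_cds else "gene"
            fh.write(
                f"{m.contig_id}\tpoolvar\t{ftype}\t{m.start}\t{m.end}\t.\t"
                f"{m.strand}\t0\t{';'.join(attrs)}\n"
            )


# ---------------------------------------------------------------------------
# samtools pileup (6/7-column)
# ---------------------------------------------------------------------------

import re

_SPECIAL_RE = re.compile(r"[^.,ACGTacgt]")


def _decode_simple(
    ref: str, bases: str, quals: str, line_no: int
) -> Tuple[Dict[str, Tuple[int, int]], int, float]:
    """Fast path: no markers/indels and a uniform passing quality string."""
    if len(bases) != len(quals):
        raise ValueError(
            f"pileup line {line_no}: depth/quality-string length mismatch "
            f"({len(bases)} bases, {len(quals)} qualities)"
        )
    counts: Dict[str, Tuple[int, int]] = {}
    depth = 0
    for b in "ACGT":
        f = bases.count(b)
        r = bases.count(b.lower())
        if b == ref:  # explicit ref letters fold into the ref allele
            f += bases.count(".")
            r += bases.count(",")
        if f or r:
            counts[b] = (f, r)
            depth += f + r
    bq = ord(quals[0]) - 33
    return counts, depth, float(bq)


def _decode_read_bases(
    ref: str,
    bases: str,
    quals: str,
    mapqs: str,
    min_baseq: int,
    min_mapq: int,
    line_no: int,
) -> Tuple[Dict[str, Tuple[int, int]], int, float]:
    """Decode one pileup base string into per-strand allele counts.

    Returns (allele_counts, depth, mean_baseq over retained bases).  A read
    whose base fails the quality gates is dropped together with any indel
    attached to it; ``*``/``#`` deletion placeholders and ``>``/``<``
    reference skips consume a quality character but never count.
    """
    counts: Dict[str, List[int]] = {}
    qual_sum = 0
    depth = 0
    i = 0  # index into bases
    q = 0  # index into quals / mapqs
    n = len(bases)
    # (allele, strand_idx, kept) of the read whose base was last consumed,
    # so a following +/- indel can attach to it
    last: Tuple[str, int, bool] | None = None

    def keep(q_idx: int) -> Tuple[bool, int]:
        bq = ord(quals[q_idx]) - 33
        ok = bq >= min_baseq
        if mapqs and ok:
            ok = (ord(mapqs[q_idx]) - 33) >= min_mapq
        return ok, bq

    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret + mapq char of the read start
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            # indel attached to the preceding read
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise ValueError(
                    f"pileup line {line_no}: bare {c!r} without length"
                )
            ilen = int(bases[i + 1 : j])
            seq = bases[j : j + ilen]
            if len(seq) != ilen:
                raise ValueError(
                    f"pileup line {line_no}: truncated indel sequence"
                )
            i = j + ilen
            if last is None:
                raise ValueError(
                    f"pileup line {line_no}: indel with no preceding read"
                )
            allele, strand, kept = last
            if kept:
                # reassign the read from its base allele to the indel allele
                counts[allele][strand] -= 1
                if sum(counts[allele]) == 0:
                    del counts[allele]
                ind = ("+" if c == "+" else "-") + seq.upper()
                counts.setdefault(ind, [0, 0])[strand] += 1
            last = None
            continue
        if q >= len(quals):
            raise ValueError(
                f"pileup line {line_no}: more bases than quality characters"
            )
        if c in "*#><":
            q += 1
            i += 1
            last = None
            continue
        if c in ".,":
            allele = ref
            strand = 0 if c == "." else 1
        elif c in "ACGTNacgtn":
            allele = c.upper()
            strand = 0 if c.isupper() else 1
        else:
            raise ValueError(
                f"pileup line {line_no}: unexpected character {c!r}"
            )
        kept, bq = keep(q)
        q += 1
        i += 1
        if kept and allele != "N":
            counts.setdefault(allele, [0, 0])[strand] += 1
            depth += 1
            qual_sum += bq
            last = (allele, strand, True)
        else:
            last = (allele, strand, False)
    if q != len(quals):
        raise ValueError(
            f"pileup line {line_no}: depth/quality-string length mismatch "
            f"({q} bases consumed, {len(quals)} qualities)"
        )
    mean_q = qual_sum / depth if depth else 0.0
    return (
        {a: (f, r) for a, (f, r) in counts.items()},
        depth,
        mean_q,
    )


def read_pileup(
    source: PathOrLines,
    min_baseq: int = 20,
    min_mapq: int = 10,
) -> Iterator[PileupSite]:
    """Stream :class:`PileupSite` records from a samtools-style pileup.

    ``source`` may be a path or an iterable of lines.  The 6-column dialect
    (chrom, pos, ref, depth, read bases, base qualities) is canonical; a 7th
    per-read mapping-quality column is honoured when present.  Bases below
    ``min_baseq`` (and reads below ``min_mapq``) are dropped and the depth
    recomputed.
    """
    if isinstance(source, (str, os.PathLike)):
        handle: Iterable[str] = open(source)
        close = True
    else:
        handle = source
        close = False
    try:
        for line_no, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) not in (6, 7):
                raise ValueError(
                    f"pileup line {line_no}: expected 6 or 7 columns, "
                    f"got {len(fields)}"
                )
            contig, pos_s, ref, depth_s, bases, quals = fields[:6]
            mapqs = fields[6] if len(fields) == 7 else ""
            ref = ref.upper()
            if (
                not mapqs
                and ref in "ACGT"
                and not _SPECIAL_RE.search(bases)
                and quals == quals[0] * len(quals)
                and ord(quals[0]) - 33 >= min_baseq
            ):
                counts, depth, mean_q = _decode_simple(
                    ref, bases, quals, line_no
                )
            else:
                counts, depth, mean_q = _decode_read_bases(
                    ref, bases, quals, mapqs, min_baseq, min_mapq, line_no
                )
            yield PileupSite(
                contig_id=contig,
                pos=int(pos_s),
                ref_base=ref,
                depth=depth,
                allele_counts=counts,
                mean_baseq=mean_q,
            )
    finally:
        if close:
            handle.close()  # type: ignore[union-attr]


def write_pileup_line(site: PileupSite, qual_char: str = "I") -> str:
    """Render a PileupSite back into a 6-column pileup line."""
    bases = []
    for allele, (fwd, rev) in sorted(site.allele_counts.items()):
        if allele == site.ref_base:
            bases.append("." * fwd + "," * rev)
        elif allele.startswith("+") or allele.startswith("-"):
            seq = allele[1:]
            tok = f"{allele[0]}{len(seq)}{seq}"
            bases.append(f".{tok}" * fwd + f",{tok.lower()}" * rev)
        else:
            bases.append(allele * fwd + allele.lower() * rev)
    basestr = "".join(bases) or "*"
    qualstr = qual_char * site.depth if site.depth else "*"
    return (
        f"{site.contig_id}\t{site.pos}\t{site.ref_base}\t{site.depth}\t"
        f"{basestr}\t{qualstr}"
    )


# ---------------------------------------------------------------------------
# Indel normalization
# ---------------------------------------------------------------------------

def left_align(
    seq: str, pos: int, ref: str, alt: str
) -> Tuple[int, str, str]:
    """Left-align an anchored indel against the reference sequence.

    An indel can be shifted one base left whenever the last base of its
    varying tail equals the current anchor base (the event is a rotation
    inside a repeat); the leftmost anchored representation makes
    (contig, pos, ref, alt) keys comparable across pools.  SNVs pass
    through unchanged.
    """
    if len(ref) == len(alt):
        return pos, ref, alt
    tail = (ref if len(ref) > len(alt) else alt)[1:]
    while pos > 1 and tail[-1] == seq[pos - 1]:
        tail = tail[-1] + tail[:-1]
        pos -= 1
    anchor = seq[pos - 1]
    if len(ref) > len(alt):
        return pos, anchor + tail, anchor
    return pos, anchor, anchor + tail


# ---------------------------------------------------------------------------
# VCF 4.2
# ---------------------------------------------------------------------------

_VCF_INFO_HEADERS = [
    '##INFO=<ID=POOL,Number=1,Type=String,Description="Pool identifier">',
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Filtered read depth">',
    '##INFO=<ID=ADF,Number=1,Type=Integer,Description="Alt reads, forward strand">',
    '##INFO=<ID=ADR,Number=1,Type=Integer,Description="Alt reads, reverse strand">',
    '##INFO=<ID=VF,Number=1,Type=Float,Description="Variant allele frequency">',
    '##INFO=<ID=PV,Number=1,Type=Float,Description="Binomial error-model p-value">',
]


def write_vcf(
    calls: Sequence[VariantCall],
    path: Union[str, os.PathLike],
    reference_meta: Mapping[str, int],
) -> None:
    """Write calls as VCF 4.2.  ``reference_meta`` maps contig id to length.

    Calls must already be sorted by (contig, pos); indels are expected in
    anchored form (anchor base included in REF/ALT).
    """
    prev: Tuple[str, int] | None = None
    for c in calls:
        key = (c.contig_id, c.pos)
        if prev is not None and key < prev:
            raise ValueError(
                f"calls not sorted at {c.contig_id}:{c.pos}; sort before writing"
            )
        prev = key
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=poolvar\n")
        for contig, length in reference_meta.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        for line in _VCF_INFO_HEADERS:
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = (
                f"POOL={c.pool_id};DP={c.depth};ADF={c.alt_fwd};"
                f"ADR={c.alt_rev};VF={c.var_freq:.6g};PV={c.p_value:.6g}"
            )
            fh.write(
                f"{c.contig_id}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n"
            )


def read_vcf(path: Union[str, os.PathLike]) -> List[VariantCall]:
    """Read a poolvar VCF back into :class:`VariantCall` records."""
    calls: List[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alt = rec.alts[0] if rec.alts else ""
            ref = rec.ref
            if len(ref) == 1 and len(alt) == 1:
                vtype = "SNV"
            elif len(alt) > len(ref):
                vtype = "insertion"
            else:
                vtype = "deletion"
            info = rec.info
            calls.append(
                VariantCall(
                    contig_id=rec.chrom,
                    pos=rec.pos,
                    ref=ref,
                    alt=alt,
                    vtype=vtype,
                    depth=int(info["DP"]),
                    alt_count=int(info["ADF"]) + int(info["ADR"]),
                    var_freq=float(info["VF"]),
                    alt_fwd=int(info["ADF"]),
                    alt_rev=int(info["ADR"]),
                    p_value=float(info["PV"]),
                    pool_id=str(info["POOL"]),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

def read_blast_tab(
    path: Union[str, os.PathLike],
    seq_lengths: Mapping[str, int],
):
    """Read 12-column BLAST tabular hits into similarity edges.

    ``seq_lengths`` supplies query/subject lengths, which the 12-column
    format lacks, so that alignment coverage can be computed.
    """
    from .pangenome import SimilarityEdge

    edges = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise ValueError(
                    f"BLAST tab line {line_no}: expected 12 columns"
                )
            q, s = f[0], f[1]
            for name in (q, s):
                if name not in seq_lengths:
                    raise ValueError(
                        f"BLAST tab line {line_no}: unknown sequence {name!r}"
                    )
            aln_len = int(f[3])
            qstart, qend, sstart, send = map(int, f[6:10])
            edges.append(
                SimilarityEdge(
                    query_id=q,
                    subject_id=s,
                    pct_identity=float(f[2]),
                    cov_query=(abs(qend - qstart) + 1) / seq_lengths[q],
                    cov_subject=(abs(send - sstart) + 1) / seq_lengths[s],
                    evalue=float(f[10]),
                    score=float(f[11]),
                )
            )
    return edges
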