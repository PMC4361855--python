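"""Synthetic genomes, mutagenized strain pools and pooled pileups.

Emulates a bulk-segregant-style pooled resequencing design: two pools of
``n_strains_per_pool`` mutagenized strains each (the defaults mirror a
30-vs-30 phenotype-selected design), sequenced as equimolar gDNA mixtures,
so a variant carried by k strains segregates at pooled frequency k/30.
Pools are simulated at the allele-count level: inference in the pipeline
begins at the pileup, so no read mapping is involved.

The mutagen spectrum defaults to 70% G·C→A·T transitions, the dominant
lesion of nitrosoguanidine (NTG) treatment, with the remainder uniform.
Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .dtypes import GeneModel, GenomeSequence, reverse_complement
from .io_formats import left_align

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))
_STOPS = ("TAA", "TAG", "TGA")
#: COG-style single-letter functional classes used to label synthetic genes
_COG_LETTERS = "JKLMNOCGEFHIPQRSTUVD"

VariantKey = Tuple[str, int, str, str]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Rates are per base pair per strain; ``mean_depth`` is reads per site
    per pool; ``base_error`` is the per-base miscall probability of the
    pooled library after quality filtering.
    """

    genome_length: int = 100_000
    gc_content: float = 0.72
    n_genes: int = 60
    gene_length_range: Tuple[int, int] = (300, 1500)
    tir_length: int = 0
    n_strains_per_pool: int = 30
    snv_rate: float = 1e-4
    indel_rate: float = 1e-5
    indel_length_range: Tuple[int, int] = (1, 3)
    transition_bias: float = 0.7
    mean_depth: float = 200.0
    base_error: float = 0.005
    seed: int = 0
    contig_id: str = "chr"

    def __post_init__(self) -> None:
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must lie in (0, 1)")
        if self.snv_rate < 0 or self.indel_rate < 0:
            raise ValueError("mutation rates must be >= 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not (0 <= self.base_error < 0.25):
            raise ValueError("base_error must lie in [0, 0.25)")
        if not (0 <= self.transition_bias <= 1):
            raise ValueError("transition_bias must lie in [0, 1]")
        if self.n_strains_per_pool < 1:
            raise ValueError("need at least one strain per pool")

    def rng(self, *stage: int) -> np.random.Generator:
        """A child generator for one pipeline stage, stable across runs."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=tuple(stage))
        )


@dataclass(frozen=True)
class TruthRecord:
    contig_id: str
    pos: int
    ref: str
    alt: str
    pool_id: str
    k: int  # carrier-strain count
    freq: float  # expected pooled frequency, k / n_strains

    @property
    def key(self) -> VariantKey:
        return (self.contig_id, self.pos, self.ref, self.alt)


@dataclass
class TruthSet:
    """Planted variants of one pool with expected pooled frequencies."""

    pool_id: str
    n_strains: int
    records: List[TruthRecord] = field(default_factory=list)

    def keys(self) -> set:
        return {r.key for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.contig_id, r.pos, r.ref, r.alt, r.pool_id, r.k, r.freq)
                for r in self.records
            ],
            columns=["contig", "pos", "ref", "alt", "pool", "k", "freq"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _pool_stage(pool_id: str) -> int:
    # stable small integer derived from the pool name
    return zlib.crc32(pool_id.encode()) % (2**16)


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p)


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def _make_cds(rng: np.random.Generator, length: int, gc: float) -> str:
    """A CDS of the given length: ATG start, stop end, no internal stops."""
    assert length % 3 == 0 and length >= 9
    body = _codes_to_str(_random_bases(rng, length - 6, gc))
    codons = [body[i : i + 3] for i in range(0, len(body), 3)]
    # neutralize internal stops; T->C keeps the codon sense (CAA/CAG/CGA)
    codons = ["C" + c[1:] if c in _STOPS else c for c in codons]
    stop = _STOPS[rng.integers(0, 3)]
    return "ATG" + "".join(codons) + stop


def generate_genome(
    config: SimulationConfig,
) -> Tuple[GenomeSequence, List[GeneModel]]:
    """Generate a linear chromosome with non-overlapping CDS gene models.

    Base composition tracks ``gc_content`` constructively; CDSs start with
    ATG, end with a stop codon and contain no internal stop.  When
    ``tir_length`` > 0 the terminal ``tir_length`` bp are set to the
    reverse complement of the initial ``tir_length`` bp, giving the genome
    a perfect terminal inverted repeat.  Deterministic given the seed.
    """
    if config.genome_length < 1000:
        raise ValueError("genome_length must be >= 1000")
    rng = config.rng(0)
    L = config.genome_length

    lo, hi = config.gene_length_range
    lo = max(lo, 9)
    n_codons_lo, n_codons_hi = lo // 3, max(hi // 3, lo // 3 + 1)
    gene_lengths = (
        rng.integers(n_codons_lo, n_codons_hi + 1, size=config.n_genes) * 3
    )
    total_genes = int(gene_lengths.sum())
    if total_genes > 0.9 * L:
        raise ValueError(
            f"infeasible packing: {total_genes} bp of genes into {L} bp genome"
        )

    # background sequence at the target composition
    codes = _random_bases(rng, L, config.gc_content)
    seq = list(_codes_to_str(codes))

    # place genes without overlap inside [1, L - tir_length] via random gaps
    avail_end = L - config.tir_length
    free = avail_end - total_genes
    if free < config.n_genes + 1:
        raise ValueError("infeasible packing: no room for gene spacing")
    cuts = np.sort(rng.choice(free, size=config.n_genes, replace=False))
    models: List[GeneModel] = []
    cursor = 0
    for i, glen in enumerate(gene_lengths):
        start0 = int(cuts[i]) + cursor  # 0-based start
        cursor += int(glen)
        cds = _make_cds(rng, int(glen), config.gc_content)
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = cds if strand == "+" else reverse_complement(cds)
        seq[start0 : start0 + int(glen)] = list(inserted)
        label = (
            _COG_LETTERS[rng.integers(0, len(_COG_LETTERS))]
            if rng.random() < 0.64
            else None
        )
        models.append(
            GeneModel(
                gene_id=f"gene_{i + 1:04d}",
                contig_id=config.contig_id,
                start=start0 + 1,
                end=start0 + int(glen),
                strand=strand,
                is_cds=True,
                category_label=label,
            )
        )

    if config.tir_length > 0:
        tir = reverse_complement("".join(seq[: config.tir_length]))
        seq[L - config.tir_length :] = list(tir)

    genome = GenomeSequence(
        contig_id=config.contig_id, sequence="".join(seq), topology="linear"
    )
    return genome, models


# ---------------------------------------------------------------------------
# Mutagenesis
# ---------------------------------------------------------------------------

def _draw_strain_variants(
    rng: np.random.Generator,
    genome: GenomeSequence,
    config: SimulationConfig,
    gc_positions: np.ndarray,
) -> List[VariantKey]:
    """Independent SNV/indel draws for one strain."""
    L = len(genome)
    seq = genome.sequence
    contig = genome.contig_id
    keys: Dict[int, VariantKey] = {}

    n_snv = rng.poisson(config.snv_rate * L)
    n_ts = rng.binomial(n_snv, config.transition_bias) if n_snv else 0
    # GC->AT transitions at G/C sites
    if n_ts and len(gc_positions):
        picks = rng.choice(gc_positions, size=n_ts, replace=False)
        for p0 in picks:
            ref = seq[p0]
            alt = "A" if ref == "G" else "T"
            keys.setdefault(int(p0) + 1, (contig, int(p0) + 1, ref, alt))
    # remaining SNVs: any site, any non-reference base
    for p0 in rng.integers(0, L, size=n_snv - n_ts):
        ref = seq[p0]
        alt = _BASES[(np.flatnonzero(_BASES != ref))[rng.integers(0, 3)]]
        keys.setdefault(int(p0) + 1, (contig, int(p0) + 1, ref, str(alt)))

    n_indel = rng.poisson(config.indel_rate * L)
    ilo, ihi = config.indel_length_range
    for _ in range(n_indel):
        ilen = int(rng.integers(ilo, ihi + 1))
        pos = int(rng.integers(1, L - ilen - 1))  # anchor, 1-based
        anchor = seq[pos - 1]
        if rng.random() < 0.5:  # insertion after anchor
            ins = _codes_to_str(_random_bases(rng, ilen, config.gc_content))
            ref, alt = anchor, anchor + ins
        else:  # deletion of ilen bases after anchor
            ref, alt = anchor + seq[pos : pos + ilen], anchor
        # normalize so planted keys match the caller's left-aligned keys
        pos, ref, alt = left_align(seq, pos, ref, alt)
        keys.setdefault(pos, (contig, pos, ref, alt))
    return list(keys.values())


def _drop_footprint_conflicts(
    records: List[TruthRecord],
) -> List[TruthRecord]:
    """Drop truth sites lying inside another indel's deleted footprint."""
    del_spans = [
        (r.pos + 1, r.pos + len(r.ref) - 1, r.key)
        for r in records
        if len(r.ref) > 1
    ]
    if not del_spans:
        return records
    kept = []
    dropped = 0
    for r in records:
        r_lo, r_hi = r.pos, r.pos + len(r.ref) - 1
        conflict = any(
            key != r.key and not (r_hi < lo or r_lo > hi)
            for (lo, hi, key) in del_spans
        )
        if conflict:
            dropped += 1
        else:
            kept.append(r)
    if dropped:
        logger.info(
            "dropped %d truth sites inside another indel's footprint", dropped
        )
    return kept


def mutagenize_pool(
    genome: GenomeSequence,
    models: Sequence[GeneModel],
    config: SimulationConfig,
    pool_id: str,
) -> Tuple[List[List[VariantKey]], TruthSet]:
    """Mutagenize ``n_strains_per_pool`` strains and pool their variants.

    Each strain draws SNVs (Poisson, with the configured transition bias)
    and indels independently; the same site may mutate in several strains,
    giving carrier counts k > 1 and expected pooled frequency k/n.
    """
    rng = config.rng(1, _pool_stage(pool_id))
    seq_arr = np.frombuffer(genome.sequence.encode(), dtype=np.uint8)
    gc_positions = np.flatnonzero((seq_arr == ord("G")) | (seq_arr == ord("C")))

    strains: List[List[VariantKey]] = []
    carrier: Dict[VariantKey, int] = {}
    for _ in range(config.n_strains_per_pool):
        variants = _draw_strain_variants(rng, genome, config, gc_positions)
        strains.append(variants)
        for key in variants:
            carrier[key] = carrier.get(key, 0) + 1

    n = config.n_strains_per_pool
    records = [
        TruthRecord(
            contig_id=key[0],
            pos=key[1],
            ref=key[2],
            alt=key[3],
            pool_id=pool_id,
            k=k,
            freq=k / n,
        )
        for key, k in sorted(carrier.items(), key=lambda kv: (kv[0][1], kv[0]))
    ]
    records = _drop_footprint_conflicts(records)
    return strains, TruthSet(pool_id=pool_id, n_strains=n, records=records)


# ---------------------------------------------------------------------------
# Pooled pileup simulation
# ---------------------------------------------------------------------------

def _alt_token(rec: TruthRecord) -> str:
    """Pileup token for the alternate allele of a truth record."""
    if len(rec.ref) == 1 and len(rec.alt) == 1:
        return rec.alt
    if len(rec.alt) > len(rec.ref):  # insertion
        return "+" + rec.alt[1:]
    return "-" + rec.ref[1:]  # deletion


def _qual_char(base_error: float) -> str:
    q = 40 if base_error <= 0 else min(
        40, max(2, round(-10 * math.log10(base_error)))
    )
    return chr(q + 33)


def simulate_pileup(
    genome: GenomeSequence,
    truth: TruthSet,
    config: SimulationConfig,
) -> Iterator[str]:
    """Yield 6-column samtools-dialect pileup lines for one pool.

    Per site, depth ~ Poisson(mean_depth); reads supporting each truth
    allele ~ Binomial(depth, f(1-e) + (1-f)e/3) with f the pooled truth
    frequency and e the base error; remaining reads are reference with
    per-read miscall probability e; every read lands on the forward strand
    with probability 1/2.  Zero-depth sites are omitted.  Deletion
    footprints downstream of the anchor are not thinned.
    """
    rng = config.rng(2, _pool_stage(truth.pool_id))
    L = len(genome)
    seq = genome.sequence
    contig = genome.contig_id
    e = config.base_error
    qc = _qual_char(e)

    truth_by_pos: Dict[int, List[TruthRecord]] = {}
    for rec in truth.records:
        truth_by_pos.setdefault(rec.pos, []).append(rec)

    depths = rng.poisson(config.mean_depth, size=L)
    n_err = (
        rng.binomial(depths, e) if e > 0 else np.zeros(L, dtype=np.int64)
    )
    fwd_plain = rng.binomial(np.maximum(depths - n_err, 0), 0.5)

    other = {
        b: [x for x in "ACGT" if x != b] for b in "ACGT"
    }

    for i in range(L):
        d = int(depths[i])
        if d == 0:
            continue
        pos = i + 1
        ref = seq[i]
        parts: List[str] = []
        if pos not in truth_by_pos:
            ne = int(n_err[i])
            nref = d - ne
            f_fwd = int(fwd_plain[i])
            parts.append("." * f_fwd + "," * (nref - f_fwd))
            if ne:
                bases = rng.integers(0, 3, size=ne)
                strands = rng.integers(0, 2, size=ne)
                for bi, si in zip(bases, strands):
                    b = other[ref][bi]
                    parts.append(b if si == 0 else b.lower())
        else:
            remaining = d
            alt_reads: List[Tuple[str, int]] = []
            exclude = {ref}
            for rec in truth_by_pos[pos]:
                p_alt = rec.freq * (1 - e) + (1 - rec.freq) * e / 3
                na = int(rng.binomial(remaining, p_alt))
                na = min(na, remaining)
                remaining -= na
                tok = _alt_token(rec)
                if len(tok) == 1:
                    exclude.add(tok)
                if na:
                    alt_reads.append((tok, na))
            ne = int(rng.binomial(remaining, e)) if e > 0 else 0
            nref = remaining - ne
            f_fwd = int(rng.binomial(nref, 0.5))
            parts.append("." * f_fwd + "," * (nref - f_fwd))
            err_choices = [b for b in "ACGT" if b not in exclude] or ["N"]
            for _ in range(ne):
                b = err_choices[int(rng.integers(0, len(err_choices)))]
                parts.append(b if rng.random() < 0.5 else b.lower())
            for tok, na in alt_reads:
                na_fwd = int(rng.binomial(na, 0.5))
                if len(tok) == 1:
                    parts.append(tok * na_fwd + tok.lower() * (na - na_fwd))
                else:
                    t = f"{tok[0]}{len(tok) - 1}{tok[1:]}"
                    parts.append(f".{t}" * na_fwd + f",{t.lower()}" * (na - na_fwd))
        yield f"{contig}\t{pos}\t{ref}\t{d}\t{''.join(parts)}\t{qc * d}"


def write_pileup(lines: Iterator[str], path) -> None:
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")


def emit_fastq(
    genome: GenomeSequence, path, read_length: int = 100, step: int = 50
) -> None:
    """Tiling single-end FASTQ at uniform Q30; interop demos only."""
    with open(path, "w") as fh:
        seq = genome.sequence
        for i, start in enumerate(range(0, len(seq) - read_length + 1, step)):
            read = seq[start : start + read_length]
            fh.write(
                f"@{genome.contig_id}_{i}\n{read}\n+\n{'?' * len(read)}\n"
            )


# ---------------------------------------------------------------------------
# Proteome simulation for the pan-genome stage
# ---------------------------------------------------------------------------

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def simulate_proteomes(
    n_species: int = 5,
    n_core_families: int = 20,
    n_dispensable_families: int = 6,
    n_specific_per_species: int = 4,
    protein_length: int = 120,
    divergence: float = 0.10,
    chrom_length: int = 1_000_000,
    seed: int = 0,
):
    """Simulate proteomes descending from a common ancestor.

    Core families are inherited by every species, dispensable families by a
    random subset of 2..n-1 species (per-lineage loss), and each species
    additionally gains novel random proteins (its specific genes).  Copies
    diverge by per-residue substitution at the given rate; with divergence
    well below 0.5 orthologs stay far above the 50%-identity clustering
    threshold while unrelated proteins stay far below it.

    Returns ``(proteins, planted_class)`` where planted_class maps each
    protein id to its true family class.
    """
    from .pangenome import ProteinRecord

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    species = [f"sp{j + 1}" for j in range(n_species)]

    def random_protein() -> np.ndarray:
        return rng.integers(0, 20, size=protein_length)

    def mutate(codes: np.ndarray) -> str:
        out = codes.copy()
        hits = np.flatnonzero(rng.random(len(out)) < divergence)
        for h in hits:
            out[h] = (out[h] + 1 + rng.integers(0, 19)) % 20
        return "".join(_AA[out])

    proteins = []
    planted: Dict[str, str] = {}

    def add(pid: str, sp: str, seq: str, cls: str) -> None:
        proteins.append(
            ProteinRecord(
                protein_id=pid,
                species_id=sp,
                sequence=seq,
                chrom_pos=int(rng.integers(1, chrom_length + 1)),
                chrom_length=chrom_length,
            )
        )
        planted[pid] = cls

    for fam in range(n_core_families):
        anc = random_protein()
        for sp in species:
            add(f"{sp}_core{fam:03d}", sp, mutate(anc), "core")
    for fam in range(n_dispensable_families):
        anc = random_protein()
        n_present = int(rng.integers(2, n_species)) if n_species > 2 else 2
        present = rng.choice(n_species, size=n_present, replace=False)
        for j in present:
            add(f"{species[j]}_disp{fam:03d}", species[j], mutate(anc),
                "dispensable")
    for sp in species:
        for g in range(n_specific_per_species):
            add(f"{sp}_spec{g:03d}", sp, "".join(_AA[random_protein()]),
                "specific")
    return proteins, planted
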