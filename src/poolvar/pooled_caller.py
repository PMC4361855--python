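"""VarScan2-style pooled variant calling from filtered pileup sites.

A non-reference allele is emitted when it clears four gates: a coverage
floor, a minimum pooled allele frequency, a one-sided binomial test
against the sequencing-error null, and (optionally) a per-strand
representation filter.  The error rate of the null is derived from the
mean retained base quality of the site, e = 10^(-Q/10); the p-value is
the exact upper tail P(X >= alt_count | X ~ Binomial(depth, e)).

Frequencies are compared as exact rationals so a frequency exactly at the
floor is called (>=, not >).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, List, Optional, Tuple

from scipy.stats import binom

from .dtypes import GenomeSequence, PileupSite, VariantCall

__all__ = ["CallerConfig", "VariantCall", "call_site", "call_pool"]


@dataclass(frozen=True)
class CallerConfig:
    """Calling thresholds; the defaults are the pooled-library settings."""

    min_coverage: int = 50
    min_var_freq: float = 0.03
    strand_filter: bool = True
    min_baseq: int = 20
    min_mapq: int = 10
    p_threshold: float = 0.01
    min_strand_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.min_var_freq < 1):
            raise ValueError("min_var_freq must lie in (0, 1)")
        if not (0 <= self.min_strand_fraction <= 0.5):
            raise ValueError("min_strand_fraction must lie in [0, 0.5]")
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


def _as_call(
    site: PileupSite,
    allele: str,
    fwd: int,
    rev: int,
    p: float,
    pool_id: str,
) -> VariantCall:
    """Build an anchored VariantCall for one qualifying allele."""
    if allele.startswith("+"):
        ref, alt, vtype = site.ref_base, site.ref_base + allele[1:], "insertion"
    elif allele.startswith("-"):
        ref, alt, vtype = site.ref_base + allele[1:], site.ref_base, "deletion"
    else:
        ref, alt, vtype = site.ref_base, allele, "SNV"
    ac = fwd + rev
    return VariantCall(
        contig_id=site.contig_id,
        pos=site.pos,
        ref=ref,
        alt=alt,
        vtype=vtype,
        depth=site.depth,
        alt_count=ac,
        var_freq=ac / site.depth,
        alt_fwd=fwd,
        alt_rev=rev,
        p_value=p,
        pool_id=pool_id,
    )


def call_site(
    site: PileupSite,
    config: CallerConfig = CallerConfig(),
    pool_id: str = "pool",
) -> List[VariantCall]:
    """Evaluate every non-reference allele of one pileup site.

    The site is assumed to be already BaseQ/MAPQ-filtered (its depth is the
    retained depth).  Multiple qualifying alleles each yield a call; a
    zero-depth site yields none.
    """
    if site.depth == 0 or site.depth < config.min_coverage:
        return []
    e = 10.0 ** (-site.mean_baseq / 10.0)
    min_f = Fraction(str(config.min_var_freq))
    min_sf = Fraction(str(config.min_strand_fraction))
    calls: List[VariantCall] = []
    for allele in sorted(site.allele_counts):
        if allele == site.ref_base:
            continue
        fwd, rev = site.allele_counts[allele]
        ac = fwd + rev
        if ac == 0:
            continue
        if Fraction(ac, site.depth) < min_f:
            continue
        if config.strand_filter and (
            Fraction(fwd, ac) < min_sf or Fraction(rev, ac) < min_sf
        ):
            continue
        p = float(binom.sf(ac - 1, site.depth, e))
        if p > config.p_threshold:
            continue
        calls.append(_as_call(site, allele, fwd, rev, p, pool_id))
    return calls


def left_align_call(call: VariantCall, genome: GenomeSequence) -> VariantCall:
    """Return the call with its indel left-aligned (VCF normalization)."""
    from .io_formats import left_align

    pos, ref, alt = left_align(genome.sequence, call.pos, call.ref, call.alt)
    if (pos, ref, alt) == (call.pos, call.ref, call.alt):
        return call
    return VariantCall(
        contig_id=call.contig_id,
        pos=pos,
        ref=ref,
        alt=alt,
        vtype=call.vtype,
        depth=call.depth,
        alt_count=call.alt_count,
        var_freq=call.var_freq,
        alt_fwd=call.alt_fwd,
        alt_rev=call.alt_rev,
        p_value=call.p_value,
        pool_id=call.pool_id,
    )


def call_pool(
    pileup: Iterable[PileupSite],
    config: CallerConfig = CallerConfig(),
    pool_id: str = "pool",
    reference: Optional[GenomeSequence] = None,
) -> List[VariantCall]:
    """Call variants over a position-sorted pileup stream.

    Streams in constant memory over the genome; raises at the first
    position inversion.  When ``reference`` is given, indel calls are
    left-aligned so that keys are comparable across pools.
    """
    calls: List[VariantCall] = []
    prev: Optional[Tuple[str, int]] = None
    for site in pileup:
        key = (site.contig_id, site.pos)
        if prev is not None and key[0] == prev[0] and key[1] <= prev[1]:
            raise ValueError(
                f"unsorted pileup stream at {site.contig_id}:{site.pos}"
            )
        prev = key
        for call in call_site(site, config, pool_id):
            if reference is not None and call.vtype != "SNV":
                call = left_align_call(call, reference)
            calls.append(call)
    return calls
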