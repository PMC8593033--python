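"""Allelic imbalance from heterozygous variants: DNA call vs RNA coverage.

A transcript allele degraded by nonsense-mediated decay (NMD) leaves a
footprint on every heterozygous SNV it carries: the RNA major-allele
fraction rises above the 0.5 expected for a balanced heterozygote. With
degradation fraction ``d`` of one allele, the expected major-allele
fraction is ``1 / (2 - d)``.

Classification uses banded major-allele fractions (phase is unknown with
short reads, so direction consistency is assessed on band agreement under
the assumption that the imbalance affects the same allele):

========  ===========================
fraction  class
========  ===========================
<= 0.60   none
0.60-0.70 modest
0.70-0.80 intermediate
> 0.80    strong
========  ===========================

Bands are half-open ``(lower, upper]``. At least two informative
heterozygous variants (here: RNA depth >= ``min_depth``) are required;
otherwise the call is ``not_assessable``. Variants disagreeing by more than
one band also yield ``not_assessable`` with ``consistent_direction=False``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .discovery import _CIGAR_I, _REF_CONSUMING, _ALIGNED, _open_alignments, iter_primary

MIN_INFORMATIVE_DEPTH = 20

IMBALANCE_CLASSES = ("not_assessable", "none", "modest", "intermediate", "strong")
_BANDS = ((0.60, "none"), (0.70, "modest"), (0.80, "intermediate"), (np.inf, "strong"))


@dataclass
class VariantAlleleCounts:
    """RNA base counts at one heterozygous SNV position."""

    contig: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    rna_ref_depth: int = 0
    rna_alt_depth: int = 0
    rna_other_depth: int = 0
    dna_het: bool = True

    @property
    def depth(self) -> int:
        return self.rna_ref_depth + self.rna_alt_depth

    @property
    def major_fraction(self) -> float:
        """Fraction of the more abundant allele among ref+alt bases (NaN at 0x)."""
        if self.depth == 0:
            return float("nan")
        return max(self.rna_ref_depth, self.rna_alt_depth) / self.depth


@dataclass
class ImbalanceCall:
    """Per-sample allelic-imbalance summary over informative variants."""

    sample_id: str
    fractions: list[float]
    n_informative: int
    label: str
    consistent_direction: bool = True

    def __post_init__(self) -> None:
        if self.label not in IMBALANCE_CLASSES:
            raise ValueError(f"unknown imbalance class {self.label!r}")


def load_heterozygous_variants(path: str | Path, sample: Optional[str] = None) -> list[VariantAlleleCounts]:
    """Read heterozygous SNVs from a VCF; non-SNV and homozygous calls are skipped."""
    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            het = True
            if rec.samples:
                name = sample if sample in rec.samples else next(iter(rec.samples))
                gt = rec.samples[name].get("GT")
                het = gt is not None and len(set(a for a in gt if a is not None)) == 2
            if not het:
                continue
            variants.append(
                VariantAlleleCounts(rec.contig, rec.pos, ref, alt, dna_het=True)
            )
    return variants


def _base_at(read, position: int) -> Optional[str]:
    """Query base aligned (match/mismatch) at a 1-based reference position."""
    seq = read.query_sequence
    if seq is None:
        return None
    ref_pos = read.reference_start  # 0-based
    query_pos = 0
    target = position - 1
    for op, length in read.cigartuples or ():
        consumes_query = op in _ALIGNED or op == _CIGAR_I or op in (4,)  # 4 = soft clip
        if op in _ALIGNED and ref_pos <= target < ref_pos + length:
            return seq[query_pos + (target - ref_pos)]
        if op in _REF_CONSUMING:
            ref_pos += length
            if ref_pos > target and op not in _ALIGNED:
                return None  # position under a gap/deletion in this read
        if consumes_query:
            query_pos += length
    return None


def pileup_allele_counts(
    alignments, variants: Sequence[VariantAlleleCounts], min_mapq: int = 0
) -> list[VariantAlleleCounts]:
    """Count RNA bases supporting each allele at the variant positions.

    Only aligned (non-gapped) bases count; reads splicing over a position
    contribute nothing there — a variant under a skipped exon therefore
    shows reduced depth. Bases other than ref/alt are tallied separately.
    Positions without coverage are retained with zero depth.
    """
    out = [
        VariantAlleleCounts(
            v.contig, v.position, v.ref_allele, v.alt_allele, dna_het=v.dna_het
        )
        for v in variants
    ]
    by_contig: dict[str, list[VariantAlleleCounts]] = {}
    for v in out:
        by_contig.setdefault(v.contig, []).append(v)
    for vs in by_contig.values():
        vs.sort(key=lambda v: v.position)

    for read in iter_primary(alignments, min_mapq=min_mapq):
        vs = by_contig.get(read.reference_name)
        if not vs:
            continue
        start1 = read.reference_start + 1
        end1 = read.reference_end
        for v in vs:
            if v.position < start1:
                continue
            if v.position > end1:
                break
            base = _base_at(read, v.position)
            if base is None:
                continue
            if base == v.ref_allele:
                v.rna_ref_depth += 1
            elif base == v.alt_allele:
                v.rna_alt_depth += 1
            else:
                v.rna_other_depth += 1
    return out


def _band(fraction: float) -> str:
    for upper, label in _BANDS:
        if fraction <= upper:
            return label
    return "strong"


def classify_imbalance(
    counts: Sequence[VariantAlleleCounts],
    sample_id: str = "",
    min_depth: int = MIN_INFORMATIVE_DEPTH,
) -> ImbalanceCall:
    """Classify a sample's allelic imbalance from its variant allele counts.

    Uses heterozygous SNVs with RNA depth >= ``min_depth``; the median
    major-allele fraction across informative variants decides the class.
    Classification works on the major-allele fraction, so it is invariant to
    which allele is labeled ref or alt.
    """
    informative = [
        v for v in counts if v.dna_het and v.depth >= min_depth
    ]
    fractions = [v.major_fraction for v in informative]
    if len(informative) < 2:
        return ImbalanceCall(sample_id, fractions, len(informative), "not_assessable")
    bands = [_band(f) for f in fractions]
    band_idx = [IMBALANCE_CLASSES.index(b) for b in bands]
    consistent = (max(band_idx) - min(band_idx)) <= 1
    if not consistent:
        return ImbalanceCall(
            sample_id, fractions, len(informative), "not_assessable", consistent_direction=False
        )
    label = _band(float(np.median(fractions)))
    return ImbalanceCall(sample_id, fractions, len(informative), label)


def imbalance_to_frame(
    counts: Sequence[VariantAlleleCounts], call: ImbalanceCall
) -> pd.DataFrame:
    """Per-variant TSV-ready table with the summary call repeated per row."""
    rows = [
        {
            "sample_id": call.sample_id,
            "contig": v.contig,
            "position": v.position,
            "ref": v.ref_allele,
            "alt": v.alt_allele,
            "rna_ref_depth": v.rna_ref_depth,
            "rna_alt_depth": v.rna_alt_depth,
            "rna_other_depth": v.rna_other_depth,
            "major_fraction": v.major_fraction,
            "imbalance_class": call.label,
            "n_informative": call.n_informative,
        }
        for v in counts
    ]
    return pd.DataFrame(rows)
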