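"""Reference transcript models and event classification.

Loads a transcript's exon structure from GTF or BED12, derives the set of
reference exon-exon junctions (``n_exons - 1`` junctions, e.g. 56 for the
57-exon NF1 transcript NM_000267.3), and classifies arbitrary splice events
against that structure (exon skipping, shifted donor/acceptor sites, cassette
exons from deep-intronic activation, ...).

All coordinates are 1-based inclusive genomic positions; junctions follow the
first/last-intron-nucleotide convention of :class:`~splicenrich.events.SpliceEvent`.
Donor and acceptor are named in genomic orientation (donor = lower-coordinate
side), so classification is invariant to the transcript's strand flag; for
minus-strand transcripts the biological 5'/3' roles are swapped in the
``detail`` wording only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gffutils

from .events import EventClass, SpliceEvent


@dataclass
class TranscriptModel:
    """Exon structure of one reference transcript.

    ``exons`` are (start, end) pairs, 1-based inclusive, sorted by genomic
    position and non-overlapping. ``coding_start``/``coding_end`` bound the
    CDS in genomic coordinates when annotated; when absent, the transcript is
    treated as coding over its full exonic extent for frame arithmetic.
    """

    transcript_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    coding_start: Optional[int] = None
    coding_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for start, end in self.exons:
            if end < start:
                raise ValueError(f"exon end < start: ({start}, {end})")
        for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap or touch; introns must have length >= 1")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals (first, last intron nt), one per exon pair."""
        return [
            (self.exons[k][1] + 1, self.exons[k + 1][0] - 1)
            for k in range(self.n_exons - 1)
        ]

    def exon_containing(self, pos: int) -> Optional[int]:
        """1-based exon index containing ``pos``, or None."""
        for k, (start, end) in enumerate(self.exons, start=1):
            if start <= pos <= end:
                return k
        return None

    def intron_containing(self, pos: int) -> Optional[int]:
        """1-based intron index (intron k follows exon k) containing ``pos``."""
        for k, (start, end) in enumerate(self.introns(), start=1):
            if start <= pos <= end:
                return k
        return None


@dataclass
class ReferenceJunctionSet:
    """The reference transcript's exon-exon junctions with exon-pair labels."""

    transcript_id: str
    junctions: list[SpliceEvent]
    exon_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.junctions)

    def __contains__(self, event: SpliceEvent) -> bool:
        return event in self.junctions

    def label(self, event: SpliceEvent) -> str:
        k, k1 = self.exon_pairs[self.junctions.index(event)]
        return f"exon{k}-exon{k1}"


def load_gene_model(path: str | Path, transcript_id: str) -> TranscriptModel:
    """Load one transcript's exon structure from a GTF or BED12 file.

    Format is chosen by extension: ``.gtf``/``.gff``/``.gff3`` are parsed with
    gffutils (Ensembl dialect, exons grouped by the ``transcript_id``
    attribute); anything else is treated as BED12. A transcript with fewer
    than two exons cannot define junctions and is rejected.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff", ".gff3"):
        model = _load_gtf(path, transcript_id)
    else:
        model = _load_bed12(path, transcript_id)
    if model.n_exons < 2:
        raise ValueError(
            f"transcript {transcript_id!r} has {model.n_exons} exon(s); "
            "at least 2 are required to derive junctions"
        )
    return model


def _load_gtf(path: Path, transcript_id: str) -> TranscriptModel:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="merge",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons: list[tuple[int, int]] = []
    cds: list[tuple[int, int]] = []
    contig = strand = None
    seen: set[str] = set()
    for feat in db.all_features():
        tid = feat.attributes.get("transcript_id", [None])[0]
        if tid:
            seen.add(tid)
        if tid != transcript_id:
            continue
        if feat.featuretype == "exon":
            exons.append((feat.start, feat.end))
            contig, strand = feat.seqid, feat.strand
        elif feat.featuretype == "CDS":
            cds.append((feat.start, feat.end))
    if not exons:
        raise ValueError(
            f"transcript {transcript_id!r} not found in {path.name}; "
            f"available: {sorted(seen)}"
        )
    coding_start = min(s for s, _ in cds) if cds else None
    coding_end = max(e for _, e in cds) if cds else None
    return TranscriptModel(
        transcript_id=transcript_id,
        contig=contig,
        strand=strand if strand in ("+", "-") else "+",
        exons=exons,
        coding_start=coding_start,
        coding_end=coding_end,
    )


def _load_bed12(path: Path, transcript_id: str) -> TranscriptModel:
    # BED is 0-based half-open; exon blocks are converted to 1-based inclusive.
    seen: set[str] = set()
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(f"{path.name}: expected 12 BED columns, got {len(fields)}")
            name = fields[3]
            seen.add(name)
            if name != transcript_id:
                continue
            chrom_start = int(fields[1])
            thick_start, thick_end = int(fields[6]), int(fields[7])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            exons = [
                (chrom_start + off + 1, chrom_start + off + size)
                for off, size in zip(starts, sizes)
            ]
            coding = thick_end > thick_start
            return TranscriptModel(
                transcript_id=transcript_id,
                contig=fields[0],
                strand=fields[5] if fields[5] in ("+", "-") else "+",
                exons=exons,
                coding_start=thick_start + 1 if coding else None,
                coding_end=thick_end if coding else None,
            )
    raise ValueError(
        f"transcript {transcript_id!r} not found in {path.name}; available: {sorted(seen)}"
    )


def reference_junctions(model: TranscriptModel) -> ReferenceJunctionSet:
    """Derive the reference junction set: one junction per adjacent exon pair.

    Junction k runs from ``exon_k.end + 1`` to ``exon_{k+1}.start - 1``
    (first/last intron nucleotide); a transcript with n exons yields n - 1
    junctions.
    """
    junctions = [
        SpliceEvent(model.contig, start, end) for start, end in model.introns()
    ]
    pairs = [(k, k + 1) for k in range(1, model.n_exons)]
    return ReferenceJunctionSet(model.transcript_id, junctions, pairs)


def convert_exon_number(systematic_index: int, n_exons: int = 57, shift_after: int = 30) -> int:
    """Convert systematic exon numbering (1..57 for NF1) to legacy numbering.

    Historical NF1 literature numbers exons with letter suffixes such that the
    legacy index equals the systematic index up to exon 30 and is shifted by
    +1 for all exons after it.
    """
    if not 1 <= systematic_index <= n_exons:
        raise ValueError(
            f"systematic exon index {systematic_index} out of range 1..{n_exons}"
        )
    return systematic_index if systematic_index <= shift_after else systematic_index + 1


def _frame_effect(delta_nt: int) -> str:
    return "in_frame" if delta_nt % 3 == 0 else "frameshift"


def _coding_overlap(model: TranscriptModel, start: int, end: int) -> int:
    """Length of [start, end] overlapping the coding exonic sequence."""
    lo = model.coding_start if model.coding_start is not None else model.span[0]
    hi = model.coding_end if model.coding_end is not None else model.span[1]
    total = 0
    for es, ee in model.exons:
        s, e = max(es, start, lo), min(ee, end, hi)
        if s <= e:
            total += e - s + 1
    return total


def classify_event(event: SpliceEvent, model: TranscriptModel) -> EventClass:
    """Classify a splice event against the reference transcript structure.

    Deterministic decision order:

    1. exact match to a reference junction -> ``reference_junction``;
    2. donor at a reference donor and acceptor at a later reference acceptor
       -> ``exon_skipping`` of the intervening exons;
    3. one side at a reference boundary, the other inside the matching exon
       or intron -> ``alt_donor`` / ``alt_acceptor`` with the nt shift;
    4. both sides inside one annotated intron -> ``cassette_exon`` boundary;
    5. both sides inside exons away from any boundary -> ``exonic_deletion``;
    6. anything else -> ``other``.
    """
    if event.contig != model.contig:
        raise ValueError(
            f"event contig {event.contig!r} does not match model contig {model.contig!r}"
        )
    ref = reference_junctions(model)
    if event in ref.junctions:
        k, k1 = ref.exon_pairs[ref.junctions.index(event)]
        return EventClass("reference_junction", f"exon{k}-exon{k1}", "unknown")

    # reference boundary positions, keyed by the exon they belong to
    donor_exon = {model.exons[k][1] + 1: k + 1 for k in range(model.n_exons - 1)}
    acceptor_exon = {model.exons[k][0] - 1: k + 1 for k in range(1, model.n_exons)}

    donor_k = donor_exon.get(event.intron_start)
    acceptor_m = acceptor_exon.get(event.intron_end)

    if donor_k is not None and acceptor_m is not None:
        if acceptor_m > donor_k + 1:
            skipped = list(range(donor_k + 1, acceptor_m))
            deleted = sum(
                _coding_overlap(model, *model.exons[k - 1]) for k in skipped
            )
            names = ",".join(str(k) for k in skipped)
            return EventClass(
                "exon_skipping", f"skip exon {names} ({deleted} nt)", _frame_effect(deleted)
            )
        # acceptor_m <= donor_k: gap runs backwards relative to exon order
        return EventClass("other", "boundary pair inconsistent with exon order")

    if donor_k is not None:
        return _shifted_side(event, model, donor_k, side="acceptor")
    if acceptor_m is not None:
        return _shifted_side(event, model, acceptor_m, side="donor")

    in_intron_start = model.intron_containing(event.intron_start)
    in_intron_end = model.intron_containing(event.intron_end)
    if in_intron_start is not None and in_intron_start == in_intron_end:
        return EventClass(
            "cassette_exon",
            f"boundary inside intron {in_intron_start}",
            "unknown",
        )
    ex_start = model.exon_containing(event.intron_start)
    ex_end = model.exon_containing(event.intron_end)
    if ex_start is not None and ex_end is not None:
        deleted = _coding_overlap(model, event.intron_start, event.intron_end)
        return EventClass(
            "exonic_deletion",
            f"deletes {deleted} nt within exon(s) {ex_start}-{ex_end}",
            _frame_effect(deleted),
        )
    return EventClass("other", "no reference boundary or single-intron match")


def _shifted_side(
    event: SpliceEvent, model: TranscriptModel, anchored_exon: int, side: str
) -> EventClass:
    """Classify an event with one boundary on a reference splice site.

    ``side`` names the deviating boundary. Deviation into the adjacent exon
    deletes exonic sequence; deviation into the adjacent intron retains
    intronic sequence. Shifts beyond the adjacent exon/intron are ``other``.
    """
    if side == "acceptor":
        # donor anchored at end of exon `anchored_exon`; normal acceptor is
        # start of the next exon
        k = anchored_exon
        ref_end = model.exons[k][0] - 1  # last intron nt of intron k
        delta = event.intron_end - ref_end
        if delta > 0 and model.exon_containing(event.intron_end) == k + 1:
            return EventClass(
                "alt_acceptor",
                f"Δ{delta}nt at genomic 5' of exon {k + 1}",
                _frame_effect(_coding_overlap(model, ref_end + 1, event.intron_end)),
            )
        if delta < 0 and model.intron_containing(event.intron_end + 1) == k:
            # acceptor in mid-intron: boundary of a retained segment or
            # cassette exon; the opposite edge is not visible from this
            # junction, so frame stays unknown
            return EventClass(
                "cassette_exon",
                f"acceptor boundary inside intron {k} ({-delta}nt retained upstream of exon {k + 1})",
                "unknown",
            )
        return EventClass("other", f"acceptor shifted beyond exon {k + 1} neighborhood")

    # donor deviates; acceptor anchored at start of exon `anchored_exon`
    m = anchored_exon
    ref_start = model.exons[m - 2][1] + 1 if m >= 2 else None  # first intron nt
    if ref_start is None:
        return EventClass("other", "acceptor at first exon has no upstream donor")
    delta = ref_start - event.intron_start
    if delta > 0 and model.exon_containing(event.intron_start) == m - 1:
        return EventClass(
            "alt_donor",
            f"Δ{delta}nt at genomic 3' of exon {m - 1}",
            _frame_effect(_coding_overlap(model, event.intron_start, ref_start - 1)),
        )
    if delta < 0 and model.intron_containing(event.intron_start - 1) == m - 1:
        return EventClass(
            "cassette_exon",
            f"donor boundary inside intron {m - 1} ({-delta}nt retained downstream of exon {m - 1})",
            "unknown",
        )
    return EventClass("other", f"donor shifted beyond exon {m - 1} neighborhood")
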