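"""Core splice-event types shared across the package.

A splice event is keyed purely by its genomic gap: contig plus the first and
last intron nucleotide in 1-based inclusive coordinates. This matches the
convention of STAR's splice-junction output, where the start position is the
first nucleotide of the intron (AG|gu) and the end position the last (ag|G).
Strand does not enter the key: on a targeted single-gene panel each locus
carries one gene, and the gap coordinates identify the event unambiguously.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple


class SpliceEvent(NamedTuple):
    """A splice junction: gap between ``intron_start`` and ``intron_end``.

    Coordinates are 1-based inclusive genomic positions of the first and last
    intron nucleotide. The donor-side last exonic base is ``intron_start - 1``
    and the acceptor-side first exonic base is ``intron_end + 1``.
    """

    contig: str
    intron_start: int
    intron_end: int

    @property
    def gap_length(self) -> int:
        """Intron size implied by the gap, ``intron_end - intron_start + 1``."""
        return self.intron_end - self.intron_start + 1

    def validate(self) -> "SpliceEvent":
        if self.intron_end < self.intron_start:
            raise ValueError(
                f"intron_end < intron_start for {self}; gap length must be >= 1"
            )
        return self


#: labels assignable by :func:`splicenrich.gene_model.classify_event`
EVENT_LABELS = (
    "reference_junction",
    "exon_skipping",
    "alt_donor",
    "alt_acceptor",
    "cassette_exon",
    "exonic_deletion",
    "other",
)

FRAME_EFFECTS = ("in_frame", "frameshift", "unknown")


@dataclass(frozen=True)
class EventClass:
    """Classification of a splice event against a reference transcript.

    ``label`` is one of :data:`EVENT_LABELS`. ``detail`` is a human-readable
    description (skipped exon indices, the nt shift at a shifted boundary,
    ...). ``frame_effect`` is derived from the net coding-length change mod 3
    and is ``unknown`` whenever that change cannot be computed from the model
    alone (e.g. a single cassette-exon boundary, or breakpoints outside the
    coding region).
    """

    label: str
    detail: str = ""
    frame_effect: str = "unknown"

    def __post_init__(self) -> None:
        if self.label not in EVENT_LABELS:
            raise ValueError(f"unknown event label {self.label!r}")
        if self.frame_effect not in FRAME_EFFECTS:
            raise ValueError(f"unknown frame effect {self.frame_effect!r}")
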