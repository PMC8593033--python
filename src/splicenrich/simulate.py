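"""Synthetic targeted RNA-seq runs with known junction usage.

Emulates the data regime of a capture-enriched single-gene panel: 150 bp
(paired-end) reads over one transcript, hundreds to thousands of spanning
reads per junction, and per-sample aberrant splicing events at inclusion
fractions psi of a few to tens of percent. Reads are placed uniformly along
transcript coordinates and lifted to gapped genomic alignments, so every
junction a read crosses yields the correct CIGAR ``N`` gap.

Each read covering an event locus carries the alternative junction with
probability psi and the reference structure otherwise (operationally: each
read is drawn from the reference isoform or from an alternative isoform
with the configured weights). Ground truth (psi, expected r and s per
event) is emitted alongside every run.

Reads are error-free by default — the counting pipeline keys on CIGAR gaps,
not base quality — with an optional substitution rate and heterozygous SNVs
for allelic-imbalance realism (allele B reads carry the alt base; NMD is
modeled by down-weighting allele B to ``(1-d)/(2-d)`` of reads).

In-memory reads are lightweight objects exposing the pysam
``AlignedSegment`` attributes the counters consume; persistence to sorted,
indexed BAM (plus truth TSV and VCF) goes through pysam/samtools.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .events import SpliceEvent
from .gene_model import TranscriptModel

_BASES = np.frombuffer(b"ACGT", dtype="S1")

_FLAG_PAIRED = 0x1
_FLAG_PROPER = 0x2
_FLAG_REVERSE = 0x10
_FLAG_MREVERSE = 0x20
_FLAG_READ1 = 0x40
_FLAG_READ2 = 0x80

_CIGAR_OPS = "MIDNSHP=X"


class SimRead:
    """Minimal in-memory alignment record, duck-typing pysam AlignedSegment."""

    __slots__ = (
        "query_name", "flag", "reference_name", "reference_start",
        "mapping_quality", "cigartuples", "query_sequence",
        "next_reference_start", "template_length",
    )

    def __init__(self, query_name, flag, reference_name, reference_start,
                 cigartuples, query_sequence=None, mapping_quality=60,
                 next_reference_start=-1, template_length=0):
        self.query_name = query_name
        self.flag = flag
        self.reference_name = reference_name
        self.reference_start = reference_start  # 0-based, as in pysam
        self.mapping_quality = mapping_quality
        self.cigartuples = cigartuples
        self.query_sequence = query_sequence
        self.next_reference_start = next_reference_start
        self.template_length = template_length

    # pysam-compatible surface -----------------------------------------
    @property
    def is_unmapped(self):
        return bool(self.flag & 0x4)

    @property
    def is_secondary(self):
        return bool(self.flag & 0x100)

    @property
    def is_supplementary(self):
        return bool(self.flag & 0x800)

    @property
    def is_reverse(self):
        return bool(self.flag & _FLAG_REVERSE)

    @property
    def is_read1(self):
        return bool(self.flag & _FLAG_READ1)

    @property
    def reference_end(self):
        pos = self.reference_start
        for op, length in self.cigartuples:
            if op in (0, 2, 3, 7, 8):
                pos += length
        return pos

    @property
    def cigarstring(self):
        return "".join(f"{length}{_CIGAR_OPS[op]}" for op, length in self.cigartuples)

    def has_tag(self, tag):
        return False

    def get_tag(self, tag):
        raise KeyError(tag)


@dataclass
class SimConfig:
    """Study conditions of a simulated run.

    ``depth`` is the target number of spanning reads per reference junction
    (scalar, or a mapping sample_id -> scalar). ``spikes`` are
    sample-specific aberrant events, ``(sample_id, term-or-event, psi)``;
    ``natural_events`` apply to every sample at a shared psi. ``nmd`` maps
    sample_id to the degradation fraction d of the alt-bearing allele;
    ``het_variants`` are genomic positions of heterozygous SNVs.
    """

    model: TranscriptModel
    n_samples: int = 6
    read_length: int = 150
    paired: bool = True
    depth: Union[int, dict] = 2000
    fragment_mean: float = 300.0
    fragment_sd: float = 50.0
    spikes: list = field(default_factory=list)
    natural_events: list = field(default_factory=list)
    het_variants: list = field(default_factory=list)
    nmd: dict = field(default_factory=dict)
    duplicate_rate: float = 0.0
    error_rate: float = 0.0
    with_sequence: bool = True
    seed: int = 0

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_samples)]


@dataclass
class SimulatedRun:
    """A simulated run: per-sample reads plus ground truth."""

    config: SimConfig
    reads: dict  # sample_id -> list[SimRead]
    truth: pd.DataFrame
    reference_sequence: str
    contig_length: int
    variants: list  # (position, ref, alt)


# -- event grammar -----------------------------------------------------

_GRAMMAR = re.compile(
    r"""^\s*(?P<op>skip|alt_acceptor|alt_donor|cassette|intron_retention)\s*
        \(\s*(?P<args>[^)]*)\)\s*$""",
    re.VERBOSE,
)


def _int_args(args: str) -> list[int]:
    return [int(x) for x in re.findall(r"-?\d+", args)]


def event_grammar(term: str, model: TranscriptModel) -> list[SpliceEvent]:
    """Expand an event grammar term into its splice events.

    Supported terms (exon/intron indices are 1-based systematic):

    * ``skip(k)`` and ``skip(k..m)`` — exon skipping;
    * ``alt_acceptor(k, d)`` — acceptor shifted d nt into exon k;
    * ``alt_donor(k, d)`` — donor shifted d nt into exon k;
    * ``cassette(intron k, offset o, length L)`` — pseudo-exon of L nt at
      offset o inside intron k (two events flank it);
    * ``intron_retention(k)`` — no junction (unbroken reads), empty list.
    """
    match = _GRAMMAR.match(term)
    if not match:
        raise ValueError(f"unparsable event grammar term {term!r}")
    op = match.group("op")
    args = _int_args(match.group("args"))
    exons = model.exons
    contig = model.contig

    def _check_exon(k):
        if not 1 <= k <= model.n_exons:
            raise ValueError(f"{term!r}: exon {k} not in model (1..{model.n_exons})")

    def _check_intron(k):
        if not 1 <= k <= model.n_exons - 1:
            raise ValueError(f"{term!r}: intron {k} not in model (1..{model.n_exons - 1})")

    if op == "skip":
        if len(args) == 1:
            k = m = args[0]
        elif len(args) == 2:
            k, m = args
        else:
            raise ValueError(f"{term!r}: skip takes 1 or 2 exon indices")
        _check_exon(k), _check_exon(m)
        if not (1 < k <= m < model.n_exons):
            raise ValueError(f"{term!r}: cannot skip terminal exons")
        return [SpliceEvent(contig, exons[k - 2][1] + 1, exons[m][0] - 1)]
    if op == "alt_acceptor":
        k, delta = args
        _check_exon(k)
        if k == 1:
            raise ValueError(f"{term!r}: first exon has no acceptor")
        return [SpliceEvent(contig, exons[k - 2][1] + 1, exons[k - 1][0] - 1 + delta)]
    if op == "alt_donor":
        k, delta = args
        _check_exon(k)
        if k == model.n_exons:
            raise ValueError(f"{term!r}: last exon has no donor")
        return [SpliceEvent(contig, exons[k - 1][1] + 1 - delta, exons[k][0] - 1)]
    if op == "cassette":
        k, offset, length = args
        _check_intron(k)
        intron_start, intron_end = exons[k - 1][1] + 1, exons[k][0] - 1
        p = intron_start + offset
        q = p + length - 1
        if q >= intron_end or p <= intron_start:
            raise ValueError(f"{term!r}: pseudo-exon does not fit inside intron {k}")
        return [
            SpliceEvent(contig, intron_start, p - 1),
            SpliceEvent(contig, q + 1, intron_end),
        ]
    # intron_retention: unbroken reads, no junction emitted
    _check_intron(args[0])
    return []


def _isoform_blocks(term: Optional[str], model: TranscriptModel) -> list[tuple[int, int]]:
    """Genomic blocks (1-based inclusive) of the isoform a term produces."""
    exons = list(model.exons)
    if term is None:
        return exons
    match = _GRAMMAR.match(term)
    if not match:
        raise ValueError(f"unparsable event grammar term {term!r}")
    op = match.group("op")
    args = _int_args(match.group("args"))
    if op == "skip":
        k, m = (args[0], args[0]) if len(args) == 1 else args
        return exons[: k - 1] + exons[m:]
    if op == "alt_acceptor":
        k, delta = args
        start, end = exons[k - 1]
        exons[k - 1] = (start + delta, end)
        return exons
    if op == "alt_donor":
        k, delta = args
        start, end = exons[k - 1]
        exons[k - 1] = (start, end - delta)
        return exons
    if op == "cassette":
        k, offset, length = args
        p = exons[k - 1][1] + 1 + offset
        return exons[:k] + [(p, p + length - 1)] + exons[k:]
    if op == "intron_retention":
        k = args[0]
        merged = exons[: k - 1] + [(exons[k - 1][0], exons[k][1])] + exons[k + 1:]
        return merged
    raise AssertionError(op)


def _isoform_for_event(event: SpliceEvent, model: TranscriptModel) -> list[tuple[int, int]]:
    """Isoform carrying one explicit junction.

    The transcript keeps all exonic sequence outside the gap; a breakpoint
    falling inside an intron retains the adjacent intronic segment up to the
    breakpoint (so alternative donor/acceptor sites in introns produce the
    expected ``ins N nt`` structure). A lone mid-intron cassette boundary is
    ambiguous from one junction; use the ``cassette(...)`` grammar term for
    a properly paired pseudo-exon.
    """
    a, b = event.intron_start, event.intron_end
    exons = model.exons
    left = [(s, min(e, a - 1)) for s, e in exons if s <= a - 1]
    if model.exon_containing(a - 1) is None:
        k = model.intron_containing(a - 1)
        if k is None:
            raise ValueError(f"event {event} donor breakpoint is off-transcript")
        left.append((exons[k - 1][1] + 1, a - 1))
    right = [(max(s, b + 1), e) for s, e in exons if e >= b + 1]
    if model.exon_containing(b + 1) is None:
        k = model.intron_containing(b + 1)
        if k is None:
            raise ValueError(f"event {event} acceptor breakpoint is off-transcript")
        right.insert(0, (b + 1, exons[k][0] - 1))
    if not left or not right:
        raise ValueError(f"event {event} leaves no flanking exon sequence")
    return left + right


def _resolve_alt(item, model: TranscriptModel):
    """Normalize a spike/natural-event entry to (label, events, isoform blocks)."""
    if isinstance(item, SpliceEvent):
        events = [item.validate()]
        blocks = _isoform_for_event(item, model)
        label = f"{item.contig}:{item.intron_start}-{item.intron_end}"
    else:
        label = str(item)
        events = event_grammar(label, model)
        blocks = _isoform_blocks(label, model)
    lo, hi = model.span
    for ev in events:
        if ev.contig != model.contig or ev.intron_start < lo or ev.intron_end > hi:
            raise ValueError(f"event {ev} lies outside the transcript model span")
    return label, events, blocks


# -- read generation ---------------------------------------------------

def _cumlen(blocks):
    lengths = np.array([e - s + 1 for s, e in blocks])
    return lengths, np.concatenate([[0], np.cumsum(lengths)])


def _lift(blocks, lengths, offsets, t_start: int, t_end: int):
    """Map a transcript interval (1-based) to genomic blocks of the isoform."""
    out = []
    bi = int(np.searchsorted(offsets, t_start - 1, side="right")) - 1
    pos = t_start
    while pos <= t_end:
        bstart, bend = blocks[bi]
        g = bstart + (pos - 1 - offsets[bi])
        take = min(t_end - pos + 1, bend - g + 1)
        out.append((g, g + take - 1))
        pos += take
        bi += 1
    return out


def _cigar_from_blocks(gblocks) -> list[tuple[int, int]]:
    cig = []
    for (s1, e1), (s2, _) in zip(gblocks, gblocks[1:]):
        cig.append((0, e1 - s1 + 1))
        cig.append((3, s2 - e1 - 1))
    s, e = gblocks[-1]
    cig.append((0, e - s + 1))
    return cig


def simulate_run(config: SimConfig) -> SimulatedRun:
    """Generate a full run per the configured study conditions.

    Deterministic: a fixed seed yields identical reads (and therefore
    byte-identical files when written).
    """
    model = config.model
    rng = np.random.default_rng(config.seed)
    span_lo, span_hi = model.span
    contig_length = span_hi + 1000

    # one shared synthetic reference per run, so all samples agree
    ref_seq = _BASES[rng.integers(0, 4, size=contig_length)].tobytes().decode()

    variants = []
    for item in config.het_variants:
        if isinstance(item, int):
            pos = item
            ref = ref_seq[pos - 1]
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        else:
            pos, ref, alt = item
        variants.append((int(pos), ref, alt))
    var_pos = {pos: (ref, alt) for pos, ref, alt in variants}

    # per-sample isoform tables; each alt = (label, events, blocks, psi)
    natural = [(*_resolve_alt(term, model), float(psi)) for term, psi in config.natural_events]
    spikes_by_sample: dict[str, list] = {}
    for sample_id, term, psi in config.spikes:
        spikes_by_sample.setdefault(str(sample_id), []).append(
            (*_resolve_alt(term, model), float(psi))
        )

    truth_rows = []
    reads: dict[str, list[SimRead]] = {}
    rl = config.read_length
    for sample_id in config.sample_ids:
        alt_terms = natural + spikes_by_sample.get(sample_id, [])
        weights = [psi for *_, psi in alt_terms]
        if any(not 0 <= w <= 1 for w in weights) or sum(weights) > 1:
            raise ValueError(f"{sample_id}: inclusion fractions must lie in [0,1] and sum <= 1")
        isoforms = [_isoform_blocks(None, model)] + [
            blocks for _, _, blocks, _ in alt_terms
        ]
        iso_lens = [int(sum(e - s + 1 for s, e in blocks)) for blocks in isoforms]
        if min(iso_lens) < rl:
            raise ValueError("an isoform is shorter than the read length")

        # psi is the probability that a read covering a junction locus carries
        # the alternative junction. Reads land uniformly per isoform, so a
        # shorter isoform concentrates more reads over any given locus;
        # weighting each isoform by psi_i * (L_i - rl + 1) makes the fraction
        # of locus-crossing reads equal psi regardless of isoform lengths.
        base_w = np.array([1.0 - sum(weights)] + weights)
        # fragment (not read) starts are what land uniformly, so the start
        # space per isoform is L - fragment_length + 1
        frag = config.fragment_mean if config.paired else rl
        eff = base_w * np.maximum(np.array(iso_lens) - frag + 1, 1.0)
        z = float(eff.sum())
        probs = eff / z

        depth = config.depth[sample_id] if isinstance(config.depth, dict) else config.depth
        mates = 2 if config.paired else 1
        n_frag = int(np.ceil(depth * z / ((rl - 1) * mates)))

        d = float(config.nmd.get(sample_id, 0.0))
        p_alt_allele = (1.0 - d) / (2.0 - d)

        sample_reads = _sample_reads(
            rng, config, sample_id, isoforms, probs, n_frag, p_alt_allele,
            ref_seq, var_pos,
        )
        reads[sample_id] = sample_reads

        for (label, events, _, psi) in alt_terms:
            for ev in events:
                truth_rows.append(
                    {
                        "sample_id": sample_id,
                        "term": label,
                        "contig": ev.contig,
                        "intron_start": ev.intron_start,
                        "intron_end": ev.intron_end,
                        "psi": psi,
                        "expected_s": depth,
                        "expected_r": psi * depth,
                    }
                )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "sample_id", "term", "contig", "intron_start", "intron_end",
            "psi", "expected_s", "expected_r",
        ],
    )
    return SimulatedRun(config, reads, truth, ref_seq, contig_length, variants)


def _sample_reads(rng, config, sample_id, isoforms, probs, n_frag,
                  p_alt_allele, ref_seq, var_pos):
    model = config.model
    rl = config.read_length
    out = []
    geoms = [_cumlen(blocks) for blocks in isoforms]
    iso_lens = [int(lengths.sum()) for lengths, _ in geoms]

    iso_choice = rng.choice(len(isoforms), size=n_frag, p=probs)
    frag_lens = rng.normal(config.fragment_mean, config.fragment_sd, size=n_frag)
    start_u = rng.random(n_frag)
    allele_alt = rng.random(n_frag) < p_alt_allele
    dup = rng.random(n_frag) < config.duplicate_rate

    for fi in range(n_frag):
        iso = int(iso_choice[fi])
        blocks = isoforms[iso]
        lengths, offsets = geoms[iso]
        iso_len = iso_lens[iso]
        frag = int(np.clip(round(frag_lens[fi]), rl, iso_len))
        fs = 1 + int(start_u[fi] * (iso_len - frag + 1))
        mate_ivals = [(fs, fs + rl - 1)]
        if config.paired:
            mate_ivals.append((fs + frag - rl, fs + frag - 1))

        gblocks_list = [
            _lift(blocks, lengths, offsets, t0, t1) for t0, t1 in mate_ivals
        ]
        g_start = [gb[0][0] for gb in gblocks_list]
        qname = f"{sample_id}.{fi}"
        n_copies = 2 if dup[fi] else 1
        for copy in range(n_copies):
            cname = qname if copy == 0 else f"{qname}.dup"
            for mi, gblocks in enumerate(gblocks_list):
                flag = 0
                if config.paired:
                    flag |= _FLAG_PAIRED | _FLAG_PROPER
                    flag |= _FLAG_READ1 if mi == 0 else _FLAG_READ2
                    flag |= _FLAG_MREVERSE if mi == 0 else _FLAG_REVERSE
                seq = None
                if config.with_sequence:
                    seq = _read_sequence(
                        rng, gblocks, ref_seq, var_pos, bool(allele_alt[fi]),
                        config.error_rate,
                    )
                tlen = 0
                if config.paired:
                    span = gblocks_list[-1][-1][1] - gblocks_list[0][0][0] + 1
                    tlen = span if mi == 0 else -span
                out.append(
                    SimRead(
                        query_name=cname,
                        flag=flag,
                        reference_name=model.contig,
                        reference_start=gblocks[0][0] - 1,
                        cigartuples=_cigar_from_blocks(gblocks),
                        query_sequence=seq,
                        next_reference_start=(
                            g_start[1 - mi] - 1 if config.paired else -1
                        ),
                        template_length=tlen,
                    )
                )
    out.sort(key=lambda r: (r.reference_start, r.query_name, r.flag))
    return out


def _read_sequence(rng, gblocks, ref_seq, var_pos, is_alt_allele, error_rate):
    parts = []
    for start, end in gblocks:
        parts.append(ref_seq[start - 1:end])
    seq = list("".join(parts))
    if var_pos:
        offset = 0
        for start, end in gblocks:
            for pos in range(start, end + 1):
                if pos in var_pos:
                    ref, alt = var_pos[pos]
                    seq[offset + pos - start] = alt if is_alt_allele else ref
            offset += end - start + 1
    if error_rate > 0:
        n = len(seq)
        hits = np.nonzero(rng.random(n) < error_rate)[0]
        for idx in hits:
            seq[idx] = "ACGT"[(("ACGT".index(seq[idx]) + 1 + int(rng.integers(0, 3))) % 4)]
    return "".join(seq)


# -- persistence -------------------------------------------------------

def write_run(run: SimulatedRun, out_dir: str | Path) -> dict[str, Path]:
    """Write sorted, indexed BAMs plus truth TSV and a VCF of het SNVs.

    Returns a mapping of sample_id -> BAM path (plus ``truth`` and ``vcf``
    keys).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = run.config.model
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": model.contig, "LN": run.contig_length}],
        }
    )
    paths: dict[str, Path] = {}
    for sample_id, reads in run.reads.items():
        bam = out_dir / f"{sample_id}.bam"
        with pysam.AlignmentFile(str(bam), "wb", header=header) as handle:
            for read in reads:
                handle.write(_to_pysam(read, header))
        pysam.index(str(bam))
        paths[sample_id] = bam

    truth_path = out_dir / "truth.tsv"
    run.truth.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path

    vcf_path = out_dir / "variants.vcf"
    _write_vcf(run, vcf_path)
    paths["vcf"] = vcf_path
    return paths


def _to_pysam(read: SimRead, header: pysam.AlignmentHeader) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = read.query_name
    seg.flag = read.flag
    seg.reference_id = 0
    seg.reference_start = read.reference_start
    seg.mapping_quality = read.mapping_quality
    seg.cigartuples = read.cigartuples
    if read.query_sequence is not None:
        seg.query_sequence = read.query_sequence
        seg.query_qualities = pysam.qualitystring_to_array("I" * len(read.query_sequence))
    if read.next_reference_start >= 0:
        seg.next_reference_id = 0
        seg.next_reference_start = read.next_reference_start
    seg.template_length = read.template_length
    return seg


def _write_vcf(run: SimulatedRun, path: Path) -> None:
    header = pysam.VariantHeader()
    header.add_line("##source=splicenrich-simulate")
    header.contigs.add(run.config.model.contig, length=run.contig_length)
    header.formats.add("GT", 1, "String", "Genotype")
    header.add_sample("SIM")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for pos, ref, alt in run.variants:
            rec = vcf.new_record(
                contig=run.config.model.contig, start=pos - 1, stop=pos,
                alleles=(ref, alt),
            )
            rec.samples["SIM"]["GT"] = (0, 1)
            rec.samples["SIM"].phased = False
            vcf.write(rec)
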