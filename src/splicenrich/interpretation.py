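"""Post-hoc interpretation of enrichment output.

Implements the review workflow applied after scoring:

* a GAP artefact filter removing events whose implied intron would be
  shorter than 4 nt (gap length ``intron_end - intron_start + 1 <= 3``,
  almost always mapping artefacts rather than splicing);
* per-sample ranking of events by descending ERS with a review flag at
  ERS > 5 (relevant events can score below 5 when a variant produces
  several events, when a natural event is merely upregulated, or when two
  samples in the run share the effect — such events still surface through
  drop linkage);
* detection of ERS *drops* at reference junctions: a highly expressed
  alternative event depresses the normal junctions in the same region, so a
  reference junction with ERS < 0.8, or the lowest ERS of the group, marks
  the neighborhood of a candidate event;
* exact-coordinate matching against a catalog of known (naturally
  occurring) events.

Automated motif scoring is out of scope; the emitted evidence columns
(r, s, gap length, drop linkage) support the manual artefact review.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .events import SpliceEvent
from .gene_model import TranscriptModel, classify_event, reference_junctions

logger = logging.getLogger(__name__)

GAP_MIN_RETAINED = 4  # smallest legal intron size; gaps <= 3 are artefacts
ERS_FLAG_THRESHOLD = 5.0
DROP_ERS_THRESHOLD = 0.8


@dataclass
class DropReport:
    """ERS drop assessment of one reference junction in one sample."""

    sample_id: str
    junction: SpliceEvent
    exon_pair: tuple[int, int]
    ers_ref: float
    group_median: float
    is_drop: bool
    low_confidence: bool = False  # group minimum but not below the threshold
    linked_events: list[SpliceEvent] = field(default_factory=list)


def _gap_lengths(df: pd.DataFrame) -> pd.Series:
    return df["intron_end"] - df["intron_start"] + 1


def gap_filter(events: pd.DataFrame, min_gap: int = GAP_MIN_RETAINED) -> pd.DataFrame:
    """Retain events with gap length >= ``min_gap`` (default: > 3).

    Idempotent and order-preserving.
    """
    if len(events) == 0:
        return events
    return events[_gap_lengths(events) >= min_gap]


class EventAnnotator:
    """Sklearn-style transformer adding interpretation columns to records.

    Adds per-row: ``gap_len``, ``gap_fail``, ``high_ers``, the event
    classification against the gene model(s) (``event_class``, ``detail``,
    ``frame_effect``), catalog matches (``known_event``, ``known_source``)
    and sorts each sample's events by descending ERS (ties broken by
    descending ``r`` then coordinates, deterministically).
    """

    def __init__(
        self,
        models: Sequence[TranscriptModel] = (),
        catalog: Optional[pd.DataFrame] = None,
        ers_flag: float = ERS_FLAG_THRESHOLD,
        min_gap: int = GAP_MIN_RETAINED,
    ):
        self.models = models
        self.catalog = catalog
        self.ers_flag = ers_flag
        self.min_gap = min_gap

    def get_params(self, deep: bool = True) -> dict:
        return {
            "models": self.models,
            "catalog": self.catalog,
            "ers_flag": self.ers_flag,
            "min_gap": self.min_gap,
        }

    def set_params(self, **params) -> "EventAnnotator":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r} for EventAnnotator")
            setattr(self, key, value)
        return self

    def fit(self, records: pd.DataFrame, y=None) -> "EventAnnotator":
        self.reference_junctions_ = {}
        for model in self.models:
            ref = reference_junctions(model)
            for ev, pair in zip(ref.junctions, ref.exon_pairs):
                self.reference_junctions_[ev] = (model, pair)
        self.catalog_ = _normalize_catalog(self.catalog)
        return self

    def _model_for(self, event: SpliceEvent) -> Optional[TranscriptModel]:
        for model in self.models:
            lo, hi = model.span
            if model.contig == event.contig and lo <= event.intron_start and event.intron_end <= hi:
                return model
        return None

    def transform(self, records: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "catalog_"):
            raise RuntimeError("EventAnnotator is not fitted")
        out = records.copy().reset_index(drop=True)
        out["gap_len"] = _gap_lengths(out)
        out["gap_fail"] = out["gap_len"] <= self.min_gap - 1
        out["high_ers"] = out["ers"] > self.ers_flag

        labels, details, frames = [], [], []
        for contig, start, end in zip(out["contig"], out["intron_start"], out["intron_end"]):
            event = SpliceEvent(contig, int(start), int(end))
            model = self._model_for(event)
            if model is None:
                labels.append("other")
                details.append("outside all gene models")
                frames.append("unknown")
            else:
                cls = classify_event(event, model)
                labels.append(cls.label)
                details.append(cls.detail)
                frames.append(cls.frame_effect)
        out["event_class"] = labels
        out["detail"] = details
        out["frame_effect"] = frames

        if self.catalog_ is not None and len(self.catalog_):
            merged = out.merge(
                self.catalog_, on=["contig", "intron_start", "intron_end"], how="left"
            )
            out["known_event"] = merged["known_source"].notna().to_numpy()
            out["known_source"] = merged["known_source"].to_numpy()
        else:
            out["known_event"] = False
            out["known_source"] = pd.NA

        out = out.sort_values(
            ["sample_id", "ers", "r", "contig", "intron_start", "intron_end"],
            ascending=[True, False, False, True, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
        return out

    def fit_transform(self, records: pd.DataFrame, y=None) -> pd.DataFrame:
        return self.fit(records).transform(records)


def rank_and_flag(
    records: pd.DataFrame,
    models: Sequence[TranscriptModel] = (),
    catalog: Optional[pd.DataFrame] = None,
    ers_flag: float = ERS_FLAG_THRESHOLD,
    min_gap: int = GAP_MIN_RETAINED,
) -> pd.DataFrame:
    """Annotate + rank one run's enrichment records (wrapper over EventAnnotator)."""
    return EventAnnotator(
        models=models, catalog=catalog, ers_flag=ers_flag, min_gap=min_gap
    ).fit_transform(records)


def _normalize_catalog(catalog: Optional[pd.DataFrame]) -> Optional[pd.DataFrame]:
    if catalog is None:
        return None
    required = {"contig", "intron_start", "intron_end"}
    missing = required - set(catalog.columns)
    if missing:
        raise ValueError(f"catalog lacks columns {sorted(missing)}")
    cat = catalog.copy()
    for col in ("intron_start", "intron_end"):
        cat[col] = pd.to_numeric(cat[col], errors="coerce")
    bad = cat[["contig", "intron_start", "intron_end"]].isna().any(axis=1)
    if bad.any():
        logger.warning("catalog: skipping %d malformed row(s)", int(bad.sum()))
        cat = cat[~bad]
    source = cat["source"] if "source" in cat.columns else cat.get("label", "catalog")
    cat = cat[["contig", "intron_start", "intron_end"]].astype(
        {"intron_start": int, "intron_end": int}
    )
    cat["known_source"] = source
    return cat.drop_duplicates(["contig", "intron_start", "intron_end"])


def load_catalog(path: str | Path) -> pd.DataFrame:
    """Load a known-events catalog TSV (contig, intron_start, intron_end, label, source)."""
    cat = pd.read_csv(path, sep="\t", comment="#")
    return cat


def reference_junction_matrix(
    records: pd.DataFrame, model: TranscriptModel
) -> pd.DataFrame:
    """ERS of each reference junction (rows) per sample (columns).

    The tabular twin of the per-cohort junction boxplots: one row per
    exon-exon junction of the reference transcript, one column per sample.
    Junctions absent from the records yield NaN.
    """
    ref = reference_junctions(model)
    samples = list(dict.fromkeys(records["sample_id"]))
    index = [f"exon{k}-exon{k1}" for k, k1 in ref.exon_pairs]
    mat = pd.DataFrame(np.nan, index=index, columns=samples)
    keyed = records.set_index(["contig", "intron_start", "intron_end", "sample_id"])
    for label, ev in zip(index, ref.junctions):
        for sid in samples:
            key = (ev.contig, ev.intron_start, ev.intron_end, sid)
            if key in keyed.index:
                mat.loc[label, sid] = keyed.loc[key, "ers"]
    return mat


class DropDetector:
    """Detect ERS drops at reference junctions and link nearby events.

    A junction is drop-flagged in a sample when its ERS is below
    ``threshold`` (default 0.8) **or** is the lowest of the whole group (the
    rule is disjunctive; minimum-only drops at ERS >= threshold carry
    ``low_confidence=True``). ``linked_events`` are the sample's
    non-reference events overlapping the dropped junction's flanking exons
    ``[start of exon k, end of exon k+1]``.
    """

    def __init__(self, model: TranscriptModel, threshold: float = DROP_ERS_THRESHOLD):
        self.model = model
        self.threshold = threshold

    def get_params(self, deep: bool = True) -> dict:
        return {"model": self.model, "threshold": self.threshold}

    def set_params(self, **params) -> "DropDetector":
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r} for DropDetector")
            setattr(self, key, value)
        return self

    def fit(self, records: pd.DataFrame, y=None) -> "DropDetector":
        self.reference_ = reference_junctions(self.model)
        return self

    def transform(self, records: pd.DataFrame) -> list[DropReport]:
        if not hasattr(self, "reference_"):
            raise RuntimeError("DropDetector is not fitted")
        samples = list(dict.fromkeys(records["sample_id"]))
        if len(samples) < 2:
            raise ValueError("drop detection needs at least 2 samples")
        ref_set = set(self.reference_.junctions)
        reports: list[DropReport] = []
        keyed = records.set_index(["contig", "intron_start", "intron_end", "sample_id"])

        # per-sample non-reference events for linkage
        alt_events: dict[str, list[SpliceEvent]] = {sid: [] for sid in samples}
        for row in records.itertuples(index=False):
            ev = SpliceEvent(row.contig, int(row.intron_start), int(row.intron_end))
            if ev not in ref_set and getattr(row, "r", 0) > 0:
                alt_events[row.sample_id].append(ev)

        for ev, pair in zip(self.reference_.junctions, self.reference_.exon_pairs):
            ers_by_sample = {}
            for sid in samples:
                key = (ev.contig, ev.intron_start, ev.intron_end, sid)
                if key in keyed.index:
                    ers_by_sample[sid] = float(keyed.loc[key, "ers"])
            if not ers_by_sample:
                continue
            values = np.array(list(ers_by_sample.values()))
            median = float(np.median(values))
            minimum = float(values.min())
            k, k1 = pair
            window = (self.model.exons[k - 1][0], self.model.exons[k1 - 1][1])
            for sid, ers in ers_by_sample.items():
                below = ers < self.threshold
                is_min = ers == minimum
                is_drop = below or is_min
                linked = [
                    alt
                    for alt in alt_events[sid]
                    if alt.intron_start <= window[1] and alt.intron_end >= window[0]
                ] if is_drop else []
                reports.append(
                    DropReport(
                        sample_id=sid,
                        junction=ev,
                        exon_pair=pair,
                        ers_ref=ers,
                        group_median=median,
                        is_drop=is_drop,
                        low_confidence=is_min and not below,
                        linked_events=linked,
                    )
                )
        return reports

    def fit_transform(self, records: pd.DataFrame, y=None) -> list[DropReport]:
        return self.fit(records).transform(records)


def detect_drops(
    records: pd.DataFrame, model: TranscriptModel, threshold: float = DROP_ERS_THRESHOLD
) -> list[DropReport]:
    """Wrapper over :class:`DropDetector`."""
    return DropDetector(model, threshold=threshold).fit_transform(records)


def drops_to_frame(reports: Iterable[DropReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        rows.append(
            {
                "sample_id": rep.sample_id,
                "contig": rep.junction.contig,
                "intron_start": rep.junction.intron_start,
                "intron_end": rep.junction.intron_end,
                "exon_pair": f"exon{rep.exon_pair[0]}-exon{rep.exon_pair[1]}",
                "ers_ref": rep.ers_ref,
                "group_median": rep.group_median,
                "is_drop": rep.is_drop,
                "low_confidence": rep.low_confidence,
                "linked_events": ";".join(
                    f"{e.contig}:{e.intron_start}-{e.intron_end}" for e in rep.linked_events
                ),
            }
        )
    return pd.DataFrame(rows)


def match_known_events(
    events: pd.DataFrame, catalog: Optional[pd.DataFrame]
) -> pd.DataFrame:
    """Exact-coordinate catalog matching; adds known_event/known_source."""
    cat = _normalize_catalog(catalog)
    out = events.copy().reset_index(drop=True)
    if cat is None or not len(cat):
        out["known_event"] = False
        out["known_source"] = pd.NA
        return out
    merged = out.merge(cat, on=["contig", "intron_start", "intron_end"], how="left")
    out["known_event"] = merged["known_source"].notna().to_numpy()
    out["known_source"] = merged["known_source"].to_numpy()
    return out
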