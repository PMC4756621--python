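"""Consensus regulatory build from segmentations and experimental peaks.

Per-cell-type genome segmentations label regions with one of eight states;
four of those states (promoter with TSS, promoter flank, enhancer, CTCF
enriched) generate consensus regulatory features. Experimental peaks not
explained by any segmentation-derived feature become unannotated TF-binding
or open-chromatin features. Every consensus feature finally carries an
active/inactive flag per cell type. The consensus, cell-type-agnostic set
plays the role of the "MultiCell" view; per-cell views are the same
features filtered by activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from regkit.intervals import (
    GenomicInterval,
    Gff3Record,
    Peak,
    merge_intervals,
    overlap_length,
    subtract_intervals,
)

SEGMENT_LABELS = (
    "tss",
    "flank",
    "transcribed",
    "enhancer",
    "ctcf",
    "repressed",
    "low",
    "heterochromatin",
)

# the four feature-generating labels, in overlap-priority order
LABEL_TO_CLASS = {
    "tss": "promoter_with_tss",
    "flank": "promoter_flank",
    "enhancer": "enhancer",
    "ctcf": "ctcf_binding_site",
}
CLASS_PRIORITY = tuple(LABEL_TO_CLASS.values())

FEATURE_CLASSES = CLASS_PRIORITY + ("tf_binding_site", "open_chromatin")

# assay names treated as open chromatin rather than TF binding
OPEN_CHROMATIN_ASSAYS = frozenset({"DNase1", "DNase", "ATAC", "FAIRE"})


@dataclass(frozen=True)
class SegmentState:
    """One labeled segmentation interval in one cell type."""

    interval: GenomicInterval
    cell_type: str
    label: str

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise ValueError(
                f"unknown segmentation label {self.label!r}; expected one of "
                f"{SEGMENT_LABELS}"
            )


@dataclass(frozen=True)
class RegulatoryFeature:
    """A consensus regulatory element with a functional class and a
    per-cell-type activity map."""

    interval: GenomicInterval
    feature_class: str
    stable_id: str = ""
    activity: dict = field(default_factory=dict)  # cell_type -> "active"|"inactive"

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")


def consolidate_segmentations(states: list[SegmentState]) -> list[RegulatoryFeature]:
    """Merge per-cell segments into disjoint consensus features.

    For each feature-generating label, segments are unioned across cell
    types (gap 0). Overlaps between classes are resolved by priority
    tss > flank > enhancer > ctcf: the footprint of every higher-priority
    class is subtracted from lower-priority candidates, so same-class and
    cross-class features never overlap. Activity starts all-inactive.
    """
    cells = sorted({s.cell_type for s in states})
    if not cells:
        raise ValueError("need at least one cell type")
    by_label: dict[str, list[GenomicInterval]] = {}
    for s in states:
        if s.label in LABEL_TO_CLASS:
            by_label.setdefault(s.label, []).append(s.interval)
    features: list[RegulatoryFeature] = []
    claimed: list[GenomicInterval] = []
    for label in LABEL_TO_CLASS:
        candidates = merge_intervals(by_label.get(label, []))
        for iv in subtract_intervals(candidates, claimed):
            features.append(
                RegulatoryFeature(
                    interval=iv,
                    feature_class=LABEL_TO_CLASS[label],
                    activity={c: "inactive" for c in cells},
                )
            )
        claimed.extend(candidates)
    features.sort(key=lambda f: (f.interval.contig, f.interval.start, f.feature_class))
    return features


def add_unexplained_evidence(
    features: list[RegulatoryFeature],
    peaks: list[Peak],
    open_chromatin_assays: frozenset = OPEN_CHROMATIN_ASSAYS,
) -> list[RegulatoryFeature]:
    """Spawn unannotated features from peaks no existing feature explains.

    A peak overlapping any existing feature (by >= 1 base) contributes
    nothing; the remaining peaks are merged per evidence kind (TF assay vs
    open-chromatin assay) into tf_binding_site / open_chromatin features.
    """
    cells = sorted(
        {c for f in features for c in f.activity} | {p.cell_type for p in peaks}
    )
    unexplained: dict[str, list[GenomicInterval]] = {"tf_binding_site": [], "open_chromatin": []}
    for p in peaks:
        if any(overlap_length(p.interval, f.interval) for f in features):
            continue
        kind = (
            "open_chromatin"
            if p.feature_type in open_chromatin_assays
            else "tf_binding_site"
        )
        unexplained[kind].append(p.interval)
    out = list(features)
    for kind in ("tf_binding_site", "open_chromatin"):
        for iv in merge_intervals(unexplained[kind]):
            out.append(
                RegulatoryFeature(
                    interval=iv,
                    feature_class=kind,
                    activity={c: "inactive" for c in cells},
                )
            )
    # widen activity maps to the full cell-type universe
    out = [
        replace(f, activity={c: f.activity.get(c, "inactive") for c in cells})
        for f in out
    ]
    out.sort(key=lambda f: (f.interval.contig, f.interval.start, f.feature_class))
    return out


def annotate_activity(
    features: list[RegulatoryFeature],
    states: list[SegmentState],
    peaks: list[Peak],
) -> list[RegulatoryFeature]:
    """Flag each feature active or inactive per cell type.

    Active in cell c iff it overlaps a segment in c whose label maps to the
    feature's class, or it overlaps any peak observed in c. All eight
    segmentation labels may drive peak-independent activity only through
    this class match; repressed/low/etc. never activate.
    """
    cells = sorted(
        {c for f in features for c in f.activity}
        | {s.cell_type for s in states}
        | {p.cell_type for p in peaks}
    )
    evidence_cells = {s.cell_type for s in states} | {p.cell_type for p in peaks}
    for c in cells:
        if c not in evidence_cells:
            warnings.warn(
                f"cell type {c!r} has no segmentation or peak data; all "
                "features inactive there",
                stacklevel=2,
            )
    out = []
    for f in features:
        activity = {}
        for c in cells:
            seg_hit = any(
                s.cell_type == c
                and LABEL_TO_CLASS.get(s.label) == f.feature_class
                and overlap_length(s.interval, f.interval)
                for s in states
            )
            peak_hit = any(
                p.cell_type == c and overlap_length(p.interval, f.interval)
                for p in peaks
            )
            activity[c] = "active" if (seg_hit or peak_hit) else "inactive"
        out.append(replace(f, activity=activity))
    return out


def assign_stable_ids(
    features: list[RegulatoryFeature], prefix: str = "RKRF"
) -> list[RegulatoryFeature]:
    """Deterministic stable ids: prefix + zero-padded rank in
    (contig, start, class) order; invariant under input permutation."""
    ordered = sorted(
        features, key=lambda f: (f.interval.contig, f.interval.start, f.feature_class)
    )
    return [
        replace(f, stable_id=f"{prefix}{rank:08d}")
        for rank, f in enumerate(ordered, start=1)
    ]


def run_build(
    states: list[SegmentState], peaks: list[Peak], prefix: str = "RKRF"
) -> list[RegulatoryFeature]:
    """Full build: consolidate segmentations, add unexplained evidence,
    annotate per-cell activity, assign stable ids."""
    features = consolidate_segmentations(states)
    features = add_unexplained_evidence(features, peaks)
    features = annotate_activity(features, states, peaks)
    return assign_stable_ids(features, prefix)


def summary_table(features: list[RegulatoryFeature]) -> pd.DataFrame:
    """Feature count per class, in priority order."""
    counts = {c: 0 for c in FEATURE_CLASSES}
    for f in features:
        counts[f.feature_class] += 1
    return pd.DataFrame(
        {"feature_class": list(counts), "count": list(counts.values())}
    )


# ---------------------------------------------------------------------------
# GFF3 bridge
# ---------------------------------------------------------------------------


def features_to_gff3(features: list[RegulatoryFeature]) -> list[Gff3Record]:
    records = []
    for f in features:
        attrs = {"ID": f.stable_id, "feature_class": f.feature_class}
        for cell in sorted(f.activity):
            attrs[f"activity_{cell}"] = f.activity[cell]
        records.append(
            Gff3Record(interval=f.interval, type="regulatory_feature", attributes=attrs)
        )
    return records


def features_from_gff3(records: list[Gff3Record]) -> list[RegulatoryFeature]:
    features = []
    for r in records:
        activity = {
            k.removeprefix("activity_"): v
            for k, v in r.attributes.items()
            if k.startswith("activity_")
        }
        features.append(
            RegulatoryFeature(
                interval=r.interval,
                feature_class=r.attributes["feature_class"],
                stable_id=r.attributes.get("ID", ""),
                activity=activity,
            )
        )
    return features


# ---------------------------------------------------------------------------
# Segmentation BED bridge (4th column label, 5th column cell type)
# ---------------------------------------------------------------------------


def read_segmentation_bed(path) -> list[SegmentState]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise ValueError(
                    f"{path}: line {lineno}: expected 5 columns "
                    "(contig start end label cell_type)"
                )
            try:
                out.append(
                    SegmentState(
                        interval=GenomicInterval(f[0], int(f[1]), int(f[2])),
                        label=f[3],
                        cell_type=f[4],
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return out


def write_segmentation_bed(states: list[SegmentState], path) -> None:
    with open(path, "w") as fh:
        for s in states:
            iv = s.interval
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{s.label}\t{s.cell_type}\n")
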