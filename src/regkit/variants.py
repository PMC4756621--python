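"""Motif-aware variant consequence annotation.

For a single-nucleotide variant overlapping a motif match, three things are
reported: the 0-based position within the motif (strand-aware — on a
minus-strand match the motif is read from the 3' genomic end, with alleles
complemented), whether that motif column carries at least `bits_min` bits
of information (a highly informative position, where a substitution can
plausibly change binding affinity), and the log2-odds score change from
substituting the alternate allele into the matched window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from regkit.intervals import GenomicInterval
from regkit.methylation import Thresholds
from regkit.motifs import _CODE, MotifMatch, PWM, column_information, to_log_odds

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class Variant:
    """A substitution in 0-based coordinates (``pos0``)."""

    contig: str
    pos0: int
    ref: str
    alt: str

    @property
    def is_snv(self) -> bool:
        return (
            len(self.ref) == 1
            and len(self.alt) == 1
            and self.ref in _COMP
            and self.alt in _COMP
        )


@dataclass(frozen=True)
class VariantMotifConsequence:
    variant: Variant
    match_id: str
    in_motif: bool
    motif_position: int | None  # 0-based offset within the motif
    high_information: bool
    score_change: float | None  # alt - ref window score, log2-odds units
    flag: str = ""  # e.g. "non_snv"


def motif_consequence(
    variant: Variant,
    matches: Sequence[MotifMatch],
    pwms: Mapping[str, PWM],
    thresholds: Thresholds = Thresholds(),
) -> list[VariantMotifConsequence]:
    """One consequence record per motif match overlapping the variant.

    Because only one base changes, the score change equals the log-odds
    difference between the alt and ref letters at the affected motif
    column (complemented for minus-strand matches).
    """
    out = []
    pos = GenomicInterval(variant.contig, variant.pos0, variant.pos0 + 1)
    for m in matches:
        if not m.interval.contains(pos):
            continue
        pwm = pwms[m.pwm_id]
        if m.interval.strand == "-":
            j = (m.interval.end - 1) - variant.pos0
        else:
            j = variant.pos0 - m.interval.start
        if not variant.is_snv:
            out.append(
                VariantMotifConsequence(
                    variant=variant,
                    match_id=m.pwm_id,
                    in_motif=True,
                    motif_position=j,
                    high_information=column_information(pwm, j, thresholds)
                    >= thresholds.bits_min,
                    score_change=None,
                    flag="non_snv",
                )
            )
            continue
        ref, alt = variant.ref, variant.alt
        if m.interval.strand == "-":
            ref, alt = _COMP[ref], _COMP[alt]
        lo = to_log_odds(pwm, thresholds).logodds
        delta = float(lo[j, _CODE[alt]] - lo[j, _CODE[ref]])
        out.append(
            VariantMotifConsequence(
                variant=variant,
                match_id=m.pwm_id,
                in_motif=True,
                motif_position=j,
                high_information=column_information(pwm, j, thresholds)
                >= thresholds.bits_min,
                score_change=delta,
            )
        )
    return out


def annotate_variants(
    variants: Iterable[Variant],
    matches: Sequence[MotifMatch],
    pwms: Mapping[str, PWM],
    thresholds: Thresholds = Thresholds(),
) -> list[VariantMotifConsequence]:
    out = []
    for v in variants:
        out.extend(motif_consequence(v, matches, pwms, thresholds))
    return out


def read_variants_table(path) -> list[Variant]:
    """Minimal VCF-like tab input: contig, pos (1-based), ref, alt."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(
                    f"{path}: line {lineno}: expected contig, pos, ref, alt"
                )
            try:
                pos1 = int(f[1])
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer position") from None
            if pos1 < 1:
                raise ValueError(f"{path}: line {lineno}: positions are 1-based")
            out.append(Variant(f[0], pos1 - 1, f[2].upper(), f[3].upper()))
    return out


def consequences_to_table(consequences: list[VariantMotifConsequence], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#contig\tpos\tref\talt\tmatch_id\tmotif_position\t"
            "high_information\tscore_change\tflag\n"
        )
        for c in consequences:
            v = c.variant
            sc = "." if c.score_change is None else f"{c.score_change:.6g}"
            fh.write(
                f"{v.contig}\t{v.pos0 + 1}\t{v.ref}\t{v.alt}\t{c.match_id}\t"
                f"{c.motif_position}\t{int(c.high_information)}\t{sc}\t{c.flag or '.'}\n"
            )
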