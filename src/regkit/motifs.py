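"""PWM motif scanning with empirical-null score calibration.

ChIP-seq peaks locate bound fragments, not the binding site itself. To get
nucleotide resolution, sequence is scanned with JASPAR position weight
matrices in log-odds form; candidate matches are kept only if (a) their
score is significant against an empirical null built from windows of random
background sequence (single-tail p-value at or below 5% by default) and
(b) they lie fully within an observed binding region.

Alphabet order is A, C, G, T everywhere. Windows containing N are skipped
rather than scored.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from io import StringIO
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from intervaltree import IntervalTree

from regkit.intervals import GenomicInterval, Peak, overlap_length
from regkit.methylation import Thresholds

ALPHABET = "ACGT"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

UNIFORM_BG = np.full(4, 0.25)


@dataclass(frozen=True)
class PWM:
    """A position count matrix with its background composition.

    `counts` is L x 4 over A,C,G,T; `background` a probability 4-vector.
    """

    id: str
    name: str
    counts: np.ndarray
    background: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        bg = UNIFORM_BG if self.background is None else np.asarray(self.background, float)
        object.__setattr__(self, "background", bg)
        if counts.ndim != 2 or counts.shape[1] != 4 or counts.shape[0] < 1:
            raise ValueError(f"PWM {self.id}: counts must be L x 4 with L >= 1")
        if (counts < 0).any():
            raise ValueError(f"PWM {self.id}: negative counts")
        if bg.shape != (4,) or abs(bg.sum() - 1) > 1e-9 or (bg <= 0).any():
            raise ValueError(f"PWM {self.id}: background must be a positive 4-simplex point")

    def __len__(self) -> int:
        return self.counts.shape[0]

    def probabilities(self, thresholds: Thresholds = Thresholds()) -> np.ndarray:
        """Pseudocounted column probabilities.

        Each column gets pseudocount * colsum extra mass, spread according
        to the background, then is renormalized.
        """
        colsum = self.counts.sum(axis=1, keepdims=True)
        if (colsum == 0).any():
            raise ValueError(f"PWM {self.id}: zero column")
        pc = thresholds.pseudocount
        return (self.counts + pc * colsum * self.background) / (colsum * (1 + pc))

    def consensus(self) -> str:
        return "".join(ALPHABET[b] for b in self.counts.argmax(axis=1))


@dataclass(frozen=True)
class ScoreMatrix:
    """Log2-odds form of a PWM against its background."""

    pwm_id: str
    logodds: np.ndarray

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.logodds.min(axis=1).sum())

    def __len__(self) -> int:
        return self.logodds.shape[0]


@dataclass(frozen=True)
class MotifMatch:
    """A scored, stranded placement of a PWM on the forward coordinate
    system; `p_emp` is absent until calibrated against an empirical null."""

    interval: GenomicInterval
    pwm_id: str
    score: float
    p_emp: float | None = None


@dataclass(frozen=True)
class EmpiricalNull:
    """Sorted scores of background windows, the reference distribution for
    single-tail motif p-values."""

    pwm_id: str
    scores: np.ndarray  # ascending

    def __post_init__(self) -> None:
        s = np.sort(np.asarray(self.scores, dtype=float))
        object.__setattr__(self, "scores", s)
        if s.size < 1:
            raise ValueError("empirical null must contain at least one score")

    @property
    def size(self) -> int:
        return int(self.scores.size)


# ---------------------------------------------------------------------------
# JASPAR I/O
# ---------------------------------------------------------------------------


def read_jaspar(text_or_path) -> list[PWM]:
    """Parse JASPAR matrices: both the bracketed dialect (``A [ 4 19 0 ]``)
    and plain 4-row counts under a ``>id name`` header."""
    if hasattr(text_or_path, "read"):
        text = text_or_path.read()
    else:
        text = str(text_or_path)
        if text.strip() and "\n" not in text and not text.startswith(">"):
            with open(text) as fh:
                text = fh.read()
    if not text.strip():
        return []
    try:
        parsed = bio_motifs.parse(StringIO(text), "jaspar")
    except Exception as exc:
        # best-effort id for the error message
        first_id = next(
            (ln[1:].split()[0] for ln in text.splitlines() if ln.startswith(">")), "?"
        )
        raise ValueError(f"malformed JASPAR matrix (near {first_id}): {exc}") from None
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in ALPHABET], dtype=float).T
        if (counts < 0).any():
            raise ValueError(f"PWM {m.matrix_id}: negative counts")
        out.append(PWM(id=m.matrix_id, name=m.name or m.matrix_id, counts=counts))
    return out


def write_jaspar(pwms: Iterable[PWM], path) -> None:
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.id} {p.name}\n")
            for b, row in zip(ALPHABET, p.counts.T):
                cells = " ".join(f"{v:g}" for v in row)
                fh.write(f"{b} [ {cells} ]\n")


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


def to_log_odds(pwm: PWM, thresholds: Thresholds = Thresholds()) -> ScoreMatrix:
    p = pwm.probabilities(thresholds)
    with np.errstate(divide="ignore"):  # zero prob -> -inf log-odds
        return ScoreMatrix(pwm_id=pwm.id, logodds=np.log2(p / pwm.background))


def encode(seq: str) -> np.ndarray:
    """Sequence to integer codes; A,C,G,T -> 0..3, anything else -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.size, 4, dtype=np.int8)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    return codes


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _window_scores(codes: np.ndarray, logodds: np.ndarray) -> np.ndarray:
    """Score of every window; NaN where the window contains a non-ACGT base."""
    L = logodds.shape[0]
    if codes.size < L:
        return np.empty(0)
    padded = np.vstack([logodds.T, np.full((1, L), np.nan)])  # row 4 = N
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return padded[windows, np.arange(L)].sum(axis=1)


def scan(
    seq: str,
    sm: ScoreMatrix,
    threshold: float | None = None,
    both_strands: bool = True,
    contig: str = "seq",
    offset: int = 0,
) -> list[MotifMatch]:
    """Emit a match at every window scoring >= threshold.

    Minus-strand windows are scored on the reverse complement but reported
    on forward coordinates. Default threshold is 60% of the maximum
    attainable score — a deliberately lenient pre-filter; the empirical
    p-value filter is the real gate.
    """
    if threshold is None:
        threshold = 0.6 * sm.max_score
    codes = encode(seq)
    L = len(sm)
    matches: list[MotifMatch] = []
    strands = [("+", sm.logodds)]
    if both_strands:
        strands.append(("-", sm.logodds[::-1, ::-1]))  # revcomp of the matrix
    per_strand = []
    for strand, lo in strands:
        scores = _window_scores(codes, lo)
        with np.errstate(invalid="ignore"):
            hits = np.nonzero(scores >= threshold)[0]
        per_strand.append((strand, hits, scores))
    seen: dict[int, list[MotifMatch]] = {}
    for strand, hits, scores in per_strand:
        for i in hits:
            m = MotifMatch(
                interval=GenomicInterval(contig, offset + int(i), offset + int(i) + L, strand),
                pwm_id=sm.pwm_id,
                score=float(scores[i]),
            )
            seen.setdefault(int(i), []).append(m)
    for i in sorted(seen):
        matches.extend(seen[i])
    return matches


def build_empirical_null(
    sm: ScoreMatrix,
    background_composition: Sequence[float] = UNIFORM_BG,
    n_samples: int = 100_000,
    seed: int = 0,
) -> EmpiricalNull:
    """Score n_samples windows drawn i.i.d. from the background composition."""
    if n_samples < 1000:
        raise ValueError("n_samples must be at least 1000")
    rng = np.random.default_rng(seed)
    comp = np.asarray(background_composition, dtype=float)
    comp = comp / comp.sum()
    L = len(sm)
    draws = rng.choice(4, size=(n_samples, L), p=comp)
    scores = sm.logodds[np.arange(L), draws].sum(axis=1)
    return EmpiricalNull(pwm_id=sm.pwm_id, scores=scores)


def empirical_pvalue(score, null: EmpiricalNull):
    """Add-one upper-tail empirical p: (1 + #{null >= score}) / (size + 1).

    Never returns 0; vectorized over `score`.
    """
    score = np.asarray(score, dtype=float)
    n_ge = null.size - np.searchsorted(null.scores, score, side="left")
    p = (1.0 + n_ge) / (null.size + 1.0)
    return float(p) if p.ndim == 0 else p


def filter_matches(
    matches: Sequence[MotifMatch],
    null: EmpiricalNull,
    thresholds: Thresholds = Thresholds(),
) -> list[MotifMatch]:
    """Keep matches with empirical p <= p_max; p_emp populated on outputs."""
    if any(m.pwm_id != null.pwm_id for m in matches):
        raise ValueError("all matches must share the null's pwm_id")
    if not matches:
        return []
    ps = empirical_pvalue(np.array([m.score for m in matches]), null)
    return [
        replace(m, p_emp=float(p))
        for m, p in zip(matches, np.atleast_1d(ps))
        if p <= thresholds.p_max
    ]


# ---------------------------------------------------------------------------
# Peak containment and association
# ---------------------------------------------------------------------------


def _peak_trees(peaks: Iterable[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.interval.contig, IntervalTree()).addi(
            p.interval.start, p.interval.end, p
        )
    return trees


def within_peaks(matches: Sequence[MotifMatch], peaks: Sequence[Peak]) -> list[MotifMatch]:
    """Keep matches fully contained in at least one peak interval."""
    trees = _peak_trees(peaks)
    out = []
    for m in matches:
        tree = trees.get(m.interval.contig)
        if tree is None:
            continue
        if any(
            iv.begin <= m.interval.start and m.interval.end <= iv.end
            for iv in tree.overlap(m.interval.start, m.interval.end)
        ):
            out.append(m)
    return out


def associate(matches: Sequence[MotifMatch], features: Sequence) -> dict[MotifMatch, list[str]]:
    """Map each match to the ids of all features overlapping it by >= 1 base.

    Features may be Peaks (id = feature_type) or anything with `stable_id`
    and `interval` attributes (regulatory features).
    """

    def feat_id(f) -> str:
        return f.stable_id if hasattr(f, "stable_id") else f.feature_type

    out: dict[MotifMatch, list[str]] = {}
    for m in matches:
        out[m] = [
            feat_id(f)
            for f in features
            if overlap_length(m.interval, f.interval) >= 1
        ]
    return out


# ---------------------------------------------------------------------------
# Information content and display quantities
# ---------------------------------------------------------------------------


def column_information(
    pwm: PWM, i: int, thresholds: Thresholds = Thresholds()
) -> float:
    """Information content of column i in bits: 2 + sum_b p log2 p.

    2 bits = a fully specific position, 0 = uninformative; computed on
    pseudocounted probabilities.
    """
    if not (0 <= i < len(pwm)):
        raise IndexError(f"column {i} out of range for PWM of length {len(pwm)}")
    p = pwm.probabilities(thresholds)[i]
    nz = p[p > 0]
    return float(2.0 + (nz * np.log2(nz)).sum())


def score_ratio(match: MotifMatch, sm: ScoreMatrix) -> float:
    """Binding score divided by the PWM's optimal score (1.0 = consensus)."""
    if sm.max_score == 0:
        raise ValueError("max_score is zero; ratio undefined")
    return match.score / sm.max_score


def associate_pwm_to_gene(
    xrefs: Mapping[str, str] | pd.DataFrame,
    besthits: Mapping[str, str] | pd.DataFrame,
) -> dict[str, str]:
    """Resolve PWM -> gene: a direct same-species cross-reference wins over
    the best protein-alignment hit; PWMs in neither table stay unmapped.

    Tables are mappings or two-column DataFrames (pwm id, gene id). A PWM
    with two conflicting direct xrefs raises.
    """

    def as_pairs(t):
        if isinstance(t, pd.DataFrame):
            return list(t.itertuples(index=False, name=None))
        return list(t.items())

    xref_map: dict[str, str] = {}
    conflicts = set()
    for pwm_id, gene in as_pairs(xrefs):
        if pwm_id in xref_map and xref_map[pwm_id] != gene:
            conflicts.add(pwm_id)
        xref_map[pwm_id] = gene
    if conflicts:
        raise ValueError(f"conflicting direct xrefs for PWM(s): {sorted(conflicts)}")
    out = dict(xref_map)
    for pwm_id, gene in as_pairs(besthits):
        out.setdefault(pwm_id, gene)
    return out
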