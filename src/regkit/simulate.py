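"""Seeded synthetic-data generators.

Every pipeline stage gets a self-contained test surface: bisulfite count
tables drawn from a known mixture model, random genomes with motif
occurrences planted at known positions, peaks around the plants, and
segmentation tracks that honor a per-cell design exactly. All generators
are pure functions of their parameters and seed, and each returns the
ground truth alongside the data.

What these emulate — and what they do not: sites are independent (no
spatial correlation of methylation along the genome), background sequence
is i.i.d. (no repeats, no CpG islands), and planted motifs are exact
consensus copies by default, so scanner recall is exactly checkable. A
probabilistic sampling mode (`exact=False` in `plant_motifs`) draws plant
letters from the PWM columns instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import betabinom as _betabinom

from regkit.intervals import COUNT_TABLE_COLUMNS, GenomicInterval, Peak
from regkit.methylation import MethylationModel, STATE_NAMES
from regkit.motifs import ALPHABET, PWM
from regkit.regbuild import SegmentState

DEFAULT_COVERAGE_LAW = ("poisson", {"mean": 15})


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth recorded by a generator run."""

    seed: int
    planted_motif_positions: list = field(default_factory=list)
    true_methylation_states: list = field(default_factory=list)
    generating_model: MethylationModel | None = None
    segmentation_design: dict = field(default_factory=dict)


def _draw_coverage(rng: np.random.Generator, law, size: int) -> np.ndarray:
    name, params = law
    if name == "poisson":
        # shifted by one so that every site has at least one read
        return rng.poisson(params["mean"], size=size) + 1
    if name == "constant":
        n = int(params["n"])
        if n < 1:
            raise ValueError("constant coverage must be >= 1")
        return np.full(size, n)
    raise ValueError(f"unknown coverage law {name!r}")


def simulate_methylome(
    model: MethylationModel,
    n_sites: int,
    coverage_law=DEFAULT_COVERAGE_LAW,
    seed: int = 0,
    contig: str = "chrS",
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Draw a count table from the three-state mixture.

    Each site's state is drawn from the mixing weights; converted counts k
    come from the state's beta-binomial (or uniform on {0..n} for the
    undetermined state). Sites sit at consecutive even positions on the
    plus strand of one synthetic contig.
    """
    rng = np.random.default_rng(seed)
    n = _draw_coverage(rng, coverage_law, n_sites)
    states = rng.choice(3, size=n_sites, p=np.asarray(model.weights))
    k = np.empty(n_sites, dtype=int)
    for idx, (a, b) in enumerate(
        [(model.alpha_m, model.beta_m), (model.alpha_u, model.beta_u)]
    ):
        mask = states == idx
        if mask.any():
            k[mask] = _betabinom.rvs(n[mask], a, b, random_state=rng)
    mask = states == 2
    if mask.any():
        k[mask] = rng.integers(0, n[mask] + 1)
    table = pd.DataFrame(
        {
            "contig": contig,
            "pos": np.arange(n_sites) * 2,
            "strand": "+",
            "converted": k,
            "total": n,
        }
    )[COUNT_TABLE_COLUMNS]
    truth = SimulationTruth(
        seed=seed,
        true_methylation_states=[STATE_NAMES[s] for s in states],
        generating_model=model,
    )
    return table, truth


def simulate_genome(
    length: int, composition=(0.25, 0.25, 0.25, 0.25), seed: int = 0
) -> str:
    """An i.i.d. random nucleotide sequence with the given ACGT composition."""
    comp = np.asarray(composition, dtype=float)
    if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1) > 1e-9:
        raise ValueError("composition must be a 4-vector on the simplex")
    rng = np.random.default_rng(seed)
    codes = rng.choice(4, size=length, p=comp)
    return "".join(ALPHABET[c] for c in codes)


def plant_motifs(
    seq: str, pwm: PWM, n: int, seed: int = 0, exact: bool = True
) -> tuple[str, list[int]]:
    """Overwrite `n` non-overlapping windows of `seq` with motif instances.

    With `exact=True` (default) each plant is the PWM consensus, so a scan
    must recover every plant at exactly the maximum score; with
    `exact=False` plant letters are sampled from the PWM column
    probabilities. Returns the modified sequence and sorted plant offsets.
    """
    rng = np.random.default_rng(seed)
    L = len(pwm)
    n_slots = len(seq) // (2 * L)
    if n > n_slots:
        raise ValueError(
            f"cannot place {n} non-overlapping plants of length {L} in a "
            f"sequence of length {len(seq)}"
        )
    slots = rng.choice(n_slots, size=n, replace=False)
    positions = sorted(int(s) * 2 * L for s in slots)
    probs = pwm.counts / pwm.counts.sum(axis=1, keepdims=True)
    chars = list(seq)
    for pos in positions:
        if exact:
            instance = pwm.consensus()
        else:
            instance = "".join(
                ALPHABET[rng.choice(4, p=probs[i])] for i in range(L)
            )
        chars[pos : pos + L] = instance
    return "".join(chars), positions


def make_peaks(
    positions: list[int],
    flank: int,
    motif_length: int,
    contig: str = "seq",
    cell_type: str = "cellA",
    feature_type: str = "TF1",
) -> list[Peak]:
    """One peak of +/- `flank` bases around each planted motif."""
    peaks = []
    for pos in positions:
        start = max(0, pos - flank)
        peaks.append(
            Peak(
                interval=GenomicInterval(contig, start, pos + motif_length + flank),
                cell_type=cell_type,
                feature_type=feature_type,
                score=100.0,
                summit=pos + motif_length // 2,
            )
        )
    return peaks


def make_segmentation(design: dict, seed: int = 0) -> list[SegmentState]:
    """Materialize a segmentation design exactly.

    `design` maps cell type -> list of (contig, start, end, label) tuples;
    the output honors it verbatim, so tests can assert against the design.
    """
    del seed  # deterministic by construction; kept for interface uniformity
    states = []
    for cell, segments in design.items():
        for contig, start, end, label in segments:
            states.append(
                SegmentState(
                    interval=GenomicInterval(contig, start, end),
                    cell_type=cell,
                    label=label,
                )
            )
    return states


def random_pwm(
    length: int, seed: int = 0, concentration: float = 0.5, total: int = 100
) -> PWM:
    """A random count matrix with Dirichlet-distributed columns; low
    `concentration` gives sharp (informative) columns."""
    rng = np.random.default_rng(seed)
    probs = rng.dirichlet([concentration] * 4, size=length)
    counts = np.round(probs * total).astype(int)
    counts[counts.sum(axis=1) == 0, 0] = 1
    return PWM(id=f"RND{seed:04d}", name=f"random{length}", counts=counts)


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
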