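"""Long-oligonucleotide probe selection for expression arrays.

One ~65-mer probe is chosen per unigene under joint physicochemical
constraints: nearest-neighbor melting temperature 67 ± 3 °C, length
65 ± 5 nt, GC content 43 ± 5%, limited hairpin/self-dimer potential, and
position within 1000 nt of the transcript 3' end (3'-biased labeling).
Unigenes with no feasible window are reported as "missing genes" with a
reason, mirroring the bookkeeping of real array designs.

Tm uses the unified nearest-neighbor thermodynamic table with a
monovalent-salt entropy correction.  The default ionic strength (25 mM
Na+) is chosen so that the three printed constraints are mutually
consistent: under this parameterization a 43%-GC 65-mer melts at ~67 °C,
so the Tm and GC windows select overlapping probe sets rather than
contradicting each other.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import Enum

import numpy as np
from Bio.SeqUtils import MeltingTemp as mt

from .precluster import reverse_complement

__all__ = [
    "ProbeConstraints",
    "ProbeCandidate",
    "DesignOutcome",
    "MissingReason",
    "gc_content",
    "melting_temperature",
    "secondary_structure_scores",
    "enumerate_candidates",
    "select_probe",
    "design_all",
]


@dataclass(frozen=True)
class ProbeConstraints:
    """Hard windows and caps a probe must satisfy.

    Units: temperatures in °C, lengths/distances in nt, GC in percent,
    salt in mM, oligo concentration in nM.
    """

    tm_target: float = 67.0
    tm_tol: float = 3.0
    length_target: int = 65
    length_tol: int = 5
    gc_target: float = 43.0
    gc_tol: float = 5.0
    max_dist_3prime: int = 1000
    max_stem: int = 8
    max_selfdimer: int = 12
    min_loop: int = 3
    na_mM: float = 25.0
    oligo_nM: float = 50.0
    # rank_score = w1*|tm-target| + w2*|gc-target| + w3*stem + w4*selfdimer
    #            + w5*dist_3prime ; constraints dominate, 3' proximity
    # breaks near-ties.
    weights: tuple[float, float, float, float, float] = (1.0, 1.0, 1.0, 1.0, 0.001)

    def __post_init__(self) -> None:
        if min(self.tm_tol, self.length_tol, self.gc_tol) < 0:
            raise ValueError("tolerances must be >= 0")
        if self.length_target - self.length_tol < 20:
            raise ValueError("minimum probe length must be >= 20 nt")

    @property
    def length_range(self) -> range:
        return range(self.length_target - self.length_tol, self.length_target + self.length_tol + 1)


class MissingReason(str, Enum):
    none = "none"
    too_short = "too_short"
    no_window_meets_constraints = "no_window_meets_constraints"


@dataclass(frozen=True)
class ProbeCandidate:
    unigene_id: str
    start: int          # 0-based offset into the unigene
    length: int
    sequence: str
    tm: float
    gc: float
    dist_3prime: int    # 3'-most probe base to the unigene 3' end
    stem_score: int
    selfdimer_score: int
    rank_score: float = float("nan")


@dataclass(frozen=True)
class DesignOutcome:
    unigene_id: str
    probe: ProbeCandidate | None
    missing_reason: MissingReason

    def __post_init__(self) -> None:
        if (self.probe is None) == (self.missing_reason is MissingReason.none):
            raise ValueError("probe present XOR missing_reason set")


def gc_content(seq: str) -> float:
    """Percent G+C of an unambiguous sequence."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"ambiguous bases not allowed in probes: {sorted(bad)}")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(seq: str, na_mM: float = 25.0, oligo_nM: float = 50.0) -> float:
    """Nearest-neighbor duplex Tm (°C) with monovalent-salt correction.

    Unified NN parameter table; salt correction applied to the duplex
    entropy (0.368·(N−1)·ln[Na+]).  Valid for length >= 8.
    """
    if len(seq) < 8:
        raise ValueError("nearest-neighbor model requires length >= 8")
    gc_content(seq)  # reject ambiguous bases
    return float(
        mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=na_mM, dnac1=oligo_nM, dnac2=0, saltcorr=5)
    )


# ---------------------------------------------------------------------------
# Secondary structure
# ---------------------------------------------------------------------------

_PAIR = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _run_matrix(seq: str) -> np.ndarray:
    """R[i, j] = length of the complementary run whose innermost pair is
    (i, j): seq[i]~seq[j], seq[i-1]~seq[j+1], ...  Runs extend outward
    (i decreasing, j increasing)."""
    n = len(seq)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in _PAIR.items():
        comp[ord(a)] = ord(b)
    c = comp[s]
    pairs = (s[:, None] == c[None, :])  # pairs[i, j]: seq[i] complements seq[j]
    r = np.zeros((n, n), dtype=np.int32)
    # recurrence along anti-diagonals: r[i, j] = r[i-1, j+1] + 1 if paired
    for d in range(2 * n - 1):  # d = i + j
        i = np.arange(max(0, d - n + 1), min(d, n - 1) + 1)
        j = d - i
        vals = pairs[i, j].astype(np.int32)
        # run length since the last non-pairing position on the diagonal
        csum = np.cumsum(vals)
        at_zero = np.where(vals == 0, csum, 0)
        r[i, j] = csum - np.maximum.accumulate(at_zero)
    return r


def _window_scores(r: np.ndarray, w0: int, w1: int, min_loop: int) -> tuple[int, int]:
    """Stem and self-dimer scores for the window [w0, w1) given the
    full-sequence run matrix.  A run ending inward at (i, j) occupies
    [i-L+1, i] and [j, j+L-1]; truncation to the window gives
    min(R, i-w0+1, w1-j)."""
    sub = r[w0:w1, w0:w1]
    n = w1 - w0
    if n == 0:
        return 0, 0
    ii = np.arange(n)[:, None]
    jj = np.arange(n)[None, :]
    trunc = np.minimum(sub, np.minimum(ii + 1, n - jj))
    selfdimer = int(trunc.max(initial=0))
    loop_ok = (jj - ii - 1) >= min_loop
    stem = int(np.where(loop_ok, trunc, 0).max(initial=0))
    return stem, selfdimer


def secondary_structure_scores(seq: str, min_loop: int = 3) -> tuple[int, int]:
    """(stem_score, selfdimer_score) in nt.

    stem_score: longest self-complementary pairing between two substrings
    separated by at least ``min_loop`` unpaired bases (hairpin stem).
    selfdimer_score: longest such pairing with no loop constraint
    (intermolecular duplex of two copies).
    """
    if not seq:
        raise ValueError("empty sequence")
    r = _run_matrix(seq)
    return _window_scores(r, 0, len(seq), min_loop)


# ---------------------------------------------------------------------------
# Candidate enumeration and selection
# ---------------------------------------------------------------------------

def enumerate_candidates(unigene_id: str, sequence: str, c: ProbeConstraints) -> list[ProbeCandidate]:
    """All windows satisfying length and 3'-distance bounds, annotated.

    Ordered by (start, length).  Windows containing ambiguous bases are
    skipped (probes must be unambiguous).  Tm/GC/structure are annotated
    but not yet filtered.
    """
    n = len(sequence)
    out: list[ProbeCandidate] = []
    r = _run_matrix(sequence) if n >= min(c.length_range, default=0) else None
    for start in range(n):
        for length in c.length_range:
            end = start + length
            if end > n:
                continue
            dist3 = n - end
            if dist3 > c.max_dist_3prime:
                continue
            window = sequence[start:end]
            if set(window) - set("ACGT"):
                continue
            gc = gc_content(window)
            tm = melting_temperature(window, na_mM=c.na_mM, oligo_nM=c.oligo_nM)
            stem, selfdimer = _window_scores(r, start, end, c.min_loop)
            out.append(
                ProbeCandidate(
                    unigene_id=unigene_id,
                    start=start,
                    length=length,
                    sequence=window,
                    tm=tm,
                    gc=gc,
                    dist_3prime=dist3,
                    stem_score=stem,
                    selfdimer_score=selfdimer,
                )
            )
    return out


def rank_score(cand: ProbeCandidate, c: ProbeConstraints) -> float:
    w1, w2, w3, w4, w5 = c.weights
    return (
        w1 * abs(cand.tm - c.tm_target)
        + w2 * abs(cand.gc - c.gc_target)
        + w3 * cand.stem_score
        + w4 * cand.selfdimer_score
        + w5 * cand.dist_3prime
    )


def satisfies_hard_constraints(cand: ProbeCandidate, c: ProbeConstraints) -> bool:
    return (
        abs(cand.tm - c.tm_target) <= c.tm_tol
        and abs(cand.gc - c.gc_target) <= c.gc_tol
        and cand.stem_score <= c.max_stem
        and cand.selfdimer_score <= c.max_selfdimer
    )


def select_probe(unigene_id: str, sequence: str, c: ProbeConstraints | None = None) -> DesignOutcome:
    """Best feasible window, or a missing outcome with reason.

    Among candidates meeting all hard constraints the probe minimizing
    ``rank_score`` is chosen, with a deterministic tie-break on
    (dist_3prime, start).
    """
    c = c or ProbeConstraints()
    if len(sequence) < min(c.length_range):
        return DesignOutcome(unigene_id, None, MissingReason.too_short)
    candidates = enumerate_candidates(unigene_id, sequence, c)
    feasible = [cand for cand in candidates if satisfies_hard_constraints(cand, c)]
    if not feasible:
        reason = MissingReason.too_short if not candidates else MissingReason.no_window_meets_constraints
        return DesignOutcome(unigene_id, None, reason)
    best = min(feasible, key=lambda cand: (rank_score(cand, c), cand.dist_3prime, cand.start))
    best = dataclasses.replace(best, rank_score=rank_score(best, c))
    return DesignOutcome(unigene_id, best, MissingReason.none)


def design_all(unigenes, c: ProbeConstraints | None = None) -> list[DesignOutcome]:
    """Design one probe per unigene; outcomes partition the input set."""
    c = c or ProbeConstraints()
    return [select_probe(u.id, u.sequence, c) for u in unigenes]


def write_design_report(outcomes, path) -> None:
    cols = "unigene_id\tstart\tlength\ttm\tgc\tstem\tselfdimer\tdist_3prime\toutcome\treason\n"
    with open(path, "w") as fh:
        fh.write(cols)
        for o in outcomes:
            if o.probe is not None:
                p = o.probe
                fh.write(
                    f"{o.unigene_id}\t{p.start}\t{p.length}\t{p.tm:.3f}\t{p.gc:.3f}\t"
                    f"{p.stem_score}\t{p.selfdimer_score}\t{p.dist_3prime}\tdesigned\t-\n"
                )
            else:
                fh.write(f"{o.unigene_id}\t-\t-\t-\t-\t-\t-\t-\tmissing\t{o.missing_reason.value}\n")


def write_missing_genes_tsv(outcomes, path) -> None:
    with open(path, "w") as fh:
        fh.write("unigene_id\treason\n")
        for o in outcomes:
            if o.probe is None:
                fh.write(f"{o.unigene_id}\t{o.missing_reason.value}\n")


def write_probes_fasta(outcomes, path) -> None:
    with open(path, "w") as fh:
        for o in outcomes:
            if o.probe is not None:
                fh.write(f">{o.unigene_id}\n{o.probe.sequence}\n")
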