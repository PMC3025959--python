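"""EST cleaning and identity-based pre-clustering.

Single-pass unigene builds start by grouping raw EST reads into
pre-clusters: two reads belong together when some local alignment between
them reaches a minimum percent identity over a minimum aligned length
(defaults 90% over 30 bp).  Pre-clusters are the single-linkage connected
components of that pairwise graph; consensus assembly of each cluster is
out of scope here.

Reads are unoriented cDNA, so both strands are compared and the better one
taken.  Low-complexity stretches (polyA tails, microsatellites) are masked
by windowed Shannon entropy before alignment so they cannot create
spurious edges.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace

from Bio import Align, SeqIO
from Bio.Seq import Seq

__all__ = [
    "ESTRead",
    "AlignmentStats",
    "SequenceCluster",
    "low_complexity_mask",
    "pairwise_local_identity",
    "precluster",
    "trim_adaptors",
    "read_fasta",
    "write_clusters_tsv",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Linear gap scoring; the slightly non-commensurate penalties ensure no
# combination of matches, mismatches and gaps sums to zero, so the
# best-scoring local alignment has a unique column composition and its
# identity percentage is well-defined (no co-optimal "free" extensions).
MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.03
GAP_SCORE = -2.11


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ESTRead:
    """A single-pass cDNA read with optional masked intervals.

    ``masked_regions`` are 0-based half-open intervals excluded from
    alignment (replaced by N before scoring).
    """

    id: str
    sequence: str
    masked_regions: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"read {self.id!r}: invalid characters {sorted(bad)}")
        merged = _normalize_intervals(self.masked_regions, len(self.sequence))
        object.__setattr__(self, "masked_regions", merged)

    @property
    def masked_sequence(self) -> str:
        """Sequence with masked intervals replaced by N."""
        chars = list(self.sequence)
        for lo, hi in self.masked_regions:
            chars[lo:hi] = "N" * (hi - lo)
        return "".join(chars)


@dataclass(frozen=True)
class AlignmentStats:
    """Identity and length of the best-scoring local alignment.

    ``identity_pct`` is over aligned columns including internal gaps;
    ``aligned_length`` counts those columns.
    """

    identity_pct: float
    aligned_length: int
    score: float

    def qualifies(self, min_identity: float, min_length: int) -> bool:
        return (
            self.aligned_length >= min_length and self.identity_pct >= min_identity
        )


@dataclass(frozen=True)
class SequenceCluster:
    cluster_id: str
    member_ids: frozenset[str]


def _normalize_intervals(
    intervals, length: int
) -> tuple[tuple[int, int], ...]:
    """Sort, bound-check and merge half-open intervals."""
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    merged: list[list[int]] = []
    for lo, hi in ivs:
        if not (0 <= lo <= hi <= length):
            raise ValueError(f"masked interval ({lo},{hi}) out of bounds 0..{length}")
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return tuple((lo, hi) for lo, hi in merged)


# ---------------------------------------------------------------------------
# Low-complexity masking
# ---------------------------------------------------------------------------

def _entropy(counts: Counter) -> float:
    total = sum(counts.values())
    h = 0.0
    for c in counts.values():
        if c:
            p = c / total
            h -= p * math.log2(p)
    return h


def windowed_entropy(seq: str, window: int, dinucleotide: bool = False) -> list[float]:
    """Shannon entropy (bits) of each full window starting at offset i.

    In dinucleotide-aware mode the first-order conditional entropy
    H(next | current) = H(overlapping 2-mers) − H(first window−1 bases)
    is used instead: it is ~0 for perfect short-period repeats like
    (ACGT)n whose plain mononucleotide entropy is maximal, so one
    threshold serves both modes.
    """
    if window < 4:
        raise ValueError("window must be >= 4")
    out = []
    for i in range(len(seq) - window + 1):
        w = seq[i : i + window]
        if dinucleotide:
            pairs = Counter(w[j : j + 2] for j in range(window - 1))
            singles = Counter(w[:-1])
            out.append(max(_entropy(pairs) - _entropy(singles), 0.0))
        else:
            out.append(_entropy(Counter(w)))
    return out


def low_complexity_mask(
    read: ESTRead,
    window: int = 16,
    entropy_threshold: float = 1.2,
    dinucleotide: bool = False,
) -> ESTRead:
    """Mask every position covered by a window of entropy below threshold.

    The sequence itself is unchanged; masking only adds intervals.
    Sequences shorter than the window are left unmasked.
    """
    if window < 4:
        raise ValueError("window must be >= 4")
    seq = read.sequence
    if len(seq) < window:
        return read
    ent = windowed_entropy(seq, window, dinucleotide=dinucleotide)
    covered: list[tuple[int, int]] = []
    for i, h in enumerate(ent):
        if h < entropy_threshold:
            covered.append((i, i + window))
    if not covered:
        return read
    return replace(read, masked_regions=read.masked_regions + tuple(covered))


# ---------------------------------------------------------------------------
# Pairwise local alignment
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    # Substitution over ACGTN: N never matches anything (masked bases
    # cannot anchor or extend an alignment).
    from Bio.Align import substitution_matrices

    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == b and a != "N":
                mat[a, b] = MATCH_SCORE
            else:
                mat[a, b] = MISMATCH_SCORE
    aligner.substitution_matrix = mat
    aligner.open_gap_score = GAP_SCORE
    aligner.extend_gap_score = GAP_SCORE
    return aligner


_ALIGNER = _make_aligner()


def _stats_one_strand(a: str, b: str) -> AlignmentStats:
    if _ALIGNER.score(a, b) <= 0:
        return AlignmentStats(0.0, 0, 0.0)
    aln = next(iter(_ALIGNER.align(a, b)))
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    ident = 100.0 * counts.identities / columns if columns else 0.0
    return AlignmentStats(ident, columns, float(aln.score))


def pairwise_local_identity(a: str, b: str, both_strands: bool = True) -> AlignmentStats:
    """Best local alignment of ``a`` vs ``b`` (both strands by default).

    Returns identity over aligned columns (internal gaps included) and the
    number of aligned columns, for the single best-scoring alignment.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    best = _stats_one_strand(a, b)
    if both_strands:
        rc = _stats_one_strand(a, reverse_complement(b))
        if rc.score > best.score:
            best = rc
    return best


# ---------------------------------------------------------------------------
# Single-linkage pre-clustering
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def precluster(
    reads,
    min_identity: float = 90.0,
    min_length: int = 30,
    both_strands: bool = True,
) -> list[SequenceCluster]:
    """Single-linkage components under the identity/length rule.

    An edge joins two reads when their best local alignment reaches
    ``min_identity`` percent over at least ``min_length`` aligned columns.
    Cluster ids are the lexicographically smallest member id, so output is
    independent of input order.
    """
    reads = list(reads)
    ids = [r.id for r in reads]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate read ids")
    if not reads:
        return []
    uf = _UnionFind(ids)
    masked = {r.id: r.masked_sequence for r in reads}
    for i in range(len(reads)):
        for j in range(i + 1, len(reads)):
            stats = pairwise_local_identity(
                masked[reads[i].id], masked[reads[j].id], both_strands=both_strands
            )
            if stats.qualifies(min_identity, min_length):
                uf.union(reads[i].id, reads[j].id)
    groups: dict[str, set[str]] = {}
    for rid in ids:
        groups.setdefault(uf.find(rid), set()).add(rid)
    clusters = [
        SequenceCluster(cluster_id=min(members), member_ids=frozenset(members))
        for members in groups.values()
    ]
    return sorted(clusters, key=lambda c: c.cluster_id)


# ---------------------------------------------------------------------------
# Adaptor trimming and I/O
# ---------------------------------------------------------------------------

def trim_adaptors(read: ESTRead, adaptors) -> ESTRead:
    """Trim exact adaptor matches from either end of the read.

    Only terminal exact matches are removed (vendor vector databases are
    out of scope); applied repeatedly until no adaptor matches.
    """
    seq = read.sequence
    changed = True
    while changed:
        changed = False
        for ad in adaptors:
            if ad and seq.startswith(ad):
                seq = seq[len(ad):]
                changed = True
            if ad and seq.endswith(ad):
                seq = seq[: len(seq) - len(ad)]
                changed = True
    if not seq:
        raise ValueError(f"read {read.id!r}: nothing left after adaptor trimming")
    if seq == read.sequence:
        return read
    return ESTRead(id=read.id, sequence=seq)


def read_fasta(path) -> list[ESTRead]:
    return [
        ESTRead(id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.sequence}\n")


def write_clusters_tsv(clusters, path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tmember_id\n")
        for c in clusters:
            for m in sorted(c.member_ids):
                fh.write(f"{c.cluster_id}\t{m}\n")
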