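"""Cross-hybridization screening of designed probes.

A probe risks picking up signal from a non-target transcript when the two
are sufficiently similar.  The screen applies a dual rule: a probe is
flagged against a non-source unigene when its overall identity to that
unigene exceeds 70% AND the two share a contiguous exact match longer
than 20 nt (both inequalities strict, both strands of the target
considered).

"Overall identity" is expressed over the probe length: matching columns
of the best local alignment divided by probe length, so unaligned probe
bases count as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .precluster import reverse_complement, _ALIGNER

__all__ = [
    "CrossHybHit",
    "longest_common_substring",
    "overall_identity",
    "screen",
]


@dataclass(frozen=True)
class CrossHybHit:
    probe_id: str
    target_unigene_id: str
    overall_identity: float   # percent over probe length
    lcs_length: int           # nt
    flagged: bool


def _lcs_one_strand(a: str, b: str) -> int:
    """Longest exact common substring, fully vectorized.

    The boolean match matrix is sheared so each diagonal becomes a
    column, then the longest run of matches per column is found with a
    cumulative-sum reset trick.
    """
    if not a or not b:
        return 0
    sa = np.frombuffer(a.encode(), dtype=np.uint8)
    sb = np.frombuffer(b.encode(), dtype=np.uint8)
    n, m = len(sa), len(sb)
    match = sa[:, None] == sb[None, :]
    sheared = np.zeros((n, m + n), dtype=np.int8)
    rows = np.arange(n)
    # column (j - i + n - 1) collects the diagonal j - i = const
    cols = np.arange(m)[None, :] - rows[:, None] + (n - 1)
    sheared[rows[:, None], cols] = match
    csum = np.cumsum(sheared, axis=0)
    at_zero = np.where(sheared == 0, csum, 0)
    runs = csum - np.maximum.accumulate(at_zero, axis=0)
    return int(runs.max())


def longest_common_substring(a: str, b: str, both_strands: bool = True) -> int:
    """Length of the longest contiguous exact match (nt), considering
    ``a`` against both strands of ``b`` when ``both_strands``."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    best = _lcs_one_strand(a, b)
    if both_strands:
        best = max(best, _lcs_one_strand(a, reverse_complement(b)))
    return best


def _identity_one_strand(probe: str, target: str) -> float:
    if _ALIGNER.score(probe, target) <= 0:
        return 0.0
    aln = next(iter(_ALIGNER.align(probe, target)))
    return 100.0 * aln.counts().identities / len(probe)


def overall_identity(probe: str, target: str, both_strands: bool = True) -> float:
    """Identity (%) of the probe's best local alignment to the target,
    over the probe length; unaligned probe bases count as mismatches."""
    if len(probe) < 20:
        raise ValueError("probe must be >= 20 nt")
    if not target:
        raise ValueError("target must be non-empty")
    best = _identity_one_strand(probe, target)
    if both_strands:
        best = max(best, _identity_one_strand(probe, reverse_complement(target)))
    return best


def screen(
    probes: dict[str, str],
    unigenes: dict[str, str],
    id_threshold: float = 70.0,
    lcs_threshold: int = 20,
) -> list[CrossHybHit]:
    """Worst-case cross-hybridization hit per probe.

    ``probes`` maps probe id (== source unigene id) to probe sequence;
    ``unigenes`` maps unigene id to sequence and must contain every
    probe's source.  A probe is flagged iff some non-source unigene
    exceeds BOTH thresholds (strict).  The returned list holds one entry
    per probe — its worst hit by (identity, lcs) — ordered by probe id.
    """
    missing = set(probes) - set(unigenes)
    if missing:
        raise ValueError(f"probes with unknown source unigene: {sorted(missing)}")
    hits: list[CrossHybHit] = []
    for pid in sorted(probes):
        pseq = probes[pid]
        best: CrossHybHit | None = None
        for uid in sorted(unigenes):
            if uid == pid:
                continue
            ident = overall_identity(pseq, unigenes[uid])
            lcs = longest_common_substring(pseq, unigenes[uid])
            flagged = ident > id_threshold and lcs > lcs_threshold
            hit = CrossHybHit(pid, uid, ident, lcs, flagged)
            if best is None or (flagged, ident, lcs) > (best.flagged, best.overall_identity, best.lcs_length):
                best = hit
        if best is not None:
            hits.append(best)
    return hits


def flagged_probes(hits) -> set[str]:
    return {h.probe_id for h in hits if h.flagged}


def write_crosshyb_tsv(hits, path) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\ttarget_id\tidentity\tlcs\tflagged\n")
        for h in hits:
            fh.write(
                f"{h.probe_id}\t{h.target_unigene_id}\t{h.overall_identity:.3f}\t"
                f"{h.lcs_length}\t{int(h.flagged)}\n"
            )
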