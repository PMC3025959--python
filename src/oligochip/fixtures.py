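"""Seeded synthetic inputs for every stage of the toolkit.

The generators emulate the study conditions the analysis modules were
built for: a unigene set with planted homologous blocks (for clustering
and cross-hybridization screening), dye-swapped two-color slides with
negative-control spots of known mean/SD, a smooth intensity-dependent
dye bias and planted log2 fold changes, and qPCR Ct tables with stable
reference genes.  Every generator is a pure function of its spec: the
same seed yields byte-identical outputs, and each generator returns a
ground-truth table sufficient to score the downstream module without
re-deriving truth from the data.

What these fixtures do NOT emulate: spatial print-tip effects, scanner
saturation, or sequence-composition biases of real transcriptomes —
conclusions from passing tests are about the algorithms, not about any
particular organism's data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .array_qc import MANDATORY_COLUMNS

__all__ = [
    "FixtureSpec",
    "UnigeneRecord",
    "generate_unigenes",
    "generate_two_color_slides",
    "generate_ct_table",
    "generate_term_map",
]

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class UnigeneRecord:
    """A non-redundant transcript sequence; the unit probes are designed
    for."""

    id: str
    sequence: str


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study.

    Defaults mirror the emulated experiment: 6 hybridizations per
    contrast (3 biological replicates × 2 dyes, half dye-swapped),
    negative controls at mean 100 / SD 15 fluorescence units, per-spot
    log2-ratio noise SD 0.3, planted 2-fold (1 log2 unit) changes, and
    Ct noise of 0.2 cycles.
    """

    seed: int = 0
    # unigene set
    n_unigenes: int = 30
    unigene_length_range: tuple[int, int] = (200, 400)
    gc_fraction: float = 0.43
    # (id_a, id_b, identity_pct, block_len) homologies realized exactly
    planted_homology: tuple[tuple[str, str, float, int], ...] = ()
    # two-color slides
    n_spots: int = 200                 # probe spots per slide
    n_negative_controls: int = 30
    n_empty: int = 30
    nc_mean: float = 100.0
    nc_sd: float = 15.0
    dye_bias_amplitude: float = 0.0    # log2 units
    n_de_genes: int = 0
    de_log2_fold: float = 1.0
    m_noise_sd: float = 0.3            # per-observation log2-ratio SD
    a_range: tuple[float, float] = (8.0, 14.0)
    replicate_layout: tuple[str, ...] = (
        "forward", "swapped", "forward", "swapped", "forward", "swapped",
    )
    # qPCR
    n_ct_genes: int = 10
    n_ct_samples: int = 4
    n_reference_genes: int = 3
    ct_reference_mean: float = 20.0
    ct_technical_replicates: int = 3
    ct_noise_sd: float = 0.2
    ct_fold_range: tuple[float, float] = (-3.0, 3.0)  # log2 units
    # annotation terms
    n_terms: int = 8
    term_density: float = 0.15

    def __post_init__(self) -> None:
        if self.n_negative_controls < 2:
            raise ValueError("need >= 2 negative controls (SD undefined below)")
        if self.n_reference_genes < 3:
            raise ValueError("need >= 3 reference genes")
        orientations = set(self.replicate_layout)
        if not orientations <= {"forward", "swapped"}:
            raise ValueError(f"bad orientations: {orientations}")


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng((spec.seed, stream))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    at = 1.0 - gc
    p = [at / 2, gc / 2, gc / 2, at / 2]
    return "".join(rng.choice(BASES, size=length, p=p))


# ---------------------------------------------------------------------------
# Unigenes with planted homology
# ---------------------------------------------------------------------------

def generate_unigenes(spec: FixtureSpec):
    """Return (unigenes, homology truth table).

    Planted homologies are constructed, not sampled: a block is copied
    between the two sequences and exactly
    ``block_len · (1 − identity/100)`` positions are substituted, so the
    realized identity equals the requested one.  A contradictory spec
    (block longer than a sequence, or a non-integral mismatch count)
    raises.
    """
    rng = _rng(spec, 1)
    lo, hi = spec.unigene_length_range
    if lo < 20:
        raise ValueError("unigene lengths must allow the shortest designable probe")
    ids = [f"u{i:04d}" for i in range(spec.n_unigenes)]
    seqs = {
        uid: _random_seq(rng, int(rng.integers(lo, hi + 1)), spec.gc_fraction)
        for uid in ids
    }
    truth_rows = []
    for id_a, id_b, pct, block_len in spec.planted_homology:
        for uid in (id_a, id_b):
            if uid not in seqs:
                raise ValueError(f"planted homology names unknown unigene {uid!r}")
            if block_len > len(seqs[uid]):
                raise ValueError(
                    f"planted block of {block_len} nt longer than {uid!r}"
                )
        n_mm = (100.0 - pct) / 100.0 * block_len
        if abs(n_mm - round(n_mm)) > 1e-9:
            raise ValueError(
                f"identity {pct}% over {block_len} nt is not realizable exactly"
            )
        n_mm = int(round(n_mm))
        pos_a = int(rng.integers(0, len(seqs[id_a]) - block_len + 1))
        block = list(seqs[id_a][pos_a : pos_a + block_len])
        mm_sites = rng.choice(block_len, size=n_mm, replace=False)
        for site in mm_sites:
            alternatives = [b for b in "ACGT" if b != block[site]]
            block[site] = alternatives[int(rng.integers(0, 3))]
        pos_b = int(rng.integers(0, len(seqs[id_b]) - block_len + 1))
        sb = list(seqs[id_b])
        sb[pos_b : pos_b + block_len] = block
        seqs[id_b] = "".join(sb)
        truth_rows.append(
            {
                "id_a": id_a, "id_b": id_b, "identity_pct": pct,
                "block_len": block_len, "pos_a": pos_a, "pos_b": pos_b,
            }
        )
    unigenes = [UnigeneRecord(uid, seqs[uid]) for uid in ids]
    truth = pd.DataFrame(
        truth_rows, columns=["id_a", "id_b", "identity_pct", "block_len", "pos_a", "pos_b"]
    )
    return unigenes, truth


def write_unigenes_fasta(unigenes, path) -> None:
    with open(path, "w") as fh:
        for u in unigenes:
            fh.write(f">{u.id}\n{u.sequence}\n")


# ---------------------------------------------------------------------------
# Two-color slides
# ---------------------------------------------------------------------------

def _dye_bias(a: np.ndarray, spec: FixtureSpec) -> np.ndarray:
    """Smooth low-order polynomial in A, scaled by the amplitude — a
    recoverable stand-in for intensity-dependent dye bias."""
    lo, hi = spec.a_range
    x = (a - (lo + hi) / 2) / ((hi - lo) / 2)  # map to [-1, 1]
    return spec.dye_bias_amplitude * (x**2 - 0.5 * x - 0.25)


def generate_two_color_slides(spec: FixtureSpec):
    """Return (slides, truth, layout).

    ``slides`` maps slide id to a spot table in the documented dialect;
    ``truth`` has one row per gene with its planted log2 fold (red/green
    in the forward orientation); ``layout`` records each slide's dye
    orientation.  Planted folds alternate in sign across the first
    ``n_de_genes`` genes.
    """
    rng = _rng(spec, 2)
    genes = [f"g{i:05d}" for i in range(spec.n_spots)]
    folds = np.zeros(spec.n_spots)
    for k in range(min(spec.n_de_genes, spec.n_spots)):
        folds[k] = spec.de_log2_fold * (1 if k % 2 == 0 else -1)
    a_base = rng.uniform(*spec.a_range, size=spec.n_spots)

    slides = {}
    layout_rows = []
    for s_idx, orientation in enumerate(spec.replicate_layout):
        slide_id = f"slide{s_idx:02d}"
        sign = 1.0 if orientation == "forward" else -1.0
        noise = rng.normal(0.0, spec.m_noise_sd, size=spec.n_spots)
        m = sign * folds + noise + _dye_bias(a_base, spec)
        r = np.power(2.0, a_base + m / 2)
        g = np.power(2.0, a_base - m / 2)
        rows = {
            "Slide": [slide_id] * spec.n_spots,
            "Block": [1] * spec.n_spots,
            "Row": [i // 100 + 1 for i in range(spec.n_spots)],
            "Column": [i % 100 + 1 for i in range(spec.n_spots)],
            "ID": genes,
            "ControlClass": ["probe"] * spec.n_spots,
            "F_red": np.round(r, 3),
            "B_red": np.round(rng.uniform(1, 5, spec.n_spots), 3),
            "F_green": np.round(g, 3),
            "B_green": np.round(rng.uniform(1, 5, spec.n_spots), 3),
            "Flag": ["ok"] * spec.n_spots,
        }
        df = pd.DataFrame(rows)
        for cls, count in (("negative", spec.n_negative_controls), ("empty", spec.n_empty)):
            fr = np.clip(rng.normal(spec.nc_mean, spec.nc_sd, count), 0, None)
            fg = np.clip(rng.normal(spec.nc_mean, spec.nc_sd, count), 0, None)
            ctrl = pd.DataFrame(
                {
                    "Slide": [slide_id] * count,
                    "Block": [1] * count,
                    "Row": [99] * count,
                    "Column": list(range(1, count + 1)),
                    "ID": [f"{cls}{i:03d}" for i in range(count)],
                    "ControlClass": [cls] * count,
                    "F_red": np.round(fr, 3),
                    "B_red": np.round(rng.uniform(1, 5, count), 3),
                    "F_green": np.round(fg, 3),
                    "B_green": np.round(rng.uniform(1, 5, count), 3),
                    "Flag": ["ok"] * count,
                }
            )
            df = pd.concat([df, ctrl], ignore_index=True)
        slides[slide_id] = df[list(MANDATORY_COLUMNS)]
        layout_rows.append({"slide_id": slide_id, "orientation": orientation})

    truth = pd.DataFrame(
        {"gene_id": genes, "log2_fold": folds, "is_de": folds != 0.0}
    )
    layout = pd.DataFrame(layout_rows)
    return slides, truth, layout


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

def generate_ct_table(spec: FixtureSpec):
    """Return (ct table, truth).

    Reference genes have constant expected Ct across samples (with
    per-reference offsets that average to zero, so the reference mean is
    exactly the nominal value); each target gene's Ct offset encodes its
    planted fold at 2-fold per cycle: Ct = ref_mean − log2(fold).
    """
    rng = _rng(spec, 3)
    samples = [f"s{i}" for i in range(spec.n_ct_samples)]
    targets = [f"q{i:03d}" for i in range(spec.n_ct_genes)]
    refs = [f"ref{i}" for i in range(spec.n_reference_genes)]
    # zero-mean reference offsets keep mean(ref Ct) == ct_reference_mean
    offsets = np.linspace(-1.0, 1.0, spec.n_reference_genes)
    offsets -= offsets.mean()

    log2rel = rng.uniform(*spec.ct_fold_range, size=(spec.n_ct_genes, spec.n_ct_samples))
    rows, truth_rows = [], []
    for j, sample in enumerate(samples):
        for r_i, ref in enumerate(refs):
            for tech in range(spec.ct_technical_replicates):
                rows.append(
                    {
                        "gene_id": ref, "sample_id": sample,
                        "ct": spec.ct_reference_mean + offsets[r_i]
                        + rng.normal(0, spec.ct_noise_sd),
                        "is_reference": True, "technical_replicate": tech,
                    }
                )
        for g_i, gene in enumerate(targets):
            for tech in range(spec.ct_technical_replicates):
                rows.append(
                    {
                        "gene_id": gene, "sample_id": sample,
                        "ct": spec.ct_reference_mean - log2rel[g_i, j]
                        + rng.normal(0, spec.ct_noise_sd),
                        "is_reference": False, "technical_replicate": tech,
                    }
                )
            truth_rows.append(
                {
                    "gene_id": gene, "sample_id": sample,
                    "log2_rel": log2rel[g_i, j],
                    "relative_expression": 2.0 ** log2rel[g_i, j],
                }
            )
    ct = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    return ct, truth


# ---------------------------------------------------------------------------
# Annotation term maps
# ---------------------------------------------------------------------------

def generate_term_map(spec: FixtureSpec, gene_ids=None) -> pd.DataFrame:
    """Random gene→term annotations over the slide genes (or a supplied
    id list); each gene-term pair is drawn independently."""
    rng = _rng(spec, 4)
    if gene_ids is None:
        gene_ids = [f"g{i:05d}" for i in range(spec.n_spots)]
    rows = []
    for t in range(spec.n_terms):
        term = f"T{t:04d}"
        hit = rng.random(len(gene_ids)) < spec.term_density
        for gid, h in zip(gene_ids, hit):
            if h:
                rows.append({"gene_id": gid, "term_id": term, "term_name": f"term {t}"})
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"])
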