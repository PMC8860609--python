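"""Anchor cohorts for TCP-IC: context, uORF-length, folding, codon and motif
groups, plus the report runner that mirrors the MIC summary tables.

An anchor is a (gene, transcript position) pair marking the first nucleotide
of a codon or motif site; cohorts are quantile splits of upstream-AUG (or
motif-window) populations by a score, each scored with the TCP-IC statistic
on its anchor-aligned signal matrix.  Quantile groups use index slices of
the stably sorted score list (ties resolved by (score, gene, position)), so
group sizes are always within one of ``floor(q * N)`` and the q = 0.5 split
partitions the population with ties going to the high group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import ContextPSSM, MotifPSSM, aug_context_at, find_augs
from .profiles import TranscriptAnnotation
from .tcpic import (
    build_signal,
    discretize_fixed,
    discretize_optimized,
    equalize_points,
    mask_points,
    mic,
    permutation_pvalue,
)

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class AnchorGroup:
    label: str
    anchors: list[tuple[str, int]]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.anchors)


def _utr_augs(annotations: list[TranscriptAnnotation]) -> list[tuple[str, int]]:
    """All (gene, transcript position) upstream AUGs (first nt in the UTR)."""
    out = []
    for a in annotations:
        for p in find_augs(a.transcript, 0, a.utr5_len):
            out.append((a.gene_id, p))
    return out


def _has_neighbor_aug(a: TranscriptAnnotation, pos: int, side: str,
                      radius: int = 50) -> bool:
    t = a.transcript
    if side == "up":
        span = find_augs(t, max(0, pos - radius), pos)
        return len(span) > 0
    nearby = [p for p in find_augs(t, pos + 1, min(len(t), pos + radius + 1))]
    return len(nearby) > 0


def _neighbor_class_ok(a, pos, neighbor_class: str) -> bool:
    if neighbor_class == "any":
        return True
    up = _has_neighbor_aug(a, pos, "up")
    down = _has_neighbor_aug(a, pos, "down")
    return {
        "none": not up and not down,
        "down": down and not up,
        "up": up and not down,
        "both": up and down,
    }[neighbor_class]


def _quantile_split(
    scored: list[tuple[float, str, int]], q: float
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Stable (score, gene, position) sort; low = bottom floor(qN), high =
    everything above the (1-q) index, so q = 0.5 partitions with ties high."""
    scored = sorted(scored, key=lambda s: (s[0], s[1], s[2]))
    N = len(scored)
    n_low = int(np.floor(q * N))
    i_high = int(np.floor((1 - q) * N))
    low = [(g, p) for _, g, p in scored[:n_low]]
    high = [(g, p) for _, g, p in scored[i_high:]]
    return high, low


# ---------------------------------------------------------------------------
# cohort constructors
# ---------------------------------------------------------------------------

def group_by_context(
    annotations: list[TranscriptAnnotation],
    pssm: ContextPSSM,
    q: float = 0.10,
    isolation: bool = False,
) -> tuple[AnchorGroup, AnchorGroup]:
    """Upstream AUGs split at the top/bottom ``q`` context-score quantiles.

    With ``isolation`` set, AUGs having another AUG within 50 nt up- or
    downstream are removed before the split.
    """
    ann = {a.gene_id: a for a in annotations}
    augs = _utr_augs(annotations)
    if not augs:
        raise ValueError("no upstream AUGs in the annotation set")
    if isolation:
        augs = [(g, p) for g, p in augs
                if not _has_neighbor_aug(ann[g], p, "up")
                and not _has_neighbor_aug(ann[g], p, "down")]
    scored = [(aug_context_at(ann[g], p, pssm), g, p) for g, p in augs]
    high, low = _quantile_split(scored, q)
    meta = {"q": q, "isolation": isolation, "n_scored": len(scored)}
    return (AnchorGroup("context_high", high, meta),
            AnchorGroup("context_low", low, meta))


def group_main_starts(
    annotations: list[TranscriptAnnotation],
    sample_size: int = 2465,
    seed: int = 0,
) -> AnchorGroup:
    """Seeded uniform sample of genes, anchored at the main start codon."""
    rng = np.random.default_rng(seed)
    genes = sorted(a.gene_id for a in annotations)
    if sample_size > len(genes):
        logger.warning("sample_size %d > %d genes; using all", sample_size, len(genes))
        chosen = genes
    else:
        chosen = sorted(rng.choice(genes, size=sample_size, replace=False))
    utr = {a.gene_id: a.utr5_len for a in annotations}
    return AnchorGroup("main_start", [(g, utr[g]) for g in chosen],
                       {"sample_size": sample_size, "seed": seed})


def stop_distance(
    a: TranscriptAnnotation, aug_pos: int, frame: int = 0
) -> int | None:
    """Nucleotides from the AUG first nt to the first in-frame stop's first nt.

    Frame 0 reads codons from the AUG itself (``AUGUAA`` gives 3); frames 1
    and 2 shift the codon lattice by +1/+2 nt.  The scan runs through the UTR
    and into the CDS; ``None`` when no stop is found.
    """
    t = a.transcript
    for s in range(aug_pos + 3 + frame, len(t) - 2, 3):
        if t[s : s + 3] in STOP_CODONS:
            return s - aug_pos
    return None


def group_by_stop_distance(
    annotations: list[TranscriptAnnotation],
    q: float = 0.20,
    frame: int = 0,
    neighbor_class: str = "any",
) -> tuple[AnchorGroup, AnchorGroup]:
    """Upstream AUGs split by distance to the nearest in-frame stop codon.

    Returns (short, long) groups at the bottom/top ``q`` distance quantiles.
    AUGs with no downstream stop are excluded; ``neighbor_class`` restricts
    to AUGs with/without another AUG within 50 nt (none/down/up/both/any).
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    ann = {a.gene_id: a for a in annotations}
    scored = []
    n_no_stop = 0
    for g, p in _utr_augs(annotations):
        if not _neighbor_class_ok(ann[g], p, neighbor_class):
            continue
        d = stop_distance(ann[g], p, frame)
        if d is None:
            n_no_stop += 1
            continue
        scored.append((float(d), g, p))
    if not scored:
        raise ValueError("no upstream AUGs with an in-frame stop")
    long_, short = _quantile_split(scored, q)
    meta = {"q": q, "frame": frame, "neighbor_class": neighbor_class,
            "excluded_no_stop": n_no_stop, "n_scored": len(scored)}
    return (AnchorGroup("uorf_short", short, meta),
            AnchorGroup("uorf_long", long_, meta))


def group_by_downstream_folding(
    annotations: list[TranscriptAnnotation],
    backend,
    q: float = 0.10,
    n_windows: int = 20,
) -> tuple[AnchorGroup, AnchorGroup]:
    """Upstream AUGs split by mean folding energy downstream of the codon.

    For each uAUG the mean MFE over ``n_windows`` 30-nt windows starting
    1..n_windows nt after the AUG's last nucleotide is computed; the stable
    group is the lowest-energy (strongest-folding) ``q`` quantile, the
    unstable group the highest.  uAUGs lacking downstream sequence for all
    windows are excluded.
    """
    ann = {a.gene_id: a for a in annotations}
    scored = []
    for g, p in _utr_augs(annotations):
        t = ann[g].transcript
        starts = [p + 3 + j for j in range(1, n_windows + 1)]
        if starts[-1] + 30 > len(t):
            continue
        vals = [backend.mfe(t[s : s + 30]) for s in starts]
        scored.append((float(np.mean(vals)), g, p))
    if not scored:
        raise ValueError("no upstream AUGs with sufficient downstream sequence")
    vals = [s[0] for s in scored]
    degenerate = min(vals) == max(vals)
    if degenerate:
        logger.warning("all downstream folding means equal; split is degenerate")
    unstable, stable = _quantile_split(scored, q)  # high energy = unstable
    meta = {"q": q, "n_windows": n_windows, "degenerate": degenerate,
            "n_scored": len(scored),
            "mean_energy": {(g, p): v for v, g, p in scored}}
    return (AnchorGroup("folding_stable", stable, meta),
            AnchorGroup("folding_unstable", unstable, meta))


def group_codon_anchors(
    annotations: list[TranscriptAnnotation],
    codon: str,
    pssm: ContextPSSM | None = None,
) -> AnchorGroup:
    """Anchors at every UTR occurrence of ``codon`` (AUG-like codon scan).

    When a context PSSM is given, each occurrence is scored with the same
    +-(6,3) flanks used for AUG context and stored in the metadata.
    """
    codon = codon.upper().replace("U", "T")
    if len(codon) != 3:
        raise ValueError("codon must be 3 nt")
    anchors, scores = [], []
    for a in annotations:
        t = a.transcript
        for p in range(a.utr5_len - 2):
            if t[p : p + 3] == codon:
                anchors.append((a.gene_id, p))
                if pssm is not None:
                    scores.append(aug_context_at(a, p, pssm))
    meta = {"codon": codon}
    if pssm is not None:
        meta["context_scores"] = np.array(scores)
    return AnchorGroup(f"codon_{codon}", anchors, meta)


def group_motif_windows(
    annotations: list[TranscriptAnnotation],
    motif: MotifPSSM,
    q: float = 0.05,
) -> tuple[AnchorGroup, AnchorGroup]:
    """Motif-width windows along each UTR split by motif score quantiles."""
    from .features import _BASE_IDX, LOG_UNIFORM  # placement scoring

    lp = motif.log_probs
    W = motif.width
    scored = []
    for a in annotations:
        u = a.utr5_seq
        for s in range(len(u) - W + 1):
            total = 0.0
            for i in range(W):
                b = u[s + i]
                total += lp[i, _BASE_IDX[b]] if b in _BASE_IDX else LOG_UNIFORM
            scored.append((total, a.gene_id, s))
    if not scored:
        raise ValueError("no UTR windows at this motif width")
    vals = [s[0] for s in scored]
    degenerate = min(vals) == max(vals)
    if degenerate:
        logger.warning("all motif scores equal; split is degenerate")
    high, low = _quantile_split(scored, q)
    meta = {"q": q, "motif": motif.name, "degenerate": degenerate,
            "n_scored": len(scored)}
    return (AnchorGroup(f"motif_{motif.name}_high", high, meta),
            AnchorGroup(f"motif_{motif.name}_low", low, meta))


# ---------------------------------------------------------------------------
# report runner
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["label", "mic", "p_value", "n_anchors", "n_points", "mode"]


def run_cohort(
    groups: list[AnchorGroup],
    profiles: dict,
    mode: str = "mean",
    n_perm: int = 0,
    seed: int = 0,
    halfwidth: int = 50,
    lengths: tuple[int, int] = (15, 100),
    equalize: bool = True,
) -> pd.DataFrame:
    """TCP-IC one row per group: MIC, permutation p, anchor and point counts.

    Signals are built per group, discretized with the shared rule, and (by
    default) equalized to the smallest surviving point count across groups
    before scoring, so MIC differences cannot stem from unequal point
    numbers.  ``n_perm = 0`` skips p-values.
    """
    rows = []
    built = []
    for grp in groups:
        if len(grp) == 0:
            logger.warning("group %s is empty; flagged", grp.label)
            built.append((grp, None, None))
            continue
        sig = build_signal(profiles, grp.anchors, halfwidth=halfwidth, lengths=lengths)
        bsig = (discretize_optimized(sig) if mode == "optimized"
                else discretize_fixed(sig, mode))
        built.append((grp, sig, bsig))
    counts = [b.n_points for _, _, b in built if b is not None and b.n_points > 0]
    target = min(counts) if (equalize and counts) else None
    for grp, sig, bsig in built:
        if sig is None:
            rows.append({"label": grp.label, "mic": np.nan, "p_value": np.nan,
                         "n_anchors": 0, "n_points": 0, "mode": mode})
            continue
        if target is not None and bsig.n_points > target:
            bsig = equalize_points(sig, bsig, target)
        xs, ys = mask_points(sig, bsig)
        res = mic(xs, ys)
        p = np.nan
        if n_perm > 0:
            p = permutation_pvalue(
                sig, mode=mode, n_perm=n_perm, seed=seed,
                equalize_to=target,
            ).p_value
        rows.append({"label": grp.label, "mic": res.mic, "p_value": p,
                     "n_anchors": sig.n_anchors, "n_points": len(xs),
                     "mode": mode})
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)
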