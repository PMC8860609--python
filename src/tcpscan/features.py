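"""Per-window transcript features for SSU-density modeling.

For every 30-nt sliding window the engine computes gene-level features
(5'UTR length, UTR/ORF length ratio), local folding-energy features over a
31-window lookahead, AUG-context features under a Kozak-like PSSM learned
from highly expressed genes, nucleotide/dinucleotide/trinucleotide
composition, and max-over-offsets motif PSSM scores.

All PSSM scores are natural-log sums of per-position probabilities; flank
positions that run off the transcript contribute log(1/4) (uniform
background).  Scores therefore are <= 0, and a larger (less negative) score
means a closer match to the consensus.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import TranscriptAnnotation, normalize_alphabet

BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(BASES)}

#: context positions around an AUG: 6 upstream (-6..-1), 3 downstream (+4..+6)
N_CONTEXT = 9
LOG_UNIFORM = math.log(0.25)

#: distance sentinel for AUG-free windows
DIST_SENTINEL = -1.0


@dataclass
class ContextPSSM:
    """9 x 4 probability matrix over the AUG flanks (-6..-1, +4..+6)."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_CONTEXT, 4):
            raise ValueError("context PSSM must be 9 x 4")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("PSSM rows must sum to 1")
        if (self.probs <= 0).any():
            raise ValueError("PSSM entries must be positive (pseudocounted)")

    @property
    def log_probs(self) -> np.ndarray:
        return np.log(self.probs)

    @property
    def score_sentinel(self) -> float:
        """Sentinel for windows with no AUG: below any attainable score."""
        return float(np.log(self.probs.min()) * N_CONTEXT - 1.0)


@dataclass
class MotifPSSM:
    name: str
    probs: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("motif PSSM must be W x 4")
        if self.probs.shape[0] > 30:
            raise ValueError("motif width must be <= 30")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("motif PSSM rows must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def log_probs(self) -> np.ndarray:
        return np.log(self.probs)


# ---------------------------------------------------------------------------
# context PSSM
# ---------------------------------------------------------------------------

def main_start_context(annotation: TranscriptAnnotation) -> str:
    """9-nt flank string of the main start codon; 'N' where truncated."""
    utr, cds = annotation.utr5_seq, annotation.cds_seq
    up = utr[-6:].rjust(6, "N")
    down = cds[3:6].ljust(3, "N")
    return up + down


def build_context_pssm(
    annotations: list[TranscriptAnnotation],
    top_fraction: float = 0.05,
    pseudocount: float = 1.0,
) -> ContextPSSM:
    """Kozak-like PSSM from the main-start contexts of highly expressed genes.

    Genes are ranked by mRNA level (ties broken by gene_id for determinism)
    and the top ``top_fraction`` with fully defined flanks contribute
    position-wise nucleotide counts, Laplace-smoothed by ``pseudocount``.
    """
    usable = [
        a for a in annotations
        if np.isfinite(a.mrna_level) and "N" not in main_start_context(a)
    ]
    if len(usable) < 20:
        raise ValueError("need at least 20 genes with full start-codon flanks")
    usable.sort(key=lambda a: (-a.mrna_level, a.gene_id))
    n_top = max(1, int(round(top_fraction * len(usable))))
    counts = np.zeros((N_CONTEXT, 4))
    for a in usable[:n_top]:
        for i, b in enumerate(main_start_context(a)):
            counts[i, _BASE_IDX[b]] += 1
    counts += pseudocount
    return ContextPSSM(counts / counts.sum(axis=1, keepdims=True))


def context_score(context9: str, pssm: ContextPSSM) -> float:
    """Sum of natural-log probabilities over the 9 flank positions.

    Positions marked 'N' (flank truncated by a transcript end) contribute
    log(0.25), i.e. a uniform background.
    """
    context9 = normalize_alphabet(context9)
    if len(context9) != N_CONTEXT:
        raise ValueError("context must give 9 flanking positions")
    lp = pssm.log_probs
    score = 0.0
    for i, b in enumerate(context9):
        if b == "N":
            score += LOG_UNIFORM
        elif b in _BASE_IDX:
            score += lp[i, _BASE_IDX[b]]
        else:
            raise ValueError(f"non-nucleotide character {b!r} in context")
    return score


def aug_context_at(annotation: TranscriptAnnotation, pos: int, pssm: ContextPSSM) -> float:
    """Context score of the codon whose first nt is at transcript ``pos``."""
    t = annotation.transcript
    up = t[max(0, pos - 6) : pos].rjust(6, "N")
    down = t[pos + 3 : pos + 6].ljust(3, "N")
    return context_score(up + down, pssm)


# ---------------------------------------------------------------------------
# per-window feature blocks
# ---------------------------------------------------------------------------

def find_augs(seq: str, start: int = 0, stop: int | None = None) -> list[int]:
    """All positions p in [start, stop) with seq[p:p+3] == ATG."""
    seq = normalize_alphabet(seq)
    if stop is None:
        stop = len(seq)
    out, p = [], seq.find("ATG", start)
    while p != -1 and p < stop:
        out.append(p)
        p = seq.find("ATG", p + 1)
    return out


def aug_features(
    annotation: TranscriptAnnotation,
    window_start: int,
    pssm: ContextPSSM,
    window: int = 30,
) -> dict[str, float]:
    """AUG-related features of one sliding window.

    Counts AUGs whose first nucleotide lies in the window and whose codon is
    fully inside the transcript.  Distance is measured from the AUG first nt
    to the main start codon's first nt (positive = upstream).  Relative
    scores divide by the main start's own context score (always < 0 under
    pseudocounting, so the division is safe).
    """
    t = annotation.transcript
    main = annotation.utr5_len
    positions = [
        p for p in find_augs(t, window_start, min(window_start + window, len(t)))
        if p + 3 <= len(t)
    ]
    if not positions:
        s = pssm.score_sentinel
        return {
            "n_aug": 0.0, "has_aug": 0.0, "mean_dist_to_main_aug": DIST_SENTINEL,
            "mean_cs": s, "max_cs": s, "mean_rel_cs": DIST_SENTINEL,
            "max_rel_cs": DIST_SENTINEL,
        }
    scores = np.array([aug_context_at(annotation, p, pssm) for p in positions])
    main_score = aug_context_at(annotation, main, pssm)
    rel = scores / main_score
    dists = np.array([float(main - p) for p in positions])
    return {
        "n_aug": float(len(positions)),
        "has_aug": 1.0,
        "mean_dist_to_main_aug": float(dists.mean()),
        "mean_cs": float(scores.mean()),
        "max_cs": float(scores.max()),
        "mean_rel_cs": float(rel.mean()),
        "max_rel_cs": float(rel.max()),
    }


_FOLD_NAMES = [
    "fe_pos1", "fe_pos31", "fe_mean_1_30", "fe_min_1_30",
    "fe_mean_15_30", "fe_min_15_30", "fe_mean_20_30", "fe_min_20_30",
]


def folding_features(
    transcript: str, window_start: int, backend, window: int = 30
) -> dict[str, float]:
    """Eight local folding-energy features of one sliding window.

    Thirty-one 30-nt windows are folded at offsets 0..30 downstream of the
    window start ("positions 1..31", 1-based).  Aggregates cover offsets
    0..29 (1:30), 14..29 (15:30) and 19..29 (20:30); offsets whose window
    would run past the transcript end are skipped from the aggregates, and
    fe_pos31 is NaN when offset 30 is unavailable.
    """
    L = len(transcript)
    if window_start + window > L:
        raise ValueError("no valid 30-nt window at offset 0")
    energies = np.full(31, np.nan)
    for off in range(31):
        s = window_start + off
        if s + window <= L:
            energies[off] = backend.mfe(transcript[s : s + window])

    def agg(lo, hi):
        vals = energies[lo:hi]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return np.nan, np.nan
        return float(vals.mean()), float(vals.min())

    m1, n1 = agg(0, 30)
    m15, n15 = agg(14, 30)
    m20, n20 = agg(19, 30)
    return dict(zip(_FOLD_NAMES, [
        float(energies[0]), float(energies[30]), m1, n1, m15, n15, m20, n20,
    ]))


_DI = ["".join(p) for p in itertools.product(BASES, repeat=2)]
_TRI = ["".join(p) for p in itertools.product(BASES, repeat=3)]


def composition_features(window30: str) -> dict[str, float]:
    """GC content plus overlapping mono/di/tri-nucleotide frequencies.

    Denominators are the number of unambiguous k-mers actually counted
    (30, 29, 28 for a clean window), so each block sums to 1.
    """
    s = normalize_alphabet(window30)
    out: dict[str, float] = {}
    valid = [c in _BASE_IDX for c in s]
    n_valid = sum(valid)
    out["gc"] = (s.count("G") + s.count("C")) / max(n_valid, 1)
    for k, names, prefix in [(1, list(BASES), "mono_"), (2, _DI, "di_"), (3, _TRI, "tri_")]:
        counts = dict.fromkeys(names, 0)
        denom = 0
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            if all(c in _BASE_IDX for c in kmer):
                counts[kmer] += 1
                denom += 1
        denom = max(denom, 1)
        for name in names:
            out[prefix + name] = counts[name] / denom
    return out


def motif_score(window30: str, motif: MotifPSSM) -> float:
    """Max over in-window placements of the motif's log-probability sum."""
    s = normalize_alphabet(window30)
    W = motif.width
    if W > len(s):
        raise ValueError("motif wider than window")
    lp = motif.log_probs
    best = -np.inf
    for off in range(len(s) - W + 1):
        total = 0.0
        for i in range(W):
            b = s[off + i]
            total += lp[i, _BASE_IDX[b]] if b in _BASE_IDX else LOG_UNIFORM
        best = max(best, total)
    return float(best)


def read_homer_motifs(path, floor: float = 1e-4) -> list[MotifPSSM]:
    """Parse HOMER motif text format.

    Headers are ``>consensus name log-odds-threshold``; each following line
    holds four probabilities (A C G T).  Rows are floored at ``floor`` and
    re-normalized so every entry is strictly positive.
    """
    motifs: list[MotifPSSM] = []
    name, rows = None, []

    def flush():
        if name is None:
            return
        probs = np.asarray(rows, dtype=float)
        probs = np.maximum(probs, floor)
        probs /= probs.sum(axis=1, keepdims=True)
        motifs.append(MotifPSSM(name=name, probs=probs, source="homer"))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split()
                name = parts[1] if len(parts) > 1 else parts[0]
                rows = []
            else:
                vals = line.split()
                if len(vals) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(vals)}")
                rows.append([float(v) for v in vals])
    flush()
    return motifs


# ---------------------------------------------------------------------------
# table assembly
# ---------------------------------------------------------------------------

def feature_registry(motifs: list[MotifPSSM]) -> list[str]:
    """Ordered column names: 2 gene + 8 folding + 7 AUG + 85 composition + motifs."""
    cols = ["utr5_len", "utr5_to_orf_ratio"]
    cols += _FOLD_NAMES
    cols += ["n_aug", "has_aug", "mean_dist_to_main_aug",
             "mean_cs", "max_cs", "mean_rel_cs", "max_rel_cs"]
    cols += ["gc"] + [f"mono_{b}" for b in BASES] + [f"di_{d}" for d in _DI] \
        + [f"tri_{t}" for t in _TRI]
    cols += [f"motif_{m.name}" for m in motifs]
    return cols


def assemble_feature_table(
    windows: list[tuple[str, int]],
    annotations: list[TranscriptAnnotation],
    pssm: ContextPSSM,
    motifs: list[MotifPSSM],
    backend,
    window: int = 30,
) -> pd.DataFrame:
    """One feature row per (gene, window_start), indexed by that pair.

    Column order follows :func:`feature_registry`; with zero motifs the table
    has 102 feature columns.
    """
    ann = {a.gene_id: a for a in annotations}
    cols = feature_registry(motifs)
    rows = []
    for gid, start in windows:
        a = ann[gid]
        t = a.transcript
        w30 = t[start : start + window]
        feats = {
            "utr5_len": float(a.utr5_len),
            "utr5_to_orf_ratio": a.utr5_len / max(len(a.cds_seq), 1),
        }
        feats.update(folding_features(t, start, backend, window=window))
        feats.update(aug_features(a, start, pssm, window=window))
        feats.update(composition_features(w30))
        for m in motifs:
            feats[f"motif_{m.name}"] = motif_score(w30, m)
        rows.append(feats)
    idx = pd.MultiIndex.from_tuples(windows, names=["gene_id", "window_start"])
    return pd.DataFrame(rows, index=idx, columns=cols)
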