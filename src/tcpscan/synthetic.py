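"""Synthetic transcriptome and TCP-seq-like footprint generator.

Real small-subunit profiling data are not bundled with the package, so every
analysis is exercised on synthetic transcripts whose footprints are drawn
from an explicit forward model of cap-to-start scanning:

* a loading intensity proportional to the gene's mRNA level;
* per-nucleotide drop-off (survival model) whose hazard grows with local
  folding strength - strong structure detaches the scanning subunit;
* dwell-time multipliers at planted upstream AUGs, larger for AUGs carrying
  a strong (consensus-like) context than a weak one;
* terminal accumulation at the main start codon split across the three
  characteristic footprint lengths (19, 29, 37 nt);
* footprint lengths away from starts drawn from a broad 15-75 nt mixture,
  with the 5' end placed a half-footprint upstream of the occupied position.

Counts are Poisson around the expected matrix.  Every planted effect can be
switched off independently, and the generator emits a truth record so that
recovery tests can ask whether the inference stages find what was planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .profiles import (
    MIN_LEN,
    N_LENGTHS,
    FootprintRecord,
    GeneProfile,
    TranscriptAnnotation,
)

# context templates planted around start codons / uAUGs.  The high template
# mirrors the A-rich yeast consensus the main starts carry, so a PSSM learned
# from main starts scores it high; the low template is its C/G-rich opposite.
HIGH_CONTEXT = ("AAAAAA", "TCT")
LOW_CONTEXT = ("CCGCCC", "GGG")

STOPS = ("TAA", "TAG", "TGA")


def default_scan_pmf(mu: float = math.log(30.0), sigma: float = 0.35) -> dict[int, float]:
    """Discretized log-normal footprint-length law on 15..75 nt."""
    lens = np.arange(15, 76)
    w = np.exp(-((np.log(lens) - mu) ** 2) / (2 * sigma**2)) / lens
    w /= w.sum()
    return {int(l): float(p) for l, p in zip(lens, w)}


@dataclass
class SyntheticConfig:
    """Study conditions for the generator; defaults emulate desk-scale yeast.

    Lengths are log-normally distributed (median 5'UTR ~60 nt, CDS ~900 nt),
    GC content matches the yeast transcriptome (~0.38), and mRNA levels span
    roughly two orders of magnitude.  Pause/drop-off magnitudes are chosen so
    the planted effects are detectable at the configured depth, since no
    quantitative dwell or detachment rates are published for this system.
    """

    n_genes: int = 200
    utr_len_law: tuple[float, float] = (math.log(60.0), 0.45)
    cds_len_law: tuple[float, float] = (math.log(900.0), 0.35)
    gc_content: float = 0.38
    mrna_law: tuple[float, float] = (1.0, 1.0)
    p_uaug_high: float = 0.35
    p_uaug_low: float = 0.35
    pause_high: float = 6.0
    pause_low: float = 1.5
    dropoff_scale: float = 0.004
    start_dwell: float = 30.0
    start_len_modes: dict[int, float] = field(
        default_factory=lambda: {19: 0.40, 29: 0.35, 37: 0.25}
    )
    scan_len_law: dict[int, float] = field(default_factory=default_scan_pmf)
    depth: float = 3.0
    min_utr_len: int = 25
    min_cds_len: int = 90
    planted_motif: str | None = None
    p_motif: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_uaug_high", "p_uaug_low", "p_motif"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        for law, name in [(self.start_len_modes, "start_len_modes"),
                          (self.scan_len_law, "scan_len_law")]:
            if not math.isclose(sum(law.values()), 1.0, abs_tol=1e-9):
                raise ValueError(f"{name} weights must sum to 1")
            if any(not (MIN_LEN <= l <= 100) for l in law):
                raise ValueError(f"{name} support must lie within [15, 100]")
        for sigma_law, name in [(self.utr_len_law, "utr_len_law"),
                                (self.cds_len_law, "cds_len_law")]:
            if sigma_law[1] <= 0:
                raise ValueError(f"{name} sigma must be positive")
        if self.min_utr_len < 16:
            raise ValueError("min_utr_len must leave room for planted contexts")


@dataclass
class PlantedAug:
    offset: int              # 0-based position of the AUG 'A' within the 5'UTR
    context_class: str       # "high" | "low"


@dataclass
class SyntheticTruth:
    """What the generator planted, per gene."""

    uaugs: dict[str, list[PlantedAug]] = field(default_factory=dict)
    motif_sites: dict[str, list[int]] = field(default_factory=dict)
    mrna_levels: dict[str, float] = field(default_factory=dict)
    occupancy: dict[str, np.ndarray] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def _plant(seq: list[str], pos: int, insert: str) -> None:
    seq[pos : pos + len(insert)] = list(insert)


def generate_transcriptome(
    cfg: SyntheticConfig,
) -> tuple[list[TranscriptAnnotation], SyntheticTruth]:
    """Sample annotated genes plus the truth record of planted signals.

    Each gene has a log-normal 5'UTR and CDS, an AUG start carrying the
    consensus context (so the context PSSM is learnable from main starts),
    and - with the configured probabilities - one high-context and/or one
    low-context upstream AUG planted at a uniform interior UTR offset.
    Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    truth = SyntheticTruth()
    annotations: list[TranscriptAnnotation] = []
    for g in range(cfg.n_genes):
        gid = f"g{g:04d}"
        utr_len = max(cfg.min_utr_len, int(round(rng.lognormal(*cfg.utr_len_law))))
        cds_len = max(cfg.min_cds_len, int(round(rng.lognormal(*cfg.cds_len_law))))
        cds_len -= cds_len % 3
        utr = list(_random_seq(rng, utr_len, cfg.gc_content))
        cds = list(_random_seq(rng, cds_len, cfg.gc_content))
        _plant(cds, 0, "ATG")
        _plant(cds, cds_len - 3, "TAA")
        # consensus context at the main start: upstream flank in the UTR tail,
        # downstream flank at CDS codon 2
        _plant(utr, utr_len - 6, HIGH_CONTEXT[0])
        _plant(cds, 3, HIGH_CONTEXT[1])

        planted: list[PlantedAug] = []
        # interior span that keeps flanks clear of the UTR edges and the
        # main-start context
        lo, hi = 7, utr_len - 16
        if hi > lo:
            if rng.random() < cfg.p_uaug_high:
                off = int(rng.integers(lo, hi))
                _plant(utr, off - 6, HIGH_CONTEXT[0])
                _plant(utr, off, "ATG")
                _plant(utr, off + 3, HIGH_CONTEXT[1])
                planted.append(PlantedAug(off, "high"))
            if rng.random() < cfg.p_uaug_low:
                off = int(rng.integers(lo, hi))
                # avoid stamping over an existing planted context
                if all(abs(off - p.offset) >= 16 for p in planted):
                    _plant(utr, off - 6, LOW_CONTEXT[0])
                    _plant(utr, off, "ATG")
                    _plant(utr, off + 3, LOW_CONTEXT[1])
                    planted.append(PlantedAug(off, "low"))
        sites: list[int] = []
        if cfg.planted_motif and rng.random() < cfg.p_motif:
            W = len(cfg.planted_motif)
            spots = [s for s in range(0, utr_len - W + 1)
                     if all(not (p.offset - 6 < s + W and s < p.offset + 6)
                            for p in planted) and s < utr_len - 16 - W]
            if spots:
                s = int(rng.choice(spots))
                _plant(utr, s, cfg.planted_motif.upper().replace("U", "T"))
                sites.append(s)

        mrna = float(rng.lognormal(*cfg.mrna_law))
        annotations.append(
            TranscriptAnnotation(gid, "".join(utr), "".join(cds), mrna_level=mrna)
        )
        truth.uaugs[gid] = planted
        truth.motif_sites[gid] = sites
        truth.mrna_levels[gid] = mrna
    return annotations, truth


def scanning_occupancy(
    gene: TranscriptAnnotation,
    truth: SyntheticTruth,
    cfg: SyntheticConfig,
    backend=None,
) -> np.ndarray:
    """Expected RC matrix (86 x transcript length) of the scanning model.

    The scanning term at UTR position p is ``loading * survival(p) *
    dwell(p)`` with ``survival(p) = prod_{q<p} (1 - hazard(q))`` and hazard
    proportional to local folding strength (uniform when no backend is
    given, so the no-drop-off and closed-form cases are exact).  The
    terminal term adds ``loading * survival(L_utr) * start_dwell`` at the
    main start, split over the 19/29/37 nt modes.  Each position's occupancy
    is spread over footprint lengths, with the 5' end placed
    ``(length - 15) // 2`` nt upstream of the occupied position and clipped
    at the transcript start.

    The per-position occupancy vector (before length assignment) is stored
    in ``truth.occupancy``.
    """
    if gene.gene_id not in truth.mrna_levels:
        raise KeyError(f"{gene.gene_id} not in truth")
    t = gene.transcript
    L, L_utr = len(t), gene.utr5_len
    loading = cfg.depth * truth.mrna_levels[gene.gene_id]

    hazard = np.zeros(L_utr)
    if cfg.dropoff_scale > 0:
        if backend is None:
            strength = np.ones(L_utr)
        else:
            strength = np.array(
                [max(0.0, -backend.mfe(t[p : p + 30])) for p in range(L_utr)]
            )
        hazard = np.clip(cfg.dropoff_scale * strength, 0.0, 0.99)
    survival = np.concatenate([[1.0], np.cumprod(1.0 - hazard)])

    dwell = np.ones(L_utr)
    for planted in truth.uaugs.get(gene.gene_id, []):
        mult = cfg.pause_high if planted.context_class == "high" else cfg.pause_low
        dwell[planted.offset] *= mult

    occ = np.zeros(L)
    occ[:L_utr] = loading * survival[:L_utr] * dwell

    expected = np.zeros((N_LENGTHS, L))
    for length, w in cfg.scan_len_law.items():
        shift = (length - MIN_LEN) // 2
        row = length - MIN_LEN
        for p in range(L_utr):
            five = max(0, p - shift)
            expected[row, five] += occ[p] * w

    start_mass = loading * survival[L_utr] * cfg.start_dwell
    occ[L_utr] += start_mass
    for length, w in cfg.start_len_modes.items():
        five = max(0, L_utr - (length - MIN_LEN) // 2)
        expected[length - MIN_LEN, five] += start_mass * w

    truth.occupancy[gene.gene_id] = occ
    return expected


def sample_footprints(
    expected: np.ndarray, gene_id: str, seed: int
) -> list[FootprintRecord]:
    """Poisson counts per (length, position) cell; deterministic given seed."""
    if (np.asarray(expected) < 0).any():
        raise ValueError("expected matrix must be non-negative")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected)
    out = []
    for row, col in zip(*np.nonzero(counts)):
        out.append(
            FootprintRecord(gene_id, int(col), int(row + MIN_LEN), float(counts[row, col]))
        )
    return out


def simulate_dataset(
    cfg: SyntheticConfig, backend=None
) -> tuple[list[TranscriptAnnotation], SyntheticTruth, list[FootprintRecord]]:
    """Transcriptome + truth + sampled footprints in one call."""
    annotations, truth = generate_transcriptome(cfg)
    records: list[FootprintRecord] = []
    # derive per-gene seeds from the master seed, keeping them below 2**31
    seed_rng = np.random.default_rng(cfg.seed + 1)
    for ann in annotations:
        expected = scanning_occupancy(ann, truth, cfg, backend=backend)
        records.extend(
            sample_footprints(expected, ann.gene_id, int(seed_rng.integers(2**31)))
        )
    return annotations, truth, records


def profiles_from_truth(
    annotations, truth, cfg, backend=None
) -> dict[str, GeneProfile]:
    """Noise-free profiles: the expected matrices themselves."""
    return {
        a.gene_id: GeneProfile(
            a.gene_id, scanning_occupancy(a, truth, cfg, backend=backend)
        )
        for a in annotations
    }
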