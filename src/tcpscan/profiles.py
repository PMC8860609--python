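"""Transcript annotations, footprint records and per-gene read-count profiles.

Coordinates are 0-based, half-open, in transcript space (5'UTR followed by
CDS); the main start codon's 'A' sits at transcript position ``utr5_len``.
Footprints are located by their 5' end and length; a gene's profile is the
dense non-negative matrix RC[length 15..100][transcript position].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: footprint lengths retained after filtering (86 classes)
MIN_LEN = 15
MAX_LEN = 100
LENGTHS = np.arange(MIN_LEN, MAX_LEN + 1)
N_LENGTHS = len(LENGTHS)

_VALID = set("ACGT")


def normalize_alphabet(seq: str) -> str:
    """Uppercase and fold RNA onto the internal DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


@dataclass
class TranscriptAnnotation:
    gene_id: str
    utr5_seq: str
    cds_seq: str
    mrna_level: float = np.nan

    def __post_init__(self):
        self.utr5_seq = normalize_alphabet(self.utr5_seq)
        self.cds_seq = normalize_alphabet(self.cds_seq)
        for part, name in [(self.utr5_seq, "utr5"), (self.cds_seq, "cds")]:
            bad = set(part) - _VALID
            if bad:
                raise ValueError(
                    f"{self.gene_id}: non-nucleotide characters {sorted(bad)} in {name}"
                )
        if self.cds_seq and not self.cds_seq.startswith("ATG"):
            raise ValueError(f"{self.gene_id}: CDS does not start with AUG")

    @property
    def transcript(self) -> str:
        return self.utr5_seq + self.cds_seq

    @property
    def utr5_len(self) -> int:
        return len(self.utr5_seq)

    @property
    def length(self) -> int:
        return len(self.utr5_seq) + len(self.cds_seq)


@dataclass
class FootprintRecord:
    gene_id: str
    five_prime_pos: int
    length: int
    weight: float = 1.0


@dataclass
class GeneProfile:
    """Dense RC matrix, rows = footprint lengths 15..100, cols = positions."""

    gene_id: str
    matrix: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != N_LENGTHS:
            raise ValueError(f"profile must have {N_LENGTHS} length rows")
        if (self.matrix < 0).any():
            raise ValueError("read counts must be non-negative")

    @property
    def n_positions(self) -> int:
        return self.matrix.shape[1]

    def row(self, length: int) -> np.ndarray:
        return self.matrix[length - MIN_LEN]


@dataclass
class WindowDensity:
    gene_id: str
    window_start: int
    length_class: int
    density: float


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_annotations(
    fasta_path, utr_table_path, mrna_path=None
) -> list[TranscriptAnnotation]:
    """Load transcript sequences plus a 5'UTR-length table (and mRNA levels).

    The UTR table is TSV with columns ``gene_id`` and ``utr5_len``.  Genes in
    the table but missing from the FASTA (or vice versa) are skipped with a
    warning.  ``mrna_path`` is an optional TSV ``gene_id\tmrna_level``.
    """
    utr = pd.read_csv(utr_table_path, sep="\t")
    utr_len = dict(zip(utr["gene_id"].astype(str), utr["utr5_len"].astype(int)))
    mrna = {}
    if mrna_path is not None:
        mt = pd.read_csv(mrna_path, sep="\t")
        mrna = dict(zip(mt["gene_id"].astype(str), mt["mrna_level"].astype(float)))

    seqs = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[rec.id] = normalize_alphabet(str(rec.seq))

    out = []
    for gid, ulen in utr_len.items():
        if gid not in seqs:
            logger.warning("gene %s in UTR table but absent from FASTA; skipped", gid)
            continue
        seq = seqs[gid]
        if ulen > len(seq):
            logger.warning("gene %s: utr5_len exceeds transcript length; skipped", gid)
            continue
        out.append(
            TranscriptAnnotation(
                gene_id=gid,
                utr5_seq=seq[:ulen],
                cds_seq=seq[ulen:],
                mrna_level=mrna.get(gid, np.nan),
            )
        )
    for gid in seqs:
        if gid not in utr_len:
            logger.warning("gene %s in FASTA but absent from UTR table; skipped", gid)
    return out


def write_annotations(annotations, fasta_path, utr_table_path, mrna_path=None):
    recs = [
        SeqRecord(Seq(a.transcript), id=a.gene_id, description="")
        for a in annotations
    ]
    SeqIO.write(recs, str(fasta_path), "fasta")
    pd.DataFrame(
        {"gene_id": [a.gene_id for a in annotations],
         "utr5_len": [a.utr5_len for a in annotations]}
    ).to_csv(utr_table_path, sep="\t", index=False)
    if mrna_path is not None:
        pd.DataFrame(
            {"gene_id": [a.gene_id for a in annotations],
             "mrna_level": [a.mrna_level for a in annotations]}
        ).to_csv(mrna_path, sep="\t", index=False)


def read_footprints(path) -> list[FootprintRecord]:
    """TSV columns: gene_id, five_prime_pos, length, count."""
    df = pd.read_csv(path, sep="\t")
    return [
        FootprintRecord(str(r.gene_id), int(r.five_prime_pos), int(r.length), float(r["count"]))
        for _, r in df.iterrows()
    ]


def write_footprints(records, path):
    pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "five_prime_pos": [r.five_prime_pos for r in records],
            "length": [r.length for r in records],
            "count": [r.weight for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def profile_to_tsv(profile: GeneProfile, path):
    pd.DataFrame(profile.matrix, index=LENGTHS).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------

def distribute_multireads(
    candidates: list[tuple[str, int]],
    profiles: dict[str, GeneProfile],
    window: int = 100,
) -> np.ndarray:
    """Fractional weights for one multi-mapped read across candidate positions.

    Each candidate's read-count density RCD is the unique-read count (summed
    over footprint lengths) in a ``window``-nt window centred on the position,
    clipped at transcript ends and divided by the number of positions the
    clipped window actually covers.  Weights are RCD_i / sum_j RCD_j; when
    every density is zero the split is uniform.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    half = window // 2
    dens = np.zeros(len(candidates))
    for i, (gene, pos) in enumerate(candidates):
        prof = profiles.get(gene)
        if prof is None:
            continue
        lo = max(0, pos - half)
        hi = min(prof.n_positions, pos + half)
        if hi <= lo:
            continue
        dens[i] = prof.matrix[:, lo:hi].sum() / (hi - lo)
    total = dens.sum()
    if total == 0:
        return np.full(len(candidates), 1.0 / len(candidates))
    return dens / total


def build_profiles(
    records: list[FootprintRecord],
    annotations: list[TranscriptAnnotation],
) -> tuple[dict[str, GeneProfile], dict]:
    """Accumulate (possibly fractional) footprint weights into RC matrices.

    Footprints outside the 15..100 nt length band, on unknown genes, or with
    5' ends beyond the transcript are dropped and tallied in the report.
    """
    ann = {a.gene_id: a for a in annotations}
    profiles = {
        a.gene_id: GeneProfile(a.gene_id, np.zeros((N_LENGTHS, a.length)))
        for a in annotations
    }
    report = {"kept": 0, "dropped_length": 0, "dropped_position": 0, "dropped_gene": 0}
    for r in records:
        if r.gene_id not in ann:
            report["dropped_gene"] += 1
            continue
        if not (MIN_LEN <= r.length <= MAX_LEN):
            report["dropped_length"] += 1
            continue
        prof = profiles[r.gene_id]
        if not (0 <= r.five_prime_pos < prof.n_positions):
            report["dropped_position"] += 1
            logger.warning(
                "footprint at %s:%d beyond transcript; dropped", r.gene_id, r.five_prime_pos
            )
            continue
        prof.matrix[r.length - MIN_LEN, r.five_prime_pos] += r.weight
        report["kept"] += 1
    return profiles, report


def normalize_by_mrna(
    profiles: dict[str, GeneProfile],
    annotations: list[TranscriptAnnotation],
) -> tuple[dict[str, GeneProfile], list[str]]:
    """Divide every RC cell by the gene's mRNA level.

    Genes whose mRNA level is zero (or missing) cannot be normalized; they
    are excluded from the output and listed in the returned exclusion report.
    """
    levels = {a.gene_id: a.mrna_level for a in annotations}
    out, excluded = {}, []
    for gid, prof in profiles.items():
        lvl = levels.get(gid, np.nan)
        if not np.isfinite(lvl) or lvl == 0:
            excluded.append(gid)
            continue
        out[gid] = GeneProfile(gid, prof.matrix / lvl, normalized=True)
    return out, excluded


def window_density_matrix(
    profile: GeneProfile, window: int = 30, n_windows: int | None = None
) -> np.ndarray:
    """Sliding-window RC sums, shape (86, n_windows), step 1 nt.

    Window ``w`` sums RC over 5'-end positions [w, w+window), clipped at the
    transcript end.  By default windows are anchored at every position of the
    transcript; pass ``n_windows`` to restrict (e.g. to the 5'UTR).
    """
    L = profile.n_positions
    if n_windows is None:
        n_windows = L
    cs = np.concatenate(
        [np.zeros((N_LENGTHS, 1)), np.cumsum(profile.matrix, axis=1)], axis=1
    )
    starts = np.arange(n_windows)
    ends = np.minimum(starts + window, L)
    return cs[:, ends] - cs[:, starts]


def window_densities(
    profile: GeneProfile, window: int = 30, n_windows: int | None = None
) -> list[WindowDensity]:
    """Record view of :func:`window_density_matrix` (one row per cell)."""
    mat = window_density_matrix(profile, window=window, n_windows=n_windows)
    out = []
    for li, length in enumerate(LENGTHS):
        for w in range(mat.shape[1]):
            out.append(WindowDensity(profile.gene_id, w, int(length), float(mat[li, w])))
    return out
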