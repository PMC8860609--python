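"""Canonical desk-scale experiments: one place for the study conditions.

Each function here fixes a complete experimental design - generator
configuration, cohort definitions, problem sizes - and runs it through the
library, so the test suite, the acceptance script and the analysis drivers
all exercise exactly the same conditions.  Sizes are desk-scale stand-ins
for the organism-scale originals: a few hundred genes instead of ~6600,
thousands of windows instead of ~1.6 million.

Design notes:

* The pause-cohort experiment isolates context-dependent pausing by
  switching the other generator effects (start-codon accumulation,
  folding drop-off) off; with them on, the accumulation shared by both
  cohorts dominates both signals and the comparison probes the background
  rather than the planted effect.
* UTRs are drawn longer (median 150 nt) than the yeast median so that most
  upstream-AUG windows do not also contain the main start codon.
* The null-calibration matrices are i.i.d. Poisson fields on a reduced
  20 x 31 grid: column exchangeability holds exactly, so the permutation
  p-value must be uniform.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import cohorts, features, profiles, regression, synthetic, tcpic
from .folding import NussinovBackend


def pause_cohort_config(seed: int) -> synthetic.SyntheticConfig:
    """Generator conditions for the context-pausing cohort comparison."""
    return synthetic.SyntheticConfig(
        n_genes=200,
        depth=15.0,
        utr_len_law=(math.log(150.0), 0.35),
        mrna_law=(1.0, 0.6),
        pause_high=8.0,
        pause_low=1.0,
        p_uaug_high=0.5,
        p_uaug_low=0.5,
        start_dwell=0.0,
        dropoff_scale=0.0,
        seed=seed,
    )


def pause_cohort_mics(
    seed: int, mode: str = "2mean", q: float = 0.10, n_perm: int = 0
) -> pd.DataFrame:
    """High- vs low-context uAUG cohorts on planted-pause synthetic data.

    Builds the transcriptome, samples footprints, normalizes by mRNA level,
    learns the context PSSM from the top-expressed genes, splits uAUGs at
    the context-score quantiles and scores both cohorts with TCP-IC.
    """
    cfg = pause_cohort_config(seed)
    ann, truth, recs = synthetic.simulate_dataset(cfg)
    profs, _ = profiles.build_profiles(recs, ann)
    norm, _ = profiles.normalize_by_mrna(profs, ann)
    pssm = features.build_context_pssm(ann, top_fraction=0.2)
    hi, lo = cohorts.group_by_context(ann, pssm, q=q)
    return cohorts.run_cohort([hi, lo], norm, mode=mode, n_perm=n_perm, seed=seed)


def main_start_cohort(
    seed: int, mode: str = "2mean", n_perm: int = 0, sample_size: int = 150
) -> pd.DataFrame:
    """Main-start-codon cohort with the start-codon accumulation switched on."""
    cfg = pause_cohort_config(seed)
    cfg.start_dwell = 30.0
    ann, truth, recs = synthetic.simulate_dataset(cfg)
    profs, _ = profiles.build_profiles(recs, ann)
    norm, _ = profiles.normalize_by_mrna(profs, ann)
    grp = cohorts.group_main_starts(ann, sample_size=sample_size, seed=seed)
    return cohorts.run_cohort([grp], norm, mode=mode, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# permutation-null calibration
# ---------------------------------------------------------------------------

def null_signal(rng: np.random.Generator, n_lengths: int = 20,
                n_offsets: int = 31, lam: float = 2.0) -> tcpic.SignalMatrix:
    """A structureless signal matrix: i.i.d. Poisson cells, full coverage."""
    vals = rng.poisson(lam, size=(n_lengths, n_offsets)).astype(float)
    half = n_offsets // 2
    return tcpic.SignalMatrix(
        values=vals,
        coverage=np.ones(n_offsets, dtype=int),
        lengths=np.arange(15, 15 + n_lengths),
        offsets=np.arange(-half, n_offsets - half),
        n_anchors=1,
    )


def null_calibration(
    seed: int, n_matrices: int = 200, n_perm: int = 200, mode: str = "mean",
    alpha: float = 0.05,
) -> tuple[float, np.ndarray]:
    """Fraction of structureless matrices called significant at ``alpha``.

    Under column exchangeability the permutation p-value is uniform, so the
    fraction should sit near ``alpha`` (slightly below, because ties under
    the strict inequality are conservative).
    """
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_matrices)
    for i in range(n_matrices):
        sig = null_signal(rng)
        perm_seed = int(rng.integers(2**31))
        pvals[i] = tcpic.permutation_pvalue(
            sig, mode=mode, n_perm=n_perm, seed=perm_seed
        ).p_value
    return float((pvals < alpha).mean()), pvals


# ---------------------------------------------------------------------------
# regression recovery
# ---------------------------------------------------------------------------

#: features carrying planted linear effects and their planted signs
PLANTED_EFFECTS = {"utr5_len": -1.0, "has_aug": +1.0, "fe_mean_1_30": +1.0}


def regression_dataset(
    seed: int, n_windows: int = 5000, n_genes: int = 60
) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table over synthetic UTR windows plus a planted-effect target.

    The target is a linear combination of standardized planted features
    (UTR length negative; AUG presence and folding energy positive, the
    directions the density analyses report) plus unit-variance Gaussian
    noise at sigma = 0.8.
    """
    cfg = synthetic.SyntheticConfig(
        n_genes=n_genes,
        utr_len_law=(math.log(150.0), 0.45),
        p_uaug_high=0.5,
        p_uaug_low=0.5,
        seed=seed,
    )
    ann, truth = synthetic.generate_transcriptome(cfg)
    windows = [(a.gene_id, s) for a in ann for s in range(a.utr5_len)]
    windows = windows[:n_windows]
    pssm = features.build_context_pssm(ann, top_fraction=0.2)
    table = features.assemble_feature_table(
        windows, ann, pssm, motifs=[], backend=NussinovBackend()
    )
    rng = np.random.default_rng(seed + 1)
    signal = np.zeros(len(table))
    for name, sign in PLANTED_EFFECTS.items():
        col = table[name].to_numpy(dtype=float)
        sd = col.std()
        if sd == 0:
            raise RuntimeError(f"degenerate planted feature {name}")
        signal += sign * (col - col.mean()) / sd
    target = signal + rng.normal(scale=0.8, size=len(table))
    return table, target


def regression_recovery(
    seed: int, n_windows: int = 5000, n_replicates: int = 20
) -> dict:
    """Greedy-selection and partial-Spearman recovery of the planted effects.

    Returns per-feature selection counts over the split replicates, and the
    fraction of (feature, replicate) pairs whose partial Spearman sign
    (against the target, controlling for the other planted features) matches
    the planted sign.
    """
    table, target = regression_dataset(seed, n_windows=n_windows)
    plans = regression.make_splits(len(table), seed, n_replicates=n_replicates)
    sel_counts = {name: 0 for name in PLANTED_EFFECTS}
    sign_hits, sign_total = 0, 0
    rhos = []
    for plan in plans:
        model = regression.greedy_fit(table, target, plan)
        rhos.append(model.validation_rho)
        for name in PLANTED_EFFECTS:
            if name in model.features:
                sel_counts[name] += 1
        tr = plan.train
        for name, sign in PLANTED_EFFECTS.items():
            others = [n for n in PLANTED_EFFECTS if n != name]
            controls = table.iloc[tr][others].to_numpy(dtype=float)
            rho, _ = regression.partial_spearman(
                table[name].to_numpy(dtype=float)[tr], target[tr], controls
            )
            sign_total += 1
            if np.sign(rho) == np.sign(sign):
                sign_hits += 1
    return {
        "selection_counts": sel_counts,
        "n_replicates": n_replicates,
        "sign_match_fraction": sign_hits / sign_total,
        "median_validation_rho": float(np.median(rhos)),
        "n_windows": len(table),
    }
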