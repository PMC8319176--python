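"""Statistical validation harnesses over the synthetic generators.

Each function runs many seeded replicates of a generator -> pipeline-stage
round trip and reports a recovery or error rate.  They exist so that test
suite and reproduction scripts measure exactly the same procedure.
"""

from __future__ import annotations

import numpy as np

from .annotate import (
    assign_head_group,
    build_acyl_library,
    infer_label_count,
    match_neutral_losses,
    propose_structure,
    N15_MASS_SHIFT,
)
from .compgen import PhenotypePartition, run_screen
from .formula import format_formula
from .metag import dunn_posthoc, kruskal_wallis
from .simulate import simulate_genomes, simulate_lipid_spectra

__all__ = [
    "recover_structure",
    "structure_recovery_rate",
    "label_recovery_rate",
    "causal_og_recovery_rate",
    "permutation_unique_sizes",
    "kruskal_type1_rate",
    "dunn_power_rate",
]


def recover_structure(spectra, nitrogen_count=None, tolerance_ppm=20.0, library=None):
    """Top structure hypothesis from a simulated MS1/MS2/MS3 spectrum set.

    Neutral losses are matched in an absolute-Da window equivalent to
    ``tolerance_ppm`` at the precursor (a loss is a difference of two
    measured m/z values, so its absolute error is set by the heavier ions).
    Returns the top :class:`LipidHypothesis` or None.
    """
    library = library or build_acyl_library(range(10, 23), range(0, 4), (0, 1))
    ms2 = next(s for s in spectra if s.level == 2)
    ms3 = next(s for s in spectra if s.level == 3)
    losses = match_neutral_losses(
        ms2, library, tolerance_da=tolerance_ppm * 1e-6 * ms2.precursor_mz
    )
    heads = assign_head_group(ms3, (100.0, 200.0), tolerance_ppm=tolerance_ppm)
    candidates = [c for cands in heads.values() for c in cands]
    try:
        hypotheses = propose_structure(
            ms2.precursor_mz, losses, candidates,
            nitrogen_count=nitrogen_count, tolerance_ppm=tolerance_ppm,
        )
    except ValueError:
        return None
    return hypotheses[0] if hypotheses else None


def structure_recovery_rate(
    n_replicates: int = 200,
    seed: int = 0,
    ppm_sigma: float = 5.0,
    n_decoys: int = 20,
    tolerance_ppm: float = 20.0,
) -> float:
    """Fraction of noisy synthetic lipids whose true structure ranks first."""
    rng = np.random.default_rng([seed, 101])
    seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    library = build_acyl_library(range(10, 23), range(0, 4), (0, 1))
    hits = 0
    for rep_seed in seeds:
        spectra, truth = simulate_lipid_spectra(
            ppm_sigma=ppm_sigma, n_decoys=n_decoys, seed=int(rep_seed)
        )
        top = recover_structure(
            spectra,
            nitrogen_count=truth.payload["n_nitrogens"],
            tolerance_ppm=tolerance_ppm,
            library=library,
        )
        if top is None:
            continue
        if (
            (top.amide_acyl.c, top.amide_acyl.d, top.amide_acyl.x)
            == tuple(truth.payload["amide_acyl"])
            and (top.ester_acyl.c, top.ester_acyl.d, top.ester_acyl.x)
            == tuple(truth.payload["ester_acyl"])
            and format_formula(top.head_group_neutral) == truth.payload["head_formula"]
        ):
            hits += 1
    return hits / n_replicates


def label_recovery_rate(
    n_replicates: int = 100,
    seed: int = 0,
    ppm_sigma: float = 5.0,
    max_mz: float = 1000.0,
) -> float:
    """Fraction of simulated labelling experiments with the true N count.

    Unlabelled and labelled m/z each carry independent Gaussian relative
    error; at ppm_sigma <= 5 and m/z <= 1000 the shift error is millidaltons
    against a 0.5 Da rounding boundary, so recovery should be total.
    """
    rng = np.random.default_rng([seed, 103])
    hits = 0
    for _ in range(n_replicates):
        true_mz = float(rng.uniform(200.0, max_mz))
        n_true = int(rng.integers(0, 4))
        obs_u = true_mz * (1 + rng.normal(0, ppm_sigma) * 1e-6)
        obs_l = (true_mz + n_true * N15_MASS_SHIFT) * (1 + rng.normal(0, ppm_sigma) * 1e-6)
        if obs_l < obs_u:  # n=0 plus noise can give a tiny negative shift
            obs_u, obs_l = obs_l, obs_u
        count, _residual = infer_label_count(obs_u, obs_l)
        hits += count == n_true
    return hits / n_replicates


def causal_og_recovery_rate(
    n_cohorts: int = 50,
    seed: int = 0,
    leaky_nonproducer: bool = False,
    n_background_ogs: int = 1000,
) -> float:
    """Fraction of synthetic cohorts whose planted causal OG is the screen's
    sole keyword candidate.

    With ``leaky_nonproducer`` the causal OG is additionally planted into one
    non-producer, which under strict presence/absence logic must drop
    recovery to zero.
    """
    rng = np.random.default_rng([seed, 107])
    seeds = rng.integers(0, 2**31 - 1, size=n_cohorts)
    hits = 0
    for cohort_seed in seeds:
        records, truth = simulate_genomes(
            n_background_ogs=n_background_ogs, seed=int(cohort_seed)
        )
        if leaky_nonproducer:
            leak = records.iloc[:1].copy()
            leak["gene_id"] = "gene_leak"
            leak["genome_id"] = truth.payload["non_producers"][0]
            leak["og_id"] = truth.payload["causal_og"]
            leak["annotation"] = "acyltransferase family protein"
            import pandas as pd

            records = pd.concat([records, leak], ignore_index=True)
        partition = PhenotypePartition(
            producers=truth.payload["producers"],
            non_producers=truth.payload["non_producers"],
        )
        report = run_screen(records, partition)
        candidates = [og for og, _a, _t in report.keyword_candidates]
        hits += candidates == [truth.payload["causal_og"]]
    return hits / n_cohorts


def permutation_unique_sizes(
    n_permutations: int = 100,
    seed: int = 0,
    n_background_ogs: int = 1000,
) -> tuple[int, list[int]]:
    """Producer-unique set size under the true labels vs shuffled labels.

    Returns (unshuffled size, list of sizes under label permutations).
    Random phenotype labellings should almost never isolate OGs as cleanly
    as the true partition, so the permutation median sits far below.
    """
    records, truth = simulate_genomes(n_background_ogs=n_background_ogs, seed=seed)
    producers = truth.payload["producers"]
    non_producers = truth.payload["non_producers"]
    genomes = producers + non_producers
    true_partition = PhenotypePartition(producers, non_producers)
    true_size = len(run_screen(records, true_partition).producer_unique)
    rng = np.random.default_rng([seed, 109])
    sizes = []
    for _ in range(n_permutations):
        shuffled = list(genomes)
        rng.shuffle(shuffled)
        partition = PhenotypePartition(
            producers=shuffled[: len(producers)],
            non_producers=shuffled[len(producers):],
        )
        sizes.append(len(run_screen(records, partition).producer_unique))
    return true_size, sizes


def kruskal_type1_rate(
    n_sims: int = 2000,
    seed: int = 0,
    n_per_group: int = 30,
    alpha: float = 0.05,
) -> float:
    """Null rejection rate of the Kruskal-Wallis test (two equal groups)."""
    rng = np.random.default_rng([seed, 113])
    rejections = 0
    for _ in range(n_sims):
        a = rng.lognormal(0.0, 1.0, size=n_per_group)
        b = rng.lognormal(0.0, 1.0, size=n_per_group)
        _h, p = kruskal_wallis([a, b])
        rejections += p < alpha
    return rejections / n_sims


def dunn_power_rate(
    n_runs: int = 200,
    seed: int = 0,
    n_per_group: int = 30,
    shift_sd: float = 5.0,
    alpha: float = 0.05,
) -> float:
    """Fraction of runs where Dunn/Holm flags both comparisons against a
    group shifted by ``shift_sd`` standard deviations (3 groups)."""
    rng = np.random.default_rng([seed, 127])
    hits = 0
    for _ in range(n_runs):
        a = rng.normal(0.0, 1.0, size=n_per_group)
        b = rng.normal(0.0, 1.0, size=n_per_group)
        c = rng.normal(shift_sd, 1.0, size=n_per_group)
        pairwise = dunn_posthoc([a, b, c], labels=["a", "b", "c"])
        flagged = {
            frozenset((i, j)) for i, j, _z, _p, adj in pairwise if adj < alpha
        }
        hits += {frozenset(("a", "c")), frozenset(("b", "c"))} <= flagged
    return hits / n_runs
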