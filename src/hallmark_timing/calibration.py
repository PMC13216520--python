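"""Type-I-error and power checks of the association statistics.

These routines run the contingency/logistic machinery over many freshly
simulated cohorts: under the null (both groups share one generative
setting) the adjusted-significance rate should stay near the nominal
level; with a planted relative-risk enrichment of one dominant CN
signature the pipeline should detect it nearly always.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .signatures import dominant_from_exposures
from .simulate import CohortConfig, generate_cohort, generate_null_cohort
from .stats import contingency_results, feature_enrichment


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def null_false_positive_rates(
    n_repeats: int = 200,
    n_per_group: int = 100,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Fraction of adjusted-significant calls per family on null cohorts.

    Contingency family: per-signature dominant-CN tests with BH.
    Logistic family: per-feature odds ratios with Bonferroni.
    Mutations are not generated (the two families under test use only the
    exposure matrix and the feature table).
    """
    n_cont = k_cont = n_logit = k_logit = 0
    for s in _child_seeds(seed, n_repeats):
        cfg = CohortConfig(n_egi=n_per_group, n_lgi=n_per_group,
                           muts_per_hallmark_mean=0.0, seed=int(s))
        cohort = generate_null_cohort(cfg)
        calls = dominant_from_exposures(cohort.cn_exposures)
        for r in contingency_results(cohort.truth_labels, calls, kind="CN"):
            n_cont += 1
            k_cont += r.p_adj < alpha
        for r in feature_enrichment(cohort.features.data, cohort.truth_labels,
                                    alpha=alpha):
            if np.isfinite(r.p_adj):
                n_logit += 1
                k_logit += r.p_adj < alpha
    return {
        "fpr_contingency": k_cont / n_cont,
        "fpr_logistic": k_logit / n_logit,
        "n_contingency_tests": n_cont,
        "n_logistic_tests": n_logit,
    }


def planted_enrichment_power(
    n_repeats: int = 200,
    n_per_group: int = 300,
    relative_risk: float = 3.0,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Detection rate of a planted dominant-signature enrichment.

    One CN signature's dominance probability is ``relative_risk`` times
    higher in EGI than in LGI; detection means its BH-adjusted contingency
    p falls below alpha.
    """
    p_lgi = 0.10
    p_egi = p_lgi * relative_risk
    others = ("CN1", "CN11", "CN18")
    probs_egi = {"CN17": p_egi} | {s: (1 - p_egi) / len(others) for s in others}
    probs_lgi = {"CN17": p_lgi} | {s: (1 - p_lgi) / len(others) for s in others}
    detected = 0
    for s in _child_seeds(seed, n_repeats):
        cfg = CohortConfig(
            n_egi=n_per_group, n_lgi=n_per_group, muts_per_hallmark_mean=0.0,
            cn_dominant_probs_egi=probs_egi, cn_dominant_probs_lgi=probs_lgi,
            seed=int(s))
        cohort = generate_cohort(cfg)
        calls = dominant_from_exposures(cohort.cn_exposures)
        rows = {r.feature: r for r in
                contingency_results(cohort.truth_labels, calls, kind="CN")}
        if "CN17" in rows and rows["CN17"].p_adj < alpha:
            detected += 1
    return detected / n_repeats
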