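"""Synthetic tumor cohorts with known early/late genome-instability structure.

The generator plants every feature the pipeline later has to recover:

* two patient groups (EGI / LGI) whose hallmark VAF *orderings* differ —
  genome instability ranked first in EGI, late in LGI, with the
  immune-evasion and inflammation hallmarks acquiring high (early) VAF in
  LGI instead;
* group-dependent SBS signature mixtures, from which trinucleotide-context
  substitutions are sampled against a reference catalog;
* one planted dominant copy-number signature per patient, encoded as an
  exposure row whose argmax is that signature;
* Gaussian per-patient immune/stemness features with group-shifted means.

Default magnitudes follow the study conditions: 200 patients per group and
per-hallmark mean-VAF differences between groups of at most ~0.05.  Gene
names are synthesized as ``<HALLMARK>_g<k>`` and the matching hallmark map
is emitted alongside, so no external gene annotation is needed.  Everything
is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .channels import SBS96_CHANNELS, channel_parts, reverse_complement
from .io import (
    CANONICAL_HALLMARKS,
    ExposureMatrix,
    FeatureTable,
    HallmarkMap,
    MutationRecord,
    SignatureCatalog,
    write_matrix,
)

EGI = "EGI"
LGI = "LGI"

#: Default hallmark acquisition orders (earliest first).  Genome instability
#: leads in EGI; in LGI the immune-evasion/inflammation hallmarks lead and
#: genome instability drops to rank 5 (a four-rank shift, i.e. ~0.05 VAF).
DEFAULT_ORDER_EGI = (
    "genome_instability", "proliferation", "growth_suppressors", "apoptosis",
    "immune_evasion", "inflammation", "immortality", "angiogenesis",
    "invasion_metastasis", "energetics",
)
DEFAULT_ORDER_LGI = (
    "immune_evasion", "inflammation", "proliferation", "growth_suppressors",
    "genome_instability", "apoptosis", "immortality", "angiogenesis",
    "invasion_metastasis", "energetics",
)

#: Rank-indexed mean VAFs: rank 1 (earliest) = 0.35, step 0.0125, so a
#: four-rank shift between groups moves a hallmark's mean by 0.05.
DEFAULT_VAF_BASE = tuple(0.35 - 0.0125 * k for k in range(10))

DEFAULT_SBS_WEIGHTS_EGI = {"SBS_A": 0.55, "SBS_B": 0.30, "SBS_C": 0.15}
DEFAULT_SBS_WEIGHTS_LGI = {"SBS_A": 0.25, "SBS_B": 0.15, "SBS_D": 0.60}

DEFAULT_CN_PROBS_EGI = {"CN1": 0.10, "CN11": 0.20, "CN17": 0.40, "CN18": 0.15, "CN19": 0.15}
DEFAULT_CN_PROBS_LGI = {"CN1": 0.45, "CN11": 0.15, "CN17": 0.10, "CN18": 0.15, "CN19": 0.15}

#: feature -> (mean_EGI, mean_LGI, sd); directions follow the planted
#: biology (resting mast cells / CD8 T cells higher in LGI, activated mast
#: cells / stemness / EMT / aneuploidy / HRD higher in EGI).
DEFAULT_FEATURE_EFFECTS: dict[str, tuple[float, float, float]] = {
    "mast_cells_resting": (0.10, 0.16, 0.12),
    "mast_cells_activated": (0.16, 0.10, 0.12),
    "cd8_t_cells": (0.12, 0.17, 0.10),
    "stemness_mrna_index": (0.55, 0.47, 0.15),
    "emt_creighton": (0.15, 0.00, 0.30),
    "aneuploidy_score": (13.0, 10.0, 6.0),
    "hrd_score": (26.0, 19.0, 14.0),
}


def synthetic_catalog(
    signatures: tuple[str, ...] = ("SBS_A", "SBS_B", "SBS_C", "SBS_D"),
    channels_per_signature: int = 10,
    seed: int = 20240117,
) -> SignatureCatalog:
    """Build a synthetic SBS reference catalog with sparse, well-separated
    spectra.

    Each signature concentrates its mass on ``channels_per_signature``
    disjoint channels (plus a small uniform floor), giving large pairwise L1
    distances so that mixture refitting is well-posed.  Deterministic for a
    given seed; the spectra are synthetic constructs, not measured signature
    data.
    """
    rng = np.random.default_rng(seed)
    n = len(signatures)
    if n * channels_per_signature > 96:
        raise ValueError("too many signatures for disjoint channel support")
    perm = rng.permutation(96)
    cols = {}
    for i, name in enumerate(signatures):
        support = perm[i * channels_per_signature : (i + 1) * channels_per_signature]
        spec = np.full(96, 1e-4)
        spec[support] += rng.dirichlet(np.full(channels_per_signature, 2.0))
        cols[name] = spec / spec.sum()
    df = pd.DataFrame(cols, index=list(SBS96_CHANNELS))
    return SignatureCatalog(df)


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic cohort generator (see module docstring)."""

    n_egi: int = 200
    n_lgi: int = 200
    hallmark_order_egi: tuple[str, ...] = DEFAULT_ORDER_EGI
    hallmark_order_lgi: tuple[str, ...] = DEFAULT_ORDER_LGI
    vaf_base: tuple[float, ...] = DEFAULT_VAF_BASE
    vaf_noise_sd: float = 0.012
    vaf_concentration: float = 120.0  # Beta concentration of per-mutation jitter
    muts_per_hallmark_mean: float = 12.0  # Poisson mean per patient per hallmark
    genes_per_hallmark: int = 20
    sbs_weights_egi: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SBS_WEIGHTS_EGI))
    sbs_weights_lgi: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SBS_WEIGHTS_LGI))
    cn_dominant_probs_egi: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CN_PROBS_EGI))
    cn_dominant_probs_lgi: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CN_PROBS_LGI))
    feature_effects: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_EFFECTS))
    catalog: SignatureCatalog | None = None
    seed: int = 123

    def __post_init__(self) -> None:
        hs = set(CANONICAL_HALLMARKS)
        for name, order in (("egi", self.hallmark_order_egi), ("lgi", self.hallmark_order_lgi)):
            if sorted(order) != sorted(hs):
                raise ValueError(
                    f"hallmark_order_{name} is not a permutation of the 10 hallmarks")
        base = np.asarray(self.vaf_base)
        if len(base) != 10 or not np.all(np.diff(base) < 0):
            raise ValueError("vaf_base must be 10 strictly decreasing values")
        if not (0 < base.min() and base.max() < 1):
            raise ValueError("vaf_base values must lie in (0, 1)")
        if self.vaf_noise_sd < 0:
            raise ValueError("vaf_noise_sd must be >= 0")
        for tag, w in (("egi", self.sbs_weights_egi), ("lgi", self.sbs_weights_lgi),
                       ("egi", self.cn_dominant_probs_egi), ("lgi", self.cn_dominant_probs_lgi)):
            if abs(sum(w.values()) - 1.0) > 1e-9:
                raise ValueError(f"{tag} mixture weights must sum to 1")

    def resolved_catalog(self) -> SignatureCatalog:
        if self.catalog is not None:
            return self.catalog
        names = tuple(sorted(set(self.sbs_weights_egi) | set(self.sbs_weights_lgi)))
        return synthetic_catalog(signatures=names)


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort plus every piece of ground truth about it."""

    mutations: list[MutationRecord]
    cn_exposures: ExposureMatrix
    features: FeatureTable
    truth_labels: dict[str, str]                 # sample_id -> EGI/LGI
    truth_weights: dict[str, dict[str, float]]   # sample_id -> SBS mixture
    truth_hallmark_means: pd.DataFrame           # latent per-patient hallmark mean VAFs
    truth_dominant_cn: dict[str, str]            # sample_id -> planted dominant CN
    hallmark_map: HallmarkMap
    catalog: SignatureCatalog


def _hallmark_means(
    order: tuple[str, ...], base: np.ndarray, noise_sd: float, rng: np.random.Generator
) -> pd.Series:
    means = pd.Series(index=list(CANONICAL_HALLMARKS), dtype=float)
    for rank0, hm in enumerate(order):
        means[hm] = base[rank0]
    noisy = means.to_numpy() + rng.normal(0.0, noise_sd, size=10)
    return pd.Series(np.clip(noisy, 0.01, 0.99), index=means.index)


def _sample_vafs(mean: float, n: int, conc: float, rng: np.random.Generator) -> np.ndarray:
    a = mean * conc
    b = (1.0 - mean) * conc
    return np.clip(rng.beta(a, b, size=n), 0.01, 0.99)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort from ``config`` (seed-deterministic).

    Per patient the latent hallmark mean VAFs are the rank-indexed base
    values permuted by the group's order plus truncated Gaussian noise;
    per-mutation VAFs are Beta jitter around the hallmark mean; substitution
    channels are sampled from the 96-channel distribution implied by the
    group's SBS mixture; one dominant CN signature is planted per patient;
    features are Gaussian with group means.
    """
    rng = np.random.default_rng(config.seed)
    catalog = config.resolved_catalog()
    cat_arr = catalog.data.to_numpy()

    group_specs = {}
    for grp, weights in ((EGI, config.sbs_weights_egi), (LGI, config.sbs_weights_lgi)):
        w = np.zeros(len(catalog.signatures))
        for name, val in weights.items():
            if name not in catalog.signatures:
                raise ValueError(f"signature {name} not in catalog")
            w[catalog.signatures.index(name)] = val
        group_specs[grp] = cat_arr @ w

    cn_sigs = tuple(sorted(set(config.cn_dominant_probs_egi) | set(config.cn_dominant_probs_lgi)))
    base = np.asarray(config.vaf_base, dtype=float)

    mutations: list[MutationRecord] = []
    truth_labels: dict[str, str] = {}
    truth_weights: dict[str, dict[str, float]] = {}
    truth_dominant_cn: dict[str, str] = {}
    means_rows = {}
    exposure_rows = {}
    feature_rows = {}
    pos_counter = 1

    plan = [(EGI, i, config.hallmark_order_egi, config.sbs_weights_egi,
             config.cn_dominant_probs_egi) for i in range(config.n_egi)]
    plan += [(LGI, i, config.hallmark_order_lgi, config.sbs_weights_lgi,
              config.cn_dominant_probs_lgi) for i in range(config.n_lgi)]

    for grp, i, order, sbs_w, cn_probs in plan:
        sid = f"{grp}_{i + 1:04d}"
        truth_labels[sid] = grp
        truth_weights[sid] = dict(sbs_w)
        means = _hallmark_means(order, base, config.vaf_noise_sd, rng)
        means_rows[sid] = means

        # mutations: per hallmark, Poisson count, Beta VAF jitter, channel
        # sampled from the group mixture spectrum
        for hm in CANONICAL_HALLMARKS:
            n_mut = rng.poisson(config.muts_per_hallmark_mean)
            if n_mut == 0:
                continue
            vafs = _sample_vafs(means[hm], n_mut, config.vaf_concentration, rng)
            chans = rng.choice(96, size=n_mut, p=group_specs[grp])
            gene_ids = rng.integers(1, config.genes_per_hallmark + 1, size=n_mut)
            flip = rng.random(n_mut) < 0.5  # emit half on the purine strand
            for j in range(n_mut):
                five, ref, alt, three = channel_parts(SBS96_CHANNELS[chans[j]])
                ctx = five + ref + three
                if flip[j]:
                    ctx = reverse_complement(ctx)
                    ref = reverse_complement(ref)
                    alt = reverse_complement(alt)
                mutations.append(MutationRecord(
                    sample_id=sid,
                    gene=f"{hm.upper()}_g{gene_ids[j]}",
                    chrom="1",
                    pos=pos_counter,
                    ref=ref,
                    alt=alt,
                    vaf=float(vafs[j]),
                    context3=ctx,
                ))
                pos_counter += 1

        # dominant CN signature encoded as an exposure row with argmax there
        probs = np.array([cn_probs.get(s, 0.0) for s in cn_sigs])
        dom = cn_sigs[rng.choice(len(cn_sigs), p=probs)]
        truth_dominant_cn[sid] = dom
        dom_val = rng.uniform(0.55, 0.90)
        rest = rng.dirichlet(np.ones(len(cn_sigs) - 1)) * (1.0 - dom_val)
        row = {}
        k = 0
        for s in cn_sigs:
            if s == dom:
                row[s] = dom_val
            else:
                row[s] = rest[k]
                k += 1
        exposure_rows[sid] = row

        feature_rows[sid] = {
            name: rng.normal(mu_egi if grp == EGI else mu_lgi, sd)
            for name, (mu_egi, mu_lgi, sd) in config.feature_effects.items()
        }

    hm_map = HallmarkMap(entries={
        f"{hm.upper()}_g{k}": frozenset({hm})
        for hm in CANONICAL_HALLMARKS
        for k in range(1, config.genes_per_hallmark + 1)
    })

    sample_ids = list(truth_labels)
    return SyntheticCohort(
        mutations=mutations,
        cn_exposures=ExposureMatrix(
            pd.DataFrame.from_dict(exposure_rows, orient="index")
            .reindex(index=sample_ids, columns=list(cn_sigs)),
            kind="CN",
        ),
        features=FeatureTable(
            pd.DataFrame.from_dict(feature_rows, orient="index").reindex(sample_ids)
        ),
        truth_labels=truth_labels,
        truth_weights=truth_weights,
        truth_hallmark_means=pd.DataFrame.from_dict(means_rows, orient="index").reindex(sample_ids),
        truth_dominant_cn=truth_dominant_cn,
        hallmark_map=hm_map,
        catalog=catalog,
    )


def generate_null_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a cohort whose two groups share identical generative
    settings (EGI's order, mixtures and feature means applied to both),
    while group labels are still recorded — the null for calibration."""
    null_cfg = replace(
        config,
        hallmark_order_lgi=config.hallmark_order_egi,
        sbs_weights_lgi=dict(config.sbs_weights_egi),
        cn_dominant_probs_lgi=dict(config.cn_dominant_probs_egi),
        feature_effects={
            name: (mu_egi, mu_egi, sd)
            for name, (mu_egi, _mu_lgi, sd) in config.feature_effects.items()
        },
    )
    return generate_cohort(null_cfg)


# ---------------------------------------------------------------------------
# on-disk emission (consumed by the CLI)
# ---------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as the TSV files the pipeline reads, plus truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": outdir / "mutations.tsv",
        "hallmark_map": outdir / "hallmark_map.tsv",
        "catalog": outdir / "sbs_catalog.tsv",
        "cn_exposures": outdir / "cn_exposures.tsv",
        "features": outdir / "features.tsv",
        "truth": outdir / "truth.tsv",
    }
    pd.DataFrame(
        [(m.sample_id, m.gene, m.chrom, m.pos, m.ref, m.alt, m.vaf, m.context3)
         for m in cohort.mutations],
        columns=["sample_id", "gene", "chrom", "pos", "ref", "alt", "vaf", "context3"],
    ).to_csv(paths["mutations"], sep="\t", index=False, float_format="%.17g")
    pd.DataFrame(
        [(g, h) for g, hs in sorted(cohort.hallmark_map.entries.items()) for h in sorted(hs)],
        columns=["gene", "hallmark"],
    ).to_csv(paths["hallmark_map"], sep="\t", index=False)
    cohort.catalog.data.to_csv(paths["catalog"], sep="\t", index_label="channel",
                               float_format="%.17g")
    write_matrix(cohort.cn_exposures.data, paths["cn_exposures"])
    write_matrix(cohort.features.data, paths["features"])
    truth = pd.DataFrame({
        "sample_id": list(cohort.truth_labels),
        "group": list(cohort.truth_labels.values()),
        "dominant_cn": [cohort.truth_dominant_cn[s] for s in cohort.truth_labels],
    })
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
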