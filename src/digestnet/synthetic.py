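"""Synthetic digester communities with known (planted) structure.

The generator emulates the statistical structure of a 43-digester survey:

* two sample clusters with distinct dominant taxa — Cluster I top-heavy
  (a few *Clostridium*-like core OTUs absorbing much of the mass, hence
  lower Shannon diversity), Cluster II more even, enriched in
  Spirochaetes/Bacteroidales analogues and methanogens;
* a planted core set present in essentially every sample, while every
  non-core OTU stays at or below the 90 % prevalence line (so prevalence
  classification is exactly recoverable);
* planted co-occurrence modules: each module's members share one latent
  log-normal factor per sample, so their abundances co-vary strongly
  (target within-module Spearman rho above the 0.6 edge threshold) while
  drifting in and out of individual samples (cosmopolitan but not core);
* four environmental covariates (NH4+-N, pH, COD, phosphate) with an
  NH4+-N / phosphate positive correlation and linear loadings on
  designated OTU blocks;
* counts drawn Dirichlet-multinomial at uniform depth (default 2230),
  giving realistic overdispersion relative to a plain multinomial;
* a random Kingman-coalescent phylogeny over the OTUs (module members are
  deliberately NOT clades).

All randomness flows from the single ``seed`` through one numpy generator.
The generated objects pass every container validation, and the ground
truth (cluster labels, module membership, core set, environmental effect
sizes) is returned for recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import OtuTable, SampleMetadata, TaxonomyMap

__all__ = [
    "SyntheticTruth",
    "SyntheticCommunity",
    "generate_community",
    "generate_segregated_presence",
    "export_truth",
    "read_truth",
]

_CORE_GENERA = [
    ("Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae", "Clostridium"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Peptostreptococcaceae", "Clostridium_XI"),
    ("Firmicutes", "Bacilli", "Erysipelotrichales", "Turicibacteraceae", "Turicibacter"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Syntrophomonadaceae", "Syntrophomonas"),
    ("Synergistetes", "Synergistia", "Synergistales", "Synergistaceae", "Cloacibacillus"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Peptococcaceae", "Sedimentibacter"),
    ("Chloroflexi", "Anaerolineae", "Anaerolineales", "Anaerolinaceae", "unclassified"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Tissierellaceae", "Tissierella"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Eubacteriaceae", "Anaerovorax"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Ruminococcus"),
]

_CLUSTER2_LINEAGES = [
    ("Spirochaetes", "Spirochaetia", "Spirochaetales", "Sphaerochaetaceae", "Sphaerochaeta"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Porphyromonadaceae", "unclassified"),
    ("Spirochaetes", "Spirochaetia", "Spirochaetales", "Spirochaetaceae", "Treponema"),
    ("Spirochaetes", "Spirochaetia", "Spirochaetales", "Cloacamonaceae", "Candidatus_Cloacamonas"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides"),
    ("Euryarchaeota", "Methanomicrobia", "Methanosarcinales", "Methanosaetaceae", "Methanosaeta"),
    ("Euryarchaeota", "Methanomicrobia", "Methanomicrobiales", "Methanocorpusculaceae", "Methanocorpusculum"),
    ("Euryarchaeota", "Methanomicrobia", "Methanomicrobiales", "Methanomicrobiaceae", "Methanoculleus"),
    ("Euryarchaeota", "Methanomicrobia", "Methanomicrobiales", "Methanomicrobiaceae", "Methanogenium"),
    ("Proteobacteria", "Deltaproteobacteria", "Syntrophobacterales", "Syntrophaceae", "Syntrophus"),
]

_MODULE_LINEAGES = [
    ("Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "unclassified"),
    ("Bacteroidetes", "Bacteroidia", "Bacteroidales", "unclassified", "unclassified"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Oscillospira"),
    ("Spirochaetes", "Spirochaetia", "Spirochaetales", "Sphaerochaetaceae", "Sphaerochaeta"),
    ("Actinobacteria", "Coriobacteriia", "Coriobacteriales", "Coriobacteriaceae", "unclassified"),
    ("Tenericutes", "Mollicutes", "Anaeroplasmatales", "Anaeroplasmataceae", "unclassified"),
]

_LOCATIONS_I = ["Pengzhou", "Deyang", "Jitian", "Gejiu", "Lanzhou"]
_LOCATIONS_II = ["Mianyang", "Leshan", "Neijiang", "Dali", "Kunming",
                 "Guiyang", "Zunyi", "Nanning", "Xian", "Wuhan"]
_SUBSTRATES = ["swine", "cattle", "human", "poultry", "mixed"]

DEFAULT_ENV_EFFECTS = {"NH4N": 0.45, "pH": 0.35, "COD": 0.35, "phosphate": 0.15}


@dataclass
class SyntheticTruth:
    """Planted ground truth of one synthetic community."""

    cluster_of_sample: dict[str, str]
    module_of_otu: dict[str, int | None]
    core_set: list[str]
    env_effects: dict[str, float]
    seed: int

    def module_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for otu, m in self.module_of_otu.items():
            if m is not None:
                out.setdefault(int(m), []).append(otu)
        return {m: sorted(v) for m, v in sorted(out.items())}

    def __eq__(self, other) -> bool:
        if not isinstance(other, SyntheticTruth):
            return NotImplemented
        return asdict(self) == asdict(other)


@dataclass
class SyntheticCommunity:
    table: OtuTable
    taxonomy: TaxonomyMap
    metadata: SampleMetadata
    tree: TreeNode
    truth: SyntheticTruth


def _random_coalescent_tree(otu_ids: list[str], rng: np.random.Generator) -> TreeNode:
    """Kingman-coalescent-style random rooted tree over the OTUs."""
    nodes = [TreeNode(name=str(o), length=None) for o in otu_ids]
    heights = [0.0] * len(nodes)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = nodes[i], nodes[j]
        a.length = t - heights[i]
        b.length = t - heights[j]
        parent = TreeNode(children=[a, b])
        nodes[j] = parent  # keep list compact
        heights[j] = t
        del nodes[i], heights[i]
    root = nodes[0]
    root.length = None
    return root


def generate_community(
    n_samples_I: int = 16,
    n_samples_II: int = 27,
    n_otus: int = 300,
    n_modules: int = 6,
    module_size: int = 15,
    n_core: int = 10,
    depth: int = 2230,
    cluster_separation: float = 1.0,
    module_factor_sd: float = 1.5,
    env_effect_sizes: dict[str, float] | None = None,
    dirichlet_concentration: float = 500.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    max_attempts: int = 20,
    core_threshold: float = 0.90,
    cosmopolitan_threshold: float = 0.5,
    enforce_prevalence: bool = True,
) -> SyntheticCommunity:
    """Generate one synthetic community with planted structure.

    Per-sample composition is the softmax of cluster baseline + module
    latent factors + environmental loadings + Gaussian noise; counts are
    Dirichlet-multinomial at ``depth``. The draw is repeated (bounded by
    *max_attempts*, each attempt with a fresh substream of the same seed)
    until the realized table satisfies the planted prevalence contract:
    every core OTU strictly above *core_threshold* prevalence, every
    non-core OTU at or below it, and every module OTU cosmopolitan.
    Setting ``cluster_separation=0``, ``module_factor_sd=0`` and zero
    ``env_effect_sizes`` yields fully exchangeable samples (a null
    community for permutation-test calibration).

    The prevalence contract needs a survey-sized sample count to leave a
    gap between the core and non-core strata (at 16 samples the >90 % line
    sits between 14/16 and 15/16, which moderately prevalent OTUs cross
    constantly); ``enforce_prevalence=False`` skips it for reduced
    fixtures where only the cluster/module structure matters.
    """
    if n_core + n_modules * module_size + 23 > n_otus:
        raise ValueError("n_otus too small for the requested planted blocks")
    env_effects = dict(DEFAULT_ENV_EFFECTS if env_effect_sizes is None else env_effect_sizes)
    master = np.random.default_rng(seed)
    structural = enforce_prevalence and (
        cluster_separation != 0 or module_factor_sd != 0
        or any(v != 0 for v in env_effects.values())
    )
    last_err = None
    for _ in range(max_attempts):
        attempt_seed = int(master.integers(2**31 - 1))
        community = _generate_once(
            n_samples_I, n_samples_II, n_otus, n_modules, module_size, n_core,
            depth, cluster_separation, module_factor_sd, env_effects,
            dirichlet_concentration, noise_sd, attempt_seed, seed,
        )
        if not structural:
            return community  # a null community has no prevalence contract
        err = _prevalence_violation(community, core_threshold, cosmopolitan_threshold)
        if err is None:
            return community
        last_err = err
    raise RuntimeError(
        f"could not satisfy planted prevalence targets after {max_attempts} attempts: {last_err}"
    )


def _generate_once(
    n_i, n_ii, n_otus, n_modules, module_size, n_core, depth,
    separation, factor_sd, env_effects, concentration, noise_sd,
    attempt_seed, master_seed,
) -> SyntheticCommunity:
    rng = np.random.default_rng(attempt_seed)
    n = n_i + n_ii
    sample_ids = [f"S{k + 1:02d}" for k in range(n)]
    clusters = np.array(["I"] * n_i + ["II"] * n_ii)

    # --- OTU roles -----------------------------------------------------
    otu_ids = [f"OTU{k + 1}" for k in range(n_otus)]
    core_idx = np.arange(n_core)
    mod_idx = np.arange(n_core, n_core + n_modules * module_size)
    c2_idx = np.arange(mod_idx[-1] + 1, mod_idx[-1] + 16)        # Cluster-II block
    c1_idx = np.arange(c2_idx[-1] + 1, c2_idx[-1] + 9)           # Cluster-I-specific block
    tail_idx = np.arange(c1_idx[-1] + 1, n_otus)
    module_of = np.full(n_otus, -1)
    for m in range(n_modules):
        module_of[mod_idx[m * module_size:(m + 1) * module_size]] = m

    # --- log-intensity baseline & cluster contrast ---------------------
    base = np.full(n_otus, -30.0)  # overwritten for every role below
    delta = np.zeros(n_otus)       # added as +delta in I, -delta in II
    core_common = np.linspace(3.6, 2.0, n_core)
    core_delta = np.concatenate([np.linspace(0.9, 0.35, 4), np.full(n_core - 4, 0.0)])
    base[core_idx] = core_common
    delta[core_idx] = core_delta
    base[mod_idx] = 0.6
    base[c2_idx] = -0.35
    delta[c2_idx] = -2.15
    base[c1_idx] = -0.9
    delta[c1_idx] = 2.1
    tail = rng.normal(-2.2, 0.8, size=tail_idx.size)
    base[tail_idx] = np.minimum(tail, -1.0)

    # --- environmental covariates --------------------------------------
    z_nh4 = rng.normal(0, 1, n) + separation * np.where(clusters == "I", 0.5, -0.3)
    z_phos = 0.75 * z_nh4 + np.sqrt(1 - 0.75**2) * rng.normal(0, 1, n)
    z_ph = rng.normal(0, 1, n)
    z_cod = rng.normal(0, 1, n)
    meta = pd.DataFrame(
        {
            "pH": np.clip(7.2 + 0.35 * z_ph, 6.0, 8.5),
            "COD": np.exp(8.3 + 0.8 * z_cod),
            "NH4N": np.exp(7.0 + 0.55 * z_nh4),
            "phosphate": np.exp(4.0 + 0.5 * z_phos),
            "location": [
                rng.choice(_LOCATIONS_I) if c == "I" else rng.choice(_LOCATIONS_II)
                for c in clusters
            ],
            "substrate": rng.choice(_SUBSTRATES, size=n),
            "cluster": clusters,
        },
        index=sample_ids,
    )

    # --- assemble log-intensities --------------------------------------
    eta = np.tile(base, (n, 1)).astype(float)
    sign = np.where(clusters == "I", 1.0, -1.0)[:, None]
    eta += separation * sign * delta[None, :]
    factors = rng.normal(0, 1, size=(n, n_modules))
    for m in range(n_modules):
        members = mod_idx[m * module_size:(m + 1) * module_size]
        eta[:, members] += factor_sd * factors[:, [m]]
    loading = np.zeros((4, n_otus))  # rows: NH4N, pH, COD, phosphate
    loading[0, core_idx[:4]] = 1.0
    loading[0, c2_idx[-5:]] = -1.0   # methanogen analogues suppressed by ammonium
    loading[1, c2_idx] = 1.0
    loading[2, c1_idx] = 1.0
    if n_modules > 0:
        loading[3, mod_idx[:module_size]] = 1.0
    zs = np.column_stack([z_nh4, z_ph, z_cod, z_phos])
    effs = np.array([env_effects.get(k, 0.0) for k in ("NH4N", "pH", "COD", "phosphate")])
    eta += (zs * effs[None, :]) @ loading
    eta += rng.normal(0, noise_sd, size=eta.shape)

    # --- compositions and counts ---------------------------------------
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    counts = np.empty((n, n_otus), dtype=np.int64)
    for s in range(n):
        w = rng.dirichlet(np.maximum(p[s] * concentration, 1e-8))
        counts[s] = rng.multinomial(depth, w)
    table = OtuTable(pd.DataFrame(counts, index=sample_ids, columns=otu_ids))

    # --- taxonomy -------------------------------------------------------
    lineages: dict[str, dict[str, str]] = {}
    ranks = ("phylum", "class", "order", "family", "genus")
    for k, idx in enumerate(core_idx):
        lineages[otu_ids[idx]] = dict(zip(ranks, _CORE_GENERA[k % len(_CORE_GENERA)]))
    for m in range(n_modules):
        lin = _MODULE_LINEAGES[m % len(_MODULE_LINEAGES)]
        for idx in mod_idx[m * module_size:(m + 1) * module_size]:
            lineages[otu_ids[idx]] = dict(zip(ranks, lin))
    for k, idx in enumerate(c2_idx):
        lineages[otu_ids[idx]] = dict(zip(ranks, _CLUSTER2_LINEAGES[k % len(_CLUSTER2_LINEAGES)]))
    for idx in c1_idx:
        lineages[otu_ids[idx]] = dict(zip(ranks, _CORE_GENERA[0]))
    for idx in tail_idx:
        phylum = rng.choice(["Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria"])
        lineages[otu_ids[idx]] = {"phylum": str(phylum), "class": "unclassified",
                                  "order": "unclassified", "family": "unclassified",
                                  "genus": "unclassified"}
    taxonomy = TaxonomyMap(lineages)

    tree = _random_coalescent_tree(otu_ids, rng)
    truth = SyntheticTruth(
        cluster_of_sample=dict(zip(sample_ids, clusters.tolist())),
        module_of_otu={
            otu_ids[k]: (int(module_of[k]) if module_of[k] >= 0 else None)
            for k in range(n_otus)
        },
        core_set=[otu_ids[k] for k in core_idx],
        env_effects=dict(env_effects),
        seed=master_seed,
    )
    return SyntheticCommunity(table, taxonomy, SampleMetadata(meta), tree, truth)


def _prevalence_violation(community: SyntheticCommunity, core_thr: float, cosmo_thr: float):
    counts = community.table.counts
    prev = (counts > 0).mean(axis=0)
    core = set(community.truth.core_set)
    module_otus = {o for o, m in community.truth.module_of_otu.items() if m is not None}
    low_core = [o for o in core if prev[o] <= core_thr]
    if low_core:
        return f"core OTUs at or below {core_thr}: {low_core}"
    high_noncore = [o for o in prev.index if o not in core and prev[o] > core_thr]
    if high_noncore:
        return f"non-core OTUs above {core_thr}: {high_noncore}"
    rare_module = [o for o in module_otus if prev[o] <= cosmo_thr]
    if rare_module:
        return f"module OTUs not cosmopolitan: {rare_module}"
    return None


def generate_segregated_presence(
    n_species: int = 20, n_sites: int = 24, flip_prob: float = 0.08, seed: int = 0
) -> np.ndarray:
    """Binary species x sites matrix with planted checkerboard segregation.

    Species and sites are split into two halves; a species is present on
    its own half's sites and absent elsewhere, then each cell is flipped
    independently with *flip_prob*. Observed C-score exceeds the
    fixed-margin null expectation with high probability.
    """
    rng = np.random.default_rng(seed)
    half_sp, half_si = n_species // 2, n_sites // 2
    mat = np.zeros((n_species, n_sites), dtype=np.int8)
    mat[:half_sp, :half_si] = 1
    mat[half_sp:, half_si:] = 1
    flips = rng.random(mat.shape) < flip_prob
    mat[flips] = 1 - mat[flips]
    return mat


# ---------------------------------------------------------------------------
# truth round-trip
# ---------------------------------------------------------------------------
def export_truth(truth: SyntheticTruth, path) -> None:
    """Write ground truth as JSON (lossless round-trip via read_truth)."""
    doc = asdict(truth)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        doc = json.load(fh)
    doc["module_of_otu"] = {
        k: (int(v) if v is not None else None) for k, v in doc["module_of_otu"].items()
    }
    return SyntheticTruth(**doc)
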