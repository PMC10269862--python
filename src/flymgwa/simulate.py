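"""Synthetic inputs for every pipeline stage, with planted ground truth.

The generator emulates the study's data shapes without any downloads:

* a strain-structured pangenome: accessory gene presence/absence evolves by
  a two-state gain/loss chain on a random Kingman-coalescent tree, so
  presence patterns are phylogenetically correlated, the accessory
  frequency spectrum is U-shaped, and patterns collapse nontrivially into
  distribution groups;
* planted persistence effects: causal genes form a co-inherited module
  (phylogenetically similar patterns, shared effect direction) plus one
  phylogenetically independent antagonist of opposite sign, mirroring the
  architecture of real pan-genome hits (e.g. an operon lost as a block,
  and one unrelated gene acting the other way);
* fly-level colony counts with lognormal dispersion on the log2(CFU+1)
  scale, a detection ceiling at 160 colonies (128,000 CFU/fly), and
  occasional contaminated or under-populated vials;
* a protein-similarity edge list consistent with a known OG partition
  (for exercising the MCL stage); and
* an OG -> KO -> pathway annotation table with one pathway enriched for a
  designated gene set at a configured odds ratio.

One global seed is split into fixed per-stage child seeds, so each stage
is independently reproducible.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .mgwa import GenePresenceMatrix


class SimulationError(ValueError):
    """Invalid configuration or an unsatisfiable simulation request."""


_STAGES = {"pangenome": 0, "effects": 1, "cfu": 2, "graph": 3, "annotation": 4}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Child generator for one pipeline stage, derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGES[stage],))
    )


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic pipeline.

    Defaults follow the assay design (triplicate vials in each of three
    experiments, four female flies sampled per vial, 160-colony ceiling at
    800 CFU per colony).  ``gain_loss_rate`` is per unit coalescent branch
    length and its default yields a distribution-group/OG compression
    ratio in the 0.2-0.3 range seen in real strain panels.  ``effect_size``, ``baseline_log_cfu``, ``fly_sd`` and
    ``strain_sd`` are all on the log2(CFU+1) scale.
    """

    n_strains: int = 40
    n_ogs: int = 1000
    core_fraction: float = 0.5
    gain_loss_rate: float = 1.0
    n_causal: int = 5
    effect_size: float = 3.0
    baseline_log_cfu: float = 10.0
    fly_sd: float = 1.0
    strain_sd: float = 0.5
    n_experiments: int = 3
    n_vials_per_experiment: int = 3
    n_flies_per_vial: int = 4
    ceiling_colonies: int = 160
    colony_scale: int = 800
    contamination_prob: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_strains < 2:
            raise SimulationError("n_strains must be at least 2")
        if self.n_ogs < 1:
            raise SimulationError("n_ogs must be positive")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise SimulationError("core_fraction must lie in [0, 1]")
        if self.gain_loss_rate < 0:
            raise SimulationError("gain_loss_rate must be nonnegative")
        if self.n_causal < 0 or self.n_causal > self.n_ogs:
            raise SimulationError("n_causal must lie in [0, n_ogs]")
        for name in ("fly_sd", "strain_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be nonnegative")
        if min(self.n_experiments, self.n_vials_per_experiment) < 1:
            raise SimulationError("experiment and vial counts must be positive")
        if self.n_flies_per_vial < 1:
            raise SimulationError("n_flies_per_vial must be at least 1")
        if self.ceiling_colonies < 1 or self.colony_scale < 1:
            raise SimulationError("ceiling_colonies and colony_scale must be positive")
        if not 0.0 <= self.contamination_prob <= 1.0:
            raise SimulationError("contamination_prob must lie in [0, 1]")

    @property
    def ceiling_cfu(self) -> int:
        return self.ceiling_colonies * self.colony_scale

    @property
    def ceiling_log_cfu(self) -> float:
        return math.log2(self.ceiling_cfu + 1)


@dataclass
class SimTruth:
    """Planted ground truth recorded alongside the generated data."""

    causal_ogs: set[str] = field(default_factory=set)
    causal_effects: dict[str, float] = field(default_factory=dict)
    strain_means: dict[str, float] = field(default_factory=dict)
    og_partition: dict[str, str] = field(default_factory=dict)
    enriched_pathways: set[str] = field(default_factory=set)

    def to_json(self, path) -> None:
        payload = {
            "causal_ogs": sorted(self.causal_ogs),
            "causal_effects": dict(sorted(self.causal_effects.items())),
            "strain_means": dict(sorted(self.strain_means.items())),
            "og_partition": dict(sorted(self.og_partition.items())),
            "enriched_pathways": sorted(self.enriched_pathways),
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True)


@dataclass
class StrainTree:
    """Rooted binary coalescent tree over the simulated strains.

    Leaves are numbered 0..n-1 (strain order); internal nodes follow.
    ``children[u]`` lists (child, branch_length) pairs in creation order,
    which also fixes the traversal (and RNG consumption) order of the
    gain/loss process.
    """

    n_leaves: int
    root: int
    children: dict[int, list[tuple[int, float]]]
    leaf_names: list[str]

    def newick(self) -> str:
        def render(u: int) -> str:
            if u < self.n_leaves:
                return self.leaf_names[u]
            parts = [f"{render(c)}:{bl:.6f}" for c, bl in self.children[u]]
            return "(" + ",".join(parts) + ")"

        return render(self.root) + ";"


def strain_names(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def og_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"OG_{i:0{width}d}" for i in range(1, n + 1)]


def sample_coalescent_tree(n: int, rng: np.random.Generator) -> StrainTree:
    """Kingman coalescent over ``n`` leaves (time in units of 2N generations).

    At each step the waiting time is exponential with rate C(k, 2) and a
    uniform pair of active lineages merges.
    """
    names = strain_names(n)
    node_time = {i: 0.0 for i in range(n)}
    active = list(range(n))
    children: dict[int, list[tuple[int, float]]] = {}
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        parent = nxt
        nxt += 1
        node_time[parent] = t
        children[parent] = [(a, t - node_time[a]), (b, t - node_time[b])]
        active = [x for x in active if x not in (a, b)]
        active.append(parent)
    return StrainTree(n, active[0], children, names)


#: Beta(a, a) shape of the per-gene stationary presence probability; a < 1
#: makes the accessory gene-frequency spectrum U-shaped, as in real
#: pangenomes where most accessory genes are either rare or near-universal
STATIONARY_BETA = 0.4


def _gain_loss_states(
    tree: StrainTree, n_ogs: int, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Leaf presence states of ``n_ogs`` genes evolving by gain/loss.

    Each gene follows a two-state Markov chain with total switching rate
    ``rate`` (per unit branch length) and a gene-specific stationary
    presence probability pi ~ Beta(a, a): along a branch of length t the
    parental state is kept with probability exp(-rate * t), otherwise the
    state re-equilibrates to Bernoulli(pi) (a gain or a loss, depending
    on the outcome).  The root state is Bernoulli(pi).

    The walk is a plain preorder recursion and its RNG call order is part
    of the definition: first the pi vector, then the root states, then per
    branch - immediately before its subtree is descended, children in
    creation order - one uniform vector deciding which genes keep the
    parental state and one deciding the re-drawn states.  Re-running with
    the same generator state reproduces the output bit for bit.
    """
    import sys

    states = np.zeros((n_ogs, tree.n_leaves), dtype=bool)
    pi = rng.beta(STATIONARY_BETA, STATIONARY_BETA, size=n_ogs)

    def walk(node: int, state: np.ndarray) -> None:
        if node < tree.n_leaves:
            states[:, node] = state
            return
        for child, length in tree.children[node]:
            keep = rng.random(n_ogs) < math.exp(-rate * length)
            redraw = rng.random(n_ogs) < pi
            walk(child, np.where(keep, state, redraw))

    limit = sys.getrecursionlimit()
    if limit < 2 * tree.n_leaves + 200:
        sys.setrecursionlimit(2 * tree.n_leaves + 200)
    try:
        walk(tree.root, rng.random(n_ogs) < pi)
    finally:
        sys.setrecursionlimit(limit)
    return states


def simulate_pangenome(config: SimConfig) -> tuple[GenePresenceMatrix, StrainTree]:
    """Binary OG x strain matrix with phylogenetically correlated patterns.

    The first ``round(core_fraction * n_ogs)`` OGs are core (present in
    every strain); the rest evolve by gain/loss on a coalescent tree drawn
    for this seed.  Deterministic for a given ``config.seed``.
    """
    config.validate()
    rng = stage_rng(config.seed, "pangenome")
    tree = sample_coalescent_tree(config.n_strains, rng)
    n_core = int(round(config.core_fraction * config.n_ogs))
    n_accessory = config.n_ogs - n_core
    rows = np.ones((config.n_ogs, config.n_strains), dtype=np.int8)
    if n_accessory:
        accessory = _gain_loss_states(tree, n_accessory, config.gain_loss_rate, rng)
        rows[n_core:] = accessory.astype(np.int8)
    data = pd.DataFrame(rows, index=og_names(config.n_ogs), columns=tree.leaf_names)
    data.index.name = "og_id"
    return GenePresenceMatrix(data, provenance="simulated"), tree


def _centered_unit_patterns(patterns: np.ndarray) -> np.ndarray:
    centered = patterns - patterns.mean(axis=1, keepdims=True)
    norms = np.sqrt((centered**2).sum(axis=1, keepdims=True))
    norms[norms == 0] = 1.0
    return centered / norms


def plant_effects(matrix: GenePresenceMatrix, config: SimConfig) -> SimTruth:
    """Select causal OGs and derive expected strain phenotypes.

    Candidates are accessory OGs with strain frequency in [0.2, 0.8], one
    representative per distinct pattern.  For ``n_causal >= 2`` the last
    causal gene is an antagonist: it carries ``-effect_size``, and its
    pattern is the candidate least correlated (in absolute value) with the
    module, which itself is the most strongly co-distributed set of
    ``n_causal - 1`` patterns (all at ``+effect_size``).  Expected strain
    phenotype = baseline + sum of carried effects + Normal(0, strain_sd).
    """
    config.validate()
    rng = stage_rng(config.seed, "effects")
    freq = matrix.frequencies()
    arr = matrix.data.to_numpy(dtype=bool)
    strains = matrix.strains

    truth = SimTruth(og_partition=partition_from_matrix(matrix))

    noise = rng.normal(0.0, config.strain_sd, len(strains))
    if config.n_causal == 0:
        means = config.baseline_log_cfu + noise
        truth.strain_means = dict(zip(strains, means.tolist()))
        return truth

    candidate_idx = []
    seen: set[bytes] = set()
    for i, og in enumerate(matrix.og_ids):
        if not 0.2 <= freq.iloc[i] <= 0.8:
            continue
        if freq.iloc[i] in (0.0, 1.0):
            continue
        key = arr[i].tobytes()
        if key in seen:
            continue
        seen.add(key)
        candidate_idx.append(i)
    if len(candidate_idx) < config.n_causal:
        raise SimulationError(
            f"only {len(candidate_idx)} distinct mid-frequency accessory patterns; "
            "increase n_ogs or gain_loss_rate"
        )

    pool = np.array(candidate_idx)
    unit = _centered_unit_patterns(arr[pool].astype(float))
    corr = unit @ unit.T

    n_module = config.n_causal if config.n_causal < 2 else config.n_causal - 1
    if n_module >= 2:
        # seed pattern: the one with the strongest top-(n_module-1) neighbours
        top = np.sort(corr, axis=1)[:, -(n_module):-1].sum(axis=1)
        seed_row = int(np.argmax(top))
        module_rows = np.argsort(-corr[seed_row], kind="stable")[:n_module]
    else:
        module_rows = np.array([int(rng.integers(len(pool)))])

    chosen_rows = list(module_rows)
    signs = [1.0] * len(module_rows)
    if config.n_causal >= 2:
        rest = np.setdiff1d(np.arange(len(pool)), module_rows)
        mean_abs = np.abs(corr[np.ix_(rest, module_rows)]).mean(axis=1)
        antagonist = int(rest[np.argmin(mean_abs)])
        chosen_rows.append(antagonist)
        signs.append(-1.0)

    chosen = pool[np.array(chosen_rows)]
    effects = config.effect_size * np.array(signs)
    means = config.baseline_log_cfu + arr[chosen].T.astype(float) @ effects + noise

    og_index = matrix.og_ids
    truth.causal_ogs = {og_index[i] for i in chosen}
    truth.causal_effects = {
        og_index[i]: float(e) for i, e in zip(chosen, effects)
    }
    truth.strain_means = dict(zip(strains, means.tolist()))
    return truth


def simulate_cfu(truth: SimTruth, config: SimConfig) -> pd.DataFrame:
    """Fly-level colony-count records for every strain in ``truth``.

    Per fly, log2(CFU+1) is Normal(strain mean, fly_sd) truncated at zero;
    CFU = round(2^x - 1) and the plate count is CFU / colony_scale,
    censored at the ceiling (the stored count is the ceiling itself and
    the record is flagged too dense).  Vial densities are drawn from
    28..60 so the <30-fly exclusion is occasionally exercised, and a vial
    is contaminated with probability ``contamination_prob`` (its undiluted
    aliquots then bear more than 5 unexpected CFU).
    """
    config.validate()
    if not truth.strain_means:
        raise SimulationError("truth carries no strain means")
    rng = stage_rng(config.seed, "cfu")
    rows = []
    for strain in sorted(truth.strain_means):
        mean = truth.strain_means[strain]
        for exp_i in range(1, config.n_experiments + 1):
            for vial_i in range(1, config.n_vials_per_experiment + 1):
                density = int(rng.integers(28, 61))
                contaminated = bool(rng.random() < config.contamination_prob)
                if contaminated:
                    unexpected = int(6 + rng.poisson(15))
                else:
                    unexpected = int(rng.integers(0, 3))
                x = rng.normal(mean, config.fly_sd, size=config.n_flies_per_vial)
                x = np.maximum(x, 0.0)
                cfu = np.maximum(0, np.rint(np.exp2(x) - 1.0)).astype(np.int64)
                colonies = np.rint(cfu / config.colony_scale).astype(np.int64)
                dense = colonies >= config.ceiling_colonies
                colonies = np.where(dense, config.ceiling_colonies, colonies)
                for fly_i in range(config.n_flies_per_vial):
                    rows.append(
                        {
                            "strain": strain,
                            "experiment": f"E{exp_i}",
                            "vial": f"V{vial_i}",
                            "fly": fly_i + 1,
                            "sex": "female",
                            "colony_count": int(colonies[fly_i]),
                            "too_dense": bool(dense[fly_i]),
                            "contaminated_vial": contaminated,
                            "unexpected_colony_count": unexpected,
                            "vial_density": density,
                        }
                    )
    return pd.DataFrame(rows)


def partition_from_matrix(matrix: GenePresenceMatrix) -> dict[str, str]:
    """One protein per (OG, carrier strain), named ``strain|ogid_p``."""
    arr = matrix.data.to_numpy(dtype=bool)
    partition: dict[str, str] = {}
    for og, row in zip(matrix.og_ids, arr):
        for strain, present in zip(matrix.strains, row):
            if present:
                partition[f"{strain}|{og.lower()}p"] = og
    return partition


def synthetic_partition(
    n_ogs: int, proteins_per_og: int, n_strains: int | None = None
) -> dict[str, str]:
    """A planted partition: ``n_ogs`` groups of ``proteins_per_og`` proteins.

    Proteins are spread round-robin over ``n_strains`` strains (default:
    one strain per within-group slot), yielding ids like ``S01|p0007``.
    """
    if n_strains is None:
        n_strains = proteins_per_og
    strains = strain_names(n_strains)
    ogs = og_names(n_ogs)
    partition = {}
    counter = itertools.count(1)
    for og_i, og in enumerate(ogs):
        for slot in range(proteins_per_og):
            strain = strains[(og_i + slot) % n_strains]
            partition[f"{strain}|p{next(counter):05d}"] = og
    return partition


def simulate_similarity_graph(
    og_partition: Mapping[str, str],
    seed: int = 0,
    p_noise: float = 0.001,
) -> pd.DataFrame:
    """ABC edge list consistent with a known OG partition.

    Every within-OG protein pair gets weight ~ Uniform(0.7, 1.0); each
    between-OG pair is added independently with probability ``p_noise``
    and weight ~ Uniform(0.0, 0.2).  For large partitions the noise pairs
    are sampled by count rather than enumerated, so a pair may very rarely
    be drawn twice (the ABC reader keeps the maximum weight).
    """
    if not og_partition:
        raise SimulationError("empty partition")
    rng = stage_rng(seed, "graph")
    by_og: dict[str, list[str]] = {}
    for protein, og in og_partition.items():
        by_og.setdefault(og, []).append(protein)
    rows: list[tuple[str, str, float]] = []
    for og in sorted(by_og):
        members = sorted(by_og[og])
        pairs = list(itertools.combinations(members, 2))
        weights = rng.uniform(0.7, 1.0, size=len(pairs))
        rows.extend((a, b, float(w)) for (a, b), w in zip(pairs, weights))
    if p_noise > 0:
        proteins = np.array(sorted(og_partition))
        og_of = np.array([og_partition[p] for p in proteins])
        n = len(proteins)
        sizes = np.array([len(by_og[o]) for o in sorted(by_og)])
        n_within = int((sizes * (sizes - 1) // 2).sum())
        n_cross = n * (n - 1) // 2 - n_within
        k = rng.binomial(n_cross, p_noise) if n_cross > 0 else 0
        drawn: set[tuple[int, int]] = set()
        while len(drawn) < k:
            cand = rng.integers(0, n, size=(max(16, 2 * (k - len(drawn))), 2))
            for i, j in cand:
                if len(drawn) >= k:
                    break
                i, j = int(min(i, j)), int(max(i, j))
                if i == j or og_of[i] == og_of[j] or (i, j) in drawn:
                    continue
                drawn.add((i, j))
        for i, j in sorted(drawn):
            rows.append((proteins[i], proteins[j], float(rng.uniform(0.0, 0.2))))
    return pd.DataFrame(rows, columns=["source", "target", "weight"])


def simulate_annotation(
    ogs: Iterable[str],
    significant_ogs: Iterable[str],
    n_pathways: int = 10,
    seed: int = 0,
    odds_ratio: float = 10.0,
    annotated_fraction: float = 0.8,
) -> tuple[pd.DataFrame, str]:
    """OG -> KO -> pathway table with one pathway planted as enriched.

    A fraction of OGs receives a (unique) KO and exactly one pathway.  The
    first pathway is loaded with the designated gene set: the odds that a
    significant OG lands there are ``odds_ratio`` times the background
    odds (uniform over pathways).  Returns the table and the planted
    pathway id.
    """
    ogs = sorted(set(ogs))
    significant = set(significant_ogs)
    if not significant <= set(ogs):
        raise SimulationError("significant_ogs must be a subset of ogs")
    if n_pathways < 1:
        raise SimulationError("n_pathways must be positive")
    if odds_ratio <= 0:
        raise SimulationError("odds_ratio must be positive")
    rng = stage_rng(seed, "annotation")
    pathways = [f"map{i:05d}" for i in range(1, n_pathways + 1)]
    planted = pathways[0]
    q = 1.0 / n_pathways
    p_planted = odds_ratio * q / (1.0 - q + odds_ratio * q)
    rows = []
    ko_counter = itertools.count(10001)
    for og in ogs:
        if rng.random() >= annotated_fraction:
            continue
        ko = f"K{next(ko_counter):05d}"
        if og in significant:
            if rng.random() < p_planted:
                pathway = planted
            else:
                pathway = pathways[1 + int(rng.integers(n_pathways - 1))] \
                    if n_pathways > 1 else planted
        else:
            pathway = pathways[int(rng.integers(n_pathways))]
        rows.append({"og_id": og, "ko_id": ko, "pathway_id": pathway})
    return pd.DataFrame(rows, columns=["og_id", "ko_id", "pathway_id"]), planted


def write_annotation_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"og_id", "ko_id", "pathway_id"} - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    return df


def simulate_all(config: SimConfig, outdir) -> SimTruth:
    """Generate every pipeline input under ``outdir`` and return the truth.

    Writes ``cfu_records.tsv``, ``similarity.abc``, ``groups.txt``,
    ``annotation.tsv``, ``tree.nwk`` and ``truth.json``.  The annotation's
    planted pathway is loaded with the true causal OGs.
    """
    from pathlib import Path

    from . import assay
    from .orthology import OgPartition, write_abc_graph, write_groups

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix, tree = simulate_pangenome(config)
    truth = plant_effects(matrix, config)
    records = simulate_cfu(truth, config)
    assay.write_cfu_tsv(records, outdir / "cfu_records.tsv")
    edges = simulate_similarity_graph(truth.og_partition, seed=config.seed)
    write_abc_graph(edges, outdir / "similarity.abc")
    groups: dict[str, set[str]] = {}
    for protein, og in truth.og_partition.items():
        groups.setdefault(og, set()).add(protein)
    write_groups(
        OgPartition({og: frozenset(m) for og, m in groups.items()}),
        outdir / "groups.txt",
    )
    annotation, planted = simulate_annotation(
        matrix.og_ids, truth.causal_ogs, seed=config.seed
    )
    truth.enriched_pathways = {planted}
    write_annotation_tsv(annotation, outdir / "annotation.tsv")
    (outdir / "tree.nwk").write_text(tree.newick() + "\n")
    truth.to_json(outdir / "truth.json")
    return truth
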