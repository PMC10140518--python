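"""Synthetic community generator with known ground truth.

Emulates the statistical structure of a paddy-soil root-compartment survey:
a 3 compartment x 3 stage x 3 replicate design (27 samples), lognormal
regional abundances, a birth-death phylogeny carrying a Brownian-motion
niche trait, Gaussian environmental filtering whose strength increases
from bulk soil toward the rhizoplane, and planted blocks of correlated
taxa for network-recovery tests.

The sampling model for one sample with environment value ``e`` and
filtering width ``sigma``:

    weight_i  ~  base_i * exp(-(trait_i - e)^2 / (2 sigma^2)) * g^{s_i}

where ``base_i`` is the taxon's lognormal regional abundance, ``g`` a
per-sample lognormal latent factor shared by a planted block (sign ``s_i``
is +1/-1 for positively/negatively coupled members, 0 otherwise), followed
by a multinomial draw of ``depth`` individuals.  Small ``sigma`` means
strong selection (low diversity); ``sigma -> inf`` recovers neutral
sampling from the regional pool.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from rhizocomm.matrix import (
    COMPARTMENTS,
    STAGES,
    CommunityMatrix,
    SampleMetadata,
    write_community_matrix,
)
from rhizocomm.tree import PhyloTree


@dataclass
class SimulationConfig:
    """Parameters of the synthetic survey.

    Defaults describe the study design the package targets: 27 samples
    (3 compartments x 3 stages x 3 replicates), 300 taxa, 10,000 reads per
    sample.  Trait and environment values share one scale: with the tree
    rescaled to height 1 and ``trait_rate`` 1, tip traits have unit
    variance, so ``sigma_env`` is expressed in trait standard deviations.
    Filtering strength increases toward the root surface
    (``sigma_env`` decreases bulk -> rhizosphere -> rhizoplane).
    """

    n_taxa: int = 300
    compartments: tuple = COMPARTMENTS
    stages: tuple = STAGES
    n_replicates: int = 3
    depth: int = 10_000
    lognormal_mean: float = 0.0
    lognormal_sd: float = 1.5
    birth_rate: float = 1.0
    death_rate: float = 0.5
    tree_height: float = 1.0
    trait_rate: float = 1.0
    sigma_env: dict = field(
        default_factory=lambda: {
            "bulk": 3.0,
            "rhizosphere": 1.5,
            "rhizoplane": 0.75,
        }
    )
    env_optima: dict = field(
        default_factory=lambda: {
            "bulk": 0.0,
            "rhizosphere": 0.8,
            "rhizoplane": 1.6,
        }
    )
    stage_drift: float = 0.0
    n_blocks: int = 2
    block_size: int = 6
    block_sd: float = 1.0
    block_abundance_scale: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        errors = []
        if self.n_taxa < 2:
            errors.append("n_taxa must be >= 2")
        if self.depth <= 0:
            errors.append("depth must be > 0")
        if not self.birth_rate > self.death_rate >= 0:
            errors.append("need birth_rate > death_rate >= 0")
        if self.trait_rate <= 0:
            errors.append("trait_rate must be > 0")
        if self.block_size < 2:
            errors.append("block_size must be >= 2")
        for c in self.compartments:
            if c not in self.sigma_env:
                errors.append(f"sigma_env missing compartment {c!r}")
            elif self.sigma_env[c] < 0:
                errors.append(f"sigma_env[{c!r}] must be >= 0")
            if c not in self.env_optima:
                errors.append(f"env_optima missing compartment {c!r}")
        if self.n_blocks * self.block_size > self.n_taxa:
            errors.append("planted blocks exceed the taxon pool")
        if errors:
            raise ValueError("; ".join(errors))

    @property
    def n_samples(self) -> int:
        return len(self.compartments) * len(self.stages) * self.n_replicates


@dataclass
class GroundTruth:
    """What the generator actually planted, for parameter-recovery tests."""

    niche_optima: dict  # taxon id -> Brownian trait value
    sample_environment: dict  # sample id -> environment value
    regimes: dict  # compartment -> "selection-dominated" | "drift-dominated"
    blocks: list  # [{"taxa": [...], "signs": [...]}, ...]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


class SyntheticDataset(NamedTuple):
    matrix: CommunityMatrix
    metadata: SampleMetadata
    tree: PhyloTree
    traits: dict
    truth: GroundTruth


def simulate_tree(
    n_taxa: int,
    birth: float = 1.0,
    death: float = 0.5,
    seed: int = 0,
    height: float | None = 1.0,
) -> PhyloTree:
    """Birth-death tree with ``n_taxa`` extant tips, ultrametric by construction.

    ``height``, if given, rescales all branch lengths so the root-to-tip
    depth equals it — convenient because trait and filtering parameters are
    then on a fixed scale regardless of the birth/death rates.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if not birth > death >= 0:
        raise ValueError("need birth > death >= 0")
    rng = random.Random(int(seed))
    tree = treesim.birth_death_tree(
        birth_rate=birth,
        death_rate=death,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    tree.purge_taxon_namespace()
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"OTU{i + 1}"
    if height is not None:
        depth = max(
            leaf.distance_from_root() for leaf in tree.leaf_node_iter()
        )
        factor = height / depth
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
    return PhyloTree(tree)


def evolve_niche_trait(t: PhyloTree, rate: float, seed: int) -> dict:
    """Brownian-motion trait along the tree, root value 0.

    Each edge adds a Normal(0, rate * edge_length) increment, so a tip's
    trait variance equals rate x root-to-tip length and the covariance of
    two tips equals rate x shared path length — the phylogenetic
    conservation that makes environmental filtering detectable by
    phylogenetic null models.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    rng = np.random.default_rng(seed)
    values: dict[int, float] = {id(t.tree.seed_node): 0.0}
    for node in t.tree.preorder_node_iter():
        if node is t.tree.seed_node:
            continue
        length = node.edge.length or 0.0
        step = rng.normal(0.0, np.sqrt(rate * length)) if length > 0 else 0.0
        values[id(node)] = values[id(node.parent_node)] + step
    return {
        leaf.taxon.label: values[id(leaf)] for leaf in t.tree.leaf_node_iter()
    }


def sample_weights(
    base: np.ndarray,
    traits: np.ndarray,
    environment: float,
    sigma: float,
    block_log_factors: np.ndarray | None = None,
) -> np.ndarray:
    """Per-taxon sampling weights for one sample (normalized to sum 1).

    Computed on the log scale and max-shifted before exponentiation so very
    strong filtering never underflows to an all-zero weight vector.
    """
    logw = np.log(base)
    if np.isfinite(sigma) and sigma > 0:
        logw = logw - (traits - environment) ** 2 / (2.0 * sigma**2)
    elif sigma == 0:
        # degenerate limit: only the taxa nearest the optimum survive
        d2 = (traits - environment) ** 2
        logw = np.where(d2 == d2.min(), logw, -np.inf)
    if block_log_factors is not None:
        logw = logw + block_log_factors
    logw = logw - np.nanmax(logw[np.isfinite(logw)])
    w = np.exp(logw)
    w[~np.isfinite(w)] = 0.0
    return w / w.sum()


def assemble_communities(
    cfg: SimulationConfig, t: PhyloTree, traits: dict
) -> tuple[CommunityMatrix, SampleMetadata, GroundTruth]:
    """Draw the full sample design from the niche-filtering model."""
    taxa = t.tip_labels
    missing = [x for x in taxa if x not in traits]
    if missing:
        raise ValueError(f"traits missing for tips: {missing[:5]}")
    if len(taxa) != cfg.n_taxa:
        raise ValueError(
            f"tree has {len(taxa)} tips but config expects {cfg.n_taxa}"
        )
    trait_vec = np.array([traits[x] for x in taxa])
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss)

    base = rng.lognormal(cfg.lognormal_mean, cfg.lognormal_sd, size=cfg.n_taxa)

    # planted correlated blocks: disjoint taxon sets sharing a latent factor
    block_members: list[np.ndarray] = []
    block_signs: list[np.ndarray] = []
    if cfg.n_blocks > 0:
        chosen = rng.choice(
            cfg.n_taxa, size=cfg.n_blocks * cfg.block_size, replace=False
        )
        for b in range(cfg.n_blocks):
            members = chosen[b * cfg.block_size : (b + 1) * cfg.block_size]
            block_members.append(members)
            block_signs.append(np.ones(cfg.block_size, dtype=int))
            # Block members share one base abundance (their realized
            # abundances stay lognormal through the latent factor), sized
            # to a modest community share: large enough that multinomial
            # noise does not drown the latent signal, small enough that the
            # factor's swings do not compositionally couple the remaining
            # taxa.
            base[members] = cfg.block_abundance_scale * np.exp(
                cfg.lognormal_mean + cfg.lognormal_sd**2 / 2
            )

    sample_rows = []
    columns = {}
    environments = {}
    for compartment in cfg.compartments:
        for s_idx, stage in enumerate(cfg.stages):
            for rep in range(1, cfg.n_replicates + 1):
                sid = f"{compartment}_{stage}_{rep}"
                env = cfg.env_optima[compartment] + cfg.stage_drift * s_idx
                environments[sid] = env
                log_factors = np.zeros(cfg.n_taxa)
                for members, signs in zip(block_members, block_signs):
                    g = rng.normal(0.0, cfg.block_sd)
                    log_factors[members] += signs * g
                w = sample_weights(
                    base,
                    trait_vec,
                    env,
                    cfg.sigma_env[compartment],
                    log_factors if block_members else None,
                )
                columns[sid] = rng.multinomial(cfg.depth, w)
                sample_rows.append(
                    {
                        "sample_id": sid,
                        "compartment": compartment,
                        "stage": stage,
                        "replicate": rep,
                    }
                )

    df = pd.DataFrame(columns, index=pd.Index(taxa, name="taxon_id"))
    matrix = CommunityMatrix(df, semantics="raw")
    metadata = SampleMetadata(pd.DataFrame(sample_rows))

    trait_sd = np.sqrt(cfg.trait_rate * (cfg.tree_height or 1.0))
    regimes = {
        c: (
            "selection-dominated"
            if cfg.sigma_env[c] <= trait_sd
            else "drift-dominated"
        )
        for c in cfg.compartments
    }
    truth = GroundTruth(
        niche_optima={x: float(traits[x]) for x in taxa},
        sample_environment={k: float(v) for k, v in environments.items()},
        regimes=regimes,
        blocks=[
            {
                "taxa": [taxa[i] for i in members],
                "signs": [int(s) for s in signs],
            }
            for members, signs in zip(block_members, block_signs)
        ],
    )
    return matrix, metadata, truth


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Tree + traits + communities in one deterministic bundle."""
    ss = np.random.SeedSequence(cfg.seed)
    tree_seed, trait_seed = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)
    )
    tree = simulate_tree(
        cfg.n_taxa,
        cfg.birth_rate,
        cfg.death_rate,
        seed=tree_seed,
        height=cfg.tree_height,
    )
    traits = evolve_niche_trait(tree, cfg.trait_rate, seed=trait_seed)
    matrix, metadata, truth = assemble_communities(cfg, tree, traits)
    return SyntheticDataset(matrix, metadata, tree, traits, truth)


def selection_regime_config(seed: int) -> SimulationConfig:
    """Two contrasting environments under strong niche filtering.

    Three replicate samples at each of two widely separated environment
    optima (+/-1.5 trait sd) with narrow filtering (sigma 0.25): pairs of
    samples from different environments are assembled by heterogeneous
    selection, the regime the phylogenetic null model should recover.
    """
    return SimulationConfig(
        n_taxa=100,
        depth=2000,
        seed=seed,
        n_blocks=0,
        compartments=("bulk", "rhizoplane"),
        stages=("tillering",),
        n_replicates=3,
        sigma_env={"bulk": 0.25, "rhizoplane": 0.25},
        env_optima={"bulk": -1.5, "rhizoplane": 1.5},
    )


def neutral_regime_config(seed: int) -> SimulationConfig:
    """No niche filtering: all samples drawn from the regional pool.

    Six replicate samples under an effectively infinite filtering width,
    the drift-dominated regime in which |betaNTI| should stay below 2 for
    most pairs.
    """
    return SimulationConfig(
        n_taxa=100,
        depth=2000,
        seed=seed,
        n_blocks=0,
        compartments=("bulk",),
        stages=("tillering", "heading"),
        n_replicates=3,
        sigma_env={"bulk": 1e9},
        env_optima={"bulk": 0.0},
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict:
    """Write matrix TSV, Newick, metadata TSV and truth JSON; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / "matrix.tsv",
        "tree": outdir / "tree.nwk",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.json",
    }
    write_community_matrix(ds.matrix, paths["matrix"])
    ds.tree.to_newick(paths["tree"])
    ds.metadata.to_tsv(paths["metadata"])
    ds.truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
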