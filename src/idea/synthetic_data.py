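"""Synthetic fixtures: membership structures, rankings, expression matrices.

Everything downstream is testable without any external download: this
module generates a gene universe with random category memberships,
fold-change rankings that are either pure noise (the exchangeable null) or
carry planted enrichment, and replicate-level expression matrices with
multiplicative treatment effects and lognormal noise.

Two planted regimes are supported, mirroring the two ways a category can
dominate a ranking: a few strongly responding members packed in a narrow
top window (small peak fraction), or many weakly responding members spread
over a wide window (diffuse signal, large peak fraction).  Planting controls
rank positions directly, which makes recovery targets (e-value, n*)
analytically transparent.

Null rankings draw |log2FC| magnitudes from a half-normal: only the order
matters to the enrichment scan, and a half-normal gives the realistic dense
pile-up of small fold changes near zero.

All generators are pure functions of (config, seed).  The master seed is
split per generator through ``numpy.random.SeedSequence([seed, tag])`` with
fixed integer tags, so the same seed can drive a whole fixture directory
while each artifact stays individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, RankedGeneList, DESIGN_COLUMNS
from .gene_sets import GeneSetCollection

__all__ = [
    "SyntheticConfig",
    "gene_ids",
    "generate_membership",
    "generate_null_ranking",
    "generate_planted_ranking",
    "generate_expression_experiment",
    "permute_ranking",
]

# SeedSequence tags, one per generator
_TAG_MEMBERSHIP = 1
_TAG_NULL_RANKING = 2
_TAG_PLANTED = 3
_TAG_EXPRESSION = 4


@dataclass
class SyntheticConfig:
    """Generator parameters for calibration and power studies.

    Defaults describe a desk-scale transcriptomics experiment: a 10 000-gene
    universe, a ranked list of 1 000 responding genes per direction, and a
    planted category of 50 members concentrated in the top 100 ranks — the
    regime in which a moderately sized target set drives weak but coherent
    transcriptional change.
    """

    universe_size: int = 10_000
    n_categories: int = 25
    category_size_min: int = 20
    category_size_max: int = 200
    list_length: int = 1_000
    direction: str = "up"
    # planted-signal spec
    n_planted: int = 1
    planted_members: int = 50        # m members forced into the window
    planted_window: int = 100        # top ranks they occupy
    planted_category_size: int | None = None  # total K; defaults to m
    # ranking noise
    noise_sigma: float = 0.25        # sd of the log2FC half-normal
    # expression experiment
    n_replicates: int = 3
    baseline_mean: float = 8.0       # log2 intensity
    baseline_sd: float = 2.0
    replicate_sd: float = 0.25       # log2-scale replicate noise
    de_fraction: float = 0.10        # fraction of genes with a true effect
    de_effect: float = 1.0           # |delta| log2FC of affected genes
    time_h: float = 24.0
    dose_nM: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        c = self
        checks = [
            ("universe_size", c.universe_size >= 1),
            ("n_categories", c.n_categories >= 0),
            ("category_size_min", 1 <= c.category_size_min <= c.category_size_max),
            ("category_size_max", c.category_size_max <= c.universe_size),
            ("list_length", 1 <= c.list_length <= c.universe_size),
            ("planted_window", 0 < c.planted_window <= c.list_length),
            ("planted_members", 0 < c.planted_members <= c.planted_window),
            ("planted_category_size",
             c.planted_category_size is None
             or c.planted_members <= c.planted_category_size <= c.universe_size),
            ("noise_sigma", c.noise_sigma > 0),
            ("n_replicates", c.n_replicates >= 2),
            ("de_fraction", 0 <= c.de_fraction <= 1),
            ("direction", c.direction in ("up", "down")),
        ]
        for name, ok in checks:
            if not ok:
                raise ValueError(f"invalid SyntheticConfig field: {name}")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(config: SyntheticConfig, tag: int, seed=None) -> np.random.Generator:
    base = config.seed if seed is None else seed
    return np.random.default_rng(np.random.SeedSequence([int(base), tag]))


def gene_ids(U: int) -> list[str]:
    """Synthetic identifiers G000001..G{U}, zero-padded to a fixed width."""
    width = max(6, len(str(U)))
    return [f"G{i:0{width}d}" for i in range(1, U + 1)]


def generate_membership(config: SyntheticConfig, seed=None) -> GeneSetCollection:
    """Random categories drawn uniformly without replacement from the universe."""
    config.validate()
    rng = _rng(config, _TAG_MEMBERSHIP, seed)
    ids = np.array(gene_ids(config.universe_size))
    categories: dict[str, set[str]] = {}
    labels: dict[str, tuple[str, ...]] = {}
    for i in range(config.n_categories):
        size = int(rng.integers(config.category_size_min, config.category_size_max + 1))
        members = rng.choice(ids, size=size, replace=False)
        name = f"SET_{i + 1:04d}"
        categories[name] = set(members.tolist())
        labels[name] = ("synthetic",)
    return GeneSetCollection(categories, set(ids.tolist()), labels)


def _sorted_magnitudes(rng: np.random.Generator, N: int, sigma: float) -> np.ndarray:
    mag = np.abs(rng.normal(0.0, sigma, size=N))
    # a zero magnitude would belong to neither direction; clamp to the
    # smallest normal double so the sigma -> 0 edge stays a valid list
    mag = np.maximum(mag, np.finfo(float).tiny)
    return np.sort(mag)[::-1]


def _make_list(genes: np.ndarray, mags: np.ndarray, direction: str,
               metadata: dict) -> RankedGeneList:
    sign = 1.0 if direction == "up" else -1.0
    order = np.lexsort((genes, -mags))  # decreasing |FC|, gene-id tie-break
    return RankedGeneList(
        genes=list(genes[order]),
        log2fc=sign * mags[order],
        direction=direction,
        metadata=metadata,
    )


def generate_null_ranking(
    config: SyntheticConfig, seed=None, genes: np.ndarray | None = None
) -> RankedGeneList:
    """A ranking with no signal: order exchangeable w.r.t. every category.

    N genes are sampled from the universe (or taken from ``genes``) and
    assigned half-normal |log2FC| magnitudes in uniformly random order, so
    category members' ranks are a uniform random subset.
    """
    config.validate()
    rng = _rng(config, _TAG_NULL_RANKING, seed)
    ids = np.array(gene_ids(config.universe_size))
    if genes is None:
        genes = rng.choice(ids, size=config.list_length, replace=False)
    else:
        genes = np.asarray(genes)
        genes = genes[rng.permutation(len(genes))]
    mags = _sorted_magnitudes(rng, len(genes), config.noise_sigma)
    # magnitudes are pre-sorted and genes pre-shuffled: pairing rank i with
    # genes[i] makes hit positions uniform; ties (sigma -> 0) collapse to the
    # lexicographic rule inside _make_list
    return _make_list(genes, mags, config.direction,
                      {"kind": "null", "seed": config.seed if seed is None else seed})


def permute_ranking(ranked: RankedGeneList, rng: np.random.Generator) -> RankedGeneList:
    """Uniformly reshuffle the gene order of a ranking, keeping magnitudes.

    The fold-change magnitudes stay attached to the ranks, the genes are
    permuted across them — the exchangeable-order null of the permutation
    test, materialized as an actual ranking object.
    """
    genes = np.array(ranked.genes)
    perm = rng.permutation(ranked.N)
    return RankedGeneList(
        genes=list(genes[perm]),
        log2fc=ranked.log2fc.copy(),
        direction=ranked.direction,
        metadata={**ranked.metadata, "kind": "shuffled"},
    )


def generate_planted_ranking(
    config: SyntheticConfig, seed=None
) -> tuple[RankedGeneList, GeneSetCollection, pd.DataFrame]:
    """A ranking with planted enrichment plus its membership and truth table.

    For each planted category, m members are forced into uniformly chosen
    ranks within the top ``planted_window``; the remainder of the list is
    filled with non-planted genes in random order.  The truth table records
    (category, m, window) so recovery can be scored from outputs alone.
    Null categories from :func:`generate_membership` are included so planted
    categories must beat genuine background competitors.
    """
    config.validate()
    if config.planted_members > config.planted_window:
        raise ValueError("planted_members cannot exceed planted_window")
    rng = _rng(config, _TAG_PLANTED, seed)
    collection = generate_membership(config, seed)
    ids = np.array(gene_ids(config.universe_size))
    N, m, window = config.list_length, config.planted_members, config.planted_window
    K = config.planted_category_size or m

    slots = np.full(N, None, dtype=object)
    free_window = list(range(window))
    used_genes: set[str] = set()
    truth_rows = []
    for p in range(config.n_planted):
        name = f"PLANTED_{p + 1:04d}"
        pool = np.array([g for g in ids if g not in used_genes])
        members = rng.choice(pool, size=K, replace=False)
        planted = members[:m]
        if len(free_window) < m:
            raise ValueError("planted window too crowded for all planted categories")
        pos = rng.choice(len(free_window), size=m, replace=False)
        chosen = [free_window[i] for i in sorted(pos)]
        for slot, gene in zip(chosen, planted):
            slots[slot] = gene
        free_window = [s for s in free_window if s not in set(chosen)]
        used_genes.update(members.tolist())
        collection.categories[name] = set(members.tolist())
        collection.source_labels[name] = ("planted",)
        truth_rows.append({"category": name, "m": m, "window": window, "K": K})

    open_slots = [i for i in range(N) if slots[i] is None]
    filler_pool = np.array([g for g in ids if g not in used_genes])
    fillers = rng.choice(filler_pool, size=len(open_slots), replace=False)
    for slot, gene in zip(open_slots, fillers):
        slots[slot] = gene
    genes = slots.astype(str)

    mags = _sorted_magnitudes(rng, N, config.noise_sigma)
    sign = 1.0 if config.direction == "up" else -1.0
    ranked = RankedGeneList(
        genes=list(genes), log2fc=sign * mags, direction=config.direction,
        metadata={"kind": "planted", "seed": config.seed if seed is None else seed},
    )
    truth = pd.DataFrame(truth_rows, columns=["category", "m", "window", "K"])
    return ranked, collection, truth


def generate_expression_experiment(
    config: SyntheticConfig, seed=None
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Replicate-level treated/control expression matrix with known effects.

    Baseline log2 intensities are Normal(baseline_mean, baseline_sd) per
    gene; every replicate adds Normal(0, replicate_sd) noise; treated
    replicates of affected genes are shifted by delta_g log2 units
    (equivalently multiplied by 2**delta_g on the linear scale).  A fraction
    ``de_fraction`` of genes get |delta| = de_effect with random sign; the
    truth table records every gene's delta.
    """
    config.validate()
    rng = _rng(config, _TAG_EXPRESSION, seed)
    ids = gene_ids(config.universe_size)
    U, r = config.universe_size, config.n_replicates

    delta = np.zeros(U)
    n_de = int(round(config.de_fraction * U))
    if n_de:
        idx = rng.choice(U, size=n_de, replace=False)
        delta[idx] = rng.choice([-1.0, 1.0], size=n_de) * config.de_effect

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=U)
    log_t = baseline[:, None] + delta[:, None] + rng.normal(0, config.replicate_sd, (U, r))
    log_c = baseline[:, None] + rng.normal(0, config.replicate_sd, (U, r))

    t_names = [f"T{i + 1}" for i in range(r)]
    c_names = [f"C{i + 1}" for i in range(r)]
    values = pd.DataFrame(
        np.power(2.0, np.hstack([log_t, log_c])),
        index=pd.Index(ids, name="feature_id"),
        columns=t_names + c_names,
    )
    design = pd.DataFrame(
        [
            {"sample_id": s, "time_h": config.time_h, "dose_nM": config.dose_nM,
             "role": "treated", "replicate": i + 1}
            for i, s in enumerate(t_names)
        ]
        + [
            {"sample_id": s, "time_h": config.time_h, "dose_nM": 0.0,
             "role": "control", "replicate": i + 1}
            for i, s in enumerate(c_names)
        ],
        columns=DESIGN_COLUMNS,
    )
    truth = pd.DataFrame({"gene": ids, "delta": delta})
    return ExpressionMatrix(values), design, truth
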