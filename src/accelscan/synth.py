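"""Seeded generator for a complete miniature study.

Produces, deterministically per seed: a placental-like tree with a
designated target leaf and 2-leaf target subtree, a reversible neutral
model, a reference-anchored MAF alignment, conserved elements, gene
models, gene lists (one enriched for accelerated tiles, one neutral),
and a per-tile truth table.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as fmt
from .elements import split_elements
from .genemap import map_elements_to_genes
from .phylo import (LikelihoodEngine, NeutralModel, Node, PhyloTree,
                    SubstitutionModel)

DEFAULT_TARGET_LEAF = "wedSeal"
DEFAULT_TARGET_SUBTREE = ("wedSeal", "walrus")


class ScenarioError(ValueError):
    """Infeasible or inconsistent scenario configuration."""


@dataclasses.dataclass
class ScenarioConfig:
    """Knobs of the miniature study; see module docstring."""

    n_species: int = 12
    target_leaf: str = DEFAULT_TARGET_LEAF
    target_subtree: tuple[str, ...] = DEFAULT_TARGET_SUBTREE
    ref_species: str = "ref"
    chrom: str = "chr1"
    genome_length: int = 10_000_000
    n_elements: int = 1000
    element_width_range: tuple[int, int] = (100, 100)
    width: int = 50
    fraction_accelerated: float = 0.05
    rho_true: float = 8.0
    accel_branches: str = "leaf"          # "leaf" or "subtree"
    list_multiplier: float = 5.0
    missing_rate: float = 0.0
    n_genes: int = 300
    gene_width_range: tuple[int, int] = (2000, 8000)
    list_a_size: int = 84
    list_b_size: int = 69
    list_subset_size: int = 14
    flank: int = 10_000
    tree_depth: float = 0.75
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.fraction_accelerated <= 1.0):
            raise ScenarioError("fraction_accelerated must be in [0, 1]")
        if self.rho_true < 1.0:
            raise ScenarioError("rho_true must be >= 1")
        if self.list_multiplier < 1.0:
            raise ScenarioError("list_multiplier must be >= 1")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ScenarioError("missing_rate must be in [0, 1)")
        if self.accel_branches not in {"leaf", "subtree"}:
            raise ScenarioError("accel_branches must be 'leaf' or 'subtree'")
        if self.n_species < 4:
            raise ScenarioError("need at least 4 species")
        self.target_subtree = tuple(self.target_subtree)
        self.element_width_range = tuple(self.element_width_range)
        self.gene_width_range = tuple(self.gene_width_range)

    @property
    def accel_leafset(self) -> frozenset[str]:
        if self.accel_branches == "leaf":
            return frozenset({self.target_leaf})
        return frozenset(self.target_subtree)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["target_subtree"] = list(self.target_subtree)
        data["element_width_range"] = list(self.element_width_range)
        data["gene_width_range"] = list(self.gene_width_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ScenarioError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Tree and model generation
# ---------------------------------------------------------------------------

def make_tree(n_species: int,
              seed: int | np.random.SeedSequence,
              depth: float = 0.75,
              target_leaf: str = DEFAULT_TARGET_LEAF,
              sister_leaf: str = "walrus",
              ref_species: str = "ref") -> PhyloTree:
    """Random coalescent-shaped tree with a guaranteed target cherry.

    A Kingman coalescent is run on ``n_species - 1`` lineages (the target
    leaf, the reference, and generic species); the sister leaf is then
    attached halfway down the target's terminal branch so the target pair
    is always a cherry.  Heights are rescaled so the root-to-tip depth of
    the coalescent part equals ``depth``; the two target terminal branches
    are extended to at least ``0.1 * depth`` so planted acceleration is
    physically expressible on them.
    """
    if n_species < 4:
        raise ValueError("need at least 4 species")
    rng = np.random.default_rng(seed)
    names = [target_leaf, ref_species] + [
        f"sp{i}" for i in range(4, n_species + 1)]
    lineages: list[tuple[Node, float]] = [(Node(nm), 0.0) for nm in names]
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (a, ha), (b, hb) = lineages[i], lineages[j]
        a.length = t - ha
        b.length = t - hb
        parent = Node()
        parent.add_child(a)
        parent.add_child(b)
        lineages[i] = (parent, t)
        del lineages[j]
    root, height = lineages[0]
    scale = depth / height
    tree = PhyloTree(root)
    for node in tree.postorder():
        node.length *= scale
    # graft the sister onto the target's terminal branch
    target = next(n for n in tree.leaves if n.name == target_leaf)
    half = target.length / 2.0
    cherry = Node(length=target.length - half)
    parent = target.parent
    parent.children[parent.children.index(target)] = cherry
    cherry.parent = parent
    target.length = half
    cherry.add_child(target)
    cherry.add_child(Node(sister_leaf, half))
    floor = 0.1 * depth
    for node in cherry.children:
        node.length = max(node.length, floor)
    tree.root.length = 0.0
    tree.validate()
    return tree


def make_rev_model(seed: int | np.random.SeedSequence) -> SubstitutionModel:
    """Random REV model with frequencies bounded away from 0 (each >= 0.1)."""
    rng = np.random.default_rng(seed)
    freqs = 0.1 + 0.6 * rng.dirichlet(np.ones(4))
    exch = rng.gamma(2.0, 1.0, size=6) + 0.2
    return SubstitutionModel.general_reversible(freqs, exch)


# ---------------------------------------------------------------------------
# Scenario generation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Scenario:
    """In-memory handles plus file paths of one generated study."""

    config: ScenarioConfig
    outdir: Path
    model: NeutralModel
    elements: list[fmt.GenomicInterval]
    tiles: list[fmt.GenomicInterval]
    genes: list[fmt.GeneModel]
    gene_lists: dict[str, list[str]]
    truth: pd.DataFrame
    paths: dict[str, Path]


def _place_intervals(rng: np.random.Generator, n: int,
                     width_range: tuple[int, int], genome_length: int,
                     what: str) -> list[tuple[int, int]]:
    lo, hi = width_range
    widths = rng.integers(lo, hi + 1, size=n)
    slack = genome_length - int(widths.sum()) - (n + 1)
    if slack <= 0:
        raise ScenarioError(
            f"infeasible placement: {n} {what} of mean width "
            f"{widths.mean():.0f} do not fit in {genome_length} bp")
    raw = rng.random(n + 1)
    gaps = np.floor(raw / raw.sum() * slack).astype(int) + 1
    starts = np.cumsum(gaps)[:n] + np.concatenate([[0], np.cumsum(widths)[:-1]])
    return [(int(s), int(s + w)) for s, w in zip(starts, widths)]


def generate_scenario(config: ScenarioConfig,
                      outdir: str | Path) -> Scenario:
    """Emit the full miniature study to ``outdir``; deterministic per seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "lists").mkdir(exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    (s_tree, s_model, s_elems, s_genes, s_lists,
     s_accel, s_sim, s_missing) = ss.spawn(8)

    tree = make_tree(config.n_species, s_tree, depth=config.tree_depth,
                     target_leaf=config.target_leaf,
                     sister_leaf=[x for x in config.target_subtree
                                  if x != config.target_leaf][0],
                     ref_species=config.ref_species)
    model = NeutralModel(tree, make_rev_model(s_model))

    # conserved elements and their 50-bp tiles
    spans = _place_intervals(np.random.default_rng(s_elems),
                             config.n_elements, config.element_width_range,
                             config.genome_length, "elements")
    elements = [fmt.GenomicInterval(config.chrom, s, e, f"el{i}")
                for i, (s, e) in enumerate(spans)]
    tiles = split_elements(elements, config.width)

    # gene models
    gene_spans = _place_intervals(np.random.default_rng(s_genes),
                                  config.n_genes, config.gene_width_range,
                                  config.genome_length, "genes")
    genes = [fmt.GeneModel(f"gene{i:04d}", config.chrom, s, e, "+")
             for i, (s, e) in enumerate(gene_spans)]

    assignments = map_elements_to_genes(tiles, genes, config.flank)
    tile_genes: dict[str, list[str]] = {t.name: [] for t in tiles}
    gene_tiles: dict[str, set[str]] = {g.gene_id: set() for g in genes}
    for a in assignments:
        tile_genes[a.element_id].append(a.gene_id)
        gene_tiles[a.gene_id].add(a.element_id)

    # gene lists: A enriched for accelerated tiles, B neutral and
    # tile-disjoint from A, plus a small sublist of B
    rng_lists = np.random.default_rng(s_lists)
    with_tiles = [g.gene_id for g in genes if gene_tiles[g.gene_id]]
    n_a = min(config.list_a_size, len(with_tiles))
    list_a = sorted(rng_lists.choice(with_tiles, size=n_a, replace=False))
    tiles_a = set().union(*(gene_tiles[g] for g in list_a)) if list_a else set()
    eligible_b = [g for g in with_tiles
                  if g not in set(list_a) and not (gene_tiles[g] & tiles_a)]
    n_b = min(config.list_b_size, len(eligible_b))
    list_b = sorted(rng_lists.choice(eligible_b, size=n_b, replace=False))
    n_sub = min(config.list_subset_size, len(list_b))
    list_b_subset = sorted(rng_lists.choice(list_b, size=n_sub,
                                            replace=False))
    gene_lists = {"listA": list(list_a), "listB": list(list_b),
                  "listB_subset": list(list_b_subset)}

    # planted acceleration: list-A tiles at multiplier x the background rate,
    # with the overall fraction held at config.fraction_accelerated
    f = config.fraction_accelerated
    w = len(tiles_a) / len(tiles) if tiles else 0.0
    p_bg = f / (1.0 + w * (config.list_multiplier - 1.0))
    p_a = min(1.0, config.list_multiplier * p_bg)
    rng_accel = np.random.default_rng(s_accel)
    accelerated = {}
    for tile in tiles:
        p = p_a if tile.name in tiles_a else p_bg
        accelerated[tile.name] = bool(rng_accel.random() < p)

    # simulate per-tile alignments and assemble MAF blocks
    engine = LikelihoodEngine(model)
    accel_leaves = config.accel_leafset
    mask = engine.subtree_mask(accel_leaves)
    rng_sim = np.random.default_rng(s_sim)
    rng_missing = np.random.default_rng(s_missing)
    blocks: list[fmt.MafBlock] = []
    truth_rows = []
    branch_set = "+".join(sorted(accel_leaves))
    for tile in tiles:
        is_acc = accelerated[tile.name]
        seqs = engine.simulate(tile.width, rng_sim,
                               rho=config.rho_true if is_acc else 1.0,
                               mask=mask if is_acc else None)
        decoded = engine.decode(seqs)
        rows = []
        for sp in engine.leaf_names:
            if sp != config.ref_species and \
                    rng_missing.random() < config.missing_rate:
                continue
            rows.append(fmt.MafRow(f"{sp}.{config.chrom}", tile.start,
                                   tile.width, "+", config.genome_length,
                                   decoded[sp]))
        # reference row first, as MAF convention suggests
        rows.sort(key=lambda r: (r.species != config.ref_species, r.species))
        blocks.append(fmt.MafBlock(tuple(rows)))
        truth_rows.append({
            "element_id": tile.name, "chrom": tile.chrom,
            "start": tile.start, "end": tile.end,
            "accelerated": int(is_acc),
            "branch_set": branch_set if is_acc else ".",
            "rho": config.rho_true if is_acc else 1.0,
            "genes": ",".join(sorted(tile_genes[tile.name])) or ".",
            "in_list_a": int(tile.name in tiles_a),
        })
    truth = pd.DataFrame(truth_rows)

    paths = {
        "tree": outdir / "tree.nwk",
        "mod": outdir / "neutral.mod",
        "maf": outdir / "aln.maf",
        "conserved": outdir / "conserved.bed",
        "genes": outdir / "genes.bed12",
        "truth": outdir / "truth.tsv",
        "config": outdir / "scenario.yaml",
    }
    paths["tree"].write_text(tree.to_newick() + "\n")
    fmt.write_mod(model, paths["mod"])
    fmt.write_maf(blocks, paths["maf"])
    fmt.write_bed(elements, paths["conserved"])
    with open(paths["genes"], "w") as fh:
        for g in genes:
            fh.write("\t".join([
                g.chrom, str(g.start), str(g.end), g.gene_id, "0",
                g.strand or "+", str(g.start), str(g.end), "0", "1",
                str(g.end - g.start), "0"]) + "\n")
    for name, members in gene_lists.items():
        p = outdir / "lists" / f"{name}.txt"
        p.write_text("".join(m + "\n" for m in members))
        paths[f"list_{name}"] = p
    truth.to_csv(paths["truth"], sep="\t", index=False)
    config.to_yaml(paths["config"])

    return Scenario(config, outdir, model, elements, tiles, genes,
                    gene_lists, truth, paths)
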