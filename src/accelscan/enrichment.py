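"""Gene-list shift test: do elements annotated to a gene list carry
systematically lower FDR q-values than the genome-wide background?

The statistic is a one-sided unpaired Welch t-test on element q-values,
oriented so a positive t (and small p) means the list mean is *below*
the background mean, i.e. list-wide acceleration.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genemap import DEFAULT_FLANK, map_elements_to_genes
from .io import GeneModel, GenomicInterval

log = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class EnrichmentResult:
    name: str
    n_list: int
    n_background: int
    mean_list: float
    mean_background: float
    t_stat: float
    df: float
    p_value: float


def elements_for_gene_list(
    results: pd.DataFrame,
    gene_list: Iterable[str],
    gene_models: Sequence[GeneModel],
    flank: int = DEFAULT_FLANK,
) -> np.ndarray:
    """q-values of elements assigned to at least one list gene (each once).

    ``results`` is a scan results table with ``element_id``, ``chrom``,
    ``start``, ``end`` and ``q_fdr`` populated genome-wide.  List genes
    absent from the gene models are logged and skipped.
    """
    wanted = set(gene_list)
    known = {g.gene_id for g in gene_models}
    missing = wanted - known
    if missing:
        log.warning("gene-list entries absent from gene models, skipped: %s",
                    sorted(missing))
    models = [g for g in gene_models if g.gene_id in wanted]
    intervals = [GenomicInterval(r.chrom, r.start, r.end, r.element_id)
                 for r in results.itertuples()]
    hit_ids = {a.element_id
               for a in map_elements_to_genes(intervals, models, flank)}
    mask = results["element_id"].isin(hit_ids)
    return results.loc[mask, "q_fdr"].to_numpy(dtype=float)


def welch_t(sample_a: np.ndarray,
            sample_b: np.ndarray) -> tuple[float, float]:
    """Welch statistic ``(mean_a - mean_b)/SE`` and Satterthwaite df."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sa, sb = va / na, vb / nb
    se2 = sa + sb
    if se2 == 0:
        raise ValueError("both samples have zero variance")
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2 ** 2 / (sa ** 2 / (na - 1) + sb ** 2 / (nb - 1))
    return float(t), float(df)


def fdr_shift_test(q_list: Sequence[float], q_background: Sequence[float],
                   name: str = "") -> EnrichmentResult:
    """One-sided unpaired Welch t-test for a downward shift in list q-values.

    ``t = (mean(background) - mean(list)) / SE``; ``p`` is the upper tail at
    the Welch–Satterthwaite df, so small p supports "list mean lower".
    """
    ql = np.asarray(q_list, dtype=float)
    qb = np.asarray(q_background, dtype=float)
    if ql.size < 2 or qb.size < 2:
        raise ValueError("need at least 2 elements in each sample")
    t, df = welch_t(qb, ql)
    p = float(stats.t.sf(t, df))
    return EnrichmentResult(name, int(ql.size), int(qb.size),
                            float(ql.mean()), float(qb.mean()), t, df, p)


def run_enrichment(
    results: pd.DataFrame,
    gene_lists: dict[str, Iterable[str]],
    gene_models: Sequence[GeneModel],
    flank: int = DEFAULT_FLANK,
    disjoint_background: bool = False,
) -> pd.DataFrame:
    """Shift-test every gene list against the genome-wide background.

    By default the background is *all* elements (list elements included);
    ``disjoint_background=True`` excludes the list's own elements instead.
    """
    rows = []
    q_all = results["q_fdr"].to_numpy(dtype=float)
    for name, genes in gene_lists.items():
        ql = elements_for_gene_list(results, genes, gene_models, flank)
        if disjoint_background:
            ids = set(elements_ids_for_gene_list(results, genes,
                                                 gene_models, flank))
            qb = results.loc[~results["element_id"].isin(ids),
                             "q_fdr"].to_numpy(dtype=float)
        else:
            qb = q_all
        res = fdr_shift_test(ql, qb, name=name)
        rows.append(dataclasses.asdict(res))
    return pd.DataFrame(rows)


def elements_ids_for_gene_list(
    results: pd.DataFrame,
    gene_list: Iterable[str],
    gene_models: Sequence[GeneModel],
    flank: int = DEFAULT_FLANK,
) -> list[str]:
    """Element ids (not q-values) assigned to a gene list; helper for
    disjoint-background comparisons and bookkeeping."""
    wanted = set(gene_list)
    models = [g for g in gene_models if g.gene_id in wanted]
    intervals = [GenomicInterval(r.chrom, r.start, r.end, r.element_id)
                 for r in results.itertuples()]
    hits = {a.element_id
            for a in map_elements_to_genes(intervals, models, flank)}
    return sorted(hits)
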