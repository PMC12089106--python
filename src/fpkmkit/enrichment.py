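"""Minimal gene-set enrichment engine.

A weighted Kolmogorov-Smirnov running sum over a ranked gene list gives the
enrichment score (ES); significance comes from a gene-sampling permutation
null (random same-size member sets), chosen over sample-label permutation
because three samples per group admit only ten distinct label splits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, NoOverlapError, ParseError
from .expression import ExpressionMatrix, SampleTable, log_transform


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ArgumentError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ArgumentError(f"gene set {self.name!r} has duplicate members")


@dataclass(frozen=True)
class RankedGeneList:
    """Genes ordered by a per-gene metric, descending; ties by gene_id."""

    gene_ids: tuple[str, ...]
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.gene_ids) != self.metric.size:
            raise ArgumentError("gene_ids and metric length mismatch")
        if not np.all(np.isfinite(self.metric)):
            raise ArgumentError("ranking metric must be finite")


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    p_permutation: float
    n_permutations: int
    leading_edge: tuple[str, ...]
    seed: int


def rank_metric(
    matrix: ExpressionMatrix,
    metadata: SampleTable,
    group_a: str = "control",
    group_b: str = "AD",
    pseudocount: float = 1.0,
) -> RankedGeneList:
    """Difference of group means on log2(FPKM + pseudocount), descending.

    Positive metric values mark genes higher in ``group_b`` than in the
    reference ``group_a``.  Ties are broken by gene identifier.
    """
    metadata.validate_against(matrix)
    in_matrix = set(matrix.sample_ids)
    samples_a = [s for s in metadata.samples_in_group(group_a) if s in in_matrix]
    samples_b = [s for s in metadata.samples_in_group(group_b) if s in in_matrix]
    for label, ss in ((group_a, samples_a), (group_b, samples_b)):
        if len(ss) < 2:
            raise ArgumentError(f"group {label!r} needs >= 2 samples, got {len(ss)}")
    logm = log_transform(matrix, pseudocount)
    idx_a = [matrix.sample_ids.index(s) for s in samples_a]
    idx_b = [matrix.sample_ids.index(s) for s in samples_b]
    diff = logm.values[:, idx_b].mean(axis=1) - logm.values[:, idx_a].mean(axis=1)
    order = np.lexsort((np.array(matrix.gene_ids), -diff))
    return RankedGeneList(
        gene_ids=tuple(matrix.gene_ids[i] for i in order), metric=diff[order]
    )


def running_sum_es(
    ranked: RankedGeneList, gene_set: GeneSet, weight_p: float = 1.0
) -> tuple[float, tuple[str, ...]]:
    """Signed maximum deviation of the weighted hit/miss running sum.

    Hits increment by ``|metric|^p`` normalized over hits; misses decrement
    by ``1/(N - N_hits)``.  The leading edge collects set members at or
    before the maximum (positive ES) or at or after the minimum (negative
    ES).
    """
    n = len(ranked.gene_ids)
    member_set = set(gene_set.members)
    is_hit = np.fromiter((g in member_set for g in ranked.gene_ids), bool, count=n)
    n_hits = int(is_hit.sum())
    if n_hits == 0:
        raise NoOverlapError(
            f"gene set {gene_set.name!r} shares no members with the ranked list"
        )
    weights = np.abs(ranked.metric) ** weight_p
    hit_w = np.where(is_hit, weights, 0.0)
    hit_total = hit_w.sum()
    if hit_total == 0:
        # all hit metrics exactly zero: fall back to uniform hit weights
        hit_w = is_hit.astype(float)
        hit_total = float(n_hits)
    miss_step = 1.0 / (n - n_hits) if n > n_hits else 0.0
    steps = hit_w / hit_total - np.where(is_hit, 0.0, miss_step)
    running = np.cumsum(steps)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    es = float(running[i_max]) if running[i_max] >= -running[i_min] else float(running[i_min])
    if es >= 0:
        edge_idx = np.flatnonzero(is_hit[: i_max + 1])
    else:
        edge_idx = i_min + np.flatnonzero(is_hit[i_min:])
    leading = tuple(ranked.gene_ids[i] for i in edge_idx)
    return es, leading


def permutation_p(
    ranked: RankedGeneList,
    gene_set: GeneSet,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> EnrichmentResult:
    """Permutation p against a gene-sampling null of same-size random sets.

    ``p = (1 + #{|ES_null| >= |ES_obs|}) / (1 + n_perm)``, so p is never
    zero and is reproducible under a fixed seed.
    """
    if n_perm < 100:
        raise ArgumentError(f"n_perm must be >= 100, got {n_perm}")
    es_obs, leading = running_sum_es(ranked, gene_set, weight_p)
    n = len(ranked.gene_ids)
    k = sum(1 for g in ranked.gene_ids if g in set(gene_set.members))
    rng = np.random.default_rng(seed)
    weights = np.abs(ranked.metric) ** weight_p
    count = 0
    for _ in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        is_hit = np.zeros(n, dtype=bool)
        is_hit[idx] = True
        hit_w = np.where(is_hit, weights, 0.0)
        hit_total = hit_w.sum()
        if hit_total == 0:
            hit_w = is_hit.astype(float)
            hit_total = float(k)
        miss_step = 1.0 / (n - k) if n > k else 0.0
        running = np.cumsum(hit_w / hit_total - np.where(is_hit, 0.0, miss_step))
        es_null = running.max() if running.max() >= -running.min() else running.min()
        if abs(es_null) >= abs(es_obs):
            count += 1
    p = (1 + count) / (1 + n_perm)
    return EnrichmentResult(
        set_name=gene_set.name,
        es=es_obs,
        p_permutation=float(p),
        n_permutations=n_perm,
        leading_edge=leading,
        seed=seed,
    )


def es_profile(
    matrix: ExpressionMatrix,
    metadata: SampleTable,
    sets: Sequence[GeneSet],
    group_a: str = "control",
    group_b: str = "AD",
    weight_p: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """One EnrichmentResult per gene set for the given contrast.

    Sets with no overlap are skipped with a warning rather than failing the
    whole profile.
    """
    if matrix.n_genes == 0:
        raise ArgumentError("empty expression matrix")
    if not sets:
        raise ArgumentError("no gene sets supplied")
    ranked = rank_metric(matrix, metadata, group_a, group_b)
    results: list[EnrichmentResult] = []
    for i, s in enumerate(sets):
        try:
            results.append(
                permutation_p(ranked, s, n_perm=n_perm, seed=seed + i, weight_p=weight_p)
            )
        except NoOverlapError as exc:
            warnings.warn(str(exc), stacklevel=2)
    return results


def es_distribution_summary(results: Sequence[EnrichmentResult]) -> dict[str, float]:
    """Mean and quartiles of the ES values in a collection."""
    es = np.array([r.es for r in results], dtype=float)
    if es.size == 0:
        return {"n": 0}
    q1, q2, q3 = np.percentile(es, [25, 50, 75])
    return {
        "n": int(es.size),
        "mean": float(es.mean()),
        "q1": float(q1),
        "median": float(q2),
        "q3": float(q3),
    }


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> list[GeneSet]:
    """GMT: one set per line — name, description, then members, tab-split."""
    path = Path(path)
    sets: list[GeneSet] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs name, description, members")
        name, desc, *members = parts
        members = [m for m in members if m]
        sets.append(GeneSet(name=name, members=tuple(members), description=desc))
    if not sets:
        raise ParseError(f"no gene sets in {path}")
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description or "na", *s.members]) + "\n")


def results_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "set_name": r.set_name,
                "es": r.es,
                "p_permutation": r.p_permutation,
                "n_permutations": r.n_permutations,
                "seed": r.seed,
                "leading_edge": ";".join(r.leading_edge),
            }
            for r in results
        ]
    )
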