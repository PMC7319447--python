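"""Enrichment statistics for hits on miRNA networks.

Four tests are provided:

* ``local_binomial_test`` — is a cluster/family richer in hits than the
  network-wide hit proportion?  Upper-tail binomial probability, computed
  by log-space summation so 1e-30-scale tails stay accurate.
* ``global_permutation_test`` — do hits aggregate on edges anywhere in the
  network?  Counts hit pairs (edges with both endpoints hits) and compares
  against trials that redraw the hit labels uniformly among measured
  nodes, keeping the hit count fixed.
* ``exact_wilcoxon_signed_rank`` — paired two-sided signed-rank test,
  exact (full sign-assignment distribution) for small tie-free samples,
  normal approximation with continuity and tie corrections otherwise.
* ``target_set_enrichment`` — per-miRNA hypergeometric enrichment of a
  gene set among predicted targets.

The local-test background uses MEASURED nodes only: nodes without a score
never enter ``n_nodes``, ``n_cluster`` or the randomization pool.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm, rankdata

from mirnet.annotation_io import ScoreTable, TargetPredictionTable
from mirnet.network_build import MiRNANetwork, connected_components
from mirnet.overlay import HitSet

logger = logging.getLogger(__name__)


def binomial_upper_tail(k: int, n: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by compensated log-space summation.

    No normal approximation: each PMF term is evaluated via log-gamma and
    the tail accumulated with ``math.fsum`` after shifting by the largest
    log term, which keeps very small tails (1e-30 scale) accurate.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n]; got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1]; got {p}")
    if k == 0:
        return 1.0
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    log_p = math.log(p)
    log_q = math.log1p(-p)
    lgamma_n1 = math.lgamma(n + 1)
    log_terms = [
        lgamma_n1 - math.lgamma(j + 1) - math.lgamma(n - j + 1) + j * log_p + (n - j) * log_q
        for j in range(k, n + 1)
    ]
    shift = max(log_terms)
    total = math.fsum(math.exp(t - shift) for t in log_terms)
    return min(1.0, math.exp(shift) * total)


@dataclass
class LocalTestResult:
    """Outcome of the binomial cluster/family enrichment test."""

    group_id: str
    n_nodes: int  # measured nodes in the whole network
    n_hits: int  # hits in the whole network
    n_cluster: int  # measured nodes in the group
    k_hits: int  # hits in the group
    pvalue: float
    pvalue_bh: float | None = None

    @property
    def background_p(self) -> float:
        return self.n_hits / self.n_nodes


def local_binomial_test(
    group: Iterable[str], hits: HitSet, network: MiRNANetwork, group_id: str = ""
) -> LocalTestResult:
    """Binomial upper-tail test of hit enrichment in one group of nodes.

    The background hit proportion ``p = n_hits / n_nodes`` is taken over
    the measured nodes of the network; the p-value is
    P(X >= k_hits) for X ~ Binomial(n_cluster, p).
    """
    nodes = set(network.graph.nodes)
    measured = hits.measured_ids & nodes
    hit_nodes = hits.hit_ids & nodes
    if not measured:
        raise ValueError("no measured nodes in the network")
    group = set(group)
    stray = group - nodes
    if stray:
        raise ValueError(f"group contains ids outside the network: {sorted(stray)[:5]}")
    n_cluster = len(group & measured)
    if n_cluster == 0:
        raise ValueError(f"no measured nodes in group {group_id or sorted(group)[:3]}")
    k_hits = len(group & hit_nodes)
    p = len(hit_nodes) / len(measured)
    pvalue = binomial_upper_tail(k_hits, n_cluster, p)
    return LocalTestResult(
        group_id=group_id,
        n_nodes=len(measured),
        n_hits=len(hit_nodes),
        n_cluster=n_cluster,
        k_hits=k_hits,
        pvalue=pvalue,
    )


@dataclass
class GlobalTestResult:
    """Outcome of the hit-pair label-permutation test."""

    observed_hit_pairs: int
    n_trials: int
    rng_seed: int
    n_trials_exceeding: int
    pvalue_strict: float  # fraction of trials strictly above the observed count
    pvalue_corrected: float  # add-one corrected, never exactly 0


def count_hit_pairs(network: MiRNANetwork, hit_ids: set[str]) -> int:
    """Number of edges with both endpoints in ``hit_ids``."""
    return sum(1 for u, v in network.graph.edges if u in hit_ids and v in hit_ids)


def global_permutation_test(
    network: MiRNANetwork,
    hits: HitSet,
    n_trials: int = 100_000,
    rng_seed: int = 0,
) -> GlobalTestResult:
    """Permutation test for hit aggregation on edges.

    Each trial randomly re-designates ``|hit_ids|`` of the measured nodes
    as hits and recounts hit pairs.  ``pvalue_strict`` is the fraction of
    trials whose randomized count strictly exceeds the observed one (ties
    do not count as exceeding); the add-one corrected variant is reported
    alongside because the strict rule can return exactly 0.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    measured = sorted(hits.measured_ids & set(network.graph.nodes))
    hit_ids = hits.hit_ids & set(measured)
    n_measured = len(measured)
    n_hits = len(hit_ids)
    observed = count_hit_pairs(network, hit_ids)
    if n_hits < 2:
        warnings.warn("fewer than 2 hits: global test is uninformative", stacklevel=2)
        return GlobalTestResult(0, n_trials, rng_seed, n_trials, 1.0, 1.0)
    index = {node: i for i, node in enumerate(measured)}
    edge_u = []
    edge_v = []
    for u, v in network.graph.edges:
        if u in index and v in index:
            edge_u.append(index[u])
            edge_v.append(index[v])
    eu = np.asarray(edge_u, dtype=np.intp)
    ev = np.asarray(edge_v, dtype=np.intp)
    rng = np.random.default_rng(rng_seed)
    exceeding = 0
    chunk = max(1, min(n_trials, 5_000_000 // max(n_measured, 1)))
    done = 0
    while done < n_trials:
        c = min(chunk, n_trials - done)
        if eu.size:
            u = rng.random((c, n_measured))
            picks = np.argpartition(u, n_hits - 1, axis=1)[:, :n_hits]
            mask = np.zeros((c, n_measured), dtype=bool)
            mask[np.arange(c)[:, None], picks] = True
            counts = (mask[:, eu] & mask[:, ev]).sum(axis=1)
            exceeding += int((counts > observed).sum())
        done += c
    pvalue_strict = exceeding / n_trials
    pvalue_corrected = (exceeding + 1) / (n_trials + 1)
    logger.info(
        "global test: observed %d hit pairs, %d/%d trials exceed (p_strict=%.3g)",
        observed,
        exceeding,
        n_trials,
        pvalue_strict,
    )
    return GlobalTestResult(observed, n_trials, rng_seed, exceeding, pvalue_strict, pvalue_corrected)


@dataclass
class WilcoxonResult:
    n_pairs_used: int
    statistic: float  # signed-rank sum W+
    pvalue_two_sided: float
    method: Literal["exact", "normal-approximation"]
    n_zeros_dropped: int = 0


#: largest tie-free sample size for which the exact distribution is enumerated
EXACT_WILCOXON_LIMIT = 25


def _signed_rank_distribution(n: int) -> np.ndarray:
    """Counts of sign assignments per W+ value for tie-free ranks 1..n.

    Dynamic program equivalent to enumerating all 2**n sign vectors: the
    generating polynomial prod_r (1 + x**r).
    """
    total = n * (n + 1) // 2
    dist = np.zeros(total + 1, dtype=np.int64)
    dist[0] = 1
    for r in range(1, n + 1):
        nxt = dist.copy()
        nxt[r:] += dist[:-r]
        dist = nxt
    return dist


def exact_wilcoxon_signed_rank(
    differences: Sequence[float], exact_limit: int = EXACT_WILCOXON_LIMIT
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test on a vector of differences.

    Zero differences are dropped.  With at most ``exact_limit`` pairs and
    no ties among absolute differences, the p-value is exact over all
    2**n sign assignments; otherwise a normal approximation with
    continuity and tie corrections is used and the method flagged.
    """
    d = np.asarray(list(differences), dtype=float)
    if d.size == 0 or np.isnan(d).any():
        raise ValueError("differences must be non-empty and free of NaN")
    nonzero = d[d != 0]
    n_zeros = int(d.size - nonzero.size)
    if nonzero.size == 0:
        raise ValueError("all differences are zero; the test is undefined")
    n = int(nonzero.size)
    ranks = rankdata(np.abs(nonzero))  # midranks on ties
    w_plus = float(ranks[nonzero > 0].sum())
    has_ties = len(np.unique(np.abs(nonzero))) < n
    if n <= exact_limit and not has_ties:
        dist = _signed_rank_distribution(n)
        denom = float(2**n)
        w = int(round(w_plus))
        p_ge = float(dist[w:].sum()) / denom
        p_le = float(dist[: w + 1].sum()) / denom
        pvalue = min(1.0, 2.0 * min(p_ge, p_le))
        return WilcoxonResult(n, w_plus, pvalue, "exact", n_zeros)
    mu = n * (n + 1) / 4.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction on the variance
    _, counts = np.unique(ranks, return_counts=True)
    sigma2 -= float((counts**3 - counts).sum()) / 48.0
    if sigma2 <= 0:
        raise ValueError("degenerate variance (all absolute differences tied at one value)")
    z = w_plus - mu
    z -= math.copysign(0.5, z) if z != 0 else 0.0  # continuity correction
    z /= math.sqrt(sigma2)
    pvalue = min(1.0, 2.0 * min(norm.sf(z), norm.cdf(z)))
    return WilcoxonResult(n, w_plus, float(pvalue), "normal-approximation", n_zeros)


def family_export_test(
    family: Iterable[str],
    condition_pairs: Sequence[tuple[str, str]],
    scores: ScoreTable,
) -> WilcoxonResult:
    """Paired Wilcoxon test of a family's shift across condition contrasts.

    For every family member and every (column_a, column_b) pair, one paired
    difference ``a - b`` is formed (e.g. vesicle minus parental-cell log2
    expression); differences from all condition pairs are concatenated and
    passed to :func:`exact_wilcoxon_signed_rank`.  Members missing in
    either column contribute no difference for that pair (reported).
    """
    diffs: list[float] = []
    n_dropped = 0
    for member in sorted(set(family)):
        for col_a, col_b in condition_pairs:
            va = scores.value(member, col_a)
            vb = scores.value(member, col_b)
            if math.isnan(va) or math.isnan(vb):
                n_dropped += 1
                continue
            diffs.append(va - vb)
    if n_dropped:
        logger.warning("family export test: %d (member, pair) difference(s) dropped", n_dropped)
    if len(diffs) < 2:
        raise ValueError(f"fewer than 2 usable paired differences ({len(diffs)})")
    return exact_wilcoxon_signed_rank(diffs)


def benjamini_hochberg(pvalues: Sequence[float]) -> list[float]:
    """BH step-up adjusted p-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return []
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        idx = order[rank_from_top]
        running = min(running, p[idx] * m / (rank_from_top + 1))
        adjusted[idx] = running
    return adjusted.tolist()


def run_local_tests_all_groups(
    network: MiRNANetwork,
    hits: HitSet,
    grouping: Literal["components"] | Sequence[tuple[str, set[str]]] = "components",
) -> list[LocalTestResult]:
    """Local binomial test for every group, with BH-adjusted p-values.

    ``grouping="components"`` tests each connected component (family or
    cluster); an explicit list of (group_id, node_set) pairs is also
    accepted.  Groups with no measured node are skipped.  Results are
    ordered by raw p-value.
    """
    if grouping == "components":
        groups = [
            (f"component_{i:03d}", comp)
            for i, comp in enumerate(connected_components(network), start=1)
        ]
    else:
        groups = [(gid, set(nodes)) for gid, nodes in grouping]
    results: list[LocalTestResult] = []
    for group_id, nodes in groups:
        if not nodes & hits.measured_ids:
            continue
        results.append(local_binomial_test(nodes, hits, network, group_id=group_id))
    adjusted = benjamini_hochberg([r.pvalue for r in results])
    for r, adj in zip(results, adjusted):
        r.pvalue_bh = adj
    results.sort(key=lambda r: (r.pvalue, r.group_id))
    return results


def target_set_enrichment(
    targets: TargetPredictionTable, gene_set: set[str], universe: set[str]
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``gene_set`` in each miRNA's targets.

    Per miRNA: draws = targets ∩ universe, observed = draws ∩ gene_set,
    p-value = P(overlap >= observed) with population ``|universe|`` and
    ``|gene_set|`` successes.  Returns a table sorted by p-value.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not gene_set <= universe:
        raise ValueError("gene_set must be a subset of the universe")
    rows = []
    for mirna_id in sorted(targets.targets):
        draws = targets.targets[mirna_id] & universe
        observed = len(draws & gene_set)
        if observed == 0:
            pvalue = 1.0
        else:
            pvalue = float(hypergeom.sf(observed - 1, len(universe), len(gene_set), len(draws)))
        rows.append(
            {
                "mirna_id": mirna_id,
                "n_targets": len(targets.targets[mirna_id]),
                "n_in_universe": len(draws),
                "overlap": observed,
                "pvalue": pvalue,
            }
        )
    df = pd.DataFrame(rows, columns=["mirna_id", "n_targets", "n_in_universe", "overlap", "pvalue"])
    if not df.empty:
        df["pvalue_bh"] = benjamini_hochberg(df["pvalue"].tolist())
        df = df.sort_values(["pvalue", "mirna_id"], kind="stable").reset_index(drop=True)
    return df
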