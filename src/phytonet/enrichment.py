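"""Gene-set over-representation analysis (hypergeometric / EASE).

For a query of n genes drawn from a background of N annotated genes, a term
covering K background genes, and k genes in common, the enrichment p-value
is the hypergeometric upper tail P(X >= k). The EASE variant evaluates the
tail at k−1, a deliberately conservative convention popularised by the
DAVID web service; it is available via ``statistic="ease"``.

Multiple-testing correction is off by default (raw p < alpha flags
significance, matching how term counts are usually reported in
network-pharmacology screens); Benjamini–Hochberg within each namespace is
available and recommended for new analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .models import GeneSetAnnotation

log = logging.getLogger(__name__)


@dataclass
class EnrichmentConfig:
    alpha: float = 0.05
    correction: str = "none"  # none | bh
    statistic: str = "hypergeometric"  # hypergeometric | ease
    background: set | None = None  # None -> union of annotation genes

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must lie in (0,1)")
        if self.correction not in ("none", "bh"):
            raise ConfigurationError(f"unknown correction {self.correction!r}")
        if self.statistic not in ("hypergeometric", "ease"):
            raise ConfigurationError(f"unknown statistic {self.statistic!r}")


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    namespace: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    p_adjusted: float
    enriched_genes: frozenset
    significant: bool
    module_label: str = "other"


def hypergeometric_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), summed in log-space.

    N is the background size, K the term size, n the query size and k the
    observed overlap. Exact to better than 10 significant digits for
    N <= 1e4.
    """
    if not (0 <= k <= min(n, K) and 0 <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} n={n} K={K} N={N}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(n, K) + 1)
    logp = hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def ease_score(k: int, n: int, K: int, N: int) -> float:
    """The EASE variant: upper tail evaluated at k−1 (more conservative)."""
    return hypergeometric_upper_tail(max(k - 1, 0), n, K, N)


def enrich(
    query: set,
    annotations: list[GeneSetAnnotation],
    cfg: EnrichmentConfig | None = None,
) -> list[EnrichmentResult]:
    """Test each annotated term for over-representation in the query.

    Only terms with at least one query gene (k >= 1) are reported, sorted by
    ascending p-value. With ``correction="bh"``, adjustment is applied
    within each namespace.
    """
    cfg = cfg or EnrichmentConfig()
    if not query:
        raise ValueError("empty query gene set")
    query = {g.upper() for g in query}
    if cfg.background is None:
        background = set().union(*(a.genes for a in annotations)) if annotations else set()
    else:
        background = {g.upper() for g in cfg.background}
        for a in annotations:
            missing = a.genes - background
            if missing:
                raise ConfigurationError(
                    f"{a.term_id}: {len(missing)} term genes outside the explicit background"
                )
    eff_query = query & background
    if not eff_query:
        warnings.warn("query does not intersect the annotation background")
        return []

    N, n = len(background), len(eff_query)
    stat = hypergeometric_upper_tail if cfg.statistic == "hypergeometric" else ease_score
    results = []
    for a in annotations:
        term_genes = a.genes & background
        hits = eff_query & term_genes
        k, K = len(hits), len(term_genes)
        if k == 0:
            continue
        p = stat(k, n, K, N)
        results.append(
            EnrichmentResult(
                term_id=a.term_id,
                term_name=a.term_name,
                namespace=a.namespace,
                k=k, n=n, K=K, N=N,
                p_value=p,
                p_adjusted=p,
                enriched_genes=frozenset(hits),
                significant=False,
                module_label=a.module_label or "other",
            )
        )

    if cfg.correction == "bh" and results:
        adjusted = {}
        for ns in sorted({r.namespace for r in results}):
            ns_results = [r for r in results if r.namespace == ns]
            _, p_adj, _, _ = multipletests(
                [r.p_value for r in ns_results], method="fdr_bh"
            )
            for r, q in zip(ns_results, p_adj):
                adjusted[r.term_id] = float(q)
        results = [replace(r, p_adjusted=adjusted[r.term_id]) for r in results]

    key = (lambda r: r.p_adjusted) if cfg.correction == "bh" else (lambda r: r.p_value)
    results = [
        replace(r, significant=key(r) < cfg.alpha)
        for r in sorted(results, key=lambda r: (r.p_value, r.term_id))
    ]
    log.info(
        "enrichment: %d/%d terms with k>=1, %d significant at alpha=%g",
        len(results), len(annotations),
        sum(r.significant for r in results), cfg.alpha,
    )
    return results


def assign_modules(results: list[EnrichmentResult], module_map) -> list[EnrichmentResult]:
    """Attach functional-module labels (e.g. inflammation / metabolism).

    ``module_map`` maps term_id → label; it may be a dict or an iterable of
    (term_id, label) pairs. Unmapped terms keep the label "other". A term
    mapped twice with conflicting labels is a configuration error.
    """
    if not isinstance(module_map, dict):
        collected: dict[str, str] = {}
        for term_id, label in module_map:
            if term_id in collected and collected[term_id] != label:
                raise ConfigurationError(
                    f"term {term_id!r} mapped to both "
                    f"{collected[term_id]!r} and {label!r}"
                )
            collected[term_id] = label
        module_map = collected
    labelled = [
        replace(r, module_label=module_map.get(r.term_id, "other")) for r in results
    ]
    counts: dict[str, int] = {}
    for r in labelled:
        counts[r.module_label] = counts.get(r.module_label, 0) + 1
    log.info("module label counts: %s", dict(sorted(counts.items())))
    return labelled


def results_to_frame(results: list[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "namespace": r.namespace,
                "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                "p": r.p_value,
                "p_adj": r.p_adjusted,
                "significant": r.significant,
                "module": r.module_label,
                "genes": ",".join(sorted(r.enriched_genes)),
            }
            for r in results
        ]
    )
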