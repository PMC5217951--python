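"""Pathway over-representation analysis of model feature sets.

Mirrors a DAVID-style analysis: a one-tailed hypergeometric test per
pathway (optionally the more conservative EASE variant computed on k−1
successes), Benjamini–Hochberg control of the false discovery rate, and
a name-pattern blocklist that removes disease-specific pathways (e.g.
"Pathways in cancer") from the significant list while still reporting
their statistics.

The background population defaults to all genes appearing in the pathway
collection, which is how DAVID behaves when no custom background is
supplied; pass ``background`` explicitly to override.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Blocklist patterns shipped as default: the analysis focuses on signalling
#: and metabolic pathways, so disease-named KEGG entries are excluded.
DEFAULT_BLOCKLIST = (r"cancer", r"diabetes mellitus", r"disease$")


@dataclass(frozen=True)
class PathwayCollection:
    """Named gene sets plus the background population ``N``.

    Pathway genes outside the background are dropped with a warning;
    empty pathways are rejected.
    """

    pathways: dict[str, frozenset[str]]
    background: frozenset[str]

    @classmethod
    def from_dict(
        cls, pathways: dict, background: set[str] | None = None
    ) -> "PathwayCollection":
        if background is None:
            background = set().union(*pathways.values()) if pathways else set()
        background = frozenset(background)
        clean = {}
        for name, genes in pathways.items():
            genes = frozenset(genes)
            if not genes:
                raise ValueError(f"pathway {name!r} has an empty gene set")
            outside = genes - background
            if outside:
                logger.warning(
                    "pathway %r: dropping %d genes outside background",
                    name,
                    len(outside),
                )
                genes -= outside
            if genes:
                clean[name] = genes
        return cls(pathways=clean, background=background)


def read_gmt(path: str | Path, background: set[str] | None = None) -> PathwayCollection:
    """Read a GMT file (pathway name, description, tab-separated genes)."""
    pathways: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 columns")
            pathways[parts[0]] = frozenset(g for g in parts[2:] if g)
    return PathwayCollection.from_dict(pathways, background)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.pathways):
            genes = "\t".join(sorted(collection.pathways[name]))
            fh.write(f"{name}\tna\t{genes}\n")


@dataclass(frozen=True)
class EnrichmentResult:
    """Contingency counts and test outcome for one pathway."""

    pathway: str
    k: int  # feature genes in the pathway
    K: int  # background genes in the pathway
    n: int  # feature-set size within the background
    N: int  # background size
    p: float
    fdr: float
    significant: bool
    excluded: bool
    exclude_reason: str = ""


def hypergeom_tail(N: int, K: int, n: int, k: int, mode: str = "exact") -> float:
    """Upper-tail probability ``P(X >= k)`` for ``X ~ Hypergeom(N, K, n)``.

    ``mode="ease"`` computes the EASE score, the same tail on ``k - 1``
    successes (floored at 0), DAVID's conservative variant.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"invalid hypergeometric bounds N={N} K={K} n={n} k={k}")
    if mode == "ease":
        k = max(k - 1, 0)
    elif mode != "exact":
        raise ValueError(f"unknown mode {mode!r}")
    # sf(k-1) = P(X >= k)
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, order-preserving."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_model(
    features: set[str],
    collection: PathwayCollection,
    blocklist: tuple[str, ...] = DEFAULT_BLOCKLIST,
    fdr_threshold: float = 0.05,
    mode: str = "exact",
) -> list[EnrichmentResult]:
    """Test every pathway for over-representation of ``features``.

    Results are sorted by p-value (ties by pathway name); a result is
    ``significant`` when its BH-adjusted value is below ``fdr_threshold``
    and its name matches no blocklist pattern (matching is case-
    insensitive substring/regex search).  Blocklisted pathways are still
    computed and reported with ``excluded=True``.
    """
    feats = frozenset(features) & collection.background
    if not feats:
        raise ValueError(
            f"none of the {len(set(features))} feature genes occur in the "
            f"{len(collection.background)}-gene background; check identifier namespaces"
        )
    N = len(collection.background)
    n = len(feats)
    names = sorted(collection.pathways)
    pvals = []
    counts = []
    for name in names:
        genes = collection.pathways[name]
        K = len(genes)
        k = len(feats & genes)
        counts.append((k, K))
        pvals.append(hypergeom_tail(N, K, n, k, mode=mode))
    fdrs = bh_adjust(pvals)
    patterns = [re.compile(pat, re.IGNORECASE) for pat in blocklist]
    results = []
    for name, (k, K), p, fdr in zip(names, counts, pvals, fdrs):
        reason = next((pat.pattern for pat in patterns if pat.search(name)), "")
        excluded = bool(reason)
        results.append(
            EnrichmentResult(
                pathway=name,
                k=k,
                K=K,
                n=n,
                N=N,
                p=float(p),
                fdr=float(fdr),
                significant=bool(fdr < fdr_threshold and not excluded),
                excluded=excluded,
                exclude_reason=reason,
            )
        )
    results.sort(key=lambda r: (r.p, r.pathway))
    return results


def significant_pathways(results: list[EnrichmentResult]) -> list[str]:
    """Names of significant, non-excluded pathways (sorted by p)."""
    return [r.pathway for r in results if r.significant]


def results_table(results: list[EnrichmentResult]):
    """Enrichment results as a DataFrame with all contingency fields."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "k": r.k,
                "K": r.K,
                "n": r.n,
                "N": r.N,
                "p": r.p,
                "fdr": r.fdr,
                "significant": r.significant,
                "excluded": r.excluded,
                "exclude_reason": r.exclude_reason,
            }
            for r in results
        ]
    )
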