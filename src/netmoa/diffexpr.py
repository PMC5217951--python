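"""Two-class differential expression with the SAM permutation scheme.

Implements the Significance Analysis of Microarrays for an unpaired
two-group design on an already-normalized, log-scale transcript matrix
(raw-array preprocessing is out of scope).  Per transcript the moderated
difference statistic is

    d = (mean_treated - mean_control) / (s + s0)

with the pooled standard error

    s = sqrt( ((1/n_t + 1/n_c) / (n_t + n_c - 2)) * (SS_t + SS_c) )

where ``SS`` is the within-group sum of squared deviations, and ``s0`` a
small "fudge factor" stabilising low-variance transcripts (default: the
5th percentile of the per-transcript ``s`` distribution).

Significance calling follows the permutation recipe: the observed order
statistics ``d_(i)`` are compared with their null expectation ``dbar_(i)``
(the mean of the sorted statistics over group-label permutations); the
smallest ``d_(i)`` with ``d_(i) - dbar_(i) > delta`` sets the upper
cutoff and, symmetrically, the largest ``d_(i)`` with
``dbar_(i) - d_(i) > delta`` the lower one.  The estimated FDR is
``pi0 * median_perm(# permuted d beyond the cutoffs) / n_called``.  When
a target FDR is given instead of ``delta``, the smallest delta on a
fixed grid whose estimate stays below the target is selected.

The module also provides the sample-QC dendrogram (1 − Pearson
correlation distance, unweighted average linkage) and the collapse of
called transcripts to protein-coding genes.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

TREATED, CONTROL = "treated", "control"

#: Enumerate all distinct treated-set assignments when there are at most
#: this many; otherwise sample ``n_perm`` assignments with the run seed.
FULL_ENUMERATION_CAP = 500

#: Delta grid scanned when calling at a target FDR.
DELTA_GRID = np.round(np.arange(0.05, 10.0001, 0.05), 10)


@dataclass
class ExpressionMatrix:
    """Transcripts × samples matrix of normalized log intensities.

    ``groups`` maps every sample (column) to ``"treated"`` or
    ``"control"``; each group needs at least two samples.
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        bad = {g for g in self.groups.values()} - {TREATED, CONTROL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")
        for g in (TREATED, CONTROL):
            if len(self.samples(g)) < 2:
                raise ValueError(f"group {g!r} needs >= 2 samples")

    def samples(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, groups_path: str | Path):
        """Read a TSV matrix (rows transcripts) and a two-column group file."""
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        gdf = pd.read_csv(
            groups_path, sep="\t", header=None, names=["sample", "group"], comment="#"
        )
        return cls(values=values, groups=dict(zip(gdf["sample"], gdf["group"])))


@dataclass
class TranscriptGeneMap:
    """Mapping transcript id → (gene id, biotype)."""

    table: pd.DataFrame  # columns: transcript_id, gene_id, biotype

    REQUIRED = ("transcript_id", "gene_id", "biotype")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"transcript map lacks column {col!r}")

    @classmethod
    def from_tsv(cls, path: str | Path):
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class SamResult:
    """Outcome of one SAM analysis.

    ``table`` holds one row per transcript: the observed statistic ``d``,
    the call flag and the direction (``up``/``down``) of called
    transcripts.  ``est_fdr`` is NaN when nothing is called.
    """

    table: pd.DataFrame  # index transcript; columns d, called, direction
    delta: float
    s0: float
    est_fdr: float
    n_called: int
    cut_up: float
    cut_low: float
    n_perm: int
    rng_seed: int | None = None
    degenerate: tuple[str, ...] = field(default_factory=tuple)

    @property
    def called(self) -> pd.DataFrame:
        return self.table[self.table["called"]]


def sam_statistic(group_a, group_b, s0: float = 0.0) -> float:
    """SAM d statistic for one transcript: ``(mean_b - mean_a) / (s + s0)``.

    ``group_a`` is the control, ``group_b`` the treated group.  A zero
    denominator (both groups constant and ``s0 == 0``) raises
    ``ZeroDivisionError`` to signal a degenerate transcript.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if s0 < 0:
        raise ValueError("s0 must be non-negative")
    s = _pooled_se(a, b)
    if s + s0 == 0.0:
        raise ZeroDivisionError("zero variance in both groups with s0 = 0")
    return float((b.mean() - a.mean()) / (s + s0))


def _pooled_se(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    return math.sqrt((1.0 / na + 1.0 / nb) / (na + nb - 2) * ss)


def _d_vector(X: np.ndarray, treated_mask: np.ndarray, s0: float):
    """Vectorized d and s for all transcripts under one label assignment."""
    a = X[:, ~treated_mask]
    b = X[:, treated_mask]
    na, nb = a.shape[1], b.shape[1]
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((b - b.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / na + 1.0 / nb) / (na + nb - 2) * ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = (b.mean(axis=1) - a.mean(axis=1)) / (s + s0)
    return d, s


def _assignments(n: int, n_treated: int, n_perm: int, rng_seed: int | None):
    """Treated-set masks: full enumeration when feasible, else sampled."""
    total = math.comb(n, n_treated)
    cols = np.arange(n)
    if total <= FULL_ENUMERATION_CAP:
        masks = np.zeros((total, n), dtype=bool)
        for i, combo in enumerate(itertools.combinations(range(n), n_treated)):
            masks[i, list(combo)] = True
        return masks
    rng = np.random.default_rng(rng_seed)
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(cols, size=n_treated, replace=False)] = True
    return masks


def _cutoffs(d_sorted: np.ndarray, dbar: np.ndarray, delta: float):
    """Upper/lower cutoffs from the observed-vs-expected quantile walk.

    The walk moves outward from the origin: the upper cutoff is the
    smallest non-negative ``d_(i)`` whose excess over the null
    expectation exceeds ``delta``, the lower cutoff its mirror image.
    """
    diff = d_sorted - dbar
    up_idx = np.nonzero((diff > delta) & (d_sorted >= 0))[0]
    low_idx = np.nonzero((-diff > delta) & (d_sorted <= 0))[0]
    cut_up = d_sorted[up_idx[0]] if up_idx.size else np.inf
    cut_low = d_sorted[low_idx[-1]] if low_idx.size else -np.inf
    return cut_up, cut_low


def sam_call(
    matrix: ExpressionMatrix,
    delta: float | None = None,
    target_fdr: float | None = None,
    n_perm: int = 100,
    rng_seed: int | None = None,
    s0: float | None = None,
    pi0: float = 1.0,
    fdr_estimator: str = "mean",
) -> SamResult:
    """Run SAM on a two-group matrix.

    Exactly one of ``delta`` (call at a fixed threshold) or
    ``target_fdr`` (select the smallest grid delta whose estimated FDR is
    below the target) must be given.  Deterministic for a fixed
    ``rng_seed``; with at most ``FULL_ENUMERATION_CAP`` distinct label
    assignments the permutation set does not depend on the seed at all.

    The estimated FDR is ``pi0`` times the number of permuted statistics
    beyond the cutoffs — averaged over permutations with
    ``fdr_estimator="mean"`` (the default; strictly conservative when
    only a handful of transcripts sit near the cutoffs) or the
    per-permutation median with ``"median"`` — divided by the number of
    calls.

    Transcripts with zero variance in both groups when ``s0 == 0`` are
    excluded from calling and reported in ``degenerate``.
    """
    if fdr_estimator not in ("mean", "median"):
        raise ValueError(f"unknown fdr_estimator {fdr_estimator!r}")
    if (delta is None) == (target_fdr is None):
        raise ValueError("give exactly one of delta or target_fdr")
    X = matrix.values.to_numpy(dtype=float)
    samples = list(matrix.values.columns)
    treated_mask = np.array([matrix.groups[s] == TREATED for s in samples])

    _, s_obs = _d_vector(X, treated_mask, s0=0.0)
    if s0 is None:
        s0 = float(np.percentile(s_obs, 5.0))
    degenerate = s_obs + s0 == 0.0
    if degenerate.any():
        logger.warning("%d degenerate zero-variance transcripts excluded", degenerate.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        num = X[:, treated_mask].mean(axis=1) - X[:, ~treated_mask].mean(axis=1)
        d_obs = np.where(degenerate, 0.0, num / (s_obs + s0))

    masks = _assignments(X.shape[1], int(treated_mask.sum()), n_perm, rng_seed)
    perm_d = np.empty((masks.shape[0], X.shape[0]))
    for i, m in enumerate(masks):
        di, _ = _d_vector(X, m, s0=s0)
        perm_d[i] = np.where(degenerate, 0.0, di)
    perm_sorted = np.sort(perm_d, axis=1)
    dbar = perm_sorted.mean(axis=0)
    order = np.argsort(d_obs, kind="stable")
    d_sorted = d_obs[order]

    def evaluate(dlt: float):
        cut_up, cut_low = _cutoffs(d_sorted, dbar, dlt)
        called = (~degenerate) & ((d_obs >= cut_up) | (d_obs <= cut_low))
        ncall = int(called.sum())
        if ncall == 0:
            return called, math.nan, cut_up, cut_low, 0
        beyond = ((perm_d >= cut_up) | (perm_d <= cut_low)).sum(axis=1)
        agg = np.mean if fdr_estimator == "mean" else np.median
        fdr = pi0 * float(agg(beyond)) / ncall
        return called, fdr, cut_up, cut_low, ncall

    if delta is not None:
        chosen = float(delta)
        called, est_fdr, cut_up, cut_low, ncall = evaluate(chosen)
    else:
        chosen = float(DELTA_GRID[-1])
        called, est_fdr, cut_up, cut_low, ncall = evaluate(chosen)
        for dlt in DELTA_GRID:
            c, f, cu, cl, nc = evaluate(float(dlt))
            # zero calls trivially control the FDR; NaN marks that case
            if nc == 0 or f < target_fdr:
                chosen, called, est_fdr, cut_up, cut_low, ncall = (
                    float(dlt), c, f, cu, cl, nc,
                )
                break
    if ncall == 0:
        logger.info("no transcripts called at delta=%.3g", chosen)

    direction = np.where(called & (d_obs > 0), "up", np.where(called, "down", ""))
    table = pd.DataFrame(
        {"d": d_obs, "called": called, "direction": direction},
        index=matrix.values.index,
    )
    return SamResult(
        table=table,
        delta=chosen,
        s0=float(s0),
        est_fdr=float(est_fdr) if not math.isnan(est_fdr) else math.nan,
        n_called=ncall,
        cut_up=float(cut_up),
        cut_low=float(cut_low),
        n_perm=int(masks.shape[0]),
        rng_seed=rng_seed,
        degenerate=tuple(matrix.values.index[degenerate]),
    )


# ---------------------------------------------------------------------------
# sample QC clustering


@dataclass
class Dendrogram:
    """Average-linkage merge tree over samples with 1 − r distances."""

    merge: np.ndarray  # scipy linkage matrix
    labels: list[str]
    groups_separate: bool

    def to_newick(self) -> str:
        from scipy.cluster.hierarchy import to_tree

        def rec(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = rec(node.left), rec(node.right)
            dl = node.dist - (0 if node.left.is_leaf() else node.left.dist)
            dr = node.dist - (0 if node.right.is_leaf() else node.right.dist)
            return f"({left}:{dl / 2:.6g},{right}:{dr / 2:.6g})"

        return rec(to_tree(self.merge)) + ";"


def cluster_samples(matrix: ExpressionMatrix) -> Dendrogram:
    """Hierarchical sample clustering: 1 − Pearson r, average linkage.

    Raises on zero-variance samples (Pearson undefined).  The
    ``groups_separate`` flag records whether cutting the tree into two
    clusters reproduces the treated/control split.
    """
    X = matrix.values.to_numpy(dtype=float).T  # samples x transcripts
    var = X.var(axis=1)
    if np.any(var == 0):
        bad = [s for s, v in zip(matrix.values.columns, var) if v == 0]
        raise ValueError(f"zero-variance samples: {bad}")
    dist = pdist(X, metric="correlation")  # == 1 - pearson r, in [0, 2]
    merge = linkage(dist, method="average")
    two = fcluster(merge, t=2, criterion="maxclust")
    labels = list(matrix.values.columns)
    split = {}
    for s, c in zip(labels, two):
        split.setdefault(c, set()).add(matrix.groups[s])
    separate = len(split) == 2 and all(len(v) == 1 for v in split.values())
    return Dendrogram(merge=merge, labels=labels, groups_separate=separate)


def distance_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Symmetric 1 − Pearson distance matrix over samples."""
    X = matrix.values.to_numpy(dtype=float).T
    d = squareform(pdist(X, metric="correlation"))
    np.fill_diagonal(d, 0.0)
    labels = list(matrix.values.columns)
    return pd.DataFrame(d, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# gene-level collapse

UP, DOWN, CONTRADICTORY = "up", "down", "contradictory"


def collapse_to_genes(
    result: SamResult,
    tmap: TranscriptGeneMap,
    biotype: str = "protein_coding",
) -> pd.DataFrame:
    """Collapse called transcripts to a gene-level regulation table.

    Transcripts without a mapping or with a biotype other than
    ``protein_coding`` are dropped (counts logged).  A gene with both up-
    and down-called transcripts is ``contradictory``.

    Returns a DataFrame with columns ``gene_id``, ``direction``,
    ``n_transcripts``.
    """
    called = result.called
    m = tmap.table.set_index("transcript_id")
    known = called.index.intersection(m.index)
    n_unmapped = len(called) - len(known)
    sub = m.loc[known]
    coding = sub[sub["biotype"] == biotype]
    n_noncoding = len(sub) - len(coding)
    if n_unmapped or n_noncoding:
        logger.info(
            "collapse: dropped %d unmapped and %d non-%s transcripts",
            n_unmapped,
            n_noncoding,
            biotype,
        )
    rows = []
    merged = coding.join(called.loc[coding.index, ["direction"]])
    for gene, grp in merged.groupby("gene_id", sort=True):
        dirs = set(grp["direction"])
        state = CONTRADICTORY if dirs == {UP, DOWN} else dirs.pop()
        rows.append(
            {"gene_id": gene, "direction": state, "n_transcripts": len(grp)}
        )
    return pd.DataFrame(rows, columns=["gene_id", "direction", "n_transcripts"])
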