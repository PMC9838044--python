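"""Expression-breadth analysis over TPM matrices.

A gene's expression breadth is the number of samples (root ages, tissues, or
cultivars) in which it is called expressed.  The module calls
expressed/not-expressed from TPM, builds per-design breadth histograms,
contrasts a target gene set against random same-size draws from a background
pool (the random-transcript negative control), extracts the core
ubiquitously-expressed set across designs, flags monotone age trends, and
groups samples by expression similarity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


class Design(str, Enum):
    """The three sample designs of the expression study."""

    AGES4 = "ages4"
    TISSUES14 = "tissues14"
    CULTIVARS42 = "cultivars42"


DESIGN_SIZES = {Design.AGES4: 4, Design.TISSUES14: 14, Design.CULTIVARS42: 42}

#: root ages (years) of the four-age design, in sampling order.
DEFAULT_AGES = (5, 12, 18, 25)


@dataclass
class ExpressionMatrix:
    """A genes x samples TPM matrix with optional design metadata.

    ``values`` is a pandas DataFrame (rows: gene ids, columns: sample ids).
    When ``design`` is given the column count must match the design and, for
    the four-age design, ``sample_labels`` (ages) must be strictly increasing.
    """

    values: pd.DataFrame
    design: Design | None = None
    sample_labels: tuple = ()

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("TPM values must be non-negative")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("gene and sample ids must be unique")
        if self.design is not None:
            self.design = Design(self.design)
            expected = DESIGN_SIZES[self.design]
            if self.values.shape[1] != expected:
                raise ValueError(
                    f"design {self.design.value} expects {expected} samples, "
                    f"got {self.values.shape[1]}"
                )
            if self.design is Design.AGES4:
                ages = tuple(self.sample_labels) or DEFAULT_AGES
                if list(ages) != sorted(ages) or len(set(ages)) != len(ages):
                    raise ValueError("ages must be strictly increasing")
                self.sample_labels = ages

    @property
    def gene_ids(self):
        return list(self.values.index)

    @property
    def sample_ids(self):
        return list(self.values.columns)


def _frame(m) -> pd.DataFrame:
    return m.values if isinstance(m, ExpressionMatrix) else m


def call_expressed(m, threshold: float = 0.0) -> pd.DataFrame:
    """Boolean expressed calls: TPM strictly greater than *threshold*."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return _frame(m) > threshold


def breadth_counts(expressed: pd.DataFrame) -> pd.Series:
    """Per-gene breadth k = number of samples with an expressed call."""
    return expressed.sum(axis=1)


def breadth_distribution(expressed: pd.DataFrame) -> pd.DataFrame:
    """Histogram of breadth k = 0..n_samples with counts and percentages.

    Counts sum to the number of genes; percent = count / genes * 100 (report
    to 1 decimal place when printing).
    """
    n_samples = expressed.shape[1]
    k = breadth_counts(expressed)
    counts = k.value_counts().reindex(range(n_samples + 1), fill_value=0)
    counts.index.name = "k"
    n_genes = expressed.shape[0]
    pct = counts / n_genes * 100.0 if n_genes else counts * 0.0
    return pd.DataFrame({"count": counts, "percent": pct})


def percent_at_least(expressed: pd.DataFrame, k_min: int = 1) -> float:
    """Percentage of genes expressed in at least *k_min* samples."""
    n = expressed.shape[0]
    return float((breadth_counts(expressed) >= k_min).sum()) / n * 100.0


@dataclass
class BackgroundComparison:
    """Target breadth vs random same-size draws from a background pool."""

    target_counts: np.ndarray  # per-k histogram of the target set
    random_mean: np.ndarray  # per-k mean over bootstrap draws
    random_sd: np.ndarray
    n_boot: int
    target_at_least_one: int  # target genes with k >= 1
    random_at_least_one: np.ndarray  # per-draw counts
    p_value: float
    significant: bool  # at the declared alpha
    alpha: float
    seed: int | None


def _prediction_t_pvalue(
    observed: float, draws: np.ndarray, sampling_fraction: float = 0.0
) -> float:
    """Two-sided p for one observation against n reference draws.

    Uses the prediction-interval t statistic
    ``t = (x - mean) / (sd * sqrt(1/(1-f) + 1/n))`` with n-1 degrees of
    freedom, calibrated when the reference counts are approximately normal.
    ``f`` is the finite-pool sampling fraction of each reference draw:
    drawing a share f of the pool without replacement deflates the draw
    variance by (1-f) relative to an independent target set, so the observed
    spread is scaled back up before comparison.
    """
    n = len(draws)
    f = min(max(sampling_fraction, 0.0), 0.99)
    mean = float(np.mean(draws))
    sd = float(np.std(draws, ddof=1))
    if sd == 0:
        return 1.0 if observed == mean else 0.0
    t = (observed - mean) / (sd * math.sqrt(1.0 / (1.0 - f) + 1.0 / n))
    return float(2.0 * stats.t.sf(abs(t), df=n - 1))


def compare_with_random_background(
    target: Iterable[str],
    pool: Iterable[str],
    m,
    n_boot: int = 20,
    seed: int | None = None,
    threshold: float = 0.0,
    alpha: float = 1.0e-02,
) -> BackgroundComparison:
    """Contrast target-set breadth against random same-size background draws.

    Each of *n_boot* draws samples ``|target|`` genes without replacement from
    the pool (target genes excluded from the pool first).  Significance of the
    'expressed in at least one sample' count is a two-sided prediction-interval
    t-test of the target count against the bootstrap counts.
    """
    df = _frame(m)
    target = sorted(set(target))
    pool = sorted(set(pool) - set(target))
    if len(pool) < len(target):
        raise ValueError("pool smaller than target after exclusion")
    missing = set(target) - set(df.index)
    if missing:
        raise ValueError(f"target genes absent from matrix: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    expressed = call_expressed(df, threshold)
    n_samples = df.shape[1]

    def hist(ids):
        k = breadth_counts(expressed.loc[ids])
        return k.value_counts().reindex(range(n_samples + 1), fill_value=0).to_numpy()

    target_hist = hist(target)
    boot_hists = np.empty((n_boot, n_samples + 1), dtype=float)
    boot_k1 = np.empty(n_boot)
    for b in range(n_boot):
        draw = list(rng.choice(pool, size=len(target), replace=False))
        h = hist(draw)
        boot_hists[b] = h
        boot_k1[b] = h[1:].sum()
    target_k1 = int(target_hist[1:].sum())
    p = _prediction_t_pvalue(target_k1, boot_k1, len(target) / len(pool))
    return BackgroundComparison(
        target_counts=target_hist,
        random_mean=boot_hists.mean(axis=0),
        random_sd=boot_hists.std(axis=0, ddof=1),
        n_boot=n_boot,
        target_at_least_one=target_k1,
        random_at_least_one=boot_k1,
        p_value=p,
        significant=p <= alpha,
        alpha=alpha,
        seed=seed,
    )


def core_gene_set(expressed_by_design: Mapping[str, pd.DataFrame]) -> set:
    """Genes expressed in every sample of every design (the ubiquitous core)."""
    if not expressed_by_design:
        raise ValueError("need at least one design")
    frames = list(expressed_by_design.values())
    universe = set(frames[0].index)
    for f in frames[1:]:
        if set(f.index) != universe:
            raise ValueError("designs must share one gene universe")
    core = universe
    for f in frames:
        core = core & set(f.index[f.all(axis=1)])
    return core


@dataclass(frozen=True)
class AgeTrend:
    gene_id: str
    direction: str  # "increasing" | "decreasing"
    fold_span: float  # max/min TPM ratio (inf when min == 0)


def age_trend_genes(m, min_fold: float = 2.0) -> list[AgeTrend]:
    """Genes whose TPM varies strictly monotonically across the age series.

    A gene is flagged increasing (decreasing) when its TPM strictly increases
    (decreases) over the age-ordered samples and the max/min ratio reaches
    *min_fold*.  Columns are assumed age-ordered (enforced by
    :class:`ExpressionMatrix` for the four-age design).
    """
    df = _frame(m)
    if isinstance(m, ExpressionMatrix) and m.design not in (None, Design.AGES4):
        raise ValueError("age trends require the four-age design")
    trends = []
    vals = df.to_numpy(dtype=float)
    for gene, row in zip(df.index, vals):
        diffs = np.diff(row)
        if (diffs > 0).all():
            direction = "increasing"
        elif (diffs < 0).all():
            direction = "decreasing"
        else:
            continue
        lo, hi = row.min(), row.max()
        span = math.inf if lo == 0 else hi / lo
        if span >= min_fold:
            trends.append(AgeTrend(str(gene), direction, span))
    return trends


def cluster_samples(m, k_groups: int = 2) -> pd.Series:
    """Group samples by expression similarity.

    Agglomerative clustering with average linkage on the distance
    ``1 - Spearman rho`` between sample columns, cut into *k_groups*.  Groups
    are renumbered 1..k in order of first appearance, so the labeling is
    deterministic for a given column order.  Zero-variance columns get rho 0
    (distance 1) against every other sample, with a warning.
    """
    df = _frame(m)
    n = df.shape[1]
    if n < k_groups:
        raise ValueError("fewer samples than requested groups")
    vals = df.to_numpy(dtype=float)
    constant = vals.std(axis=0) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant sample column(s); "
            "assigned by unit distance",
            stacklevel=2,
        )
    if n == 2:
        rho = np.array([[1.0, 0.0], [0.0, 1.0]]) if constant.any() else None
        if rho is None:
            r = stats.spearmanr(vals[:, 0], vals[:, 1]).statistic
            rho = np.array([[1.0, r], [r, 1.0]])
    else:
        rho = stats.spearmanr(vals).statistic
    rho = np.asarray(rho, dtype=float)
    rho[np.isnan(rho)] = 0.0
    np.fill_diagonal(rho, 1.0)
    dist = 1.0 - rho
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    labels = fcluster(linkage(squareform(dist, checks=False), method="average"),
                      t=k_groups, criterion="maxclust")
    remap, out = {}, []
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out.append(remap[lab])
    return pd.Series(out, index=df.columns, name="group")


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

def read_tpm_matrix(path, design=None) -> ExpressionMatrix:
    """Read a TPM TSV (genes in rows, sample-id header) into a matrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, design=Design(design) if design else None)


def trends_to_frame(trends: Sequence[AgeTrend]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [t.gene_id for t in trends],
            "direction": [t.direction for t in trends],
            "fold_span": [t.fold_span for t in trends],
        }
    )


def comparison_to_dict(c: BackgroundComparison) -> dict:
    return {
        "target_counts": [int(x) for x in c.target_counts],
        "random_mean": [float(x) for x in c.random_mean],
        "random_sd": [float(x) for x in c.random_sd],
        "n_boot": c.n_boot,
        "target_at_least_one": c.target_at_least_one,
        "random_at_least_one_mean": float(np.mean(c.random_at_least_one)),
        "p_value": c.p_value,
        "significant": bool(c.significant),
        "alpha": c.alpha,
        "seed": c.seed,
    }
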