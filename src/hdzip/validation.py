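"""Independent oracles and simulation experiments validating the pipeline.

The oracles here are deliberately written as brute-force enumerations that
share no code path with the estimators they check: NG86 site/difference
counting is re-derived by enumerating mutation fates and substitution
orderings directly from the genetic code, and Spearman significance is
checked against the exact permutation distribution at small n.  The
simulation experiments (type-I error, planted-hub recovery, divergence
recovery, fold-change recovery) re-run the analysis operations on generated
data with known truth and report summary rates.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

from . import expression, network, simulate, stress
from .molevo import CodonAlignment, compute_ka_ks, jukes_cantor

_BASES = ("A", "C", "G", "T")
_STOPS = set(standard_dna_table.stop_codons)


def _aa(codon: str) -> str:
    return "*" if codon in _STOPS else standard_dna_table.forward_table[codon]


# ---------------------------------------------------------------------------
# NG86 brute-force oracle
# ---------------------------------------------------------------------------

def oracle_codon_sites(codon: str) -> float:
    """Synonymous sites of one codon by enumerating all nine mutation fates."""
    syn = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in _STOPS and _aa(mut) == _aa(codon):
                syn += 1
    return syn / 3.0


def oracle_codon_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(Sd, Nd) for one codon pair by explicit pathway enumeration.

    Every ordering of the differing positions is walked base by base;
    orderings passing through a stop codon are discarded (all orderings are
    kept if none survives), and the remainder are averaged with equal weight.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    pathways = []
    for order in permutations(diff):
        cur, steps, ok = codon_a, [], True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in _STOPS and nxt != codon_b:
                ok = False
            steps.append((_aa(cur), _aa(nxt)))
            cur = nxt
        pathways.append((ok, steps))
    usable = [s for ok, s in pathways if ok] or [s for _, s in pathways]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if a == b:
                sd += 1.0
            else:
                nd += 1.0
    return sd / len(usable), nd / len(usable)


def ng86_exhaustive_check(max_diffs: int = 2) -> dict:
    """Compare the estimator with the oracle on all sense-codon pairs.

    Runs every ordered pair of sense codons differing at <= *max_diffs*
    positions through :func:`compute_ka_ks` (as a one-codon alignment) and
    the oracle, returning the largest absolute discrepancies in site and
    difference counts, plus the worst site-conservation residual.
    """
    sense = sorted(standard_dna_table.forward_table)
    max_site_err = max_sd_err = max_nd_err = max_conservation = 0.0
    n_pairs = 0
    for a in sense:
        for b in sense:
            if sum(x != y for x, y in zip(a, b)) > max_diffs:
                continue
            n_pairs += 1
            res = compute_ka_ks(CodonAlignment(a, b))
            s_oracle = (oracle_codon_sites(a) + oracle_codon_sites(b)) / 2.0
            sd_o, nd_o = oracle_codon_diffs(a, b)
            max_site_err = max(max_site_err, abs(res.s_sites - s_oracle))
            max_sd_err = max(max_sd_err, abs(res.sd - sd_o))
            max_nd_err = max(max_nd_err, abs(res.nd - nd_o))
            max_conservation = max(
                max_conservation, abs(res.s_sites + res.n_sites - 3.0)
            )
    return {
        "n_pairs": n_pairs,
        "max_site_error": max_site_err,
        "max_sd_error": max_sd_err,
        "max_nd_error": max_nd_err,
        "max_site_conservation_residual": max_conservation,
    }


def site_conservation_residual(n_pairs: int = 20, n_codons: int = 120,
                               seed: int = 0) -> float:
    """Worst |N+S - 3*codons| over random generated alignments."""
    worst = 0.0
    for i in range(n_pairs):
        a, b, _ = simulate.gen_cds_pair(n_codons, 0.2, 0.1, seed=seed + i)
        res = compute_ka_ks(CodonAlignment(a, b))
        worst = max(worst, abs(res.s_sites + res.n_sites - 3.0 * n_codons))
    return worst


# ---------------------------------------------------------------------------
# Spearman exact-permutation oracle (n = 8)
# ---------------------------------------------------------------------------

def spearman_permutation_error(n: int = 8) -> float:
    """Worst |t-approximation p - exact permutation p| over fixture pairs.

    The exact two-sided p is the share of all n! rank permutations whose
    |rho| reaches the observed |rho| (no ties, so rho reduces to the
    rank-difference formula).
    """
    perms = np.array(list(permutations(range(1, n + 1))), dtype=float)
    base = np.arange(1, n + 1, dtype=float)
    d2 = ((perms - base) ** 2).sum(axis=1)
    rho_null = 1.0 - 6.0 * d2 / (n * (n**2 - 1))
    fixtures = [
        np.array([3, 1, 4, 2, 6, 5, 8, 7], dtype=float),
        np.array([2, 4, 1, 3, 6, 8, 5, 7], dtype=float),
        np.array([8, 6, 7, 5, 3, 4, 1, 2], dtype=float),
        np.array([1, 3, 2, 5, 4, 7, 6, 8], dtype=float),
    ]
    worst = 0.0
    for y in fixtures:
        res = stats.spearmanr(base, y)
        exact = float(np.mean(np.abs(rho_null) >= abs(res.statistic) - 1e-12))
        worst = max(worst, abs(res.pvalue - exact))
    return worst


# ---------------------------------------------------------------------------
# network properties and simulations
# ---------------------------------------------------------------------------

def nesting_violations(n_fixtures: int = 200, seed: int = 0) -> int:
    """Count threshold-nesting violations over random edge-list fixtures.

    For each fixture, networks built at a tighter p cutoff must have an edge
    set contained in the looser network's, and node/edge counts must be
    non-increasing as the threshold tightens.
    """
    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(n_fixtures):
        n_genes = int(rng.integers(6, 16))
        genes = [f"g{i:02d}" for i in range(n_genes)]
        edges = []
        for i in range(n_genes):
            for j in range(i + 1, n_genes):
                edges.append(
                    network.CorrelationEdge(
                        genes[i], genes[j],
                        rho=float(rng.uniform(-1, 1)),
                        p=float(rng.uniform(0, 0.2) ** 2),
                        n=14,
                    )
                )
        thresholds = sorted(rng.uniform(0.0005, 0.06, size=3), reverse=True)
        nets = [network.build_network(edges, t) for t in thresholds]
        for loose, tight in zip(nets, nets[1:]):
            tight_edges = {tuple(sorted(e)) for e in tight.graph.edges}
            loose_edges = {tuple(sorted(e)) for e in loose.graph.edges}
            if not tight_edges <= loose_edges:
                violations += 1
            if tight.n_edges > loose.n_edges or len(tight.nodes) > len(loose.nodes):
                violations += 1
    return violations


def type_one_error_background(
    n_sims: int = 1000,
    n_target: int = 117,
    n_pool: int = 1000,
    n_samples: int = 4,
    expressed_fraction: float = 0.4,
    alpha: float = 1.0e-02,
    seed: int = 0,
) -> float:
    """Null rejection rate of the breadth background comparison.

    Target and pool genes are drawn iid from one distribution (each gene
    expressed with the same probability, positive TPM where expressed), so
    any detected difference is a false positive.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    genes = [f"g{i}" for i in range(n_target + n_pool)]
    for _ in range(n_sims):
        vals = rng.exponential(1.0, (n_target + n_pool, n_samples))
        vals[rng.random(n_target + n_pool) >= expressed_fraction] = 0.0
        df = pd.DataFrame(vals, index=genes)
        res = expression.compare_with_random_background(
            genes[:n_target], genes[n_target:], df,
            n_boot=20, seed=int(rng.integers(2**31)), alpha=alpha,
        )
        rejections += res.p_value <= alpha
    return rejections / n_sims


def type_one_error_tendency(
    n_sims: int = 1000,
    n_target: int = 20,
    n_pool: int = 300,
    n_samples: int = 14,
    alpha: float = 1.0e-02,
    seed: int = 0,
) -> float:
    """Null rejection rate of the network-formation-tendency edge test.

    All genes are iid noise; rejection is a significant edge-count excess at
    the loosest threshold of the sweep.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    genes = [f"g{i}" for i in range(n_target + n_pool)]
    for _ in range(n_sims):
        vals = rng.standard_normal((n_target + n_pool, n_samples))
        df = pd.DataFrame(vals, index=genes)
        curve = network.tendency_test(
            genes[:n_target], genes[n_target:], df, thresholds=(5.0e-02,),
            n_boot=20, seed=int(rng.integers(2**31)), alpha=alpha,
        )
        rejections += curve.edge_p[0] <= alpha
    return rejections / n_sims


def tendency_power_check(seed: int = 0) -> dict:
    """Planted-module alternative: target shares a latent factor, pool is noise.

    Returns per-threshold significance flags and counts for one study-sized
    run (target of 20 correlated genes vs a 300-gene noise pool, 42 samples).
    """
    m, truth = simulate.gen_expression(
        n_family=20, n_pool=300, design=expression.Design.CULTIVARS42,
        module_spec=({"size": 20, "loading": 0.8},),
        pool_expressed_fraction=1.0, seed=seed,
    )
    curve = network.tendency_test(
        truth["family_ids"], truth["pool_ids"], m,
        thresholds=network.THRESHOLD_SWEEP, n_boot=20, seed=seed + 1,
    )
    return {
        "significant_all_thresholds": bool(curve.significant().all()),
        "target_edges": [int(x) for x in curve.target_edges],
        "random_edges_mean": [float(x) for x in curve.random_edges.mean(axis=0)],
        "n_boot": curve.n_boot,
    }


def hub_recovery_rate(
    n_runs: int = 100,
    n_partners: int = 20,
    loading: float = 0.8,
    n_noise: int = 50,
    threshold_p: float = 1.0e-03,
    min_connectivity: int = 15,
    seed: int = 0,
) -> float:
    """Share of seeded runs where the planted hub is called a hub.

    Each run plants one hub with *n_partners* partner genes (loading 0.8)
    among independent noise genes over 42 cultivar samples, thresholds the
    network at p <= 1e-3 and asks whether the planted gene exceeds the
    connectivity cutoff.
    """
    hits = 0
    for r in range(n_runs):
        m, truth = simulate.gen_expression(
            n_family=1 + n_partners + n_noise, n_pool=0,
            design=expression.Design.CULTIVARS42,
            hub_spec={"n_partners": n_partners, "loading": loading},
            seed=seed + r,
        )
        edges = network.spearman_edges(m.values.loc[truth["family_ids"]])
        net = network.build_network(edges, threshold_p)
        hubs = {h.gene_id for h in network.find_hubs(net, min_connectivity)}
        hits += truth["hub_ids"][0] in hubs
    return hits / n_runs


# ---------------------------------------------------------------------------
# divergence and qPCR recovery
# ---------------------------------------------------------------------------

def ks_recovery(
    n_runs: int = 100,
    n_codons: int = 500,
    target_ps: float = 0.3,
    target_pn: float = 0.1,
    seed: int = 0,
) -> dict:
    """Ks estimates on generated pairs vs the Jukes-Cantor-transformed truth.

    Per pair, the estimator's Ks is compared with JC(true_ps) from the
    generator's bookkeeping (max absolute deviation), and the run mean is
    compared with JC(target_ps) as a z-score against the Monte-Carlo
    standard error.
    """
    estimates, truths = [], []
    for r in range(n_runs):
        a, b, truth = simulate.gen_cds_pair(n_codons, target_ps, target_pn,
                                            seed=seed + r)
        res = compute_ka_ks(CodonAlignment(a, b))
        estimates.append(res.ks)
        truths.append(jukes_cantor(truth["true_ps"]))
    estimates = np.asarray(estimates)
    truths = np.asarray(truths)
    diffs = estimates - truths
    se = float(estimates.std(ddof=1) / math.sqrt(n_runs))
    target_ks = jukes_cantor(target_ps)
    return {
        "mean_ks": float(estimates.mean()),
        "target_ks": target_ks,
        "mc_se": se,
        "z_vs_target": float((estimates.mean() - target_ks) / se) if se else 0.0,
        "max_abs_vs_bookkeeping": float(np.abs(diffs).max()),
    }


def qpcr_fold_recovery(
    n_runs: int = 100,
    planted: float = 3.0,
    ct_noise_sd: float = 0.1,
    seed: int = 0,
) -> dict:
    """Mean recovered fold for a planted induction across seeded runs."""
    folds = []
    for r in range(n_runs):
        table, _ = simulate.gen_qpcr(
            genes=("G1",), planted_fold={"G1": {4.0: planted}},
            ct_noise_sd=ct_noise_sd, seed=seed + r,
        )
        rel = stress.relative_expression(table)
        summ = stress.summarize_folds(rel)
        row = summ[(summ.gene_id == "G1") & (summ.group == 4.0)]
        folds.append(float(row["mean_fold"].iloc[0]))
    folds = np.asarray(folds)
    return {"mean_fold": float(folds.mean()), "min": float(folds.min()),
            "max": float(folds.max()), "planted": planted}


def hub_sign_pattern_recovery(n_runs: int = 100, seed: int = 0) -> float:
    """Recovery rate of a planted coupling-sign pattern among five hub genes.

    One gene is positively coupled to two others and negatively to a fourth
    (the fifth responds independently); per run, the Spearman matrix over the
    15 group x replicate fold values must reproduce all planted signs.
    """
    genes = ("H1", "H2", "H3", "H4", "H5")
    groups = (4.0, 5.0, 6.0, 7.0, 8.0)
    hits = 0
    for r in range(n_runs):
        rng = np.random.default_rng(seed + r)
        base = {g: float(2.0 ** rng.uniform(-2.0, 2.0)) for g in groups}
        planted = {
            "H1": {g: base[g] for g in groups},
            "H2": {g: base[g] * 1.1 for g in groups},
            "H3": {g: base[g] * 0.9 for g in groups},
            "H4": {g: 1.0 / base[g] for g in groups},
            "H5": {g: float(2.0 ** rng.uniform(-1.0, 1.0)) for g in groups},
        }
        table, _ = simulate.gen_qpcr(
            genes=genes, planted_fold=planted, ct_noise_sd=0.1, seed=seed + r,
        )
        rel = stress.relative_expression(table)
        mat = stress.hub_correlations(rel)
        rho = mat.rho
        ok = (
            rho.loc["H1", "H2"] > 0
            and rho.loc["H1", "H3"] > 0
            and rho.loc["H1", "H4"] < 0
        )
        hits += bool(ok)
    return hits / n_runs


def sample_clustering_recovery(n_runs: int = 50, seed: int = 0) -> float:
    """Mean agreement of two-group sample clustering with a planted split.

    Fourteen tissue samples form two blocks driven by opposite signs of one
    latent gene program plus noise; agreement is the best label matching
    between recovered and planted groups.
    """
    agree = []
    for r in range(n_runs):
        rng = np.random.default_rng(seed + r)
        n_genes, n_samples = 60, 14
        block = np.array([1] * 7 + [2] * 7)
        program = rng.standard_normal(n_genes)
        vals = np.empty((n_genes, n_samples))
        for s in range(n_samples):
            signn = 1.0 if block[s] == 1 else -1.0
            vals[:, s] = signn * program + 0.8 * rng.standard_normal(n_genes)
        df = pd.DataFrame(
            np.exp(vals), index=[f"g{i}" for i in range(n_genes)],
            columns=[f"t{s:02d}" for s in range(n_samples)],
        )
        labels = expression.cluster_samples(df, k_groups=2).to_numpy()
        match = max(
            (labels == block).mean(), (labels == (3 - block)).mean()
        )
        agree.append(match)
    return float(np.mean(agree))
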