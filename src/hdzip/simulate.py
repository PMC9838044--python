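"""Synthetic fixtures with ground truth for every pipeline stage.

Every generator is deterministic given (seed, parameters) and returns the
dataset together with the planted truth, so downstream analyses can be
checked as generated-data -> truth comparisons.  Default sizes mirror the
study conditions: 117 family transcripts, candidate sets of 114/83/112 with
a single method-exclusive id, 64 genome loci (5 genotype-specific), sample
designs of 4 root ages / 14 tissues / 42 cultivars, 20 bootstrap draws, and
five-pH qPCR assays with 3 replicates.

Expression matrices come from a latent-factor Gaussian model exponentiated
to TPM-like values; Spearman statistics are invariant to the monotone
transform, so planted rank correlations survive exactly.  Expression-breadth
classes are planted as structural zeros, so the default TPM > 0 call
recovers them without error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import molevo
from .expression import DEFAULT_AGES, DESIGN_SIZES, Design, ExpressionMatrix
from .family import CandidateSet, Domain, GenomeAlignment, Method, Subfamily

#: domain content of each subfamily, per the classification rules.
SUBFAMILY_DOMAINS = {
    Subfamily.I: (Domain.HD, Domain.HALZ),
    Subfamily.II: (Domain.HD, Domain.HALZ, Domain.CPSCE),
    Subfamily.III: (Domain.HD, Domain.START, Domain.MEKHLA),
    Subfamily.IV: (Domain.HD, Domain.START),
}

#: domain sets violating both composite family rules (rejected candidates).
REJECTED_DOMAIN_SETS = (
    (Domain.HALZ,),
    (Domain.START,),
    (Domain.HD,),
    (Domain.HALZ, Domain.CPSCE),
    (Domain.START, Domain.MEKHLA),
)

#: default subfamily sizes of the family fixture.
DEFAULT_SUBFAMILY_SIZES = {
    Subfamily.I: 73,
    Subfamily.II: 13,
    Subfamily.III: 11,
    Subfamily.IV: 20,
}

_DOMAIN_SPAN = {
    Domain.HD: (10, 70),
    Domain.HALZ: (75, 110),
    Domain.CPSCE: (115, 125),
    Domain.START: (120, 330),
    Domain.MEKHLA: (340, 450),
    Domain.HDZIP_NTERM: (1, 9),
}


# ---------------------------------------------------------------------------
# domain-hit tables and candidate sets
# ---------------------------------------------------------------------------

def gen_domain_table(
    n_per_subfamily: Mapping | None = None,
    n_rejected: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Domain-hit TSV rows plus per-transcript truth labels.

    Each generated transcript carries exactly the domain set of its assigned
    subfamily; rejected transcripts get a domain set violating both composite
    rules.  Truth maps transcript_id -> subfamily value or "rejected".
    """
    sizes = dict(DEFAULT_SUBFAMILY_SIZES) if n_per_subfamily is None else {
        Subfamily(k): int(v) for k, v in n_per_subfamily.items()
    }
    if any(v < 0 for v in sizes.values()) or n_rejected < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    rows, truth = [], {}
    idx = 0
    for sub in Subfamily:
        for _ in range(sizes.get(sub, 0)):
            idx += 1
            tid = f"T{idx:04d}"
            truth[tid] = sub.value
            for dom in SUBFAMILY_DOMAINS[sub]:
                lo, hi = _DOMAIN_SPAN[dom]
                rows.append(
                    {
                        "transcript_id": tid,
                        "domain": dom.value,
                        "start": lo,
                        "end": hi,
                        "evalue": float(10.0 ** -rng.uniform(6, 40)),
                    }
                )
    for r in range(n_rejected):
        idx += 1
        tid = f"T{idx:04d}"
        truth[tid] = "rejected"
        for dom in REJECTED_DOMAIN_SETS[r % len(REJECTED_DOMAIN_SETS)]:
            lo, hi = _DOMAIN_SPAN[dom]
            rows.append(
                {
                    "transcript_id": tid,
                    "domain": dom.value,
                    "start": lo,
                    "end": hi,
                    "evalue": float(10.0 ** -rng.uniform(6, 40)),
                }
            )
    return pd.DataFrame(rows), truth


def gen_candidate_sets(
    member_ids: Sequence[str] | None = None,
    sizes: tuple[int, int, int] = (114, 83, 112),
    seed: int = 0,
) -> tuple[list[CandidateSet], dict]:
    """Three overlapping candidate sets whose union is the full member list.

    Defaults reproduce the study's search-method cardinalities (114, 83, 112
    over a 117-id union) with exactly one id exclusive to the second method.
    """
    if member_ids is None:
        member_ids = [f"T{i:04d}" for i in range(1, 118)]
    ids = list(member_ids)
    n = len(ids)
    s1, s2, s3 = sizes
    if not (s1 < n and s3 < n and s2 <= n):
        raise ValueError("construction expects set sizes below the union size")
    rng = np.random.default_rng(seed)
    set1 = ids[:s1]
    # set3 covers everything set1 misses except the set2-exclusive last id
    start3 = n - 1 - s3
    set3 = ids[start3 : n - 1]
    exclusive2 = ids[n - 1]
    others = rng.choice(ids[: n - 1], size=s2 - 1, replace=False)
    set2 = [exclusive2, *map(str, others)]
    sets = [
        CandidateSet.of(Method.DOMAIN_TBLASTN, set1),
        CandidateSet.of(Method.KNOWN_GENE_BLAST, set2),
        CandidateSet.of(Method.HMM_SEARCH, set3),
    ]
    truth = {
        "union": set(ids),
        "exclusive_to_known_gene_blast": {exclusive2},
        "sizes": {cs.method.value: len(cs.transcript_ids) for cs in sets},
    }
    return sets, truth


# ---------------------------------------------------------------------------
# genome-alignment tables with planted loci
# ---------------------------------------------------------------------------

def gen_alignment_table(
    n_shared: int = 59,
    n_focal_specific: int = 5,
    focal: str = "Damaya",
    other_genotypes: tuple = ("ChP", "IR826"),
    n_filtered: int = 6,
    seed: int = 0,
) -> tuple[list[GenomeAlignment], dict]:
    """Alignments forming known loci: shared, focal-specific, and filter decoys.

    Defaults plant 64 loci (59 shared by all genotypes + 5 focal-specific),
    the study's locus count, with occasional second focal transcripts so the
    transcript count exceeds the locus count.  Decoy alignments each fail
    exactly one filter (length < 180, identity < 99, or E-value > 1e-6).
    """
    rng = np.random.default_rng(seed)
    alignments: list[GenomeAlignment] = []
    truth_loci = []
    specific_ids = []
    tcount = 0
    n_loci = n_shared + n_focal_specific
    for i in range(n_loci):
        chrom = f"chr{(i % 24) + 1}"
        base = 100_000 + (i // 24) * 1_000_000 + (i % 24) * 50_000
        length = int(rng.integers(900, 2400))
        is_specific = i >= n_shared
        members = {}
        tcount += 1
        focal_id = f"{focal[:1]}T{tcount:04d}"
        focal_ids = [focal_id]
        if not is_specific and rng.random() < 0.5:  # isoform at the same locus
            tcount += 1
            focal_ids.append(f"{focal[:1]}T{tcount:04d}")
        for k, tid in enumerate(focal_ids):
            alignments.append(
                GenomeAlignment(
                    transcript_id=tid,
                    genotype=focal,
                    chromosome=chrom,
                    start=base + 40 * k,
                    end=base + length + 40 * k,
                    aligned_length=max(180, length - 50),
                    identity=float(np.round(rng.uniform(99.0, 100.0), 2)),
                    evalue=float(10.0 ** -rng.uniform(20, 80)),
                )
            )
        members[focal] = set(focal_ids)
        if not is_specific:
            for g in other_genotypes:
                tcount += 1
                tid = f"{g[:1]}T{tcount:04d}"
                alignments.append(
                    GenomeAlignment(
                        transcript_id=tid,
                        genotype=g,
                        chromosome=chrom,
                        start=base + int(rng.integers(0, length // 2)),
                        end=base + length + int(rng.integers(0, 200)),
                        aligned_length=max(180, length - 60),
                        identity=float(np.round(rng.uniform(99.0, 100.0), 2)),
                        evalue=float(10.0 ** -rng.uniform(20, 80)),
                    )
                )
                members[g] = {tid}
        truth_loci.append(
            {"chromosome": chrom, "members": members, "specific": is_specific}
        )
        if is_specific:
            specific_ids.extend(sorted(members[focal]))
    # decoys: one failed filter each, far from any planted locus
    fail_modes = ("length", "identity", "evalue")
    for j in range(n_filtered):
        tcount += 1
        mode = fail_modes[j % 3]
        alignments.append(
            GenomeAlignment(
                transcript_id=f"XT{tcount:04d}",
                genotype=focal,
                chromosome=f"chr{(j % 24) + 1}",
                start=90_000_000 + j * 10_000,
                end=90_000_000 + j * 10_000 + 500,
                aligned_length=150 if mode == "length" else 500,
                identity=98.5 if mode == "identity" else 99.8,
                evalue=1.0e-03 if mode == "evalue" else 1.0e-30,
            )
        )
    truth = {
        "n_loci": n_loci,
        "loci": truth_loci,
        "focal_specific_transcripts": specific_ids,
        "n_filtered_decoys": n_filtered,
    }
    return alignments, truth


# ---------------------------------------------------------------------------
# divergence-controlled CDS pairs
# ---------------------------------------------------------------------------

def _substitution_options(codon: str):
    """Synonymous and nonsynonymous single-nt variants (stops excluded)."""
    aa = molevo.translate_codon(codon)
    syn, nonsyn = [], []
    for pos in range(3):
        for b in molevo.BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut in molevo.STOP_CODONS:
                continue
            (syn if molevo.translate_codon(mut) == aa else nonsyn).append(mut)
    return syn, nonsyn


def gen_cds_pair(
    n_codons: int,
    target_ps: float,
    target_pn: float,
    seed: int = 0,
) -> tuple[str, str, dict]:
    """A CDS pair with controlled synonymous/nonsynonymous divergence.

    The ancestor is drawn uniformly over sense codons; the derived sequence
    applies at most one substitution per codon, with synonymous and
    nonsynonymous changes placed to approximate the target proportions
    (relative to the ancestor's NG86 site counts).  No stop codons are
    introduced.  Truth records the realized difference counts and the NG86
    site counts of the final pair, so ``ps = sd / s_sites`` is exact.
    """
    if n_codons < 50:
        raise ValueError("need at least 50 codons")
    if not (0 <= target_ps < 0.7 and 0 <= target_pn < 0.7):
        raise ValueError("target proportions must lie in [0, 0.7)")
    rng = np.random.default_rng(seed)
    codons = list(rng.choice(molevo.SENSE_CODONS, size=n_codons))
    s_anc = sum(molevo.SYN_SITES[c] for c in codons)
    n_anc = 3.0 * n_codons - s_anc
    need_s = round(target_ps * s_anc)
    need_n = round(target_pn * n_anc)
    order = list(rng.permutation(n_codons))
    derived = list(codons)
    placed_s = placed_n = 0
    for i in order:
        if placed_s >= need_s and placed_n >= need_n:
            break
        syn, nonsyn = _substitution_options(codons[i])
        if placed_s < need_s and syn:
            derived[i] = syn[rng.integers(len(syn))]
            placed_s += 1
        elif placed_n < need_n and nonsyn:
            derived[i] = nonsyn[rng.integers(len(nonsyn))]
            placed_n += 1
    if placed_s < need_s or placed_n < need_n:
        raise ValueError("infeasible divergence targets for this length")
    seq_a, seq_b = "".join(codons), "".join(derived)
    aln = molevo.CodonAlignment(seq_a, seq_b)
    s_sites = sum(
        (molevo.SYN_SITES[a] + molevo.SYN_SITES[b]) / 2.0
        for a, b in aln.codon_pairs()
    )
    n_sites = 3.0 * n_codons - s_sites
    truth = {
        "sd": placed_s,
        "nd": placed_n,
        "s_sites": s_sites,
        "n_sites": n_sites,
        "true_ps": placed_s / s_sites,
        "true_pn": placed_n / n_sites,
        "seed": seed,
    }
    return seq_a, seq_b, truth


# ---------------------------------------------------------------------------
# expression matrices with planted structure
# ---------------------------------------------------------------------------

#: default ages4 breadth classes (k -> gene count) for a 117-gene family;
#: the two-age class is inferred so classes with k >= 1 total 95.
DEFAULT_AGES4_BREADTH = {0: 22, 1: 18, 2: 11, 3: 19, 4: 47}


def _sample_names(design: Design) -> list[str]:
    if design is Design.AGES4:
        return [f"age_{a}" for a in DEFAULT_AGES]
    if design is Design.TISSUES14:
        return [f"tissue_{i:02d}" for i in range(1, 15)]
    return [f"cv{i:02d}" for i in range(1, 43)]


def gen_expression(
    n_family: int = 117,
    n_pool: int = 1000,
    design: Design = Design.CULTIVARS42,
    module_spec: Sequence[Mapping] = (),
    hub_spec: Mapping | None = None,
    breadth_spec: Mapping | None = None,
    pool_expressed_fraction: float = 0.4,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, dict]:
    """TPM matrix of family + background-pool genes with planted structure.

    * ``module_spec``: iterable of ``{"size": g, "loading": l}`` dicts; each
      module's genes share one latent sample factor with loading *l*, so the
      expected pairwise Spearman correlation is about *l* at ``noise_sd=1``
      and exactly 1 at ``noise_sd=0``.
    * ``hub_spec``: ``{"n_partners": k, "loading": l}``; one family gene is
      the latent factor itself and *k* partner genes load on it.
    * ``breadth_spec``: mapping breadth-class k -> number of family genes;
      realized as structural zeros in randomly chosen sample columns.
      Module/hub genes keep full breadth.  Family genes not covered by the
      spec are fully expressed.
    * background pool: mutually independent genes; a
      ``pool_expressed_fraction`` share is expressed, the rest all-zero.
    """
    design = Design(design)
    n_samples = DESIGN_SIZES[design]
    rng = np.random.default_rng(seed)
    family_ids = [f"FAM{i:04d}" for i in range(1, n_family + 1)]
    pool_ids = [f"BG{i:04d}" for i in range(1, n_pool + 1)]

    latent = rng.standard_normal((n_family + n_pool, n_samples)) * max(noise_sd, 0.0)
    if noise_sd == 0:
        latent = np.zeros_like(latent)

    truth: dict = {
        "seed": seed,
        "design": design.value,
        "family_ids": family_ids,
        "pool_ids": pool_ids,
        "module_membership": {},
        "hub_ids": [],
        "hub_partners": {},
        "breadth_class": {},
    }

    structured: list[int] = []
    cursor = 0
    for mi, spec in enumerate(module_spec):
        size, loading = int(spec["size"]), float(spec["loading"])
        if not 0 <= loading <= 1:
            raise ValueError("module loading must be in [0, 1]")
        idx = list(range(cursor, cursor + size))
        if idx and idx[-1] >= n_family:
            raise ValueError("module spec exceeds family size")
        factor = rng.standard_normal(n_samples)
        for i in idx:
            eps = rng.standard_normal(n_samples)
            latent[i] = loading * factor + noise_sd * math.sqrt(1 - loading**2) * eps
        truth["module_membership"][f"M{mi + 1:02d}"] = [family_ids[i] for i in idx]
        structured.extend(idx)
        cursor += size

    if hub_spec:
        k = int(hub_spec["n_partners"])
        loading = float(hub_spec.get("loading", 0.8))
        idx = list(range(cursor, cursor + 1 + k))
        if idx[-1] >= n_family:
            raise ValueError("hub spec exceeds family size")
        factor = rng.standard_normal(n_samples)
        latent[idx[0]] = factor
        for i in idx[1:]:
            eps = rng.standard_normal(n_samples)
            latent[i] = loading * factor + noise_sd * math.sqrt(1 - loading**2) * eps
        truth["hub_ids"] = [family_ids[idx[0]]]
        truth["hub_partners"][family_ids[idx[0]]] = [family_ids[i] for i in idx[1:]]
        structured.extend(idx)
        cursor += 1 + k

    tpm = np.exp(1.5 + latent)  # monotone map to positive TPM-like values

    # breadth classes via structural zeros on unstructured family genes
    free = [i for i in range(n_family) if i not in set(structured)]
    if breadth_spec:
        needed = sum(int(v) for k, v in breadth_spec.items() if int(k) < n_samples)
        if needed > len(free):
            raise ValueError("breadth spec exceeds unstructured family genes")
        free_iter = iter(free)
        for k_class, count in sorted(breadth_spec.items()):
            k_class = int(k_class)
            if not 0 <= k_class <= n_samples:
                raise ValueError("breadth class outside sample range")
            for _ in range(int(count)):
                if k_class == n_samples:
                    continue  # fully expressed: nothing to zero
                i = next(free_iter)
                off = rng.choice(n_samples, size=n_samples - k_class, replace=False)
                tpm[i, off] = 0.0
                truth["breadth_class"][family_ids[i]] = k_class
    for i in range(n_family):
        truth["breadth_class"].setdefault(family_ids[i], n_samples)

    # background pool: expressed subset, remainder all-zero
    n_expressed = int(round(pool_expressed_fraction * n_pool))
    silent = rng.choice(n_pool, size=n_pool - n_expressed, replace=False)
    tpm[n_family + silent] = 0.0
    truth["expressed_pool_ids"] = sorted(
        pool_ids[i] for i in range(n_pool) if i not in set(silent)
    )

    df = pd.DataFrame(tpm, index=family_ids + pool_ids,
                      columns=_sample_names(design))
    return ExpressionMatrix(df, design=design), truth


# ---------------------------------------------------------------------------
# qPCR Ct tables with planted fold changes
# ---------------------------------------------------------------------------

def gen_qpcr(
    genes: Sequence[str] = ("G1", "G2", "G3", "G4", "G5"),
    groups: Sequence[float] = (4.0, 5.0, 6.0, 7.0, 8.0),
    planted_fold: Mapping | None = None,
    ct_noise_sd: float = 0.1,
    n_replicates: int = 3,
    control_group: float = 6.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Replicate Ct table with planted 2^-ddCt fold changes.

    ``planted_fold[gene][group]`` is the true fold relative to the control
    group (default 1 everywhere; the control group's fold is forced to 1).
    Per replicate: ``ct_reference ~ 15`` and
    ``ct_target = ct_reference + dct_base - log2(fold) + noise``.
    """
    if control_group not in groups:
        raise ValueError("control group must be among the groups")
    planted_fold = planted_fold or {}
    rng = np.random.default_rng(seed)
    rows = []
    truth: dict = {"planted_fold": {}, "seed": seed}
    for gene in genes:
        dct_base = 5.0 + rng.uniform(-1, 1)
        gene_truth = {}
        for grp in groups:
            fold = float(planted_fold.get(gene, {}).get(grp, 1.0))
            if grp == control_group:
                fold = 1.0
            if fold <= 0:
                raise ValueError("planted folds must be positive")
            gene_truth[grp] = fold
            for rep in range(1, n_replicates + 1):
                ct_ref = 15.0 + rng.normal(0.0, ct_noise_sd)
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rows.append(
                    {
                        "group": grp,
                        "replicate": rep,
                        "gene_id": gene,
                        "ct_target": ct_ref + dct_base - math.log2(fold) + noise,
                        "ct_reference": ct_ref,
                    }
                )
        truth["planted_fold"][gene] = gene_truth
    return pd.DataFrame(rows), truth


def gen_fresh_weight(
    groups: Sequence[float] = (4.0, 5.0, 6.0, 7.0, 8.0),
    effects: Mapping | None = None,
    base_grams: float = 2.0,
    noise_sd: float = 0.05,
    n_replicates: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Per-flask fresh weights with additive per-group effects (grams)."""
    effects = effects or {}
    rng = np.random.default_rng(seed)
    rows = []
    for grp in groups:
        mu = base_grams + float(effects.get(grp, 0.0))
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "group": grp,
                    "replicate": rep,
                    "grams": mu + rng.normal(0.0, noise_sd),
                }
            )
    truth = {"effects": {g: float(effects.get(g, 0.0)) for g in groups},
             "base_grams": base_grams, "seed": seed}
    return pd.DataFrame(rows), truth
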