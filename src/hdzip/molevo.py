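"""Ka/Ks estimation (Nei-Gojobori 1986 counting) and molecular-clock dating.

The NG86 method counts, for every codon, the expected fraction of synonymous
single-nucleotide mutation fates under the standard genetic code (averaged
between the two sequences of an alignment), partitions observed codon
differences into synonymous/nonsynonymous counts by equal-weight averaging
over substitution pathways (pathways passing through stop codons are
excluded), and applies the Jukes-Cantor correction
``d = -(3/4) * ln(1 - (4/3) * p)`` to the raw proportions.

Mutations to stop codons count as nonsynonymous, with per-codon
normalization to exactly 3 sites, so ``N_sites + S_sites == 3 * codons``
holds exactly.

Divergence dates follow the synonymous molecular clock ``T = Ks / (2 * lambda)``
with a default rate of 6.5e-9 substitutions per synonymous site per year.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, permutations
from typing import Iterable, Sequence

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

BASES = ("A", "C", "G", "T")
STOP_CODONS = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS = tuple(sorted(standard_dna_table.forward_table))


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon, ``*`` for a stop codon."""
    if codon in STOP_CODONS:
        return "*"
    return standard_dna_table.forward_table[codon]


def _syn_site_fractions() -> dict:
    """Per-codon synonymous site count (0..3), stops counted as nonsynonymous."""
    table = {}
    for codon in SENSE_CODONS:
        aa = translate_codon(codon)
        s = 0.0
        for pos in range(3):
            for b in BASES:
                if b == codon[pos]:
                    continue
                mutant = codon[:pos] + b + codon[pos + 1 :]
                if mutant not in STOP_CODONS and translate_codon(mutant) == aa:
                    s += 1.0 / 3.0
        table[codon] = s
    return table


#: codon -> synonymous sites (the nonsynonymous complement is 3 - s).
SYN_SITES = _syn_site_fractions()


@dataclass(frozen=True)
class ClockParams:
    """Synonymous molecular clock: substitutions per synonymous site per year."""

    lam: float = 6.5e-09

    def __post_init__(self):
        if self.lam <= 0:
            raise ValueError("clock rate lambda must be positive")


@dataclass
class CodonAlignment:
    """A gap-free pairwise codon alignment over {A,C,G,T}."""

    seq_a: str
    seq_b: str

    def __post_init__(self):
        a, b = self.seq_a.upper(), self.seq_b.upper()
        if len(a) != len(b):
            raise ValueError("aligned sequences must have equal length")
        if len(a) % 3 != 0:
            raise ValueError("alignment length must be divisible by 3")
        for seq, name in ((a, "seq_a"), (b, "seq_b")):
            if set(seq) - set(BASES):
                raise ValueError(f"{name} contains non-ACGT characters")
            for i in range(0, len(seq), 3):
                if seq[i : i + 3] in STOP_CODONS:
                    raise ValueError(f"internal stop codon in {name} at {i}")
        self.seq_a, self.seq_b = a, b

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_pairs(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass
class KaKsResult:
    ka: float
    ks: float
    omega: float  # NaN when Ks == 0 (undefined)
    n_sites: float
    s_sites: float
    nd: float
    sd: float
    t_mya: float  # divergence date from the synonymous clock, NaN if Ks saturated
    saturated_n: bool = False
    saturated_s: bool = False

    @property
    def omega_defined(self) -> bool:
        return not math.isnan(self.omega)


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction; NaN when p >= 3/4 (saturated)."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p) + 0.0


def _pathway_counts(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts for one codon pair.

    Codons differing at k positions are connected by k! substitution
    orderings; each valid pathway (no stop-codon intermediate) contributes
    equally.  If every pathway passes through a stop codon, all pathways are
    used as a fallback so the differences are still counted.
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = codon_a
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon_b:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((blocked, steps))
    valid = [steps for blocked, steps in paths if not blocked]
    if not valid:
        valid = [steps for _, steps in paths]
    sd = nd = 0.0
    w = 1.0 / len(valid)
    for steps in valid:
        for cur, nxt in steps:
            if translate_codon(cur) == translate_codon(nxt):
                sd += w
            else:
                nd += w
    return sd, nd


def compute_ka_ks(aln: CodonAlignment, clock: ClockParams | None = None) -> KaKsResult:
    """NG86 Ka/Ks for a pairwise codon alignment.

    Site counts are averaged between the two sequences; the result is
    symmetric under swapping ``seq_a``/``seq_b``.  ``omega`` is NaN when
    Ks == 0 and the ``saturated_*`` flags mark proportions >= 3/4 where the
    Jukes-Cantor correction is undefined.
    """
    clock = clock or ClockParams()
    s_sites = sd = nd = 0.0
    for ca, cb in aln.codon_pairs():
        s_sites += (SYN_SITES[ca] + SYN_SITES[cb]) / 2.0
        dsd, dnd = _pathway_counts(ca, cb)
        sd += dsd
        nd += dnd
    n_sites = 3.0 * aln.n_codons - s_sites

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    saturated_s = math.isnan(ks)
    saturated_n = math.isnan(ka)
    omega = kaks_ratio(ka, ks)
    t = math.nan if saturated_s else divergence_time(ks, clock)
    return KaKsResult(
        ka=ka,
        ks=ks,
        omega=omega,
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        t_mya=t,
        saturated_n=saturated_n,
        saturated_s=saturated_s,
    )


def kaks_ratio(ka: float, ks: float) -> float:
    """omega = Ka/Ks; NaN (undefined) when Ks == 0 or either input is NaN."""
    if math.isnan(ka) or math.isnan(ks) or ks == 0:
        return math.nan
    return ka / ks


def divergence_time(ks: float, clock: ClockParams | None = None) -> float:
    """Divergence date in million years: T = Ks / (2 * lambda) * 1e-6."""
    clock = clock or ClockParams()
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    return ks / (2.0 * clock.lam) * 1.0e-06


# ---------------------------------------------------------------------------
# codon-aware pairwise alignment and duplicate-pair selection
# ---------------------------------------------------------------------------

_GAP_PENALTY = -2.0  # per codon-gap, on the 0..3 nucleotide-match scale


def _codons(seq: str, name: str) -> list[str]:
    seq = seq.upper().replace("U", "T")
    rem = len(seq) % 3
    if rem:
        warnings.warn(f"{name}: trailing {rem} nt trimmed to codon boundary",
                      stacklevel=3)
        seq = seq[: len(seq) - rem]
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def _codon_score(a: str, b: str) -> float:
    return float(sum(x == y for x, y in zip(a, b)))


def align_codon_pair(seq_a: str, seq_b: str) -> CodonAlignment:
    """Global codon-granularity alignment (Needleman-Wunsch on codon units).

    Scoring: +1 per matching nucleotide within a codon pair (0..3), -2 per
    codon indel.  Gap columns are removed from the returned alignment, as are
    codon columns where either sequence carries a stop codon.
    """
    ca = _codons(seq_a, "seq_a")
    cb = _codons(seq_b, "seq_b")
    n, m = len(ca), len(cb)
    if n == 0 or m == 0:
        raise ValueError("sequence shorter than one codon")
    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    move = [[0] * (m + 1) for _ in range(n + 1)]  # 1 diag, 2 up(gap b), 3 left(gap a)
    for i in range(1, n + 1):
        score[i][0] = i * _GAP_PENALTY
        move[i][0] = 2
    for j in range(1, m + 1):
        score[0][j] = j * _GAP_PENALTY
        move[0][j] = 3
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = score[i - 1][j - 1] + _codon_score(ca[i - 1], cb[j - 1])
            up = score[i - 1][j] + _GAP_PENALTY
            left = score[i][j - 1] + _GAP_PENALTY
            best = max(diag, up, left)
            score[i][j] = best
            move[i][j] = 1 if best == diag else (2 if best == up else 3)
    i, j = n, m
    cols: list[tuple[str, str]] = []
    while i > 0 or j > 0:
        mv = move[i][j]
        if mv == 1:
            cols.append((ca[i - 1], cb[j - 1]))
            i, j = i - 1, j - 1
        elif mv == 2:
            i -= 1  # codon deleted in b: gap column, dropped
        else:
            j -= 1
    cols.reverse()
    kept = [
        (x, y)
        for x, y in cols
        if x not in STOP_CODONS and y not in STOP_CODONS
    ]
    if not kept:
        raise ValueError("no alignable non-stop codon columns")
    return CodonAlignment("".join(x for x, _ in kept), "".join(y for _, y in kept))


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent nucleotide identity over the ungapped codon alignment columns."""
    aln = align_codon_pair(seq_a, seq_b)
    matches = sum(x == y for x, y in zip(aln.seq_a, aln.seq_b))
    return 100.0 * matches / len(aln.seq_a)


def select_duplicate_pairs(
    records: Iterable, top: int | None = None
) -> list[tuple[str, str, float]]:
    """Rank all sequence pairs by percent identity (candidate duplicates).

    ``records`` may be Bio.SeqRecord objects or ``(id, sequence)`` tuples.
    Self-pairs are excluded; sequences shorter than one codon are skipped with
    a warning.  Returns ``(id_a, id_b, identity)`` sorted by identity
    descending, ties broken lexicographically, optionally truncated to the
    *top* pairs.
    """
    seqs: dict[str, str] = {}
    for rec in records:
        if hasattr(rec, "id"):
            name, seq = rec.id, str(rec.seq)
        else:
            name, seq = rec
        if len(seq) < 3:
            warnings.warn(f"{name}: shorter than one codon; skipped", stacklevel=2)
            continue
        seqs[str(name)] = str(seq)
    if len(seqs) < 2:
        raise ValueError("need at least two usable sequences")
    ranked = []
    for a, b in combinations(sorted(seqs), 2):
        ranked.append((a, b, pairwise_identity(seqs[a], seqs[b])))
    ranked.sort(key=lambda t: (-t[2], t[0], t[1]))
    return ranked[:top] if top is not None else ranked


def kaks_table(
    pairs: Sequence[tuple[str, str, str, str]],
    clock: ClockParams | None = None,
) -> pd.DataFrame:
    """Ka/Ks summary table for named CDS pairs.

    ``pairs`` holds ``(name_a, name_b, cds_a, cds_b)``; unaligned sequences
    are run through the codon-aware global alignment first.  Columns mirror a
    duplication/divergence report: pair, Ka, Ks, Ka/Ks, Date_MYA.
    """
    rows = []
    for name_a, name_b, cds_a, cds_b in pairs:
        aln = align_codon_pair(cds_a, cds_b)
        res = compute_ka_ks(aln, clock=clock)
        rows.append(
            {
                "pair": f"{name_a}/{name_b}",
                "Ka": res.ka,
                "Ks": res.ks,
                "Ka/Ks": res.omega,
                "Date_MYA": res.t_mya,
            }
        )
    return pd.DataFrame(rows)
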