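"""Gene-family identification from domain evidence.

HD-Zip transcription factors are defined by co-occurrence of a homeodomain
(HD) with either a leucine-zipper (HALZ) or a START lipid-transfer domain.
The four canonical subfamilies are distinguished by two additional C-terminal
motifs: CPSCE (subfamily II) and MEKHLA (subfamily III).  This module turns
tabular domain-hit evidence into family membership calls, merges candidate
transcript sets produced by independent search strategies, places transcripts
onto genome loci from BLAST-style alignment tables, detects genotype-specific
loci, and summarizes GO categorization per subfamily.
"""

from __future__ import annotations

import json
import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd


class Domain(str, Enum):
    """Conserved domains/motifs used for family and subfamily diagnosis."""

    HD = "HD"
    HALZ = "HALZ"
    START = "START"
    MEKHLA = "MEKHLA"
    CPSCE = "CPSCE"
    HDZIP_NTERM = "HDZIP_NTERM"


class Method(str, Enum):
    """Independent candidate-search strategies whose outputs are merged."""

    DOMAIN_TBLASTN = "domain_tblastn"
    KNOWN_GENE_BLAST = "known_gene_blast"
    HMM_SEARCH = "hmm_search"


class Subfamily(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


#: GO primary categories, in canonical order.
GO_CATEGORIES = ("BP", "MF", "CC")


class SubfamilyRejection(ValueError):
    """Raised when a domain set fails both composite family rules."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class DomainHit:
    """A single domain match on a translated transcript (1-based inclusive)."""

    transcript_id: str
    domain: Domain
    start: int
    end: int
    evalue: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start > end for {self.transcript_id}")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


@dataclass(frozen=True)
class CandidateSet:
    method: Method
    transcript_ids: frozenset

    @classmethod
    def of(cls, method, ids: Iterable[str]) -> "CandidateSet":
        return cls(Method(method), frozenset(ids))


@dataclass
class FamilyMember:
    transcript_id: str
    domains: frozenset
    subfamily: Subfamily
    source_methods: frozenset = frozenset()


@dataclass(frozen=True)
class GenomeAlignment:
    """One BLASTn alignment of a transcript to the reference chromosomes."""

    transcript_id: str
    genotype: str
    chromosome: str
    start: int
    end: int
    aligned_length: int
    identity: float
    evalue: float

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("start > end")
        if not 0 <= self.identity <= 100:
            raise ValueError("identity must be a percentage in [0, 100]")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


@dataclass
class Locus:
    locus_id: str
    chromosome: str
    start: int
    end: int
    members: dict  # genotype -> set of transcript_ids

    @property
    def genotypes(self):
        return {g for g, ids in self.members.items() if ids}

    @property
    def n_transcripts(self):
        return sum(len(ids) for ids in self.members.values())


@dataclass(frozen=True)
class GoAnnotation:
    transcript_id: str
    categories: frozenset  # subset of GO_CATEGORIES
    level2_terms: frozenset = frozenset()

    def __post_init__(self):
        if not self.categories:
            raise ValueError("annotated transcript must have >=1 category")
        unknown = set(self.categories) - set(GO_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown GO categories: {unknown}")


# ---------------------------------------------------------------------------
# subfamily classification
# ---------------------------------------------------------------------------

def classify_or_reject(domains: Iterable) -> tuple:
    """Classify a domain set, returning ``(Subfamily, None)`` or ``(None, reason)``.

    Rules (checked in order, so motif-bearing subfamilies II/III take
    precedence over their plain supersets I/IV):

    * HD + START + MEKHLA -> III
    * HD + START          -> IV
    * HD + HALZ + CPSCE   -> II
    * HD + HALZ           -> I

    Anything else is rejected with a stated reason.
    """
    ds = {Domain(d) for d in domains}
    if Domain.HD not in ds:
        return None, "no HD"
    if Domain.START in ds:
        if Domain.MEKHLA in ds:
            return Subfamily.III, None
        return Subfamily.IV, None
    if Domain.HALZ in ds:
        if Domain.CPSCE in ds:
            return Subfamily.II, None
        return Subfamily.I, None
    return None, "HD without HALZ or START"


def classify_subfamily(domains: Iterable) -> Subfamily:
    """Classify a domain set into subfamily I-IV or raise :class:`SubfamilyRejection`."""
    sub, reason = classify_or_reject(domains)
    if sub is None:
        raise SubfamilyRejection(reason)
    return sub


def identify_family(
    hits: Iterable[DomainHit],
    provenance: Mapping[str, Iterable] | None = None,
) -> tuple[list[FamilyMember], list[tuple[str, str]]]:
    """Call family members from per-transcript domain evidence.

    Returns ``(members, rejected)`` where *rejected* lists
    ``(transcript_id, reason)`` for candidates failing the composite rules,
    mirroring deleted candidates in a screening pipeline.
    """
    domains_by_id: dict[str, set] = defaultdict(set)
    for h in hits:
        domains_by_id[h.transcript_id].add(Domain(h.domain))
    provenance = provenance or {}
    members, rejected = [], []
    for tid in sorted(domains_by_id):
        sub, reason = classify_or_reject(domains_by_id[tid])
        if sub is None:
            rejected.append((tid, reason))
        else:
            methods = frozenset(Method(m) for m in provenance.get(tid, ()))
            members.append(
                FamilyMember(tid, frozenset(domains_by_id[tid]), sub, methods)
            )
    return members, rejected


# ---------------------------------------------------------------------------
# candidate-set merging
# ---------------------------------------------------------------------------

def merge_candidate_sets(sets: Sequence[CandidateSet]) -> dict[str, set]:
    """Union candidate sets, recording which methods found each transcript.

    Returns a mapping transcript_id -> set of :class:`Method`.  The union of
    the keys is exactly the union of the input sets.
    """
    if len(sets) == 0:
        raise ValueError("need at least one candidate set")
    provenance: dict[str, set] = defaultdict(set)
    for cs in sets:
        for tid in cs.transcript_ids:
            provenance[tid].add(Method(cs.method))
    return dict(provenance)


def method_exclusive(provenance: Mapping[str, set], method) -> set:
    """Transcripts found by *method* and by no other method."""
    m = Method(method)
    return {tid for tid, ms in provenance.items() if ms == {m}}


# ---------------------------------------------------------------------------
# locus assignment
# ---------------------------------------------------------------------------

def _chrom_key(chromosome: str) -> int:
    label = str(chromosome)
    if label.lower().startswith("chr"):
        label = label[3:]
    try:
        num = int(label)
    except ValueError:
        raise ValueError(f"unknown chromosome label: {chromosome!r}") from None
    if not 1 <= num <= 24:
        raise ValueError(f"unknown chromosome label: {chromosome!r}")
    return num


def assign_loci(
    alignments: Iterable[GenomeAlignment],
    min_len: int = 180,
    min_identity: float = 99.0,
    max_evalue: float = 1.0e-06,
) -> list[Locus]:
    """Collapse filtered alignments into genome loci.

    Alignments failing any of the three filters (aligned length, percent
    identity, E-value) are discarded.  Each surviving transcript is placed at
    its single best alignment (lowest E-value, ties broken by highest
    identity, then leftmost start).  Best alignments on the same chromosome
    whose intervals overlap by >=1 bp are merged transitively into one locus.
    Locus ids are assigned in (chromosome, start) order.
    """
    surviving = [
        a
        for a in alignments
        if a.aligned_length >= min_len
        and a.identity >= min_identity
        and a.evalue <= max_evalue
    ]
    for a in surviving:
        _chrom_key(a.chromosome)  # validate labels up front

    best: dict[str, GenomeAlignment] = {}
    for a in surviving:
        cur = best.get(a.transcript_id)
        key = (a.evalue, -a.identity, _chrom_key(a.chromosome), a.start)
        if cur is None or key < (
            cur.evalue,
            -cur.identity,
            _chrom_key(cur.chromosome),
            cur.start,
        ):
            best[a.transcript_id] = a

    by_chrom: dict[int, list[GenomeAlignment]] = defaultdict(list)
    for a in best.values():
        by_chrom[_chrom_key(a.chromosome)].append(a)

    loci: list[Locus] = []
    for cnum in sorted(by_chrom):
        alns = sorted(by_chrom[cnum], key=lambda a: (a.start, a.end, a.transcript_id))
        cluster: list[GenomeAlignment] = []
        cluster_end = None
        for a in alns:
            if cluster and a.start <= cluster_end:
                cluster.append(a)
                cluster_end = max(cluster_end, a.end)
            else:
                if cluster:
                    loci.append(_make_locus(cluster))
                cluster = [a]
                cluster_end = a.end
        if cluster:
            loci.append(_make_locus(cluster))

    for i, locus in enumerate(loci, start=1):
        locus.locus_id = f"L{i:03d}"
    return loci


def _make_locus(cluster: list[GenomeAlignment]) -> Locus:
    members: dict[str, set] = defaultdict(set)
    for a in cluster:
        members[str(a.genotype)].add(a.transcript_id)
    return Locus(
        locus_id="",
        chromosome=cluster[0].chromosome,
        start=min(a.start for a in cluster),
        end=max(a.end for a in cluster),
        members=dict(members),
    )


def find_genotype_specific(loci: Sequence[Locus], focal: str) -> list[Locus]:
    """Loci whose members come from the focal genotype and no other."""
    seen = set()
    for locus in loci:
        seen |= locus.genotypes
    if focal not in seen:
        raise ValueError(f"focal genotype {focal!r} absent from loci")
    return [locus for locus in loci if locus.genotypes == {focal}]


# ---------------------------------------------------------------------------
# GO summarization
# ---------------------------------------------------------------------------

def _venn_cell(categories: Iterable[str]) -> str:
    return "&".join(c for c in GO_CATEGORIES if c in set(categories))


VENN_CELLS = (
    "BP",
    "MF",
    "CC",
    "BP&MF",
    "BP&CC",
    "MF&CC",
    "BP&MF&CC",
)


@dataclass
class GoSummary:
    n_annotated: int
    venn: dict  # cell label -> count (disjoint partition of annotated members)
    venn_by_subfamily: dict  # subfamily -> cell label -> count
    category_counts_by_subfamily: dict  # subfamily -> category -> count


def summarize_go(
    annotations: Iterable[GoAnnotation], members: Sequence[FamilyMember]
) -> GoSummary:
    """Per-subfamily GO category counts and the 7-cell Venn partition.

    Each annotated member falls in exactly one Venn cell (its exact category
    combination), so cells are disjoint and sum to the number of annotated
    members.  Annotations for transcripts that are not family members are
    skipped with a warning.
    """
    sub_by_id = {m.transcript_id: m.subfamily for m in members}
    venn = {c: 0 for c in VENN_CELLS}
    venn_by_sub = {s: {c: 0 for c in VENN_CELLS} for s in Subfamily}
    cat_by_sub = {s: {c: 0 for c in GO_CATEGORIES} for s in Subfamily}
    n_annotated = 0
    seen = set()
    for ann in annotations:
        if ann.transcript_id not in sub_by_id:
            warnings.warn(
                f"GO annotation for unknown member {ann.transcript_id!r}; skipped",
                stacklevel=2,
            )
            continue
        if ann.transcript_id in seen:
            warnings.warn(
                f"duplicate GO annotation for {ann.transcript_id!r}; skipped",
                stacklevel=2,
            )
            continue
        seen.add(ann.transcript_id)
        n_annotated += 1
        cell = _venn_cell(ann.categories)
        sub = sub_by_id[ann.transcript_id]
        venn[cell] += 1
        venn_by_sub[sub][cell] += 1
        for cat in ann.categories:
            cat_by_sub[sub][cat] += 1
    return GoSummary(
        n_annotated=n_annotated,
        venn=venn,
        venn_by_subfamily={s.value: d for s, d in venn_by_sub.items()},
        category_counts_by_subfamily={s.value: d for s, d in cat_by_sub.items()},
    )


# ---------------------------------------------------------------------------
# tabular IO
# ---------------------------------------------------------------------------

def read_domain_hits(path) -> list[DomainHit]:
    """Read a domain-hit TSV with columns transcript_id, domain, start, end, evalue."""
    df = pd.read_csv(path, sep="\t")
    return [
        DomainHit(
            str(r.transcript_id), Domain(r.domain), int(r.start), int(r.end),
            float(r.evalue),
        )
        for r in df.itertuples(index=False)
    ]


#: BLAST outfmt-6 column names, plus a trailing genotype column.
OUTFMT6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore genotype"
).split()


def read_alignments(path) -> list[GenomeAlignment]:
    """Read a BLAST outfmt-6-like TSV (with genotype column) into alignments.

    The subject (chromosome) coordinates are normalized so start <= end;
    strand is ignored for locus identity.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(OUTFMT6_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"alignment table missing columns: {sorted(missing)}")
    out = []
    for r in df.itertuples(index=False):
        s, e = int(r.sstart), int(r.send)
        out.append(
            GenomeAlignment(
                transcript_id=str(r.qseqid),
                genotype=str(r.genotype),
                chromosome=str(r.sseqid),
                start=min(s, e),
                end=max(s, e),
                aligned_length=int(r.length),
                identity=float(r.pident),
                evalue=float(r.evalue),
            )
        )
    return out


def read_go_annotations(path) -> list[GoAnnotation]:
    """Read GO TSV (transcript_id, category, level2_term), one row per term."""
    df = pd.read_csv(path, sep="\t")
    cats = defaultdict(set)
    terms = defaultdict(set)
    for r in df.itertuples(index=False):
        cats[str(r.transcript_id)].add(str(r.category))
        terms[str(r.transcript_id)].add(str(r.level2_term))
    return [
        GoAnnotation(tid, frozenset(cats[tid]), frozenset(terms[tid]))
        for tid in sorted(cats)
    ]


def members_to_frame(members: Sequence[FamilyMember]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transcript_id": [m.transcript_id for m in members],
            "subfamily": [m.subfamily.value for m in members],
            "domains": [
                ",".join(sorted(d.value for d in m.domains)) for m in members
            ],
            "methods": [
                ",".join(sorted(x.value for x in m.source_methods)) for m in members
            ],
        }
    )


def loci_to_frame(loci: Sequence[Locus]) -> pd.DataFrame:
    rows = []
    for locus in loci:
        for genotype, ids in sorted(locus.members.items()):
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "chromosome": locus.chromosome,
                    "start": locus.start,
                    "end": locus.end,
                    "genotype": genotype,
                    "transcripts": ",".join(sorted(ids)),
                }
            )
    return pd.DataFrame(rows)


def write_summary_json(path, members, rejected, loci, go_summary: GoSummary | None):
    counts = defaultdict(int)
    for m in members:
        counts[m.subfamily.value] += 1
    payload = {
        "n_members": len(members),
        "subfamily_counts": dict(sorted(counts.items())),
        "n_rejected": len(rejected),
        "rejected": [{"transcript_id": t, "reason": r} for t, r in rejected],
        "n_loci": len(loci),
    }
    if go_summary is not None:
        payload["go"] = {
            "n_annotated": go_summary.n_annotated,
            "venn": go_summary.venn,
            "venn_by_subfamily": go_summary.venn_by_subfamily,
        }
    Path(path).write_text(json.dumps(payload, indent=2))
    return payload
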